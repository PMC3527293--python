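import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circastat import (
    SimulationConfig,
    TimeSeriesMatrix,
    call_circadian,
    ct_label_sequence,
    g_factor,
    permutation_curve,
    phase_table,
    score_matrix,
    simulate_expression,
)

from conftest import cosine_profile, oracle_g_factor


# ---------------------------------------------------------------------------
# g_factor
# ---------------------------------------------------------------------------


def test_pure_cosine_scores_one_with_correct_phase(ct_grid_48h):
    x = cosine_profile(ct_grid_48h, phase=6.0)
    s = g_factor(x, ct_grid_48h)
    assert s.g_factor == pytest.approx(1.0, abs=1e-12)
    assert s.phase_ct == pytest.approx(6.0, abs=1e-9)
    assert s.relative_amplitude == pytest.approx(1.5, abs=1e-9)


def test_constant_vector_scores_zero(ct_grid_48h):
    s = g_factor(np.full(12, 7.3), ct_grid_48h)
    assert s.g_factor == 0.0
    assert np.isnan(s.phase_ct)
    assert s.relative_amplitude == 0.0


def test_off_period_cosine_has_no_24h_power(ct_grid_48h):
    # a 16-h-period cosine is orthogonal to the 24-h mode on this grid
    x = 5 + np.cos(2 * np.pi * ct_grid_48h / 16.0)
    s = g_factor(x, ct_grid_48h)
    assert s.g_factor < 1e-10


def test_matches_direct_dft_oracle(ct_grid_48h, oracle_g):
    rng = np.random.default_rng(42)
    for _ in range(200):
        x = rng.normal(size=12)
        expected, _ = oracle_g(x, ct_grid_48h)
        assert g_factor(x, ct_grid_48h).g_factor == pytest.approx(expected, abs=1e-10)


def test_phase_matches_oracle_coefficient(ct_grid_48h, oracle_g):
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    _, coef = oracle_g(x, ct_grid_48h)
    expected_phase = (ct_grid_48h[0] - np.angle(coef) * 24 / (2 * np.pi)) % 24
    assert g_factor(x, ct_grid_48h).phase_ct == pytest.approx(expected_phase, abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(a=st.floats(-100, 100).filter(lambda v: abs(v) > 1e-3),
       b=st.floats(-100, 100),
       seed=st.integers(0, 1000))
def test_scale_and_offset_invariance(a, b, seed):
    grid = 14.0 + 4.0 * np.arange(12)
    x = np.random.default_rng(seed).normal(size=12)
    g0 = g_factor(x, grid).g_factor
    g1 = g_factor(a * x + b, grid).g_factor
    assert g1 == pytest.approx(g0, abs=1e-9)


@pytest.mark.parametrize("times,period,match", [
    (np.array([0, 4, 8, 16]), 24.0, "uniform"),          # non-uniform sampling
    (14 + 4 * np.arange(12), 18.0, "frequency grid"),    # period off the grid
    (np.arange(3) * 8.0, 24.0, "4 samples"),             # too short
])
def test_g_factor_input_errors(times, period, match):
    with pytest.raises(ValueError, match=match):
        g_factor(np.arange(len(times), dtype=float), times, period)


def test_harmonic_variant_adds_harmonic_power(ct_grid_48h):
    # 24 h + 12 h harmonic: harmonic variant captures both in the numerator
    x = np.cos(2 * np.pi * ct_grid_48h / 24) + 0.5 * np.cos(2 * np.pi * ct_grid_48h / 12)
    plain = g_factor(x, ct_grid_48h).g_factor
    harm = g_factor(x, ct_grid_48h, include_harmonics=True).g_factor
    assert plain < 1.0
    assert harm == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# score_matrix
# ---------------------------------------------------------------------------


def _matrix(values, start_ct=14, interval=4):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, k = values.shape
    return TimeSeriesMatrix([f"t{i}" for i in range(n)],
                            ct_label_sequence(start_ct, interval, k), values, scale="log")


def test_score_matrix_preserves_order_and_ids(ct_grid_48h):
    rng = np.random.default_rng(0)
    m = _matrix(rng.normal(size=(3, 12)))
    scores = score_matrix(m)
    assert [s.transcript_id for s in scores] == ["t0", "t1", "t2"]


def test_score_matrix_empty_and_duplicate_rows(ct_grid_48h):
    assert score_matrix(_matrix(np.empty((0, 12)))) == []
    row = np.random.default_rng(1).normal(size=12)
    scores = score_matrix(_matrix(np.vstack([row, row])))
    assert scores[0].g_factor == scores[1].g_factor


# ---------------------------------------------------------------------------
# permutation curve and calling
# ---------------------------------------------------------------------------


def test_permutation_curve_deterministic_under_seed():
    m, _ = simulate_expression(SimulationConfig(n_transcripts=100, seed=5))
    c1 = permutation_curve(m, n_permutations=20, seed=11)
    c2 = permutation_curve(m, n_permutations=20, seed=11)
    np.testing.assert_array_equal(c1.random_mean, c2.random_mean)
    np.testing.assert_array_equal(c1.detection, c2.detection)


def test_permutation_curve_requires_seed_and_enough_permutations():
    m, _ = simulate_expression(SimulationConfig(n_transcripts=10, seed=5))
    with pytest.raises(ValueError, match="seed"):
        permutation_curve(m, n_permutations=10)
    with pytest.raises(ValueError, match="at least 2"):
        permutation_curve(m, n_permutations=1, seed=1)


def test_detection_functions_monotone_non_increasing():
    m, _ = simulate_expression(SimulationConfig(n_transcripts=300, seed=9))
    curve = permutation_curve(m, n_permutations=30, seed=2)
    assert (np.diff(curve.detection) <= 0).all()
    assert (np.diff(curve.random_mean) <= 1e-12).all()


def test_null_matrix_detection_matches_random():
    """Type-I control: on pure noise, real and random detection agree.

    The worst standardized deviation over the cutoff grid is itself a noisy
    extreme statistic, so its median over independent null data sets is the
    robust calibration check at this small scale.
    """
    max_z = []
    for seed in range(5):
        cfg = SimulationConfig(n_transcripts=500, rhythmic_fraction=0.0, seed=30 + seed)
        m, _ = simulate_expression(cfg)
        curve = permutation_curve(m, n_permutations=100, seed=60 + seed)
        dev = np.abs(curve.detection - curve.random_mean)
        max_z.append(np.max(dev / np.maximum(curve.random_sd, 1.0)))
    assert np.median(max_z) <= 3.0


def test_noiseless_cosines_all_called():
    cfg = SimulationConfig(n_transcripts=100, rhythmic_fraction=1.0, noise_sd=0.0,
                           amplitude_range=(1.0, 2.0), seed=3)
    m, _ = simulate_expression(cfg)
    curve = permutation_curve(m, n_permutations=50, seed=4)
    i = np.searchsorted(curve.cutoffs, 0.5)
    assert curve.detection[i] == 100
    assert curve.random_mean[i] < 5
    assert curve.tp_rate[i] > 0.95
    calls = call_circadian(curve, score_matrix(m), 0.90)
    assert calls.attainable and len(calls.calls) == 100
    assert all(s.g_factor >= calls.cutoff for s in calls.calls)


def test_unattainable_tp_rate_reported():
    cfg = SimulationConfig(n_transcripts=200, rhythmic_fraction=0.0, seed=6)
    m, _ = simulate_expression(cfg)
    curve = permutation_curve(m, n_permutations=50, seed=7)
    calls = call_circadian(curve, score_matrix(m), required_tp_rate=0.999)
    assert not calls.attainable
    assert calls.calls == []
    assert calls.best_achievable_rate < 0.999 or np.isnan(calls.best_achievable_rate)


def test_harmonic_variant_calls_same_set_on_cosine_data():
    # pure cosine signals carry no harmonic power, so at the same demanded TP
    # rate both g-factor definitions must call exactly the rhythmic transcripts
    cfg = SimulationConfig(n_transcripts=400, rhythmic_fraction=0.1, noise_sd=0.0,
                           amplitude_range=(1.0, 2.0), seed=13)
    m, gt = simulate_expression(cfg)
    rhythmic = {tid for tid, r in zip(gt.transcript_ids, gt.is_rhythmic) if r}
    for harm in (False, True):
        curve = permutation_curve(m, n_permutations=100, seed=14, include_harmonics=harm)
        calls = call_circadian(curve, score_matrix(m, include_harmonics=harm), 0.90)
        assert calls.attainable
        assert set(calls.transcript_ids) == rhythmic


# ---------------------------------------------------------------------------
# phase table
# ---------------------------------------------------------------------------


def test_phase_table_shift_theorem(ct_grid_48h):
    rng = np.random.default_rng(8)
    row = cosine_profile(ct_grid_48h, phase=3.0) + rng.normal(0, 0.1, 12)
    shifted = np.roll(row, -1)  # same values observed one 4-h sample earlier
    s0 = g_factor(row, ct_grid_48h)
    s1 = g_factor(shifted, ct_grid_48h)
    diff = (s0.phase_ct - s1.phase_ct) % 24
    assert diff == pytest.approx(4.0, abs=1e-6) or diff == pytest.approx(20.0, abs=1e-6)


def test_phase_table_contents_and_empty():
    cfg = SimulationConfig(n_transcripts=50, rhythmic_fraction=1.0, noise_sd=0.0,
                           fixed_phase=6.0, seed=10)
    m, _ = simulate_expression(cfg)
    curve = permutation_curve(m, n_permutations=20, seed=11)
    calls = call_circadian(curve, score_matrix(m), 0.90)
    table = phase_table(calls)
    assert len(table) == 50
    np.testing.assert_allclose(table["phase_ct"], 6.0, atol=1e-6)
    empty = call_circadian(curve, [], required_tp_rate=2.0)  # force no calls
    assert phase_table(empty).empty
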