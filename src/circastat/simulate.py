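"""Synthetic data with the statistical structure the analysis assumes.

Three generators make every downstream stage testable without real data:

* ``simulate_expression`` — log-scale expression matrices on a circadian
  sampling grid (default: 12 points at 4-h intervals starting CT14, spanning
  48 h = two full periods).  A stated fraction of transcripts follows
  baseline + A*cos(2*pi*(t - phi)/24) plus Gaussian noise; the rest is
  baseline plus noise.  Ground truth (flag, phase, amplitude) is returned for
  parameter-recovery tests.
* ``simulate_activity`` — per-larva locomotor traces in 10-min bins, with
  rhythmic individuals peaking mid subjective day and arrhythmic individuals
  flat on average; Gaussian noise, clipped at zero because distance moved is
  non-negative.
* ``simulate_alignments`` — a SAM-format stream of proper read pairs placed
  inside gene coding intervals, with a stated fraction of exact positional
  duplicates, exercising the PCR-dedup and counting rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import ActivityRecord
from .io import HOURS_PER_DAY, GeneModel, TimeSeriesMatrix, ct_label_sequence


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of a synthetic expression time course (log2 scale).

    Defaults mirror the two-day pineal sampling design: 12 time points at 4-h
    intervals starting at CT14.  ``fixed_phase`` pins every rhythmic
    transcript's peak CT; ``None`` draws phases uniformly on [0, 24).
    """

    n_transcripts: int
    n_timepoints: int = 12
    interval_h: float = 4.0
    start_ct: float = 14.0
    rhythmic_fraction: float = 0.1
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    fixed_phase: float | None = None
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be non-negative")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be at least 2")
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        if not 0.0 <= self.rhythmic_fraction <= 1.0:
            raise ValueError("rhythmic_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("amplitude_range must be a non-negative (low, high) pair")
        lo, hi = self.baseline_range
        if hi < lo:
            raise ValueError("baseline_range must be a (low, high) pair")
        if self.fixed_phase is not None and not 0.0 <= self.fixed_phase < HOURS_PER_DAY:
            raise ValueError("fixed_phase must lie in [0, 24)")

    @property
    def hours(self) -> np.ndarray:
        return self.start_ct + np.arange(self.n_timepoints) * self.interval_h


@dataclass
class GroundTruth:
    """Per-transcript simulation truth: rhythmicity flag, peak CT, amplitude."""

    transcript_ids: list[str]
    is_rhythmic: np.ndarray
    phase_ct: np.ndarray      # NaN for non-rhythmic transcripts
    amplitude: np.ndarray     # 0 for non-rhythmic transcripts

    def __post_init__(self) -> None:
        n = len(self.transcript_ids)
        self.is_rhythmic = np.asarray(self.is_rhythmic, dtype=bool)
        self.phase_ct = np.asarray(self.phase_ct, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if not (self.is_rhythmic.size == self.phase_ct.size == self.amplitude.size == n):
            raise ValueError("ground-truth arrays must have one entry per transcript")
        finite = self.phase_ct[np.isfinite(self.phase_ct)]
        if ((finite < 0) | (finite >= HOURS_PER_DAY)).any():
            raise ValueError("phases must lie in [0, 24)")


def simulate_expression(config: SimulationConfig) -> tuple[TimeSeriesMatrix, GroundTruth]:
    """Draw a seeded expression matrix plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n, t = config.n_transcripts, config.hours

    n_rhythmic = int(round(config.rhythmic_fraction * n))
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[rng.choice(n, size=n_rhythmic, replace=False)] = True

    baseline = rng.uniform(*config.baseline_range, size=n)
    amplitude = np.where(is_rhythmic, rng.uniform(*config.amplitude_range, size=n), 0.0)
    if config.fixed_phase is not None:
        phase = np.full(n, float(config.fixed_phase))
    else:
        phase = rng.uniform(0.0, HOURS_PER_DAY, size=n)
    phase = np.where(is_rhythmic, phase, np.nan)

    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n, t.size))
    if n_rhythmic:
        cos = np.cos(2.0 * np.pi * (t[None, :] - phase[is_rhythmic, None]) / HOURS_PER_DAY)
        values[is_rhythmic] += amplitude[is_rhythmic, None] * cos

    ids = [f"tx{i:06d}" for i in range(n)]
    matrix = TimeSeriesMatrix(
        transcript_ids=ids,
        ct_labels=ct_label_sequence(config.start_ct, config.interval_h, t.size),
        values=values,
        scale="log",
        hours=t,
    )
    return matrix, GroundTruth(ids, is_rhythmic, phase, amplitude)


def write_ground_truth(truth: GroundTruth, path) -> None:
    import pandas as pd
    pd.DataFrame({
        "transcript_id": truth.transcript_ids,
        "is_rhythmic": truth.is_rhythmic.astype(int),
        "phase_ct": truth.phase_ct,
        "amplitude": truth.amplitude,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Locomotor activity
# ---------------------------------------------------------------------------


def simulate_activity(n_individuals: int, days: int, bin_min: float = 10.0,
                      rhythmic: bool = True, day_night_ratio: float = 3.0,
                      noise_sd: float = 4.0, baseline: float = 10.0,
                      peak_ct: float = 6.0, group: str | None = None,
                      seed: int = 0) -> list[ActivityRecord]:
    """Seeded locomotor traces for one group of larvae.

    Rhythmic individuals have mean activity b*(1 + m*cos(2*pi*(t - peak)/24))
    with modulation depth m = (r - 1)/(r + 1) set by the day:night mean ratio
    r, peaking mid subjective day (CT6); arrhythmic individuals have constant
    mean b.  Gaussian noise is added per bin and the result clipped at zero.
    """
    if n_individuals < 0:
        raise ValueError("n_individuals must be non-negative")
    if days < 1:
        raise ValueError("days must be at least 1")
    if (24 * 60) % bin_min != 0:
        raise ValueError(f"bin_min={bin_min} must divide 24 h")
    if day_night_ratio <= 0:
        raise ValueError("day_night_ratio must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_bins = int(days * 24 * 60 / bin_min)
    t = np.arange(n_bins) * bin_min / 60.0
    if rhythmic:
        m = (day_night_ratio - 1.0) / (day_night_ratio + 1.0)
        mean = baseline * (1.0 + m * np.cos(2.0 * np.pi * (t - peak_ct) / HOURS_PER_DAY))
    else:
        mean = np.full(n_bins, float(baseline))
    label = group or ("rhythmic" if rhythmic else "arrhythmic")
    traces = np.clip(mean[None, :] + rng.normal(0.0, noise_sd, size=(n_individuals, n_bins)),
                     0.0, None)
    return [
        ActivityRecord(f"{label}_{i:03d}", label, traces[i], bin_min, start_ct=0.0)
        for i in range(n_individuals)
    ]


# ---------------------------------------------------------------------------
# Alignments (SAM fixture for the dedup/count rule)
# ---------------------------------------------------------------------------


def simulate_alignments(gene_models: list[GeneModel], reads_per_gene: int | dict[str, int],
                        duplicate_fraction: float = 0.0, seed: int = 0,
                        read_length: int = 50) -> str:
    """Generate a SAM text stream of proper pairs inside gene coding intervals.

    Per gene, round(duplicate_fraction * reads) pairs are exact positional
    copies of previously generated pairs (fresh query names), emulating PCR
    duplicates; the rest are drawn independently.  Mate start positions are
    sampled so each read lies fully inside one coding interval.  Gene models
    overlapping on the same chromosome and strand are rejected.
    """
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ValueError("duplicate_fraction must lie in [0, 1]")
    _check_no_overlap(gene_models)
    rng = np.random.default_rng(seed)

    chrom_len: dict[str, int] = {}
    for g in gene_models:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.span[1] + read_length)
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{c}\tLN:{ln}" for c, ln in sorted(chrom_len.items())]

    lines: list[str] = []
    serial = 0
    for g in gene_models:
        n_reads = reads_per_gene[g.gene_id] if isinstance(reads_per_gene, dict) \
            else int(reads_per_gene)
        if n_reads == 0:
            continue
        starts = np.concatenate([
            np.arange(a, b - read_length + 1) for a, b in g.intervals
            if b - a >= read_length
        ]) if any(b - a >= read_length for a, b in g.intervals) else None
        if starts is None or starts.size == 0:
            raise ValueError(f"gene {g.gene_id} has no interval of length >= {read_length}")
        n_dup = int(round(duplicate_fraction * n_reads))
        originals = []
        for _ in range(n_reads - n_dup):
            lo, hi = sorted(rng.choice(starts, size=2, replace=True))
            originals.append((int(lo), int(hi)))
        for j in range(n_dup):
            lo, hi = originals[int(rng.integers(len(originals)))]
            originals.append((lo, hi))
        for lo, hi in originals:
            qname = f"pair{serial:07d}"
            serial += 1
            tlen = hi + read_length - lo
            lines.append(_sam_line(qname, 99, g.chrom, lo, read_length, hi, tlen))
            lines.append(_sam_line(qname, 147, g.chrom, hi, read_length, lo, -tlen))
    return "\n".join(header + lines) + "\n"


def _sam_line(qname: str, flag: int, chrom: str, pos0: int, read_length: int,
              mate_pos0: int, tlen: int, nm: int = 0, nh: int = 1) -> str:
    seq = "A" * read_length
    qual = "I" * read_length
    return "\t".join([
        qname, str(flag), chrom, str(pos0 + 1), "60", f"{read_length}M",
        "=", str(mate_pos0 + 1), str(tlen), seq, qual, f"NM:i:{nm}", f"NH:i:{nh}",
    ])


def _check_no_overlap(models: list[GeneModel]) -> None:
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in models:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    for (chrom, strand), genes in by_key.items():
        genes = sorted(genes, key=lambda g: g.span)
        for g1, g2 in zip(genes, genes[1:]):
            if g2.span[0] < g1.span[1]:
                raise ValueError(
                    f"gene models {g1.gene_id} and {g2.gene_id} overlap on "
                    f"{chrom}{strand}"
                )
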