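"""Gene-set enrichment and cross-platform validation statistics.

Enrichment of a circadian call set within a curated gene set is tested with
the exact binomial upper tail: under the null, each of the n genes of the set
is circadian independently with probability p = (circadian genes)/(background
genes), so the tail P(X >= k), X ~ Binomial(n, p), bounds how surprising an
overlap of k is.  Cross-platform agreement is summarised on the universe of
genes measured by both platforms, and individual expression profiles are
validated against independent measurements with the Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("circastat")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int           # n (after restriction to the background)
    overlap: int            # k
    background_total: int   # M
    circadian_total: int    # m
    p_success: float        # m / M
    tail_probability: float  # P(X >= k), X ~ Binomial(n, p)

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= self.set_size):
            raise ValueError("overlap must lie in [0, set size]")


def binomial_tail(n: int, k: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("success probability must be in [0, 1]")
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def binomial_enrichment(call_set: Iterable[str], gene_set: Iterable[str],
                        background: Iterable[str],
                        set_name: str = "gene_set") -> EnrichmentResult:
    """Binomial-cumulative enrichment of a gene set in the circadian calls.

    Gene-set ids absent from the background are dropped with a warning and the
    set size adjusted; call-set ids must all belong to the background.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    calls = set(call_set)
    stray = calls - bg
    if stray:
        raise ValueError(f"call set contains ids outside the background: "
                         f"{sorted(stray)[:5]}{'...' if len(stray) > 5 else ''}")
    gs = set(gene_set)
    outside = gs - bg
    if outside:
        logger.warning("dropping %d gene-set ids outside the background", len(outside))
        gs -= outside
    n, k = len(gs), len(gs & calls)
    p = len(calls) / len(bg)
    return EnrichmentResult(set_name, n, k, len(bg), len(calls), p,
                            binomial_tail(n, k, p))


def batch_enrichment(gene_sets: Mapping[str, Iterable[str]], call_set: Iterable[str],
                     background: Iterable[str], adjust: bool = False) -> pd.DataFrame:
    """Enrichment of several gene sets, optionally BH-adjusted across sets."""
    results = [binomial_enrichment(call_set, gs, background, name)
               for name, gs in gene_sets.items()]
    df = pd.DataFrame({
        "set_name": [r.set_name for r in results],
        "n": [r.set_size for r in results],
        "k": [r.overlap for r in results],
        "p_success": [r.p_success for r in results],
        "tail_probability": [r.tail_probability for r in results],
    })
    if adjust and len(df):
        df["tail_probability_bh"] = stats.false_discovery_control(
            df["tail_probability"].to_numpy(), method="bh")
    return df


@dataclass
class OverlapSummary:
    """2x2 cross-platform agreement on the jointly measured universe."""

    universe_size: int
    called_both: int
    called_a_only: int
    called_b_only: int
    called_neither: int

    def __post_init__(self) -> None:
        total = self.called_both + self.called_a_only + self.called_b_only + self.called_neither
        if total != self.universe_size:
            raise ValueError("overlap counts do not sum to the universe size")

    @property
    def fraction_of_a_in_b(self) -> float:
        called_a = self.called_both + self.called_a_only
        return self.called_both / called_a if called_a else float("nan")

    @property
    def fraction_of_b_in_a(self) -> float:
        called_b = self.called_both + self.called_b_only
        return self.called_both / called_b if called_b else float("nan")


def overlap_summary(calls_a: Iterable[str], calls_b: Iterable[str],
                    measured_a: Iterable[str], measured_b: Iterable[str]) -> OverlapSummary:
    """Tabulate call-set agreement restricted to genes measured on both platforms."""
    ma, mb = set(measured_a), set(measured_b)
    ca, cb = set(calls_a), set(calls_b)
    if not ca <= ma:
        raise ValueError("calls_a contains ids not in measured_a")
    if not cb <= mb:
        raise ValueError("calls_b contains ids not in measured_b")
    universe = ma & mb
    ca &= universe
    cb &= universe
    both = len(ca & cb)
    a_only = len(ca - cb)
    b_only = len(cb - ca)
    return OverlapSummary(len(universe), both, a_only, b_only,
                          len(universe) - both - a_only - b_only)


def profile_correlation(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Pearson correlation of two expression profiles on matching CT grids."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("profiles must have at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance profile")
    return float(stats.pearsonr(a, b).statistic)


def read_gene_list(path) -> list[str]:
    """Read a plain-text gene list, one id per line, ignoring blanks."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
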