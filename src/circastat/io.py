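"""Expression-data ingestion and normalization.

Covers the pre-processing side of the pineal time-course analysis:

* parsing gene x time-point TSV matrices whose columns carry circadian-time
  (CT) labels such as ``CT14 ... CT10b`` (a trailing lower-case letter marks a
  repeated CT value in a later cycle of a multi-day sampling design);
* the paired-end RNA-seq counting rule: keep only uniquely aligned read pairs
  with at most two mismatches per read, collapse PCR duplicates (pairs that
  share both mates' start positions), and count a pair for a gene when both
  mates' leftmost positions fall inside the gene's coding intervals;
* log2 transformation and quantile normalization across time points.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("circastat")

HOURS_PER_DAY = 24.0

# ---------------------------------------------------------------------------
# Circadian-time labels
# ---------------------------------------------------------------------------

_CT_RE = re.compile(r"^CT\s*(\d+(?:\.\d+)?)([a-z]?)$")


def parse_ct_labels(labels: Sequence[str]) -> np.ndarray:
    """Convert CT labels into absolute hours since subjective dawn of day 1.

    Labels record time-of-day within the subjective cycle; collection order is
    the column order.  Each successive sample is placed at the smallest
    strictly positive time increment consistent with its CT value, so the
    sequence ``CT14, CT18, CT22, CT2, ...`` maps to ``14, 18, 22, 26, ...``.
    The optional letter suffix (``CT14b`` = second sample taken at CT14) only
    disambiguates repeated labels and carries no extra timing information.
    """
    hours_mod = []
    for lab in labels:
        m = _CT_RE.match(str(lab).strip())
        if m is None:
            raise ValueError(f"unparseable circadian-time label {lab!r}")
        hours_mod.append(float(m.group(1)))
        if hours_mod[-1] >= HOURS_PER_DAY:
            raise ValueError(f"circadian-time label {lab!r} exceeds 24 h")
    if not hours_mod:
        return np.array([], dtype=float)
    abs_hours = [hours_mod[0]]
    for h in hours_mod[1:]:
        step = (h - abs_hours[-1]) % HOURS_PER_DAY
        if step == 0.0:
            step = HOURS_PER_DAY
        abs_hours.append(abs_hours[-1] + step)
    return np.asarray(abs_hours, dtype=float)


def ct_label_sequence(start_ct: float, interval_h: float, n: int) -> list[str]:
    """Generate CT labels for a uniform design, suffixing repeats b, c, ..."""
    labels: list[str] = []
    seen: dict[float, int] = {}
    for i in range(n):
        h = (start_ct + i * interval_h) % HOURS_PER_DAY
        count = seen.get(h, 0)
        seen[h] = count + 1
        base = f"CT{h:g}"
        labels.append(base if count == 0 else base + chr(ord("a") + count))
    return labels


# ---------------------------------------------------------------------------
# TimeSeriesMatrix
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesMatrix:
    """A transcripts x time-points expression matrix with CT-labelled columns.

    ``hours`` are absolute sampling times (monotone increasing, e.g. 14..58
    for the 12-point / 4-h / 48-h design); ``scale`` records whether values
    are raw intensities/counts or log2-transformed.
    """

    transcript_ids: list[str]
    ct_labels: list[str]
    values: np.ndarray  # shape (n_transcripts, n_timepoints)
    scale: str = "raw"  # "raw" | "log"
    hours: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.transcript_ids), len(self.ct_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.ct_labels)} labels"
            )
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValueError("duplicate transcript ids")
        if self.hours is None:
            self.hours = parse_ct_labels(self.ct_labels)
        else:
            self.hours = np.asarray(self.hours, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing values")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.ct_labels)

    @property
    def start_ct(self) -> float:
        return float(self.hours[0] % HOURS_PER_DAY) if self.n_timepoints else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.transcript_ids, columns=self.ct_labels)


def read_matrix(path: str | Path, scale: str = "raw") -> TimeSeriesMatrix:
    """Read a TSV expression matrix (row = transcript, header = CT labels).

    Rows containing blank or non-numeric cells are dropped with a logged
    warning; duplicate transcript ids and malformed CT labels raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    labels = [str(c) for c in df.columns]
    for lab in labels:
        if _CT_RE.match(lab.strip()) is None:
            raise ValueError(f"unparseable circadian-time label in column {lab!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        for tid in numeric.index[bad]:
            logger.warning("dropping transcript %s: missing or non-numeric cell", tid)
        numeric = numeric.loc[~bad]
    return TimeSeriesMatrix(
        transcript_ids=[str(i) for i in numeric.index],
        ct_labels=labels,
        values=numeric.to_numpy(dtype=float),
        scale=scale,
    )


def write_matrix(m: TimeSeriesMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def log_transform(m: TimeSeriesMatrix, pseudocount: float = 1.0) -> TimeSeriesMatrix:
    """log2(value + pseudocount); rejects already-log input and negatives.

    Pseudocount 1.0 suits count data; microarray intensities are strictly
    positive so pseudocount 0 is allowed.
    """
    if m.scale == "log":
        raise ValueError("matrix is already on log scale")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if (m.values < 0).any():
        raise ValueError("raw matrix contains negative values")
    if pseudocount == 0 and (m.values == 0).any():
        raise ValueError("zero values require a positive pseudocount")
    return replace(m, values=np.log2(m.values + pseudocount), scale="log")


def quantile_normalize(m: TimeSeriesMatrix, allow_raw: bool = False) -> TimeSeriesMatrix:
    """Force every column (time point) onto a common value distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix (Bolstad-style).  Tied values within a column receive the mean of
    the reference values their rank span covers, so ties stay tied.
    """
    if m.scale != "log" and not allow_raw:
        raise ValueError("quantile normalization expects a log-scale matrix "
                         "(pass allow_raw=True to override)")
    if m.n_timepoints < 2:
        raise ValueError("quantile normalization requires at least 2 columns")
    return replace(m, values=quantile_normalize_values(m.values))


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    if n == 0:
        return v.copy()
    ref = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(k):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        out[order, j] = ref
        sorted_col = col[order]
        # average the reference over each tied run
        i = 0
        while i < n:
            hi = i
            while hi + 1 < n and sorted_col[hi + 1] == sorted_col[i]:
                hi += 1
            if hi > i:
                out[order[i : hi + 1], j] = ref[i : hi + 1].mean()
            i = hi + 1
    return out


# ---------------------------------------------------------------------------
# Gene models (BED6) and read pairs
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Coding intervals of one gene (0-based, half-open, sorted, disjoint)."""

    gene_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        iv = sorted((int(a), int(b)) for a, b in self.intervals)
        for a, b in iv:
            if b <= a:
                raise ValueError(f"empty or inverted interval ({a}, {b}) in {self.gene_id}")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping intervals within gene {self.gene_id}")
        self.intervals = iv

    def contains(self, pos: int) -> bool:
        for a, b in self.intervals:
            if a <= pos < b:
                return True
        return False

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]


def read_bed6(path: str | Path) -> list[GeneModel]:
    """Read gene models from 6-column BED; lines sharing a name form one gene."""
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"expected 6 BED columns, got {len(fields)}: {line!r}")
            chrom, start, end, name, _score, strand = fields[:6]
            g = groups.setdefault(name, {"chrom": chrom, "strand": strand, "iv": []})
            if g["chrom"] != chrom or g["strand"] != strand:
                raise ValueError(f"gene {name} spans multiple chromosomes or strands")
            g["iv"].append((int(start), int(end)))
    return [GeneModel(name, g["chrom"], g["strand"], g["iv"]) for name, g in groups.items()]


def write_bed6(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            for a, b in g.intervals:
                fh.write(f"{g.chrom}\t{a}\t{b}\t{g.gene_id}\t0\t{g.strand}\n")


@dataclass(frozen=True)
class ReadPair:
    """A mapped proper pair reduced to what the dedup/count rule needs.

    ``start_lo``/``start_hi`` are the ordered leftmost mapped coordinates of
    the two mates (0-based); ``mismatches`` is the worse mate's NM count.
    """

    name: str
    chrom: str
    strand: str
    start_lo: int
    start_hi: int
    unique: bool
    mismatches: int

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start_lo, self.start_hi)


def iter_read_pairs(sam: str | Path, stats: dict | None = None) -> Iterable[ReadPair]:
    """Assemble primary-alignment read pairs from a SAM file.

    Records that are secondary/supplementary, unmapped, mate-unmapped or on a
    different chromosome than their mate are skipped and tallied in ``stats``.
    """
    if stats is None:
        stats = {}
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                stats["secondary"] = stats.get("secondary", 0) + 1
                continue
            if rec.is_unmapped or rec.mate_is_unmapped:
                stats["unmapped_mate"] = stats.get("unmapped_mate", 0) + 1
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            if mate.reference_name != rec.reference_name:
                stats["cross_chromosome"] = stats.get("cross_chromosome", 0) + 1
                continue
            first = rec if rec.is_read1 else mate
            starts = sorted((rec.reference_start, mate.reference_start))
            nh = max(_tag(rec, "NH", 1), _tag(mate, "NH", 1))
            nm = max(_tag(rec, "NM", 0), _tag(mate, "NM", 0))
            yield ReadPair(
                name=rec.query_name,
                chrom=rec.reference_name,
                strand="-" if first.is_reverse else "+",
                start_lo=starts[0],
                start_hi=starts[1],
                unique=nh <= 1,
                mismatches=nm,
            )
    if pending:
        stats["orphan"] = stats.get("orphan", 0) + len(pending)


def _tag(rec: pysam.AlignedSegment, tag: str, default: int) -> int:
    try:
        return int(rec.get_tag(tag))
    except KeyError:
        return default


def filter_pairs(pairs: Iterable[ReadPair], max_mismatches: int = 2,
                 stats: dict | None = None) -> list[ReadPair]:
    """Drop non-unique pairs and pairs with a mate above the mismatch limit."""
    if stats is None:
        stats = {}
    out = []
    for p in pairs:
        if not p.unique:
            stats["non_unique"] = stats.get("non_unique", 0) + 1
        elif p.mismatches > max_mismatches:
            stats["mismatch_excess"] = stats.get("mismatch_excess", 0) + 1
        else:
            out.append(p)
    return out


def dedup_pairs(pairs: Sequence[ReadPair]) -> list[ReadPair]:
    """Collapse PCR duplicates: keep the first pair per (chrom, strand, start, start)."""
    seen: set[tuple] = set()
    out = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            out.append(p)
    return out


def count_pairs(pairs: Sequence[ReadPair], models: Sequence[GeneModel],
                stats: dict | None = None) -> pd.Series:
    """Count pairs whose two mate starts both lie inside one gene's coding intervals.

    Pairs hitting no gene, straddling two genes, or mapping to a chromosome
    absent from the models are discarded (tallied in ``stats``).
    """
    if stats is None:
        stats = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    counts = pd.Series(0, index=[g.gene_id for g in models], dtype=int)
    for p in pairs:
        genes = by_chrom.get(p.chrom)
        if genes is None:
            stats["unknown_chromosome"] = stats.get("unknown_chromosome", 0) + 1
            logger.warning("read pair %s on unknown chromosome %s", p.name, p.chrom)
            continue
        hits_lo = {g.gene_id for g in genes if g.contains(p.start_lo)}
        hits_hi = {g.gene_id for g in genes if g.contains(p.start_hi)}
        common = hits_lo & hits_hi
        if len(common) == 1:
            counts[common.pop()] += 1
        else:
            stats["unassigned"] = stats.get("unassigned", 0) + 1
    return counts


def dedup_and_count(sam: str | Path, models: Sequence[GeneModel],
                    max_mismatches: int = 2) -> tuple[pd.Series, dict]:
    """Full RNA-seq counting rule: filter, collapse duplicates, count per gene."""
    stats: dict = {}
    pairs = filter_pairs(iter_read_pairs(sam, stats), max_mismatches, stats)
    stats["surviving_pairs_pre_dedup"] = len(pairs)
    unique = dedup_pairs(pairs)
    stats["surviving_pairs"] = len(unique)
    counts = count_pairs(unique, models, stats)
    stats["counted_pairs"] = int(counts.sum())
    return counts, stats
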