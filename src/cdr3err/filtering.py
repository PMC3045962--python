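"""Clonotype tables and single-nucleotide-mismatch culling.

A clonotype is a unique CDR3 nucleotide sequence with its read counts
(total / forward / reverse / per lane). Most sequencing errors are single
substitutions of an abundant parental sequence, so erroneous clonotypes sit
at Hamming distance 1 from a much more frequent "index" clonotype:

* monoclonal mode culls distance-1 neighbors of the known true sequence whose
  count is at or below ``cutoff × index count`` and reports the residual
  erroneous fraction;
* polyclonal mode tallies, for the top-k index clonotypes, distance-1
  lower-count clonotypes below a relative-frequency cutoff grid, plus the
  global lower-frequency-neighbor tally over all clonotypes;
* a direction-skew screen flags clonotypes whose forward-read count falls
  outside exact-binomial boundaries expected under direction-neutral
  sequencing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .extract import CDR3Record
from .models import binom_boundaries


class CloneTable:
    """Clonotype abundance table.

    Wraps a DataFrame with one row per unique CDR3 nt sequence and columns
    ``cdr3_nt, total_count, forward_count, reverse_count`` plus one
    ``lane_<x>`` column per lane seen, sorted by descending count then
    lexicographically by sequence.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"cdr3_nt", "total_count", "forward_count", "reverse_count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.sort_values(
            ["total_count", "cdr3_nt"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        if (df["forward_count"] + df["reverse_count"] != df["total_count"]).any():
            raise ValueError("forward + reverse must equal total per row")
        self.df = df
        self._counts: dict[str, int] = dict(zip(df["cdr3_nt"], df["total_count"].astype(int)))

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, seq: str) -> bool:
        return seq in self._counts

    def count(self, seq: str) -> int:
        return self._counts[seq]

    @property
    def counts(self) -> Mapping[str, int]:
        return self._counts

    @property
    def total_reads(self) -> int:
        return int(self.df["total_count"].sum())

    def frequencies(self) -> pd.Series:
        return self.df.set_index("cdr3_nt")["total_count"] / self.total_reads

    def top(self, k: int) -> list[str]:
        """The k most frequent sequences (ties broken lexicographically)."""
        return self.df["cdr3_nt"].head(k).tolist()

    def drop(self, seqs: Iterable[str]) -> "CloneTable":
        seqs = set(seqs)
        return CloneTable(self.df[~self.df["cdr3_nt"].isin(seqs)].copy())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CloneTable":
        return cls(pd.read_csv(path, sep="\t"))


def build_clone_table(records: Sequence[CDR3Record]) -> CloneTable:
    """Group validated records by exact CDR3 sequence, counting by direction and lane."""
    total: dict[str, int] = defaultdict(int)
    fwd: dict[str, int] = defaultdict(int)
    lanes: dict[str, dict] = defaultdict(lambda: defaultdict(int))
    for r in records:
        total[r.cdr3_nt] += 1
        if r.orientation == "forward":
            fwd[r.cdr3_nt] += 1
        if r.lane is not None:
            lanes[r.cdr3_nt][r.lane] += 1
    seqs = sorted(total)
    all_lanes = sorted({lane for d in lanes.values() for lane in d})
    data = {
        "cdr3_nt": seqs,
        "total_count": [total[s] for s in seqs],
        "forward_count": [fwd[s] for s in seqs],
        "reverse_count": [total[s] - fwd[s] for s in seqs],
    }
    for lane in all_lanes:
        data[f"lane_{lane}"] = [lanes[s].get(lane, 0) for s in seqs]
    return CloneTable(pd.DataFrame(data))


def hamming1_pairs(seqs: Sequence[str]) -> Iterator[tuple[str, str]]:
    """All unordered pairs of equal-length sequences at Hamming distance 1.

    Indexed by position-wildcard keys, so each pair is produced exactly once
    (two distinct sequences share a wildcard key iff they differ only at that
    wildcarded position).
    """
    buckets: dict[tuple[int, str, str], list[str]] = defaultdict(list)
    for s in seqs:
        for i in range(len(s)):
            buckets[(i, s[:i], s[i + 1 :])].append(s)
    for members in buckets.values():
        if len(members) > 1:
            yield from combinations(members, 2)


def single_mismatch_neighbors(table: CloneTable) -> dict[str, list[str]]:
    """Per sequence, the lower-count sequences at Hamming distance 1.

    Only equal-length sequences can be neighbors; "lower frequency" is strict
    (equal-count pairs are mutually non-neighbors), keeping the relation
    antisymmetric.
    """
    counts = table.counts
    neighbors: dict[str, list[str]] = {s: [] for s in counts}
    for a, b in hamming1_pairs(list(counts)):
        if counts[a] > counts[b]:
            neighbors[a].append(b)
        elif counts[b] > counts[a]:
            neighbors[b].append(a)
    for s in neighbors:
        neighbors[s].sort()
    return neighbors


@dataclass
class CullReport:
    """Result of monoclonal single-mismatch culling."""

    culled: pd.DataFrame
    residual_error_fraction: float
    kept: CloneTable = field(repr=False, default=None)
    true_seq: str = ""
    cutoff: float = 0.0


def cull_monoclonal(table: CloneTable, true_seq: str, cutoff: float) -> CullReport:
    """Cull distance-1 neighbors of the known true sequence.

    A sequence is removed iff it is at Hamming distance 1 from ``true_seq``
    and its count is at or below ``cutoff × count(true_seq)`` (inclusive, so
    cutoff 1 removes every distance-1 sequence at or below the index
    frequency; cutoff 0 removes nothing since counts are >= 1). The residual
    erroneous fraction is the share of remaining reads that are not the true
    sequence.
    """
    if true_seq not in table:
        raise ValueError("true sequence absent from table")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    index_count = table.count(true_seq)
    threshold = cutoff * index_count
    culled_rows = []
    L = len(true_seq)
    for seq, count in table.counts.items():
        if seq == true_seq or len(seq) != L:
            continue
        if count <= threshold and _hamming(seq, true_seq) == 1:
            culled_rows.append((seq, count, true_seq, index_count, count / index_count))
    culled = pd.DataFrame(
        culled_rows, columns=["sequence", "count", "index_sequence", "index_count", "ratio"]
    )
    kept = table.drop(culled["sequence"]) if len(culled) else table
    remaining_total = kept.total_reads
    residual = (remaining_total - index_count) / remaining_total if remaining_total else np.nan
    return CullReport(
        culled=culled,
        residual_error_fraction=float(residual),
        kept=kept,
        true_seq=true_seq,
        cutoff=cutoff,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


DEFAULT_CUTOFF_GRID = (0.001, 0.002, 0.004, 0.006, 0.008, 0.01)


@dataclass
class PolyCullReport:
    """Neighbor tallies for polyclonal repertoires over a cutoff grid."""

    per_cutoff_totals: dict[float, int]
    per_index: pd.DataFrame
    global_tally: int
    top_k_used: int
    index_sequences: list[str] = field(default_factory=list)


def cull_polyclonal(
    table: CloneTable,
    cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
    top_k: int = 20,
) -> PolyCullReport:
    """Tally presumed erroneous distance-1 neighbors of top index clonotypes.

    For the ``top_k`` most frequent sequences and each relative-frequency
    cutoff, counts distance-1 lower-count sequences present at strictly less
    than ``cutoff × index count``. Indexes are processed in descending count
    order and a sequence already attributed to one index is not re-counted
    for another. Also reports the global tally: the summed number of
    lower-count distance-1 neighbors over *all* sequences (no cutoff).
    """
    k = min(top_k, len(table))
    indexes = table.top(k)
    neighbors = single_mismatch_neighbors(table)
    counts = table.counts
    global_tally = sum(len(v) for v in neighbors.values())
    per_cutoff: dict[float, int] = {}
    rows = []
    for cutoff in cutoffs:
        assigned: set[str] = set()
        total = 0
        for index_seq in indexes:
            limit = cutoff * counts[index_seq]
            hits = [s for s in neighbors[index_seq] if counts[s] < limit and s not in assigned]
            assigned.update(hits)
            rows.append((cutoff, index_seq, counts[index_seq], len(hits)))
            total += len(hits)
        per_cutoff[cutoff] = total
    per_index = pd.DataFrame(rows, columns=["cutoff", "index_sequence", "index_count", "tally"])
    return PolyCullReport(
        per_cutoff_totals=per_cutoff,
        per_index=per_index,
        global_tally=global_tally,
        top_k_used=k,
        index_sequences=indexes,
    )


@dataclass
class SkewScreenResult:
    """Direction-skew screen over sufficiently abundant clonotypes."""

    table: pd.DataFrame
    fraction_within: float
    p_fwd: float
    min_reads: int
    tail: float


def direction_skew_screen(
    table: CloneTable,
    p_fwd: float | None = None,
    min_reads: int = 20,
    tail: float = 0.01,
    exclude: Sequence[str] = (),
) -> SkewScreenResult:
    """Flag clonotypes whose forward-read count is outside binomial boundaries.

    ``p_fwd`` defaults to the forward fraction of the most abundant sequence
    (the presumed correct one). Sequences with fewer than ``min_reads`` total
    reads are not assessed; ``exclude`` removes e.g. the true sequence itself
    from the screen. Direction-neutral clonotypes should fall within the
    boundaries ~(1 − 2·tail) of the time.
    """
    df = table.df
    if p_fwd is None:
        top = df.iloc[0]
        p_fwd = float(top["forward_count"] / top["total_count"])
    if not 0 < p_fwd < 1:
        raise ValueError("p_fwd must be in (0, 1)")
    boundary_cache: dict[int, tuple[int, int]] = {}
    rows = []
    excluded = set(exclude)
    for _, row in df.iterrows():
        n = int(row["total_count"])
        if n < min_reads or row["cdr3_nt"] in excluded:
            continue
        if n not in boundary_cache:
            boundary_cache[n] = binom_boundaries(n, p_fwd, tail)
        lower, upper = boundary_cache[n]
        f = int(row["forward_count"])
        rows.append((row["cdr3_nt"], n, f, f / n, lower, upper, lower <= f <= upper))
    out = pd.DataFrame(
        rows,
        columns=["cdr3_nt", "total", "forward", "pct_forward", "lower", "upper", "within"],
    )
    frac = float(out["within"].mean()) if len(out) else np.nan
    return SkewScreenResult(
        table=out, fraction_within=frac, p_fwd=p_fwd, min_reads=min_reads, tail=tail
    )
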