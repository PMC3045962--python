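"""Descriptive error statistics for monoclonal control sequencing.

Every accepted CDR3 is compared with the single known true CDR3 of the
monoclonal sample, classified (correct / substitution / truncated /
elongated), and aggregated into:

* per-Phred-cutoff error summaries (error percent, unique erroneous
  sequences, length-class composition, multi-substitution spectrum),
* a position × substitution rate matrix stratified by lane, read direction
  and/or sample (the per-cell "which base turned into which, where, and how
  often" view),
* per-nucleotide substitution rates averaged over positions sharing an
  origin base, split by read direction, and
* lane-effect statistics: composite coefficients of variation within and
  across lanes, and per-cell one-way ANOVA across lanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extract import CDR3Record, phred_filter
from .sequtil import NT_ORDER

CATEGORIES = ("correct", "substitution", "truncated", "elongated")


@dataclass(frozen=True)
class ErrorClassification:
    """Outcome of comparing one CDR3 with the reference.

    ``n_subs`` is defined only for correct-length sequences; ``sub_list``
    holds (position, from_nt, to_nt) with 0-based positions inside the CDR3.
    """

    category: str
    n_subs: int | None
    sub_list: tuple[tuple[int, str, str], ...] = ()


def _seq_of(record) -> str:
    return record.cdr3_nt if isinstance(record, CDR3Record) else str(record)


def classify(record, reference_cdr3: str) -> ErrorClassification:
    """Classify a CDR3 against the known reference (monoclonal mode)."""
    seq = _seq_of(record)
    if len(seq) < len(reference_cdr3):
        return ErrorClassification("truncated", None)
    if len(seq) > len(reference_cdr3):
        return ErrorClassification("elongated", None)
    if seq == reference_cdr3:
        return ErrorClassification("correct", 0)
    subs = tuple(
        (i, a, b) for i, (a, b) in enumerate(zip(reference_cdr3, seq)) if a != b
    )
    return ErrorClassification("substitution", len(subs), subs)


class _ClassCache:
    """Classification depends only on the CDR3 string; memoize per sequence."""

    def __init__(self, reference: str):
        self.reference = reference
        self._cache: dict[str, ErrorClassification] = {}

    def __call__(self, record) -> ErrorClassification:
        seq = _seq_of(record)
        hit = self._cache.get(seq)
        if hit is None:
            hit = classify(seq, self.reference)
            self._cache[seq] = hit
        return hit


@dataclass
class ProfileSummary:
    """Error summary of one record set at one Phred cutoff."""

    q_cutoff: int
    n_total: int
    n_error: int
    error_percent: float | None
    n_unique_error: int
    unique_error_by_sample: dict[str, int]
    length_class_percent: dict[str, float | None]
    spectrum: dict[int, float]
    multi_error_freq: dict[int, float]
    pct_correct_excluded: float | None = None
    pct_error_excluded: float | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["spectrum"] = {str(k): v for k, v in self.spectrum.items()}
        d["multi_error_freq"] = {str(k): v for k, v in self.multi_error_freq.items()}
        return d


def _summarize_one(records: Sequence[CDR3Record], cache: _ClassCache, q_cutoff: int) -> ProfileSummary:
    n_total = len(records)
    by_class: dict[str, int] = {c: 0 for c in CATEGORIES}
    spectrum_counts: dict[int, int] = {}
    unique_err: set[str] = set()
    unique_by_sample: dict[str, set[str]] = {}
    for r in records:
        cl = cache(r)
        by_class[cl.category] += 1
        if cl.category == "substitution":
            spectrum_counts[cl.n_subs] = spectrum_counts.get(cl.n_subs, 0) + 1
        if cl.category != "correct":
            seq = _seq_of(r)
            unique_err.add(seq)
            sample = str(r.sample_path) if isinstance(r, CDR3Record) else "all"
            unique_by_sample.setdefault(sample, set()).add(seq)
    n_error = n_total - by_class["correct"]
    n_sub = by_class["substitution"]
    return ProfileSummary(
        q_cutoff=q_cutoff,
        n_total=n_total,
        n_error=n_error,
        error_percent=(100.0 * n_error / n_total) if n_total else None,
        n_unique_error=len(unique_err),
        unique_error_by_sample={k: len(v) for k, v in sorted(unique_by_sample.items())},
        length_class_percent={
            "substitution": (100.0 * by_class["substitution"] / n_error) if n_error else None,
            "truncated": (100.0 * by_class["truncated"] / n_error) if n_error else None,
            "elongated": (100.0 * by_class["elongated"] / n_error) if n_error else None,
        },
        spectrum={m: c / n_sub for m, c in sorted(spectrum_counts.items())} if n_sub else {},
        multi_error_freq={m: c / n_total for m, c in sorted(spectrum_counts.items())} if n_total else {},
    )


def summarize(
    records: Sequence[CDR3Record],
    reference_cdr3: str,
    q_cutoffs: Sequence[int] = (0, 10, 20, 30),
) -> dict[int, ProfileSummary]:
    """Per-cutoff error summaries, with exclusion percentages relative to q=0.

    For each cutoff the Phred filter is applied first; the summary then
    reports how selectively the cutoff removed erroneous vs correct
    sequences compared with the unfiltered (q=0) baseline.
    """
    records = list(records)
    cache = _ClassCache(reference_cdr3)
    base_pass, _ = phred_filter(records, 0)
    base = _summarize_one(base_pass, cache, 0)
    base_correct = base.n_total - base.n_error
    out: dict[int, ProfileSummary] = {}
    for q in q_cutoffs:
        passing, _ = phred_filter(records, q)
        summary = _summarize_one(passing, cache, q)
        n_correct = summary.n_total - summary.n_error
        if base_correct:
            summary.pct_correct_excluded = 100.0 * (1 - n_correct / base_correct)
        if base.n_error:
            summary.pct_error_excluded = 100.0 * (1 - summary.n_error / base.n_error)
        out[q] = summary
    return out


@dataclass
class SubstitutionMatrix:
    """Tidy position × substitution rate table for a fixed reference CDR3.

    ``data`` has one row per stratum × position × alternative nucleotide:
    the stratification columns (``by``), position (0-based in the CDR3),
    from_nt, to_nt, count, denominator (total accepted sequences in the
    stratum) and rate = count/denominator. Reverse-direction records are
    already in reference coordinates (the extractor oriented them).
    """

    reference: str
    by: tuple[str, ...]
    data: pd.DataFrame

    def rate(self, position: int, to_nt: str, **stratum) -> float:
        df = self.data
        mask = (df["position"] == position) & (df["to_nt"] == to_nt)
        for k, v in stratum.items():
            mask &= df[k] == v
        sel = df.loc[mask, "rate"]
        if sel.empty:
            raise KeyError((position, to_nt, stratum))
        return float(sel.iloc[0])

    def argmax(self) -> tuple[int, str, str]:
        """(position, from_nt, to_nt) of the highest-rate cell (summed over strata)."""
        agg = (
            self.data.groupby(["position", "from_nt", "to_nt"], sort=True)[["count", "denominator"]]
            .sum()
            .assign(rate=lambda d: d["count"] / d["denominator"].clip(lower=1))
        )
        pos, fr, to = agg["rate"].idxmax()
        return int(pos), fr, to

    def total_substitution_events(self) -> int:
        return int(self.data["count"].sum())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


_STRATUM_GETTERS = {
    "lane": lambda r: r.lane,
    "direction": lambda r: r.orientation,
    "sample_path": lambda r: r.sample_path,
}


def substitution_matrix(
    records: Sequence[CDR3Record],
    reference_cdr3: str,
    by: Sequence[str] = ("lane", "direction"),
) -> SubstitutionMatrix:
    """Count every (position, to_nt) substitution event per stratum.

    Only correct-length records contribute substitution counts; denominators
    are the total records in each stratum (correct ones included), so each
    cell's rate is "fraction of accepted sequences carrying this particular
    substitution" — multi-error sequences contribute to several cells.
    """
    by = tuple(by)
    for key in by:
        if key not in _STRATUM_GETTERS:
            raise ValueError(f"unknown stratification key {key!r}")
    cache = _ClassCache(reference_cdr3)
    L = len(reference_cdr3)
    counts: dict[tuple, int] = {}
    denoms: dict[tuple, int] = {}
    for r in records:
        stratum = tuple(_STRATUM_GETTERS[k](r) for k in by)
        denoms[stratum] = denoms.get(stratum, 0) + 1
        cl = cache(r)
        for pos, _fr, to in cl.sub_list:
            key = (stratum, pos, to)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for stratum in sorted(denoms):
        denom = denoms[stratum]
        for pos in range(L):
            ref_nt = reference_cdr3[pos]
            for to in NT_ORDER:
                if to == ref_nt:
                    continue
                c = counts.get((stratum, pos, to), 0)
                rows.append((*stratum, pos, ref_nt, to, c, denom, c / denom))
    cols = [*by, "position", "from_nt", "to_nt", "count", "denominator", "rate"]
    return SubstitutionMatrix(reference=reference_cdr3, by=by, data=pd.DataFrame(rows, columns=cols))


def per_nt_substitution_rates(matrix: SubstitutionMatrix) -> pd.DataFrame:
    """Average substitution rate per origin nucleotide, split by read direction.

    For each of the 12 ordered substitutions from_nt→to_nt and each direction,
    the mean of the cell rates over reference positions bearing from_nt.
    Substitutions whose origin base is absent from the reference are flagged
    undefined. Requires a matrix stratified by direction.
    """
    if "direction" not in matrix.by:
        raise ValueError("matrix must be stratified by direction")
    df = matrix.data
    group_keys = ["direction", "from_nt", "to_nt"]
    # collapse any extra strata (e.g. lane) by pooling counts first
    pooled = (
        df.groupby(["direction", "position", "from_nt", "to_nt"], sort=True)[["count", "denominator"]]
        .sum()
        .reset_index()
    )
    pooled["rate"] = pooled["count"] / pooled["denominator"].clip(lower=1)
    rows = []
    directions = sorted(pooled["direction"].unique())
    for direction in directions:
        sub = pooled[pooled["direction"] == direction]
        for fr in NT_ORDER:
            cells = sub[sub["from_nt"] == fr]
            for to in NT_ORDER:
                if to == fr:
                    continue
                c = cells[cells["to_nt"] == to]
                defined = not c.empty
                rows.append(
                    (
                        direction,
                        fr,
                        to,
                        float(c["rate"].mean()) if defined else np.nan,
                        int(c.shape[0]),
                        defined,
                    )
                )
    return pd.DataFrame(rows, columns=["direction", "from_nt", "to_nt", "rate", "n_positions", "defined"])


@dataclass
class LaneCVResult:
    """Composite coefficients of variation of per-sample cell rates.

    ``lane_cv_mean ± lane_cv_sd`` summarizes CVs computed within each lane
    (across the samples loaded on it); ``pooled_cv_mean ± pooled_cv_sd`` are
    the lane-ignoring CVs across all samples — larger when lanes differ.
    Cells with zero mean rate have undefined CV and are excluded (counted).
    """

    lane_cv_mean: float
    lane_cv_sd: float
    pooled_cv_mean: float
    pooled_cv_sd: float
    n_undefined_lane: int
    n_undefined_pooled: int
    cell_cvs: pd.DataFrame = field(repr=False, default=None)


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=1) / mean)


def lane_cv(matrix: SubstitutionMatrix) -> LaneCVResult:
    """Composite CV of cell rates within lanes vs ignoring lanes.

    Requires a matrix stratified by ("lane", "sample_path") with >= 2 samples
    per lane.
    """
    if set(matrix.by) != {"lane", "sample_path"}:
        raise ValueError('matrix must be stratified by ("lane", "sample_path")')
    df = matrix.data
    for lane, g in df.groupby("lane"):
        if g["sample_path"].nunique() < 2:
            raise ValueError(f"lane {lane} has fewer than 2 samples")
    lane_rows = []
    for (lane, pos, to), g in df.groupby(["lane", "position", "to_nt"], sort=True):
        lane_rows.append((lane, pos, to, _cv(g["rate"].to_numpy())))
    lane_df = pd.DataFrame(lane_rows, columns=["lane", "position", "to_nt", "cv"])
    pooled_rows = []
    for (pos, to), g in df.groupby(["position", "to_nt"], sort=True):
        pooled_rows.append((pos, to, _cv(g["rate"].to_numpy())))
    pooled_df = pd.DataFrame(pooled_rows, columns=["position", "to_nt", "cv"])
    lv = lane_df["cv"].dropna()
    pv = pooled_df["cv"].dropna()
    return LaneCVResult(
        lane_cv_mean=float(lv.mean()) if len(lv) else np.nan,
        lane_cv_sd=float(lv.std(ddof=1)) if len(lv) > 1 else np.nan,
        pooled_cv_mean=float(pv.mean()) if len(pv) else np.nan,
        pooled_cv_sd=float(pv.std(ddof=1)) if len(pv) > 1 else np.nan,
        n_undefined_lane=int(lane_df["cv"].isna().sum()),
        n_undefined_pooled=int(pooled_df["cv"].isna().sum()),
        cell_cvs=lane_df,
    )


@dataclass
class AnovaResult:
    """Per-cell one-way ANOVA of per-sample rates grouped by lane."""

    table: pd.DataFrame
    fraction_significant: float
    alpha: float = 0.05


def lane_anova(matrix: SubstitutionMatrix, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA per (position, substitution) cell.

    Per-sample rates are grouped by lane; cells where every rate is identical
    (no variance anywhere) get p = 1 by convention. Raw rates, raw p-values
    (no transform, no multiplicity correction) — the reported quantity is the
    fraction of cells with p < alpha.
    """
    if set(matrix.by) != {"lane", "sample_path"}:
        raise ValueError('matrix must be stratified by ("lane", "sample_path")')
    df = matrix.data
    rows = []
    for (pos, fr, to), g in df.groupby(["position", "from_nt", "to_nt"], sort=True):
        groups = [lg["rate"].to_numpy() for _, lg in g.groupby("lane", sort=True)]
        if len(groups) < 2 or any(len(x) < 2 for x in groups):
            raise ValueError("need >= 2 lanes with >= 2 samples each")
        values = np.concatenate(groups)
        if np.allclose(values, values[0]):
            f_stat, p = 0.0, 1.0
        else:
            with np.errstate(all="ignore"):
                f_stat, p = stats.f_oneway(*groups)
            if np.isnan(p):
                p = 1.0
        rows.append((pos, fr, to, float(f_stat), float(p)))
    table = pd.DataFrame(rows, columns=["position", "from_nt", "to_nt", "F", "p"])
    frac = float((table["p"] < alpha).mean()) if len(table) else np.nan
    return AnovaResult(table=table, fraction_significant=frac, alpha=alpha)
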