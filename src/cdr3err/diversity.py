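"""Clonotype richness estimation (ACE) and before/after-filter reporting.

The abundance-based coverage estimator (Chao & Lee) splits clonotypes at a
rare/abundant cutoff k (10 by default, the EstimateS convention "n = 10"):

    S_rare  = number of clonotypes with count <= k
    S_abund = number with count > k
    F_i     = number of clonotypes with count exactly i
    N_rare  = sum_{i<=k} i * F_i
    C_ace   = 1 - F1 / N_rare                       (sample coverage)
    gamma^2 = max[(S_rare/C_ace) * sum_{i<=k} i(i-1)F_i / (N_rare (N_rare-1)) - 1, 0]

    ACE = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2

When every rare clonotype is a singleton the coverage estimate is 0 and ACE
is undefined; the estimator then falls back to bias-corrected Chao1 with
F2 = 0, i.e. S_obs + F1(F1-1)/2, and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class AceResult:
    estimate: float
    s_obs: int
    s_rare: int
    s_abund: int
    f1: int
    n_rare: int
    c_ace: float | None
    gamma2: float | None
    method: str  # "ace", "chao1_fallback", or "no_rare"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def ace(abundances: Sequence[int], rare_cutoff: int = 10) -> AceResult:
    """Abundance-based coverage estimate of clonotype richness.

    ``abundances`` are per-clonotype read counts (all >= 1); order is
    irrelevant. ACE >= S_obs whenever the coverage estimate is in (0, 1].
    """
    counts = np.asarray(abundances)
    if counts.size == 0:
        raise ValueError("abundance vector is empty")
    if (counts < 1).any():
        raise ValueError("all abundances must be >= 1")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("abundances must be integer counts")
        counts = np.round(counts).astype(np.int64)
    s_obs = int(counts.size)
    rare = counts[counts <= rare_cutoff]
    s_rare = int(rare.size)
    s_abund = s_obs - s_rare
    f1 = int((counts == 1).sum())
    n_rare = int(rare.sum())
    if s_rare == 0:
        return AceResult(float(s_abund), s_obs, 0, s_abund, 0, 0, None, None, "no_rare")
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0
        return AceResult(float(chao1), s_obs, s_rare, s_abund, f1, n_rare, 0.0, None, "chao1_fallback")
    if n_rare > 1:
        sum_iim1 = float((rare * (rare - 1)).sum())
        gamma2 = max((s_rare / c_ace) * sum_iim1 / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    estimate = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return AceResult(float(estimate), s_obs, s_rare, s_abund, f1, n_rare, c_ace, gamma2, "ace")


def richness_report(table_q0, table_q30, rare_cutoff: int = 10) -> dict:
    """Totals, unique clonotypes and ACE before and after quality filtering.

    Takes paired clone tables built from the same reads without filtering
    (q=0) and with a q=30 filter, and reports each cohort's total reads,
    unique clonotypes and ACE, plus the percent reduction from filtering.
    """
    def _one(table) -> dict:
        counts = table.df["total_count"].to_numpy()
        return {
            "total_reads": int(counts.sum()),
            "unique_clonotypes": int(len(counts)),
            "ace": ace(counts, rare_cutoff).estimate if len(counts) else 0.0,
        }

    q0, q30 = _one(table_q0), _one(table_q30)

    def _reduction(a: float, b: float) -> float | None:
        return 100.0 * (1 - b / a) if a else None

    return {
        "q0": q0,
        "q30": q30,
        "reduction_percent": {
            "total_reads": _reduction(q0["total_reads"], q30["total_reads"]),
            "unique_clonotypes": _reduction(q0["unique_clonotypes"], q30["unique_clonotypes"]),
            "ace": _reduction(q0["ace"], q30["ace"]),
        },
        "rare_cutoff": rare_cutoff,
    }
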