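"""Analytic models for error multiplicity, read-direction skew, and culling.

Three small exact-probability tools:

* the independence expectation for multi-substitution reads,
  ``p = C(N, M) · SER^M`` with ``C = N!/(M!(N−M)!)`` — observed excess over
  this expectation ("complementation") indicates correlated error formation;
* exact-binomial boundaries on the forward-read count of a clonotype, the
  per-tail <1% limits between which ~98% of direction-neutral sequences
  should fall;
* culling-count thresholds for low-count index sequences: the naive
  ``index_count × cutoff`` rule, and the binomially adjusted smallest count
  k whose Binomial(index_count, cutoff) CDF reaches a target confidence.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom


class ModelBreakdownWarning(UserWarning):
    """The independence formula produced p > 1 (SER too large for it)."""


def expected_multi_error_rate(
    ser: float, m: int, n: int, include_survival: bool = False
) -> float:
    """Expected per-sequence frequency of exactly ``m`` substitutions.

    ``ser`` is the per-position single-error rate, ``n`` the CDR3 length in
    nucleotides. The default is the plain combinatorial form
    ``C(n, m)·ser^m``; with ``include_survival`` the binomial factor
    ``(1−ser)^(n−m)`` is included (the two agree to <1% for ser ≲ 1e-4 at
    CDR3-scale n). Computed in log space for stability; p > 1 is flagged as
    model breakdown.
    """
    if not 0 <= ser <= 1:
        raise ValueError("ser must be in [0, 1]")
    if not 0 < m <= n:
        raise ValueError("require 0 < m <= n")
    if ser == 0:
        return 0.0
    log_c = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    log_p = log_c + m * np.log(ser)
    if include_survival and ser < 1:
        log_p += (n - m) * np.log1p(-ser)
    p = float(np.exp(log_p))
    if p > 1:
        warnings.warn(
            f"p = {p:.3g} > 1 for ser={ser}, m={m}, n={n}: independence "
            "approximation breaks down",
            ModelBreakdownWarning,
            stacklevel=2,
        )
    return p


def estimate_ser(multi_error_freq: Mapping[int, float], n: int) -> float:
    """Per-position single-error rate from an observed multiplicity spectrum.

    Defined as (fraction of sequences with exactly one substitution) / n, the
    per-position reading that makes ``C(n, m)·SER^m`` dimensionally consistent
    with per-sequence frequencies.
    """
    return float(multi_error_freq.get(1, 0.0)) / n


def complementation_test(
    multi_error_freq: Mapping[int, float],
    n: int,
    ser: float | None = None,
    m_values: Sequence[int] = range(2, 11),
    include_survival: bool = False,
) -> pd.DataFrame:
    """Observed vs expected multi-substitution frequencies.

    ``multi_error_freq`` maps M (number of substitutions) to the fraction of
    all accepted sequences carrying exactly M substitutions. The expectation
    assumes independent errors at rate ``ser`` per position (estimated from
    the M=1 frequency when not given). Ratios ≈ 1 indicate independent error
    formation; ratios > 1 indicate complementation (correlated errors).
    Undefined ratios (expected 0 with nonzero observed) are NaN.
    """
    if ser is None:
        ser = estimate_ser(multi_error_freq, n)
    rows = []
    for m in m_values:
        observed = float(multi_error_freq.get(m, 0.0))
        expected = (
            expected_multi_error_rate(ser, m, n, include_survival) if ser > 0 else 0.0
        )
        ratio = observed / expected if expected > 0 else np.nan
        rows.append((m, observed, expected, ratio))
    return pd.DataFrame(rows, columns=["M", "observed", "expected", "ratio"])


def binom_boundaries(n: int, p_fwd: float, tail: float = 0.01) -> tuple[int, int]:
    """Exact-binomial direction boundaries for a clonotype read ``n`` times.

    ``upper`` is the smallest integer k with P(X > k) < tail and ``lower`` the
    largest k with P(X < k) < tail under X ~ Binomial(n, p_fwd): the counts
    outside [lower, upper] are each seen with per-tail probability < tail
    (ties broken toward wider intervals). With tail = 0.01 at least 98% of
    direction-neutral clonotypes fall inside.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < p_fwd < 1:
        raise ValueError("p_fwd must be in (0, 1)")
    if not 0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")

    upper = int(binom.isf(tail, n, p_fwd))
    upper = min(max(upper, 0), n)
    while upper < n and binom.sf(upper, n, p_fwd) >= tail:
        upper += 1
    while upper > 0 and binom.sf(upper - 1, n, p_fwd) < tail:
        upper -= 1

    lower = int(binom.ppf(tail, n, p_fwd))
    lower = min(max(lower, 0), n)
    while lower > 0 and binom.cdf(lower - 1, n, p_fwd) >= tail:
        lower -= 1
    while lower < n and binom.cdf(lower, n, p_fwd) < tail:
        lower += 1

    return lower, upper


def cull_threshold(
    index_count: int,
    cutoff: float,
    confidence: float = 0.95,
    mode: str = "binomial",
) -> float | int:
    """Culling-count threshold for single-mismatch sequences near an index.

    ``naive`` mode returns the real-valued ``index_count × cutoff``. In
    ``binomial`` mode the threshold is the smallest integer k such that the
    Binomial(index_count, cutoff) CDF at k is at least ``confidence``:
    culling every mismatch sequence seen k or fewer times eliminates, with at
    least that confidence, any error sequence whose true frequency is
    ``cutoff`` of the index. (At index 200 and cutoff 0.5% the naive rule
    culls only singletons, while 95% confidence requires culling counts up
    to 3.)
    """
    if index_count < 1:
        raise ValueError("index_count must be >= 1")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    if mode == "naive":
        return index_count * cutoff
    if mode != "binomial":
        raise ValueError("mode must be 'naive' or 'binomial'")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    k = int(binom.ppf(confidence, index_count, cutoff))
    k = min(max(k, 0), index_count)
    while k > 0 and binom.cdf(k - 1, index_count, cutoff) >= confidence:
        k -= 1
    while k < index_count and binom.cdf(k, index_count, cutoff) < confidence:
        k += 1
    return k
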