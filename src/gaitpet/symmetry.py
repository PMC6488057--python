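"""Inter-limb symmetry: SI/ASI, ASI summaries, normality screen, exact signed-rank test.

The symmetry index of muscle i compares the dominant (d) and non-dominant (n)
limb values relative to their mean:

    SI_i  = 100% * (d - n) / ((d + n) / 2)        in [-200%, 200%]
    ASI_i = |SI_i|                                in [0%, 200%]

SI is antisymmetric under limb swap and invariant under a common positive
rescaling of both limbs, so it applies equally to SUV (g/mL) and AUV (g).

Paired dominant vs non-dominant comparisons use the Wilcoxon matched-pair
signed-rank test, computed exactly for small samples by enumerating all 2^n
sign assignments (midranks for tied |differences|, zero differences dropped),
with a normal approximation above n = 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LimbPair",
    "SymmetryResult",
    "SignedRankResult",
    "symmetry_index",
    "absolute_symmetry_index",
    "symmetry_result",
    "summarize_asymmetry",
    "paired_signed_rank_test",
    "normality_screen",
    "select_largest_muscles",
    "holm_correction",
]

EXACT_ENUMERATION_MAX_N = 20


@dataclass
class LimbPair:
    """One muscle's value (SUV or AUV) on both limbs of one subject."""

    muscle_name: str
    value_dominant: float
    value_non_dominant: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.value_dominant < 0 or self.value_non_dominant < 0:
            raise ValueError("limb values must be non-negative")


@dataclass
class SymmetryResult:
    si: float
    asi: float


@dataclass
class SignedRankResult:
    """Two-sided signed-rank test result.

    ``statistic`` is W+, the sum of midranks of positive differences after
    dropping zeros. ``exact`` marks enumeration (vs normal approximation);
    ``degenerate`` marks the all-zero-differences case (p fixed at 1).
    """

    p_value: float
    statistic: float
    n_used: int
    exact: bool
    degenerate: bool = False


def _pair_values(pair_or_d, n=None) -> tuple[float, float]:
    if n is None:
        return float(pair_or_d.value_dominant), float(pair_or_d.value_non_dominant)
    return float(pair_or_d), float(n)


def symmetry_index(pair_or_dominant, non_dominant: float | None = None) -> float:
    """SI in percent; accepts a LimbPair or the two limb values."""
    d, n = _pair_values(pair_or_dominant, non_dominant)
    if d + n <= 0:
        raise ValueError("symmetry index undefined when both limb values are zero")
    return 100.0 * (d - n) / ((d + n) / 2.0)


def absolute_symmetry_index(pair_or_dominant, non_dominant: float | None = None) -> float:
    """ASI = |SI| in percent; invariant under limb swap."""
    return abs(symmetry_index(pair_or_dominant, non_dominant))


def symmetry_result(pair: LimbPair) -> SymmetryResult:
    si = symmetry_index(pair)
    return SymmetryResult(si=si, asi=abs(si))


def summarize_asymmetry(
    asi_by_subject: Sequence[float],
    threshold: float = 25.0,
    subject_ids: Sequence[str] | None = None,
) -> dict:
    """Median/range ASI summary with a strict count of subjects above threshold."""
    asi = np.asarray(asi_by_subject, dtype=float)
    if asi.size == 0:
        raise ValueError("empty ASI list")
    if subject_ids is None:
        subject_ids = [str(i + 1) for i in range(asi.size)]
    above = asi > threshold  # strict, so a subject exactly at threshold is not counted
    return {
        "median": float(np.median(asi)),
        "min": float(asi.min()),
        "max": float(asi.max()),
        "n_above_threshold": int(above.sum()),
        "subject_ids_above": [str(s) for s, a in zip(subject_ids, above) if a],
    }


def _midranks(abs_diffs: np.ndarray) -> np.ndarray:
    return stats.rankdata(abs_diffs, method="average")


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p by full enumeration of sign assignments.

    Midranks are multiples of 0.5, so doubling them gives integers and the
    null distribution of 2*W+ is built by dynamic-programming convolution
    (equivalent to enumerating all 2^n sign patterns).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_obs))
    p_ge = counts[w2:].sum()
    p_le = counts[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_signed_rank_test(diffs: Sequence[float]) -> SignedRankResult:
    """Two-sided Wilcoxon matched-pair signed-rank test on paired differences.

    Zeros are dropped before ranking. Exact enumeration for n <= 20 (handles
    ties via midranks); tie-corrected normal approximation with continuity
    correction above.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        return SignedRankResult(p_value=1.0, statistic=0.0, n_used=0, exact=True, degenerate=True)
    n = d.size
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(ranks, w_pos)
        return SignedRankResult(p_value=p, statistic=w_pos, n_used=n, exact=True)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SignedRankResult(p_value=p, statistic=w_pos, n_used=n, exact=False)


def normality_screen(values: Sequence[float], alpha: float = 0.05) -> dict:
    """One-sample Kolmogorov-Smirnov screen against a fitted normal.

    The reference normal uses the sample mean and SD (the classical screen;
    known to be anticonservative with estimated parameters). Constant samples
    are degenerate and flagged as rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality screen needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return {"statistic": float("nan"), "p_value": 0.0, "reject_at_0.05": True, "degenerate": True}
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "reject_at_0.05": bool(p <= alpha),
        "degenerate": False,
    }


def select_largest_muscles(volumes_by_muscle: dict[str, float], segments: dict[str, str], per_segment: int = 5) -> list[str]:
    """Pick the ``per_segment`` largest muscles (by volume) in each segment.

    ``volumes_by_muscle`` maps muscle name to a representative volume (e.g.
    mean over subjects and limbs); ties are broken by name order.
    """
    chosen: list[str] = []
    by_segment: dict[str, list[str]] = {}
    for m in volumes_by_muscle:
        by_segment.setdefault(segments[m], []).append(m)
    for seg in sorted(by_segment):
        ranked = sorted(by_segment[seg], key=lambda m: (-volumes_by_muscle[m], m))
        chosen.extend(ranked[:per_segment])
    return chosen


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; the default analysis is uncorrected)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
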