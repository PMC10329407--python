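"""Statistical moments, group summaries, significance and diagnostic power.

Feature distributions (scan-count profiles, wavelet scale lines, raw
invariant maps) are summarized by their central statistical moments: mean
Z1 = M, dispersion Z2 = D (population variance), skewness Z3 and excess
kurtosis Z4.  Two-group differentiation is quantified by sensitivity
Se = p/(p+g)*100%, specificity Sp = c/(c+d)*100% and balanced accuracy
Ac = 0.5*(Se+Sp), where p/g count correct/incorrect diagnoses in the case
group and c/d in the control group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "MomentSet",
    "central_moments",
    "DiagnosticPower",
    "diagnostic_power",
    "SignificanceResult",
    "group_significance",
    "GroupSummary",
    "group_summary",
]


@dataclass(frozen=True)
class MomentSet:
    """Central statistical moments Z1 (mean), Z2 (dispersion), Z3, Z4.

    Z3 and Z4 are NaN with ``degenerate=True`` when Z2 = 0.
    """

    Z1: float
    Z2: float
    Z3: float
    Z4: float
    degenerate: bool = False


def central_moments(values: Sequence[float]) -> MomentSet:
    """Moments of a sample: mean, population variance, skewness, excess kurtosis.

    Z3 = m3 / Z2^(3/2) and Z4 = m4 / Z2^2 - 3 with central moments m_k; both
    are flagged undefined (NaN) for a constant sample.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("central_moments requires a non-empty input")
    z1 = float(v.mean())
    d = v - z1
    z2 = float(np.mean(d * d))
    # constant input up to rounding: higher moments are undefined
    if z2 <= 1e-28 * max(1.0, z1 * z1):
        return MomentSet(Z1=z1, Z2=0.0, Z3=float("nan"), Z4=float("nan"), degenerate=True)
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return MomentSet(Z1=z1, Z2=z2, Z3=m3 / z2**1.5, Z4=m4 / z2**2 - 3.0)


@dataclass(frozen=True)
class DiagnosticPower:
    """Operating characteristics of a two-group scalar feature.

    ``p``/``g`` are correct/incorrect case diagnoses, ``c``/``d``
    correct/incorrect control diagnoses; Se, Sp, Ac are percentages and
    Ac = 0.5*(Se+Sp) holds exactly.
    """

    se: float
    sp: float
    ac: float
    p: int
    g: int
    c: int
    d: int
    degenerate: bool = False

    @classmethod
    def from_counts(cls, p: int, g: int, c: int, d: int, degenerate: bool = False):
        if min(p, g, c, d) < 0 or p + g == 0 or c + d == 0:
            raise ValueError("need non-negative counts with non-empty groups")
        se = 100.0 * p / (p + g)
        sp = 100.0 * c / (c + d)
        return cls(se=se, sp=sp, ac=0.5 * (se + sp), p=p, g=g, c=c, d=d,
                   degenerate=degenerate)

    @staticmethod
    def balanced_accuracy(se: float, sp: float) -> float:
        """Ac from (possibly rounded/printed) Se and Sp percentages."""
        return 0.5 * (se + sp)


def _classify_midpoint(
    case: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out midpoint-threshold predictions (True = 'case')."""
    pred_case = np.zeros(case.size, dtype=bool)
    pred_ctrl = np.zeros(control.size, dtype=bool)
    mu_ctrl_full = control.mean()
    mu_case_full = case.mean()
    n_case, n_ctrl = case.size, control.size
    for i in range(n_case):
        mu_case = (mu_case_full * n_case - case[i]) / (n_case - 1) if n_case > 1 else mu_case_full
        thr = 0.5 * (mu_case + mu_ctrl_full)
        if mu_case > mu_ctrl_full:
            pred_case[i] = case[i] > thr
        elif mu_case < mu_ctrl_full:
            pred_case[i] = case[i] < thr
        # equal means: polarity undefined -> predict control
    for i in range(n_ctrl):
        mu_ctrl = (mu_ctrl_full * n_ctrl - control[i]) / (n_ctrl - 1) if n_ctrl > 1 else mu_ctrl_full
        thr = 0.5 * (mu_case_full + mu_ctrl)
        if mu_case_full > mu_ctrl:
            pred_ctrl[i] = control[i] > thr
        elif mu_case_full < mu_ctrl:
            pred_ctrl[i] = control[i] < thr
    return pred_case, pred_ctrl


def _classify_optimal(
    case: np.ndarray, control: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """In-sample threshold and polarity maximizing balanced accuracy."""
    pooled = np.unique(np.concatenate([case, control]))
    cands = np.concatenate([[pooled[0] - 1.0], 0.5 * (pooled[1:] + pooled[:-1]), [pooled[-1] + 1.0]])
    best = (-1.0, pooled[0], 1)
    for thr in cands:
        for pol in (1, -1):
            se = np.mean(pol * case > pol * thr)
            sp = np.mean(pol * control <= pol * thr)
            ba = 0.5 * (se + sp)
            if ba > best[0]:
                best = (ba, thr, pol)
    _, thr, pol = best
    return pol * case > pol * thr, pol * control > pol * thr


def diagnostic_power(
    case_values: Sequence[float],
    control_values: Sequence[float],
    threshold_rule: str = "midpoint",
) -> DiagnosticPower:
    """Se/Sp/Ac of a scalar feature separating a case from a control group.

    ``threshold_rule='midpoint'`` (default) classifies each sample against
    the midpoint of the two group means, with the sample itself left out of
    its own group mean and polarity set by the order of the means.
    ``'optimal'`` uses the in-sample threshold maximizing balanced accuracy.
    A feature constant and identical across both groups is degenerate:
    every sample is called control (Se=0, Sp=100, Ac=50, flagged).
    """
    case = np.asarray(case_values, dtype=float).ravel()
    control = np.asarray(control_values, dtype=float).ravel()
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")

    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return DiagnosticPower.from_counts(
            p=0, g=case.size, c=control.size, d=0, degenerate=True
        )

    if threshold_rule == "midpoint":
        pred_case, pred_ctrl = _classify_midpoint(case, control)
    elif threshold_rule == "optimal":
        pred_case, pred_ctrl = _classify_optimal(case, control)
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")

    p = int(pred_case.sum())
    g = case.size - p
    d = int(pred_ctrl.sum())  # controls called 'case' are incorrect
    c = control.size - d
    return DiagnosticPower.from_counts(p=p, g=g, c=c, d=d)


@dataclass(frozen=True)
class SignificanceResult:
    """Two-group significance: p-value with a degeneracy flag."""

    p_value: float
    degenerate: bool = False


def group_significance(groupA: Sequence[float], groupB: Sequence[float]) -> SignificanceResult:
    """Two-sided Mann-Whitney rank test between two independent groups.

    Chosen for robustness at small group sizes; an all-ties degenerate input
    returns p = 1 with a flag.
    """
    a = np.asarray(groupA, dtype=float).ravel()
    b = np.asarray(groupB, dtype=float).ravel()
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return SignificanceResult(p_value=1.0, degenerate=True)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return SignificanceResult(p_value=float(min(res.pvalue, 1.0)))


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean feature levels with across-sample standard deviations."""

    label: str
    n: int
    mean_M: float
    mean_D: float
    sd_M: float
    sd_D: float


def group_summary(
    per_sample_M: Sequence[float], per_sample_D: Sequence[float], label: str = ""
) -> GroupSummary:
    """Mean and SD (ddof=1) of per-sample means M and dispersions D."""
    m = np.asarray(per_sample_M, dtype=float)
    d = np.asarray(per_sample_D, dtype=float)
    if m.size != d.size or m.size == 0:
        raise ValueError("M and D must be equally sized and non-empty")
    sd_m = float(m.std(ddof=1)) if m.size >= 2 else float("nan")
    sd_d = float(d.std(ddof=1)) if d.size >= 2 else float("nan")
    return GroupSummary(label=label, n=int(m.size), mean_M=float(m.mean()),
                        mean_D=float(d.mean()), sd_M=sd_m, sd_D=sd_d)
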