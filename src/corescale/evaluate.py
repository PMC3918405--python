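"""Seven statistics comparing a subcore collection to its initial collection.

MD      percent of traits whose means differ significantly (pooled t-test)
VD      percent of traits whose variances differ significantly (F-test)
CR      mean percent of each trait's range retained by the subset
VR      mean percent ratio of subset to initial coefficient of variation
CR_max  mean percent ratio of subset to initial maximum
CR_min  mean percent ratio of initial to subset minimum (inverted so that
        a subset whose minimum drifts upward scores below 100)
CR_mea  mean percent ratio of subset to initial mean

All statistics are computed on unstandardized trait values, and the subset
is compared against the full initial collection.  Ratio terms with a zero
denominator, or whose numerator and denominator differ in sign, are
excluded from that statistic's average and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import TraitMatrix

PARAMETERS = ("MD", "VD", "CR", "VR", "CR_max", "CR_min", "CR_mea")

__all__ = ["PARAMETERS", "EvaluationReport", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    MD: float
    VD: float
    CR: Optional[float]
    VR: Optional[float]
    CR_max: Optional[float]
    CR_min: Optional[float]
    CR_mea: Optional[float]
    n_traits: int
    S_t: int
    S_F: int
    alpha: float
    detail: pd.DataFrame = field(repr=False)
    exclusions: tuple = ()

    def parameter(self, name: str) -> Optional[float]:
        if name not in PARAMETERS:
            raise KeyError(f"unknown evaluation parameter {name!r}")
        return getattr(self, name)


def _ratio(num: float, den: float):
    """Percent ratio, or an exclusion reason."""
    if den == 0:
        return None, "zero denominator"
    if num * den < 0:
        return None, "numerator and denominator differ in sign"
    return 100.0 * num / den, None


def _mean_or_none(values):
    return float(np.mean(values)) if values else None


def evaluate(initial: TraitMatrix, core_ids: Iterable[str],
             alpha: float = 0.05) -> EvaluationReport:
    """Score the subset ``core_ids`` against the initial collection."""
    core = initial.subset(core_ids)
    if core.n_accessions < 2:
        raise ValueError("a subcore needs at least 2 accessions")
    n = initial.n_traits

    rows, exclusions = [], []
    cr, vr, cmax, cmin, cmea = [], [], [], [], []
    s_t = s_f = 0
    for t in range(n):
        name = initial.trait_names[t]
        xi, xc = initial.values[:, t], core.values[:, t]

        t_stat, t_p = stats.ttest_ind(xc, xi, equal_var=True)
        vi, vc = xi.var(ddof=1), xc.var(ddof=1)
        if vi == 0 and vc == 0:
            f_p = 1.0
        elif vi == 0 or vc == 0:
            f_p = 0.0
        else:
            F = vc / vi
            dist = stats.f(len(xc) - 1, len(xi) - 1)
            f_p = 2 * min(dist.cdf(F), dist.sf(F))
        sig_mean = bool(t_p < alpha)
        sig_var = bool(f_p < alpha)
        s_t += sig_mean
        s_f += sig_var

        def push(stat_name, num, den, bucket):
            val, reason = _ratio(num, den)
            if val is None:
                exclusions.append((name, stat_name, reason))
            else:
                bucket.append(val)
            return val

        r_c, r_i = np.ptp(xc), np.ptp(xi)
        cr_t = push("CR", r_c, r_i, cr)
        mi, mc = xi.mean(), xc.mean()
        if mi == 0 or mc == 0:
            exclusions.append((name, "VR", "CV undefined at zero mean"))
            vr_t = None
        else:
            vr_t = push("VR", np.sqrt(vc) / mc, np.sqrt(vi) / mi, vr)
        cmax_t = push("CR_max", xc.max(), xi.max(), cmax)
        cmin_t = push("CR_min", xi.min(), xc.min(), cmin)  # inverted ratio
        cmea_t = push("CR_mea", mc, mi, cmea)

        rows.append({"trait": name, "t_p": float(t_p), "F_p": float(f_p),
                     "mean_significant": sig_mean,
                     "variance_significant": sig_var,
                     "CR": cr_t, "VR": vr_t, "CR_max": cmax_t,
                     "CR_min": cmin_t, "CR_mea": cmea_t})

    detail = pd.DataFrame(rows)
    return EvaluationReport(
        MD=100.0 * s_t / n, VD=100.0 * s_f / n,
        CR=_mean_or_none(cr), VR=_mean_or_none(vr),
        CR_max=_mean_or_none(cmax), CR_min=_mean_or_none(cmin),
        CR_mea=_mean_or_none(cmea),
        n_traits=n, S_t=s_t, S_F=s_f, alpha=alpha,
        detail=detail, exclusions=tuple(exclusions))
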