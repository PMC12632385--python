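"""Sex-stratified p-value combination and stratified FDR control.

Per-sex p-values from the time-course differential test are combined with
Fisher's sum-of-logs statistic, X^2 = -2(ln p_M + ln p_F), which is
chi-square distributed with 4 degrees of freedom under the joint null
(2 p-values, 2 df each). The combined "training p-value" is then adjusted
by Benjamini-Hochberg within each tissue stratum ("bh_by_tissue"), a fully
specifiable stand-in for covariate-weighted FDR procedures that preserves
per-tissue calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: p-values are floored here before taking logs so underflowed inputs do
#: not produce infinite statistics.
P_FLOOR = 1e-300

FISHER_DF = 4  # 2 sexes x 2 df per p-value

#: label stamped on outputs to flag the FDR procedure in use
FDR_PROCEDURE = "bh_by_tissue"


@dataclass(frozen=True)
class CombinedP:
    feature_id: str
    x2: float
    p_combined: float
    q: float | None = None


def _validate_p(p: np.ndarray, name: str) -> None:
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(f"{name}: p-values must lie in (0, 1]")


def fisher_combine(p_male, p_female):
    """Fisher sum-of-logs combination of male and female p-values.

    Returns ``(x2, p_combined)``; both arguments may be scalars or arrays.
    ``p_combined`` is the chi-square(4) upper-tail probability at ``x2``.
    """
    pm = np.asarray(p_male, dtype=float)
    pf = np.asarray(p_female, dtype=float)
    _validate_p(pm, "p_male")
    _validate_p(pf, "p_female")
    pm = np.maximum(pm, P_FLOOR)
    pf = np.maximum(pf, P_FLOOR)
    x2 = -2.0 * (np.log(pm) + np.log(pf))
    p_comb = stats.chi2.sf(x2, FISHER_DF)
    if np.ndim(p_male) == 0 and np.ndim(p_female) == 0:
        return float(x2), float(p_comb)
    return x2, p_comb


def bh_adjust(p_values, stratum_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, per stratum.

    Within each stratum independently, q_(i) = min_{j >= i} p_(j) * m / j,
    clipped at 1, mapped back to input order. With no strata the whole
    vector is one stratum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    _validate_p(p, "p_values")
    q = np.empty_like(p)
    if stratum_labels is None:
        strata = {None: np.arange(p.size)}
    else:
        labels = np.asarray(stratum_labels)
        if labels.size != p.size:
            raise ValueError("stratum_labels length mismatch")
        strata = {
            lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)
        }
    for idx in strata.values():
        ps = p[idx]
        m = ps.size
        order = np.argsort(ps, kind="stable")
        ranked = ps[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        qs = np.empty(m)
        qs[order] = adj
        q[idx] = qs
    return q


def combine_and_adjust(df: pd.DataFrame, stratum_col: str | None = None,
                       ) -> pd.DataFrame:
    """Combine per-sex p-values and BH-adjust for a table of features.

    ``df`` needs columns ``feature_id``, ``p_male``, ``p_female`` and, when
    ``stratum_col`` is given, that column too. Returns the table with
    ``x2``, ``p_combined``, ``q`` and ``fdr_procedure`` columns appended.
    """
    out = df.copy()
    x2, p_comb = fisher_combine(out["p_male"].to_numpy(),
                                out["p_female"].to_numpy())
    out["x2"] = x2
    out["p_combined"] = p_comb
    strata = out[stratum_col].to_numpy() if stratum_col else None
    out["q"] = bh_adjust(p_comb, strata)
    out["fdr_procedure"] = FDR_PROCEDURE
    return out
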