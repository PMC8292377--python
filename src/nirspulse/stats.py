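"""Cohort correlation analysis with normality gating and FDR control.

Procedure: each variable is gated once for normality (Lilliefors test at
the 5% level, on all available values of that variable); a correlation is
Pearson when both variables pass and Spearman otherwise; p-values over the
reported family are adjusted by Benjamini-Hochberg FDR at alpha = 0.05.
Missing cells are handled by pairwise deletion, so the n differs per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError

ALPHA_DEFAULT = 0.05

#: Default report layout: NiRS indices (rows) x comparator factors (columns).
INDEX_ROWS = ("TI", "PReFx")
FACTOR_COLS = ("CRF", "age", "AI_TCD", "PI_MRI")


@dataclass
class CorrelationResult:
    r: float
    p: float
    method: str              # "pearson" | "spearman"
    n: int
    x: str = ""
    y: str = ""
    significant_after_fdr: bool | None = None


def normality_gate(x, alpha: float = ALPHA_DEFAULT) -> bool:
    """True iff the Lilliefors test does not reject normality at ``alpha``.

    Degenerate (constant) vectors are reported non-normal rather than
    raising, since they carry no distributional evidence.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise InsufficientDataError("normality test needs n >= 4")
    if np.ptp(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return bool(p >= alpha)


def correlate(x, y, normal_x: bool, normal_y: bool,
              x_name: str = "", y_name: str = "") -> CorrelationResult:
    """Pearson iff both variables are normal, else Spearman; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise InsufficientDataError("correlation needs >= 3 complete pairs")
    if normal_x and normal_y:
        r, p = sstats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sstats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(r=float(r), p=float(p), method=method,
                             n=len(x), x=x_name, y=y_name)


def fdr_adjust(results: list[CorrelationResult],
               alpha: float = ALPHA_DEFAULT) -> list[CorrelationResult]:
    """Benjamini-Hochberg step-up over the family; sets significance flags."""
    if not results:
        raise InsufficientDataError("empty result family")
    pvals = [r.p for r in results]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for res, rej in zip(results, reject):
        res.significant_after_fdr = bool(rej)
    return results


def bh_stepup(pvals, alpha: float = ALPHA_DEFAULT) -> np.ndarray:
    """Reference Benjamini-Hochberg rejection mask (independent of above).

    Direct evaluation of the step-up criterion: reject all p <= p_(k) where
    k is the largest rank with p_(k) <= (k/m) * alpha.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) / m) * alpha
    below = np.nonzero(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if len(below):
        reject[order[: below[-1] + 1]] = True
    return reject


def report(table: pd.DataFrame,
           index_cols: tuple = INDEX_ROWS,
           factor_cols: tuple = FACTOR_COLS,
           alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Correlation-matrix report over the (index x factor) family.

    ``table`` has one row per subject and one column per variable; missing
    cells are allowed. Returns a tidy frame with one row per cell carrying
    r, p, method, n, FDR flag and the least-squares slope/intercept for
    scatter plotting. Entirely missing columns are omitted with a warning.
    """
    if len(table) < 3:
        raise InsufficientDataError("report needs >= 3 subjects")
    import warnings

    present_idx, present_fac = [], []
    for name, bucket in ((index_cols, present_idx), (factor_cols, present_fac)):
        for col in name:
            if col in table.columns and table[col].notna().sum() >= 3:
                bucket.append(col)
            else:
                warnings.warn(f"column {col!r} missing or empty; omitted",
                              stacklevel=2)
    normal = {col: normality_gate(table[col].dropna())
              for col in present_idx + present_fac}
    results, rows = [], []
    for ix in present_idx:
        for fac in present_fac:
            res = correlate(table[ix], table[fac], normal[ix], normal[fac],
                            x_name=ix, y_name=fac)
            results.append(res)
            sub = table[[ix, fac]].dropna()
            slope, intercept = np.polyfit(sub[fac], sub[ix], 1)
            rows.append({"index": ix, "factor": fac, "slope": float(slope),
                         "intercept": float(intercept)})
    fdr_adjust(results, alpha=alpha)
    out = pd.DataFrame([{
        "index": res.x, "factor": res.y, "r": res.r, "p": res.p,
        "method": res.method, "n": res.n,
        "significant_after_fdr": res.significant_after_fdr,
    } for res in results])
    fit = pd.DataFrame(rows)
    return out.merge(fit, on=["index", "factor"])
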