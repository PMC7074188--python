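"""Drug-sensitivity screening of candidate biomarker genes.

Cell lines are split at the median expression of each gene; a two-sided
Welch t-test compares IC50 between the High and Low halves (t > 0 means the
High-expression lines are more resistant).  Separately, each gene's
expression is scored as a ranking classifier for the resistant class
(IC50 above the across-line mean) via the Mann-Whitney AUC with midrank tie
handling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .stats import bh_adjust

__all__ = ["median_split", "ic50_ttest", "predictive_auc", "run_drug_screen"]


def median_split(values: pd.Series) -> pd.Series:
    """Split cell lines at the median; values >= median are High."""
    values = pd.Series(values).astype(float)
    if values.size < 4:
        raise ValueError("need at least 4 cell lines")
    if np.ptp(values.to_numpy()) == 0:
        raise ValueError("degenerate split: all values identical")
    med = float(np.median(values.to_numpy()))
    return pd.Series(np.where(values.to_numpy() >= med, "High", "Low"), index=values.index)


def ic50_ttest(ic50_high, ic50_low) -> tuple[float, float]:
    """Welch two-sided t-test on IC50 values, oriented High minus Low."""
    a = np.asarray(ic50_high, dtype=float)
    b = np.asarray(ic50_low, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means (infinite t)")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def predictive_auc(expression, ic50) -> float:
    """AUC of expression for predicting resistance (IC50 above the mean).

    Mann-Whitney formulation: the probability that a resistant line scores
    above a sensitive one, counting ties as 1/2.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(ic50, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression and ic50 must be paired 1-D vectors")
    resistant = y > y.mean()
    n_r = int(resistant.sum())
    n_s = int((~resistant).sum())
    if n_r == 0 or n_s == 0:
        raise ValueError("AUC undefined: one response class is empty")
    ranks = rankdata(x, method="average")
    u = ranks[resistant].sum() - n_r * (n_r + 1) / 2.0
    return float(u / (n_r * n_s))


def run_drug_screen(
    cellline_expr: pd.DataFrame,
    ic50_table: pd.DataFrame,
    genes: list[str],
) -> pd.DataFrame:
    """Full gene × compound screen: median split + Welch t + predictive AUC.

    Compounds measured on fewer than 4 shared cell lines are skipped; the
    skip count is attached as ``result.attrs['n_skipped']``.  ``adj_p`` is
    BH across the whole grid.
    """
    missing = [g for g in genes if g not in cellline_expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    shared = [c for c in cellline_expr.columns if c in ic50_table.index]
    rows = []
    skipped = 0
    for comp in ic50_table.columns:
        ic50_all = ic50_table.loc[shared, comp].astype(float)
        measured = ic50_all.dropna()
        if measured.size < 4:
            skipped += 1
            continue
        lines = list(measured.index)
        for g in genes:
            expr = cellline_expr.loc[g, lines].astype(float)
            groups = median_split(expr)
            hi = (groups == "High").to_numpy()
            vals = measured.to_numpy()
            t, p = ic50_ttest(vals[hi], vals[~hi])
            auc = predictive_auc(expr.to_numpy(), vals)
            rows.append(
                {
                    "gene": g,
                    "compound": comp,
                    "n_high": int(hi.sum()),
                    "n_low": int((~hi).sum()),
                    "mean_ic50_high": float(vals[hi].mean()),
                    "mean_ic50_low": float(vals[~hi].mean()),
                    "t": t,
                    "p": p,
                    "auc": auc,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "compound", "n_high", "n_low", "mean_ic50_high",
            "mean_ic50_low", "t", "p", "auc",
        ],
    )
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if not out.empty else pd.Series(dtype=float)
    out.attrs["n_skipped"] = skipped
    return out
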