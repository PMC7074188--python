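"""Two-group differential expression with an empirical-Bayes moderated t.

The comparison is always case group minus reference group on log2 values,
so ``log2_fc`` is directly the log2 fold change.  Per-feature variances are
shrunk toward a common prior fitted across all features (see
:mod:`mirmaster.stats`), which stabilises the t-statistic when per-group
sample sizes are small relative to the number of features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, squeeze_variances

__all__ = ["dedupe_features", "moderated_de", "select_regulators", "select_targets"]


def dedupe_features(expr: pd.DataFrame, id_map: dict[str, str]) -> pd.DataFrame:
    """Collapse duplicate features mapping to the same symbol.

    For each symbol the row with the maximal mean expression is kept; ties
    are broken by the lexicographically smallest original feature id.  The
    returned matrix is indexed by symbol, ordered by first appearance.
    """
    if expr.shape[0] == 0:
        return expr.copy()
    missing = [f for f in expr.index if f not in id_map]
    if missing:
        raise KeyError(f"id_map does not cover features: {missing[:5]}")
    means = expr.mean(axis=1)
    best: dict[str, str] = {}
    order: list[str] = []
    for fid in expr.index:
        sym = id_map[fid]
        if sym not in best:
            best[sym] = fid
            order.append(sym)
        else:
            cur = best[sym]
            # larger mean wins; on exact ties the smaller original id wins
            if means[fid] > means[cur] or (means[fid] == means[cur] and fid < cur):
                best[sym] = fid
    out = expr.loc[[best[s] for s in order]].copy()
    out.index = pd.Index(order, name=expr.index.name)
    return out


def moderated_de(
    expr: pd.DataFrame,
    labels: pd.Series,
    case: str = "squamous",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group differential expression.

    Parameters
    ----------
    expr : feature × sample log2 matrix.
    labels : sample → group label; samples not labelled ``case`` form the
        reference group.
    case : label of the case group (numerator of the fold change).
    prior_df : override the fitted prior degrees of freedom (0 recovers the
        ordinary pooled-variance t; ``inf`` fully trusts the prior).

    Returns a table with columns ``feature_id, log2_fc, t, p, adj_p``
    (BH across all rows).
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every sample column")
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    case_mask = (labels == case).to_numpy()
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"degenerate design: need >=2 samples per group, got {n1}/{n2}")

    x = expr.to_numpy(dtype=float)
    g1, g2 = x[:, case_mask], x[:, ~case_mask]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    lfc = m1 - m2
    df = n1 + n2 - 2
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df

    s2_post, d0, _ = squeeze_variances(s2, df, prior_df=prior_df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "feature_id": expr.index.astype(str),
            "log2_fc": lfc,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
        }
    ).reset_index(drop=True)


def select_regulators(
    de: pd.DataFrame, max_lfc: float = -0.5, alpha: float = 0.05
) -> list[str]:
    """Candidate regulators: adj_p < alpha and log2_fc < max_lfc (strict)."""
    keep = (de["adj_p"] < alpha) & (de["log2_fc"] < max_lfc)
    return de.loc[keep, "feature_id"].tolist()


def select_targets(
    de: pd.DataFrame, min_lfc: float = 0.25, alpha: float = 0.05
) -> list[str]:
    """Candidate target genes: adj_p < alpha and log2_fc > min_lfc (strict)."""
    keep = (de["adj_p"] < alpha) & (de["log2_fc"] > min_lfc)
    return de.loc[keep, "feature_id"].tolist()
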