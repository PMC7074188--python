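"""Direct-target prioritization and upstream methylation association.

A gene is called a direct target of a master miRNA when it sits in the
four-way intersection of (i) the miRNA's inferred regulon, (ii) the
phenotype signature gene set, and (iii, iv) two physical target-prediction
databases.  Each prioritized pair is annotated with the Spearman correlation
between the miRNA and gene expression profiles — true repressed targets
should be inversely correlated.

Promoter methylation is screened both for a subtype difference (two-sided
Wilcoxon rank-sum) and for association with the miRNA's own expression
(Spearman), emulating the search for an epigenetic cause of regulator
silencing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .netinf import TRN

__all__ = [
    "intersect_targets",
    "spearman",
    "evaluate_targets",
    "methylation_association",
]


def intersect_targets(
    regulon: set[str],
    signature: set[str],
    physical_a: set[str],
    physical_b: set[str],
) -> list[str]:
    """Exact four-way intersection, sorted for determinism."""
    for s in (regulon, signature, physical_a, physical_b):
        if s is None:
            raise ValueError("input sets may be empty but not None")
    return sorted(set(regulon) & set(signature) & set(physical_a) & set(physical_b))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; p from the t
    approximation t = rho * sqrt((n-2) / (1-rho^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if x.size < 5:
        raise ValueError("need at least 5 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def evaluate_targets(
    trn: TRN,
    signature: set[str],
    physical_a: dict[str, set[str]],
    physical_b: dict[str, set[str]],
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    regulators: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (regulator, prioritized gene) with membership flags and
    the miRNA–gene Spearman correlation, sorted by rho ascending.

    ``regulators`` restricts evaluation (e.g. to MRA-called masters); by
    default every regulon in the network is evaluated.  A prioritized gene
    missing from the gene expression matrix is reported with
    ``profile_missing = True`` rather than dropped.
    """
    if list(mirna_expr.columns) != list(gene_expr.columns):
        raise ValueError("expression matrices must share the sample axis")
    regulons = trn.regulons
    if regulators is None:
        regulators = sorted(regulons)
    rows = []
    for reg in regulators:
        regulon = regulons.get(reg, set())
        prioritized = intersect_targets(
            regulon, signature, physical_a.get(reg, set()), physical_b.get(reg, set())
        )
        for g in prioritized:
            missing = g not in gene_expr.index or reg not in mirna_expr.index
            if missing:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearman(
                    mirna_expr.loc[reg].to_numpy(), gene_expr.loc[g].to_numpy()
                )
            rows.append(
                {
                    "regulator": reg,
                    "gene": g,
                    "in_signature": True,
                    "in_regulon": True,
                    "in_physical_a": True,
                    "in_physical_b": True,
                    "profile_missing": missing,
                    "spearman_rho": rho,
                    "spearman_p": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "regulator", "gene", "in_signature", "in_regulon", "in_physical_a",
            "in_physical_b", "profile_missing", "spearman_rho", "spearman_p",
        ],
    )
    if not out.empty:
        out = out.sort_values("spearman_rho", kind="mergesort", na_position="last")
        out = out.reset_index(drop=True)
    return out


def methylation_association(
    meth: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    labels: pd.Series,
    case: str = "squamous",
) -> pd.DataFrame:
    """Per-miRNA promoter methylation screen.

    For every promoter row whose id matches a miRNA expression row:
    ``group_diff_p`` is a two-sided Wilcoxon rank-sum (normal approximation,
    tie-corrected) of methylation between case and reference samples, and
    ``meth_expr_rho/p`` the Spearman association between methylation and the
    miRNA's expression across all samples.  Unmatched promoters are skipped;
    their count is attached as ``result.attrs['n_skipped']``.
    """
    if list(meth.columns) != list(mirna_expr.columns):
        raise ValueError("methylation and expression must share the sample axis")
    labels = labels.reindex(meth.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every sample")
    case_mask = (labels == case).to_numpy()
    rows = []
    skipped = 0
    for mir in meth.index.astype(str):
        if mir not in mirna_expr.index:
            skipped += 1
            continue
        m = meth.loc[mir].to_numpy(dtype=float)
        e = mirna_expr.loc[mir].to_numpy(dtype=float)
        a, b = m[case_mask], m[~case_mask]
        if np.ptp(m) == 0:
            gp = 1.0
        else:
            gp = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
        if np.ptp(m) == 0 or np.ptp(e) == 0:
            rho, rp = np.nan, np.nan
        else:
            rho, rp = spearman(m, e)
        rows.append({"mirna": mir, "group_diff_p": gp, "meth_expr_rho": rho, "meth_expr_p": rp})
    out = pd.DataFrame(rows, columns=["mirna", "group_diff_p", "meth_expr_rho", "meth_expr_p"])
    out.attrs["n_skipped"] = skipped
    return out
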