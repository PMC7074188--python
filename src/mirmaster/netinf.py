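"""miRNA → gene regulatory network inference.

Three stages, mirroring the ARACNe family of algorithms:

1. **Mutual information + permutation filter.**  MI is the maximum-likelihood
   plug-in estimate on equal-frequency (quantile) bins of rank-transformed
   data, in nats.  For each regulator a permutation null is built by
   shuffling the regulator's sample labels; the permuted MI values against
   all targets are pooled, and each pair's permutation p-value is

       perm_p = (1 + count_ge / T) / (1 + n_perm)

   where ``count_ge`` counts pooled null values >= the observed MI and T is
   the number of targets, so the minimal achievable p is 1/(1+n_perm).
   Because that empirical p is floored at 1/(1+n_perm), it cannot resolve
   the far tail that multiple-testing correction over thousands of pairs
   requires; edge *selection* therefore uses a gamma distribution fitted by
   moments to the same pooled null (the plug-in MI null is asymptotically a
   scaled chi-square, which the gamma family contains), giving a continuous
   tail p-value.  Pairs are kept when the BH-adjusted fitted p falls below
   ``alpha``; both p-values are reported per edge.

2. **Bootstrap stability filter.**  Edges are re-scored on bootstrap
   resamples of the samples; in each resample an edge counts as supported
   when its MI exceeds the 95th percentile of a per-regulator permutation
   null computed on that same resample.  Edges with support below the
   consensus fraction are dropped.

3. **DPI pruning.**  Every triplet of two regulators and one shared target
   in which the regulator–regulator MI is available is scanned; the
   regulator–target edge with the smallest MI is marked for removal when it
   is smaller than both other MI values by a factor (1 - eps).  Removal is
   simultaneous after the full scan; regulator–regulator entries are never
   deleted.  Exact ties for the smallest value remove nothing.

All randomness flows from one master seed; the permutation and bootstrap
stages draw from independently spawned streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .stats import bh_adjust

__all__ = [
    "NetInfParams",
    "TRN",
    "mutual_information",
    "regulator_mi_matrix",
    "permutation_filter",
    "bootstrap_filter",
    "apply_dpi",
    "infer_trn",
]

_EDGE_COLUMNS = ["regulator", "target", "mi", "perm_p", "perm_p_fit", "adj_perm_p", "boot_support"]


@dataclass(frozen=True)
class NetInfParams:
    """Tunable parameters of the three-stage inference."""

    n_perm: int = 1000
    alpha: float = 0.01
    n_boot: int = 100
    consensus: float = 0.95
    eps: float = 0.0
    n_bins: int | None = None  # default: round(sqrt(n_samples))
    per_regulator_bh: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# binning and plug-in MI
# ---------------------------------------------------------------------------

def _default_bins(n: int) -> int:
    return max(2, int(round(np.sqrt(n))))


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per sample; ties share a bin (average ranks)."""
    n = x.shape[-1]
    r = rankdata(x, method="average", axis=-1)  # 1..n
    b = ((np.ceil(r).astype(np.int64) - 1) * n_bins) // n
    return np.minimum(b, n_bins - 1)


def _mi_from_counts(joint: np.ndarray, n: int) -> np.ndarray:
    """Plug-in MI (nats) from joint count arrays of shape (..., nb, nb)."""
    p = joint / n
    pi = p.sum(axis=-1, keepdims=True)
    pj = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        # grouping the marginal logs keeps the expression invariant under
        # transposition (float addition is commutative)
        term = p * (np.log(p) - (np.log(pi) + np.log(pj)))
    term = np.where(np.isfinite(term), term, 0.0)
    nb = term.shape[-1]
    flat = term.reshape(term.shape[:-2] + (nb * nb,))
    # summing in sorted order makes MI(x, y) == MI(y, x) bit-exactly
    # (the term matrices are transposes of each other)
    return np.sort(flat, axis=-1).sum(axis=-1)


def _joint_counts(reg_bins: np.ndarray, tgt_bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Joint counts of one regulator against T targets → (T, nb, nb)."""
    T, n = tgt_bins.shape
    codes = (reg_bins[None, :] * n_bins + tgt_bins) + (
        np.arange(T, dtype=np.int64)[:, None] * n_bins * n_bins
    )
    flat = np.bincount(codes.ravel(), minlength=T * n_bins * n_bins)
    return flat.reshape(T, n_bins, n_bins)


def _mi_profile(reg_bins: np.ndarray, tgt_bins: np.ndarray, n_bins: int) -> np.ndarray:
    return _mi_from_counts(_joint_counts(reg_bins, tgt_bins, n_bins), reg_bins.shape[0])


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Plug-in MI (nats) between two sample vectors on quantile bins of ranks.

    Constant vectors have zero MI with anything.  Symmetric and >= 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 paired samples")
    nb = n_bins if n_bins is not None else _default_bins(n)
    if nb < 2:
        raise ValueError("n_bins must be >= 2")
    bx = _bin_indices(x, nb)
    by = _bin_indices(y, nb)
    mi = float(_mi_profile(bx, by[None, :], nb)[0])
    return max(mi, 0.0)


def regulator_mi_matrix(reg_expr: pd.DataFrame, n_bins: int | None = None) -> pd.DataFrame:
    """Symmetric regulator–regulator MI matrix (zero diagonal)."""
    regs = list(reg_expr.index)
    n = reg_expr.shape[1]
    nb = n_bins if n_bins is not None else _default_bins(n)
    bins = _bin_indices(reg_expr.to_numpy(dtype=float), nb)
    out = np.zeros((len(regs), len(regs)))
    for i in range(len(regs)):
        if i + 1 < len(regs):
            mi = _mi_profile(bins[i], bins[i + 1:], nb)
            out[i, i + 1:] = mi
            out[i + 1:, i] = mi
    return pd.DataFrame(out, index=regs, columns=regs)


# ---------------------------------------------------------------------------
# TRN container
# ---------------------------------------------------------------------------

@dataclass
class TRN:
    """A regulator → target network with filtering provenance."""

    edges: pd.DataFrame                      # columns _EDGE_COLUMNS
    reg_reg_mi: pd.DataFrame                 # symmetric regulator × regulator
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.edges.columns) != _EDGE_COLUMNS:
            self.edges = self.edges.reindex(columns=_EDGE_COLUMNS)
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")

    @property
    def regulons(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for reg, sub in self.edges.groupby("regulator", sort=True):
            out[str(reg)] = set(sub["target"].astype(str))
        return out

    def n_edges(self) -> int:
        return len(self.edges)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "edges": self.edges.to_dict(orient="records"),
            "reg_reg_mi": {
                "regulators": list(self.reg_reg_mi.index.astype(str)),
                "matrix": self.reg_reg_mi.to_numpy().tolist(),
            },
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TRN":
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
        doc = json.loads(text)
        edges = pd.DataFrame(doc["edges"], columns=_EDGE_COLUMNS)
        edges = edges.astype(
            {"regulator": str, "target": str, "mi": float, "perm_p": float,
             "perm_p_fit": float, "adj_perm_p": float, "boot_support": float}
        )
        regs = doc["reg_reg_mi"]["regulators"]
        mat = pd.DataFrame(np.array(doc["reg_reg_mi"]["matrix"]).reshape(len(regs), len(regs)),
                           index=regs, columns=regs)
        return cls(edges=edges, reg_reg_mi=mat, provenance=doc.get("provenance", {}))

    def to_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.edges.iterrows():
                fh.write(f"{row['regulator']}\trepresses\t{row['target']}\n")


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "regulator": pd.Series(dtype=str),
            "target": pd.Series(dtype=str),
            "mi": pd.Series(dtype=float),
            "perm_p": pd.Series(dtype=float),
            "perm_p_fit": pd.Series(dtype=float),
            "adj_perm_p": pd.Series(dtype=float),
            "boot_support": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# stage 1: permutation filter
# ---------------------------------------------------------------------------

def _gamma_tail_p(null: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Continuous tail probability of ``obs`` under a gamma moment-fit of the
    pooled permutation null (falls back to the empirical tail when the null
    is degenerate)."""
    mean = float(null.mean())
    var = float(null.var())
    if var <= 0 or mean <= 0:
        count_ge = null.size - np.searchsorted(null, obs, side="left")
        return (1.0 + count_ge) / (1.0 + null.size)
    shape = mean * mean / var
    scale = var / mean
    return sps.gamma.sf(obs, shape, scale=scale)

def permutation_filter(
    reg_expr: pd.DataFrame,
    tgt_expr: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.01,
    n_bins: int | None = None,
    seed: int = 0,
    per_regulator_bh: bool = False,
) -> pd.DataFrame:
    """Score all regulator × target pairs and keep permutation-significant ones.

    Returns an edge table (one row per surviving pair) with observed MI,
    permutation p and its BH adjustment.
    """
    if list(reg_expr.columns) != list(tgt_expr.columns):
        raise ValueError("regulator and target matrices must share the sample axis")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = reg_expr.shape[1]
    nb = n_bins if n_bins is not None else _default_bins(n)
    regs = list(reg_expr.index.astype(str))
    tgts = list(tgt_expr.index.astype(str))
    if not regs or not tgts:
        return _empty_edges()

    reg_bins = _bin_indices(reg_expr.to_numpy(dtype=float), nb)
    tgt_bins = _bin_indices(tgt_expr.to_numpy(dtype=float), nb)
    T = len(tgts)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))

    rows = []
    for ri, reg in enumerate(regs):
        obs = _mi_profile(reg_bins[ri], tgt_bins, nb)
        null = np.empty(n_perm * T)
        for b in range(n_perm):
            perm = rng.permutation(reg_bins[ri])
            null[b * T:(b + 1) * T] = _mi_profile(perm, tgt_bins, nb)
        null.sort()
        count_ge = null.size - np.searchsorted(null, obs, side="left")
        perm_p = (1.0 + count_ge / T) / (1.0 + n_perm)
        p_fit = _gamma_tail_p(null, obs)
        for ti, tgt in enumerate(tgts):
            rows.append((reg, tgt, float(obs[ti]), float(perm_p[ti]), float(p_fit[ti])))

    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi", "perm_p", "perm_p_fit"])
    if per_regulator_bh:
        edges["adj_perm_p"] = edges.groupby("regulator")["perm_p_fit"].transform(
            lambda p: bh_adjust(p.to_numpy())
        )
    else:
        edges["adj_perm_p"] = bh_adjust(edges["perm_p_fit"].to_numpy())
    edges["boot_support"] = np.nan
    edges = edges[edges["adj_perm_p"] < alpha].reset_index(drop=True)
    return edges.reindex(columns=_EDGE_COLUMNS)


# ---------------------------------------------------------------------------
# stage 2: bootstrap filter
# ---------------------------------------------------------------------------

def bootstrap_filter(
    edges: pd.DataFrame,
    reg_expr: pd.DataFrame,
    tgt_expr: pd.DataFrame,
    n_boot: int = 100,
    consensus: float = 0.95,
    n_bins: int | None = None,
    seed: int = 0,
    n_null_perm: int = 10,
) -> pd.DataFrame:
    """Keep edges whose bootstrap support reaches the consensus fraction.

    Support = fraction of bootstrap resamples in which the edge's MI exceeds
    the 95th percentile of a per-regulator permutation null computed on the
    same resample (``n_null_perm`` regulator shuffles pooled over that
    regulator's candidate targets).
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    if edges.empty:
        out = edges.copy()
        return out.reindex(columns=_EDGE_COLUMNS)
    n = reg_expr.shape[1]
    nb = n_bins if n_bins is not None else _default_bins(n)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    reg_rows = {r: i for i, r in enumerate(reg_expr.index.astype(str))}
    tgt_rows = {t: i for i, t in enumerate(tgt_expr.index.astype(str))}
    by_reg: dict[str, np.ndarray] = {
        reg: sub["target"].map(tgt_rows).to_numpy()
        for reg, sub in edges.groupby("regulator", sort=True)
    }
    reg_mat = reg_expr.to_numpy(dtype=float)
    tgt_mat = tgt_expr.to_numpy(dtype=float)

    support = {reg: np.zeros(len(idx)) for reg, idx in by_reg.items()}
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        for reg, tgt_idx in by_reg.items():
            row = reg_mat[reg_rows[reg]]
            rbins = _bin_indices(row[take], nb)
            tbins = _bin_indices(tgt_mat[tgt_idx][:, take], nb)
            mi = _mi_profile(rbins, tbins, nb)
            # the null permutes regulator values in the ORIGINAL sample space
            # and then applies the same bootstrap indices, so the duplicate
            # structure of the resample (which itself inflates MI) is shared
            # by observed and null scores
            null = np.concatenate(
                [
                    _mi_profile(_bin_indices(row[rng.permutation(n)[take]], nb), tbins, nb)
                    for _ in range(n_null_perm)
                ]
            )
            thr = np.quantile(null, 0.95)
            support[reg] += mi > thr

    out = edges.copy().reset_index(drop=True)
    boot = np.empty(len(out))
    for reg, sub in out.groupby("regulator", sort=True):
        boot[sub.index.to_numpy()] = support[reg] / n_boot
    out["boot_support"] = boot
    out = out[out["boot_support"] >= consensus].reset_index(drop=True)
    return out.reindex(columns=_EDGE_COLUMNS)


# ---------------------------------------------------------------------------
# stage 3: DPI
# ---------------------------------------------------------------------------

def apply_dpi(trn: TRN, eps: float = 0.0) -> TRN:
    """Prune likely-indirect regulator–target edges via the data processing
    inequality.

    For every triplet (r1, r2, g) with both regulator–target edges present,
    the regulator–regulator MI must be available; a regulator–target edge is
    marked when its MI is the strict minimum of the triplet by factor
    (1 - eps), and all marked edges are removed after the full scan.
    """
    edges = trn.edges
    if edges.empty:
        out = TRN(edges=edges.copy(), reg_reg_mi=trn.reg_reg_mi.copy(),
                  provenance=dict(trn.provenance))
        out.provenance["edges_after_dpi"] = 0
        return out

    mi_of: dict[tuple[str, str], float] = {
        (row.regulator, row.target): row.mi for row in edges.itertuples()
    }
    targets_of: dict[str, set[str]] = {}
    for row in edges.itertuples():
        targets_of.setdefault(row.regulator, set()).add(row.target)

    regs = sorted(targets_of)
    rr = trn.reg_reg_mi
    removed: set[tuple[str, str]] = set()
    factor = 1.0 - eps
    for i, r1 in enumerate(regs):
        for r2 in regs[i + 1:]:
            shared = targets_of[r1] & targets_of[r2]
            if not shared:
                continue
            if r1 not in rr.index or r2 not in rr.columns:
                raise ValueError(f"missing regulator-regulator MI for pair ({r1}, {r2})")
            mi12 = float(rr.loc[r1, r2])
            for g in shared:
                mi1 = mi_of[(r1, g)]
                mi2 = mi_of[(r2, g)]
                if mi1 < factor * mi2 and mi1 < factor * mi12:
                    removed.add((r1, g))
                elif mi2 < factor * mi1 and mi2 < factor * mi12:
                    removed.add((r2, g))
                # smallest value on the regulator-regulator entry, or a tie:
                # nothing removed

    keep = ~edges.apply(lambda row: (row["regulator"], row["target"]) in removed, axis=1)
    out_edges = edges[keep].reset_index(drop=True)
    prov = dict(trn.provenance)
    prov["edges_removed_by_dpi"] = int(len(edges) - len(out_edges))
    prov["edges_after_dpi"] = int(len(out_edges))
    return TRN(edges=out_edges, reg_reg_mi=trn.reg_reg_mi.copy(), provenance=prov)


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def infer_trn(
    reg_expr: pd.DataFrame,
    tgt_expr: pd.DataFrame,
    params: NetInfParams = NetInfParams(),
) -> TRN:
    """Permutation filter → bootstrap filter → DPI, with provenance counts."""
    if reg_expr.shape[0] == 0 or tgt_expr.shape[0] == 0:
        prov = {
            "n_regulators": int(reg_expr.shape[0]),
            "n_targets": int(tgt_expr.shape[0]),
            "edges_after_permutation": 0,
            "edges_after_bootstrap": 0,
            "edges_removed_by_dpi": 0,
            "edges_after_dpi": 0,
            "params": asdict(params),
        }
        rr = regulator_mi_matrix(reg_expr, params.n_bins) if reg_expr.shape[0] else pd.DataFrame()
        return TRN(edges=_empty_edges(), reg_reg_mi=rr, provenance=prov)

    edges = permutation_filter(
        reg_expr, tgt_expr,
        n_perm=params.n_perm, alpha=params.alpha, n_bins=params.n_bins,
        seed=params.seed, per_regulator_bh=params.per_regulator_bh,
    )
    n_after_perm = len(edges)
    edges = bootstrap_filter(
        edges, reg_expr, tgt_expr,
        n_boot=params.n_boot, consensus=params.consensus,
        n_bins=params.n_bins, seed=params.seed,
    )
    n_after_boot = len(edges)
    rr = regulator_mi_matrix(reg_expr, params.n_bins)
    trn = TRN(edges=edges, reg_reg_mi=rr, provenance={})
    trn = apply_dpi(trn, eps=params.eps)
    trn.provenance.update(
        {
            "n_regulators": int(reg_expr.shape[0]),
            "n_targets": int(tgt_expr.shape[0]),
            "edges_after_permutation": int(n_after_perm),
            "edges_after_bootstrap": int(n_after_boot),
            "params": asdict(params),
        }
    )
    return trn
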