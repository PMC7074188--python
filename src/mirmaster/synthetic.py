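"""Seeded synthetic multi-omics cohort with planted master-regulator structure.

The generator emulates the statistical features of a subtyped tumor cohort
profiled for miRNA and mRNA expression, promoter methylation, survival and
cell-line drug response:

* a minority "squamous" subtype;
* a handful of master miRNAs down-shifted in the squamous samples;
* target genes repressed by their master miRNA (inverse correlation), which
  therefore come out up-regulated in the squamous subtype;
* additional differentially expressed decoy genes and mildly down-shifted
  decoy miRNAs, so that downstream selection steps face a realistic mixture
  of signal and subtype-driven confounding;
* a signature gene set enriched for true targets;
* two "physical target prediction" databases, each holding every planted
  edge plus independently sampled decoy edges;
* promoter methylation negatively coupled (within subtype) to the
  expression of the first master miRNA only;
* exponential survival with log-hazard increasing in mean target expression;
* cell-line IC50 values increasing with target-gene expression for half of
  the compounds.

All expression values live on the log2 scale.  Everything is driven by one
``numpy`` generator seeded from ``SimulationConfig.seed``, so an identical
config yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_cohort", "write_cohort", "read_cohort"]

# Nuisance-structure magnitudes (log2 units): decoy miRNAs are shifted down by
# U(low, high) in squamous samples; decoy DE genes are shifted up by
# U(low, high), spanning the selection cutoffs so the candidate-gene universe
# stays much larger than the planted-target set across fold-change thresholds.
# Decoy gene noise is inflated in proportion to the shift (above the
# reference shift) so their subtype-driven correlation with the master
# miRNAs stays weak regardless of fold change, as for high-variance genes in
# real cohorts.
_DECOY_MIRNA_SHIFT = (0.6, 0.9)
_DECOY_GENE_SHIFT = (0.3, 1.2)
_DECOY_NOISE_REF_SHIFT = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the scale of a 149-sample pancreatic cancer cohort with a
    31-sample squamous minority, 44 candidate miRNAs and 1486 candidate
    genes.
    """

    n_samples: int = 149
    n_squamous: int = 31
    n_mirnas: int = 44
    n_master_mirnas: int = 2
    n_genes: int = 1486
    targets_per_master: int = 40
    n_signature_genes: int = 46
    signature_overlap_frac: float = 0.5
    mirna_shift: float = 1.0
    repression_beta: float = 1.5
    noise_sd: float = 0.5
    surv_gamma: float = 0.5
    surv_censor_rate: float = 0.3
    n_cell_lines: int = 26
    n_compounds: int = 8
    ic50_slope: float = 0.8
    n_decoy_regulators: int = 8
    decoy_gene_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            "n_samples", "n_squamous", "n_mirnas", "n_master_mirnas", "n_genes",
            "targets_per_master", "n_signature_genes", "n_cell_lines",
            "n_compounds", "n_decoy_regulators",
        ]
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_squamous >= self.n_samples:
            raise ValueError("n_squamous must be smaller than n_samples")
        if self.n_master_mirnas > self.n_mirnas:
            raise ValueError("n_master_mirnas cannot exceed n_mirnas")
        if self.targets_per_master * self.n_master_mirnas > self.n_genes:
            raise ValueError("targets_per_master * n_master_mirnas cannot exceed n_genes")
        for name in ("signature_overlap_frac", "surv_censor_rate", "decoy_gene_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("mirna_shift", "repression_beta", "noise_sd", "surv_gamma", "ic50_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted ground truth."""

    mirna_expr: pd.DataFrame
    gene_expr: pd.DataFrame
    methylation: pd.DataFrame
    subtype_labels: pd.Series          # sample -> {"squamous", "non-squamous"}
    survival: pd.DataFrame             # index sample, columns time, event
    signature: set[str]
    physical_targets_a: dict[str, set[str]]
    physical_targets_b: dict[str, set[str]]
    cellline_expr: pd.DataFrame
    ic50: pd.DataFrame                 # cell line x compound
    truth_edges: set[tuple[str, str]]
    truth_masters: set[str]
    coupled_compounds: set[str]
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def samples(self) -> list[str]:
        return list(self.mirna_expr.columns)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one synthetic cohort from ``config`` (deterministic in seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    mirnas = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]
    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    is_sq = np.zeros(cfg.n_samples, dtype=bool)
    is_sq[rng.choice(cfg.n_samples, size=cfg.n_squamous, replace=False)] = True
    subtype = pd.Series(np.where(is_sq, "squamous", "non-squamous"), index=samples, name="subtype")

    # --- regulators -------------------------------------------------------
    mirna_order = rng.permutation(cfg.n_mirnas)
    masters = [mirnas[i] for i in mirna_order[: cfg.n_master_mirnas]]
    n_decoy = min(cfg.n_decoy_regulators, cfg.n_mirnas - cfg.n_master_mirnas)
    decoy_regs = [mirnas[i] for i in mirna_order[cfg.n_master_mirnas: cfg.n_master_mirnas + n_decoy]]

    mirna_base = rng.uniform(4.0, 8.0, size=cfg.n_mirnas)
    shift = np.zeros(cfg.n_mirnas)
    for m in masters:
        shift[mirnas.index(m)] = cfg.mirna_shift
    for d in decoy_regs:
        shift[mirnas.index(d)] = rng.uniform(*_DECOY_MIRNA_SHIFT)

    mirna_vals = (
        mirna_base[:, None]
        - shift[:, None] * is_sq[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_mirnas, cfg.n_samples))
    )
    mirna_expr = pd.DataFrame(mirna_vals, index=mirnas, columns=samples)

    # --- genes ------------------------------------------------------------
    gene_order = rng.permutation(cfg.n_genes)
    truth_edges: set[tuple[str, str]] = set()
    target_of: dict[str, str] = {}
    pos = 0
    for m in masters:
        for _ in range(cfg.targets_per_master):
            g = genes[gene_order[pos]]
            pos += 1
            truth_edges.add((m, g))
            target_of[g] = m
    planted_targets = [g for g in genes if g in target_of]

    non_targets = [genes[i] for i in gene_order[pos:]]
    n_decoy_genes = int(round(cfg.decoy_gene_frac * len(non_targets)))
    decoy_genes = non_targets[:n_decoy_genes]

    gene_base = rng.uniform(4.0, 10.0, size=cfg.n_genes)
    gene_vals = np.empty((cfg.n_genes, cfg.n_samples))
    decoy_offsets = {g: rng.uniform(*_DECOY_GENE_SHIFT) for g in decoy_genes}
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    for gi, g in enumerate(genes):
        base = gene_base[gi]
        if g in target_of:
            m = target_of[g]
            mi = mirnas.index(m)
            gene_vals[gi] = base - cfg.repression_beta * (mirna_vals[mi] - mirna_base[mi]) + noise[gi]
        elif g in decoy_offsets:
            u = decoy_offsets[g]
            scale = max(1.0, u / _DECOY_NOISE_REF_SHIFT)
            gene_vals[gi] = base + u * is_sq + noise[gi] * scale
        else:
            gene_vals[gi] = base + noise[gi]
    gene_expr = pd.DataFrame(gene_vals, index=genes, columns=samples)

    # --- signature --------------------------------------------------------
    n_true_sig = int(round(cfg.signature_overlap_frac * cfg.n_signature_genes))
    n_true_sig = min(n_true_sig, len(planted_targets))
    sig_true = list(rng.choice(planted_targets, size=n_true_sig, replace=False)) if n_true_sig else []
    pool = decoy_genes if decoy_genes else non_targets
    n_false_sig = min(cfg.n_signature_genes - n_true_sig, len(pool))
    sig_false = list(rng.choice(pool, size=n_false_sig, replace=False)) if n_false_sig else []
    signature = set(map(str, sig_true)) | set(map(str, sig_false))

    # --- physical target databases ---------------------------------------
    def _physical_db() -> dict[str, set[str]]:
        db: dict[str, set[str]] = {}
        for mir in mirnas:
            true = {g for (m, g) in truth_edges if m == mir}
            n_decoys = len(true) if true else cfg.targets_per_master
            candidates = [g for g in genes if g not in true]
            decs = rng.choice(candidates, size=min(n_decoys, len(candidates)), replace=False)
            db[mir] = true | set(map(str, decs))
        return db

    physical_a = _physical_db()
    physical_b = _physical_db()

    # --- promoter methylation --------------------------------------------
    meth_vals = rng.beta(2.0, 5.0, size=(cfg.n_mirnas, cfg.n_samples))
    if masters:
        mi = mirnas.index(masters[0])
        resid = mirna_vals[mi] - (mirna_base[mi] - shift[mi] * is_sq)
        meth_vals[mi] = 0.45 - 0.12 * _standardize(resid) + rng.normal(0.0, 0.05, cfg.n_samples)
    meth_vals = np.clip(meth_vals, 0.01, 0.99)
    methylation = pd.DataFrame(meth_vals, index=mirnas, columns=samples)

    # --- survival ---------------------------------------------------------
    if planted_targets:
        z = _standardize(gene_expr.loc[planted_targets].mean(axis=0).to_numpy())
    else:
        z = np.zeros(cfg.n_samples)
    h0 = np.log(2.0) / 500.0  # baseline median survival 500 days
    hazard = h0 * np.exp(cfg.surv_gamma * z)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(cfg.n_samples) < cfg.surv_censor_rate
    obs_time = np.where(censored, event_time * rng.random(cfg.n_samples), event_time)
    survival = pd.DataFrame(
        {"time": np.maximum(obs_time, 1e-3), "event": (~censored).astype(int)},
        index=samples,
    )

    # --- cell lines & drug response --------------------------------------
    cell_lines = [f"CL{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    compounds = [f"DRUG{i + 1:02d}" for i in range(cfg.n_compounds)]
    cl_vals = gene_base[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_cell_lines))
    # planted targets share a latent activity axis across cell lines (they
    # are co-regulated in tumors), which also drives drug response below
    cl_activity = rng.normal(size=cfg.n_cell_lines)
    for g in planted_targets:
        cl_vals[genes.index(g)] += cl_activity
    cellline_expr = pd.DataFrame(cl_vals, index=genes, columns=cell_lines)
    if planted_targets and cfg.n_cell_lines:
        z_cl = _standardize(cellline_expr.loc[planted_targets].mean(axis=0).to_numpy())
    else:
        z_cl = np.zeros(cfg.n_cell_lines)
    coupled = set(compounds[: cfg.n_compounds // 2]) if cfg.n_compounds else set()
    ic50_vals = np.empty((cfg.n_cell_lines, cfg.n_compounds))
    for ci, comp in enumerate(compounds):
        base = rng.uniform(-1.0, 1.0)
        slope = cfg.ic50_slope if comp in coupled else 0.0
        ic50_vals[:, ci] = base + slope * z_cl + rng.normal(0.0, 0.5, cfg.n_cell_lines)
    ic50 = pd.DataFrame(ic50_vals, index=cell_lines, columns=compounds)

    return SyntheticCohort(
        mirna_expr=mirna_expr,
        gene_expr=gene_expr,
        methylation=methylation,
        subtype_labels=subtype,
        survival=survival,
        signature=signature,
        physical_targets_a=physical_a,
        physical_targets_b=physical_b,
        cellline_expr=cellline_expr,
        ic50=ic50,
        truth_edges=truth_edges,
        truth_masters=set(masters),
        coupled_compounds=coupled,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write every cohort component to ``directory`` as plain text.

    Returns a mapping of component name to file path.  The files round-trip
    losslessly through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_expr": directory / "mirna_expr.tsv",
        "gene_expr": directory / "gene_expr.tsv",
        "methylation": directory / "methylation.tsv",
        "annotation": directory / "annotation.tsv",
        "survival": directory / "survival.tsv",
        "signature": directory / "signature.gmt",
        "physical_a": directory / "physical_targets_a.gmt",
        "physical_b": directory / "physical_targets_b.gmt",
        "cellline_expr": directory / "cellline_expr.tsv",
        "ic50": directory / "ic50.tsv",
        "truth": directory / "truth.json",
    }
    io.write_expression(cohort.mirna_expr, paths["mirna_expr"])
    io.write_expression(cohort.gene_expr, paths["gene_expr"])
    io.write_expression(cohort.methylation, paths["methylation"])
    io.write_annotation(cohort.subtype_labels.to_frame(), paths["annotation"])
    io.write_survival(cohort.survival, paths["survival"])
    io.write_gmt({"signature": cohort.signature}, paths["signature"])
    io.write_gmt(cohort.physical_targets_a, paths["physical_a"])
    io.write_gmt(cohort.physical_targets_b, paths["physical_b"])
    io.write_expression(cohort.cellline_expr, paths["cellline_expr"], index_label="gene_id")
    cohort.ic50.to_csv(paths["ic50"], sep="\t", index_label="cell_line")
    io.write_json(
        {
            "edges": sorted(map(list, cohort.truth_edges)),
            "masters": sorted(cohort.truth_masters),
            "coupled_compounds": sorted(cohort.coupled_compounds),
            "config": asdict(cohort.config) if cohort.config is not None else None,
        },
        paths["truth"],
    )
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Inverse of :func:`write_cohort`."""
    directory = Path(directory)
    truth = io.read_json(directory / "truth.json")
    config = SimulationConfig(**truth["config"]) if truth.get("config") else None
    ann = io.read_annotation(directory / "annotation.tsv")
    return SyntheticCohort(
        mirna_expr=io.read_expression(directory / "mirna_expr.tsv"),
        gene_expr=io.read_expression(directory / "gene_expr.tsv"),
        methylation=io.read_expression(directory / "methylation.tsv"),
        subtype_labels=ann["subtype"] if "subtype" in ann else ann.iloc[:, 0],
        survival=io.read_survival(directory / "survival.tsv"),
        signature=io.read_gmt(directory / "signature.gmt")["signature"],
        physical_targets_a=io.read_gmt(directory / "physical_targets_a.gmt"),
        physical_targets_b=io.read_gmt(directory / "physical_targets_b.gmt"),
        cellline_expr=io.read_expression(directory / "cellline_expr.tsv"),
        ic50=pd.read_csv(directory / "ic50.tsv", sep="\t", index_col=0).rename_axis(None),
        truth_edges={(m, g) for m, g in truth["edges"]},
        truth_masters=set(truth["masters"]),
        coupled_compounds=set(truth.get("coupled_compounds", [])),
        config=config,
    )
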