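"""End-to-end orchestration: cohort → differential expression → network
inference → master regulator analysis → target prioritization → survival and
drug-sensitivity screens.

Every stage persists its table under the output directory so any step can be
re-entered, and a JSON run report summarises per-stage record counts,
timings and the seed.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from . import clinical, diffexp, drugresp, io, mra, targets
from .netinf import NetInfParams, infer_trn
from .synthetic import SimulationConfig, SyntheticCohort, generate_cohort, read_cohort, write_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "threshold_sensitivity"]

logger = logging.getLogger("mirmaster")


@dataclass(frozen=True)
class PipelineConfig:
    """One config object for the whole workflow.

    Either ``simulation`` (generate a synthetic cohort) or ``input_dir``
    (read a previously written cohort directory) must be set.
    """

    out_dir: str = "mirmaster_run"
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    mirna_lfc: float = -0.5
    gene_lfc: float = 0.25
    de_alpha: float = 0.05
    min_regulon: int = 15
    master_alpha: float = 0.05
    survival_q: float = 0.25
    net: NetInfParams = field(default_factory=NetInfParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("config needs either a simulation block or an input_dir")
        if not (0 < self.de_alpha < 1 and 0 < self.master_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not (0 < self.survival_q < 1):
            raise ValueError("survival_q must lie in (0, 1)")
        if self.min_regulon < 0:
            raise ValueError("min_regulon must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        net = doc.pop("net", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim else None,
            net=NetInfParams(**net) if net else NetInfParams(),
            **doc,
        )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class RunReport:
    seed: int
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    version: str = ""

    def as_dict(self) -> dict:
        return {"seed": self.seed, "counts": self.counts,
                "timings_s": self.timings_s, "version": self.version}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_cohort(config: PipelineConfig) -> SyntheticCohort:
    if config.input_dir is not None:
        path = Path(config.input_dir)
        if not path.exists():
            raise FileNotFoundError(f"input directory not found: {path}")
        return read_cohort(path)
    sim = replace(config.simulation, seed=config.seed)
    return generate_cohort(sim)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order, persisting all intermediate tables."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)

    def stage(name):
        def deco(fn):
            t0 = _time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # abort with stage name, keep partial output
                io.write_json(report.as_dict(), out / "report.json")
                raise StageError(name, exc) from exc
            report.timings_s[name] = round(_time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.2fs", name, report.timings_s[name])
            return result
        return deco

    cohort = stage("load_cohort")(lambda: _load_cohort(config))
    if config.input_dir is None:
        stage("write_inputs")(lambda: write_cohort(cohort, out / "inputs"))

    de_mirna = stage("de_mirna")(
        lambda: diffexp.moderated_de(cohort.mirna_expr, cohort.subtype_labels)
    )
    de_gene = stage("de_gene")(
        lambda: diffexp.moderated_de(cohort.gene_expr, cohort.subtype_labels)
    )
    io.write_table(de_mirna, out / "de_mirna.tsv")
    io.write_table(de_gene, out / "de_gene.tsv")

    regulators = diffexp.select_regulators(de_mirna, max_lfc=config.mirna_lfc, alpha=config.de_alpha)
    target_genes = diffexp.select_targets(de_gene, min_lfc=config.gene_lfc, alpha=config.de_alpha)
    report.counts["mirnas_selected"] = len(regulators)
    report.counts["genes_selected"] = len(target_genes)

    net_params = replace(config.net, seed=config.seed)
    trn = stage("network_inference")(
        lambda: infer_trn(
            cohort.mirna_expr.loc[regulators],
            cohort.gene_expr.loc[target_genes],
            net_params,
        )
    )
    trn.to_json(out / "network.json")
    trn.to_sif(out / "network.sif")
    for key in ("edges_after_permutation", "edges_after_bootstrap", "edges_after_dpi"):
        report.counts[key] = int(trn.provenance.get(key, 0))

    mra_table = stage("mra")(
        lambda: (
            mra.run_mra(trn, cohort.signature, set(target_genes), config.min_regulon)
            if target_genes
            else _empty_mra()
        )
    )
    io.write_table(mra_table, out / "mra.tsv")
    masters = mra_table.loc[mra_table["adj_p"] < config.master_alpha, "regulator"].tolist()
    report.counts["regulons_tested"] = len(mra_table)
    report.counts["masters_called"] = len(masters)

    target_table = stage("targets")(
        lambda: targets.evaluate_targets(
            trn, cohort.signature, cohort.physical_targets_a, cohort.physical_targets_b,
            cohort.mirna_expr, cohort.gene_expr, regulators=masters,
        )
    )
    io.write_table(target_table, out / "targets.tsv")
    prioritized = sorted(set(target_table["gene"]))
    report.counts["targets_prioritized"] = len(prioritized)

    meth_table = stage("methylation")(
        lambda: targets.methylation_association(
            cohort.methylation, cohort.mirna_expr, cohort.subtype_labels
        )
    )
    io.write_table(meth_table, out / "methylation_association.tsv")

    usable = [g for g in prioritized if g in cohort.gene_expr.index]
    surv_table = stage("survival")(
        lambda: clinical.survival_screen(
            cohort.gene_expr, cohort.survival, usable, q=config.survival_q
        )
    )
    io.write_table(surv_table, out / "survival_screen.tsv")
    report.counts["genes_survival_screened"] = len(surv_table)

    drug_genes = [g for g in prioritized if g in cohort.cellline_expr.index]
    drug_table = stage("drug_screen")(
        lambda: drugresp.run_drug_screen(cohort.cellline_expr, cohort.ic50, drug_genes)
    )
    io.write_table(drug_table, out / "drug_screen.tsv")
    report.counts["drug_tests"] = len(drug_table)

    io.write_json(report.as_dict(), out / "report.json")
    return report


def _empty_mra():
    import pandas as pd

    return pd.DataFrame(
        columns=["regulator", "universe_size", "regulon_size", "total_hits",
                 "expected_hits", "observed_hits", "p", "adj_p"]
    )


def threshold_sensitivity(config: PipelineConfig, gene_lfc_grid) -> dict[float, list[str]]:
    """Re-run selection → network inference → MRA across gene log2-FC cutoffs.

    Returns the called master set per grid value, for stability inspection;
    a higher cutoff always yields a (not necessarily strict) subset of
    candidate genes.
    """
    grid = list(gene_lfc_grid)
    if not grid:
        raise ValueError("gene_lfc_grid must be non-empty")
    cohort = _load_cohort(config)
    de_mirna = diffexp.moderated_de(cohort.mirna_expr, cohort.subtype_labels)
    de_gene = diffexp.moderated_de(cohort.gene_expr, cohort.subtype_labels)
    regulators = diffexp.select_regulators(de_mirna, max_lfc=config.mirna_lfc, alpha=config.de_alpha)
    out: dict[float, list[str]] = {}
    for lfc in grid:
        target_genes = diffexp.select_targets(de_gene, min_lfc=lfc, alpha=config.de_alpha)
        if not regulators or not target_genes:
            out[lfc] = []
            continue
        trn = infer_trn(
            cohort.mirna_expr.loc[regulators],
            cohort.gene_expr.loc[target_genes],
            replace(config.net, seed=config.seed),
        )
        table = mra.run_mra(trn, cohort.signature, set(target_genes), config.min_regulon)
        out[lfc] = table.loc[table["adj_p"] < config.master_alpha, "regulator"].tolist()
    return out
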