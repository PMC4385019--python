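"""End-to-end orchestration: simulate -> design -> normalize -> DE -> CRE
scan/enrichment -> complexity -> qPCR validation -> machine-readable report.

``run_pipeline`` chains every stage on a synthetic dataset and writes a
``report.json`` whose schema is published alongside it
(``report.schema.json``, generated from the pydantic model).  All numbers
in the report are computed by the stages at run time; the configuration and
master seed are echoed so a rerun reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from ferrex import cre, microarray, qpcr, simulate
from ferrex.simulate import SimulationConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    fc_cutoff: float = 1.0
    alpha: float = 0.05
    bandwidth: float | None = None  # None: 10% of the grid diagonal
    background: str = "set"  # CRE background model: set | uniform
    mismatch_limit: int = 3
    check_specificity: bool = True

    @property
    def seed(self) -> int:
        return self.sim.seed

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class DeReport(BaseModel):
    n_up: int
    n_down: int
    pct_up: float | None
    n_de_loci: int | None
    n_total_loci: int | None
    pct_de_loci: int | None
    n_families_de: int | None


class ComplexityReport(BaseModel):
    mu: float
    sigma: float
    upper_threshold: float
    lower_threshold: float
    group_sizes: dict[str, int]


class CreReport(BaseModel):
    n_catalog: int
    n_significant_set_level: int
    n_significant_set_level_ltr: int
    complexity: ComplexityReport | None
    venn: dict[str, int] | None
    aba: dict[str, int | None] | None
    ltr_chi2_motif: str | None
    ltr_chi2: float | None
    ltr_chi2_p: float | None


class QpcrReport(BaseModel):
    pearson_r: float
    pearson_p: float
    n_genes: int


class Report(BaseModel):
    """Schema of report.json."""

    seed: int
    config: dict
    n_probes: int
    n_locus_specific_probes: int | None
    de: DeReport
    cre: CreReport
    qpcr: QpcrReport
    truth_recovery: dict[str, float | int]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a fresh synthetic dataset; return the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    log.info("stage simulate: %d genes, %d TE loci", config.sim.n_genes, config.sim.n_te_loci)
    features, truth = simulate.generate_features(config.sim)
    layout = simulate.build_layout(features, config.sim)
    intensities = simulate.generate_intensities(features, layout, truth, config.sim)
    qpcr_table = simulate.generate_qpcr(features, truth, config.sim)
    simulate.write_outputs(outdir, config.sim, features, truth, layout, intensities, qpcr_table)

    # --- probe specificity ------------------------------------------------
    n_specific = None
    locus_specific = None
    if config.check_specificity:
        from ferrex.probes import annotate_specificity

        annotate_specificity(layout, features.chromosomes, max_mismatch=config.mismatch_limit)
        locus_specific = {p.id: bool(p.locus_specific) for p in layout.probes}
        n_specific = sum(locus_specific.values())
        log.info("stage design: %d/%d probes locus specific", n_specific, len(layout))

    # --- normalize + DE ---------------------------------------------------
    normalized = microarray.normalize(intensities, bandwidth=config.bandwidth)
    values = microarray.summarize_features(normalized, locus_specific)
    kind_of = {f.id: f.kind for f in features.features}
    gene_values = values.loc[[f for f in values.index if kind_of.get(f) == "gene"]]
    te_values = values.loc[[f for f in values.index if kind_of.get(f) == "te_locus"]]
    gene_records = microarray.de_table(gene_values, normalized.conditions, kind="gene")
    gene_records = microarray.call_de(gene_records, config.fc_cutoff, config.alpha)
    te_records = microarray.de_table(te_values, normalized.conditions, kind="te_locus")
    te_records = microarray.call_de(te_records, config.fc_cutoff, config.alpha)
    family_of = {f.id: f.family for f in features.te_loci()}
    family_records = microarray.family_rollup(te_records, family_of)
    expression = pd.concat([gene_records, te_records], ignore_index=True)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    summary = microarray.de_summary(gene_records, te_records, family_records)

    # --- truth recovery ---------------------------------------------------
    merged = expression.merge(
        truth.effects[["feature", "status"]].rename(columns={"status": "true_status"}),
        on="feature", how="left",
    )
    planted = merged["true_status"].isin(["up", "down"])
    called = merged["status"] != "ns"
    correct = planted & (merged["status"] == merged["true_status"])
    sign_errors = int(
        ((merged["status"] == "down") & (merged["true_status"] == "up")).sum()
        + ((merged["status"] == "up") & (merged["true_status"] == "down")).sum()
    )
    recovery = {
        "n_planted": int(planted.sum()),
        "n_recovered": int(correct.sum()),
        "recall": float(correct.sum() / planted.sum()) if planted.any() else 1.0,
        "n_sign_errors": sign_errors,
        "n_false_calls": int((called & ~planted).sum()),
    }

    # --- CRE analysis -----------------------------------------------------
    motifs = cre.load_catalog()
    by_id = features.by_id()
    up_genes = gene_records.loc[gene_records["status"] == "up", "feature"]
    up_promoters = {g: by_id[g].promoter for g in up_genes}
    cre_report: dict = {
        "n_catalog": len(motifs),
        "n_significant_set_level": 0,
        "n_significant_set_level_ltr": 0,
        "complexity": None,
        "venn": None,
        "aba": None,
        "ltr_chi2_motif": None,
        "ltr_chi2": None,
        "ltr_chi2_p": None,
    }
    if up_promoters:
        occ = cre.scan_catalog(motifs, up_promoters, background=config.background)
        enrichment = cre.enrich_catalog(motifs, occ, up_promoters, set_label="up_promoters",
                                        alpha=config.alpha)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        occ.to_tsv(outdir / "occurrences.tsv")
        cre_report["n_significant_set_level"] = int(
            ((enrichment["p"] <= config.alpha) & ~enrichment["flagged"]).sum()
        )
        if len(up_promoters) >= 2:
            groups = cre.classify_complexity(occ.distinct_significant(config.alpha))
            cre_report["complexity"] = {
                "mu": groups.mu,
                "sigma": groups.sigma,
                "upper_threshold": groups.upper,
                "lower_threshold": groups.lower,
                "group_sizes": groups.sizes(),
            }
            sets = cre.group_cre_sets(occ, groups, config.alpha)
            cre_report["venn"] = cre.venn_partition(sets["simple"], sets["normal"], sets["complex"])
        aba = cre.aba_cre_summary(occ, motifs, alpha=config.alpha)
        aba.per_cre.to_csv(outdir / "aba_summary.tsv", sep="\t", index=False)
        cre_report["aba"] = {
            "n_aba_cres_present": aba.n_aba_cres_present,
            "n_genes_with_any": aba.n_genes_with_any,
            "n_up": aba.n_up,
            "percent": aba.percent,
        }

    up_te = set(te_records.loc[te_records["status"] == "up", "feature"])
    all_ltrs = {}
    for f in features.te_loci():
        all_ltrs[f"{f.id}|LTR5"] = f.ltr5
        all_ltrs[f"{f.id}|LTR3"] = f.ltr3
    up_ltrs = {name: seq for name, seq in all_ltrs.items() if name.split("|")[0] in up_te}
    if up_ltrs:
        occ_ltr = cre.scan_catalog(motifs, up_ltrs, background=config.background)
        enr_ltr = cre.enrich_catalog(motifs, occ_ltr, up_ltrs, set_label="up_ltrs",
                                     alpha=config.alpha)
        cre_report["n_significant_set_level_ltr"] = int(
            ((enr_ltr["p"] <= config.alpha) & ~enr_ltr["flagged"]).sum()
        )
        # chi2 on the most set-enriched CRE in up-regulated LTRs
        valid = enr_ltr.loc[~enr_ltr["flagged"]]
        top = valid.loc[valid["z"].idxmax()]
        top_motif = next(m for m in motifs if m.id == top["motif_id"])
        occ_all = cre.scan_catalog([top_motif], all_ltrs, background=config.background)
        sig_ids = set(occ_all.pvalues.index[occ_all.pvalues[top_motif.id] <= config.alpha])
        chi2, p, _, _ = cre.ltr_distribution_chi2(sig_ids, set(up_ltrs), set(all_ltrs))
        cre_report["ltr_chi2_motif"] = str(top["motif_id"])
        cre_report["ltr_chi2"] = None if np.isnan(chi2) else float(chi2)
        cre_report["ltr_chi2_p"] = float(p)

    # --- qPCR validation --------------------------------------------------
    targets = qpcr_table.loc[~qpcr_table["is_reference"]]
    quantified = qpcr.quantify_all(targets)
    validation = qpcr.validation_table(gene_records, quantified)
    validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    r, p_r, n_pairs = qpcr.validate_correlation(validation["log2FC"], validation["log2_rq"])

    report = {
        "seed": config.seed,
        "config": config.as_dict(),
        "n_probes": len(layout),
        "n_locus_specific_probes": n_specific,
        "de": summary.as_dict(),
        "cre": cre_report,
        "qpcr": {"pearson_r": r, "pearson_p": p_r, "n_genes": n_pairs},
        "truth_recovery": recovery,
    }
    report = _jsonable(report)
    Report.model_validate(report)  # schema check before writing
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (outdir / "report.schema.json").write_text(
        json.dumps(Report.model_json_schema(), indent=2, sort_keys=True) + "\n"
    )
    return report
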