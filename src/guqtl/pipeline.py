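"""End-to-end pipeline: simulate (optional) -> filter -> usage -> guQTL ->
conditional -> network -> enrichment -> similarity -> allele linkage.

Every stage writes its tables under the output directory and appends to a
machine-readable manifest (seeds, thresholds, per-stage record counts), so a
rerun with the same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .association import run_conditional_scans, run_guqtl
from .enrichment import enrichment_table, fisher_enrichment, gwas_overlap, overlap_variants
from .linkage import allele_linkage_tests
from .locus import LocusModel, default_model
from .network import build_gene_graph, clique_table, edge_table, variant_gene_histogram
from .similarity import asd_matrix, compare_asd_groups, pairwise_usage_correlation
from .simulate import simulate_haplotypes
from .usage import usage_from_clones

log = logging.getLogger("guqtl")

STAGES = (
    "simulate", "filter", "usage", "guqtl", "conditional",
    "network", "enrich", "similarity", "allele_assoc",
)


@dataclass
class RunConfig:
    out_dir: str = "guqtl_run"
    seed: int = 0
    # inputs (ignored when simulate=True)
    vcf: str | None = None
    airr_dir: str | None = None
    covariates: str | None = None
    features_bed: str | None = None
    gwas_tsv: str | None = None
    model_yaml: str | None = None
    simulate: bool = True
    n_samples: int = 150
    mean_clones: int = 9000
    isotype: str = "IgM"
    # thresholds (defaults are the analysis' stated values)
    maf_min: float = 0.05
    min_genotyped: int = 40
    hwe_min: float = 1e-6
    alpha: float = 0.05
    min_stratum_n: int = 50
    ld_collapse_r2: float = 1.0
    clique_min_weight: int = 3
    min_clones: int = 200
    min_reads: int = 100
    gwas_p_max: float = 4e-6
    asd_bins: int = 4
    dosage_policy: str = "haploid-doubled"
    impute_policy: str = "drop"

    def validate(self):
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min outside [0, 0.5]")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha outside (0, 1]")
        for name in ("min_genotyped", "min_stratum_n", "min_clones", "min_reads", "asd_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.isotype not in ("IgM", "IgG"):
            raise ValueError("isotype must be IgM or IgG")


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}}
    state: dict = {}

    for stage in STAGES:
        t0 = time.time()
        try:
            counts = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.time() - t0, 3),
            **counts,
        }
        log.info("stage %s complete: %s", stage, counts)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest, out):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, st: dict, out: Path) -> dict:
    if not cfg.simulate:
        st["genotypes"] = gio.read_vcf(cfg.vcf)
        st["clones"] = gio.read_cohort_clones(cfg.airr_dir) if cfg.airr_dir else None
        st["covariates"] = gio.read_covariates(cfg.covariates)
        st["cohort"] = None
        return {"n_samples": st["genotypes"].n_samples, "simulated": False}
    model = (
        LocusModel.from_yaml(cfg.model_yaml) if cfg.model_yaml else default_model()
    )
    cohort = simulate_haplotypes(model, cfg.n_samples, cfg.seed)
    clones = cohort.simulate_all_clones(
        cfg.seed, mean_clones=cfg.mean_clones, isotypes=(cfg.isotype,)
    )
    gio.write_cohort(cohort, out / "cohort", clones=clones)
    st["cohort"] = cohort
    st["genotypes"] = cohort.genotypes
    st["clones"] = clones
    st["covariates"] = cohort.covariates
    return {"n_samples": cohort.n_samples, "n_clone_rows": len(clones), "simulated": True}


def _stage_filter(cfg: RunConfig, st: dict, out: Path) -> dict:
    G = st["genotypes"].impute_missing(cfg.impute_policy, seed=cfg.seed)
    Gf, flog = G.filter_common(
        maf_min=cfg.maf_min, min_genotyped=cfg.min_genotyped, hwe_min=cfg.hwe_min
    )
    flog.to_csv(out / "variant_filter_log.tsv", sep="\t", index=False)
    st["genotypes_common"] = Gf
    return {"n_before": G.n_variants, "n_common": Gf.n_variants}


def _stage_usage(cfg: RunConfig, st: dict, out: Path) -> dict:
    cohort = st.get("cohort")
    deleted = None
    if cohort is not None:
        deleted = {
            s: {g for g, c in cohort.gene_copy_number(s).items() if c == 0}
            for s in cohort.sample_ids
        }
    um, qc_log = usage_from_clones(
        st["clones"],
        covariates=st["covariates"],
        isotype=cfg.isotype,
        deleted_genes=deleted,
        min_reads_per_isotype=cfg.min_reads,
        min_clones=cfg.min_clones,
    )
    qc_log.to_csv(out / "qc_log.tsv", sep="\t", index=False)
    um.fractions.to_csv(out / "usage_fractions.csv")
    st["usage"] = um
    return {"n_genes": len(um.fractions), "n_samples": len(um.samples)}


def _stage_guqtl(cfg: RunConfig, st: dict, out: Path) -> dict:
    scan = run_guqtl(
        st["usage"], st["genotypes_common"],
        alpha=cfg.alpha, ld_collapse_r2=cfg.ld_collapse_r2,
    )
    scan.table.to_csv(out / "guqtl_results.tsv", sep="\t", index=False)
    _summary_table(scan).to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
    st["scan"] = scan
    return {
        "n_tests": scan.n_tests,
        "effective_tests": scan.effective_tests,
        "threshold": scan.threshold,
        "n_significant_pairs": len(scan.significant_pairs),
    }


def _stage_conditional(cfg: RunConfig, st: dict, out: Path) -> dict:
    cond = run_conditional_scans(
        st["scan"], st["usage"], st["genotypes_common"],
        alpha=cfg.alpha, min_stratum_n=cfg.min_stratum_n,
        maf_min=cfg.maf_min, min_genotyped=cfg.min_genotyped,
        hwe_min=cfg.hwe_min, ld_collapse_r2=cfg.ld_collapse_r2,
    )
    rows = []
    for gene, results in cond.items():
        for r in results:
            rows.append(
                {
                    "gene": gene,
                    "lead_variant": r.lead_variant,
                    "stratum": r.stratum,
                    "n_stratum": r.n_stratum,
                    "tested": r.tested,
                    "skip_reason": r.skip_reason,
                    "n_significant": len(r.significant),
                    "secondary_variants": ",".join(a.variant for a in r.significant),
                }
            )
    pd.DataFrame(rows).to_csv(out / "conditional_results.tsv", sep="\t", index=False)
    st["conditional"] = cond
    return {"n_genes_scanned": len(cond)}


def _stage_network(cfg: RunConfig, st: dict, out: Path) -> dict:
    G = build_gene_graph(st["scan"].significant_pairs)
    edge_table(G).to_csv(out / "gene_graph_edges.tsv", sep="\t", index=False)
    cl = clique_table(G, min_weight=cfg.clique_min_weight)
    cl.to_csv(out / "cliques.tsv", sep="\t", index=False)
    variant_gene_histogram(G).rename("n_variants").to_csv(out / "variant_gene_histogram.tsv", sep="\t")
    st["graph"] = G
    return {"n_nodes": G.number_of_nodes(), "n_edges": G.number_of_edges(), "n_cliques": len(cl)}


def _stage_enrich(cfg: RunConfig, st: dict, out: Path) -> dict:
    scan = st["scan"]
    G = st["genotypes_common"]
    snvs = {v.id: v.position for v in G.variants if v.var_class == "SNV"}
    sig = scan.significant_variants() & set(snvs)
    bg = set(snvs) - sig
    if cfg.features_bed:
        features = gio.read_bed(cfg.features_bed)
    else:
        features = []
    counts: dict = {"n_guqtl_snvs": len(sig), "n_background_snvs": len(bg)}
    if features and sig and bg:
        membership = overlap_variants(snvs, features)
        res = fisher_enrichment(sig, bg, membership)
        enrichment_table(res).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        counts["n_feature_classes"] = len(res)
    if cfg.gwas_tsv:
        gw = gwas_overlap(
            {v: p for v, p in snvs.items() if v in sig},
            gio.read_gwas(cfg.gwas_tsv),
            p_max=cfg.gwas_p_max,
        )
        gw.to_csv(out / "gwas_overlap.tsv", sep="\t", index=False)
        counts["n_gwas_overlaps"] = len(gw)
    return counts


def _stage_similarity(cfg: RunConfig, st: dict, out: Path) -> dict:
    scan = st["scan"]
    G = st["genotypes_common"]
    um = st["usage"]
    leads = sorted(
        {
            min(s.lead_variants, key=lambda v: G.variant(v).position)
            for s in scan.summaries.values()
            if s.n_significant > 0 and s.lead_variants
        }
    )
    all_sig = sorted(scan.significant_variants())
    counts = {}
    C = None
    for name, vset in (("lead", leads), ("all", all_sig)):
        vset = [v for v in vset if G.variant(v).is_biallelic]
        if len(vset) < 1:
            counts[f"{name}_n_variants"] = 0
            continue
        A = asd_matrix(G, vset)
        shared = [s for s in um.samples if s in A.index]
        A = A.loc[shared, shared]
        C = pairwise_usage_correlation(um.fractions[shared])
        res = compare_asd_groups(A, C, n_bins=cfg.asd_bins)
        A.to_csv(out / f"asd_{name}.csv")
        summary = pd.DataFrame(
            {
                "bin": res.bin_means.index,
                "n_pairs": res.bin_counts.values,
                "mean_correlation": res.bin_means.values,
            }
        )
        summary.to_csv(out / f"asd_{name}_bins.tsv", sep="\t", index=False)
        counts[f"{name}_n_variants"] = len(vset)
        counts[f"{name}_ks_p"] = res.ks_p
        counts[f"{name}_low_bin_mean"] = res.low_bin_mean
        counts[f"{name}_high_bin_mean"] = res.high_bin_mean
        if name == "lead":
            st["similarity"] = res
    if C is not None:
        C.to_csv(out / "usage_correlations.csv")
    return counts


def _stage_allele_assoc(cfg: RunConfig, st: dict, out: Path) -> dict:
    cohort = st.get("cohort")
    if cohort is None:
        return {"skipped": "no coding-allele source without a simulated cohort"}
    tab = allele_linkage_tests(
        cohort, st["scan"].lead_variants(), st["genotypes_common"], seed=cfg.seed
    )
    tab.to_csv(out / "allele_linkage.tsv", sep="\t", index=False)
    n_sig = int((tab["p_value"] < 0.05).sum()) if not tab.empty else 0
    return {"n_genes_tested": len(tab), "n_p_below_0.05": n_sig}


def _summary_table(scan) -> pd.DataFrame:
    rows = []
    for gene, s in scan.summaries.items():
        rows.append(
            {
                "gene": gene,
                "n_significant": s.n_significant,
                "lead_variants": ",".join(s.lead_variants),
                "lead_p": s.lead_p,
                "lead_minus_log10_p": -np.log10(s.lead_p) if s.lead_p > 0 else np.inf,
                "lead_class": s.lead_class,
                "lead_r2_adj": s.lead_r2_adj,
                "lead_fold_change": s.lead_fold_change,
            }
        )
    return pd.DataFrame(rows)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "usage": _stage_usage,
    "guqtl": _stage_guqtl,
    "conditional": _stage_conditional,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "similarity": _stage_similarity,
    "allele_assoc": _stage_allele_assoc,
}
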