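"""Gene-usage QTL association scan.

For every retained gene x common variant pair, gene usage fractions are
tested against genotype with two models, both adjusted for age and
sequencing platform:

* linear regression  usage ~ dosage + age + platform  (t test on the dosage
  coefficient); dosage is the alt-allele count 0/1/2, with hemizygous calls
  encoded 0/2 ("haploid-doubled");
* ANOVA with genotype as a categorical factor (F test of the genotype term
  over the covariate-only model), applied to SNVs, complex SVs and mSVs --
  the multi-allelic-capable test.

Genotype classes observed in fewer than 3 samples are dropped from a
variant's test (the generalisation of excluding the rare 3-copy duplication
haplotype carriers).  Significance is gated on the linear-regression p for
biallelic variants and the ANOVA p for multi-allelic variants, against a
Bonferroni threshold alpha / (number of perfect-LD variant groups): variants
in complete LD (r^2 = 1) represent a single association test.

Variance explained (``r2_adj``) is the incremental adjusted R^2 of the
genotype term: adjusted R^2 of the full model minus adjusted R^2 of the
covariate-only model.  Fold change is the ratio of the larger to the smaller
homozygote-genotype-class mean usage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .usage import UsageMatrix
from .variants import ANOVA_CLASSES, HEMI, MISSING, GenotypeMatrix

P_FLOOR = 1e-300  # reported p-values are clamped into (0, 1]


@dataclass
class AssociationResult:
    gene: str
    variant: str
    var_class: str
    n_used: int
    p_lm: float
    p_anova: float
    beta: float
    r2_adj: float
    fold_change: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def p_gate(self) -> float:
        """The p-value used for the significance gate."""
        return self.p_anova if math.isnan(self.p_lm) else self.p_lm


@dataclass
class ConditionalResult:
    gene: str
    lead_variant: str
    stratum: str  # genotype label of the homozygous stratum
    n_stratum: int
    tested: bool
    skip_reason: str = ""
    threshold: float = math.nan
    effective_tests: int = 0
    significant: list[AssociationResult] = field(default_factory=list)


@dataclass
class GeneSummary:
    gene: str
    n_significant: int
    lead_variants: list[str]
    lead_p: float
    lead_class: str
    lead_r2_adj: float
    lead_fold_change: float
    conditional: list[ConditionalResult] = field(default_factory=list)


@dataclass
class ScanResult:
    table: pd.DataFrame  # one row per gene x variant pair tested
    summaries: dict[str, GeneSummary]
    threshold: float
    effective_tests: int
    n_tests: int
    significant_pairs: list[tuple[str, str]]  # (gene, variant)

    def significant_variants(self) -> set[str]:
        return {v for _, v in self.significant_pairs}

    def lead_variants(self) -> dict[str, list[str]]:
        return {g: s.lead_variants for g, s in self.summaries.items() if s.lead_variants}


def bonferroni_threshold(alpha: float = 0.05, effective_tests: int = 1) -> float:
    if effective_tests < 1:
        raise ValueError("effective_tests must be >= 1")
    return alpha / effective_tests


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """[1, age, platform indicator columns] in sample order."""
    n = len(covariates)
    cols = [np.ones(n), covariates["age"].to_numpy(float)]
    levels = sorted(covariates["platform"].unique())
    for lv in levels[1:]:
        cols.append((covariates["platform"] == lv).to_numpy(float))
    return np.column_stack(cols)


def _q_of(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis (rank-revealing, tolerant of collinearity)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _genotype_classes(labels: np.ndarray, min_class_n: int = 3):
    """Return (mask of usable samples, list of retained class labels).

    Drops missing calls and genotype classes observed in < min_class_n
    samples."""
    ok = labels != "./."
    keep_labels = []
    for lab in pd.unique(labels[ok]):
        if (labels == lab).sum() >= min_class_n:
            keep_labels.append(lab)
    usable = ok & np.isin(labels, keep_labels)
    return usable, keep_labels


def _fold_change(labels, usage, keep_labels) -> float:
    """Ratio of larger to smaller homozygote-class mean usage (diploid
    homozygote classes only)."""
    hom_means = []
    for lab in keep_labels:
        parts = lab.split("/")
        if len(parts) == 2 and parts[0] == parts[1]:
            hom_means.append(usage[labels == lab].mean())
    if len(hom_means) < 2:
        return math.nan
    lo, hi = min(hom_means), max(hom_means)
    if lo == hi == 0:
        return math.nan
    if lo == 0:
        return math.inf
    return float(hi / lo)


# ---------------------------------------------------------------------------
# Single-pair association
# ---------------------------------------------------------------------------


def associate(
    usage: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    variant_id: str,
    covariates: pd.DataFrame,
    gene: str = "",
    min_class_n: int = 3,
) -> AssociationResult:
    """Association of one gene's usage fractions with one variant."""
    u = np.asarray(usage, dtype=float)
    v = genotypes.variant(variant_id)
    labels = genotypes.genotype_labels(variant_id)
    usable, keep_labels = _genotype_classes(labels, min_class_n)
    if usable.sum() < 3:
        raise ValueError(f"{variant_id}: fewer than 3 usable samples")

    uu = u[usable]
    ll = labels[usable]
    cov = covariates.iloc[usable]
    X_cov = _covariate_design(cov)
    n = len(uu)

    group_means = {lab: float(uu[ll == lab].mean()) for lab in keep_labels}
    group_sizes = {lab: int((ll == lab).sum()) for lab in keep_labels}
    fold = _fold_change(ll, uu, keep_labels)

    sst = float(((uu - uu.mean()) ** 2).sum())
    if sst == 0:  # constant usage
        return AssociationResult(
            gene, variant_id, v.var_class, n, 1.0, 1.0, 0.0, 0.0, fold,
            group_means, group_sizes,
        )

    Q_cov = _q_of(X_cov)
    u_res = uu - Q_cov @ (Q_cov.T @ uu)
    sse_cov = float(u_res @ u_res)
    k_cov = Q_cov.shape[1]

    # linear regression on dosage (biallelic variants only)
    p_lm = math.nan
    beta = math.nan
    r2_adj = math.nan
    if v.is_biallelic:
        d = genotypes.dosage(variant_id)[usable]
        d_res = d - Q_cov @ (Q_cov.T @ d)
        dvar = float(d_res @ d_res)
        if dvar <= 1e-12:
            raise ValueError(f"{variant_id}: constant genotype after covariate adjustment")
        beta = float((u_res @ d_res) / dvar)
        sse_full = sse_cov - (u_res @ d_res) ** 2 / dvar
        df = n - k_cov - 1
        if df <= 0 or sse_full <= 0:
            p_lm = P_FLOOR
        else:
            se = math.sqrt(sse_full / df / dvar)
            t = beta / se if se > 0 else math.inf
            p_lm = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
        r2_adj = _incremental_adj_r2(sst, sse_cov, sse_full, n, k_cov, 1)

    # ANOVA with genotype as categorical factor
    p_anova = math.nan
    if v.var_class in ANOVA_CLASSES or not v.is_biallelic:
        if len(keep_labels) < 2:
            p_anova = 1.0
        else:
            dummies = np.column_stack(
                [(ll == lab).astype(float) for lab in keep_labels[1:]]
            )
            Q_full = _q_of(np.column_stack([X_cov, dummies]))
            res_full = uu - Q_full @ (Q_full.T @ uu)
            sse_full_a = float(res_full @ res_full)
            q = Q_full.shape[1] - k_cov
            df2 = n - Q_full.shape[1]
            if q <= 0 or df2 <= 0:
                p_anova = 1.0
            else:
                num = (sse_cov - sse_full_a) / q
                den = sse_full_a / df2
                if den <= 0:
                    p_anova = P_FLOOR
                else:
                    p_anova = max(stats.f.sf(num / den, q, df2), P_FLOOR)
            if not v.is_biallelic:
                r2_adj = _incremental_adj_r2(sst, sse_cov, sse_full_a, n, k_cov, q)

    return AssociationResult(
        gene, variant_id, v.var_class, n, p_lm, p_anova, beta, r2_adj, fold,
        group_means, group_sizes,
    )


def _incremental_adj_r2(sst, sse_cov, sse_full, n, k_cov, k_term) -> float:
    """Adjusted R^2 of the full model minus adjusted R^2 of the covariate-only
    model: the variance fraction attributable to the genotype term."""
    if n - k_cov - k_term <= 0 or n - k_cov <= 0 or sst <= 0:
        return math.nan
    adj_full = 1.0 - (sse_full / (n - k_cov - k_term)) / (sst / (n - 1))
    adj_cov = 1.0 - (sse_cov / (n - k_cov)) / (sst / (n - 1))
    return float(adj_full - adj_cov)


# ---------------------------------------------------------------------------
# Cohort-level scan
# ---------------------------------------------------------------------------


def run_guqtl(
    usage: UsageMatrix,
    genotypes: GenotypeMatrix,
    alpha: float = 0.05,
    ld_collapse_r2: float = 1.0,
    min_class_n: int = 3,
    genes: list[str] | None = None,
    threshold: float | None = None,
    effective_tests: int | None = None,
    group_means: bool = True,
) -> ScanResult:
    """Scan every retained gene against every variant of the genotype matrix.

    The Bonferroni threshold is alpha divided by the number of perfect-LD
    variant groups, computed once over all variants (a single threshold shared
    by genes); pass ``threshold``/``effective_tests`` to reuse a precomputed
    gate (conditional scans recompute both within the stratum)."""
    shared = [s for s in usage.samples if s in genotypes.samples]
    if not shared:
        raise ValueError("no overlapping samples between usage and genotypes")
    G = genotypes.subset(sample_ids=shared)
    U = usage.fractions[shared]
    cov = usage.covariates.loc[shared] if usage.covariates is not None else None
    if cov is None:
        raise ValueError("usage matrix has no covariates")
    gene_list = genes if genes is not None else list(U.index)

    if effective_tests is None:
        groups = G.collapse_perfect_ld(ld_collapse_r2)
        effective_tests = len(groups)
    if threshold is None:
        threshold = bonferroni_threshold(alpha, effective_tests)

    Umat = U.loc[gene_list].to_numpy(float)  # genes x samples
    X_cov_full = _covariate_design(cov)
    chunks = []
    n_tests = 0
    for v in G.variants:
        res = _scan_variant(Umat, gene_list, G, v, X_cov_full, min_class_n, group_means)
        if res is None:
            continue
        chunks.append(res)
        n_tests += len(res["gene"])

    table = (
        pd.DataFrame(
            {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
        )
        if chunks
        else pd.DataFrame()
    )
    if not table.empty:
        table["significant"] = table["p_gate"] < threshold
    summaries = _summarise(table, gene_list)
    sig_pairs = (
        [(r.gene, r.variant) for r in table[table["significant"]].itertuples()]
        if not table.empty
        else []
    )
    return ScanResult(
        table=table,
        summaries=summaries,
        threshold=threshold,
        effective_tests=effective_tests,
        n_tests=n_tests,
        significant_pairs=sig_pairs,
    )


def _scan_variant(Umat, gene_list, G, v, X_cov_full, min_class_n, with_group_means=True):
    """Vectorised over genes: association statistics of one variant."""
    labels = G.genotype_labels(v.id)
    usable, keep_labels = _genotype_classes(labels, min_class_n)
    n = int(usable.sum())
    if n < 3 or len(keep_labels) < 2:
        return None
    uu = Umat[:, usable]  # genes x n
    ll = labels[usable]
    X_cov = X_cov_full[usable]
    Q_cov = _q_of(X_cov)
    k_cov = Q_cov.shape[1]

    u_mean = uu.mean(axis=1, keepdims=True)
    sst = ((uu - u_mean) ** 2).sum(axis=1)
    proj = uu @ Q_cov  # genes x k
    u_res = uu - proj @ Q_cov.T
    sse_cov = (u_res**2).sum(axis=1)

    n_genes = len(gene_list)
    p_lm = np.full(n_genes, np.nan)
    beta = np.full(n_genes, np.nan)
    r2_adj = np.full(n_genes, np.nan)
    p_anova = np.full(n_genes, np.nan)

    if v.is_biallelic:
        d = G.dosage(v.id)[usable]
        d_res = d - Q_cov @ (Q_cov.T @ d)
        dvar = float(d_res @ d_res)
        if dvar <= 1e-12:
            return None  # constant genotype: skip variant
        cross = u_res @ d_res
        beta = cross / dvar
        sse_full = np.maximum(sse_cov - cross**2 / dvar, 0.0)
        df = n - k_cov - 1
        if df > 0:
            se2 = sse_full / df / dvar
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se2 > 0, beta / np.sqrt(se2), np.inf)
            p_lm = np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)
        else:
            p_lm = np.full(n_genes, P_FLOOR)
        r2_adj = _vec_incr_adj_r2(sst, sse_cov, sse_full, n, k_cov, 1)

    if v.var_class in ANOVA_CLASSES or not v.is_biallelic:
        dummies = np.column_stack([(ll == lab).astype(float) for lab in keep_labels[1:]])
        Q_full = _q_of(np.column_stack([X_cov, dummies]))
        res_full = uu - (uu @ Q_full) @ Q_full.T
        sse_full_a = (res_full**2).sum(axis=1)
        q = Q_full.shape[1] - k_cov
        df2 = n - Q_full.shape[1]
        if q > 0 and df2 > 0:
            num = np.maximum(sse_cov - sse_full_a, 0.0) / q
            den = sse_full_a / df2
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(den > 0, num / den, np.inf)
            p_anova = np.maximum(stats.f.sf(F, q, df2), P_FLOOR)
        else:
            p_anova = np.ones(n_genes)
        if not v.is_biallelic:
            r2_adj = _vec_incr_adj_r2(sst, sse_cov, sse_full_a, n, k_cov, q)

    # per-class means and sizes (shared across genes for sizes)
    class_masks = {lab: ll == lab for lab in keep_labels}
    class_sizes = {lab: int(m.sum()) for lab, m in class_masks.items()}
    class_means = {lab: uu[:, m].mean(axis=1) for lab, m in class_masks.items()}
    hom_labels = [
        lab
        for lab in keep_labels
        if len(lab.split("/")) == 2 and lab.split("/")[0] == lab.split("/")[1]
    ]

    n_genes = len(gene_list)
    const_usage = sst == 0
    p_lm = np.where(const_usage, 1.0, p_lm)
    p_anova = np.where(const_usage, 1.0, p_anova)
    beta = np.where(const_usage, 0.0, beta)
    r2_adj = np.where(const_usage, 0.0, r2_adj)
    p_gate = np.where(np.isnan(p_lm), p_anova, p_lm)

    if len(hom_labels) >= 2:
        hom = np.vstack([class_means[lab] for lab in hom_labels])
        lo = hom.min(axis=0)
        hi = hom.max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(
                (lo == 0) & (hi == 0), np.nan, np.where(lo == 0, np.inf, hi / lo)
            )
    else:
        fold = np.full(n_genes, np.nan)

    out = {
        "gene": np.asarray(gene_list, dtype=object),
        "variant": np.repeat(v.id, n_genes),
        "var_class": np.repeat(v.var_class, n_genes),
        "position": np.repeat(v.position, n_genes),
        "n_used": np.repeat(n, n_genes),
        "p_lm": p_lm,
        "p_anova": p_anova,
        "p_gate": p_gate,
        "beta": beta,
        "r2_adj": r2_adj,
        "fold_change": fold,
    }
    if with_group_means:
        out["group_means"] = np.array(
            [
                ";".join(
                    f"{lab}:{class_means[lab][gi]:.6g}:{class_sizes[lab]}"
                    for lab in keep_labels
                )
                for gi in range(n_genes)
            ],
            dtype=object,
        )
    return out


def _vec_incr_adj_r2(sst, sse_cov, sse_full, n, k_cov, k_term):
    out = np.full(len(sst), np.nan)
    if n - k_cov - k_term <= 0 or n - k_cov <= 0:
        return out
    ok = sst > 0
    adj_full = 1.0 - (sse_full[ok] / (n - k_cov - k_term)) / (sst[ok] / (n - 1))
    adj_cov = 1.0 - (sse_cov[ok] / (n - k_cov)) / (sst[ok] / (n - 1))
    out[ok] = adj_full - adj_cov
    return out


def _summarise(table: pd.DataFrame, gene_list) -> dict[str, GeneSummary]:
    summaries = {}
    for gene in gene_list:
        if table.empty:
            summaries[gene] = GeneSummary(gene, 0, [], math.nan, "", math.nan, math.nan)
            continue
        sub = table[table["gene"] == gene]
        if sub.empty:
            summaries[gene] = GeneSummary(gene, 0, [], math.nan, "", math.nan, math.nan)
            continue
        lead_p = sub["p_gate"].min()
        leads = sub[sub["p_gate"] == lead_p].sort_values("position")
        lead = leads.iloc[0]
        summaries[gene] = GeneSummary(
            gene=gene,
            n_significant=int(sub["significant"].sum()),
            lead_variants=list(leads["variant"]),
            lead_p=float(lead_p),
            lead_class=str(lead["var_class"]),
            lead_r2_adj=float(lead["r2_adj"]),
            lead_fold_change=float(lead["fold_change"]),
        )
    return summaries


# ---------------------------------------------------------------------------
# Conditional (secondary) scans
# ---------------------------------------------------------------------------


def conditional_scan(
    gene: str,
    lead_variant: str,
    usage: UsageMatrix,
    genotypes: GenotypeMatrix,
    alpha: float = 0.05,
    min_stratum_n: int = 50,
    maf_min: float = 0.05,
    min_genotyped: int = 40,
    hwe_min: float = 1e-6,
    ld_collapse_r2: float = 1.0,
    min_class_n: int = 3,
) -> list[ConditionalResult]:
    """Secondary guQTL scan within each homozygous stratum of the lead variant.

    For both the homozygous-reference and homozygous-alternate strata (with at
    least ``min_stratum_n`` samples; smaller strata are reported as skipped),
    variant filtering is re-run inside the stratum and the gene is re-scanned
    against all remaining variants (the lead itself is constant within the
    stratum and drops out).  Hemizygous samples carry their single allele as
    the full genotype and stratify with the matching homozygote class."""
    shared = [s for s in usage.samples if s in genotypes.samples]
    G = genotypes.subset(sample_ids=shared)
    v = G.variant(lead_variant)
    d = G.dosage(lead_variant) if v.is_biallelic else None
    results: list[ConditionalResult] = []
    strata = (("ref_hom", 0.0), ("alt_hom", 2.0))
    for name, dose in strata:
        if d is None:
            a1 = G.a1[:, G.variant_index(lead_variant)]
            a2 = G.a2[:, G.variant_index(lead_variant)]
            tgt = 0 if name == "ref_hom" else 1
            mask = (a1 == tgt) & ((a2 == tgt) | (a2 == HEMI))
        else:
            mask = d == dose
        stratum_samples = [s for s, m in zip(G.samples, mask) if m]
        n_str = len(stratum_samples)
        if n_str < min_stratum_n:
            results.append(
                ConditionalResult(
                    gene, lead_variant, name, n_str, tested=False,
                    skip_reason=f"stratum n={n_str} < {min_stratum_n}",
                )
            )
            continue
        Gs = G.subset(sample_ids=stratum_samples)
        Gs, _ = Gs.filter_common(maf_min=maf_min, min_genotyped=min_genotyped, hwe_min=hwe_min)
        Gs = Gs.subset(
            variant_ids=[w.id for w in Gs.variants if w.id != lead_variant]
        )
        if Gs.n_variants == 0:
            results.append(
                ConditionalResult(
                    gene, lead_variant, name, n_str, tested=True,
                    skip_reason="no polymorphic variants in stratum",
                )
            )
            continue
        Us = UsageMatrix(
            counts=usage.counts[stratum_samples],
            fractions=usage.fractions[stratum_samples],
            gene_segment=usage.gene_segment,
            covariates=usage.covariates.loc[stratum_samples],
        )
        scan = run_guqtl(
            Us, Gs, alpha=alpha, ld_collapse_r2=ld_collapse_r2,
            min_class_n=min_class_n, genes=[gene],
        )
        sig = (
            scan.table[scan.table["significant"]]
            if not scan.table.empty
            else pd.DataFrame()
        )
        sig_results = [
            AssociationResult(
                gene=r.gene, variant=r.variant, var_class=r.var_class,
                n_used=r.n_used, p_lm=r.p_lm, p_anova=r.p_anova, beta=r.beta,
                r2_adj=r.r2_adj, fold_change=r.fold_change,
            )
            for r in sig.itertuples()
        ]
        results.append(
            ConditionalResult(
                gene, lead_variant, name, n_str, tested=True,
                threshold=scan.threshold, effective_tests=scan.effective_tests,
                significant=sig_results,
            )
        )
    return results


def run_conditional_scans(
    scan: ScanResult,
    usage: UsageMatrix,
    genotypes: GenotypeMatrix,
    **kwargs,
) -> dict[str, list[ConditionalResult]]:
    """Conditional scans for every gene with a significant lead guQTL; the
    left-most co-lead (lowest locus position) anchors stratification."""
    out = {}
    for gene, summary in scan.summaries.items():
        if summary.n_significant == 0 or not summary.lead_variants:
            continue
        if summary.lead_p >= scan.threshold:
            continue
        lead = min(summary.lead_variants, key=lambda v: genotypes.variant(v).position)
        res = conditional_scan(gene, lead, usage, genotypes, **kwargs)
        summary.conditional = res
        out[gene] = res
    return out
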