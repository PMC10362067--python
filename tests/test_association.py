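"""Association scan: linear model, ANOVA, Bonferroni gating, fold change,
conditional analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from guqtl.association import (
    associate,
    bonferroni_threshold,
    conditional_scan,
    run_guqtl,
)
from guqtl.usage import UsageMatrix
from guqtl.variants import HEMI, MISSING

from test_variants import make_matrix
from _util import usage_from_counts


def _cov(n, rng=None, platforms=("A", "B", "C")):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 70, n).round(1),
            "platform": rng.choice(platforms, n),
        },
        index=[f"S{i}" for i in range(n)],
    )


def _matrix_from_dosage(d):
    col = []
    for x in d:
        col.append({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(x)])
    return make_matrix({"v": col})


def test_noiseless_linear_recovery():
    """Exact recovery of a planted linear effect with a platform batch term."""
    rng = np.random.default_rng(1)
    n = 120
    d = rng.integers(0, 3, n)
    cov = _cov(n, rng)
    usage = 0.01 * d + 0.002 * (cov["platform"] == "B").to_numpy() + 0.05
    m = _matrix_from_dosage(d)
    res = associate(usage, m, "v", cov)
    assert res.beta == pytest.approx(0.01, abs=1e-10)
    assert res.p_lm < 1e-200


def test_fold_change_is_homozygote_mean_ratio():
    """Group means 7.4% and 13% give fold change 13/7.4."""
    n = 90
    d = np.array([0] * 45 + [2] * 45)
    usage = np.where(d == 0, 0.074, 0.13)
    # add tiny noise so usage is not constant within groups
    usage = usage + np.linspace(0, 1e-9, n)
    m = _matrix_from_dosage(d)
    res = associate(usage, m, "v", _cov(n))
    assert res.fold_change == pytest.approx(0.13 / 0.074, rel=1e-6)
    assert res.group_means["0/0"] == pytest.approx(0.074, abs=1e-9)
    assert res.group_sizes == {"0/0": 45, "1/1": 45}


def test_null_permutation_p_values_are_uniform(rng):
    """Permuting genotypes against fixed usage yields uniform p (KS)."""
    n = 100
    d = rng.integers(0, 3, n)
    usage = rng.normal(0.1, 0.01, n)
    cov = _cov(n, rng)
    ps = []
    for _ in range(400):
        perm = rng.permutation(d)
        m = _matrix_from_dosage(perm)
        ps.append(associate(usage, m, "v", cov).p_lm)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_agrees_with_statsmodels_ols(rng):
    """beta and p match an independent OLS fit to 1e-8 on random instances."""
    for _ in range(20):
        n = int(rng.integers(30, 120))
        d = rng.integers(0, 3, n)
        if len(np.unique(d)) < 2:
            continue
        cov = _cov(n, rng)
        usage = 0.1 + 0.01 * d + rng.normal(0, 0.02, n)
        m = _matrix_from_dosage(d)
        res = associate(usage, m, "v", cov, min_class_n=1)
        X = pd.DataFrame(
            {
                "dosage": d.astype(float),
                "age": cov["age"].to_numpy(),
                "pB": (cov["platform"] == "B").astype(float).to_numpy(),
                "pC": (cov["platform"] == "C").astype(float).to_numpy(),
            }
        )
        fit = sm.OLS(usage, sm.add_constant(X)).fit()
        assert res.beta == pytest.approx(fit.params["dosage"], abs=1e-8)
        assert res.p_lm == pytest.approx(fit.pvalues["dosage"], abs=1e-8)


def test_anova_matches_f_test_oracle(rng):
    """Categorical genotype F test equals statsmodels anova comparison."""
    n = 90
    d = rng.integers(0, 3, n)
    cov = _cov(n, rng)
    usage = 0.1 + 0.005 * (d == 2) + rng.normal(0, 0.01, n)
    m = _matrix_from_dosage(d)
    res = associate(usage, m, "v", cov, min_class_n=1)
    X0 = sm.add_constant(
        pd.DataFrame(
            {
                "age": cov["age"].to_numpy(),
                "pB": (cov["platform"] == "B").astype(float).to_numpy(),
                "pC": (cov["platform"] == "C").astype(float).to_numpy(),
            }
        )
    )
    X1 = X0.copy()
    X1["g1"] = (d == 1).astype(float)
    X1["g2"] = (d == 2).astype(float)
    fit0 = sm.OLS(usage, X0).fit()
    fit1 = sm.OLS(usage, X1).fit()
    f = (fit0.ssr - fit1.ssr) / 2 / (fit1.ssr / fit1.df_resid)
    p = stats.f.sf(f, 2, fit1.df_resid)
    assert res.p_anova == pytest.approx(p, abs=1e-8)


def test_rare_genotype_classes_are_dropped():
    """Classes with < 3 samples (the 3-copy-haplotype rule generalised) are
    excluded from the test and the fold-change groups."""
    d = np.array([0] * 50 + [1] * 48 + [2] * 2)
    usage = 0.1 + 0.01 * d
    m = _matrix_from_dosage(d)
    res = associate(usage, m, "v", _cov(100))
    assert res.n_used == 98
    assert "1/1" not in res.group_sizes
    assert np.isnan(res.fold_change)  # only one homozygote class left


def test_constant_usage_gives_p_one():
    d = np.array([0] * 10 + [1] * 10 + [2] * 10)
    m = _matrix_from_dosage(d)
    res = associate(np.full(30, 0.25), m, "v", _cov(30))
    assert res.p_lm == 1.0 and res.beta == 0.0


def test_constant_genotype_is_flagged():
    m = make_matrix({"v": [(0, 0)] * 30})
    with pytest.raises(ValueError):
        associate(np.random.default_rng(0).normal(size=30), m, "v", _cov(30))


@pytest.mark.parametrize(
    "alpha, n, expected",
    [(0.05, 5000, 1e-5), (0.05, 5435, 9.199632014719412e-06), (0.05, 1, 0.05)],
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_rejects_zero_tests():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


# ------------------------------------------------------------------ full scan


def _usage_matrix(fractions: pd.DataFrame, covariates: pd.DataFrame):
    seg = pd.Series({g: "V" for g in fractions.index})
    return UsageMatrix(
        counts=fractions, fractions=fractions, gene_segment=seg, covariates=covariates
    )


def test_single_gene_perfect_association():
    rng = np.random.default_rng(2)
    n = 100
    d = rng.integers(0, 3, n)
    cov = _cov(n, rng)
    frac = pd.DataFrame(
        {f"S{i}": [0.2 + 0.05 * d[i], 0.8 - 0.05 * d[i], 1e-3] for i in range(n)},
        index=["g1", "g2", "g3"],
    )
    m = _matrix_from_dosage(d)
    m.samples = [f"S{i}" for i in range(n)]
    scan = run_guqtl(_usage_matrix(frac, cov), m, alpha=0.05)
    s = scan.summaries["g1"]
    assert s.n_significant == 1 and s.lead_variants == ["v"]
    assert scan.effective_tests == 1 and scan.threshold == 0.05


def test_scan_lead_recovery_on_simulated_cohort(default_cohort):
    """The deletion SV (or an r^2=1 proxy) is the lead guQTL for genes it
    deletes; the planted regulatory SNV leads its target gene."""
    um = usage_from_counts(default_cohort, seed=31)
    G, _ = default_cohort.genotypes.filter_common()
    scan = run_guqtl(um, G)
    s = scan.summaries["IGHD1-7"]
    assert "sv_del_D" in s.lead_variants or any(
        G.compute_ld(v, "sv_del_D")[1] >= 1 - 1e-9 for v in s.lead_variants
    )
    s2 = scan.summaries["IGHV3-53"]
    assert "snv_reg_A" in s2.lead_variants or any(
        G.compute_ld(v, "snv_reg_A")[1] >= 1 - 1e-9 for v in s2.lead_variants
    )
    assert s2.lead_p < scan.threshold


def test_scan_monotone_group_means_for_copy_number_series(default_cohort):
    """Fitted genotype-class means at the duplication SV are monotone in
    merged gene copy number (2/3/4)."""
    um = usage_from_counts(default_cohort, seed=32)
    G, _ = default_cohort.genotypes.filter_common()
    res = associate(
        um.fractions.loc["IGHV3-23/3-23D", G.samples].to_numpy(float),
        G,
        "sv_dup_V3-23",
        um.covariates.loc[G.samples],
    )
    # REF carries both genes: 0/0 -> 4 copies, 0/1 -> 3, 1/1 -> 2
    assert res.group_means["1/1"] < res.group_means["0/1"] < res.group_means["0/0"]


def test_scan_ties_are_co_leads(default_cohort):
    """Variants in perfect LD with the lead share its p-value and are all
    reported as co-leads."""
    um = usage_from_counts(default_cohort, seed=33)
    G, _ = default_cohort.genotypes.filter_common()
    scan = run_guqtl(um, G, genes=["IGHV3-53"])
    leads = scan.summaries["IGHV3-53"].lead_variants
    assert len(leads) >= 2
    for v in leads[1:]:
        assert G.compute_ld(leads[0], v)[1] == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- conditional


def test_conditional_scan_recovers_secondary_effect(default_cohort):
    """Within the deletion ref-hom stratum, the planted secondary SNV is a
    significant conditional guQTL; the small alt-hom stratum is skipped."""
    um = usage_from_counts(default_cohort, seed=34)
    G, _ = default_cohort.genotypes.filter_common()
    results = conditional_scan("IGHD3-3", "sv_del_D", um, G, min_stratum_n=50)
    by_stratum = {r.stratum: r for r in results}
    ref = by_stratum["ref_hom"]
    assert ref.tested
    sig_vars = {a.variant for a in ref.significant}
    assert "snv_reg_B" in sig_vars
    alt = by_stratum["alt_hom"]
    assert not alt.tested and "50" in alt.skip_reason


def test_conditional_stratum_of_49_not_tested():
    rng = np.random.default_rng(3)
    n = 60
    # 49 ref-hom, 11 others
    d = np.array([0] * 49 + [1] * 8 + [2] * 3)
    col2 = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(n)]
    m = make_matrix({"lead": [{0: (0, 0), 1: (0, 1), 2: (1, 1)}[x] for x in d],
                     "other": col2})
    m.samples = [f"S{i}" for i in range(n)]
    frac = pd.DataFrame(
        {f"S{i}": [0.3, 0.7] for i in range(n)}, index=["g1", "g2"]
    )
    res = conditional_scan("g1", "lead", _usage_matrix(frac, _cov(n)), m, min_stratum_n=50)
    assert all(not r.tested for r in res)
    assert any(r.n_stratum == 49 for r in res)


def test_conditional_monomorphic_stratum_empty():
    n = 120
    d = np.array([0] * 60 + [2] * 60)
    other = [(0, 0)] * 60 + [(0, 1)] * 30 + [(1, 1)] * 30  # constant in ref-hom
    m = make_matrix({"lead": [{0: (0, 0), 2: (1, 1)}[x] for x in d], "other": other})
    m.samples = [f"S{i}" for i in range(n)]
    rng = np.random.default_rng(4)
    frac = pd.DataFrame(
        {f"S{i}": [0.4 + 0.001 * rng.normal(), 0.6] for i in range(n)},
        index=["g1", "g2"],
    )
    res = conditional_scan("g1", "lead", _usage_matrix(frac, _cov(n)), m, min_stratum_n=50)
    ref = next(r for r in res if r.stratum == "ref_hom")
    assert ref.tested and ref.significant == []
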