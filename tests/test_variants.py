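"""Genotype matrix statistics, filters, dosage, LD and HWE."""

import numpy as np
import pytest

from guqtl.variants import (
    HEMI,
    MISSING,
    GenotypeCall,
    GenotypeMatrix,
    VariantRecord,
    encode_dosage,
    hwe_exact_test,
)

from _util import hwe_oracle, ld_groups_oracle


def make_matrix(columns: dict[str, list[tuple[int, int]]], classes=None) -> GenotypeMatrix:
    """columns: variant id -> list of (a1, a2) codes per sample."""
    ids = list(columns)
    n = len(next(iter(columns.values())))
    classes = classes or {}
    variants = [
        VariantRecord(v, 100 + 10 * k, classes.get(v, "SNV"), ("A", "G"))
        for k, v in enumerate(ids)
    ]
    a1 = np.array([[columns[v][i][0] for v in ids] for i in range(n)], dtype=np.int16)
    a2 = np.array([[columns[v][i][1] for v in ids] for i in range(n)], dtype=np.int16)
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, a1, a2)


# ---------------------------------------------------------------- allele stats


def test_allele_stats_counting():
    m = make_matrix({"v": [(0, 1)] * 10})
    st = m.allele_stats("v")
    assert st.counts == (10, 10) and st.maf == 0.5 and st.n_genotyped == 10

    m = make_matrix({"v": [(1, HEMI)] * 4 + [(0, 0)] * 6})
    st = m.allele_stats("v")
    assert st.counts == (12, 4)  # hemizygous contribute one copy
    assert st.maf == pytest.approx(4 / 16)

    m = make_matrix({"v": [(MISSING, MISSING)] * 5})
    st = m.allele_stats("v")
    assert st.n_genotyped == 0 and np.isnan(st.maf)


def test_allele_copy_conservation_property(rng):
    """Counted copies = 2 x diploid + 1 x hemizygous calls."""
    for _ in range(25):
        n = int(rng.integers(5, 60))
        states = rng.integers(0, 3, size=n)  # 0 dip, 1 hemi, 2 missing
        col = []
        for s in states:
            if s == 0:
                col.append(tuple(rng.integers(0, 2, 2)))
            elif s == 1:
                col.append((int(rng.integers(0, 2)), HEMI))
            else:
                col.append((MISSING, MISSING))
        m = make_matrix({"v": col})
        st = m.allele_stats("v")
        assert sum(st.counts) == 2 * (states == 0).sum() + (states == 1).sum()


# ------------------------------------------------------------------------ HWE


@pytest.mark.parametrize(
    "counts", [(100, 0, 0), (25, 50, 25), (0, 100, 0), (57, 14, 50), (3, 2, 1)]
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)


def test_hwe_all_het_is_extreme():
    assert hwe_exact_test(0, 100, 0) < 1e-6
    assert hwe_exact_test(100, 0, 0) == 1.0  # monomorphic


def test_hwe_random_instances_match_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(1, 100))
        aa = int(rng.integers(0, n + 1))
        ab = int(rng.integers(0, n - aa + 1))
        bb = n - aa - ab
        assert hwe_exact_test(aa, ab, bb) == pytest.approx(
            hwe_oracle(aa, ab, bb), abs=1e-12
        )


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ------------------------------------------------------------------ filtering


def test_filter_common_rules():
    n = 100
    cols = {
        "under_genotyped": [(0, 1)] * 39 + [(MISSING, MISSING)] * 61,
        "rare": [(0, 1)] * 2 + [(0, 0)] * 98,
        "boundary_maf": [(0, 1)] * 10 + [(0, 0)] * 90,  # MAF exactly 0.05
        "monomorphic": [(0, 0)] * n,
        "hwe_violation": [(0, 1)] * n,  # all-het
        "keeper": [(0, 0)] * 50 + [(0, 1)] * 40 + [(1, 1)] * 10,
    }
    m = make_matrix(cols)
    filtered, log = m.filter_common(maf_min=0.05, min_genotyped=40, hwe_min=1e-6)
    kept = {v.id for v in filtered.variants}
    assert kept == {"boundary_maf", "keeper"}
    removed = dict(zip(log["variant"], log["removed_by"]))
    assert removed["under_genotyped"] == "min_genotyped"
    assert removed["rare"] == "maf"
    assert removed["monomorphic"] == "maf"
    assert removed["hwe_violation"] == "hwe"


def test_filter_common_is_idempotent():
    cols = {
        "a": [(0, 1)] * 30 + [(0, 0)] * 70,
        "b": [(0, 1)] * 2 + [(0, 0)] * 98,
    }
    m = make_matrix(cols)
    f1, _ = m.filter_common()
    f2, _ = f1.filter_common()
    assert [v.id for v in f1.variants] == [v.id for v in f2.variants]
    np.testing.assert_array_equal(f1.a1, f2.a1)


def test_hemizygous_excluded_from_hwe():
    """A variant whose diploid calls are in HWE is kept even when many calls
    are hemizygous."""
    col = [(0, 0)] * 25 + [(0, 1)] * 50 + [(1, 1)] * 25 + [(1, HEMI)] * 50
    m = make_matrix({"v": col})
    assert m.hwe_p("v") == pytest.approx(hwe_oracle(25, 50, 25), abs=1e-12)


# ----------------------------------------------------------------- imputation


def test_impute_drop_is_identity():
    m = make_matrix({"v": [(0, 1), (MISSING, MISSING)]})
    m2 = m.impute_missing("drop")
    np.testing.assert_array_equal(m.a1, m2.a1)


def test_impute_frequency_from_degenerate_distribution():
    m = make_matrix({"v": [(0, 0)] * 9 + [(MISSING, MISSING)]})
    m2 = m.impute_missing("frequency", seed=1)
    assert (m2.a1 == 0).all() and (m2.a2 == 0).all()


def test_impute_frequency_deterministic():
    col = [(0, 0)] * 5 + [(0, 1)] * 5 + [(MISSING, MISSING)] * 5
    m = make_matrix({"v": col})
    r1 = m.impute_missing("frequency", seed=42)
    r2 = m.impute_missing("frequency", seed=42)
    np.testing.assert_array_equal(r1.a1, r2.a1)
    np.testing.assert_array_equal(r1.a2, r2.a2)


def test_impute_unknown_policy():
    m = make_matrix({"v": [(0, 1)] * 3})
    with pytest.raises(ValueError):
        m.impute_missing("beagle")


def test_impute_never_fills_homozygous_deletions(tiny_cohort):
    """Positions inside hom-deleted SVs stay missing under frequency policy."""
    G = tiny_cohort.genotypes
    imp = G.impute_missing("frequency", seed=3)
    j = G.variant_index("in_sv_1")
    k = G.variant_index("sv_del")
    hom_del = (G.a1[:, k] == 1) & (G.a2[:, k] == 1)
    assert hom_del.any()
    assert (imp.a1[hom_del, j] == MISSING).all()
    not_del = ~hom_del
    assert (imp.a1[not_del, j] != MISSING).all()


# --------------------------------------------------------------------- dosage


@pytest.mark.parametrize(
    "call, expected",
    [
        (GenotypeCall.diploid(0, 1), 1),
        (GenotypeCall.diploid(1, 1), 2),
        (GenotypeCall.diploid(0, 0), 0),
        (GenotypeCall.hemizygous(1), 2),
        (GenotypeCall.hemizygous(0), 0),
    ],
)
def test_encode_dosage(call, expected):
    assert encode_dosage(call) == expected


def test_encode_dosage_rejects_missing():
    with pytest.raises(ValueError):
        encode_dosage(GenotypeCall.missing())


def test_dosage_vector_counts_alt_alleles():
    m = make_matrix({"v": [(0, 0), (0, 1), (1, 1), (1, HEMI), (MISSING, MISSING)]})
    d = m.dosage("v")
    np.testing.assert_array_equal(d[:4], [0, 1, 2, 2])
    assert np.isnan(d[4])


# ------------------------------------------------------------------------- LD


def test_ld_identical_and_mirrored():
    base = [(0, 0)] * 5 + [(0, 1)] * 5 + [(1, 1)] * 5
    flipped = [(1, 1)] * 5 + [(0, 1)] * 5 + [(0, 0)] * 5
    m = make_matrix({"a": base, "b": list(base), "c": flipped})
    assert m.compute_ld("a", "b") == (pytest.approx(1.0), pytest.approx(1.0))
    r, r2 = m.compute_ld("a", "c")
    assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)
    # symmetry
    assert m.compute_ld("a", "c") == m.compute_ld("c", "a")


def test_ld_constant_vector_flagged():
    m = make_matrix({"a": [(0, 0)] * 6, "b": [(0, 1)] * 3 + [(0, 0)] * 3})
    r, r2 = m.compute_ld("a", "b")
    assert np.isnan(r) and np.isnan(r2)


def test_independent_variants_mean_r2_near_1_over_n(rng):
    """E[r^2] ~ 1/n for independent variants (simulation oracle)."""
    n, reps = 200, 600
    r2s = []
    for _ in range(reps):
        d1 = rng.binomial(2, 0.4, n).astype(float)
        d2 = rng.binomial(2, 0.4, n).astype(float)
        if d1.std() == 0 or d2.std() == 0:
            continue
        r = np.corrcoef(d1, d2)[0, 1]
        r2s.append(r * r)
    mean = np.mean(r2s)
    se = np.std(r2s) / np.sqrt(len(r2s))
    assert abs(mean - 1 / n) < 4 * se + 5e-4


def test_collapse_perfect_ld_groups():
    col = [(0, 0)] * 5 + [(0, 1)] * 5 + [(1, 1)] * 5
    other = [(0, 1)] * 8 + [(0, 0)] * 7
    cols = {f"v{i}": list(col) for i in range(10)}
    cols["w"] = other
    m = make_matrix(cols)
    groups = m.collapse_perfect_ld()
    assert sorted(map(len, groups)) == [1, 10]
    assert len(groups) == 2  # effective test count


def test_collapse_no_perfect_pairs():
    rng = np.random.default_rng(5)
    cols = {}
    for i in range(6):
        cols[f"v{i}"] = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(40)]
    m = make_matrix(cols)
    groups = m.collapse_perfect_ld()
    r2s = []
    for i in range(6):
        for j in range(i + 1, 6):
            _, r2 = m.compute_ld(f"v{i}", f"v{j}")
            r2s.append(r2)
    if all(r2 < 1 - 1e-9 for r2 in r2s if not np.isnan(r2)):
        assert len(groups) == 6


def test_collapse_matches_transitive_closure_oracle(rng):
    """Random matrices with duplicated/missing columns: grouping equals the
    brute-force closure over the r^2 >= 1 relation."""
    for _ in range(100):
        n = int(rng.integers(10, 40))
        m_var = int(rng.integers(3, 8))
        base = rng.binomial(2, 0.5, size=(n, m_var)).astype(float)
        # duplicate a couple of columns to create perfect LD
        dup_of = rng.integers(0, m_var, size=2)
        D = np.column_stack([base, base[:, dup_of]])
        # sprinkle missing values
        mask = rng.random(D.shape) < 0.05
        D[mask] = np.nan
        cols = {}
        for k in range(D.shape[1]):
            col = []
            for x in D[:, k]:
                if np.isnan(x):
                    col.append((MISSING, MISSING))
                elif x == 0:
                    col.append((0, 0))
                elif x == 1:
                    col.append((0, 1))
                else:
                    col.append((1, 1))
            cols[f"v{k}"] = col
        mat = make_matrix(cols)
        got = {frozenset(g) for g in mat.collapse_perfect_ld()}
        ids = [f"v{k}" for k in range(D.shape[1])]
        expected = {
            frozenset(ids[i] for i in grp)
            for grp in ld_groups_oracle(
                np.column_stack([mat.dosage(v) for v in ids])
            )
        }
        assert got == expected
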