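"""Clone counting, gene merging, QC filters and usage fractions."""

import numpy as np
import pandas as pd
import pytest

from guqtl.usage import (
    DEFAULT_EXCLUDED_GENES,
    DEFAULT_MERGE_GROUPS,
    count_clones,
    merge_map_from_groups,
    parse_gene,
    qc_filter,
    usage_fractions,
)

from _util import recount_oracle


def clone_rows(rows):
    """rows: list of (sample, v_call, d_call, j_call)"""
    return pd.DataFrame(
        {
            "sequence_id": [f"q{i}" for i in range(len(rows))],
            "sample_id": [r[0] for r in rows],
            "c_call": "IGHM",
            "v_call": [r[1] for r in rows],
            "d_call": [r[2] for r in rows],
            "j_call": [r[3] for r in rows],
            "duplicate_count": 1,
            "clone_id": [f"c{i}" for i in range(len(rows))],
        }
    )


def test_parse_gene_strips_allele():
    assert parse_gene("IGHV3-23*02") == "IGHV3-23"
    assert parse_gene("IGHD4-11") == "IGHD4-11"
    with pytest.raises(ValueError):
        parse_gene("garbage!!")


def test_duplicated_genes_merge_into_one_row():
    rows = [("S1", "IGHV3-23*01", "IGHD1-1*01", "IGHJ4*01")] * 5
    rows += [("S1", "IGHV3-23D*01", "IGHD1-1*01", "IGHJ4*01")] * 3
    res = count_clones(clone_rows(rows))
    assert res.counts.loc["IGHV3-23/3-23D", "S1"] == 8
    assert "IGHV3-23" not in res.counts.index


def test_merge_map_covers_the_four_default_groups():
    m = merge_map_from_groups(DEFAULT_MERGE_GROUPS)
    assert m["IGHV3-23"] == m["IGHV3-23D"]
    assert m["IGHV3-30"] == m["IGHV3-33"] == m["IGHV3-30-3"] == m["IGHV3-30-5"]
    assert m["IGHV1-69"] == m["IGHV1-69D"]
    assert m["IGHD4-4"] == m["IGHD4-11"]


def test_clones_on_double_deleted_genes_are_dropped():
    rows = [("S1", "IGHV1-8*01", "IGHD1-1*01", "IGHJ4*01")] * 4
    rows += [("S2", "IGHV1-8*01", "IGHD1-1*01", "IGHJ4*01")] * 4
    res = count_clones(clone_rows(rows), deleted_genes={"S1": {"IGHV1-8"}})
    assert "IGHV1-8" in res.counts.index
    assert res.counts.loc["IGHV1-8", "S1"] == 0
    assert res.counts.loc["IGHV1-8", "S2"] == 4
    assert res.n_dropped_deleted == 4


def test_excluded_genes_absent():
    rows = [("S1", "IGHV3-16*01", "IGHD5-5*01", "IGHJ4*01")] * 3
    rows += [("S1", "IGHV1-2*01", "IGHD1-1*01", "IGHJ4*01")] * 2
    res = count_clones(clone_rows(rows))
    assert not set(DEFAULT_EXCLUDED_GENES) & set(res.counts.index)
    assert res.counts.loc["IGHV1-2", "S1"] == 2


def test_multi_assignment_resolved_by_genomic_deletion():
    """A clone assigned to two genes resolves to the one present in the
    sample's genome; unresolvable multi-assignments are dropped (default) or
    split (option)."""
    rows = [("S1", "IGHV1-8*01,IGHV3-9*01", "IGHD1-1*01", "IGHJ4*01")] * 6
    res = count_clones(clone_rows(rows), deleted_genes={"S1": {"IGHV1-8"}})
    assert res.counts.loc["IGHV3-9", "S1"] == 6
    assert res.n_dropped_ambiguous == 0

    res2 = count_clones(clone_rows(rows))  # both present: ambiguous
    assert res2.n_dropped_ambiguous == 6
    assert "IGHV1-8" not in res2.counts.index or res2.counts.loc["IGHV1-8", "S1"] == 0

    res3 = count_clones(clone_rows(rows), ambiguous_policy="split")
    assert res3.counts.loc["IGHV1-8", "S1"] == pytest.approx(3.0)
    assert res3.counts.loc["IGHV3-9", "S1"] == pytest.approx(3.0)


def test_count_matches_bruteforce_recount(rng):
    genes_v = ["IGHV1-2", "IGHV3-23", "IGHV3-23D", "IGHV1-8"]
    genes_d = ["IGHD1-1", "IGHD4-4", "IGHD4-11"]
    genes_j = ["IGHJ4", "IGHJ6"]
    samples = ["S1", "S2", "S3"]
    deleted = {"S2": {"IGHV1-8"}}
    rows = [
        (
            rng.choice(samples),
            rng.choice(genes_v) + "*01",
            rng.choice(genes_d) + "*01",
            rng.choice(genes_j) + "*01",
        )
        for _ in range(500)
    ]
    table = clone_rows(rows)
    res = count_clones(table, deleted_genes=deleted)
    merge = merge_map_from_groups(DEFAULT_MERGE_GROUPS)
    for col in ("v_call", "d_call", "j_call"):
        oracle = recount_oracle(table, col, merge, set(DEFAULT_EXCLUDED_GENES), deleted)
        for (gene, sample), count in oracle.items():
            assert res.counts.loc[gene, sample] == count


def test_total_clones_conserved_by_merging(rng):
    genes = ["IGHV3-23", "IGHV3-23D", "IGHV1-2", "IGHV1-8"]
    rows = [
        ("S1", rng.choice(genes) + "*01", "IGHD1-1*01", "IGHJ4*01") for _ in range(300)
    ]
    deleted = {"S1": {"IGHV1-8"}}
    res = count_clones(clone_rows(rows), deleted_genes=deleted)
    v_rows = [g for g in res.counts.index if res.gene_segment[g] == "V"]
    assert res.counts.loc[v_rows, "S1"].sum() == 300 - res.n_dropped_deleted


# ------------------------------------------------------------------------- QC


def _clones_with_sizes(repertoires):
    """repertoires: list of (sample, isotype_call, n_clones, dup_count)."""
    frames = []
    for sample, iso, n, dup in repertoires:
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": [f"{sample}{iso}{i}" for i in range(n)],
                    "sample_id": sample,
                    "c_call": iso,
                    "v_call": "IGHV1-2*01",
                    "d_call": "IGHD1-1*01",
                    "j_call": "IGHJ4*01",
                    "duplicate_count": dup,
                    "clone_id": [f"{sample}{iso}c{i}" for i in range(n)],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_qc_removes_low_clone_repertoires():
    clones = _clones_with_sizes([("S1", "IGHM", 199, 5), ("S2", "IGHM", 200, 5)])
    kept, log = qc_filter(clones)
    assert set(kept["sample_id"]) == {"S2"}
    row = log[(log.sample_id == "S1")].iloc[0]
    assert not row.pass_clones and row.pass_reads


def test_qc_read_rule_is_per_isotype():
    clones = _clones_with_sizes(
        [("S1", "IGHG1", 99, 1), ("S1", "IGHM", 10_000, 1)]
    )
    kept, _ = qc_filter(clones, min_clones=50)
    assert set(kept["c_call"]) == {"IGHM"}


def test_qc_identity_when_all_pass():
    clones = _clones_with_sizes([("S1", "IGHM", 300, 2), ("S2", "IGHM", 400, 2)])
    kept, _ = qc_filter(clones)
    pd.testing.assert_frame_equal(kept, clones)


# ------------------------------------------------------------------ fractions


def test_fraction_examples():
    C = pd.DataFrame(
        {"S1": [50, 50, 7], "S2": [10, 30, 4]},
        index=["IGHV1-2", "IGHV3-7", "IGHD1-1"],
    )
    seg = pd.Series({"IGHV1-2": "V", "IGHV3-7": "V", "IGHD1-1": "D"})
    um = usage_fractions(C, seg)
    assert um.fractions.loc["IGHV1-2", "S1"] == pytest.approx(0.5)
    assert um.fractions.loc["IGHV1-2", "S2"] == pytest.approx(0.25)
    assert um.fractions.loc["IGHD1-1", "S1"] == pytest.approx(1.0)  # single-gene class


def test_fractions_match_hand_division_and_are_column_stochastic(rng):
    C = pd.DataFrame(
        rng.integers(1, 100, size=(6, 4)).astype(float),
        index=[f"IGHV{i}" for i in range(4)] + ["IGHD0", "IGHJ0"],
        columns=[f"S{i}" for i in range(4)],
    )
    seg = pd.Series(
        {f"IGHV{i}": "V" for i in range(4)} | {"IGHD0": "D", "IGHJ0": "J"}
    )
    um = usage_fractions(C, seg)
    v = [f"IGHV{i}" for i in range(4)]
    np.testing.assert_allclose(um.fractions.loc[v].sum(axis=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(
        um.fractions.loc[v].to_numpy(),
        C.loc[v].to_numpy() / C.loc[v].sum(axis=0).to_numpy(),
    )


def test_zero_total_sample_rejected():
    C = pd.DataFrame({"S1": [0.0, 0.0]}, index=["IGHV1", "IGHV2"])
    seg = pd.Series({"IGHV1": "V", "IGHV2": "V"})
    with pytest.raises(ValueError, match="zero"):
        usage_fractions(C, seg)


def test_negative_counts_rejected():
    C = pd.DataFrame({"S1": [-1.0, 2.0]}, index=["IGHV1", "IGHV2"])
    seg = pd.Series({"IGHV1": "V", "IGHV2": "V"})
    with pytest.raises(ValueError):
        usage_fractions(C, seg)


def test_repertoire_normalisation_option():
    C = pd.DataFrame({"S1": [3.0, 1.0]}, index=["IGHV1", "IGHD1"])
    seg = pd.Series({"IGHV1": "V", "IGHD1": "D"})
    um = usage_fractions(C, seg, normalisation="repertoire")
    assert um.fractions["S1"].sum() == pytest.approx(1.0)
    assert um.fractions.loc["IGHV1", "S1"] == pytest.approx(0.75)
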