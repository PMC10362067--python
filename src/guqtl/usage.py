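"""From clone-level repertoire tables to gene usage matrices.

A clone table (AIRR Rearrangement rows) is turned into a genes x samples
clone-count matrix C, applying the merging of indistinguishable duplicated
genes, removal of genes excluded from analysis, removal of clones assigned
only to genes deleted from both chromosomes in the sample's genome, and
genomic resolution of multi-gene assignments.  Usage fractions are then
computed per segment class: every clone carries exactly one V, one D and one
J gene, so V fractions are normalised over V genes, D over D, J over J.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Duplicated gene pairs whose repertoire reads cannot be told apart.
DEFAULT_MERGE_GROUPS: tuple[tuple[str, ...], ...] = (
    ("IGHV3-23", "IGHV3-23D"),
    ("IGHV3-30", "IGHV3-30-3", "IGHV3-30-5", "IGHV3-33"),
    ("IGHV1-69", "IGHV1-69D"),
    ("IGHD4-4", "IGHD4-11"),
)
DEFAULT_EXCLUDED_GENES: tuple[str, ...] = ("IGHD5-5", "IGHV3-16")

_CALL_COLS = {"V": "v_call", "D": "d_call", "J": "j_call"}
_GENE_RE = re.compile(r"^(IGH[VDJ][\w.\-/]*?)(\*\d+)?$")


def merge_map_from_groups(groups=DEFAULT_MERGE_GROUPS) -> dict[str, str]:
    """gene -> merged-row name ('A/B' style, first member's prefix kept)."""
    mapping: dict[str, str] = {}
    for grp in groups:
        merged = grp[0] + "".join("/" + g.split("IGH", 1)[1][1:] for g in grp[1:])
        # e.g. ("IGHV3-23","IGHV3-23D") -> "IGHV3-23/3-23D"
        for g in grp:
            mapping[g] = merged
    return mapping


def parse_gene(call: str) -> str:
    """Strip the allele suffix from a single gene call ('IGHV3-23*02')."""
    m = _GENE_RE.match(call.strip())
    if not m:
        raise ValueError(f"unparseable gene call {call!r}")
    return m.group(1)


@dataclass
class CountResult:
    counts: pd.DataFrame  # (merged) genes x samples, per segment class stacked
    gene_segment: pd.Series  # gene -> V/D/J
    n_dropped_deleted: int  # clones whose only assignment was double-deleted
    n_dropped_ambiguous: int  # multi-assignments that could not be resolved


def count_clones(
    clones: pd.DataFrame,
    merge_groups=DEFAULT_MERGE_GROUPS,
    exclusions: tuple[str, ...] = DEFAULT_EXCLUDED_GENES,
    deleted_genes: dict[str, set[str]] | None = None,
    ambiguous_policy: str = "drop",
) -> CountResult:
    """Build the clone-count matrix C from AIRR rows.

    ``deleted_genes`` maps sample_id -> genes with diploid copy number 0 in
    that sample's genome; clone assignments to those genes are removed, and
    multi-gene assignments are re-assigned to the single remaining present
    gene when possible.  Unresolvable multi-assignments are dropped
    (``ambiguous_policy="drop"``) or split equally (``"split"``).
    """
    if ambiguous_policy not in ("drop", "split"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    deleted_genes = deleted_genes or {}
    merge = merge_map_from_groups(merge_groups)
    excluded = set(exclusions)

    samples = list(dict.fromkeys(clones["sample_id"]))
    sample_pos = {s: i for i, s in enumerate(samples)}
    counts: dict[str, np.ndarray] = {}
    gene_segment: dict[str, str] = {}
    n_deleted = 0
    n_ambiguous = 0
    any_deleted = set().union(*deleted_genes.values()) if deleted_genes else set()

    def add(gene: str, segment: str, sample: str, amount: float):
        row = counts.setdefault(gene, np.zeros(len(samples)))
        gene_segment[gene] = segment
        row[sample_pos[sample]] += amount

    for segment, col in _CALL_COLS.items():
        call = clones[col].astype(str)
        sample = clones["sample_id"]
        multi = call.str.contains(",", regex=False)

        # fast path: single-gene assignments
        g = call[~multi].str.split("*").str[0].str.strip()
        ok = g.str.match(_GENE_RE.pattern)
        if not ok.all():
            bad = call[~multi][~ok].iloc[0]
            raise ValueError(f"unparseable gene call {bad!r}")
        df = pd.DataFrame({"sample": sample[~multi], "gene": g})
        df = df[~df["gene"].isin(excluded)]
        if any_deleted:
            maybe = df["gene"].isin(any_deleted)
            if maybe.any():
                sub = df[maybe]
                drop = np.array(
                    [gg in deleted_genes.get(ss, ()) for ss, gg in zip(sub["sample"], sub["gene"])]
                )
                n_deleted += int(drop.sum())
                df = df.drop(sub.index[drop])
        df["gene"] = df["gene"].map(lambda x: merge.get(x, x))
        tab = df.groupby(["gene", "sample"], sort=False).size()
        for (gene, smp), n in tab.items():
            add(gene, segment, smp, float(n))

        # slow path: comma-separated multi-assignments
        for smp, raw in zip(sample[multi], call[multi]):
            dele = deleted_genes.get(smp, set())
            genes = []
            for part in raw.split(","):
                gg = parse_gene(part)
                if gg in excluded:
                    continue
                genes.append(gg)
            present = [gg for gg in genes if gg not in dele]
            merged = list(dict.fromkeys(merge.get(gg, gg) for gg in present))
            if not merged:
                if genes:  # only deleted assignments
                    n_deleted += 1
                continue
            if len(merged) == 1:
                add(merged[0], segment, smp, 1.0)
            elif ambiguous_policy == "split":
                for gg in merged:
                    add(gg, segment, smp, 1.0 / len(merged))
            else:
                n_ambiguous += 1

    seg_order = {"V": 0, "D": 1, "J": 2}
    gene_names = sorted(gene_segment, key=lambda g: (seg_order[gene_segment[g]], g))
    C = pd.DataFrame(
        np.vstack([counts[g] for g in gene_names]) if gene_names else np.zeros((0, len(samples))),
        index=gene_names,
        columns=samples,
    )
    return CountResult(
        counts=C,
        gene_segment=pd.Series({g: gene_segment[g] for g in gene_names}),
        n_dropped_deleted=n_deleted,
        n_dropped_ambiguous=n_ambiguous,
    )


def qc_filter(
    clones: pd.DataFrame,
    min_reads_per_isotype: int = 100,
    min_clones: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove sample/isotype repertoires with fewer than
    ``min_reads_per_isotype`` reads (sum of duplicate_count) or fewer than
    ``min_clones`` distinct clones.  Returns (filtered rows, QC log)."""
    dup = clones.get("duplicate_count", pd.Series(1, index=clones.index))
    grp = clones.assign(_dup=dup).groupby(["sample_id", "c_call"], sort=False)
    stats = grp.agg(n_reads=("_dup", "sum"), n_clones=("clone_id", "nunique")).reset_index()
    stats["pass_reads"] = stats["n_reads"] >= min_reads_per_isotype
    stats["pass_clones"] = stats["n_clones"] >= min_clones
    stats["retained"] = stats["pass_reads"] & stats["pass_clones"]
    keep = {
        (r.sample_id, r.c_call) for r in stats.itertuples() if r.retained
    }
    mask = [
        (s, c) in keep for s, c in zip(clones["sample_id"], clones["c_call"])
    ]
    return clones[np.asarray(mask)].reset_index(drop=True), stats


@dataclass
class UsageMatrix:
    counts: pd.DataFrame  # genes x samples
    fractions: pd.DataFrame  # genes x samples, column-stochastic per class
    gene_segment: pd.Series
    covariates: pd.DataFrame | None = None
    clone_totals: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def samples(self) -> list[str]:
        return list(self.fractions.columns)

    def genes_of_class(self, segment: str) -> list[str]:
        return list(self.gene_segment[self.gene_segment == segment].index)

    def class_fractions(self, segment: str) -> pd.DataFrame:
        return self.fractions.loc[self.genes_of_class(segment)]


def usage_fractions(
    C: pd.DataFrame,
    gene_segment: pd.Series,
    covariates: pd.DataFrame | None = None,
    normalisation: str = "class",
) -> UsageMatrix:
    """Usage-fraction matrix U: u[g,s] = C[g,s] / sum_g' C[g',s], with the sum
    over genes of the same segment class (default) or over all genes
    (``normalisation="repertoire"``)."""
    if (C.to_numpy() < 0).any():
        raise ValueError("negative clone counts")
    U = C.astype(float).copy()
    if normalisation == "class":
        for seg in ("V", "D", "J"):
            genes = [g for g in C.index if gene_segment.get(g) == seg]
            if not genes:
                continue
            tot = C.loc[genes].sum(axis=0)
            if (tot == 0).any():
                bad = list(tot.index[tot == 0])
                raise ValueError(f"samples with zero {seg} clones (QC should have removed): {bad}")
            U.loc[genes] = C.loc[genes] / tot
    elif normalisation == "repertoire":
        tot = C.sum(axis=0)
        if (tot == 0).any():
            raise ValueError("samples with zero clones")
        U = C / tot
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")
    return UsageMatrix(
        counts=C,
        fractions=U,
        gene_segment=gene_segment.loc[C.index],
        covariates=covariates,
        clone_totals=C.sum(axis=0),
    )


def usage_from_clones(
    clones: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    isotype: str = "IgM",
    deleted_genes: dict[str, set[str]] | None = None,
    merge_groups=DEFAULT_MERGE_GROUPS,
    exclusions: tuple[str, ...] = DEFAULT_EXCLUDED_GENES,
    min_reads_per_isotype: int = 100,
    min_clones: int = 200,
) -> tuple[UsageMatrix, pd.DataFrame]:
    """QC -> count -> fractions for one isotype; returns (usage, qc log)."""
    iso_call = {"IgM": "IGHM", "IgG": "IGHG1"}[isotype]
    rows = clones[clones["c_call"] == iso_call]
    rows, qc_log = qc_filter(rows, min_reads_per_isotype, min_clones)
    if rows.empty:
        raise ValueError(f"no {isotype} repertoires left after QC")
    res = count_clones(
        rows,
        merge_groups=merge_groups,
        exclusions=exclusions,
        deleted_genes=deleted_genes,
    )
    cov = covariates.loc[res.counts.columns] if covariates is not None else None
    um = usage_fractions(res.counts, res.gene_segment, covariates=cov)
    return um, qc_log
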