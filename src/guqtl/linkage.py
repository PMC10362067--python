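"""Coding-allele x guQTL linkage and the novel-allele acceptance filter.

For each gene, samples are cross-tabulated by their coding-region allele
genotype (unordered pair of allele labels, e.g. *01/*03; hemizygous samples
form single-allele classes) against their genotype class at the gene's lead
guQTL, and independence is tested with a Fisher exact test: exact for 2x2,
exact by enumeration over all tables with the observed margins for small
totals, and a seeded Monte-Carlo estimate (tables drawn conditional on the
margins) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass(frozen=True)
class AlleleObservation:
    sample: str
    gene: str
    allele: str
    read_count: int
    exact_match: bool = True

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError("read count must be >= 0")


def allele_genotype_label(alleles: tuple[str, ...]) -> str:
    """Unordered genotype label: ('*03','*01') -> '*01/*03'; a single label
    (hemizygous) stands alone."""
    return "/".join(sorted(alleles))


def allele_guqtl_table(
    allele_genotypes: pd.Series,
    guqtl_genotypes: pd.Series,
) -> pd.DataFrame:
    """Cross-tabulate samples: coding-allele genotype classes (rows) x guQTL
    genotype classes (columns).  Both inputs are indexed by sample id; missing
    values ('' or NaN) are dropped, as are zero-margin classes."""
    df = pd.DataFrame({"allele": allele_genotypes, "guqtl": guqtl_genotypes}).dropna()
    df = df[(df["allele"] != "") & (df["guqtl"] != "") & (df["guqtl"] != "./.")]
    tab = pd.crosstab(df["allele"], df["guqtl"])
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need >= 2 classes on each margin")
    return tab


# ---------------------------------------------------------------------------
# Fisher exact test for RxC tables
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of an RxC table given its margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(rows, cols):
    """All non-negative integer tables with the given margins (recursive over
    rows; feasible for small totals)."""
    r = len(rows)

    def rec(row_idx, remaining_cols, current):
        if row_idx == r - 1:
            last = remaining_cols
            if (last >= 0).all():
                yield current + [list(last)]
            return
        target = rows[row_idx]

        def fill(col_idx, left, row_acc):
            if col_idx == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill(col_idx + 1, left - v, row_acc + [v])

        for row in fill(0, target, []):
            yield from rec(
                row_idx + 1, remaining_cols - np.array(row), current + [row]
            )

    yield from rec(0, np.array(cols), [])


def _n_tables_bound(rows, n_cols: int) -> float:
    """Upper bound on the enumeration work for tables with the given row
    margins (the last row is determined by the column margins)."""
    from math import comb

    est = 1.0
    for r in list(rows)[:-1]:
        est *= comb(int(r) + n_cols - 1, n_cols - 1)
        if est > 1e12:
            break
    return est


def fisher_assoc(
    table: pd.DataFrame | np.ndarray,
    seed: int = 0,
    exact_total_max: int = 200,
    max_enum_tables: float = 2e5,
    n_mc: int = 100_000,
) -> tuple[float, str]:
    """Fisher exact p for an RxC contingency table.

    Returns (p, method) with method one of "exact-2x2", "exact-enum",
    "monte-carlo".  The p-value is the probability, conditional on the
    margins, of tables as or less probable than the observed one.  Exact
    enumeration is used when the table space is small enough; otherwise the p
    is estimated from seeded draws conditional on the margins.
    """
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need a table of at least 2x2")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins")
    if T.shape == (2, 2):
        return float(stats.fisher_exact(T, alternative="two-sided")[1]), "exact-2x2"
    total = int(T.sum())
    log_obs = _log_table_prob(T)
    tol = 1e-9
    if (
        total <= exact_total_max
        and T.size <= 16
        and _n_tables_bound(T.sum(axis=1), T.shape[1]) <= max_enum_tables
    ):
        p = 0.0
        rows = list(T.sum(axis=1))
        cols = list(T.sum(axis=0))
        for cand in _enumerate_tables(rows, cols):
            lp = _log_table_prob(np.array(cand))
            if lp <= log_obs + tol:
                p += math.exp(lp)
        return float(min(1.0, p)), "exact-enum"
    rng = np.random.default_rng(seed)
    rt = stats.random_table(T.sum(axis=1), T.sum(axis=0))
    draws = rt.rvs(n_mc, random_state=rng)
    const = (
        gammaln(T.sum(axis=1) + 1).sum()
        + gammaln(T.sum(axis=0) + 1).sum()
        - gammaln(total + 1)
    )
    lps = const - gammaln(draws + 1).sum(axis=(1, 2))
    hits = int((lps <= log_obs + tol).sum())
    return float((hits + 1) / (n_mc + 1)), "monte-carlo"


# ---------------------------------------------------------------------------
# Novel-allele acceptance
# ---------------------------------------------------------------------------


def filter_novel_alleles(
    observations: list[AlleleObservation],
    database_alleles: set[str],
    min_reads: int = 10,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Accept putative novel alleles absent from the reference database when
    they have exact matches to at least ``min_reads`` reads in a single
    sample, or are identified in at least ``min_samples`` distinct samples."""
    by_allele: dict[tuple[str, str], list[AlleleObservation]] = {}
    for obs in observations:
        by_allele.setdefault((obs.gene, obs.allele), []).append(obs)
    rows = []
    for (gene, allele), group in sorted(by_allele.items()):
        known = allele in database_alleles or f"{gene}{allele}" in database_alleles
        max_exact = max((o.read_count for o in group if o.exact_match), default=0)
        n_samples = len({o.sample for o in group})
        accepted = (not known) and (max_exact >= min_reads or n_samples >= min_samples)
        rows.append(
            {
                "gene": gene,
                "allele": allele,
                "in_database": known,
                "max_exact_reads": max_exact,
                "n_samples": n_samples,
                "accepted": accepted,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "allele", "in_database", "max_exact_reads", "n_samples", "accepted"],
    )


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------


def coding_allele_genotypes(cohort, gene: str) -> pd.Series:
    """Coding-allele genotype label per sample from a simulated cohort."""
    m = cohort.model
    tag_block = m.coding_tag.get(gene)
    if tag_block is None:
        raise KeyError(f"gene {gene} has no coding-allele tag block")
    bj = [b.id for b in m.blocks].index(tag_block)
    gj = [g.name for g in m.genes].index(gene)
    cn = cohort._hap_cn()[:, :, gj]  # (n, 2) haploid copies
    labels = []
    for i in range(cohort.n_samples):
        alleles = [
            m.coding_allele(gene, int(cohort.block_haps[i, h, bj]))
            for h in range(2)
            if cn[i, h] > 0
        ]
        labels.append(allele_genotype_label(tuple(alleles)) if alleles else "")
    return pd.Series(labels, index=cohort.sample_ids)


def allele_linkage_tests(
    cohort,
    lead_variants: dict[str, list[str]],
    genotypes,
    seed: int = 0,
) -> pd.DataFrame:
    """Per gene with a lead guQTL: Fisher association between coding-allele
    genotypes and lead-guQTL genotype classes."""
    rows = []
    for gene, leads in sorted(lead_variants.items()):
        if not leads:
            continue
        lead = min(leads, key=lambda v: genotypes.variant(v).position)
        try:
            alleles = coding_allele_genotypes(cohort, gene)
        except KeyError:
            continue
        guqtl = pd.Series(
            genotypes.genotype_labels(lead), index=genotypes.samples
        ).reindex(alleles.index)
        try:
            tab = allele_guqtl_table(alleles, guqtl)
        except ValueError:
            continue
        p, method = fisher_assoc(tab, seed=seed)
        rows.append(
            {
                "gene": gene,
                "lead_variant": lead,
                "n_allele_classes": tab.shape[0],
                "n_genotype_classes": tab.shape[1],
                "p_value": p,
                "method": method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "lead_variant", "n_allele_classes", "n_genotype_classes", "p_value", "method"],
    )
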