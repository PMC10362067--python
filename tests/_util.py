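"""Shared fixtures helpers and independent brute-force oracles.

The oracles here are deliberately naive (exact rational arithmetic,
exhaustive enumeration, pure-python recounts) and independent of the package
implementations they are used to check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from guqtl.usage import usage_fractions


def usage_from_counts(cohort, seed, mean_clones=9000):
    """UsageMatrix straight from multinomial clone counts (no AIRR rows),
    applying the same gene merging and exclusions as clone counting."""
    from guqtl.usage import DEFAULT_EXCLUDED_GENES, DEFAULT_MERGE_GROUPS, merge_map_from_groups

    merge = merge_map_from_groups(DEFAULT_MERGE_GROUPS)
    frames, seg_map = [], {}
    for seg in ("V", "D", "J"):
        if not cohort.model.genes_of_class(seg):
            continue
        cc = cohort.clone_counts(mean_clones, seed, seg)
        cc = cc.drop(index=[g for g in DEFAULT_EXCLUDED_GENES if g in cc.index])
        cc = cc.groupby([merge.get(g, g) for g in cc.index]).sum()
        frames.append(cc)
        seg_map.update({g: seg for g in cc.index})
    return usage_fractions(
        pd.concat(frames), pd.Series(seg_map), covariates=cohort.covariates
    )


# ---------------------------------------------------------------------------
# Exact-probability oracles (rational arithmetic)
# ---------------------------------------------------------------------------


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """HWE exact p by full enumeration with Fraction arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het  # copies of the reference allele

    def ways(h):
        aa = (n_a - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0:
            return 0
        # multinomial count of genotype assignments x 2^h phase choices
        w = Fraction(1)
        # n! / (aa! h! bb!)
        from math import factorial

        w = Fraction(factorial(n), factorial(aa) * factorial(h) * factorial(bb))
        return w * (2**h)

    total = sum(ways(h) for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2))
    probs = {
        h: Fraction(ways(h), total)
        for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
        if ways(h) > 0
    }
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def fisher2x2_oracle(a: int, b: int, c: int, d: int, alternative="two-sided") -> float:
    """Fisher exact p for a 2x2 table by hypergeometric enumeration with
    Fraction arithmetic."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    probs = {k: Fraction(comb(row1, k) * comb(row2, col1 - k), denom) for k in range(lo, hi + 1)}
    obs = probs[a]
    if alternative == "greater":
        return float(sum(p for k, p in probs.items() if k >= a))
    if alternative == "less":
        return float(sum(p for k, p in probs.items() if k <= a))
    return float(sum(p for p in probs.values() if p <= obs))


def rxc_fisher_oracle(T) -> float:
    """Fisher exact p for a small RxC table by exhaustive enumeration of the
    free (R-1)x(C-1) submatrix with Fraction arithmetic."""
    from itertools import product
    from math import factorial

    T = np.asarray(T, dtype=int)
    R, C = T.shape
    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    n = int(T.sum())
    norm = Fraction(1)
    for r in rows:
        norm *= factorial(int(r))
    for c in cols:
        norm *= factorial(int(c))
    norm = Fraction(norm, factorial(n))

    def prob(M):
        den = 1
        for x in M.flat:
            den *= factorial(int(x))
        return norm / den

    obs = prob(T)
    ranges = [
        range(int(min(rows[i], cols[j])) + 1)
        for i in range(R - 1)
        for j in range(C - 1)
    ]
    p = Fraction(0)
    for vals in product(*ranges):
        M = np.zeros((R, C), dtype=int)
        M[: R - 1, : C - 1] = np.array(vals).reshape(R - 1, C - 1)
        M[: R - 1, C - 1] = rows[: R - 1] - M[: R - 1, : C - 1].sum(axis=1)
        M[R - 1, :] = cols - M[: R - 1, :].sum(axis=0)
        if (M >= 0).all():
            pr = prob(M)
            if pr <= obs:
                p += pr
    return float(p)


# ---------------------------------------------------------------------------
# Combinatorial oracles
# ---------------------------------------------------------------------------


def cliques_oracle(edges: dict[tuple[str, str], int], min_weight: int) -> set[frozenset]:
    """Maximal cliques (size >= 2) of the pruned graph by exhaustive subset
    enumeration; feasible for <= ~12 nodes."""
    kept = {frozenset(e) for e, w in edges.items() if w >= min_weight}
    nodes = sorted({v for e in kept for v in e})
    complete = []
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(frozenset(p) in kept for p in combinations(subset, 2)):
                complete.append(frozenset(subset))
    return {c for c in complete if not any(c < other for other in complete)}


def ld_groups_oracle(D: np.ndarray, r2_threshold: float = 1.0) -> list[set[int]]:
    """Transitive closure of the pairwise r^2 >= threshold relation, computed
    per pair with numpy.corrcoef and grouped by BFS."""
    m = D.shape[1]
    adj = {i: set() for i in range(m)}
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(D[:, i]) & ~np.isnan(D[:, j])
            if ok.sum() < 2:
                continue
            x, y = D[ok, i], D[ok, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r >= r2_threshold - 1e-12:
                adj[i].add(j)
                adj[j].add(i)
    seen, groups = set(), []
    for i in range(m):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        groups.append(comp)
    return groups


def crosstab_oracle(rows, cols) -> dict[tuple, int]:
    """Pure-python cross-tabulation."""
    out: dict[tuple, int] = {}
    for r, c in zip(rows, cols):
        out[(r, c)] = out.get((r, c), 0) + 1
    return out


def recount_oracle(clones: pd.DataFrame, col: str, merge: dict, excluded: set,
                   deleted: dict) -> dict[tuple[str, str], float]:
    """Pure-python clone recount for single-assignment tables."""
    out: dict[tuple[str, str], float] = {}
    for _, row in clones.iterrows():
        gene = str(row[col]).split("*")[0]
        if gene in excluded:
            continue
        if gene in deleted.get(row["sample_id"], set()):
            continue
        gene = merge.get(gene, gene)
        key = (gene, row["sample_id"])
        out[key] = out.get(key, 0) + 1
    return out
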