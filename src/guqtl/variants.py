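"""Variant records and hemizygosity-aware genotype matrices.

Genotypes are stored as two integer allele arrays ``a1``/``a2`` of shape
(n_samples, n_variants):

* diploid call: ``a1, a2 >= 0`` (allele indices, unordered);
* hemizygous call (one chromosome deleted): ``a1 >= 0, a2 == HEMI``;
* missing call: ``a1 == a2 == MISSING``.

Hemizygous calls contribute a single allele copy to frequency counts, are
excluded from Hardy-Weinberg testing (HWE is a statement about diploid
genotype frequencies), and are dosage-encoded as 0/2 under the default
"haploid-doubled" policy (the single allele is the sample's entire dosage at
the locus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

MISSING = -1
HEMI = -2

VAR_CLASSES = ("SNV", "INDEL", "SV", "COMPLEX_SV", "MSV", "TANDEM_REPEAT")
# classes tested with ANOVA (categorical genotype) in addition to regression
ANOVA_CLASSES = ("SNV", "COMPLEX_SV", "MSV")


class CallState(Enum):
    DIPLOID = "diploid"
    HEMIZYGOUS = "hemizygous"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    state: CallState
    alleles: tuple[int, ...] = ()

    @classmethod
    def diploid(cls, a1: int, a2: int) -> "GenotypeCall":
        return cls(CallState.DIPLOID, (min(a1, a2), max(a1, a2)))

    @classmethod
    def hemizygous(cls, a: int) -> "GenotypeCall":
        return cls(CallState.HEMIZYGOUS, (a,))

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(CallState.MISSING)

    def label(self) -> str:
        if self.state is CallState.MISSING:
            return "./."
        if self.state is CallState.HEMIZYGOUS:
            return str(self.alleles[0])
        return "/".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class VariantRecord:
    id: str
    position: int  # 1-based locus coordinate
    var_class: str
    alleles: tuple[str, ...]  # reference first
    containing_sv: str | None = None
    span: tuple[int, int] | None = None  # SV classes only
    gene_cn: dict[str, dict[str, int]] | None = None  # SV: allele name -> gene -> copies

    def __post_init__(self):
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if len(self.alleles) < 2:
            raise ValueError(f"{self.id}: need >= 2 alleles")
        if self.var_class == "SNV" and len(self.alleles) != 2:
            raise ValueError(f"{self.id}: biallelic SNV expected")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2


@dataclass(frozen=True)
class AlleleStats:
    counts: tuple[int, ...]  # allele copies per allele index
    n_genotyped: int  # samples with a non-missing call
    maf: float  # NaN when no genotyped samples

    @property
    def frequencies(self) -> tuple[float, ...]:
        tot = sum(self.counts)
        if tot == 0:
            return tuple(math.nan for _ in self.counts)
        return tuple(c / tot for c in self.counts)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test for a biallelic variant.

    Sums the probability, conditional on the observed allele counts, of all
    heterozygote counts whose probability does not exceed the observed one.
    Hemizygous samples must be excluded before counting.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped diploid sample")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele copies
    # log-probability of each possible het count h (h has the parity of n_rare)
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(h) proportional to n! / (n_aa! n_ab! n_bb!) * 2^h, with
    # n_ab = h, n_aa = (n_rare - h)/2, n_bb = n - n_ab - n_aa
    n_aa = (n_rare - hs) // 2
    n_bb = n - hs - n_aa
    logp = (
        hs * math.log(2.0)
        - _lgamma_arr(hs + 1)
        - _lgamma_arr(n_aa + 1)
        - _lgamma_arr(n_bb + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.nonzero(hs == n_het)[0][0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    samples: list[str]
    variants: list[VariantRecord]
    a1: np.ndarray  # (n_samples, n_variants) int16
    a2: np.ndarray

    def __post_init__(self):
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        self._vidx = {v.id: j for j, v in enumerate(self.variants)}

    # ------------------------------------------------------------------ access

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self._vidx[variant_id]]

    def variant_index(self, variant_id: str) -> int:
        return self._vidx[variant_id]

    def call(self, sample_id: str, variant_id: str) -> GenotypeCall:
        i = self.samples.index(sample_id)
        j = self._vidx[variant_id]
        return self._call_at(i, j)

    def _call_at(self, i: int, j: int) -> GenotypeCall:
        a1, a2 = int(self.a1[i, j]), int(self.a2[i, j])
        if a1 == MISSING:
            return GenotypeCall.missing()
        if a2 == HEMI:
            return GenotypeCall.hemizygous(a1)
        return GenotypeCall.diploid(a1, a2)

    def subset(self, sample_ids=None, variant_ids=None) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self.samples.index(s) for s in sample_ids], dtype=int)
        )
        cols = (
            np.arange(self.n_variants)
            if variant_ids is None
            else np.array([self._vidx[v] for v in variant_ids], dtype=int)
        )
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            variants=[self.variants[j] for j in cols],
            a1=self.a1[np.ix_(rows, cols)].copy(),
            a2=self.a2[np.ix_(rows, cols)].copy(),
        )

    # ------------------------------------------------------------------- stats

    def allele_stats(self, variant_id: str) -> AlleleStats:
        j = self._vidx[variant_id]
        v = self.variants[j]
        a1, a2 = self.a1[:, j], self.a2[:, j]
        counts = np.zeros(v.n_alleles, dtype=int)
        diploid = (a1 >= 0) & (a2 >= 0)
        hemi = (a1 >= 0) & (a2 == HEMI)
        for arr, mask in ((a1, diploid | hemi), (a2, diploid)):
            np.add.at(counts, arr[mask], 1)
        n_genotyped = int((a1 != MISSING).sum())
        tot = counts.sum()
        if tot == 0:
            maf = math.nan
        else:
            freqs = counts / tot
            maf = float(min(freqs)) if v.is_biallelic else float(1.0 - freqs.max())
        return AlleleStats(counts=tuple(int(c) for c in counts), n_genotyped=n_genotyped, maf=maf)

    def hwe_p(self, variant_id: str) -> float:
        """HWE exact p over diploid samples; 1.0 for multi-allelic variants
        (the test is applied to biallelic SNVs in the filtering step)."""
        j = self._vidx[variant_id]
        v = self.variants[j]
        if not v.is_biallelic:
            return 1.0
        a1, a2 = self.a1[:, j], self.a2[:, j]
        diploid = (a1 >= 0) & (a2 >= 0)
        alt = (a1[diploid] == 1).astype(int) + (a2[diploid] == 1).astype(int)
        n = int(diploid.sum())
        if n == 0:
            return 1.0
        return hwe_exact_test(int((alt == 0).sum()), int((alt == 1).sum()), int((alt == 2).sum()))

    # ------------------------------------------------------------------ dosage

    def dosage(self, variant_id: str, policy: str = "haploid-doubled") -> np.ndarray:
        """Alt-allele dosage vector with NaN at missing calls (biallelic only)."""
        j = self._vidx[variant_id]
        if not self.variants[j].is_biallelic:
            raise ValueError(f"{variant_id}: dosage encoding requires a biallelic variant")
        a1, a2 = self.a1[:, j], self.a2[:, j]
        return _dosage_arrays(a1, a2, policy)

    def genotype_labels(self, variant_id: str) -> np.ndarray:
        """Categorical genotype label per sample ('0/1', '1', './.')."""
        j = self._vidx[variant_id]
        a1, a2 = self.a1[:, j].astype(int), self.a2[:, j].astype(int)
        codes = (np.minimum(a1, a2) + 10) * 1000 + (np.maximum(a1, a2) + 10)
        uniq, first = np.unique(codes, return_index=True)
        labels = {}
        for code, i in zip(uniq, first):
            a, b = int(a1[i]), int(a2[i])
            if a == MISSING:
                labels[code] = "./."
            elif b == HEMI:
                labels[code] = str(a)
            else:
                labels[code] = f"{min(a, b)}/{max(a, b)}"
        return np.array([labels[c] for c in codes], dtype=object)

    # --------------------------------------------------------------- filtering

    def filter_common(
        self,
        maf_min: float = 0.05,
        min_genotyped: int = 40,
        hwe_min: float = 1e-6,
    ) -> tuple["GenotypeMatrix", "pd.DataFrame"]:
        """Common-variant selection: MAF >= maf_min, genotyped in at least
        ``min_genotyped`` samples, HWE exact p >= hwe_min (biallelic SNVs).
        Returns the filtered matrix and a per-variant removal log."""
        keep, log_rows = [], []
        for v in self.variants:
            st = self.allele_stats(v.id)
            rule = None
            if st.n_genotyped < min_genotyped:
                rule = "min_genotyped"
            elif not (st.maf >= maf_min):  # NaN fails too
                rule = "maf"
            elif v.var_class == "SNV" and self.hwe_p(v.id) < hwe_min:
                rule = "hwe"
            if rule is None:
                keep.append(v.id)
            log_rows.append(
                {
                    "variant": v.id,
                    "var_class": v.var_class,
                    "maf": st.maf,
                    "n_genotyped": st.n_genotyped,
                    "removed_by": rule or "",
                }
            )
        return self.subset(variant_ids=keep), pd.DataFrame(log_rows)

    # -------------------------------------------------------------- imputation

    def impute_missing(self, policy: str = "drop", seed: int = 0) -> "GenotypeMatrix":
        """'drop' leaves missing calls missing (they are excluded pairwise in
        associations); 'frequency' fills them by drawing from the observed
        genotype-call distribution.  Positions missing because of homozygous
        deletions (inside an SV called hom-deleted) are never filled."""
        if policy == "drop":
            return self
        if policy != "frequency":
            raise ValueError(f"unknown imputation policy {policy!r}")
        rng = np.random.default_rng(seed)
        a1 = self.a1.copy()
        a2 = self.a2.copy()
        sv_idx = {
            v.id: j for j, v in enumerate(self.variants) if v.gene_cn is not None
        }
        for j, v in enumerate(self.variants):
            miss = a1[:, j] == MISSING
            if not miss.any():
                continue
            protected = np.zeros(self.n_samples, dtype=bool)
            if v.containing_sv is not None and v.containing_sv in sv_idx:
                k = sv_idx[v.containing_sv]
                sv = self.variants[k]
                deleting = np.array(
                    [False]
                    + [
                        all(c == 0 for c in sv.gene_cn[a.strip("<>")].values())
                        for a in sv.alleles[1:]
                    ]
                )
                protected = deleting[a1[:, k]] & deleting[np.maximum(a2[:, k], 0)]
            fill = miss & ~protected
            if not fill.any():
                continue
            obs = np.nonzero(~miss)[0]
            if len(obs) == 0:
                continue
            pick = rng.choice(obs, size=int(fill.sum()))
            a1[fill, j] = a1[pick, j]
            a2[fill, j] = a2[pick, j]
        return GenotypeMatrix(self.samples, self.variants, a1, a2)

    # ---------------------------------------------------------------------- LD

    def compute_ld(self, v1: str, v2: str, policy: str = "haploid-doubled"):
        """(r, r2): Pearson correlation of dosages over pairwise-complete
        samples; (nan, nan) when either vector is constant."""
        d1 = self.dosage(v1, policy)
        d2 = self.dosage(v2, policy)
        ok = ~np.isnan(d1) & ~np.isnan(d2)
        if ok.sum() < 2:
            raise ValueError("need >= 2 pairwise-complete samples")
        x, y = d1[ok], d2[ok]
        if np.std(x) == 0 or np.std(y) == 0:
            return math.nan, math.nan
        r = float(np.corrcoef(x, y)[0, 1])
        return r, r * r

    def collapse_perfect_ld(
        self, r2_threshold: float = 1.0, policy: str = "haploid-doubled"
    ) -> list[list[str]]:
        """Partition variants into perfect-LD groups (transitive closure of the
        pairwise r^2 >= threshold relation over biallelic variants; variants
        that cannot be dosage-encoded form singleton groups).  The number of
        groups is the effective test count for Bonferroni correction."""
        bi = [v.id for v in self.variants if v.is_biallelic]
        D = np.full((self.n_samples, len(bi)), np.nan)
        for k, vid in enumerate(bi):
            D[:, k] = self.dosage(vid, policy)
        parent = list(range(len(bi)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[max(rx, ry)] = min(rx, ry)

        tol = 1e-12
        has_nan = np.isnan(D).any(axis=0)
        full = np.nonzero(~has_nan)[0]
        # complete columns: one bulk correlation matrix
        if len(full) >= 2:
            X = D[:, full]
            sd = X.std(axis=0)
            ok_sd = sd > 0
            Xc = X[:, ok_sd] - X[:, ok_sd].mean(axis=0)
            denom = np.sqrt((Xc**2).sum(axis=0))
            R = (Xc.T @ Xc) / np.outer(denom, denom)
            cols = full[ok_sd]
            ii, jj = np.nonzero(np.triu(R * R >= r2_threshold - tol, k=1))
            for a, b in zip(ii, jj):
                union(int(cols[a]), int(cols[b]))
        # columns with missing calls: pairwise-complete correlations,
        # vectorised against all complete columns per missing column
        nan_cols = np.nonzero(has_nan)[0]
        for i in nan_cols:
            ok = ~np.isnan(D[:, i])
            if ok.sum() < 2:
                continue
            x = D[ok, i]
            if np.std(x) == 0:
                continue
            if len(full):
                Y = D[np.ix_(ok, full)]
                xc = x - x.mean()
                Yc = Y - Y.mean(axis=0)
                xn = np.sqrt((xc**2).sum())
                yn = np.sqrt((Yc**2).sum(axis=0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = (Yc.T @ xc) / (xn * yn)
                for k in np.nonzero(r * r >= r2_threshold - tol)[0]:
                    union(int(i), int(full[k]))
            for j in nan_cols:
                if j <= i:
                    continue
                ok2 = ok & ~np.isnan(D[:, j])
                if ok2.sum() < 2:
                    continue
                a, b = D[ok2, i], D[ok2, j]
                if np.std(a) == 0 or np.std(b) == 0:
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                if r * r >= r2_threshold - tol:
                    union(int(i), int(j))
        groups: dict[int, list[str]] = {}
        for k, vid in enumerate(bi):
            groups.setdefault(find(k), []).append(vid)
        out = [sorted(g, key=self._vidx.get) for g in groups.values()]
        out.sort(key=lambda g: self._vidx[g[0]])
        for v in self.variants:  # multi-allelic: one group each
            if not v.is_biallelic:
                out.append([v.id])
        return out


def _dosage_arrays(a1: np.ndarray, a2: np.ndarray, policy: str) -> np.ndarray:
    if policy not in ("haploid-doubled",):
        raise ValueError(f"unknown dosage policy {policy!r}")
    d = np.full(a1.shape, np.nan)
    diploid = (a1 >= 0) & (a2 >= 0)
    hemi = (a1 >= 0) & (a2 == HEMI)
    d[diploid] = (a1[diploid] == 1).astype(float) + (a2[diploid] == 1).astype(float)
    d[hemi] = 2.0 * (a1[hemi] == 1)
    return d


def encode_dosage(call: GenotypeCall, policy: str = "haploid-doubled"):
    """Numeric dosage for one call; raises on missing calls."""
    if call.state is CallState.MISSING:
        raise ValueError("cannot encode a missing call")
    if policy == "categorical":
        return call.label()
    if policy != "haploid-doubled":
        raise ValueError(f"unknown dosage policy {policy!r}")
    if call.state is CallState.HEMIZYGOUS:
        return 2 * int(call.alleles[0] == 1)
    return int(call.alleles[0] == 1) + int(call.alleles[1] == 1)
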