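"""Simulation of a diploid IGH cohort: haplotypes, genotypes, usage
probabilities and clone-level antibody repertoires.

Each simulated chromosome is a tuple of (one pool-haplotype index per LD
block, one allele per SV).  Genotypes, gene copy numbers, usage probabilities
and clone tables are all derived deterministically from these haplotypes and
the model, so every downstream quantity has an accessible ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locus import LocusModel, SEGMENT_CLASSES
from .variants import (
    HEMI,
    MISSING,
    GenotypeMatrix,
    VariantRecord,
)

ISOTYPES = ("IgM", "IgG")
_C_CALL = {"IgM": "IGHM", "IgG": "IGHG1"}

# fixed offsets splitting a master seed into per-stage child streams
_STAGE = {"haplotypes": 0, "covariates": 1, "clones": 2}


def _child_seed(master: int, stage: str, extra: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(master, spawn_key=(_STAGE[stage], extra))
    return np.random.default_rng(ss)


@dataclass
class SimulatedCohort:
    model: LocusModel
    sample_ids: list[str]
    # (n_samples, 2, n_blocks) pool haplotype index per block per chromosome
    block_haps: np.ndarray
    # (n_samples, 2, n_svs) allele index per SV per chromosome
    sv_alleles: np.ndarray
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame  # index sample_id; columns age, platform
    master_seed: int
    # lazy caches
    _usage: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    # ------------------------------------------------------------- copy number

    def gene_copy_number(self, sample_id: str) -> dict[str, int]:
        """Diploid copy number per gene (sum of the two haploid copy maps;
        genes outside any SV carry 1 copy per haplotype)."""
        i = self.sample_index(sample_id)
        return {
            g.name: int(self._cn_matrix()[i, j])
            for j, g in enumerate(self.model.genes)
        }

    def _cn_matrix(self) -> np.ndarray:
        """(n_samples, n_genes) diploid copy numbers."""
        if not hasattr(self, "_cn"):
            self._cn = self._hap_cn().sum(axis=1)
        return self._cn

    def _hap_cn(self) -> np.ndarray:
        """(n_samples, 2, n_genes) haploid copy numbers."""
        if hasattr(self, "_hapcn"):
            return self._hapcn
        m = self.model
        n = self.n_samples
        cn = np.ones((n, 2, len(m.genes)), dtype=np.int32)
        gene_pos = {g.name: j for j, g in enumerate(m.genes)}
        for k, sv in enumerate(m.sv_defs):
            allele_cn = np.zeros((len(sv.alleles), len(m.genes)), dtype=np.int32)
            cols = []
            for g in sv.alleles[0].gene_cn:
                cols.append(gene_pos[g])
            for a, al in enumerate(sv.alleles):
                for g, c in al.gene_cn.items():
                    allele_cn[a, gene_pos[g]] = c
            idx = self.sv_alleles[:, :, k]  # (n, 2)
            cn[:, :, cols] = allele_cn[idx][:, :, cols]
        self._hapcn = cn
        return cn

    # ---------------------------------------------------------------- usage

    def _hap_weights(self) -> np.ndarray:
        """(n_samples, 2, n_genes) unnormalised per-haplotype weights:
        copies x baseline x product of active cis multipliers."""
        if hasattr(self, "_hw"):
            return self._hw
        m = self.model
        gene_pos = {g.name: j for j, g in enumerate(m.genes)}
        base = np.array([m.baseline_weights[g.name] for g in m.genes])
        w = self._hap_cn() * base[None, None, :]
        w = w.astype(float)
        snv_pos = {s.id: j for j, s in enumerate(m.snv_defs)}
        block_pos = {b.id: j for j, b in enumerate(m.blocks)}
        sv_pos = {s.id: j for j, s in enumerate(m.sv_defs)}
        for eff in m.effect_map:
            gj = gene_pos[eff.gene]
            if ":" in eff.variant and eff.variant.split(":", 1)[0] in sv_pos:
                sv_id, allele_name = eff.variant.split(":", 1)
                sv = m.sv(sv_id)
                a_idx = [a.name for a in sv.alleles].index(allele_name)
                carried = self.sv_alleles[:, :, sv_pos[sv_id]] == a_idx
            else:
                snv = m.snv_defs[snv_pos[eff.variant]]
                bj = block_pos[snv.block]
                carried = np.isin(self.block_haps[:, :, bj], snv.carriers)
                if snv.containing_sv is not None:
                    sv = m.sv(snv.containing_sv)
                    deleted = np.array([a.deletes_snvs for a in sv.alleles])
                    carried &= ~deleted[self.sv_alleles[:, :, sv_pos[snv.containing_sv]]]
            w[:, :, gj] *= np.where(carried, eff.multiplier, 1.0)
        self._hw = w
        return w

    def usage_probs(self, segment: str) -> pd.DataFrame:
        """True per-sample usage probabilities for one segment class
        (genes x samples), normalised to sum to 1 within the class."""
        if segment in self._usage:
            return self._usage[segment]
        m = self.model
        idx = [j for j, g in enumerate(m.genes) if g.segment == segment]
        names = [m.genes[j].name for j in idx]
        w = self._hap_weights()[:, :, idx].sum(axis=1)  # (n_samples, n_genes)
        cov = m.covariate_model
        lvl = {p: k for k, p in enumerate(cov.platform_levels)}
        age = self.covariates["age"].to_numpy(float)
        plat = self.covariates["platform"].map(lvl).to_numpy()
        mid_age = float(np.mean(cov.age_range))
        for j, name in enumerate(names):
            pe = cov.platform_effect.get(name)
            if pe is not None:
                w[:, j] *= np.asarray(pe)[plat]
            slope = cov.age_slope.get(name, 0.0)
            if slope:
                w[:, j] *= np.clip(1.0 + slope * (age - mid_age), 1e-6, None)
        tot = w.sum(axis=1)
        if np.any(tot <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(tot <= 0)[0]]
            raise ValueError(f"degenerate samples with all {segment} genes deleted: {bad}")
        probs = (w / tot[:, None]).T  # genes x samples
        df = pd.DataFrame(probs, index=names, columns=self.sample_ids)
        self._usage[segment] = df
        return df

    def usage_prob_vector(self, sample_id: str) -> pd.Series:
        """Concatenated per-class usage probabilities for one sample."""
        parts = [self.usage_probs(s)[sample_id] for s in SEGMENT_CLASSES]
        return pd.concat(parts)

    # ---------------------------------------------------------------- clones

    def clone_counts(self, n_clones: int, seed: int, segment: str = "V") -> pd.DataFrame:
        """Multinomial clone counts (genes x samples) for one segment class."""
        probs = self.usage_probs(segment)
        rng = np.random.default_rng(seed)
        counts = np.column_stack(
            [rng.multinomial(n_clones, probs[s].to_numpy()) for s in self.sample_ids]
        )
        return pd.DataFrame(counts, index=probs.index, columns=self.sample_ids)

    def simulate_clones(
        self,
        sample_id: str,
        n_clones: int,
        seed: int,
        isotype: str = "IgM",
    ) -> pd.DataFrame:
        """Clone-level AIRR rows for one sample/isotype.

        The V, D and J gene of each clone are drawn independently from the
        sample's class usage probabilities; the coding-allele suffix of each
        call comes from the originating haplotype (chosen proportionally to
        that haplotype's weight contribution for the gene).
        """
        if n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if isotype not in ISOTYPES:
            raise ValueError(f"isotype must be one of {ISOTYPES}")
        i = self.sample_index(sample_id)
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(i, ISOTYPES.index(isotype)))
        )
        m = self.model
        hw = self._hap_weights()[i]  # (2, n_genes)
        block_pos = {b.id: j for j, b in enumerate(m.blocks)}
        calls: dict[str, np.ndarray] = {}
        for seg in SEGMENT_CLASSES:
            idx = [j for j, g in enumerate(m.genes) if g.segment == seg]
            p = self.usage_probs(seg)[sample_id].to_numpy()
            gene_draw = rng.choice(len(idx), size=n_clones, p=p)
            labels = np.empty(n_clones, dtype=object)
            for k_local in np.unique(gene_draw):
                j = idx[k_local]
                gene = m.genes[j]
                sel = gene_draw == k_local
                wpair = hw[:, j]
                tot = wpair.sum()
                if tot > 0:
                    hap_choice = rng.random(int(sel.sum())) < (wpair[1] / tot)
                else:  # deleted on both haplotypes; cannot be drawn (p=0)
                    hap_choice = np.zeros(int(sel.sum()), dtype=bool)
                tag_block = m.coding_tag.get(gene.name)
                if tag_block is None:
                    alleles = np.array(["*01", "*01"])
                else:
                    bj = block_pos[tag_block]
                    alleles = np.array(
                        [m.coding_allele(gene.name, int(h)) for h in self.block_haps[i, :, bj]]
                    )
                labels[sel] = gene.name + alleles[hap_choice.astype(int)]
            calls[seg] = labels
        n = n_clones
        df = pd.DataFrame(
            {
                "sequence_id": [f"{sample_id}_{isotype}_{k}" for k in range(n)],
                "sample_id": sample_id,
                "c_call": _C_CALL[isotype],
                "v_call": calls["V"],
                "d_call": calls["D"],
                "j_call": calls["J"],
                "junction_length": rng.integers(10, 21, size=n) * 3,
                "duplicate_count": 1 + rng.poisson(1.5, size=n),
                "clone_id": [f"{sample_id}_{isotype}_c{k}" for k in range(n)],
            }
        )
        return df

    def simulate_all_clones(
        self,
        seed: int,
        mean_clones: int = 9000,
        isotypes: tuple[str, ...] = ("IgM",),
    ) -> pd.DataFrame:
        """Clone tables for every sample; per-repertoire clone numbers are
        Poisson around ``mean_clones`` (the cohort-scale mean)."""
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
        tables = []
        for s in self.sample_ids:
            for iso in isotypes:
                n = max(1, int(rng.poisson(mean_clones)))
                tables.append(self.simulate_clones(s, n, seed, isotype=iso))
        return pd.concat(tables, ignore_index=True)

    # ------------------------------------------------------------ ground truth

    def true_usage_fractions(self) -> tuple[pd.DataFrame, pd.Series]:
        """Noise-free usage on the analysis basis: excluded genes removed,
        duplicated genes merged, renormalised within segment class.  Returns
        (genes x samples frame, gene -> segment map)."""
        if hasattr(self, "_tuf"):
            return self._tuf
        from .usage import (
            DEFAULT_EXCLUDED_GENES,
            DEFAULT_MERGE_GROUPS,
            merge_map_from_groups,
        )

        merge = merge_map_from_groups(DEFAULT_MERGE_GROUPS)
        frames, seg_map = [], {}
        for seg in SEGMENT_CLASSES:
            if not self.model.genes_of_class(seg):
                continue
            probs = self.usage_probs(seg)
            probs = probs.drop(index=[g for g in DEFAULT_EXCLUDED_GENES if g in probs.index])
            probs = probs.groupby([merge.get(g, g) for g in probs.index]).sum()
            probs = probs / probs.sum(axis=0)
            frames.append(probs)
            seg_map.update({g: seg for g in probs.index})
        self._tuf = (pd.concat(frames), pd.Series(seg_map))
        return self._tuf

    def true_dosage(self, variant_id: str) -> np.ndarray:
        """Alt-dosage (0/1/2) straight from the haplotypes, ignoring
        deletion-induced missingness (SVs: index of the non-reference allele)."""
        m = self.model
        for j, s in enumerate(m.snv_defs):
            if s.id == variant_id:
                bj = [b.id for b in m.blocks].index(s.block)
                return np.isin(self.block_haps[:, :, bj], s.carriers).sum(axis=1)
        for k, sv in enumerate(m.sv_defs):
            if sv.id == variant_id:
                return (self.sv_alleles[:, :, k] != 0).sum(axis=1)
        raise KeyError(variant_id)

    def true_r2(
        self,
        gene: str,
        variant_id: str,
        n_clones: int | None = None,
        adjust_covariates: bool = False,
    ) -> float:
        """Fraction of variance of the usage of ``gene`` explained by the
        variant's dosage across the cohort, on the analysis basis
        (merged/excluded/renormalised) when the gene is a retained row, else
        on the raw model basis.

        With ``n_clones`` given, the returned value is the population R^2 of
        the *observed* usage process: multinomial clone sampling adds
        ~u(1-u)/n_clones of genotype-independent variance per sample, which
        attenuates the explainable fraction.  With ``adjust_covariates`` the
        usage and dosage are first residualised on age and platform, matching
        the estimand of the covariate-adjusted association model."""
        frame, _ = self.true_usage_fractions()
        if gene in frame.index:
            u = frame.loc[gene].to_numpy(float)
        else:
            seg = self.model.gene(gene).segment
            u = self.usage_probs(seg).loc[gene].to_numpy(float)
        d = self.true_dosage(variant_id).astype(float)
        noise_var = float(np.mean(u * (1.0 - u))) / n_clones if n_clones else 0.0
        if adjust_covariates:
            cov = self.covariates
            cols = [np.ones(self.n_samples), cov["age"].to_numpy(float)]
            for lv in sorted(cov["platform"].unique())[1:]:
                cols.append((cov["platform"] == lv).to_numpy(float))
            X = np.column_stack(cols)
            q, _ = np.linalg.qr(X)
            u = u - q @ (q.T @ u)
            d = d - q @ (q.T @ d)
        if np.std(d) == 0 or np.std(u) == 0:
            return 0.0
        r = np.corrcoef(u, d)[0, 1]
        r2 = float(r * r)
        if n_clones:
            var_true = float(u.var())
            r2 *= var_true / (var_true + noise_var)
        return r2

    def truth_registry(self) -> dict:
        m = self.model
        return {
            "master_seed": self.master_seed,
            "effects": [
                {
                    "variant": e.variant,
                    "gene": e.gene,
                    "multiplier": e.multiplier,
                    "true_r2": self.true_r2(e.gene, e.variant.split(":", 1)[0]),
                }
                for e in m.effect_map
            ],
            "sv_genes": {
                sv.id: sorted(sv.alleles[0].gene_cn) for sv in m.sv_defs
            },
            "sv_true_r2": {
                sv.id: {g: self.true_r2(g, sv.id) for g in sv.alleles[0].gene_cn}
                for sv in m.sv_defs
            },
        }


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------


def simulate_haplotypes(model: LocusModel, n_samples: int, seed: int) -> SimulatedCohort:
    """Draw a cohort of diploid haplotypes from the model.

    Block haplotypes are drawn independently per block (so LD is high within
    and near-zero across blocks); SV alleles are drawn at their stated
    frequencies; the genotype matrix is derived, with SNVs inside heterozygous
    deletions reported hemizygous and inside homozygous deletions missing.
    """
    model.validate()
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = _child_seed(seed, "haplotypes")
    n_blocks = len(model.blocks)
    n_svs = len(model.sv_defs)
    block_haps = np.zeros((n_samples, 2, n_blocks), dtype=np.int16)
    for j, b in enumerate(model.blocks):
        block_haps[:, :, j] = rng.choice(
            len(b.hap_freqs), size=(n_samples, 2), p=np.asarray(b.hap_freqs)
        )
    sv_alleles = np.zeros((n_samples, 2, n_svs), dtype=np.int16)
    for k, sv in enumerate(model.sv_defs):
        sv_alleles[:, :, k] = rng.choice(
            len(sv.alleles), size=(n_samples, 2), p=np.asarray([a.frequency for a in sv.alleles])
        )

    crng = _child_seed(seed, "covariates")
    cov = model.covariate_model
    ages = np.round(crng.uniform(*cov.age_range, size=n_samples), 1)
    platforms = crng.choice(cov.platform_levels, size=n_samples, p=np.asarray(cov.platform_freqs))
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    covariates = pd.DataFrame(
        {"age": ages, "platform": platforms}, index=pd.Index(sample_ids, name="sample_id")
    )

    genotypes = _derive_genotypes(model, sample_ids, block_haps, sv_alleles)
    return SimulatedCohort(
        model=model,
        sample_ids=sample_ids,
        block_haps=block_haps,
        sv_alleles=sv_alleles,
        genotypes=genotypes,
        covariates=covariates,
        master_seed=seed,
    )


def _derive_genotypes(model, sample_ids, block_haps, sv_alleles) -> GenotypeMatrix:
    n = len(sample_ids)
    records: list[VariantRecord] = []
    a1_cols: list[np.ndarray] = []
    a2_cols: list[np.ndarray] = []
    block_pos = {b.id: j for j, b in enumerate(model.blocks)}
    sv_pos = {s.id: j for j, s in enumerate(model.sv_defs)}

    for s in model.snv_defs:
        bj = block_pos[s.block]
        alt = np.isin(block_haps[:, :, bj], s.carriers).astype(np.int16)  # (n, 2)
        present = np.ones((n, 2), dtype=bool)
        if s.containing_sv is not None:
            sv = model.sv(s.containing_sv)
            deleted = np.array([a.deletes_snvs for a in sv.alleles])
            present = ~deleted[sv_alleles[:, :, sv_pos[s.containing_sv]]]
        a1 = np.where(present[:, 0], alt[:, 0], MISSING)
        a2 = np.where(present[:, 1], alt[:, 1], MISSING)
        # normalise: haplotype 0 absent but 1 present -> hemizygous call in a1
        swap = (a1 == MISSING) & (a2 != MISSING)
        a1s = np.where(swap, a2, a1)
        a2s = np.where(swap, HEMI, np.where((a1 != MISSING) & (a2 == MISSING), HEMI, a2))
        ref, alt_allele = ("A", "G") if s.var_class == "SNV" else ("AT", "A")
        records.append(
            VariantRecord(
                id=s.id,
                position=s.position,
                var_class=s.var_class,
                alleles=(ref, alt_allele),
                containing_sv=s.containing_sv,
            )
        )
        a1_cols.append(a1s.astype(np.int16))
        a2_cols.append(a2s.astype(np.int16))

    for sv in model.sv_defs:
        k = sv_pos[sv.id]
        alleles = ("N",) + tuple(f"<{a.name}>" for a in sv.alleles[1:])
        records.append(
            VariantRecord(
                id=sv.id,
                position=sv.span[0],
                var_class=sv.var_class,
                alleles=alleles,
                span=sv.span,
                gene_cn={a.name: dict(a.gene_cn) for a in sv.alleles},
            )
        )
        a1_cols.append(sv_alleles[:, 0, k].astype(np.int16))
        a2_cols.append(sv_alleles[:, 1, k].astype(np.int16))

    order = np.argsort([r.position for r in records], kind="stable")
    records = [records[j] for j in order]
    a1 = np.column_stack([a1_cols[j] for j in order])
    a2 = np.column_stack([a2_cols[j] for j in order])
    return GenotypeMatrix(samples=list(sample_ids), variants=records, a1=a1, a2=a2)


def simulate_cohort(
    model: LocusModel | None = None,
    n_samples: int = 150,
    seed: int = 0,
) -> SimulatedCohort:
    """Convenience wrapper: default model + haplotypes + covariates."""
    from .locus import default_model

    if model is None:
        model = default_model()
    return simulate_haplotypes(model, n_samples, seed)
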