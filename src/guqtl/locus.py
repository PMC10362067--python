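"""Generative model of the IGH locus used by the synthetic cohort simulator.

The model describes, for one haplotype of the locus:

* an ordered set of V/D/J gene segments with per-copy baseline recombination
  weights (the propensity of a gene to be chosen during V(D)J recombination);
* structural variants (SVs) whose alleles change the haploid copy number of
  the genes they span -- deletions, duplications and multi-allelic SVs (mSVs);
* SNVs/indels organised into LD blocks: each block has a small pool of
  ancestral block haplotypes, and every simulated chromosome carries one pool
  haplotype per block, which is what produces high within-block and near-zero
  across-block linkage disequilibrium;
* cis-regulatory effects: a variant allele carried on a haplotype multiplies
  the recombination weight of its target gene on that same haplotype;
* a covariate model (age slope per gene, a multiplicative per-gene batch
  factor per sequencing platform).

Usage probabilities for a diploid individual are additive over the two
haplotypes and normalised within each segment class (V, D, J), mirroring the
observed additive relationship between diploid gene copy number and usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

SEGMENT_CLASSES = ("V", "D", "J")


@dataclass(frozen=True)
class GeneDef:
    """One germline gene segment."""

    name: str
    segment: str  # "V", "D" or "J"
    position: int  # 1-based locus coordinate of the gene body midpoint
    functional: bool = True

    def __post_init__(self):
        if self.segment not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.segment!r}")


@dataclass(frozen=True)
class SVAllele:
    """One allele of a structural variant.

    ``gene_cn`` maps spanned gene names to the haploid copy number carried by
    this allele.  ``deletes_snvs`` marks alleles on which the spanned sequence
    is absent, so SNVs inside the span cannot be called on that haplotype
    (the source of hemizygous and missing SNV genotypes).
    """

    name: str
    frequency: float
    gene_cn: dict[str, int] = field(default_factory=dict)
    deletes_snvs: bool = False


@dataclass(frozen=True)
class SVDef:
    id: str
    span: tuple[int, int]  # 1-based inclusive start, end
    alleles: tuple[SVAllele, ...]  # reference allele first
    var_class: str = "SV"  # "SV", "COMPLEX_SV" or "MSV"


@dataclass(frozen=True)
class LDBlock:
    """A pool of block haplotypes with draw frequencies."""

    id: str
    hap_freqs: tuple[float, ...]


@dataclass(frozen=True)
class SNVDef:
    """A small variant (SNV or indel) belonging to one LD block.

    ``carriers`` lists the pool-haplotype indices of the block that carry the
    alternate allele; the alternate allele frequency is therefore the sum of
    the corresponding pool frequencies.
    """

    id: str
    position: int
    block: str
    carriers: tuple[int, ...]
    var_class: str = "SNV"  # "SNV" or "INDEL"
    containing_sv: str | None = None


@dataclass(frozen=True)
class EffectDef:
    """A cis effect: each copy of the variant allele on a haplotype multiplies
    the target gene's recombination weight on that haplotype.

    ``variant`` is an SNV id, or ``"<sv_id>:<allele_name>"`` for an SV allele.
    """

    variant: str
    gene: str
    multiplier: float


@dataclass
class CovariateModel:
    platform_levels: tuple[str, ...] = ("A", "B", "C")
    platform_freqs: tuple[float, ...] = (0.45, 0.35, 0.20)
    # per-gene multiplicative factor per platform level (missing genes -> 1.0)
    platform_effect: dict[str, tuple[float, ...]] = field(default_factory=dict)
    age_slope: dict[str, float] = field(default_factory=dict)  # per year, usually 0
    age_range: tuple[float, float] = (18.0, 75.0)


@dataclass
class LocusModel:
    genes: list[GeneDef]
    sv_defs: list[SVDef]
    blocks: list[LDBlock]
    snv_defs: list[SNVDef]
    effect_map: list[EffectDef]
    baseline_weights: dict[str, float]
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    # per gene: LD block whose pool haplotype determines the coding allele label
    coding_tag: dict[str, str] = field(default_factory=dict)
    contig: str = "igh"
    locus_length: int = 1_300_000

    # ------------------------------------------------------------------ helpers

    def gene(self, name: str) -> GeneDef:
        return self._gene_index()[name]

    def _gene_index(self) -> dict[str, GeneDef]:
        if not hasattr(self, "_gidx"):
            self._gidx = {g.name: g for g in self.genes}
        return self._gidx

    def block(self, block_id: str) -> LDBlock:
        if not hasattr(self, "_bidx"):
            self._bidx = {b.id: b for b in self.blocks}
        return self._bidx[block_id]

    def sv(self, sv_id: str) -> SVDef:
        if not hasattr(self, "_svidx"):
            self._svidx = {s.id: s for s in self.sv_defs}
        return self._svidx[sv_id]

    def gene_sv(self, gene: str) -> str | None:
        """Id of the SV whose alleles control this gene's copy number."""
        if not hasattr(self, "_gene_sv"):
            m: dict[str, str] = {}
            for sv in self.sv_defs:
                for al in sv.alleles:
                    for g in al.gene_cn:
                        m[g] = sv.id
            self._gene_sv = m
        return self._gene_sv.get(gene)

    def snv_alt_frequency(self, snv: SNVDef) -> float:
        freqs = self.block(snv.block).hap_freqs
        return float(sum(freqs[i] for i in snv.carriers))

    def coding_allele(self, gene: str, block_hap_index: int) -> str:
        return f"*{block_hap_index + 1:02d}"

    def genes_of_class(self, segment: str) -> list[GeneDef]:
        return [g for g in self.genes if g.segment == segment]

    # --------------------------------------------------------------- validation

    def validate(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        for g in self.genes:
            w = self.baseline_weights.get(g.name)
            if w is None or not w > 0:
                raise ValueError(f"baseline weight for {g.name} must be > 0")
        gene_owner: dict[str, str] = {}
        for sv in self.sv_defs:
            freqs = [a.frequency for a in sv.alleles]
            if not freqs or all(f == 0 for f in freqs):
                raise ValueError(f"SV {sv.id}: all allele frequencies zero")
            if any(f < 0 or f > 1 for f in freqs):
                raise ValueError(f"SV {sv.id}: allele frequency outside [0,1]")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"SV {sv.id}: allele frequencies must sum to 1")
            ref = sv.alleles[0]
            for g, cn in ref.gene_cn.items():
                if cn != 1:
                    raise ValueError(
                        f"SV {sv.id}: reference allele must carry 1 copy of {g}"
                    )
            for al in sv.alleles:
                for g, cn in al.gene_cn.items():
                    if g not in self._gene_index():
                        raise ValueError(f"SV {sv.id}: unknown gene {g}")
                    if not (isinstance(cn, (int, np.integer)) and cn >= 0):
                        raise ValueError(f"SV {sv.id}: copy number must be int >= 0")
                if set(al.gene_cn) != set(ref.gene_cn):
                    raise ValueError(f"SV {sv.id}: alleles span different gene sets")
            for g in ref.gene_cn:
                if g in gene_owner:
                    raise ValueError(f"gene {g} spanned by more than one SV")
                gene_owner[g] = sv.id
        for b in self.blocks:
            if abs(sum(b.hap_freqs) - 1.0) > 1e-9:
                raise ValueError(f"block {b.id}: pool frequencies must sum to 1")
            if any(f < 0 for f in b.hap_freqs):
                raise ValueError(f"block {b.id}: negative pool frequency")
        sv_spans = {s.id: s.span for s in self.sv_defs}
        for s in self.snv_defs:
            nhap = len(self.block(s.block).hap_freqs)
            if any(c < 0 or c >= nhap for c in s.carriers):
                raise ValueError(f"SNV {s.id}: carrier index out of range")
            inside = [
                sid for sid, (a, b) in sv_spans.items() if a <= s.position <= b
            ]
            if inside and s.containing_sv not in inside:
                raise ValueError(
                    f"SNV {s.id} at {s.position} lies inside SV span "
                    f"{inside[0]} but containing_sv={s.containing_sv!r}"
                )
        for e in self.effect_map:
            if e.multiplier <= 0:
                raise ValueError(f"effect on {e.gene}: multiplier must be > 0")
            if e.gene not in self._gene_index():
                raise ValueError(f"effect references unknown gene {e.gene}")

    # ------------------------------------------------------------ serialisation

    def to_yaml(self, path) -> None:
        doc = {
            "contig": self.contig,
            "locus_length": self.locus_length,
            "genes": [asdict(g) for g in self.genes],
            "svs": [
                {
                    "id": s.id,
                    "span": list(s.span),
                    "var_class": s.var_class,
                    "alleles": [asdict(a) for a in s.alleles],
                }
                for s in self.sv_defs
            ],
            "blocks": [{"id": b.id, "hap_freqs": list(b.hap_freqs)} for b in self.blocks],
            "snvs": [
                {
                    "id": s.id,
                    "position": s.position,
                    "block": s.block,
                    "carriers": list(s.carriers),
                    "var_class": s.var_class,
                    "containing_sv": s.containing_sv,
                }
                for s in self.snv_defs
            ],
            "effects": [asdict(e) for e in self.effect_map],
            "baseline_weights": dict(self.baseline_weights),
            "coding_tag": dict(self.coding_tag),
            "covariates": {
                "platform_levels": list(self.covariate_model.platform_levels),
                "platform_freqs": list(self.covariate_model.platform_freqs),
                "platform_effect": {
                    g: list(v) for g, v in self.covariate_model.platform_effect.items()
                },
                "age_slope": dict(self.covariate_model.age_slope),
                "age_range": list(self.covariate_model.age_range),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LocusModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cov = doc.get("covariates", {})
        model = cls(
            genes=[GeneDef(**g) for g in doc["genes"]],
            sv_defs=[
                SVDef(
                    id=s["id"],
                    span=tuple(s["span"]),
                    var_class=s.get("var_class", "SV"),
                    alleles=tuple(SVAllele(**a) for a in s["alleles"]),
                )
                for s in doc.get("svs", [])
            ],
            blocks=[LDBlock(b["id"], tuple(b["hap_freqs"])) for b in doc.get("blocks", [])],
            snv_defs=[
                SNVDef(
                    id=s["id"],
                    position=s["position"],
                    block=s["block"],
                    carriers=tuple(s["carriers"]),
                    var_class=s.get("var_class", "SNV"),
                    containing_sv=s.get("containing_sv"),
                )
                for s in doc.get("snvs", [])
            ],
            effect_map=[EffectDef(**e) for e in doc.get("effects", [])],
            baseline_weights=dict(doc["baseline_weights"]),
            covariate_model=CovariateModel(
                platform_levels=tuple(cov.get("platform_levels", ("A", "B", "C"))),
                platform_freqs=tuple(cov.get("platform_freqs", (0.45, 0.35, 0.20))),
                platform_effect={
                    g: tuple(v) for g, v in cov.get("platform_effect", {}).items()
                },
                age_slope=dict(cov.get("age_slope", {})),
                age_range=tuple(cov.get("age_range", (18.0, 75.0))),
            ),
            coding_tag=dict(doc.get("coding_tag", {})),
            contig=doc.get("contig", "igh"),
            locus_length=doc.get("locus_length", 1_300_000),
        )
        model.validate()
        return model


# ---------------------------------------------------------------------------
# Default locus model
# ---------------------------------------------------------------------------

# Ordered by locus position; genes spanned by one SV are kept adjacent so the
# SV span does not cover unrelated genes.
_V_GENES = [
    "IGHV6-1", "IGHV1-2", "IGHV1-3", "IGHV2-5", "IGHV7-4-1", "IGHV3-7",
    "IGHV1-8", "IGHV3-9", "IGHV3-64D", "IGHV5-10-1", "IGHV3-11", "IGHV3-13",
    "IGHV3-15", "IGHV3-16", "IGHV1-18", "IGHV3-20", "IGHV3-21", "IGHV3-23",
    "IGHV3-23D", "IGHV1-24", "IGHV2-26", "IGHV4-28", "IGHV3-30", "IGHV3-30-3",
    "IGHV3-30-5", "IGHV3-33", "IGHV4-31", "IGHV4-34", "IGHV4-39", "IGHV3-43",
    "IGHV1-46", "IGHV3-48", "IGHV3-49", "IGHV5-51", "IGHV3-53", "IGHV4-59",
    "IGHV4-61", "IGHV3-64", "IGHV3-66", "IGHV1-69", "IGHV1-69D", "IGHV2-70D",
    "IGHV2-70", "IGHV3-72", "IGHV3-73", "IGHV3-74",
]
_D_GENES = [
    "IGHD1-1", "IGHD2-2", "IGHD3-9", "IGHD3-10", "IGHD5-18", "IGHD6-19",
    "IGHD2-21", "IGHD5-5", "IGHD2-8", "IGHD1-7", "IGHD6-6", "IGHD4-11",
    "IGHD4-4", "IGHD3-3",
]
_J_GENES = ["IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"]

# Genes whose haploid copy number is controlled by the default SVs.
DELETION_SV_GENES = ("IGHD2-8", "IGHD1-7", "IGHD6-6", "IGHD4-11", "IGHD4-4", "IGHD3-3")
DUPLICATION_GENES = ("IGHV3-23", "IGHV3-23D")
MSV_GENES = ("IGHV3-64D", "IGHV5-10-1", "IGHV1-8", "IGHV3-9")

# Target mean usage of the merged IGHV3-23/-23D entity in 2-copy homozygotes;
# 4-copy homozygotes then sit near 2t/(1+t) = 13.8 % by construction.
DUP_TWO_COPY_USAGE = 0.074

PRIMARY_EFFECT_SNV = "snv_reg_A"       # cis effect on IGHV3-53
SECONDARY_EFFECT_SNV = "snv_reg_B"     # cis effect on IGHD3-3 (inside-deletion gene)
PRIMARY_EFFECT_GENE = "IGHV3-53"
SECONDARY_EFFECT_GENE = "IGHD3-3"


def default_model(
    n_blocks: int = 40,
    mean_snvs_per_block: float = 12.0,
    model_seed: int = 777,
    primary_effect: float = 1.6,
    secondary_effect: float = 1.5,
) -> LocusModel:
    """Construct the default ~60-gene IGH model.

    Three SVs (a D-region deletion, the IGHV3-23/-23D duplication, and a
    3-allele complex mSV over the IGHV1-8/IGHV3-9 region), ~480 SNVs/indels in
    ``n_blocks`` LD blocks, one primary cis-regulatory SNV effect on a gene
    outside any SV and one secondary cis effect on a gene inside the deletion
    SV.  Construction is deterministic given ``model_seed``.
    """
    rng = np.random.default_rng(model_seed)

    genes: list[GeneDef] = []
    # J genes 10-25 kb, D genes 40-90 kb, V genes 120 kb onward.
    for i, name in enumerate(_J_GENES):
        genes.append(GeneDef(name, "J", 10_000 + 2_500 * i))
    for i, name in enumerate(_D_GENES):
        genes.append(GeneDef(name, "D", 40_000 + 3_500 * i))
    for i, name in enumerate(_V_GENES):
        genes.append(GeneDef(name, "V", 120_000 + 21_000 * i))
    gpos = {g.name: g.position for g in genes}

    def span_over(gs, pad=1_500):
        lo = min(gpos[g] for g in gs) - pad
        hi = max(gpos[g] for g in gs) + pad
        return (lo, hi)

    sv_del = SVDef(
        id="sv_del_D",
        span=span_over(DELETION_SV_GENES),
        alleles=(
            SVAllele("REF", 0.70, {g: 1 for g in DELETION_SV_GENES}),
            SVAllele("DEL", 0.30, {g: 0 for g in DELETION_SV_GENES}, deletes_snvs=True),
        ),
        var_class="SV",
    )
    # The reference assembly carries both IGHV3-23 and IGHV3-23D (a 2-copy
    # haplotype of the merged unit); the alternate allele deletes IGHV3-23D,
    # so merged diploid copy number segregates between 2 and 4.
    sv_dup = SVDef(
        id="sv_dup_V3-23",
        span=span_over(DUPLICATION_GENES),
        alleles=(
            SVAllele("REF", 0.50, {"IGHV3-23": 1, "IGHV3-23D": 1}),
            SVAllele("DEL1", 0.50, {"IGHV3-23": 1, "IGHV3-23D": 0}),
        ),
        var_class="SV",
    )
    sv_msv = SVDef(
        id="msv_V1-8",
        span=span_over(MSV_GENES),
        alleles=(
            SVAllele("REF", 0.50, {g: 1 for g in MSV_GENES}),
            SVAllele("DEL", 0.30, {g: 0 for g in MSV_GENES}, deletes_snvs=True),
            SVAllele(
                "DEL2",
                0.20,
                {"IGHV3-64D": 0, "IGHV5-10-1": 0, "IGHV1-8": 1, "IGHV3-9": 1},
            ),
        ),
        var_class="MSV",
    )
    sv_defs = [sv_del, sv_dup, sv_msv]
    spans = {s.id: s.span for s in sv_defs}

    # LD blocks tile the locus; most have two pool haplotypes (all-ref /
    # all-alt on the block's SNVs, i.e. perfect within-block LD), every fifth
    # has a third recombinant haplotype that breaks r^2 below 1.
    blocks: list[LDBlock] = []
    snv_defs: list[SNVDef] = []
    tile = 1_250_000 // n_blocks
    for b in range(n_blocks):
        core = float(rng.uniform(0.10, 0.90))
        if b % 5 == 2:
            minor = float(rng.uniform(0.03, 0.08))
            freqs = (1.0 - core - minor, core, minor)
        else:
            freqs = (1.0 - core, core)
        bid = f"blk{b:02d}"
        blocks.append(LDBlock(bid, freqs))
        lo = 20_000 + b * tile
        n_snv = max(3, int(rng.poisson(mean_snvs_per_block)))
        positions = np.sort(rng.choice(np.arange(lo, lo + tile - 10), n_snv, replace=False))
        for j, pos in enumerate(positions):
            pos = int(pos)
            inside = next((sid for sid, (a, c) in spans.items() if a <= pos <= c), None)
            carriers = (1,) if len(freqs) == 2 else ((1,) if j % 3 else (1, 2))
            var_class = "INDEL" if (b * 31 + j) % 25 == 0 else "SNV"
            snv_defs.append(
                SNVDef(
                    id=f"{'indel' if var_class == 'INDEL' else 'snv'}_{bid}_{j:03d}",
                    position=pos,
                    block=bid,
                    carriers=carriers,
                    var_class=var_class,
                    containing_sv=inside,
                )
            )

    # Dedicated effect blocks (two pool haplotypes each, outside every SV span)
    # carrying the regulatory SNVs plus a few perfect-LD companions.
    for bid, freq, base_pos, tag in (
        ("blk_regA", 0.35, 1_245_000, "A"),
        ("blk_regB", 0.40, 1_260_000, "B"),
    ):
        blocks.append(LDBlock(bid, (1.0 - freq, freq)))
        for j in range(6):
            pos = base_pos + 40 * j
            sid = f"snv_reg_{tag}" if j == 0 else f"snv_{bid}_{j:03d}"
            snv_defs.append(SNVDef(id=sid, position=pos, block=bid, carriers=(1,)))

    snv_defs.sort(key=lambda s: s.position)

    # Baseline per-copy weights: lognormal spread, then calibrate (a) the
    # merged duplication pair so 2-copy homozygotes sit at DUP_TWO_COPY_USAGE
    # and (b) the regulatory-effect target gene to ~3% usage, the scale of
    # the genes whose cis effects the analysis characterises.
    baseline: dict[str, float] = {}
    for g in genes:
        baseline[g.name] = float(rng.lognormal(mean=0.0, sigma=0.5))
    t = DUP_TWO_COPY_USAGE
    t_eff = 0.03
    rest = sum(
        baseline[g.name]
        for g in genes
        if g.segment == "V"
        and g.name not in DUPLICATION_GENES
        and g.name != PRIMARY_EFFECT_GENE
    )
    total = rest / (1.0 - t - t_eff)
    baseline["IGHV3-23"] = t * total
    baseline["IGHV3-23D"] = t * total
    baseline[PRIMARY_EFFECT_GENE] = t_eff * total

    effects = [
        EffectDef(PRIMARY_EFFECT_SNV, PRIMARY_EFFECT_GENE, primary_effect),
        EffectDef(SECONDARY_EFFECT_SNV, SECONDARY_EFFECT_GENE, secondary_effect),
    ]

    # Platform batch factors: modest multiplicative wobble on a subset of genes.
    platform_effect: dict[str, tuple[float, ...]] = {}
    for g in genes:
        if rng.random() < 0.4:
            platform_effect[g.name] = (
                1.0,
                float(rng.lognormal(0.0, 0.05)),
                float(rng.lognormal(0.0, 0.05)),
            )
    cov = CovariateModel(platform_effect=platform_effect)

    # Coding-allele tag: nearest LD block by position.
    block_pos = {}
    for s in snv_defs:
        block_pos.setdefault(s.block, []).append(s.position)
    block_mid = {b: float(np.mean(p)) for b, p in block_pos.items()}
    coding_tag = {
        g.name: min(block_mid, key=lambda b: abs(block_mid[b] - g.position))
        for g in genes
    }

    model = LocusModel(
        genes=genes,
        sv_defs=sv_defs,
        blocks=blocks,
        snv_defs=snv_defs,
        effect_map=effects,
        baseline_weights=baseline,
        covariate_model=cov,
        coding_tag=coding_tag,
    )
    model.validate()
    return model


def null_model(
    n_genes: int = 200,
    n_blocks: int = 40,
    mean_snvs_per_block: float = 12.5,
    model_seed: int = 778,
) -> LocusModel:
    """A model with no SVs and no cis effects: usage varies only through
    multinomial sampling and covariate batch factors.  Used for type-I-error
    calibration of the association scan."""
    rng = np.random.default_rng(model_seed)
    genes = [GeneDef(f"IGHVN-{i + 1}", "V", 20_000 + 6_000 * i) for i in range(n_genes)]
    blocks: list[LDBlock] = []
    snv_defs: list[SNVDef] = []
    tile = 1_250_000 // n_blocks
    for b in range(n_blocks):
        core = float(rng.uniform(0.10, 0.90))
        bid = f"nblk{b:02d}"
        blocks.append(LDBlock(bid, (1.0 - core, core)))
        lo = 20_000 + b * tile
        n_snv = max(3, int(rng.poisson(mean_snvs_per_block)))
        positions = np.sort(rng.choice(np.arange(lo, lo + tile - 10), n_snv, replace=False))
        for j, pos in enumerate(positions):
            snv_defs.append(SNVDef(f"snv_{bid}_{j:03d}", int(pos), bid, (1,)))
    baseline = {g.name: float(rng.lognormal(0.0, 0.5)) for g in genes}
    platform_effect = {
        g.name: (1.0, float(rng.lognormal(0.0, 0.05)), float(rng.lognormal(0.0, 0.05)))
        for g in genes
        if rng.random() < 0.4
    }
    model = LocusModel(
        genes=genes,
        sv_defs=[],
        blocks=blocks,
        snv_defs=snv_defs,
        effect_map=[],
        baseline_weights=baseline,
        covariate_model=CovariateModel(platform_effect=platform_effect),
        coding_tag={},
    )
    model.validate()
    return model
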