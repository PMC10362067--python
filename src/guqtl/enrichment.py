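"""Regulatory-feature enrichment and GWAS-catalog overlap of guQTL variants.

Variant positions are 1-based; feature intervals are BED-style 0-based
half-open, so a variant at position p lies in [start, end) iff
start <= p - 1 < end.  Enrichment of guQTL variants over the non-guQTL
background (common variants tested but significant for no gene) is a
one-sided Fisher exact test per feature class on
[[guQTL in, guQTL out], [background in, background out]].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    feature_class: str
    source: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"malformed interval [{self.start}, {self.end})")


@dataclass
class EnrichmentResult:
    feature_class: str
    n_guqtl_in: int
    n_guqtl_out: int
    n_background_in: int
    n_background_out: int
    odds_ratio: float
    p_value: float  # one-sided (enrichment)

    @property
    def table(self):
        return [
            [self.n_guqtl_in, self.n_guqtl_out],
            [self.n_background_in, self.n_background_out],
        ]


def overlap_variants(
    positions: dict[str, int],
    features: list[FeatureInterval],
) -> dict[str, set[str]]:
    """Per feature class, the set of variant ids falling inside the union of
    that class's intervals.  ``positions`` maps variant id -> 1-based
    position."""
    classes: dict[str, list[FeatureInterval]] = {}
    for f in features:
        classes.setdefault(f.feature_class, []).append(f)
    ids = np.array(list(positions.keys()), dtype=object)
    pos0 = np.array([positions[v] for v in ids], dtype=np.int64) - 1
    out: dict[str, set[str]] = {}
    for cls, ivs in classes.items():
        starts = np.array([f.start for f in ivs])
        ends = np.array([f.end for f in ivs])
        inside = ((pos0[:, None] >= starts[None, :]) & (pos0[:, None] < ends[None, :])).any(axis=1)
        out[cls] = set(ids[inside])
    return out


def fisher_enrichment(
    guqtl_set: set[str],
    background_set: set[str],
    membership: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """One-sided (enrichment-direction) Fisher exact test per feature class.

    ``guqtl_set`` and ``background_set`` must be disjoint variant-id sets;
    ``membership`` is the per-class output of :func:`overlap_variants`."""
    if not guqtl_set or not background_set:
        raise ValueError("guQTL and background sets must be non-empty")
    if guqtl_set & background_set:
        raise ValueError("guQTL and background sets overlap")
    results = []
    for cls in sorted(membership):
        members = membership[cls]
        a = len(guqtl_set & members)
        b = len(guqtl_set) - a
        c = len(background_set & members)
        d = len(background_set) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(
            EnrichmentResult(
                feature_class=cls,
                n_guqtl_in=a,
                n_guqtl_out=b,
                n_background_in=c,
                n_background_out=d,
                odds_ratio=float(odds) if not math.isinf(odds) else math.inf,
                p_value=float(p),
            )
        )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "feature_class": r.feature_class,
                "guqtl_in": r.n_guqtl_in,
                "guqtl_out": r.n_guqtl_out,
                "background_in": r.n_background_in,
                "background_out": r.n_background_out,
                "odds_ratio": r.odds_ratio,
                "p_one_sided": r.p_value,
            }
            for r in results
        ]
    )
    if not df.empty:
        # reference-only BH column; class-level significance is gated on raw p
        df["p_bh"] = _benjamini_hochberg(df["p_one_sided"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def gwas_overlap(
    guqtl_variants: dict[str, int],
    gwas_table: pd.DataFrame,
    p_max: float = 4e-6,
    id_col: str = "SNPS",
    pos_col: str = "CHR_POS",
    trait_col: str = "DISEASE/TRAIT",
    p_col: str = "P-VALUE",
    study_col: str = "STUDY ACCESSION",
) -> pd.DataFrame:
    """GWAS rows with p < p_max whose variant matches a significant guQTL
    (by id first, then by position)."""
    tab = gwas_table.copy()
    tab[p_col] = pd.to_numeric(tab[p_col], errors="coerce")
    tab = tab[tab[p_col] < p_max]
    pos_to_id = {}
    for vid, pos in guqtl_variants.items():
        pos_to_id.setdefault(int(pos), vid)
    rows = []
    for r in tab.itertuples(index=False, name=None):
        rd = dict(zip(tab.columns, r))
        rid = str(rd.get(id_col, "") or "")
        match = rid if rid in guqtl_variants else None
        if match is None:
            try:
                match = pos_to_id.get(int(rd.get(pos_col)))
            except (TypeError, ValueError):
                match = None
        if match is not None:
            rows.append(
                {
                    "guqtl_variant": match,
                    "gwas_id": rid,
                    "trait": rd.get(trait_col, ""),
                    "gwas_p": rd.get(p_col),
                    "study": rd.get(study_col, ""),
                }
            )
    return pd.DataFrame(rows, columns=["guqtl_variant", "gwas_id", "trait", "gwas_p", "study"])
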