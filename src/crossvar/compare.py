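"""Cross-comparison of intra- and inter-species variant call sets.

Four call sets exist for a species pair A/B: AA (A's reads on A's genome),
BB (B on B), AB (A's reads on B's genome) and BA (B on A).  An intra-species
set is compared with the inter-species set that shares its reference
coordinate system (AA with AB, BB with BA); variants are matched by
position, and for small variants by alternate allele:

* IDENTICAL      - same position, intersecting alt-allele sets
* NONIDENTICAL   - same position, disjoint alt alleles (A→T within vs A→G between)
* UNIQUE_INTRA   - position only in the intra-species set
* UNIQUE_INTER   - position only in the inter-species set

Structural variants match on (type, start within a tolerance, reciprocal
overlap) instead of allele identity.  Per-gene mutation loads count the
distinct variants in each gene's region (gene body +/- 5 kbp); candidate
genes are selected by quantile thresholding on the loads (median by
default, strictly greater).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionIndex
from .variants import SmallVariant, StructuralVariant, LENGTH_RULE_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonCategory",
    "SharingLabel",
    "SelectionConfig",
    "SvMatchConfig",
    "MutationLoadTable",
    "allele_key",
    "index_by_position",
    "index_sv",
    "classify_sharing",
    "classify_sv_sharing",
    "mutation_load",
    "select_candidate_genes",
    "PAIRINGS",
]


class ComparisonCategory(str, Enum):
    AA = "AA"  # intra-species A
    BB = "BB"  # intra-species B
    AB = "AB"  # inter, A reads vs B genome
    BA = "BA"  # inter, B reads vs A genome


#: the only legal intra/inter pairings: both members share a reference genome
PAIRINGS = (
    (ComparisonCategory.AA, ComparisonCategory.AB),
    (ComparisonCategory.BB, ComparisonCategory.BA),
)


class SharingLabel(str, Enum):
    IDENTICAL = "IDENTICAL"
    NONIDENTICAL = "NONIDENTICAL"
    UNIQUE_INTRA = "UNIQUE_INTRA"
    UNIQUE_INTER = "UNIQUE_INTER"


@dataclass(frozen=True)
class SelectionConfig:
    """Quantile-threshold selection of high-load genes (median by default)."""

    quantile: float = 0.5
    strict: bool = True

    def __post_init__(self):
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")


@dataclass(frozen=True)
class SvMatchConfig:
    """SV equivalence: same type, |start delta| <= tolerance and, for types
    with a defined length, reciprocal overlap >= min_reciprocal_overlap."""

    tolerance: int = 50
    min_reciprocal_overlap: float = 0.8


def allele_key(ref: str, alt: str) -> str:
    """Canonical allele identity for position matching.

    Bare alt for SNPs; left-anchored indels carry their REF too, since two
    different-length deletions share the anchor base as ALT but are
    different variants.
    """
    if len(ref) == 1 and len(alt) == 1:
        return alt
    return f"{ref}>{alt}"


def index_by_position(variants: Iterable[SmallVariant]) -> dict:
    """Map (scaffold, pos) -> set of allele keys; multi-allelic rows
    contribute every alt at their position."""
    idx: dict[tuple, set] = defaultdict(set)
    for v in variants:
        idx[(v.scaffold, v.pos)].update(allele_key(v.ref, a) for a in v.alts)
    return dict(idx)


def index_sv(variants: Iterable[StructuralVariant]) -> dict:
    """Group SVs per (scaffold, svtype), sorted by start."""
    idx: dict[tuple, list] = defaultdict(list)
    for v in variants:
        idx[(v.scaffold, v.svtype)].append(v)
    return {k: sorted(vs, key=lambda v: v.start) for k, vs in idx.items()}


def _check_shared_reference(intra_keys, inter_keys):
    intra_scafs = {s for s, _ in intra_keys}
    inter_scafs = {s for s, _ in inter_keys}
    if intra_scafs and inter_scafs and not (intra_scafs & inter_scafs):
        raise ValueError(
            "intra and inter sets share no scaffold names; the sharing "
            "comparison requires both call sets on one reference genome"
        )


def classify_sharing(intra: Mapping, inter: Mapping):
    """Assign a :class:`SharingLabel` to every position of both indexed sets.

    Returns ``(intra_labels, inter_labels)``, each a dict
    (scaffold, pos) -> SharingLabel.
    """
    _check_shared_reference(intra.keys(), inter.keys())
    intra_labels = {}
    inter_labels = {}
    for key, alts in intra.items():
        other = inter.get(key)
        if other is None:
            intra_labels[key] = SharingLabel.UNIQUE_INTRA
        elif alts & other:
            intra_labels[key] = SharingLabel.IDENTICAL
        else:
            intra_labels[key] = SharingLabel.NONIDENTICAL
    for key, alts in inter.items():
        other = intra.get(key)
        if other is None:
            inter_labels[key] = SharingLabel.UNIQUE_INTER
        elif alts & other:
            inter_labels[key] = SharingLabel.IDENTICAL
        else:
            inter_labels[key] = SharingLabel.NONIDENTICAL
    return intra_labels, inter_labels


def _sv_key(v: StructuralVariant) -> tuple:
    return (v.scaffold, v.svtype, v.start, v.end)


def _sv_matches(a: StructuralVariant, b: StructuralVariant, cfg: SvMatchConfig) -> bool:
    if a.svtype != b.svtype or a.scaffold != b.scaffold:
        return False
    if abs(a.start - b.start) > cfg.tolerance:
        return False
    if a.svtype in LENGTH_RULE_TYPES:
        ov = min(a.end, b.end) - max(a.start, b.start) + 1
        if ov <= 0:
            return False
        ro = min(ov / (a.end - a.start + 1), ov / (b.end - b.start + 1))
        return ro >= cfg.min_reciprocal_overlap
    return True


def classify_sv_sharing(
    intra: Sequence[StructuralVariant],
    inter: Sequence[StructuralVariant],
    cfg: SvMatchConfig | None = None,
):
    """Sharing labels for SV sets; matching is type- and overlap-aware.

    A pair of same-type SVs within the start tolerance and reciprocal
    overlap is IDENTICAL on both sides; a different-type SV whose start
    lies within the tolerance makes the location NONIDENTICAL; otherwise
    the SV is UNIQUE to its side.  Returns two dicts keyed by
    (scaffold, svtype, start, end).
    """
    cfg = cfg or SvMatchConfig()
    if intra and inter:
        _check_shared_reference(
            ((v.scaffold, v.start) for v in intra),
            ((v.scaffold, v.start) for v in inter),
        )

    def _label_side(side: Sequence[StructuralVariant], other: Sequence[StructuralVariant], unique: SharingLabel):
        by_scaf: dict[str, list] = defaultdict(list)
        for v in other:
            by_scaf[v.scaffold].append(v)
        labels = {}
        for v in side:
            cands = by_scaf.get(v.scaffold, ())
            match = any(_sv_matches(v, o, cfg) for o in cands)
            if match:
                labels[_sv_key(v)] = SharingLabel.IDENTICAL
            elif any(abs(v.start - o.start) <= cfg.tolerance for o in cands):
                labels[_sv_key(v)] = SharingLabel.NONIDENTICAL
            else:
                labels[_sv_key(v)] = unique
        return labels

    return (
        _label_side(intra, inter, SharingLabel.UNIQUE_INTRA),
        _label_side(inter, intra, SharingLabel.UNIQUE_INTER),
    )


@dataclass
class MutationLoadTable:
    """gene -> category -> variant class ('SMV'/'SV') -> count."""

    counts: dict = field(default_factory=dict)

    def add(self, gene: str, category: ComparisonCategory, vclass: str, n: int = 1):
        self.counts.setdefault(gene, {}).setdefault(category, {"SMV": 0, "SV": 0})
        self.counts[gene][category][vclass] += n

    def load(self, gene: str, category: ComparisonCategory, vclass: str) -> int:
        return self.counts.get(gene, {}).get(category, {}).get(vclass, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, cats in sorted(self.counts.items()):
            for cat, classes in cats.items():
                rows.append({"gene": gene, "category": cat.value,
                             "smv_load": classes["SMV"], "sv_load": classes["SV"]})
        return pd.DataFrame(rows, columns=["gene", "category", "smv_load", "sv_load"])


def mutation_load(
    variants_by_category: Mapping[ComparisonCategory, tuple],
    index: RegionIndex,
    flank: int = 5000,
) -> MutationLoadTable:
    """Count, per gene region (gene body +/- ``flank``), the distinct
    variants of each category; small and structural variants are tallied
    separately.  A variant increments every gene whose region it
    intersects, once per gene."""
    trees = index.gene_regions(flank)
    table = MutationLoadTable()
    for cat, (smvs, svs) in variants_by_category.items():
        for v in smvs:
            tree = trees.get(v.scaffold)
            if tree is None:
                continue
            for iv in tree.overlap(v.pos - 1, v.pos - 1 + len(v.ref)):
                table.add(iv.data, cat, "SMV")
        for v in svs:
            tree = trees.get(v.scaffold)
            if tree is None:
                continue
            for iv in tree.overlap(v.start - 1, max(v.start, v.end)):
                table.add(iv.data, cat, "SV")
    return table


def select_candidate_genes(
    table: MutationLoadTable,
    cfg: SelectionConfig | None = None,
) -> dict:
    """Quantile-threshold gene selection per (category, variant class).

    For each category and class, the load quantile at ``cfg.quantile`` is
    computed over genes with load > 0; genes with load strictly greater
    (or >= when ``strict`` is False) are selected.  Returns
    {(category, vclass): set of genes}.
    """
    cfg = cfg or SelectionConfig()
    if not table.counts:
        raise ValueError("empty mutation-load table")
    out: dict[tuple, set] = {}
    cats = {cat for g in table.counts.values() for cat in g}
    for cat in cats:
        for vclass in ("SMV", "SV"):
            loads = {
                g: table.load(g, cat, vclass)
                for g in table.counts
                if table.load(g, cat, vclass) > 0
            }
            if not loads:
                logger.warning("all %s loads zero for category %s: empty selection", vclass, cat.value)
                out[(cat, vclass)] = set()
                continue
            thr = float(np.quantile(list(loads.values()), cfg.quantile))
            if cfg.strict:
                out[(cat, vclass)] = {g for g, x in loads.items() if x > thr}
            else:
                out[(cat, vclass)] = {g for g, x in loads.items() if x >= thr}
    return out
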