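"""Functional-region model of an annotated genome.

Every genomic position is classified into one or more functional region
classes derived from the gene models: promoter (a window around the TSS),
5'/3' UTR, coding sequence, splice site (the intronic bases flanking each
exon junction), intron, upstream/downstream gene flanks, and intergenic as
the default.  Labels may overlap (a promoter window can reach into the
transcript, flanks of neighbouring genes can overlap); a fixed severity
order flattens overlapping labels to a single class per position:

    SPLICE > CODING > UTR5 > UTR3 > INTRON > PROMOTER > UPSTREAM
           > DOWNSTREAM > INTERGENIC

Interface coordinates are 1-based inclusive (GFF3/VCF convention); all
internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import gffutils
import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "RegionClass",
    "RegionConfig",
    "RegionIndex",
    "TranscriptModel",
    "GeneModel",
    "build_region_index",
    "genome_coverage",
]


class RegionClass(IntEnum):
    """Functional region classes; numeric value encodes flattening severity."""

    INTERGENIC = 0
    DOWNSTREAM = 1
    UPSTREAM = 2
    PROMOTER = 3
    INTRON = 4
    UTR3 = 5
    UTR5 = 6
    CODING = 7
    SPLICE = 8

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class RegionConfig:
    """Window sizes defining promoter, flank and splice regions.

    promoter_up/promoter_down anchor the promoter at the TSS (2 kbp
    upstream, 200 bp downstream by default); gene_flank sets the
    upstream/downstream windows beyond the gene body (5 kbp); splice_core
    is the number of intronic bases at each intron end treated as splice
    site (2 = the canonical donor/acceptor dinucleotides).
    """

    promoter_up: int = 2000
    promoter_down: int = 200
    gene_flank: int = 5000
    splice_core: int = 2

    def __post_init__(self):
        for name in ("promoter_up", "promoter_down", "gene_flank", "splice_core"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TranscriptModel:
    """One transcript: sorted exon and CDS intervals, 0-based half-open."""

    transcript_id: str
    gene_id: str
    scaffold: str
    strand: str
    exons: list  # [(start0, end0)] ascending
    cds: list  # [(start0, end0)] ascending

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of the spliced CDS in transcription order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.cds]) if self.cds else np.empty(0, dtype=int)
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    start0: int
    end0: int
    strand: str
    transcripts: list = field(default_factory=list)


class RegionIndex:
    """Interval map from genomic position to (gene, transcript, RegionClass)."""

    def __init__(self, scaffold_lengths: Mapping[str, int]):
        self.scaffold_lengths = dict(scaffold_lengths)
        self.trees: dict[str, IntervalTree] = {s: IntervalTree() for s in self.scaffold_lengths}
        self.genes: dict[str, GeneModel] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        self.rejects: dict[str, int] = {}

    def _add(self, scaffold: str, start0: int, end0: int, gene: str, transcript: str, cls: RegionClass):
        L = self.scaffold_lengths[scaffold]
        s, e = max(0, start0), min(L, end0)
        if s < e:
            self.trees[scaffold].addi(s, e, (gene, transcript, cls))

    # ---- queries -------------------------------------------------------

    def locate(self, scaffold: str, start: int, end: int | None = None):
        """Classify a 1-based inclusive interval.

        Returns ``(labels, flattened)`` where labels is a set of
        (gene_id, RegionClass) pairs the interval intersects and flattened
        is the single highest-severity class (INTERGENIC if none).
        """
        if scaffold not in self.trees:
            raise KeyError(f"unknown scaffold {scaffold!r}")
        if end is None:
            end = start
        s0, e0 = start - 1, end  # to 0-based half-open
        hits = self.trees[scaffold].overlap(s0, e0)
        labels = {(iv.data[0], iv.data[2]) for iv in hits}
        flattened = max((cls for _, cls in labels), default=RegionClass.INTERGENIC)
        return labels, flattened

    def gene_regions(self, flank: int = 5000) -> dict[str, IntervalTree]:
        """Per-scaffold interval trees of gene body +/- ``flank`` windows."""
        trees: dict[str, IntervalTree] = {s: IntervalTree() for s in self.scaffold_lengths}
        for g in self.genes.values():
            L = self.scaffold_lengths[g.scaffold]
            trees[g.scaffold].addi(max(0, g.start0 - flank), min(L, g.end0 + flank), g.gene_id)
        return trees

    def to_bed(self) -> Iterable[str]:
        """Region intervals as BED lines (0-based half-open, name = class)."""
        for scaffold in sorted(self.trees):
            for iv in sorted(self.trees[scaffold]):
                gene, tx, cls = iv.data
                yield f"{scaffold}\t{iv.begin}\t{iv.end}\t{cls.name}\t{gene}\t{tx}"


def _transcript_windows(index: RegionIndex, tx: TranscriptModel, cfg: RegionConfig):
    """Emit promoter/flank/UTR/CDS/intron/splice intervals for one transcript."""
    g, t, scaf = tx.gene_id, tx.transcript_id, tx.scaffold
    t0, t1 = tx.exons[0][0], tx.exons[-1][1]
    if tx.strand == "+":
        index._add(scaf, t0 - cfg.promoter_up, t0 + cfg.promoter_down, g, t, RegionClass.PROMOTER)
        index._add(scaf, t0 - cfg.gene_flank, t0 - cfg.promoter_up, g, t, RegionClass.UPSTREAM)
        index._add(scaf, t1, t1 + cfg.gene_flank, g, t, RegionClass.DOWNSTREAM)
    else:
        index._add(scaf, t1 - cfg.promoter_down, t1 + cfg.promoter_up, g, t, RegionClass.PROMOTER)
        index._add(scaf, t1 + cfg.promoter_up, t1 + cfg.gene_flank, g, t, RegionClass.UPSTREAM)
        index._add(scaf, t0 - cfg.gene_flank, t0, g, t, RegionClass.DOWNSTREAM)

    # CDS
    for s, e in tx.cds:
        index._add(scaf, s, e, g, t, RegionClass.CODING)

    # UTRs: exonic sequence outside the CDS span, oriented by strand
    if tx.cds:
        c0, c1 = tx.cds[0][0], tx.cds[-1][1]
        for s, e in tx.exons:
            left = (max(s, 0), min(e, c0))  # exonic, 5' of CDS on + strand
            right = (max(s, c1), e)
            if left[0] < left[1]:
                cls = RegionClass.UTR5 if tx.strand == "+" else RegionClass.UTR3
                index._add(scaf, left[0], left[1], g, t, cls)
            if right[0] < right[1]:
                cls = RegionClass.UTR3 if tx.strand == "+" else RegionClass.UTR5
                index._add(scaf, right[0], right[1], g, t, cls)

    # introns and splice cores
    k = cfg.splice_core
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        i0, i1 = e1, s2
        if i1 <= i0:
            continue
        if i1 - i0 <= 2 * k:
            index._add(scaf, i0, i1, g, t, RegionClass.SPLICE)
        else:
            index._add(scaf, i0, i0 + k, g, t, RegionClass.SPLICE)
            index._add(scaf, i1 - k, i1, g, t, RegionClass.SPLICE)
            index._add(scaf, i0 + k, i1 - k, g, t, RegionClass.INTRON)


def build_region_index(
    gff3: str,
    scaffold_lengths: Mapping[str, int],
    config: RegionConfig | None = None,
) -> RegionIndex:
    """Build a :class:`RegionIndex` from a GFF3 file.

    Malformed transcripts (no exons, CDS outside exons, unknown strand) are
    skipped with a warning and tallied in ``index.rejects``.
    """
    cfg = config or RegionConfig()
    index = RegionIndex(scaffold_lengths)
    try:
        db = gffutils.create_db(
            gff3, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return index  # no gene models: everything stays intergenic
    for gene in db.features_of_type("gene"):
        if gene.seqid not in index.scaffold_lengths:
            index.rejects["gene_on_unknown_scaffold"] = index.rejects.get("gene_on_unknown_scaffold", 0) + 1
            logger.warning("gene %s on unknown scaffold %s: skipped", gene.id, gene.seqid)
            continue
        gm = GeneModel(gene.id, gene.seqid, gene.start - 1, gene.end, gene.strand)
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
            cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
            if not exons:
                index.rejects["transcript_without_exons"] = index.rejects.get("transcript_without_exons", 0) + 1
                logger.warning("transcript %s has no exons: skipped", mrna.id)
                continue
            if mrna.strand not in ("+", "-"):
                index.rejects["unknown_strand"] = index.rejects.get("unknown_strand", 0) + 1
                logger.warning("transcript %s has strand %r: skipped", mrna.id, mrna.strand)
                continue
            if any(not any(es <= cs and ce <= ee for es, ee in exons) for cs, ce in cds):
                index.rejects["cds_outside_exons"] = index.rejects.get("cds_outside_exons", 0) + 1
                logger.warning("transcript %s has CDS outside exons: skipped", mrna.id)
                continue
            tx = TranscriptModel(mrna.id, gene.id, gene.seqid, mrna.strand, exons, cds)
            gm.transcripts.append(tx.transcript_id)
            index.transcripts[tx.transcript_id] = tx
            _transcript_windows(index, tx, cfg)
        if gm.transcripts:
            index.genes[gm.gene_id] = gm
    return index


def genome_coverage(index: RegionIndex) -> dict:
    """Fraction of the genome covered by each region class (GCOV).

    Each position is counted once under its highest-severity label;
    fractions sum to 1 over the total genome length.
    """
    counts = np.zeros(len(RegionClass), dtype=np.int64)
    for scaffold, L in index.scaffold_lengths.items():
        sev = np.zeros(L, dtype=np.uint8)
        for iv in index.trees[scaffold]:
            cls = iv.data[2]
            np.maximum(sev[iv.begin:iv.end], np.uint8(cls), out=sev[iv.begin:iv.end])
        counts += np.bincount(sev, minlength=len(RegionClass))
    total = counts.sum()
    if total == 0:
        raise ValueError("empty genome")
    return {cls: counts[cls] / total for cls in RegionClass}
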