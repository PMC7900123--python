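"""Reading, filtering, typing and effect-annotating variant call sets.

Small variants (SNPs and short InDels) are kept when their phred-scaled
quality is at least ``min_qual`` (default 30).  Structural variants need at
least ``min_support_pairs`` discordant read pairs (default 5) and — for
deletions, inversions and duplications only — a minimum length of
``min_sv_len`` bp (default 300); translocations and insertions are exempt
from the length rule.

Effect annotation rebuilds the affected codon for coding SNPs in transcript
orientation and translates it with the standard genetic code; impact
classes follow the SnpEff convention (HIGH / MODERATE / LOW / MODIFIER).
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from .regions import RegionClass, RegionIndex

logger = logging.getLogger(__name__)

__all__ = [
    "SmallVariant",
    "StructuralVariant",
    "FilterConfig",
    "FilterReport",
    "VariantEffect",
    "Impact",
    "CodingConsequence",
    "SummaryStats",
    "EffectDistribution",
    "read_and_filter_smv",
    "read_and_filter_sv",
    "classify_smv",
    "annotate_effects",
    "summarize_dataset",
    "variant_rate",
    "effect_distribution",
    "distribution_from_counts",
    "location_distribution",
    "gene_hit_proportions",
]

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")
LENGTH_RULE_TYPES = frozenset({"DEL", "INV", "DUP"})

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class CodingConsequence(str, Enum):
    NONSENSE = "NONSENSE"
    MISSENSE = "MISSENSE"
    SILENT = "SILENT"
    NONE = "NONE"


class ClassificationError(ValueError):
    """A record cannot be typed as a small variant (e.g. symbolic allele)."""


class IntegrityError(ValueError):
    """Variant REF allele disagrees with the genome sequence."""


@dataclass(frozen=True)
class SmallVariant:
    scaffold: str
    pos: int  # 1-based
    ref: str
    alts: tuple
    qual: float | None = None

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    def types(self) -> list[str]:
        """Per-alt variant types; MNPs decompose into per-base SNPs."""
        out = []
        for alt in self.alts:
            out.extend(classify_smv(self.ref, alt))
        return out


@dataclass(frozen=True)
class StructuralVariant:
    scaffold: str
    start: int  # 1-based
    end: int  # 1-based; == start for TRA/INS breakpoints
    svtype: str
    support_pairs: int
    mate_scaffold: str | None = None
    mate_pos: int | None = None

    @property
    def length(self) -> int | None:
        if self.svtype in LENGTH_RULE_TYPES:
            return self.end - self.start + 1
        return None


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 30.0
    min_support_pairs: int = 5
    min_sv_len: int = 300

    def __post_init__(self):
        if self.min_qual < 0 or self.min_support_pairs < 0 or self.min_sv_len < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterReport:
    kept: int = 0
    dropped: int = 0
    dropped_missing: int = 0
    dropped_by_rule: Counter = field(default_factory=Counter)


def read_and_filter_smv(path: str, cfg: FilterConfig | None = None):
    """Read a small-variant VCF, keeping records with QUAL >= min_qual.

    Records with missing QUAL are dropped and logged.  Returns
    ``(variants, report)``.
    """
    cfg = cfg or FilterConfig()
    out: list[SmallVariant] = []
    rep = FilterReport()
    for rec in VCF(path):
        qual = rec.QUAL
        if qual is None:
            rep.dropped += 1
            rep.dropped_missing += 1
            rep.dropped_by_rule["missing_qual"] += 1
            logger.warning("record %s:%d has no QUAL: dropped", rec.CHROM, rec.POS)
            continue
        if qual < cfg.min_qual:
            rep.dropped += 1
            rep.dropped_by_rule["qual"] += 1
            continue
        out.append(SmallVariant(rec.CHROM, rec.POS, rec.REF, tuple(rec.ALT), float(qual)))
        rep.kept += 1
    return out, rep


def read_and_filter_sv(path: str, cfg: FilterConfig | None = None):
    """Read a structural-variant VCF and apply the support and length rules.

    Support >= min_support_pairs is required for every type; length >=
    min_sv_len only for DEL/INV/DUP.  Paired translocation breakends
    (MATEID) collapse into a single event.  Unknown SVTYPEs are skipped
    with a warning.  Returns ``(variants, report)``.
    """
    cfg = cfg or FilterConfig()
    out: list[StructuralVariant] = []
    rep = FilterReport()
    seen_mates: set[str] = set()
    for rec in VCF(path):
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in SV_TYPES:
            rep.dropped += 1
            rep.dropped_by_rule["unknown_svtype"] += 1
            logger.warning("record %s:%d has unknown SVTYPE %r: skipped", rec.CHROM, rec.POS, svtype)
            continue
        rec_id = rec.ID
        mate_id = rec.INFO.get("MATEID")
        if svtype == "TRA" and mate_id is not None:
            if mate_id in seen_mates:
                continue  # partner of an already-collapsed breakend pair
            if rec_id is not None:
                seen_mates.add(rec_id)
        support = int(rec.INFO.get("PE", 0))
        end = int(rec.INFO.get("END", rec.POS))
        sv = StructuralVariant(
            rec.CHROM, rec.POS, end if svtype in LENGTH_RULE_TYPES else rec.POS,
            svtype, support,
            mate_scaffold=rec.INFO.get("CHR2"),
            mate_pos=end if svtype == "TRA" else None,
        )
        if support < cfg.min_support_pairs:
            rep.dropped += 1
            rep.dropped_by_rule["support"] += 1
            continue
        if svtype in LENGTH_RULE_TYPES and (sv.length or 0) < cfg.min_sv_len:
            rep.dropped += 1
            rep.dropped_by_rule["length"] += 1
            continue
        out.append(sv)
        rep.kept += 1
    return out, rep


def classify_smv(ref: str, alt: str) -> list[str]:
    """Type one REF/ALT pair: SNP, INS or DEL.

    Equal-length multi-base substitutions (MNPs) decompose into one SNP per
    differing base.  Symbolic or breakend alleles raise
    :class:`ClassificationError`.
    """
    if not ref or not alt:
        raise ClassificationError("empty allele")
    if alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*"):
        raise ClassificationError(f"symbolic alt allele {alt!r} in a small-variant context")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return ["SNP"]
        return ["SNP"] * sum(1 for a, b in zip(ref, alt) if a != b)
    return ["INS"] if len(alt) > len(ref) else ["DEL"]


@dataclass(frozen=True)
class VariantEffect:
    scaffold: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    labels: frozenset  # RegionClass labels for this gene (or flattened set)
    impact: Impact
    coding_consequence: CodingConsequence
    variant_key: tuple = ()  # identifies the source VCF record


def _codon_consequence(tx, p0: int, ref: str, alt: str, genome: Mapping[str, str]):
    """Consequence of a SNP at genomic position p0 (0-based) inside tx's CDS."""
    cds_pos = tx.cds_positions()
    hits = np.flatnonzero(cds_pos == p0)
    if hits.size == 0:
        return None
    off = int(hits[0])
    codon_idx, in_codon = divmod(off, 3)
    codon_positions = cds_pos[codon_idx * 3: codon_idx * 3 + 3]
    if codon_positions.size < 3:
        return None  # truncated terminal codon
    seq = genome[tx.scaffold]
    bases = [seq[int(p)] for p in codon_positions]
    if tx.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_b = alt.translate(_COMPLEMENT)
    else:
        alt_b = alt
    old = "".join(bases).upper()
    new = old[:in_codon] + alt_b.upper() + old[in_codon + 1:]
    aa_old = CODON_TABLE.get(old, "X")
    aa_new = CODON_TABLE.get(new, "X")
    if aa_new == aa_old:
        return CodingConsequence.SILENT
    if aa_new == "*":
        return CodingConsequence.NONSENSE
    return CodingConsequence.MISSENSE


def annotate_effects(
    variants: Sequence[SmallVariant | StructuralVariant],
    index: RegionIndex,
    genome: Mapping[str, str],
) -> list[VariantEffect]:
    """Annotate variants with per-gene region labels, impact and consequence.

    One effect is produced per (variant, gene, alt); variants outside any
    gene region yield a single MODIFIER effect with gene None.  Coding SNPs
    are translated codon-wise; coding InDels are HIGH if frameshifting and
    MODERATE otherwise (their consequence stays NONE, as the
    nonsense/missense/silent trichotomy applies to SNPs only).  Structural
    variants get HIGH when they touch coding or splice sequence, MODIFIER
    otherwise.

    Raises :class:`IntegrityError` when a small variant's REF disagrees
    with the genome.
    """
    effects: list[VariantEffect] = []
    for v in variants:
        if isinstance(v, SmallVariant):
            seq = genome[v.scaffold]
            gref = seq[v.pos - 1: v.pos - 1 + len(v.ref)].upper()
            if gref != v.ref.upper():
                raise IntegrityError(
                    f"REF mismatch at {v.scaffold}:{v.pos}: VCF has {v.ref!r}, genome has {gref!r}"
                )
            labels, _ = index.locate(v.scaffold, v.pos, v.pos + len(v.ref) - 1)
            key = (v.scaffold, v.pos, v.ref, v.alts)
            by_gene = defaultdict(set)
            for gene, cls in labels:
                by_gene[gene].add(cls)
            if not by_gene:
                for alt in v.alts:
                    effects.append(VariantEffect(
                        v.scaffold, v.pos, v.ref, alt, None,
                        frozenset({RegionClass.INTERGENIC}),
                        Impact.MODIFIER, CodingConsequence.NONE, key,
                    ))
                continue
            for gene, classes in by_gene.items():
                for alt in v.alts:
                    vtypes = classify_smv(v.ref, alt)
                    is_snp = vtypes == ["SNP"] and len(v.ref) == 1
                    consequence = CodingConsequence.NONE
                    impact = Impact.MODIFIER
                    if RegionClass.CODING in classes and is_snp:
                        cons = None
                        for tid in index.genes[gene].transcripts:
                            cons = _codon_consequence(index.transcripts[tid], v.pos - 1, v.ref, alt, genome)
                            if cons is not None:
                                break
                        consequence = cons or CodingConsequence.NONE
                    if RegionClass.SPLICE in classes or consequence == CodingConsequence.NONSENSE:
                        impact = Impact.HIGH
                    elif consequence == CodingConsequence.MISSENSE:
                        impact = Impact.MODERATE
                    elif consequence == CodingConsequence.SILENT:
                        impact = Impact.LOW
                    elif RegionClass.CODING in classes and not is_snp:
                        indel_len = abs(len(alt) - len(v.ref))
                        impact = Impact.HIGH if indel_len % 3 else Impact.MODERATE
                    effects.append(VariantEffect(
                        v.scaffold, v.pos, v.ref, alt, gene,
                        frozenset(classes), impact, consequence, key,
                    ))
        else:  # StructuralVariant
            labels, _ = index.locate(v.scaffold, v.start, max(v.start, v.end))
            key = (v.scaffold, v.start, v.svtype, v.end)
            by_gene = defaultdict(set)
            for gene, cls in labels:
                by_gene[gene].add(cls)
            if not by_gene:
                effects.append(VariantEffect(
                    v.scaffold, v.start, v.svtype, v.svtype, None,
                    frozenset({RegionClass.INTERGENIC}),
                    Impact.MODIFIER, CodingConsequence.NONE, key,
                ))
                continue
            for gene, classes in by_gene.items():
                high = RegionClass.CODING in classes or RegionClass.SPLICE in classes
                effects.append(VariantEffect(
                    v.scaffold, v.start, v.svtype, v.svtype, gene,
                    frozenset(classes),
                    Impact.HIGH if high else Impact.MODIFIER,
                    CodingConsequence.NONE, key,
                ))
    return effects


@dataclass(frozen=True)
class SummaryStats:
    """One dataset's headline numbers: counts, composition and rate."""

    n_processed: int
    n_multiallelic: int
    n_snp: int
    n_ins: int
    n_del: int
    genome_total_length: int
    effective_length: int
    rate_bases: int | None

    def as_dict(self) -> dict:
        return {
            "n_variants_processed": self.n_processed,
            "n_multiallelic_entries": self.n_multiallelic,
            "n_snp": self.n_snp,
            "n_ins": self.n_ins,
            "n_del": self.n_del,
            "genome_total_length": self.genome_total_length,
            "genome_effective_length": self.effective_length,
            "variant_rate_bases": self.rate_bases,
        }


def variant_rate(effective_length: int, n_variants: int) -> int | None:
    """1-variant-in-N-bases rate: floor(effective_length / n_variants)."""
    if n_variants == 0:
        return None
    return int(math.floor(effective_length / n_variants))


def summarize_dataset(
    variants: Sequence[SmallVariant],
    genome_total_length: int,
    effective_length: int,
) -> SummaryStats:
    """Per-dataset counts, composition and variant rate."""
    if effective_length <= 0:
        raise ValueError("effective_length must be > 0")
    if effective_length > genome_total_length:
        raise ValueError("effective_length cannot exceed genome_total_length")
    types = Counter()
    n_multi = 0
    for v in variants:
        types.update(v.types())
        n_multi += v.is_multiallelic
    return SummaryStats(
        n_processed=len(variants),
        n_multiallelic=n_multi,
        n_snp=types["SNP"],
        n_ins=types["INS"],
        n_del=types["DEL"],
        genome_total_length=genome_total_length,
        effective_length=effective_length,
        rate_bases=variant_rate(effective_length, len(variants)),
    )


def _pct(x: int, total: int, places: int = 2) -> float:
    q = Decimal(10) ** -places
    return float((Decimal(100) * x / total).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EffectDistribution:
    impact_counts: dict
    impact_pct: dict
    coding_counts: dict
    coding_pct: dict


def distribution_from_counts(
    impact_counts: Mapping,
    coding_counts: Mapping,
) -> EffectDistribution:
    """Distribution percentages from raw per-class counts.

    Impact percentages are over all effects; coding percentages are over
    NONSENSE + MISSENSE + SILENT only, both rounded half-up to 2 decimals.
    """
    total = sum(impact_counts.get(i, 0) for i in Impact)
    if total == 0:
        raise ValueError("no effects")
    ctot = sum(coding_counts.get(c, 0)
               for c in CodingConsequence if c != CodingConsequence.NONE)
    return EffectDistribution(
        impact_counts={i: impact_counts.get(i, 0) for i in Impact},
        impact_pct={i: _pct(impact_counts.get(i, 0), total) for i in Impact},
        coding_counts={c: coding_counts.get(c, 0)
                       for c in CodingConsequence if c != CodingConsequence.NONE},
        coding_pct={
            c: (_pct(coding_counts.get(c, 0), ctot) if ctot else 0.0)
            for c in CodingConsequence if c != CodingConsequence.NONE
        },
    )


def effect_distribution(effects: Sequence[VariantEffect]) -> EffectDistribution:
    """Impact-class distribution and coding-consequence breakdown of a
    list of annotated effects."""
    if not effects:
        raise ValueError("effects list is empty")
    imp = Counter(e.impact for e in effects)
    coding = Counter(
        e.coding_consequence for e in effects
        if e.coding_consequence != CodingConsequence.NONE
    )
    return distribution_from_counts(imp, coding)


def location_distribution(effects: Sequence[VariantEffect], gcov: Mapping) -> dict:
    """Per-class variant fraction (flattened label) and representation ratio.

    Each source variant contributes once, under the highest-severity label
    across all its per-gene effects.  The representation ratio divides the
    variant fraction by the class's genome coverage; 1 means the class holds
    exactly its genome share of variants.  A class with zero coverage but
    observed variants reports an infinite ratio with a warning.
    """
    by_variant: dict[tuple, RegionClass] = {}
    for e in effects:
        cls = max(e.labels)
        prev = by_variant.get(e.variant_key)
        if prev is None or cls > prev:
            by_variant[e.variant_key] = cls
    n = len(by_variant)
    if n == 0:
        raise ValueError("no effects")
    counts = Counter(by_variant.values())
    out = {}
    for cls in RegionClass:
        frac = counts.get(cls, 0) / n
        g = gcov.get(cls, 0.0)
        if g > 0:
            ratio = frac / g
        elif frac > 0:
            logger.warning("class %s has variants but zero genome coverage", cls.name)
            ratio = math.inf
        else:
            ratio = math.nan
        out[cls] = {"variant_fraction": frac, "gcov": g, "ratio": ratio}
    return out


def gene_hit_proportions(effects: Sequence[VariantEffect], genes: Iterable[str]) -> dict:
    """Per region class, the fraction of genes with >= 1 variant in that class.

    Uses the full per-gene label sets, so a gene scores for PROMOTER if any
    variant hits its promoter even when the variant's flattened label is a
    higher-severity class of another gene.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    hit: dict[RegionClass, set] = defaultdict(set)
    for e in effects:
        if e.gene is None:
            continue
        for cls in e.labels:
            hit[cls].add(e.gene)
    return {cls: len(hit.get(cls, ())) / len(genes) for cls in RegionClass}
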