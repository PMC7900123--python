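"""Synthetic two-species comparison bundle.

Emulates the data the comparative analysis consumes, without any download:
a reference genome with N-gaps, multi-exon gene models on both strands
with valid ORFs, a small single-rooted is_a ontology with gene-to-term
annotations, and four variant call sets — intra-species A (AA), intra B
(BB), inter A-vs-B (AB) and inter B-vs-A (BA) — with controlled position
sharing between the paired sets, controlled SNP/InDel/SV composition, a
configurable fraction of records that fail the downstream quality filters,
and GO terms planted with excess mutation load.  Every emitted record has
a ground-truth row, and the bundle is byte-identical for a fixed config.

Default variant intensities mirror the observed call rates of the cichlid
comparison this emulates: roughly one small variant per ~220 bp between
species and one per ~1600-2500 bp within species, with a 75/12.5/12.5
SNP/insertion/deletion split, and structural variants dominated by
deletions and translocations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .compare import SharingLabel, allele_key
from .regions import RegionConfig, build_region_index

__all__ = ["SimConfig", "Bundle", "generate_bundle", "write_bundle", "simulate_bundle"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SMV_TYPES = ("SNP", "INS", "DEL")
SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")

_DEFAULT_SMV_INTENSITY = {
    # variants per kbp, per category and type
    "AA": {"SNP": 0.30, "INS": 0.05, "DEL": 0.05},   # ~1 per 2.5 kbp
    "BB": {"SNP": 0.48, "INS": 0.08, "DEL": 0.08},   # ~1 per 1.6 kbp
    "AB": {"SNP": 3.40, "INS": 0.55, "DEL": 0.55},   # ~1 per 220 bp
    "BA": {"SNP": 3.40, "INS": 0.55, "DEL": 0.55},
}
_DEFAULT_SV_INTENSITY = {
    # events per Mbp, per category and type
    "AA": {"DEL": 15.0, "DUP": 3.0, "INV": 1.5, "TRA": 12.0, "INS": 2.0},
    "BB": {"DEL": 22.0, "DUP": 4.0, "INV": 2.0, "TRA": 16.0, "INS": 2.5},
    "AB": {"DEL": 60.0, "DUP": 4.0, "INV": 2.0, "TRA": 20.0, "INS": 14.0},
    "BA": {"DEL": 62.0, "DUP": 2.5, "INV": 1.3, "TRA": 13.0, "INS": 16.0},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic bundle; the defaults are the study
    conditions every downstream test assumes."""

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 300_000
    n_run_rate: float = 2.0               # expected N-gaps per scaffold
    gap_len_range: tuple = (10, 60)       # bp, inclusive
    n_genes: int = 120
    intergene_gap: tuple = (4500, 8000)   # bp between gene bodies, inclusive
    exons_per_gene: tuple = (2, 5)        # inclusive range
    mean_exon_len: int = 160
    mean_intron_len: int = 300
    utr_len: int = 60                     # bases reserved at each transcript end
    strand_fraction: float = 0.5          # fraction of genes on the minus strand
    fraction_unannotated: float = 0.1     # genes left out of the GO map
    n_go_terms: int = 60
    dag_depth: int = 4
    terms_per_gene: tuple = (1, 3)
    smv_intensity: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SMV_INTENSITY.items()})
    sv_intensity: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SV_INTENSITY.items()})
    sharing_identical: float = 0.35
    sharing_nonidentical: float = 0.15
    multiallelic_fraction: float = 0.01
    fail_fraction: float = 0.10           # decoy records failing the filters
    # one planted term per bundle: several planted terms sharing an ancestor
    # make the decorrelating weight test attribute the union signal to the
    # ancestor, which is correct behaviour but an ill-posed recovery target
    enriched_terms: tuple = ((None, 10.0),)  # (term id or None=auto, load multiplier)
    enriched_genes_per_term: int = 15
    gene_flank: int = 5000                # the mutation-load window
    max_rejections: int = 10_000

    def __post_init__(self):
        if self.scaffold_length < 1000:
            raise ValueError("scaffold_length must be >= 1 kbp")
        if self.n_go_terms < 1:
            raise ValueError("n_go_terms must be >= 1")
        if self.n_go_terms > 1 and self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")
        if self.sharing_identical + self.sharing_nonidentical > 1:
            raise ValueError("sharing fractions must sum to <= 1")
        for cat in ("AA", "BB", "AB", "BA"):
            for d in (self.smv_intensity[cat], self.sv_intensity[cat]):
                if any(v < 0 for v in d.values()):
                    raise ValueError("intensities must be >= 0")


@dataclass
class Bundle:
    """An in-memory fixture bundle plus its ground truth."""

    config: SimConfig
    genome: dict                  # scaffold -> str
    gaps: dict                    # scaffold -> [(start0, end0)]
    gff3: str
    obo: str
    gene2go: list                 # (gene, term) pairs
    genes: dict                   # gene -> (scaffold, start0, end0, strand)
    smv: dict                     # category -> list of SMV record dicts
    sv: dict                      # category -> list of SV record dicts
    truth: pd.DataFrame
    planted_loads: pd.DataFrame   # gene x category loads of filter-passing variants
    enriched_terms: list          # term ids with planted excess load
    enriched_genes: dict          # term -> list of member genes

    def callable_intervals(self) -> dict:
        """Non-N intervals per scaffold (0-based half-open)."""
        out = {}
        for scaf, seq in self.genome.items():
            gaps = sorted(self.gaps.get(scaf, []))
            iv, prev = [], 0
            for s, e in gaps:
                if s > prev:
                    iv.append((prev, s))
                prev = e
            if prev < len(seq):
                iv.append((prev, len(seq)))
            out[scaf] = iv
        return out

    def effective_length(self) -> int:
        return sum(e - s for iv in self.callable_intervals().values() for s, e in iv)


# --------------------------------------------------------------------------
# ontology


def generate_ontology(config: SimConfig, rng: np.random.Generator | None = None):
    """Single-rooted acyclic is_a DAG serialised as minimal OBO.

    Terms are spread over ``dag_depth`` levels; each non-root term gets one
    or two parents from the level above.  Returns ``(obo_text, edges,
    levels)`` where edges are (child, parent) pairs.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_go_terms
    terms = [f"GO:{i + 1:07d}" for i in range(n)]
    levels = {terms[0]: 0}
    by_level: dict[int, list] = {0: [terms[0]]}
    depth = max(2, config.dag_depth) if n > 1 else 1
    for i, t in enumerate(terms[1:]):
        # fill shallow levels first so every level is populated
        lvl = min(1 + i, depth - 1) if 1 + i < depth else int(rng.integers(1, depth))
        levels[t] = lvl
        by_level.setdefault(lvl, []).append(t)
    edges = []
    for t in terms[1:]:
        lvl = levels[t]
        parent_pool = by_level.get(lvl - 1) or [terms[0]]
        k = min(len(parent_pool), 1 + int(rng.random() < 0.3))
        parents = rng.choice(len(parent_pool), size=k, replace=False)
        for p in sorted(parents):
            edges.append((t, parent_pool[int(p)]))
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: synthetic\n")
    parent_map: dict[str, list] = {}
    for c, p in edges:
        parent_map.setdefault(c, []).append(p)
    for t in terms:
        buf.write(f"\n[Term]\nid: {t}\nname: synthetic term {int(t[3:]):d}\n")
        buf.write("namespace: biological_process\n")
        for p in parent_map.get(t, []):
            buf.write(f"is_a: {p} ! synthetic term {int(p[3:]):d}\n")
    return buf.getvalue(), edges, levels


# --------------------------------------------------------------------------
# genome


def _plant_gaps(rng, length: int, rate: float, len_range: tuple, max_rej: int):
    n = int(rng.poisson(rate))
    gaps: list[tuple] = []
    tries = 0
    while len(gaps) < n and tries < max_rej:
        tries += 1
        glen = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(100, max(101, length - 100 - glen)))
        if all(start + glen + 50 <= s or start >= e + 50 for s, e in gaps):
            gaps.append((start, start + glen))
    return sorted(gaps)


def generate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random uppercase A/C/G/T scaffolds with planted N-gaps.

    Returns ``(arrays, gaps)`` where arrays maps scaffold name to a mutable
    byte array (gene sequences are written into it later) and gaps lists
    the N runs (0-based half-open)."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    arrays: dict[str, np.ndarray] = {}
    gaps: dict[str, list] = {}
    for i in range(config.n_scaffolds):
        name = f"scaffold_{i + 1}"
        seq = _BASES[rng.integers(0, 4, size=config.scaffold_length)].copy()
        g = _plant_gaps(rng, config.scaffold_length, config.n_run_rate,
                        config.gap_len_range, config.max_rejections)
        for s, e in g:
            seq[s:e] = b"N"
        arrays[name] = seq
        gaps[name] = g
    return arrays, gaps


# --------------------------------------------------------------------------
# gene models


def _gene_structure(rng, config: SimConfig):
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    min_terminal = config.utr_len + 24
    exon_lens = [max(min_terminal if i in (0, n_ex - 1) else 42,
                     int(rng.poisson(config.mean_exon_len)))
                 for i in range(n_ex)]
    intron_lens = [max(20, int(rng.poisson(config.mean_intron_len))) for _ in range(n_ex - 1)]
    return exon_lens, intron_lens


def generate_gene_models(arrays: Mapping, gaps: Mapping, config: SimConfig,
                         rng: np.random.Generator | None = None):
    """Place non-overlapping multi-exon genes and write their CDS into the
    genome so every ORF starts with ATG, ends with a stop codon and has no
    internal stop.  Returns ``(gff3_text, genes, gene2go_pairs,
    enriched_terms, enriched_genes, tx_details)``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    scaffolds = list(arrays)
    genes: dict[str, tuple] = {}
    gff_rows: list[str] = []
    gene_idx = 0
    cursors = {s: 300 for s in scaffolds}
    attempts = 0
    while gene_idx < config.n_genes and attempts < config.n_genes * 20:
        attempts += 1
        scaf = scaffolds[attempts % len(scaffolds)]
        L = len(arrays[scaf])
        exon_lens, intron_lens = _gene_structure(rng, config)
        glen = sum(exon_lens) + sum(intron_lens)
        start = cursors[scaf] + int(rng.integers(config.intergene_gap[0],
                                                 config.intergene_gap[1] + 1))
        end = start + glen
        if end + 300 > L:
            cursors[scaf] = L  # scaffold exhausted
            continue
        hit_gap = [g for g in gaps[scaf] if not (end <= g[0] or start >= g[1])]
        if hit_gap:
            cursors[scaf] = max(g[1] for g in hit_gap) + 10
            continue
        cursors[scaf] = end
        gene_idx += 1
        gid = f"g{gene_idx:04d}"
        strand = "-" if rng.random() < config.strand_fraction else "+"

        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_lens[i] if i < len(intron_lens) else 0)

        total_exonic = sum(exon_lens)
        cds_len = total_exonic - 2 * config.utr_len
        cds_len -= cds_len % 3
        utr5, utr3 = config.utr_len, total_exonic - config.utr_len - cds_len
        lo = utr5 if strand == "+" else utr3  # genomic-ascending exonic offset of CDS start

        # genomic positions of exonic bases, ascending
        exonic = np.concatenate([np.arange(s, e) for s, e in exons])
        cds_positions = exonic[lo:lo + cds_len]

        n_codons = cds_len // 3 - 2
        body = rng.choice(len(_NONSTOP_CODONS), size=n_codons)
        cds_seq = "ATG" + "".join(_NONSTOP_CODONS[int(i)] for i in body) \
                  + _STOPS[int(rng.integers(0, 3))]
        arr = arrays[scaf]
        if strand == "+":
            for j, p in enumerate(cds_positions):
                arr[p] = cds_seq[j].encode()
        else:
            for j, p in enumerate(cds_positions):
                arr[p] = _COMP[cds_seq[cds_len - 1 - j]].encode()

        # CDS genomic intervals: contiguous runs of cds_positions
        cds_iv = []
        run_start = int(cds_positions[0])
        prev = run_start
        for p in cds_positions[1:]:
            p = int(p)
            if p != prev + 1:
                cds_iv.append((run_start, prev + 1))
                run_start = p
            prev = p
        cds_iv.append((run_start, prev + 1))

        genes[gid] = (scaf, start, end, strand)
        tid = f"{gid}.t1"
        gff_rows.append(f"{scaf}\tsim\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}")
        gff_rows.append(f"{scaf}\tsim\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\tID={tid};Parent={gid}")
        for s, e in exons:
            gff_rows.append(f"{scaf}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={tid}")
        order = cds_iv if strand == "+" else cds_iv[::-1]
        cum = 0
        phased = {}
        for s, e in order:
            phased[(s, e)] = (3 - cum % 3) % 3
            cum += e - s
        for s, e in cds_iv:
            gff_rows.append(f"{scaf}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phased[(s, e)]}\tParent={tid}")

    if gene_idx < config.n_genes:
        raise ValueError(
            f"genome too small: placed only {gene_idx} of {config.n_genes} genes"
        )

    header = "##gff-version 3\n" + "".join(
        f"##sequence-region {s} 1 {len(arrays[s])}\n" for s in scaffolds
    )
    return header + "\n".join(gff_rows) + "\n", genes


def assign_annotations(genes: Mapping, term_levels: Mapping, config: SimConfig,
                       rng: np.random.Generator):
    """gene->GO pairs; a configured fraction of genes stays unannotated and
    each planted enriched term receives a fixed-size member gene set."""
    gene_ids = sorted(genes)
    order = list(rng.permutation(len(gene_ids)))
    n_annot = int(round(len(gene_ids) * (1 - config.fraction_unannotated)))
    annotated = [gene_ids[i] for i in order[:n_annot]]
    terms = sorted(term_levels)
    non_root = [t for t in terms if term_levels[t] > 0] or terms

    # planted terms are chosen first and reserved: their (direct) member
    # sets are exactly the planted genes, so the planted load signal maps
    # onto a well-defined term
    max_level = max(term_levels.values())
    deep = [t for t in terms if term_levels[t] == max_level]
    enriched_terms, enriched_genes = [], {}
    pool = list(annotated)
    for spec_term, _mult in config.enriched_terms:
        term = spec_term
        if term is None:
            cands = [t for t in deep if t not in enriched_terms] or \
                    [t for t in non_root if t not in enriched_terms]
            term = cands[int(rng.integers(0, len(cands)))]
        n_members = min(config.enriched_genes_per_term, len(pool))
        members = [pool[int(i)] for i in rng.choice(len(pool), size=n_members, replace=False)]
        pool = [g for g in pool if g not in members]
        enriched_terms.append(term)
        enriched_genes[term] = sorted(members)

    background_terms = [t for t in non_root if t not in enriched_terms] or non_root
    pairs = []
    for g in annotated:
        k = int(rng.integers(config.terms_per_gene[0], config.terms_per_gene[1] + 1))
        for i in rng.choice(len(background_terms), size=min(k, len(background_terms)), replace=False):
            pairs.append((g, background_terms[int(i)]))
    for term in enriched_terms:
        for g in enriched_genes[term]:
            pairs.append((g, term))
    return sorted(set(pairs)), enriched_terms, enriched_genes


# --------------------------------------------------------------------------
# variants


class _CallableSampler:
    """Uniform position sampling over callable (non-N) genome intervals."""

    def __init__(self, intervals: Mapping):
        self.scafs, self.starts, self.ends, self.offsets = [], [], [], [0]
        for scaf in intervals:
            for s, e in intervals[scaf]:
                self.scafs.append(scaf)
                self.starts.append(s)
                self.ends.append(e)
                self.offsets.append(self.offsets[-1] + (e - s))
        self.total = self.offsets[-1]
        self._off = np.asarray(self.offsets)

    def draw(self, rng) -> tuple:
        r = int(rng.integers(0, self.total))
        i = int(np.searchsorted(self._off, r, side="right")) - 1
        return self.scafs[i], self.starts[i] + (r - self.offsets[i])


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _snp_at(seq, pos, rng, exclude=()):
    ref = seq[pos]
    choices = [b for b in "ACGT" if b != ref and b not in exclude]
    return ref, choices[int(rng.integers(0, len(choices)))]


def _region_ok(seq, pos, k):
    frag = seq[pos:pos + k]
    return len(frag) == k and "N" not in frag


def _make_record(kind, seq, scaf, pos, rng, config):
    """One SMV at 0-based pos; returns dict or None if infeasible here."""
    if seq[pos] == "N":
        return None
    if kind == "SNP":
        ref, alt = _snp_at(seq, pos, rng)
        alts = [alt]
        if rng.random() < config.multiallelic_fraction:
            _, alt2 = _snp_at(seq, pos, rng, exclude=(alt,))
            alts.append(alt2)
        return {"scaffold": scaf, "pos": pos + 1, "ref": ref, "alts": tuple(alts), "type": "SNP"}
    if kind == "INS":
        ins_len = int(rng.integers(1, 6))
        ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=ins_len))
        ref = seq[pos]
        return {"scaffold": scaf, "pos": pos + 1, "ref": ref, "alts": (ref + ins,), "type": "INS"}
    # DEL: left-anchored, REF includes the base before the deleted run
    del_len = int(rng.integers(1, 6))
    if not _region_ok(seq, pos, del_len + 1):
        return None
    ref = seq[pos:pos + del_len + 1]
    return {"scaffold": scaf, "pos": pos + 1, "ref": ref, "alts": (ref[0],), "type": "DEL"}


def _sample_smv(rng, config, genome, sampler, enriched_samplers, category,
                forbidden: set, n_override: Mapping | None = None):
    """Core (filter-passing) SMVs for one category, honouring planted load."""
    records: dict[tuple, dict] = {}
    intens = config.smv_intensity[category]
    plans = []
    for kind in SMV_TYPES:
        lam = intens[kind] * sampler.total / 1000.0
        n = int(rng.poisson(lam)) if n_override is None else n_override.get(kind, 0)
        plans.append((kind, n, sampler))
        for es, mult in enriched_samplers:
            lam_e = intens[kind] * (mult - 1.0) * es.total / 1000.0
            plans.append((kind, int(rng.poisson(lam_e)), es))
    rejections = 0
    for kind, n, smp in plans:
        made = 0
        while made < n:
            if rejections > config.max_rejections:
                raise RuntimeError(
                    f"position sampling for {category} exceeded "
                    f"{config.max_rejections} rejections; lower the intensities"
                )
            scaf, pos = smp.draw(rng)
            key = (scaf, pos + 1)
            if key in records or key in forbidden:
                rejections += 1
                continue
            rec = _make_record(kind, genome[scaf], scaf, pos, rng, config)
            if rec is None:
                rejections += 1
                continue
            records[key] = rec
            made += 1
    return records


def _reemit(rng, config, genome, intra: Mapping):
    """Re-emit intra positions into the paired inter set per the sharing
    fractions; returns (inter_records, intra_labels, inter_labels)."""
    f_id, f_non = config.sharing_identical, config.sharing_nonidentical
    inter: dict[tuple, dict] = {}
    intra_labels: dict[tuple, str] = {}
    inter_labels: dict[tuple, str] = {}
    for key, rec in intra.items():
        u = rng.random()
        if u < f_id:
            inter[key] = dict(rec)
            intra_labels[key] = SharingLabel.IDENTICAL.value
            inter_labels[key] = SharingLabel.IDENTICAL.value
        elif u < f_id + f_non:
            seq = genome[rec["scaffold"]]
            pos0 = rec["pos"] - 1
            if rec["type"] == "SNP":
                ref, alt = _snp_at(seq, pos0, rng, exclude=tuple(a for a in rec["alts"]))
                new = {"scaffold": rec["scaffold"], "pos": rec["pos"], "ref": ref,
                       "alts": (alt,), "type": "SNP"}
            elif rec["type"] == "INS":
                cur = rec["alts"][0][1:]
                ins = cur
                while ins == cur:
                    ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=len(cur) or 1))
                new = {"scaffold": rec["scaffold"], "pos": rec["pos"], "ref": rec["ref"],
                       "alts": (rec["ref"] + ins,), "type": "INS"}
            else:  # DEL: different deletion length at the same anchor
                cur_len = len(rec["ref"]) - 1
                alt_len = cur_len + 1 if _region_ok(seq, pos0, cur_len + 2) else max(1, cur_len - 1)
                if alt_len == cur_len or not _region_ok(seq, pos0, alt_len + 1):
                    # fall back to a SNP at the anchor with a novel alt
                    ref, alt = _snp_at(seq, pos0, rng)
                    new = {"scaffold": rec["scaffold"], "pos": rec["pos"], "ref": ref,
                           "alts": (alt,), "type": "SNP"}
                else:
                    ref = seq[pos0:pos0 + alt_len + 1]
                    new = {"scaffold": rec["scaffold"], "pos": rec["pos"], "ref": ref,
                           "alts": (ref[0],), "type": "DEL"}
            new_keys = {allele_key(new["ref"], a) for a in new["alts"]}
            old_keys = {allele_key(rec["ref"], a) for a in rec["alts"]}
            if new_keys & old_keys:
                # alleles must differ for a NONIDENTICAL plant
                intra_labels[key] = SharingLabel.UNIQUE_INTRA.value
                continue
            inter[key] = new
            intra_labels[key] = SharingLabel.NONIDENTICAL.value
            inter_labels[key] = SharingLabel.NONIDENTICAL.value
        else:
            intra_labels[key] = SharingLabel.UNIQUE_INTRA.value
    return inter, intra_labels, inter_labels


def _sample_sv(rng, config, genome, gaps, category, enriched_regions, mult_lookup):
    """Core SVs for one category; enriched gene regions get multiplied rates."""
    scaffolds = list(genome)
    total_mbp = sum(len(genome[s]) for s in scaffolds) / 1e6
    intens = config.sv_intensity[category]
    records = []
    idx = 0
    used: set = set()

    def _place(svtype, region=None):
        nonlocal idx
        for _ in range(200):
            if region is None:
                scaf = scaffolds[int(rng.integers(0, len(scaffolds)))]
                L = len(genome[scaf])
                start0 = int(rng.integers(100, L - 3200))
            else:
                scaf, r0, r1 = region
                L = len(genome[scaf])
                start0 = int(rng.integers(r0, max(r0 + 1, min(r1, L - 3200))))
            if (scaf, start0) in used:
                continue
            if svtype in ("DEL", "DUP", "INV"):
                length = int(rng.integers(300, 3001))
                end0 = min(start0 + length, L - 10)
            else:
                end0 = start0
            used.add((scaf, start0))
            rec = {"scaffold": scaf, "start": start0 + 1, "end": end0 if svtype in ("DEL", "DUP", "INV") else start0 + 1,
                   "svtype": svtype, "support": int(rng.integers(5, 41)),
                   "id": f"sv_{category}_{idx:05d}"}
            if svtype == "TRA":
                mate = scaffolds[int(rng.integers(0, len(scaffolds)))]
                rec["mate_scaffold"] = mate
                rec["mate_pos"] = int(rng.integers(100, len(genome[mate]) - 100)) + 1
            if svtype == "INS":
                rec["svlen"] = int(rng.integers(50, 501))
            idx += 1
            return rec
        return None

    for svtype in SV_TYPES:
        lam = intens[svtype] * total_mbp
        for _ in range(int(rng.poisson(lam))):
            rec = _place(svtype)
            if rec:
                records.append(rec)
        for (scaf, r0, r1), mult in zip(enriched_regions, mult_lookup):
            lam_e = intens[svtype] * (mult - 1.0) * (r1 - r0) / 1e6
            for _ in range(int(rng.poisson(lam_e))):
                rec = _place(svtype, region=(scaf, r0, r1))
                if rec:
                    records.append(rec)
    return records


def _reemit_sv(rng, config, genome, intra: list, category: str):
    """Share intra SVs into the paired inter set (jittered same-type copy =
    IDENTICAL, different type at the same start = NONIDENTICAL)."""
    f_id, f_non = config.sharing_identical, config.sharing_nonidentical
    inter = []
    intra_labels, inter_labels = {}, {}
    for i, rec in enumerate(intra):
        key = (rec["scaffold"], rec["svtype"], rec["start"], rec["end"])
        u = rng.random()
        if u < f_id:
            jitter = int(rng.integers(-10, 11))
            new = dict(rec)
            new["start"] = max(1, rec["start"] + jitter)
            new["end"] = rec["end"] + jitter if rec["svtype"] in ("DEL", "DUP", "INV") else new["start"]
            new["support"] = int(rng.integers(5, 41))
            new["id"] = f"sv_{category}_re{i:05d}"
            inter.append(new)
            intra_labels[key] = SharingLabel.IDENTICAL.value
            inter_labels[(new["scaffold"], new["svtype"], new["start"], new["end"])] = \
                SharingLabel.IDENTICAL.value
        elif u < f_id + f_non:
            other = {"DEL": "DUP", "DUP": "DEL", "INV": "DEL", "TRA": "INS", "INS": "TRA"}[rec["svtype"]]
            new = dict(rec)
            new["svtype"] = other
            if other in ("DEL", "DUP", "INV"):
                L = len(genome[rec["scaffold"]])
                new["end"] = min(new["start"] + int(rng.integers(300, 3001)), L - 10)
            else:
                new["end"] = new["start"]
                if other == "INS":
                    new["svlen"] = int(rng.integers(50, 501))
                    new.pop("mate_scaffold", None)
                    new.pop("mate_pos", None)
                else:
                    L = len(genome[rec["scaffold"]])
                    new["mate_scaffold"] = rec["scaffold"]
                    new["mate_pos"] = min(rec["start"] + 5000, L - 100)
            new["support"] = int(rng.integers(5, 41))
            new["id"] = f"sv_{category}_re{i:05d}"
            inter.append(new)
            intra_labels[key] = SharingLabel.NONIDENTICAL.value
            inter_labels[(new["scaffold"], new["svtype"], new["start"], new["end"])] = \
                SharingLabel.NONIDENTICAL.value
        else:
            intra_labels[key] = SharingLabel.UNIQUE_INTRA.value
    return inter, intra_labels, inter_labels


def _decoys_smv(rng, config, genome, sampler, n_core, forbidden):
    """Records deliberately failing the QUAL filter."""
    n = int(rng.poisson(config.fail_fraction * n_core))
    out = {}
    tries = 0
    while len(out) < n and tries < config.max_rejections:
        tries += 1
        scaf, pos = sampler.draw(rng)
        key = (scaf, pos + 1)
        if key in forbidden or key in out:
            continue
        rec = _make_record("SNP", genome[scaf], scaf, pos, rng, config)
        if rec is None:
            continue
        rec["decoy"] = True
        out[key] = rec
    return out


def _decoys_sv(rng, config, genome, n_core, category):
    n = int(rng.poisson(config.fail_fraction * n_core))
    scaffolds = list(genome)
    out = []
    for i in range(n):
        scaf = scaffolds[int(rng.integers(0, len(scaffolds)))]
        L = len(genome[scaf])
        start0 = int(rng.integers(100, L - 3200))
        if rng.random() < 0.5:
            # under-supported deletion
            rec = {"scaffold": scaf, "start": start0 + 1,
                   "end": start0 + int(rng.integers(300, 3001)),
                   "svtype": "DEL", "support": int(rng.integers(1, 5))}
        else:
            # well-supported but too short
            rec = {"scaffold": scaf, "start": start0 + 1,
                   "end": start0 + int(rng.integers(50, 300)),
                   "svtype": "DEL", "support": int(rng.integers(5, 41))}
        rec["decoy"] = True
        rec["id"] = f"sv_{category}_dec{i:05d}"
        out.append(rec)
    return out


# --------------------------------------------------------------------------
# assembly of the full bundle


def generate_bundle(config: SimConfig | None = None) -> Bundle:
    """Generate the complete fixture bundle for one seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(8)
    rng_onto = np.random.default_rng(keys[0])
    rng_gen = np.random.default_rng(keys[1])
    rng_genes = np.random.default_rng(keys[2])
    rng_annot = np.random.default_rng(keys[3])
    rng_var = np.random.default_rng(keys[4])
    rng_qual = np.random.default_rng(keys[5])
    rng_sv = np.random.default_rng(keys[6])
    rng_dec = np.random.default_rng(keys[7])

    obo, edges, term_levels = generate_ontology(config, rng_onto)
    arrays, gaps = generate_genome(config, rng_gen)
    gff3, genes = generate_gene_models(arrays, gaps, config, rng_genes)
    gene2go, enriched_terms, enriched_genes = assign_annotations(
        genes, term_levels, config, rng_annot)

    genome = {s: arr.tobytes().decode() for s, arr in arrays.items()}
    scaffolds = list(genome)

    bundle = Bundle(
        config=config, genome=genome, gaps=gaps, gff3=gff3, obo=obo,
        gene2go=gene2go, genes=genes, smv={}, sv={},
        truth=pd.DataFrame(), planted_loads=pd.DataFrame(),
        enriched_terms=enriched_terms, enriched_genes=enriched_genes,
    )
    callable_iv = bundle.callable_intervals()
    sampler = _CallableSampler(callable_iv)

    # enriched gene regions (gene body +/- flank, clipped, merged per scaffold)
    all_members = sorted({g for gs in enriched_genes.values() for g in gs})
    regions_by_scaf: dict[str, list] = {}
    mult = max(m for _, m in config.enriched_terms) if config.enriched_terms else 1.0
    for g in all_members:
        scaf, s, e, _ = genes[g]
        L = len(genome[scaf])
        regions_by_scaf.setdefault(scaf, []).append(
            (max(0, s - config.gene_flank), min(L, e + config.gene_flank)))
    enriched_regions = []
    for scaf, ivs in regions_by_scaf.items():
        for s, e in _merge(ivs):
            enriched_regions.append((scaf, s, e))
    enriched_samplers = [
        (_CallableSampler({scaf: [(s, e)]}), mult) for scaf, s, e in enriched_regions
    ]

    # ---- SMVs with planted sharing -----------------------------------
    smv: dict[str, dict] = {}
    labels: dict[str, dict] = {c: {} for c in ("AA", "BB", "AB", "BA")}
    for intra_cat, inter_cat in (("AA", "AB"), ("BB", "BA")):
        intra = _sample_smv(rng_var, config, genome, sampler, enriched_samplers,
                            intra_cat, forbidden=set())
        inter_re, intra_lab, inter_lab = _reemit(rng_var, config, genome, intra)
        own = _sample_smv(rng_var, config, genome, sampler, enriched_samplers,
                          inter_cat, forbidden=set(intra) | set(inter_re))
        inter = dict(inter_re)
        inter.update(own)
        for key in own:
            inter_lab[key] = SharingLabel.UNIQUE_INTER.value
        smv[intra_cat], smv[inter_cat] = intra, inter
        labels[intra_cat] = intra_lab
        labels[inter_cat] = inter_lab

    # quality scores + decoys
    for cat in ("AA", "BB", "AB", "BA"):
        for rec in smv[cat].values():
            rec["qual"] = round(float(rng_qual.uniform(30.0, 60.0)), 2)
            rec["decoy"] = False
        dec = _decoys_smv(rng_dec, config, genome, sampler, len(smv[cat]), set(smv[cat]))
        for rec in dec.values():
            rec["qual"] = round(float(rng_dec.uniform(3.0, 29.9)), 2)
        smv[cat].update(dec)

    # ---- SVs ----------------------------------------------------------
    mults = [mult] * len(enriched_regions)
    sv: dict[str, list] = {}
    sv_labels: dict[str, dict] = {c: {} for c in ("AA", "BB", "AB", "BA")}
    for intra_cat, inter_cat in (("AA", "AB"), ("BB", "BA")):
        intra = _sample_sv(rng_sv, config, genome, gaps, intra_cat, enriched_regions, mults)
        inter_re, intra_lab, inter_lab = _reemit_sv(rng_sv, config, genome, intra, inter_cat)
        own = _sample_sv(rng_sv, config, genome, gaps, inter_cat, enriched_regions, mults)
        for rec in own:
            inter_lab.setdefault(
                (rec["scaffold"], rec["svtype"], rec["start"], rec["end"]),
                SharingLabel.UNIQUE_INTER.value)
        for rec in intra:
            rec["decoy"] = False
        inter = inter_re + own
        for rec in inter:
            rec["decoy"] = False
        sv_labels[intra_cat] = intra_lab
        sv_labels[inter_cat] = inter_lab
        sv[intra_cat] = intra + _decoys_sv(rng_dec, config, genome, len(intra), intra_cat)
        sv[inter_cat] = inter + _decoys_sv(rng_dec, config, genome, len(inter), inter_cat)

    bundle.smv = {c: _sorted_records(smv[c], scaffolds) for c in smv}
    bundle.sv = {c: _sorted_sv(sv[c], scaffolds) for c in sv}

    # ---- ground truth -------------------------------------------------
    index = build_region_index(_as_tempfile(gff3), {s: len(genome[s]) for s in scaffolds},
                               RegionConfig())
    rows = []
    for cat in ("AA", "BB", "AB", "BA"):
        for rec in bundle.smv[cat]:
            key = (rec["scaffold"], rec["pos"])
            _, flat = index.locate(rec["scaffold"], rec["pos"], rec["pos"] + len(rec["ref"]) - 1)
            rows.append({
                "dataset": cat, "vclass": "SMV", "scaffold": rec["scaffold"],
                "pos": rec["pos"], "ref": rec["ref"], "alt": ",".join(rec["alts"]),
                "type": rec["type"], "qual_or_support": rec["qual"],
                "passes_filter": not rec["decoy"], "is_decoy": rec["decoy"],
                "sharing": labels[cat].get(key, ""), "region": flat.name,
            })
        scaf_order = {s: i for i, s in enumerate(scaffolds)}
        for rec in bundle.sv[cat]:
            key = (rec["scaffold"], rec["svtype"], rec["start"], rec["end"])
            # a TRA breakend pair is consumed downstream at whichever
            # breakend sorts first in the VCF
            if rec["svtype"] == "TRA" and rec.get("mate_scaffold"):
                a = (scaf_order[rec["scaffold"]], rec["start"])
                b = (scaf_order[rec["mate_scaffold"]], rec["mate_pos"])
                rep_scaf, rep_pos = ((rec["scaffold"], rec["start"]) if a <= b
                                     else (rec["mate_scaffold"], rec["mate_pos"]))
                rep_end = rep_pos
            else:
                rep_scaf, rep_pos, rep_end = rec["scaffold"], rec["start"], rec["end"]
            _, flat = index.locate(rep_scaf, rep_pos, max(rep_pos, rep_end))
            rows.append({
                "dataset": cat, "vclass": "SV", "scaffold": rep_scaf,
                "pos": rep_pos, "ref": rec["svtype"], "alt": f"end={rep_end}",
                "type": rec["svtype"], "qual_or_support": rec["support"],
                "passes_filter": not rec["decoy"], "is_decoy": rec["decoy"],
                "sharing": sv_labels[cat].get(key, ""), "region": flat.name,
            })
    bundle.truth = pd.DataFrame(rows, columns=[
        "dataset", "vclass", "scaffold", "pos", "ref", "alt", "type",
        "qual_or_support", "passes_filter", "is_decoy", "sharing", "region"])
    bundle.planted_loads = _planted_loads(bundle)
    return bundle


def _planted_loads(bundle: Bundle) -> pd.DataFrame:
    """Per-gene loads of filter-passing variants, by direct interval check."""
    flank = bundle.config.gene_flank
    cols = ["gene", "category", "smv_load", "sv_load"]
    if bundle.truth.empty:
        return pd.DataFrame(
            [{"gene": g, "category": c, "smv_load": 0, "sv_load": 0}
             for g in sorted(bundle.genes) for c in ("AA", "BB", "AB", "BA")],
            columns=cols)
    passing = bundle.truth[bundle.truth.passes_filter.astype(bool)]
    spans: dict[tuple, tuple] = {}
    for (scaf, cat, vc), df in passing.groupby(["scaffold", "dataset", "vclass"]):
        s = df.pos.to_numpy() - 1
        if vc == "SMV":
            e = s + df.ref.str.len().to_numpy()
        else:
            e = df.alt.str.replace("end=", "", regex=False).astype(int).to_numpy()
        spans[(scaf, cat, vc)] = (s, e)
    rows = []
    for gid, (scaf, gs, ge, _) in sorted(bundle.genes.items()):
        L = len(bundle.genome[scaf])
        r0, r1 = max(0, gs - flank), min(L, ge + flank)
        for cat in ("AA", "BB", "AB", "BA"):
            counts = {}
            for vc in ("SMV", "SV"):
                s, e = spans.get((scaf, cat, vc), (np.empty(0, int), np.empty(0, int)))
                counts[vc] = int(np.count_nonzero((e > r0) & (s < r1)))
            rows.append({"gene": gid, "category": cat,
                         "smv_load": counts["SMV"], "sv_load": counts["SV"]})
    return pd.DataFrame(rows)


def _sorted_records(records: Mapping, scaffolds: list) -> list:
    order = {s: i for i, s in enumerate(scaffolds)}
    return sorted(records.values(), key=lambda r: (order[r["scaffold"]], r["pos"]))


def _sorted_sv(records: list, scaffolds: list) -> list:
    order = {s: i for i, s in enumerate(scaffolds)}
    return sorted(records, key=lambda r: (order[r["scaffold"]], r["start"], r["id"]))


_TMPFILES = []


def _as_tempfile(text: str) -> str:
    import tempfile

    f = tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False)
    f.write(text)
    f.close()
    _TMPFILES.append(f.name)
    return f.name


# --------------------------------------------------------------------------
# serialisation


def _vcf_header(genome: Mapping, sv: bool) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for s, seq in genome.items():
        lines.append(f"##contig=<ID={s},length={len(seq)}>")
    if sv:
        lines += [
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Insertion length">',
            '##INFO=<ID=PE,Number=1,Type=Integer,Description="Supporting discordant read pairs">',
            '##INFO=<ID=MATEID,Number=1,Type=String,Description="Breakend mate">',
            '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">',
        ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_smv_vcf(records: list, genome: Mapping, path: Path):
    with open(path, "w") as fh:
        fh.write(_vcf_header(genome, sv=False))
        for r in records:
            fh.write(f"{r['scaffold']}\t{r['pos']}\t.\t{r['ref']}\t"
                     f"{','.join(r['alts'])}\t{r['qual']:.2f}\t.\t.\n")


def write_sv_vcf(records: list, genome: Mapping, path: Path):
    scaf_order = {s: i for i, s in enumerate(genome)}
    lines: list[tuple] = []
    for r in records:
        info = [f"SVTYPE={r['svtype']}", f"PE={r['support']}"]
        rid = r["id"]
        if r["svtype"] in ("DEL", "DUP", "INV"):
            info.append(f"END={r['end']}")
            lines.append((scaf_order[r["scaffold"]], r["start"], rid,
                          f"{r['scaffold']}\t{r['start']}\t{rid}\t"
                          f"{genome[r['scaffold']][r['start'] - 1]}\t<{r['svtype']}>\t.\t.\t{';'.join(info)}"))
        elif r["svtype"] == "INS":
            info.append(f"SVLEN={r.get('svlen', 100)}")
            lines.append((scaf_order[r["scaffold"]], r["start"], rid,
                          f"{r['scaffold']}\t{r['start']}\t{rid}\t"
                          f"{genome[r['scaffold']][r['start'] - 1]}\t<INS>\t.\t.\t{';'.join(info)}"))
        else:  # TRA as a breakend pair
            m_scaf, m_pos = r.get("mate_scaffold", r["scaffold"]), r.get("mate_pos", r["start"])
            b1 = genome[r["scaffold"]][r["start"] - 1]
            b2 = genome[m_scaf][m_pos - 1]
            i1 = info + [f"CHR2={m_scaf}", f"MATEID={rid}_2"]
            i2 = info + [f"CHR2={r['scaffold']}", f"MATEID={rid}"]
            lines.append((scaf_order[r["scaffold"]], r["start"], rid,
                          f"{r['scaffold']}\t{r['start']}\t{rid}\t{b1}\t"
                          f"{b1}[{m_scaf}:{m_pos}[\t.\t.\t{';'.join(i1)}"))
            lines.append((scaf_order[m_scaf], m_pos, f"{rid}_2",
                          f"{m_scaf}\t{m_pos}\t{rid}_2\t{b2}\t"
                          f"{b2}[{r['scaffold']}:{r['start']}[\t.\t.\t{';'.join(i2)}"))
    with open(path, "w") as fh:
        fh.write(_vcf_header(genome, sv=True))
        for _, _, _, line in sorted(lines):
            fh.write(line + "\n")


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict:
    """Serialise the bundle; returns a name->path manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    fa = out / "genome.fa"
    with open(fa, "w") as fh:
        for scaf, seq in bundle.genome.items():
            fh.write(f">{scaf}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    paths["genome"] = fa

    bed = out / "callable.bed"
    with open(bed, "w") as fh:
        for scaf, ivs in bundle.callable_intervals().items():
            for s, e in ivs:
                fh.write(f"{scaf}\t{s}\t{e}\n")
    paths["callable"] = bed

    (out / "genes.gff3").write_text(bundle.gff3)
    paths["gff3"] = out / "genes.gff3"
    (out / "ontology.obo").write_text(bundle.obo)
    paths["obo"] = out / "ontology.obo"

    g2g = out / "gene2go.tsv"
    with open(g2g, "w") as fh:
        for gene, term in bundle.gene2go:
            fh.write(f"{gene}\t{term}\n")
    paths["gene2go"] = g2g

    for cat in ("AA", "BB", "AB", "BA"):
        p = out / f"smv_{cat}.vcf"
        write_smv_vcf(bundle.smv[cat], bundle.genome, p)
        paths[f"smv_{cat}"] = p
        p = out / f"sv_{cat}.vcf"
        write_sv_vcf(bundle.sv[cat], bundle.genome, p)
        paths[f"sv_{cat}"] = p

    bundle.truth.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    paths["truth_variants"] = out / "truth_variants.tsv"
    bundle.planted_loads.to_csv(out / "truth_loads.tsv", sep="\t", index=False)
    paths["truth_loads"] = out / "truth_loads.tsv"
    (out / "truth_enriched_terms.txt").write_text(
        "".join(f"{t}\n" for t in bundle.enriched_terms))
    paths["enriched_terms"] = out / "truth_enriched_terms.txt"
    return paths


def simulate_bundle(config: SimConfig | None = None, outdir: str | Path = ".") -> dict:
    """Generate and serialise a bundle in one call."""
    bundle = generate_bundle(config)
    return write_bundle(bundle, outdir)
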