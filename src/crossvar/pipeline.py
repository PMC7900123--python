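"""End-to-end orchestration: validate, filter, annotate, compare, enrich.

A single declarative configuration names the genome, gene models, ontology,
annotation map and the four paired variant call sets (AA/AB on one
reference, BB/BA on the other — here the same synthetic reference).  The
pipeline emits the summary tables (per-dataset counts and rates, impact
distributions, region location distributions, per-gene hit proportions),
the sharing labels, mutation loads, candidate gene sets and the GO
enrichment reports, plus a JSON manifest with input checksums and the
effective parameter set so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import asmstats as _asm
from .compare import (
    ComparisonCategory,
    SelectionConfig,
    classify_sharing,
    classify_sv_sharing,
    index_by_position,
    mutation_load,
    select_candidate_genes,
)
from .enrich import (
    EnrichmentConfig,
    enrichment_report,
    load_ontology,
    propagate_annotations,
    read_gene2go,
    run_enrichment,
)
from .regions import RegionConfig, build_region_index, genome_coverage
from .variants import (
    FilterConfig,
    annotate_effects,
    effect_distribution,
    gene_hit_proportions,
    location_distribution,
    read_and_filter_smv,
    read_and_filter_sv,
    summarize_dataset,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("AA", "BB", "AB", "BA")

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome: str
    gff3: str
    obo: str
    gene2go: str
    smv_vcfs: dict          # category -> path, categories AA/BB/AB/BA
    sv_vcfs: dict
    outdir: str
    callable_bed: str | None = None
    region: RegionConfig = field(default_factory=RegionConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (("region", RegionConfig), ("filters", FilterConfig),
                         ("selection", SelectionConfig), ("enrichment", EnrichmentConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    @classmethod
    def from_bundle_dir(cls, bundle_dir: str, outdir: str, **kwargs) -> "PipelineConfig":
        d = Path(bundle_dir)
        return cls(
            genome=str(d / "genome.fa"),
            gff3=str(d / "genes.gff3"),
            obo=str(d / "ontology.obo"),
            gene2go=str(d / "gene2go.tsv"),
            smv_vcfs={c: str(d / f"smv_{c}.vcf") for c in CATEGORIES},
            sv_vcfs={c: str(d / f"sv_{c}.vcf") for c in CATEGORIES},
            callable_bed=str(d / "callable.bed"),
            outdir=outdir,
            **kwargs,
        )

    def params(self) -> dict:
        return {
            "region": dataclasses.asdict(self.region),
            "filters": dataclasses.asdict(self.filters),
            "selection": dataclasses.asdict(self.selection),
            "enrichment": dataclasses.asdict(self.enrichment),
            "seed": self.seed,
        }


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _load_genome(path: str) -> dict:
    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def _read_callable_bed(path: str) -> int:
    total = 0
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                _, s, e = line.split("\t")[:3]
                total += int(e) - int(s)
    return total


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Parse-check every input and cross-check coordinate namespaces."""
    rep = ValidationReport()
    scaffolds: set = set()
    try:
        genome = _load_genome(config.genome)
        scaffolds = set(genome)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        rep.errors.append(f"genome: {exc}")
    try:
        import gffutils

        db = gffutils.create_db(config.gff3, ":memory:", force=True, merge_strategy="create_unique")
        gene_ids = {g.id for g in db.features_of_type("gene")}
        bad = {g.seqid for g in db.features_of_type("gene")} - scaffolds
        if scaffolds and bad:
            rep.errors.append(f"gff3: genes on scaffolds absent from the genome: {sorted(bad)[:5]}")
    except Exception as exc:  # noqa: BLE001
        rep.errors.append(f"gff3: {exc}")
        gene_ids = set()
    try:
        dag = load_ontology(config.obo)
    except Exception as exc:  # noqa: BLE001
        rep.errors.append(f"obo: {exc}")
        dag = None
    try:
        ann = read_gene2go(config.gene2go)
        if dag is not None:
            unknown = {t for ts in ann.gene2terms.values() for t in ts if t not in dag}
            if unknown:
                rep.warnings.append(f"gene2go: {len(unknown)} terms absent from the ontology")
        no_go = gene_ids - ann.genes
        if no_go:
            rep.warnings.append(
                f"{len(no_go)} genes without GO terms (excluded from the enrichment universe)")
    except Exception as exc:  # noqa: BLE001
        rep.errors.append(f"gene2go: {exc}")
    from cyvcf2 import VCF

    for kind, paths in (("smv", config.smv_vcfs), ("sv", config.sv_vcfs)):
        for cat in CATEGORIES:
            if cat not in paths:
                rep.errors.append(f"{kind}: missing category {cat} (pairings AA-AB, BB-BA required)")
                continue
            try:
                vcf = VCF(paths[cat])
                vcf_scafs = set(vcf.seqnames)
                if scaffolds and not vcf_scafs <= scaffolds:
                    rep.errors.append(
                        f"{kind}_{cat}: scaffolds absent from the genome: "
                        f"{sorted(vcf_scafs - scaffolds)[:5]}")
            except Exception as exc:  # noqa: BLE001
                rep.errors.append(f"{kind}_{cat}: {exc}")
    return rep


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, comment: str):
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": config.params(),
        "inputs": {},
        "artifacts": {},
        "complete": False,
    }
    for name in ("genome", "gff3", "obo", "gene2go"):
        manifest["inputs"][name] = _sha256(getattr(config, name))
    for cat in CATEGORIES:
        manifest["inputs"][f"smv_{cat}"] = _sha256(config.smv_vcfs[cat])
        manifest["inputs"][f"sv_{cat}"] = _sha256(config.sv_vcfs[cat])

    stage = "load"
    try:
        genome = _load_genome(config.genome)
        scaffold_lengths = {s: len(seq) for s, seq in genome.items()}
        total_length = sum(scaffold_lengths.values())
        if config.callable_bed:
            effective_length = _read_callable_bed(config.callable_bed)
        else:
            effective_length = total_length - sum(
                _asm.count_n_bases(s) for s in genome.values())

        stage = "assembly_stats"
        stats = _asm.assembly_stats(genome.values())
        _write_tsv(pd.DataFrame([stats.as_dict()]), out / "assembly_stats.tsv",
                   "scaffold contiguity and size statistics")
        manifest["artifacts"]["assembly_stats"] = "assembly_stats.tsv"

        stage = "region_index"
        index = build_region_index(config.gff3, scaffold_lengths, config.region)
        gcov = genome_coverage(index)
        _write_tsv(
            pd.DataFrame([{"region": c.name, "fraction": f} for c, f in gcov.items()]),
            out / "gcov.tsv", "genome coverage per functional region class (GCOV)")
        manifest["artifacts"]["gcov"] = "gcov.tsv"

        stage = "filter"
        smv, sv, filter_rows = {}, {}, []
        for cat in CATEGORIES:
            smv[cat], rep = read_and_filter_smv(config.smv_vcfs[cat], config.filters)
            filter_rows.append({"dataset": cat, "vclass": "SMV",
                                "kept": rep.kept, "dropped": rep.dropped})
            sv[cat], rep = read_and_filter_sv(config.sv_vcfs[cat], config.filters)
            filter_rows.append({"dataset": cat, "vclass": "SV",
                                "kept": rep.kept, "dropped": rep.dropped})
        _write_tsv(pd.DataFrame(filter_rows), out / "filter_report.tsv",
                   "records kept/dropped by the quality and support filters")
        manifest["artifacts"]["filter_report"] = "filter_report.tsv"

        stage = "summarize"
        t8_rows = []
        effects = {}
        t9_rows = []
        loc_rows = []
        hit_rows = []
        for cat in CATEGORIES:
            s = summarize_dataset(smv[cat], total_length, effective_length)
            row = {"dataset": cat, **s.as_dict()}
            sv_types = Counter(v.svtype for v in sv[cat])
            for t in ("DEL", "DUP", "INV", "TRA", "INS"):
                row[f"sv_{t.lower()}"] = sv_types.get(t, 0)
            row["sv_total"] = sum(sv_types.values())
            t8_rows.append(row)

            effects[cat] = annotate_effects(list(smv[cat]) + list(sv[cat]), index, genome)
            dist = effect_distribution(effects[cat])
            for imp, n in dist.impact_counts.items():
                t9_rows.append({"dataset": cat, "group": "impact", "class": imp.value,
                                "count": n, "pct": dist.impact_pct[imp]})
            for cons, n in dist.coding_counts.items():
                t9_rows.append({"dataset": cat, "group": "coding", "class": cons.value,
                                "count": n, "pct": dist.coding_pct[cons]})
            for cls, d in location_distribution(effects[cat], gcov).items():
                loc_rows.append({"dataset": cat, "region": cls.name, **d})
            for cls, frac in gene_hit_proportions(effects[cat], index.genes).items():
                hit_rows.append({"dataset": cat, "region": cls.name, "gene_fraction": frac})
        _write_tsv(pd.DataFrame(t8_rows), out / "dataset_summary.tsv",
                   "per-dataset variant counts, composition and rates")
        _write_tsv(pd.DataFrame(t9_rows), out / "effect_distribution.tsv",
                   "impact classes and coding consequences per dataset")
        _write_tsv(pd.DataFrame(loc_rows), out / "location_distribution.tsv",
                   "variant location distribution vs genome coverage")
        _write_tsv(pd.DataFrame(hit_rows), out / "gene_hit_proportions.tsv",
                   "fraction of genes with >=1 variant per region class")
        manifest["artifacts"].update({
            "dataset_summary": "dataset_summary.tsv",
            "effect_distribution": "effect_distribution.tsv",
            "location_distribution": "location_distribution.tsv",
            "gene_hit_proportions": "gene_hit_proportions.tsv",
        })

        stage = "compare"
        sharing_rows = []
        for intra_cat, inter_cat in (("AA", "AB"), ("BB", "BA")):
            intra_lab, inter_lab = classify_sharing(
                index_by_position(smv[intra_cat]), index_by_position(smv[inter_cat]))
            for (scaf, pos), lab in sorted(intra_lab.items()):
                sharing_rows.append({"pair": f"{intra_cat}-{inter_cat}", "side": intra_cat,
                                     "vclass": "SMV", "scaffold": scaf, "pos": pos,
                                     "label": lab.value})
            for (scaf, pos), lab in sorted(inter_lab.items()):
                sharing_rows.append({"pair": f"{intra_cat}-{inter_cat}", "side": inter_cat,
                                     "vclass": "SMV", "scaffold": scaf, "pos": pos,
                                     "label": lab.value})
            sv_intra_lab, sv_inter_lab = classify_sv_sharing(sv[intra_cat], sv[inter_cat])
            for key, lab in sorted(sv_intra_lab.items()):
                sharing_rows.append({"pair": f"{intra_cat}-{inter_cat}", "side": intra_cat,
                                     "vclass": "SV", "scaffold": key[0], "pos": key[2],
                                     "label": lab.value})
            for key, lab in sorted(sv_inter_lab.items()):
                sharing_rows.append({"pair": f"{intra_cat}-{inter_cat}", "side": inter_cat,
                                     "vclass": "SV", "scaffold": key[0], "pos": key[2],
                                     "label": lab.value})
        _write_tsv(pd.DataFrame(sharing_rows), out / "sharing_labels.tsv",
                   "within/between-species sharing label per variant position")
        manifest["artifacts"]["sharing_labels"] = "sharing_labels.tsv"

        stage = "mutation_load"
        load_table = mutation_load(
            {ComparisonCategory(c): (smv[c], sv[c]) for c in CATEGORIES}, index,
            flank=config.region.gene_flank)
        _write_tsv(load_table.to_frame(), out / "mutation_loads.tsv",
                   "per-gene variant counts (mutation loads) per category")
        manifest["artifacts"]["mutation_loads"] = "mutation_loads.tsv"

        stage = "select"
        selections = select_candidate_genes(load_table, config.selection)
        sel_rows = [
            {"category": cat.value, "vclass": vclass, "gene": g}
            for (cat, vclass), genes in sorted(selections.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))
            for g in sorted(genes)
        ]
        _write_tsv(pd.DataFrame(sel_rows, columns=["category", "vclass", "gene"]),
                   out / "candidate_genes.tsv",
                   "genes above the load quantile threshold per category")
        manifest["artifacts"]["candidate_genes"] = "candidate_genes.tsv"

        stage = "enrich"
        dag = load_ontology(config.obo)
        annotations = propagate_annotations(read_gene2go(config.gene2go), dag)
        enr_frames = []
        for (cat, vclass), study in sorted(selections.items(),
                                           key=lambda kv: (kv[0][0].value, kv[0][1])):
            study = set(study) & annotations.genes
            if not study:
                continue
            results = run_enrichment(dag, annotations, study, config.enrichment)
            rep = enrichment_report(results, config.enrichment)
            rep.insert(0, "vclass", vclass)
            rep.insert(0, "category", cat.value)
            if not rep.empty:
                enr_frames.append(rep)
        enr = (pd.concat(enr_frames, ignore_index=True) if enr_frames
               else pd.DataFrame(columns=["category", "vclass", "term", "name", "annotated",
                                          "significant", "expected", "p_classic", "p_method"]))
        _write_tsv(enr, out / "enrichment.tsv",
                   "GO terms enriched in the candidate gene sets (topology-aware)")
        manifest["artifacts"]["enrichment"] = "enrichment.tsv"

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["artifact_checksums"] = {
        name: _sha256(str(out / rel)) for name, rel in manifest["artifacts"].items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
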