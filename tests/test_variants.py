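import math

import numpy as np
import pytest

from conftest import write_minimal_vcf
from crossvar.regions import RegionClass, RegionConfig, build_region_index
from crossvar.variants import (
    ClassificationError,
    CodingConsequence,
    FilterConfig,
    Impact,
    IntegrityError,
    SmallVariant,
    annotate_effects,
    classify_smv,
    distribution_from_counts,
    effect_distribution,
    gene_hit_proportions,
    location_distribution,
    read_and_filter_smv,
    read_and_filter_sv,
    summarize_dataset,
    variant_rate,
)


class TestClassify:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "T", ["SNP"]),
            ("A", "AT", ["INS"]),
            ("AT", "A", ["DEL"]),
            ("ACG", "ATG", ["SNP"]),          # MNP, one differing base
            ("ACG", "TTG", ["SNP", "SNP"]),   # MNP, two differing bases
            ("AC", "AGGT", ["INS"]),
        ],
    )
    def test_typing(self, ref, alt, expected):
        assert classify_smv(ref, alt) == expected

    def test_symbolic_alt_rejected(self):
        with pytest.raises(ClassificationError):
            classify_smv("A", "<DEL>")
        with pytest.raises(ClassificationError):
            classify_smv("A", "A[s2:100[")

    def test_multiallelic_counts_once_but_types_per_alt(self):
        v = SmallVariant("s1", 10, "A", ("T", "AT"), 50.0)
        assert v.is_multiallelic
        assert sorted(v.types()) == ["INS", "SNP"]


class TestSmvFilter:
    def test_qual_threshold_is_inclusive(self, tmp_path):
        p = tmp_path / "x.vcf"
        write_minimal_vcf(p, [("s1", 10, "A", "T", "29.9", "."),
                              ("s1", 20, "A", "T", "30.0", "."),
                              ("s1", 30, "A", "T", "31", ".")])
        kept, rep = read_and_filter_smv(str(p))
        assert rep.kept == 2 and rep.dropped == 1
        assert [v.pos for v in kept] == [20, 30]

    def test_empty_vcf(self, tmp_path):
        p = tmp_path / "e.vcf"
        write_minimal_vcf(p, [])
        kept, rep = read_and_filter_smv(str(p))
        assert kept == [] and rep.kept == 0 and rep.dropped == 0

    def test_missing_qual_dropped_and_logged(self, tmp_path):
        p = tmp_path / "m.vcf"
        write_minimal_vcf(p, [("s1", 10, "A", "T", ".", ".")])
        kept, rep = read_and_filter_smv(str(p))
        assert kept == [] and rep.dropped_missing == 1

    def test_random_quals_match_direct_recount(self, tmp_path):
        rng = np.random.default_rng(3)
        quals = rng.uniform(0, 60, size=100)
        rows = [("s1", i + 1, "A", "T", f"{q:.3f}", ".") for i, q in enumerate(quals)]
        p = tmp_path / "r.vcf"
        write_minimal_vcf(p, rows)
        kept, rep = read_and_filter_smv(str(p))
        expect = sum(1 for q in quals if float(f"{q:.3f}") >= 30)
        assert rep.kept == len(kept) == expect


class TestSvFilter:
    def _write(self, tmp_path, rows):
        p = tmp_path / "sv.vcf"
        write_minimal_vcf(p, rows, sv=True)
        return str(p)

    def test_deletion_length_rule(self, tmp_path):
        p = self._write(tmp_path, [
            ("s1", 100, "A", "<DEL>", ".", "SVTYPE=DEL;END=398;PE=10"),   # len 299
            ("s1", 600, "A", "<DEL>", ".", "SVTYPE=DEL;END=899;PE=10"),   # len 300
        ])
        kept, rep = read_and_filter_sv(p)
        assert rep.kept == 1 and kept[0].start == 600
        assert rep.dropped_by_rule["length"] == 1

    def test_translocation_exempt_from_length(self, tmp_path):
        p = self._write(tmp_path, [
            ("s1", 100, "A", "A[s1:9000[", ".", "SVTYPE=TRA;PE=5;CHR2=s1;MATEID=x_2"),
        ])
        kept, rep = read_and_filter_sv(p)
        assert rep.kept == 1 and kept[0].svtype == "TRA"

    def test_insertion_support_rule(self, tmp_path):
        p = self._write(tmp_path, [
            ("s1", 100, "A", "<INS>", ".", "SVTYPE=INS;PE=4;SVLEN=200"),
        ])
        kept, rep = read_and_filter_sv(p)
        assert rep.kept == 0 and rep.dropped_by_rule["support"] == 1

    def test_unknown_svtype_skipped(self, tmp_path):
        p = self._write(tmp_path, [
            ("s1", 100, "A", "<CNV>", ".", "SVTYPE=CNV;PE=10"),
        ])
        kept, rep = read_and_filter_sv(p)
        assert kept == [] and rep.dropped_by_rule["unknown_svtype"] == 1

    def test_breakend_pair_collapses_to_one_event(self, tmp_path):
        rows = [
            ("s1", 100, "A", "A[s1:5000[", ".", "SVTYPE=TRA;PE=8;CHR2=s1;MATEID=t1_2"),
            ("s1", 5000, "C", "C[s1:100[", ".", "SVTYPE=TRA;PE=8;CHR2=s1;MATEID=t1"),
        ]
        # IDs must pair; rewrite with explicit IDs
        p = tmp_path / "bnd.vcf"
        with open(p, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=s1,length=100000>\n")
            for k, t in (("SVTYPE", "String"), ("PE", "Integer"),
                         ("MATEID", "String"), ("CHR2", "String")):
                fh.write(f'##INFO=<ID={k},Number=1,Type={t},Description="x">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("s1\t100\tt1\tA\tA[s1:5000[\t.\t.\tSVTYPE=TRA;PE=8;CHR2=s1;MATEID=t1_2\n")
            fh.write("s1\t5000\tt1_2\tC\tC[s1:100[\t.\t.\tSVTYPE=TRA;PE=8;CHR2=s1;MATEID=t1\n")
        kept, rep = read_and_filter_sv(str(p))
        assert rep.kept == 1
        assert kept[0].start == 100


# ---------------------------------------------------------------------------
# effect annotation on a hand-built coding gene

CODING_GFF = """##gff-version 3
##sequence-region s1 1 10000
s1\tt\tgene\t101\t130\t.\t+\t.\tID=gp
s1\tt\tmRNA\t101\t130\t.\t+\t.\tID=gp.t1;Parent=gp
s1\tt\texon\t101\t130\t.\t+\t.\tParent=gp.t1
s1\tt\tCDS\t101\t109\t.\t+\t0\tParent=gp.t1
s1\tt\tgene\t2101\t2130\t.\t-\t.\tID=gm
s1\tt\tmRNA\t2101\t2130\t.\t-\t.\tID=gm.t1;Parent=gm
s1\tt\texon\t2101\t2130\t.\t-\t.\tParent=gm.t1
s1\tt\tCDS\t2122\t2130\t.\t-\t0\tParent=gm.t1
"""


@pytest.fixture(scope="module")
def coding_setup(tmp_path_factory):
    # plus-strand CDS at 101-109: ATG AAA TAA
    # minus-strand CDS at 2122-2130 reading right-to-left: ATG AAA TAA
    # => genomic forward sequence there is TTA TTT CAT
    seq = ["G"] * 10_000
    seq[100:109] = list("ATGAAATAA")
    seq[2121:2130] = list("TTATTTCAT")
    genome = {"s1": "".join(seq)}
    gff = tmp_path_factory.mktemp("coding") / "c.gff3"
    gff.write_text(CODING_GFF)
    index = build_region_index(str(gff), {"s1": 10_000}, RegionConfig())
    return genome, index


class TestEffects:
    def test_nonsense_snp_is_high(self, coding_setup):
        genome, index = coding_setup
        # codon 2 AAA -> TAA: position 104 (1-based), A->T
        v = SmallVariant("s1", 104, "A", ("T",), 50.0)
        (eff,) = [e for e in annotate_effects([v], index, genome) if e.gene == "gp"]
        assert eff.coding_consequence == CodingConsequence.NONSENSE
        assert eff.impact == Impact.HIGH

    def test_silent_snp_is_low(self, coding_setup):
        genome, index = coding_setup
        # codon 2 AAA -> AAG (both Lys): position 106 A->G
        v = SmallVariant("s1", 106, "A", ("G",), 50.0)
        (eff,) = [e for e in annotate_effects([v], index, genome) if e.gene == "gp"]
        assert eff.coding_consequence == CodingConsequence.SILENT
        assert eff.impact == Impact.LOW

    def test_missense_snp_is_moderate(self, coding_setup):
        genome, index = coding_setup
        # codon 2 AAA -> ACA (Lys -> Thr): position 105 A->C
        v = SmallVariant("s1", 105, "A", ("C",), 50.0)
        (eff,) = [e for e in annotate_effects([v], index, genome) if e.gene == "gp"]
        assert eff.coding_consequence == CodingConsequence.MISSENSE
        assert eff.impact == Impact.MODERATE

    def test_minus_strand_consequence_mirrors_plus(self, coding_setup):
        """The same codon change on the minus-strand gene: codon 2 AAA->TAA.
        Transcript base = complement of genomic; codon 2 spans genomic
        2125-2127 (TTT on the forward strand)."""
        genome, index = coding_setup
        v = SmallVariant("s1", 2127, "T", ("A",), 50.0)  # transcript A->T at codon 2 pos 1
        (eff,) = [e for e in annotate_effects([v], index, genome) if e.gene == "gm"]
        assert eff.coding_consequence == CodingConsequence.NONSENSE
        assert eff.impact == Impact.HIGH

    def test_noncoding_snp_is_modifier(self, coding_setup):
        genome, index = coding_setup
        v = SmallVariant("s1", 115, "G", ("A",), 50.0)  # 3' UTR of gp
        effs = [e for e in annotate_effects([v], index, genome) if e.gene == "gp"]
        assert effs and all(e.impact == Impact.MODIFIER for e in effs)
        assert all(e.coding_consequence == CodingConsequence.NONE for e in effs)

    def test_frameshift_indel_high_inframe_moderate(self, coding_setup):
        genome, index = coding_setup
        fs = SmallVariant("s1", 104, "A", ("AT",), 50.0)       # +1 bp in CDS
        inframe = SmallVariant("s1", 104, "A", ("ATTT",), 50.0)  # +3 bp in CDS
        effs = {e.alt: e for e in annotate_effects([fs, inframe], index, genome)
                if e.gene == "gp"}
        assert effs["AT"].impact == Impact.HIGH
        assert effs["ATTT"].impact == Impact.MODERATE
        assert effs["AT"].coding_consequence == CodingConsequence.NONE

    def test_ref_mismatch_raises_integrity_error(self, coding_setup):
        genome, index = coding_setup
        with pytest.raises(IntegrityError):
            annotate_effects([SmallVariant("s1", 104, "C", ("T",), 50.0)], index, genome)

    def test_intergenic_variant_yields_modifier_with_no_gene(self, coding_setup):
        genome, index = coding_setup
        (eff,) = annotate_effects([SmallVariant("s1", 9_000, "G", ("A",), 50.0)],
                                  index, genome)
        assert eff.gene is None and eff.impact == Impact.MODIFIER


class TestSummary:
    @pytest.mark.parametrize(
        "n, eff, expected",
        [
            (4_105_604, 906_396_323, 220),
            (4_178_777, 913_305_292, 218),
            (356_428, 905_543_956, 2540),
            (577_124, 901_211_269, 1561),
            (1, 100, 100),
        ],
    )
    def test_variant_rate_floors(self, n, eff, expected):
        assert variant_rate(eff, n) == expected

    def test_summarize_counts_types_at_alt_level(self):
        vs = [
            SmallVariant("s1", 1, "A", ("T",), 40.0),
            SmallVariant("s1", 5, "A", ("T", "AT"), 40.0),  # SNP + INS, one multiallelic row
            SmallVariant("s1", 9, "AT", ("A",), 40.0),
        ]
        s = summarize_dataset(vs, 1000, 900)
        assert s.n_processed == 3
        assert s.n_multiallelic == 1
        assert (s.n_snp, s.n_ins, s.n_del) == (2, 1, 1)
        assert s.rate_bases == 300

    def test_zero_variants_rate_absent(self):
        s = summarize_dataset([], 1000, 900)
        assert s.rate_bases is None

    def test_bad_effective_length(self):
        with pytest.raises(ValueError):
            summarize_dataset([], 1000, 0)


class TestDistribution:
    def test_printed_impact_counts_give_printed_percentages(self):
        dist = distribution_from_counts(
            {Impact.HIGH: 13_761, Impact.MODERATE: 84_185,
             Impact.LOW: 149_561, Impact.MODIFIER: 8_799_110},
            {CodingConsequence.NONSENSE: 788, CodingConsequence.MISSENSE: 78_503,
             CodingConsequence.SILENT: 101_260},
        )
        assert dist.impact_pct[Impact.MODIFIER] == 97.26
        assert dist.impact_pct[Impact.HIGH] == 0.15
        assert dist.coding_pct[CodingConsequence.MISSENSE] == 43.48
        assert dist.coding_pct[CodingConsequence.SILENT] == 56.08
        assert sum(dist.impact_pct.values()) == pytest.approx(100, abs=0.02)

    def test_single_effect_is_100_percent(self, coding_setup):
        genome, index = coding_setup
        effs = annotate_effects([SmallVariant("s1", 9_000, "G", ("A",), 50.0)],
                                index, genome)
        dist = effect_distribution(effs)
        assert dist.impact_pct[Impact.MODIFIER] == 100.0

    def test_empty_effects_rejected(self):
        with pytest.raises(ValueError):
            effect_distribution([])


class TestLocationDistribution:
    def test_all_variants_in_one_intron(self, coding_setup):
        genome, index = coding_setup
        from crossvar.regions import genome_coverage

        gcov = genome_coverage(index)
        # intergenic positions only
        vs = [SmallVariant("s1", p, genome["s1"][p - 1], ("A" if genome["s1"][p - 1] != "A" else "T",), 50.0)
              for p in (8_000, 8_500, 9_000)]
        effs = annotate_effects(vs, index, genome)
        dist = location_distribution(effs, gcov)
        assert dist[RegionClass.INTERGENIC]["variant_fraction"] == 1.0
        assert dist[RegionClass.CODING]["variant_fraction"] == 0.0

    def test_gene_hit_proportions_promoter(self, coding_setup):
        genome, index = coding_setup
        v = SmallVariant("s1", 95, "G", ("A",), 50.0)  # promoter of gp
        effs = annotate_effects([v], index, genome)
        prop = gene_hit_proportions(effs, ["gp", "gm"])
        assert prop[RegionClass.PROMOTER] == 0.5

    def test_uniform_null_ratios_near_one(self, bundle):
        """Variants placed uniformly over the genome occupy each region
        class in proportion to its genome coverage."""
        from crossvar.regions import genome_coverage
        from crossvar.simulate import _as_tempfile

        index = build_region_index(
            _as_tempfile(bundle.gff3),
            {s: len(v) for s, v in bundle.genome.items()})
        gcov = genome_coverage(index)
        rng = np.random.default_rng(11)
        n = 20_000
        scafs = list(bundle.genome)
        lens = np.array([len(bundle.genome[s]) for s in scafs])
        total = lens.sum()
        variants = []
        for r in rng.integers(0, total, size=n):
            i = int(np.searchsorted(np.cumsum(lens), r, side="right"))
            pos0 = int(r - np.concatenate([[0], np.cumsum(lens)])[i])
            ref = bundle.genome[scafs[i]][pos0]
            alt = "A" if ref != "A" else "T"
            variants.append(SmallVariant(scafs[i], pos0 + 1, ref, (alt,), 50.0))
        effs = annotate_effects(variants, index, bundle.genome)
        dist = location_distribution(effs, gcov)
        for cls in RegionClass:
            p = gcov[cls]
            if p == 0:
                continue
            se = math.sqrt((1 - p) / (n * p))
            assert abs(dist[cls]["ratio"] - 1) <= 3 * se, cls
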