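import pytest

from crossvar.simulate import SimConfig, generate_bundle, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """One synthetic two-species bundle shared across the suite."""
    return generate_bundle(SimConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_out(bundle_dir, tmp_path_factory):
    """A completed pipeline run on the shared bundle."""
    from crossvar.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    manifest = run_pipeline(PipelineConfig.from_bundle_dir(str(bundle_dir), str(out)))
    return out, manifest


def write_minimal_vcf(path, rows, contigs=(("s1", 100000),), sv=False):
    """rows: list of (chrom, pos, ref, alt, qual, info) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        if sv:
            for k, t in (("SVTYPE", "String"), ("END", "Integer"),
                         ("PE", "Integer"), ("SVLEN", "Integer"),
                         ("MATEID", "String"), ("CHR2", "String")):
                fh.write(f'##INFO=<ID={k},Number=1,Type={t},Description="x">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, qual, info in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\n")
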