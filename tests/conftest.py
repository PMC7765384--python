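from pathlib import Path

import pytest

import triosift as ts


@pytest.fixture(scope="session")
def table3_paths(tmp_path_factory):
    """The packaged family-study fixture written once per session."""
    d = tmp_path_factory.mktemp("table3")
    vcf, ann, ped = ts.build_table3_fixture(d)
    return {"vcf": vcf, "annotations": ann, "ped": ped, "dir": d}


@pytest.fixture(scope="session")
def table3_loaded(table3_paths):
    design = ts.read_ped(table3_paths["ped"])
    vset = ts.read_multisample_vcf(table3_paths["vcf"], list(design.sample_ids))
    vset = ts.attach_annotations(
        vset, ts.read_annotation_table(table3_paths["annotations"])
    )
    ts.validate_design(design, vset)
    return vset, design


@pytest.fixture(scope="session")
def trio_design():
    return ts.FamilyDesign(
        samples=(
            ts.SampleInfo("A1", affected=True, role="sibling"),
            ts.SampleInfo("A2", affected=True, role="sibling"),
            ts.SampleInfo("U1", affected=False, role="father"),
        )
    )


def write_vcf_text(path: Path, body: str, samples=("A1", "A2", "U1")) -> Path:
    """Write a small hand-rolled VCF for reader tests."""
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n##contig=<ID=2>\n##contig=<ID=22>\n"
        '##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="AF">\n'
        '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
        '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="consequence">\n'
        '##INFO=<ID=ACMG,Number=1,Type=String,Description="class">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    path.write_text(header + body)
    return path
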