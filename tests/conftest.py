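import textwrap

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=1>
    ##contig=<ID=3>
    """
)


def make_vcf(path, rows, samples):
    """Write a minimal VCF; rows are (chrom, pos, ref, alt, [gt, ...])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


@pytest.fixture
def family_files(tmp_path):
    """A two-affected-sibling family carrying a shared homozygous missense
    variant with heterozygous unaffected parents, plus a benign decoy site."""
    vcf = make_vcf(
        tmp_path / "fam.vcf",
        [
            ("3", 49_920_100, "T", "G", ["0/1", "0/1", "1/1", "1/1"]),
            ("3", 49_920_200, "C", "A", ["0/1", "0/0", "0/1", "0/0"]),
        ],
        ["FATHER", "MOTHER", "PROBAND", "SISTER"],
    )
    ped = tmp_path / "fam.ped"
    ped.write_text(
        "FAM1 FATHER 0 0 1 1\n"
        "FAM1 MOTHER 0 0 2 1\n"
        "FAM1 PROBAND FATHER MOTHER 1 2\n"
        "FAM1 SISTER FATHER MOTHER 2 2\n"
    )
    ann = tmp_path / "ann.tsv"
    ann.write_text(
        "variant_id\tgene\tconsequence\tmaf\thom_maf\tcadd\n"
        "3:49920100:T:G\tMST1R\tmissense\t0.005\t0.0001\t23.4\n"
        "3:49920200:C:A\tMST1R\tsynonymous\t0.01\t0.0001\t3.0\n"
    )
    return {"vcf": str(vcf), "ped": str(ped), "ann": str(ann)}
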