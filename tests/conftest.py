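import io

import pytest

from vcfsieve import Dataset, generate_trio, generate_vcf

HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic">
##INFO=<ID=IMPACT,Number=1,Type=String,Description="Impact, e.g. HIGH">
##FILTER=<ID=PASS,Description="Passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""

BODY = """\
1\t100\t.\tA\tT\t50\tPASS\tDP=10;SOMATIC;IMPACT=HIGH\tGT:AD:DP\t0/1:12,5:17\t0/0:20,0:20
1\t200\trs1\tG\tC\t.\tPASS\tAF=0.5;IMPACT=LOW\tGT:DP\t1/1:30\t./.:.
2\t50\t.\tT\tA,G\t99\tPASS\tAF=0.1,0.9;DP=40\tGT:AD\t1/2:4,6,8\t0/1:10,3,0
"""

TOY_VCF = HEADER + BODY


def as_stream(text: str):
    return io.BytesIO(text.encode())


@pytest.fixture
def toy_vcf_text():
    return TOY_VCF


@pytest.fixture
def toy_dataset():
    return Dataset.from_vcf(as_stream(TOY_VCF))


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A seeded 500-variant, 4-sample dataset for randomized checks."""
    text = generate_vcf(500, 4, seed=11, multiallelic_fraction=0.0)
    return Dataset.from_vcf(as_stream(text))


@pytest.fixture(scope="session")
def trio_fixture():
    return generate_trio(
        200,
        {"AR": 12, "deNovo": 9, "NonMendelian": 7, "XLD": 6,
         "CompoundHet": 5},
        seed=5,
    )


@pytest.fixture
def trio_dataset(trio_fixture):
    return Dataset.from_vcf(as_stream(trio_fixture.vcf_text))
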