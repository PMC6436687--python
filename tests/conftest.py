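"""Shared fixtures: toy pedigrees, a hand-transcribable VCF, toy gene models."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from famsieve.pedigree import Individual, Pedigree
from famsieve.variants import GenotypeMatrix, VariantKey

TOY_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##contig=<ID=chr2>
    ##FILTER=<ID=VQSRTrancheSNP99.70+,Description="tranche">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    chr1\t100\t.\tA\tC,T\t50\tPASS\t.\tGT\t0/1\t1/2\t2/2
    chr1\t200\t.\tG\tA\t99\tPASS\t.\tGT\t./.\t0/0\t0/1
    chr1\t300\t.\tCAG\tCAT\t10\tVQSRTrancheSNP99.70+\t.\tGT\t0/1\t0/0\t0/0
    chr2\t150\t.\tT\tTA\t.\t.\t.\tGT\t1/1\t0/1\t./.
    """
)


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def trio_ped_file(tmp_path):
    p = tmp_path / "trio.ped"
    p.write_text(
        "FAM\tDAD\t0\t0\t1\t1\n"
        "FAM\tMOM\t0\t0\t2\t1\n"
        "FAM\tKID\tDAD\tMOM\t1\t2\n"
    )
    return p


@pytest.fixture
def sibling_pedigree():
    """Founder couple with two children."""
    return Pedigree(
        [
            Individual("P1", sex="male"),
            Individual("P2", sex="female"),
            Individual("A", father_id="P1", mother_id="P2", affection="affected"),
            Individual("B", father_id="P1", mother_id="P2", affection="affected"),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    """First cousins through one shared grandparent couple."""
    return Pedigree(
        [
            Individual("GF", sex="male"),
            Individual("GM", sex="female"),
            Individual("U1", father_id="GF", mother_id="GM", sex="male"),
            Individual("U2", father_id="GF", mother_id="GM", sex="female"),
            Individual("W1", sex="female"),
            Individual("W2", sex="male"),
            Individual("C1", father_id="U1", mother_id="W1"),
            Individual("C2", father_id="W2", mother_id="U2"),
        ]
    )


def make_matrix(dosage_rows, samples, chrom="chr1"):
    """Small GenotypeMatrix: one variant per row of dosages."""
    dosage = np.array(dosage_rows, dtype=np.int8)
    variants = [
        VariantKey(chrom, 1000 + 10 * i, "A", "T") for i in range(dosage.shape[0])
    ]
    meta = pd.DataFrame(
        {"FILTER": ["PASS"] * len(variants), "QUAL": [99.0] * len(variants)}
    )
    return GenotypeMatrix(variants, samples, dosage, meta)
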