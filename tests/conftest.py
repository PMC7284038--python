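import numpy as np
import pandas as pd
import pytest

from ldlprs.io import GenotypeMatrix


def make_genotypes(dosages, chroms=None, positions=None, ids=None, ref="A", alt="G"):
    """GenotypeMatrix from a samples x variants array with optional metadata."""
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else [1000 * (j + 1) for j in range(m)],
            "ref": [ref] * m,
            "alt": [alt] * m,
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n)], variants=variants, dosages=X
    )


@pytest.fixture
def genotypes_factory():
    return make_genotypes


@pytest.fixture
def small_vcf(tmp_path):
    """Hand-written VCF exercising GT, DS, missing and multiallelic records."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trsA\tG\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0
1\t200\trsB\tA\tC\t.\tPASS\t.\tGT:DS\t0/1:1.7\t0/0:0.1\t1/1:2.0
1\t300\trsC\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
1\t400\trsM\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0
"""
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path
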