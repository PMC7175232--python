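import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

VCF_HEADER = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr4,length=100000>",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tacc1\tacc2\tacc3\tacc4",
    ]
)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small 4-accession VCF from tab-joined body lines."""

    def _make(lines, name="panel.vcf"):
        path = tmp_path / name
        path.write_text(VCF_HEADER + "\n" + "\n".join(lines) + "\n")
        return path

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_codon_alignment(rng, n_codons, p_mut=0.3):
    """A random sense-codon row plus a copy with codons resampled at rate
    p_mut — moderately diverged, below the saturation regime."""
    from paralogkit._genetics import SENSE_CODONS

    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    base = ["".join(SENSE_CODONS[i]) for i in idx]
    other = [
        SENSE_CODONS[rng.integers(len(SENSE_CODONS))] if rng.random() < p_mut else c
        for c in base
    ]
    return "".join(base), "".join(other)
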