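"""Shared fixtures: hand-built VCF text and site constructors."""

from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import settings

from asedetect.filtering import InformativeSnp
from asedetect.vcf_io import SampleCall, VariantSite

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_site(
    chrom="1",
    pos=100,
    ref="A",
    alts=("G",),
    qual=50.0,
    filter_status="PASS",
    info=None,
    calls=(),
):
    return VariantSite(
        chrom=chrom,
        pos=pos,
        id=None,
        ref=ref,
        alts=tuple(alts),
        qual=qual,
        filter_status=filter_status,
        info=dict(info or {}),
        calls=list(calls),
    )


def het(ref_reads, alt_reads):
    return SampleCall(gt=(0, 1), ad=(ref_reads, alt_reads), missing=False)


def hom(allele, depth):
    ad = (depth, 0) if allele == 0 else (0, depth)
    return SampleCall(gt=(allele, allele), ad=ad, missing=False)


def make_informative(counts, pos=100, chrom="1"):
    """InformativeSnp from a list of (ref, alt) count pairs."""
    refs = np.array([c[0] for c in counts])
    alts = np.array([c[1] for c in counts])
    site = make_site(chrom=chrom, pos=pos, calls=[het(r, a) for r, a in counts])
    return InformativeSnp(
        site=site,
        samples=tuple(f"S{i + 1:02d}" for i in range(len(counts))),
        ref_counts=refs,
        alt_counts=alts,
    )


def vcf_text(records, samples=("SAMPLE_A", "SAMPLE_B"), fmt="GT:AD"):
    """Minimal VCF v4.2 document from pre-formatted record lines."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines.extend(records)
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_sample_vcf():
    return vcf_text(
        [
            "1\t100\t.\tA\tG\t50\tPASS\t.\tGT:AD\t0/1:10,12\t0/0:30,0",
            "1\t500\trs1\tC\tT\t60\tPASS\t.\tGT:AD\t0/1:25,25\t1|1:0,40",
            "2\t100\t.\tG\tA\t.\t.\t.\tGT:AD\t./.:.\t0/1:15,15",
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
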