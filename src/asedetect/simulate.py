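"""Synthetic VCF fixtures with planted ASE and a ground-truth table.

The generator emulates a multi-sample RNA-seq call set at the level the
detector consumes: per-site allelic depths.  Heterozygous calls draw alt
reads from Binomial(depth, skew) — skew 0.5 for null sites, a configured
skew for true-ASE sites — with per-call depth from a truncated negative
binomial (RNA-seq coverage is overdispersed; a Poisson switch exists for
closed-form checks).  Contaminant site classes (indels, near-indel SNPs,
multiallelic sites, low-QUAL sites, caller-failed sites, all-homozygous
sites) are planted at configurable rates and recorded in a truth table so
filter accounting can be checked exactly.

It does **not** emulate read-level phenomena: mapping bias (except via
``spike_reference_bias``), genotyping error, allele-depth miscounting or
correlated samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .vcf_io import SampleCall, VariantSite, read_vcf, write_vcf

__all__ = [
    "SimConfig",
    "generate",
    "spike_reference_bias",
    "simulate_informative",
]

_BASES = ("A", "C", "G", "T")

# category -> removal reason expected from the filter cascade
# (clean categories survive to the informative set)
EXPECTED_OUTCOME = {
    "clean_null": "informative",
    "clean_ase": "informative",
    "indel": "indel",
    "near_indel": "near_indel",
    "multiallelic": "multiallelic",
    "low_qual": "low_qual",
    "gatk_fail": "gatk_fail",
    "all_homozygous": "no_testable_samples",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic call set.

    Defaults emulate one tissue of a moderately sized RNA-seq cohort:
    23 samples, mean depth 50 with negative-binomial overdispersion
    (dispersion = NB size parameter; variance = mean + mean^2/size),
    heterozygosity 0.3 per sample per site, 14% of variants with true
    ASE at alt-allele proportion 0.7.  Contaminant rates default to zero
    so the clean statistical properties are the baseline; tests that
    exercise the filter cascade switch them on explicitly.
    """

    n_variants: int = 1000
    n_samples: int = 23
    het_rate: float = 0.3
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    depth_model: Literal["nb", "poisson"] = "nb"
    ase_fraction: float = 0.14
    skew: float = 0.7
    indel_rate: float = 0.0
    near_indel_rate: float = 0.0
    multiallelic_rate: float = 0.0
    low_qual_rate: float = 0.0
    gatk_fail_rate: float = 0.0
    all_homozygous_rate: float = 0.0
    min_informative_depth: int = 20
    contamination: float = 0.01  # minor-allele reads in homozygous calls
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.het_rate,
            self.ase_fraction,
            self.indel_rate,
            self.near_indel_rate,
            self.multiallelic_rate,
            self.low_qual_rate,
            self.gatk_fail_rate,
            self.all_homozygous_rate,
            self.contamination,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_variants == 0 and self.ase_fraction > 0:
            raise ValueError("ase_fraction > 0 requires n_variants > 0")
        total_rate = (
            self.indel_rate
            + self.near_indel_rate
            + self.multiallelic_rate
            + self.low_qual_rate
            + self.gatk_fail_rate
            + self.all_homozygous_rate
        )
        if total_rate > 1.0:
            raise ValueError("contaminant rates sum to more than 1")
        if self.near_indel_rate > 0 and self.indel_rate == 0:
            raise ValueError("near-indel SNPs need indels to be near")


def _draw_depths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.depth_model == "poisson":
        d = rng.poisson(cfg.depth_mean, size=n)
    else:
        size = cfg.depth_dispersion
        p = size / (size + cfg.depth_mean)
        d = rng.negative_binomial(size, p, size=n)
    return np.maximum(d, 1)  # truncate at 1 read


def _category_counts(rng: np.random.Generator, cfg: SimConfig) -> dict[str, int]:
    rates = {
        "indel": cfg.indel_rate,
        "near_indel": cfg.near_indel_rate,
        "multiallelic": cfg.multiallelic_rate,
        "low_qual": cfg.low_qual_rate,
        "gatk_fail": cfg.gatk_fail_rate,
        "all_homozygous": cfg.all_homozygous_rate,
    }
    clean_rate = 1.0 - sum(rates.values())
    names = list(rates) + ["clean_ase", "clean_null"]
    probs = list(rates.values()) + [
        clean_rate * cfg.ase_fraction,
        clean_rate * (1.0 - cfg.ase_fraction),
    ]
    counts = rng.multinomial(cfg.n_variants, probs)
    out = dict(zip(names, (int(c) for c in counts)))
    if out["near_indel"] > 0 and out["indel"] == 0:
        # rare multinomial edge: reassign one near-indel draw to an indel
        out["indel"] += 1
        out["near_indel"] -= 1
    return out


def _het_call(
    rng: np.random.Generator, depth: int, alt_fraction: float
) -> SampleCall:
    alt = int(rng.binomial(depth, alt_fraction))
    return SampleCall(gt=(0, 1), ad=(depth - alt, alt), missing=False)


def _hom_call(rng: np.random.Generator, depth: int, cfg: SimConfig, allele: int) -> SampleCall:
    minor = int(rng.binomial(depth, cfg.contamination))
    if allele == 0:
        ad = (depth - minor, minor)
    else:
        ad = (minor, depth - minor)
    return SampleCall(gt=(allele, allele), ad=ad, missing=False)


def _site_calls(
    rng: np.random.Generator,
    cfg: SimConfig,
    alt_fraction: float,
    force_first_testable: bool,
    all_hom: bool = False,
    n_alts: int = 1,
) -> tuple[list[SampleCall], list[str]]:
    calls: list[SampleCall] = []
    genotypes: list[str] = []
    depths = _draw_depths(rng, cfg, cfg.n_samples)
    for j in range(cfg.n_samples):
        is_het = (not all_hom) and rng.random() < cfg.het_rate
        if force_first_testable and j == 0:
            # guarantee the site is informative: redraw until the call
            # clears the depth and minor-fraction thresholds
            while True:
                depth = max(int(depths[j]), cfg.min_informative_depth)
                call = _het_call(rng, depth, alt_fraction)
                assert call.ad is not None
                if min(call.ad) / depth >= 0.01:
                    break
                depths[j] = _draw_depths(rng, cfg, 1)[0]
            calls.append(call)
            genotypes.append("het")
            continue
        if is_het:
            calls.append(_het_call(rng, int(depths[j]), alt_fraction))
            genotypes.append("het")
        else:
            allele = int(rng.random() < 0.5)
            calls.append(_hom_call(rng, int(depths[j]), cfg, allele))
            genotypes.append("hom_ref" if allele == 0 else "hom_alt")
    if n_alts == 2:
        # pad AD with a few stray reads on the second alt
        padded = []
        for c in calls:
            assert c.ad is not None
            padded.append(SampleCall(gt=c.gt, ad=c.ad + (int(rng.binomial(4, 0.25)),), missing=False))
        calls = padded
    return calls, genotypes


def _snp_alleles(rng: np.random.Generator, n_alts: int = 1) -> tuple[str, tuple[str, ...]]:
    picks = rng.choice(4, size=1 + n_alts, replace=False)
    return _BASES[picks[0]], tuple(_BASES[i] for i in picks[1:])


def generate(cfg: SimConfig) -> tuple[str, pd.DataFrame]:
    """Generate (VCF text, truth table); the same seed gives identical bytes.

    Sites are laid out 1000 bp apart on one chromosome; near-indel SNPs
    are placed 30–75 bp from a planted indel (inclusive window).  Clean
    sites are guaranteed informative by forcing the first sample to be a
    testable heterozygote.  The truth table has one row per variant with
    its category, true alt-allele fraction and expected filter outcome.
    """
    if cfg.n_variants == 0:
        samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
        buf = io.StringIO()
        write_vcf([], samples, buf)
        return buf.getvalue(), pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "category", "true_alt_fraction", "expected_outcome"]
        )

    rng = np.random.default_rng(cfg.seed)
    counts = _category_counts(rng, cfg)
    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]

    # position layout: every non-near-indel site owns a 1000 bp block;
    # near-indel SNPs attach to indel blocks at offsets 30..75
    planned: list[tuple[str, int]] = []  # (category, pos)
    block = 0
    indel_positions: list[int] = []
    for cat in ("clean_null", "clean_ase", "indel", "multiallelic",
                "low_qual", "gatk_fail", "all_homozygous"):
        for _ in range(counts[cat]):
            block += 1
            pos = 1000 * block
            planned.append((cat, pos))
            if cat == "indel":
                indel_positions.append(pos)
    offsets = list(range(30, 76, 5))
    if counts["near_indel"] > len(indel_positions) * len(offsets):
        raise ValueError("too many near-indel SNPs for the planted indels")
    for i in range(counts["near_indel"]):
        anchor = indel_positions[i % len(indel_positions)]
        offset = offsets[i // len(indel_positions)]
        planned.append(("near_indel", anchor + offset))
    planned.sort(key=lambda t: t[1])

    sites: list[VariantSite] = []
    truth_rows: list[dict] = []
    for cat, pos in planned:
        n_alts = 2 if cat == "multiallelic" else 1
        ref, alts = _snp_alleles(rng, n_alts)
        if cat == "indel":
            ins = _BASES[int(rng.integers(4))]
            alts = (ref + ins,)
        qual = (
            float(np.round(rng.uniform(0.0, 19.9), 2))
            if cat == "low_qual"
            else float(np.round(rng.uniform(30.0, 90.0), 2))
        )
        filter_status = "LowQual" if cat == "gatk_fail" else "PASS"
        if cat == "clean_ase":
            # either allele can be the over-expressed one
            alt_fraction = cfg.skew if rng.random() < 0.5 else 1.0 - cfg.skew
        else:
            alt_fraction = 0.5
        calls, genotypes = _site_calls(
            rng,
            cfg,
            alt_fraction,
            force_first_testable=cat in ("clean_null", "clean_ase"),
            all_hom=cat == "all_homozygous",
            n_alts=n_alts,
        )
        sites.append(
            VariantSite(
                chrom="1",
                pos=pos,
                id=None,
                ref=ref,
                alts=alts,
                qual=qual,
                filter_status=filter_status,
                info={},
                calls=calls,
            )
        )
        truth_rows.append(
            {
                "chrom": "1",
                "pos": pos,
                "ref": ref,
                "alt": ",".join(alts),
                "category": cat,
                "true_alt_fraction": alt_fraction,
                "expected_outcome": EXPECTED_OUTCOME[cat],
                "n_het_samples": genotypes.count("het"),
            }
        )

    buf = io.StringIO()
    write_vcf(sites, samples, buf)
    truth = pd.DataFrame(truth_rows)
    return buf.getvalue(), truth


def spike_reference_bias(vcf_text: str, bias: float, seed: int = 0) -> str:
    """Re-draw heterozygous allele depths with reference proportion ``bias``.

    Emulates reference-mapping bias (as when aligning to an unmasked
    genome): each het call's total depth is kept and its reference count
    redrawn from Binomial(depth, bias).  ``bias`` must lie in [0.5, 1).
    """
    if not 0.5 <= bias < 1.0:
        raise ValueError("bias must lie in [0.5, 1)")
    rng = np.random.default_rng(seed)
    reader = read_vcf(io.StringIO(vcf_text))
    sites = []
    for site in reader:
        new_calls = []
        for call in site.calls:
            if call.is_het_ref_alt and call.ad is not None and len(call.ad) == 2:
                depth = sum(call.ad)
                ref = int(rng.binomial(depth, bias))
                call = SampleCall(gt=call.gt, ad=(ref, depth - ref), missing=False, phased=call.phased)
            new_calls.append(call)
        site.calls = new_calls
        sites.append(site)
    buf = io.StringIO()
    write_vcf(sites, reader.samples, buf)
    return buf.getvalue()


def simulate_informative(
    n_variants: int,
    n_samples: int,
    depth: int,
    alt_fraction: float,
    rng: np.random.Generator,
) -> list:
    """Count-level shortcut: informative SNPs with fixed depth, no VCF text.

    Every sample is a testable heterozygote with exactly ``depth`` reads
    and alt reads ~ Binomial(depth, alt_fraction).  Used for statistical
    calibration runs where the VCF round-trip adds nothing.
    """
    from .filtering import InformativeSnp

    samples = tuple(f"S{j + 1:02d}" for j in range(n_samples))
    alt = rng.binomial(depth, alt_fraction, size=(n_variants, n_samples))
    out = []
    for i in range(n_variants):
        site = VariantSite(
            chrom="1",
            pos=1000 * (i + 1),
            id=None,
            ref="A",
            alts=("G",),
            qual=50.0,
            filter_status="PASS",
            info={},
            calls=[],
        )
        out.append(
            InformativeSnp(
                site=site,
                samples=samples,
                ref_counts=depth - alt[i],
                alt_counts=alt[i],
            )
        )
    return out
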