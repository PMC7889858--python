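"""The variant filter cascade producing informative SNPs.

A site must survive, in this fixed order: an optional INFO-field prefilter
(strand bias FS, quality-by-depth QD, total depth DP), the caller's own
FILTER verdict, the indel / multiallelic / low-QUAL checks, and an
indel-proximity mask.  Within surviving biallelic SNPs, each sample is
testable only if it is a called 0/1 heterozygote with total allele depth
at or above the depth threshold and a minor-allele fraction of at least
``min_minor_fraction``.  A SNP with at least one testable sample is
"informative" and enters the statistics.  Every removed site is tallied
under exactly one reason so the accounting partitions the input.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .vcf_io import SampleCall, VariantSite

__all__ = [
    "FilterConfig",
    "FilterReason",
    "FilterOutcome",
    "InformativeSnp",
    "FilterAccounting",
    "site_prefilter",
    "classify_site",
    "indel_proximity_mask",
    "classify_sample",
    "collect_informative",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade.

    Defaults follow common practice for 75 bp paired-end RNA-seq: SNPs
    within one read length (75 bp) of an indel are suspect, site QUAL must
    reach 20, a sample needs 20 reads to be testable, and its minor allele
    must carry at least 1% of the reads.  The prefilter thresholds mirror
    typical hard filters applied by upstream variant callers (Fisher
    strand > 30, quality-by-depth < 2, total depth < 100) and are off by
    default because most call sets arrive with them already applied.
    """

    indel_distance: int = 75
    min_qual: float = 20.0
    min_depth: int = 20
    min_minor_fraction: float = 0.01
    prefilter_fs_max: float = 30.0
    prefilter_qd_min: float = 2.0
    prefilter_dp_min: float = 100.0
    prefilter_enabled: bool = False

    def __post_init__(self) -> None:
        if self.indel_distance < 0 or self.min_qual < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_minor_fraction <= 0.5:
            raise ValueError("min_minor_fraction must lie in [0, 0.5]")


class FilterReason(str, enum.Enum):
    """Mutually exclusive removal reasons, in cascade order."""

    PREFILTER_FS = "prefilter_fs"
    PREFILTER_QD = "prefilter_qd"
    PREFILTER_DP = "prefilter_dp"
    GATK_FAIL = "gatk_fail"
    INDEL = "indel"
    MULTIALLELIC = "multiallelic"
    LOW_QUAL = "low_qual"
    NEAR_INDEL = "near_indel"
    NO_TESTABLE_SAMPLES = "no_testable_samples"


# order in which reasons are reported in the accounting waterfall
REASON_ORDER: tuple[FilterReason, ...] = (
    FilterReason.PREFILTER_FS,
    FilterReason.PREFILTER_QD,
    FilterReason.PREFILTER_DP,
    FilterReason.GATK_FAIL,
    FilterReason.INDEL,
    FilterReason.MULTIALLELIC,
    FilterReason.LOW_QUAL,
    FilterReason.NEAR_INDEL,
    FilterReason.NO_TESTABLE_SAMPLES,
)


@dataclass(frozen=True)
class FilterOutcome:
    passed: bool
    reason: FilterReason | None = None

    def __post_init__(self) -> None:
        if self.passed and self.reason is not None:
            raise ValueError("a passing outcome carries no reason")
        if not self.passed and self.reason is None:
            raise ValueError("a failing outcome needs exactly one reason")


PASS = FilterOutcome(True)


@dataclass
class InformativeSnp:
    """A biallelic SNP that survived all filters, with its testable samples.

    ``samples``, ``ref_counts`` and ``alt_counts`` are aligned and cover
    only the testable samples (>= 1 by construction).
    """

    site: VariantSite
    samples: tuple[str, ...]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        if len(self.samples) == 0:
            raise ValueError("an informative SNP needs >= 1 testable sample")
        if not (len(self.samples) == len(self.ref_counts) == len(self.alt_counts)):
            raise ValueError("samples and count arrays must align")

    @property
    def n_testable(self) -> int:
        return len(self.samples)

    def key(self) -> tuple[str, int, str, str]:
        return self.site.key()


@dataclass
class FilterAccounting:
    """Per-reason removal counts; removed + informative == total exactly."""

    removed: "OrderedDict[FilterReason, int]" = field(
        default_factory=lambda: OrderedDict((r, 0) for r in REASON_ORDER)
    )
    informative: int = 0
    total: int = 0

    def record(self, outcome: FilterOutcome) -> None:
        self.total += 1
        if outcome.passed:
            self.informative += 1
        else:
            assert outcome.reason is not None
            self.removed[outcome.reason] += 1

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check_partition(self) -> bool:
        return self.n_removed + self.informative == self.total

    def rows(self) -> list[tuple[str, int]]:
        out = [(r.value, n) for r, n in self.removed.items()]
        out.append(("informative", self.informative))
        out.append(("total", self.total))
        return out


def site_prefilter(site: VariantSite, cfg: FilterConfig) -> FilterOutcome:
    """INFO-field hard filter; criteria checked in order FS, QD, DP.

    An absent INFO key passes that criterion (the annotation cannot be
    recomputed from a VCF alone).
    """
    fs = site.info.get("FS")
    if fs is not None and fs > cfg.prefilter_fs_max:
        return FilterOutcome(False, FilterReason.PREFILTER_FS)
    qd = site.info.get("QD")
    if qd is not None and qd < cfg.prefilter_qd_min:
        return FilterOutcome(False, FilterReason.PREFILTER_QD)
    dp = site.info.get("DP")
    if dp is not None and dp < cfg.prefilter_dp_min:
        return FilterOutcome(False, FilterReason.PREFILTER_DP)
    return PASS


def classify_site(site: VariantSite, cfg: FilterConfig) -> FilterOutcome:
    """Site-level checks in order: caller FILTER, indel, multiallelic, QUAL.

    QUAL is the site-level quality column; a null QUAL fails (no evidence
    of quality is treated as low quality).
    """
    if site.filter_status not in ("PASS", "."):
        return FilterOutcome(False, FilterReason.GATK_FAIL)
    if site.is_indel:
        return FilterOutcome(False, FilterReason.INDEL)
    if len(site.alts) > 1:
        return FilterOutcome(False, FilterReason.MULTIALLELIC)
    if site.qual is None or site.qual < cfg.min_qual:
        return FilterOutcome(False, FilterReason.LOW_QUAL)
    return PASS


def indel_proximity_mask(
    sites: Sequence[VariantSite], distance: int
) -> set[tuple[str, int]]:
    """Loci within ``distance`` bp (inclusive) of any indel, per chromosome.

    Indels are identified by allele length alone, regardless of their own
    FILTER verdict — a failing indel still renders its neighbourhood
    suspect.  Input must be position-sorted within each chromosome.
    """
    indel_pos: dict[str, list[int]] = {}
    order_check: dict[str, int] = {}
    for site in sites:
        last = order_check.get(site.chrom)
        if last is not None and site.pos < last:
            raise ValueError(
                f"sites not position-sorted on {site.chrom}: {site.pos} after {last}"
            )
        order_check[site.chrom] = site.pos
        if site.is_indel:
            indel_pos.setdefault(site.chrom, []).append(site.pos)

    masked: set[tuple[str, int]] = set()
    for site in sites:
        if site.is_indel:
            continue
        positions = indel_pos.get(site.chrom)
        if not positions:
            continue
        i = bisect_left(positions, site.pos)
        near = (i < len(positions) and positions[i] - site.pos <= distance) or (
            i > 0 and site.pos - positions[i - 1] <= distance
        )
        if near:
            masked.add((site.chrom, site.pos))
    return masked


def classify_sample(
    call: SampleCall, cfg: FilterConfig
) -> tuple[bool, str | None]:
    """Testability of one sample at a passing biallelic SNP.

    Returns ``(testable, reason)`` with reason in {"no_data",
    "homozygous", "low_depth", "low_minor_fraction"} when not testable.
    A missing genotype is "no data" even if AD is present: the binomial
    null requires a called heterozygote.
    """
    if call.missing or call.gt is None or call.ad is None:
        return False, "no_data"
    if not call.is_het_ref_alt:
        return False, "homozygous"
    ref, alt = call.ad[0], call.ad[1]
    depth = ref + alt
    if depth < cfg.min_depth:
        return False, "low_depth"
    if min(ref, alt) / depth < cfg.min_minor_fraction:
        return False, "low_minor_fraction"
    return True, None


def collect_informative(
    sites: Iterable[VariantSite],
    samples: Sequence[str],
    cfg: FilterConfig | None = None,
) -> tuple[list[InformativeSnp], FilterAccounting]:
    """Run the full cascade and tally one removal reason per failed site.

    Materialises the input (the indel-proximity mask needs whole-chromosome
    context before site verdicts are final).
    """
    cfg = cfg or FilterConfig()
    site_list = list(sites)
    masked = indel_proximity_mask(site_list, cfg.indel_distance)

    informative: list[InformativeSnp] = []
    accounting = FilterAccounting()
    for site in site_list:
        outcome = _classify_full(site, masked, samples, cfg)
        accounting.record(outcome[0])
        if outcome[0].passed:
            informative.append(outcome[1])  # type: ignore[arg-type]
    return informative, accounting


def _classify_full(
    site: VariantSite,
    masked: set[tuple[str, int]],
    samples: Sequence[str],
    cfg: FilterConfig,
) -> tuple[FilterOutcome, InformativeSnp | None]:
    if cfg.prefilter_enabled:
        out = site_prefilter(site, cfg)
        if not out.passed:
            return out, None
    out = classify_site(site, cfg)
    if not out.passed:
        return out, None
    if (site.chrom, site.pos) in masked:
        return FilterOutcome(False, FilterReason.NEAR_INDEL), None

    names: list[str] = []
    refs: list[int] = []
    alts: list[int] = []
    for name, call in zip(samples, site.calls):
        testable, _ = classify_sample(call, cfg)
        if testable:
            assert call.ad is not None
            names.append(name)
            refs.append(call.ad[0])
            alts.append(call.ad[1])
    if not names:
        return FilterOutcome(False, FilterReason.NO_TESTABLE_SAMPLES), None
    snp = InformativeSnp(
        site=site,
        samples=tuple(names),
        ref_counts=np.array(refs, dtype=np.int64),
        alt_counts=np.array(alts, dtype=np.int64),
    )
    return PASS, snp
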