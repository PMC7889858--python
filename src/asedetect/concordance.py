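"""Genotype concordance between two VCF call sets.

Validates RNA-seq variant calls against an independent genotyping panel:
both files are filtered, their SNPs and samples intersected, and percent
genotype agreement computed per sample pair — matched samples on the
diagonal, or all pairs as a shuffled control.  Genotypes are compared as
unordered multisets of allele *sequences*, so phase, allele order and a
ref/alt swap between the files are all harmonised automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import FilterConfig, classify_site, indel_proximity_mask
from .vcf_io import SampleCall, VariantSite

__all__ = [
    "ConcordanceMatrix",
    "filter_panel_vcf",
    "filter_rnaseq_vcf",
    "concordance_matrix",
]


@dataclass
class ConcordanceMatrix:
    """Pairwise percent genotype agreement and compared-site counts."""

    a_samples: tuple[str, ...]
    b_samples: tuple[str, ...]
    percent: pd.DataFrame  # rows = file A samples, cols = file B samples
    n_compared: pd.DataFrame
    n_intersected_snps: int

    def matched_mean(self) -> float:
        """Mean concordance over same-named sample pairs (the diagonal)."""
        shared = [s for s in self.a_samples if s in self.b_samples]
        if not shared:
            raise ValueError("no shared sample names")
        return float(np.mean([self.percent.loc[s, s] for s in shared]))

    def off_diagonal_mean(self) -> float:
        """Mean concordance over mismatched pairs (the shuffled control)."""
        vals = [
            self.percent.loc[a, b]
            for a in self.a_samples
            for b in self.b_samples
            if a != b and not np.isnan(self.percent.loc[a, b])
        ]
        if not vals:
            raise ValueError("no off-diagonal pairs")
        return float(np.mean(vals))


def filter_panel_vcf(
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    min_call_rate: float = 0.97,
    sample_whitelist: Sequence[str] | None = None,
) -> list[VariantSite]:
    """Keep SNPs whose genotype call rate among whitelisted samples is >= threshold.

    The call rate counts non-missing genotypes; the boundary is inclusive
    (exactly 97% passes at the default).
    """
    if sample_whitelist is not None and len(sample_whitelist) == 0:
        raise ValueError("sample whitelist must not be empty")
    whitelist = set(sample_whitelist) if sample_whitelist is not None else set(samples)
    idx = [i for i, s in enumerate(samples) if s in whitelist]
    if not idx:
        raise ValueError("no samples match the whitelist")

    kept = []
    for site in sites:
        if site.is_indel:
            continue
        n_called = sum(1 for i in idx if not site.calls[i].missing)
        if n_called / len(idx) >= min_call_rate:
            kept.append(site)
    return kept


def filter_rnaseq_vcf(
    sites: Sequence[VariantSite],
    cfg: FilterConfig | None = None,
) -> list[VariantSite]:
    """Filter RNA-seq calls for concordance comparison.

    Removes sites failing the caller FILTER, indels and SNPs within the
    indel-proximity window, and low-QUAL sites; multiallelic SNPs are kept
    (genotypes compare fine as allele multisets).  Individual genotypes
    with total allele depth below ``min_depth`` are masked missing so they
    drop out of every pair's denominator rather than removing the site.
    """
    cfg = cfg or FilterConfig()
    masked = indel_proximity_mask(sites, cfg.indel_distance)
    kept: list[VariantSite] = []
    for site in sites:
        if site.filter_status not in ("PASS", "."):
            continue
        if site.is_indel:
            continue
        if (site.chrom, site.pos) in masked:
            continue
        if site.qual is None or site.qual < cfg.min_qual:
            continue
        new_calls = []
        for call in site.calls:
            if not call.missing and call.ad is not None and sum(call.ad) < cfg.min_depth:
                call = replace(call, missing=True)
            new_calls.append(call)
        kept.append(replace(site, calls=new_calls))
    return kept


def _genotype_alleles(site: VariantSite, call: SampleCall) -> tuple[str, str] | None:
    """Unordered pair of allele sequences for one call, or None if missing."""
    if call.missing or call.gt is None:
        return None
    alleles = (site.ref,) + site.alts
    a, b = alleles[call.gt[0]], alleles[call.gt[1]]
    return (a, b) if a <= b else (b, a)


def _allele_set(site: VariantSite) -> frozenset[str]:
    return frozenset((site.ref,) + site.alts)


def concordance_matrix(
    a_sites: Sequence[VariantSite],
    a_samples: Sequence[str],
    b_sites: Sequence[VariantSite],
    b_samples: Sequence[str],
    pairing: Literal["matched", "all_pairs"] = "matched",
    rename_map: Mapping[str, str] | None = None,
) -> ConcordanceMatrix:
    """Percent genotype agreement between two filtered call sets.

    Sites are joined on (chrom, pos) and kept when their allele *sets*
    agree — a plain ref/alt swap between files therefore still matches,
    and comparing allele sequences (not indices) recodes it implicitly.
    ``rename_map`` translates file-B sample names onto file-A names.
    In ``matched`` pairing only same-named pairs are computed;``all_pairs``
    fills the whole matrix for the shuffled-control analysis.  A pair's
    denominator counts sites where both calls are non-missing.
    """
    if rename_map:
        b_samples = [rename_map.get(s, s) for s in b_samples]

    a_by_locus = {(s.chrom, s.pos): s for s in a_sites}
    shared: list[tuple[VariantSite, VariantSite]] = []
    for b in b_sites:
        a = a_by_locus.get((b.chrom, b.pos))
        if a is not None and _allele_set(a) == _allele_set(b):
            shared.append((a, b))
    if not shared:
        raise ValueError("no overlapping SNPs between the two call sets")

    a_idx = {s: i for i, s in enumerate(a_samples)}
    b_idx = {s: i for i, s in enumerate(b_samples)}

    # genotype tables: one row per shared site, one column per sample
    a_gt = [
        [_genotype_alleles(sa, sa.calls[a_idx[s]]) for s in a_samples]
        for sa, _ in shared
    ]
    b_gt = [
        [_genotype_alleles(sb, sb.calls[b_idx[s]]) for s in b_samples]
        for _, sb in shared
    ]

    pct = pd.DataFrame(np.nan, index=list(a_samples), columns=list(b_samples))
    cnt = pd.DataFrame(0, index=list(a_samples), columns=list(b_samples))
    for ia, sa in enumerate(a_samples):
        for ib, sb in enumerate(b_samples):
            if pairing == "matched" and sa != sb:
                continue
            agree = 0
            n = 0
            for row in range(len(shared)):
                ga = a_gt[row][ia]
                gb = b_gt[row][ib]
                if ga is None or gb is None:
                    continue
                n += 1
                if ga == gb:
                    agree += 1
            cnt.loc[sa, sb] = n
            pct.loc[sa, sb] = 100.0 * agree / n if n else np.nan
    return ConcordanceMatrix(
        a_samples=tuple(a_samples),
        b_samples=tuple(b_samples),
        percent=pct,
        n_compared=cnt,
        n_intersected_snps=len(shared),
    )
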