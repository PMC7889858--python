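"""Statistical core: binomial tests, Fisher's method + BH, and mdFDR.

Two models answer two questions about each informative SNP:

* the **meta-analysis** combines the per-sample exact binomial p-values
  with Fisher's method and controls FDR across variants with
  Benjamini–Hochberg — it declares *ASE variants*;
* the **mdFDR procedure** (Guo–Sarkar–Peddada style two-stage
  screen-then-test) declares, per variant, which individual *samples*
  show ASE and in which direction, while controlling the mixed
  directional FDR at the variant level.

The exact binomial test is computed for every count pair with a null
proportion of 0.5; no normal approximation is used at any depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import binom, chi2

from .filtering import InformativeSnp

__all__ = [
    "binomial_test",
    "binomial_test_many",
    "fisher_combine",
    "bh_adjust",
    "SampleTest",
    "MetaResult",
    "MdfdrResult",
    "run_meta_analysis",
    "run_mdfdr",
]

# smallest positive normal double; p-values of exactly 0 are clamped here
# before taking logs so Fisher's statistic stays finite
_P_CLAMP = float(np.finfo(np.float64).tiny)

Direction = Literal["ref_higher", "alt_higher", "tie"]


def binomial_test_many(
    ref_counts: np.ndarray, alt_counts: np.ndarray
) -> np.ndarray:
    """Vectorised exact two-sided binomial test at null proportion 0.5.

    With a symmetric null the two-sided p-value is
    ``min(1, 2 * P(X >= max(ref, alt)))`` for ``X ~ Binomial(ref+alt, 0.5)``;
    perfectly balanced counts give exactly 1.  Tail probabilities come from
    the regularised incomplete beta via ``scipy.stats.binom.sf``.
    """
    ref = np.asarray(ref_counts, dtype=np.int64)
    alt = np.asarray(alt_counts, dtype=np.int64)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    n = ref + alt
    if np.any(n < 1):
        raise ValueError("total read count must be >= 1")
    k = np.maximum(ref, alt)
    p = 2.0 * binom.sf(k - 1, n, 0.5)
    return np.minimum(p, 1.0)


def binomial_test(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial p-value for one (ref, alt) count pair."""
    return float(binomial_test_many(np.array([ref_count]), np.array([alt_count]))[0])


def _clamp_pvalues(p: np.ndarray) -> np.ndarray:
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0.0):
        warnings.warn(
            f"p-value of 0 clamped to {_P_CLAMP:g} before log transform",
            stacklevel=3,
        )
        p = np.maximum(p, _P_CLAMP)
    return p


def fisher_combine(pvalues: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X = -2 * sum(ln p_i), p from chi-square with 2k df.

    With a single p-value the combination is the identity.  Zero inputs
    are clamped to the smallest positive normal double (warned once).
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    p = _clamp_pvalues(p)
    x = float(-2.0 * np.sum(np.log(p)))
    combined = float(chi2.sf(x, 2 * p.size))
    return x, combined


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` on the sorted sequence,
    capped at 1; sorting is stable so ties break deterministically.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m, dtype=np.float64)
    adj[order] = adj_sorted
    return adj


def _direction(ref: int, alt: int) -> Direction:
    if alt > ref:
        return "alt_higher"
    if ref > alt:
        return "ref_higher"
    return "tie"


@dataclass(frozen=True)
class SampleTest:
    """One sample's binomial test at one variant."""

    sample: str
    ref_count: int
    alt_count: int
    p: float

    @property
    def direction(self) -> Direction:
        return _direction(self.ref_count, self.alt_count)


@dataclass
class MetaResult:
    """Per-variant meta-analysis record."""

    chrom: str
    pos: int
    ref: str
    alt: str
    k: int
    fisher_x: float
    df: int
    combined_p: float
    adj_p: float = float("nan")
    is_ase: bool = False

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MdfdrResult:
    """Per-variant mdFDR record with per-sample decisions.

    ``samples``, ``ref_counts``, ``alt_counts``, ``pvalues``,
    ``significant`` and ``directions`` are aligned over the variant's
    testable samples.  ``r_selected`` and ``m_variants`` echo the run-wide
    Stage-1 selection so the Stage-2 threshold
    ``alpha * R / (m * k)`` is reconstructible from any single record.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    screen_p: float
    screen_adj_p: float
    selected: bool
    samples: tuple[str, ...]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    directions: tuple[Direction, ...]
    r_selected: int
    m_variants: int
    alpha: float

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def k(self) -> int:
        return len(self.samples)

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))


def _per_sample_pvalues(
    informative: Sequence[InformativeSnp],
) -> list[np.ndarray]:
    """Binomial p-values for every (variant, sample) pair, one array per SNP."""
    if not informative:
        return []
    ref = np.concatenate([s.ref_counts for s in informative])
    alt = np.concatenate([s.alt_counts for s in informative])
    flat = binomial_test_many(ref, alt)
    sizes = [s.n_testable for s in informative]
    return list(np.split(flat, np.cumsum(sizes)[:-1]))


def run_meta_analysis(
    informative: Sequence[InformativeSnp], alpha: float = 0.05
) -> list[MetaResult]:
    """Fisher's-method combination per variant, BH across all variants.

    BH is applied once over the full informative set (m = number of
    informative SNPs); a variant is an ASE variant iff its adjusted
    p-value is <= ``alpha``.
    """
    if not informative:
        raise ValueError("meta-analysis requires at least one informative SNP")
    pvalue_lists = _per_sample_pvalues(informative)

    results: list[MetaResult] = []
    for snp, pvals in zip(informative, pvalue_lists):
        x, combined = fisher_combine(pvals)
        chrom, pos, ref, alt = snp.key()
        results.append(
            MetaResult(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                k=snp.n_testable,
                fisher_x=x,
                df=2 * snp.n_testable,
                combined_p=combined,
            )
        )
    adj = bh_adjust([r.combined_p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
        r.is_ase = bool(a <= alpha)
    return results


def _screen_pvalue(pvals: np.ndarray, method: str) -> float:
    """Stage-1 screening p-value for one variant.

    ``sidak``: 1 - (1 - min p)^k, the Šidák-corrected minimum — exact for
    independent samples and the canonical choice in the two-stage mdFDR
    construction.  ``fisher``: the Fisher combined p, sensitive to many
    weak signals rather than one strong one.
    """
    if method == "sidak":
        pmin = float(np.min(pvals))
        if pmin >= 1.0:
            return 1.0
        pmin = max(pmin, _P_CLAMP)
        return float(-np.expm1(len(pvals) * np.log1p(-pmin)))
    if method == "fisher":
        return fisher_combine(pvals)[1]
    raise ValueError(f"unknown screening method {method!r}")


def run_mdfdr(
    informative: Sequence[InformativeSnp],
    alpha: float = 0.05,
    screening: Literal["sidak", "fisher"] = "sidak",
) -> list[MdfdrResult]:
    """Two-stage mixed-directional FDR procedure.

    Stage 1 screens variants: a per-variant screening p-value is
    BH-adjusted across the m informative variants and variants with
    adjusted p <= alpha are selected (R of m).  Stage 2 tests samples
    within each selected variant against the uniform threshold
    ``alpha * R / (m * k_i)`` (within-variant Bonferroni scaled by the
    selection fraction); the direction of a significant sample is the
    sign of alt - ref.  Non-selected variants have zero significant
    samples by construction.
    """
    if not informative:
        raise ValueError("mdFDR requires at least one informative SNP")
    pvalue_lists = _per_sample_pvalues(informative)
    screen = np.array(
        [_screen_pvalue(p, screening) for p in pvalue_lists], dtype=np.float64
    )
    screen_adj = bh_adjust(screen)
    selected = screen_adj <= alpha
    r = int(np.sum(selected))
    m = len(informative)

    results: list[MdfdrResult] = []
    for snp, pvals, sp, sa, sel in zip(
        informative, pvalue_lists, screen, screen_adj, selected
    ):
        k = snp.n_testable
        if sel and r > 0:
            threshold = alpha * r / (m * k)
            sig = pvals <= threshold
        else:
            sig = np.zeros(k, dtype=bool)
        chrom, pos, ref, alt = snp.key()
        results.append(
            MdfdrResult(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                screen_p=float(sp),
                screen_adj_p=float(sa),
                selected=bool(sel),
                samples=snp.samples,
                ref_counts=snp.ref_counts,
                alt_counts=snp.alt_counts,
                pvalues=pvals,
                significant=sig,
                directions=tuple(
                    _direction(int(rc), int(ac))
                    for rc, ac in zip(snp.ref_counts, snp.alt_counts)
                ),
                r_selected=r,
                m_variants=m,
                alpha=alpha,
            )
        )
    return results


def sample_tests(snp: InformativeSnp) -> list[SampleTest]:
    """Per-sample binomial tests for one informative SNP."""
    pvals = binomial_test_many(snp.ref_counts, snp.alt_counts)
    return [
        SampleTest(sample=s, ref_count=int(r), alt_count=int(a), p=float(p))
        for s, r, a, p in zip(snp.samples, snp.ref_counts, snp.alt_counts, pvals)
    ]
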