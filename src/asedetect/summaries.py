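"""Downstream summaries of the ASE calls.

Covers the analyses typically reported alongside per-variant ASE results:
how often each variant shows ASE across samples (frequency binning), how
consistently the same allele is the higher-expressed one (direction
concordance), whether reads favour the reference allele overall
(reference-allele ratio), per-gene ASE scores, enrichment of annotation
categories among ASE variants, and association of per-sample ASE status
with a binary sample grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .ase_stats import MdfdrResult, bh_adjust
from .filtering import InformativeSnp

__all__ = [
    "FrequencySummary",
    "ase_frequency",
    "direction_concordance",
    "reference_allele_ratio",
    "gene_ase_scores",
    "global_gene_scores",
    "score_thresholds",
    "annotation_enrichment",
    "group_ase_association",
]

BIN_LABELS = tuple(f"{lo / 10:.1f}-{(lo + 1) / 10:.1f}" for lo in range(10))


@dataclass
class FrequencySummary:
    """Ten-bin histogram of per-variant ASE frequency.

    Bins are left-closed right-open over [0, 1] except the last, which is
    closed ([0.9, 1.0]); a frequency of exactly 0.1 therefore falls in the
    second bin.  Counts always partition the variant set.
    """

    labels: tuple[str, ...]
    counts: np.ndarray
    n_variants: int
    n_samples: int | None

    @property
    def percents(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(len(self.labels))
        return 100.0 * self.counts / self.n_variants

    def rows(self) -> list[dict]:
        return [
            {"bin": lab, "count": int(c), "percent": float(p)}
            for lab, c, p in zip(self.labels, self.counts, self.percents)
        ]


def _bin_index(freq: float) -> int:
    # last bin is closed at 1.0
    return min(int(freq * 10), 9)


def ase_frequency(
    mdfdr: Sequence[MdfdrResult],
    denominator: Literal["testable", "all_samples"] = "testable",
    n_total_samples: int | None = None,
) -> tuple[pd.DataFrame, FrequencySummary]:
    """Per-variant ASE frequency = significant samples / denominator.

    The denominator is either the variant's own testable-sample count
    (default) or a fixed total sample count for the run; both readings of
    "number of ASE samples / total number of samples" are defensible, so
    the per-variant table reports both frequencies.
    """
    if denominator == "all_samples" and not n_total_samples:
        raise ValueError("denominator='all_samples' requires n_total_samples")

    rows = []
    counts = np.zeros(10, dtype=np.int64)
    for res in mdfdr:
        n_sig = res.n_significant
        denom_testable = res.k
        denom_all = n_total_samples
        if denominator == "testable":
            denom = denom_testable
        else:
            denom = denom_all
        if not denom:
            warnings.warn(
                f"variant {res.chrom}:{res.pos} skipped: zero frequency denominator"
            )
            continue
        freq = n_sig / denom
        idx = _bin_index(freq)
        counts[idx] += 1
        rows.append(
            {
                "chrom": res.chrom,
                "pos": res.pos,
                "ref": res.ref,
                "alt": res.alt,
                "n_significant": n_sig,
                "n_testable": denom_testable,
                "freq_testable": n_sig / denom_testable,
                "freq_all_samples": (n_sig / denom_all) if denom_all else None,
                "frequency": freq,
                "bin": BIN_LABELS[idx],
            }
        )
    table = pd.DataFrame(rows)
    summary = FrequencySummary(
        labels=BIN_LABELS,
        counts=counts,
        n_variants=int(counts.sum()),
        n_samples=n_total_samples,
    )
    return table, summary


def direction_concordance(
    mdfdr: Sequence[MdfdrResult],
) -> tuple[pd.DataFrame, float | None]:
    """Agreement across significant samples on which allele is higher.

    Per variant: majority fraction = max(#alt_higher, #ref_higher) over
    the significant samples.  The global percentage pools significant
    (variant, sample) results over variants with >= 2 significant samples;
    single-sample variants are trivially 100% concordant and would inflate
    the pooled figure, so they are excluded from it (but still listed).
    Returns (per-variant table, global percent or None if no variant
    qualifies).
    """
    rows = []
    agreeing = 0
    total = 0
    for res in mdfdr:
        n_sig = res.n_significant
        if n_sig == 0:
            continue
        dirs = [d for d, s in zip(res.directions, res.significant) if s]
        n_alt = sum(1 for d in dirs if d == "alt_higher")
        n_ref = sum(1 for d in dirs if d == "ref_higher")
        majority = max(n_alt, n_ref)
        rows.append(
            {
                "chrom": res.chrom,
                "pos": res.pos,
                "ref": res.ref,
                "alt": res.alt,
                "n_significant": n_sig,
                "n_alt_higher": n_alt,
                "n_ref_higher": n_ref,
                "majority_fraction": majority / n_sig,
                "majority_allele": "alt" if n_alt >= n_ref else "ref",
            }
        )
        if n_sig >= 2:
            agreeing += majority
            total += n_sig
    global_pct = 100.0 * agreeing / total if total else None
    return pd.DataFrame(rows), global_pct


def reference_allele_ratio(informative: Sequence[InformativeSnp]) -> float:
    """Mean percent of reads supporting the reference allele.

    Averaged over all testable (variant, sample) pairs; ~50% indicates no
    residual reference-mapping bias.
    """
    ratios: list[np.ndarray] = []
    for snp in informative:
        total = snp.ref_counts + snp.alt_counts
        ratios.append(snp.ref_counts / total)
    if not ratios:
        raise ValueError("reference_allele_ratio requires >= 1 testable pair")
    return float(100.0 * np.mean(np.concatenate(ratios)))


def _dedupe_variant_gene(snp_gene_map: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_key", "gene_id"}
    if not required <= set(snp_gene_map.columns):
        raise ValueError(f"snp_gene_map needs columns {sorted(required)}")
    return snp_gene_map[["variant_key", "gene_id"]].drop_duplicates()


def gene_ase_scores(
    snp_gene_map: pd.DataFrame,
    informative_keys: Mapping[str, set],
    ase_keys: Mapping[str, set],
) -> pd.DataFrame:
    """Normalised gene ASE score per tissue: (ASE SNPs / informative SNPs) x 100.

    ``informative_keys`` and ``ase_keys`` map tissue name -> set of variant
    keys ("chrom:pos:ref:alt" strings); every ASE key must be informative.
    A variant mapping to several genes counts once for each gene.  Genes
    with zero informative SNPs in a tissue are omitted for that tissue.
    """
    pairs = _dedupe_variant_gene(snp_gene_map)
    rows = []
    for tissue, inf in informative_keys.items():
        ase = ase_keys.get(tissue, set())
        stray = ase - inf
        if stray:
            raise ValueError(
                f"{len(stray)} ASE keys absent from informative set in {tissue!r}"
            )
        sub = pairs[pairs["variant_key"].isin(inf)]
        for gene_id, grp in sub.groupby("gene_id", sort=True):
            n_inf = len(grp)
            n_ase = int(grp["variant_key"].isin(ase).sum())
            rows.append(
                {
                    "tissue": tissue,
                    "gene_id": gene_id,
                    "informative_snps": n_inf,
                    "ase_snps": n_ase,
                    "score": 100.0 * n_ase / n_inf,
                }
            )
    return pd.DataFrame(
        rows, columns=["tissue", "gene_id", "informative_snps", "ase_snps", "score"]
    )


def global_gene_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Cross-tissue gene score: unweighted mean of per-tissue scores.

    Only tissues in which the gene has >= 1 informative SNP contribute
    (they are the only rows present).
    """
    if scores.empty:
        return pd.DataFrame(columns=["gene_id", "n_tissues", "global_score"])
    grouped = scores.groupby("gene_id", sort=True)["score"]
    out = grouped.agg(n_tissues="size", global_score="mean").reset_index()
    return out


def score_thresholds(global_scores: pd.DataFrame) -> dict[str, int]:
    """Counts of genes with global score >= 50, >= 80 and == 100 percent."""
    s = global_scores["global_score"]
    return {
        "ge_50": int((s >= 50.0).sum()),
        "ge_80": int((s >= 80.0).sum()),
        "eq_100": int((s == 100.0).sum()),
    }


def annotation_enrichment(
    informative_annotations: pd.DataFrame,
    ase_annotations: pd.DataFrame,
    grouping: str = "impact",
    contrast: Literal["all_informative", "non_ase"] = "all_informative",
) -> pd.DataFrame:
    """Fisher-exact enrichment of annotation categories among ASE variants.

    Inputs are VEP-style tables with at least ``variant_key`` and the
    ``grouping`` column (e.g. "impact" or "consequence"); rows are
    deduplicated to unique (variant, category) pairs.  Each category is
    tested with a 2x2 Fisher exact test of category-vs-rest against
    ASE-vs-background, where the background is all informative variants
    (default, the superset contrast) or informative-minus-ASE.  Fold
    change is the ratio of category percentages (ASE / background);
    a category present only in the ASE set reports ``inf``.  p-values are
    BH-adjusted across the categories of the grouping.
    """
    for name, df in (("informative", informative_annotations), ("ase", ase_annotations)):
        if "variant_key" not in df.columns or grouping not in df.columns:
            raise ValueError(f"{name} table needs columns 'variant_key' and {grouping!r}")

    inf_pairs = informative_annotations[["variant_key", grouping]].drop_duplicates()
    ase_pairs = ase_annotations[["variant_key", grouping]].drop_duplicates()
    if contrast == "non_ase":
        ase_variants = set(ase_pairs["variant_key"])
        inf_pairs = inf_pairs[~inf_pairs["variant_key"].isin(ase_variants)]

    n_ase = ase_pairs["variant_key"].nunique()
    n_bg = inf_pairs["variant_key"].nunique()
    categories = sorted(set(inf_pairs[grouping]) | set(ase_pairs[grouping]))

    rows = []
    for cat in categories:
        a = ase_pairs.loc[ase_pairs[grouping] == cat, "variant_key"].nunique()
        c = inf_pairs.loc[inf_pairs[grouping] == cat, "variant_key"].nunique()
        table = np.array([[a, n_ase - a], [c, n_bg - c]])
        _, p = fisher_exact(table, alternative="two-sided")
        pct_ase = 100.0 * a / n_ase if n_ase else 0.0
        pct_bg = 100.0 * c / n_bg if n_bg else 0.0
        fold = pct_ase / pct_bg if pct_bg > 0 else (float("inf") if pct_ase > 0 else float("nan"))
        rows.append(
            {
                "category": cat,
                "ase_count": int(a),
                "ase_total": int(n_ase),
                "background_count": int(c),
                "background_total": int(n_bg),
                "pct_ase": pct_ase,
                "pct_background": pct_bg,
                "fold_change": fold,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def group_ase_association(
    mdfdr: Sequence[MdfdrResult],
    sample_metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant Fisher exact test of ASE status against a binary label.

    ``sample_metadata`` has columns ``sample`` and ``label`` with exactly
    one label per sample; every testable sample must be labelled.  For
    each variant the 2x2 table crosses label with per-sample significance
    among the variant's testable samples; degenerate margins give p = 1.
    """
    if not {"sample", "label"} <= set(sample_metadata.columns):
        raise ValueError("sample_metadata needs columns 'sample' and 'label'")
    labels = dict(zip(sample_metadata["sample"], sample_metadata["label"]))
    level_names = sorted(set(labels.values()))
    if len(level_names) > 2:
        raise ValueError("group_ase_association supports at most two labels")

    rows = []
    for res in mdfdr:
        missing = [s for s in res.samples if s not in labels]
        if missing:
            raise ValueError(f"unlabelled samples: {missing}")
        table = np.zeros((2, 2), dtype=np.int64)
        for s, sig in zip(res.samples, res.significant):
            i = level_names.index(labels[s]) if len(level_names) == 2 else 0
            table[i, 0 if sig else 1] += 1
        if len(level_names) < 2 or table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            p = 1.0
        else:
            _, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "chrom": res.chrom,
                "pos": res.pos,
                "ref": res.ref,
                "alt": res.alt,
                "n_testable": res.k,
                "n_significant": res.n_significant,
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
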