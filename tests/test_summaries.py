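"""Frequency binning, concordance, reference ratio, gene scores, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from asedetect.ase_stats import run_mdfdr
from asedetect.summaries import (
    annotation_enrichment,
    ase_frequency,
    direction_concordance,
    gene_ase_scores,
    global_gene_scores,
    group_ase_association,
    reference_allele_ratio,
    score_thresholds,
)

from .conftest import make_informative


def mdfdr_stub(per_variant):
    """MdfdrResult list from [(n_significant_alt, n_significant_ref, k)] specs."""
    from asedetect.ase_stats import MdfdrResult

    out = []
    for i, (n_alt, n_ref, k) in enumerate(per_variant):
        n_sig = n_alt + n_ref
        assert n_sig <= k
        sig = np.array([True] * n_sig + [False] * (k - n_sig))
        directions = tuple(
            ["alt_higher"] * n_alt + ["ref_higher"] * n_ref + ["tie"] * (k - n_sig)
        )
        out.append(
            MdfdrResult(
                chrom="1",
                pos=1000 * (i + 1),
                ref="A",
                alt="G",
                screen_p=0.01,
                screen_adj_p=0.01,
                selected=n_sig > 0,
                samples=tuple(f"S{j + 1:02d}" for j in range(k)),
                ref_counts=np.full(k, 10),
                alt_counts=np.full(k, 30),
                pvalues=np.full(k, 0.001),
                significant=sig,
                directions=directions,
                r_selected=len(per_variant),
                m_variants=len(per_variant),
                alpha=0.05,
            )
        )
    return out


class TestAseFrequency:
    def test_frequency_and_bin(self):
        table, summary = ase_frequency(mdfdr_stub([(15, 0, 23)]))
        assert table.loc[0, "frequency"] == pytest.approx(15 / 23)
        assert table.loc[0, "bin"] == "0.6-0.7"

    def test_zero_significant_lands_in_first_bin(self):
        table, _ = ase_frequency(mdfdr_stub([(0, 0, 10)]))
        assert table.loc[0, "bin"] == "0.0-0.1"

    def test_boundary_tenth_goes_right(self):
        table, _ = ase_frequency(mdfdr_stub([(1, 0, 10)]))
        assert table.loc[0, "bin"] == "0.1-0.2"

    def test_full_frequency_in_last_bin(self):
        table, _ = ase_frequency(mdfdr_stub([(5, 0, 5)]))
        assert table.loc[0, "bin"] == "0.9-1.0"

    def test_counts_partition_variants(self):
        specs = [(i % 4, 0, 10) for i in range(37)]
        _, summary = ase_frequency(mdfdr_stub(specs))
        assert summary.counts.sum() == 37
        assert summary.percents.sum() == pytest.approx(100.0)

    def test_all_samples_denominator(self):
        table, _ = ase_frequency(
            mdfdr_stub([(5, 0, 10)]), denominator="all_samples", n_total_samples=23
        )
        assert table.loc[0, "frequency"] == pytest.approx(5 / 23)
        with pytest.raises(ValueError):
            ase_frequency(mdfdr_stub([(1, 0, 5)]), denominator="all_samples")


class TestDirectionConcordance:
    def test_unanimous_variant_is_100(self):
        table, global_pct = direction_concordance(mdfdr_stub([(3, 0, 5)]))
        assert table.loc[0, "majority_fraction"] == 1.0
        assert global_pct == 100.0

    def test_three_to_one_split(self):
        table, _ = direction_concordance(mdfdr_stub([(3, 1, 6)]))
        assert table.loc[0, "majority_fraction"] == 0.75

    def test_global_pools_over_multi_sample_variants(self):
        # (alt, alt) and (ref, alt): (2 + 1) agreeing of 4 significant
        _, global_pct = direction_concordance(mdfdr_stub([(2, 0, 4), (1, 1, 4)]))
        assert global_pct == pytest.approx(75.0)

    def test_single_significant_variants_excluded_from_global(self):
        _, global_pct = direction_concordance(mdfdr_stub([(1, 0, 4), (1, 0, 4)]))
        assert global_pct is None


class TestReferenceAlleleRatio:
    def test_balanced_counts_give_50(self):
        assert reference_allele_ratio([make_informative([(10, 10), (10, 10)])]) == 50.0

    def test_symmetric_pairs_give_50(self):
        assert reference_allele_ratio([make_informative([(30, 10), (10, 30)])]) == 50.0

    def test_label_swap_symmetry(self, rng):
        counts = [(int(r), int(a)) for r, a in rng.integers(10, 60, size=(50, 2))]
        swapped = [(a, r) for r, a in counts]
        fwd = reference_allele_ratio([make_informative(counts)])
        rev = reference_allele_ratio([make_informative(swapped)])
        assert fwd + rev == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reference_allele_ratio([])


class TestGeneScores:
    @pytest.fixture
    def annotation(self):
        rows = []
        for gene, n in (("g1", 4), ("g2", 3), ("g3", 2)):
            for i in range(n):
                rows.append({"variant_key": f"1:{gene}:{i}", "gene_id": gene})
        return pd.DataFrame(rows)

    def test_stated_formula(self, annotation):
        informative = {"liver": set(annotation["variant_key"])}
        ase = {"liver": {"1:g1:0", "1:g1:1", "1:g3:0", "1:g3:1"}}
        scores = gene_ase_scores(annotation, informative, ase)
        by_gene = scores.set_index("gene_id")["score"]
        assert by_gene["g1"] == 50.0
        assert by_gene["g2"] == 0.0
        assert by_gene["g3"] == 100.0

    def test_global_mean_across_tissues(self, annotation):
        keys = set(annotation["variant_key"])
        g1 = {k for k in keys if ":g1:" in k}
        informative = {t: keys for t in ("a", "b", "c")}
        ase = {"a": g1, "b": {"1:g1:0", "1:g1:1"}, "c": set()}
        scores = gene_ase_scores(annotation, informative, ase)
        glob = global_gene_scores(scores).set_index("gene_id")
        # per-tissue scores for g1: 100, 50, 0
        assert glob.loc["g1", "global_score"] == pytest.approx(50.0)
        assert glob.loc["g1", "n_tissues"] == 3

    def test_threshold_counts(self, annotation):
        glob = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "n_tissues": 1, "global_score": [100.0, 80.0, 30.0]}
        )
        assert score_thresholds(glob) == {"ge_50": 2, "ge_80": 2, "eq_100": 1}

    def test_ase_key_outside_informative_is_contract_error(self, annotation):
        with pytest.raises(ValueError, match="absent"):
            gene_ase_scores(annotation, {"t": {"1:g1:0"}}, {"t": {"1:g2:0"}})

    def test_removing_ase_snp_never_raises_score(self, annotation):
        informative = {"t": set(annotation["variant_key"])}
        full = {"1:g1:0", "1:g1:1"}
        s_full = gene_ase_scores(annotation, informative, {"t": full})
        s_less = gene_ase_scores(annotation, informative, {"t": {"1:g1:0"}})
        g_full = s_full.set_index("gene_id")["score"]
        g_less = s_less.set_index("gene_id")["score"]
        assert (g_less <= g_full).all()


def annotations_from_counts(counts):
    """Build a variant_key/impact table with given {category: n} composition."""
    rows = []
    i = 0
    for cat, n in counts.items():
        for _ in range(n):
            rows.append({"variant_key": f"1:{i}:A:G", "impact": cat})
            i += 1
    return pd.DataFrame(rows)


class TestEnrichment:
    def test_identical_proportions_are_null(self):
        inf = annotations_from_counts({"HIGH": 10, "LOW": 90})
        ase = inf.iloc[::10]  # every 10th row keeps proportions exact
        out = annotation_enrichment(inf, ase, grouping="impact")
        assert np.allclose(out["fold_change"], 1.0)
        assert np.allclose(out["p"], 1.0)

    def test_fisher_p_matches_hypergeometric_tail(self):
        # ASE: 10 of 100 in category; background: 50 of 100
        inf = annotations_from_counts({"HIGH": 50, "LOW": 50})
        ase = annotations_from_counts({"HIGH": 10, "LOW": 90})
        out = annotation_enrichment(inf, ase, grouping="impact").set_index("category")
        # two-sided Fisher exact by point-probability rule on the 2x2 table
        a, n_ase, c, n_bg = 10, 100, 50, 100
        M, K, N = n_ase + n_bg, a + c, n_ase
        pmf = hypergeom.pmf(np.arange(0, K + 1), M, K, N)
        expected = pmf[pmf <= pmf[a] * (1 + 1e-9)].sum()
        assert out.loc["HIGH", "p"] == pytest.approx(expected, rel=1e-8)

    def test_category_only_in_ase_reports_inf(self):
        inf = annotations_from_counts({"LOW": 50})
        ase = annotations_from_counts({"HIGH": 5, "LOW": 5})
        out = annotation_enrichment(inf, ase, grouping="impact").set_index("category")
        assert math.isinf(out.loc["HIGH", "fold_change"])
        assert 0.0 <= out.loc["HIGH", "p"] <= 1.0

    def test_counts_reproduce_set_sizes(self):
        inf = annotations_from_counts({"HIGH": 7, "MODERATE": 13, "LOW": 30})
        ase = annotations_from_counts({"HIGH": 4, "LOW": 6})
        out = annotation_enrichment(inf, ase, grouping="impact")
        assert out["background_count"].sum() == 50
        assert out["ase_count"].sum() == 10


class TestGroupAssociation:
    def make_meta(self, samples, labels):
        return pd.DataFrame({"sample": samples, "label": labels})

    def test_balanced_table_is_null(self):
        res = mdfdr_stub([(10, 0, 20)])
        meta = self.make_meta(
            [f"S{j + 1:02d}" for j in range(20)], ["A"] * 10 + ["B"] * 10
        )
        # first 10 samples significant: 5 A's and 5 B's each way requires interleave
        res[0].significant = np.array([True, False] * 10)
        out = group_ase_association(res, meta)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_perfect_separation_hypergeometric(self):
        res = mdfdr_stub([(6, 0, 12)])
        meta = self.make_meta(
            [f"S{j + 1:02d}" for j in range(12)], ["A"] * 6 + ["B"] * 6
        )
        out = group_ase_association(res, meta)
        assert out.loc[0, "p"] == pytest.approx(2 / math.comb(12, 6), rel=1e-9)

    def test_single_label_degenerate_margin(self):
        res = mdfdr_stub([(3, 0, 6)])
        meta = self.make_meta([f"S{j + 1:02d}" for j in range(6)], ["A"] * 6)
        out = group_ase_association(res, meta)
        assert out.loc[0, "p"] == 1.0

    def test_unlabelled_sample_is_contract_error(self):
        res = mdfdr_stub([(1, 0, 3)])
        meta = self.make_meta(["S01"], ["A"])
        with pytest.raises(ValueError, match="unlabelled"):
            group_ase_association(res, meta)
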