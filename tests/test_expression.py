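"""Expression calls, TR, Fisher/KS oracles and footprint coverage."""

import math

import numpy as np
import pytest

from _oracles import enumerate_fisher_p, permutation_ks_p

from lncproteo.config import PipelineConfig
from lncproteo.expression import (
    chromosome_enrichment,
    compute_rpkm,
    compute_tr,
    detection_pattern,
    fisher_exact_2x2,
    is_true_expression,
    ks_two_sample,
    rfp_coverage,
    translation_profiles,
)
from lncproteo.io import ExpressionRecord
from lncproteo.orfs import OrfCandidate
from lncproteo.simulate import SimulationParams, simulate_expression, simulate_transcriptome


class TestRpkm:
    def test_arithmetic(self):
        assert compute_rpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert compute_rpkm(0, 500, 10**6) == 0.0

    def test_scale_invariance(self):
        base = compute_rpkm(10, 1000, 10**6)
        assert compute_rpkm(30, 1000, 3 * 10**6) == pytest.approx(base)

    def test_rejects_zero_denominators(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            compute_rpkm(1, 100, 0)


class TestTrueExpression:
    """Boundary behaviour of the >=10 reads AND >=RPKM-threshold rule."""

    def _rec(self, count, rpkm):
        return ExpressionRecord("g", "s", "mRNA", count, rpkm)

    def test_nine_reads_never_expressed(self):
        assert not is_true_expression(self._rec(9, 100.0))

    def test_rpkm_below_threshold(self):
        assert not is_true_expression(self._rec(10, 0.05))

    def test_both_boundaries_inclusive(self):
        assert is_true_expression(self._rec(10, 0.1))


class TestTranslationRatio:
    def test_ratio(self):
        assert compute_tr(4.0, 2.0) == 2.0

    def test_identity(self):
        assert compute_tr(3.7, 3.7) == 1.0

    def test_undefined_at_zero_mrna(self):
        with pytest.raises(ValueError):
            compute_tr(1.0, 0.0)

    def test_profiles_flag_undefined_tr(self):
        records = [
            ExpressionRecord("g1", "s1", "mRNA", 0, 0.0),
            ExpressionRecord("g1", "s1", "RNC", 5, 1.0),
        ]
        df = translation_profiles(records)
        assert math.isnan(df.loc[0, "tr"])

    def test_planted_tr_shift_recovered(self):
        """A 4x RNC enrichment on a designated 200-gene subset is recovered
        within [3, 5] at 2000 genes."""
        params = SimulationParams(
            seed=13, n_coding_genes=1900, n_lncrnas=100, frac_lncrna_with_orf=0.2,
            tr_shift=4.0,
        )
        sim = simulate_transcriptome(params)
        rng = np.random.default_rng(14)
        high_tr = set(rng.choice([t.gene_id for t in sim.transcripts],
                                 size=200, replace=False))
        records, truth = simulate_expression(sim, high_tr_gene_ids=high_tr)
        df = translation_profiles(records).merge(truth, on="gene_id")
        shifted = df[df["truth_tr"] > 1]["tr"].median()
        flat = df[df["truth_tr"] == 1]["tr"].median()
        assert 3.0 <= shifted / flat <= 5.0


class TestDetectionPattern:
    def _records(self, detected_in):
        recs = []
        for s in range(9):
            hit = s in detected_in
            recs.append(ExpressionRecord("g", f"s{s}", "mRNA",
                                         50 if hit else 3, 5.0 if hit else 0.01))
        return recs

    def test_ubiquitous(self):
        pm = detection_pattern(self._records(set(range(9))))
        assert pm.gene_class["g"] == "ubiquitous"

    def test_cell_specific(self):
        pm = detection_pattern(self._records({0}))
        assert pm.gene_class["g"] == "cell_specific"

    def test_raising_threshold_monotone(self):
        rng = np.random.default_rng(4)
        recs = [
            ExpressionRecord(f"g{i}", f"s{s}", "mRNA",
                             int(rng.integers(0, 100)), float(rng.uniform(0, 2)))
            for i in range(20) for s in range(9)
        ]
        low = detection_pattern(recs, rpkm_threshold=0.1).matrix.sum(axis=1)
        high = detection_pattern(recs, rpkm_threshold=1.0).matrix.sum(axis=1)
        assert (high <= low).all()


class TestFisherExact:
    def test_all_zero_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_symmetric_table(self):
        assert fisher_exact_2x2(4, 4, 4, 4) == pytest.approx(1.0)

    def test_extreme_table_vs_enumeration(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(enumerate_fisher_p(5, 0, 0, 5))

    def test_enumeration_oracle_all_small_margins(self):
        """Agreement with full hypergeometric enumeration for all margins <= 12."""
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    for d in range(6):
                        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            enumerate_fisher_p(a, b, c, d), abs=1e-12
                        ), (a, b, c, d)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 0, 0)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1.0, 2, 3], [1.0, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0
        assert p < 0.2

    def test_permutation_oracle_n5(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = list(rng.normal(0, 1, 5))
            y = list(rng.normal(1, 1, 5))
            _, p = ks_two_sample(x, y)
            assert p == pytest.approx(permutation_ks_p(x, y), abs=1e-9)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestChromosomeEnrichment:
    def test_counts_sum_to_new_set_size(self):
        rng = np.random.default_rng(0)
        bg = {f"g{i}": f"chr{rng.integers(1, 23)}" for i in range(500)}
        new = {k: bg[k] for k in list(bg)[:40]}
        table = chromosome_enrichment(new, bg)
        assert table["n_new"].sum() == len(new)

    def test_uniform_draw_shows_no_enrichment(self):
        """Null calibration: uniformly drawn gene sets rarely reach p < 0.01."""
        rng = np.random.default_rng(1)
        bg = {f"g{i}": f"chr{(i % 22) + 1}" for i in range(1100)}
        n_significant = 0
        n_runs = 20
        for _ in range(n_runs):
            chosen = rng.choice(list(bg), size=50, replace=False)
            new = {g: bg[g] for g in chosen}
            table = chromosome_enrichment(new, bg)
            n_significant += int((table["p_value"] < 0.01).sum())
        assert n_significant / n_runs < 1.0

    def test_concentrated_set_is_enriched(self):
        bg = {f"g{i}": f"chr{(i % 22) + 1}" for i in range(2200)}
        new = {g: "chr1" for g, c in bg.items() if c == "chr1"}
        table = chromosome_enrichment(new, bg).set_index("chromosome")
        assert table.loc["chr1", "p_value"] < 1e-6

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrZ"):
            chromosome_enrichment({"g1": "chrZ"}, {"g2": "chr1"})


class TestRfpCoverage:
    def _orf(self):
        return OrfCandidate("t", 0, 100, 280, "M" * 59)

    def test_no_footprints(self):
        frac, ratio = rfp_coverage(self._orf(), [])
        assert frac == 0.0 and math.isnan(ratio)

    def test_full_cds_coverage_inside_only(self):
        frac, ratio = rfp_coverage(self._orf(), [(100, 280)], transcript_len=400)
        assert frac == 1.0 and math.isinf(ratio)

    def test_density_ratio_recovered(self):
        from lncproteo.simulate import simulate_footprints

        orf = self._orf()
        rng = np.random.default_rng(3)
        intervals = simulate_footprints(orf, 1000, n_footprints=20000,
                                        inside_outside_ratio=10.0, rng=rng)
        _, ratio = rfp_coverage(orf, intervals, transcript_len=1000)
        assert 8.0 <= ratio <= 12.0
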