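"""Dominant-marker index suite: frequencies, per-unit indices, Gst, Nm."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from markerdiv.datasets import load_diversity_table, load_gradient_table
from markerdiv.diversity import (
    band_frequencies,
    differentiation,
    diversity_summary,
    estimate_allele_frequencies,
    gene_flow,
    gst_from_nm,
    locus_statistics,
)
from markerdiv.marker_data import MarkerMatrix
from markerdiv.synthetic_data import SimulationConfig, simulate_dominant_markers


def _one_pop(column):
    vals = np.asarray(column).reshape(-1, 1)
    ids = [f"i{k}" for k in range(len(column))]
    return MarkerMatrix(ids, ["L1"], vals, {i: "A" for i in ids})


class TestBandFrequencies:
    @pytest.mark.parametrize(
        "column, expected",
        [((1, 1, 1, 0), 0.75), ((1, 1, 1, 1), 1.0), ((0, 0, 0, 0), 0.0)],
    )
    def test_counting(self, column, expected):
        assert band_frequencies(_one_pop(column), "A")[0] == pytest.approx(expected)

    def test_unknown_unit(self, tiny_matrix):
        with pytest.raises(KeyError):
            band_frequencies(tiny_matrix, "nope")


class TestAlleleFrequencies:
    def test_sqrt_estimator(self):
        # B = 0.75 -> q = sqrt(0.25) = 0.5
        f = estimate_allele_frequencies(_one_pop([1, 1, 1, 0]), "A", "sqrt")
        assert f.q[0] == pytest.approx(0.5)
        assert f.p[0] == pytest.approx(0.5)

    def test_sqrt_all_absent(self):
        f = estimate_allele_frequencies(_one_pop([0, 0]), "A", "sqrt")
        assert f.p[0] == 0.0 and f.q[0] == 1.0

    def test_sqrt_b096(self):
        f = estimate_allele_frequencies(_one_pop([1] * 24 + [0]), "A", "sqrt")
        assert f.q[0] == pytest.approx(0.2)
        assert f.p[0] == pytest.approx(0.8)

    def test_lynch_milligan_bias_correction_direction(self):
        # LM inflates q relative to sqrt for intermediate B at small n
        m = _one_pop([1, 1, 1, 0])
        q_sqrt = estimate_allele_frequencies(m, "A", "sqrt").q[0]
        q_lm = estimate_allele_frequencies(m, "A", "lynch_milligan").q[0]
        assert q_lm > q_sqrt

    def test_unknown_method(self, tiny_matrix):
        with pytest.raises(ValueError):
            estimate_allele_frequencies(tiny_matrix, "A", "parsimony")

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_p_plus_q_is_one(self, B):
        n = 50
        k = round(B * n)
        m = _one_pop([1] * k + [0] * (n - k))
        f = estimate_allele_frequencies(m, "A", "sqrt")
        assert f.p[0] + f.q[0] == pytest.approx(1.0)
        assert 0.0 <= f.p[0] <= 1.0


class TestLocusStatistics:
    def test_symmetric_biallelic_maximum(self):
        na, ne, h, i = locus_statistics(
            np.array([0.5]), np.array([0.5]), np.array([True])
        )
        assert na[0] == 2 and ne[0] == pytest.approx(2.0)
        assert h[0] == pytest.approx(0.5)
        assert i[0] == pytest.approx(np.log(2))

    def test_monomorphic(self):
        na, ne, h, i = locus_statistics(
            np.array([1.0]), np.array([0.0]), np.array([False])
        )
        assert na[0] == 1 and ne[0] == pytest.approx(1.0)
        assert h[0] == 0.0 and i[0] == 0.0

    def test_bounds_on_dense_grid(self):
        p = np.linspace(0.001, 0.999, 999)
        _, ne, h, i = locus_statistics(p, 1 - p, np.ones_like(p, bool))
        assert (ne <= 2.0 + 1e-12).all()
        assert np.allclose(h, 1 - 1 / ne)
        assert (h <= 0.5 + 1e-12).all()
        assert (i >= h - 1e-12).all()  # Shannon dominates gene diversity


class TestDiversitySummary:
    def test_na_identity_and_percentages(self, study_scale_matrix):
        matrix, _ = study_scale_matrix
        for unit in ["Pop1", "Pop7", "all"]:
            s = diversity_summary(matrix, unit)
            assert s.Na == pytest.approx(1 + s.P / 100, abs=1e-12)
            assert 0 <= s.P <= 100
            assert 1 <= s.Ne <= 2 and 0 <= s.h <= 0.5 and 0 <= s.I <= np.log(2)

    def test_known_counts(self):
        # two loci polymorphic, one monomorphic-present, one absent
        vals = np.array([[1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 1, 0]])
        ids = ["i1", "i2", "i3"]
        m = MarkerMatrix(ids, list("abcd"), vals, {i: "A" for i in ids})
        s = diversity_summary(m, "A")
        assert s.n_polymorphic == 2
        assert s.P == pytest.approx(50.0)

    def test_empty_unit_errors(self, tiny_matrix):
        with pytest.raises(KeyError):
            diversity_summary(tiny_matrix, "Z")


class TestDifferentiation:
    def test_complete_differentiation(self):
        vals = np.array([[0], [0], [1], [1]])
        m = MarkerMatrix(
            ["a1", "a2", "b1", "b2"], ["L1"], vals,
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        d = differentiation(m)
        assert d.Hs == pytest.approx(0.0)
        assert d.Ht == pytest.approx(0.5)
        assert d.Gst == pytest.approx(1.0)

    def test_identical_units_have_zero_gst(self):
        vals = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        m = MarkerMatrix(
            ["a1", "a2", "b1", "b2"], ["L1", "L2"], vals,
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        d = differentiation(m)
        assert d.Gst == pytest.approx(0.0, abs=1e-12)

    def test_nei_formulas_p03_p07(self):
        # direct evaluation: Hs = 0.42, Ht = 0.5, Gst = 0.16
        p = np.array([[0.3], [0.7]])
        hs = (1 - p**2 - (1 - p) ** 2).mean()
        pbar = p.mean()
        ht = 1 - pbar**2 - (1 - pbar) ** 2
        assert hs == pytest.approx(0.42)
        assert ht == pytest.approx(0.5)
        assert (ht - hs) / ht == pytest.approx(0.16)

    def test_label_permutation_invariance(self, study_scale_matrix):
        matrix, _ = study_scale_matrix
        pops = matrix.populations
        d1 = differentiation(matrix, units=pops)
        d2 = differentiation(matrix, units=list(reversed(pops)))
        assert d1.Gst == pytest.approx(d2.Gst)
        assert d1.Ht == pytest.approx(d2.Ht)

    def test_all_monomorphic_everywhere_errors(self):
        vals = np.ones((4, 2), dtype=int)
        m = MarkerMatrix(
            ["a1", "a2", "b1", "b2"], ["L1", "L2"], vals,
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        with pytest.raises(ZeroDivisionError):
            differentiation(m)


class TestGeneFlow:
    @pytest.mark.parametrize(
        "gst, nm",
        [(0.7609, 0.1571), (0.5, 0.5), (0.5663, 0.3830)],
    )
    def test_published_and_fixed_points(self, gst, nm):
        assert gene_flow(gst) == pytest.approx(nm, abs=1.5e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            gene_flow(bad)

    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_round_trip_and_monotonicity(self, gst):
        nm = gene_flow(gst)
        assert gst_from_nm(nm) == pytest.approx(gst, abs=1e-12)
        assert gene_flow(min(gst + 1e-3, 1.0)) <= nm

    def test_all_published_gradient_pairs_round_trip(self):
        t7 = load_gradient_table()
        calc = t7["Gst"].apply(gene_flow)
        assert (calc - t7["Nm"]).abs().max() <= 1e-4 + 1e-12

    def test_gst_increases_with_simulated_fst(self):
        """Estimated Gst tracks the simulated island-model differentiation."""
        gsts = {}
        for fst in (0.05, 0.15, 0.30):
            reps = []
            for rep in range(5):
                m, _ = simulate_dominant_markers(
                    SimulationConfig(
                        n_populations=8, n_individuals=10, n_loci=150,
                        fst=fst, seed=1000 + rep,
                    )
                )
                reps.append(differentiation(m).Gst)
            gsts[fst] = np.mean(reps)
        assert gsts[0.05] < gsts[0.15] < gsts[0.30]


class TestAgainstPublishedTable:
    def test_published_per_population_na_identity(self):
        """Published per-population rows satisfy Na = 1 + P/100 exactly."""
        t5 = load_diversity_table(values_only=False)
        assert np.allclose(t5["Na"], 1 + t5["P"] / 100, atol=5.1e-5)
        assert np.allclose(t5["P"], 100 * t5["n"] / 288, atol=5.1e-3)
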