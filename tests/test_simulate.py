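"""Genotype simulation along a genetic map and epistatic trait calibration."""

import numpy as np
import pytest

from gsmodels import (
    TraitSimulationSpec,
    calibrate_effects,
    epistatic_benchmark_spec,
    expand_interactions,
    haldane_recombination,
    simulate_dataset,
    simulate_genotypes,
)


class TestGenotypeSimulation:
    def test_zero_distance_markers_are_identical(self):
        geno = simulate_genotypes(200, [0.0, 0.0], seed=1)
        np.testing.assert_array_equal(geno.dosages[:, 0], geno.dosages[:, 1])

    def test_unlinked_markers_are_uncorrelated(self):
        """1,800 cM apart: recombination 1/2, dosage correlation ~ 0."""
        geno = simulate_genotypes(10_000, [0.0, 1800.0], seed=2)
        r = np.corrcoef(geno.dosages.T)[0, 1]
        assert abs(r) < 0.05

    def test_benchmark_map_mean_dosage(self):
        """121 markers at 15 cM, allele frequency 1/2: mean dosage near 1."""
        geno = simulate_genotypes(600, np.arange(121) * 15.0, seed=3)
        assert geno.dosages.shape == (600, 121)
        means = geno.dosages.mean(axis=0)
        assert np.all(np.abs(means - 1.0) < 0.15)

    def test_linkage_decays_with_map_distance(self):
        """Empirical LD r^2 against the first marker decreases along the map."""
        positions = np.array([0.0, 15.0, 45.0, 105.0, 300.0])
        geno = simulate_genotypes(10_000, positions, seed=4)
        X = geno.dosages.astype(float)
        r2 = [np.corrcoef(X[:, 0], X[:, j])[0, 1] ** 2 for j in range(1, 5)]
        assert all(a > b for a, b in zip(r2, r2[1:]))
        # adjacent-marker correlation should match the Haldane expectation
        expected = np.exp(-2 * 15.0 / 100.0)
        assert np.corrcoef(X[:, 0], X[:, 1])[0, 1] == pytest.approx(expected, abs=0.03)

    def test_seeded_runs_bit_reproducible(self):
        a = simulate_genotypes(50, np.arange(10) * 10.0, seed=9)
        b = simulate_genotypes(50, np.arange(10) * 10.0, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n must be"):
            simulate_genotypes(1, [0.0, 10.0], seed=0)
        with pytest.raises(ValueError, match="non-decreasing"):
            simulate_genotypes(10, [10.0, 0.0], seed=0)

    def test_haldane_limits(self):
        assert haldane_recombination(0.0) == 0.0
        assert haldane_recombination(1e9) == pytest.approx(0.5)


class TestEffectCalibration:
    def test_single_additive_qtl_realizes_target(self):
        """One QTL at 20%, residual 80%: realized fraction in [0.18, 0.22]."""
        spec = TraitSimulationSpec(
            10_000, 150.0, 15.0, additive_qtl=[(5, 0.20)], seed=0
        )
        ds = simulate_dataset(spec, seed=11)
        term = ds.genetic_values
        frac = term.var() / ds.phenotypes.var()
        assert 0.18 <= frac <= 0.22

    def test_null_trait_is_pure_noise(self):
        spec = TraitSimulationSpec(500, 150.0, 15.0, seed=0)
        ds = simulate_dataset(spec, seed=1)
        assert np.all(ds.genetic_values == 0)
        assert ds.phenotypes.std() > 0

    def test_benchmark_preset_total_genetic_fraction(self):
        """Realized genetic fraction matches the preset's sum within 0.02."""
        spec = epistatic_benchmark_spec()
        ds = simulate_dataset(spec, seed=5)
        assert ds.heritability == pytest.approx(spec.genetic_fraction, abs=0.02)
        realized = np.array(list(ds.realized_fractions.values()))
        targets = np.array(
            [f for _, f in spec.additive_qtl] + [f for _, _, f in spec.epistatic_pairs]
        )
        np.testing.assert_allclose(realized, targets, rtol=0.15)

    def test_preset_fractions_within_stated_range(self):
        spec = epistatic_benchmark_spec()
        fracs = [f for _, f in spec.additive_qtl] + [f for _, _, f in spec.epistatic_pairs]
        assert len(spec.additive_qtl) == 9
        assert len(spec.epistatic_pairs) == 13
        assert all(0.005 <= f <= 0.20 for f in fracs)
        assert sum(fracs) < 1

    def test_overcommitted_fractions_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            TraitSimulationSpec(
                100, 150.0, 15.0, additive_qtl=[(j, 0.2) for j in range(6)]
            )

    def test_bad_marker_index_rejected(self):
        spec = TraitSimulationSpec(100, 150.0, 15.0, additive_qtl=[(99, 0.1)])
        geno = simulate_genotypes(100, spec.marker_positions, seed=0)
        with pytest.raises(IndexError):
            calibrate_effects(spec, geno)

    def test_dataset_reproducible(self):
        spec = epistatic_benchmark_spec(n_individuals=100)
        a = simulate_dataset(spec, seed=3)
        b = simulate_dataset(spec, seed=3)
        np.testing.assert_array_equal(a.phenotypes, b.phenotypes)


class TestInteractionExpansion:
    @pytest.mark.parametrize("p", list(range(1, 26)))
    def test_column_count_is_p_choose_2_plus_diagonal(self, p, rng):
        from gsmodels import GenotypeMatrix

        geno = GenotypeMatrix(
            [f"L{i}" for i in range(3)],
            [f"m{j}" for j in range(p)],
            rng.integers(0, 3, (3, p)),
        )
        assert expand_interactions(geno).n_columns == p * (p + 1) // 2

    def test_hand_enumeration_p3(self):
        from gsmodels import GenotypeMatrix

        geno = GenotypeMatrix(["A", "B"], ["m1", "m2", "m3"], [[0, 1, 2], [1, 1, 1]])
        exp = expand_interactions(geno)
        assert exp.column_ids == ["m1:m1", "m1:m2", "m1:m3", "m2:m2", "m2:m3", "m3:m3"]
        np.testing.assert_array_equal(exp.values[0], [0, 0, 0, 1, 2, 4])

    def test_single_marker_gives_square(self):
        from gsmodels import GenotypeMatrix

        geno = GenotypeMatrix(["A", "B", "C"], ["m1"], [[0], [1], [2]])
        exp = expand_interactions(geno)
        np.testing.assert_array_equal(exp.values[:, 0], [0, 1, 4])

    def test_values_in_dosage_product_set(self, small_genotypes):
        exp = expand_interactions(small_genotypes)
        assert set(np.unique(exp.values)) <= {0, 1, 2, 4}

    def test_main_effects_prepended_when_requested(self, small_genotypes):
        exp = expand_interactions(small_genotypes, include_main=True)
        p = small_genotypes.n_markers
        assert exp.n_columns == p + p * (p + 1) // 2
        np.testing.assert_array_equal(exp.values[:, :p], small_genotypes.dosages)

    def test_centered_coding_orthogonal_to_mains(self, rng):
        """Centered products have ~zero covariance with the marker columns."""
        from gsmodels import simulate_genotypes

        geno = simulate_genotypes(2000, np.arange(6) * 500.0, seed=8)
        exp = expand_interactions(geno, coding="centered")
        X = geno.dosages - geno.dosages.mean(axis=0)
        # off-diagonal products only (diagonal squares do correlate)
        cols = [
            k
            for k, cid in enumerate(exp.column_ids)
            if cid.split(":")[0] != cid.split(":")[1]
        ]
        cov = X.T @ exp.values[:, cols] / len(X)
        assert np.abs(cov).max() < 0.06
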