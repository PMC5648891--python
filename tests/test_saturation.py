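"""Saturation curves, subsampling, and error-rate estimators."""

import numpy as np
import pandas as pd
import pytest

from digicount import (
    SHORT_DESIGN,
    ClusteringParams,
    cluster_observations,
    coverage_curve,
    estimate_base_composition,
    estimate_fixed_base_mismatch_rates,
    estimate_substitution_rate,
    make_observations,
    random_base_curve,
    required_random_bases,
    run_pipeline,
    simulate,
    subsample_reads,
    truncate_random_bases,
)
from digicount.saturation import consensus_barcode

from conftest import single_template_config

P2 = ClusteringParams(distance=2)


class TestSubsample:
    def test_full_fraction_returns_everything(self):
        observations = list(range(100))
        assert subsample_reads(observations, 1.0, 1) == observations

    def test_exact_cardinality_and_membership(self):
        observations = list(range(1000))
        subset = subsample_reads(observations, 0.1, 3)
        assert len(subset) == 100
        assert set(subset) <= set(observations)

    def test_seed_determinism(self):
        observations = list(range(500))
        assert subsample_reads(observations, 0.25, 7) == subsample_reads(
            observations, 0.25, 7
        )

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            subsample_reads([1, 2, 3], fraction, 0)


class TestTruncation:
    def test_full_set(self):
        params = truncate_random_bases(P2, SHORT_DESIGN, 24)
        assert params.resolve_positions(SHORT_DESIGN) == tuple(
            sorted(SHORT_DESIGN.random_positions)
        )

    def test_first_four_random_positions(self):
        params = truncate_random_bases(P2, SHORT_DESIGN, 4)
        assert params.resolve_positions(SHORT_DESIGN) == (1, 2, 3, 4)

    @pytest.mark.parametrize("k", [0, 25])
    def test_out_of_range(self, k):
        with pytest.raises(ValueError):
            truncate_random_bases(P2, SHORT_DESIGN, k)


@pytest.fixture(scope="module")
def clean_pipeline_obs():
    """Filtered observations from a zero-error 300-molecule-per-index run."""
    config = single_template_config(
        copies=300, seed=21, substitution_rate=0.0, insertion_rate=0.0,
        deletion_rate=0.0, n_rate=0.0, index_swap_rate=0.0, dispersion=None,
    )
    reads, _ = simulate(config)
    result = run_pipeline(reads, config.references, P2, mode="per_category")
    return result.observations


class TestCoverageCurve:
    def test_zero_error_plateau_at_molecule_count(self, clean_pipeline_obs):
        """With no errors and coverage >= ~10 per molecule, the curve is flat
        at the true molecule count (both indices: 600)."""
        curve = coverage_curve(
            clean_pipeline_obs, P2, fractions=(1.0, 0.8, 0.63), n_repeats=4, seed=0
        )
        assert curve["mean"].iloc[-1] == 600.0
        assert np.allclose(curve["mean"], 600.0, atol=2.0)
        assert curve["sd"].iloc[-1] == 0.0  # fraction 1: no resampling
        assert curve.attrs["reference"] == 600.0

    def test_low_coverage_undercounts(self, clean_pipeline_obs):
        """Below one read per molecule the count drops toward the
        coupon-collector expectation N(1-(1-1/N)^reads)."""
        n_molecules = 600
        curve = coverage_curve(
            clean_pipeline_obs, P2, fractions=(0.02, 1.0), n_repeats=6, seed=1
        )
        low = curve.iloc[0]
        expected = n_molecules * (1 - (1 - 1 / n_molecules) ** low["reads"])
        assert low["mean"] < n_molecules
        assert low["mean"] == pytest.approx(expected, rel=0.12)

    def test_relative_is_one_at_reference(self, clean_pipeline_obs):
        curve = coverage_curve(
            clean_pipeline_obs, P2, fractions=(0.5, 1.0), n_repeats=3, seed=2
        )
        assert curve["relative"].iloc[-1] == 1.0


class TestRandomBaseCurve:
    def test_monotone_and_saturating(self, clean_pipeline_obs):
        curve = random_base_curve(
            clean_pipeline_obs, P2, ks=(2, 4, 8, 16, 24), fraction=1.0
        )
        assert (curve["mean"].diff().dropna() >= 0).all()
        assert curve["relative"].iloc[-1] == 1.0

    def test_few_random_bases_saturate_at_barcode_space(self):
        """With k random bases only 4^k barcodes exist; at high copy number
        the count approaches the birthday-saturation bound K(1-(1-1/K)^N)."""
        config = single_template_config(
            copies=4000, seed=3, substitution_rate=0.0, insertion_rate=0.0,
            deletion_rate=0.0, n_rate=0.0, index_swap_rate=0.0,
            indices=("A",), mean_coverage=3.0,
        )
        reads, _ = simulate(config)
        result = run_pipeline(reads, config.references, P2, mode="per_category")
        curve = random_base_curve(
            result.observations, ClusteringParams(distance=0), ks=(4, 24), fraction=1.0
        )
        K = 4**4
        expected = K * (1 - (1 - 1 / K) ** 4000)
        assert curve["mean"].iloc[0] == pytest.approx(expected, rel=0.05)
        assert curve["mean"].iloc[0] < 0.1 * curve["mean"].iloc[-1]


class TestRequiredRandomBases:
    def test_threshold_scan(self):
        curve = pd.DataFrame(
            {
                "swept": [4, 8, 12, 16, 20, 24],
                "relative": [0.01, 0.60, 0.93, 0.96, 0.99, 1.0],
            }
        )
        curve.attrs["swept_variable"] = "random_bases"
        assert required_random_bases(curve, 0.95) == 16

    def test_flat_curve_returns_smallest_k(self):
        curve = pd.DataFrame({"swept": [4, 8], "relative": [1.0, 1.0]})
        curve.attrs["swept_variable"] = "random_bases"
        assert required_random_bases(curve) == 4

    def test_not_reached(self):
        curve = pd.DataFrame({"swept": [4, 8], "relative": [0.2, 0.9]})
        curve.attrs["swept_variable"] = "random_bases"
        assert required_random_bases(curve) is None

    def test_wrong_sweep_rejected(self):
        curve = pd.DataFrame({"swept": [1.0], "relative": [1.0]})
        curve.attrs["swept_variable"] = "coverage_fraction"
        with pytest.raises(ValueError):
            required_random_bases(curve)


class TestEstimators:
    def _clusters(self, config_overrides, seed):
        config = single_template_config(
            copies=400, seed=seed, insertion_rate=0.0, deletion_rate=0.0,
            n_rate=0.0, index_swap_rate=0.0, indices=("A",), **config_overrides
        )
        reads, truth = simulate(config)
        result = run_pipeline(reads, config.references, P2, mode="per_category",
                              fixed_selection="all")
        clusters = cluster_observations(result.observations, P2)
        return clusters, result.observations, truth

    def test_consensus_majority_and_tie_break(self):
        assert consensus_barcode(["AAC", "AAG", "ATC"]) == "AAC"
        assert consensus_barcode(["AT", "TA"]) == "AA"  # ties -> smallest base

    def test_zero_error_rate_is_zero(self):
        clusters, _, _ = self._clusters({"substitution_rate": 0.0}, seed=31)
        assert estimate_substitution_rate(clusters, SHORT_DESIGN) == 0.0

    def test_injected_substitution_rate_recovered(self):
        clusters, _, _ = self._clusters({"substitution_rate": 0.01}, seed=32)
        rate = estimate_substitution_rate(clusters, SHORT_DESIGN)
        assert rate == pytest.approx(0.01, rel=0.15)

    def test_miseq_like_rate_recovered(self):
        """At the measured 0.23–0.29% error window the estimate falls in a
        compatible range."""
        clusters, _, _ = self._clusters({"substitution_rate": 0.0025}, seed=33)
        rate = estimate_substitution_rate(clusters, SHORT_DESIGN)
        assert 0.0018 <= rate <= 0.0032

    def test_fixed_base_mismatch_rates_zero_without_errors(self):
        _, observations, _ = self._clusters({"substitution_rate": 0.0}, seed=34)
        rates = estimate_fixed_base_mismatch_rates(observations, SHORT_DESIGN)
        assert (rates == 0.0).all()

    def test_substitution_noise_gives_uniform_fixed_rates(self):
        """Pure substitution noise at rate e mismatches each fixed base at
        rate e, independent of position."""
        config = single_template_config(
            copies=2000, seed=35, substitution_rate=0.01, insertion_rate=0.0,
            deletion_rate=0.0, n_rate=0.0, index_swap_rate=0.0, indices=("A",),
        )
        reads, _ = simulate(config)
        observations = make_observations(reads)
        from digicount import extract_barcodes

        observations, _ = extract_barcodes(observations, SHORT_DESIGN)
        rates = estimate_fixed_base_mismatch_rates(observations, SHORT_DESIGN)
        assert rates.mean() == pytest.approx(0.01, rel=0.15)
        assert rates.max() - rates.min() < 0.01

    def test_indels_raise_downstream_fixed_rates(self):
        """Indel errors shift the frame, so fixed-base mismatch rates grow
        with distance from the sequencing primer site."""
        config = single_template_config(
            copies=2000, seed=36, substitution_rate=0.0, insertion_rate=0.005,
            deletion_rate=0.005, n_rate=0.0, index_swap_rate=0.0, indices=("A",),
        )
        reads, _ = simulate(config)
        observations = make_observations(reads)
        from digicount import extract_barcodes

        observations, _ = extract_barcodes(observations, SHORT_DESIGN)
        rates = estimate_fixed_base_mismatch_rates(observations, SHORT_DESIGN)
        assert rates.loc[28] > rates.loc[6]
        assert rates.sort_index().is_monotonic_increasing

    def test_base_composition_uniform(self):
        clusters, _, _ = self._clusters({"substitution_rate": 0.0}, seed=37)
        comp = estimate_base_composition(clusters, SHORT_DESIGN)
        assert np.allclose(comp.sum(axis=1), 1.0)
        assert comp.to_numpy().max() < 0.40 and comp.to_numpy().min() > 0.12

    def test_skewed_composition_recovered(self):
        config = single_template_config(
            copies=2000, seed=38, substitution_rate=0.0, insertion_rate=0.0,
            deletion_rate=0.0, n_rate=0.0, index_swap_rate=0.0, indices=("A",),
            composition=(0.17, 0.29, 0.29, 0.25),
        )
        reads, _ = simulate(config)
        result = run_pipeline(reads, config.references, P2, mode="per_category")
        clusters = cluster_observations(result.observations, P2)
        comp = estimate_base_composition(clusters, SHORT_DESIGN)
        assert comp["A"].mean() == pytest.approx(0.17, abs=0.02)
        assert comp["C"].mean() == pytest.approx(0.29, abs=0.02)

    def test_empty_cluster_set(self):
        assert estimate_base_composition([], SHORT_DESIGN).empty


def test_plot_curve_renders(clean_pipeline_obs):
    matplotlib = pytest.importorskip("matplotlib")
    matplotlib.use("Agg")
    from digicount.saturation import plot_curve

    curve = coverage_curve(clean_pipeline_obs, P2, fractions=(0.5, 1.0),
                           n_repeats=2, seed=0)
    ax = plot_curve(curve)
    assert ax.get_ylabel() == "number of clusters"
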