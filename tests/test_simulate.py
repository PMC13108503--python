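import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from netseg import (
    CohortSpec,
    default_parcellation,
    generate_cohort,
    generate_timeseries,
    pearson_adjacency,
    segregation_sweep,
    simulate_ss_study,
)
from netseg.connectivity import concatenate_runs
from netseg.simulate import (
    block_correlation_matrix,
    nearest_psd,
    null_cognition_spec,
)

SMALL = dict(n_rois=60, n_networks=4, n_volumes_per_run=200, n_runs=1)


class TestCohortSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_young=0),
            dict(age_range_old=(70.0, 70.0)),
            dict(rho_between_mean=-0.1),
            dict(rho_within_mean_old=0.1, rho_between_mean=0.3),
            dict(rho_within_sd_young=-0.01),
            dict(sex_proportion_female=(1.2, 0.5)),
            dict(missing_rate=1.5),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_young=25, n_old=20)
        p1, s1 = generate_cohort(spec, seed=11)
        p2, s2 = generate_cohort(spec, seed=11)
        assert p1.equals(p2)
        assert s1 == s2

    def test_ages_respect_group_ranges(self):
        spec = CohortSpec(n_young=40, n_old=40)
        pheno, _ = generate_cohort(spec, seed=3)
        young = pheno[pheno.age_group == "younger"]["age"]
        old = pheno[pheno.age_group == "older"]["age"]
        assert young.between(18, 34).all() and old.between(60, 89).all()
        assert pheno["group_relative_age"].between(0, 1).all()

    def test_null_cognition_model_shows_no_group_difference(self):
        """With all systematic effects zeroed, cognition is exchangeable
        between groups: a two-sample test stays non-significant in at least
        94% of seeds."""
        spec = null_cognition_spec(CohortSpec(missing_rate=0.0))
        rejections = 0
        for seed in range(100):
            pheno, _ = generate_cohort(spec, seed=seed)
            young = pheno[pheno.age_group == "younger"]["executive"]
            old = pheno[pheno.age_group == "older"]["executive"]
            if mannwhitneyu(young, old).pvalue < 0.05:
                rejections += 1
        assert rejections <= 6

    def test_latent_segregation_higher_in_young_across_seeds(self):
        """Default generative contrast (rho_w 0.45 vs 0.35) makes latent g
        separably higher in the younger group."""
        spec = CohortSpec()
        detected = 0
        for seed in range(100):
            _, states = generate_cohort(spec, seed=seed)
            gy = [s.g for s in states if s.group == "younger"]
            go = [s.g for s in states if s.group == "older"]
            if (np.mean(gy) > np.mean(go)
                    and mannwhitneyu(gy, go).pvalue < 0.05):
                detected += 1
        assert detected >= 95

    def test_missingness_leaves_cohort_draws_untouched(self):
        spec = CohortSpec(n_young=30, n_old=30)
        p_missing, _ = generate_cohort(spec, seed=5)
        p_full, _ = generate_cohort(
            CohortSpec(n_young=30, n_old=30, missing_rate=0.0), seed=5
        )
        # same draws wherever not masked
        obs = p_missing["executive"].notna()
        np.testing.assert_allclose(
            p_missing.loc[obs, "executive"], p_full.loc[obs, "executive"]
        )


class TestGenerateTimeseries:
    def test_equal_within_and_between_gives_near_zero_ss(self):
        from netseg import LatentSubjectState

        spec = CohortSpec(noise_sd=0.0, n_young=25, n_old=25, **SMALL)
        parc = default_parcellation(60, 4)
        vals = []
        for i in range(50):
            s = LatentSubjectState(
                subject=f"sub-{i}", index=i, group="younger",
                rho_within=0.3, rho_between=0.3, sex="female",
                site="site1", age=25.0,
            )
            run = generate_timeseries(s, parc, spec, seed=2)[0]
            W = pearson_adjacency(run)
            vals.append(segregation_sweep(W, parc, [0.15]).value(0.15))
        assert abs(np.nanmean(vals)) < 0.05

    def test_population_matrix_oracle_on_long_series(self):
        """A long series' empirical SS approaches the SS of the thresholded
        population correlation matrix itself."""
        spec = CohortSpec(
            rho_within_mean_young=0.9, rho_within_sd_young=0.0,
            rho_between_mean=0.0, noise_sd=0.0,
            n_rois=60, n_networks=4, n_volumes_per_run=5000, n_runs=1,
        )
        parc = default_parcellation(60, 4)
        _, states = generate_cohort(CohortSpec(
            n_young=1, n_old=1, rho_within_mean_young=0.9,
            rho_within_sd_young=0.0, rho_within_mean_old=0.9,
            rho_within_sd_old=0.0, rho_between_mean=0.0, noise_sd=0.0,
            **dict(SMALL, n_volumes_per_run=5000),
        ), seed=4)
        state = states[0]
        run = generate_timeseries(state, parc, spec, seed=4)[0]
        empirical = segregation_sweep(
            pearson_adjacency(run), parc, [0.15]
        ).value(0.15)
        pop = block_correlation_matrix(parc.labels_array(), 0.9, 0.0)
        np.fill_diagonal(pop, 0.0)
        from netseg import WeightedAdjacency

        population = segregation_sweep(
            WeightedAdjacency(np.clip(pop, 0, None)), parc, [0.15]
        ).value(0.15)
        assert empirical == pytest.approx(population, abs=0.05)

    def test_sample_correlation_converges_to_specified_matrix(self):
        spec = CohortSpec(
            rho_within_mean_young=0.5, rho_within_sd_young=0.0,
            rho_between_mean=0.2, noise_sd=0.0,
            n_rois=40, n_networks=4, n_volumes_per_run=20000, n_runs=1,
        )
        parc = default_parcellation(40, 4)
        _, states = generate_cohort(
            CohortSpec(n_young=1, n_old=1, rho_within_mean_young=0.5,
                       rho_within_sd_young=0.0, rho_between_mean=0.2,
                       rho_within_mean_old=0.5, rho_within_sd_old=0.0),
            seed=6,
        )
        run = generate_timeseries(states[0], parc, spec, seed=6)[0]
        emp = np.corrcoef(run.data, rowvar=False)
        target = block_correlation_matrix(parc.labels_array(), 0.5, 0.2)
        assert np.max(np.abs(emp - target)) < 0.05

    def test_monotone_in_contrast_at_fixed_sum(self):
        """At fixed rho_w + rho_b, widening the contrast strictly increases
        expected empirical global SS (3-point grid, 50 subjects each)."""
        means = []
        for rw, rb in [(0.36, 0.24), (0.40, 0.20), (0.44, 0.16)]:
            spec = CohortSpec(
                n_young=25, n_old=25,
                rho_within_mean_young=rw, rho_within_mean_old=rw,
                rho_within_sd_young=0.0, rho_within_sd_old=0.0,
                rho_between_mean=rb, noise_sd=0.3, **SMALL,
            )
            parc = default_parcellation(60, 4)
            _, states = generate_cohort(spec, seed=8)
            vals = [
                segregation_sweep(
                    pearson_adjacency(
                        generate_timeseries(s, parc, spec, seed=8)[0]
                    ),
                    parc, [0.15],
                ).value(0.15)
                for s in states
            ]
            means.append(np.nanmean(vals))
        assert means[0] < means[1] < means[2]

    def test_parcellation_size_mismatch_rejected(self):
        spec = CohortSpec(**SMALL)
        _, states = generate_cohort(CohortSpec(n_young=1, n_old=1), seed=1)
        with pytest.raises(ValueError, match="ROIs"):
            generate_timeseries(states[0], default_parcellation(200, 7),
                                spec, seed=1)


class TestSeedIsolation:
    def test_cohort_untouched_by_timeseries_stream(self):
        spec = CohortSpec(n_young=4, n_old=4, **SMALL)
        p_direct, _ = generate_cohort(spec, seed=9)
        p_full, _, _ = simulate_ss_study(spec, seed=9)
        assert p_direct.equals(p_full)

    def test_runs_differ_across_run_index_and_subjects(self):
        spec = CohortSpec(n_young=2, n_old=2, **dict(SMALL, n_runs=2))
        parc = default_parcellation(60, 4)
        _, states = generate_cohort(spec, seed=10)
        r0, r1 = generate_timeseries(states[0], parc, spec, seed=10)
        other = generate_timeseries(states[1], parc, spec, seed=10)[0]
        assert not np.allclose(r0.data, r1.data)
        assert not np.allclose(r0.data, other.data)


def test_nearest_psd_repairs_indefinite_matrix():
    A = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
    assert np.linalg.eigvalsh(A).min() < 0
    R = nearest_psd(A)
    assert np.linalg.eigvalsh(R).min() >= 0
    assert np.max(np.abs(R - A)) < 0.5


def test_study_simulation_is_deterministic():
    spec = CohortSpec(n_young=3, n_old=3, **SMALL)
    a = simulate_ss_study(spec, seed=12)
    b = simulate_ss_study(spec, seed=12)
    assert a[0].equals(b[0]) and a[1].equals(b[1])


def test_concatenated_default_run_layout_has_392_volumes():
    spec = CohortSpec(n_young=1, n_old=1)
    parc = default_parcellation(200, 7)
    _, states = generate_cohort(spec, seed=13)
    runs = generate_timeseries(states[0], parc, spec, seed=13)
    ts = concatenate_runs(runs, 5, 200)
    assert ts.n_volumes == 392
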