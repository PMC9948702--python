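"""The pool-well cycle engine: sampling, phases, lineages, extinction."""

import itertools

import numpy as np
import pytest

from poolwell.core import STRAINS, GrowthModelParams, Strain, default_params
from poolwell.distributions import point_mass, uniform_distribution
from poolwell.engine import (
    ConstantSchedule,
    CycleConfig,
    FeedbackSchedule,
    normalize_to_pool,
    run_lineage,
    run_well_phase,
    sample_community,
    sample_ecologies,
)

UNIFORM = uniform_distribution()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"K": -1.0},
            {"n_wells": 0},
            {"d": 0.5},
            {"dt": 0.0},
            {"nonviable_mode": "weird"},
            {"inoculum_mode": "weird"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CycleConfig(**kwargs)

    def test_default_inoculum_is_half_capacity(self):
        assert CycleConfig(K=10).total_inoculum == 5.0
        assert CycleConfig(K=10, inoculum_density=2.0).total_inoculum == 2.0


class TestEcologySampling:
    def test_point_mass_fills_all_wells_with_one_ecology(self, rng):
        idx = sample_ecologies(point_mass(16), 96, rng)
        assert len(idx) == 96
        assert (idx == 16).all()

    def test_uniform_sampling_frequencies_converge(self, rng):
        idx = sample_ecologies(UNIFORM, 100_000, rng)
        freqs = np.bincount(idx - 1, minlength=16) / 100_000
        assert np.abs(freqs - 0.0625).max() < 0.01


class TestCommunitySampling:
    def test_monoculture_pool_yields_half_capacity_of_one_strain(self, rng):
        dens, members = sample_community(np.array([1.0, 0, 0, 0]), 10.0, 4, rng)
        assert dens.tolist() == [5.0, 0, 0, 0]
        assert members == {Strain.ADE}

    def test_total_inoculum_is_always_half_capacity(self, rng):
        for _ in range(50):
            dens, _ = sample_community(np.full(4, 0.25), 10.0, 4, rng)
            assert dens.sum() == pytest.approx(5.0)

    def test_expected_densities_are_k_over_8_each(self, rng):
        total = np.zeros(4)
        n = 4000
        for _ in range(n):
            dens, _ = sample_community(np.full(4, 0.25), 10.0, 4, rng)
            total += dens
        assert np.allclose(total / n, 1.25, atol=0.05)

    def test_ordered_slot_assignments_number_256(self):
        # 4 slots x 4 strains: the ordered assignment space behind the
        # community sampler has exactly 4^4 distinct outcomes
        outcomes = set(itertools.product(range(4), repeat=4))
        assert len(outcomes) == 256

    def test_extinct_pool_cannot_be_sampled(self, rng):
        with pytest.raises(ValueError):
            sample_community(np.zeros(4), 10.0, 4, rng)


class TestWellPhase:
    def test_pure_his_pool_under_uniform_ecologies_dies_at_the_bound(self, rng):
        cfg = CycleConfig()
        deaths = [
            run_well_phase(
                np.array([0, 0, 1.0, 0]), UNIFORM, cfg, default_params(), rng
            )[1]
            for _ in range(100)
        ]
        # per-well death is Bernoulli(14/16); 100 phases x 96 wells
        assert np.mean(deaths) == pytest.approx(0.875, abs=0.02)

    def test_rich_point_mass_ecology_supports_every_well(self, rng):
        cfg = CycleConfig()
        agg, death, hist = run_well_phase(
            np.full(4, 0.25), point_mass(16), cfg, default_params(), rng
        )
        assert death == 0.0
        assert hist[15] == 96 and hist.sum() == 96
        assert agg.sum() > 0

    def test_histogram_counts_sampled_ecologies(self, rng):
        cfg = CycleConfig(n_wells=10)
        _, _, hist = run_well_phase(
            np.full(4, 0.25), UNIFORM, cfg, default_params(), rng
        )
        assert hist.sum() == 10

    def test_nonviable_modes_agree_on_death_rate(self):
        cfg_log = CycleConfig()
        cfg_exp = CycleConfig(nonviable_mode="exponential")
        p = default_params()
        out = []
        for cfg in (cfg_log, cfg_exp):
            rng = np.random.default_rng(5)
            out.append(
                run_well_phase(np.full(4, 0.25), UNIFORM, cfg, p, rng)[1]
            )
        assert out[0] == out[1]


class TestNormalization:
    def test_frequencies_from_aggregated_densities(self):
        pool = normalize_to_pool(np.array([2.0, 2.0, 4.0, 2.0]), 1.0)
        assert np.allclose(pool.frequencies, [0.2, 0.2, 0.4, 0.2])
        assert pool.total == pytest.approx(1.0)

    def test_zero_aggregate_is_extinct(self):
        assert normalize_to_pool(np.zeros(4)).extinct


def _equal_rate_params():
    return GrowthModelParams(
        base_rates=(1.0, 1.0, 1.0, 1.0),
        crossfeed_factor=1.0,
        pool_rates=(1.0, 1.0, 1.0, 1.0),
    )


class TestLineage:
    def test_zero_cycles_yield_only_the_initial_record(self):
        res = run_lineage(
            CycleConfig(n_cycles=0), default_params(),
            ConstantSchedule(UNIFORM),
        )
        assert len(res.records) == 1
        assert not res.extinct
        assert np.allclose(res.records[0].strain_proportions, 0.25)

    def test_same_seed_reproduces_bit_identically(self):
        cfg = CycleConfig(n_cycles=4, seed=42)
        a = run_lineage(cfg, default_params(), ConstantSchedule(UNIFORM))
        b = run_lineage(cfg, default_params(), ConstantSchedule(UNIFORM))
        assert (a.proportions_matrix() == b.proportions_matrix()).all()
        assert (a.death_rates() == b.death_rates()).all()

    def test_symmetric_rates_in_rich_wells_keep_equal_proportions(self):
        # with identical rates and a rich point-mass ecology nothing
        # distinguishes the strains: inoculum sampling jitters single
        # runs, but the replicate-mean proportions stay at 0.25
        from poolwell.experiments import Scenario, run_replicates

        sc = Scenario(
            name="symmetric",
            config=CycleConfig(n_cycles=5),
            params=_equal_rate_params(),
            schedule_factory=lambda: ConstantSchedule(point_mass(16)),
        )
        summary = run_replicates(sc, n_runs=60, seed=8)
        assert np.abs(summary.mean_proportions - 0.25).max() < 0.02
        assert (summary.mean_death_rate == 0).all()

    def test_proportions_form_a_simplex_until_extinction(self):
        res = run_lineage(
            CycleConfig(n_cycles=6, seed=3), default_params(),
            ConstantSchedule(UNIFORM),
        )
        for rec in res.records:
            p = rec.strain_proportions
            assert (p >= 0).all()
            assert p.sum() == pytest.approx(1.0) or (p == 0).all()

    def test_capacity_invariance_under_scaled_inoculum(self):
        # with the inoculum pinned to K/2, substituting u = x/K removes
        # K from the within-well system entirely: proportions must not
        # depend on the carrying capacity (K scaled by a power of two
        # keeps even the floating-point arithmetic identical)
        runs = [
            run_lineage(
                CycleConfig(n_cycles=4, seed=11, K=K),
                default_params(),
                ConstantSchedule(UNIFORM),
            )
            for K in (10.0, 160.0)
        ]
        assert np.allclose(
            runs[0].proportions_matrix(), runs[1].proportions_matrix(),
            rtol=1e-12, atol=1e-14,
        )

    def test_pure_his_pool_in_barren_wells_goes_extinct_at_once(self):
        # a pure-HIS pool inoculates only all-HIS communities, none of
        # which survive the metabolite-free ecology: every well dies in
        # cycle 1 and the lineage is extinct thereafter
        res = run_lineage(
            CycleConfig(n_cycles=5, seed=0, initial_proportions=(0, 0, 1.0, 0)),
            default_params(),
            ConstantSchedule(point_mass(1)),
        )
        assert res.extinct
        assert res.extinction_cycle == 1
        assert res.records[1].death_rate == 1.0
        for rec in res.records[2:]:
            assert (rec.strain_proportions == 0).all()
            assert rec.death_rate == 1.0

    def test_feedback_schedule_switches_on_at_start_cycle(self):
        sched = FeedbackSchedule(UNIFORM, start_cycle=3)
        freqs = np.array([0, 0, 1.0, 0])
        assert sched(2, freqs) is UNIFORM
        assert sched(3, freqs).prob(3) == pytest.approx(1.0)
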