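"""Synthetic morphometry, Poisson drive, allocation protocols, datasets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twostage as ts
from twostage.integration import IntegrationMode, compare_groups
from twostage.synth import (
    ClassMoments,
    MorphometryDistributions,
    allocate_dispersed,
    allocate_grouped,
    background_firing_rate,
    generate_poisson_train,
    protocol_grid_allocations,
    sample_morphology,
    surrogate_firing_dataset,
)


class TestMorphometry:
    def test_degenerate_mixture_all_sublinear(self):
        dist = MorphometryDistributions(supra_fraction=0.0)
        branches = sample_morphology(dist, 5, seed=0)
        assert len(branches) == 5
        assert all(b.mode is IntegrationMode.SUBLINEAR for b in branches)

    def test_seed_determinism(self):
        a = sample_morphology(MorphometryDistributions(), 40, seed=3)
        b = sample_morphology(MorphometryDistributions(), 40, seed=3)
        assert [(x.length, x.diam) for x in a] == [(y.length, y.diam) for y in b]

    def test_diameter_cap_enforced(self):
        branches = sample_morphology(MorphometryDistributions(), 500, seed=1)
        assert max(b.diam for b in branches) <= 1.2

    def test_monte_carlo_volume_ratio_matches_configured_moments(self):
        # empirical supra/sub mean-volume ratio within 10% of the ratio
        # implied by the configured log-normal moments
        dist = MorphometryDistributions()
        branches = sample_morphology(dist, 1000, seed=5)
        sup = [b.volume for b in branches if b.mode is IntegrationMode.SUPRALINEAR]
        sub = [b.volume for b in branches if b.mode is IntegrationMode.SUBLINEAR]
        implied = dist.supralinear.mean_volume(dist.diam_cap) / dist.sublinear.mean_volume(
            dist.diam_cap
        )
        assert np.mean(sup) / np.mean(sub) == pytest.approx(implied, rel=0.10)

    def test_group_separation_significant_at_n40(self):
        # supralinear branches: larger volume, smaller input resistance
        rng = np.random.default_rng(2)
        dist = MorphometryDistributions()
        sup, sub = [], []
        while len(sup) < 40 or len(sub) < 40:
            for b in sample_morphology(dist, 200, seed=int(rng.integers(2**31))):
                (sup if b.mode is IntegrationMode.SUPRALINEAR else sub).append(b)
        vol_s, vol_u = [b.volume for b in sup[:40]], [b.volume for b in sub[:40]]
        rin_s, rin_u = [b.r_in for b in sup[:40]], [b.r_in for b in sub[:40]]
        assert np.mean(vol_s) > np.mean(vol_u)
        assert np.mean(rin_s) < np.mean(rin_u)
        assert compare_groups(vol_s, vol_u)[1] < 0.05
        assert compare_groups(rin_s, rin_u)[1] < 0.05

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MorphometryDistributions(supra_fraction=1.5)
        with pytest.raises(ValueError):
            MorphometryDistributions(
                supralinear=ClassMoments(110.0, -0.1, 0.9, 0.15)
            )
        with pytest.raises(ValueError):
            sample_morphology(MorphometryDistributions(), 1, seed=0)


class TestPoissonTrain:
    def test_zero_rate_gives_empty_train(self):
        train = generate_poisson_train(0.0, 1000.0, seed=0)
        assert len(train) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_poisson_train(-1.0, 1000.0, seed=0)

    def test_seed_reproducibility(self):
        t1 = generate_poisson_train(50.0, 1000.0, seed=9)
        t2 = generate_poisson_train(50.0, 1000.0, seed=9)
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_times_sorted_within_duration(self):
        t = generate_poisson_train(80.0, 500.0, seed=4)
        assert np.all(np.diff(t.times) >= 0)
        assert t.times.min() >= 0 and t.times.max() < 500.0

    def test_count_statistics_match_poisson_law(self):
        # mean and variance of event counts within 3 standard errors
        # at 1e4 replicates (Poisson: mean = var = rate * duration)
        counts = np.array(
            [len(generate_poisson_train(50.0, 1000.0, seed=s)) for s in range(10_000)]
        )
        lam = 50.0
        se_mean = np.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 3 * se_mean
        # SE of the sample variance of a Poisson: sqrt((2 lam^2 + lam)/n)
        se_var = np.sqrt((2 * lam**2 + lam) / len(counts))
        assert abs(counts.var() - lam) < 3 * se_var


class TestAllocations:
    def test_minimal_dispersed_allocation(self, morph):
        (alloc,) = allocate_dispersed(morph, 2, step=2, repeats=1, seed=0)
        assert alloc.n_touched == 1
        assert alloc.vector.sum() == 2

    def test_dispersed_60_step_10_touches_six_dendrites(self, morph):
        for alloc in allocate_dispersed(morph, 60, step=10, repeats=5, seed=1):
            assert alloc.n_touched == 6
            assert set(alloc.counts.values()) == {10}

    def test_single_dendrite_forced_stacking(self):
        tiny = ts.sample_morphology(ts.MorphometryDistributions(), 2, seed=0)[:1]
        (alloc,) = allocate_dispersed(tiny, 4, step=2, repeats=1, seed=0)
        assert alloc.vector.tolist() == [4]

    def test_grouped_60_by_20_gives_three_dendrites(self, morph):
        for alloc in allocate_grouped(morph, 60, sclu=20, repeats=5, seed=1):
            assert alloc.n_touched == 3
            assert set(alloc.counts.values()) == {20}

    def test_grouped_remainder_rule(self, morph):
        (alloc,) = allocate_grouped(morph, 30, sclu=20, repeats=1, seed=2)
        assert alloc.n_touched == 2
        assert sorted(alloc.counts.values()) == [10, 20]

    def test_grouped_single_group(self, morph):
        (alloc,) = allocate_grouped(morph, 60, sclu=60, repeats=1, seed=0)
        assert alloc.n_touched == 1

    def test_sclu_above_nsyn_rejected(self, morph):
        with pytest.raises(ValueError):
            allocate_grouped(morph, 10, sclu=20, repeats=1, seed=0)

    def test_default_repeat_structure_is_five_times_n_dendrites(self, morph):
        allocs = allocate_dispersed(morph, 10, step=5, seed=0)
        assert len(allocs) == 5 * len(morph)

    @settings(max_examples=30, deadline=None)
    @given(
        nsyn=st.integers(2, 60),
        step=st.sampled_from([2, 5, 10]),
        seed=st.integers(0, 1000),
    )
    def test_conservation_and_spread_invariants(self, nsyn, step, seed):
        morph = ts.default_morphology(0)
        for alloc in allocate_dispersed(morph, nsyn, step, repeats=3, seed=seed):
            assert alloc.vector.sum() == nsyn
            assert np.all(alloc.vector >= 0)
            assert alloc.n_touched >= nsyn / 10

    def test_seed_determinism(self, morph):
        a = allocate_dispersed(morph, 20, 2, repeats=4, seed=5)
        b = allocate_dispersed(morph, 20, 2, repeats=4, seed=5)
        assert all(np.array_equal(x.vector, y.vector) for x, y in zip(a, b))


class TestSurrogateDataset:
    def test_empty_allocation_list(self, morph):
        ds = surrogate_firing_dataset(morph, [], seed=0)
        assert len(ds) == 0

    def test_zero_synapses_silent(self, morph):
        alloc = ts.SynapticAllocation(np.zeros(len(morph), int), "dispersed", 0)
        ds = surrogate_firing_dataset(morph, [alloc], seed=0)
        assert ds.rates[0] == 0.0

    def test_determinism_and_schema(self, morph):
        allocs = allocate_dispersed(morph, 20, 2, repeats=4, seed=1)
        d1 = surrogate_firing_dataset(morph, allocs, trials=2, seed=3)
        d2 = surrogate_firing_dataset(morph, allocs, trials=2, seed=3)
        np.testing.assert_array_equal(d1.rates, d2.rates)
        df = d1.to_frame()
        assert {"protocol", "nsyn", "rate_hz"} <= set(df.columns)
        assert (df["nsyn"] == 20).all()

    def test_dispersed_beats_grouped_at_matched_counts(self, morph):
        # the bimodal reference cell prefers spatially dispersed input
        for nsyn in (20, 40, 60):
            disp = allocate_dispersed(morph, nsyn, 2, repeats=20, seed=7)
            grp = allocate_grouped(morph, nsyn, min(20, nsyn), repeats=20, seed=7)
            dd = surrogate_firing_dataset(morph, disp, trials=1, seed=8, duration=500)
            dg = surrogate_firing_dataset(morph, grp, trials=1, seed=8, duration=500)
            assert np.median(dd.rates) > np.median(dg.rates)
            assert dd.rates.mean() >= dg.rates.mean()

    def test_protocol_grid_composition(self, morph):
        allocs = protocol_grid_allocations(
            morph, seed=0, nsyn_values=(20, 40), grid_reps=2, challenge_reps=3
        )
        assert all(a.vector.sum() in (20, 40) for a in allocs)
        assert {a.protocol for a in allocs} == {"dispersed", "grouped"}

    def test_background_protocol_rate_is_low(self, morph):
        # sparse in-vivo-like drive keeps the cell at a few Hz, far from gamma
        r = np.mean([background_firing_rate(morph, s, duration=2000.0) for s in range(4)])
        assert 0.5 < r < 8.0
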