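"""Maturation simulator: conservation laws, oracles and scenario behaviour."""

import numpy as np
import pytest
from scipy.stats import binom

from coremature.master_equation import (
    cp_processed_distribution,
    intermediate_fraction_exact,
    time_of_mean_maturation,
)
from coremature.simulate import (
    CROSS_CUT,
    INTACT,
    PROCESSED,
    HPState,
    RateParameters,
    SubunitSpec,
    build_topology,
    dimerization_rate,
    preformed_cp_pool,
    processed_count_distribution,
    simulate,
)
from coremature.scenarios import run_scenario
from coremature.synth import gen_mixture_hp_pool

WT = SubunitSpec()
TTOA = SubunitSpec(catalytic=False)
EL = SubunitSpec(loop_variant="el")
SL = SubunitSpec(loop_variant="sl")


def tv_distance(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


class TestTopology:
    def test_intra_only_two_disjoint_7_cycles(self):
        g = build_topology("intra_only")
        assert g.number_of_edges() == 14
        assert all(d == 2 for _, d in g.degree)
        assert not any(a < 7 <= b or b < 7 <= a for a, b in g.edges)

    def test_intra_plus_one_cross_per_site_degree_3(self):
        g = build_topology("intra_plus_cross")
        assert all(d == 3 for _, d in g.degree)

    def test_malformed_cross_pairs_rejected(self):
        with pytest.raises(ValueError):
            build_topology("intra_plus_cross", cross_pairs=[(0, 14)])
        with pytest.raises(ValueError):
            build_topology("intra_plus_cross", cross_pairs=[(3, 3)])

    def test_geometry_derived_edges_accepted(self, ideal_geometry):
        from coremature.geometry import LoopSpanModel, feasible_cross_edges

        sites, anchors = ideal_geometry
        ids = sites.ordered_ids()
        edges = feasible_cross_edges(sites, anchors, LoopSpanModel())
        pairs = [(ids.index(a), ids.index(b)) for a, b in edges]
        g = build_topology("intra_plus_cross", cross_pairs=pairs)
        assert g.number_of_edges() == 14 + len(pairs)


class TestDimerizationRate:
    def test_all_wildtype_gives_base_rate(self):
        p = RateParameters(k_dimer0=0.7)
        assert dimerization_rate(HPState.uniform(WT), HPState.uniform(WT), p) == pytest.approx(0.7)

    def test_one_sided_extended_loops_unpenalized(self):
        """An extended loop meeting a normal-loop partner dimerizes at base rate."""
        p = RateParameters(k_dimer0=1.0)
        hp_el = HPState.uniform(EL)
        hp_wt = HPState.uniform(WT)
        assert dimerization_rate(hp_el, hp_wt, p) == pytest.approx(1.0)

    def test_two_sided_extended_loops_strongly_penalized(self):
        p = RateParameters(k_dimer0=1.0, el_penalty=0.01)
        pool = gen_mixture_hp_pool(0.5, 40, EL, TTOA, seed=0)
        rates = [dimerization_rate(a, b, p) for a, b in zip(pool[::2], pool[1::2])]
        assert max(rates) <= 0.01  # every pair has min(nA_el, nB_el) >= 1 here or is 0

    def test_penalty_monotone_in_min_extended_count(self):
        p = RateParameters(k_dimer0=1.0, el_penalty=0.1)

        def hp_with_el(n):
            specs = [EL] * n + [WT] * (7 - n)
            from coremature.simulate import SubunitState

            return HPState(subunits=[SubunitState(spec=s) for s in specs])

        rates = [dimerization_rate(hp_with_el(n), hp_with_el(3), p) for n in range(4)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_truncation_accelerates_dimerization(self):
        p = RateParameters()
        d23 = HPState.uniform(SubunitSpec(truncation=23))
        assert dimerization_rate(d23, d23, p) > dimerization_rate(
            HPState.uniform(WT), HPState.uniform(WT), p
        )


class TestSimulateInvariants:
    def test_all_ttoa_pool_never_processes(self):
        pool = [HPState.uniform(TTOA) for _ in range(20)]
        traj = simulate(pool, RateParameters(), model="cooperative", t_end=50.0, seed=1)
        assert np.nansum(traj.processed_counts) == 0

    def test_mass_conservation_along_trajectory(self):
        pool = [HPState.uniform(WT) for _ in range(30)]
        traj = simulate(pool, RateParameters(), t_end=60.0, seed=2)
        for ti, t in enumerate(traj.record_times):
            n_cp = int((traj.cp_formation_times <= t).sum())
            assert 7 * traj.free_hp[ti] + 14 * n_cp == 7 * traj.n_hp_initial

    def test_processed_count_monotone_per_cp(self):
        pool = preformed_cp_pool(50)
        traj = simulate(pool, RateParameters(), t_end=30.0, seed=3)
        diffs = np.diff(traj.processed_counts, axis=0)
        assert np.nanmin(diffs) >= 0

    def test_ttoa_subunits_reach_cross_cut_but_never_processed(self):
        pool = gen_mixture_hp_pool(0.5, 60, WT, TTOA, seed=4)
        traj = simulate(pool, RateParameters(), t_end=100.0, seed=5, record_events=True)
        states = [s for cp in traj.cps for s in cp.subunits]
        dead = [s for s in states if not s.spec.catalytic]
        assert all(s.propeptide != PROCESSED for s in dead)
        assert any(s.propeptide == CROSS_CUT for s in dead)  # terminal cross-cut products

    def test_cross_cut_events_audited_against_replay(self):
        """Each cross-cut happens only with a processed competent neighbour."""
        pool = gen_mixture_hp_pool(0.5, 40, WT, TTOA, seed=6)
        topo = build_topology("intra_plus_cross")
        traj = simulate(pool, RateParameters(), t_end=100.0, seed=7, topology=topo,
                        record_events=True)
        assert traj.events, "expected at least one event"
        state = {}  # (cp, site) -> propeptide state
        specs = {
            (ci, si): s.spec
            for ci, cp in enumerate(traj.cps)
            for si, s in enumerate(cp.subunits)
        }
        for ev in sorted(traj.events, key=lambda e: e.time):
            if ev.kind == "cross_cut":
                n_active = sum(
                    state.get((ev.cp_index, j)) == PROCESSED and specs[(ev.cp_index, j)].catalytic
                    for j in topo.neighbors(ev.site)
                )
                assert n_active >= 1
                assert ev.n_processed_neighbors == n_active
                state[(ev.cp_index, ev.site)] = CROSS_CUT
            else:
                assert specs[(ev.cp_index, ev.site)].catalytic
                state[(ev.cp_index, ev.site)] = PROCESSED

    def test_deterministic_given_seed(self):
        pool = [HPState.uniform(WT) for _ in range(20)]
        t1 = simulate(pool, RateParameters(), t_end=40.0, seed=11)
        t2 = simulate(pool, RateParameters(), t_end=40.0, seed=11)
        np.testing.assert_array_equal(t1.processed_counts, t2.processed_counts)
        np.testing.assert_array_equal(t1.cp_formation_times, t2.cp_formation_times)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            simulate([HPState.uniform(WT)], RateParameters(), model="magic", t_end=1.0)

    def test_cooperative_requires_fast_at_least_slow(self):
        bad = RateParameters(k_auto_slow=1.0, k_auto_fast=0.1)
        with pytest.raises(ValueError, match="k_auto_fast"):
            simulate([HPState.uniform(WT)], bad, model="cooperative", t_end=1.0)


class TestOracleEquivalence:
    def test_independent_model_matches_binomial(self):
        """Processed counts of pre-formed CPs are Binomial(14, 1 - e^{-kt})."""
        k, t_end, n = 0.1, 10.0, 3000
        traj = simulate(
            preformed_cp_pool(n),
            RateParameters(k_auto_slow=k, k_cross=0.0),
            model="independent",
            t_end=t_end,
            n_record_times=3,
            seed=21,
        )
        dist = processed_count_distribution(traj, t_end)
        ref = binom.pmf(np.arange(15), 14, 1 - np.exp(-k * t_end))
        assert tv_distance(dist.histogram, ref) < 0.05

    def test_cooperative_reduces_to_independent_when_rates_equal(self):
        k, t_end, n = 0.1, 10.0, 3000
        indep = RateParameters(k_auto_slow=k, k_cross=0.0)
        coop = RateParameters(k_auto_slow=k, k_auto_fast=k, k_cross=0.0)
        d1 = processed_count_distribution(
            simulate(preformed_cp_pool(n), indep, model="independent",
                     t_end=t_end, n_record_times=3, seed=22),
            t_end,
        )
        d2 = processed_count_distribution(
            simulate(preformed_cp_pool(n), coop, model="cooperative",
                     t_end=t_end, n_record_times=3, seed=22),
            t_end,
        )
        assert tv_distance(d1.histogram, d2.histogram) < 0.05

    def test_cooperative_matches_master_equation_on_ring_topology(self):
        """Event-driven runs agree with exact master-equation integration."""
        k_slow, ratio, n = 0.05, 30.0, 3000
        k_fast = k_cross = k_slow * ratio
        t_star = time_of_mean_maturation(k_slow, k_fast, k_cross)
        topo = build_topology("intra_only")
        traj = simulate(
            preformed_cp_pool(n, topology=topo),
            RateParameters(k_auto_slow=k_slow, k_auto_fast=k_fast, k_cross=k_cross),
            model="cooperative",
            t_end=t_star,
            n_record_times=2,
            seed=23,
            topology=topo,
        )
        dist = processed_count_distribution(traj, t_star)
        exact = cp_processed_distribution(k_slow, k_fast, k_cross, t_star)
        assert dist.mean_processed == pytest.approx(7.0, abs=0.3)
        assert tv_distance(dist.histogram, exact) < 0.05


class TestProcessedCountDistribution:
    def test_fully_matured_population_point_mass_at_14(self):
        traj = simulate(
            preformed_cp_pool(50),
            RateParameters(k_auto_slow=10.0, k_auto_fast=10.0),
            t_end=50.0,
            n_record_times=3,
            seed=31,
        )
        dist = processed_count_distribution(traj, 50.0)
        assert dist.histogram[14] == 1.0
        assert dist.intermediate_fraction == 0.0

    def test_independent_intermediate_fraction_at_half_processing(self):
        """At p = 1/2 the binomial puts ~0.99988 of mass on 1..13."""
        k = 0.1
        t_half = np.log(2) / k
        traj = simulate(
            preformed_cp_pool(4000),
            RateParameters(k_auto_slow=k, k_cross=0.0),
            model="independent",
            t_end=t_half,
            n_record_times=2,
            seed=32,
        )
        dist = processed_count_distribution(traj, t_half)
        expected = 1 - 2 * 0.5**14
        assert dist.intermediate_fraction == pytest.approx(expected, abs=0.003)
        assert np.argmax(dist.histogram) == 7

    def test_no_cps_flags_empty(self):
        pool = [HPState.uniform(WT) for _ in range(4)]
        params = RateParameters(k_dimer0=0.0)
        traj = simulate(pool, params, t_end=5.0, seed=33)
        dist = processed_count_distribution(traj, 5.0)
        assert dist.empty and dist.n_cps == 0

    def test_cooperativity_lowers_intermediate_fraction(self):
        """At matched mean maturation the cooperative model shows fewer
        intermediates than the independent one (all-or-none signature)."""
        k_slow = 0.05
        ratio = 100.0
        t_star = time_of_mean_maturation(k_slow, k_slow * ratio, k_slow * ratio)
        topo = build_topology("intra_only")
        traj = simulate(
            preformed_cp_pool(2000, topology=topo),
            RateParameters(k_auto_slow=k_slow, k_auto_fast=k_slow * ratio, k_cross=k_slow * ratio),
            model="cooperative",
            t_end=t_star,
            n_record_times=2,
            seed=34,
            topology=topo,
        )
        dist = processed_count_distribution(traj, t_star)
        independent_value = 1 - 2 * 0.5**14
        assert dist.intermediate_fraction < independent_value
        exact = intermediate_fraction_exact(k_slow, k_slow * ratio, k_slow * ratio, t_star)
        assert dist.intermediate_fraction == pytest.approx(exact, abs=0.05)


class TestScenarios:
    def test_wildtype_mature_cp_rises_monotonically(self):
        rep = run_scenario("wt_30C", n_hp=80, seed=41)
        mature = rep.timecourse["cp_fully_matured"].to_numpy()
        assert (np.diff(mature) >= 0).all()
        assert mature[-1] > 0

    def test_truncation_exposes_preholo_pool(self):
        """Fast dimerization + slow first cut make the pre-holo CP visible."""
        wt = run_scenario("wt_30C", n_hp=80, seed=42)
        d23 = run_scenario("delta23", n_hp=80, seed=42)
        assert d23.timecourse["cp_preholo"].max() > wt.timecourse["cp_preholo"].max()

    def test_shortened_loop_self_dimerization_below_5pct_of_wt(self):
        wt = run_scenario("wt_30C", n_hp=80, seed=43)
        sl = run_scenario("sl1_selfdimer", n_hp=80, seed=43)
        assert sl.timecourse["cp_total"].iloc[-1] <= 0.05 * max(
            wt.timecourse["cp_total"].iloc[-1], 1
        )

    def test_cold_reconstitution_arrests_dimerization(self):
        rep = run_scenario("wt_4C", n_hp=80, seed=44)
        assert rep.timecourse["cp_total"].iloc[-1] == 0

    def test_extended_loop_dilution_rescues_cp_yield(self):
        """1:7 el:TtoA mixtures out-assemble 1:1 mixtures."""
        one_one = run_scenario("el1_ttoa_1to1", n_hp=120, seed=45)
        one_seven = run_scenario("el1_ttoa_1to7", n_hp=120, seed=45)
        assert (
            one_seven.timecourse["cp_total"].iloc[-1]
            > one_one.timecourse["cp_total"].iloc[-1]
        )

    def test_premixed_hp_cross_interface_cutting(self):
        """HP(sl1) x HP(d23-TtoA) premix forms CPs whose dead subunits get
        cross-cut across the dimer interface."""
        rep = run_scenario(
            "sl1_delta23ttoa_premix", n_hp=60, seed=46, record_events=True
        )
        assert rep.timecourse["cp_total"].iloc[-1] > 0
        cross_cuts = [e for e in rep.trajectories.events if e.kind == "cross_cut"]
        dead_cut = [
            e
            for e in cross_cuts
            if not rep.trajectories.cps[e.cp_index].subunits[e.site].spec.catalytic
        ]
        assert dead_cut, "expected cross-cutting of catalytically dead subunits"

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            run_scenario("nope")
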