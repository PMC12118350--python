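"""Screening protocols: enumeration, feasibility, experiments, competition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from admixscreen.ags import generate_random_graph
from admixscreen.landscape import build_hex_landscape
from admixscreen.protocols import (
    PROTOCOLS,
    ExperimentSpec,
    FeasibilityCriterion,
    apply_feasibility,
    criterion_grid,
    draw_randomized_experiment,
    draw_systematic_experiment,
    enumerate_ags_nonrotating,
    enumerate_ags_rotating,
    filter_distal,
    model_competition,
    run_experiment,
    ssl_sampling_frame,
    systematic_experiment_grid,
)
from admixscreen.qpadm import QpAdmModel, QpAdmResult


def fake_result(model, p=0.5, weights=None, se=None):
    n = model.n_way
    w = np.array(weights if weights is not None else [1.0 / n] * n)
    s = np.array(se if se is not None else [0.01] * n)
    return QpAdmResult(
        target=model.target,
        sources=model.sources,
        rights=model.rights,
        weights=w,
        se=s,
        p_value=p,
        statistic=1.0,
        dof=max(len(model.rights) - n, 1),
        n_snps=1000,
    )


class TestEnumeration:
    def test_rotating_counts_858(self):
        models = enumerate_ags_rotating(list("ABCDEFGHIJKLM"))
        assert len(models) == 858
        for m in models:
            assert len(m.left) == 3 and len(m.rights) == 10
            assert set(m.left).isdisjoint(m.rights)

    def test_rotating_small_case(self):
        assert len(enumerate_ags_rotating(list("ABCD"))) == 12

    @settings(max_examples=10, deadline=None)
    @given(st.integers(5, 20))
    def test_rotating_closed_form(self, n):
        from math import comb

        groups = [f"g{i}" for i in range(n)]
        assert len(enumerate_ags_rotating(groups)) == n * comb(n - 1, 2)

    def test_nonrotating_counts_105(self):
        graph = generate_random_graph(13, 10, 800, seed=4)
        models = enumerate_ags_nonrotating(graph)
        assert len(models) == 105
        rights = set(models[0].rights)
        assert len(rights) == 6
        # rights are the 6 oldest sampled groups
        dates = sorted(graph.sample_time.values(), reverse=True)
        assert min(graph.sample_time[r] for r in rights) >= dates[6] - 1e-9

    def test_nonrotating_alphabetical_tie_break(self):
        graph = generate_random_graph(13, 0, 800, seed=2)
        for lf in graph.leaves:
            graph.sample_time[lf] = 50.0
        models = enumerate_ags_nonrotating(graph)
        assert set(models[0].rights) == set("ABCDEF")

    def test_distal_filter_matches_date_oracle(self):
        graph = generate_random_graph(13, 10, 800, seed=9)
        models = enumerate_ags_nonrotating(graph)
        distal = filter_distal(models, graph.sample_time)
        for m in models:
            ok = all(
                graph.sample_time[m.target] <= graph.sample_time[s]
                for s in m.sources
            )
            assert (m in distal) == ok


class TestFeasibility:
    def test_grid_has_36_distinct_criteria(self):
        grid = criterion_grid()
        assert len(grid) == len(set(grid)) == 36

    def test_ags_composite_example(self):
        model = QpAdmModel("T", ("A", "B"), tuple("RSTUVWXYZ0"))
        res = fake_result(model, p=0.5, weights=[0.6, 0.4], se=[0.05, 0.05])
        crit = FeasibilityCriterion("strict", 0.01, "same")
        trailing = [fake_result(model, p=0.001) for _ in range(3)]
        assert apply_feasibility(res, trailing, crit)
        # a trailing model that fits spoils the composite criterion
        trailing[0] = fake_result(model, p=0.5)
        assert not apply_feasibility(res, trailing, crit)

    def test_loose_interval_arithmetic(self):
        model = QpAdmModel("T", ("A", "B"), tuple("RSTUVW"))
        res = fake_result(model, p=0.9, weights=[1.2, -0.2], se=[0.01, 0.01])
        assert not apply_feasibility(res, None, FeasibilityCriterion("strict", 0.01, "none"))
        assert not apply_feasibility(res, None, FeasibilityCriterion("plain", 0.01, "none"))
        assert apply_feasibility(res, None, FeasibilityCriterion("loose", 0.01, "none"))

    def test_monotone_in_p_threshold(self):
        model = QpAdmModel("T", ("A", "B"), tuple("RSTUVW"))
        rng = np.random.default_rng(0)
        for _ in range(50):
            res = fake_result(
                model,
                p=float(rng.uniform()),
                weights=[rng.normal(0.5, 0.4), 0.0],
                se=[abs(rng.normal(0, 0.1)), 0.01],
            )
            res.weights[1] = 1 - res.weights[0]
            feasible = [
                apply_feasibility(
                    res, None, FeasibilityCriterion("plain", p, "none")
                )
                for p in (0.001, 0.01, 0.05, 0.1, 0.5)
            ]
            # raising the threshold can only remove feasible calls
            for lo, hi in zip(feasible, feasible[1:]):
                assert lo or not hi

    def test_parse_round_trip(self):
        crit = FeasibilityCriterion.parse("loose:0.05:fixed-0.001")
        assert str(crit) == "loose:0.05:fixed-0.001"


class TestRandomizedDraws:
    def test_distal_nonrotating_membership(self):
        frame = ssl_sampling_frame(64)
        spec = draw_randomized_experiment(frame, "distal-nonrotating", 13, seed=1)
        assert spec.target.endswith("_t0")
        assert len(spec.rights) == 10 and len(spec.proxies) == 10
        assert all(r.endswith("_t300") for r in spec.rights)
        assert all(p.endswith("_t100") for p in spec.proxies)

    def test_proximal_rotating_never_targets_oldest_slice(self):
        frame = ssl_sampling_frame(64)
        rng = np.random.default_rng(3)
        for _ in range(200):
            spec = draw_randomized_experiment(frame, "proximal-rotating", 13, rng)
            assert not spec.target.endswith("_t300")
            assert len(spec.rotating) == 13

    def test_draw_frequencies_near_uniform(self):
        frame = ssl_sampling_frame(64)
        rng = np.random.default_rng(7)
        counts = {}
        n_draws = 4000
        for _ in range(n_draws):
            spec = draw_randomized_experiment(frame, "distal-rotating", 13, rng)
            for g in spec.rotating:
                counts[g] = counts.get(g, 0) + 1
        observed = np.array(
            [counts.get(g, 0) for g in frame[frame["slice"] > 0]["group"]]
        )
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.01


class TestSystematicDraws:
    def test_all_six_neighbors_included(self, landscape):
        ring1 = sorted(landscape.hex_ring(0, 1))
        assert len(ring1) == 6
        spec = draw_systematic_experiment(landscape, 0, tuple(ring1))
        demes = {int(g.split("_")[0][1:]) for g in spec.rotating}
        assert set(ring1) <= demes
        assert len(spec.rotating) == 16

    def test_zero_first_circle_uses_third_only(self, landscape):
        spec = draw_systematic_experiment(landscape, 0, ())
        demes = {int(g.split("_")[0][1:]) for g in spec.rotating}
        assert demes <= set(landscape.hex_ring(0, 3))

    def test_boundary_target_without_full_circle_errors(self, landscape):
        boundary = max(
            range(64),
            key=lambda i: np.hypot(*landscape.coords[i]),
        )
        with pytest.raises(ValueError):
            draw_systematic_experiment(landscape, boundary, ())

    def test_grid_of_64_experiments(self, landscape):
        specs = systematic_experiment_grid(landscape, 0)
        assert len(specs) == 64


class TestRunExperiment:
    def make_spec(self, n_pool=6):
        pool = tuple(f"d{i}_t100" for i in range(n_pool))
        return ExperimentSpec(
            "distal-rotating", "d9_t0", pool, max_complexity=3
        )

    def test_one_way_pass_stops_at_level_one(self):
        spec = self.make_spec()
        crit = FeasibilityCriterion("plain", 0.01, "none")
        outcome = run_experiment(
            spec, crit, lambda m: fake_result(m, p=0.9), exhaustive=False
        )
        assert outcome.stop_level == 1
        assert len(outcome.levels) == 1

    def test_hand_traced_two_way_stop(self):
        spec = self.make_spec(4)
        crit = FeasibilityCriterion("plain", 0.01, "none")
        passing = {("d0_t100", "d1_t100"), ("d2_t100", "d3_t100")}

        def fitter(m):
            if m.n_way == 1:
                return fake_result(m, p=1e-6)
            p = 0.9 if tuple(sorted(m.sources)) in passing else 1e-6
            return fake_result(m, p=p)

        outcome = run_experiment(spec, crit, fitter)
        assert outcome.stop_level == 2
        assert len(outcome.feasible_at_stop()) == 2

    def test_level_sizes_match_binomials(self):
        pool = tuple(f"g{i}" for i in range(13))
        spec = ExperimentSpec("distal-rotating", "T", pool, max_complexity=4)
        crit = FeasibilityCriterion("plain", 0.01, "none")
        outcome = run_experiment(spec, crit, lambda m: fake_result(m, p=1e-9))
        from math import comb

        assert [len(outcome.levels[n]) for n in (1, 2, 3, 4)] == [
            comb(13, n) for n in (1, 2, 3, 4)
        ]
        assert outcome.stop_level is None

    def test_rotating_rights_complement_sources(self):
        spec = self.make_spec()
        for model in spec.models(2):
            assert set(model.sources).isdisjoint(model.rights)
            assert set(model.sources) | set(model.rights) == set(spec.rotating)


class TestModelCompetition:
    def test_singleton_passes_automatically(self):
        m = QpAdmModel("T", ("A", "B"), ("R1", "R2", "R3", "R4"))
        crit = FeasibilityCriterion("plain", 0.01, "none")
        out = model_competition([m], crit, fitter=None)
        assert out == [m]

    def test_one_by_one_retests_each_alternative(self):
        m1 = QpAdmModel("T", ("A", "B"), ("R1", "R2", "R3", "R4"))
        m2 = QpAdmModel("T", ("A", "C"), ("R1", "R2", "R3", "R4"))
        seen = []

        def fitter(model):
            seen.append(model)
            return fake_result(model, p=0.9, weights=[0.5, 0.5])

        crit = FeasibilityCriterion("plain", 0.01, "none")
        out = model_competition([m1, m2], crit, fitter, mode="one-by-one")
        assert out == [m1, m2]
        # each model retested once per non-shared alternative source
        assert len(seen) == 2
        assert "C" in seen[0].rights and "B" in seen[1].rights

    def test_pool_right_rejection_drops_model(self):
        m1 = QpAdmModel("T", ("A", "B"), ("R1", "R2", "R3", "R4"))
        m2 = QpAdmModel("T", ("A", "C"), ("R1", "R2", "R3", "R4"))

        def fitter(model):
            p = 1e-6 if "C" in model.rights else 0.9
            return fake_result(model, p=p, weights=[0.5, 0.5])

        crit = FeasibilityCriterion("plain", 0.01, "none")
        out = model_competition([m1, m2], crit, fitter, mode="pool-right")
        assert out == [m2]
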