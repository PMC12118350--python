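"""Optimality metrics, confusion summaries, support rules, metric space."""

import math

import numpy as np
import pandas as pd
import pytest

from admixscreen.evaluation import (
    ConfusionSummary,
    OptimalityMetrics,
    admixture_support,
    classify_experiment_misleading,
    classify_optimal,
    fdr_from_rates,
    ld_prune,
    ld_prune_and_pca,
    min_sts_angle,
    model_metrics,
    pca_support,
    st_distance,
    summarize_metric_space,
)
from admixscreen.protocols import ExperimentSpec, ExperimentOutcome
from admixscreen.qpadm import QpAdmModel

from .conftest import toy_dataset


class TestSpatialMetrics:
    def test_same_deme_distance_zero(self, landscape):
        assert st_distance(landscape, 5, 5) == 0.0

    def test_adjacent_demes_distance_one(self, landscape):
        nbr = landscape.neighbors(0)[0]
        assert st_distance(landscape, 0, nbr) == 1.0

    def test_collinear_two_steps(self, landscape):
        # walk two steps in the same lattice direction from the centre
        q0, r0 = landscape.axial[0]
        idx = {tuple(a): i for i, a in enumerate(map(tuple, landscape.axial))}
        two = idx[(q0 + 2, r0)]
        assert st_distance(landscape, 0, two) == 2.0

    def test_max_distance_is_nine(self, landscape):
        hops = landscape.hop_matrix()
        assert hops.max() == 9.0

    def test_opposite_neighbors_angle_180(self, landscape):
        idx = {tuple(a): i for i, a in enumerate(map(tuple, landscape.axial))}
        q0, r0 = landscape.axial[0]
        a, b = idx[(q0 + 1, r0)], idx[(q0 - 1, r0)]
        assert min_sts_angle(landscape, 0, [a, b]) == pytest.approx(180.0)

    def test_sixty_degree_neighbors(self, landscape):
        idx = {tuple(a): i for i, a in enumerate(map(tuple, landscape.axial))}
        q0, r0 = landscape.axial[0]
        a, b = idx[(q0 + 1, r0)], idx[(q0, r0 + 1)]
        assert min_sts_angle(landscape, 0, [a, b]) == pytest.approx(60.0)

    def test_source_on_target_angle_undefined(self, landscape):
        nbr = landscape.neighbors(0)[0]
        assert min_sts_angle(landscape, 0, [0, nbr]) is None

    def test_avg_never_exceeds_max(self, landscape):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t, *ss = rng.choice(64, size=4, replace=False)
            met = model_metrics(landscape, t, ss)
            assert met.avg_st <= met.max_st + 1e-12


class TestClassifyOptimal:
    def test_ideal_two_way_distance_zero(self):
        met = OptimalityMetrics(2, 1.0, 1.0, 180.0)
        assert met.distance_to_ideal() == pytest.approx(0.0)
        assert classify_optimal(met)

    def test_forced_arithmetic_example(self):
        met = OptimalityMetrics(2, 3.0, 3.0, 60.0)
        assert met.distance_to_ideal() == pytest.approx(math.sqrt(40))
        assert not classify_optimal(met)

    def test_undefined_angle_not_classifiable(self):
        met = OptimalityMetrics(2, 3.0, 1.5, None)
        assert classify_optimal(met) is None

    def test_normalization_bounds(self):
        for n, ang in ((2, 180.0), (3, 120.0), (4, 90.0)):
            met = OptimalityMetrics(n, 1.0, 1.0, ang)
            assert met.normalized_angle == pytest.approx(9.0)

    def test_systematic_nearest_neighbor_rule_15_of_120(self, landscape):
        from itertools import combinations

        from admixscreen.protocols import draw_systematic_experiment

        ring1 = sorted(landscape.hex_ring(0, 1))
        spec = draw_systematic_experiment(landscape, 0, tuple(ring1))
        demes = [int(g.split("_")[0][1:]) for g in spec.rotating]
        optimal = 0
        total = 0
        for pair in combinations(demes, 2):
            met = model_metrics(landscape, 0, pair)
            total += 1
            if classify_optimal(met, rule="nearest-neighbors"):
                optimal += 1
        assert total == 120 and optimal == 15


class TestConfusion:
    def test_fpr_zero_means_fdr_zero(self):
        assert fdr_from_rates(0.5, 0.0, 0.3) == 0.0

    def test_fnr_one_means_fdr_one(self):
        assert fdr_from_rates(0.7, 0.2, 1.0) == pytest.approx(1.0)

    def test_counts_and_rates_agree_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(1, 200, size=4)
            c = ConfusionSummary(int(tp), int(fp), int(tn), int(fn))
            via_rates = fdr_from_rates(c.prestudy_odds, c.fpr, c.fnr)
            assert via_rates == pytest.approx(c.fdr, abs=1e-12)
            assert c.ppv + c.fdr == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            fdr_from_rates(0.5, 0.0, 1.0)


def _outcome(stop_level, rows_by_level):
    spec = ExperimentSpec("distal-rotating", "T", ("a", "b"))
    return ExperimentOutcome(spec=spec, levels=rows_by_level, stop_level=stop_level)


class TestMisleadingRule:
    def metrics_fn_factory(self, table):
        def fn(model):
            return table.get(model.sources)
        return fn

    def test_threshold_arithmetic(self):
        m_good = QpAdmModel("T", ("a", "b"), ())
        m_bad = QpAdmModel("T", ("c", "d"), ())
        # nonrejected distance-to-ideal 9.5; rejected 1.0 -> misleading
        table = {
            ("a", "b"): OptimalityMetrics(2, 6.0, 6.0, 18.6),    # d ~ 9.5
            ("c", "d"): OptimalityMetrics(2, 1.35, 1.35, 160.2),  # d ~ 1.0
        }
        assert table[("a", "b")].distance_to_ideal() == pytest.approx(9.5, abs=0.1)
        assert table[("c", "d")].distance_to_ideal() == pytest.approx(1.0, abs=0.1)
        rows = {2: [(m_good, None, True), (m_bad, None, False)]}
        out = _outcome(2, rows)
        assert classify_experiment_misleading(out, self.metrics_fn_factory(table))

    def test_one_way_rule_uses_st_distance(self):
        m1 = QpAdmModel("T", ("a",), ())
        m2 = QpAdmModel("T", ("b",), ())
        table = {
            ("a",): OptimalityMetrics(1, 4.0, 4.0, None),
            ("b",): OptimalityMetrics(1, 1.0, 1.0, None),
        }
        rows = {1: [(m1, None, True), (m2, None, False)]}
        assert classify_experiment_misleading(
            _outcome(1, rows), self.metrics_fn_factory(table)
        )

    def test_all_feasible_is_vacuously_fine(self):
        m1 = QpAdmModel("T", ("a", "b"), ())
        table = {("a", "b"): OptimalityMetrics(2, 1.0, 1.0, 180.0)}
        rows = {2: [(m1, None, True)]}
        assert not classify_experiment_misleading(
            _outcome(2, rows), self.metrics_fn_factory(table)
        )


class TestPcaSupport:
    def make_pcs(self, target_center):
        rows = []
        for g, center in (("S1", (0, 0, 0)), ("S2", (10, 0, 0)), ("T", target_center)):
            for k in range(4):
                jitter = 0.1 * np.array([k, -k, k])
                rows.append(
                    {"group": g, "PC1": center[0] + jitter[0],
                     "PC2": center[1] + jitter[1], "PC3": center[2] + jitter[2]}
                )
        return pd.DataFrame(rows)

    def test_midpoint_supported(self):
        pcs = self.make_pcs((5, 0, 0))
        assert pca_support(pcs, "T", "S1", "S2")

    def test_far_off_segment_unsupported(self):
        # target cluster diameter ~0.5; 5 diameters off the segment
        pcs = self.make_pcs((5, 3.0, 0))
        assert not pca_support(pcs, "T", "S1", "S2")


class TestAdmixtureSupport:
    def q_table(self, rows):
        recs = []
        for group, comps in rows:
            for c in comps:
                recs.append({"group": group, **{f"C{i}": v for i, v in enumerate(c)}})
        return pd.DataFrame(recs)

    def test_separating_components_supported(self):
        q = self.q_table([
            ("T", [[0.5, 0.5]] * 10),
            ("S1", [[1.0, 0.0]] * 10),
            ("S2", [[0.0, 1.0]] * 10),
        ])
        model = QpAdmModel("T", ("S1", "S2"), ())
        assert admixture_support({4: q}, model)

    def test_single_shared_component_unsupported(self):
        q = self.q_table([
            ("T", [[1.0, 0.0]] * 10),
            ("S1", [[1.0, 0.0]] * 10),
            ("S2", [[1.0, 0.0]] * 10),
        ])
        model = QpAdmModel("T", ("S1", "S2"), ())
        assert not admixture_support({4: q}, model)

    def test_source_private_components_ignored(self):
        q = self.q_table([
            ("T", [[0.5, 0.5, 0.0]] * 10),
            ("S1", [[0.6, 0.0, 0.4]] * 10),   # C2 private to the source
            ("S2", [[0.0, 1.0, 0.0]] * 10),
        ])
        model = QpAdmModel("T", ("S1", "S2"), ())
        assert admixture_support({4: q}, model)

    def test_any_single_k_suffices(self):
        bad = self.q_table([
            ("T", [[1.0, 0.0]] * 10),
            ("S1", [[1.0, 0.0]] * 10),
            ("S2", [[1.0, 0.0]] * 10),
        ])
        good = self.q_table([
            ("T", [[0.5, 0.5]] * 10),
            ("S1", [[1.0, 0.0]] * 10),
            ("S2", [[0.0, 1.0]] * 10),
        ])
        model = QpAdmModel("T", ("S1", "S2"), ())
        assert admixture_support({3: bad, 4: good}, model)


class TestLdPruneAndPca:
    def test_duplicated_site_pruned(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        geno[10] = geno[5]  # exact duplicate, r^2 = 1
        data = toy_dataset(geno, ["A"] * 5 + ["B"] * 5)
        keep = ld_prune(data, window=30, step=10, r2_threshold=0.5)
        assert 5 in keep and 10 not in keep

    def test_matches_all_pairs_window_oracle(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        data = toy_dataset(geno, ["A"] * 4 + ["B"] * 4)
        keep = set(ld_prune(data, window=50, step=50, r2_threshold=0.5))
        # oracle: greedy scan removing the later of each correlated pair
        centered = geno - geno.mean(axis=1, keepdims=True)
        removed = set()
        for i in range(50):
            if i in removed:
                continue
            for j in range(i + 1, 50):
                if j in removed:
                    continue
                denom = np.linalg.norm(centered[i]) * np.linalg.norm(centered[j])
                r = centered[i] @ centered[j] / denom if denom else 0.0
                if r**2 > 0.5:
                    removed.add(j)
        assert keep == set(range(50)) - removed

    def test_pc1_separates_diverged_populations(self):
        rng = np.random.default_rng(3)
        freq_a = rng.uniform(0, 0.2, size=300)
        freq_b = rng.uniform(0.8, 1.0, size=300)
        geno = np.concatenate(
            [
                rng.binomial(2, freq_a[:, None], size=(300, 6)),
                rng.binomial(2, freq_b[:, None], size=(300, 6)),
            ],
            axis=1,
        ).astype(np.int8)
        data = toy_dataset(geno, ["A"] * 6 + ["B"] * 6)
        pcs = ld_prune_and_pca(data, window=300, step=100)
        assert list(pcs.columns[2:]) == [f"PC{i}" for i in range(1, 11)]
        a = pcs[pcs["group"] == "A"]["PC1"].to_numpy()
        b = pcs[pcs["group"] == "B"]["PC1"].to_numpy()
        gap = abs(a.mean() - b.mean())
        spread = max(a.std(), b.std())
        assert gap > 2 * spread


class TestMetricSpace:
    def test_all_feasible_gives_rho_one(self):
        rng = np.random.default_rng(4)
        mets = [
            OptimalityMetrics(2, float(rng.integers(1, 9)), 1.0,
                              float(rng.uniform(5, 175)))
            for _ in range(200)
        ]
        table, rho = summarize_metric_space(mets, [True] * 200)
        assert rho == pytest.approx(1.0)

    def test_empty_feasible_set_undefined(self):
        mets = [OptimalityMetrics(2, 2.0, 2.0, 90.0)] * 10
        _table, rho = summarize_metric_space(mets, [False] * 10)
        assert rho is None

    def test_sharper_rule_lowers_correlation(self):
        rng = np.random.default_rng(5)
        mets, loose_flags, sharp_flags = [], [], []
        for _ in range(2000):
            ang = float(rng.uniform(0, 180))
            st = float(rng.integers(1, 9))
            mets.append(OptimalityMetrics(2, st, st, ang))
            # loose rule: accept nearly everything; sharp: symmetric only
            loose_flags.append(rng.uniform() < 0.9)
            sharp_flags.append(ang > 150 and st <= 2)
        _t, rho_loose = summarize_metric_space(mets, loose_flags)
        _t, rho_sharp = summarize_metric_space(mets, sharp_flags)
        assert rho_sharp < rho_loose
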