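import logging

import numpy as np
import pytest

import foundertrace as ft
from foundertrace.dating import FounderCluster


@pytest.fixture
def eight_sample_tree(hap):
    """Hand-built source+sink fixture.

    Root ('ref') is source-observed with three source-derived branches;
    node 16120A is source-observed with exactly one source-derived branch
    (16120A 16130A), so it survives f1 but dissolves under f2.
    """
    x, y, a, b, c = [(16100 + 10 * i, "A") for i in range(5)]
    haps = [hap("r1", set()), hap("r2", {x}), hap("r3", {y}),
            hap("sa", {a}), hap("sa1", {a, b}),
            hap("k1", {a}, role="sink"), hap("k2", {a, c}, role="sink"),
            hap("k3", {a, c}, role="sink")]
    net = ft.median_joining_network(haps)
    return ft.root_network(net, "outgroup_consensus", outgroup=hap("og", set(), role="excluded"))


class TestIdentifyFounders:
    def test_f1_keeps_single_derived_branch_candidate(self, eight_sample_tree):
        (cluster,) = ft.identify_founders(eight_sample_tree, "f1")
        assert cluster.founder_node == "16120A"
        assert cluster.n == 3
        assert cluster.rho == pytest.approx(2 / 3)
        dists = {sid: d for sid, _, d in cluster.members}
        assert dists == {"k1": 0, "k2": 1, "k3": 1}

    def test_f2_dissolves_it_and_members_climb(self, eight_sample_tree):
        (f1,) = ft.identify_founders(eight_sample_tree, "f1")
        (f2,) = ft.identify_founders(eight_sample_tree, "f2")
        assert f2.founder_node == "ref"
        assert f2.rho > f1.rho  # climbing can only lengthen distances
        # sample conservation across criteria
        assert sorted(s for s, _, _ in f2.members) \
            == sorted(s for s, _, _ in f1.members)

    def test_sink_identical_to_source_state_has_distance_zero(
            self, eight_sample_tree):
        (cluster,) = ft.identify_founders(eight_sample_tree, "f1")
        assert ("k1", "16120A", 0) in cluster.members

    def test_all_sink_data_fall_back_to_root_with_warning(self, hap, caplog):
        haps = [hap("a", set(), role="sink"),
                hap("b", {(16100, "A")}, role="sink"),
                hap("c", {(16100, "A"), (16150, "C")}, role="sink")]
        net = ft.median_joining_network(haps)
        tree = ft.root_network(net, "midpoint")
        with caplog.at_level(logging.WARNING):
            clusters = ft.identify_founders(tree, "f1")
        assert len(clusters) == 1
        assert clusters[0].founder_node == tree.root
        assert "assigned to the root" in caplog.text

    def test_unknown_criterion_rejected(self, eight_sample_tree):
        with pytest.raises(ValueError):
            ft.identify_founders(eight_sample_tree, "f3")


class TestMigrationPosterior:
    def test_zero_mutation_cluster_resolves_to_youngest_time(self):
        c = FounderCluster.star(5, 0)
        grid = np.arange(0.0, 2001.0, 200.0)
        post = ft.migration_posterior(c, grid, ft.CLOCKS["hvs1"])
        assert post[0] == 1.0
        assert post[1:].sum() == 0.0

    def test_mode_at_rho_times_clock(self):
        # rho=1, n_eff=10: continuous-Poisson mode at T = rho*Q = 16677
        c = FounderCluster.star(10, 1)
        grid = np.arange(0.0, 70001.0, 200.0)
        post = ft.migration_posterior(c, grid, ft.CLOCKS["hvs1"])
        mode = grid[int(np.argmax(post))]
        assert abs(mode - 16677.0) <= 200.0

    def test_equidistant_times_split_half_half(self):
        # two candidate times with identical likelihood get exactly half
        # the mass each under a uniform prior
        c = FounderCluster.star(10, 1)
        q = ft.CLOCKS["hvs1"].years_per_mutation
        post = ft.migration_posterior(c, np.array([q, q]),
                                      ft.CLOCKS["hvs1"])
        assert post == pytest.approx([0.5, 0.5])

    def test_mode_nondecreasing_in_rho(self):
        grid = np.arange(0.0, 70001.0, 200.0)
        modes = []
        for d in (1, 2, 3):
            c = FounderCluster.star(10, d)
            post = ft.migration_posterior(c, grid, ft.CLOCKS["hvs1"])
            modes.append(grid[int(np.argmax(post))])
        assert modes == sorted(modes)

    def test_str_clock_posterior(self):
        c = FounderCluster.star(10, 2)
        grid = np.arange(0.0, 20001.0, 200.0)
        post = ft.migration_posterior(c, grid,
                                      ft.CLOCKS["ystr_calibrated"],
                                      n_loci=19)
        # mode at rho/(r*n_loci) = 2/(4.08e-5*19) ~ 2580 y
        mode = grid[int(np.argmax(post))]
        assert abs(mode - 2.0 / (4.08e-5 * 19)) <= 200.0

    def test_rows_sum_to_one(self):
        c = FounderCluster.star(10, 1)
        grid = np.arange(0.0, 70001.0, 200.0)
        post = ft.migration_posterior(c, grid, ft.CLOCKS["hvs1"])
        assert abs(post.sum() - 1.0) < 1e-12


class TestScan:
    def test_single_founder_aggregate_equals_posterior(self):
        c = FounderCluster.star(5, 1)
        scan = ft.scan_migrations([c], ft.CLOCKS["hvs1"])
        assert np.allclose(scan.aggregate, scan.per_founder_posterior[0])
        assert len(scan.grid) == 351

    def test_two_equal_founders_give_bimodal_aggregate(self):
        q = ft.CLOCKS["hvs1"].years_per_mutation
        # rho*Q near 4500 and 8000: distances 27/100 and 48/100
        c1 = FounderCluster(
            "f1", [(f"a{i}", f"a{i}", 1) for i in range(27)]
            + [(f"b{i}", f"b{i}", 0) for i in range(73)],
            [(1, 1)] * 27)
        c2 = FounderCluster(
            "f2", [(f"c{i}", f"c{i}", 1) for i in range(48)]
            + [(f"d{i}", f"d{i}", 0) for i in range(52)],
            [(1, 1)] * 48)
        scan = ft.scan_migrations([c1, c2], ft.CLOCKS["hvs1"])
        agg = scan.aggregate
        # local maxima of the aggregate near each cluster's rho*Q
        maxima = [scan.grid[i] for i in range(1, 350)
                  if agg[i] >= agg[i - 1] and agg[i] >= agg[i + 1]]
        assert any(abs(m - 0.27 * q) <= 200.0 for m in maxima)
        assert any(abs(m - 0.48 * q) <= 200.0 for m in maxima)

    def test_grid_refinement_keeps_mode(self):
        c = FounderCluster.star(10, 1)
        coarse = ft.scan_migrations([c], ft.CLOCKS["hvs1"], step=200.0)
        fine = ft.scan_migrations([c], ft.CLOCKS["hvs1"], step=100.0)
        assert abs(coarse.mode_years() - fine.mode_years()) <= 200.0

    def test_empty_founder_list_rejected(self):
        with pytest.raises(ValueError):
            ft.scan_migrations([], ft.CLOCKS["hvs1"])


class TestPartition:
    def test_single_founder_fractions_equal_posterior(self):
        c = FounderCluster.star(5, 1)
        model = ft.MigrationModel(ft.MTDNA_EVENT_TIMES)
        part = ft.partition_migrations([c], model, ft.CLOCKS["hvs1"])
        assert np.allclose(part.fractions, part.per_founder_probs[0])
        assert abs(part.fractions.sum() - 1.0) < 1e-12

    def test_neolithic_founder_concentrates_on_4500(self):
        # rho*Q = 4500 with n_eff = 50 puts >= 0.9 mass on the 4.5 ka event
        q = ft.CLOCKS["hvs1"].years_per_mutation
        rho = 4500.0 / q
        n = 50
        m = int(round(rho * n))
        c = FounderCluster(
            "f", [(f"a{i}", f"a{i}", 1) for i in range(m)]
            + [(f"b{i}", f"b{i}", 0) for i in range(n - m)],
            [(1, 1)] * m)
        model = ft.MigrationModel(ft.MTDNA_EVENT_TIMES)
        part = ft.partition_migrations([c], model, ft.CLOCKS["hvs1"])
        assert part.per_founder_probs[0][1] >= 0.9

    def test_event_time_validation(self):
        with pytest.raises(ValueError):
            ft.MigrationModel([4500.0, 4500.0])
        with pytest.raises(ValueError):
            ft.MigrationModel([4500.0, 500.0])
        with pytest.raises(ValueError):
            ft.MigrationModel([500.0, 4500.0], prior=[0.9, 0.2])

    def test_presets_match_study_design(self):
        assert ft.MTDNA_EVENT_TIMES == (500.0, 4500.0, 8000.0, 50000.0)
        assert ft.Y_EVENT_TIMES == (500.0, 4500.0, 8000.0, 20000.0)


class TestPipelineRecovery:
    """End-to-end single-pulse recovery on synthetic two-deme data."""

    @pytest.mark.parametrize("t_star", [4500.0, 8000.0])
    def test_scan_mode_recovers_pulse_time(self, t_star):
        modes = []
        for seed in range(25):
            scenario = ft.SimScenario(pulses=[(t_star, 1.0)], seed=seed)
            samples, _ = ft.simulate_two_deme(scenario)
            result = ft.run_founder_analysis(
                samples, ft.CLOCKS["hvs1"], criterion="f1",
                root_method="midpoint")
            modes.append(result.scan.mode_years())
        assert abs(np.median(modes) - t_star) <= 600.0

    def test_f1_and_f2_conserve_sink_samples(self):
        scenario = ft.SimScenario(pulses=[(4500.0, 1.0)], seed=77)
        samples, _ = ft.simulate_two_deme(scenario)
        net = ft.median_joining_network(samples)
        tree = ft.root_network(net, "midpoint")
        ids = {}
        for crit in ("f1", "f2"):
            clusters = ft.identify_founders(tree, crit)
            ids[crit] = sorted(s for c in clusters
                               for s, _, _ in c.members)
        assert ids["f1"] == ids["f2"]
        assert len(ids["f1"]) == scenario.n_sink
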