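"""Edge bootstrap, difference tests, case-dropping stability."""

import numpy as np
import pytest

import panelnet as pn
from tests.conftest import panel_from_items


@pytest.fixture(scope="module")
def boot(small_panel):
    return pn.bootstrap_edges(small_panel, "pre", None, n_boot=100, seed=5)


class TestBootstrapEdges:
    def test_minimum_draws_enforced(self, small_panel):
        with pytest.raises(ValueError, match="minimum"):
            pn.bootstrap_edges(small_panel, "pre", None, n_boot=2, seed=0)

    def test_deterministic_for_fixed_seed(self, small_panel, boot):
        again = pn.bootstrap_edges(small_panel, "pre", None, n_boot=100, seed=5)
        assert np.array_equal(again.samples, boot.samples)
        assert again.mean_ci_width == boot.mean_ci_width

    def test_interval_ordering(self, boot):
        # the percentile bracket holds wherever the interval is non-degenerate
        # (a point-mass-at-zero edge with a rare tail draw can place the mean
        # epsilon outside its zero-width interval)
        open_iv = boot.ci_high - boot.ci_low > 0
        assert np.all(boot.ci_low[open_iv] <= boot.boot_mean[open_iv] + 1e-12)
        assert np.all(boot.boot_mean[open_iv] <= boot.ci_high[open_iv] + 1e-12)
        width = boot.ci_high - boot.ci_low
        assert boot.mean_ci_width == pytest.approx(width.mean())

    def test_duplicated_data_shrinks_intervals(self):
        """Tiling one dataset many times removes sampling noise, so every
        percentile interval collapses (continuous penalized weights)."""
        truth = pn.make_ground_truth(seed=0)
        base = pn.simulate_panel(truth, n=150, seed=1)
        dup = panel_from_items(np.tile(base.items_pre, (100, 1)))
        eb = pn.bootstrap_edges(dup, "pre", {"refit": False}, n_boot=100, seed=0)
        assert np.all(eb.ci_high - eb.ci_low < 0.05)

    def test_point_estimates_inside_intervals(self, boot):
        inside = (boot.point_estimate >= boot.ci_low - 1e-12) & \
                 (boot.point_estimate <= boot.ci_high + 1e-12)
        assert inside.mean() >= 0.99


class TestDifferenceTest:
    def test_same_index_rejected(self, boot):
        with pytest.raises(ValueError):
            pn.difference_test(boot, 3, 3)

    def test_disjoint_ranges_significant(self, boot):
        # synthesize two edges with non-overlapping bootstrap ranges
        fake = boot.samples.copy()
        fake[:, 0] = np.linspace(0.5, 0.6, fake.shape[0])
        fake[:, 1] = np.linspace(-0.2, -0.1, fake.shape[0])
        b2 = pn.EdgeBootstrap(node_labels=boot.node_labels, edges=boot.edges,
                              point_estimate=boot.point_estimate, samples=fake,
                              ei_point=boot.ei_point, ei_samples=boot.ei_samples,
                              n_boot=boot.n_boot, seed=boot.seed)
        res = pn.difference_test(b2, 0, 1)
        assert res["significant"]

    def test_symmetry(self, boot):
        for a, b in [(0, 5), (2, 9)]:
            r1 = pn.difference_test(boot, a, b)
            r2 = pn.difference_test(boot, b, a)
            assert r1["significant"] == r2["significant"]
            lo1, hi1 = r1["ci_of_difference"]
            lo2, hi2 = r2["ci_of_difference"]
            assert lo1 == pytest.approx(-hi2)

    def test_ei_kind(self, boot):
        res = pn.difference_test(boot, 0, 1, kind="ei")
        assert set(res) == {"significant", "ci_of_difference", "mean_difference"}

    def test_out_of_range(self, boot):
        with pytest.raises(IndexError):
            pn.difference_test(boot, 0, 10_000)


class TestCsCoefficient:
    def test_perfectly_preserved_centrality_hits_grid_max(self):
        truth = pn.make_ground_truth(seed=0)
        base = pn.simulate_panel(truth, n=60, seed=1)
        dup = panel_from_items(np.tile(base.items_pre, (40, 1)))
        prof = pn.cs_coefficient(dup, "pre", "ei",
                                 drop_grid=np.arange(0.1, 0.71, 0.1),
                                 n_boot=20, seed=3)
        assert prof.cs_value == pytest.approx(0.7)

    def test_pure_noise_gives_zero(self):
        rng = np.random.default_rng(5)
        noise = panel_from_items(rng.integers(0, 5, size=(600, 20)))
        prof = pn.cs_coefficient(noise, "pre", "ei",
                                 drop_grid=np.arange(0.1, 0.71, 0.1),
                                 n_boot=20, seed=3)
        assert prof.cs_value <= 0.1

    def test_stricter_threshold_never_increases_cs(self, small_panel):
        grid = np.array([0.1, 0.3, 0.5, 0.7])
        loose = pn.cs_coefficient(small_panel, "pre", "ei", grid, n_boot=15,
                                  cor_threshold=0.7, seed=2)
        strict = pn.cs_coefficient(small_panel, "pre", "ei", grid, n_boot=15,
                                   cor_threshold=1.0, seed=2)
        assert strict.cs_value <= loose.cs_value

    def test_grid_bound_enforced(self, small_panel):
        with pytest.raises(ValueError, match="0.75"):
            pn.cs_coefficient(small_panel, "pre", "ei", np.array([0.5, 0.9]))

    def test_cs_value_in_grid_or_zero(self, small_panel):
        grid = np.array([0.2, 0.4, 0.6])
        prof = pn.cs_coefficient(small_panel, "pre", "ei", grid, n_boot=15, seed=0)
        assert prof.cs_value in {0.0, 0.2, 0.4, 0.6}

    def test_profile_json(self, tmp_path, small_panel):
        prof = pn.cs_coefficient(small_panel, "pre", "ei",
                                 np.array([0.2, 0.5]), n_boot=10, seed=0)
        prof.to_json(tmp_path / "prof.json")
        import json
        doc = json.loads((tmp_path / "prof.json").read_text())
        assert doc["cs_value"] == prof.cs_value
        assert doc["cor_threshold"] == 0.7
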