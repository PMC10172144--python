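"""Connectivity: Fisher-z oracles, seed sweeps, contrasts, region stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from scanmap import connectivity as conn
from scanmap import synthetic as syn
from scanmap.synthetic import BoldRun


def _run(data, tr=1.0):
    return BoldRun(data=np.asarray(data, dtype=float), tr=tr, run_type="rest")


class TestFisherConnectivity:
    def test_matches_brute_force_pairwise_loop(self, rng):
        data = rng.standard_normal((10, 50))
        z = conn.fisher_connectivity(_run(data)).z
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                r = np.corrcoef(data[i], data[j])[0, 1]
                expected = np.arctanh(np.clip(r, -conn.R_CLIP, conn.R_CLIP))
                assert z[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_timecourses_clipped(self, rng):
        x = rng.standard_normal(40)
        m = conn.fisher_connectivity(_run(np.stack([x, x])))
        assert m.z[0, 1] == pytest.approx(np.arctanh(conn.R_CLIP))
        assert np.isfinite(m.z).all()

    def test_orthogonal_sinusoids_zero(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        m = conn.fisher_connectivity(_run(np.stack([np.sin(t), np.cos(t)])))
        assert m.z[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_all_constant_masked_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            m = conn.fisher_connectivity(_run(np.ones((4, 20))))
        assert not m.mask.any()

    def test_symmetry_and_diagonal_masked(self, rng):
        m = conn.fisher_connectivity(_run(rng.standard_normal((8, 30))))
        assert np.array_equal(m.z, m.z.T)
        assert not m.mask.diagonal().any()

    def test_fisher_transform_monotone(self, rng):
        r = np.sort(rng.uniform(-0.99, 0.99, 50))
        z = conn.fisher_z(r)
        assert np.all(np.diff(z) > 0)


class TestSeedSweep:
    def test_one_map_per_axis_vertex_in_order(self, strip, rest_run):
        maps = conn.seed_sweep(conn.fisher_connectivity(rest_run), strip)
        assert len(maps) == strip.axis_length
        assert [m.seed_id for m in maps] == strip.axis_line.tolist()

    def test_map_equals_matrix_row(self, strip, rest_run):
        cmat = conn.fisher_connectivity(rest_run)
        maps = conn.seed_sweep(cmat, strip)
        v = maps[5].seed_id
        assert np.array_equal(maps[5].z, cmat.z[v])
        assert not maps[5].mask[v]  # own vertex excluded

    def test_inter_seed_prefers_other_inter_regions(self, strip, rest_run):
        cmat = conn.fisher_connectivity(rest_run)
        maps = conn.seed_sweep(cmat, strip)
        seed_pos = int(round(strip.region_center("inter_superior")))
        m = maps[seed_pos]
        z_inter = np.mean(
            [m.z[strip.vertices_of(r)].mean() for r in ("inter_middle", "inter_inferior")]
        )
        z_neigh = np.mean(
            [m.z[strip.vertices_of(r)].mean() for r in ("foot", "hand")]
        )
        assert z_inter > z_neigh

    def test_empty_axis_rejected(self, rest_run, strip):
        cmat = conn.fisher_connectivity(rest_run)
        bare = syn.CorticalStrip(
            coords=strip.coords,
            axis_line=np.array([], dtype=int),
            region_labels=strip.region_labels,
        )
        with pytest.raises(ValueError, match="empty axis"):
            conn.seed_sweep(cmat, bare)


class TestPercentileThreshold:
    def _map(self, values):
        v = np.asarray(values, dtype=float)
        return conn.SeedMap(seed_id=0, z=v, mask=np.ones(v.size, dtype=bool))

    def test_97th_percentile_of_1000_keeps_30(self, rng):
        m = self._map(rng.permutation(1000).astype(float))  # all distinct
        out = conn.percentile_threshold(m, 97.0)
        assert int(out.mask.sum()) == 30

    def test_constant_map_ties_all_survive(self):
        out = conn.percentile_threshold(self._map(np.full(50, 1.5)), 80.0)
        assert out.mask.all()

    def test_survivors_nested_across_thresholds(self, rng):
        m = self._map(rng.standard_normal(500))
        s80 = conn.percentile_threshold(m, 80.0).mask
        s97 = conn.percentile_threshold(m, 97.0).mask
        assert np.all(~s97 | s80)  # s97 subset of s80

    @pytest.mark.parametrize("q", [0.0, 100.0, -5.0, 120.0])
    def test_invalid_percentile_rejected(self, q):
        with pytest.raises(ValueError):
            conn.percentile_threshold(self._map(np.arange(10.0)), q)


class TestRegionMeanConnectivity:
    def test_region_vs_itself_clipped_max(self, strip, rest_run):
        z = conn.region_mean_connectivity(rest_run, strip, "hand", "hand")
        assert z == pytest.approx(np.arctanh(conn.R_CLIP))

    def test_shared_latent_noiseless_clipped_max(self, strip):
        truth = syn.default_truth(strip)
        truth.noise_sd = 0.0
        truth.region_lags_s = {r: 0.0 for r in truth.region_lags_s}
        run = syn.generate_rest_run(strip, truth, 128, 1.0, seed=4)
        z = conn.region_mean_connectivity(run, strip, "inter_superior", "CON")
        assert z == pytest.approx(np.arctanh(conn.R_CLIP))

    def test_matches_brute_force_recomputation(self, strip, rest_run):
        z = conn.region_mean_connectivity(rest_run, strip, "foot", "CON")
        a = rest_run.data[strip.vertices_of("foot")].mean(axis=0)
        b = rest_run.data[strip.vertices_of("CON")].mean(axis=0)
        expected = np.arctanh(np.clip(np.corrcoef(a, b)[0, 1], -conn.R_CLIP, conn.R_CLIP))
        assert z == pytest.approx(expected, abs=1e-12)

    def test_empty_region_rejected(self, strip, rest_run):
        with pytest.raises(ValueError, match="empty region"):
            conn.region_mean_connectivity(rest_run, strip, "foot", "no_such_region")


class TestConservativeContrast:
    def test_arithmetic_examples(self):
        out = conn.conservative_contrast(
            np.array([0.5]), [np.array([0.2]), np.array([0.3]), np.array([0.1])]
        )
        assert out[0] == pytest.approx(0.2)
        out = conn.conservative_contrast(np.array([0.3]), [np.array([0.3])])
        assert out[0] == pytest.approx(0.0)

    def test_matches_elementwise_loop(self, rng):
        t = rng.standard_normal(100)
        comps = [rng.standard_normal(100) for _ in range(3)]
        out = conn.conservative_contrast(t, comps)
        for v in range(100):
            assert out[v] == t[v] - max(c[v] for c in comps)

    @settings(derandomize=True, max_examples=25)
    @given(hst.integers(0, 2))
    def test_never_exceeds_single_competitor_difference(self, k):
        rng = np.random.default_rng(k)
        t = rng.standard_normal(50)
        comps = [rng.standard_normal(50) for _ in range(3)]
        out = conn.conservative_contrast(t, comps)
        assert np.all(out <= t - comps[k] + 1e-15)

    def test_misaligned_maps_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            conn.conservative_contrast(np.zeros(5), [np.zeros(4)])


class TestPairedTTestFDR:
    def test_all_zero_differences(self):
        t = conn.paired_ttest_fdr({"c": (np.ones(5), np.ones(5))})
        assert t.loc[0, "t"] == 0.0
        assert t.loc[0, "p"] == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        t = conn.paired_ttest_fdr({"c": (np.array([2.0, 2, 2, 2]), np.ones(4))})
        assert bool(t.loc[0, "degenerate"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            conn.paired_ttest_fdr({"c": (np.array([1.0]), np.array([0.0]))})

    def test_bh_q_matches_manual_computation(self, rng):
        comps = {f"c{i}": (rng.standard_normal(8), rng.standard_normal(8)) for i in range(10)}
        table = conn.paired_ttest_fdr(comps)
        p = table["p"].to_numpy()
        order = np.argsort(p)
        m = p.size
        q_manual = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[idx] * m / rank)
            q_manual[idx] = running
        np.testing.assert_allclose(table["q"].to_numpy(), q_manual, atol=1e-12)

    def test_null_rejection_rate_calibrated(self, rng):
        # modest Monte-Carlo check at unit-test scale
        n_reps, n = 2000, 7
        a = rng.standard_normal((n_reps, n))
        b = rng.standard_normal((n_reps, n))
        table = conn.paired_ttest_fdr({f"r{i}": (a[i], b[i]) for i in range(n_reps)})
        rate = (table["p"] < 0.05).mean()
        assert 0.038 <= rate <= 0.062


class TestNetworkMinDifference:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["subject", "network", "region", "z"])

    def test_trivial_example(self):
        rows = [
            (0, "CON", "inter_effector", 0.4),
            (0, "CON", "foot", 0.1),
            (0, "CON", "hand", 0.2),
            (0, "CON", "mouth", 0.3),
        ]
        t = conn.network_min_difference(self._table(rows).pipe(lambda d: pd.concat([d, d.assign(subject=1)])))
        assert t.loc[0, "min_difference"] == pytest.approx(0.1)

    def test_all_equal_gives_zero(self):
        rows = [(s, "CON", r, 0.5) for s in (0, 1) for r in ("inter_effector", "foot", "hand", "mouth")]
        t = conn.network_min_difference(self._table(rows))
        assert t.loc[0, "min_difference"] == pytest.approx(0.0)

    def test_matches_per_subject_loop(self, rng):
        rows = []
        for s in range(5):
            for net in ("CON", "aud"):
                for r in ("inter_effector", "foot", "hand", "mouth"):
                    rows.append((s, net, r, float(rng.standard_normal())))
        df = self._table(rows)
        t = conn.network_min_difference(df)
        for net in ("CON", "aud"):
            diffs = []
            for s in range(5):
                sub = df[(df.subject == s) & (df.network == net)].set_index("region")["z"]
                diffs.append(min(sub["inter_effector"] - sub[e] for e in ("foot", "hand", "mouth")))
            expected = np.mean(diffs)
            got = t.loc[t.network == net, "min_difference"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_cell_rejected(self):
        rows = [(0, "CON", "inter_effector", 0.4), (0, "CON", "foot", 0.1)]
        with pytest.raises(ValueError, match="missing region"):
            conn.network_min_difference(self._table(rows))


class TestRegionScalarCompare:
    def test_injected_thinner_inter_significant(self, strip):
        maps = []
        for s in range(7):
            effects = {}
            rng = np.random.default_rng(s)
            for r in syn.MOTOR_AXIS_ORDER:
                mean = 2.3 if r in syn.INTER_REGIONS else 2.7
                effects[r] = {"thickness": (mean + rng.normal(0, 0.03), 0.1),
                              "fa": (0.4, 0.0), "myelin": (1.0, 0.0)}
            maps.append(syn.generate_structural_maps(strip, effects, seed=100 + s).thickness)
        _, stats_table = conn.region_scalar_compare(np.stack(maps), strip)
        assert (stats_table["q"] < 0.05).all()
        assert (stats_table["mean_diff"] < 0).all()

    def test_identical_regions_null(self, strip, rng):
        base = rng.standard_normal(strip.n_vertices) * 0 + 2.5
        maps = np.stack([base, base + 0.1, base - 0.1])
        _, stats_table = conn.region_scalar_compare(maps, strip)
        assert (stats_table["t"] == 0).all()
        assert (stats_table["p"] == 1).all()

    def test_region_means_match_brute_force(self, strip, rng):
        maps = rng.standard_normal((3, strip.n_vertices))
        means, _ = conn.region_scalar_compare(maps, strip)
        expected = maps[:, strip.vertices_of("foot")].mean(axis=1)
        np.testing.assert_allclose(means["foot"].to_numpy(), expected, atol=1e-12)
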