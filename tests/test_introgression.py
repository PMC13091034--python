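"""Tests of Patterson's D with block jackknife and the U50 scan."""

import numpy as np
import pytest

import feralscan as fs
from feralscan.containers import WindowSpec
from feralscan.introgression import d_statistic, u50_scan

from conftest import make_gm, simple_popmap


def _four_pop_gm(p_w, p_x, p_y, p_z, n=10, seed=0, spacing=1000):
    """Cohort with given per-site derived frequencies; outgroup 'og' is
    fixed ancestral so ALT == derived after polarization."""
    rng = np.random.default_rng(seed)
    n_sites = len(p_w)
    blocks, labels = [], {}
    for name, p in (("W", p_w), ("X", p_x), ("Y", p_y), ("Z", p_z)):
        haps = (rng.random((n, n_sites, 2)) < np.asarray(p)[None, :, None])
        blocks.append(haps.astype(np.int8))
    og = np.zeros((2, n_sites, 2), dtype=np.int8)
    blocks.append(og)
    genos = np.concatenate(blocks, axis=0)
    gm = make_gm(genos, spacing=spacing)
    pops = {
        "W": [f"s{i}" for i in range(n)],
        "X": [f"s{i}" for i in range(n, 2 * n)],
        "Y": [f"s{i}" for i in range(2 * n, 3 * n)],
        "Z": [f"s{i}" for i in range(3 * n, 4 * n)],
        "og": [f"s{i}" for i in range(4 * n, 4 * n + 2)],
    }
    pm = simple_popmap(gm, pops, {"og": "outgroup"})
    freqs = fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)
    return gm, pm, freqs


class TestDStatistic:
    def test_antisymmetry_under_w_x_swap(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 2000)
        gm, pm, freqs = _four_pop_gm(p, p, rng.uniform(0, 1, 2000), p * 0.1,
                                     seed=2, spacing=5000)
        a = d_statistic(freqs, "W", "X", "Y", "Z", block_size=2_000_000)
        b = d_statistic(freqs, "X", "W", "Y", "Z", block_size=2_000_000)
        assert a.d == pytest.approx(-b.d, abs=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_degenerate_py_zero_everywhere(self):
        p = np.full(500, 0.5)
        gm, pm, freqs = _four_pop_gm(p, p, np.zeros(500), np.zeros(500), seed=3)
        with pytest.raises(ValueError, match="ABBA"):
            d_statistic(freqs, "W", "X", "Y", "Z", block_size=100_000)

    def test_requires_polarized_frequencies(self, small_cohort):
        _, gm, popmap, _ = small_cohort
        freqs = fs.allele_frequencies(gm, popmap)  # not polarized
        with pytest.raises(ValueError, match="polarize"):
            d_statistic(freqs, "SAI", "HKF", "banteng", "buffalo")

    def test_needs_two_blocks(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 200)
        gm, pm, freqs = _four_pop_gm(p, p, rng.uniform(0, 1, 200), p * 0.1, seed=5)
        with pytest.raises(ValueError, match="block"):
            d_statistic(freqs, "W", "X", "Y", "Z", block_size=10**9)

    def test_null_cohort_z_below_three(self):
        """W and X exchangeable by construction -> D ~ 0, |Z| small."""
        cfg = fs.default_config(seed=31, contig_length=100_000_000)
        gm, pm, _ = fs.simulate_cohort(cfg)
        freqs = fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)
        res = d_statistic(freqs, "SAI", "HKF", "banteng", "buffalo")
        assert abs(res.z) < 3
        assert abs(res.d) < 0.05

    def test_planted_introgression_recovered(self):
        cfg = fs.default_config(seed=32, contig_length=100_000_000)
        gm, pm, truth = fs.simulate_cohort(cfg)
        fs.plant_introgression(
            gm, pm, truth, ("chr1", 0, 100_000_000), "banteng", "HKF", 0.10, 8
        )
        freqs = fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)
        res = d_statistic(freqs, "SAI", "HKF", "banteng", "buffalo")
        assert res.d > 0 and res.z > 3

    def test_jackknife_se_shrinks_with_more_blocks(self):
        """SE ~ 1/sqrt(n_blocks) on homogeneous simulations."""
        rng = np.random.default_rng(6)
        ses = []
        for n_sites in (4000, 64_000):
            p = rng.uniform(0.1, 0.9, n_sites)
            py = rng.uniform(0, 1, n_sites)
            gm, pm, freqs = _four_pop_gm(p, p, py, p * 0.05, seed=7, spacing=1000)
            res = d_statistic(freqs, "W", "X", "Y", "Z", block_size=500_000)
            ses.append((res.n_blocks, res.se))
        (b1, se1), (b2, se2) = ses
        assert b2 == 16 * b1
        # 16x blocks/sites -> SE ~ se1/4; generous band for jackknife noise
        assert 0.1 * se1 < se2 < 0.6 * se1


class TestU50Scan:
    def _freq_gm(self, table):
        """Build a cohort realizing exact allele counts per site.

        table rows: (derived count A of 20, B of 40, C of 8)."""
        n_a, n_b, n_c = 10, 20, 4
        n_sites = len(table)
        genos = np.zeros((n_a + n_b + n_c + 2, n_sites, 2), dtype=np.int8)
        for j, (da, db, dc) in enumerate(table):
            genos[:n_a, j, :] = (
                np.arange(2 * n_a).reshape(n_a, 2) < da
            )
            genos[n_a : n_a + n_b, j, :] = (
                np.arange(2 * n_b).reshape(n_b, 2) < db
            )
            genos[n_a + n_b : n_a + n_b + n_c, j, :] = (
                np.arange(2 * n_c).reshape(n_c, 2) < dc
            )
        gm = make_gm(genos, spacing=1000)
        pops = {
            "A": [f"s{i}" for i in range(n_a)],
            "B": [f"s{i}" for i in range(n_a, n_a + n_b)],
            "C": [f"s{i}" for i in range(n_a + n_b, n_a + n_b + n_c)],
            "og": [f"s{i}" for i in range(n_a + n_b + n_c, n_a + n_b + n_c + 2)],
        }
        pm = simple_popmap(gm, pops, {"og": "outgroup"})
        return gm, fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)

    def test_enumerated_window_count(self):
        # 3 qualifying sites (A=0, B=24/40=0.6, C=8/8 fixed) + decoys
        table = [
            (0, 24, 8), (0, 24, 8), (0, 24, 8),   # qualify
            (0, 24, 7),                            # donor not fixed (7/8)
            (2, 24, 8),                            # A frequency 0.1 >= 1%
            (0, 18, 8),                            # B frequency 0.45 <= 50%
        ]
        gm, freqs = self._freq_gm(table)
        windows = [WindowSpec("chr1", 0, 50_000)]
        out, _ = u50_scan(freqs, "A", "B", "C", windows)
        assert out["count"].iloc[0] == 3

    def test_donor_near_fixation_never_counts(self):
        """y = 1.0 is exact fixation: donor at 98% (49/50 alleles) fails."""
        n_c = 25  # 50 donor alleles
        genos = np.zeros((10 + 20 + n_c + 2, 1, 2), dtype=np.int8)
        genos[10:30, 0, :] = np.arange(40).reshape(20, 2) < 24  # B = 0.6
        genos[30 : 30 + n_c, 0, :] = 1
        genos[30, 0, 0] = 0  # 49/50 derived
        gm = make_gm(genos)
        pops = {
            "A": [f"s{i}" for i in range(10)],
            "B": [f"s{i}" for i in range(10, 30)],
            "C": [f"s{i}" for i in range(30, 30 + n_c)],
            "og": [f"s{i}" for i in range(30 + n_c, 32 + n_c)],
        }
        pm = simple_popmap(gm, pops, {"og": "outgroup"})
        freqs = fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)
        out, _ = u50_scan(freqs, "A", "B", "C", [WindowSpec("chr1", 0, 50_000)])
        assert out["count"].iloc[0] == 0

    def test_matches_per_site_loop_oracle(self):
        cfg = fs.default_config(seed=33, contig_length=5_000_000, snp_spacing=500)
        gm, pm, truth = fs.simulate_cohort(cfg)
        fs.plant_introgression(
            gm, pm, truth, ("chr1", 1_000_000, 2_000_000), "banteng", "HKF", 0.5, 9
        )
        freqs = fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)
        windows = fs.make_windows({"chr1": 5_000_000})
        out, _ = u50_scan(freqs, "SAI", "HKF", "banteng", windows)
        # brute-force per-site qualification then per-window recount
        pa = freqs.p_derived("SAI")
        pb = freqs.p_derived("HKF")
        dc, nc = freqs.derived_count("banteng"), freqs.n_called["banteng"]
        pos = freqs.variants["pos"].to_numpy()
        for w_i, w in enumerate(windows):
            count = 0
            for j in range(len(pos)):
                if not (w.start < pos[j] <= w.end):
                    continue
                if not freqs.polarizable[j] or nc[j] < 2 or dc[j] != nc[j]:
                    continue
                if np.isnan(pa[j]) or np.isnan(pb[j]):
                    continue
                if pa[j] < 0.01 and pb[j] > 0.50:
                    count += 1
            assert out["count"].iloc[w_i] == count

    def test_count_monotone_in_thresholds(self):
        cfg = fs.default_config(seed=34, contig_length=5_000_000, snp_spacing=500)
        gm, pm, truth = fs.simulate_cohort(cfg)
        fs.plant_introgression(
            gm, pm, truth, ("chr1", 1_000_000, 2_000_000), "banteng", "HKF", 0.5, 10
        )
        freqs = fs.allele_frequencies(gm, pm, polarize_by_outgroup=True)
        windows = fs.make_windows({"chr1": 5_000_000})
        base, _ = u50_scan(freqs, "SAI", "HKF", "banteng", windows)
        stricter_x, _ = u50_scan(freqs, "SAI", "HKF", "banteng", windows, x=0.8)
        looser_w, _ = u50_scan(freqs, "SAI", "HKF", "banteng", windows, w=0.10)
        assert (stricter_x["count"] <= base["count"]).all()
        assert (looser_w["count"] >= base["count"]).all()

    def test_no_qualifying_sites_warns_with_empty_set(self):
        p = np.full(100, 0.5)
        gm, pm, freqs = _four_pop_gm(p, p, np.zeros(100), np.zeros(100), seed=11)
        with pytest.warns(UserWarning, match="no qualifying"):
            out, regions = u50_scan(
                freqs, "W", "X", "Y", [WindowSpec("chr1", 0, 100_000)]
            )
        assert not out["tail"].any()
        assert regions.total_length() == 0
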