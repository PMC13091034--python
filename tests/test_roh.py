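"""Tests of ROH detection, mixture classification, interval algebra and
burden comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import feralscan as fs
from feralscan.intervals import IntervalSet, coverage_mask
from feralscan.roh import (
    ROHParams,
    classify_segments,
    common_roh,
    detect_roh,
    fit_roh_mixture,
    roh_burden_compare,
    specific_roh,
)

from conftest import make_gm, simple_popmap


def _planted_cohort(seed=7, segments=None):
    cfg = fs.default_config(seed=seed)
    gm, pm, truth = fs.simulate_cohort(cfg)
    segments = segments or {
        "HKF_01": ("chr1", 2_000_000, 4_000_000),
        "HKF_02": ("chr1", 5_000_000, 6_800_000),
    }
    for s, seg in segments.items():
        fs.plant_autozygosity(gm, truth, s, seg)
    return gm, pm, truth, segments


class TestDetectRoh:
    def test_planted_segment_recovered(self):
        gm, pm, truth, planted = _planted_cohort()
        segs = detect_roh(gm)
        for s, (c, a, b) in planted.items():
            det = IntervalSet.from_records(
                [(r.contig, r.start, r.end)
                 for r in segs[segs["sample"] == s].itertuples()]
            )
            tp = det.covered_length(c, a, b)
            assert tp / (b - a) >= 0.95          # base-level recall
            assert tp / det.total_length() >= 0.90  # base-level precision

    def test_fully_heterozygous_sample_yields_nothing(self):
        genos = np.zeros((1, 500, 2), dtype=np.int8)
        genos[0, :, 1] = 1  # het everywhere
        gm = make_gm(genos, spacing=2000)
        assert len(detect_roh(gm)) == 0

    def test_short_planted_segment_rejected_by_length_minimum(self):
        gm, pm, truth, _ = _planted_cohort(
            seed=8, segments={"HKF_05": ("chr1", 2_000_000, 2_500_000)}
        )
        segs = detect_roh(gm)
        assert (segs["sample"] != "HKF_05").all()

    def test_phase_invariance(self):
        gm, pm, truth, _ = _planted_cohort(seed=9)
        segs_a = detect_roh(gm)
        swapped = gm.alleles[:, :, ::-1].copy()
        gm2 = make_gm(swapped, spacing=2000,
                      positions=gm.variants["pos"].tolist(),
                      samples=list(gm.samples))
        segs_b = detect_roh(gm2)
        pd.testing.assert_frame_equal(segs_a, segs_b)

    def test_contig_shorter_than_window_skipped(self):
        genos = np.zeros((1, 10, 2), dtype=np.int8)
        gm = make_gm(genos, spacing=2000)
        assert len(detect_roh(gm)) == 0


class TestMixture:
    def _segments(self, n_per=1000, seed=5, means=(2.8, 3.3, 4.0), sd=0.05):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(m, sd, n_per) for m in means])
        labels = np.repeat(["short", "medium", "long"], n_per)
        return pd.DataFrame({"length": 10**x}), labels

    def test_parameter_recovery_and_accuracy(self):
        segs, labels = self._segments()
        fit = fit_roh_mixture(segs, k=3, seed=0)
        assert fit.converged
        assert np.allclose(fit.means, [2.8, 3.3, 4.0], atol=0.05)
        assert (fit.labels == labels).mean() >= 0.95
        assert len(fit.boundaries) == 2
        assert fit.boundaries[0] < fit.boundaries[1]

    def test_k1_single_class_no_boundaries(self):
        segs, _ = self._segments(n_per=20, means=(3.0,) * 3)
        fit = fit_roh_mixture(segs, k=1, seed=0)
        assert len(fit.boundaries) == 0
        assert len(set(fit.labels)) == 1

    def test_log_likelihood_monotone(self):
        segs, _ = self._segments(seed=6)
        fit = fit_roh_mixture(segs, k=3, seed=0)
        ll = np.array(fit.log_likelihood_path)
        assert (np.diff(ll) >= -1e-6).all()

    def test_agrees_with_sklearn_gmm(self):
        """Independent EM implementation (scikit-learn) recovers the same
        component means on well-separated data."""
        from sklearn.mixture import GaussianMixture

        segs, _ = self._segments(seed=7)
        fit = fit_roh_mixture(segs, k=3, seed=0)
        x = np.log10(segs["length"].to_numpy()).reshape(-1, 1)
        gmm = GaussianMixture(n_components=3, random_state=0, n_init=3).fit(x)
        ref_means = np.sort(gmm.means_.ravel())
        assert np.allclose(fit.means, ref_means, atol=0.02)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_roh_mixture(pd.DataFrame({"length": [1e6] * 5}), k=3)


class TestCommonSpecificRoh:
    def _popmap(self, samples_by_pop):
        assignments = {s: p for p, ss in samples_by_pop.items() for s in ss}
        from feralscan.containers import PopulationMap

        return PopulationMap(assignments, {})

    def test_two_of_three_carriers_included(self):
        segs = pd.DataFrame(
            {
                "sample": ["a", "b", "c"],
                "contig": ["chr1"] * 3,
                "start": [100, 150, 900_000],
                "end": [500, 500, 950_000],
                "length": [400, 350, 50_000],
                "n_snps": [10, 10, 10],
            }
        )
        pm = self._popmap({"p": ["a", "b", "c"]})
        out = common_roh(segs, pm, "p")
        assert out.intervals["chr1"] == [(150, 500)]  # 2/3 = 66.7% > 50%

    def test_exactly_half_excluded(self):
        segs = pd.DataFrame(
            {
                "sample": ["a", "b"],
                "contig": ["chr1"] * 2,
                "start": [100, 100],
                "end": [500, 500],
                "length": [400, 400],
                "n_snps": [10, 10],
            }
        )
        pm = self._popmap({"p": ["a", "b", "c", "d"]})  # 2/4 = exactly 50%
        out = common_roh(segs, pm, "p")
        assert out.intervals == {}

    def test_matches_per_base_counting_oracle(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(6)]
        rows = []
        for s in samples:
            for _ in range(rng.integers(1, 6)):
                a = int(rng.integers(0, 9000))
                b = a + int(rng.integers(100, 1500))
                rows.append({"sample": s, "contig": "chr1", "start": a, "end": b,
                             "length": b - a, "n_snps": 5})
        segs = pd.DataFrame(rows)
        pm = self._popmap({"p": samples})
        out = common_roh(segs, pm, "p", min_fraction=0.5)
        mask = np.zeros(11_000, dtype=int)
        for s in samples:  # per-base oracle with per-sample dedup
            cov = coverage_mask(
                [(r.start, r.end) for r in segs[segs["sample"] == s].itertuples()],
                11_000,
            )
            mask += cov > 0
        expect = mask > 0.5 * len(samples)
        got = np.zeros(11_000, dtype=bool)
        for a, b in out.intervals.get("chr1", []):
            got[a:b] = True
        assert np.array_equal(got, expect)

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(11)
        rows = []
        for i in range(8):
            rows.append({"sample": f"s{i}", "contig": "chr1",
                         "start": int(rng.integers(0, 5000)),
                         "end": int(rng.integers(5000, 10000)),
                         "length": 1, "n_snps": 5})
        segs = pd.DataFrame(rows)
        pm = self._popmap({"p": [f"s{i}" for i in range(8)]})
        lengths = [
            common_roh(segs, pm, "p", min_fraction=f).total_length()
            for f in (0.25, 0.5, 0.75)
        ]
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_specific_roh_set_algebra(self):
        focal = IntervalSet.from_records([("chr1", 0, 1000), ("chr1", 5000, 6000)])
        other = IntervalSet.from_records([("chr1", 500, 800)])
        out = specific_roh({"f": focal, "o": other}, "f")
        assert out.intervals["chr1"] == [(0, 500), (800, 1000), (5000, 6000)]
        # disjoint from every other population's set — exact
        assert out.intersect(other).total_length() == 0
        # focal contained in another set -> empty
        sub = specific_roh(
            {"f": other, "o": IntervalSet.from_records([("chr1", 0, 1000)])}, "f"
        )
        assert sub.total_length() == 0

    def test_specific_roh_matches_per_base_oracle(self):
        rng = np.random.default_rng(12)

        def random_set():
            recs = []
            for _ in range(rng.integers(2, 8)):
                a = int(rng.integers(0, 9000))
                recs.append(("chr1", a, a + int(rng.integers(50, 2000))))
            return IntervalSet.from_records(recs)

        sets = {p: random_set() for p in ("f", "o1", "o2")}
        out = specific_roh(sets, "f")
        masks = {}
        for p, ivs in sets.items():
            masks[p] = coverage_mask(ivs.intervals.get("chr1", []), 12_000) > 0
        expect = masks["f"] & ~masks["o1"] & ~masks["o2"]
        got = coverage_mask(out.intervals.get("chr1", []), 12_000) > 0
        assert np.array_equal(got, expect)


class TestBurdenCompare:
    def _popmap(self, n_a=5, n_b=5):
        from feralscan.containers import PopulationMap

        assignments = {f"a{i}": "A" for i in range(n_a)}
        assignments.update({f"b{i}": "B" for i in range(n_b)})
        return PopulationMap(assignments, {})

    def _segments(self, lengths_by_sample):
        rows = []
        for s, lengths in lengths_by_sample.items():
            for i, ln in enumerate(lengths):
                rows.append({"sample": s, "contig": "chr1",
                             "start": i * 10_000_000,
                             "end": i * 10_000_000 + ln,
                             "length": ln, "n_snps": 100,
                             "size_class": "all"})
        return pd.DataFrame(rows)

    def test_identical_burdens_give_p_one(self):
        segs = self._segments(
            {f"a{i}": [1_000_000] for i in range(5)}
            | {f"b{i}": [1_000_000] for i in range(5)}
        )
        _, tests, _ = roh_burden_compare(segs, self._popmap())
        assert tests["p_value"].iloc[0] == pytest.approx(1.0)

    def test_equal_length_segments_correlate_exactly(self):
        L = 1_200_000
        lengths = {f"a{i}": [L] * (i + 1) for i in range(5)}
        lengths |= {f"b{i}": [L] * (i + 2) for i in range(5)}
        segs = self._segments(lengths)
        _, _, corr = roh_burden_compare(segs, self._popmap())
        assert corr["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_wilcoxon_matches_exact_enumeration(self):
        """n=5 vs 5, no ties: p equals the exhaustive rank-permutation
        distribution."""
        rng = np.random.default_rng(13)
        xa = rng.uniform(1e6, 3e6, 5)
        xb = rng.uniform(2e6, 4e6, 5)
        segs = self._segments(
            {f"a{i}": [int(xa[i])] for i in range(5)}
            | {f"b{i}": [int(xb[i])] for i in range(5)}
        )
        _, tests, _ = roh_burden_compare(segs, self._popmap())
        # exhaustive enumeration oracle
        pooled = np.concatenate([xa, xb])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:5].sum() - 5 * 6 / 2
        count = 0
        total = 0
        for comb in itertools.combinations(range(10), 5):
            u = ranks[list(comb)].sum() - 5 * 6 / 2
            if min(u, 25 - u) <= min(u_obs, 25 - u_obs):
                count += 1
            total += 1
        assert tests["p_value"].iloc[0] == pytest.approx(count / total, abs=1e-12)

    def test_classified_pipeline_round_trip(self):
        gm, pm, truth, _ = _planted_cohort(seed=14)
        segs = detect_roh(gm)
        rng = np.random.default_rng(0)
        extra = pd.DataFrame({
            "sample": rng.choice(gm.samples, 100),
            "contig": "chr1",
            "start": 0, "end": 0,
            "length": (10 ** rng.normal(6.2, 0.3, 100)).astype(int),
            "n_snps": 500,
        })
        allsegs = pd.concat([segs, extra], ignore_index=True)
        fit = fit_roh_mixture(allsegs, k=3, seed=0)
        classified = classify_segments(allsegs, fit)
        assert set(classified["size_class"]) <= {"short", "medium", "long",
                                                 "unclassified"}
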