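"""Runs of homozygosity: sliding-window detection, Gaussian-mixture size
classification, population-common and population-specific ROH interval
algebra, and cross-population burden comparison.

Detection follows the classical SNP-window scheme: a 50-SNP window is
"homozygous" if it carries at most 1 heterozygous and at most 5 missing
calls; a SNP is inside a run if at least 5% of the windows overlapping
it are homozygous; maximal in-run stretches are kept if they satisfy
minimum SNP count, minimum length, SNP density and maximum-gap rules.
Detection uses genotypes only and is therefore phase-invariant.

Size classes (short / medium / long) are not fixed constants: a k = 3
univariate Gaussian mixture is fitted per dataset on log10 segment
length by EM, and class boundaries fall at the equal-posterior crossing
points between adjacent components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .containers import MISSING, GenotypeMatrix, PopulationMap
from .intervals import IntervalSet, coverage_intervals

log = logging.getLogger(__name__)

SIZE_CLASSES = ("short", "medium", "long")


@dataclass
class ROHParams:
    """Detection parameters (defaults follow the common PLINK settings)."""

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_fraction: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    max_bp_per_snp: int = 50_000  # density: at least 1 SNP per this many bp
    max_gap_bp: int = 1_000_000


def detect_roh(
    gm: GenotypeMatrix,
    params: ROHParams | None = None,
) -> pd.DataFrame:
    """Detect per-sample ROH segments.

    Returns a frame with columns ``sample, contig, start, end, length,
    n_snps`` (0-based half-open coordinates; start is the base of the
    first SNP in the run, end the base after the last).
    """
    params = params or ROHParams()
    w = params.window_snps
    rows: list[dict] = []
    for contig, sl in gm.contig_slices().items():
        pos = gm.variants["pos"].to_numpy()[sl]
        n = len(pos)
        if n < w:
            log.warning("contig %s has %d < %d SNPs; skipped", contig, n, w)
            continue
        sub = gm.alleles[:, sl, :]
        both_called = (sub != MISSING).all(axis=2)
        het = both_called & (sub[:, :, 0] != sub[:, :, 1])
        miss = ~both_called
        for i, sample in enumerate(gm.samples):
            in_roh = _in_roh_mask(het[i], miss[i], params)
            for a, b in _runs(in_roh):
                seg_pos = pos[a:b]
                for ga, gb in _split_gaps(seg_pos, params.max_gap_bp):
                    p = seg_pos[ga:gb]
                    n_snps = len(p)
                    start, end = int(p[0]) - 1, int(p[-1])
                    length = end - start
                    if (
                        n_snps >= params.min_snps
                        and length >= params.min_length_bp
                        and length <= n_snps * params.max_bp_per_snp
                    ):
                        rows.append(
                            {
                                "sample": sample,
                                "contig": contig,
                                "start": start,
                                "end": end,
                                "length": length,
                                "n_snps": n_snps,
                            }
                        )
    return pd.DataFrame(
        rows, columns=["sample", "contig", "start", "end", "length", "n_snps"]
    )


def _in_roh_mask(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP in-ROH flag from the sliding homozygous-window vote."""
    w = params.window_snps
    n = len(het)
    cum_het = np.concatenate([[0], np.cumsum(het)])
    cum_mis = np.concatenate([[0], np.cumsum(miss)])
    het_w = cum_het[w:] - cum_het[:-w]  # het count in window starting at j
    mis_w = cum_mis[w:] - cum_mis[:-w]
    hom_w = (het_w <= params.window_max_het) & (mis_w <= params.window_max_missing)
    # windows overlapping SNP i start at j in [i-w+1, i] clipped to [0, n-w]
    cum_hom = np.concatenate([[0], np.cumsum(hom_w)])
    i = np.arange(n)
    lo = np.clip(i - w + 1, 0, n - w)
    hi = np.clip(i, 0, n - w) + 1
    hits = cum_hom[hi] - cum_hom[lo]
    denom = hi - lo
    return hits / denom >= params.hit_fraction


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True stretches of a boolean array as [a, b) index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts.tolist(), ends.tolist()))


def _split_gaps(pos: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    if len(pos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
    edges = np.concatenate([[0], breaks, [len(pos)]])
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class MixtureFit:
    """Univariate Gaussian mixture on log10 segment length."""

    weights: np.ndarray
    means: np.ndarray  # sorted ascending
    sds: np.ndarray
    boundaries: np.ndarray  # k-1 equal-posterior cut points, log10 bp
    converged: bool
    log_likelihood: float
    log_likelihood_path: list[float] = field(default_factory=list)
    labels: np.ndarray | None = None  # max-posterior component per segment

    @property
    def k(self) -> int:
        return len(self.means)

    def classify(self, lengths_bp: np.ndarray) -> np.ndarray:
        """Map lengths to size-class names via component membership."""
        x = np.log10(np.asarray(lengths_bp, dtype=float))
        post = self._posteriors(x)
        comp = post.argmax(axis=1)
        names = (
            list(SIZE_CLASSES)
            if self.k == 3
            else [f"class{i + 1}" for i in range(self.k)]
        )
        return np.array([names[c] for c in comp])

    def _posteriors(self, x: np.ndarray) -> np.ndarray:
        dens = np.stack(
            [
                w * stats.norm.pdf(x, m, s)
                for w, m, s in zip(self.weights, self.means, self.sds)
            ],
            axis=1,
        )
        tot = dens.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return dens / tot


def fit_roh_mixture(
    segments: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """EM fit of a k-component Gaussian mixture to log10 segment lengths.

    Initialization is quantile-based (k-means style on sorted data), so
    the fit is deterministic given the data and ``k``; ``seed`` only
    perturbs initialization when the quantile split is degenerate.
    Components are sorted by mean; unequal variances are allowed.
    """
    lengths = segments["length"].to_numpy(dtype=float)
    if len(lengths) < 10 * k:
        raise ValueError(f"need at least {10 * k} segments to fit k={k}")
    x = np.log10(lengths)
    order = np.argsort(x)
    chunks = np.array_split(x[order], k)
    means = np.array([c.mean() for c in chunks])
    sds = np.array([max(c.std(), 1e-3) for c in chunks])
    if len(np.unique(means)) < k:  # degenerate split: jitter
        rng = np.random.default_rng(seed)
        means = means + rng.normal(0, 1e-3, size=k)
    weights = np.full(k, 1.0 / k)

    ll_path: list[float] = []
    converged = False
    for _ in range(max_iter):
        dens = np.stack(
            [w * stats.norm.pdf(x, m, s) for w, m, s in zip(weights, means, sds)],
            axis=1,
        )
        tot = dens.sum(axis=1)
        tot[tot <= 0] = np.finfo(float).tiny
        ll = float(np.log(tot).sum())
        resp = dens / tot[:, None]
        nk = resp.sum(axis=0)
        nk[nk <= 0] = np.finfo(float).tiny
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, 1e-6))
        ll_path.append(ll)
        if len(ll_path) > 1 and abs(ll_path[-1] - ll_path[-2]) < tol:
            converged = True
            break
    order = np.argsort(means)
    weights, means, sds = weights[order], means[order], sds[order]

    boundaries = []
    for i in range(k - 1):
        f = lambda t: (  # noqa: E731
            weights[i] * stats.norm.pdf(t, means[i], sds[i])
            - weights[i + 1] * stats.norm.pdf(t, means[i + 1], sds[i + 1])
        )
        lo, hi = means[i], means[i + 1]
        try:
            if f(lo) * f(hi) < 0:
                boundaries.append(brentq(f, lo, hi))
            else:
                boundaries.append((lo + hi) / 2.0)
        except ValueError:
            boundaries.append((lo + hi) / 2.0)
    fit = MixtureFit(
        weights=weights,
        means=means,
        sds=sds,
        boundaries=np.array(boundaries),
        converged=converged,
        log_likelihood=ll_path[-1] if ll_path else float("nan"),
        log_likelihood_path=ll_path,
    )
    if converged:
        fit.labels = fit.classify(lengths)
    else:
        log.warning("ROH mixture EM did not converge; segments left unclassified")
        fit.labels = np.array(["unclassified"] * len(lengths))
    return fit


def classify_segments(segments: pd.DataFrame, fit: MixtureFit) -> pd.DataFrame:
    out = segments.copy()
    out["size_class"] = (
        fit.labels
        if fit.labels is not None and len(fit.labels) == len(segments)
        else fit.classify(segments["length"].to_numpy())
    )
    return out


def common_roh(
    segments: pd.DataFrame,
    popmap: PopulationMap,
    pop: str,
    min_fraction: float = 0.5,
) -> IntervalSet:
    """Bases inside an ROH in strictly more than ``min_fraction`` of the
    population's individuals, merged into intervals."""
    pop_samples = popmap.samples_of(pop)
    if len(pop_samples) < 2:
        raise ValueError(f"population {pop!r} needs >= 2 individuals")
    n = len(pop_samples)
    # strict "more than": smallest integer count with count/n > min_fraction
    min_count = int(np.floor(min_fraction * n)) + 1
    sub = segments[segments["sample"].isin(pop_samples)]
    out: dict[str, list[tuple[int, int]]] = {}
    for contig, rows in sub.groupby("contig"):
        per_sample: list[tuple[int, int]] = []
        for sample, srows in rows.groupby("sample"):
            merged = IntervalSet.from_records(
                [(contig, r.start, r.end) for r in srows.itertuples()]
            )
            per_sample.extend(merged.intervals.get(contig, []))
        covered = coverage_intervals(per_sample, min_count)
        if covered:
            out[contig] = covered
    return IntervalSet(out)


def specific_roh(
    common_sets: dict[str, IntervalSet], focal_pop: str
) -> IntervalSet:
    """Focal population's common-ROH set minus every other population's."""
    if focal_pop not in common_sets:
        raise KeyError(f"no common-ROH set for {focal_pop!r}")
    result = common_sets[focal_pop]
    for pop, ivs in common_sets.items():
        if pop != focal_pop:
            result = result.subtract(ivs)
    return result


def roh_burden_compare(
    segments: pd.DataFrame, popmap: PopulationMap
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample ROH burden, pairwise Wilcoxon rank-sum tests, and the
    count-vs-cumulative-length Pearson correlation per size class.

    Samples with no segment in a class count as zero burden.  Returns
    ``(burden, tests, correlations)``.
    """
    if "size_class" not in segments.columns:
        segments = segments.assign(size_class="all")
    classes = [c for c in segments["size_class"].unique()]
    burden_rows = []
    for sample, pop in popmap.assignments.items():
        sub = segments[segments["sample"] == sample]
        for cls in classes:
            s = sub[sub["size_class"] == cls]
            burden_rows.append(
                {
                    "sample": sample,
                    "population": pop,
                    "size_class": cls,
                    "n_segments": len(s),
                    "cumulative_length": int(s["length"].sum()),
                }
            )
    burden = pd.DataFrame(burden_rows)

    pops = popmap.populations
    test_rows = []
    for cls in classes:
        bc = burden[burden["size_class"] == cls]
        for i, pa in enumerate(pops):
            for pb in pops[i + 1 :]:
                xa = bc.loc[bc["population"] == pa, "cumulative_length"].to_numpy()
                xb = bc.loc[bc["population"] == pb, "cumulative_length"].to_numpy()
                if (xa.sum() == 0 and xb.sum() == 0) or not len(xa) or not len(xb):
                    continue  # class absent: skip comparison
                stat, p = _rank_sum(xa, xb)
                test_rows.append(
                    {
                        "size_class": cls,
                        "pop_a": pa,
                        "pop_b": pb,
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    tests = pd.DataFrame(
        test_rows, columns=["size_class", "pop_a", "pop_b", "statistic", "p_value"]
    )

    corr_rows = []
    for cls in classes:
        bc = burden[burden["size_class"] == cls]
        has = bc[bc["n_segments"] > 0]
        if len(has) < 3:
            continue
        n = has["n_segments"].to_numpy(dtype=float)
        cum = has["cumulative_length"].to_numpy(dtype=float)
        if np.std(n) == 0 or np.std(cum) == 0:
            r, p = (1.0, 0.0) if np.allclose(cum / n, cum[0] / n[0]) else (np.nan, np.nan)
        else:
            r, p = stats.pearsonr(n, cum)
        corr_rows.append(
            {"size_class": cls, "pearson_r": float(r), "p_value": float(p)}
        )
    correlations = pd.DataFrame(
        corr_rows, columns=["size_class", "pearson_r", "p_value"]
    )
    return burden, tests, correlations


def _rank_sum(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U): exact when sample
    sizes allow and there are no ties, normal approximation otherwise."""
    if np.all(xa == xa[0]) and np.all(xb == xa[0]):
        return float(len(xa) * len(xb) / 2), 1.0  # all tied: no evidence
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
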