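"""Selection scans: the per-SNP Di statistic and the joint FST / theta-pi
ratio window scan.

Di for a focal population sums, over every (focal, other) population
pair, the genome-standardized deviation of the per-site FST from that
pair's genome-wide mean:

    Di = sum_j [ FST_site(focal, j) - mean_genome(focal, j) ] / sd_genome(focal, j)

Large Di flags SNPs whose differentiation is focal-specific.  The joint
window scan calls a sweep candidate where a window sits in the upper
tail of both the focal-vs-reference FST and of
``log2(pi_reference / pi_focal)``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import FrequencyTable
from .diversity import hudson_fst_components
from .intervals import IntervalSet

log = logging.getLogger(__name__)


def di_statistic(
    freqs: FrequencyTable,
    focal_pop: str,
    other_pops: list[str],
    top_fraction: float = 0.001,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-SNP Di for ``focal_pop`` against each population in ``other_pops``.

    Per-site pairwise FST is the Hudson ratio N/D (sites with D <= 0 or
    missing data in the pair are skipped for that pair).  Genome-wide
    mean and SD per pair are taken over all usable sites.  Returns the
    full record frame and the indices of the top ``top_fraction`` SNPs
    by Di.
    """
    if len(other_pops) < 2:
        raise ValueError("Di needs at least two non-focal populations")
    n_sites = len(freqs.variants)
    di = np.zeros(n_sites)
    n_pairs_used = np.zeros(n_sites, dtype=int)
    for other in other_pops:
        num, den = hudson_fst_components(freqs, focal_pop, other)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = num / den
        ok = np.isfinite(fst) & (den > 0)
        if ok.sum() < 2:
            warnings.warn(f"pair ({focal_pop}, {other}) has <2 usable sites; skipped")
            continue
        mean = float(fst[ok].mean())
        sd = float(fst[ok].std())
        if sd == 0:
            warnings.warn(
                f"pair ({focal_pop}, {other}) has zero genome-wide FST SD; skipped"
            )
            continue
        z = np.where(ok, (fst - mean) / sd, 0.0)
        di += z
        n_pairs_used += ok.astype(int)
    records = pd.DataFrame(
        {
            "contig": freqs.variants["contig"].to_numpy(),
            "pos": freqs.variants["pos"].to_numpy(),
            "di": di,
            "n_pairs": n_pairs_used,
        }
    )
    scored = records.index[records["n_pairs"] > 0].to_numpy()
    k = max(1, int(round(top_fraction * len(scored)))) if len(scored) else 0
    order = scored[np.argsort(-di[scored], kind="stable")]
    selected = np.sort(order[:k])
    return records, selected


def fst_pi_ratio_scan(
    fst_windows: pd.DataFrame,
    pi_windows_focal: pd.DataFrame,
    pi_windows_reference: pd.DataFrame,
    tail: float = 0.01,
) -> tuple[pd.DataFrame, IntervalSet]:
    """Joint upper-tail scan of windowed FST and log2 pi-ratio.

    All three frames must share an identical window grid.  The pi ratio
    is ``log2(pi_reference / max(pi_focal, floor))`` where the floor is
    the smallest positive focal window pi divided by 10 — this keeps
    fully swept (pi = 0) windows finite and maximal.  Windows flagged
    ``low_support`` are excluded from the tail quantiles and from
    candidacy.  Returns the scan frame plus merged candidate intervals.
    """
    if not 0 < tail < 1:
        raise ValueError(f"tail must be in (0, 1), got {tail}")
    for other in (pi_windows_focal, pi_windows_reference):
        same = (
            len(other) == len(fst_windows)
            and (other["contig"].to_numpy() == fst_windows["contig"].to_numpy()).all()
            and (other["start"].to_numpy() == fst_windows["start"].to_numpy()).all()
            and (other["end"].to_numpy() == fst_windows["end"].to_numpy()).all()
        )
        if not same:
            raise ValueError("window grids of the three inputs differ")
    pi_f = pi_windows_focal["value"].to_numpy(dtype=float)
    pi_r = pi_windows_reference["value"].to_numpy(dtype=float)
    fst = fst_windows["value"].to_numpy(dtype=float)
    positive = pi_f[pi_f > 0]
    floor = positive.min() / 10.0 if len(positive) else 1e-12
    floored = pi_f < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pi_r / np.maximum(pi_f, floor))
    usable = (
        ~fst_windows["low_support"].to_numpy()
        & np.isfinite(fst)
        & np.isfinite(ratio)
    )
    if usable.sum() == 0:
        raise ValueError("no usable windows for the scan")
    # strictly above the quantile: a degenerate axis (all windows tied,
    # e.g. pi_ratio identically zero) then yields no tail at all
    fst_thr = float(np.quantile(fst[usable], 1.0 - tail))
    ratio_thr = float(np.quantile(ratio[usable], 1.0 - tail))
    passed_fst = usable & (fst > fst_thr)
    passed_ratio = usable & (ratio > ratio_thr)
    candidate = passed_fst & passed_ratio
    scan = fst_windows[["contig", "start", "end", "n_snps"]].copy()
    scan["fst_value"] = fst
    scan["pi_ratio"] = ratio
    scan["pi_floor_applied"] = floored
    scan["passed_fst_tail"] = passed_fst
    scan["passed_pi_tail"] = passed_ratio
    scan["candidate"] = candidate
    regions = IntervalSet.from_records(
        [
            (row.contig, row.start, row.end)
            for row in scan.itertuples()
            if row.candidate
        ]
    )
    return scan, regions
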