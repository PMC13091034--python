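"""Gene-flow tests: Patterson's D (ABBA-BABA) with a delete-one block
jackknife, and the U-statistic window scan for adaptive introgression.

Both operate on outgroup-polarized derived-allele frequencies.  For a
population configuration D(W, X; Y, Z) with Z the outgroup,

    ABBA = (1 - pW) pX pY (1 - pZ)
    BABA = pW (1 - pX) pY (1 - pZ)
    D    = sum(ABBA - BABA) / sum(ABBA + BABA)

so D > 0 indicates excess allele sharing between X and the donor Y.
The standard error comes from a delete-one jackknife over contiguous
genomic blocks (default 5 Mb), robust to local LD.

The U scan counts, per window, sites where the derived allele is fixed
in the donor (exactly 100% of called donor alleles, requiring at least
two of them), rare in a non-admixed reference population A (< w) and
common in the focal population B (> x).  Windows in the top 5% of
counts are candidate adaptively introgressed regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FrequencyTable, WindowSpec
from .genotypes import window_site_slices
from .intervals import IntervalSet

log = logging.getLogger(__name__)


@dataclass
class DStatResult:
    pops: tuple[str, str, str, str]  # (W, X, Y, Z)
    sum_abba: float
    sum_baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    block_size_bp: int
    degenerate_se: bool = False


def _require_polarized(freqs: FrequencyTable) -> None:
    if not freqs.polarized:
        raise ValueError(
            "derived-allele frequencies required: polarize by the outgroup first"
        )


def d_statistic(
    freqs: FrequencyTable,
    w_pop: str,
    x_pop: str,
    y_pop: str,
    z_pop: str,
    block_size: int = 5_000_000,
) -> DStatResult:
    """Frequency-based Patterson's D with block-jackknife SE and Z score.

    Sites unpolarizable by the outgroup, or with no called alleles in
    any of the four populations, are excluded.  Raises if the total
    ABBA+BABA is zero (D undefined) or fewer than two non-empty blocks
    exist.
    """
    _require_polarized(freqs)
    p = {pop: freqs.p_derived(pop) for pop in (w_pop, x_pop, y_pop, z_pop)}
    ok = freqs.polarizable.copy()
    for arr in p.values():
        ok &= ~np.isnan(arr)
    pw, px, py, pz = (p[w_pop][ok], p[x_pop][ok], p[y_pop][ok], p[z_pop][ok])
    abba = (1 - pw) * px * py * (1 - pz)
    baba = pw * (1 - px) * py * (1 - pz)
    num = abba - baba
    den = abba + baba
    tot_den = float(den.sum())
    if tot_den == 0.0:
        raise ValueError("D undefined: ABBA + BABA sums to zero")
    d_all = float(num.sum() / tot_den)

    contig = freqs.variants["contig"].to_numpy()[ok]
    pos = freqs.variants["pos"].to_numpy()[ok]
    # contiguous genomic blocks: (contig, floor((pos-1)/block_size))
    block_of = pd.factorize(
        pd.Series(contig).astype(str) + ":" + pd.Series((pos - 1) // block_size).astype(str)
    )[0]
    n_blocks = int(block_of.max()) + 1
    if n_blocks < 2:
        raise ValueError("block jackknife needs at least two non-empty blocks")
    num_b = np.bincount(block_of, weights=num, minlength=n_blocks)
    den_b = np.bincount(block_of, weights=den, minlength=n_blocks)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_jack = (num.sum() - num_b) / (tot_den - den_b)
    d_jack = d_jack[np.isfinite(d_jack)]
    b = len(d_jack)
    se = float(np.sqrt((b - 1) / b * np.sum((d_jack - d_jack.mean()) ** 2)))
    degenerate = se == 0.0
    if degenerate:
        warnings.warn("jackknife SE is zero; Z reported as 0 and flagged degenerate")
        z = 0.0
    else:
        z = d_all / se
    return DStatResult(
        pops=(w_pop, x_pop, y_pop, z_pop),
        sum_abba=float(abba.sum()),
        sum_baba=float(baba.sum()),
        d=d_all,
        se=se,
        z=z,
        n_blocks=b,
        n_sites=int(ok.sum()),
        block_size_bp=block_size,
        degenerate_se=degenerate,
    )


def u50_scan(
    freqs: FrequencyTable,
    a_pop: str,
    b_pop: str,
    c_donor: str,
    windows: list[WindowSpec],
    w: float = 0.01,
    x: float = 0.50,
    y: float = 1.00,
    top_fraction: float = 0.05,
    min_donor_haplotypes: int = 2,
) -> tuple[pd.DataFrame, IntervalSet]:
    """U(w, x, y) adaptive-introgression window scan.

    Counts per window the sites where the derived allele is fixed in
    the donor C (frequency exactly ``y`` = 1.0, judged on integer
    counts over at least ``min_donor_haplotypes`` called alleles), has
    frequency < ``w`` in reference A and > ``x`` in focal B.  Windows
    in the top ``top_fraction`` of counts (and with at least one
    qualifying site) are flagged candidates and merged into intervals.
    """
    _require_polarized(freqs)
    der_c = freqs.derived_count(c_donor)
    n_c = freqs.n_called[c_donor]
    if y == 1.0:
        donor_fixed = (n_c >= min_donor_haplotypes) & (der_c == n_c)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            donor_fixed = (n_c >= min_donor_haplotypes) & (der_c / n_c >= y)
    pa = freqs.p_derived(a_pop)
    pb = freqs.p_derived(b_pop)
    qualifying = (
        freqs.polarizable
        & donor_fixed
        & np.nan_to_num(pa < w, nan=False)
        & np.nan_to_num(pb > x, nan=False)
    )
    cum = np.concatenate([[0], np.cumsum(qualifying)])
    slices = window_site_slices(windows, freqs.variants)
    counts = np.array([cum[hi] - cum[lo] for lo, hi in slices], dtype=int)
    n_snps = np.array([hi - lo for lo, hi in slices], dtype=int)
    if counts.sum() == 0:
        warnings.warn("no qualifying U-scan site genome-wide; empty candidate set")
        tail = np.zeros(len(windows), dtype=bool)
    else:
        # smallest integer count threshold whose exceedance fraction is
        # within the top fraction; counts are small integers with heavy
        # ties at zero, so a plain quantile would over- or under-flag
        thr = None
        for t in range(1, int(counts.max()) + 1):
            if (counts >= t).mean() <= top_fraction:
                thr = t
                break
        tail = counts >= thr if thr is not None else np.zeros(len(windows), bool)
    out = pd.DataFrame(
        {
            "contig": [wd.contig for wd in windows],
            "start": [wd.start for wd in windows],
            "end": [wd.end for wd in windows],
            "n_snps": n_snps,
            "count": counts,
            "tail": tail,
        }
    )
    regions = IntervalSet.from_records(
        [(r.contig, r.start, r.end) for r in out.itertuples() if r.tail]
    )
    return out, regions
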