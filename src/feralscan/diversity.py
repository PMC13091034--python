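"""Windowed nucleotide diversity, per-sample heterozygosity/inbreeding,
and Hudson's FST (per site and as ratio-of-averages over windows).

The Hudson estimator is the Bhatia-style form: per site a numerator
``N = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)`` and denominator
``D = pA(1-pB) + pB(1-pA)``, combined across sites as ``sum(N)/sum(D)``
(ratio of averages, never the average of per-site ratios).  Per-site
values may be negative; the finite-sample correction makes the
estimator unbiased for unequal sample sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    FrequencyTable,
    GenotypeMatrix,
    PopulationMap,
    WindowSpec,
)
from .genotypes import window_site_slices

LOW_SUPPORT_SNPS = 10  # windows below this SNP count are flagged


def site_pi(alt_count: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 j (n - j) / (n (n - 1)).

    Sites with fewer than two called alleles contribute 0.
    """
    j = alt_count.astype(float)
    n = n_called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi


def _window_frame(
    windows: list[WindowSpec], n_snps: np.ndarray, values: np.ndarray, **extra
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": n_snps,
            "value": values,
        }
    )
    for k, v in extra.items():
        df[k] = v
    df["low_support"] = df["n_snps"] < LOW_SUPPORT_SNPS
    return df


def window_pi(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop: str,
    windows: list[WindowSpec],
    per_callable_bp: bool = False,
) -> pd.DataFrame:
    """Windowed nucleotide diversity for one population.

    The window value is the sum of per-site pi divided by the full
    window length in bp (``per_callable_bp=True`` divides by the number
    of genotyped sites instead).
    """
    idx = popmap.sample_indices(gm, pop)
    sub = gm.alleles[idx]
    n_called = (sub != MISSING).sum(axis=(0, 2))
    alt = (sub == 1).sum(axis=(0, 2))
    pi = site_pi(alt, n_called)
    cum = np.concatenate([[0.0], np.cumsum(pi)])
    cum_sites = np.concatenate([[0], np.cumsum(n_called >= 2)])
    slices = window_site_slices(windows, gm.variants)
    n_snps = np.array([hi - lo for lo, hi in slices])
    sums = np.array([cum[hi] - cum[lo] for lo, hi in slices])
    if per_callable_bp:
        lengths = np.array(
            [max(1, cum_sites[hi] - cum_sites[lo]) for lo, hi in slices], dtype=float
        )
    else:
        lengths = np.array([w.length for w in windows], dtype=float)
    return _window_frame(windows, n_snps, sums / lengths)


def het_inbreeding(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-sample observed heterozygosity Ho and inbreeding coefficient F.

    ``F = (O_hom - E_hom) / (n_sites - E_hom)`` where the expected
    homozygous count uses cohort allele frequencies with the small-
    sample correction ``E_hom(site) = 1 - 2 p (1 - p) n/(n - 1)``
    (PLINK ``--het`` convention).  Both statistics count only sites
    called in the sample.
    """
    a = gm.alleles
    called_alleles = (a != MISSING).sum(axis=(0, 2))
    alt = (a == 1).sum(axis=(0, 2))
    n = called_alleles.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
        e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)
    usable = n >= 2
    rows = []
    for i, sample in enumerate(gm.samples):
        g = a[i]
        called = (g != MISSING).all(axis=1) & usable
        n_sites = int(called.sum())
        if n_sites == 0:
            raise ValueError(f"sample {sample} has zero called sites")
        hom = int((g[:, 0] == g[:, 1])[called].sum())
        e_hom = float(e_hom_site[called].sum())
        ho = (n_sites - hom) / n_sites
        denom = n_sites - e_hom
        f = (hom - e_hom) / denom if denom != 0 else float("nan")
        rows.append(
            {
                "sample": sample,
                "population": popmap.assignments.get(sample, ""),
                "observed_hom": hom,
                "expected_hom": e_hom,
                "n_sites": n_sites,
                "Ho": ho,
                "F": f,
            }
        )
    return pd.DataFrame(rows)


def hudson_fst_components(
    freqs: FrequencyTable, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator arrays.

    Sites where either population has fewer than two called alleles get
    NaN in both components and are excluded from any aggregation.
    """
    pa, pb = freqs.p_alt(pop_a), freqs.p_alt(pop_b)
    na = freqs.n_called[pop_a].astype(float)
    nb = freqs.n_called[pop_b].astype(float)
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (pa - pb) ** 2
            - pa * (1 - pa) / (na - 1)
            - pb * (1 - pb) / (nb - 1)
        )
        den = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def hudson_fst(
    freqs: FrequencyTable,
    pop_a: str,
    pop_b: str,
    windows: list[WindowSpec] | None = None,
) -> pd.DataFrame | float:
    """Hudson FST as a ratio of averages.

    With ``windows`` returns a per-window frame (NaN where the summed
    denominator is zero, i.e. both populations monomorphic and
    identical); without windows returns the single genome-wide value.
    """
    num, den = hudson_fst_components(freqs, pop_a, pop_b)
    if windows is None:
        tot = np.nansum(den)
        if tot == 0:
            raise ValueError("FST undefined: zero denominator genome-wide")
        return float(np.nansum(num) / tot)
    cum_n = np.concatenate([[0.0], np.nancumsum(num)])
    cum_d = np.concatenate([[0.0], np.nancumsum(den)])
    cum_sites = np.concatenate([[0], np.cumsum(~np.isnan(den))])
    slices = window_site_slices(windows, freqs.variants)
    n_snps = np.array([cum_sites[hi] - cum_sites[lo] for lo, hi in slices])
    sums_n = np.array([cum_n[hi] - cum_n[lo] for lo, hi in slices])
    sums_d = np.array([cum_d[hi] - cum_d[lo] for lo, hi in slices])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(sums_d != 0, sums_n / sums_d, np.nan)
    return _window_frame(windows, n_snps, vals)
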