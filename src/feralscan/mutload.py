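"""Loss-of-function mutation load.

LoF sites are taken from a consequence-annotation table (the output of
an external annotator) restricted to the five canonical LoF classes:
stop_gained, stop_lost, start_lost, splice_donor_variant and
splice_acceptor_variant.  Per individual the homozygous-derived and
heterozygous LoF genotypes are counted and summarized as

    ratio = 2 * hom / (2 * hom + het)

on outgroup-polarized derived alleles.  "Homozygous" means homozygous
for the derived allele — homozygous-ancestral genotypes carry no
derived load.  Sites the outgroup cannot polarize are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MISSING, FrequencyTable, GenotypeMatrix, PopulationMap
from .synthetic import LOF_CLASSES

log = logging.getLogger(__name__)


def classify_lof(annotation: pd.DataFrame) -> set[tuple[str, int]]:
    """Sites whose consequence is one of the five LoF classes.

    Rows with any other (or unknown) consequence label are ignored;
    the ignored-row count is logged.
    """
    need = {"contig", "pos", "consequence"}
    if not need.issubset(annotation.columns):
        raise OSError(f"annotation table needs columns {sorted(need)}")
    is_lof = annotation["consequence"].isin(LOF_CLASSES)
    n_other = int((~is_lof).sum())
    if n_other:
        log.info("%d non-LoF annotation rows ignored", n_other)
    sub = annotation[is_lof]
    return {
        (str(c), int(p)) for c, p in zip(sub["contig"], sub["pos"])
    }


def lof_burden(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    lof_sites: set[tuple[str, int]],
    freqs: FrequencyTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual homozygous-derived LoF burden and the population
    summary (mean +/- sd of the per-individual ratios, plus the pooled
    ratio computed from summed counts).

    Individuals carrying no called LoF genotype get a NaN ratio and an
    ``undefined`` flag.
    """
    if not freqs.polarized:
        raise ValueError("lof_burden requires outgroup-polarized frequencies")
    keys = list(
        zip(gm.variants["contig"].astype(str), gm.variants["pos"].astype(int))
    )
    site_mask = np.array([k in lof_sites for k in keys], dtype=bool)
    site_mask &= freqs.polarizable
    n_excluded = len(lof_sites) - int(site_mask.sum())
    if n_excluded > 0:
        log.info("%d LoF sites unpolarizable or absent; excluded", n_excluded)
    idx = np.flatnonzero(site_mask)
    # derived allele code: ALT where ancestral is REF, else REF
    derived_code = np.where(freqs.ancestral_is_ref[idx], 1, 0).astype(np.int8)

    rows = []
    for i, sample in enumerate(gm.samples):
        g = gm.alleles[i, idx, :]
        called = (g != MISSING).all(axis=1)
        hom_derived = int(
            ((g[:, 0] == derived_code) & (g[:, 1] == derived_code) & called).sum()
        )
        het = int(((g[:, 0] != g[:, 1]) & called).sum())
        denom = 2 * hom_derived + het
        ratio = 2 * hom_derived / denom if denom > 0 else float("nan")
        rows.append(
            {
                "sample": sample,
                "population": popmap.assignments.get(sample, ""),
                "hom_derived_lof": hom_derived,
                "het_lof": het,
                "ratio": ratio,
                "undefined": denom == 0,
            }
        )
    records = pd.DataFrame(rows)

    summ = []
    for pop, sub in records.groupby("population"):
        ok = sub[~sub["undefined"]]
        hom_tot = int(sub["hom_derived_lof"].sum())
        het_tot = int(sub["het_lof"].sum())
        pooled_denom = 2 * hom_tot + het_tot
        summ.append(
            {
                "population": pop,
                "n_samples": len(sub),
                "mean_ratio": float(ok["ratio"].mean()) if len(ok) else float("nan"),
                "sd_ratio": float(ok["ratio"].std(ddof=1)) if len(ok) > 1 else float("nan"),
                "pooled_ratio": (
                    2 * hom_tot / pooled_denom if pooled_denom > 0 else float("nan")
                ),
            }
        )
    summary = pd.DataFrame(summ)
    return records, summary
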