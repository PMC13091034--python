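"""Genotype-level filtering and the frequency/window scaffolding that
all downstream statistics consume.

Frequencies are always computed over called alleles only.  Outgroup
polarization declares the outgroup's major allele ancestral and
re-expresses population frequencies on the derived scale; sites where
the outgroup is split exactly 50/50 or entirely missing are flagged
unpolarizable and excluded from derived-allele statistics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import (
    MISSING,
    FrequencyTable,
    GenotypeMatrix,
    PopulationMap,
    WindowSpec,
)

log = logging.getLogger(__name__)


def _pop_counts(gm: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = gm.alleles[idx]  # (n, V, 2)
    called = (sub != MISSING).sum(axis=(0, 2))
    alt = (sub == 1).sum(axis=(0, 2))
    return alt.astype(np.int64), called.astype(np.int64)


def filter_maf(
    gm: GenotypeMatrix, popmap: PopulationMap | None, maf_min: float
) -> GenotypeMatrix:
    """Drop variants with cohort-wide minor allele frequency below ``maf_min``.

    MAF is computed over all called alleles in the whole cohort; a site
    with MAF exactly ``maf_min`` is retained.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if maf_min == 0.0:
        return gm
    alt, called = _pop_counts(gm, np.arange(gm.n_samples))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / called, np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    keep &= ~np.isnan(maf)
    if not keep.any():
        warnings.warn("MAF filter removed every variant", stacklevel=2)
    return gm.subset_variants(keep)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy LD pruning on genotype dosages (PLINK ``--indep-pairwise`` style).

    Slides a ``window_snps`` window in ``step_snps`` increments within
    each contig.  Inside a window, pairs of retained SNPs with squared
    dosage correlation above ``r2_max`` lose the later (higher-index)
    member.  Missing dosages are pairwise-deleted.  Returns the sorted
    retained variant indices.
    """
    if gm.n_variants < 2:
        return np.arange(gm.n_variants)
    dos = gm.dosage()  # (samples, variants)
    removed = np.zeros(gm.n_variants, dtype=bool)
    for contig, sl in gm.contig_slices().items():
        lo, hi = sl.start, sl.stop
        start = lo
        while start < hi:
            stop = min(start + window_snps, hi)
            idx = [j for j in range(start, stop) if not removed[j]]
            for a_i, j in enumerate(idx):
                if removed[j]:
                    continue
                for k in idx[a_i + 1 :]:
                    if removed[j]:
                        break
                    if removed[k]:
                        continue
                    r2 = _dosage_r2(dos[:, j], dos[:, k])
                    if r2 is not None and r2 > r2_max:
                        removed[k] = True
            if stop >= hi:
                break
            start += step_snps
    return np.flatnonzero(~removed)


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return None
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return None
    c = np.mean((xs - xs.mean()) * (ys - ys.mean()))
    return float(c * c / (vx * vy))


def allele_frequencies(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    polarize_by_outgroup: bool = False,
) -> FrequencyTable:
    """Per-population ALT-allele counts, optionally outgroup-polarized."""
    for sample in popmap.assignments:
        gm.sample_index(sample)  # raises on unknown sample
    alt: dict[str, np.ndarray] = {}
    called: dict[str, np.ndarray] = {}
    for pop in popmap.populations:
        idx = popmap.sample_indices(gm, pop)
        alt[pop], called[pop] = _pop_counts(gm, idx)
    table = FrequencyTable(gm.variants, alt, called)
    if polarize_by_outgroup:
        og = popmap.outgroup()
        if og not in alt:
            raise KeyError(f"outgroup population {og!r} absent from genotypes")
        og_alt, og_n = alt[og], called[og]
        # outgroup major allele = ancestral; exact 50/50 or all-missing
        # cannot be polarized
        polarizable = (og_n > 0) & (2 * og_alt != og_n)
        ancestral_is_ref = np.where(2 * og_alt < og_n, True, False)
        table.polarized = True
        table.ancestral_is_ref = ancestral_is_ref
        table.polarizable = polarizable
        n_bad = int((~polarizable).sum())
        if n_bad:
            log.info("%d sites unpolarizable by outgroup %s", n_bad, og)
    return table


def make_windows(
    contig_lengths: dict[str, int], size: int = 50_000, step: int = 20_000
) -> list[WindowSpec]:
    """Sliding windows tiling each contig, truncated at the contig end."""
    if not (size >= step > 0):
        raise ValueError(f"need size >= step > 0, got size={size} step={step}")
    out: list[WindowSpec] = []
    for contig, length in contig_lengths.items():
        start = 0
        while start < length:
            out.append(WindowSpec(contig, start, min(start + size, length)))
            start += step
    return out


def window_site_slices(
    windows: list[WindowSpec], variants
) -> list[tuple[int, int]]:
    """For each window, the variant-row range ``[lo, hi)`` of sites inside it.

    Variant positions are 1-based, windows half-open 0-based, so a site
    at ``pos`` is inside ``[start, end)`` iff ``start < pos <= end``.
    """
    contigs = variants["contig"].to_numpy()
    pos = variants["pos"].to_numpy()
    blocks: dict[str, tuple[int, np.ndarray]] = {}
    if len(contigs):
        change = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(contigs)]])
        for s, e in zip(starts, ends):
            blocks[contigs[s]] = (int(s), pos[s:e])
    out: list[tuple[int, int]] = []
    for w in windows:
        if w.contig not in blocks:
            out.append((0, 0))
            continue
        offset, cpos = blocks[w.contig]
        lo = int(np.searchsorted(cpos, w.start, side="right"))
        hi = int(np.searchsorted(cpos, w.end, side="right"))
        out.append((offset + lo, offset + hi))
    return out
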