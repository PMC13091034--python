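"""Core in-memory containers shared by every analysis module.

Coordinate conventions
----------------------
Variant positions are stored 1-based, as in VCF.  All intervals and
windows are 0-based half-open ``[start, end)`` (BED convention).  The
single conversion happens here: a variant at 1-based position ``pos``
occupies the 0-based base ``pos - 1`` and therefore falls in window
``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

ROLE_FOCAL = "focal"
ROLE_REFERENCE = "reference"
ROLE_DONOR = "donor"
ROLE_OUTGROUP = "outgroup"
VALID_ROLES = {ROLE_FOCAL, ROLE_REFERENCE, ROLE_DONOR, ROLE_OUTGROUP}


@dataclass
class GenotypeMatrix:
    """Bi-allelic SNP genotypes for a cohort.

    Attributes
    ----------
    samples : list of str
        Ordered sample labels.
    variants : pandas.DataFrame
        One row per variant with columns ``contig, pos, ref, alt``;
        ``pos`` is 1-based.  Positions are strictly increasing within a
        contig and contigs form contiguous blocks of rows.
    alleles : numpy.ndarray, int8, shape (n_samples, n_variants, 2)
        Allele codes 0 (REF), 1 (ALT) or -1 (missing).
    phased : bool
        Whether the two allele columns are haplotype-resolved.
    """

    samples: list[str]
    variants: pd.DataFrame
    alleles: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.samples), len(self.variants), 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        for contig, sub in self.variants.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def dosage(self) -> np.ndarray:
        """ALT dosage 0/1/2 per sample x variant, NaN where any allele missing."""
        a = self.alleles
        d = a.sum(axis=2).astype(float)
        d[(a == MISSING).any(axis=2)] = np.nan
        return d

    def contig_slices(self) -> dict[str, slice]:
        """Map contig -> slice of variant rows (contigs are row blocks)."""
        out: dict[str, slice] = {}
        contigs = self.variants["contig"].to_numpy()
        if len(contigs) == 0:
            return out
        change = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(contigs)]])
        for s, e in zip(starts, ends):
            out[contigs[s]] = slice(int(s), int(e))
        return out

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = np.sort(mask.astype(int))
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            alleles=self.alleles[:, idx, :],
            phased=self.phased,
        )

    def variant_index(self, contig: str, pos: int) -> int:
        """Row index of the variant at 1-based ``pos`` on ``contig``."""
        sl = self.contig_slices().get(contig)
        if sl is None:
            raise KeyError(f"unknown contig {contig!r}")
        positions = self.variants["pos"].to_numpy()[sl]
        i = int(np.searchsorted(positions, pos))
        if i >= len(positions) or positions[i] != pos:
            raise KeyError(f"no variant at {contig}:{pos}")
        return sl.start + i


@dataclass
class PopulationMap:
    """Sample-to-population assignment plus per-population roles."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"invalid role {role!r} for population {pop!r}")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for pop in self.assignments.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def samples_of(self, pop: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == pop]
        if not out:
            raise KeyError(f"population {pop!r} has no samples")
        return out

    def sample_indices(self, gm: GenotypeMatrix, pop: str) -> np.ndarray:
        return np.array([gm.sample_index(s) for s in self.samples_of(pop)], dtype=int)

    def outgroup(self) -> str:
        out = [p for p, r in self.roles.items() if r == ROLE_OUTGROUP]
        if len(out) != 1:
            raise ValueError(
                f"exactly one outgroup required for polarization, found {len(out)}"
            )
        return out[0]

    def pops_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.roles.items() if r == role]


@dataclass
class FrequencyTable:
    """Per-population allele counts and frequencies at every variant.

    ``alt_count[pop]`` and ``n_called[pop]`` are integer arrays over
    variants; ``p_alt[pop] = alt_count / n_called`` (NaN where nothing
    called).  After outgroup polarization, ``ancestral_is_ref`` says
    which allele was declared ancestral and ``polarizable`` marks sites
    where the outgroup gave a usable majority call.  ``p_derived`` and
    ``derived_count`` are only available when polarized.
    """

    variants: pd.DataFrame
    alt_count: dict[str, np.ndarray]
    n_called: dict[str, np.ndarray]
    polarized: bool = False
    ancestral_is_ref: np.ndarray | None = None
    polarizable: np.ndarray | None = None

    @property
    def populations(self) -> list[str]:
        return list(self.alt_count)

    def p_alt(self, pop: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_called[pop] > 0,
                self.alt_count[pop] / self.n_called[pop],
                np.nan,
            )

    def derived_count(self, pop: str) -> np.ndarray:
        if not self.polarized:
            raise ValueError("frequencies were not polarized by an outgroup")
        alt, n = self.alt_count[pop], self.n_called[pop]
        return np.where(self.ancestral_is_ref, alt, n - alt)

    def p_derived(self, pop: str) -> np.ndarray:
        d = self.derived_count(pop)
        n = self.n_called[pop]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, d / n, np.nan)
        return np.where(self.polarizable, p, np.nan)


@dataclass(frozen=True, order=True)
class WindowSpec:
    """Half-open genomic window ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start
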