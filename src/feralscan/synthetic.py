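"""Synthetic cohort generator with planted, manifest-recorded ground truth.

The simulator emulates a small multi-population resequencing cohort of
the kind used to study feral/landrace cattle: several drift-separated
domestic populations, two divergent wild donor species, and a distant
outgroup used for allele polarization.  Allele frequencies follow the
Balding–Nichols model: at each site an ancestral derived-allele
frequency ``p ~ Uniform(0.05, 0.95)`` is drawn, and each population's
frequency is a ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` draw with its own drift
parameter ``F``.  Haplotypes are independent Bernoulli draws from the
population frequency, so there is no background LD — planted features
(introgression tracts, sweeps, autozygous segments) are the only
spatial structure.

The ALT allele of every simulated site is the derived allele; the
outgroup is simulated with a very small drift ``F`` so its major allele
almost always equals the ancestral (REF) state, making outgroup
polarization realistic but imperfect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ROLE_DONOR,
    ROLE_FOCAL,
    ROLE_OUTGROUP,
    ROLE_REFERENCE,
    GenotypeMatrix,
    PopulationMap,
)

LOF_CLASSES = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_donor_variant",
    "splice_acceptor_variant",
)
NON_LOF_CLASSES = (
    "synonymous_variant",
    "missense_variant",
    "intron_variant",
    "intergenic_variant",
    "3_prime_UTR_variant",
)

_NUCS = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    pass


@dataclass
class PopulationSpec:
    label: str
    n_samples: int
    drift_F: float
    role: str = ROLE_REFERENCE


@dataclass
class CohortConfig:
    """Structural parameters of a simulated cohort.

    ``n_sites`` is per contig; if omitted it is derived from
    ``snp_spacing``.  Positions are evenly spaced and strictly
    increasing within each contig.
    """

    n_contigs: int = 1
    contig_length: int = 10_000_000
    snp_spacing: int = 2_000
    n_sites: int | None = None
    populations: list[PopulationSpec] = field(default_factory=list)
    donor_drift_F: float = 0.8
    # fraction of sites per donor population that are donor-lineage fixed
    # differences: fixed derived in that donor, near-absent elsewhere
    # (incomplete-lineage-sorting leakage below ``leakage_max``).
    # Species-level donors carry many such diagnostic alleles;
    # shared-ancestral-polymorphism drift alone cannot produce them.
    donor_private_fraction: float = 0.08
    leakage_max: float = 0.05
    seed: int = 0
    # per-generation mutation rate / generation time: carried as
    # documented constants for demographic work; unused by the
    # frequency-model simulator.
    mutation_rate: float = 1.26e-8
    generation_time_years: float = 6.0

    def sites_per_contig(self) -> int:
        if self.n_sites is not None:
            return self.n_sites
        return self.contig_length // self.snp_spacing

    def validate(self) -> None:
        if not self.populations:
            raise ConfigurationError("no populations configured")
        for p in self.populations:
            if p.n_samples < 2:
                raise ConfigurationError(
                    f"population {p.label!r} needs >= 2 samples, got {p.n_samples}"
                )
            if not 0.0 < p.drift_F < 1.0:
                raise ConfigurationError(
                    f"population {p.label!r} drift F must be in (0, 1)"
                )
        if self.sites_per_contig() < 1:
            raise ConfigurationError("no sites: contig too short for spacing")


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study design: five domestic populations, two wild
    donors, one outgroup.  Drift values reflect moderately diverged
    breeds (F 0.15–0.25), species-level donor divergence (F 0.8) and a
    near-ancestral outgroup (F 0.01)."""
    pops = [
        PopulationSpec("HKF", 20, 0.15, ROLE_FOCAL),
        PopulationSpec("EAI", 15, 0.15, ROLE_REFERENCE),
        PopulationSpec("SAI", 10, 0.20, ROLE_REFERENCE),
        PopulationSpec("EUT", 15, 0.25, ROLE_REFERENCE),
        PopulationSpec("NEAT", 10, 0.25, ROLE_REFERENCE),
        PopulationSpec("banteng", 4, 0.8, ROLE_DONOR),
        PopulationSpec("gaur", 4, 0.8, ROLE_DONOR),
        PopulationSpec("buffalo", 2, 0.01, ROLE_OUTGROUP),
    ]
    cfg = CohortConfig(populations=pops, seed=seed)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown config field {key!r}")
        setattr(cfg, key, val)
    return cfg


@dataclass
class IntrogressionTract:
    contig: str
    start: int
    end: int
    donor_label: str
    focal_pop: str
    alpha: float


@dataclass
class SweepRegion:
    contig: str
    start: int
    end: int
    focal_pop: str
    intensity: float


@dataclass
class AutozygousSegment:
    sample: str
    contig: str
    start: int
    end: int


@dataclass
class DifferentiatedCnvr:
    contig: str
    start: int
    end: int
    cnv_type: str
    group_cn_means: dict[str, float]


@dataclass
class GroundTruth:
    """Manifest of every planted feature, on 0-based half-open intervals."""

    introgression_tracts: list[IntrogressionTract] = field(default_factory=list)
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    autozygous_segments: list[AutozygousSegment] = field(default_factory=list)
    differentiated_cnvrs: list[DifferentiatedCnvr] = field(default_factory=list)
    background_cnvrs: list[tuple[str, int, int, str]] = field(default_factory=list)
    lof_sites: list[tuple[str, int, str]] = field(default_factory=list)
    pop_freqs: dict[str, np.ndarray] | None = None  # Beta-level frequencies
    ancestral_freq: np.ndarray | None = None
    donor_private_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "introgression_tracts": [vars(t) for t in self.introgression_tracts],
            "sweep_regions": [vars(r) for r in self.sweep_regions],
            "autozygous_segments": [vars(s) for s in self.autozygous_segments],
            "differentiated_cnvrs": [
                dict(vars(c)) for c in self.differentiated_cnvrs
            ],
            "background_cnvrs": [list(c) for c in self.background_cnvrs],
            "lof_sites": [list(s) for s in self.lof_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _check_interval(contig: str, start: int, end: int, config_len: int) -> None:
    if not (0 <= start < end <= config_len):
        raise ValueError(
            f"interval [{start}, {end}) out of bounds on {contig} (len {config_len})"
        )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[GenotypeMatrix, PopulationMap, GroundTruth]:
    """Draw a cohort under the Balding–Nichols frequency model.

    Deterministic given ``config.seed``: identical configs produce
    bit-identical genotype matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per_contig = config.sites_per_contig()
    spacing = config.contig_length // n_per_contig
    n_sites = n_per_contig * config.n_contigs

    contigs: list[str] = []
    positions: list[int] = []
    for c in range(config.n_contigs):
        name = f"chr{c + 1}"
        contigs.extend([name] * n_per_contig)
        positions.extend(((np.arange(n_per_contig) + 1) * spacing).tolist())

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    # ref/alt nucleotides are cosmetic; ALT is the derived allele
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    samples: list[str] = []
    assignments: dict[str, str] = {}
    roles: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    pop_freqs: dict[str, np.ndarray] = {}
    for spec in config.populations:
        F = spec.drift_F
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_pop = rng.beta(a, b)
        pop_freqs[spec.label] = p_pop
        haps = (
            rng.random((spec.n_samples, n_sites, 2)) < p_pop[None, :, None]
        ).astype(np.int8)
        blocks.append(haps)
        for i in range(spec.n_samples):
            name = f"{spec.label}_{i + 1:02d}"
            samples.append(name)
            assignments[name] = spec.label
        roles[spec.label] = spec.role

    variants = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "ref": _NUCS[ref_idx],
            "alt": _NUCS[alt_idx],
        }
    )
    gm = GenotypeMatrix(samples, variants, np.concatenate(blocks, axis=0))
    popmap = PopulationMap(assignments, roles)
    truth = GroundTruth(pop_freqs=pop_freqs, ancestral_freq=p_anc)

    # donor-lineage fixed differences: disjoint site sets per donor,
    # fixed derived in that donor, leakage-level frequency elsewhere
    donors = [s.label for s in config.populations if s.role == ROLE_DONOR]
    frac = config.donor_private_fraction
    if donors and frac > 0:
        free = rng.permutation(n_sites)
        n_per = int(frac * n_sites)
        offset = 0
        for donor in donors:
            sites = np.sort(free[offset : offset + n_per])
            offset += n_per
            truth.donor_private_sites[donor] = sites
            p_leak = rng.uniform(0.0, config.leakage_max, size=len(sites))
            for spec in config.populations:
                idx = popmap.sample_indices(gm, spec.label)
                if spec.label == donor:
                    gm.alleles[np.ix_(idx, sites)] = 1
                    pop_freqs[spec.label][sites] = 1.0
                else:
                    draws = (
                        rng.random((len(idx), len(sites), 2))
                        < p_leak[None, :, None]
                    ).astype(np.int8)
                    gm.alleles[np.ix_(idx, sites)] = draws
                    pop_freqs[spec.label][sites] = p_leak
    return gm, popmap, truth


def _sites_in(gm: GenotypeMatrix, contig: str, start: int, end: int) -> np.ndarray:
    """Variant row indices whose 0-based base lies in [start, end)."""
    inside = (
        (gm.variants["contig"].to_numpy() == contig)
        & (gm.variants["pos"].to_numpy() - 1 >= start)
        & (gm.variants["pos"].to_numpy() - 1 < end)
    )
    return np.flatnonzero(inside)


def plant_introgression(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    truth: GroundTruth,
    tract: tuple[str, int, int],
    donor_pop: str,
    focal_pop: str,
    alpha: float,
    seed: int,
) -> GenotypeMatrix:
    """Replace a fraction ``alpha`` of focal haplotypes with donor draws
    inside a tract.

    Haplotypes are chosen once per haplotype (not per site), so the
    tract carries contiguous donor ancestry the way local-ancestry
    methods assume.  Replacement alleles are Bernoulli draws from the
    donor's empirical allele frequency at each site.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"admixture fraction alpha must be in [0, 1), got {alpha}")
    contig, start, end = tract
    _check_interval(contig, start, end, int(gm.variants["pos"].max()))
    donor_idx = popmap.sample_indices(gm, donor_pop)
    focal_idx = popmap.sample_indices(gm, focal_pop)
    sites = _sites_in(gm, contig, start, end)
    if alpha == 0.0 or len(sites) == 0:
        truth.introgression_tracts.append(
            IntrogressionTract(contig, start, end, donor_pop, focal_pop, alpha)
        )
        return gm
    rng = np.random.default_rng(seed)
    donor_sub = gm.alleles[donor_idx][:, sites, :]
    called = (donor_sub != -1).sum(axis=(0, 2))
    alt = (donor_sub == 1).sum(axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_donor = np.where(called > 0, alt / called, 0.5)
    n_haps = 2 * len(focal_idx)
    # exactly round(alpha * n) haplotypes, chosen once for the whole tract
    n_chosen = int(round(alpha * n_haps))
    chosen = rng.choice(n_haps, size=n_chosen, replace=False)
    for h in np.sort(chosen):
        s, hap = focal_idx[h // 2], h % 2
        gm.alleles[s, sites, hap] = (rng.random(len(sites)) < p_donor).astype(np.int8)
    truth.introgression_tracts.append(
        IntrogressionTract(contig, start, end, donor_pop, focal_pop, alpha)
    )
    return gm


def plant_sweep(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    truth: GroundTruth,
    region: tuple[str, int, int],
    focal_pop: str,
    intensity: float = 0.95,
    seed: int = 0,
) -> GenotypeMatrix:
    """Push focal-population derived-allele frequencies toward fixation
    inside a region (per-site frequency drawn Uniform(intensity, 1])."""
    contig, start, end = region
    _check_interval(contig, start, end, int(gm.variants["pos"].max()))
    for t in truth.introgression_tracts:
        if t.contig == contig and start < t.end and t.start < end:
            raise ValueError(
                "sweep region overlaps a planted introgression tract; "
                "ground truths must stay separable"
            )
    focal_idx = popmap.sample_indices(gm, focal_pop)
    sites = _sites_in(gm, contig, start, end)
    rng = np.random.default_rng(seed)
    q = rng.uniform(intensity, 1.0, size=len(sites))
    if intensity >= 1.0:
        q[:] = 1.0
    draws = (
        rng.random((len(focal_idx), len(sites), 2)) < q[None, :, None]
    ).astype(np.int8)
    gm.alleles[np.ix_(focal_idx, sites)] = draws
    truth.sweep_regions.append(SweepRegion(contig, start, end, focal_pop, intensity))
    return gm


def plant_autozygosity(
    gm: GenotypeMatrix,
    truth: GroundTruth,
    sample: str,
    segment: tuple[str, int, int],
) -> GenotypeMatrix:
    """Copy the sample's first haplotype over its second inside a segment,
    forcing homozygosity everywhere in it."""
    contig, start, end = segment
    _check_interval(contig, start, end, int(gm.variants["pos"].max()))
    s = gm.sample_index(sample)
    sites = _sites_in(gm, contig, start, end)
    gm.alleles[s, sites, 1] = gm.alleles[s, sites, 0]
    truth.autozygous_segments.append(AutozygousSegment(sample, contig, start, end))
    return gm


def simulate_cnv_calls(
    groups: dict[str, list[str]],
    n_background: int = 25,
    n_differentiated: int = 5,
    jitter_bp: int = 1_000,
    seed: int = 0,
    contig: str = "chr1",
    region_length: int = 10_000,
    region_gap: int = 40_000,
    carrier_rate: float = 0.6,
    diff_means: tuple[float, float] = (2.0, 4.0),
    cn_sd: float = 0.3,
    n_junk: int = 10,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-sample CNV call tables over planted regions.

    Background regions draw copy numbers from one shared distribution
    for every carrier; differentiated regions draw group-specific means
    (default 2 vs 4, i.e. the first group carries no call).  Call
    boundaries are jittered by up to ``jitter_bp`` so reciprocal-overlap
    merging is exercised, and a handful of junk calls (short, high p,
    high q0) is appended so the quality filters have work to do.
    """
    if len(groups) < 2:
        raise ConfigurationError("need at least two phenotype groups")
    if jitter_bp >= region_length // 2:
        raise ConfigurationError("jitter must be below half the region length")
    rng = np.random.default_rng(seed)
    all_samples = [s for ss in groups.values() for s in ss]
    group_labels = list(groups)
    truth = GroundTruth()
    rows: list[dict] = []
    pos = region_gap

    def emit(sample: str, start: int, end: int, cnv_type: str, cn: float) -> None:
        js = int(rng.integers(0, jitter_bp + 1))
        je = int(rng.integers(0, jitter_bp + 1))
        rows.append(
            {
                "sample": sample,
                "contig": contig,
                "start": start + js,
                "end": end + je,
                "type": cnv_type,
                "copy_number": round(max(0.0, cn), 3),
                "p_value": float(rng.uniform(1e-9, 1e-4)),
                "q0": float(rng.uniform(0.0, 0.4)),
            }
        )

    for _ in range(n_background):
        start, end = pos, pos + region_length
        cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
        base_cn = 1.0 if cnv_type == "deletion" else 3.0
        for s in all_samples:
            if rng.random() < carrier_rate:
                emit(s, start, end, cnv_type, base_cn + rng.normal(0.0, cn_sd))
        truth.background_cnvrs.append((contig, start, end, cnv_type))
        pos = end + region_gap

    for _ in range(n_differentiated):
        start, end = pos, pos + region_length
        means = dict(zip(group_labels, diff_means))
        for g, samples in groups.items():
            mu = means[g]
            if abs(mu - 2.0) < 1e-9:
                continue  # diploid group: no call, copy number 2 by default
            cnv_type = "deletion" if mu < 2.0 else "duplication"
            for s in samples:
                emit(s, start, end, cnv_type, mu + rng.normal(0.0, cn_sd))
        truth.differentiated_cnvrs.append(
            DifferentiatedCnvr(contig, start, end, "duplication"
                               if max(diff_means) > 2 else "deletion", means)
        )
        pos = end + region_gap

    for _ in range(n_junk):
        start = pos + int(rng.integers(0, region_gap))
        kind = rng.integers(0, 3)
        rows.append(
            {
                "sample": all_samples[int(rng.integers(0, len(all_samples)))],
                "contig": contig,
                "start": start,
                # short call / high p / high q0 — each fails one filter
                "end": start + (800 if kind == 0 else region_length),
                "type": "deletion",
                "copy_number": 1.0,
                "p_value": 0.05 if kind == 1 else 1e-6,
                "q0": 0.7 if kind == 2 else 0.1,
            }
        )
    calls = pd.DataFrame(rows)
    return calls, truth


def annotate_lof(
    gm: GenotypeMatrix, fraction_lof: float, seed: int = 0
) -> pd.DataFrame:
    """Assign consequence classes to every site; a random ``fraction_lof``
    of sites gets one of the five LoF classes, the rest non-LoF labels."""
    if not 0.0 <= fraction_lof < 1.0:
        raise ValueError(f"fraction_lof must be in [0, 1), got {fraction_lof}")
    rng = np.random.default_rng(seed)
    n = gm.n_variants
    is_lof = rng.random(n) < fraction_lof
    classes = np.where(
        is_lof,
        rng.choice(LOF_CLASSES, size=n),
        rng.choice(NON_LOF_CLASSES, size=n),
    )
    return pd.DataFrame(
        {
            "contig": gm.variants["contig"].to_numpy(),
            "pos": gm.variants["pos"].to_numpy(),
            "consequence": classes,
        }
    )
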