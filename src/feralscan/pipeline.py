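"""End-to-end orchestration: simulate a cohort (or load inputs), run the
requested analysis stages in dependency order, and write TSV/BED/JSON
outputs plus a manifest.

Every source of randomness flows from the single top-level ``seed``
via fixed per-stage offsets, so re-running the same config reproduces
every output byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnvmod
from . import diversity, genotypes, introgression, io, mutload, roh, selection
from . import synthetic
from .containers import GenotypeMatrix, PopulationMap
from .intervals import IntervalSet

log = logging.getLogger(__name__)

_STAGE_OFFSETS = {
    "simulate": 11,
    "introgression": 23,
    "sweep": 37,
    "autozygosity": 41,
    "lof": 53,
    "cnv": 67,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 9973 + _STAGE_OFFSETS.get(stage, 97)) % (2**31 - 1)


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (generic helper for the scan outputs)."""
    from scipy.stats import false_discovery_control

    p = np.asarray(p_values, dtype=float)
    return false_discovery_control(p, method="bh")


def annotate_regions(
    candidate_intervals: IntervalSet, gene_bed: list[tuple[str, int, int, str]]
) -> pd.DataFrame:
    """Genes overlapping each candidate interval by >= 1 bp (half-open)."""
    rows = []
    for contig, start, end in candidate_intervals.to_records():
        for g_contig, g_start, g_end, name in gene_bed:
            if g_contig != contig:
                continue
            ov = min(end, g_end) - max(start, g_start)
            if ov > 0:
                rows.append(
                    {
                        "contig": contig,
                        "start": start,
                        "end": end,
                        "gene": name,
                        "gene_start": g_start,
                        "gene_end": g_end,
                        "overlap_bp": ov,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "gene", "gene_start", "gene_end",
                 "overlap_bp"],
    )


def _simulate_stage(
    cfg: dict, seed: int, out: Path, manifest: dict
) -> tuple[GenotypeMatrix, PopulationMap, synthetic.GroundTruth, pd.DataFrame | None,
           pd.DataFrame | None, dict[str, str]]:
    sim = cfg.get("simulate", {}) or {}
    overrides = {
        k: sim[k]
        for k in ("n_contigs", "contig_length", "snp_spacing", "n_sites")
        if k in sim
    }
    config = synthetic.default_config(seed=_stage_seed(seed, "simulate"), **overrides)
    gm, popmap, truth = synthetic.simulate_cohort(config)

    for i, t in enumerate(sim.get("introgression", []) or []):
        synthetic.plant_introgression(
            gm, popmap, truth,
            (t["contig"], int(t["start"]), int(t["end"])),
            donor_pop=t["donor"], focal_pop=t.get("focal", _focal(cfg, popmap)),
            alpha=float(t["alpha"]),
            seed=_stage_seed(seed, "introgression") + i,
        )
    for i, r in enumerate(sim.get("sweeps", []) or []):
        synthetic.plant_sweep(
            gm, popmap, truth,
            (r["contig"], int(r["start"]), int(r["end"])),
            focal_pop=r.get("focal", _focal(cfg, popmap)),
            intensity=float(r.get("intensity", 0.95)),
            seed=_stage_seed(seed, "sweep") + i,
        )
    for s in sim.get("autozygosity", []) or []:
        synthetic.plant_autozygosity(
            gm, truth, s["sample"], (s["contig"], int(s["start"]), int(s["end"]))
        )

    annotation = None
    if sim.get("lof_fraction"):
        annotation = synthetic.annotate_lof(
            gm, float(sim["lof_fraction"]), seed=_stage_seed(seed, "lof")
        )
        io.write_table(annotation, out / "annotation.tsv")

    phenotype_map = _phenotypes(popmap, _focal(cfg, popmap))
    cnv_calls = None
    cnv_cfg = sim.get("cnv")
    if cnv_cfg:
        groups: dict[str, list[str]] = {}
        for s, g in phenotype_map.items():
            groups.setdefault(g, []).append(s)
        cnv_calls, cnv_truth = synthetic.simulate_cnv_calls(
            groups,
            n_background=int(cnv_cfg.get("n_background", 25)),
            n_differentiated=int(cnv_cfg.get("n_differentiated", 5)),
            jitter_bp=int(cnv_cfg.get("jitter_bp", 1000)),
            seed=_stage_seed(seed, "cnv"),
        )
        truth.differentiated_cnvrs = cnv_truth.differentiated_cnvrs
        truth.background_cnvrs = cnv_truth.background_cnvrs
        io.write_table(cnv_calls, out / "cnv_calls.tsv")

    contig_lengths = {
        f"chr{c + 1}": config.contig_length for c in range(config.n_contigs)
    }
    io.write_vcf(gm, out / "cohort.vcf", contig_lengths)
    io.write_population_map(popmap, out / "population_map.tsv")
    pheno_df = pd.DataFrame(
        {"sample": list(phenotype_map), "group": list(phenotype_map.values())}
    )
    io.write_table(pheno_df, out / "phenotypes.tsv")
    truth.to_json(out / "ground_truth.json")
    _truth_bed(truth, out / "ground_truth.bed")
    manifest["simulate"] = {
        "n_samples": gm.n_samples,
        "n_variants": gm.n_variants,
        "n_introgression_tracts": len(truth.introgression_tracts),
        "n_sweeps": len(truth.sweep_regions),
        "n_autozygous_segments": len(truth.autozygous_segments),
    }
    return gm, popmap, truth, annotation, cnv_calls, phenotype_map


def _truth_bed(truth: synthetic.GroundTruth, path: Path) -> None:
    recs = []
    for t in truth.introgression_tracts:
        recs.append((t.contig, t.start, t.end,
                     f"introgression:{t.donor_label}:{t.alpha}"))
    for r in truth.sweep_regions:
        recs.append((r.contig, r.start, r.end, f"sweep:{r.focal_pop}"))
    for s in truth.autozygous_segments:
        recs.append((s.contig, s.start, s.end, f"autozygous:{s.sample}"))
    io.write_bed(recs, path)


def _load_inputs(
    cfg: dict, manifest: dict
) -> tuple[GenotypeMatrix, PopulationMap, synthetic.GroundTruth,
           pd.DataFrame | None, pd.DataFrame | None, dict[str, str]]:
    """Load a cohort from files instead of simulating one."""
    inputs = cfg["inputs"]
    if "vcf" not in inputs or "population_map" not in inputs:
        raise ValueError("inputs block needs 'vcf' and 'population_map' paths")
    gm, _ = io.read_vcf(inputs["vcf"])
    popmap = io.read_population_map(inputs["population_map"])
    annotation = (
        io.read_annotation(inputs["annotation"]) if inputs.get("annotation") else None
    )
    cnv_calls = (
        io.read_cnv_calls(inputs["cnv_calls"]) if inputs.get("cnv_calls") else None
    )
    if inputs.get("phenotypes"):
        ph = io.read_table(inputs["phenotypes"])
        phenotype_map = dict(zip(ph["sample"].astype(str), ph["group"].astype(str)))
    else:
        phenotype_map = _phenotypes(popmap, _focal(cfg, popmap))
    manifest["inputs"] = {
        "n_samples": gm.n_samples, "n_variants": gm.n_variants,
    }
    return gm, popmap, synthetic.GroundTruth(), annotation, cnv_calls, phenotype_map


def _focal(cfg: dict, popmap: PopulationMap) -> str:
    if "focal" in cfg:
        return cfg["focal"]
    focal = popmap.pops_with_role("focal")
    if len(focal) != 1:
        raise ValueError("config must name a focal population")
    return focal[0]


def _phenotypes(popmap: PopulationMap, focal: str) -> dict[str, str]:
    """Deterministic two-group split of the focal population (coat color)."""
    samples = popmap.samples_of(focal)
    half = len(samples) // 2
    return {
        s: ("black" if i < half else "yellow") for i, s in enumerate(samples)
    }


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ["simulate"])
    manifest: dict = {"seed": seed, "stages": list(stages)}

    if cfg.get("inputs"):
        gm, popmap, truth, annotation, cnv_calls, phenotype_map = _load_inputs(
            cfg, manifest
        )
    elif "simulate" in stages:
        gm, popmap, truth, annotation, cnv_calls, phenotype_map = _simulate_stage(
            cfg, seed, out, manifest
        )
    else:
        raise ValueError(
            "config needs either an 'inputs' block or the simulate stage"
        )

    wcfg = cfg.get("windows", {}) or {}
    contig_lengths = {
        c: int(gm.variants.loc[gm.variants["contig"] == c, "pos"].max())
        for c in gm.variants["contig"].unique()
    }
    windows = genotypes.make_windows(
        contig_lengths,
        size=int(wcfg.get("size", 50_000)),
        step=int(wcfg.get("step", 20_000)),
    )
    focal = _focal(cfg, popmap)
    reference = cfg.get("reference") or popmap.pops_with_role("reference")[0]
    freqs = genotypes.allele_frequencies(gm, popmap, polarize_by_outgroup=True)

    if "diversity" in stages:
        for pop in (focal, reference):
            pi = diversity.window_pi(gm, popmap, pop, windows)
            io.write_table(pi, out / f"pi_{pop}.tsv")
        het = diversity.het_inbreeding(gm, popmap)
        io.write_table(het, out / "het_inbreeding.tsv")
        fst_w = diversity.hudson_fst(freqs, focal, reference, windows)
        io.write_table(fst_w, out / f"fst_{focal}_{reference}.tsv")
        manifest["diversity"] = {"n_windows": len(windows)}

    if "sweep_scan" in stages:
        others = [p for p in popmap.pops_with_role("reference")]
        di_records, di_top = selection.di_statistic(
            freqs, focal, others,
            top_fraction=float(cfg.get("di_top_fraction", 0.001)),
        )
        io.write_table(di_records, out / "di_snps.tsv")
        fst_w = diversity.hudson_fst(freqs, focal, reference, windows)
        pi_f = diversity.window_pi(gm, popmap, focal, windows)
        pi_r = diversity.window_pi(gm, popmap, reference, windows)
        scan, regions = selection.fst_pi_ratio_scan(
            fst_w, pi_f, pi_r, tail=float(cfg.get("sweep_tail", 0.01))
        )
        io.write_table(scan, out / "sweep_scan.tsv")
        io.write_bed(regions.to_records(), out / "sweep_candidates.bed")
        manifest["sweep_scan"] = {
            "n_di_selected": len(di_top),
            "n_candidate_regions": len(regions.to_records()),
        }

    if "dstat" in stages:
        dcfg = cfg.get("dstat", {}) or {}
        res = introgression.d_statistic(
            freqs,
            dcfg.get("w", reference),
            dcfg.get("x", focal),
            dcfg.get("y", popmap.pops_with_role("donor")[0]),
            dcfg.get("z", popmap.outgroup()),
            block_size=int(dcfg.get("block_size", 5_000_000)),
        )
        io.write_table(
            pd.DataFrame(
                [
                    {
                        "W": res.pops[0], "X": res.pops[1],
                        "Y": res.pops[2], "Z": res.pops[3],
                        "D": res.d, "SE": res.se, "Z_score": res.z,
                        "n_blocks": res.n_blocks, "n_sites": res.n_sites,
                    }
                ]
            ),
            out / "dstat.tsv",
        )
        manifest["dstat"] = {"D": res.d, "Z": res.z}

    if "u50" in stages:
        ucfg = cfg.get("u50", {}) or {}
        u_df, u_regions = introgression.u50_scan(
            freqs,
            ucfg.get("a", reference),
            ucfg.get("b", focal),
            ucfg.get("c", popmap.pops_with_role("donor")[0]),
            windows,
        )
        io.write_table(u_df, out / "u50_windows.tsv")
        io.write_bed(u_regions.to_records(), out / "u50_candidates.bed")
        manifest["u50"] = {"n_candidate_windows": int(u_df["tail"].sum())}

    if "roh" in stages:
        segments = roh.detect_roh(gm)
        if len(segments) >= 30:
            fit = roh.fit_roh_mixture(segments, k=3, seed=seed)
            segments = roh.classify_segments(segments, fit)
        io.write_table(segments, out / "roh_segments.tsv")
        common = {}
        for pop in popmap.populations:
            if popmap.roles.get(pop) == "outgroup":
                continue
            try:
                common[pop] = roh.common_roh(segments, popmap, pop)
            except (KeyError, ValueError):
                continue
        if focal in common:
            spec = roh.specific_roh(common, focal)
            io.write_bed(spec.to_records(), out / f"roh_specific_{focal}.bed")
        burden, tests, corr = roh.roh_burden_compare(segments, popmap)
        io.write_table(burden, out / "roh_burden.tsv")
        io.write_table(tests, out / "roh_tests.tsv")
        io.write_table(corr, out / "roh_correlation.tsv")
        manifest["roh"] = {"n_segments": len(segments)}

    if "load" in stages and annotation is not None:
        lof_sites = mutload.classify_lof(annotation)
        records, summary = mutload.lof_burden(gm, popmap, lof_sites, freqs)
        io.write_table(records, out / "lof_burden.tsv")
        io.write_table(summary, out / "lof_summary.tsv")
        manifest["load"] = {"n_lof_sites": len(lof_sites)}

    if "cnv" in stages and cnv_calls is not None:
        filtered = cnvmod.filter_calls(cnv_calls)
        cnvrs = cnvmod.merge_cnvrs(filtered)
        mat = cnvmod.copy_number_matrix(cnvrs, gm.samples)
        io.write_table(mat, out / "cnvr_matrix.tsv")
        vst = cnvmod.vst_scan(
            cnvrs, phenotype_map, "black", "yellow",
            top_fraction=float(cfg.get("vst_top_fraction", 0.01)),
        )
        io.write_table(vst, out / "cnvr_vst.tsv")
        manifest["cnv"] = {
            "n_calls_raw": len(cnv_calls),
            "n_calls_filtered": len(filtered),
            "n_cnvrs": len(cnvrs),
            "n_vst_candidates": int(vst["candidate"].sum()),
        }

    gene_bed_path = cfg.get("gene_bed")
    if gene_bed_path:
        genes = io.read_bed(gene_bed_path)
        for bed_name in ("sweep_candidates.bed", "u50_candidates.bed"):
            p = out / bed_name
            if p.exists():
                regions = IntervalSet.from_records(
                    [(c, s, e) for c, s, e, *_ in io.read_bed(p)]
                )
                hits = annotate_regions(regions, genes)
                io.write_table(hits, out / bed_name.replace(".bed", "_genes.tsv"))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
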