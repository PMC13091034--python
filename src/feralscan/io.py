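"""File-format I/O: VCF, population/phenotype maps, annotation and CNV
call tables, BED tracks.

VCF reading goes through :mod:`cyvcf2`; writing emits minimal VCF v4.2
text directly, which keeps synthetic cohorts plain-text and round-trip
stable.  Only bi-allelic SNPs are loaded — multi-allelic and non-SNP
records are skipped with a count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass
class VcfReadStats:
    n_loaded: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def read_vcf(
    path: str | Path, region: str | None = None
) -> tuple[GenotypeMatrix, VcfReadStats]:
    """Load bi-allelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Returns the matrix and a skip-count record.  Missing genotypes are
    preserved as ``-1``; phase is taken from the first genotype record.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    stats = VcfReadStats()
    contigs: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    phased = True
    it = vcf(region) if region else vcf
    for v in it:
        if len(v.ALT) != 1:
            stats.n_skipped_multiallelic += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            stats.n_skipped_non_snp += 1
            continue
        gts = np.asarray(v.genotypes, dtype=int)  # (n_samples, 3): a0, a1, phased
        if gts.shape != (len(samples), 3):
            raise OSError(f"malformed GT at {v.CHROM}:{v.POS} in {path}")
        phased = phased and bool(gts[:, 2].all())
        alleles = gts[:, :2].astype(np.int8)
        alleles[alleles < 0] = MISSING
        contigs.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(alleles)
        stats.n_loaded += 1
    vcf.close()
    if stats.n_skipped_multiallelic or stats.n_skipped_non_snp:
        log.info(
            "%s: skipped %d multi-allelic and %d non-SNP records",
            path,
            stats.n_skipped_multiallelic,
            stats.n_skipped_non_snp,
        )
    variants = pd.DataFrame(
        {"contig": contigs, "pos": positions, "ref": refs, "alt": alts}
    )
    alleles_arr = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0, 2), dtype=np.int8)
    )
    return GenotypeMatrix(samples, variants, alleles_arr, phased=phased), stats


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    sep = "|" if gm.phased else "/"
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##contig=<ID={contig},length={length}>\n")
        else:
            for contig in gm.variants["contig"].unique():
                fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        contigs = gm.variants["contig"].to_numpy()
        pos = gm.variants["pos"].to_numpy()
        refs = gm.variants["ref"].to_numpy()
        alts = gm.variants["alt"].to_numpy()
        a = gm.alleles
        for j in range(gm.n_variants):
            gts = []
            for i in range(gm.n_samples):
                a0, a1 = a[i, j, 0], a[i, j, 1]
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                gts.append(f"{s0}{sep}{s1}")
            fh.write(
                f"{contigs[j]}\t{pos[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tpopulation\trole\n")
        for sample, pop in popmap.assignments.items():
            role = popmap.roles.get(pop, "")
            fh.write(f"{sample}\t{pop}\t{role}\n")


def read_population_map(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df or "population" not in df:
        raise OSError(f"{path}: need 'sample' and 'population' columns")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise OSError(f"{path}: sample {dup!r} assigned more than once")
    assignments = dict(zip(df["sample"], df["population"]))
    roles: dict[str, str] = {}
    if "role" in df:
        for pop, sub in df.groupby("population"):
            vals = sub["role"].dropna().unique()
            if len(vals) == 1 and vals[0]:
                roles[pop] = vals[0]
    return PopulationMap(assignments, roles)


def write_table(df: pd.DataFrame, path: str | Path,
                float_format: str = "%.6g") -> None:
    """TSV with header; fixed float format keeps reruns byte-identical."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"contig", "pos", "consequence"}
    if not need.issubset(df.columns):
        raise OSError(f"{path}: annotation table needs columns {sorted(need)}")
    return df


def read_cnv_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "contig", "start", "end", "type", "copy_number",
            "p_value", "q0"}
    if not need.issubset(df.columns):
        raise OSError(f"{path}: CNV call table needs columns {sorted(need)}")
    return df


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a 3+ column BED; returns (contig, start, end, name)."""
    out: list[tuple[str, int, int, str]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OSError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise OSError(f"{path}:{lineno}: non-integer coordinates") from None
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], start, end, name))
    return out


def write_bed(records: list[tuple], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
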