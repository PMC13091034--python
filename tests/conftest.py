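import numpy as np
import pandas as pd
import pytest

from feralscan.containers import GenotypeMatrix, PopulationMap


def make_gm(
    genos,
    contig: str = "chr1",
    spacing: int = 1_000,
    phased: bool = True,
    samples: list[str] | None = None,
    positions: list[int] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a literal (samples x variants x 2) array."""
    genos = np.asarray(genos, dtype=np.int8)
    n_samples, n_variants = genos.shape[0], genos.shape[1]
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if positions is None:
        positions = [(j + 1) * spacing for j in range(n_variants)]
    variants = pd.DataFrame(
        {
            "contig": [contig] * n_variants,
            "pos": positions,
            "ref": ["A"] * n_variants,
            "alt": ["G"] * n_variants,
        }
    )
    return GenotypeMatrix(samples, variants, genos, phased=phased)


def simple_popmap(gm: GenotypeMatrix, pops: dict[str, list[str]],
                  roles: dict[str, str] | None = None) -> PopulationMap:
    assignments = {s: p for p, ss in pops.items() for s in ss}
    return PopulationMap(assignments, roles or {})


@pytest.fixture(scope="session")
def small_cohort():
    """Default 10 Mb / 2 kb-spacing cohort shared by read-only tests."""
    import feralscan as fs

    cfg = fs.default_config(seed=11)
    gm, popmap, truth = fs.simulate_cohort(cfg)
    return cfg, gm, popmap, truth
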