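
import pandas as pd
import pytest

from karyoshift.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact cohort: ~160 divergent sites, 40 genes, 3 lines."""
    return SimConfig(
        n_scaffolds=2,
        scaffold_length=40_000,
        snp_density=2.0,
        n_genes=40,
        offspring_p=(0.4, 0.6),
        seed=20,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_records(small_cohort) -> pd.DataFrame:
    return pd.concat(small_cohort.dna.values(), ignore_index=True)


def pooled_wgs(records: pd.DataFrame) -> pd.DataFrame:
    """Pool a line's replicates into one deep WGS-like record set."""
    pooled = records.groupby(["scaffold", "pos", "ref", "alt"], as_index=False).agg(
        ref_depth=("ref_depth", "sum"), alt_depth=("alt_depth", "sum")
    )
    pooled["total_depth"] = pooled["ref_depth"] + pooled["alt_depth"]
    pooled["n_alts"] = 1
    pooled["is_snp"] = True
    pooled["qual"] = 60.0
    return pooled
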