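import numpy as np
import pandas as pd
import pytest

from cumulcnv import (BinMatrix, CohortSpec, EventSpec, probe_table_from_frame,
                      synth_bin_cohort)
from cumulcnv.simulate import make_arm_table, make_bin_map


@pytest.fixture
def small_probes():
    """30 probes on chromosomes 1 and 2 with gene annotation."""
    rows = []
    rng = np.random.default_rng(7)
    for chrom, n in (("1", 20), ("2", 10)):
        pos = np.sort(rng.choice(np.arange(1, 200_000), size=n, replace=False))
        for k, p in enumerate(pos):
            rows.append({"probe_id": f"cg{chrom}_{k}", "chrom": chrom,
                         "pos": int(p), "gene": f"G{chrom}"})
    return probe_table_from_frame(pd.DataFrame(rows))


@pytest.fixture
def tiny_bin_map():
    return make_bin_map({"1": 30, "2": 20})


@pytest.fixture
def null_cohort():
    """10 samples x 50 bins of pure noise (sd 0.1), seeded."""
    cohort, _ = synth_bin_cohort(
        CohortSpec(n_samples=10, chrom_bins={"1": 30, "2": 20}, seed=11))
    return cohort


@pytest.fixture
def step_cohort():
    """5 samples with a strong shared gain on chr1 bins 10..19."""
    spec = CohortSpec(n_samples=5, chrom_bins={"1": 40, "2": 20}, seed=3,
                      events=[EventSpec("1", 10, 19, 1.0, 1.0)])
    cohort, truth = synth_bin_cohort(spec)
    return cohort, truth


@pytest.fixture
def small_arms():
    return make_arm_table({"1": 30, "2": 20})


def constant_bin_matrix(values_by_chrom: dict[str, float], n_bins: int = 10,
                        n_samples: int = 3) -> BinMatrix:
    """Helper: piecewise-constant cohort, identical across samples."""
    bin_map = make_bin_map({c: n_bins for c in values_by_chrom})
    vals = np.concatenate([np.full(n_bins, v) for v in values_by_chrom.values()])
    values = np.tile(vals[:, None], (1, n_samples))
    samples = [f"S{i}" for i in range(n_samples)]
    return BinMatrix(values, bin_map, samples,
                     np.full_like(values, 0.01))
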