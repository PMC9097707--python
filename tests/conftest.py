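import numpy as np
import pandas as pd
import pytest

import tgmeth
from tgmeth import SimulationConfig
from tgmeth.matrix import MethylationMatrix, SampleSheet


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast default-structured configuration (6k CpGs)."""
    return SimulationConfig(n_cpgs=6000, n_genes=60, master_seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    ann = tgmeth.simulate_annotation(small_config)
    matrix, sheet, truth = tgmeth.simulate_experiment(small_config, ann)
    return ann, matrix, sheet, truth


def make_matrix(meth, total, chrom="chr1", samples=None) -> MethylationMatrix:
    """Toy matrix builder from 2-D lists/arrays (sites x samples)."""
    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    n, s = meth.shape
    sites = pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n + 1) * 10})
    if samples is None:
        samples = [f"s{i}" for i in range(s)]
    return MethylationMatrix(sites, list(samples), meth, total)


def make_sheet(sample_ids, treatment="control", experiment="T1",
               generation="F1") -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "experiment": experiment,
        "treatment": treatment,
        "generation": generation,
        "clone_line": [f"B{i % 5 + 1}" for i in range(len(sample_ids))],
    }))
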