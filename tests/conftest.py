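import numpy as np
import pandas as pd
import pytest

from canrec.gmap import GeneticMap
from canrec.simulate import ArtifactRates, SimConfig


def uniform_map(chrom="chr1", length_bp=100_000_000, rate=1.0, n_intervals=100,
                sex="sex-averaged"):
    """A single-chromosome map with constant rate (cM/Mb)."""
    edges = np.linspace(0, length_bp, n_intervals + 1)
    return GeneticMap.from_rates(chrom, edges[:-1], edges[1:],
                                 np.full(n_intervals, rate), sex=sex)


def make_calls(rows):
    """Call table from (meiosis, parent, sex, chrom, left, right, prob) tuples."""
    return pd.DataFrame(
        [{"meiosis_id": m, "parent_id": p, "child_id": m + "c", "parent_sex": s,
          "chrom": c, "left_bp": float(l), "right_bp": float(r),
          "probability": float(pr)}
         for m, p, s, c, l, r, pr in rows]
    )


@pytest.fixture
def small_sim_config():
    """Compact 4-chromosome design used across simulator tests."""
    chroms = {f"chr{i}": 60_000_000 for i in range(1, 5)}
    return SimConfig(
        n_meioses_per_sex=24,
        chrom_lengths=chroms,
        genetic_lengths={"female": {c: 70.0 for c in chroms},
                         "male": {c: 55.0 for c in chroms}},
        censor_fraction=0.1,
        seed=11,
    )


@pytest.fixture
def artifact_sim_config(small_sim_config):
    cfg = small_sim_config
    cfg.artifact_rates = ArtifactRates(cluster_groups=5.0, outlier_fraction=0.05)
    return cfg
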