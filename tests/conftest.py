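import numpy as np
import pandas as pd
import pytest

from methylquad import (
    MethylationMatrix,
    SimulationConfig,
    compute_ams,
    scale_per_region_class,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort at a fixed seed."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_scaled(default_cohort):
    c = default_cohort
    ams = compute_ams(
        c.counts,
        c.roi_info["length"],
        c.library_sizes,
        c.samples,
        cpg_counts=c.roi_info["cpg_count"],
    )
    return scale_per_region_class(ams)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, smaller cohort for plumbing-level tests."""
    cfg = SimulationConfig(
        n_genes=80,
        n_pairs_per_subtype=5,
        n_planted_hyper=3,
        n_planted_hypo=3,
        n_shared=2,
        n_clinical_subjects=60,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_matrix():
    """Tiny paired matrix with one clear hyper and one clear hypo row."""
    samples = pd.DataFrame(
        {
            "subtype": ["TNBC"] * 8,
            "tumor_normal": ["tumor", "normal"] * 4,
            "pair_id": np.repeat([f"P{i}" for i in range(4)], 2),
        },
        index=[f"S{i}" for i in range(8)],
    )
    t_cols = samples.index[samples.tumor_normal == "tumor"]
    n_cols = samples.index[samples.tumor_normal == "normal"]
    values = pd.DataFrame(
        0.5, index=["gA|CDS", "gB|CDS", "gC|CDS"], columns=samples.index
    )
    values.loc["gA|CDS", t_cols] = [0.82, 0.80, 0.78, 0.81]
    values.loc["gA|CDS", n_cols] = [0.50, 0.49, 0.52, 0.51]
    values.loc["gB|CDS", t_cols] = [0.18, 0.20, 0.22, 0.21]
    values.loc["gB|CDS", n_cols] = [0.52, 0.50, 0.49, 0.50]
    values.loc["gC|CDS", t_cols] = [0.51, 0.49, 0.50, 0.52]
    values.loc["gC|CDS", n_cols] = [0.50, 0.51, 0.49, 0.50]
    return MethylationMatrix(values, samples, scaled=True)
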