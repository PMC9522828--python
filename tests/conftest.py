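import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from alphamark.read_io import build_distributions
from alphamark.regions import RegionIndex
from alphamark.simulate import Cohort, SimConfig, Truth, make_toy_reference, simulate_cohort, simulate_sample

SMALL_CONFIG = SimConfig(
    n_regions=80,
    n_pairs_per_type=6,
    n_normals_per_tissue=4,
    n_cancer_plasma_per_type=6,
    n_noncancer_plasma=30,
    n_shared_hyper=5,
    n_shared_hypo=5,
    n_type_hyper=2,
    n_type_hypo=2,
    n_tissue_hyper=2,
    n_tissue_hypo=2,
)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A desk-scale cohort shared by discovery/pipeline tests."""
    return simulate_cohort(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_dists(small_cohort):
    dists, _ = build_distributions(small_cohort.reads, RegionIndex(small_cohort.regions))
    return dists


def make_pair_data(
    seed: int,
    n_regions: int = 50,
    n_pairs: int = 10,
    depth: int = 30,
    delta: float = 0.6,
    n_dmr: int = 5,
    direction: str = "hyper",
    kappa: float = 5.0,
):
    """Minimal paired tumor/normal simulation with planted DMRs.

    Returns (alpha distributions, region ids, sample pairs, planted region ids).
    """
    rng = np.random.default_rng(seed)
    _, regions = make_toy_reference(seed, n_regions)
    region_ids = [r.region_id for r in regions]
    baseline = rng.uniform(0.05, 0.95, size=n_regions)
    levels = pd.DataFrame({"normal": baseline.copy(), "tumor": baseline.copy()}, index=region_ids)
    dmr_idx = rng.choice(n_regions, n_dmr, replace=False) if n_dmr else np.array([], dtype=int)
    for i in dmr_idx:
        if direction == "hyper":
            base = rng.uniform(0.05, 1.0 - delta - 0.05)
            levels.iloc[i] = [base, base + delta]
        else:
            base = rng.uniform(delta + 0.05, 0.95)
            levels.iloc[i] = [base, base - delta]
    truth = Truth(regions, levels, pd.DataFrame(), {})
    frames = []
    pairs = []
    for p in range(n_pairs):
        t_id, n_id = f"t{p}", f"n{p}"
        frames.append(simulate_sample(truth, "tumor", depth, kappa, rng, t_id))
        frames.append(simulate_sample(truth, "normal", depth, kappa, rng, n_id))
        pairs.append((t_id, n_id))
    reads = pd.concat(frames, ignore_index=True)
    dists, _ = build_distributions(reads, RegionIndex(regions))
    planted = [region_ids[i] for i in dmr_idx]
    return dists, region_ids, pairs, planted
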