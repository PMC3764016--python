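import numpy as np
import pandas as pd
import pytest

import tfsig


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset under the default stated world (seed 11)."""
    return tfsig.simulate_dataset(tfsig.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_pipeline(default_dataset):
    """Full in-memory pipeline on the default dataset (links with gamma,
    both mixture fits, genome-wide binding profile)."""
    ds = default_dataset
    links = tfsig.assign_peaks_to_genes(ds.peaks, ds.genes)
    dmix = tfsig.fit_distance_mixture(links)
    links = tfsig.peak_functional_posterior(links, dmix)
    scores = tfsig.binding_scores(links, ds.genes)
    smix = tfsig.fit_score_mixture(scores)
    profile = tfsig.build_binding_profile(
        ds.genes, tfsig.binding_probabilities(scores, smix)
    )
    return {"ds": ds, "links": links, "dmix": dmix, "smix": smix, "profile": profile}


@pytest.fixture()
def toy_genes():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "chrom": ["chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+"],
            "tss": [1_500_000, 3_000_000, 2_000_000],
        }
    )


def make_random_instance(rng, n_genes=20, n_peaks=60, span=4_000_000):
    """Small random peaks+genes pair for brute-force comparisons."""
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": rng.choice(["chrA", "chrB"], size=n_genes),
            "strand": rng.choice(["+", "-"], size=n_genes),
            "tss": rng.integers(0, span, size=n_genes),
        }
    )
    start = rng.integers(0, span, size=n_peaks)
    peaks = pd.DataFrame(
        {
            "chrom": rng.choice(["chrA", "chrB"], size=n_peaks),
            "start": start,
            "end": start + rng.integers(1, 500, size=n_peaks),
            "intensity": rng.gamma(2.0, 2.0, size=n_peaks),
            "summit_offset": np.nan,
        }
    )
    return genes, peaks
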