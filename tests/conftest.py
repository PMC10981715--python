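"""Shared fixtures: a small simulated dataset and HMM parameter helpers.

Everything is generated programmatically at session scope; no stored
binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from fragmeth.features import (
    FilterConfig, attach_truth, build_cpg_index, extract_fragments, zscore_features,
)
from fragmeth.hmm import FragmentMethylationHMM
from fragmeth.simulate import (
    SimulationConfig, simulate_fragments, simulate_genome, simulate_methylomes,
    simulate_sample_mixture, write_prior_bedgraph,
)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast simulation condition for unit tests."""
    base = dict(genome_length=120_000, n_islands=12, n_fragments=1500)
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Simulated genome + methylomes + prior + BAM + truth on disk."""
    out = tmp_path_factory.mktemp("sim")
    cfg = small_config()
    genome = simulate_genome(cfg, out)
    methylomes, prior = simulate_methylomes(cfg, genome)
    sample = simulate_sample_mixture(methylomes, np.array([1.0, 0, 0, 0, 0]))
    simulate_fragments(cfg, genome, sample, out / "reads.bam", out / "truth.tsv")
    write_prior_bedgraph(out / "prior.bedgraph", prior)
    return {"dir": out, "cfg": cfg, "genome": genome, "methylomes": methylomes,
            "prior_track": prior, "sample": sample}


@pytest.fixture(scope="session")
def sim_fragments(sim_dir):
    """Extracted, z-scored, truth-annotated fragments from the toy BAM."""
    out = sim_dir["dir"]
    index = build_cpg_index(str(out / "genome.fa"))
    fragments, stats = extract_fragments(str(out / "reads.bam"), index, FilterConfig())
    zscore_features(fragments, stats)
    attach_truth(fragments, str(out / "truth.tsv"))
    return {"fragments": fragments, "stats": stats, "index": index}


def random_model(rng: np.random.Generator, sticky: bool = True) -> FragmentMethylationHMM:
    """A random valid NH-HMM over the default bin layout."""
    n_off, n_dist = 6, 7
    start = rng.dirichlet(np.ones(2), size=n_off)
    if sticky:
        trans = np.empty((n_dist, 2, 2))
        for b in range(n_dist):
            for s in range(2):
                stay = rng.uniform(0.6, 0.95)
                trans[b, s] = [stay, 1 - stay] if s == 0 else [1 - stay, stay]
    else:
        trans = rng.dirichlet(np.ones(2), size=(n_dist, 2))
    weights = rng.uniform(0.2, 0.8, size=(2, 3))
    means = rng.normal(0, 1, size=(2, 3, 2))
    variances = rng.uniform(0.2, 1.5, size=(2, 3, 2))
    return FragmentMethylationHMM.from_parameters(start, trans, weights, means, variances)


def well_separated_model() -> FragmentMethylationHMM:
    """An NH-HMM with clearly bimodal emissions and distinct transitions,
    used as ground truth in recovery checks. State M has the larger mean
    distance-to-center (feature index 2), matching the labelling rule."""
    n_off, n_dist = 6, 7
    start = np.tile([0.6, 0.4], (n_off, 1)).astype(float)
    start[1] = [0.3, 0.7]
    stay_u = np.linspace(0.92, 0.65, n_dist)
    stay_m = np.linspace(0.88, 0.7, n_dist)
    trans = np.stack(
        [np.stack([[u, 1 - u], [1 - m, m]]) for u, m in zip(stay_u, stay_m)]
    )
    means = np.array(
        [
            [[-1.8, -0.6], [-1.5, -0.4], [-2.0, -0.9]],  # state U
            [[0.6, 1.8], [0.4, 1.6], [0.9, 2.1]],  # state M
        ]
    )
    weights = np.full((2, 3), 0.45)
    variances = np.full((2, 3, 2), 0.35)
    return FragmentMethylationHMM.from_parameters(start, trans, weights, means, variances)
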