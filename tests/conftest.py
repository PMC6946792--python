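import numpy as np
import pandas as pd
import pytest

from adnet import (
    AbundanceTable,
    generate_community,
    generate_metadata,
    prevalence_filter,
    spearman_all_pairs,
    rmt_threshold,
    build_network,
)


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples count table."""
    data = pd.DataFrame(
        [[5, 0], [1, 2], [0, 7]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["s1", "s2"],
    )
    return AbundanceTable(data=data, kind="count")


@pytest.fixture(scope="session")
def community():
    """One seeded synthetic community with metadata (shared, read-only)."""
    table, truth = generate_community(seed=7)
    meta = generate_metadata(table, truth, seed=8)
    return table, truth, meta


@pytest.fixture(scope="session")
def community_network(community):
    """The community's inferred network plus the filtered table and cutoff."""
    table, truth, meta = community
    filt = prevalence_filter(table, 9)
    corr = spearman_all_pairs(filt)
    cutoff = rmt_threshold(corr).chosen_cutoff
    net = build_network(corr, q_cutoff=0.001, rho_cutoff=cutoff,
                        taxonomy=filt.taxonomy)
    return net, filt, corr, cutoff


def random_count_table(n_taxa, n_samples, seed, max_count=50):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.integers(0, max_count, size=(n_taxa, n_samples)),
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return AbundanceTable(data=data, kind="count")
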