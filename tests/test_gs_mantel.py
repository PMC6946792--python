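import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from adnet import (
    AbundanceTable,
    connectivity_distance,
    gene_significance,
    gs_distance,
    mantel,
    partial_mantel,
    table2_analysis,
)

import networkx as nx


def dm(matrix, ids=None):
    m = np.asarray(matrix, dtype=float)
    return DistanceMatrix(m, ids=ids or [str(i) for i in range(m.shape[0])])


def random_dm(n, seed):
    rng = np.random.default_rng(seed)
    return dm(squareform(pdist(rng.random((n, 4)))))


class TestGeneSignificance:
    def _table(self, rows):
        arr = np.asarray(rows, dtype=float)
        return AbundanceTable(
            data=pd.DataFrame(arr, index=[f"t{i}" for i in range(arr.shape[0])],
                              columns=[f"s{j}" for j in range(arr.shape[1])]),
            kind="signal",
        )

    def test_identical_profile_gives_one(self):
        y = [1.0, 2.0, 5.0, 3.0, 4.0]
        gs = gene_significance(self._table([y]), y)
        assert gs["t0"] == pytest.approx(1.0)

    def test_r_squared_value(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        y = 0.5 * x + rng.normal(0, 0.3, 30)
        gs = gene_significance(self._table([x]), y)
        r = np.corrcoef(x, y)[0, 1]
        assert gs["t0"] == pytest.approx(r**2)

    def test_constant_taxon_is_nan(self):
        gs = gene_significance(self._table([[1, 1, 1, 1], [1, 2, 3, 4]]),
                               [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(gs["t0"]) and gs["t1"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        t = self._table(rng.random((5, 12)))
        y = rng.random(12)
        a = gene_significance(t, y)
        b = gene_significance(t, 3.5 * y - 20.0)
        pd.testing.assert_series_equal(a, b)


class TestDistances:
    def test_gs_distance_examples(self):
        gs = pd.DataFrame(
            [[1.0, 0, 0], [0, 1.0, 0], [1.0, 0, 0]],
            index=["a", "b", "c"], columns=["p1", "p2", "p3"],
        )
        d = gs_distance(gs)
        assert d["a", "c"] == pytest.approx(0.0)
        assert d["a", "b"] == pytest.approx(np.sqrt(2))

    def test_gs_distance_too_few_taxa(self):
        gs = pd.DataFrame([[1.0], [0.0]], index=["a", "b"], columns=["p"])
        with pytest.raises(ValueError):
            gs_distance(gs)

    def test_connectivity_distance(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        d = connectivity_distance(g)
        assert d["b", "c"] == pytest.approx(0.0)   # equal degrees
        assert d["a", "d"] == pytest.approx(2.0)   # degrees 3 and 1

    def test_connectivity_distance_subset_keeps_overall_degrees(self):
        g = nx.star_graph(4)  # hub 0 degree 4, leaves degree 1
        d = connectivity_distance(g, [1, 2, 0])
        assert d["0", "1"] == pytest.approx(3.0)

    def test_taxon_missing_from_network_rejected(self):
        with pytest.raises(ValueError):
            connectivity_distance(nx.path_graph(3), [0, 99])


class TestMantel:
    def test_identical_matrices(self):
        d = random_dm(10, 0)
        res = mantel(d, d, n_permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_statistic_symmetric_in_arguments(self):
        d1, d2 = random_dm(12, 1), random_dm(12, 2)
        assert mantel(d1, d2, 99, seed=0).r == pytest.approx(
            mantel(d2, d1, 99, seed=0).r)

    def test_independent_matrices_near_null(self):
        ok = 0
        for seed in range(50):
            d1, d2 = random_dm(30, 100 + seed), random_dm(30, 200 + seed)
            res = mantel(d1, d2, n_permutations=199, seed=seed)
            if abs(res.r) < 0.2 and res.p > 0.05:
                ok += 1
        assert ok >= 45  # >= 90% of seeds

    def test_matches_full_permutation_enumeration(self):
        """On 5 taxa, the permutation p from sampling agrees with exhaustive
        enumeration over all 120 row/column permutations, and r is exact."""
        d1, d2 = random_dm(5, 3), random_dm(5, 4)
        res = mantel(d1, d2, n_permutations=4999, seed=5)

        def upper(m):
            return m[np.triu_indices(5, 1)]

        x = upper(d1.data)
        r_exact = np.corrcoef(x, upper(d2.data))[0, 1]
        assert res.r == pytest.approx(r_exact)
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            yp = upper(d2.data[np.ix_(perm, perm)])
            total += 1
            if np.corrcoef(x, yp)[0, 1] >= r_exact - 1e-12:
                count += 1
        exact_p = count / total
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_agrees_with_skbio_oracle(self):
        d1, d2 = random_dm(20, 6), random_dm(20, 7)
        r_skbio, p_skbio, _ = skbio_mantel(d1, d2, permutations=999,
                                           alternative="greater")
        res = mantel(d1, d2, n_permutations=999, seed=8)
        assert res.r == pytest.approx(r_skbio, abs=1e-12)
        assert res.p == pytest.approx(p_skbio, abs=0.05)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mantel(random_dm(5, 0), random_dm(6, 0))


class TestPartialMantel:
    def test_uncorrelated_control_changes_little(self):
        diffs = []
        for seed in range(30):
            d1, d2 = random_dm(20, seed), random_dm(20, 1000 + seed)
            dc = random_dm(20, 2000 + seed)
            plain = mantel(d1, d2, 49, seed=seed).r
            part = partial_mantel(d1, d2, dc, 49, seed=seed).r
            diffs.append(abs(plain - part))
        assert np.median(diffs) < 0.05

    def test_control_explains_d2_gives_zero(self):
        dc = random_dm(15, 10)
        d2 = dm(1.5 * dc.data + 2.0 * (dc.data > 0))  # affine in control
        d1 = random_dm(15, 11)
        res = partial_mantel(d1, d2, dc, 99, seed=0)
        assert abs(res.r) < 0.1

    def test_identical_pair_with_independent_control(self):
        d1 = random_dm(15, 12)
        res = partial_mantel(d1, d1, random_dm(15, 13), 99, seed=1)
        assert res.r > 0.95

    def test_constant_control_falls_back_to_plain(self, caplog):
        d1, d2 = random_dm(10, 14), random_dm(10, 15)
        n = d1.shape[0]
        dc = dm(np.ones((n, n)) - np.eye(n))
        res = partial_mantel(d1, d2, dc, 99, seed=2)
        plain = mantel(d1, d2, 99, seed=2)
        assert res.r == pytest.approx(plain.r)


class TestTable2Analysis:
    def test_small_subsets_skipped(self, community, community_network):
        table, truth, meta = community
        net, filt, _, _ = community_network
        out = table2_analysis(net, filt, meta, n_permutations=49, seed=0)
        assert "All" in out.index
        skipped = out[out["skipped"].astype(bool)]
        # every reported (non-skipped) subset has >= 3 taxa
        assert (out[~out["skipped"].astype(bool)]["n_taxa"] >= 3).all()

    def test_null_metadata_gives_null_mantel(self, community):
        """With beta = 0 the performance columns are pure noise, so no
        subset should show a significant performance partial Mantel beyond
        chance."""
        from adnet import generate_metadata, prevalence_filter, spearman_all_pairs
        from adnet import rmt_threshold, build_network
        table, truth, _ = community
        meta0 = generate_metadata(table, truth, effect_size_beta=0.0, seed=99)
        filt = prevalence_filter(table, 9)
        corr = spearman_all_pairs(filt)
        net = build_network(corr, 0.001, rmt_threshold(corr).chosen_cutoff,
                            taxonomy=filt.taxonomy)
        out = table2_analysis(net, filt, meta0, n_permutations=199, seed=3)
        ok = out[~out["skipped"].astype(bool)]
        sig = (ok["p_perf_env_controlled"] < 0.05).mean()
        assert sig <= 0.35  # at/near the nominal false-positive rate
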