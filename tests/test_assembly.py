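import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rarescape.assembly import (
    DISPERSAL_LIMITATION,
    HOMOGENEOUS_SELECTION,
    HOMOGENIZING_DISPERSAL,
    PROCESSES,
    UNDOMINATED,
    VARIABLE_SELECTION,
    bnti,
    classify_pair,
    map_rarity_types,
    pairwise_turnover,
    per_division_assembly,
    permanova,
    raup_crick_bray,
    summarize_window_processes,
)
from rarescape.errors import (
    ClassificationError,
    EmptySummaryError,
    InsufficientDataError,
)
from rarescape.io_formats import EnvTable, OtuTable
from rarescape.phylo import DistanceMatrix, cophenetic_distance
from rarescape.rarity import RacWindow
from rarescape.synthetic_data import simulate_tree

from conftest import random_table


class TestClassifyPair:
    @pytest.mark.parametrize("b,r,expect", [
        (2.5, 0.3, VARIABLE_SELECTION),
        (0.5, 0.97, DISPERSAL_LIMITATION),
        (0.5, 0.3, UNDOMINATED),
        (-2.4, 0.0, HOMOGENEOUS_SELECTION),
        (0.0, -0.99, HOMOGENIZING_DISPERSAL),
    ])
    def test_published_rule(self, b, r, expect):
        assert classify_pair(b, r) == expect

    @pytest.mark.parametrize("b,r,expect", [
        (2.0, 0.0, UNDOMINATED),      # boundary |bnti| = 2 is not selection
        (-2.0, 0.0, UNDOMINATED),
        (0.0, 0.95, UNDOMINATED),     # boundary |rc| = 0.95 is not dispersal
        (0.0, -0.95, UNDOMINATED),
    ])
    def test_boundaries_strict(self, b, r, expect):
        assert classify_pair(b, r) == expect

    def test_total_on_grid(self):
        for b in np.linspace(-4, 4, 33):
            for r in np.linspace(-1, 1, 21):
                assert classify_pair(b, r) in PROCESSES

    def test_nan_raises(self):
        with pytest.raises(ClassificationError):
            classify_pair(np.nan, 0.0)
        with pytest.raises(ClassificationError):
            classify_pair(0.0, np.inf)

    def test_selection_wins_over_dispersal(self):
        # |bnti| > 2 dominates regardless of rc
        assert classify_pair(3.0, 0.99) == VARIABLE_SELECTION
        assert classify_pair(-3.0, -0.99) == HOMOGENEOUS_SELECTION


class TestRarityMapping:
    @pytest.mark.parametrize("process,expect", [
        (VARIABLE_SELECTION, "ConditionallyRare"),
        (HOMOGENEOUS_SELECTION, "PermanentlyRare"),
        (HOMOGENIZING_DISPERSAL, "PermanentlyRare"),
        (DISPERSAL_LIMITATION, "TransientlyRare"),
        (UNDOMINATED, "TransientlyRare"),
    ])
    def test_mapping(self, process, expect):
        assert map_rarity_types(process) == expect

    def test_abundant_subset_suppressed(self):
        for p in PROCESSES:
            assert map_rarity_types(p, subset_is_abundant=True) is None

    def test_unknown_process(self):
        with pytest.raises(ClassificationError):
            map_rarity_types("Magic")


class TestBnti:
    def test_identical_samples_degenerate_null(self, star_tree3):
        t = OtuTable(["s0", "s1"], ["A", "B"], np.array([[5, 5], [5, 5]]),
                     ["nano"] * 2)
        res = bnti(t, cophenetic_distance(star_tree3), n_null=99, seed=0)
        assert res["bnti"].iloc[0] == 0.0
        assert bool(res["degenerate_null"].iloc[0])

    def test_reproducible(self, rng):
        t = random_table(rng, 5, 10)
        tree = simulate_tree(10, seed=4)
        d = DistanceMatrix(t.otu_ids, cophenetic_distance(tree).values)
        a = bnti(t, d, n_null=99, seed=42)
        b = bnti(t, d, n_null=99, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_null_calibration(self):
        # communities generated by the null's own process: taxa drawn
        # uniformly at random from the tip pool
        rng = np.random.default_rng(2024)
        n_otus, n_samples = 150, 15
        tree = simulate_tree(n_otus, seed=8)
        dist = cophenetic_distance(tree)
        counts = np.zeros((n_samples, n_otus), dtype=int)
        for s in range(n_samples):
            k = rng.integers(20, 50)
            taxa = rng.choice(n_otus, size=k, replace=False)
            counts[s, taxa] = rng.integers(1, 50, size=k)
        t = OtuTable([f"s{i}" for i in range(n_samples)], dist.ids, counts,
                     ["nano"] * n_samples)
        res = bnti(t, dist, n_null=199, seed=7)
        assert len(res) >= 100
        assert abs(res["bnti"].mean()) < 0.3
        assert (res["bnti"].abs() > 2).mean() <= 0.10

    def test_single_sample_error(self, star_tree3):
        t = OtuTable(["s0"], ["A"], np.array([[3]]), ["nano"])
        with pytest.raises(InsufficientDataError):
            bnti(t, cophenetic_distance(star_tree3), n_null=99, seed=0)


def enumerate_raup_crick(counts, obs_bc):
    """Exhaustive enumeration of the null Bray-Curtis distribution.

    Mirrors the generator contract: occupancy drawn without replacement
    with probability proportional to occurrence frequency (sequential
    renormalization, numpy semantics), one read per drawn taxon, remaining
    reads multinomial on metacommunity relative abundance.
    """
    counts = np.asarray(counts)
    n_otus = counts.shape[1]
    occ = (counts > 0).sum(axis=0).astype(float)
    p_occ = occ / occ.sum()
    pool = counts.sum(axis=0).astype(float)
    pool_rel = pool / pool.sum()

    def subset_prob(subset):
        total = 0.0
        for perm in itertools.permutations(subset):
            p, rem = 1.0, 1.0
            for t_ in perm:
                p *= p_occ[t_] / rem
                rem -= p_occ[t_]
            total += p
        return total

    def allocations(total, k):
        if k == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in allocations(total - first, k - 1):
                yield (first,) + rest

    def sample_nulls(richness, total):
        out = []
        for subset in itertools.combinations(range(n_otus), richness):
            ps = subset_prob(subset)
            w = pool_rel[list(subset)]
            w = w / w.sum()
            remaining = total - richness
            for alloc in allocations(remaining, richness):
                # multinomial pmf
                pa = math.factorial(remaining)
                for a, wi in zip(alloc, w):
                    pa = pa / math.factorial(a) * (wi ** a)
                vec = np.zeros(n_otus)
                vec[list(subset)] = 1 + np.array(alloc)
                out.append((ps * pa, vec / vec.sum()))
        return out

    nulls = [sample_nulls(int((counts[s] > 0).sum()), int(counts[s].sum()))
             for s in range(2)]
    p_lt = p_eq = 0.0
    for pr1, v1 in nulls[0]:
        for pr2, v2 in nulls[1]:
            bc = np.abs(v1 - v2).sum() / (v1 + v2).sum()
            pr = pr1 * pr2
            if abs(bc - obs_bc) < 1e-12:
                p_eq += pr
            elif bc < obs_bc:
                p_lt += pr
    return 2.0 * (p_lt + 0.5 * p_eq) - 1.0


class TestRaupCrick:
    def test_identical_rich_samples_negative(self, rng):
        base = rng.integers(5, 40, size=20)
        counts = np.vstack([base, base])
        t = OtuTable(["s0", "s1"], [f"o{j}" for j in range(20)], counts,
                     ["nano"] * 2)
        res = raup_crick_bray(t, n_null=199, seed=0)
        assert res["rc"].iloc[0] <= -0.95

    def test_bounds(self, rng):
        t = random_table(rng, 6, 15, depth=100)
        res = raup_crick_bray(t, n_null=99, seed=1)
        assert res["rc"].between(-1, 1).all()

    def test_exhaustive_enumeration_oracle(self):
        counts = np.array([[3, 1, 0], [0, 2, 1]])
        t = OtuTable(["s0", "s1"], ["o0", "o1", "o2"], counts, ["nano"] * 2)
        rel = counts / counts.sum(axis=1, keepdims=True)
        obs_bc = np.abs(rel[0] - rel[1]).sum() / (rel[0] + rel[1]).sum()
        expect = enumerate_raup_crick(counts, obs_bc)
        res = raup_crick_bray(t, n_null=999, seed=5)
        assert res["rc"].iloc[0] == pytest.approx(expect, abs=0.05)

    def test_seed_stability_bounded_mc_error(self, rng):
        t = random_table(rng, 6, 12, depth=80)
        r1 = raup_crick_bray(t, n_null=999, seed=1)["rc"]
        r2 = raup_crick_bray(t, n_null=999, seed=2)["rc"]
        assert (r1 - r2).abs().max() <= 0.15

    def test_single_taxon_sample_ok(self):
        counts = np.array([[4, 0, 0], [1, 2, 3]])
        t = OtuTable(["s0", "s1"], ["o0", "o1", "o2"], counts, ["nano"] * 2)
        res = raup_crick_bray(t, n_null=99, seed=0)
        assert np.isfinite(res["rc"]).all()


class TestSummaries:
    def _pairs(self, labels):
        return pd.DataFrame({
            "sample_i": [f"a{i}" for i in range(len(labels))],
            "sample_j": [f"b{i}" for i in range(len(labels))],
            "process": labels,
        })

    def test_all_one_process(self):
        w = RacWindow("5000", 1, 5000)
        s = summarize_window_processes(self._pairs([VARIABLE_SELECTION] * 10), w,
                                       n_samples=9)
        assert s[VARIABLE_SELECTION].iloc[0] == 1.0
        assert sum(s[p].iloc[0] for p in PROCESSES if p != VARIABLE_SELECTION) == 0
        assert s["n_samples"].iloc[0] == 9
        assert s["rarity_type"].iloc[0] == "ConditionallyRare"

    def test_fractions_sum_to_one(self, rng):
        labels = rng.choice(PROCESSES, size=57)
        s = summarize_window_processes(self._pairs(list(labels)))
        assert sum(s[p].iloc[0] for p in PROCESSES) == pytest.approx(1.0, abs=1e-9)

    def test_abundant_suppresses_rarity_type(self):
        s = summarize_window_processes(self._pairs([UNDOMINATED] * 3),
                                       subset_is_abundant=True)
        assert s["rarity_type"].iloc[0] == ""

    def test_empty_error(self):
        with pytest.raises(EmptySummaryError):
            summarize_window_processes(pd.DataFrame())


class TestPerDivision:
    def _table_with_divisions(self, rng, sizes):
        otus, tax = [], {}
        for d, (name, size) in enumerate(sizes.items()):
            for j in range(size):
                o = f"d{d}o{j}"
                otus.append(o)
                tax[o] = f"Supergroup;{name};x"
        counts = rng.integers(0, 20, size=(5, len(otus)))
        counts[:, 0] += 1
        return OtuTable([f"s{i}" for i in range(5)], otus, counts,
                        ["nano"] * 5, taxonomy=tax)

    def test_threshold_boundary(self, rng):
        t = self._table_with_divisions(rng, {"Big": 20, "Small": 19})
        tree = simulate_tree(t.n_otus, seed=1)
        dist = DistanceMatrix(t.otu_ids, cophenetic_distance(tree).values)
        with pytest.warns(UserWarning):
            res = per_division_assembly(t, t.taxonomy, dist, n_null=99, seed=3)
        assert list(res["division"]) == ["Big"]

    def test_consistency_with_restricted_run(self, rng):
        t = self._table_with_divisions(rng, {"Big": 25, "Other": 25})
        tree = simulate_tree(t.n_otus, seed=2)
        dist = DistanceMatrix(t.otu_ids, cophenetic_distance(tree).values)
        res = per_division_assembly(t, t.taxonomy, dist, min_otus=20,
                                    n_null=99, seed=11)
        big_otus = [o for o in t.otu_ids if "Big" in t.taxonomy[o]]
        manual = pairwise_turnover(t.subset_otus(big_otus), dist,
                                   n_null=99, seed=11)
        manual_sum = summarize_window_processes(manual, n_samples=5)
        row = res[res["division"] == "Big"].iloc[0]
        for p in PROCESSES:
            assert row[p] == pytest.approx(manual_sum[p].iloc[0], abs=1e-12)


def brute_force_permanova_f(d, x_terms):
    """Sequential pseudo-F via explicit projection matrices (oracle)."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    xs = [np.ones((n, 1))]
    fs = []
    prev_h = xs[0] @ np.linalg.pinv(xs[0])
    for term in x_terms:
        z = (term - term.mean()) / term.std()
        xs.append(z[:, None])
        x = np.hstack(xs)
        h = x @ np.linalg.pinv(x)
        ss = np.trace((h - prev_h) @ g)
        fs.append(ss)
        prev_h = h
    h_full = prev_h
    ss_res = np.trace((np.eye(n) - h_full) @ g)
    df_res = n - len(x_terms) - 1
    return [ss / (ss_res / df_res) for ss in fs]


class TestPermanova:
    def test_pseudo_f_matches_brute_force(self, rng):
        n = 5
        x = rng.random((n, 2)) * 3
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        ids = [f"s{i}" for i in range(n)]
        env = EnvTable(ids, pd.DataFrame(
            {"temperature": rng.normal(10, 2, n),
             "salinity": rng.normal(34, 1, n)}, index=ids))
        res = permanova(DistanceMatrix(ids, d), env, n_perm=19, seed=0)
        expect = brute_force_permanova_f(
            d, [env.values["temperature"].to_numpy(),
                env.values["salinity"].to_numpy()])
        assert np.allclose(res["pseudo_F"], expect, atol=1e-9)

    def test_power_single_driver(self, rng):
        n = 20
        temp = rng.uniform(0, 10, n)
        d = np.abs(temp[:, None] - temp[None, :])
        ids = [f"s{i}" for i in range(n)]
        env = EnvTable(ids, pd.DataFrame(
            {"temperature": temp, "salinity": rng.normal(34, 1, n)}, index=ids))
        res = permanova(DistanceMatrix(ids, d), env, n_perm=999, seed=0)
        row = res[res["term"] == "temperature"].iloc[0]
        assert row["p_value"] <= 0.001 + 1e-12
        assert row["r_squared"] > 0.5

    def test_constant_predictor_dropped(self, rng):
        n = 8
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        ids = [f"s{i}" for i in range(n)]
        env = EnvTable(ids, pd.DataFrame(
            {"temperature": rng.normal(size=n), "salinity": np.full(n, 34.0)},
            index=ids))
        with pytest.warns(UserWarning):
            res = permanova(DistanceMatrix(ids, d), env, n_perm=19, seed=0)
        assert list(res["term"]) == ["temperature"]

    def test_reproducible(self, rng):
        n = 10
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        ids = [f"s{i}" for i in range(n)]
        env = EnvTable(ids, pd.DataFrame({"temperature": rng.normal(size=n)},
                                         index=ids))
        a = permanova(DistanceMatrix(ids, d), env, n_perm=99, seed=5)
        b = permanova(DistanceMatrix(ids, d), env, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPairwiseTurnover:
    def test_columns_and_labels(self, rng):
        t = random_table(rng, 4, 8)
        tree = simulate_tree(8, seed=9)
        d = DistanceMatrix(t.otu_ids, cophenetic_distance(tree).values)
        pairs = pairwise_turnover(t, d, n_null=99, seed=0)
        assert len(pairs) == 6
        assert set(pairs["process"]).issubset(set(PROCESSES))
        for col in ("bmntd_obs", "null_mean", "null_sd", "bnti", "bray_obs",
                    "rc", "n_null"):
            assert col in pairs.columns

    def test_seed_determinism(self, rng):
        t = random_table(rng, 4, 8)
        tree = simulate_tree(8, seed=9)
        d = DistanceMatrix(t.otu_ids, cophenetic_distance(tree).values)
        a = pairwise_turnover(t, d, n_null=99, seed=3)
        b = pairwise_turnover(t, d, n_null=99, seed=3)
        pd.testing.assert_frame_equal(a, b)
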