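import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from symbionet import (
    ValidationError,
    barber_modularity,
    connectance,
    interaction_asymmetry,
    interaction_evenness,
    modularity_dirtlpawb,
    specialization_h2,
    species_degree,
    species_strength,
    wnodf,
)
from conftest import make_matrix

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def wnodf_oracle(m):
    """Direct-definition weighted NODF, written independently of the package:
    order by fill (marginal-total tiebreak), pairs with non-decreasing fill
    score zero, otherwise percent of the poorer species' links that are
    strictly exceeded by the richer species in the same cells."""
    a = m.counts

    def axis_scores(mat):
        fills = [sum(1 for v in row if v > 0) for row in mat]
        tots = [sum(row) for row in mat]
        order = sorted(range(len(mat)), key=lambda i: (-fills[i], -tots[i]))
        mat = [mat[i] for i in order]
        fills = [fills[i] for i in order]
        out = []
        for u, v in itertools.combinations(range(len(mat)), 2):
            if fills[u] <= fills[v] or fills[v] == 0:
                out.append(0.0)
                continue
            hits = sum(1 for k in range(len(mat[v])) if mat[v][k] > 0 and mat[v][k] < mat[u][k])
            out.append(100.0 * hits / fills[v])
        return out

    rows = axis_scores([list(r) for r in a])
    cols = axis_scores([list(c) for c in a.T])
    return float(np.mean(rows + cols))


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def exhaustive_best_q(m):
    """Global maximum of Barber Q by enumerating all row partitions; given a
    row partition each column independently joins its best module (or none)."""
    dev = m.counts - np.outer(m.row_totals, m.col_totals) / m.F
    best = 0.0
    for part in set_partitions(list(range(m.I))):
        col_gain = 0.0
        for j in range(m.J):
            col_gain += max(0.0, max(dev[block, j].sum() for block in part))
        best = max(best, col_gain / m.F)
    return best


def enumerate_margin_tables(row_sums, col_sums):
    """All non-negative integer matrices with the given margins."""

    def rows(remaining_cols, row_iter):
        row_iter = list(row_iter)
        if not row_iter:
            if all(c == 0 for c in remaining_cols):
                yield []
            return
        total = row_iter[0]

        def comps(total, caps):
            if len(caps) == 1:
                if total <= caps[0]:
                    yield (total,)
                return
            for v in range(min(total, caps[0]) + 1):
                for tail in comps(total - v, caps[1:]):
                    yield (v,) + tail

        for row in comps(total, remaining_cols):
            rest = tuple(c - v for c, v in zip(remaining_cols, row))
            for tail in rows(rest, row_iter[1:]):
                yield [row] + tail

    yield from rows(tuple(col_sums), row_sums)


# ---------------------------------------------------------------------------
# Connectance, evenness, asymmetry
# ---------------------------------------------------------------------------


class TestSimpleMetrics:
    def test_connectance_extremes(self, im):
        assert connectance(im(np.ones((5, 5), dtype=int))) == 1.0
        assert connectance(im(np.eye(4, dtype=int) * 3)) == 0.25

    def test_evenness_single_link_is_zero(self, im):
        assert interaction_evenness(im([[7, 0], [0, 0]])) == 0.0

    def test_evenness_uniform_links_denominator(self, im):
        m = im([[1, 1, 0], [1, 0, 1], [0, 1, 1]])
        assert interaction_evenness(m, denominator="links") == pytest.approx(1.0)

    def test_evenness_hand_example(self, im):
        # -(0.5 log2 0.5 + 2 * 0.25 log2 0.25) / log2 4 = 0.75
        assert interaction_evenness(im([[2, 1], [1, 0]])) == pytest.approx(0.75)

    def test_asymmetry_mutually_exclusive_pairs(self, im):
        per, mean = interaction_asymmetry(im([[10, 0], [0, 10]]), guild="columns")
        assert mean == 0.0 and all(v == 0.0 for v in per.values())

    def test_asymmetry_single_pair(self, im):
        _, mean = interaction_asymmetry(im([[5]]), guild="rows")
        assert mean == 0.0

    def test_asymmetry_near_one_for_lopsided_dependence(self, im):
        # fungus f00 gets 1% of a generalist plant's interactions but depends
        # on it entirely; |d| = (1 - 0.01)/1 = 0.99
        m = im([[1, 99]])
        per, _ = interaction_asymmetry(m, guild="columns")
        assert per["f00"] == pytest.approx(0.99)

    @pytest.mark.parametrize("guild", ["rows", "columns"])
    def test_asymmetry_matches_direct_double_loop(self, random_network, guild):
        a = random_network.counts.astype(float)
        rt, ct = a.sum(axis=1), a.sum(axis=0)
        per, mean = interaction_asymmetry(random_network, guild=guild)
        labels = random_network.row_labels if guild == "rows" else random_network.col_labels
        for idx, label in enumerate(labels):
            ds = []
            if guild == "rows":
                cells = [(idx, j) for j in range(a.shape[1]) if a[idx, j] > 0]
            else:
                cells = [(i, idx) for i in range(a.shape[0]) if a[i, idx] > 0]
            for i, j in cells:
                sij, sji = a[i, j] / rt[i], a[i, j] / ct[j]
                ds.append(abs(sij - sji) / max(sij, sji))
            assert per[label] == pytest.approx(np.mean(ds))


# ---------------------------------------------------------------------------
# H2'
# ---------------------------------------------------------------------------


class TestSpecialization:
    def test_perfect_specialization(self, im):
        assert specialization_h2(im(np.eye(3, dtype=int) * 4)) == pytest.approx(1.0)

    def test_independence_table_is_zero(self, im):
        # outer product of margins / F: (2,2) x (2,2) / 4
        assert specialization_h2(im([[1, 1], [1, 1]])) == pytest.approx(0.0)

    def test_heuristic_close_to_exhaustive_integer_bounds(self, im):
        row_sums, col_sums = (6, 3, 3), (4, 4, 4)
        entropies = []
        for table in enumerate_margin_tables(row_sums, col_sums):
            p = np.array(table, dtype=float).ravel() / 12.0
            p = p[p > 0]
            entropies.append(float(-(p * np.log(p)).sum()))
        h_min, h_max = min(entropies), max(entropies)
        observed = im([[3, 2, 1], [1, 1, 1], [0, 1, 2]])  # margins (6,3,3)/(4,4,4)
        p = observed.counts.ravel() / 12.0
        p = p[p > 0]
        h_obs = float(-(p * np.log(p)).sum())
        exact = (h_max - h_obs) / (h_max - h_min)
        assert specialization_h2(observed) == pytest.approx(exact, abs=0.02)

    def test_degenerate_margins_rejected(self, im):
        with pytest.raises(ValidationError):
            specialization_h2(im([[1, 2, 3]]))


# ---------------------------------------------------------------------------
# WNODF
# ---------------------------------------------------------------------------


class TestWnodf:
    def test_perfectly_nested_is_100(self, im):
        m = im([[9, 8, 7, 6], [5, 4, 3, 0], [2, 1, 0, 0], [1, 0, 0, 0]])
        assert wnodf(m) == pytest.approx(100.0)

    def test_identical_species_pairs_score_zero(self, im):
        # equal fills fail the decreasing-fill condition for every pair:
        # rows are identical and all columns have the same number of links
        m = im([[3, 2, 1], [3, 2, 1]])
        assert wnodf(m) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_direct_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.choice([(3, 3), (3, 4), (4, 4), (4, 3)])
        counts = rng.integers(0, 6, size=tuple(shape))
        counts[0] += 1
        counts[:, 0] += 1
        m = make_matrix(counts).drop_empty()
        if m.I < 2 or m.J < 2:
            pytest.skip("degenerate draw")
        assert wnodf(m) == pytest.approx(wnodf_oracle(m), abs=1e-10)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


class TestModularity:
    def test_single_row_network_q_zero(self, im):
        part = modularity_dirtlpawb(im([[3, 1, 4]]), n_restarts=5, seed=0)
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_blocks(self, im):
        m = im([[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 5, 5], [0, 0, 5, 5]])
        part = modularity_dirtlpawb(m, n_restarts=10, seed=1)
        assert part.Q == pytest.approx(0.5, abs=1e-12)  # 1 - 2 * (1/2)^2

    def test_partition_q_is_recomputable(self, random_network):
        part = modularity_dirtlpawb(random_network, n_restarts=10, seed=3)
        q = barber_modularity(random_network, part.row_modules, part.col_modules)
        assert q == pytest.approx(part.Q, abs=1e-12)

    def test_reaches_exhaustive_optimum_on_small_matrices(self):
        rng = np.random.default_rng(99)
        hits, total = 0, 0
        for _ in range(100):
            shape = (3, 3) if rng.random() < 0.5 else (3, 4)
            counts = rng.integers(0, 3, size=shape)
            if counts.sum() == 0 or (counts.sum(1) == 0).any() or (counts.sum(0) == 0).any():
                continue
            m = make_matrix(counts)
            total += 1
            best = exhaustive_best_q(m)
            found = modularity_dirtlpawb(m, n_restarts=40, seed=rng).Q
            hits += found >= best - 1e-12
        assert total >= 80
        assert hits / total >= 0.99

    def test_deterministic_given_seed(self, random_network):
        a = modularity_dirtlpawb(random_network, n_restarts=10, seed=7)
        b = modularity_dirtlpawb(random_network, n_restarts=10, seed=7)
        assert a.Q == b.Q
        np.testing.assert_array_equal(a.row_modules, b.row_modules)


# ---------------------------------------------------------------------------
# Degree and strength
# ---------------------------------------------------------------------------


class TestDegreeStrength:
    def test_degree_trivial_cases(self, im):
        full = species_degree(im(np.ones((3, 4), dtype=int)))
        assert set(full["plants"].values()) == {4} and set(full["fungi"].values()) == {3}
        diag = species_degree(im(np.eye(3, dtype=int)))
        assert set(diag["plants"].values()) == {1}

    def test_strength_hand_example(self, im):
        s = species_strength(im([[3, 1], [0, 4]]))
        assert s["fungi"]["f00"] == pytest.approx(3 / 4)
        assert s["fungi"]["f01"] == pytest.approx(1 / 4 + 1)

    def test_strengths_sum_to_partner_guild_size(self, random_network):
        s = species_strength(random_network)
        assert sum(s["fungi"].values()) == pytest.approx(random_network.I)
        assert sum(s["plants"].values()) == pytest.approx(random_network.J)


# ---------------------------------------------------------------------------
# Permutation invariance (property)
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    counts=arrays(np.int64, (4, 5), elements=st.integers(0, 8)),
    perm_seed=st.integers(0, 1000),
)
def test_metrics_invariant_under_species_relabeling(counts, perm_seed):
    if (counts.sum(1) == 0).any() or (counts.sum(0) == 0).any() or counts.sum() < 2:
        return
    m = make_matrix(counts)
    rng = np.random.default_rng(perm_seed)
    pr, pc = rng.permutation(4), rng.permutation(5)
    # keep the original labels attached to the permuted rows/cols
    from symbionet import InteractionMatrix

    mp = InteractionMatrix(
        counts=counts[np.ix_(pr, pc)],
        row_labels=tuple(m.row_labels[i] for i in pr),
        col_labels=tuple(m.col_labels[j] for j in pc),
    )
    assert connectance(mp) == pytest.approx(connectance(m))
    assert interaction_evenness(mp) == pytest.approx(interaction_evenness(m))
    assert wnodf(mp) == pytest.approx(wnodf(m))
    assert specialization_h2(mp) == pytest.approx(specialization_h2(m))
    assert interaction_asymmetry(mp, "columns")[1] == pytest.approx(
        interaction_asymmetry(m, "columns")[1]
    )
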