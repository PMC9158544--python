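import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from symbionet import (
    Phylogeny,
    TraitVector,
    ValidationError,
    blomberg_k,
    mantel,
    pagel_lambda,
    partner_dissimilarity,
    phylo_distance,
    simulate_tree_and_trait,
)
from conftest import make_matrix


class TestPartnerDissimilarity:
    def test_identical_and_disjoint_profiles(self, im):
        m = im([[2, 1, 0], [2, 1, 0], [0, 0, 5]])
        labels, d = partner_dissimilarity(m, guild="rows")
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)
        assert (np.diag(d) == 0).all() and np.allclose(d, d.T)

    def test_hand_computed_value(self, im):
        m = im([[2, 1, 0], [0, 1, 2]])
        _, d = partner_dissimilarity(m, guild="rows")
        assert d[0, 1] == pytest.approx(2 / 3)


class TestPhyloDistance:
    def test_two_tip_cherry(self):
        t = Phylogeny.from_newick("(a:1,b:2);")
        labels, d = phylo_distance(t)
        assert d[labels.index("a"), labels.index("b")] == pytest.approx(3.0)

    def test_ultrametric_depth(self):
        t = Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        _, d = phylo_distance(t)
        # pairs spanning the root sit at twice the tree depth
        assert d[0, 2] == pytest.approx(4.0)

    def test_matches_path_walk_oracle(self):
        tree, _ = simulate_tree_and_trait(8, 1.0, 1.0, seed=13)
        labels, d = phylo_distance(tree)
        # oracle: climb to the root from both tips and splice the paths
        leaves = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}

        def path_to_root(node):
            out = {}
            dist = 0.0
            while node is not None:
                out[id(node)] = dist
                dist += node.edge.length or 0.0
                node = node.parent_node
            return out

        for i, a in enumerate(labels):
            up_a = path_to_root(leaves[a])
            for j, b in enumerate(labels):
                if j <= i:
                    continue
                node, climbed = leaves[b], 0.0
                while id(node) not in up_a:
                    climbed += node.edge.length or 0.0
                    node = node.parent_node
                assert d[i, j] == pytest.approx(climbed + up_a[id(node)], abs=1e-9)


class TestMantel:
    def test_perfect_and_affine_correlation(self):
        rng = np.random.default_rng(0)
        from scipy.spatial.distance import squareform

        d = squareform(rng.random(45))
        r, _ = mantel(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        r2, _ = mantel(d, 2.5 * d + 1.0, n_perm=99, seed=1)
        assert r2 == pytest.approx(1.0)

    def test_type_one_error_calibration(self):
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        hits = 0
        n_exp = 600
        for _ in range(n_exp):
            d1 = squareform(rng.random(28))
            d2 = squareform(rng.random(28))
            _, p = mantel(d1, d2, tail="greater", n_perm=99, seed=rng)
            hits += p <= 0.05
        assert 0.02 <= hits / n_exp <= 0.09

    def test_spearman_flag(self):
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(2)
        d = squareform(rng.random(45))
        r, _ = mantel(d, d**3, method="spearman", n_perm=99, seed=0)
        assert r == pytest.approx(1.0)  # monotone transform

    def test_constant_matrix_rejected(self):
        d = np.zeros((5, 5))
        with pytest.raises(ValidationError):
            mantel(d, d, n_perm=99)


class TestBlombergK:
    def test_star_tree_k_is_one_for_any_trait(self):
        star = Phylogeny.from_newick("(a:1,b:1,c:1,d:1,e:1,f:1);")
        x = TraitVector.from_dict({"a": 3.0, "b": -1.0, "c": 0.5, "d": 9.0, "e": 2.2, "f": -4.0})
        res = blomberg_k(star, x, n_rand=0)
        assert res.estimate == pytest.approx(1.0, abs=1e-10)

    def test_brownian_calibration(self):
        ks = []
        for s in range(100):
            tree, trait = simulate_tree_and_trait(48, 1.0, 1.0, seed=1000 + s)
            ks.append(blomberg_k(tree, trait, n_rand=0).estimate)
        assert np.mean(ks) == pytest.approx(1.0, abs=0.12)

    def test_shuffled_trait_loses_signal(self):
        tree, trait = simulate_tree_and_trait(48, 1.0, 1.0, seed=7)
        rng = np.random.default_rng(3)
        shuffled = TraitVector(labels=trait.labels, values=rng.permutation(trait.values))
        k_orig = blomberg_k(tree, trait, n_rand=0).estimate
        k_shuf = blomberg_k(tree, shuffled, n_rand=0).estimate
        assert k_shuf < k_orig and k_shuf < 1.0

    def test_randomization_p_small_under_brownian_signal(self):
        tree, trait = simulate_tree_and_trait(48, 1.0, 1.0, seed=11)
        res = blomberg_k(tree, trait, n_rand=199, seed=4)
        assert res.p_value <= 0.05

    def test_constant_trait_rejected(self):
        tree, _ = simulate_tree_and_trait(8, 1.0, 1.0, seed=0)
        x = TraitVector(labels=tuple(sorted(tree.tip_labels)), values=np.zeros(8))
        with pytest.raises(ValidationError):
            blomberg_k(tree, x, n_rand=0)


class TestPagelLambda:
    def test_lambda_zero_equals_independent_normals(self):
        tree, trait = simulate_tree_and_trait(16, 1.0, 1.0, seed=21)
        labels, v = tree.vcv()
        order = {l: i for i, l in enumerate(trait.labels)}
        x = np.array([trait.values[order[l]] for l in labels])
        res = pagel_lambda(tree, trait)
        # closed form at lambda = 0: uncorrelated normals with variances
        # sigma2 * diag(V), mean and sigma2 at their profile optima
        d = np.diag(v)
        w = 1.0 / d
        mu = (w * x).sum() / w.sum()
        n = len(x)
        s2 = ((x - mu) ** 2 / d).sum() / n
        ll0 = -0.5 * (n * np.log(2 * np.pi * s2) + np.log(d).sum() + n)
        assert res.detail["loglik_lambda0"] == pytest.approx(ll0, abs=1e-8)

    def test_brownian_recovery(self):
        lams = [
            pagel_lambda(*simulate_tree_and_trait(64, 1.0, 1.0, seed=2000 + s)).estimate
            for s in range(40)
        ]
        assert np.mean(lams) >= 0.9

    def test_independent_trait_recovery(self):
        lams, ps = [], []
        for s in range(40):
            tree, trait = simulate_tree_and_trait(64, 0.0, 1.0, seed=3000 + s)
            res = pagel_lambda(tree, trait)
            lams.append(res.estimate)
            ps.append(res.p_value)
        assert np.median(lams) <= 0.1
        assert np.mean(np.array(ps) >= 0.05) >= 0.8

    def test_optimum_beats_endpoints(self):
        tree, trait = simulate_tree_and_trait(32, 0.6, 1.0, seed=17)
        res = pagel_lambda(tree, trait)
        assert res.detail["loglik"] >= res.detail["loglik_lambda0"] - 1e-8


class TestAgainstPhytools:
    """Cross-validation against the reference R implementation (phytools)."""

    def test_k_and_lambda_match_phylosig(self, tmp_path):
        tree, trait = simulate_tree_and_trait(24, 0.7, 1.0, seed=42)
        tree.write(tmp_path / "t.nwk")
        pd.DataFrame({"label": trait.labels, "value": trait.values}).to_csv(
            tmp_path / "x.tsv", sep="\t", index=False
        )
        script = tmp_path / "phylosig.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages({library(ape); library(phytools)})
                args <- commandArgs(TRUE)
                tree <- read.tree(args[1])
                tr <- read.table(args[2], header=TRUE, sep="\\t")
                x <- setNames(tr$value, tr$label)
                k <- phylosig(tree, x, method="K", test=FALSE)
                l <- phylosig(tree, x, method="lambda", test=FALSE)
                cat(sprintf("%.10f %.10f", as.numeric(k), l$lambda))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "t.nwk"), str(tmp_path / "x.tsv")],
            capture_output=True, text=True, timeout=120,
        )
        assert out.returncode == 0, out.stderr
        k_ref, lam_ref = map(float, out.stdout.split())
        assert blomberg_k(tree, trait, n_rand=0).estimate == pytest.approx(k_ref, abs=1e-6)
        assert pagel_lambda(tree, trait).estimate == pytest.approx(lam_ref, abs=1e-3)
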