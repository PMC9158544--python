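"""Phylogenetic structure of interaction patterns.

Two complementary questions are addressed for each guild:

1. Do closely related species interact with similar partner assemblages?
   Partner profiles are compared with Bray-Curtis dissimilarity and related
   to patristic phylogenetic distance by a Mantel permutation test.
2. Do per-species network statistics (degree, strength) carry phylogenetic
   signal?  Blomberg's K (randomization test on the variance of
   phylogenetically independent contrasts) and Pagel's lambda (maximum
   likelihood with a likelihood-ratio test against lambda = 0), both under
   the Brownian-motion tip covariance implied by the tree.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .data_model import InteractionMatrix, Phylogeny, as_rng
from .errors import ValidationError

__all__ = [
    "TraitVector",
    "SignalResult",
    "partner_dissimilarity",
    "phylo_distance",
    "mantel",
    "blomberg_k",
    "pagel_lambda",
]


@dataclass(frozen=True)
class TraitVector:
    """A per-tip numeric trait (species degree or strength)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.labels):
            raise ValidationError("trait labels/values mismatch")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "TraitVector":
        labels = tuple(sorted(mapping))
        return cls(labels=labels, values=np.array([mapping[l] for l in labels], dtype=float))


@dataclass(frozen=True)
class SignalResult:
    """Outcome of one phylogenetic-signal test."""

    statistic: str  # "K" or "lambda"
    estimate: float
    p_value: float
    n_tips: int
    detail: dict

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")
        if self.statistic == "K" and self.estimate < 0:
            raise ValidationError("Blomberg's K cannot be negative")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def partner_dissimilarity(m: InteractionMatrix, guild: str = "rows"):
    """Bray-Curtis dissimilarity between partner-abundance profiles.

    Returns ``(labels, matrix)``; BC(u, v) = sum|a_u - a_v| / sum(a_u + a_v)
    over the two species' partner profiles — 0 for identical profiles, 1
    for disjoint partner sets.
    """
    if guild == "rows":
        profiles, labels = m.counts.astype(float), m.row_labels
    elif guild == "columns":
        profiles, labels = m.counts.T.astype(float), m.col_labels
    else:
        raise ValidationError(f"unknown guild {guild!r}")
    if (profiles.sum(axis=1) == 0).any():
        raise ValidationError("species with empty partner profile; drop it first")
    return labels, squareform(pdist(profiles, metric="braycurtis"))


def phylo_distance(t: Phylogeny, labels=None):
    """Patristic distance matrix (summed branch lengths between tips)."""
    return t.patristic_matrix(labels)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    tail: str = "greater",
    n_perm: int = 999,
    seed: int | None | np.random.Generator = None,
    method: str = "pearson",
) -> tuple[float, float]:
    """Mantel permutation test between two distance matrices.

    r is the Pearson (or Spearman) correlation of corresponding
    off-diagonal entries; the p-value permutes rows and columns of ``d2``
    simultaneously, with the add-one rule.  ``tail``: ``"greater"``,
    ``"less"`` or ``"two_sided"``.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = d1.shape[0]
    if d1.shape != (n, n) or d2.shape != (n, n):
        raise ValidationError("distance matrices must be square and equal-sized")
    if not (np.allclose(d1, d1.T) and np.allclose(d2, d2.T)):
        raise ValidationError("distance matrices must be symmetric")
    if n_perm < 99:
        raise ValidationError("need at least 99 permutations")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    iu0, iu1 = np.triu_indices(n, k=1)
    x = d1[iu0, iu1]
    y = d2[iu0, iu1]
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant distance matrix: Mantel r undefined")
    xc = (x - x.mean()) / x.std()

    def corr_rows(rows: np.ndarray) -> np.ndarray:
        if method == "spearman":
            from scipy.stats import rankdata

            rows = rankdata(rows, axis=1)
        sd = rows.std(axis=1)
        sd[sd == 0] = np.inf
        centered = rows - rows.mean(axis=1, keepdims=True)
        return (centered / sd[:, None] * xc).mean(axis=1)

    r_obs = float(corr_rows(y[None, :])[0])
    rng = as_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_flat = d2[perms[:, iu0], perms[:, iu1]]  # each row: permuted off-diagonal
    perm_r = corr_rows(perm_flat)
    p_hi = (1 + int((perm_r >= r_obs).sum())) / (n_perm + 1)
    p_lo = (1 + int((perm_r <= r_obs).sum())) / (n_perm + 1)
    if tail == "greater":
        p = p_hi
    elif tail == "less":
        p = p_lo
    elif tail == "two_sided":
        p = min(1.0, 2 * min(p_hi, p_lo))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return r_obs, p


# ---------------------------------------------------------------------------
# Shared tree/trait plumbing
# ---------------------------------------------------------------------------

def _align(t: Phylogeny, x: TraitVector, min_tips: int):
    tips = set(t.tip_labels)
    labels = tuple(l for l in x.labels if l in tips)
    if len(labels) < len(x.labels):
        import logging

        logging.getLogger("symbionet").warning(
            "excluding %d species absent from the tree", len(x.labels) - len(labels)
        )
    if len(labels) < min_tips:
        raise ValidationError(f"need at least {min_tips} tips on the tree; have {len(labels)}")
    tree = t.retain(labels) if len(labels) < len(tips) else t
    lab, v = tree.vcv(sorted(labels))
    order = {l: i for i, l in enumerate(x.labels)}
    values = np.array([x.values[order[l]] for l in lab], dtype=float)
    return tree, lab, v, values


def _pic_variance(tree: Phylogeny, values_by_label: dict[str, float]) -> float:
    """Variance (mean square) of phylogenetically independent contrasts.

    Felsenstein's pruning: at each internal node the contrast between the
    two daughter values, standardized by its branch-length variance; the
    returned statistic is the mean squared standardized contrast.
    """
    work = tree.tree.clone(depth=1)
    work.resolve_polytomies()
    contrasts: list[float] = []
    state: dict[int, tuple[float, float]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            state[id(node)] = (values_by_label[node.taxon.label], node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        x1, v1 = state[id(children[0])]
        for child in children[1:]:
            x2, v2 = state[id(child)]
            if v1 + v2 <= 0:
                raise ValidationError("zero-length sister branches: contrasts undefined")
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            x1 = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 else (x1 + x2) / 2
            v1 = (v1 * v2) / (v1 + v2)
        state[id(node)] = (x1, v1 + (node.edge.length or 0.0))
    return float(np.mean(np.square(contrasts)))


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def blomberg_k(
    t: Phylogeny,
    x: TraitVector,
    n_rand: int = 999,
    seed: int | None | np.random.Generator = None,
) -> SignalResult:
    """Blomberg's K with a tip-shuffling randomization test.

    K is the ratio of the observed mean-square signal (relative to the
    GLS phylogenetic mean) to its Brownian-motion expectation on the tree;
    K = 1 under Brownian evolution, K -> 0 when trait values are
    independent of phylogeny.  The p-value is the add-one proportion of
    tip-label permutations whose PIC variance is as small as observed.
    """
    tree, labels, v, values = _align(t, x, min_tips=4)
    n = len(values)
    if np.allclose(values, values[0]):
        raise ValidationError("trait has zero variance: K undefined")
    vinv = np.linalg.inv(v)
    ones = np.ones(n)
    a_hat = float(ones @ vinv @ values) / float(ones @ vinv @ ones)
    resid = values - a_hat
    mse0 = float(resid @ resid)
    mse = float(resid @ vinv @ resid)
    expected = (np.trace(v) - n / float(ones @ vinv @ ones)) / (n - 1)
    k = (mse0 / mse) / expected
    detail: dict = {"n_randomizations": n_rand}
    if n_rand > 0:
        rng = as_rng(seed)
        obs_pic = _pic_variance(tree, dict(zip(labels, values)))
        hits = 0
        for _ in range(n_rand):
            shuffled = rng.permutation(values)
            if _pic_variance(tree, dict(zip(labels, shuffled))) <= obs_pic:
                hits += 1
        p = (1 + hits) / (n_rand + 1)
        detail["pic_variance"] = obs_pic
    else:
        p = 1.0
    return SignalResult(statistic="K", estimate=float(k), p_value=p, n_tips=n, detail=detail)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

def _lambda_transform(v: np.ndarray, lam: float) -> np.ndarray:
    out = v * lam
    np.fill_diagonal(out, np.diag(v))
    return out


def _profile_loglik(values: np.ndarray, v_lam: np.ndarray) -> float:
    """Gaussian log-likelihood with mean and scale profiled out analytically."""
    n = len(values)
    sign, logdet = np.linalg.slogdet(v_lam)
    if sign <= 0:
        return float("-inf")
    ones = np.ones(n)
    try:
        sol = np.linalg.solve(v_lam, np.column_stack([values, ones]))
    except np.linalg.LinAlgError:
        return float("-inf")
    denom = float(ones @ sol[:, 1])
    if not np.isfinite(denom) or abs(denom) < 1e-300:
        return float("-inf")
    mu = float(ones @ sol[:, 0]) / denom
    resid = values - mu
    try:
        sigma2 = float(resid @ np.linalg.solve(v_lam, resid)) / n
    except np.linalg.LinAlgError:
        return float("-inf")
    if not np.isfinite(sigma2) or sigma2 <= 0:
        return float("-inf")
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(t: Phylogeny, x: TraitVector, max_evals: int = 500) -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    lambda multiplies the off-diagonal entries of the Brownian tip
    covariance (diagonal preserved): 0 means tip values are phylogenetically
    independent, 1 recovers Brownian motion.  The profile likelihood over
    lambda in [0, lambda_max] is maximised by bounded scalar search
    (lambda_max keeps every implied ancestral covariance at most as large
    as the corresponding tip variances).  p compares the fitted model to
    lambda = 0 via the likelihood ratio against chi-square with 1 df.
    """
    _, labels, v, values = _align(t, x, min_tips=4)
    if np.allclose(values, values[0]):
        raise ValidationError("trait has zero variance: lambda undefined")
    off = v[~np.eye(len(v), dtype=bool)]
    max_off = off.max() if off.size else 0.0
    lam_max = float(np.min(np.diag(v)) / max_off) if max_off > 0 else 1.0
    lam_max = max(lam_max, 1.0)

    def neg(lam):
        return -_profile_loglik(values, _lambda_transform(v, lam))

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, lam_max), method="bounded",
        options={"xatol": 1e-6, "maxiter": max_evals},
    )
    if not res.success and not np.isfinite(res.fun):
        raise ValidationError(f"lambda optimization failed: {res.message}")
    candidates = [(0.0, -neg(0.0)), (lam_max, -neg(lam_max)), (float(res.x), -float(res.fun))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll0 = -neg(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return SignalResult(
        statistic="lambda",
        estimate=float(lam_hat),
        p_value=max(p, np.nextafter(0, 1)),
        n_tips=len(values),
        detail={"loglik": ll_hat, "loglik_lambda0": ll0, "LR": lr, "lambda_max": lam_max},
    )
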