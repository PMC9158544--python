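"""Structural metrics of quantitative bipartite networks.

Implements the six network-level statistics commonly reported for
plant-fungus interaction webs — connectance, interaction evenness,
interaction asymmetry, complementarity specialization H2', weighted
nestedness (WNODF) and Barber weighted bipartite modularity (optimised by
label propagation with randomized restarts) — plus per-species degree and
strength.

Conventions: plants are rows, fungi are columns; a_ij is the interaction
count between plant i and fungus j; F is the grand total and L the number
of realized links.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import InteractionMatrix, as_rng
from .errors import ValidationError

__all__ = [
    "MetricSet",
    "ModulePartition",
    "connectance",
    "connectance_from_counts",
    "interaction_evenness",
    "interaction_asymmetry",
    "specialization_h2",
    "wnodf",
    "modularity_dirtlpawb",
    "barber_modularity",
    "species_degree",
    "species_strength",
    "compute_all_metrics",
]


@dataclass(frozen=True)
class MetricSet:
    """The six network-level metrics, each within its documented range."""

    connectance: float
    evenness: float
    mean_asymmetry_fungi: float
    specialization_h2: float
    wnodf: float
    modularity: float

    def __post_init__(self) -> None:
        for name in ("connectance", "evenness", "mean_asymmetry_fungi", "specialization_h2", "modularity"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not (-1e-7 <= self.wnodf <= 100 + 1e-7):
            raise ValidationError(f"wnodf={self.wnodf} outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {
            "connectance": self.connectance,
            "evenness": self.evenness,
            "mean_asymmetry_fungi": self.mean_asymmetry_fungi,
            "specialization_h2": self.specialization_h2,
            "wnodf": self.wnodf,
            "modularity": self.modularity,
        }


@dataclass(frozen=True)
class ModulePartition:
    """Module assignment for both guilds together with its Barber Q."""

    row_modules: np.ndarray
    col_modules: np.ndarray
    Q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules.tolist()) | set(self.col_modules.tolist()))


# ---------------------------------------------------------------------------
# Simple metrics
# ---------------------------------------------------------------------------

def connectance(m: InteractionMatrix) -> float:
    """Proportion of realized links: C = L / (I*J)."""
    if m.I < 1 or m.J < 1 or m.F == 0:
        raise ValidationError("connectance undefined for an empty network")
    return m.L / (m.I * m.J)


def connectance_from_counts(links: int, n_rows: int, n_cols: int) -> float:
    """C = L/(I*J) directly from printed summary counts."""
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("need at least one species per guild")
    return links / (n_rows * n_cols)


def interaction_evenness(m: InteractionMatrix, denominator: str = "grand_total") -> float:
    """Shannon evenness of interaction weights.

    H = -sum_{a_ij>0} p_ij log2 p_ij / log2 D with p_ij = a_ij / F.  The
    normalising D is the grand total F (``denominator="grand_total"``, the
    default) or the link count L (``denominator="links"``).  Zero cells
    contribute nothing.
    """
    if m.F <= 1:
        raise ValidationError("evenness requires total interactions F > 1")
    p = m.counts[m.counts > 0].astype(float) / m.F
    entropy = float(-(p * np.log2(p)).sum())
    if denominator == "grand_total":
        denom = np.log2(m.F)
    elif denominator == "links":
        if m.L <= 1:
            return 0.0
        denom = np.log2(m.L)
    else:
        raise ValidationError(f"unknown evenness denominator {denominator!r}")
    return entropy / denom


def interaction_asymmetry(m: InteractionMatrix, guild: str = "columns"):
    """Per-species mean dependence asymmetry and the guild mean.

    For a realized pair (i, j), s_ij = a_ij / rowsum_i is plant i's
    dependence on fungus j and s_ji = a_ij / colsum_j the reverse;
    d_ij = (s_ij - s_ji) / max(s_ij, s_ji).  A species' asymmetry is the
    mean |d| over its realized partners, so A_i in [0, 1]; 0 means every
    pairwise dependence is mutually balanced.

    Returns ``(per_species: dict label -> A, guild_mean)``; ``guild`` is
    ``"rows"`` (plants) or ``"columns"`` (fungi, the reported guild).
    """
    a = m.counts.astype(float)
    rt = m.row_totals.astype(float)
    ct = m.col_totals.astype(float)
    if (rt == 0).any() or (ct == 0).any():
        raise ValidationError("asymmetry undefined with zero-total species; drop them first")
    s_plant = a / rt[:, None]       # dependence of plant on fungus
    s_fungus = a / ct[None, :]      # dependence of fungus on plant
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (s_plant - s_fungus) / np.maximum(s_plant, s_fungus)
    d = np.where(a > 0, d, 0.0)
    nz = a > 0
    if guild == "rows":
        k = nz.sum(axis=1)
        per = np.abs(d).sum(axis=1) / k
        labels = m.row_labels
    elif guild == "columns":
        k = nz.sum(axis=0)
        per = np.abs(d).sum(axis=0) / k
        labels = m.col_labels
    else:
        raise ValidationError(f"unknown guild {guild!r}")
    per_species = dict(zip(labels, per.tolist()))
    return per_species, float(per.mean())


# ---------------------------------------------------------------------------
# Specialization H2'
# ---------------------------------------------------------------------------

def _shannon_nats(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2_min_greedy(row_tot: np.ndarray, col_tot: np.ndarray) -> float:
    """Entropy of the margin-respecting table built by greedy packing.

    Repeatedly allocates min(largest remaining row margin, largest remaining
    column margin) to that row/column pair; this concentrates mass into as
    few, large cells as the margins allow and approximates the minimum
    two-dimensional entropy.
    """
    r = row_tot.astype(float).copy()
    c = col_tot.astype(float).copy()
    total = r.sum()
    cells: list[float] = []
    while r.max() > 1e-12 and c.max() > 1e-12:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        amount = min(r[i], c[j])
        cells.append(amount)
        r[i] -= amount
        c[j] -= amount
    p = np.asarray(cells) / total
    return _shannon_nats(p)


def specialization_h2(m: InteractionMatrix) -> float:
    """Network-level complementarity specialization H2'.

    H2 = -sum p_ij ln p_ij is standardized between the maximum entropy
    attainable under the observed margins (the independence table
    r_i c_j / F, the fixed point of iterative proportional fitting) and the
    minimum-entropy table found by greedy packing:
    H2' = (H2max - H2) / (H2max - H2min), clamped to [0, 1].  0 means
    interactions follow the margins (no specialization), 1 means maximal
    partner complementarity.
    """
    if m.I < 2 or m.J < 2:
        raise ValidationError("H2' requires at least 2 species per guild")
    if m.F < 2:
        raise ValidationError("H2' requires total interactions F >= 2")
    F = float(m.F)
    p = m.counts.astype(float).ravel() / F
    h2 = _shannon_nats(p)
    pr = m.row_totals / F
    pc = m.col_totals / F
    h2max = _shannon_nats(pr) + _shannon_nats(pc)  # entropy of outer product
    h2min = _h2_min_greedy(m.row_totals, m.col_totals)
    if h2max - h2min < 1e-12:
        raise ValidationError("degenerate margins: H2max equals H2min")
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Weighted nestedness (WNODF)
# ---------------------------------------------------------------------------

def _wnodf_pair_scores(mat: np.ndarray, fills: np.ndarray) -> list[float]:
    """Scores for ordered pairs along one axis (rows of ``mat``)."""
    scores = []
    n = mat.shape[0]
    for u in range(n):
        for v in range(u + 1, n):
            if fills[u] <= fills[v] or fills[v] == 0:
                scores.append(0.0)
                continue
            lower_nz = mat[v] > 0
            n_less = int((lower_nz & (mat[v] < mat[u])).sum())
            scores.append(100.0 * n_less / int(lower_nz.sum()))
    return scores


def wnodf(m: InteractionMatrix) -> float:
    """Weighted nestedness with the decreasing-fill condition, in [0, 100].

    Rows and columns are ordered by decreasing fill (number of links, ties
    broken by decreasing marginal total then label).  A pair scores 0
    unless the upper species has strictly more links than the lower one;
    otherwise the score is the percentage of the lower species' links whose
    counts are strictly smaller than the upper species' counts in the same
    cells.  WNODF averages the scores over all row pairs and column pairs.
    """
    if m.I < 2 or m.J < 2:
        raise ValidationError("WNODF requires at least 2 species per guild")
    a = m.counts
    r_fill = (a > 0).sum(axis=1)
    c_fill = (a > 0).sum(axis=0)
    r_order = sorted(range(m.I), key=lambda i: (-r_fill[i], -m.row_totals[i], m.row_labels[i]))
    c_order = sorted(range(m.J), key=lambda j: (-c_fill[j], -m.col_totals[j], m.col_labels[j]))
    a_sorted = a[np.ix_(r_order, c_order)]
    scores = _wnodf_pair_scores(a_sorted, r_fill[r_order]) + _wnodf_pair_scores(
        a_sorted.T, c_fill[c_order]
    )
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Barber weighted bipartite modularity via label propagation
# ---------------------------------------------------------------------------

def barber_modularity(m: InteractionMatrix, row_modules: np.ndarray, col_modules: np.ndarray) -> float:
    """Barber's weighted bipartite Q for a given two-guild partition.

    Q = (1/F) * sum_ij (a_ij - r_i c_j / F) * [g_i == g_j].
    """
    a = m.counts.astype(float)
    F = float(m.F)
    expected = np.outer(m.row_totals, m.col_totals) / F
    same = row_modules[:, None] == col_modules[None, :]
    return float(((a - expected) * same).sum() / F)


def _best_labels(dev_side: np.ndarray, other_lab: np.ndarray) -> np.ndarray:
    """Optimal label per node given the other guild's labels.

    Each node takes the opposite-guild label maximising its summed deviation
    score; nodes whose best score is negative get a fresh singleton label
    (a module with no cross-guild partner contributes 0 to Q).
    """
    labels = np.unique(other_lab)
    scores = dev_side @ (other_lab[:, None] == labels[None, :]).astype(float)
    best = np.argmax(scores, axis=1)
    out = labels[best]
    fresh = scores[np.arange(len(best)), best] < 0
    if fresh.any():
        out = out.copy()
        out[fresh] = labels.max() + 1 + np.arange(int(fresh.sum()))
    return out


def _lpa_local_max(a, expect, row_lab, col_lab, F, max_iter):
    """Alternating optimal label updates until Q stops improving."""
    dev = a - expect  # modularity contribution per cell

    def q_of(rl, cl):
        return float((dev * (rl[:, None] == cl[None, :])).sum() / F)

    q_prev = q_of(row_lab, col_lab)
    for _ in range(max_iter):
        col_lab = _best_labels(dev.T, row_lab)
        row_lab = _best_labels(dev, col_lab)
        q = q_of(row_lab, col_lab)
        if q <= q_prev + 1e-12:
            q_prev = max(q_prev, q)
            break
        q_prev = q
    return q_prev, row_lab, col_lab


def _agglomerate(a, expect, row_lab, col_lab, F):
    """Greedy module merging while any merge increases Q."""
    dev = a - expect
    improved = True
    while improved:
        improved = False
        labels = np.unique(np.concatenate([row_lab, col_lab]))
        k = len(labels)
        if k < 2:
            break
        # module-level aggregates of the deviation matrix
        rind = (row_lab[:, None] == labels[None, :]).astype(float)
        cind = (col_lab[:, None] == labels[None, :]).astype(float)
        block = rind.T @ dev @ cind  # k x k : sum of dev over (rows in l, cols in m)
        best_gain, best_pair = 1e-12, None
        for x in range(k):
            for y in range(x + 1, k):
                gain = (block[x, y] + block[y, x]) / F
                if gain > best_gain:
                    best_gain, best_pair = gain, (x, y)
        if best_pair is not None:
            x, y = best_pair
            row_lab = np.where(row_lab == labels[y], labels[x], row_lab)
            col_lab = np.where(col_lab == labels[y], labels[x], col_lab)
            improved = True
    same = row_lab[:, None] == col_lab[None, :]
    return float((dev * same).sum() / F), row_lab, col_lab


def modularity_dirtlpawb(
    m: InteractionMatrix,
    max_iter: int = 10_000,
    n_restarts: int = 100,
    seed: int | None | np.random.Generator = None,
) -> ModulePartition:
    """Maximise Barber weighted modularity by label propagation with restarts.

    Each restart seeds the row guild with a random assignment into a random
    number of initial modules (the first restart uses the canonical
    one-module-per-row start), runs alternating label propagation to a local
    maximum, then greedily merges modules while that raises Q, re-running
    propagation after merges.  The best partition over all restarts is
    returned; with a fixed seed the result is deterministic.
    """
    if m.F == 0:
        raise ValidationError("modularity undefined for an empty network")
    rng = as_rng(seed)
    a = m.counts.astype(float)
    F = float(m.F)
    expect = np.outer(m.row_totals, m.col_totals) / F
    best = (-np.inf, None, None)
    max_modules = max(1, min(m.I, m.J))
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            row_lab = np.arange(m.I)
        else:
            k = int(rng.integers(1, max_modules + 1))
            row_lab = rng.integers(0, k, size=m.I)
        col_lab = np.zeros(m.J, dtype=int)
        q, row_lab, col_lab = _lpa_local_max(a, expect, row_lab, col_lab, F, max_iter)
        while True:
            q2, row_lab, col_lab = _agglomerate(a, expect, row_lab, col_lab, F)
            q3, row_lab, col_lab = _lpa_local_max(a, expect, row_lab, col_lab, F, max_iter)
            if max(q2, q3) <= q + 1e-12:
                q = max(q, q2, q3)
                break
            q = max(q2, q3)
        if q > best[0]:
            best = (q, row_lab.copy(), col_lab.copy())
    q, row_lab, col_lab = best
    # single-module partition always achieves Q = 0; never report worse
    if q < 0.0:
        row_lab = np.zeros(m.I, dtype=int)
        col_lab = np.zeros(m.J, dtype=int)
        q = 0.0
    # relabel modules densely for stable output
    labels = {l: i for i, l in enumerate(dict.fromkeys(np.concatenate([row_lab, col_lab]).tolist()))}
    row_modules = np.array([labels[l] for l in row_lab.tolist()])
    col_modules = np.array([labels[l] for l in col_lab.tolist()])
    return ModulePartition(row_modules=row_modules, col_modules=col_modules, Q=float(q))


# ---------------------------------------------------------------------------
# Per-species statistics
# ---------------------------------------------------------------------------

def species_degree(m: InteractionMatrix) -> dict[str, dict[str, int]]:
    """Number of realized partners per species, for both guilds."""
    nz = m.counts > 0
    return {
        "plants": dict(zip(m.row_labels, nz.sum(axis=1).astype(int).tolist())),
        "fungi": dict(zip(m.col_labels, nz.sum(axis=0).astype(int).tolist())),
    }


def species_strength(m: InteractionMatrix) -> dict[str, dict[str, float]]:
    """Summed partner dependences per species, for both guilds.

    The strength of fungus j is sum_i a_ij / rowsum_i; strengths of one
    guild sum to the number of species in the other guild.
    """
    rt = m.row_totals.astype(float)
    ct = m.col_totals.astype(float)
    if (rt == 0).any() or (ct == 0).any():
        raise ValidationError("strength undefined with zero-total species; drop them first")
    a = m.counts.astype(float)
    fungus_strength = (a / rt[:, None]).sum(axis=0)
    plant_strength = (a / ct[None, :]).sum(axis=1)
    return {
        "plants": dict(zip(m.row_labels, plant_strength.tolist())),
        "fungi": dict(zip(m.col_labels, fungus_strength.tolist())),
    }


def compute_all_metrics(
    m: InteractionMatrix,
    evenness_denominator: str = "grand_total",
    modularity_restarts: int = 20,
    seed: int | None | np.random.Generator = None,
) -> MetricSet:
    """Convenience wrapper computing the full MetricSet for one network."""
    _, asym_mean = interaction_asymmetry(m, guild="columns")
    part = modularity_dirtlpawb(m, n_restarts=modularity_restarts, seed=seed)
    return MetricSet(
        connectance=connectance(m),
        evenness=interaction_evenness(m, denominator=evenness_denominator),
        mean_asymmetry_fungi=asym_mean,
        specialization_h2=specialization_h2(m),
        wnodf=wnodf(m),
        modularity=max(0.0, part.Q),
    )
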