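"""Swap null model for quantitative matrices and significance assessment.

The null preserves three observed quantities exactly: row marginal totals,
column marginal totals, and the number of realized links L (connectance).
Each replicate starts from a Patefield random fill of the margins (via
``scipy.stats.random_table``) and is then pushed toward the target L with
2x2 submatrix moves that conserve the margins while changing the number of
nonzero cells.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import InteractionMatrix, as_rng
from .errors import InfeasibleModelError, ValidationError

__all__ = ["NullDistribution", "swap_null", "significance"]


@dataclass(frozen=True)
class NullDistribution:
    """Observed metric value against a null/randomized reference distribution."""

    metric: str
    observed: float
    replicates: np.ndarray
    ci95: tuple[float, float]
    p_value: float
    tail: str = "two_sided"
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.ci95[0] > self.ci95[1] + 1e-12:
            raise ValidationError("ci95 lower bound exceeds upper bound")
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")

    @property
    def n_reps(self) -> int:
        return len(self.replicates)

    @property
    def inside_ci(self) -> bool:
        return self.ci95[0] <= self.observed <= self.ci95[1]


def _adjust_fill(
    table: np.ndarray, target_l: int, rng: np.random.Generator, move_budget: int
) -> np.ndarray:
    """Drive the nonzero-cell count of a margin-fixed table toward target_l.

    A move adds k to cells (r1,c1),(r2,c2) and subtracts k from
    (r1,c2),(r2,c1); both margins are invariant for any feasible k.  Extreme
    k values zero out cells (reducing fill), |k| = 1 moves split mass into
    empty cells (raising fill).  Only moves that strictly improve
    |L - target| are accepted.
    """
    t = table.copy()
    n_rows, n_cols = t.shape
    current = int(np.count_nonzero(t))
    if current == target_l:
        return t
    for _ in range(move_budget):
        r = rng.choice(n_rows, size=2, replace=False)
        c = rng.choice(n_cols, size=2, replace=False)
        sub = t[np.ix_(r, c)]
        a, b = sub[0]
        cc, d = sub[1]
        candidates = set()
        lo, hi = -min(a, d), min(b, cc)
        for k in (lo, hi, -1, 1):
            if lo <= k <= hi and k != 0:
                candidates.add(int(k))
        best_k, best_l = None, current
        for k in candidates:
            new = np.array([[a + k, b - k], [cc - k, d + k]])
            new_l = current - int((sub > 0).sum()) + int((new > 0).sum())
            if abs(new_l - target_l) < abs(best_l - target_l):
                best_k, best_l = k, new_l
        if best_k is not None:
            k = best_k
            t[r[0], c[0]] += k
            t[r[0], c[1]] -= k
            t[r[1], c[0]] -= k
            t[r[1], c[1]] += k
            current = best_l
            if current == target_l:
                return t
    raise InfeasibleModelError(
        f"could not reach {target_l} filled cells within the move budget "
        f"({move_budget}); stalled at {current}"
    )


def swap_null(
    m: InteractionMatrix,
    n_reps: int = 1000,
    seed: int | None | np.random.Generator = None,
    move_budget: int = 100_000,
) -> list[InteractionMatrix]:
    """Generate null networks preserving margins and link count.

    Every replicate has exactly the row sums, column sums and number of
    nonzero cells of ``m``; within those constraints, counts are shuffled
    randomly.  Deterministic given ``seed``.
    """
    if m.I < 2 or m.J < 2:
        raise ValidationError("swap null requires at least a 2x2 network")
    rng = as_rng(seed)
    dist = stats.random_table(m.row_totals, m.col_totals)
    out = []
    for _ in range(n_reps):
        table = np.asarray(dist.rvs(random_state=rng), dtype=np.int64)
        table = _adjust_fill(table, m.L, rng, move_budget)
        out.append(
            InteractionMatrix(counts=table, row_labels=m.row_labels, col_labels=m.col_labels)
        )
    return out


def significance(
    observed: float,
    replicates: np.ndarray,
    tail: str = "two_sided",
    metric: str = "metric",
) -> NullDistribution:
    """Permutation-style significance of an observed metric against replicates.

    The CI is the empirical 2.5-97.5 percentile interval of the replicate
    values.  The p-value uses the add-one convention,
    p = (1 + #{as-or-more extreme}) / (n + 1); the two-sided p doubles the
    smaller tail and is capped at 1.
    """
    replicates = np.asarray(replicates, dtype=float)
    n = len(replicates)
    if n < 100:
        raise ValidationError("need at least 100 replicates for CI reporting")
    ci = (float(np.percentile(replicates, 2.5)), float(np.percentile(replicates, 97.5)))
    p_hi = (1 + int((replicates >= observed).sum())) / (n + 1)
    p_lo = (1 + int((replicates <= observed).sum())) / (n + 1)
    if tail == "greater":
        p = p_hi
    elif tail == "less":
        p = p_lo
    elif tail == "two_sided":
        p = min(1.0, 2 * min(p_hi, p_lo))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return NullDistribution(
        metric=metric, observed=float(observed), replicates=replicates, ci95=ci, p_value=p, tail=tail
    )
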