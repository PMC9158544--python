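"""Pairwise interaction-probability hypotheses: Ab, Sp, AbSp, Null, Obs.

Each builder returns a :class:`ProbabilityMatrix` over the same plant x
fungus grid as the network, with entries summing to one:

* ``Ab``   — neutral encounter: product of relative abundances.
* ``Sp``   — spatial overlap: normalized count of co-occupied quadrats;
  pairs never co-occurring get probability exactly zero.
* ``AbSp`` — combined hypothesis: elementwise product of Ab and Sp,
  renormalized.
* ``Null`` — equiprobable: 1/(I*J) everywhere.
* ``Obs``  — observed relative interaction frequencies a_ij / F.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AbundanceVector, InteractionMatrix, OccurrenceMatrix
from .errors import InfeasibleModelError, ValidationError

__all__ = [
    "ProbabilityMatrix",
    "build_ab",
    "build_sp",
    "build_absp",
    "build_null",
    "build_obs",
    "MODEL_NAMES",
]

MODEL_NAMES = ("Ab", "Sp", "AbSp", "Null", "Obs")


@dataclass(frozen=True)
class ProbabilityMatrix:
    """A simplex-normalized interaction-probability matrix under one hypothesis."""

    name: str
    probs: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("probability matrix labels do not match shape")
        if (probs < 0).any():
            raise ValidationError("probabilities must be non-negative")
        total = probs.sum()
        if not np.isclose(total, 1.0, atol=1e-12, rtol=1e-9):
            raise ValidationError(f"probabilities sum to {total}, not 1")
        object.__setattr__(self, "probs", probs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.probs, index=list(self.row_labels), columns=list(self.col_labels))

    def write(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        self.to_frame().to_csv(path, sep=sep)


def _check_aligned(a: ProbabilityMatrix, b: ProbabilityMatrix) -> None:
    if a.row_labels != b.row_labels or a.col_labels != b.col_labels:
        raise ValidationError("probability matrices are not label-aligned")


def build_ab(plants: AbundanceVector, fungi: AbundanceVector) -> ProbabilityMatrix:
    """Neutral hypothesis: p_ij = (n_i / sum n) * (m_j / sum m).

    The outer product of two simplex vectors, so the result sums to one by
    construction and is invariant to rescaling either abundance vector.
    """
    for vec, guild in ((plants, "plant"), (fungi, "fungus")):
        zero = [l for l, v in zip(vec.labels, vec.values) if v <= 0]
        if zero:
            raise ValidationError(f"zero abundance for {guild} species {zero[:5]}")
    p = np.outer(plants.values / plants.values.sum(), fungi.values / fungi.values.sum())
    return ProbabilityMatrix(name="Ab", probs=p, row_labels=plants.labels, col_labels=fungi.labels)


def build_sp(occ_plants: OccurrenceMatrix, occ_fungi: OccurrenceMatrix) -> ProbabilityMatrix:
    """Spatial-overlap hypothesis: p_ij proportional to co-occupied quadrats.

    o_ij counts quadrats where plant i and fungus j are both present; the
    matrix is normalized to sum one.  Pairs with no overlap keep probability
    exactly zero — the hypothesis forbids those interactions.
    """
    if occ_plants.quadrats != occ_fungi.quadrats:
        raise ValidationError("plant and fungus occurrence matrices use different quadrat sets")
    for occ, guild in ((occ_plants, "plant"), (occ_fungi, "fungus")):
        empty = [l for l, row in zip(occ.species, occ.presence) if row.sum() == 0]
        if empty:
            raise ValidationError(f"{guild} species occupying zero quadrats: {empty[:5]}")
    overlap = occ_plants.presence.astype(np.int64) @ occ_fungi.presence.T.astype(np.int64)
    total = overlap.sum()
    if total == 0:
        raise InfeasibleModelError("no plant-fungus pair shares a quadrat")
    return ProbabilityMatrix(
        name="Sp",
        probs=overlap / total,
        row_labels=occ_plants.species,
        col_labels=occ_fungi.species,
    )


def build_absp(ab: ProbabilityMatrix, sp: ProbabilityMatrix) -> ProbabilityMatrix:
    """Combined hypothesis: elementwise Ab*Sp, renormalized to sum one."""
    _check_aligned(ab, sp)
    prod = ab.probs * sp.probs
    total = prod.sum()
    if total <= 0:
        raise InfeasibleModelError("Ab and Sp supports are disjoint: no feasible interaction")
    return ProbabilityMatrix(
        name="AbSp", probs=prod / total, row_labels=ab.row_labels, col_labels=ab.col_labels
    )


def build_null(
    n_plants: int,
    n_fungi: int,
    row_labels: tuple[str, ...] | None = None,
    col_labels: tuple[str, ...] | None = None,
) -> ProbabilityMatrix:
    """Equiprobable hypothesis: every pair gets 1/(I*J)."""
    if n_plants < 1 or n_fungi < 1:
        raise ValidationError("need at least one species per guild")
    if row_labels is None:
        row_labels = tuple(f"plant_{i}" for i in range(n_plants))
    if col_labels is None:
        col_labels = tuple(f"fungus_{j}" for j in range(n_fungi))
    p = np.full((n_plants, n_fungi), 1.0 / (n_plants * n_fungi))
    return ProbabilityMatrix(name="Null", probs=p, row_labels=row_labels, col_labels=col_labels)


def build_obs(m: InteractionMatrix) -> ProbabilityMatrix:
    """Observed relative frequencies: p_ij = a_ij / F."""
    if m.F == 0:
        raise ValidationError("observed probability matrix undefined for an empty network")
    return ProbabilityMatrix(
        name="Obs",
        probs=m.counts / m.F,
        row_labels=m.row_labels,
        col_labels=m.col_labels,
    )
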