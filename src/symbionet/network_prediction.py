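"""Constrained randomization of interactions under a probability hypothesis.

``assign_interactions`` distributes the observed total number of
interactions F across the plant x fungus grid according to a probability
matrix, with the single constraint that every species receives at least one
interaction.  ``predict_metric_distribution`` repeats this to obtain the
predicted 95% interval of each structural metric under the hypothesis.
"""
from __future__ import annotations

import logging

import numpy as np

from . import network_metrics as nm
from .data_model import InteractionMatrix, as_rng
from .errors import InfeasibleModelError, ValidationError
from .null_models import NullDistribution, significance
from .probability_models import ProbabilityMatrix

logger = logging.getLogger("symbionet")

__all__ = ["assign_interactions", "predict_metric_distribution", "DEFAULT_METRICS"]

DEFAULT_METRICS = (
    "connectance",
    "evenness",
    "mean_asymmetry_fungi",
    "specialization_h2",
    "wnodf",
    "modularity",
)


def assign_interactions(
    p: ProbabilityMatrix,
    f_total: int,
    seed: int | None | np.random.Generator = None,
) -> InteractionMatrix:
    """Sample a network with ``f_total`` interactions from probabilities ``p``.

    Two phases: (1) connectivity — cells are drawn with probability p_ij and
    a draw is accepted only while it links a so-far-unlinked plant or fungus,
    until both guilds are fully covered (rejected draws are discarded and do
    not count toward the total); (2) fill — the remaining interactions are
    drawn i.i.d. multinomially with probabilities p.  Cells with p_ij = 0
    can never receive interactions.
    """
    probs = p.probs
    n_rows, n_cols = probs.shape
    if (probs.sum(axis=1) == 0).any() or (probs.sum(axis=0) == 0).any():
        raise InfeasibleModelError(
            f"{p.name}: some species have zero total interaction probability"
        )
    if f_total < max(n_rows, n_cols):
        raise ValidationError(
            f"f_total={f_total} cannot give every species an interaction "
            f"({n_rows} plants, {n_cols} fungi)"
        )
    rng = as_rng(seed)
    flat = probs.ravel()
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    row_linked = np.zeros(n_rows, dtype=bool)
    col_linked = np.zeros(n_cols, dtype=bool)
    assigned = 0
    # phase 1: draw in blocks for speed; accept only coverage-extending draws
    while not (row_linked.all() and col_linked.all()):
        block = rng.choice(flat.size, size=256, p=flat)
        for cell in block:
            i, j = divmod(int(cell), n_cols)
            if row_linked[i] and col_linked[j]:
                continue
            counts[i, j] += 1
            assigned += 1
            row_linked[i] = True
            col_linked[j] = True
            if row_linked.all() and col_linked.all():
                break
    if assigned > f_total:
        raise InfeasibleModelError(
            f"connectivity phase needed {assigned} interactions but f_total={f_total}"
        )
    # phase 2: multinomial fill of the remainder
    counts += rng.multinomial(f_total - assigned, flat).reshape(n_rows, n_cols)
    return InteractionMatrix(counts=counts, row_labels=p.row_labels, col_labels=p.col_labels)


def _metric_value(m: InteractionMatrix, metric: str, seed) -> float:
    if metric == "connectance":
        return nm.connectance(m)
    if metric == "evenness":
        return nm.interaction_evenness(m)
    if metric == "mean_asymmetry_fungi":
        return nm.interaction_asymmetry(m, guild="columns")[1]
    if metric == "specialization_h2":
        return nm.specialization_h2(m)
    if metric == "wnodf":
        return nm.wnodf(m)
    if metric == "modularity":
        return max(0.0, nm.modularity_dirtlpawb(m, n_restarts=10, seed=seed).Q)
    raise ValidationError(f"unknown metric {metric!r}")


def predict_metric_distribution(
    p: ProbabilityMatrix,
    f_total: int,
    n_reps: int = 1000,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    seed: int | None | np.random.Generator = None,
    observed: dict[str, float] | None = None,
) -> dict[str, NullDistribution]:
    """Predicted metric distributions under hypothesis ``p``.

    Runs ``assign_interactions`` ``n_reps`` times, computes the requested
    metrics on each replicate network, and summarises each metric by its
    2.5-97.5 percentile interval.  If ``observed`` values are supplied they
    are stored so each distribution can report whether the observation falls
    inside the predicted interval.  Replicates on which a metric is
    undefined (degenerate draws) are excluded for that metric, with the
    exclusion count recorded.
    """
    if n_reps < 100:
        raise ValidationError("need n_reps >= 100 for interval reporting")
    rng = as_rng(seed)
    values: dict[str, list[float]] = {name: [] for name in metrics}
    failures: dict[str, int] = {name: 0 for name in metrics}
    for _ in range(n_reps):
        net = assign_interactions(p, f_total, rng)
        for name in metrics:
            try:
                values[name].append(_metric_value(net, name, rng))
            except (ValidationError, InfeasibleModelError):
                failures[name] += 1
    out: dict[str, NullDistribution] = {}
    for name in metrics:
        reps = np.asarray(values[name], dtype=float)
        if len(reps) < 100:
            raise InfeasibleModelError(
                f"metric {name!r} defined on only {len(reps)}/{n_reps} replicates"
            )
        if failures[name]:
            logger.warning(
                "%s: metric %s undefined on %d/%d replicates (excluded)",
                p.name, name, failures[name], n_reps,
            )
        obs = (observed or {}).get(name, np.nan)
        if np.isnan(obs):
            ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
            out[name] = NullDistribution(
                metric=name, observed=float(np.median(reps)), replicates=reps,
                ci95=ci, p_value=1.0, tail="two_sided", n_failed=failures[name],
            )
        else:
            dist = significance(obs, reps, tail="two_sided", metric=name)
            out[name] = NullDistribution(
                metric=name, observed=dist.observed, replicates=reps, ci95=dist.ci95,
                p_value=dist.p_value, tail=dist.tail, n_failed=failures[name],
            )
    return out
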