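"""Multinomial-likelihood comparison of interaction-probability hypotheses.

Given the observed count matrix and a candidate probability matrix, the
likelihood treats the F observed interactions as one draw from a
multinomial over the I*J cells.  Candidates are ranked by AIC; Akaike
weights give the relative support for each hypothesis.

The module also provides the package's fitted-model interface:
:class:`NetworkAssemblyModel` holds the observed network and its candidate
hypotheses; ``fit()`` returns a :class:`NetworkAssemblyResults` carrying
the comparison table, with ``summary()`` and ``predict_metrics()``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_model import InteractionMatrix
from .errors import InfeasibleModelError, ValidationError
from .probability_models import ProbabilityMatrix

logger = logging.getLogger("symbionet")

__all__ = [
    "multinomial_loglik",
    "aic_table",
    "ModelComparisonTable",
    "NetworkAssemblyModel",
    "NetworkAssemblyResults",
]


def multinomial_loglik(
    m: InteractionMatrix, p: ProbabilityMatrix, zero_policy: str = "strict"
) -> float:
    """Multinomial log-likelihood of the observed counts under ``p``.

    log L = lgamma(F+1) - sum lgamma(a_ij+1) + sum_{a_ij>0} a_ij log p_ij.

    ``zero_policy`` governs cells observed but assigned zero probability:
    ``"strict"`` returns -inf (the hypothesis is falsified by the data);
    ``"epsilon"`` replaces zero entries by (smallest positive p)/100 and
    renormalizes before evaluating, which keeps hypotheses with hard zeros
    comparable (the substitution is logged).
    """
    if m.counts.shape != p.probs.shape or m.row_labels != p.row_labels or m.col_labels != p.col_labels:
        raise ValidationError("interaction matrix and probability matrix are not aligned")
    counts = m.counts.astype(float)
    probs = p.probs
    if zero_policy == "epsilon":
        positive = probs[probs > 0]
        if positive.size == 0:
            raise ValidationError("probability matrix has no positive entries")
        if (probs == 0).any():
            eps = positive.min() / 100.0
            probs = np.where(probs == 0, eps, probs)
            probs = probs / probs.sum()
            logger.info("%s: epsilon policy filled %d zero cells", p.name, int((p.probs == 0).sum()))
    elif zero_policy != "strict":
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    support_violation = (counts > 0) & (probs == 0)
    coef = float(gammaln(m.F + 1) - gammaln(counts + 1).sum())
    if support_violation.any():
        return float("-inf")
    nz = counts > 0
    return coef + float((counts[nz] * np.log(probs[nz])).sum())


@dataclass(frozen=True)
class ModelComparisonTable:
    """Per-hypothesis log-likelihood, AIC, delta-AIC and Akaike weight."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        finite = np.isfinite(t["aic"].to_numpy())
        if finite.any():
            deltas = t.loc[finite, "delta_aic"].to_numpy()
            if abs(deltas.min()) > 1e-9:
                raise ValidationError("minimum delta AIC must be 0")
        if abs(t["weight"].sum() - 1.0) > 1e-12:
            raise ValidationError("Akaike weights must sum to 1")

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def __str__(self) -> str:
        with pd.option_context("display.float_format", "{:.6g}".format):
            return self.table.to_string(index=False)


def aic_table(
    logliks: dict[str, float], k: dict[str, int] | None = None
) -> ModelComparisonTable:
    """Build the AIC / delta-AIC / Akaike-weight comparison table.

    AIC = -2 logL + 2k.  By default k = 0 for every hypothesis: the
    probability matrices are fixed inputs with no fitted parameters, so all
    deltas are pure deviance differences (any common k shifts all AICs
    equally and leaves deltas and weights unchanged).  Hypotheses with
    -inf log-likelihood get weight 0.
    """
    if len(logliks) < 2:
        raise ValidationError("need at least two models to compare")
    if all(not np.isfinite(v) for v in logliks.values()):
        raise InfeasibleModelError("all candidate models have -inf log-likelihood")
    k = k or {}
    rows = []
    for name, ll in logliks.items():
        kk = int(k.get(name, 0))
        aic = float("inf") if not np.isfinite(ll) else -2.0 * ll + 2.0 * kk
        rows.append({"model": name, "loglik": ll, "k": kk, "aic": aic})
    best = min(r["aic"] for r in rows)
    for r in rows:
        r["delta_aic"] = r["aic"] - best if np.isfinite(r["aic"]) else float("inf")
    rel = np.array([np.exp(-0.5 * r["delta_aic"]) if np.isfinite(r["delta_aic"]) else 0.0 for r in rows])
    weights = rel / rel.sum()
    for r, w in zip(rows, weights):
        r["weight"] = float(w)
    frame = pd.DataFrame(rows).sort_values(["aic", "model"], kind="stable").reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return ModelComparisonTable(table=frame[["rank", "model", "loglik", "k", "aic", "delta_aic", "weight"]])


# ---------------------------------------------------------------------------
# Fitted-model interface
# ---------------------------------------------------------------------------

class NetworkAssemblyModel:
    """Observed quantitative network plus candidate assembly hypotheses.

    Parameters
    ----------
    network : InteractionMatrix
        The observed plant x fungus count matrix.
    hypotheses : dict[str, ProbabilityMatrix]
        Candidate interaction-probability matrices (e.g. Ab, Sp, AbSp,
        Null), label-aligned with the network.
    """

    def __init__(self, network: InteractionMatrix, hypotheses: dict[str, ProbabilityMatrix]):
        if len(hypotheses) < 2:
            raise ValidationError("need at least two hypotheses to compare")
        for name, p in hypotheses.items():
            if p.row_labels != network.row_labels or p.col_labels != network.col_labels:
                raise ValidationError(f"hypothesis {name!r} is not label-aligned with the network")
        self.network = network
        self.hypotheses = dict(hypotheses)

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, hypotheses: dict[str, ProbabilityMatrix]):
        return cls(InteractionMatrix.from_frame(counts), hypotheses)

    def loglike(self, name: str, zero_policy: str = "strict") -> float:
        return multinomial_loglik(self.network, self.hypotheses[name], zero_policy)

    def fit(self, zero_policy: str = "strict", k: dict[str, int] | None = None) -> "NetworkAssemblyResults":
        logliks = {name: self.loglike(name, zero_policy) for name in self.hypotheses}
        return NetworkAssemblyResults(
            model=self, comparison=aic_table(logliks, k=k), zero_policy=zero_policy
        )


class NetworkAssemblyResults:
    """Result of comparing assembly hypotheses by multinomial likelihood."""

    def __init__(self, model: NetworkAssemblyModel, comparison: ModelComparisonTable, zero_policy: str):
        self.model = model
        self.comparison = comparison
        self.zero_policy = zero_policy

    @property
    def best_model(self) -> str:
        return self.comparison.best_model

    @property
    def llf(self) -> dict[str, float]:
        t = self.comparison.table
        return dict(zip(t["model"], t["loglik"]))

    @property
    def akaike_weights(self) -> dict[str, float]:
        t = self.comparison.table
        return dict(zip(t["model"], t["weight"]))

    def predict_metrics(
        self,
        hypothesis: str,
        n_reps: int = 1000,
        metrics=None,
        seed=None,
    ):
        """Predicted metric intervals under one hypothesis at the observed F."""
        from .network_prediction import DEFAULT_METRICS, predict_metric_distribution
        from .network_metrics import compute_all_metrics

        metrics = tuple(metrics) if metrics is not None else DEFAULT_METRICS
        observed = compute_all_metrics(self.model.network, seed=0).as_dict()
        return predict_metric_distribution(
            self.model.hypotheses[hypothesis],
            self.model.network.F,
            n_reps=n_reps,
            metrics=metrics,
            seed=seed,
            observed=observed,
        )

    def summary(self) -> str:
        net = self.model.network
        lines = [
            "Network assembly hypothesis comparison (multinomial likelihood)",
            "=" * 64,
            f"Observed network: {net.I} plants x {net.J} fungi, F={net.F}, L={net.L}",
            f"Zero-probability policy: {self.zero_policy}",
            "",
            str(self.comparison),
            "",
            f"Best-supported hypothesis: {self.best_model}",
        ]
        return "\n".join(lines)
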