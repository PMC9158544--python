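"""Virtual plant-fungus communities with the statistical structure the
analysis assumes.

The generator emulates the study system a field survey would produce:
right-skewed (log-normal) species abundances, spatially aggregated
occupancy on a rectangular grid of 20 x 20 m quadrats (each species
occupies disc-shaped patches around cluster centres, more centres for more
abundant species), interaction counts drawn from a chosen generative
probability model through the same constrained randomization the analysis
uses for prediction, and tip traits evolved on Yule trees under a
lambda-scaled Brownian-motion covariance.

Everything is reproducible bit-for-bit from ``(scenario, seed)``.
"""
from __future__ import annotations

import random as _random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .data_model import AbundanceVector, InteractionMatrix, OccurrenceMatrix, Phylogeny
from .errors import ValidationError
from .network_prediction import assign_interactions
from .probability_models import (
    ProbabilityMatrix,
    build_ab,
    build_absp,
    build_null,
    build_sp,
)

__all__ = [
    "CommunityScenario",
    "SimulatedCommunity",
    "simulate_abundances",
    "simulate_occupancy",
    "simulate_network",
    "simulate_tree_and_trait",
]


@dataclass(frozen=True)
class CommunityScenario:
    """Parameters of one virtual community.

    Defaults describe a community small enough to analyse quickly but with
    the study system's qualitative features: a 25 x 50 grid of 20-m
    quadrats (a 50-ha plot), log-normal abundances (sdlog 1 gives the
    right-skew and an abundance CV above 1), plants widespread (larger
    patch radius, more cluster centres) and fungi tightly aggregated
    (patch radius ~3 quadrats, echoing spatial autocorrelation over tens
    of metres), and interactions drawn under one of the four assembly
    hypotheses.
    """

    n_plants: int = 15
    n_fungi: int = 60
    grid_shape: tuple[int, int] = (25, 50)
    # log-normal abundance parameters per guild (meanlog, sdlog)
    plant_abundance_logmean: float = 6.0
    plant_abundance_logsd: float = 1.0
    fungus_abundance_logmean: float = 6.0
    fungus_abundance_logsd: float = 1.0
    # spatial aggregation: patch radius (in quadrat units) and max cluster centres
    plant_patch_radius: float = 8.0
    fungus_patch_radius: float = 3.0
    plant_max_centers: int = 8
    fungus_max_centers: int = 4
    generative_model: str = "Sp"
    f_total: int = 2000
    # trait-evolution parameters for the companion trees
    lambda_true: float = 1.0
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.n_fungi < 1 or self.f_total < 1:
            raise ValidationError("scenario counts must be positive")
        if self.generative_model not in ("Null", "Ab", "Sp", "AbSp"):
            raise ValidationError(f"unknown generative model {self.generative_model!r}")

    @property
    def n_quadrats(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def with_(self, **kwargs) -> "CommunityScenario":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulatedCommunity:
    """A complete virtual data set plus its generative ground truth."""

    scenario: CommunityScenario
    network: InteractionMatrix
    true_model: str
    probability: ProbabilityMatrix
    plant_abundance: AbundanceVector
    fungus_abundance: AbundanceVector
    plant_occurrence: OccurrenceMatrix
    fungus_occurrence: OccurrenceMatrix


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}_{i:0{width}d}" for i in range(1, n + 1))


def simulate_abundances(scenario: CommunityScenario) -> tuple[AbundanceVector, AbundanceVector]:
    """Log-normal abundances per guild, rounded up to at least one individual."""
    rng = _stage_rng(scenario.seed, 1)
    plants = np.ceil(
        rng.lognormal(scenario.plant_abundance_logmean, scenario.plant_abundance_logsd, scenario.n_plants)
    )
    fungi = np.ceil(
        rng.lognormal(scenario.fungus_abundance_logmean, scenario.fungus_abundance_logsd, scenario.n_fungi)
    )
    return (
        AbundanceVector(labels=_labels("plant", scenario.n_plants), values=plants),
        AbundanceVector(labels=_labels("fungus", scenario.n_fungi), values=fungi),
    )


def _occupancy_one_guild(
    rng: np.random.Generator,
    labels: tuple[str, ...],
    abundances: np.ndarray,
    grid_shape: tuple[int, int],
    radius: float,
    max_centers: int,
    allowed: np.ndarray | None = None,
) -> OccurrenceMatrix:
    gr, gc = grid_shape
    ys, xs = np.mgrid[0:gr, 0:gc]
    coords = np.column_stack([ys.ravel(), xs.ravel()]).astype(float)
    center_pool = np.arange(len(coords)) if allowed is None else np.flatnonzero(allowed)
    a_max = abundances.max()
    rows = []
    for a in abundances:
        n_centers = max(1, int(round(max_centers * a / a_max)))
        centers = coords[center_pool[rng.integers(0, len(center_pool), size=n_centers)]]
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        present = (d2.min(axis=1) <= radius**2).astype(np.int8)
        if present.sum() == 0:  # radius < 1 cell: keep the centre quadrats
            present[np.unique((centers[:, 0] * gc + centers[:, 1]).astype(int))] = 1
        rows.append(present)
    quadrats = tuple(f"q{i:04d}" for i in range(gr * gc))
    return OccurrenceMatrix(presence=np.vstack(rows), species=labels, quadrats=quadrats)


def simulate_occupancy(
    scenario: CommunityScenario,
    abundances: tuple[AbundanceVector, AbundanceVector] | None = None,
) -> tuple[OccurrenceMatrix, OccurrenceMatrix]:
    """Clustered quadrat occupancy per guild.

    Each species gets cluster centres (count scaling with its abundance)
    and occupies every quadrat within the guild's patch radius of a centre;
    a radius covering the grid diagonal yields full occupancy, radius zero
    leaves only the centre quadrats.  Fungal centres are restricted to
    quadrats already occupied by at least one plant: these are
    root-associated symbionts, observable only where hosts grow, which also
    guarantees every fungus has positive spatial overlap with the plant
    guild.
    """
    if abundances is None:
        abundances = simulate_abundances(scenario)
    plants_ab, fungi_ab = abundances
    rng = _stage_rng(scenario.seed, 2)
    occ_p = _occupancy_one_guild(
        rng, plants_ab.labels, plants_ab.values, scenario.grid_shape,
        scenario.plant_patch_radius, scenario.plant_max_centers,
    )
    host_cover = occ_p.presence.max(axis=0).astype(bool)
    occ_f = _occupancy_one_guild(
        rng, fungi_ab.labels, fungi_ab.values, scenario.grid_shape,
        scenario.fungus_patch_radius, scenario.fungus_max_centers,
        allowed=host_cover,
    )
    return occ_p, occ_f


def build_scenario_probability(
    scenario: CommunityScenario,
    abundances: tuple[AbundanceVector, AbundanceVector],
    occupancy: tuple[OccurrenceMatrix, OccurrenceMatrix],
) -> ProbabilityMatrix:
    plants_ab, fungi_ab = abundances
    if scenario.generative_model == "Null":
        return build_null(
            scenario.n_plants, scenario.n_fungi,
            row_labels=plants_ab.labels, col_labels=fungi_ab.labels,
        )
    if scenario.generative_model == "Ab":
        return build_ab(plants_ab, fungi_ab)
    sp = build_sp(*occupancy)
    if scenario.generative_model == "Sp":
        return sp
    return build_absp(build_ab(plants_ab, fungi_ab), sp)


def simulate_network(scenario: CommunityScenario) -> SimulatedCommunity:
    """Full virtual community under the scenario's generative model."""
    abundances = simulate_abundances(scenario)
    occupancy = simulate_occupancy(scenario, abundances)
    prob = build_scenario_probability(scenario, abundances, occupancy)
    rng = _stage_rng(scenario.seed, 3)
    network = assign_interactions(prob, scenario.f_total, rng)
    return SimulatedCommunity(
        scenario=scenario,
        network=network,
        true_model=scenario.generative_model,
        probability=prob,
        plant_abundance=abundances[0],
        fungus_abundance=abundances[1],
        plant_occurrence=occupancy[0],
        fungus_occurrence=occupancy[1],
    )


def simulate_tree_and_trait(
    n_tips: int,
    lambda_true: float = 1.0,
    sigma2: float = 1.0,
    seed: int = 0,
    prefix: str = "tip",
):
    """Yule tree scaled to unit depth plus a lambda-Brownian trait.

    The trait is multivariate normal with covariance sigma2 * V(lambda):
    the Brownian tip covariance of the tree with off-diagonals multiplied
    by ``lambda_true`` — exactly the generating model the lambda estimator
    fits, so recovery is a well-posed check.
    """
    if n_tips < 4:
        raise ValidationError("need at least 4 tips")
    pyrng = _random.Random(seed)
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace(_labels(prefix, n_tips))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=pyrng,
    )
    # the simulator stops at the n-th speciation, leaving the newest sister
    # pair with zero-length branches; extend all tips by the waiting time to
    # the next (uncommitted) event so every branch has positive length
    extra = pyrng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None  # no stem edge above the root
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    phylo = Phylogeny(tree=tree)
    labels, v = phylo.vcv()
    cov = sigma2 * (v * lambda_true)
    np.fill_diagonal(cov, sigma2 * np.diag(v))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    if sigma2 == 0:
        values = np.zeros(len(labels))
    else:
        jitter = 1e-12 * np.eye(len(labels))
        chol = np.linalg.cholesky(cov + jitter)
        values = chol @ rng.standard_normal(len(labels))
    from .phylogenetic_signal import TraitVector

    return phylo, TraitVector(labels=tuple(labels), values=values)
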