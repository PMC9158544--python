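"""Domain types and file I/O for quantitative bipartite plant-fungus networks.

The package's central object is the :class:`InteractionMatrix`: a plant
(rows) by fungal-OTU (columns) matrix of non-negative integer interaction
counts, typically mean rarefied read abundances per host species.  Around it
sit species abundance vectors, binary species-by-quadrat occurrence matrices
for the spatial-overlap hypothesis, and rooted phylogenies with branch
lengths for the signal tests.

All delimited I/O is TSV by default (CSV accepted), first row and first
column holding labels; trees are Newick.  Label ordering is lexicographic
everywhere so that identical inputs always produce identical in-memory
objects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("symbionet")

__all__ = [
    "SampleReadTable",
    "InteractionMatrix",
    "AbundanceVector",
    "OccurrenceMatrix",
    "Phylogeny",
    "rarefy_sample",
    "aggregate_samples",
    "load_inputs",
    "as_rng",
]


def as_rng(seed: int | None | np.random.Generator) -> np.random.Generator:
    """Normalise ``seed`` (int, None or Generator) into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - message pass-through
        raise ValidationError(f"{path}: cannot parse delimited file ({exc})") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


# ---------------------------------------------------------------------------
# Sample-level read table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleReadTable:
    """Per-root-sample OTU read counts with a sample-to-host-species map.

    ``counts`` is samples x OTUs; every sample maps to exactly one host.
    """

    counts: pd.DataFrame
    host_of: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.host_of)
        if missing:
            raise ValidationError(f"samples without a host mapping: {sorted(missing)[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
            raise ValidationError("read counts must be non-negative numbers")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def otus(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @classmethod
    def read(cls, counts_path: str | Path, mapping_path: str | Path) -> "SampleReadTable":
        counts = _read_delimited(counts_path)
        mapping = _read_delimited(mapping_path)
        if mapping.shape[1] < 1:
            raise ValidationError(f"{mapping_path}: expected a host_species column")
        host_of = {str(k): str(v) for k, v in mapping.iloc[:, 0].items()}
        return cls(counts=counts, host_of=host_of)


# ---------------------------------------------------------------------------
# Interaction matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionMatrix:
    """Quantitative bipartite network: plants in rows, fungi in columns."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("interaction matrix must be 2-dimensional")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("label lengths do not match matrix shape")
        if (counts < 0).any():
            raise ValidationError("interaction counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("interaction counts must be integers")
            counts = np.round(counts).astype(np.int64)
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if len(set(self.row_labels)) != len(self.row_labels) or len(
            set(self.col_labels)
        ) != len(self.col_labels):
            raise ValidationError("duplicate species labels in interaction matrix")

    # -- basic summaries -----------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol for #plants
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def F(self) -> int:
        """Grand total of interaction counts."""
        return int(self.counts.sum())

    @property
    def L(self) -> int:
        """Number of realized links (nonzero cells)."""
        return int(np.count_nonzero(self.counts))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    # -- construction / conversion -------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, drop_empty: bool = True) -> "InteractionMatrix":
        frame = frame.sort_index(axis=0).sort_index(axis=1)
        m = cls(
            counts=frame.to_numpy(),
            row_labels=tuple(str(x) for x in frame.index),
            col_labels=tuple(str(x) for x in frame.columns),
        )
        return m.drop_empty() if drop_empty else m

    @classmethod
    def read(cls, path: str | Path, drop_empty: bool = True) -> "InteractionMatrix":
        return cls.from_frame(_read_delimited(path), drop_empty=drop_empty)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        self.to_frame().to_csv(path, sep=sep)

    def drop_empty(self) -> "InteractionMatrix":
        """Remove all-zero rows/columns; such species are not part of the network."""
        keep_r = self.counts.sum(axis=1) > 0
        keep_c = self.counts.sum(axis=0) > 0
        if keep_r.all() and keep_c.all():
            return self
        dropped = [l for l, k in zip(self.row_labels, keep_r) if not k] + [
            l for l, k in zip(self.col_labels, keep_c) if not k
        ]
        logger.warning("dropping %d species with no interactions: %s", len(dropped), dropped[:10])
        return InteractionMatrix(
            counts=self.counts[np.ix_(keep_r, keep_c)],
            row_labels=tuple(l for l, k in zip(self.row_labels, keep_r) if k),
            col_labels=tuple(l for l, k in zip(self.col_labels, keep_c) if k),
        )


# ---------------------------------------------------------------------------
# Abundance and occurrence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceVector:
    """Species abundances: stem counts for plants, summed rarefied reads for fungi."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.labels):
            raise ValidationError("abundance vector labels/values mismatch")
        if (values < 0).any():
            raise ValidationError("abundances must be non-negative")
        object.__setattr__(self, "values", values)

    def subset(self, labels: Sequence[str]) -> "AbundanceVector":
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise ValidationError(f"species missing from abundance vector: {missing[:5]}")
        idx = [index[l] for l in labels]
        return AbundanceVector(labels=tuple(labels), values=self.values[idx])

    @classmethod
    def read(cls, path: str | Path) -> "AbundanceVector":
        frame = _read_delimited(path)
        series = frame.iloc[:, 0].sort_index()
        return cls(labels=tuple(series.index), values=series.to_numpy(dtype=float))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame({"abundance": self.values}, index=list(self.labels)).rename_axis(
            "species"
        ).to_csv(path, sep=sep)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary species-by-quadrat presence matrix on the plot grid."""

    presence: np.ndarray
    species: tuple[str, ...]
    quadrats: tuple[str, ...]

    def __post_init__(self) -> None:
        presence = np.asarray(self.presence)
        if presence.shape != (len(self.species), len(self.quadrats)):
            raise ValidationError("occurrence labels do not match matrix shape")
        uniq = np.unique(presence)
        if not np.isin(uniq, [0, 1]).all():
            raise ValidationError(f"occurrence matrix must be binary; found values {uniq[:5]}")
        object.__setattr__(self, "presence", presence.astype(np.int8))

    def subset(self, labels: Sequence[str]) -> "OccurrenceMatrix":
        index = {l: i for i, l in enumerate(self.species)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise ValidationError(f"species missing from occurrence matrix: {missing[:5]}")
        idx = [index[l] for l in labels]
        return OccurrenceMatrix(
            presence=self.presence[idx], species=tuple(labels), quadrats=self.quadrats
        )

    @classmethod
    def read(cls, path: str | Path) -> "OccurrenceMatrix":
        frame = _read_delimited(path).sort_index(axis=0)
        arr = frame.to_numpy()
        uniq = np.unique(arr)
        if not np.isin(uniq, [0, 1]).all():
            raise ValidationError(f"{path}: occurrence matrix must be binary; found {uniq[:5]}")
        return cls(presence=arr, species=tuple(frame.index), quadrats=tuple(frame.columns))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(self.presence, index=list(self.species), columns=list(self.quadrats)).to_csv(
            path, sep=sep
        )


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, wrapping a dendropy Tree."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter()))

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        path = Path(source)
        try:
            if path.exists():
                tree = dendropy.Tree.get(path=str(path), schema="newick")
            else:
                tree = dendropy.Tree.get(data=str(source), schema="newick")
        except Exception as exc:
            raise ValidationError(f"cannot parse Newick from {source!r}: {exc}") from exc
        return cls(tree=tree)

    def write(self, path: str | Path) -> None:
        self.tree.write(
            path=str(path), schema="newick",
            suppress_rooting=True, unquoted_underscores=True,
        )

    def _check_lengths(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValidationError("phylogeny has missing branch lengths")
            if edge.length < 0:
                raise ValidationError("phylogeny has negative branch lengths")

    def retain(self, labels: Iterable[str]) -> "Phylogeny":
        """Prune the tree to the given tip labels (order-insensitive)."""
        labels = set(labels)
        present = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = labels - present
        if missing:
            raise ValidationError(f"tips absent from tree: {sorted(missing)[:5]}")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(list(labels))
        return Phylogeny(tree=tree)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip distances; the root's own stem edge does not count."""
        self._check_lengths()
        depths: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                node._sn_depth = 0.0
            else:
                node._sn_depth = node.parent_node._sn_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._sn_depth
        return depths

    def patristic_matrix(self, labels: Sequence[str] | None = None):
        """Pairwise sum of branch lengths along tip-to-tip paths.

        Returns ``(labels, matrix)`` with rows/cols in the requested (or
        lexicographic) label order.
        """
        self._check_lengths()
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {leaf.taxon.label: leaf.taxon for leaf in self.tree.leaf_node_iter()}
        if labels is None:
            labels = tuple(sorted(taxa))
        labels = tuple(labels)
        missing = [l for l in labels if l not in taxa]
        if missing:
            raise ValidationError(f"tips absent from tree: {missing[:5]}")
        n = len(labels)
        out = np.zeros((n, n), dtype=float)
        for a in range(n):
            for b in range(a + 1, n):
                d = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
                out[a, b] = out[b, a] = d
        return labels, out

    def vcv(self, labels: Sequence[str] | None = None):
        """Brownian-motion tip covariance: V[i,j] = depth of the MRCA of i and j.

        Computed from tip depths and patristic distances:
        ``V_ij = (depth_i + depth_j - d_ij) / 2`` and ``V_ii = depth_i``.
        """
        depths = self.tip_depths()
        if labels is None:
            labels = tuple(sorted(depths))
        labels, dist = self.patristic_matrix(labels)
        dep = np.array([depths[l] for l in labels])
        v = (dep[:, None] + dep[None, :] - dist) / 2.0
        np.fill_diagonal(v, dep)
        return labels, v


# ---------------------------------------------------------------------------
# Rarefaction and aggregation
# ---------------------------------------------------------------------------

def rarefy_sample(
    counts: np.ndarray, depth: int, seed: int | None | np.random.Generator = None
) -> np.ndarray:
    """Subsample a read-count vector to ``depth`` reads without replacement.

    Draws follow the multivariate hypergeometric distribution, so the
    expected rarefied count of OTU i is ``depth * counts[i] / counts.sum()``.
    Samples with fewer than ``depth`` total reads are rejected with an error;
    callers decide whether to skip them.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    if (counts < 0).any():
        raise ValidationError("read counts must be non-negative")
    total = int(counts.sum())
    if total < depth:
        raise ValidationError(f"sample has {total} reads, fewer than depth {depth}")
    if total == depth:
        return counts.copy()
    rng = as_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def aggregate_samples(
    table: SampleReadTable,
    rarefy_depth: int | None = 3000,
    seed: int | None | np.random.Generator = None,
) -> InteractionMatrix:
    """Build the host-species x OTU interaction matrix from sample reads.

    Each sample is rarefied to ``rarefy_depth`` reads (samples below depth
    are excluded, with a log notice); cell (host, OTU) is the mean rarefied
    count across that host's samples, rounded half-up to the nearest integer.
    OTUs with no nonzero cell are dropped.
    """
    if table.counts.empty:
        raise ValidationError("empty sample read table")
    rng = as_rng(seed)
    rows: dict[str, list[np.ndarray]] = {}
    skipped = []
    # iterate in sorted sample order so aggregation is order-invariant
    for sample_id in sorted(table.sample_ids):
        vec = table.counts.loc[sample_id].to_numpy(dtype=np.int64)
        if rarefy_depth is not None:
            try:
                vec = rarefy_sample(vec, rarefy_depth, rng)
            except ValidationError:
                skipped.append(sample_id)
                continue
        rows.setdefault(table.host_of[sample_id], []).append(vec)
    if skipped:
        logger.warning(
            "excluded %d sample(s) below rarefaction depth %s: %s",
            len(skipped), rarefy_depth, skipped[:10],
        )
    if not rows:
        raise ValidationError("no samples survived rarefaction")
    hosts = sorted(rows)
    means = np.vstack([np.mean(rows[h], axis=0) for h in hosts])
    cells = np.floor(means + 0.5).astype(np.int64)  # round-half-up
    frame = pd.DataFrame(cells, index=hosts, columns=list(table.otus))
    return InteractionMatrix.from_frame(frame, drop_empty=True)


# ---------------------------------------------------------------------------
# Config-driven loading
# ---------------------------------------------------------------------------

def load_inputs(config: Mapping[str, str], base_dir: str | Path = ".") -> dict:
    """Load and cross-align all analysis inputs named in a config mapping.

    Recognised keys: ``interaction_matrix``, ``plant_abundance``,
    ``fungus_abundance``, ``plant_occurrence``, ``fungus_occurrence``,
    ``plant_tree``, ``fungus_tree`` (trees optional).  Species present in
    the network but missing from a tree are excluded from phylogenetic
    tests only, with a warning.
    """
    base = Path(base_dir)
    out: dict = {}
    matrix = InteractionMatrix.read(base / config["interaction_matrix"])
    out["interaction_matrix"] = matrix
    if "plant_abundance" in config:
        out["plant_abundance"] = AbundanceVector.read(base / config["plant_abundance"]).subset(
            matrix.row_labels
        )
    if "fungus_abundance" in config:
        out["fungus_abundance"] = AbundanceVector.read(base / config["fungus_abundance"]).subset(
            matrix.col_labels
        )
    if "plant_occurrence" in config:
        out["plant_occurrence"] = OccurrenceMatrix.read(base / config["plant_occurrence"]).subset(
            matrix.row_labels
        )
    if "fungus_occurrence" in config:
        out["fungus_occurrence"] = OccurrenceMatrix.read(
            base / config["fungus_occurrence"]
        ).subset(matrix.col_labels)
    for key, labels in (("plant_tree", matrix.row_labels), ("fungus_tree", matrix.col_labels)):
        if key in config:
            tree = Phylogeny.from_newick(base / config[key])
            on_tree = set(tree.tip_labels)
            missing = [l for l in labels if l not in on_tree]
            if missing:
                logger.warning(
                    "%s: %d network species absent from tree, excluded from "
                    "phylogenetic tests: %s", key, len(missing), missing[:10],
                )
            out[key] = tree
    return out
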