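"""Featurization of segmented-cell tables into bag-of-cells documents.

Multiplexed imaging (CODEX, MIBI-TOF) yields one record per segmented cell:
position, phenotype, sample of origin.  The local microenvironment of an
*anchor* cell is summarized order-invariantly as the vector of phenotype
counts of its neighbors within a fixed-radius ball — a "document" in the
topic-model sense.  Spatial coherence between anchors is encoded by a graph
connecting anchors whose Voronoi cells share a facet (Delaunay neighbors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree

logger = logging.getLogger("celltopics")

__all__ = [
    "CellTable",
    "NeighborhoodCorpus",
    "SpatialGraph",
    "build_neighborhood_corpus",
    "build_spatial_graph",
    "assemble_difference_operator",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Validated table of segmented cells.

    Parameters
    ----------
    data:
        One row per cell with columns ``sample_id``, ``cell_id``, ``x``,
        ``y`` (optionally ``z``), ``phenotype`` and optionally ``is_anchor``.
    """

    data: pd.DataFrame
    vocabulary: list[str] = field(default_factory=list)

    REQUIRED = ("sample_id", "cell_id", "x", "y", "phenotype")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cell table is missing required columns: {missing}")
        for col in ("x", "y") + (("z",) if "z" in df.columns else ()):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric coordinate in column {col!r} at row {row}"
                )
            self.data[col] = vals
        dup = df.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(
                f"duplicate cell_id within sample at row {row} "
                f"(cell_id={df['cell_id'].iloc[row]!r})"
            )
        if "z" in df.columns:
            # Each sample must be consistently 2D or 3D.
            for sid, grp in df.groupby("sample_id", observed=True):
                n_nan = grp["z"].isna().sum()
                if 0 < n_nan < len(grp):
                    raise ValueError(
                        f"sample {sid!r} mixes 2D and 3D coordinates "
                        f"({n_nan} missing z values)"
                    )
        if "is_anchor" not in df.columns:
            self.data["is_anchor"] = True
        if not self.vocabulary:
            self.vocabulary = sorted(df["phenotype"].astype(str).unique())

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def positions(self, sample_id=None) -> np.ndarray:
        """Coordinate matrix for one sample (native 2D or 3D)."""
        df = self.data if sample_id is None else self.data[self.data["sample_id"] == sample_id]
        cols = ["x", "y"]
        if "z" in df.columns and df["z"].notna().all() and len(df):
            cols.append("z")
        return df[cols].to_numpy(dtype=float)


@dataclass
class NeighborhoodCorpus:
    """Bag-of-cells documents: one phenotype-count row per anchor cell."""

    counts: np.ndarray                 # (N, V) non-negative integers
    anchor_index: pd.DataFrame         # columns sample_id, cell_id; row order = counts rows
    anchor_positions: np.ndarray       # (N, 2 or 3)
    radius: float
    vocabulary: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if len(self.anchor_index) != self.counts.shape[0]:
            raise ValueError("anchor_index length must match counts rows")
        if self.counts.shape[1] != len(self.vocabulary):
            raise ValueError("vocabulary length must match counts columns")

    @property
    def n_documents(self) -> int:
        return self.counts.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.anchor_index["sample_id"].to_numpy()


@dataclass
class SpatialGraph:
    """Voronoi-facet adjacency between anchors of the same sample.

    ``edges[l] = (i, j)`` with ``i < j``; ``weights[l]`` is the dissimilarity
    d_ij entering the fused prior with coefficient 1/d_ij.
    """

    edges: np.ndarray      # (L, 2) int, i < j
    weights: np.ndarray    # (L,) positive d_ij
    n_nodes: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights must have the same length")
        if len(self.edges):
            if np.any(self.edges[:, 0] >= self.edges[:, 1]):
                raise ValueError("edges must satisfy i < j (no self-edges)")
            if np.any(self.edges >= self.n_nodes) or np.any(self.edges < 0):
                raise ValueError("edge endpoint out of range")
            uniq = {tuple(e) for e in self.edges}
            if len(uniq) != len(self.edges):
                raise ValueError("duplicate edges")
            if np.any(self.weights <= 0):
                raise ValueError("all edge weights d_ij must be positive")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def difference_operator(self) -> sp.csr_matrix:
        """Signed incidence A (L × N): row l has +1 at i, −1 at j."""
        L = self.n_edges
        if L == 0:
            return sp.csr_matrix((0, self.n_nodes))
        rows = np.repeat(np.arange(L), 2)
        cols = self.edges.reshape(-1)
        vals = np.tile([1.0, -1.0], L)
        return sp.csr_matrix((vals, (rows, cols)), shape=(L, self.n_nodes))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _as_predicate(flt):
    """Accept a callable, a collection of phenotypes, or None (match all)."""
    if flt is None:
        return lambda p: np.ones(len(p), dtype=bool)
    if callable(flt):
        return lambda p: np.asarray([bool(flt(x)) for x in p])
    allowed = set(flt)
    return lambda p: np.asarray([x in allowed for x in p])


def build_neighborhood_corpus(
    cells: CellTable,
    anchor_filter=None,
    neighbor_filter=None,
    radius: float = 100.0,
    *,
    use_anchor_flag: bool = True,
    drop_empty: bool = False,
) -> NeighborhoodCorpus:
    """Count, for every anchor cell, its in-range neighbors by phenotype.

    A neighbor is any other cell passing ``neighbor_filter`` whose Euclidean
    distance to the anchor is at most ``radius`` (closed ball, in the native
    2D/3D dimensionality of the sample).  The anchor never counts itself.
    The vocabulary is the set of phenotypes passing ``neighbor_filter``.

    ``anchor_filter``/``neighbor_filter`` may be callables over phenotype
    labels or collections of accepted labels; ``None`` accepts every
    phenotype.  With ``use_anchor_flag`` the table's ``is_anchor`` column is
    additionally required for anchors.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    df = cells.data
    phen = df["phenotype"].astype(str).to_numpy()
    is_anchor = _as_predicate(anchor_filter)(phen)
    if use_anchor_flag and "is_anchor" in df.columns:
        is_anchor &= df["is_anchor"].astype(bool).to_numpy()
    if not is_anchor.any():
        raise ValueError("no cells pass the anchor filter; nothing to featurize")
    is_neighbor = _as_predicate(neighbor_filter)(phen)

    vocabulary = sorted(np.unique(phen[is_neighbor]))
    vindex = {v: k for k, v in enumerate(vocabulary)}
    V = len(vocabulary)

    rows_counts, rows_index, rows_pos = [], [], []
    for sid, grp in df.groupby("sample_id", observed=True, sort=True):
        gidx = grp.index.to_numpy()
        pos = cells.positions(sid)
        if pos.shape[0] != len(grp):
            raise ValueError(f"inconsistent coordinate dimensionality in sample {sid!r}")
        loc = df.index.get_indexer(gidx)
        a_mask = is_anchor[loc]
        n_mask = is_neighbor[loc]
        if not a_mask.any():
            continue
        a_pos = pos[a_mask]
        n_pos = pos[n_mask]
        n_codes = np.array([vindex[p] for p in phen[loc][n_mask]], dtype=np.int64)
        counts = np.zeros((a_mask.sum(), V), dtype=np.int64)
        if len(n_pos):
            tree = cKDTree(n_pos)
            hits = tree.query_ball_point(a_pos, r=radius)
            # map anchor row -> its own index among neighbor-eligible cells
            order = np.cumsum(n_mask) - 1
            self_idx = np.where(a_mask & n_mask, order, -1)[a_mask]
            for a, (hit, own) in enumerate(zip(hits, self_idx)):
                for h in hit:
                    if h != own:
                        counts[a, n_codes[h]] += 1
        rows_counts.append(counts)
        rows_index.append(grp.loc[gidx[a_mask], ["sample_id", "cell_id"]])
        rows_pos.append(a_pos)

    counts = np.vstack(rows_counts)
    index = pd.concat(rows_index, ignore_index=True)
    positions = np.vstack(rows_pos) if len({p.shape[1] for p in rows_pos}) == 1 else None
    if positions is None:
        raise ValueError("samples have mismatched coordinate dimensionality")
    if drop_empty:
        keep = counts.sum(axis=1) > 0
        counts, positions = counts[keep], positions[keep]
        index = index.loc[keep].reset_index(drop=True)
    return NeighborhoodCorpus(counts, index, positions, float(radius), vocabulary)


def _delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay-neighbor pairs; falls back to a chain for degenerate inputs."""
    n = len(points)
    if n < 2:
        return set()
    if n == 2:
        return {(0, 1)}
    try:
        tri = Delaunay(points)
    except QhullError:
        logger.warning(
            "degenerate point configuration (collinear/coplanar); "
            "falling back to a nearest-neighbor chain"
        )
        # Order along the principal axis and chain consecutive points.
        centered = points - points.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        order = np.argsort(centered @ vt[0])
        return {tuple(sorted((int(order[i]), int(order[i + 1])))) for i in range(n - 1)}
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((i, j) if i < j else (j, i))
    return edges


def build_spatial_graph(
    anchor_positions: np.ndarray,
    sample_ids: np.ndarray,
    weight_rule: str = "constant",
    *,
    constant: float = 1.0,
    max_edge_length: float | None = None,
) -> SpatialGraph:
    """Connect anchors whose Voronoi cells share a facet, per sample.

    Voronoi facet adjacency is computed as Delaunay neighborhood of the
    anchor point set in its native dimensionality.  ``weight_rule`` sets the
    dissimilarity d_ij: ``"constant"`` (value ``constant``) or
    ``"euclidean"`` (inter-anchor distance).  ``max_edge_length`` optionally
    removes spuriously long hull-adjacent edges.
    """
    anchor_positions = np.asarray(anchor_positions, dtype=float)
    sample_ids = np.asarray(sample_ids)
    if weight_rule not in ("constant", "euclidean"):
        raise ValueError(f"unknown weight_rule {weight_rule!r}")
    n = len(anchor_positions)
    all_edges: list[tuple[int, int]] = []
    for sid in pd.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == sid)
        for i, j in _delaunay_edges(anchor_positions[idx]):
            gi, gj = int(idx[i]), int(idx[j])
            all_edges.append((gi, gj) if gi < gj else (gj, gi))
    all_edges.sort()
    edges = np.array(all_edges, dtype=np.int64).reshape(-1, 2)
    if len(edges):
        lengths = np.linalg.norm(
            anchor_positions[edges[:, 0]] - anchor_positions[edges[:, 1]], axis=1
        )
        if max_edge_length is not None:
            keep = lengths <= max_edge_length
            edges, lengths = edges[keep], lengths[keep]
        weights = np.full(len(edges), float(constant)) if weight_rule == "constant" else lengths
    else:
        weights = np.zeros(0)
    return SpatialGraph(edges, weights, n_nodes=n)


def assemble_difference_operator(graph: SpatialGraph):
    """Return (A, C): signed incidence A (L×N) and stacked C = [[A, −I], [−A, −I]].

    C is the constraint matrix of the epigraph form of the fused penalty:
    the rows encode Aξ − χ ≤ 0 and −Aξ − χ ≤ 0.
    """
    A = graph.difference_operator
    L = graph.n_edges
    eye = sp.identity(L, format="csr")
    C = sp.bmat([[A, -eye], [-A, -eye]], format="csr")
    return A, C
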