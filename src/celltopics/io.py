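"""Readers, writers, run configuration and summarization utilities."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .featurization import CellTable, NeighborhoodCorpus, SpatialGraph
from .inference import SpatialLDAModel

logger = logging.getLogger("celltopics")

__all__ = [
    "RunConfig",
    "TopicSummary",
    "read_cell_table",
    "write_corpus",
    "read_corpus",
    "write_graph",
    "read_graph",
    "save_model",
    "load_model",
    "export_tables",
    "summarize_topic_fractions",
    "group_mean_profiles",
]


@dataclass
class RunConfig:
    """Validated run configuration; persisted verbatim into outputs."""

    n_topics: int = 5
    eta: float = 1.0
    rho: float | None = None             # None -> 1/N
    penalty_scale: float | None = None   # None -> 1/N
    radius: float = 100.0
    weight_rule: str = "constant"
    max_edge_length: float | None = None
    seed: int = 0
    tol_estep: float = 1e-4
    tol_em: float = 1e-4
    tol_outer: float = 1e-5
    max_estep_iter: int = 100
    max_em_sweeps: int = 100
    max_outer: int = 50
    admm_tol: float = 1e-7
    admm_max_iter: int = 500
    anchor_phenotypes: list[str] | None = None
    neighbor_phenotypes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        for name in ("eta", "rho", "radius"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.penalty_scale is not None and self.penalty_scale < 0:
            raise ValueError("penalty_scale must be non-negative")
        if self.weight_rule not in ("constant", "euclidean"):
            raise ValueError(f"unknown weight_rule {self.weight_rule!r}")
        for name in ("tol_estep", "tol_em", "tol_outer", "admm_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(path, sep=None) -> CellTable:
    """Read and validate a cell table from CSV/TSV (header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return CellTable(df)


def write_corpus(corpus: NeighborhoodCorpus, counts_path, sidecar_path=None) -> None:
    """Corpus counts as CSV plus a JSON sidecar (vocabulary, anchors, radius)."""
    counts_path = Path(counts_path)
    pd.DataFrame(corpus.counts, columns=corpus.vocabulary).to_csv(counts_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else counts_path.with_suffix(".json")
    meta = {
        "vocabulary": list(corpus.vocabulary),
        "radius": corpus.radius,
        "anchors": corpus.anchor_index.to_dict(orient="list"),
        "anchor_positions": np.asarray(corpus.anchor_positions).tolist(),
    }
    sidecar.write_text(json.dumps(meta))


def read_corpus(counts_path, sidecar_path=None) -> NeighborhoodCorpus:
    counts_path = Path(counts_path)
    counts = pd.read_csv(counts_path).to_numpy(dtype=np.int64)
    sidecar = Path(sidecar_path) if sidecar_path else counts_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return NeighborhoodCorpus(
        counts,
        pd.DataFrame(meta["anchors"]),
        np.asarray(meta["anchor_positions"], dtype=float),
        float(meta["radius"]),
        list(meta["vocabulary"]),
    )


def write_graph(graph: SpatialGraph, path) -> None:
    """Edge list as TSV with columns i, j, d_ij."""
    df = pd.DataFrame({
        "i": graph.edges[:, 0] if graph.n_edges else np.zeros(0, dtype=int),
        "j": graph.edges[:, 1] if graph.n_edges else np.zeros(0, dtype=int),
        "d_ij": graph.weights,
    })
    df.to_csv(path, sep="\t", index=False)


def read_graph(path, n_nodes: int) -> SpatialGraph:
    df = pd.read_csv(path, sep="\t")
    return SpatialGraph(df[["i", "j"]].to_numpy(dtype=np.int64),
                        df["d_ij"].to_numpy(dtype=float), n_nodes=n_nodes)


def save_model(model: SpatialLDAModel, path) -> None:
    """Model bundle as HDF5 (λ, ξ, γ, vocabulary, config, ELBO trace)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("lambda", data=model.lam)
        fh.create_dataset("xi", data=model.xi)
        fh.create_dataset("gamma", data=model.gamma)
        if model.phi is not None:
            fh.create_dataset("phi", data=model.phi)
        fh.create_dataset("elbo_trace", data=np.asarray(model.elbo_trace))
        fh.create_dataset(
            "vocabulary",
            data=np.asarray(model.vocabulary, dtype=h5py.string_dtype()),
        )
        fh.attrs["eta"] = model.eta
        fh.attrs["converged"] = model.converged
        fh.attrs["config"] = json.dumps(model.config)


def load_model(path) -> SpatialLDAModel:
    with h5py.File(path, "r") as fh:
        return SpatialLDAModel(
            lam=fh["lambda"][...],
            eta=float(fh.attrs["eta"]),
            xi=fh["xi"][...],
            gamma=fh["gamma"][...],
            phi=fh["phi"][...] if "phi" in fh else None,
            vocabulary=[v.decode() if isinstance(v, bytes) else str(v)
                        for v in fh["vocabulary"][...]],
            elbo_trace=list(fh["elbo_trace"][...]),
            converged=bool(fh.attrs["converged"]),
            config=json.loads(fh.attrs["config"]),
        )


def export_tables(model: SpatialLDAModel, corpus: NeighborhoodCorpus, outdir) -> None:
    """CSV export of topic × phenotype and anchor × topic tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K = model.n_topics
    pd.DataFrame(model.topic_distributions, columns=model.vocabulary,
                 index=[f"topic_{k}" for k in range(K)]).to_csv(outdir / "topics.csv")
    cells = corpus.anchor_index.copy()
    weights = model.topic_weights
    for k in range(K):
        cells[f"topic_{k}"] = weights[:, k]
    cells["dominant_topic"] = weights.argmax(axis=1)
    cells.to_csv(outdir / "cell_topics.csv", index=False)


# ---------------------------------------------------------------------------
# Summarization
# ---------------------------------------------------------------------------

@dataclass
class TopicSummary:
    """Per-sample topic prevalence and per-anchor dominant topics.

    ``fractions`` rows are samples, columns topics: the fraction of anchors
    whose (row-normalized) topic weight strictly exceeds 1/K.
    """

    fractions: pd.DataFrame
    dominant_topic: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("fractions must lie in [0, 1]")


def summarize_topic_fractions(weights, sample_ids, n_topics=None) -> TopicSummary:
    """Fraction of anchors per sample with topic weight > 1/K, per topic.

    ``weights`` is N × K (γ or θ; rows are normalized before thresholding
    — 1/K is only meaningful on the simplex).  The dominant topic is the
    argmax with lowest-index tie-break.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    K = n_topics or weights.shape[1]
    if weights.shape[1] != K:
        raise ValueError("weights have the wrong number of topics")
    weights = weights / weights.sum(axis=1, keepdims=True)
    sample_ids = np.asarray(sample_ids)
    thr = 1.0 / K
    rows = {}
    for sid in pd.unique(sample_ids):
        sub = weights[sample_ids == sid]
        rows[sid] = (sub > thr).mean(axis=0)
    fractions = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"topic_{k}" for k in range(K)]
    )
    return TopicSummary(fractions, weights.argmax(axis=1), thr)


def group_mean_profiles(features: pd.DataFrame, dominant_topic, *,
                        log2: bool = False, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-dominant-topic mean of each numeric feature (optional log2).

    Rows are topics 0..K−1 where K = max(dominant) + 1; a topic with no
    anchors yields a missing-value row with a warning.  With ``log2`` the
    profile is log2(mean + pseudocount).
    """
    dominant_topic = np.asarray(dominant_topic, dtype=int)
    numeric = features.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError("no numeric feature columns")
    K = int(dominant_topic.max()) + 1 if len(dominant_topic) else 0
    out = pd.DataFrame(index=pd.RangeIndex(K, name="topic"), columns=numeric.columns,
                       dtype=float)
    for k in range(K):
        mask = dominant_topic == k
        if not mask.any():
            warnings.warn(f"topic {k} has no anchors; emitting missing values")
            continue
        out.loc[k] = numeric[mask].mean(axis=0)
    if log2:
        out = np.log2(out + pseudocount)
    return out
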