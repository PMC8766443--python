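"""Downstream single-cell analysis on CLR scores: embeddings, clustering,
flow-style gating, light-chain clonality, and non-specific-cell flagging.

The analysis mirrors standard immunophenotyping practice: PCA on CLR
scores, k-means on the top components to separate populations, t-SNE (PCA
initialized) for visualization, hierarchical marker gates, and the
kappa/lambda light-chain ratio whose normal range is 1-2 (values outside
indicate clonal B-cell expansion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .quantify import CLRMatrix, positivity_split

_COMPARATORS = {
    ">": np.greater, ">=": np.greater_equal,
    "<": np.less, "<=": np.less_equal,
}


@dataclass
class Embedding:
    """Per-cell coordinates from a dimension reduction."""

    coords: np.ndarray                    # cells x components
    kind: str                             # "pca" | "tsne"
    loadings: np.ndarray | None = None    # components x antibodies (PCA)
    explained_variance: np.ndarray | None = None
    feature_names: list[str] | None = None
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def pca(clr: CLRMatrix, n_components: int = 3) -> Embedding:
    """Centered PCA of the CLR matrix.

    Component signs are fixed so each component's largest-magnitude loading
    is positive, making results deterministic across runs and libraries.
    """
    n_feat = clr.values.shape[1]
    if n_components > n_feat:
        raise ValueError(
            f"n_components {n_components} exceeds antibody count {n_feat}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(clr.values)
    loadings = model.components_
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return Embedding(coords=scores * flip, kind="pca",
                     loadings=loadings * flip[:, None],
                     explained_variance=model.explained_variance_,
                     feature_names=clr.antibody_names)


def kmeans_cluster(scores: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 10) -> np.ndarray:
    """Best-of-restarts k-means labels on embedding scores."""
    scores = np.asarray(scores, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > scores.shape[0]:
        raise ValueError(f"k = {k} exceeds cell count {scores.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(scores)


def tsne_embed(clr: CLRMatrix, seed: int = 0, perplexity: float = 30.0,
               pca_init: bool = True) -> Embedding:
    """2-D t-SNE of CLR scores, initialized from the top-2 PCA scores."""
    n = clr.values.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity} "
            f"(need > 3x perplexity)")
    if pca_init:
        init_scores = pca(clr, n_components=2).coords
        # scale so early embedding variance matches sklearn's convention
        init = (init_scores / np.std(init_scores[:, 0]) * 1e-4).astype(
            np.float32)
    else:
        init = "random"
    ts = TSNE(n_components=2, perplexity=perplexity, init=init,
              random_state=seed)
    return Embedding(coords=ts.fit_transform(clr.values.astype(np.float32)),
                     kind="tsne", seed=seed)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

@dataclass
class GateEntry:
    name: str
    parent: str
    marker: str | None
    comparator: str | None
    threshold: float | None
    mask: np.ndarray

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class GateSet:
    """Hierarchy of boolean cell masks; the root gate holds every cell."""

    n_cells: int
    entries: dict[str, GateEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "all" not in self.entries:
            self.entries["all"] = GateEntry(
                "all", "", None, None, None,
                np.ones(self.n_cells, dtype=bool))

    def mask(self, name: str) -> np.ndarray:
        return self.entries[name].mask

    def fraction_of_parent(self, name: str) -> float:
        entry = self.entries[name]
        parent_n = self.entries[entry.parent].count if entry.parent else \
            self.n_cells
        return entry.count / parent_n if parent_n else math.nan

    def report(self) -> pd.DataFrame:
        rows = [{"gate": e.name, "parent": e.parent, "marker": e.marker,
                 "comparator": e.comparator, "threshold": e.threshold,
                 "count": e.count,
                 "fraction_of_parent": self.fraction_of_parent(e.name)
                 if e.parent else 1.0}
                for e in self.entries.values()]
        return pd.DataFrame(rows)


def gate(clr: CLRMatrix, marker: str, comparator: str,
         threshold: float | None = None, parent: str = "all",
         gates: GateSet | None = None, name: str | None = None) -> GateSet:
    """Add one marker gate nested under ``parent``.

    ``threshold=None`` sets the cut automatically by a 2-means split of the
    marker's CLR scores within the parent gate (the threshold-free analogue
    of drawing the gate by eye on a flow plot).
    """
    if marker not in clr.antibody_names:
        raise ValueError(f"unknown marker {marker!r}")
    if comparator not in _COMPARATORS:
        raise ValueError(f"unknown comparator {comparator!r}")
    gates = gates if gates is not None else GateSet(clr.values.shape[0])
    parent_mask = gates.mask(parent)
    scores = clr.column(marker)
    if threshold is None:
        # unimodal scores => no positive population: +inf threshold makes
        # ">" gates empty and "<" gates pass the whole parent
        _, threshold = positivity_split(scores[parent_mask])
    mask = parent_mask & _COMPARATORS[comparator](scores, threshold)
    sym = {"<": "-", "<=": "-", ">": "+", ">=": "+"}[comparator]
    gname = name or f"{marker}{sym}|{parent}"
    gates.entries[gname] = GateEntry(gname, parent, marker, comparator,
                                     float(threshold), mask)
    return gates


# ---------------------------------------------------------------------------
# kappa/lambda clonality
# ---------------------------------------------------------------------------

@dataclass
class KappaLambdaResult:
    n_kappa: int
    n_lambda: int
    ratio: float
    interpretation: str       # normal / kappa-expanded / lambda-expanded


def kappa_lambda_ratio(clr: CLRMatrix, b_cell_gate: np.ndarray,
                       kappa_marker: str = "kappa",
                       lambda_marker: str = "lambda",
                       positivity_threshold: float | None = None
                       ) -> KappaLambdaResult:
    """Light-chain restriction within a B-cell gate.

    ratio = (#kappa-positive) / (#lambda-positive); the normal range is
    [1, 2].  Ratios above 2 flag kappa expansion, below 1 lambda expansion
    — both signatures of clonal B-cell disease.
    """
    for m in (kappa_marker, lambda_marker):
        if m not in clr.antibody_names:
            raise ValueError(f"marker {m!r} not in panel")
    b_cell_gate = np.asarray(b_cell_gate, dtype=bool)
    if not b_cell_gate.any():
        raise ValueError("B-cell gate is empty")

    def n_positive(marker: str) -> int:
        scores = clr.column(marker)[b_cell_gate]
        if positivity_threshold is not None:
            return int((scores > positivity_threshold).sum())
        mask, _ = positivity_split(scores)
        return int(mask.sum())

    n_k, n_l = n_positive(kappa_marker), n_positive(lambda_marker)
    if n_l == 0:
        warnings.warn("no lambda-positive cells in gate; ratio is infinite")
        ratio = math.inf
    else:
        ratio = n_k / n_l
    if 1.0 <= ratio <= 2.0:
        label = "normal"
    elif ratio > 2.0:
        label = "kappa-expanded"
    else:
        label = "lambda-expanded"
    return KappaLambdaResult(n_k, n_l, ratio, label)


# ---------------------------------------------------------------------------
# non-specific-cell flagging
# ---------------------------------------------------------------------------

def flag_nonspecific(clr: CLRMatrix, embedding: Embedding,
                     control_markers: list[str],
                     mad_threshold: float = 2.5,
                     min_loading_mass: float = 0.05) -> np.ndarray:
    """Flag cells dominated by non-specific staining controls.

    Finds the principal component whose absolute loading mass is most
    concentrated on the control markers (isotype controls, stray
    hashtags), orients it so control loadings point positive, and flags
    cells beyond ``mad_threshold`` robust z-scores on that component.
    Returns an all-false mask (with a warning) when no component carries
    meaningful control loading.
    """
    if not control_markers:
        raise ValueError("need at least one control marker")
    if embedding.loadings is None or embedding.feature_names is None:
        raise ValueError("embedding must carry PCA loadings")
    missing = [m for m in control_markers if m not in embedding.feature_names]
    if missing:
        raise ValueError(f"control markers not in panel: {missing}")
    idx = [embedding.feature_names.index(m) for m in control_markers]
    load = np.abs(embedding.loadings)
    total = load.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        concentration = np.where(total > 0, load[:, idx].sum(axis=1) / total,
                                 0.0)
    best = int(concentration.argmax())
    if concentration[best] <= min_loading_mass:
        warnings.warn("no principal component loads on the control markers; "
                      "empty non-specific mask")
        return np.zeros(embedding.coords.shape[0], dtype=bool)
    sign = np.sign(embedding.loadings[best, idx].sum()) or 1.0
    comp = embedding.coords[:, best] * sign
    med = np.median(comp)
    mad = np.median(np.abs(comp - med))
    if mad == 0:
        warnings.warn("zero spread on the control component; empty mask")
        return np.zeros(comp.size, dtype=bool)
    z = (comp - med) / (1.4826 * mad)
    return z > mad_threshold
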