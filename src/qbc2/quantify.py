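"""Quantification layer: CLR transform, barcode-collision math, hashtag
sample demultiplexing, spike-in control QC.

Antibody counts are compositional — a cell's library depth is arbitrary —
so all downstream analysis runs on centered log-ratio (CLR) scores,
log((x_i + c) / g(x + c)) with g the geometric mean over the cell's
antibodies.  Collision (doublet) risk of the split-pool design follows the
classic birthday/occupancy form: with n cells over m = w1*w2*w3 barcode
triples, a given cell collides with probability 1 - (1 - 1/m)^(n-1),
well-approximated by the Poisson form 1 - exp(-(n-1)/m) at low occupancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .demux import CountMatrix
from .schema import HASHTAG, MARKER, AntibodyPanel, HashtagCode

UNDETERMINED = "undetermined"
MULTI_SAMPLE = "multi_sample"


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

@dataclass
class CLRMatrix:
    """Dense cells x antibodies CLR scores with their provenance."""

    values: np.ndarray
    barcodes: list[str]
    features: pd.DataFrame           # columns: name, class
    pseudocount: float = 1.0
    log_base: float | None = math.e  # None => raw-ratio (no-log) variant

    @property
    def antibody_names(self) -> list[str]:
        return list(self.features["name"])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.antibody_names.index(name)]

    def columns(self, names) -> np.ndarray:
        idx = [self.antibody_names.index(n) for n in names]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.barcodes,
                            columns=self.antibody_names)

    def save(self, path: str | Path) -> None:
        self.to_frame().rename_axis("barcode").to_csv(path, sep="\t")


def clr_transform(counts: CountMatrix, pseudocount: float = 1.0,
                  log_base: float = math.e, log: bool = True) -> CLRMatrix:
    """Centered log-ratio transform of a count matrix.

    score_i = log((x_i + c) / g(x + c)), g = geometric mean over the cell's
    antibodies; rows then sum to zero.  ``log=False`` gives the raw-ratio
    variant (x_i + c) / g(x + c) instead.
    """
    x = counts.matrix.toarray().astype(float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("pseudocount must be positive when zeros are present")
    logs = np.log(x)
    centered = logs - logs.mean(axis=1, keepdims=True)
    if log:
        values = centered / math.log(log_base)
        base = float(log_base)
    else:
        values = np.exp(centered)
        base = None
    return CLRMatrix(values, list(counts.barcodes), counts.features.copy(),
                     pseudocount=pseudocount, log_base=base)


# ---------------------------------------------------------------------------
# collision / loading math
# ---------------------------------------------------------------------------

@dataclass
class CollisionModel:
    """Occupancy model for n cells over m = w1*w2*w3 barcode triples."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.m < 1:
            raise ValueError("need n >= 0 and m >= 1")

    @property
    def occupancy(self) -> float:
        return self.n / self.m

    @property
    def collision_fraction(self) -> float:
        return expected_collision_fraction(self.n, self.m)


def expected_collision_fraction(n: int, m: int, approx: bool = False) -> float:
    """Probability a given cell shares its barcode triple with >= 1 other.

    Exact form 1 - (1 - 1/m)^(n-1); ``approx=True`` returns the Poisson
    approximation 1 - exp(-(n-1)/m), accurate to ~1e-4 for n/m <= 5%.
    """
    if n < 0 or m < 1:
        raise ValueError("need n >= 0 and m >= 1")
    if n <= 1:
        return 0.0
    if approx:
        return 1.0 - math.exp(-(n - 1) / m)
    return 1.0 - (1.0 - 1.0 / m) ** (n - 1)


def monte_carlo_collision_fraction(n: int, m: int, n_replicates: int = 20,
                                   seed: int = 0) -> tuple[float, float]:
    """Empirical colliding-cell fraction: mean and SE over replicates."""
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_replicates)
    for r in range(n_replicates):
        bins = rng.integers(0, m, size=n)
        occ = np.bincount(bins, minlength=0)
        fracs[r] = occ[occ > 1].sum() / n
    se = fracs.std(ddof=1) / math.sqrt(n_replicates) if n_replicates > 1 else 0.0
    return float(fracs.mean()), float(se)


def max_loading(m: int, target_occupancy: float) -> int:
    """Largest cell count keeping occupancy at the target fraction of the
    barcode capacity (the dilution rule)."""
    if not 0 < target_occupancy < 1:
        raise ValueError("target_occupancy must lie in (0, 1)")
    return math.floor(target_occupancy * m)


# ---------------------------------------------------------------------------
# positivity calling and sample assignment
# ---------------------------------------------------------------------------

def positivity_split(scores: np.ndarray, min_separation: float = 1.0,
                     seed: int = 0) -> tuple[np.ndarray, float]:
    """Two-class 1-D k-means split of per-cell scores.

    Returns (boolean positive mask, threshold).  When the two cluster
    centers are closer than ``min_separation`` the score is judged
    unimodal and every cell is called negative (threshold = +inf).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.ptp(scores) == 0:
        return np.zeros(scores.size, dtype=bool), math.inf
    km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(
        scores.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    hi, lo = centers.max(), centers.min()
    if hi - lo < min_separation:
        return np.zeros(scores.size, dtype=bool), math.inf
    threshold = (hi + lo) / 2.0
    return scores > threshold, float(threshold)


@dataclass
class SampleAssignment:
    """Per-cell sample labels plus the per-hashtag positivity calls."""

    labels: list[str]                       # sample_id / undetermined / multi_sample
    positive: pd.DataFrame                  # cells x hashtags, boolean
    thresholds: dict[str, float] = field(default_factory=dict)

    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    def save(self, path: str | Path, barcodes=None) -> None:
        df = pd.DataFrame({"label": self.labels})
        if barcodes is not None:
            df.insert(0, "barcode", list(barcodes))
        df.to_csv(path, sep="\t", index=False)


def assign_samples(clr: CLRMatrix, code: HashtagCode,
                   positivity_method: str = "2means",
                   thresholds: dict[str, float] | None = None,
                   min_separation: float = 1.0) -> SampleAssignment:
    """Decode each cell's sample from its hashtag positivity pattern.

    Per hashtag, cells split positive/negative by a 2-means split on that
    hashtag's CLR scores (default) or by fixed thresholds.  A cell whose
    positive set exactly matches a sample's code gets that sample; a set
    covering the union of two or more codes is ``multi_sample`` (barcode
    collision / doublet signature); anything else is ``undetermined``.
    """
    hashtags = code.hashtags
    missing = [h for h in hashtags if h not in clr.antibody_names]
    if missing:
        raise ValueError(f"code hashtags missing from matrix: {missing}")
    pos = {}
    thr: dict[str, float] = {}
    for h in hashtags:
        scores = clr.column(h)
        if positivity_method == "threshold":
            if not thresholds or h not in thresholds:
                raise ValueError(f"no threshold supplied for hashtag {h!r}")
            thr[h] = thresholds[h]
            pos[h] = scores > thresholds[h]
        elif positivity_method == "2means":
            pos[h], thr[h] = positivity_split(scores, min_separation)
        else:
            raise ValueError(f"unknown positivity method {positivity_method!r}")
    positive = pd.DataFrame(pos, index=clr.barcodes)

    code_sets = {s: frozenset(sub) for s, sub in code.mapping.items()}
    pair_unions = set()
    sets = list(code_sets.values())
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pair_unions.add(sets[i] | sets[j])
    labels = []
    for row in positive.itertuples(index=False):
        p = frozenset(h for h, v in zip(hashtags, row) if v)
        sample = code.decode(p)
        if sample is not None:
            labels.append(sample)
        elif any(u <= p for u in pair_unions):
            labels.append(MULTI_SAMPLE)
        else:
            labels.append(UNDETERMINED)
    return SampleAssignment(labels, positive, thr)


# ---------------------------------------------------------------------------
# spike-in control QC
# ---------------------------------------------------------------------------

def flag_hashtag_only(counts: CountMatrix, panel: AntibodyPanel,
                      min_fraction: float = 0.75
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Flag cells whose UMIs are dominated by hashtag antibodies.

    Spike-in control cells are stained only with a hashtag, so nearly all
    their UMIs come from hashtag-class antibodies; ordinary cells carry a
    marker payload.  Returns (boolean mask, dominant-hashtag name per cell;
    '' where not flagged).
    """
    dense = counts.matrix.toarray().astype(float)
    ht_idx = [j for j, c in enumerate(counts.features["class"])
              if c == HASHTAG]
    if not ht_idx:
        raise ValueError("panel has no hashtag antibodies")
    total = dense.sum(axis=1)
    ht_total = dense[:, ht_idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, ht_total / np.maximum(total, 1e-12), 0.0)
    mask = frac >= min_fraction
    names = np.array(counts.features["name"])[ht_idx]
    dominant = np.where(mask, names[dense[:, ht_idx].argmax(axis=1)], "")
    return mask, dominant


@dataclass
class QCReport:
    """Spike-in control outcomes for one run."""

    n_cells: int
    ht2_cells_detected: int
    ht3_cells_detected: int
    ht2_fraction: float
    ht2_marker_clr_mean: float       # marker signal ON control cells (leakage)
    other_marker_clr_mean: float     # marker signal on ordinary cells
    isotype_clr_mean: float
    isotype_clr_median: float
    discard_ledger: dict = field(default_factory=dict)

    @property
    def ht2_marker_leakage(self) -> float:
        return self.ht2_marker_clr_mean

    def to_series(self) -> pd.Series:
        d = {k: v for k, v in self.__dict__.items() if k != "discard_ledger"}
        for reason, n in self.discard_ledger.items():
            d[f"discarded_{reason}"] = n
        return pd.Series(d)

    def save(self, path: str | Path) -> None:
        self.to_series().rename_axis("metric").to_frame("value").to_csv(
            path, sep="\t")


def control_qc(counts: CountMatrix, panel: AntibodyPanel,
               clr: CLRMatrix | None = None,
               control_flags: dict[str, str] | None = None,
               ht2_hashtag: str = "HT2", ht3_hashtag: str = "HT3",
               ledger: dict | None = None,
               min_fraction: float = 0.75) -> QCReport:
    """Quantify swap and blocking failure from the spike-in controls.

    HT2 controls were present from the start: any marker signal on them
    measures antibody swapping / barcode hopping.  HT3 controls joined
    after round 1 and can never complete a barcode triple: any called
    HT3-dominated cell measures splint-blocking failure.

    ``control_flags`` (triple key -> flag) uses simulation truth when
    available; otherwise controls are inferred from their hashtag-only
    count signature.
    """
    from .simulate import FLAG_HT2, FLAG_HT3  # flag vocabulary

    if clr is None:
        clr = clr_transform(counts)
    if control_flags is not None:
        flags = np.array([control_flags.get(bc, "none")
                          for bc in counts.barcodes])
        ht2_mask = flags == FLAG_HT2
        ht3_mask = flags == FLAG_HT3
    else:
        mask, dominant = flag_hashtag_only(counts, panel, min_fraction)
        ht2_mask = mask & (dominant == ht2_hashtag)
        ht3_mask = mask & (dominant == ht3_hashtag)

    marker_names = panel.markers
    n = len(counts.barcodes)
    if marker_names and n:
        marker_scores = clr.columns(marker_names)
        ht2_marker = float(marker_scores[ht2_mask].mean()) if ht2_mask.any() \
            else math.nan
        other_marker = float(marker_scores[~ht2_mask & ~ht3_mask].mean()) \
            if (~ht2_mask & ~ht3_mask).any() else math.nan
    else:
        ht2_marker = other_marker = math.nan
    iso_names = panel.isotypes
    if iso_names and n:
        iso = clr.columns(iso_names)
        iso_mean, iso_median = float(iso.mean()), float(np.median(iso))
    else:
        iso_mean = iso_median = math.nan
    if not iso_names:
        warnings.warn("panel has no isotype control; isotype QC skipped")

    return QCReport(
        n_cells=n,
        ht2_cells_detected=int(ht2_mask.sum()),
        ht3_cells_detected=int(ht3_mask.sum()),
        ht2_fraction=float(ht2_mask.mean()) if n else math.nan,
        ht2_marker_clr_mean=ht2_marker,
        other_marker_clr_mean=other_marker,
        isotype_clr_mean=iso_mean,
        isotype_clr_median=iso_median,
        discard_ledger=dict(ledger or {}),
    )
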