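"""Resampling consensus K-means stratification of the encoded matrix.

Monti-style consensus clustering: for each of ``repetitions`` runs, 80% of
patients and 80% of (z-scored) latent features are subsampled without
replacement and partitioned by K-means for each k in [k_min, k_max].  The
consensus matrix entry CM[i, j] is the fraction of co-sampled runs in which
patients i and j landed in the same cluster (0 when never co-sampled).  Final
subtype labels come from agglomerative clustering (average linkage by
default) on the distance 1 - CM, cut at k.  The same patient/feature
subsample is reused across k within a repetition, and each repetition's RNG
is seeded as master seed + repetition index, so the whole procedure is
reproducible bit-for-bit.

No k is auto-selected: diagnostics (PAC, consensus CDFs, within/between
consensus) inform the choice, which in this method is made by clinical
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.cluster import KMeans

from .autoencoder import EncodedMatrix
from .data_io import ValidationError

__all__ = [
    "ConsensusConfig",
    "ConsensusMatrix",
    "SubtypeAssignment",
    "kmeans",
    "consensus_cluster",
    "consensus_diagnostics",
    "consensus_cdf",
    "render_heatmap",
]


@dataclass
class ConsensusConfig:
    k_min: int = 2
    k_max: int = 6
    repetitions: int = 1000
    patient_fraction: float = 0.8
    feature_fraction: float = 0.8
    kmeans_restarts: int = 10
    linkage: str = "average"
    feature_scaling: str = "zscore"  # zscore | none
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if not (0 < self.patient_fraction <= 1 and 0 < self.feature_fraction <= 1):
            raise ValueError("sampling fractions must be in (0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ConsensusMatrix:
    patients: list[str]
    values: np.ndarray  # patients x patients, entries in [0, 1]
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.patients)
        if self.values.shape != (n, n):
            raise ValidationError("consensus matrix must be square over patients")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.patients)


@dataclass
class SubtypeAssignment:
    k: int
    labels: dict[str, int]  # patient_id -> cluster index in 1..k
    sizes: dict[int, int]
    warnings: list[str] = field(default_factory=list)

    def label_array(self, patients: list[str]) -> np.ndarray:
        return np.array([self.labels[p] for p in patients])


def kmeans(
    X: np.ndarray, k: int, restarts: int = 10, seed: int = 0
) -> np.ndarray:
    """Best-of-``restarts`` Lloyd's K-means with k-means++ seeding.

    Returns 0-based labels; deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of items ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(X)


def _scale_features(V: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return V
    if how != "zscore":
        raise ValueError(f"unknown feature scaling {how!r}")
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (V - mu) / sd


def consensus_cluster(
    EM: EncodedMatrix, cfg: ConsensusConfig | None = None
) -> dict[int, tuple[ConsensusMatrix, SubtypeAssignment]]:
    """Run the full consensus procedure for every k in [k_min, k_max]."""
    cfg = cfg or ConsensusConfig()
    n, d = EM.values.shape
    if n < cfg.k_max:
        raise ValidationError(f"need at least k_max={cfg.k_max} patients (got {n})")
    V = _scale_features(EM.values, cfg.feature_scaling)
    n_pat = int(np.floor(cfg.patient_fraction * n))
    n_feat = max(1, int(np.floor(cfg.feature_fraction * d)))
    ks = list(range(cfg.k_min, cfg.k_max + 1))

    connect = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))

    for rep in range(cfg.repetitions):
        rng = np.random.default_rng(cfg.seed + rep)
        pats = np.sort(rng.choice(n, size=n_pat, replace=False))
        feats = np.sort(rng.choice(d, size=n_feat, replace=False))
        sub = V[np.ix_(pats, feats)]
        co_sampled[np.ix_(pats, pats)] += 1
        for k in ks:
            labels = kmeans(
                sub, k, restarts=cfg.kmeans_restarts, seed=int(cfg.seed + rep)
            )
            for c in range(k):
                members = pats[labels == c]
                connect[k][np.ix_(members, members)] += 1

    results: dict[int, tuple[ConsensusMatrix, SubtypeAssignment]] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in ks:
            CM = np.where(co_sampled > 0, connect[k] / np.where(co_sampled == 0, 1, co_sampled), 0.0)
            CM = (CM + CM.T) / 2  # numerically symmetric by construction; enforce exactly
            cm = ConsensusMatrix(patients=list(EM.patients), values=CM, k=k)
            assignment = _final_assignment(cm, cfg.linkage)
            results[k] = (cm, assignment)
    return results


def _final_assignment(cm: ConsensusMatrix, linkage: str) -> SubtypeAssignment:
    """Agglomerative cut of the consensus distances 1 - CM at k clusters."""
    n = len(cm.patients)
    D = 1.0 - cm.values
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = sch.linkage(ssd.squareform(D, checks=False), method=linkage)
    raw = sch.fcluster(Z, t=cm.k, criterion="maxclust")
    # relabel to contiguous 1..k' in order of first appearance
    remap: dict[int, int] = {}
    labels = {}
    for pid, lab in zip(cm.patients, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[pid] = remap[lab]
    sizes = {c: sum(1 for v in labels.values() if v == c) for c in sorted(set(labels.values()))}
    warnings = []
    if len(sizes) < cm.k:
        warnings.append(
            f"only {len(sizes)} of {cm.k} requested clusters are non-empty"
        )
    return SubtypeAssignment(k=cm.k, labels=labels, sizes=sizes, warnings=warnings)


def consensus_cdf(cm: ConsensusMatrix, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Empirical CDF of the upper-triangular consensus entries."""
    grid = np.linspace(0, 1, 101) if grid is None else np.asarray(grid)
    iu = np.triu_indices(len(cm.patients), k=1)
    vals = cm.values[iu]
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / max(1, vals.size)
    return pd.DataFrame({"consensus": grid, "cdf": cdf})


def _pac(cm: ConsensusMatrix, lower: float = 0.1, upper: float = 0.9) -> float:
    iu = np.triu_indices(len(cm.patients), k=1)
    vals = cm.values[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > lower) & (vals < upper)))


def consensus_diagnostics(
    results: dict[int, tuple[ConsensusMatrix, SubtypeAssignment]],
    pac_band: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Per-k stability summary: PAC plus mean within/between-cluster consensus.

    Lower PAC (proportion of ambiguous clustering — consensus entries inside
    the intermediate band) means more stable clustering.  The summary informs
    but never decides k.
    """
    if not results:
        raise ValidationError("no consensus results to summarize")
    rows = []
    for k in sorted(results):
        cm, assignment = results[k]
        labs = assignment.label_array(cm.patients)
        same = labs[:, None] == labs[None, :]
        iu = np.triu_indices(len(cm.patients), k=1)
        vals, same_u = cm.values[iu], same[iu]
        rows.append(
            {
                "k": k,
                "pac": _pac(cm, *pac_band),
                "mean_within": float(vals[same_u].mean()) if same_u.any() else np.nan,
                "mean_between": float(vals[~same_u].mean()) if (~same_u).any() else np.nan,
                "n_nonempty_clusters": len(assignment.sizes),
            }
        )
    return pd.DataFrame(rows)


def render_heatmap(
    cm: ConsensusMatrix, assignment: SubtypeAssignment, path: str | Path
) -> Path:
    """White-to-blue consensus heatmap, patients blocked by final subtype.

    Within each subtype, patients follow the dendrogram leaf order so stable
    blocks sit on the diagonal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(cm.patients)
    if n > 1:
        D = np.clip(1.0 - cm.values, 0.0, None)
        np.fill_diagonal(D, 0.0)
        Z = sch.linkage(ssd.squareform((D + D.T) / 2, checks=False), method="average")
        leaf_order = sch.leaves_list(Z)
    else:
        leaf_order = np.array([0])
    labs = assignment.label_array(cm.patients)
    order = sorted(leaf_order, key=lambda i: (labs[i],))
    M = cm.values[np.ix_(order, order)]

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(M, cmap="Blues", vmin=0, vmax=1, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"k = {cm.k}")
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
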