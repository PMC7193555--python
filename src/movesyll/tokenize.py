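"""Movement-syllable vocabulary learning and symbolic assignment.

The vocabulary is a set of k centroid window-vectors learned by k-means over
pooled windows (k = 24 by default, chosen by the elbow method on the inertia
curve).  Any window set is then mapped to an ordered sequence of syllable
indices (0-based) by nearest-centroid assignment in Euclidean distance.
Windows are clustered on their raw band-limited values: amplitude carries
clinical information (bradykinesia reduces it) so no per-window normalization
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from movesyll.errors import ValidationError
from movesyll.preprocess import WindowSet

__all__ = [
    "SyllableVocabulary",
    "SyllableSequence",
    "fit_vocabulary",
    "assign_syllables",
    "elbow_curve",
]

_N_RESTARTS = 10  # k-means++ restarts; guards against poor local minima


@dataclass
class SyllableVocabulary:
    """The learned movement-syllable dictionary (the set of centroids)."""

    centroids: np.ndarray  # (k, d)
    seed: int
    training_source: str = "healthy_pool"
    training_sessions: tuple[str, ...] = ()
    units: str = "g"
    inertia: float | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2:
            raise ValidationError("centroids must be a (k, d) matrix")

    @property
    def k(self) -> int:
        return int(self.centroids.shape[0])

    @property
    def vector_length(self) -> int:
        return int(self.centroids.shape[1])


@dataclass
class SyllableSequence:
    """One session's (or one ADL's) ordered symbol string."""

    session_id: str
    symbols: np.ndarray      # (n,) ints in [0, k)
    start_times: np.ndarray  # (n,) seconds, aligned to symbols
    k: int
    adl_label: str | None = None

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.symbols.shape != self.start_times.shape:
            raise ValidationError("symbols and start_times lengths differ")
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.k
        ):
            raise ValidationError("symbol out of vocabulary")

    def __len__(self) -> int:
        return int(self.symbols.size)


def _pool_windows(windows: list[WindowSet] | WindowSet) -> tuple[np.ndarray, list[str], str]:
    if isinstance(windows, WindowSet):
        windows = [windows]
    if not windows:
        raise ValidationError("no window sets given")
    units = {ws.units for ws in windows}
    if len(units) > 1:
        raise ValidationError(f"mixed units in training pool: {sorted(units)}")
    X = np.vstack([ws.window_vectors for ws in windows])
    ids = [ws.session_id for ws in windows]
    return X, ids, units.pop()


def fit_vocabulary(
    windows: list[WindowSet] | WindowSet,
    k: int = 24,
    seed: int = 0,
    training_source: str = "healthy_pool",
) -> SyllableVocabulary:
    """Learn k syllable centroids by k-means over the pooled windows.

    k-means++ initialization with 10 restarts and a fixed seed: results are
    reproducible and robust to local minima.  The sessions that trained the
    vocabulary are recorded so downstream outputs can state their provenance.
    """
    X, ids, units = _pool_windows(windows)
    if X.shape[0] < k:
        raise ValidationError(
            f"insufficient data: {X.shape[0]} windows for k={k}"
        )
    km = KMeans(n_clusters=k, n_init=_N_RESTARTS, random_state=seed)
    km.fit(X)
    return SyllableVocabulary(
        centroids=km.cluster_centers_,
        seed=seed,
        training_source=training_source,
        training_sessions=tuple(ids),
        units=units,
        inertia=float(km.inertia_),
    )


def assign_syllables(ws: WindowSet, vocab: SyllableVocabulary) -> SyllableSequence:
    """Map each window to its nearest centroid (Euclidean; ties -> lowest index)."""
    if ws.vector_length != vocab.vector_length:
        raise ValidationError(
            "vocabulary incompatible: window length "
            f"{ws.vector_length} != centroid length {vocab.vector_length}"
        )
    if ws.units != vocab.units:
        raise ValidationError(
            f"vocabulary incompatible: units {ws.units!r} != {vocab.units!r}"
        )
    # argmin over squared distances; np.argmin returns the first (lowest)
    # index on ties, which is the documented tie-break.
    x2 = np.einsum("ij,ij->i", ws.window_vectors, ws.window_vectors)
    c2 = np.einsum("ij,ij->i", vocab.centroids, vocab.centroids)
    d2 = x2[:, None] - 2.0 * ws.window_vectors @ vocab.centroids.T + c2[None, :]
    symbols = np.argmin(d2, axis=1)
    return SyllableSequence(
        session_id=ws.session_id,
        symbols=symbols,
        start_times=ws.start_times,
        k=vocab.k,
        adl_label=ws.adl_label,
    )


def nearest_centroid_bruteforce(
    ws: WindowSet, vocab: SyllableVocabulary
) -> np.ndarray:
    """Plain per-window nearest-centroid scan (reference oracle)."""
    out = np.empty(ws.n_windows, dtype=np.int64)
    for i, v in enumerate(ws.window_vectors):
        d = np.linalg.norm(vocab.centroids - v[None, :], axis=1)
        out[i] = int(np.argmin(d))
    return out


def elbow_curve(
    windows: list[WindowSet] | WindowSet,
    k_values: list[int],
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Inertia-vs-k curve and the elbow-suggested k.

    The suggested k is the point of maximum perpendicular distance from the
    (k, inertia) curve to the chord joining its endpoints -- the usual
    geometric reading of the elbow heuristic.
    """
    if not k_values:
        raise ValidationError("empty k_values")
    ks = list(k_values)
    if ks != sorted(ks):
        raise ValidationError("k_values must be sorted ascending")
    X, _, _ = _pool_windows(windows)
    if max(ks) > X.shape[0]:
        raise ValidationError("max k exceeds window count")

    inertias = np.empty(len(ks))
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=k, n_init=_N_RESTARTS, random_state=seed)
        km.fit(X)
        inertias[i] = km.inertia_

    if len(ks) < 3:
        return inertias, ks[int(np.argmin(inertias))]
    # perpendicular distance of each point to the endpoint chord, with both
    # axes scaled to [0, 1] so k and inertia are commensurate
    x = (np.asarray(ks, float) - ks[0]) / max(ks[-1] - ks[0], 1)
    span = inertias[0] - inertias[-1]
    y = (inertias - inertias[-1]) / (span if span > 0 else 1.0)
    # chord runs (0, y0=1) -> (1, 0); distance ~ |x + y - 1| / sqrt(2)
    dist = np.abs(x + y - 1.0)
    return inertias, ks[int(np.argmax(dist))]
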