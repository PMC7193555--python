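"""MDS embedding of SMR dissimilarities and severity regression.

Sessions are placed in a 3-D space whose pairwise distances approximate the
L1 dissimilarities between SMRs (classical/Torgerson MDS by default, SMACOF
behind a flag), and motor severity -- the UPDRS-III total or a subscore --
is regressed on the three coordinates with ordinary least squares.  The
module also computes the UPDRS-III subscore sums from individual exam items,
Cook's-distance participant QC, and the at-home diurnal/nocturnal analysis
(30-minute clock-aligned segments, night 00:00-06:00, day 08:00-20:00).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import linalg
from sklearn.manifold import MDS as _SKMDS

from movesyll.errors import ComputationError, ValidationError
from movesyll.markov import SMR, DissimilarityMatrix, smr_from_sequences
from movesyll.tokenize import SyllableSequence

__all__ = [
    "ClinicalScores",
    "Embedding3D",
    "SeverityModel",
    "PhaseWindows",
    "UPDRS3_ITEMS",
    "total_updrs3",
    "mds_embed",
    "fit_severity_model",
    "flag_outliers_cook",
    "segment_athome_stream",
    "phase_severity_models",
]

# MDS-UPDRS Part III items grouped into the subscores used for severity.
UPDRS3_ITEMS: dict[str, tuple[str, ...]] = {
    "bradykinesia": (
        "Pronation Supination Right", "Pronation Supination Left",
        "Toe Tapping Right", "Toe Tapping Left",
        "Leg Right", "Leg Left",
        "Tapping Right", "Tapping Left",
        "Hand Movement Right", "Hand Movement Left",
        "Rigidity Neck",
        "Rigidity Upper Right", "Rigidity Upper Left",
        "Rigidity Lower Right", "Rigidity Lower Left",
    ),
    "tremor": (
        "Postural Tremor Right", "Postural Tremor Left",
        "Kinetic Tremor Right", "Kinetic Tremor Left",
        "Rest Tremor Amplitude Upper Right", "Rest Tremor Amplitude Upper Left",
        "Rest Tremor Amplitude Lower Right", "Rest Tremor Amplitude Lower Left",
        "Amplitude Lip", "Rest Tremor Constancy",
    ),
    "pigd": (
        "Arising From Chair", "Posture", "Gait Score", "Freeze Score",
        "Postural Stability",
    ),
    "facial": ("Facial Expression Score",),
    "speech": ("Speech Score",),
}

_CANON = {
    item.lower(): (sub, item)
    for sub, items in UPDRS3_ITEMS.items()
    for item in items
}


@dataclass
class ClinicalScores:
    """UPDRS-III subscores; total = brady + tremor + PIGD + facial + speech."""

    participant_id: str
    bradykinesia: float = 0.0
    tremor: float = 0.0
    pigd: float = 0.0
    facial: float = 0.0
    speech: float = 0.0

    @property
    def total(self) -> float:
        return self.bradykinesia + self.tremor + self.pigd + self.facial + self.speech


@dataclass
class Embedding3D:
    """Low-dimensional MDS coordinates for a set of sessions."""

    session_ids: tuple[str, ...]
    coords: np.ndarray          # (n, dims)
    flavor: str = "classical"
    seed: int | None = None
    stress: float = 0.0
    clamped_eigenmass: float = 0.0  # |sum of clamped negative eigenvalues| / sum of positive

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != len(self.session_ids):
            raise ValidationError("one coordinate row per session required")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite embedding coordinates")


@dataclass
class SeverityModel:
    """OLS fit of a severity score on embedding coordinates."""

    params: np.ndarray           # intercept first, then slopes
    r_squared: float
    loocv_r_squared: float
    fitted: np.ndarray
    residuals: np.ndarray
    cooks_distances: np.ndarray
    observation_ids: tuple[str, ...]
    target: str = "total"

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.params[1:]


@dataclass
class PhaseWindows:
    """Per-participant 30-minute segment SMRs with circadian phase labels."""

    participant_id: str
    start_clock_s: np.ndarray      # seconds since local midnight, per segment
    start_abs_s: np.ndarray        # seconds since stream origin, per segment
    smrs: np.ndarray               # (n_segments, k)
    phases: np.ndarray             # "nocturnal" | "diurnal" | "excluded"

    def __post_init__(self) -> None:
        n = self.smrs.shape[0]
        if not (len(self.start_clock_s) == len(self.phases) == n):
            raise ValidationError("segment arrays must align")


def total_updrs3(items: dict[str, float], participant_id: str = "") -> ClinicalScores:
    """Sum individual UPDRS-III exam items into the five subscores.

    Item labels are matched case-insensitively against the known item lists;
    an unrecognized label is an error, and every listed item must be present
    (a missing rating cannot silently count as zero).
    """
    sums = {sub: 0.0 for sub in UPDRS3_ITEMS}
    seen: set[str] = set()
    for label, value in items.items():
        key = label.strip().lower()
        if key not in _CANON:
            raise ValidationError(f"unknown UPDRS item {label!r}")
        sub, canon = _CANON[key]
        if canon in seen:
            raise ValidationError(f"duplicate UPDRS item {label!r}")
        seen.add(canon)
        sums[sub] += float(value)
    missing = {i for its in UPDRS3_ITEMS.values() for i in its} - seen
    if missing:
        raise ValidationError(f"missing UPDRS items: {sorted(missing)[:3]}...")
    return ClinicalScores(participant_id=participant_id, **sums)


def _classical_mds(D: np.ndarray, dims: int) -> tuple[np.ndarray, float]:
    """Torgerson double-centering: B = -J D^2 J / 2, top-eigen coordinates.

    L1 dissimilarities are not guaranteed Euclidean, so negative eigenvalues
    can occur; they are clamped to zero and the clamped mass reported.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    w, V = linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0.0, None)
    clamped = float(-w[w < 0].sum() / max(pos.sum(), 1e-300))
    coords = V[:, :dims] * np.sqrt(pos[:dims])[None, :]
    return coords, clamped


def mds_embed(
    D: DissimilarityMatrix,
    dims: int = 3,
    flavor: str = "classical",
    seed: int = 0,
) -> Embedding3D:
    """Embed a dissimilarity matrix in ``dims`` dimensions.

    ``classical`` (default) is deterministic Torgerson scaling; ``smacof``
    is iterative stress majorization (seeded).  Embedded pairwise distances
    approximate the input dissimilarities in either case.
    """
    if dims > D.n - 1:
        raise ValidationError(f"dims={dims} too large for {D.n} sessions")
    if flavor == "classical":
        coords, clamped = _classical_mds(D.D, dims)
        emb_d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        stress = float(np.sqrt(((D.D - emb_d) ** 2).sum() / 2.0))
        return Embedding3D(
            session_ids=D.session_ids, coords=coords, flavor="classical",
            stress=stress, clamped_eigenmass=clamped,
        )
    if flavor == "smacof":
        import inspect

        # scikit-learn renamed (dissimilarity, metric) -> (metric, metric_mds)
        params = inspect.signature(_SKMDS.__init__).parameters
        if "metric_mds" in params:
            kw = {"metric": "precomputed", "metric_mds": True, "init": "random"}
        else:
            kw = {"dissimilarity": "precomputed", "metric": True}
        mds = _SKMDS(
            n_components=dims, random_state=seed, n_init=4,
            normalized_stress=False, **kw,
        )
        coords = mds.fit_transform(D.D)
        return Embedding3D(
            session_ids=D.session_ids, coords=coords, flavor="smacof",
            seed=seed, stress=float(mds.stress_),
        )
    raise ValidationError(f"unknown MDS flavor {flavor!r}")


def _ols_with_diagnostics(
    X: np.ndarray, y: np.ndarray, ids: tuple[str, ...], target: str
) -> SeverityModel:
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # collinear design (e.g. identical day and night coordinates):
        # fall back to the minimum-norm pseudoinverse solution
        fit = sm.OLS(y, Xd).fit(method="pinv")
        params = np.asarray(fit.params)
        fitted = np.asarray(fit.fittedvalues)
        resid = y - fitted
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
        n = len(y)
        cooks = np.zeros(n)
        loo = _press_r2(Xd, y, fitted, rank)
        return SeverityModel(
            params=params, r_squared=r2, loocv_r_squared=loo,
            fitted=fitted, residuals=resid, cooks_distances=cooks,
            observation_ids=ids, target=target,
        )
    fit = sm.OLS(y, Xd).fit()
    infl = fit.get_influence()
    cooks = np.asarray(infl.cooks_distance[0])
    sst = float(((y - y.mean()) ** 2).sum())
    if sst > 0:
        press = float((np.asarray(infl.resid_press) ** 2).sum())
        loo = 1.0 - press / sst
        r2 = float(fit.rsquared)
    else:
        loo = 0.0
        r2 = 0.0
    return SeverityModel(
        params=np.asarray(fit.params),
        r_squared=r2,
        loocv_r_squared=loo,
        fitted=np.asarray(fit.fittedvalues),
        residuals=np.asarray(fit.resid),
        cooks_distances=cooks,
        observation_ids=ids,
        target=target,
    )


def _press_r2(Xd: np.ndarray, y: np.ndarray, fitted: np.ndarray, rank: int) -> float:
    H = Xd @ np.linalg.pinv(Xd)
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    press = float((((y - fitted) / (1.0 - h)) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / sst if sst > 0 else 0.0


def fit_severity_model(
    emb: Embedding3D,
    scores: list[ClinicalScores],
    target: str = "total",
) -> SeverityModel:
    """OLS of a severity score on the embedding coordinates (+ intercept).

    ``target`` selects the UPDRS-III total or one subscore.  The in-sample
    r-squared is reported together with a leave-one-out (PRESS) r-squared,
    which exposes the optimism of the in-sample number; Cook's distance per
    observation supports influence-based QC.
    """
    if len(scores) != len(emb.session_ids):
        raise ValidationError("one score per embedded session required")
    if len(scores) < 5:
        raise ValidationError("need at least 5 observations")
    if target not in ("total", "bradykinesia", "tremor", "pigd"):
        raise ValidationError(f"unknown target {target!r}")
    y = np.array([
        s.total if target == "total" else getattr(s, target) for s in scores
    ], dtype=float)
    X = emb.coords
    if np.linalg.matrix_rank(sm.add_constant(X, has_constant="add")) <= 1:
        raise ComputationError("degenerate embedding: coordinates are constant")
    return _ols_with_diagnostics(X, y, emb.session_ids, target)


def flag_outliers_cook(model: SeverityModel, threshold: float = 0.16) -> list[str]:
    """IDs of observations whose Cook's distance exceeds the threshold.

    0.16 is the exclusion cut used for participant QC; influence above it
    means one participant is steering the severity fit.
    """
    return [
        oid for oid, d in zip(model.observation_ids, model.cooks_distances)
        if d > threshold
    ]


def segment_athome_stream(
    seq: SyllableSequence,
    k: int,
    window_minutes: int = 30,
    night_span: tuple[float, float] = (0.0, 6.0),
    day_span: tuple[float, float] = (8.0, 20.0),
    min_transitions: int = 100,
    eps: float = 1e-10,
) -> PhaseWindows:
    """Cut an at-home symbol stream into clock-aligned 30-minute segments.

    ``seq.start_times`` must be absolute clock seconds (seconds since the
    local midnight starting the stream).  Each segment gets its own smoothed
    SMR from the transitions inside it; segments starting in [00:00, 06:00)
    are nocturnal, [08:00, 20:00) diurnal, anything else excluded.  Segments
    with fewer than ``min_transitions`` transitions are excluded too --
    an idle half hour yields a near-uniform, uninformative SMR.
    """
    if len(seq) == 0:
        raise ValidationError("empty sequence")
    W = window_minutes * 60.0
    t = seq.start_times
    seg_idx = np.floor(t / W).astype(np.int64)
    starts, clocks, smrs, phases = [], [], [], []
    for si in np.unique(seg_idx):
        mask = seg_idx == si
        sym = seq.symbols[mask]
        seg_start = si * W
        clock = seg_start % 86400.0
        hour = clock / 3600.0
        if night_span[0] <= hour < night_span[1]:
            phase = "nocturnal"
        elif day_span[0] <= hour < day_span[1]:
            phase = "diurnal"
        else:
            phase = "excluded"
        if sym.size - 1 < min_transitions:
            phase = "excluded"
        sub = SyllableSequence(
            session_id=seq.session_id, symbols=sym,
            start_times=seq.start_times[mask], k=k,
        )
        smrs.append(smr_from_sequences(sub, k, eps).pi)
        starts.append(seg_start)
        clocks.append(clock)
        phases.append(phase)
    return PhaseWindows(
        participant_id=seq.session_id,
        start_clock_s=np.asarray(clocks),
        start_abs_s=np.asarray(starts),
        smrs=np.vstack(smrs),
        phases=np.asarray(phases, dtype=object),
    )


def phase_severity_models(
    cohort: list[PhaseWindows],
    embedding: Embedding3D,
    scores: dict[str, float],
    mode: str = "both",
) -> SeverityModel:
    """Regress participant scores on phase-averaged MDS coordinates.

    ``embedding`` must hold one coordinate row per segment across the whole
    cohort, with session_ids of the form ``participant_id`` repeated per
    segment (joint embedding over all participants' segments).  For each
    participant the 3 coordinates are averaged over the nocturnal and/or
    diurnal segments; ``mode='both'`` concatenates both averages (6
    predictors).  Participants lacking usable segments in a required phase
    are excluded with a warning.
    """
    if mode not in ("night", "day", "both"):
        raise ValidationError(f"unknown mode {mode!r}")
    need = {"night": ("nocturnal",), "day": ("diurnal",),
            "both": ("nocturnal", "diurnal")}[mode]
    emb_ids = np.asarray(embedding.session_ids, dtype=object)

    rows, ys, ids = [], [], []
    for pw in cohort:
        if pw.participant_id not in scores:
            continue
        sel = emb_ids == pw.participant_id
        coords = embedding.coords[sel]
        if coords.shape[0] != pw.smrs.shape[0]:
            raise ValidationError(
                f"embedding rows for {pw.participant_id} do not match segments"
            )
        feats = []
        ok = True
        for phase in need:
            mask = pw.phases == phase
            if not mask.any():
                warnings.warn(
                    f"participant {pw.participant_id} has no {phase} segments; "
                    "excluded from this phase model",
                    stacklevel=2,
                )
                ok = False
                break
            feats.append(coords[mask].mean(axis=0))
        if not ok:
            continue
        rows.append(np.concatenate(feats))
        ys.append(scores[pw.participant_id])
        ids.append(pw.participant_id)
    if len(rows) < 5:
        raise ValidationError("need at least 5 participants with usable phases")
    X = np.vstack(rows)
    y = np.asarray(ys, dtype=float)
    if np.ptp(y) == 0:
        # no variance to explain; report a zero-r2 model rather than failing
        n = len(y)
        return SeverityModel(
            params=np.concatenate([[y.mean()], np.zeros(X.shape[1])]),
            r_squared=0.0, loocv_r_squared=0.0,
            fitted=np.full(n, y.mean()), residuals=np.zeros(n),
            cooks_distances=np.zeros(n), observation_ids=tuple(ids),
            target=f"total[{mode}]",
        )
    return _ols_with_diagnostics(X, y, tuple(ids), target=f"total[{mode}]")
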