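"""Markov-chain modelling of syllable sequences and the SMR.

A session's symbol sequences define a first-order Markov chain over the k
syllables.  Transition rates are the maximum-likelihood row-normalized counts
P(a,b) = N(a,b) / N_a; unseen transitions are smoothed with a tiny constant
(1e-10) so every entry is strictly positive, making the chain irreducible and
its stationary distribution unique.  That stationary distribution -- the
Symbolic Movement Representation (SMR) -- is a k-dimensional probability
vector summarizing the session's movement grammar; sessions are compared by
the L1 distance between their SMRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from movesyll.errors import ComputationError, ValidationError
from movesyll.tokenize import SyllableSequence

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "SMR",
    "DissimilarityMatrix",
    "count_transitions",
    "estimate_transition_matrix",
    "stationary_distribution",
    "stationary_power_iteration",
    "smr_distance",
    "dissimilarity_matrix",
    "smr_stability_curve",
    "smr_from_sequences",
]

_ROW_SUM_TOL = 1e-12
_STATIONARY_TOL = 1e-10


@dataclass
class TransitionCounts:
    """Pair counts N(a,b) within sequences; pairs never span two sequences."""

    counts: np.ndarray  # (k, k) nonnegative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("counts must be square")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def k(self) -> int:
        return int(self.counts.shape[0])

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionMatrix:
    """Row-stochastic, strictly positive (smoothed) transition matrix."""

    P: np.ndarray
    smoothing_eps: float = 1e-10

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValidationError("P must be square")

    @property
    def k(self) -> int:
        return int(self.P.shape[0])

    def validate(self) -> None:
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("invalid transition matrix: rows must sum to 1")
        if (self.P <= 0).any():
            raise ValidationError("invalid transition matrix: entries must be > 0")


@dataclass
class SMR:
    """Stationary distribution of a session's smoothed syllable chain."""

    pi: np.ndarray
    session_id: str = ""
    adl_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 1:
            raise ValidationError("pi must be a vector")
        if (self.pi < -1e-12).any() or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValidationError("pi must be a probability vector")

    @property
    def k(self) -> int:
        return int(self.pi.shape[0])


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise L1 distances between SMRs, zero diagonal."""

    session_ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.session_ids)
        if self.D.shape != (n, n):
            raise ValidationError("D shape must match session_ids")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValidationError("D must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise ValidationError("D diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.session_ids)


def count_transitions(
    seqs: list[SyllableSequence] | SyllableSequence, k: int
) -> TransitionCounts:
    """Count adjacent symbol pairs within each sequence.

    Boundaries between sequences (ADLs or sessions) contribute no pair: the
    chain models transitions inside continuous movement, and concatenation
    order must not create spurious transitions.
    """
    if isinstance(seqs, SyllableSequence):
        seqs = [seqs]
    counts = np.zeros((k, k), dtype=np.int64)
    for s in seqs:
        sym = s.symbols
        if sym.size and sym.max() >= k:
            raise ValidationError(
                f"symbol out of vocabulary: {int(sym.max())} >= k={k}"
            )
        if sym.size >= 2:
            np.add.at(counts, (sym[:-1], sym[1:]), 1)
    return TransitionCounts(counts=counts)


def estimate_transition_matrix(
    c: TransitionCounts, eps: float = 1e-10
) -> TransitionMatrix:
    """Maximum-likelihood rates with additive smoothing of unseen entries.

    P(a,b) = N(a,b) / N_a for observed rows; eps is then added to every zero
    entry and rows renormalized, so all entries are strictly positive and the
    chain irreducible.  A syllable never observed as a source (N_a = 0) gets
    a uniform row -- with no evidence, any destination is equally likely.
    """
    if c.k < 2:
        raise ValidationError("need k >= 2")
    counts = c.counts.astype(float)
    totals = c.row_totals.astype(float)
    P = np.full((c.k, c.k), 1.0 / c.k)
    seen = totals > 0
    P[seen] = counts[seen] / totals[seen, None]
    zero = P == 0.0
    if zero.any():
        P[zero] = eps
        P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P=P, smoothing_eps=eps)


def stationary_distribution(tm: TransitionMatrix) -> SMR:
    """Solve pi = pi P for the unique stationary distribution.

    For a row-stochastic P the stationary law is the left eigenvector at
    eigenvalue 1.  It is computed as the linear system (I - P^T) pi = 0 with
    one equation replaced by the normalization sum(pi) = 1; if that system is
    singular to working precision a least-squares solve of the full stacked
    system is used instead.  Power iteration exists separately as an
    independent oracle, never on this path.
    """
    tm.validate()
    k = tm.k
    A = np.eye(k) - tm.P.T
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    try:
        lu, piv = linalg.lu_factor(A)
        pi = linalg.lu_solve((lu, piv), b)
        # one step of iterative refinement: near-absorbing chains make A
        # ill-conditioned and the raw solve can be off by ~cond * eps_machine
        r = b - A @ pi
        pi = pi + linalg.lu_solve((lu, piv), r)
    except linalg.LinAlgError:
        A2 = np.vstack([np.eye(k) - tm.P.T, np.ones((1, k))])
        b2 = np.concatenate([np.zeros(k), [1.0]])
        pi, *_ = linalg.lstsq(A2, b2)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = float(np.abs(pi - pi @ tm.P).sum())
    if resid > _STATIONARY_TOL:
        raise ComputationError(f"stationary solve residual {resid:.2e}")
    return SMR(pi=pi)


def stationary_power_iteration(
    tm: TransitionMatrix, tol: float = 1e-12, max_iter: int = 1_000_000
) -> np.ndarray:
    """Independent power-iteration oracle for the stationary distribution."""
    pi = np.full(tm.k, 1.0 / tm.k)
    for _ in range(max_iter):
        nxt = pi @ tm.P
        nxt /= nxt.sum()
        if np.abs(nxt - pi).sum() < tol:
            return nxt
        pi = nxt
    return pi


def smr_from_sequences(
    seqs: list[SyllableSequence] | SyllableSequence,
    k: int,
    eps: float = 1e-10,
    session_id: str = "",
) -> SMR:
    """Sequences -> counts -> smoothed chain -> stationary distribution."""
    if isinstance(seqs, SyllableSequence):
        seqs = [seqs]
    counts = count_transitions(seqs, k)
    tm = estimate_transition_matrix(counts, eps)
    smr = stationary_distribution(tm)
    smr.session_id = session_id or (seqs[0].session_id if seqs else "")
    smr.adl_labels = tuple(s.adl_label or "" for s in seqs)
    return smr


def smr_distance(p: SMR | np.ndarray, q: SMR | np.ndarray) -> float:
    """L1 distance between two SMRs: sum_i |p_i - q_i| (range [0, 2]).

    The total-variation distance on a finite space is half this value; the
    unhalved L1 norm is reported, matching the dissimilarity definition used
    throughout.
    """
    pv = p.pi if isinstance(p, SMR) else np.asarray(p, float)
    qv = q.pi if isinstance(q, SMR) else np.asarray(q, float)
    if pv.shape != qv.shape:
        raise ValidationError("dimension mismatch")
    return float(np.abs(pv - qv).sum())


def dissimilarity_matrix(
    smrs: list[SMR], order_by_reference: list[SMR] | None = None
) -> DissimilarityMatrix:
    """All pairwise L1 distances between SMRs.

    If ``order_by_reference`` is given (e.g. the healthy participants'
    SMRs), rows/columns are sorted by distance from the mean reference SMR,
    which makes severity gradients visible in the matrix image.
    """
    if not smrs:
        raise ValidationError("empty SMR list")
    ks = {s.k for s in smrs}
    if len(ks) > 1:
        raise ValidationError("SMRs have differing k")
    X = np.vstack([s.pi for s in smrs])
    ids = [s.session_id for s in smrs]
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    if order_by_reference is not None:
        ref = np.mean([r.pi for r in order_by_reference], axis=0)
        order = np.argsort(np.abs(X - ref[None, :]).sum(axis=1), kind="stable")
        D = D[np.ix_(order, order)]
        ids = [ids[i] for i in order]
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DissimilarityMatrix(session_ids=tuple(ids), D=D)


def smr_stability_curve(
    adl_seqs: list[SyllableSequence],
    k: int,
    n_shuffles: int = 50,
    seed: int = 0,
    eps: float = 1e-10,
) -> np.ndarray:
    """Variance of the leading principal component of m-ADL SMRs, for each m.

    For m = 1..len(adl_seqs): shuffle the ADL order ``n_shuffles`` times,
    build the SMR of the first m ADLs of each shuffle, project the resulting
    SMRs onto their first principal component, and record the variance along
    it.  A curve decaying toward zero means the SMR estimator stabilizes as
    more activities are pooled (at m = all ADLs every shuffle pools the same
    set, so the variance is exactly zero).
    """
    if len(adl_seqs) < 2:
        raise ValidationError("need at least 2 ADL sequences")
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    M = len(adl_seqs)
    curve = np.empty(M)
    for m in range(1, M + 1):
        smrs = np.empty((n_shuffles, k))
        for j in range(n_shuffles):
            order = rng.permutation(M)[:m]
            subset = [adl_seqs[i] for i in order]
            smrs[j] = smr_from_sequences(subset, k, eps).pi
        centered = smrs - smrs.mean(axis=0, keepdims=True)
        # leading PC variance = largest eigenvalue of the covariance
        sv = np.linalg.svd(centered, compute_uv=False)
        curve[m - 1] = float(sv[0] ** 2 / max(n_shuffles - 1, 1))
    return curve
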