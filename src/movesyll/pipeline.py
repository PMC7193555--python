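"""End-to-end pipelines tying the stages together.

``run_inclinic_pipeline`` executes preprocess -> tokenize -> markov ->
embed/regress for a scripted-activity cohort: the vocabulary is learned from
the pooled healthy participants, each session is summarized as one SMR over
its activities, sessions are compared by L1 distance, embedded with 3-D MDS,
and severity is regressed on the coordinates.

``run_athome_pipeline`` handles the continuous-monitoring protocol: the
vocabulary is learned from the least-affected participant, each participant's
stream is cut into 30-minute clock segments with per-segment SMRs, all
segments are embedded jointly, and night / day / combined severity models are
fitted on phase-averaged coordinates with Cook's-distance QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from movesyll import io as msio
from movesyll.config import PipelineConfig
from movesyll.embed_regress import (
    Embedding3D,
    PhaseWindows,
    SeverityModel,
    fit_severity_model,
    flag_outliers_cook,
    mds_embed,
    phase_severity_models,
    segment_athome_stream,
)
from movesyll.errors import ValidationError
from movesyll.markov import (
    SMR,
    DissimilarityMatrix,
    dissimilarity_matrix,
    smr_from_sequences,
)
from movesyll.preprocess import RawRecording, preprocess_recording
from movesyll.tokenize import (
    SyllableSequence,
    SyllableVocabulary,
    assign_syllables,
    fit_vocabulary,
)

__all__ = [
    "InclinicResult",
    "AthomeResult",
    "run_inclinic_pipeline",
    "run_athome_pipeline",
]


@dataclass
class InclinicResult:
    vocabulary: SyllableVocabulary
    sequences: list[SyllableSequence]
    smrs: list[SMR]
    dissimilarity: DissimilarityMatrix
    embedding: Embedding3D
    model: SeverityModel
    scores: dict[str, float]


@dataclass
class AthomeResult:
    vocabulary: SyllableVocabulary
    phase_windows: list[PhaseWindows]
    embedding: Embedding3D
    models: dict[str, SeverityModel]
    flagged: list[str]
    scores: dict[str, float]


def _session_scores(manifest: pd.DataFrame) -> dict[str, float]:
    """Score per session: manifest value for PD, 0 for healthy participants."""
    out: dict[str, float] = {}
    for sid, grp in manifest.groupby("session_id", sort=False):
        row = grp.iloc[0]
        raw = row.get("score_total", "")
        if row["group"] == "healthy" or raw in ("", None) or pd.isna(raw):
            out[str(sid)] = 0.0
        else:
            out[str(sid)] = float(raw)
    return out


def _scores_for_session(manifest: pd.DataFrame, session_id: str):
    """Build ClinicalScores for one session from the manifest's score columns.

    Healthy participants (or sessions without scores) enter with all-zero
    subscores, mirroring the assumption that unrated healthy participants
    score 0.
    """
    from movesyll.embed_regress import ClinicalScores

    grp = manifest[manifest["session_id"].astype(str) == session_id]
    row = grp.iloc[0]

    def val(col: str) -> float:
        raw = row.get(col, "")
        if row["group"] == "healthy" or raw in ("", None) or pd.isna(raw):
            return 0.0
        return float(raw)

    return ClinicalScores(
        participant_id=str(row["participant_id"]),
        bradykinesia=val("score_brady"),
        tremor=val("score_tremor"),
        pigd=val("score_pigd"),
        facial=val("score_facial"),
        speech=val("score_speech"),
    )


def _preprocess_all(
    recordings: list[RawRecording],
    manifest: pd.DataFrame,
    cfg: PipelineConfig,
) -> list:
    labels = (
        manifest["adl_label"].tolist()
        if "adl_label" in manifest.columns
        else [None] * len(recordings)
    )
    windows = []
    for rec, label in zip(recordings, labels):
        ws = preprocess_recording(
            rec,
            rate_hz=cfg.rate_hz,
            low_hz=cfg.band_low_hz,
            high_hz=cfg.band_high_hz,
            order=cfg.filter_order,
            window_s=cfg.window_s,
            step_s=cfg.step_s,
        )
        ws.adl_label = None if label in (None, "") else str(label)
        windows.append(ws)
    return windows


def run_inclinic_pipeline(
    manifest: pd.DataFrame,
    recordings: list[RawRecording],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    target: str = "total",
) -> InclinicResult:
    """Scripted-activity pipeline (vocabulary from the healthy pool)."""
    cfg = cfg or PipelineConfig()
    if len(recordings) != len(manifest):
        raise ValidationError("one manifest row per recording required")
    windows = _preprocess_all(recordings, manifest, cfg)

    healthy_idx = [
        i for i, g in enumerate(manifest["group"]) if str(g) == "healthy"
    ]
    train_idx = healthy_idx if healthy_idx else list(range(len(windows)))
    vocab = fit_vocabulary(
        [windows[i] for i in train_idx],
        k=cfg.k,
        seed=cfg.seed,
        training_source="healthy_pool",
    )

    sequences = [assign_syllables(ws, vocab) for ws in windows]

    session_ids = list(dict.fromkeys(manifest["session_id"].astype(str)))
    smrs = []
    for sid in session_ids:
        seqs = [
            s for s, msid in zip(sequences, manifest["session_id"].astype(str))
            if msid == sid
        ]
        smrs.append(
            smr_from_sequences(seqs, vocab.k, cfg.smoothing_eps, session_id=sid)
        )

    D = dissimilarity_matrix(smrs)
    emb = mds_embed(D, dims=cfg.mds_dims, flavor=cfg.mds_flavor, seed=cfg.seed)
    scores = _session_scores(manifest)
    score_objs = [_scores_for_session(manifest, sid) for sid in emb.session_ids]
    model = fit_severity_model(emb, score_objs, target=target)

    result = InclinicResult(
        vocabulary=vocab, sequences=sequences, smrs=smrs,
        dissimilarity=D, embedding=emb, model=model, scores=scores,
    )
    if out_dir is not None:
        _write_inclinic(result, cfg, Path(out_dir))
    return result


def _write_inclinic(res: InclinicResult, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    msio.write_vocabulary(res.vocabulary, out / "vocabulary.json")
    msio.write_sequences(res.sequences, out / "sequences.csv", **meta)
    msio.write_smrs(res.smrs, out / "smr.tsv", **meta)
    msio.write_dissimilarity(res.dissimilarity, out / "dissimilarity.tsv", **meta)
    msio.write_embedding(res.embedding, out / "embedding.tsv", **meta)
    msio.write_model_report(res.model, out / "model.json", cfg.cook_threshold)


def run_athome_pipeline(
    manifest: pd.DataFrame,
    recordings: list[RawRecording],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> AthomeResult:
    """Continuous-monitoring pipeline (vocabulary from the least-affected
    participant; joint MDS over all 30-minute segments)."""
    cfg = cfg or PipelineConfig()
    if len(recordings) != len(manifest):
        raise ValidationError("one manifest row per recording required")
    windows = _preprocess_all(recordings, manifest, cfg)

    pids = manifest["participant_id"].astype(str)
    scores: dict[str, float] = {}
    for pid, grp in manifest.groupby("participant_id", sort=False):
        raw = grp.iloc[0].get("score_total", "")
        scores[str(pid)] = (
            0.0 if raw in ("", None) or pd.isna(raw) else float(raw)
        )
    reference = min(scores, key=lambda p: scores[p])
    train = [w for w, p in zip(windows, pids) if p == reference]
    vocab = fit_vocabulary(
        train, k=cfg.k, seed=cfg.seed,
        training_source=f"reference_participant:{reference}",
    )

    phase_windows: list[PhaseWindows] = []
    for pid in dict.fromkeys(pids):
        seqs = [
            assign_syllables(w, vocab)
            for w, p in zip(windows, pids)
            if p == pid
        ]
        stream = SyllableSequence(
            session_id=pid,
            symbols=np.concatenate([s.symbols for s in seqs]),
            start_times=np.concatenate([s.start_times for s in seqs]),
            k=vocab.k,
        )
        order = np.argsort(stream.start_times, kind="stable")
        stream.symbols = stream.symbols[order]
        stream.start_times = stream.start_times[order]
        phase_windows.append(
            segment_athome_stream(
                stream, vocab.k,
                window_minutes=cfg.segment_minutes,
                night_span=cfg.night_span,
                day_span=cfg.day_span,
                min_transitions=cfg.min_segment_transitions,
                eps=cfg.smoothing_eps,
            )
        )

    all_smrs = [
        SMR(pi=pw.smrs[i], session_id=pw.participant_id)
        for pw in phase_windows
        for i in range(pw.smrs.shape[0])
    ]
    D = dissimilarity_matrix(all_smrs)
    emb = mds_embed(D, dims=cfg.mds_dims, flavor=cfg.mds_flavor, seed=cfg.seed)

    models = {
        mode: phase_severity_models(phase_windows, emb, scores, mode=mode)
        for mode in ("night", "day", "both")
    }
    flagged = flag_outliers_cook(models["both"], cfg.cook_threshold)

    result = AthomeResult(
        vocabulary=vocab, phase_windows=phase_windows, embedding=emb,
        models=models, flagged=flagged, scores=scores,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
        msio.write_vocabulary(result.vocabulary, out / "vocabulary.json")
        msio.write_embedding(emb, out / "segments_embedding.tsv", **meta)
        for mode, model in models.items():
            msio.write_model_report(
                model, out / f"model_{mode}.json", cfg.cook_threshold
            )
    return result
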