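"""Readers and writers for the plain-text interchange formats.

All tabular outputs are TSV/CSV with a small metadata header of ``#`` comment
lines (tool version, config hash, seeds) so any result file states its own
provenance.  Canonical formats:

- accelerometer CSV: ``time_s,ax,ay,az`` one row per sample (.gz accepted);
- session manifest CSV: participant/session/group/wrist/rate/units/path plus
  optional clinical-score columns (empty for healthy participants);
- vocabulary JSON; sequence CSV; SMR and dissimilarity TSV; embedding TSV;
  model-report JSON.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from movesyll.embed_regress import Embedding3D, SeverityModel
from movesyll.errors import ValidationError
from movesyll.markov import SMR, DissimilarityMatrix
from movesyll.preprocess import RawRecording
from movesyll.tokenize import SyllableSequence, SyllableVocabulary

MANIFEST_COLUMNS = [
    "participant_id", "session_id", "group", "wrist_side", "rate_hz",
    "units", "path",
    "score_total", "score_brady", "score_tremor", "score_pigd",
    "score_facial", "score_speech",
]

SCORE_COLUMNS = MANIFEST_COLUMNS[7:]


def _version() -> str:
    from movesyll import __version__

    return __version__


def metadata_header(**fields: Any) -> str:
    lines = [f"# movesyll {_version()}"]
    for key, val in fields.items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + "\n"


def write_recording_csv(rec: RawRecording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "time_s": rec.t, "ax": rec.accel[:, 0],
        "ay": rec.accel[:, 1], "az": rec.accel[:, 2],
    })
    text = df.to_csv(index=False, float_format="%.6g")
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def read_recording_csv(
    path: str | Path,
    participant_id: str = "",
    session_id: str = "",
    rate_hz: float | None = None,
    wrist_side: str | None = None,
    units: str = "g",
) -> RawRecording:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"recording file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, comment="#")
    expected = ["time_s", "ax", "ay", "az"]
    if list(df.columns[:4]) != expected:
        raise ValidationError(
            f"{path}: expected columns {expected}, got {list(df.columns[:4])}"
        )
    t = df["time_s"].to_numpy(float)
    if rate_hz is None:
        if len(t) < 2:
            raise ValidationError(f"{path}: cannot infer rate from <2 samples")
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return RawRecording(
        participant_id=participant_id,
        session_id=session_id or path.stem,
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        rate_hz=float(rate_hz),
        wrist_side=wrist_side,
        units=units,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str, "session_id": str})
    missing = set(MANIFEST_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    units = df["units"].dropna().unique()
    if len(units) > 1:
        raise ValidationError(f"mixed units in manifest: {sorted(units)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path, **meta: Any) -> None:
    Path(path).write_text(
        metadata_header(**meta) + df.to_csv(index=False)
    )


def load_manifest_recordings(
    manifest: pd.DataFrame, base_dir: str | Path | None = None
) -> list[RawRecording]:
    """Read every recording a manifest references (paths relative to base_dir)."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    recs = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        try:
            recs.append(read_recording_csv(
                p,
                participant_id=str(row["participant_id"]),
                session_id=str(row["session_id"]),
                rate_hz=float(row["rate_hz"]),
                wrist_side=str(row["wrist_side"]),
                units=str(row["units"]),
            ))
        except ValidationError as exc:
            raise ValidationError(
                f"session {row['session_id']}: {exc}"
            ) from exc
    return recs


def write_vocabulary(vocab: SyllableVocabulary, path: str | Path) -> None:
    obj = {
        "tool": f"movesyll {_version()}",
        "k": vocab.k,
        "seed": vocab.seed,
        "units": vocab.units,
        "training_source": vocab.training_source,
        "training_sessions": list(vocab.training_sessions),
        "inertia": vocab.inertia,
        "centroids": vocab.centroids.tolist(),
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_vocabulary(path: str | Path) -> SyllableVocabulary:
    obj = json.loads(Path(path).read_text())
    vocab = SyllableVocabulary(
        centroids=np.asarray(obj["centroids"], dtype=float),
        seed=int(obj["seed"]),
        training_source=obj.get("training_source", "healthy_pool"),
        training_sessions=tuple(obj.get("training_sessions", ())),
        units=obj.get("units", "g"),
        inertia=obj.get("inertia"),
    )
    if vocab.k != int(obj["k"]):
        raise ValidationError("vocabulary file inconsistent: k != len(centroids)")
    return vocab


def write_sequences(seqs: list[SyllableSequence], path: str | Path, **meta: Any) -> None:
    frames = [
        pd.DataFrame({
            "session_id": s.session_id,
            "adl_label": s.adl_label or "",
            "start_time_s": s.start_times,
            "symbol": s.symbols,
        })
        for s in seqs
    ]
    df = pd.concat(frames, ignore_index=True)
    Path(path).write_text(metadata_header(**meta) + df.to_csv(index=False))


def read_sequences(path: str | Path, k: int) -> list[SyllableSequence]:
    df = pd.read_csv(path, comment="#", dtype={"session_id": str})
    df["adl_label"] = df.get("adl_label", "").fillna("")
    out = []
    for (sid, adl), grp in df.groupby(["session_id", "adl_label"], sort=False):
        out.append(SyllableSequence(
            session_id=str(sid),
            symbols=grp["symbol"].to_numpy(np.int64),
            start_times=grp["start_time_s"].to_numpy(float),
            k=k,
            adl_label=str(adl) or None,
        ))
    return out


def write_smrs(smrs: list[SMR], path: str | Path, **meta: Any) -> None:
    rows = [[s.session_id, *s.pi.tolist()] for s in smrs]
    k = smrs[0].k if smrs else 0
    df = pd.DataFrame(rows, columns=["session_id", *[f"p{i}" for i in range(k)]])
    Path(path).write_text(
        metadata_header(**meta) + df.to_csv(index=False, sep="\t")
    )


def read_smrs(path: str | Path) -> list[SMR]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"session_id": str})
    return [
        SMR(pi=row.iloc[1:].to_numpy(float), session_id=str(row.iloc[0]))
        for _, row in df.iterrows()
    ]


def write_dissimilarity(D: DissimilarityMatrix, path: str | Path, **meta: Any) -> None:
    df = pd.DataFrame(D.D, index=list(D.session_ids), columns=list(D.session_ids))
    Path(path).write_text(
        metadata_header(**meta) + df.to_csv(sep="\t", index_label="session_id")
    )


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return DissimilarityMatrix(
        session_ids=tuple(str(c) for c in df.columns),
        D=df.to_numpy(float),
    )


def write_embedding(emb: Embedding3D, path: str | Path, **meta: Any) -> None:
    dims = emb.coords.shape[1]
    df = pd.DataFrame(
        emb.coords, columns=[f"m{i + 1}" for i in range(dims)]
    )
    df.insert(0, "session_id", list(emb.session_ids))
    head = metadata_header(
        flavor=emb.flavor, stress=emb.stress,
        clamped_eigenmass=emb.clamped_eigenmass, **meta,
    )
    Path(path).write_text(head + df.to_csv(index=False, sep="\t"))


def read_embedding(path: str | Path) -> Embedding3D:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"session_id": str})
    return Embedding3D(
        session_ids=tuple(df["session_id"]),
        coords=df.drop(columns="session_id").to_numpy(float),
    )


def write_model_report(model: SeverityModel, path: str | Path, threshold: float = 0.16) -> None:
    from movesyll.embed_regress import flag_outliers_cook

    obj = {
        "tool": f"movesyll {_version()}",
        "target": model.target,
        "coefficients": model.params.tolist(),
        "r_squared": model.r_squared,
        "loocv_r_squared": model.loocv_r_squared,
        "cooks_distances": dict(
            zip(model.observation_ids, model.cooks_distances.tolist())
        ),
        "cook_threshold": threshold,
        "flagged": flag_outliers_cook(model, threshold),
    }
    Path(path).write_text(json.dumps(obj, indent=1))
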