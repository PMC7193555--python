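"""Synthetic movement-cohort simulator.

Generates everything the pipeline consumes, with no clinical data: a set of
band-limited syllable waveform templates, per-participant Markov grammars
whose disorder grows with a severity parameter in [0, 1], rendered tri-axial
accelerometer recordings (template concatenation with crossfades plus sensor
noise, emitted at a device rate), UPDRS-like severity scores linear in the
severity parameter, and an at-home circadian mode where a low-amplitude
"rest" syllable dominates the night hours.

The disorder model interpolates each participant's base grammar toward the
uniform transition matrix -- the simplest one-parameter family in which
transitions become increasingly disorganized while the chain stays
irreducible.  Severity also shrinks movement amplitude by a factor
(1 - 0.3 s) to mimic bradykinesia (configurable off, so grammar-only effects
can be isolated).

All randomness flows from one master seed through per-participant spawned
seeds, so a cohort can be extended without reshuffling existing participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from movesyll.errors import ValidationError
from movesyll.markov import TransitionMatrix
from movesyll.preprocess import RawRecording

__all__ = [
    "SyllableTemplate",
    "CohortConfig",
    "make_templates",
    "make_base_grammar",
    "make_grammar",
    "simulate_session",
    "simulate_cohort",
]


@dataclass
class SyllableTemplate:
    """One second of band-limited 3-axis waveform defining a syllable."""

    template_id: int
    waveform: np.ndarray  # (L, 3) samples at the analysis rate

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 2 or self.waveform.shape[1] != 3:
            raise ValidationError("waveform must be (L, 3)")


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults describe the in-clinic emulation: 40 participants (8 healthy
    with severity 0, 32 affected with severities spanning (0, 0.8]), 12
    scripted activities of 30 s each, 24 true syllable templates at ~0.5 g
    RMS, 0.05 g sensor noise, device rate 250 Hz, and a score map
    total = 50 * severity + N(0, 2^2) clamped at 0 -- yielding the 0-45
    score range typical of a moderate-severity Parkinson cohort.
    """

    n_participants: int = 40
    n_healthy: int = 8
    max_severity: float = 0.8
    k_true: int = 24
    n_adls: int = 12
    adl_duration_s: float = 30.0
    render_noise_sd: float = 0.05
    template_rms_g: float = 0.5
    device_rate_hz: float = 250.0
    rate_hz: float = 25.0
    window_s: float = 1.0
    score_slope: float = 50.0
    score_intercept: float = 0.0
    score_noise_sd: float = 2.0
    amplitude_decline: float = 0.3   # bradykinesia: amplitude * (1 - this * s)
    personal_grammar_weight: float = 0.05
    seed: int = 0
    # at-home mode
    athome: bool = False
    n_days: int = 2
    night_block_hours: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    day_block_hours: tuple[float, ...] = (8.5, 10.0, 12.0, 14.0, 16.0, 18.0)
    block_minutes: int = 30

    def severities(self) -> np.ndarray:
        """Severity per participant: healthy zeros then an even PD gradient."""
        n_pd = self.n_participants - (0 if self.athome else self.n_healthy)
        if self.athome:
            # the continuous-monitoring cohort is all-PD with graded severity
            return np.linspace(self.max_severity / n_pd, self.max_severity, n_pd)
        if n_pd <= 0:
            return np.zeros(self.n_participants)
        pd_sev = np.linspace(self.max_severity / n_pd, self.max_severity, n_pd)
        return np.concatenate([np.zeros(self.n_healthy), pd_sev])


def _participant_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    )


def make_templates(
    k: int,
    rate_hz: float = 25.0,
    window_s: float = 1.0,
    seed: int = 0,
    rms_g: float = 0.5,
    min_separation: float | None = None,
) -> list[SyllableTemplate]:
    """Draw k distinct band-limited syllable waveforms.

    Each axis is synthesized from random Fourier coefficients confined to the
    0.2-3 Hz pass band of a one-window DFT, so templates survive the
    pipeline's band-pass essentially unchanged (out-of-band energy is zero by
    construction).  Waveforms are scaled to a common RMS amplitude; a redraw
    loop enforces a minimum pairwise L2 separation.
    """
    if k < 2:
        raise ValidationError("need k >= 2 templates")
    rng = np.random.default_rng(seed)
    L = int(round(window_s * rate_hz))
    freqs = np.fft.rfftfreq(L, d=1.0 / rate_hz)
    band = (freqs >= 0.2) & (freqs <= 3.0)
    if min_separation is None:
        # comfortably resolvable by clustering at the default noise level
        min_separation = 1.0 * rms_g * np.sqrt(3 * L)

    def draw() -> np.ndarray:
        spec = np.zeros((freqs.size, 3), dtype=complex)
        coeff = rng.standard_normal((int(band.sum()), 3)) + 1j * rng.standard_normal(
            (int(band.sum()), 3)
        )
        spec[band] = coeff
        wf = np.fft.irfft(spec, n=L, axis=0)
        wf *= rms_g / np.sqrt((wf ** 2).mean())
        return wf

    templates: list[np.ndarray] = []
    attempts = 0
    while len(templates) < k:
        wf = draw()
        if all(
            np.linalg.norm((wf - other).ravel()) >= min_separation * 0.5
            for other in templates
        ):
            templates.append(wf)
        attempts += 1
        if attempts > 100 * k:
            raise ValidationError("could not draw separated templates")
    return [SyllableTemplate(i, wf) for i, wf in enumerate(templates)]


def make_base_grammar(k: int, seed: int = 0, concentration: float = 0.02) -> TransitionMatrix:
    """A structured (sparse-ish) random row-stochastic base grammar.

    Dirichlet rows with small concentration put most mass on a few preferred
    successors per syllable -- an organized movement grammar for severity 0.
    Organized behavior has strongly preferred transitions, so the default
    concentration is low; disorder is then injected by ``make_grammar``.
    """
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.full(k, concentration), size=k)
    P = np.clip(P, 1e-12, None)
    P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P=P, smoothing_eps=0.0)


def make_grammar(base: TransitionMatrix, severity: float) -> TransitionMatrix:
    """Interpolate a base grammar toward uniform: P_s = (1-s) P + s U."""
    if not 0.0 <= severity <= 1.0:
        raise ValidationError(f"severity {severity} outside [0, 1]")
    k = base.k
    U = np.full((k, k), 1.0 / k)
    P = (1.0 - severity) * base.P + severity * U
    return TransitionMatrix(P=P, smoothing_eps=base.smoothing_eps)


def sample_path(
    grammar: TransitionMatrix, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a syllable path of length n_steps from the chain."""
    k = grammar.k
    cdf = np.cumsum(grammar.P, axis=1)
    path = np.empty(n_steps, dtype=np.int64)
    state = int(rng.integers(k))
    for i in range(n_steps):
        path[i] = state
        state = int(np.searchsorted(cdf[state], rng.random()))
        state = min(state, k - 1)
    return path


_CROSSFADE_S = 0.2


def render_path(
    path: np.ndarray,
    templates: list[SyllableTemplate],
    rate_hz: float = 25.0,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Concatenate templates along a path with a 0.2 s linear crossfade.

    Syllable i occupies samples [i*L, (i+1)*L); within the first 0.2 s of
    each syllable the previous template's cyclic continuation is blended in
    linearly, removing concatenation clicks.  A constant path therefore
    renders as an exactly periodic repetition of one template.
    """
    L = templates[0].waveform.shape[0]
    F = int(round(_CROSSFADE_S * rate_hz))
    out = np.empty((len(path) * L, 3))
    for i, s in enumerate(path):
        out[i * L:(i + 1) * L] = templates[int(s)].waveform
    w = (np.arange(1, F + 1) / (F + 1))[:, None]
    for i in range(1, len(path)):
        prev = templates[int(path[i - 1])].waveform[:F]  # cyclic continuation
        cur = templates[int(path[i])].waveform[:F]
        out[i * L:i * L + F] = (1.0 - w) * prev + w * cur
    return out * amplitude_scale


def simulate_session(
    grammar: TransitionMatrix,
    templates: list[SyllableTemplate],
    duration_s: float,
    noise_sd: float = 0.05,
    seed: int = 0,
    device_rate_hz: float = 250.0,
    rate_hz: float = 25.0,
    amplitude_scale: float = 1.0,
    start_time_s: float = 0.0,
    participant_id: str = "sim",
    session_id: str = "sim-session",
    wrist_side: str = "left",
) -> RawRecording:
    """Render one recording: chain path -> crossfaded templates -> noise -> device rate.

    The render happens on the 25 Hz analysis grid; i.i.d. Gaussian sensor
    noise is added per axis, and the result is emitted at the device rate via
    band-limited (polyphase) upsampling, emulating what a wrist sensor would
    deliver to the pipeline.
    """
    L = templates[0].waveform.shape[0]
    window_s = L / rate_hz
    n_syll = int(np.floor(duration_s / window_s))
    if n_syll < 1:
        raise ValidationError("duration shorter than one template")
    rng = np.random.default_rng(seed)
    path = sample_path(grammar, n_syll, rng)
    sig = render_path(path, templates, rate_hz, amplitude_scale)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    if device_rate_hz != rate_hz:
        ratio = device_rate_hz / rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError("device rate must be a multiple of the render rate")
        sig = signal.resample_poly(sig, int(round(ratio)), 1, axis=0)
    if wrist_side == "right":
        # a right-wrist device records the mirrored body frame; the
        # pipeline's harmonization step undoes this flip
        sig = sig.copy()
        sig[:, 1] = -sig[:, 1]
    t = start_time_s + np.arange(sig.shape[0]) / device_rate_hz
    return RawRecording(
        participant_id=participant_id,
        session_id=session_id,
        t=t,
        accel=sig,
        rate_hz=float(device_rate_hz),
        wrist_side=wrist_side,
        units="g",
    )


@dataclass
class SimulatedCohort:
    """In-memory cohort: manifest rows, recordings, and ground truth."""

    manifest: "object"                 # pandas.DataFrame
    recordings: list[RawRecording]
    adl_labels: list[str]              # one per recording
    severities: dict[str, float]       # participant_id -> true severity
    scores: dict[str, float]           # participant_id -> UPDRS-like total
    templates: list[SyllableTemplate]
    config: CohortConfig


def _split_score(total: float, rng: np.random.Generator) -> dict[str, int]:
    """Split a total into integer subscores (brady/tremor/pigd/facial/speech)."""
    props = np.array([0.5, 0.2, 0.2, 0.05, 0.05])
    raw = props * total
    parts = np.floor(raw).astype(int)
    remainder = int(round(total)) - int(parts.sum())
    for i in np.argsort(raw - parts)[::-1][:max(remainder, 0)]:
        parts[i] += 1
    return dict(zip(["brady", "tremor", "pigd", "facial", "speech"], parts.tolist()))


def simulate_cohort(
    cfg: CohortConfig, out_dir: str | Path | None = None
) -> SimulatedCohort:
    """Generate a full cohort (manifest + recordings + scores).

    In-clinic mode renders ``n_adls`` scripted-activity recordings per
    participant, all within one session.  At-home mode renders clock-aligned
    30-minute blocks across ``n_days`` days, with night blocks drawn from a
    rest-dominated grammar (template 0 is shrunk to a rest syllable).

    If ``out_dir`` is given, recordings and the manifest are written in the
    pipeline's CSV dialects; generation is byte-reproducible from the master
    seed either way.
    """
    import pandas as pd

    templates = make_templates(
        cfg.k_true, cfg.rate_hz, cfg.window_s, seed=cfg.seed,
        rms_g=cfg.template_rms_g,
    )
    if cfg.athome:
        # template 0 becomes a low-amplitude rest syllable for the night mode
        templates[0] = SyllableTemplate(0, templates[0].waveform * 0.04)
    base = make_base_grammar(cfg.k_true, seed=cfg.seed + 1)
    severities = cfg.severities()

    rows, recordings, adl_labels = [], [], []
    sev_map, score_map = {}, {}
    for idx in range(cfg.n_participants):
        rng = _participant_rng(cfg.seed, idx)
        pid = f"P{idx:03d}"
        s = float(severities[idx])
        healthy = idx < cfg.n_healthy and not cfg.athome
        sev_map[pid] = s
        # personal grammar: participant-specific deviation from the base
        pers = rng.dirichlet(np.full(cfg.k_true, 0.5), size=cfg.k_true)
        w = cfg.personal_grammar_weight
        P_p = TransitionMatrix(P=(1 - w) * base.P + w * pers)
        grammar = make_grammar(P_p, s)
        amp = 1.0 - cfg.amplitude_decline * s
        if healthy:
            score = 0.0
        else:
            score = cfg.score_intercept + cfg.score_slope * s + rng.normal(
                0.0, cfg.score_noise_sd
            )
            score = max(score, 0.0)
        score_map[pid] = score
        sub = _split_score(score, rng)
        wrist = "left" if idx % 2 == 0 else "right"
        group = "healthy" if healthy else "pd"

        def add_recording(rec: RawRecording, label: str) -> None:
            recordings.append(rec)
            adl_labels.append(label)
            rows.append({
                "participant_id": pid,
                "session_id": rec.session_id,
                "group": group,
                "wrist_side": wrist,
                "rate_hz": rec.rate_hz,
                "units": "g",
                "path": f"{rec.session_id}_{label}.csv",
                "score_total": "" if healthy else int(round(score)),
                "score_brady": "" if healthy else sub["brady"],
                "score_tremor": "" if healthy else sub["tremor"],
                "score_pigd": "" if healthy else sub["pigd"],
                "score_facial": "" if healthy else sub["facial"],
                "score_speech": "" if healthy else sub["speech"],
                "adl_label": label,
            })

        if not cfg.athome:
            sid = f"{pid}-visit1"
            for a in range(cfg.n_adls):
                rec = simulate_session(
                    grammar, templates, cfg.adl_duration_s,
                    noise_sd=cfg.render_noise_sd,
                    seed=int(rng.integers(2 ** 31)),
                    device_rate_hz=cfg.device_rate_hz,
                    rate_hz=cfg.rate_hz,
                    amplitude_scale=amp,
                    participant_id=pid,
                    session_id=sid,
                    wrist_side=wrist,
                )
                add_recording(rec, f"adl{a:02d}")
        else:
            sid = f"{pid}-home"
            k = cfg.k_true
            # night grammar: mostly the rest syllable; rest weight declines
            # with severity (disturbed sleep moves more)
            rest_w = 0.85 - 0.3 * s
            R = np.zeros((k, k))
            R[:, 0] = 1.0
            Pn = rest_w * R + (1 - rest_w) * grammar.P
            night = TransitionMatrix(P=Pn / Pn.sum(axis=1, keepdims=True))
            block_s = cfg.block_minutes * 60.0
            for day in range(cfg.n_days):
                day0 = day * 86400.0
                for hours, gram in (
                    (cfg.night_block_hours, night),
                    (cfg.day_block_hours, grammar),
                ):
                    for h in hours:
                        start = day0 + h * 3600.0
                        rec = simulate_session(
                            gram, templates, block_s,
                            noise_sd=cfg.render_noise_sd,
                            seed=int(rng.integers(2 ** 31)),
                            device_rate_hz=cfg.device_rate_hz,
                            rate_hz=cfg.rate_hz,
                            amplitude_scale=amp,
                            start_time_s=start,
                            participant_id=pid,
                            session_id=sid,
                            wrist_side=wrist,
                        )
                        add_recording(rec, f"d{day}h{h:04.1f}")

    manifest = pd.DataFrame(rows)
    cohort = SimulatedCohort(
        manifest=manifest, recordings=recordings, adl_labels=adl_labels,
        severities=sev_map, scores=score_map, templates=templates, config=cfg,
    )
    if out_dir is not None:
        from movesyll import io as msio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(recordings, rows):
            msio.write_recording_csv(rec, out / row["path"])
        msio.write_manifest(manifest, out / "manifest.csv", seed=cfg.seed)
    return cohort
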