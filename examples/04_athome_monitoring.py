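"""At-home circadian monitoring on a synthetic cohort.

Simulates continuous wrist data for 10 participants over 2 days (rest-
dominated nights, active days), cuts each stream into 30-minute clock
segments, embeds all segment SMRs jointly, and fits night-only, day-only,
and combined severity models.
"""

import collections

from movesyll import PipelineConfig
from movesyll.pipeline import run_athome_pipeline
from movesyll.simulate import CohortConfig, simulate_cohort

cfg = CohortConfig(athome=True, n_participants=10, n_days=2,
                   device_rate_hz=25.0, seed=5)
cohort = simulate_cohort(cfg)
res = run_athome_pipeline(cohort.manifest, cohort.recordings,
                          PipelineConfig(seed=5))

phases = collections.Counter(
    p for pw in res.phase_windows for p in pw.phases.tolist()
)
print(f"participants: {len(res.phase_windows)}, segments: {dict(phases)}")
print("(nocturnal = starts 00:00-06:00, diurnal = 08:00-20:00)")
for mode, model in res.models.items():
    print(f"{mode:>5} model r^2 = {model.r_squared:.3f}")
print(f"Cook's-distance flags (> 0.16): {res.flagged or 'none'}")
print("combining day and night coordinates should explain at least as much")
print("score variance as either phase alone; with 10 participants and 6")
print("predictors the combined fit is near-saturated, so influence flags")
print("are common at this cohort size.")
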