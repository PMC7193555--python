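"""In-clinic pipeline on a small synthetic cohort.

Simulates a 12-participant scripted-activity cohort (4 healthy, 8 with
graded severity), runs the full pipeline — preprocessing, healthy-pool
vocabulary, per-session SMRs, L1 dissimilarities, 3-D MDS, severity
regression — and prints the model fit.
"""

import numpy as np
from scipy.stats import spearmanr

from movesyll import PipelineConfig, smr_distance
from movesyll.pipeline import run_inclinic_pipeline
from movesyll.simulate import CohortConfig, simulate_cohort

cfg = CohortConfig(n_participants=12, n_healthy=4, n_adls=8,
                   adl_duration_s=30.0, seed=7)
cohort = simulate_cohort(cfg)
res = run_inclinic_pipeline(cohort.manifest, cohort.recordings,
                            PipelineConfig(seed=7))

print(f"sessions: {len(res.smrs)}, vocabulary k = {res.vocabulary.k}")
print(f"severity model  r^2 = {res.model.r_squared:.3f} "
      f"(leave-one-out r^2 = {res.model.loocv_r_squared:.3f})")

healthy = res.smrs[:4]
ref = np.mean([h.pi for h in healthy], axis=0)
sids = [s.session_id for s in res.smrs]
sev = [cohort.severities[s.split("-")[0]] for s in sids]
d = [float(np.abs(s.pi - ref).sum()) for s in res.smrs]
rho = spearmanr(d, sev).statistic
print(f"Spearman rho, distance-from-healthy vs true severity: {rho:.3f}")
print("r^2 close to 1 means the 3 MDS coordinates linearly encode the")
print("severity score; rho > 0 means more affected participants sit farther")
print("from the healthy movement grammar in SMR space.")
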