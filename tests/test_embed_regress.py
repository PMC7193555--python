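"""MDS embedding, severity regression, UPDRS sums, QC, circadian segmentation."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from movesyll.embed_regress import (
    ClinicalScores,
    Embedding3D,
    UPDRS3_ITEMS,
    fit_severity_model,
    flag_outliers_cook,
    mds_embed,
    phase_severity_models,
    segment_athome_stream,
    total_updrs3,
)
from movesyll.errors import ValidationError
from movesyll.markov import SMR, DissimilarityMatrix
from movesyll.tokenize import SyllableSequence


def all_items(value=0):
    return {item: value for items in UPDRS3_ITEMS.values() for item in items}


class TestUpdrsSums:
    def test_all_zero(self):
        s = total_updrs3(all_items(0))
        assert s.total == 0

    def test_subscore_sums_add_up(self):
        items = all_items(0)
        brady = UPDRS3_ITEMS["bradykinesia"]
        for it in brady[:10]:
            items[it] = 1
        for it in UPDRS3_ITEMS["tremor"][:5]:
            items[it] = 1
        for it in UPDRS3_ITEMS["pigd"][:4]:
            items[it] = 1
        items["Facial Expression Score"] = 1
        items["Speech Score"] = 1
        s = total_updrs3(items)
        assert (s.bradykinesia, s.tremor, s.pigd, s.facial, s.speech) == (10, 5, 4, 1, 1)
        assert s.total == 21

    def test_unknown_item_rejected(self):
        items = all_items(0)
        items["Foo Score"] = 2
        with pytest.raises(ValidationError, match="unknown UPDRS item"):
            total_updrs3(items)

    def test_missing_item_rejected(self):
        items = all_items(0)
        items.pop("Posture")
        with pytest.raises(ValidationError, match="missing"):
            total_updrs3(items)


def euclidean_dissimilarity(points):
    ids = tuple(f"s{i}" for i in range(points.shape[0]))
    return DissimilarityMatrix(
        session_ids=ids, D=squareform(pdist(points))
    )


class TestMds:
    def test_classical_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5, 3))
        D = euclidean_dissimilarity(pts)
        emb = mds_embed(D, dims=3, flavor="classical")
        # distances reproduced to numerical precision
        emb_d = squareform(pdist(emb.coords))
        assert np.allclose(emb_d, D.D, atol=1e-8)
        # configuration matches after optimal rigid alignment
        a = emb.coords - emb.coords.mean(axis=0)
        b = pts - pts.mean(axis=0)
        R, _ = orthogonal_procrustes(a, b)
        assert np.allclose(a @ R, b, atol=1e-8)

    def test_identical_smrs_coincide(self):
        p = np.array([0.2, 0.3, 0.5])
        smrs = [SMR(pi=p, session_id=f"s{i}") for i in range(3)]
        smrs.append(SMR(pi=np.array([0.6, 0.2, 0.2]), session_id="other"))
        from movesyll.markov import dissimilarity_matrix

        emb = mds_embed(dissimilarity_matrix(smrs), dims=2)
        assert np.allclose(emb.coords[0], emb.coords[1], atol=1e-6)

    def test_smacof_runs_and_reports_stress(self):
        rng = np.random.default_rng(1)
        D = euclidean_dissimilarity(rng.normal(size=(8, 3)))
        emb = mds_embed(D, dims=3, flavor="smacof", seed=0)
        assert emb.stress >= 0
        assert emb.coords.shape == (8, 3)

    def test_dims_bound(self):
        D = euclidean_dissimilarity(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            mds_embed(D, dims=3)


def linear_embedding(n=40, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n, 3))
    return Embedding3D(
        session_ids=tuple(f"s{i}" for i in range(n)), coords=coords
    ), rng


class TestSeverityModel:
    def test_exactly_linear_target_r2_one(self):
        emb, _ = linear_embedding()
        beta = np.array([2.0, -1.0, 0.5])
        y = 3.0 + emb.coords @ beta
        scores = [
            ClinicalScores(participant_id=s, bradykinesia=float(v))
            for s, v in zip(emb.session_ids, y)
        ]
        m = fit_severity_model(emb, scores, target="bradykinesia")
        assert m.r_squared > 1 - 1e-10
        assert np.allclose(m.params, [3.0, *beta], atol=1e-8)

    def test_null_target_r2_small(self):
        emb, rng = linear_embedding(n=200, seed=3)
        y = rng.permutation(np.arange(200.0))
        scores = [
            ClinicalScores(participant_id=s, tremor=float(v))
            for s, v in zip(emb.session_ids, y)
        ]
        m = fit_severity_model(emb, scores, target="tremor")
        # expectation ~ p/(n-1) = 3/199
        assert m.r_squared < 0.05
        assert m.loocv_r_squared < m.r_squared

    def test_loo_consistent_with_refit_oracle(self):
        emb, rng = linear_embedding(n=30, seed=5)
        y = emb.coords @ np.array([1.0, 2.0, 0.0]) + rng.normal(0, 0.5, 30)
        scores = [
            ClinicalScores(participant_id=s, pigd=float(v))
            for s, v in zip(emb.session_ids, y)
        ]
        m = fit_severity_model(emb, scores, target="pigd")
        # brute-force leave-one-out PRESS
        X = np.column_stack([np.ones(30), emb.coords])
        press = 0.0
        for i in range(30):
            keep = np.arange(30) != i
            beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            press += (y[i] - X[i] @ beta) ** 2
        loo_oracle = 1.0 - press / ((y - y.mean()) ** 2).sum()
        assert abs(m.loocv_r_squared - loo_oracle) < 1e-8

    def test_residuals_sum_to_zero(self):
        emb, rng = linear_embedding(n=25, seed=8)
        y = rng.normal(size=25)
        scores = [
            ClinicalScores(participant_id=s, bradykinesia=float(v))
            for s, v in zip(emb.session_ids, y)
        ]
        m = fit_severity_model(emb, scores, target="total")
        assert abs(m.residuals.sum()) < 1e-8


class TestCookFlags:
    @staticmethod
    def _fit(y, emb):
        scores = [
            ClinicalScores(participant_id=s, bradykinesia=float(v))
            for s, v in zip(emb.session_ids, y)
        ]
        return fit_severity_model(emb, scores, target="bradykinesia")

    def test_homoscedastic_design_unflagged(self):
        emb, rng = linear_embedding(n=100, seed=1)
        y = emb.coords @ np.array([1.0, 1.0, 1.0]) + rng.normal(0, 1, 100)
        m = self._fit(y, emb)
        assert flag_outliers_cook(m, threshold=0.16) == []

    def test_gross_outlier_flagged(self):
        emb, rng = linear_embedding(n=60, seed=2)
        emb.coords[0] = [4.0, 4.0, 4.0]  # leverage point
        y = emb.coords @ np.array([1.0, 1.0, 1.0]) + rng.normal(0, 1, 60)
        y[0] += 10.0
        m = self._fit(y, emb)
        assert "s0" in flag_outliers_cook(m, threshold=0.16)

    def test_infinite_threshold_flags_nothing(self):
        emb, rng = linear_embedding(n=20, seed=4)
        m = self._fit(rng.normal(size=20), emb)
        assert flag_outliers_cook(m, threshold=np.inf) == []


def clocked_sequence(hours, symbols_per_segment=400, k=4, seed=0):
    """One symbol stream with segments starting at the given clock hours."""
    rng = np.random.default_rng(seed)
    syms, times = [], []
    for h in hours:
        start = h * 3600.0
        n = symbols_per_segment
        syms.append(rng.integers(0, k, size=n))
        times.append(start + np.arange(n) * 0.24)
    return SyllableSequence(
        session_id="p1",
        symbols=np.concatenate(syms),
        start_times=np.concatenate(times),
        k=k,
    )


class TestAthomeSegmentation:
    def test_phase_labels_follow_clock_rule(self):
        seq = clocked_sequence([2.0, 10.0, 7.0])
        pw = segment_athome_stream(seq, k=4, min_transitions=10)
        by_clock = dict(zip(pw.start_clock_s / 3600.0, pw.phases))
        assert by_clock[2.0] == "nocturnal"
        assert by_clock[10.0] == "diurnal"
        assert by_clock[7.0] == "excluded"

    def test_segment_count_bounded_by_48_per_day(self):
        hours = [h + d * 24 for d in range(6) for h in np.arange(0, 24, 0.5)]
        seq = clocked_sequence(hours, symbols_per_segment=5)
        pw = segment_athome_stream(seq, k=4, min_transitions=1)
        assert pw.smrs.shape[0] <= 288

    def test_segment_smrs_are_probability_vectors(self):
        seq = clocked_sequence([1.0, 9.0], seed=3)
        pw = segment_athome_stream(seq, k=4, min_transitions=10)
        assert np.allclose(pw.smrs.sum(axis=1), 1.0, atol=1e-9)

    def test_sparse_segment_excluded(self):
        seq = clocked_sequence([2.0], symbols_per_segment=20)
        pw = segment_athome_stream(seq, k=4, min_transitions=100)
        assert list(pw.phases) == ["excluded"]


class TestPhaseModels:
    @staticmethod
    def _cohort(n=8, day_equals_night=False, constant_scores=False, seed=0):
        rng = np.random.default_rng(seed)
        cohort, coords, ids = [], [], []
        scores = {}
        for i in range(n):
            pid = f"p{i}"
            sev = i / (n - 1)
            seq = clocked_sequence([2.0, 3.0, 10.0, 11.0], k=4, seed=100 + i)
            pw = segment_athome_stream(seq, k=4, min_transitions=10)
            night = sev + rng.normal(0, 0.05, (2, 3))
            day = night if day_equals_night else -sev + rng.normal(0, 0.05, (2, 3))
            segs = np.vstack([night, day])
            coords.append(segs)
            ids.extend([pid] * 4)
            cohort.append(pw)
            scores[pid] = 10.0 if constant_scores else 50 * sev
        emb = Embedding3D(session_ids=tuple(ids), coords=np.vstack(coords))
        return cohort, emb, scores

    def test_severity_recovered_in_both_mode(self):
        cohort, emb, scores = self._cohort()
        m_both = phase_severity_models(cohort, emb, scores, mode="both")
        m_night = phase_severity_models(cohort, emb, scores, mode="night")
        m_day = phase_severity_models(cohort, emb, scores, mode="day")
        assert m_both.r_squared >= max(m_night.r_squared, m_day.r_squared) - 0.05

    def test_constant_scores_r2_zero(self):
        cohort, emb, scores = self._cohort(constant_scores=True)
        m = phase_severity_models(cohort, emb, scores, mode="day")
        assert m.r_squared == 0.0

    def test_identical_phases_collinear_design_handled(self):
        cohort, emb, scores = self._cohort(day_equals_night=True)
        m_both = phase_severity_models(cohort, emb, scores, mode="both")
        m_night = phase_severity_models(cohort, emb, scores, mode="night")
        assert abs(m_both.r_squared - m_night.r_squared) < 1e-6

    def test_participant_without_night_excluded_with_warning(self):
        cohort, emb, scores = self._cohort()
        cohort[0].phases[:] = "diurnal"
        with pytest.warns(UserWarning, match="no nocturnal"):
            m = phase_severity_models(cohort, emb, scores, mode="night")
        assert "p0" not in m.observation_ids
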