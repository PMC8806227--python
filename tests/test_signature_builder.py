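"""Screen, LASSO-Cox, risk scoring, cutoff calibration, frozen validation."""

import numpy as np
import pytest

from conftest import make_clinical
from pairhazard.data_model_io import GeneList, SignatureModel, read_signature, write_signature
from pairhazard.errors import AlignmentError, DomainError, NoSignalError
from pairhazard.gene_filtering import filter_genes
from pairhazard.pair_engine import (GenePair, PairScoreMatrix, build_pair_matrix,
                                    select_candidate_pairs)
from pairhazard.signature_builder import (assign_groups, calibrate_cutoff,
                                          clinical_cox, lasso_cox, risk_scores,
                                          subgroup_km, univariate_screen, validate)
from pairhazard.survival_core import cox_fit


def _train_matrices(study):
    (e1, c1), (e2, c2) = study.cohorts
    genes = GeneList.from_iterable(g for g in e1.gene_ids if g.startswith("G"))
    retained = filter_genes(genes, e1, e2).retained
    m1 = build_pair_matrix(retained, e1)
    m2 = build_pair_matrix(retained, e2)
    cand = select_candidate_pairs(m1, m2)
    return m1.subset(cand), m2.subset(cand), c1, c2


def _pair_matrix(rows: dict[str, list[int]]) -> PairScoreMatrix:
    pairs = [GenePair(*pid.split("|")) for pid in rows]
    scores = np.array(list(rows.values()), dtype=np.uint8)
    return PairScoreMatrix(pairs, [f"S{i}" for i in range(scores.shape[1])], scores)


class TestUnivariateScreen:
    def test_planted_pair_passes(self, study):
        m1, _, c1, _ = _train_matrices(study)
        results = univariate_screen(m1, c1)
        by_pair = {f"{r.pair[0]}|{r.pair[1]}": r for r in results}
        for pid in study.truth.pair_ids():
            assert by_pair[pid].passed, f"planted pair {pid} failed the screen"
            assert by_pair[pid].hazard_ratio > 1

    def test_constant_pair_flagged_degenerate(self):
        m = _pair_matrix({"A|B": [1, 1, 1, 1, 1, 1], "C|D": [0, 1, 0, 1, 0, 1]})
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 0])
        res = univariate_screen(m, clin, raise_on_empty=False)
        assert res[0].note == "degenerate" and not res[0].passed

    def test_empty_screen_raises(self):
        m = _pair_matrix({"A|B": [1, 1, 1, 1, 1, 1]})
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 0])
        with pytest.raises(NoSignalError, match="empty screen"):
            univariate_screen(m, clin)

    def test_results_keep_input_pair_order(self, small_study):
        m1, _, c1, _ = _train_matrices(small_study)
        res = univariate_screen(m1, c1, raise_on_empty=False)
        assert [r.pair for r in res] == [(p.gene_hi, p.gene_lo) for p in m1.pairs]


class TestLassoCox:
    def test_large_lambda_gives_empty_model(self, small_study):
        m1, _, c1, _ = _train_matrices(small_study)
        with pytest.raises(NoSignalError):
            lasso_cox(m1, c1, alphas=[1e6], seed=0)

    def test_lambda_zero_matches_unpenalized_cox(self, small_study):
        m1, _, c1, _ = _train_matrices(small_study)
        two = m1.subset(m1.pairs[:2])
        model = lasso_cox(two, c1, alphas=[1e-9], seed=0)
        oracle = cox_fit(c1.os_time, c1.os_event,
                         two.scores.T.astype(float), ties="breslow")
        assert model.coefficients == pytest.approx(oracle.coefficients, abs=1e-4)

    def test_selected_pairs_include_planted(self, study):
        m1, _, c1, _ = _train_matrices(study)
        screened = [p for p, r in zip(m1.pairs, univariate_screen(m1, c1))
                    if r.passed]
        model = lasso_cox(m1.subset(screened), c1, seed=42)
        planted = set(study.truth.pair_ids())
        assert len(planted & set(model.pair_ids)) >= 2

    def test_needs_two_pairs(self, small_study):
        m1, _, c1, _ = _train_matrices(small_study)
        with pytest.raises(DomainError):
            lasso_cox(m1.subset(m1.pairs[:1]), c1, seed=0)

    def test_deterministic_in_seed(self, small_study):
        m1, _, c1, _ = _train_matrices(small_study)
        sub = m1.subset(m1.pairs[:30])
        a = lasso_cox(sub, c1, seed=5)
        b = lasso_cox(sub, c1, seed=5)
        assert a.pair_ids == b.pair_ids
        assert np.array_equal(a.coefficients, b.coefficients)


class TestRiskScores:
    def test_dot_product(self):
        m = _pair_matrix({"A|B": [1, 0], "C|D": [0, 0], "E|F": [1, 1]})
        model = SignatureModel(pairs=[("A", "B"), ("C", "D"), ("E", "F")],
                               coefficients=np.array([0.5, -0.2, 0.3]))
        scores = [p.risk_score for p in risk_scores(model, m)]
        assert scores == pytest.approx([0.8, 0.3])

    def test_all_zero_scores_give_zero(self):
        m = _pair_matrix({"A|B": [0, 0], "C|D": [0, 0]})
        model = SignatureModel(pairs=[("A", "B"), ("C", "D")],
                               coefficients=np.array([1.0, 2.0]))
        assert [p.risk_score for p in risk_scores(model, m)] == [0.0, 0.0]

    def test_missing_pair_named(self):
        m = _pair_matrix({"A|B": [0, 1]})
        model = SignatureModel(pairs=[("X", "Y")], coefficients=np.array([1.0]))
        with pytest.raises(AlignmentError, match=r"X\|Y"):
            risk_scores(model, m)

    def test_round_trip_model_scores_identical(self, tmp_path, small_study):
        m1, _, c1, _ = _train_matrices(small_study)
        screened = [p for p, r in zip(m1.pairs, univariate_screen(m1, c1))
                    if r.passed]
        model = lasso_cox(m1.subset(screened), c1, seed=3)
        write_signature(model, tmp_path / "m.json")
        reloaded = read_signature(tmp_path / "m.json")
        a = [p.risk_score for p in risk_scores(model, m1)]
        b = [p.risk_score for p in risk_scores(reloaded, m1)]
        assert a == pytest.approx(b, rel=1e-12)

    def test_strict_group_rule(self):
        m = _pair_matrix({"A|B": [1, 0]})
        model = SignatureModel(pairs=[("A", "B")], coefficients=np.array([1.0]))
        profiles = assign_groups(risk_scores(model, m), cutoff=1.0)
        assert [p.group for p in profiles] == ["low", "low"]  # 1.0 not > 1.0
        profiles = assign_groups(risk_scores(model, m), cutoff=0.5)
        assert [p.group for p in profiles] == ["high", "low"]


@pytest.fixture(scope="module")
def trained(study):
    m1, m2, c1, c2 = _train_matrices(study)
    screened = [p for p, r in zip(m1.pairs, univariate_screen(m1, c1))
                if r.passed]
    model = lasso_cox(m1.subset(screened), c1, seed=42)
    model = calibrate_cutoff(model, m1.subset(screened), c1, horizon=1.0)
    return model, m1, m2, c1, c2


@pytest.fixture(scope="module")
def profiles_and_clinical(trained):
    model, m1, _, c1, _ = trained
    profiles = assign_groups(risk_scores(model, m1), model.cutoff)
    return profiles, c1


class TestCalibrateCutoffAndValidate:
    def test_cutoff_matches_brute_force_youden(self, trained):
        model, m1, _, c1, _ = trained
        profiles = risk_scores(model, m1)
        score_of = {p.sample_id: p.risk_score for p in profiles}
        marker = np.array([score_of[s] for s in c1.sample_ids])
        from pairhazard.survival_core import td_roc
        roc = td_roc(c1.os_time, c1.os_event, marker, 1.0)
        j = roc.tpr - roc.fpr  # exhaustive Youden search over every threshold
        idx = int(np.nonzero(roc.thresholds == model.cutoff)[0][0])
        assert j[idx] == pytest.approx(j.max(), abs=1e-12)
        # and the cutoff splits training into two non-empty groups
        groups = [p.group for p in assign_groups(profiles, model.cutoff)]
        assert {"high", "low"} <= set(groups)

    def test_validation_recovers_planted_risk(self, trained):
        model, _, m2, _, c2 = trained
        rep = validate(model, m2, c2)
        assert rep.hazard_ratio > 1
        assert rep.logrank_p < 0.05
        assert rep.aucs[1.0] > 0.7

    def test_validation_never_recalibrates(self, trained):
        model, _, m2, _, c2 = trained
        rep = validate(model, m2, c2)
        splits = {p.group == "high" for p in rep.profiles}
        by_score = all((p.risk_score > model.cutoff) == (p.group == "high")
                       for p in rep.profiles)
        assert by_score and splits == {True, False}

    def test_uncalibrated_model_rejected(self, trained):
        _, _, m2, _, c2 = trained
        raw = SignatureModel(pairs=[(m2.pairs[0].gene_hi, m2.pairs[0].gene_lo)],
                             coefficients=np.array([1.0]))
        with pytest.raises(DomainError, match="cutoff"):
            validate(raw, m2, c2)

    def test_shuffled_validation_covers_null(self, trained):
        """Label-shuffled survival should usually leave the HR CI covering 1."""
        model, _, m2, _, c2 = trained
        rng = np.random.default_rng(0)
        covered = 0
        n_shuffles = 20
        for _ in range(n_shuffles):
            perm = rng.permutation(len(c2.sample_ids))
            shuffled = make_clinical(c2.os_time[perm], c2.os_event[perm])
            shuffled.data.index = c2.sample_ids
            rep = validate(model, m2, shuffled, horizons=[])
            if rep.hr_ci and rep.hr_ci[0] <= 1 <= rep.hr_ci[1]:
                covered += 1
        assert covered >= 0.9 * n_shuffles


class TestSubgroupAndClinicalCox:
    def test_partition_conserves_event_counts(self, profiles_and_clinical):
        profiles, clin = profiles_and_clinical
        res = subgroup_km(profiles, clin, "stage")
        assert sum(r.n_events for r in res) == int(clin.os_event.sum())

    def test_stage_independent_of_risk_keeps_global_hr(self, profiles_and_clinical):
        profiles, clin = profiles_and_clinical
        global_hr = cox_fit(clin.os_time, clin.os_event,
                            np.array([float(p.group == "high") for p in profiles])
                            ).hazard_ratios[0]
        for r in subgroup_km(profiles, clin, "stage"):
            if not r.skipped and r.hr_ci is not None:
                assert r.hr_ci[0] < global_hr < r.hr_ci[1]

    def test_single_group_stratum_skipped(self):
        profiles = assign_groups(
            risk_scores(SignatureModel(pairs=[("A", "B")],
                                       coefficients=np.array([1.0])),
                        _pair_matrix({"A|B": [1, 1, 1, 0, 0, 0]})), 0.5)
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 0],
                             stage=["I", "I", "I", "II", "II", "II"])
        res = {r.stratum: r for r in subgroup_km(profiles, clin, "stage")}
        assert res["I"].skipped and res["II"].skipped  # single risk group each

    def test_clinical_cox_multivariate_keeps_risk_significant(self, profiles_and_clinical):
        profiles, clin = profiles_and_clinical
        uni, multi = clinical_cox(profiles, clin,
                                  covariates=("age", "gender", "grade", "stage"))
        assert set(uni["covariate"]) == {"risk_score", "age", "gender",
                                         "grade", "stage"}
        assert multi.converged
        assert multi.p_values[0] < 0.05  # risk_score is the first covariate

    def test_null_covariates_cover_one(self, profiles_and_clinical):
        # stage/grade/age/gender were simulated independently of survival
        profiles, clin = profiles_and_clinical
        uni, _ = clinical_cox(profiles, clin)
        null_rows = uni[uni.covariate != "risk_score"]
        covers = ((null_rows.ci_lower <= 1) & (1 <= null_rows.ci_upper)).sum()
        assert covers >= len(null_rows) - 1

    def test_duplicated_covariate_flags_nonconvergence(self, profiles_and_clinical):
        profiles, clin = profiles_and_clinical
        clin2 = clin.data.copy()
        clin2["stage2"] = clin2["stage"]
        from pairhazard.data_model_io import ClinicalTable
        uni, multi = clinical_cox(profiles, ClinicalTable(clin2),
                                  covariates=("stage", "stage2"))
        assert not multi.converged
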