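"""Three-stage analysis: paired comparisons, pipeline, sign
classification, net flow."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import gazestate as gs
from gazestate.errors import DegenerateDataError, PairingError, SchemaError
from gazestate.estimation import InvalidScoreError, paired_dwell_tests
from gazestate.indicators import LabeledSequence
from gazestate.reference import manual_transitions


class TestClassifyScore:
    @pytest.mark.parametrize(
        "score,state",
        [(-0.5, "automated"), (0.3, "manual"), (0.0, "manual"), (-1e-12, "automated")],
    )
    def test_sign_rule(self, score, state):
        assert gs.classify_score(score) == state

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidScoreError):
            gs.classify_score(float("nan"))


def _paired_trials(manual_rows, auto_rows):
    """Build labelled trials whose dwell percentages equal the given
    per-participant rows (percentages over a 200-sample trial)."""
    trials = []
    for p, (m, a) in enumerate(zip(manual_rows, auto_rows)):
        for cond, row in ((1, m), (-1, a)):
            labels = []
            counts = np.round(np.asarray(row) * 2).astype(int)  # % -> /200
            counts[0] += 200 - counts.sum()
            for aoi, c in zip(gs.AOI_CODES, counts):
                labels.extend([aoi] * c)
            trials.append(
                LabeledSequence(labels=labels, participant=p, condition=cond)
            )
    return trials


class TestCompareConditions:
    def test_identical_pairs_show_nothing(self):
        row = np.full(13, 100.0 / 13)
        trials = _paired_trials([row] * 6, [row] * 6)
        out = gs.compare_conditions(trials)
        assert np.allclose(out["difference"], 0.0)
        assert not out["significant"].any()

    def test_shifted_aoi_detected_after_holm(self, rng):
        base = np.full(13, 100.0 / 13)
        manual, auto = [], []
        for _ in range(12):
            jit = rng.normal(0, 0.5, size=13)
            jit -= jit.mean()
            m = base + jit
            a = m.copy()
            a[0] -= 10.0  # RC loses 10 points under automation
            a[1] += 10.0
            manual.append(m)
            auto.append(a)
        out = gs.compare_conditions(_paired_trials(manual, auto))
        assert out.loc["RC", "significant"]
        assert out.loc["RC", "difference"] < 0

    def test_p_values_match_textbook_statistic(self, rng):
        """p-values equal the closed-form paired t computation."""
        manual = rng.uniform(2, 10, size=(12, 13))
        auto = manual + rng.normal(0, 1, size=(12, 13))
        out = paired_dwell_tests(manual, auto)
        for j, aoi in enumerate(gs.AOI_CODES):
            d = auto[:, j] - manual[:, j]
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
            assert out.loc[aoi, "p_value"] == pytest.approx(p, rel=1e-10)

    def test_unpaired_participants_rejected(self):
        trials = [
            LabeledSequence(labels=["RC"] * 10, participant=0, condition=1),
            LabeledSequence(labels=["RC"] * 10, participant=1, condition=-1),
        ]
        with pytest.raises(PairingError):
            gs.compare_conditions(trials)


class TestNetFlow:
    def test_empty_set_is_all_equilibrium(self):
        out = gs.net_flow([])
        assert (out["net"] == 0).all()
        assert (out["class"] == "equilibrium").all()

    def test_single_transition(self):
        out = gs.net_flow([("Up", "RC")])
        assert out.loc["Up", "net"] == -1 and out.loc["Up", "class"] == "exiting"
        assert out.loc["RC", "net"] == 1 and out.loc["RC", "class"] == "entering"

    def test_manual_signature_makes_rc_entering(self):
        out = gs.net_flow(manual_transitions())
        assert out.loc["RC", "in_count"] == 8
        assert out.loc["RC", "out_count"] == 1
        assert out.loc["RC", "net"] == 7
        assert out.loc["RC", "class"] == "entering"

    def test_net_flows_sum_to_zero(self, rng):
        aois = list(gs.AOI_CODES)
        for _ in range(20):
            trans = [
                (aois[i], aois[j])
                for i, j in rng.integers(0, 13, size=(15, 2))
            ]
            assert gs.net_flow(trans)["net"].sum() == 0

    def test_unknown_code_rejected(self):
        with pytest.raises(SchemaError):
            gs.net_flow([("RC", "Windscreen")])


class TestRunPipeline:
    def test_deterministic(self, small_cohort):
        a = gs.run_pipeline(small_cohort.sequences, "S")
        b = gs.run_pipeline(small_cohort.sequences, "S")
        assert np.array_equal(a.scores, b.scores)
        assert a.to_dict() == b.to_dict()

    def test_negated_conditions_flip_every_classification(self, small_cohort):
        trials = small_cohort.sequences
        flipped = [dataclasses.replace(t, condition=-t.condition) for t in trials]
        a = gs.run_pipeline(trials, "S")
        b = gs.run_pipeline(flipped, "S")
        assert np.allclose(a.scores, -b.scores, atol=1e-9)
        swap = {"manual": "automated", "automated": "manual"}
        assert tuple(swap[p] for p in a.predicted) == b.predicted

    def test_error_count_consistency(self, small_cohort):
        rep = gs.run_pipeline(small_cohort.sequences, "PRC")
        assert rep.n_errors == sum(p != t for p, t in zip(rep.predicted, rep.true))
        assert rep.n_selected <= 1

    def test_single_condition_rejected(self, small_cohort):
        manual_only = [t for t in small_cohort.sequences if t.condition == 1]
        with pytest.raises(DegenerateDataError):
            gs.run_pipeline(manual_only, "S")
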