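import itertools

import numpy as np
import pytest
import yaml

from screenrisk.hmm_risk import (
    AlphaState,
    HiddenMarkovRisk,
    HMMParams,
    filter_history,
    forward_update,
    init_alpha,
    predict_state_probs,
)
from screenrisk.markov import TransitionCache, stationary_distribution, transition_matrix
from screenrisk.screening_data import ExamRecord

from conftest import make_history


def toy_params(generator=None, emission_cyt=None):
    return HMMParams(
        generator=generator
        if generator is not None
        else [[-0.3, 0.2, 0.1], [0.3, -0.5, 0.2], [0.1, 0.2, -0.3]],
        initial_band_edges=(36.0, 46.0),
        initial_probs=[[0.5, 0.3, 0.2]] * 3,
        emission={
            "cytology": emission_cyt
            if emission_cyt is not None
            else [[0.9, 0.08, 0.02], [0.5, 0.4, 0.1], [0.1, 0.4, 0.5]],
            "histology": [[0.95, 0.04, 0.01], [0.1, 0.8, 0.1], [0.02, 0.08, 0.9]],
        },
        exam_intensity={"cytology": [1.0, 1.0, 1.0], "histology": [0.1, 0.5, 1.0]},
    )


def brute_force_posterior(history, params):
    """Path-enumeration oracle for the filtered hidden-state distribution."""
    recs = history.records
    cache = TransitionCache(params.generator)
    total = np.zeros(3)
    for path in itertools.product(range(3), repeat=len(recs)):
        p = params.initial_law(recs[0].time)[path[0]]
        p *= params.emission[recs[0].exam_type][path[0], recs[0].state - 1]
        for i in range(1, len(recs)):
            trans = cache(recs[i].time - recs[i - 1].time)
            p *= trans[path[i - 1], path[i]]
            p *= params.emission[recs[i].exam_type][path[i], recs[i].state - 1]
        total[path[-1]] += p
    return total / total.sum()


class TestInitAlpha:
    def test_hand_multiplied_example(self):
        params = toy_params(emission_cyt=[[0.9, 0.05, 0.05],
                                          [0.5, 0.4, 0.1],
                                          [0.1, 0.4, 0.5]])
        rec = ExamRecord(time=25.0, exam_type="cytology", state=1)
        alpha = init_alpha(rec, params)
        expected = np.array([0.5 * 0.9, 0.3 * 0.5, 0.2 * 0.1])
        assert np.allclose(alpha.probs, expected / expected.sum())

    def test_point_mass_prior_restricts_support(self):
        params = toy_params()
        params.initial_probs = np.array([[1.0, 0.0, 0.0]] * 3)
        rec = ExamRecord(time=25.0, exam_type="cytology", state=2)
        alpha = init_alpha(rec, params)
        assert alpha.probs[0] == pytest.approx(1.0)

    def test_zero_support_rejected(self):
        params = toy_params(emission_cyt=[[0.9, 0.0, 0.1],
                                          [0.5, 0.0, 0.5],
                                          [0.1, 0.0, 0.9]])
        params.initial_probs = np.array([[0.5, 0.3, 0.2]] * 3)
        rec = ExamRecord(time=25.0, exam_type="cytology", state=2)
        with pytest.raises(ValueError):
            init_alpha(rec, params)


class TestForwardUpdate:
    def test_repeated_evidence_sharpens_with_frozen_chain(self):
        params = toy_params(generator=np.zeros((3, 3)))
        recs = [(25.0 + i, "cytology", 1) for i in range(5)]
        h = make_history("x", recs)
        alpha = init_alpha(h.records[0], params)
        prev = alpha.probs[0]
        for rec in h.records[1:]:
            alpha = forward_update(alpha, rec, params)
            assert alpha.probs[0] > prev
            prev = alpha.probs[0]

    def test_long_gap_relaxes_to_stationary_law(self):
        q = np.array([[-0.3, 0.2, 0.1], [0.3, -0.5, 0.2], [0.1, 0.2, -0.3]])
        pi = stationary_distribution(q)
        p_long = transition_matrix(q, 500.0)
        assert np.allclose(p_long, np.tile(pi, (3, 1)), atol=1e-8)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            q = rng.uniform(0, 1, size=(3, 3))
            np.fill_diagonal(q, 0)
            np.fill_diagonal(q, -q.sum(axis=1))
            d1, d2 = rng.uniform(0.1, 5, size=2)
            lhs = transition_matrix(q, d1) @ transition_matrix(q, d2)
            assert np.allclose(lhs, transition_matrix(q, d1 + d2), atol=1e-10)

    @pytest.mark.parametrize("n_visits", [1, 2, 3, 4])
    def test_filter_matches_path_enumeration(self, n_visits):
        rng = np.random.default_rng(n_visits)
        params = toy_params()
        times = np.sort(22 + rng.uniform(0, 10, size=n_visits))
        h = make_history(
            "x",
            [
                (float(t), ["cytology", "histology"][rng.integers(2)],
                 int(rng.integers(1, 4)))
                for t in times
            ],
        )
        alpha = filter_history(h, params)
        brute = brute_force_posterior(h, params)
        assert np.max(np.abs(alpha.probs - brute)) < 1e-10

    def test_non_increasing_time_rejected(self):
        params = toy_params()
        alpha = init_alpha(ExamRecord(time=25.0, exam_type="cytology", state=1), params)
        with pytest.raises(ValueError):
            forward_update(
                alpha, ExamRecord(time=25.0, exam_type="cytology", state=1), params
            )


class TestPredictStateProbs:
    def test_point_mass_short_gap_single_exam_type(self):
        params = toy_params()
        params.exam_intensity = {
            "cytology": np.array([1.0, 1.0, 1.0]),
            "histology": np.array([1e-12, 1e-12, 1e-12]),
        }
        alpha = AlphaState(log_alpha=np.array([0.0, -np.inf, -np.inf]), time=30.0)
        triple = predict_state_probs(alpha, 30.0 + 1e-9, params)
        assert np.allclose(
            triple.probs, params.emission["cytology"][0], atol=1e-6
        )

    def test_severity_relabel_symmetry(self):
        flip = [2, 1, 0]
        params = toy_params()
        flipped = HMMParams(
            generator=np.asarray(params.generator)[np.ix_(flip, flip)],
            initial_band_edges=params.initial_band_edges,
            initial_probs=params.initial_probs[:, flip],
            emission={k: v[np.ix_(flip, flip)] for k, v in params.emission.items()},
            exam_intensity={k: v[flip] for k, v in params.exam_intensity.items()},
        )
        h = make_history("x", [(25.0, "cytology", 1), (27.0, "histology", 2)])
        h_flip = make_history("x", [(25.0, "cytology", 3), (27.0, "histology", 2)])
        p = predict_state_probs(filter_history(h, params), 29.0, params).probs
        p_flip = predict_state_probs(
            filter_history(h_flip, flipped), 29.0, flipped
        ).probs
        assert np.allclose(p, p_flip[::-1], atol=1e-12)

    def test_matches_bruteforce_marginalization(self):
        params = toy_params()
        h = make_history("x", [(24.0, "cytology", 1), (26.5, "histology", 2)])
        t_hat = 27.5
        alpha = filter_history(h, params)
        triple = predict_state_probs(alpha, t_hat, params)
        # term-by-term oracle
        cache = TransitionCache(params.generator)
        trans = cache(t_hat - 26.5)
        a = alpha.probs
        p_exam = params.exam_type_probs()  # (exam, hidden)
        brute = np.zeros(3)
        for s in range(3):
            for e, ex in enumerate(("cytology", "histology")):
                for h_hat in range(3):
                    for h_now in range(3):
                        brute[s] += (
                            params.emission[ex][h_hat, s]
                            * p_exam[e, h_hat]
                            * trans[h_now, h_hat]
                            * a[h_now]
                        )
        assert np.allclose(triple.probs, brute / brute.sum(), atol=1e-12)

    def test_future_time_required(self):
        params = toy_params()
        alpha = AlphaState(log_alpha=np.zeros(3), time=30.0)
        with pytest.raises(ValueError):
            predict_state_probs(alpha, 29.0, params)


class TestParams:
    def test_emission_rows_must_be_stochastic(self):
        with pytest.raises(ValueError):
            toy_params(emission_cyt=[[0.9, 0.2, 0.02]] * 3)

    def test_yaml_round_trip(self, tmp_path):
        params = HMMParams.default()
        path = tmp_path / "hmm.yaml"
        from screenrisk.hmm_risk import _DEFAULT

        path.write_text(yaml.safe_dump(_DEFAULT))
        loaded = HMMParams.from_yaml(path)
        assert np.allclose(loaded.generator, params.generator)
        assert np.allclose(
            loaded.emission["cytology"], params.emission["cytology"]
        )

    def test_exam_type_probs_normalized(self):
        p = toy_params().exam_type_probs()
        assert np.allclose(p.sum(axis=0), 1.0)

    def test_estimator_contract(self):
        est = HiddenMarkovRisk().fit()
        h = make_history("x", [(25.0, "cytology", 1), (26.0, "cytology", 1)])
        session = est.begin(h)
        session = est.update(
            session, ExamRecord(time=27.0, exam_type="cytology", state=2)
        )
        triple = est.predict_risk(session, 28.0)
        assert triple.probs.sum() == pytest.approx(1.0)
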