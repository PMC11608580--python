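import numpy as np
import pytest

from gazemind import (
    APPROPRIATE_MR,
    GeneratorConfig,
    between_dyad_analysis,
    code_coincidence,
    coordination_analysis,
    generate_study,
    halves_analysis,
    summarize_comments,
    summarize_looking,
    window_sweep,
)
from conftest import make_session


class TestCodeCoincidence:
    def test_hand_enumerated_windows(self):
        """Looking frames at t=10,40; onsets 9.0 (appropriate), 20.0, 38.2."""
        s = make_session(
            duration=60,
            looking_t=[10, 40],
            comments=[(9.0, APPROPRIATE_MR), (20.0, "other"), (38.2, "other")],
        )
        recs = code_coincidence(s, window=5.0)
        assert [r.looked for r in recs] == [True, False, True]
        assert recs[0].comment_class == "appropriate"
        assert recs[0].looked_before is False  # frames 7,8,9 not looking
        assert recs[0].looked_after is True  # frame 10 in (9.0, 11.5]

    def test_no_looking_no_coincidence(self):
        s = make_session(duration=30, comments=[(5.0, "other"), (15.0, "other")])
        assert all(not r.looked for r in code_coincidence(s))

    def test_looked_is_before_or_after(self, small_study):
        for s in small_study:
            for r in code_coincidence(s):
                assert r.looked == (r.looked_before or r.looked_after)

    def test_onset_frame_counts_as_before(self):
        s = make_session(duration=30, looking_t=[10], comments=[(10.0, "other")])
        r = code_coincidence(s)[0]
        assert r.looked_before and not r.looked_after

    def test_nested_windows_monotone(self, small_study):
        for s in small_study:
            by_window = {
                w: [r.looked for r in code_coincidence(s, window=w)]
                for w in (4.0, 5.0, 6.0)
            }
            for small, big in [(4.0, 5.0), (5.0, 6.0)]:
                for a, b in zip(by_window[small], by_window[big]):
                    assert b or not a  # a => b


class TestBetweenDyad:
    def test_identical_dyads_zero_slope(self):
        sessions = [
            make_session(dyad_id=f"d{i}", duration=40, looking_t=range(0, 40, 2),
                         comments=[(float(j), APPROPRIATE_MR if j % 10 == 0 else "other")
                                   for j in range(1, 31)])
            for i in range(5)
        ]
        look = [summarize_looking(s) for s in sessions]
        comm = [summarize_comments(s.comments, dyad_id=s.dyad_id) for s in sessions]
        fit, _ = between_dyad_analysis(look, comm)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-6)

    def test_null_link_slope_centered_at_zero(self):
        slopes = []
        for seed in range(12):
            study = generate_study(
                GeneratorConfig(n_dyads=20, duration=400, seed=seed, rho_link=0.0)
            )
            look = [summarize_looking(s) for s in study]
            comm = [summarize_comments(s.comments, dyad_id=s.dyad_id) for s in study]
            fit, _ = between_dyad_analysis(look, comm)
            slopes.append(fit.coefficients[1])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se

    def test_positive_link_detected(self):
        detected = 0
        for seed in range(10):
            study = generate_study(
                GeneratorConfig(n_dyads=30, duration=600, seed=seed, rho_link=0.6)
            )
            look = [summarize_looking(s) for s in study]
            comm = [summarize_comments(s.comments, dyad_id=s.dyad_id) for s in study]
            fit, test = between_dyad_analysis(look, comm)
            detected += (fit.coefficients[1] > 0) and (test.p < 0.05)
        assert detected >= 8

    def test_too_few_dyads_errors(self):
        s = make_session(duration=20, looking_t=[1], comments=[(2.0, "other")])
        with pytest.raises(ValueError):
            between_dyad_analysis([summarize_looking(s)],
                                  [summarize_comments(s.comments, dyad_id=s.dyad_id)])


class TestCoordinationAnalysis:
    def test_positive_coupling_recovered(self, small_study):
        fit, test, records = coordination_analysis(small_study)
        assert fit.converged
        assert fit.fixed_effects[1] > 0
        assert len(records) == sum(len(s.comments) for s in small_study)

    def test_all_same_class_errors(self):
        s1 = make_session(dyad_id="a", duration=30, looking_t=[5],
                          comments=[(4.0, "other"), (20.0, "other")])
        s2 = make_session(dyad_id="b", duration=30, looking_t=[10],
                          comments=[(9.0, "other")])
        with pytest.raises(ValueError):
            coordination_analysis([s1, s2])

    def test_relabeling_invariance(self, small_study):
        fit1, t1, _ = coordination_analysis(small_study)
        renamed = []
        for i, s in enumerate(small_study):
            c = s.copy()
            c.dyad_id = f"mother_{chr(97 + i)}"
            renamed.append(c)
        fit2, t2, _ = coordination_analysis(list(reversed(renamed)))
        assert fit1.fixed_effects[1] == pytest.approx(fit2.fixed_effects[1], abs=1e-6)
        assert t1.chi2 == pytest.approx(t2.chi2, abs=1e-6)


class TestWindowSweep:
    def test_single_window_matches_direct_analysis(self, small_study):
        direct_fit, direct_test, _ = coordination_analysis(small_study, window=5.0)
        sweep = window_sweep(small_study, windows=(5.0,))
        fit, test = sweep[5.0]
        assert fit.loglik == pytest.approx(direct_fit.loglik, abs=1e-9)
        assert test.chi2 == pytest.approx(direct_test.chi2, abs=1e-9)

    def test_three_windows_same_sign(self, small_study):
        sweep = window_sweep(small_study)
        signs = {np.sign(f.fixed_effects[1]) for f, _ in sweep.values()}
        assert signs == {1.0}


class TestHalvesAnalysis:
    def test_symmetric_outcomes_give_zero_chi2(self):
        sessions = []
        for i in range(4):
            looking = [9, 11] if i % 2 == 0 else []
            comments = [(10.0, APPROPRIATE_MR), (40.0, APPROPRIATE_MR)]
            sessions.append(
                make_session(dyad_id=f"d{i}", duration=60, looking_t=looking,
                             comments=comments)
            )
        # construction: every appropriate comment has looked_before==looked_after
        for s in sessions:
            for r in code_coincidence(s):
                assert r.looked_before == r.looked_after
        _, test = halves_analysis(sessions)
        assert test.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_post_onset_coupling_detected(self):
        hits = 0
        for seed in range(8):
            study = generate_study(
                GeneratorConfig(n_dyads=30, duration=900, seed=seed,
                                beta_couple=1.5, couple_side="after")
            )
            fit, test = halves_analysis(study)
            hits += (fit.fixed_effects[1] > 0) and (test.p < 0.05)
        assert hits >= 6

    def test_no_appropriate_comments_errors(self):
        s = make_session(duration=20, comments=[(3.0, "other")])
        s2 = make_session(dyad_id="d1", duration=20, comments=[(5.0, "other")])
        with pytest.raises(ValueError):
            halves_analysis([s, s2])
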