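"""Change-point patient streams and online two-sided monitoring."""

import numpy as np
import pytest
from scipy.stats import chisquare

from racusum import (
    BetaBinomialMix,
    CusumChart,
    MarkovConfig,
    ScenarioSpec,
    arl_markov_discrete,
    generate_stream,
    monitor_stream,
    w_atoms,
)

PHASE1 = BetaBinomialMix(71, 0.59, 4.12)
HIGH_RISK = BetaBinomialMix(71, 1.50, 4.00)
LOW_RISK = BetaBinomialMix(71, 0.30, 8.00)


def _spec(**kw):
    base = dict(
        pre_mix=PHASE1,
        post_mix=PHASE1,
        qstar_pre=1.0,
        qstar_post=1.0,
        tau=201,
        total=1000,
        seed=1,
    )
    base.update(kw)
    return ScenarioSpec(**base)


class TestGenerateStream:
    def test_tau_one_is_all_post_change(self, model):
        spec = _spec(post_mix=HIGH_RISK, tau=1, total=30_000, seed=4)
        df = generate_stream(spec, model)
        assert len(df) == 30_000
        mu = HIGH_RISK.mean_score()
        sd = np.sqrt(HIGH_RISK.raw_moment2() - mu**2)
        assert abs(df["score"].mean() - mu) < 3 * sd / np.sqrt(len(df))

    def test_seed_reproducibility(self, model):
        a = generate_stream(_spec(seed=9), model)
        b = generate_stream(_spec(seed=9), model)
        assert a.equals(b)

    def test_in_control_death_rate(self, model):
        """Empirical death fraction matches the mix-weighted mean of
        pi(s) within binomial 3 SE at K = 1e5."""
        spec = _spec(total=100_000, tau=1, seed=12)
        df = generate_stream(spec, model)
        p = float(np.dot(PHASE1.probs, model.prob_death(PHASE1.support)))
        se = np.sqrt(p * (1 - p) / len(df))
        assert abs(df["outcome"].mean() - p) < 3 * se

    def test_post_change_mean_score(self, model):
        """After a step change to the high-risk mix the post-change
        scores average 19.36 within 3 SE."""
        spec = _spec(post_mix=HIGH_RISK, tau=201, total=60_000, seed=21)
        df = generate_stream(spec, model)
        post = df[df["index"] >= 201]["score"]
        mu = HIGH_RISK.mean_score()
        sd = np.sqrt(HIGH_RISK.raw_moment2() - mu**2)
        assert abs(post.mean() - mu) < 3 * sd / np.sqrt(len(post))

    def test_score_distribution_gof(self, model):
        """Chi-square goodness of fit of generated scores against the
        generating pmf (binned tail), p > 0.001."""
        spec = _spec(total=100_000, tau=1, seed=33)
        scores = generate_stream(spec, model)["score"].to_numpy()
        counts = np.bincount(scores, minlength=72)
        expected = PHASE1.probs * len(scores)
        # merge sparse upper tail so expected counts stay above ~5
        cut = np.searchsorted(np.cumsum(expected), len(scores) - 5.0)
        obs = np.append(counts[:cut], counts[cut:].sum())
        exp = np.append(expected[:cut], expected[cut:].sum())
        stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.001

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            _spec(tau=0)


class TestMonitorStream:
    up = CusumChart("up", qa=2.0, h=2.0)
    down = CusumChart("down", qa=0.5, h=2.0)

    def test_signal_report_fields(self, model):
        df = generate_stream(_spec(qstar_post=4.0, tau=1, total=2000, seed=5), model)
        rep = monitor_stream(df, self.up, self.down, model)
        assert rep.upper_path.shape == (2000,)
        assert rep.lower_path.shape == (2000,)
        assert rep.upper_signal is not None
        first = rep.first_signal()
        assert first is not None and first[1] == "up"

    def test_in_control_signal_rate(self, model):
        """Short in-control streams signal at a rate close to
        length/ARL0 (rare-event check over 200 seeded replications)."""
        arl0 = arl_markov_discrete(
            w_atoms(PHASE1, model, 2.0), self.up.h, MarkovConfig(gamma=2000)
        ).arl
        length, reps = 150, 200
        signals = 0
        for r in range(reps):
            df = generate_stream(_spec(total=length, tau=1, seed=1000 + r), model)
            if monitor_stream(df, self.up, self.down, model).upper_signal is not None:
                signals += 1
        p = length / arl0  # small-probability approximation
        se = np.sqrt(reps * p * (1 - p))
        assert abs(signals - reps * p) < 3 * se + 1

    def _post_change_delay(self, df, model, cap):
        """Signal index of the upper chart restarted at the change."""
        post = df[df["index"] >= 201]
        rep = monitor_stream(post, self.up, self.down, model)
        return rep.upper_signal if rep.upper_signal is not None else cap

    def test_deterioration_detection_delay_matches_arl1(self, model):
        """Step change Q*: 1 -> 2 at tau: the mean detection delay of
        the upper chart (restarted at the change) agrees with the
        zero-state ARL1 of the engine within 3 ensemble SE."""
        h = self.up.h
        arl1 = arl_markov_discrete(
            w_atoms(PHASE1, model, 2.0, qstar=2.0), h, MarkovConfig(gamma=2000)
        ).arl
        delays = []
        for r in range(300):
            df = generate_stream(
                _spec(qstar_post=2.0, tau=201, total=1500, seed=5000 + r), model
            )
            delays.append(self._post_change_delay(df, model, cap=1300))
        delays = np.asarray(delays, dtype=float)
        se = delays.std(ddof=1) / np.sqrt(len(delays))
        assert abs(delays.mean() - arl1) < 3 * se

    def test_low_risk_shift_masks_deterioration(self, model):
        """A simultaneous switch to a low-risk mix hides the doubled
        odds: detection is much slower than with an unchanged mix."""
        delays = {}
        for name, post_mix in (("const", PHASE1), ("lowrisk", LOW_RISK)):
            d = [
                self._post_change_delay(
                    generate_stream(
                        _spec(post_mix=post_mix, qstar_post=2.0, tau=201, total=3200, seed=7000 + r),
                        model,
                    ),
                    model,
                    cap=3000,
                )
                for r in range(150)
            ]
            delays[name] = np.mean(d)
        assert delays["lowrisk"] > 1.5 * delays["const"]

    def test_mix_shift_alone_triggers_false_deterioration_signal(self, model):
        """A pure patient-mix change to high risk (performance
        unchanged) still fires the deterioration chart well before its
        in-control ARL would suggest."""
        sigs = []
        for r in range(100):
            df = generate_stream(
                _spec(post_mix=HIGH_RISK, qstar_post=1.0, tau=201, total=4000, seed=9000 + r),
                model,
            )
            rep = monitor_stream(df, self.up, self.down, model)
            sigs.append(rep.upper_signal if rep.upper_signal else 4000)
        arl0 = arl_markov_discrete(
            w_atoms(PHASE1, model, 2.0), self.up.h, MarkovConfig(gamma=2000)
        ).arl
        assert np.median(sigs) < arl0
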