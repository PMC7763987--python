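"""Unit tests for the synthetic corpus and cohort generators and the
packaged experiment table.

Band-power assertions use scipy's Welch periodogram directly as an
independent oracle on the generated signals.
"""

import numpy as np
import pytest
from scipy import signal as spsig

import affecteeg.synthetic as syn
from affecteeg.synthetic import (
    BANDS,
    GeneratorParams,
    GroupLatents,
    generate_cohort,
    generate_deap_like,
    load_table2,
    strong_coupling_params,
    synthesize_trial,
)

FAST = GeneratorParams(trial_seconds=2.0)


def welch_band_power(x, rate, band):
    f, pxx = spsig.welch(x, fs=rate, nperseg=min(len(x), 256))
    sel = (f >= band[0]) & (f < band[1])
    return np.trapezoid(pxx[sel], f[sel])


class TestDeapLikeCorpus:
    def test_shape_forced_by_configuration(self):
        corpus = generate_deap_like(2, FAST, seed=7)
        assert len(corpus.subjects) == 2
        for subj in corpus.subjects:
            assert len(subj.trials) == 40
            for t in subj.trials:
                assert t.signal.shape == (40, 256)
                assert 1.0 <= t.valence <= 9.0
                assert 1.0 <= t.arousal <= 9.0

    def test_full_scale_trial_shape(self):
        # one subject at the benchmark geometry: 60 s at 128 Hz = 7680 samples
        corpus = generate_deap_like(1, GeneratorParams(), seed=7)
        assert corpus.subjects[0].trials[0].signal.shape == (40, 7680)

    def test_seeded_determinism(self):
        a = generate_deap_like(2, FAST, seed=7)
        b = generate_deap_like(2, FAST, seed=7)
        for sa, sb in zip(a.subjects, b.subjects):
            for ta, tb in zip(sa.trials, sb.trials):
                assert ta.valence == tb.valence
                assert np.array_equal(ta.signal, tb.signal)
        c = generate_deap_like(2, FAST, seed=8)
        assert not np.array_equal(
            a.subjects[0].trials[0].signal, c.subjects[0].trials[0].signal
        )

    def test_seed_required_and_counts_validated(self):
        with pytest.raises(ValueError, match="seed"):
            generate_deap_like(2, FAST)
        with pytest.raises(ValueError):
            generate_deap_like(0, FAST, seed=1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(background_sd=0.0)
        with pytest.raises(ValueError):
            GeneratorParams(valence_power_ratio=-1.0)
        with pytest.raises(ValueError):
            GeneratorParams(band_base_sd={"alpha": -2.0})
        with pytest.raises(ValueError, match="band"):
            GeneratorParams(valence_band="delta")


class TestBandPowerCoupling:
    def test_doubled_coupling_doubles_alpha_power(self):
        """Power ratio 2 between the extreme labels shows up as a factor
        2 +/- 10% in the Welch periodogram of the coupled channels."""
        params = GeneratorParams(trial_seconds=4.0, valence_power_ratio=2.0)
        lo_ch, hi_ch = params.valence_channels
        rng_hi = np.random.default_rng(1)
        rng_lo = np.random.default_rng(2)
        p_hi, p_lo = [], []
        for _ in range(6):
            sig_hi = synthesize_trial(rng_hi, params, valence=9.0, arousal=5.0)
            sig_lo = synthesize_trial(rng_lo, params, valence=1.0, arousal=5.0)
            for ch in range(lo_ch, hi_ch):
                p_hi.append(welch_band_power(sig_hi[ch], 128.0, BANDS["alpha"]))
                p_lo.append(welch_band_power(sig_lo[ch], 128.0, BANDS["alpha"]))
        # subtract the label-independent floor (background + noise) measured
        # in the alpha band of uncoupled channels
        floor = np.mean([
            welch_band_power(synthesize_trial(
                np.random.default_rng(3), params, 5.0, 5.0)[35], 128.0, BANDS["alpha"])
            for _ in range(4)
        ])
        ratio = (np.mean(p_hi) - floor) / (np.mean(p_lo) - floor)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_band_power_monotone_in_coupling(self):
        """Raising the coupling ratio never lowers high-label band power."""
        powers = []
        for ratio in (1.0, 2.0, 4.0):
            params = GeneratorParams(trial_seconds=2.0, valence_power_ratio=ratio)
            rng = np.random.default_rng(5)
            sig = synthesize_trial(rng, params, valence=9.0, arousal=5.0)
            p = np.mean([welch_band_power(sig[ch], 128.0, BANDS["alpha"])
                         for ch in range(*params.valence_channels)])
            powers.append(p)
        assert powers[0] <= powers[1] <= powers[2]

    def test_peripheral_channels_carry_no_oscillations(self):
        params = strong_coupling_params(trial_seconds=4.0)
        sig = synthesize_trial(np.random.default_rng(0), params, 9.0, 9.0)
        scalp_alpha = welch_band_power(sig[0], 128.0, BANDS["alpha"])
        periph_alpha = welch_band_power(sig[39], 128.0, BANDS["alpha"])
        assert scalp_alpha > 5 * periph_alpha


class TestCohort:
    def test_default_cohort_matches_observed_regime(self):
        cohort = generate_cohort(seed=3, with_signals=False)
        assert len(cohort) == 40
        g1 = [r for r in cohort if r.group == "photographic"]
        g2 = [r for r in cohort if r.group == "illustrated"]
        assert len(g1) == len(g2) == 20
        # the photographic group's latent valence distribution sits deep in
        # the negative half-plane
        assert all(-1.0 < r.latent_valence < 0.0 for r in g1)

    def test_empty_cohort_allowed(self):
        assert generate_cohort(n_per_group=0, seed=1, with_signals=False) == []

    def test_zero_sd_degenerates_to_identical_latents(self):
        gp = {"a": GroupLatents(-0.5, 0.0, 0.3, 0.0),
              "b": GroupLatents(0.2, 0.0, 0.1, 0.0)}
        cohort = generate_cohort(gp, n_per_group=4, seed=2, with_signals=False)
        a = [r for r in cohort if r.group == "a"]
        assert all(r.latent_valence == -0.5 and r.latent_arousal == 0.3 for r in a)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            GroupLatents(0.0, -0.1, 0.0, 0.1)

    def test_epoch_bounds_partition_clip_exactly(self):
        cohort = generate_cohort(n_per_group=1, seed=4, with_signals=True,
                                 params=GeneratorParams(trial_seconds=2.0),
                                 clip_seconds=40.0, epoch_seconds=10.0)
        rec = cohort[0]
        bounds = rec.epoch_bounds
        assert bounds[0][0] == 0
        assert bounds[-1][1] == rec.signal.shape[1]
        for (a0, a1), (b0, _) in zip(bounds, bounds[1:]):
            assert a1 == b0

    def test_cohort_determinism(self):
        a = generate_cohort(n_per_group=3, seed=9, with_signals=False)
        b = generate_cohort(n_per_group=3, seed=9, with_signals=False)
        assert [(r.latent_valence, r.latent_arousal) for r in a] == \
               [(r.latent_valence, r.latent_arousal) for r in b]


class TestSimulatedScores:
    def test_table_shape_and_ranges(self):
        cohort = generate_cohort(n_per_group=5, seed=6, with_signals=False)
        df = syn.simulate_cohort_scores(cohort, seed=1)
        assert list(df.columns) == ["participant", "group", "eeg_valence",
                                    "eeg_arousal", "user_valence", "user_arousal"]
        assert df["eeg_valence"].between(-1, 1).all()
        assert df["user_valence"].between(1, 9).all()
        assert df["user_valence"].dtype.kind == "i"

    def test_deterministic_given_seed(self):
        cohort = generate_cohort(n_per_group=5, seed=6, with_signals=False)
        a = syn.simulate_cohort_scores(cohort, seed=1)
        b = syn.simulate_cohort_scores(cohort, seed=1)
        assert a.equals(b)


class TestPackagedTable:
    def test_row_counts_and_group_split(self, table2):
        assert len(table2) == 40
        assert (table2["group"].value_counts() == 20).all()
        assert list(table2[table2["group"] == "photographic"]["participant"])[:1] == ["01"]

    def test_known_rows(self, table2):
        r02 = table2[table2["participant"] == "02"].iloc[0]
        assert (r02["eeg_valence"], r02["eeg_arousal"]) == (-0.91, 0.64)
        assert (r02["user_valence"], r02["user_arousal"]) == (1, 9)
        r30 = table2[table2["participant"] == "30"].iloc[0]
        assert r30["eeg_arousal"] == 0.311

    def test_column_means_match_hand_computation(self, table2):
        g1 = table2[table2["group"] == "photographic"]
        assert g1["eeg_valence"].mean() == pytest.approx(-0.8315, abs=5e-5)
        assert g1["eeg_arousal"].mean() == pytest.approx(0.5415, abs=5e-5)

    def test_checksum_guard(self, monkeypatch):
        monkeypatch.setattr(syn, "TABLE2_SHA256", "0" * 64)
        with pytest.raises(IOError, match="checksum"):
            load_table2()
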