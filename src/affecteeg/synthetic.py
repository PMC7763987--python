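"""Synthetic EEG corpora with controllable, recoverable affect structure.

Two generators share one signal model:

* a benchmark-shaped training corpus — 32 subjects x 40 trials, 40 channels
  (32 scalp + 8 peripheral), 60 s at 128 Hz, with continuous valence and
  arousal self-ratings on [1, 9];
* two-group experiment cohorts — 20 participants per group watching a 100 s
  clip of ten 10 s stimulus images, each participant carrying a latent
  (valence, arousal) on (-1, 1).

Signal model
------------
Each channel is the sum of a 1/f ("pink") background, band-limited
oscillations in the four classical EEG bands (theta 4-8, alpha 8-13,
beta 13-30, gamma 30-45 Hz), and white sensor noise, all on a microvolt
scale.  Affect enters through band power: the power of the valence-coupled
band (alpha by default) scales as ``ratio ** ((label - 1) / 8)``, so a
trial rated 9 carries ``ratio`` times the band power of a trial rated 1,
monotonically in between; arousal couples to beta the same way.  Each
dimension modulates its band on its own scalp-channel group (by default
valence on the anterior half of the montage, arousal on the posterior
half, echoing frontal-alpha-asymmetry and central-beta arousal markers),
which keeps the two dimensions separately recoverable after per-window
amplitude normalization.  Scalp channels carry the oscillations; the 8
peripheral channels carry only background and noise.  This is deliberately idealized — no blinks, EMG
bursts or electrode drift — just enough spectral structure for a
classifier to recover the labels.

All randomness flows from one top-level integer seed through
``numpy.random.SeedSequence`` spawning (one child per subject, one
grandchild per trial), so identical (seed, params) reproduce a corpus
bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "GeneratorParams",
    "strong_coupling_params",
    "TrialRecord",
    "SubjectRecord",
    "DeapLikeCorpus",
    "CohortRecording",
    "GroupLatents",
    "generate_deap_like",
    "generate_cohort",
    "default_cohort_params",
    "simulate_cohort_scores",
    "load_table2",
    "band_power",
    "TABLE2_SHA256",
]

#: Classical EEG frequency bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

TABLE2_SHA256 = "5bfec54129ef32c5e43552860179b5c37af631d2feb8b602181192e5f02fb57c"

GROUP1 = "photographic"
GROUP2 = "illustrated"


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic signal model.

    Amplitudes are standard deviations in microvolts.  ``*_power_ratio`` is
    the band-power ratio between the extreme labels (9 vs 1) of the coupled
    dimension; 1.0 decouples the band from the label entirely.
    """

    sampling_rate: float = 128.0
    trial_seconds: float = 60.0
    n_channels: int = 40
    n_scalp: int = 32
    background_sd: float = 8.0
    sensor_noise_sd: float = 2.0
    band_base_sd: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 2.0, "alpha": 3.0, "beta": 3.0, "gamma": 1.5}
    )
    valence_band: str = "alpha"
    arousal_band: str = "beta"
    valence_power_ratio: float = 2.0
    arousal_power_ratio: float = 2.0
    #: scalp-channel index ranges whose coupled band is modulated by each
    #: dimension.  Defaults mirror the classic topography — valence in the
    #: anterior half of the montage (frontal alpha), arousal in the
    #: posterior half (central/parietal beta) — and keep the two label
    #: dimensions separately recoverable from relative band power.
    valence_channels: tuple[int, int] = (0, 16)
    arousal_channels: tuple[int, int] = (16, 32)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.trial_seconds <= 0:
            raise ValueError("sampling_rate and trial_seconds must be positive")
        if not 0 < self.n_scalp <= self.n_channels:
            raise ValueError("need 0 < n_scalp <= n_channels")
        if self.background_sd <= 0 or self.sensor_noise_sd <= 0:
            raise ValueError("background_sd and sensor_noise_sd must be positive")
        for name, sd in self.band_base_sd.items():
            if name not in BANDS:
                raise ValueError(f"unknown band {name!r}")
            if sd <= 0:
                raise ValueError(f"band_base_sd[{name!r}] must be positive")
        for name, r in (("valence_power_ratio", self.valence_power_ratio),
                        ("arousal_power_ratio", self.arousal_power_ratio)):
            if r <= 0:
                raise ValueError(f"{name} must be positive, got {r}")
        for b in (self.valence_band, self.arousal_band):
            if b not in BANDS:
                raise ValueError(f"unknown coupling band {b!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.sampling_rate))


def strong_coupling_params(**overrides) -> GeneratorParams:
    """A strongly separated regime: 16x band-power swing, low background.

    Used where a corpus with easily recoverable labels is wanted, e.g. to
    exercise the classifier end to end at reduced scale.
    """
    base = dict(
        valence_power_ratio=16.0,
        arousal_power_ratio=16.0,
        background_sd=4.0,
        sensor_noise_sd=1.0,
    )
    base.update(overrides)
    return GeneratorParams(**base)


# ---------------------------------------------------------------------------
# signal synthesis


def _pink_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """1/f-power background: white noise spectrally shaped to ~1/sqrt(f) amplitude."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(spec * shape, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                band: tuple[float, float], sd: float) -> np.ndarray:
    """Band-limited Gaussian oscillation with exactly the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (f >= band[0]) & (f < band[1])
    x = np.fft.irfft(spec * mask, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_sd(params: GeneratorParams, band: str, channel: int,
             valence: float, arousal: float) -> float:
    """Standard deviation of one band's oscillation on one scalp channel.

    Power multiplier is ``ratio ** ((label - 1) / 8)``: 1 at label 1,
    ``ratio`` at label 9; it applies only on the channels of the coupled
    dimension's group, so the other channels carry the band at base power.
    If both dimensions couple to the same band and channel the multipliers
    combine multiplicatively.
    """
    power = params.band_base_sd.get(band, 0.0) ** 2
    if power == 0.0:
        return 0.0
    v_lo, v_hi = params.valence_channels
    a_lo, a_hi = params.arousal_channels
    if band == params.valence_band and v_lo <= channel < v_hi:
        power *= params.valence_power_ratio ** ((valence - 1.0) / 8.0)
    if band == params.arousal_band and a_lo <= channel < a_hi:
        power *= params.arousal_power_ratio ** ((arousal - 1.0) / 8.0)
    return float(np.sqrt(power))


def synthesize_trial(rng: np.random.Generator, params: GeneratorParams,
                     valence: float, arousal: float,
                     n_samples: Optional[int] = None) -> np.ndarray:
    """One trial: (n_channels, n_samples) float32 microvolt signal."""
    n = n_samples if n_samples is not None else params.n_samples
    rate = params.sampling_rate
    sig = np.empty((params.n_channels, n), dtype=np.float32)
    for ch in range(params.n_channels):
        x = _pink_noise(rng, n, rate, params.background_sd)
        if ch < params.n_scalp:
            for b in params.band_base_sd:
                sd = _band_sd(params, b, ch, valence, arousal)
                if sd > 0:
                    x = x + _band_noise(rng, n, rate, BANDS[b], sd)
        x = x + rng.standard_normal(n) * params.sensor_noise_sd
        sig[ch] = x.astype(np.float32)
    return sig


def band_power(signal, rate: float, band: tuple[float, float]) -> float:
    """Mean band power of a 1-D signal from its Welch periodogram."""
    from scipy import signal as spsig

    x = np.asarray(signal, dtype=float)
    nperseg = min(x.size, 1024)
    f, pxx = spsig.welch(x, fs=rate, nperseg=nperseg)
    sel = (f >= band[0]) & (f < band[1])
    return float(np.trapezoid(pxx[sel], f[sel]))


# ---------------------------------------------------------------------------
# benchmark-shaped corpus

TRIALS_PER_SUBJECT = 40


@dataclass
class TrialRecord:
    signal: np.ndarray  # (n_channels, n_samples) float32
    valence: float      # self-rating in [1, 9]
    arousal: float


@dataclass
class SubjectRecord:
    subject_id: str
    trials: list[TrialRecord]


@dataclass
class DeapLikeCorpus:
    subjects: list[SubjectRecord]
    sampling_rate: float
    params: GeneratorParams
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.subjects)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def generate_deap_like(
    n_subjects: int = 32,
    params: Optional[GeneratorParams] = None,
    seed: Optional[int] = None,
) -> DeapLikeCorpus:
    """Generate a benchmark-shaped corpus of ``n_subjects`` x 40 labelled trials.

    Labels are drawn uniformly on [1, 9] per trial and stored alongside the
    signal; the binary low/high classes used by the classifier are derived
    downstream.  ``seed`` is required: reproducibility is part of the
    contract, so there is no implicit entropy source.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    p = params or GeneratorParams()
    subject_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects = []
    for si in range(n_subjects):
        trial_seeds = subject_seeds[si].spawn(TRIALS_PER_SUBJECT)
        trials = []
        for ti in range(TRIALS_PER_SUBJECT):
            rng = np.random.default_rng(trial_seeds[ti])
            valence = float(rng.uniform(1.0, 9.0))
            arousal = float(rng.uniform(1.0, 9.0))
            sig = synthesize_trial(rng, p, valence, arousal)
            trials.append(TrialRecord(signal=sig, valence=valence, arousal=arousal))
        subjects.append(SubjectRecord(subject_id=f"s{si + 1:02d}", trials=trials))
    return DeapLikeCorpus(subjects=subjects, sampling_rate=p.sampling_rate, params=p, seed=seed)


# ---------------------------------------------------------------------------
# two-group experiment cohorts


@dataclass(frozen=True)
class GroupLatents:
    """Latent affect distribution of one participant group on (-1, 1)."""

    valence_mean: float
    valence_sd: float
    arousal_mean: float
    arousal_sd: float

    def __post_init__(self) -> None:
        for name, sd in (("valence_sd", self.valence_sd), ("arousal_sd", self.arousal_sd)):
            if sd < 0:
                raise ValueError(f"{name} must be non-negative, got {sd}")
        for name, m in (("valence_mean", self.valence_mean), ("arousal_mean", self.arousal_mean)):
            if not -1.0 < m < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {m}")


@dataclass
class CohortRecording:
    """One experiment participant: a continuous clip recording plus latents."""

    participant_id: str
    group: str
    latent_valence: float
    latent_arousal: float
    sampling_rate: float
    epoch_seconds: float
    n_epochs: int
    signal: Optional[np.ndarray] = None  # (n_channels, n_samples) or None (stats-only)

    @property
    def epoch_bounds(self) -> list[tuple[int, int]]:
        """Sample index ranges of the stimulus epochs; they tile the clip exactly."""
        step = int(round(self.epoch_seconds * self.sampling_rate))
        return [(i * step, (i + 1) * step) for i in range(self.n_epochs)]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -1.0, hi: float = 1.0) -> float:
    if sd == 0.0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    raise RuntimeError("truncated normal rejection sampling failed; check mean/sd")


def default_cohort_params() -> dict[str, GroupLatents]:
    """Group latent distributions matching the packaged experiment table.

    Means/SDs are the empirical column statistics of the EEG-estimated
    scores in the packaged per-participant results, so simulated cohorts
    land in the observed regime of the original experiment.
    """
    t2 = load_table2()
    out = {}
    for g in (GROUP1, GROUP2):
        sub = t2[t2["group"] == g]
        out[g] = GroupLatents(
            valence_mean=float(sub["eeg_valence"].mean()),
            valence_sd=float(sub["eeg_valence"].std(ddof=1)),
            arousal_mean=float(sub["eeg_arousal"].mean()),
            arousal_sd=float(sub["eeg_arousal"].std(ddof=1)),
        )
    return out


def generate_cohort(
    group_params: Optional[Mapping[str, GroupLatents]] = None,
    n_per_group: int = 20,
    seed: Optional[int] = None,
    params: Optional[GeneratorParams] = None,
    clip_seconds: float = 100.0,
    epoch_seconds: float = 10.0,
    with_signals: bool = True,
) -> list[CohortRecording]:
    """Simulate a two-group image-viewing experiment.

    Each participant gets a latent (valence, arousal) drawn from their
    group's distribution truncated to (-1, 1), constant across the clip's
    stimulus epochs (one affective state per participant; the original
    experiment reports one score per participant, and how it aggregated
    over the ten images is not recorded).  With ``with_signals=True`` a
    continuous 40-channel recording of the whole clip is synthesized with
    the same band-power coupling model as the training corpus, mapping the
    latent v to the label scale via ``u = 5 + 4 v``.
    """
    if seed is None:
        raise ValueError("seed is required")
    if n_per_group < 0:
        raise ValueError("n_per_group must be >= 0")
    gp = dict(group_params) if group_params is not None else default_cohort_params()
    p = params or GeneratorParams()
    n_epochs = int(round(clip_seconds / epoch_seconds))
    if abs(n_epochs * epoch_seconds - clip_seconds) > 1e-9:
        raise ValueError("epoch_seconds must divide clip_seconds exactly")
    n_samples = int(round(clip_seconds * p.sampling_rate))

    top = np.random.SeedSequence(seed).spawn(len(gp) * max(n_per_group, 1))
    recordings: list[CohortRecording] = []
    pid = 0
    for gi, (group, lat) in enumerate(gp.items()):
        for k in range(n_per_group):
            pid += 1
            rng = np.random.default_rng(top[gi * n_per_group + k])
            v = _truncated_normal(rng, lat.valence_mean, lat.valence_sd)
            a = _truncated_normal(rng, lat.arousal_mean, lat.arousal_sd)
            sig = None
            if with_signals:
                sig = synthesize_trial(rng, p, 5.0 + 4.0 * v, 5.0 + 4.0 * a,
                                       n_samples=n_samples)
            recordings.append(
                CohortRecording(
                    participant_id=f"{pid:02d}",
                    group=group,
                    latent_valence=v,
                    latent_arousal=a,
                    sampling_rate=p.sampling_rate,
                    epoch_seconds=epoch_seconds,
                    n_epochs=n_epochs,
                    signal=sig,
                )
            )
    return recordings


def simulate_cohort_scores(
    cohort: Sequence[CohortRecording],
    seed: int,
    measurement_sd: float = 0.05,
    annotation_sd: float = 0.15,
) -> pd.DataFrame:
    """Stats-only observation model: score table straight from the latents.

    Bypasses signal synthesis and the classifier: the EEG-estimated score is
    the latent plus Gaussian measurement noise (clipped to [-1, 1]); the
    questionnaire mark is the latent plus annotation noise mapped to the
    nine-point scale and rounded to an integer mark.  Useful when only the
    group-statistics stage is under study.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for rec in cohort:
        ev = float(np.clip(rec.latent_valence + rng.normal(0, measurement_sd), -1, 1))
        ea = float(np.clip(rec.latent_arousal + rng.normal(0, measurement_sd), -1, 1))
        uv = int(np.clip(round(5 + 4 * (rec.latent_valence + rng.normal(0, annotation_sd))), 1, 9))
        ua = int(np.clip(round(5 + 4 * (rec.latent_arousal + rng.normal(0, annotation_sd))), 1, 9))
        rows.append(
            dict(participant=rec.participant_id, group=rec.group,
                 eeg_valence=ev, eeg_arousal=ea, user_valence=uv, user_arousal=ua)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged experiment table


def load_table2() -> pd.DataFrame:
    """Load the packaged 40-participant experiment results table.

    Columns: participant (zero-padded string), group (photographic /
    illustrated), eeg_valence, eeg_arousal on (-1, 1), user_valence,
    user_arousal as integer nine-point marks.  The file's checksum is
    verified on every load so silent corruption cannot slip through.
    """
    ref = resources.files("affecteeg.data").joinpath("table2.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise IOError(
            f"packaged experiment table failed its checksum: got {digest}, "
            f"expected {TABLE2_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), dtype={"participant": str})
    df["user_valence"] = df["user_valence"].astype(int)
    df["user_arousal"] = df["user_arousal"].astype(int)
    return df
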