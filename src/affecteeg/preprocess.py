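"""EEG signal preparation: resampling, band-pass filtering, channel
selection, and 32x32 window construction.

The preparation chain mirrors the common preprocessing of benchmark affect
corpora: signals are brought to 128 Hz, band-passed to 4.0-45.0 Hz (theta
through gamma, removing drift and line noise), reduced from the 40 recorded
channels to the 32 scalp EEG channels, and cut into non-overlapping windows
of 32 consecutive samples per channel, giving 32-channel x 32-sample inputs
for the classifier (240 windows for a 60 s trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as spsig

__all__ = [
    "PreprocessConfig",
    "TrialWindowSet",
    "DEAP_CHANNEL_LABELS",
    "SCALP_CHANNEL_LABELS",
    "bandpass",
    "resample",
    "select_channels",
    "window_trial",
    "normalize_windows",
    "preprocess_trial",
]

# 32 scalp electrodes in the standard benchmark ordering (10/20 placement),
# followed by the 8 peripheral channels recorded alongside them.
SCALP_CHANNEL_LABELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)
PERIPHERAL_CHANNEL_LABELS: tuple[str, ...] = (
    "hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Resp", "Plet", "Temp",
)
DEAP_CHANNEL_LABELS: tuple[str, ...] = SCALP_CHANNEL_LABELS + PERIPHERAL_CHANNEL_LABELS


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preparation chain.

    Defaults are the benchmark-corpus conventions: 128 Hz, 4-45 Hz band,
    keep the 32 scalp channels out of 40, and non-overlapping 32-sample
    windows (stride = window length).
    """

    target_rate: float = 128.0
    band: tuple[float, float] = (4.0, 45.0)
    n_channels_in: int = 40
    keep_channels: tuple[str, ...] = SCALP_CHANNEL_LABELS
    window_len: int = 32
    window_stride: int = 32
    filter_order: int = 4

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0.0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if high >= self.target_rate / 2:
            raise ValueError(
                f"band high edge {high} Hz must lie below the Nyquist rate "
                f"{self.target_rate / 2} Hz"
            )
        if self.window_len < 1 or self.window_stride < 1:
            raise ValueError("window_len and window_stride must be positive")

    @property
    def n_channels_kept(self) -> int:
        return len(self.keep_channels)


@dataclass
class TrialWindowSet:
    """Ordered model-ready windows of one trial.

    ``windows`` has shape (n_windows, n_channels, window_len).  Binary class
    labels (0 = low, 1 = high) are carried when the trial is labelled;
    recordings to be scored leave them as None.
    """

    windows: np.ndarray
    trial_id: str = ""
    valence_class: Optional[int] = None
    arousal_class: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows)
        if self.windows.ndim != 3:
            raise ValueError("windows must have shape (n_windows, channels, samples)")
        for lbl in (self.valence_class, self.arousal_class):
            if lbl is not None and lbl not in (0, 1):
                raise ValueError(f"class labels must be 0/1 or None, got {lbl!r}")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_shape(self) -> tuple[int, int]:
        return self.windows.shape[1], self.windows.shape[2]


def _as_2d(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2:
        raise ValueError("signal must be a (channels, samples) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return x


def bandpass(signal, low: float, high: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    The filter is applied forward and backward (``sosfiltfilt``), so
    band-interior components keep their phase; the effective magnitude
    response is the squared one-pass response.
    """
    if low <= 0:
        raise ValueError(f"band low edge must be positive, got {low} Hz")
    if high <= low:
        raise ValueError(f"band high edge {high} Hz must exceed the low edge {low} Hz")
    if high >= rate / 2:
        raise ValueError(f"band high edge {high} Hz must lie below Nyquist {rate / 2} Hz")
    x = _as_2d(signal)
    sos = spsig.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    out = spsig.sosfiltfilt(sos, x, axis=-1)
    return out if np.asarray(signal).ndim == 2 else out[0]


def resample(signal, from_rate: float, to_rate: float = 128.0) -> np.ndarray:
    """Anti-aliased downsample along the time axis.

    Polyphase resampling with the rational factor ``to_rate / from_rate``;
    the low-pass stage of the polyphase filter provides the anti-aliasing.
    Output length is ``round(n * to_rate / from_rate)``.  Upsampling is
    outside this pipeline's contract and is rejected.
    """
    if to_rate > from_rate:
        raise ValueError(
            f"upsampling requested ({from_rate} -> {to_rate} Hz); only downsampling is supported"
        )
    x = _as_2d(signal)
    if from_rate == to_rate:
        out = x.copy()
    else:
        frac = Fraction(to_rate / from_rate).limit_denominator(1000)
        out = spsig.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
        want = int(round(x.shape[-1] * to_rate / from_rate))
        out = out[..., :want]
    return out if np.asarray(signal).ndim == 2 else out[0]


def select_channels(recording, labels: Sequence[str], keep: Sequence[str]) -> np.ndarray:
    """Return the rows of ``recording`` named in ``keep``, in that order."""
    x = _as_2d(recording)
    if x.shape[0] != len(labels):
        raise ValueError(
            f"recording has {x.shape[0]} channels but {len(labels)} labels were given"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    rows = []
    for lab in keep:
        if lab not in index:
            raise KeyError(f"channel label {lab!r} not present in recording")
        rows.append(index[lab])
    return x[rows]


def window_trial(trial, config: PreprocessConfig | None = None, trial_id: str = "",
                 valence_class: Optional[int] = None,
                 arousal_class: Optional[int] = None) -> TrialWindowSet:
    """Cut a (channels, samples) trial into consecutive fixed-length windows.

    Window k covers samples ``[k*stride, k*stride + window_len)``; the count
    is ``floor((n - window_len) / stride) + 1``.  At the default stride
    (= window length) the windows tile the trial without overlap and every
    retained sample belongs to exactly one window.
    """
    cfg = config or PreprocessConfig()
    x = _as_2d(trial)
    n = x.shape[-1]
    if n < cfg.window_len:
        raise ValueError(
            f"trial has {n} samples, fewer than the window length {cfg.window_len}"
        )
    view = np.lib.stride_tricks.sliding_window_view(x, cfg.window_len, axis=-1)
    windows = view[:, :: cfg.window_stride, :].transpose(1, 0, 2).copy()
    return TrialWindowSet(
        windows=windows,
        trial_id=trial_id,
        valence_class=valence_class,
        arousal_class=arousal_class,
        meta={"stride": cfg.window_stride, "n_samples": n},
    )


def normalize_windows(tws: TrialWindowSet, eps: float = 1e-12) -> TrialWindowSet:
    """Z-score each channel within each window (zero mean, unit variance).

    Channels with variance below ``eps`` (flat channels) are set to zero
    rather than divided, so degenerate inputs never produce NaN.  The
    result is invariant to rescaling the input amplitude.
    """
    w = np.asarray(tws.windows, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("windows must be finite")
    mean = w.mean(axis=-1, keepdims=True)
    sd = w.std(axis=-1, keepdims=True)
    flat = sd < eps
    centered = w - mean
    out = np.where(flat, 0.0, centered / np.where(flat, 1.0, sd))
    return TrialWindowSet(
        windows=out,
        trial_id=tws.trial_id,
        valence_class=tws.valence_class,
        arousal_class=tws.arousal_class,
        meta={**tws.meta, "normalized": True},
    )


def preprocess_trial(
    signal,
    labels: Sequence[str] = DEAP_CHANNEL_LABELS,
    config: PreprocessConfig | None = None,
    from_rate: Optional[float] = None,
    trial_id: str = "",
    valence_class: Optional[int] = None,
    arousal_class: Optional[int] = None,
) -> TrialWindowSet:
    """Full chain: (resample) -> band-pass -> channel selection -> windows -> z-score."""
    cfg = config or PreprocessConfig()
    x = _as_2d(signal)
    if from_rate is not None and from_rate != cfg.target_rate:
        x = resample(x, from_rate, cfg.target_rate)
    x = bandpass(x, cfg.band[0], cfg.band[1], cfg.target_rate, cfg.filter_order)
    x = select_channels(x, labels, cfg.keep_channels)
    tws = window_trial(x, cfg, trial_id=trial_id,
                       valence_class=valence_class, arousal_class=arousal_class)
    return normalize_windows(tws)
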