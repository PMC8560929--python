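"""SEEG log-power feature extraction.

Raw intracranial signals are reduced to the slow power envelope that the 2D
Epileptor models: high-pass filter, sliding-window power, natural log,
low-pass smoothing, and resampling to a fixed number of time points
(300 by default).  The augmented feature is the per-channel total power,
the second sample moment of each channel's log-power trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal

__all__ = [
    "SEEGRecording",
    "FeatureConfig",
    "DataFeatures",
    "extract_log_power",
    "total_sensor_power",
]


@dataclass
class SEEGRecording:
    """Multichannel recording: ``samples`` is (channels, time)."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch-{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    @classmethod
    def from_delimited(cls, path, sidecar_path=None) -> "SEEGRecording":
        """Load a delimited (channels x time) matrix with a JSON sidecar
        holding ``sampling_rate`` and optional ``channel_labels``."""
        samples = np.loadtxt(path)
        sidecar_path = sidecar_path or str(path) + ".json"
        meta = json.loads(Path(sidecar_path).read_text())
        return cls(
            samples=samples,
            sampling_rate=float(meta["sampling_rate"]),
            channel_labels=list(meta.get("channel_labels", [])),
        )

    @classmethod
    def from_edf(cls, path) -> "SEEGRecording":
        """Load an EDF file (requires mne)."""
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return cls(
            samples=raw.get_data(),
            sampling_rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
        )


@dataclass
class FeatureConfig:
    """Knobs of the log-power pipeline.

    ``highpass_hz`` removes the slow drift/baseline before computing power;
    ``window_s`` and ``overlap`` define the sliding mean-square window;
    ``lowpass_frac`` is the smoothing cutoff as a fraction of the envelope
    Nyquist (the per-recording "tuned" smoothing); ``n_points`` is the
    fixed output length.
    """

    highpass_hz: float = 10.0
    window_s: float = 1.0
    overlap: float = 0.5
    lowpass_frac: float = 0.1
    n_points: int = 300
    filter_order: int = 4
    power_floor: float = 1e-12

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.n_points < 2:
            raise ValueError("need at least two output points")


@dataclass
class DataFeatures:
    """Fitted data features: T x M log power S and per-channel total power rho."""

    S: np.ndarray  # (T, M)
    rho: np.ndarray  # (M,)
    times: np.ndarray  # (T,) seconds
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.S.shape[0] != self.times.shape[0]:
            raise ValueError("one timestamp per feature sample required")
        if self.S.shape[1] != self.rho.shape[0]:
            raise ValueError("one rho per channel required")
        if not self.channel_labels:
            self.channel_labels = [f"ch-{i}" for i in range(self.S.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]

    @property
    def n_times(self) -> int:
        return self.S.shape[0]

    def save(self, path_prefix) -> None:
        np.savetxt(str(path_prefix) + "_logpower.txt", self.S)
        meta = {
            "times": self.times.tolist(),
            "rho": self.rho.tolist(),
            "channel_labels": self.channel_labels,
        }
        Path(str(path_prefix) + "_features.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path_prefix) -> "DataFeatures":
        S = np.loadtxt(str(path_prefix) + "_logpower.txt")
        meta = json.loads(Path(str(path_prefix) + "_features.json").read_text())
        S = S.reshape(len(meta["times"]), -1)
        return cls(
            S=S,
            rho=np.array(meta["rho"]),
            times=np.array(meta["times"]),
            channel_labels=list(meta["channel_labels"]),
        )


def total_sensor_power(S: np.ndarray) -> np.ndarray:
    """Second sample moment of each channel's log-power trace.

    rho_i = (1/T) sum_j s_i(t_j)^2 for the T x M matrix S.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] < 1 or S.size == 0:
        raise ValueError("empty log-power matrix")
    return np.mean(S ** 2, axis=0)


def _sliding_power(x: np.ndarray, win: int, hop: int):
    """Mean square over a sliding rectangular window.

    Returns the (channels, frames) power matrix and the window-center
    sample positions.
    """
    n = x.shape[1]
    starts = np.arange(0, n - win + 1, hop)
    frames = np.stack([np.mean(x[:, s:s + win] ** 2, axis=1) for s in starts], axis=1)
    return frames, starts + win / 2.0


def extract_log_power(
    rec: SEEGRecording, config: Optional[FeatureConfig] = None
) -> DataFeatures:
    """Log-power pipeline: high-pass, sliding power, log, low-pass, resample.

    Filters are applied forward-backward (zero phase) so the envelope is not
    lagged — onset times are the scientific output downstream.  Power is
    floored before the log so silent channels stay finite.  The smoothed
    envelope is resampled to exactly ``config.n_points`` samples spanning
    the recording.
    """
    config = config or FeatureConfig()
    fs = rec.sampling_rate
    x = rec.samples
    win = max(2, int(round(config.window_s * fs)))
    if x.shape[1] <= win:
        raise ValueError("recording shorter than one analysis window")

    if config.highpass_hz > 0 and config.highpass_hz < fs / 2:
        sos = signal.butter(
            config.filter_order, config.highpass_hz, btype="highpass", fs=fs,
            output="sos",
        )
        x = signal.sosfiltfilt(sos, x, axis=1)

    hop = max(1, int(round(win * (1.0 - config.overlap))))
    power, centers = _sliding_power(x, win, hop)
    logp = np.log(np.maximum(power, config.power_floor))

    if 0 < config.lowpass_frac < 1 and logp.shape[1] > 3 * config.filter_order:
        sos = signal.butter(
            config.filter_order, config.lowpass_frac, btype="lowpass", output="sos"
        )  # cutoff as fraction of the envelope Nyquist
        logp = signal.sosfiltfilt(sos, logp, axis=1)

    t_env = centers / fs
    t_out = np.linspace(t_env[0], t_env[-1], config.n_points)
    S = np.empty((config.n_points, logp.shape[0]))
    for i in range(logp.shape[0]):
        S[:, i] = np.interp(t_out, t_env, logp[i])
    return DataFeatures(
        S=S,
        rho=total_sensor_power(S),
        times=t_out,
        channel_labels=list(rec.channel_labels),
    )
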