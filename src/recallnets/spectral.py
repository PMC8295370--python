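"""Spectral feature extraction: bipolar montage, notch filter, Morlet power,
epoching and session normalization.

The feature space shared by every downstream model is the log of Morlet
wavelet power (wave number 5) at eight logarithmically spaced frequencies
from 3 to 180 Hz, downsampled to 50 Hz and z-scored per session within each
electrode x frequency feature.  Encoding epochs span the 1600 ms word
presentation; retrieval epochs span 900 to 100 ms before vocalization onset
(40 samples at 20 ms) and are discarded when another vocalization onset
falls in the preceding 1500 ms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

logger = logging.getLogger(__name__)

__all__ = [
    "frequency_axis",
    "PowerTensor",
    "bipolar_reference",
    "notch_filter",
    "morlet_power",
    "epoch_normalize",
    "screen_retrieval_onsets",
]

FS_OUT = 50.0
ENCODING_WINDOW_MS = (0.0, 1600.0)
RETRIEVAL_WINDOW_MS = (-900.0, -100.0)
N_RETRIEVAL_SAMPLES = 40
SCREEN_GAP_MS = 1500.0


def frequency_axis(n: int = 8, fmin: float = 3.0, fmax: float = 180.0) -> np.ndarray:
    """Logarithmically spaced analysis frequencies, endpoints included."""
    return np.logspace(np.log10(fmin), np.log10(fmax), n)


@dataclass
class PowerTensor:
    """Events x electrodes x frequencies (x time) normalized log power."""

    data: np.ndarray
    frequencies: np.ndarray
    electrode_ids: list[str] | None = None
    time_ms: np.ndarray | None = None
    normalized: bool = False
    session_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("power tensor contains non-finite values")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def time_average(self) -> "PowerTensor":
        """Collapse the time axis (encoding-model feature convention)."""
        if self.data.ndim != 4:
            return self
        return PowerTensor(
            data=self.data.mean(axis=3), frequencies=self.frequencies,
            electrode_ids=self.electrode_ids, normalized=self.normalized,
            session_stats=self.session_stats,
        )

    def to_hdf5(self, path, name: str = "power") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("data", data=self.data)
            g.create_dataset("frequencies", data=self.frequencies)
            if self.time_ms is not None:
                g.create_dataset("time_ms", data=self.time_ms)
            if self.electrode_ids is not None:
                g.attrs["electrode_ids"] = list(self.electrode_ids)
            g.attrs["normalized"] = self.normalized

    @classmethod
    def from_hdf5(cls, path, name: str = "power") -> "PowerTensor":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[name]
            return cls(
                data=g["data"][()],
                frequencies=g["frequencies"][()],
                time_ms=g["time_ms"][()] if "time_ms" in g else None,
                electrode_ids=list(g.attrs["electrode_ids"])
                if "electrode_ids" in g.attrs else None,
                normalized=bool(g.attrs.get("normalized", False)),
            )


def bipolar_reference(signals: np.ndarray, contact_groups: list[list[int]],
                      coordinates: np.ndarray | None = None):
    """Difference of adjacent contacts within each strip/grid/depth group.

    Parameters
    ----------
    signals : (channels, samples) raw voltage.
    contact_groups : channel indices per physical electrode, in geometric
        order; each group of n contacts yields n-1 bipolar channels.
    coordinates : optional (channels, 3) mm positions; pair centroids are
        recorded in the returned table.

    Returns ``(referenced, pair_table)`` with pair_table columns
    anode, cathode (channel indices) and centroid x/y/z when available.
    """
    signals = np.asarray(signals, dtype=float)
    out = []
    rows = []
    for group in contact_groups:
        if len(group) < 2:
            warnings.warn(f"singleton contact group {group}: no bipolar pairs")
            continue
        for a, b in zip(group, group[1:]):
            out.append(signals[a] - signals[b])
            row = {"anode": a, "cathode": b}
            if coordinates is not None:
                cx, cy, cz = (coordinates[a] + coordinates[b]) / 2
                row.update({"x_mm": cx, "y_mm": cy, "z_mm": cz})
            rows.append(row)
    referenced = np.array(out) if out else np.zeros((0, signals.shape[1]))
    return referenced, pd.DataFrame(rows)


def notch_filter(signal: np.ndarray, fs: float, line_freq: float = 60.0,
                 bandwidth: float = 2.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-stop around the line frequency.

    Fourth-order, 2 Hz stop band centered on 60 Hz by default; applied
    forward-backward (filtfilt) so event timing is preserved.
    """
    if fs <= 2 * (line_freq + bandwidth / 2):
        raise ValueError(
            f"sampling rate {fs} Hz too low to notch at {line_freq} Hz")
    lo = (line_freq - bandwidth / 2) / (fs / 2)
    hi = (line_freq + bandwidth / 2) / (fs / 2)
    b, a = spsig.butter(order, [lo, hi], btype="bandstop")
    return spsig.filtfilt(b, a, np.asarray(signal, dtype=float), axis=-1)


def _morlet_wavelet(freq: float, fs: float, wave_number: float) -> np.ndarray:
    """Complex Morlet carrier with Gaussian envelope sd = wave_number/(2*pi*f),
    truncated at +-4 sd and L2... amplitude-normalized so a unit sinusoid at
    ``freq`` yields unit peak amplitude after convolution."""
    sigma_t = wave_number / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    wavelet = envelope * np.exp(2j * np.pi * freq * t)
    # normalize so |conv| returns the analytic amplitude of a sinusoid
    wavelet /= envelope.sum() / 2
    return wavelet


def morlet_power(
    signal: np.ndarray,
    fs: float,
    frequencies: np.ndarray | None = None,
    wave_number: float = 5.0,
    buffer_ms: float = 1000.0,
    mirrored: bool = False,
) -> np.ndarray:
    """Morlet wavelet power of a (channels, samples) signal.

    Power is the squared magnitude of the complex wavelet convolution.  A
    ``buffer_ms`` stretch at each end is used to absorb edge artifacts and
    trimmed from the output: with ``mirrored=False`` the input must already
    contain the buffers (its first and last buffer_ms are dropped); with
    ``mirrored=True`` the signal is reflection-padded first and nothing of
    the original extent is lost (the convention for retrieval epochs).

    Returns (channels, n_freq, samples_out).
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if frequencies is None:
        frequencies = frequency_axis()
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies >= fs / 2):
        raise ValueError("analysis frequency at or above Nyquist")
    nbuf = int(round(buffer_ms * fs / 1000.0))
    if mirrored:
        if x.shape[1] < 2:
            raise ValueError("signal too short to mirror")
        pad = min(nbuf, x.shape[1] - 1)
        x = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
        nbuf = pad
    elif x.shape[1] <= 2 * nbuf:
        raise ValueError("signal shorter than twice the buffer")

    out = np.empty((x.shape[0], frequencies.size,
                    x.shape[1] - 2 * nbuf if nbuf else x.shape[1]))
    for fi, f in enumerate(frequencies):
        w = _morlet_wavelet(f, fs, wave_number)
        conv = spsig.fftconvolve(x, w[None, :], mode="same", axes=1)
        power = np.abs(conv) ** 2
        out[:, fi, :] = power[:, nbuf: x.shape[1] - nbuf] if nbuf else power
    return out


def screen_retrieval_onsets(onsets_ms: np.ndarray,
                            gap_ms: float = SCREEN_GAP_MS) -> np.ndarray:
    """Keep recalls with no earlier vocalization onset in the preceding gap.

    Returns a boolean mask over onsets (assumed sorted within a list)."""
    onsets = np.asarray(onsets_ms, dtype=float)
    keep = np.ones(onsets.size, dtype=bool)
    for i in range(1, onsets.size):
        if onsets[i] - onsets[i - 1] < gap_ms:
            keep[i] = False
    return keep


def _downsample(power: np.ndarray, fs: float, fs_out: float = FS_OUT) -> np.ndarray:
    """Decimate the time axis; the wavelet envelope has already smoothed the
    power series, acting as the anti-alias stage at analysis frequencies."""
    step = fs / fs_out
    if step < 1:
        raise ValueError("cannot upsample power")
    idx = np.round(np.arange(0, power.shape[-1], step)).astype(int)
    idx = idx[idx < power.shape[-1]]
    return power[..., idx]


def epoch_normalize(
    power: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    window_ms: tuple[float, float],
    fs_out: float = FS_OUT,
    frequencies: np.ndarray | None = None,
    screen_gap_ms: float | None = None,
) -> tuple[PowerTensor, pd.DataFrame]:
    """Epoch continuous power, log-transform, downsample and z-score.

    Parameters
    ----------
    power : (channels, n_freq, samples) continuous wavelet power.
    events : table with ``onset_ms`` and ``session`` columns; retrieval
        tables additionally carry per-list ordering for screening.
    window_ms : epoch extent relative to onset, half-open [start, stop).
    screen_gap_ms : when given, drop events preceded by another onset of the
        same list within this gap (retrieval screening).

    Events whose epoch exceeds the recording are dropped with a log entry.
    Returns the normalized tensor and the surviving event rows.
    """
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive before log")
    events = events.reset_index(drop=True)
    keep = np.ones(len(events), dtype=bool)
    if screen_gap_ms is not None:
        group_cols = [c for c in ("session", "list") if c in events.columns]
        if group_cols:
            for _, grp in events.groupby(group_cols):
                mask = screen_retrieval_onsets(grp["onset_ms"].to_numpy(),
                                               screen_gap_ms)
                keep[grp.index] = mask
        else:
            keep = screen_retrieval_onsets(events["onset_ms"].to_numpy(),
                                           screen_gap_ms)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("screened out %d retrieval events within %.0f ms of a "
                        "previous vocalization", n_dropped, screen_gap_ms)

    logp = np.log(power)
    logp = _downsample(logp, fs, fs_out)
    n_out = logp.shape[-1]
    start_offset = window_ms[0] / 1000.0 * fs_out
    n_samples = int(round((window_ms[1] - window_ms[0]) / 1000.0 * fs_out))

    epochs = []
    kept_rows = []
    for i, row in events.iterrows():
        if not keep[i]:
            continue
        first = int(round(row["onset_ms"] / 1000.0 * fs_out + start_offset))
        last = first + n_samples
        if first < 0 or last > n_out:
            logger.info("event at %.0f ms exceeds recording; dropped",
                        row["onset_ms"])
            continue
        epochs.append(logp[:, :, first:last])
        kept_rows.append(i)
    if not epochs:
        warnings.warn("no epochs survived screening/bounds checks")
        data = np.zeros((0, power.shape[0], power.shape[1], n_samples))
    else:
        data = np.stack(epochs)  # (events, channels, freq, time)
    surviving = events.loc[kept_rows].reset_index(drop=True)

    # per-session z-score of each electrode x frequency feature, pooling all
    # epoch samples of the session
    stats: dict = {}
    sessions = surviving["session"].to_numpy() if "session" in surviving else \
        np.zeros(len(surviving), dtype=int)
    for sess in np.unique(sessions):
        m = sessions == sess
        vals = data[m]                                   # (n, C, F, T)
        mean = vals.mean(axis=(0, 3), keepdims=True)
        sd = vals.std(axis=(0, 3), keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        data[m] = (vals - mean) / sd
        stats[int(sess)] = (mean.squeeze(), sd.squeeze())

    time_ms = window_ms[0] + np.arange(n_samples) * 1000.0 / fs_out
    tensor = PowerTensor(data=data, frequencies=np.asarray(
        frequencies if frequencies is not None else frequency_axis()),
        time_ms=time_ms, normalized=True, session_stats=stats)
    return tensor, surviving
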