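"""From raw recordings to sequences of epoch cross-spectra.

Pipeline: zero-phase Butterworth bandpass (0.5–70 Hz, order 5) and 50 Hz
notch; division into non-overlapping 2000 ms epochs; per-epoch complex
cross-spectral density on the 1–40 Hz grid by multitaper estimation; and
averaging of induced spectral activity over repeated, onset-aligned
seizures.  A complex-Gaussian-wavelet criterion selects the longest epoch
over which the spectral profile is approximately stationary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pywt
from scipy.fft import rfft, rfftfreq
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt
from scipy.signal.windows import dpss

from .forward import EpochSpectrum, FrequencyGrid, default_grid

__all__ = [
    "Recording",
    "EpochSequence",
    "filter_recording",
    "epoch_and_csd",
    "select_window_length",
    "retained_fraction",
    "average_induced",
    "read_delimited",
    "write_delimited",
    "read_edf",
]

logger = logging.getLogger(__name__)

MULTITAPER_NW = 3.0   # time–bandwidth product; 2·NW − 1 tapers


@lru_cache(maxsize=8)
def _dpss_cached(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)


@dataclass
class Recording:
    """Uniformly sampled multichannel time series."""

    data: np.ndarray                 # (n_channels, n_samples)
    fs: float                        # sampling rate, Hz
    ch_names: list = field(default_factory=list)
    annotations: list = field(default_factory=list)  # (label, onset_s, offset_s)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochSequence:
    """Ordered per-epoch spectra with uniform epoch duration."""

    spectra: list                    # EpochSpectrum per epoch
    epoch_ms: float = 2000.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("an epoch sequence needs at least one epoch")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def grid(self) -> FrequencyGrid:
        return self.spectra[0].grid

    def to_json(self, path: str | Path) -> None:
        d = {"epoch_ms": self.epoch_ms, "provenance": self.provenance,
             "spectra": [s.to_dict() for s in self.spectra]}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "EpochSequence":
        d = json.loads(Path(path).read_text())
        return cls([EpochSpectrum.from_dict(s) for s in d["spectra"]],
                   epoch_ms=d["epoch_ms"], provenance=d.get("provenance", {}))


def filter_recording(rec: Recording, band=(0.5, 70.0), notch: float = 50.0,
                     order: int = 5, rereference: bool = False) -> Recording:
    """Zero-phase bandpass (Butterworth) plus notch filtering.

    Requires a sampling rate above twice the bandpass top (at least
    140 Hz for the default 0.5–70 Hz band).
    """
    fmin_rate = 2.0 * band[1]
    if rec.fs <= fmin_rate:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low; need > {fmin_rate} Hz "
            f"for a {band[1]} Hz bandpass")
    x = rec.data
    if rereference and rec.n_channels > 1:
        x = x - x.mean(axis=0, keepdims=True)
    sos = butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    x = sosfiltfilt(sos, x, axis=-1)
    if notch is not None and notch < rec.fs / 2:
        b, a = iirnotch(notch, Q=30.0, fs=rec.fs)
        x = filtfilt(b, a, x, axis=-1)
    return Recording(x, rec.fs, list(rec.ch_names), list(rec.annotations))


def multitaper_csd(x: np.ndarray, fs: float, nw: float = MULTITAPER_NW):
    """One-sided multitaper cross-spectral density.

    Returns (freqs, csd) with csd of shape (n_freq, n_ch, n_ch); the
    Hermitian cross-spectral matrix at each frequency.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    k = max(int(2 * nw - 1), 1)
    tapers = _dpss_cached(n, nw, k)                 # (k, n), unit energy
    X = rfft(tapers[:, None, :] * x[None, :, :], axis=-1)  # (k, n_ch, n_f)
    csd = 2.0 / (fs * k) * np.einsum("kif,kjf->fij", X, np.conj(X))
    freqs = rfftfreq(n, 1.0 / fs)
    return freqs, csd


def _grid_indices(freqs: np.ndarray, grid: FrequencyGrid) -> np.ndarray:
    idx = np.array([np.argmin(np.abs(freqs - f)) for f in grid.values])
    if np.max(np.abs(freqs[idx] - grid.values)) > 0.25:
        raise ValueError("epoch length too short to resolve the frequency grid")
    return idx


def epoch_and_csd(rec: Recording, epoch_ms: float = 2000.0,
                  grid: FrequencyGrid | None = None,
                  channel: int | None = None) -> EpochSequence:
    """Divide a recording into non-overlapping epochs and estimate spectra.

    A trailing partial epoch is dropped.  Single-channel recordings (or a
    selected ``channel``) yield real auto-spectra; multichannel recordings
    yield Hermitian cross-spectral matrices.
    """
    grid = grid or default_grid()
    n_per = int(round(rec.fs * epoch_ms / 1000.0))
    if rec.data.shape[1] < n_per:
        raise ValueError("recording shorter than one epoch")
    x = rec.data if channel is None else rec.data[channel:channel + 1]
    n_epochs = rec.data.shape[1] // n_per
    spectra = []
    idx = None
    for i in range(n_epochs):
        seg = x[:, i * n_per:(i + 1) * n_per]
        freqs, csd = multitaper_csd(seg, rec.fs)
        if idx is None:
            idx = _grid_indices(freqs, grid)
        csd = csd[idx]
        if csd.shape[1] == 1:
            csd = csd[:, 0, 0].real.astype(complex)
        spectra.append(EpochSpectrum(grid, csd))
    prov = {"epoch_ms": epoch_ms, "fs": rec.fs, "multitaper_nw": MULTITAPER_NW,
            "n_avg": 1}
    return EpochSequence(spectra, epoch_ms=epoch_ms, provenance=prov)


def _wavelet_power(x: np.ndarray, fs: float, freqs: np.ndarray,
                   wavelet: str = "cgau4") -> np.ndarray:
    """Time–frequency power |W(t,f)|² from a complex Gaussian wavelet."""
    w = pywt.ContinuousWavelet(wavelet)
    scales = pywt.scale2frequency(w, 1.0) * fs / freqs
    coef, _ = pywt.cwt(x, scales, w, sampling_period=1.0 / fs)
    return np.abs(coef) ** 2            # (n_freq, n_samples)


def retained_fraction(rec: Recording, window_ms: float, channel: int = 0,
                      freqs: np.ndarray | None = None,
                      wavelet: str = "cgau4") -> float:
    """Fraction of wavelet spectral energy captured by a stationary profile.

    The time–frequency power in each window is approximated by its
    time-averaged spectral profile; the retained fraction is the energy of
    that rank-one (constant-in-time) approximation relative to the total,
    averaged over windows.  Equals 1 for stationary signals and decreases
    with window length under amplitude modulation.
    """
    freqs = np.arange(2.0, 41.0, 2.0) if freqs is None else freqs
    P = _wavelet_power(rec.data[channel], rec.fs, freqs, wavelet)
    n_per = int(round(rec.fs * window_ms / 1000.0))
    n_win = P.shape[1] // n_per
    if n_win == 0:
        raise ValueError("window longer than the recording")
    fracs = []
    for i in range(n_win):
        M = P[:, i * n_per:(i + 1) * n_per]
        profile = M.mean(axis=1)
        captured = np.sum(profile ** 2) * M.shape[1]
        total = np.sum(M ** 2)
        fracs.append(captured / total if total > 0 else 1.0)
    return float(np.mean(fracs))


def select_window_length(rec: Recording, candidates, threshold: float = 0.90,
                         channel: int = 0) -> float:
    """Largest candidate window (ms) retaining ≥ 90% of the spectral power.

    Candidates must be sorted ascending.  When no candidate qualifies the
    smallest is returned with a warning.
    """
    candidates = list(candidates)
    if candidates != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    best = None
    for L in candidates:
        if retained_fraction(rec, L, channel=channel) >= threshold:
            best = L
    if best is None:
        logger.warning("no candidate window retains %.0f%% of spectral power; "
                       "falling back to %s ms", 100 * threshold, candidates[0])
        return float(candidates[0])
    return float(best)


def average_induced(sequences) -> EpochSequence:
    """Arithmetic mean of per-epoch CSDs over onset-aligned seizures.

    Shorter sequences contribute up to their length; the per-epoch
    ``n_avg`` records how many seizures entered each average.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need at least one sequence to average")
    if len({s.epoch_ms for s in sequences}) != 1:
        raise ValueError("sequences must share the epoch duration")
    n_max = max(len(s) for s in sequences)
    grid = sequences[0].grid
    out = []
    for i in range(n_max):
        stack = [s[i].csd for s in sequences if len(s) > i]
        out.append(EpochSpectrum(grid, np.mean(stack, axis=0), n_avg=len(stack)))
    prov = dict(sequences[0].provenance)
    prov["n_avg"] = len(sequences)
    return EpochSequence(out, epoch_ms=sequences[0].epoch_ms, provenance=prov)


# ---------------------------------------------------------------------------
# readers / writers

def write_delimited(rec: Recording, path: str | Path, extra: dict | None = None) -> None:
    """One column per channel, plus a JSON sidecar with the sampling rate."""
    path = Path(path)
    np.savetxt(path, rec.data.T, delimiter="\t",
               header="\t".join(rec.ch_names), comments="")
    meta = {"fs": rec.fs, "ch_names": rec.ch_names,
            "annotations": rec.annotations}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_delimited(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2).T
    return Recording(data, meta["fs"], meta.get("ch_names", []),
                     [tuple(a) for a in meta.get("annotations", [])])


def read_edf(path: str | Path) -> Recording:
    """Read an EDF recording (channels and annotations) via MNE."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    ann = [(a["description"], float(a["onset"]),
            float(a["onset"] + a["duration"])) for a in raw.annotations]
    return Recording(raw.get_data(), raw.info["sfreq"], list(raw.ch_names), ann)
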