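"""Electrogastrogram spectral analysis: the normo-to-tachy ratio (NTT).

Gastric myoelectrical activity cycles at about 3 cycles per minute (cpm) in
healthy, non-nauseated subjects ("normogastria").  Visually induced nausea
shifts power toward faster rhythms ("tachygastria"), so the ratio of
normogastric to tachygastric spectral power drops during nausea.

The analysis window is the last 300 s of a recording period, split into three
overlapping 3-min epochs advanced by 1 min (minutes 1–3, 2–4, 3–5).  Each
epoch is linearly detrended, tapered with a Hamming window, and its
periodogram summed over the normogastric band (2.5–3 cpm) and the
tachygastric band (3.75–9.75 cpm).  The NTT is the mean of the three epoch
ratios; its natural log is used in downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

DEFAULT_FS = 15.625  # Hz
NORMOGASTRIC_CPM = (2.5, 3.0)
TACHYGASTRIC_CPM = (3.75, 9.75)
WINDOW_SECONDS = 300.0
EPOCH_SECONDS = 180.0
EPOCH_STEP_SECONDS = 60.0


@dataclass
class EggTrace:
    """A raw electrogastrogram voltage trace sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class NttResult:
    epoch_ratios: np.ndarray  # normo/tachy power per epoch
    ntt: float  # arithmetic mean of the epoch ratios
    log_ntt: float  # natural log, used in statistics


def band_power(segment: np.ndarray, fs: float, band_cpm: tuple[float, float]) -> float:
    """Periodogram power of ``segment`` summed over a closed band in cpm.

    The segment is linearly detrended and tapered with a Hamming window before
    the FFT.  A bin belongs to the band when its center frequency, expressed
    in cycles per minute, lies in the closed interval ``band_cpm``.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) < 2:
        raise ValueError("segment must contain at least 2 samples")
    lo, hi = band_cpm
    nyquist_cpm = fs * 60.0 / 2.0
    if not (0 < lo <= hi < nyquist_cpm):
        raise ValueError(f"band {band_cpm} cpm outside (0, {nyquist_cpm}) cpm")
    detrended = sp_signal.detrend(segment, type="linear")
    tapered = detrended * np.hamming(len(segment))
    spec = np.fft.rfft(tapered)
    power = np.abs(spec) ** 2
    freqs_cpm = np.fft.rfftfreq(len(segment), d=1.0 / fs) * 60.0
    in_band = (freqs_cpm >= lo) & (freqs_cpm <= hi)
    if not in_band.any():
        resolution = freqs_cpm[1] if len(freqs_cpm) > 1 else np.nan
        raise ValueError(
            f"band {band_cpm} cpm contains no FFT bins at resolution "
            f"{resolution:.4f} cpm ({len(segment)} samples)"
        )
    return float(power[in_band].sum())


def compute_ntt(trace: EggTrace, period_end: float | None = None) -> NttResult:
    """NTT over the last 300 s of a period ending at ``period_end`` seconds.

    Three 3-min epochs advanced by 1 min; per-epoch ratio of normogastric to
    tachygastric power; NTT is the mean ratio and ``log_ntt`` its natural log.

    Raises if the trace does not cover the window or if any epoch has zero
    tachygastric power (the ratio would be undefined).
    """
    if period_end is None:
        period_end = trace.duration
    if period_end > trace.duration + 1e-9:
        raise ValueError(
            f"period_end {period_end:.1f}s beyond trace end {trace.duration:.1f}s"
        )
    if period_end < WINDOW_SECONDS:
        raise ValueError(
            f"trace covers {period_end:.1f}s before period_end; "
            f"{WINDOW_SECONDS:.0f}s required"
        )
    start = int(round((period_end - WINDOW_SECONDS) * trace.fs))
    window = trace.samples[start : start + int(round(WINDOW_SECONDS * trace.fs))]
    n_epoch = int(round(EPOCH_SECONDS * trace.fs))
    step = int(round(EPOCH_STEP_SECONDS * trace.fs))
    ratios = []
    for k in range(3):
        epoch = window[k * step : k * step + n_epoch]
        normo = band_power(epoch, trace.fs, NORMOGASTRIC_CPM)
        tachy = band_power(epoch, trace.fs, TACHYGASTRIC_CPM)
        if tachy <= 0:
            raise ValueError(f"epoch {k + 1}: zero tachygastric power, NTT undefined")
        ratios.append(normo / tachy)
    ratios = np.array(ratios)
    ntt = float(ratios.mean())
    return NttResult(epoch_ratios=ratios, ntt=ntt, log_ntt=float(np.log(ntt)))


def read_trace_tsv(path, fs: float = DEFAULT_FS) -> EggTrace:
    """Read a single-column TSV of voltages (time implicit from ``fs``)."""
    samples = np.loadtxt(path, dtype=float)
    return EggTrace(samples=np.atleast_1d(samples), fs=fs)
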