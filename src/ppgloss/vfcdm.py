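"""Variable-frequency complex demodulation (VFCDM) time-frequency spectra.

Complex demodulation isolates a narrow band around a center frequency
``f_c`` by multiplying the signal with ``exp(-j 2 pi f_c t)`` and low-pass
filtering; the filtered analytic component's magnitude and phase give the
band's instantaneous amplitude and frequency.  VFCDM runs this in two
stages:

1. *Fixed-frequency* stage: demodulate at a bank of fixed centers spaced
   ``2*Fw`` apart with a low-pass cutoff ``Fw``, so the bands tile the
   analysis range ``[0, f_max]`` without overlap.  This yields a coarse
   decomposition and, per band, an instantaneous-frequency trajectory.
2. *Variable-frequency* stage: re-demodulate the *original* signal along
   each band's instantaneous-frequency trajectory (cumulative-trapezoid
   phase) with a much narrower cutoff ``Fv``.  Because the carrier now
   tracks the band's content, the component sits near zero offset where
   the filter gain is ~1, which restores amplitude calibration even for
   content near a stage-1 band edge and produces the high-resolution
   spectrum.

The time-frequency spectrum deposits each refined component's amplitude at
its refined instantaneous frequency on a fixed grid (nearest bin; max on
collision, since the downstream statistic is a band maximum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, RecordError


@dataclass(frozen=True)
class VFCDMConfig:
    """Numeric parameters of the VFCDM analysis.

    Attributes
    ----------
    fs_d : float
        Analysis sampling rate in Hz; PPG at 80 Hz is decimated to 20 Hz,
        keeping Nyquist (10 Hz) far above heart-rate harmonics.
    fw : float
        Stage-1 low-pass cutoff in Hz; band centers sit at
        ``fw, 3*fw, 5*fw, ...`` so bands of width ``2*fw`` tile the axis.
        0.5 Hz separates the respiratory band (< 0.5 Hz) from the
        heart-rate band.
    fv : float
        Stage-2 low-pass cutoff in Hz; must be < fw ("high resolution").
    filter_len : int or None
        FIR low-pass length in taps, odd; None picks ``4*fs_d/fw`` rounded
        up to odd.
    f_max : float or None
        Top analysis frequency; None means ``fs_d / 2``.
    grid_step : float
        Frequency-grid spacing of the output spectrum, <= fv.
    """

    fs_d: float = 20.0
    fw: float = 0.5
    fv: float = 0.15
    filter_len: int | None = None
    f_max: float | None = None
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.fv < self.fw:
            raise ConfigError(f"need 0 < fv < fw, got fv={self.fv}, fw={self.fw}")
        if self.fs_d <= 0:
            raise ConfigError("fs_d must be positive")
        fmax = self.top_frequency
        n_bands = fmax / (2.0 * self.fw)
        if abs(n_bands - round(n_bands)) > 1e-9 or round(n_bands) < 1:
            raise ConfigError(
                f"f_max={fmax} is not an integer number of 2*fw={2 * self.fw} bands")
        if self.filter_len is not None and self.filter_len % 2 == 0:
            raise ConfigError(f"filter_len={self.filter_len} must be odd")
        if not 0.0 < self.grid_step <= self.fv:
            raise ConfigError("grid_step must lie in (0, fv]")

    @property
    def top_frequency(self) -> float:
        return self.fs_d / 2.0 if self.f_max is None else self.f_max

    @property
    def taps(self) -> int:
        if self.filter_len is not None:
            return self.filter_len
        n = int(np.ceil(4.0 * self.fs_d / self.fw))
        return n + 1 if n % 2 == 0 else n

    @property
    def band_centers(self) -> np.ndarray:
        """Stage-1 demodulation centers ``fw, 3*fw, ..., f_max - fw``."""
        return np.arange(self.fw, self.top_frequency, 2.0 * self.fw)

    @property
    def edge_samples(self) -> int:
        """Samples at each end contaminated by filter transients."""
        return self.taps // 2


@dataclass
class BandComponent:
    """One demodulated band: instantaneous amplitude/frequency/phase."""

    center_hz: float
    inst_amplitude: np.ndarray
    inst_frequency: np.ndarray
    inst_phase: np.ndarray

    def __post_init__(self) -> None:
        if (self.inst_amplitude < 0).any():
            raise ValueError("instantaneous amplitude must be nonnegative")


@dataclass
class TimeFrequencySpectrum:
    """Time x frequency amplitude grid with axis vectors.

    ``amplitude[i, k]`` is the instantaneous amplitude at ``times[i]``,
    ``freqs[k]`` in the units of the input signal.  The first and last
    ``edge_samples`` time samples carry filter transients and are excluded
    from downstream statistics (``interior`` mask).
    """

    times: np.ndarray
    freqs: np.ndarray
    amplitude: np.ndarray
    edge_samples: int = 0

    def __post_init__(self) -> None:
        if (np.diff(self.times) <= 0).any() or (np.diff(self.freqs) <= 0).any():
            raise ValueError("TFS axes must be strictly increasing")
        if self.amplitude.shape != (len(self.times), len(self.freqs)):
            raise ValueError("amplitude shape does not match axes")
        if (self.amplitude < 0).any():
            raise ValueError("TFS amplitudes must be nonnegative")

    @property
    def interior(self) -> np.ndarray:
        """Boolean mask of time samples free of filter edge transients."""
        mask = np.zeros(len(self.times), dtype=bool)
        e = self.edge_samples
        if 2 * e < len(self.times):
            mask[e:len(self.times) - e] = True
        return mask

    def band_max(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Per-time-sample maximum amplitude over ``[f_lo, f_hi]``."""
        cols = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not cols.any():
            raise ValueError(f"no grid frequencies in [{f_lo}, {f_hi}]")
        return self.amplitude[:, cols].max(axis=1)


def decimate(signal: np.ndarray, fs_native: float, fs_d: float) -> np.ndarray:
    """Anti-alias low-pass (cutoff 0.45*fs_d, zero phase) then subsample.

    ``fs_native`` must be an integer multiple of ``fs_d``.
    """
    x = np.asarray(signal, dtype=float)
    ratio = fs_native / fs_d
    if abs(ratio - round(ratio)) > 1e-9:
        raise RecordError(
            f"fs_native={fs_native} is not an integer multiple of fs_d={fs_d}")
    q = round(ratio)
    if q == 1:
        return x.copy()
    # 4*fs_native+1 taps: ~0.8 Hz transition at 80 Hz, comfortably inside
    # the 0.45..0.5*fs_d guard band
    numtaps = int(4 * fs_native) + 1
    h = sps.firwin(numtaps, 0.45 * fs_d, fs=fs_native)
    return sps.filtfilt(h, [1.0], x)[::q]


def _lowpass_taps(cutoff: float, config: VFCDMConfig) -> np.ndarray:
    return sps.firwin(config.taps, cutoff, fs=config.fs_d)


def _zero_phase_filter(z: np.ndarray, h: np.ndarray) -> np.ndarray:
    # symmetric odd-length FIR applied with 'same' alignment == zero phase
    return sps.fftconvolve(z, h, mode="same")


def _check_length(signal: np.ndarray, config: VFCDMConfig) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise RecordError("VFCDM expects a 1-D signal")
    if x.size <= config.taps:
        raise RecordError(
            f"signal of {x.size} samples is too short: need more than "
            f"{config.taps} (the FIR length)")
    return x


def fixed_cdm(signal: np.ndarray, fs_d: float,
              config: VFCDMConfig = VFCDMConfig()) -> list[BandComponent]:
    """Stage 1: fixed-frequency complex demodulation into tiling bands.

    For each center ``f_c`` the signal is multiplied by
    ``exp(-j 2 pi f_c t)`` and low-passed at cutoff ``fw`` with a
    zero-phase FIR.  Instantaneous amplitude is ``2*|filtered|``; the
    instantaneous phase is the unwrapped total phase and instantaneous
    frequency its central-difference derivative, clipped to the band
    ``f_c +- fw``.
    """
    if fs_d != config.fs_d:
        config = VFCDMConfig(fs_d=fs_d, fw=config.fw, fv=config.fv,
                             filter_len=config.filter_len, f_max=config.f_max,
                             grid_step=config.grid_step)
    x = _check_length(signal, config)
    t = np.arange(x.size) / config.fs_d
    dt = 1.0 / config.fs_d
    h = _lowpass_taps(config.fw, config)
    comps: list[BandComponent] = []
    for fc in config.band_centers:
        z = _zero_phase_filter(x * np.exp(-2j * np.pi * fc * t), h)
        amp = 2.0 * np.abs(z)
        resid_phase = np.unwrap(np.angle(z))
        phase = 2.0 * np.pi * fc * t + resid_phase
        freq = np.clip(np.gradient(phase, dt) / (2.0 * np.pi),
                       fc - config.fw, fc + config.fw)
        comps.append(BandComponent(center_hz=float(fc), inst_amplitude=amp,
                                   inst_frequency=freq, inst_phase=phase))
    return comps


def _refine_component(x: np.ndarray, comp: BandComponent,
                      h_v: np.ndarray, config: VFCDMConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2 for one band: re-demodulate along its frequency trajectory."""
    dt = 1.0 / config.fs_d
    carrier_phase = 2.0 * np.pi * np.concatenate(
        ([0.0], np.cumsum(0.5 * (comp.inst_frequency[1:] +
                                 comp.inst_frequency[:-1]) * dt)))
    z = _zero_phase_filter(x * np.exp(-1j * carrier_phase), h_v)
    amp = 2.0 * np.abs(z)
    resid = np.unwrap(np.angle(z))
    freq = comp.inst_frequency + np.gradient(resid, dt) / (2.0 * np.pi)
    return amp, freq


def vfcdm_tfs(signal: np.ndarray, fs_d: float,
              config: VFCDMConfig = VFCDMConfig()) -> TimeFrequencySpectrum:
    """Full two-stage VFCDM time-frequency spectrum.

    Stage-1 components provide instantaneous-frequency trajectories; the
    original signal is re-demodulated along each trajectory and low-passed
    at the narrower ``fv``.  Refined amplitudes are deposited at the
    nearest grid frequency (max-combine on collisions).
    """
    if fs_d != config.fs_d:
        config = VFCDMConfig(fs_d=fs_d, fw=config.fw, fv=config.fv,
                             filter_len=config.filter_len, f_max=config.f_max,
                             grid_step=config.grid_step)
    x = _check_length(signal, config)
    t = np.arange(x.size) / config.fs_d
    comps = fixed_cdm(x, config.fs_d, config)
    h_v = _lowpass_taps(config.fv, config)

    freqs = np.arange(0.0, config.top_frequency + 0.5 * config.grid_step,
                      config.grid_step)
    tfs = np.zeros((x.size, freqs.size))
    rows = np.arange(x.size)
    for comp in comps:
        amp, freq = _refine_component(x, comp, h_v, config)
        cols = np.clip(np.round(freq / config.grid_step).astype(int),
                       0, freqs.size - 1)
        np.maximum.at(tfs, (rows, cols), amp)
    return TimeFrequencySpectrum(times=t, freqs=freqs, amplitude=tfs,
                                 edge_samples=config.edge_samples)
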