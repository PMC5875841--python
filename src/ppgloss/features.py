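"""Heart-rate-band amplitude trend features from one PPG recording.

The pipeline per recording:

1. Select the cleanest channel (minimum Shannon entropy).
2. Cut the channel into 2-minute sequences; within each sequence slide a
   1-minute window in 10-second steps (7 windows per sequence).
3. For every window compute the VFCDM time-frequency spectrum, take the
   maximum amplitude over the heart-rate band per time sample, average
   over the window, then average the 7 window values: the sequence's mean
   heart-rate-band amplitude (AM_HR).
4. Fit an ordinary-least-squares line through the AM_HR values versus the
   sequence center times.  The feature vector is (r^2, slope, percentage
   change, signed change between the first and last AM_HR values).

Sign semantics: a positive slope / change indicates euvolemia, a negative
one hypovolemia, because the heart-rate-band spectral amplitude of the PPG
declines with progressive blood loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .entropy import EntropyConfig, select_channel
from .exceptions import ConfigError, RecordError
from .io import PPGRecord
from .vfcdm import VFCDMConfig, decimate, vfcdm_tfs


@dataclass(frozen=True)
class WindowScheme:
    """Sequence/window layout: 2-min sequences, 1-min windows, 10-s shifts.

    ``starts_s`` optionally fixes the sequence start times; by default the
    recording is cut into consecutive non-overlapping ``seq_len_s`` blocks
    (clinical recordings used irregular instants; synthetic ones need not).
    """

    seq_len_s: float = 120.0
    win_len_s: float = 60.0
    shift_s: float = 10.0
    starts_s: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.win_len_s < self.seq_len_s:
            raise ConfigError("need 0 < win_len_s < seq_len_s")
        k = (self.seq_len_s - self.win_len_s) / self.shift_s
        if abs(k - round(k)) > 1e-9:
            raise ConfigError(
                "(seq_len_s - win_len_s) must be divisible by shift_s")

    @property
    def n_windows(self) -> int:
        return round((self.seq_len_s - self.win_len_s) / self.shift_s) + 1

    def sequence_starts(self, duration_s: float) -> list[float]:
        if self.starts_s is not None:
            starts = [s for s in self.starts_s
                      if s + self.seq_len_s <= duration_s + 1e-9]
        else:
            starts = [float(s) for s in
                      np.arange(0.0, duration_s - self.seq_len_s + 1e-9,
                                self.seq_len_s)]
        return starts


@dataclass(frozen=True)
class HRBand:
    """Heart-rate frequency band, default 0.66-3.0 Hz (40-180 bpm).

    The lower edge stays above 0.5 Hz to exclude the respiratory
    component; the upper edge must remain below the analysis Nyquist.
    """

    f_lo: float = 0.66
    f_hi: float = 3.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.f_lo < self.f_hi:
            raise ConfigError("need 0.5 <= f_lo < f_hi")


@dataclass
class AMHRSeries:
    """Mean heart-rate-band amplitude per sequence, vs sequence centers."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size or self.times.size < 2:
            raise RecordError("AM_HR series needs >= 2 matched points")
        if (np.diff(self.times) <= 0).any():
            raise RecordError("AM_HR times must be strictly increasing")
        if (self.values < 0).any():
            raise RecordError("AM_HR values must be nonnegative")


@dataclass(frozen=True)
class FeatureVector:
    """The 4 trend features of one recording.

    r2 : goodness of fit of the AM_HR trend line, in [0, 1]
    slope : trend-line slope, signal units per second
    pct_change : 100 * (last - first) / first, percent
    abs_change : last - first, signal units (signed)
    """

    r2: float
    slope: float
    pct_change: float
    abs_change: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r2, self.slope, self.pct_change, self.abs_change])


@dataclass
class FeatureResult:
    """Features plus per-record audit trail."""

    vector: FeatureVector
    series: AMHRSeries
    channel_index: int
    channel_entropies: np.ndarray


_MIN_DURATION_FACTOR = 2  # >= 2 sequences, so a trend line exists


def extract_sequences(record: PPGRecord, scheme: WindowScheme = WindowScheme(),
                      channel: int | None = None,
                      entropy_config: EntropyConfig = EntropyConfig()
                      ) -> list[tuple[float, np.ndarray]]:
    """Cut the selected channel into full-length sequences.

    Returns ``(start_s, samples)`` pairs; partial trailing blocks are
    dropped.  ``channel=None`` triggers minimum-entropy selection.
    """
    min_dur = _MIN_DURATION_FACTOR * scheme.seq_len_s
    if record.duration_s < min_dur:
        raise RecordError(
            f"recording too short for trend analysis: {record.duration_s:.0f} s "
            f"< {min_dur:.0f} s (need >= 2 sequences of {scheme.seq_len_s:.0f} s)")
    if channel is None:
        channel, _ = select_channel(record, entropy_config)
    x = record.channel(channel)
    n_seq = round(scheme.seq_len_s * record.fs)
    out = []
    for start in scheme.sequence_starts(record.duration_s):
        i0 = round(start * record.fs)
        out.append((start, x[i0:i0 + n_seq]))
    if len(out) < 2:
        raise RecordError("fewer than 2 sequences fit the recording; "
                          "trend analysis needs at least 2 time points")
    return out


def amhr_from_sequence(sequence: np.ndarray, fs: float,
                       band: HRBand = HRBand(),
                       vfcdm_config: VFCDMConfig = VFCDMConfig(),
                       scheme: WindowScheme = WindowScheme()) -> float:
    """Mean heart-rate-band amplitude of one 2-minute sequence.

    The sequence is decimated once to the analysis rate; each 1-minute
    window gets a VFCDM spectrum whose interior band-maximum amplitudes
    are averaged over time, and the window values are averaged.
    """
    if band.f_hi > vfcdm_config.top_frequency:
        raise ConfigError(
            f"HR band upper edge {band.f_hi} Hz exceeds analysis Nyquist "
            f"{vfcdm_config.top_frequency} Hz")
    x_d = decimate(np.asarray(sequence, dtype=float), fs, vfcdm_config.fs_d)
    n_win = round(scheme.win_len_s * vfcdm_config.fs_d)
    n_shift = round(scheme.shift_s * vfcdm_config.fs_d)
    values = []
    for w in range(scheme.n_windows):
        seg = x_d[w * n_shift: w * n_shift + n_win]
        tfs = vfcdm_tfs(seg, vfcdm_config.fs_d, vfcdm_config)
        band_amp = tfs.band_max(band.f_lo, band.f_hi)
        values.append(float(band_amp[tfs.interior].mean()))
    return float(np.mean(values))


def trend_features(series: AMHRSeries) -> FeatureVector:
    """OLS trend line through the AM_HR series plus endpoint changes.

    A constant series (zero total variance) has no trend evidence: slope
    and r^2 are both 0.  ``pct_change`` requires a positive first value.
    """
    t = series.times
    v = series.values
    tc = t - t.mean()
    ss_tot = float(((v - v.mean()) ** 2).sum())
    if ss_tot == 0.0:
        slope, r2 = 0.0, 0.0
    else:
        slope = float((tc * (v - v.mean())).sum() / (tc ** 2).sum())
        resid = v - (v.mean() + slope * tc)
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    abs_change = float(v[-1] - v[0])
    if v[0] == 0.0:
        if abs_change == 0.0:
            pct_change = 0.0
        else:
            raise RecordError(
                "percentage change undefined: first AM_HR value is 0")
    else:
        pct_change = 100.0 * abs_change / float(v[0])
    return FeatureVector(r2=r2, slope=slope, pct_change=pct_change,
                         abs_change=abs_change)


def featurize_record(record: PPGRecord,
                     scheme: WindowScheme = WindowScheme(),
                     band: HRBand = HRBand(),
                     vfcdm_config: VFCDMConfig = VFCDMConfig(),
                     entropy_config: EntropyConfig = EntropyConfig()
                     ) -> FeatureResult:
    """Full per-record pipeline: channel -> sequences -> AM_HR -> trend."""
    channel, entropies = select_channel(record, entropy_config)
    seqs = extract_sequences(record, scheme, channel=channel)
    times = np.array([s + scheme.seq_len_s / 2.0 for s, _ in seqs])
    values = np.array([amhr_from_sequence(x, record.fs, band, vfcdm_config,
                                          scheme) for _, x in seqs])
    series = AMHRSeries(times=times, values=values)
    return FeatureResult(vector=trend_features(series), series=series,
                         channel_index=channel, channel_entropies=entropies)


def truncate_record(record: PPGRecord, max_duration_s: float) -> PPGRecord:
    """Keep only the leading ``max_duration_s`` seconds of a recording.

    Models early-detection analyses that see only the initial portion of a
    bleed.  If the record is already shorter, it is returned unchanged
    apart from a warning flag in its metadata.
    """
    if max_duration_s < _MIN_DURATION_FACTOR * WindowScheme().seq_len_s:
        raise RecordError(
            f"max_duration_s={max_duration_s} below the 240 s minimum "
            "for trend analysis")
    meta = dict(record.meta)
    if max_duration_s >= record.duration_s:
        warnings.warn(f"record {record.record_id} is only "
                      f"{record.duration_s:.0f} s; truncation to "
                      f"{max_duration_s:.0f} s is a no-op", stacklevel=2)
        meta["truncation_noop"] = True
        samples = record.samples.copy()
    else:
        meta["truncated_to_s"] = float(max_duration_s)
        samples = record.samples[: round(max_duration_s * record.fs)].copy()
    return PPGRecord(fs=record.fs, samples=samples,
                     channel_ids=list(record.channel_ids),
                     record_id=record.record_id, location=record.location,
                     label=record.label, start_time_s=record.start_time_s,
                     meta=meta)
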