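"""Seeded synthetic photoplethysmogram generator.

Emulates the statistical structure the downstream pipeline assumes: a
pulsatile component at the heart-rate fundamental with decaying-weight
harmonics, respiratory amplitude modulation (plus an additive respiratory
baseline component below 0.5 Hz), slow baseline wander, independent
per-channel Gaussian noise (so entropy-based channel selection has work to
do), and a linear decay of the heart-rate-band amplitude over the recording
for the blood-loss class.

The envelope model is linear, matching the trend-line analysis applied
downstream: ``a(t) = hr_amp0 * (1 - amp_decay_frac * t / duration_s)``.
``amp_decay_frac > 0`` mimics progressive blood loss; values near 0 (small
positive or negative drifts) mimic euvolemia.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError
from .io import PPGRecord


def _harmonic_weights(n_harmonics: int) -> np.ndarray:
    # 1/(k+1) weights: a plausible PPG pulse shape whose largest spectral
    # line stays at the fundamental, which is what the HR-band statistic
    # tracks.  Exact morphology is irrelevant to the method.
    return 1.0 / (1.0 + np.arange(n_harmonics + 1))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated PPG recording.

    Attributes
    ----------
    duration_s : float
        Recording length in seconds.
    fs : float
        Sampling rate in Hz (80 Hz is the native rate of the pulse
        oximeters this emulates).
    hr_hz : float
        Heart-rate fundamental in Hz (1.2 Hz = 72 bpm).
    hr_amp0 : float
        Initial amplitude of the heart-rate fundamental, arbitrary units.
    amp_decay_frac : float
        Fractional change of the HR-band envelope from start to end;
        positive = decay (hypovolemia-like), small/negative = euvolemic
        drift.  Allowed range [-1, 1].
    resp_hz : float
        Respiratory frequency in Hz; must stay below 0.5 Hz.
    resp_mod_frac : float
        Fractional respiratory amplitude modulation of the pulse, also the
        relative amplitude of the additive respiratory baseline component.
    n_harmonics : int
        Number of harmonics above the fundamental.
    channel_noise_sd : tuple of float
        Additive white-noise SD per channel; the list length sets the
        channel count.
    wander_amp, wander_hz : float
        Baseline-wander sinusoid amplitude and frequency.
    seed : int
        Seed; identical seeds give bit-identical records.
    """

    duration_s: float = 600.0
    fs: float = 80.0
    hr_hz: float = 1.2
    hr_amp0: float = 1.0
    amp_decay_frac: float = 0.0
    resp_hz: float = 0.3
    resp_mod_frac: float = 0.1
    n_harmonics: int = 2
    channel_noise_sd: tuple[float, ...] = (0.02, 0.1, 0.3)
    wander_amp: float = 0.2
    wander_hz: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.hr_hz * (self.n_harmonics + 1):
            raise ConfigError(
                f"fs={self.fs} violates fs > 2*hr_hz*(n_harmonics+1)="
                f"{2.0 * self.hr_hz * (self.n_harmonics + 1)}")
        if not -1.0 <= self.amp_decay_frac <= 1.0:
            raise ConfigError(
                f"amp_decay_frac={self.amp_decay_frac} outside [-1, 1]")
        if not 0.0 < self.resp_hz < 0.5:
            raise ConfigError(f"resp_hz={self.resp_hz} must lie in (0, 0.5)")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"duration_s*fs={n} is not an integer sample count")
        if len(self.channel_noise_sd) < 1:
            raise ConfigError("need at least one channel noise SD")
        if any(sd < 0 for sd in self.channel_noise_sd):
            raise ConfigError("channel noise SDs must be nonnegative")
        if self.hr_amp0 < 0 or self.wander_amp < 0 or self.resp_mod_frac < 0:
            raise ConfigError("amplitudes must be nonnegative")


def simulate_record(config: SimConfig, record_id: str = "sim",
                    label: str | None = None,
                    location: str = "unknown") -> PPGRecord:
    """Simulate one multi-channel PPG record.

    Every channel shares the deterministic waveform and differs only in its
    additive Gaussian noise, drawn channel-by-channel from a generator
    seeded with ``config.seed``.
    """
    n = round(config.duration_s * config.fs)
    t = np.arange(n) / config.fs

    envelope = config.hr_amp0 * (1.0 - config.amp_decay_frac * t / config.duration_s)
    resp = np.sin(2.0 * np.pi * config.resp_hz * t)
    weights = _harmonic_weights(config.n_harmonics)
    pulse = np.zeros(n)
    for k, c_k in enumerate(weights):
        pulse += c_k * np.sin(2.0 * np.pi * (k + 1) * config.hr_hz * t)

    clean = envelope * (1.0 + config.resp_mod_frac * resp) * pulse
    # additive respiratory baseline: the strong sub-0.5 Hz component seen
    # in real PPG time-frequency spectra
    clean = clean + config.resp_mod_frac * envelope * resp
    clean = clean + config.wander_amp * np.sin(2.0 * np.pi * config.wander_hz * t)

    rng = np.random.default_rng(config.seed)
    samples = np.empty((n, len(config.channel_noise_sd)))
    for j, sd in enumerate(config.channel_noise_sd):
        noise = rng.standard_normal(n) * sd if sd > 0 else 0.0
        samples[:, j] = clean + noise

    return PPGRecord(
        fs=config.fs,
        samples=samples,
        channel_ids=[f"ch_{j}" for j in range(samples.shape[1])],
        record_id=record_id,
        location=location,
        label=label,
        meta={"amp_decay_frac": config.amp_decay_frac,
              "hr_hz": config.hr_hz, "seed": config.seed},
    )


@dataclass(frozen=True)
class CohortSpec:
    """A labeled cohort of simulated recordings.

    Per-record heart rates and envelope-decay fractions are drawn from
    class-specific uniform ranges; everything else comes from ``base``.
    The blood-loss class must draw its decay from a strictly positive
    range, the no-blood-loss class from a range straddling zero.
    """

    n_bl: int = 29
    n_nbl: int = 65
    bl_decay_range: tuple[float, float] = (0.3, 0.6)
    nbl_decay_range: tuple[float, float] = (-0.05, 0.05)
    hr_hz_range: tuple[float, float] = (0.9, 1.5)
    duration_s: float = 600.0
    seed: int = 0
    base: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.n_bl < 1 or self.n_nbl < 1:
            raise ConfigError("n_bl and n_nbl must both be >= 1")
        if self.bl_decay_range[0] <= 0:
            raise ConfigError("bl_decay_range must be strictly positive")
        for lo, hi in (self.bl_decay_range, self.nbl_decay_range,
                       self.hr_hz_range):
            if lo > hi:
                raise ConfigError(f"empty range ({lo}, {hi})")


def _record_seed(master_seed: int, index: int) -> int:
    """Deterministic, platform-portable per-record seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(spec: CohortSpec) -> list[tuple[PPGRecord, str]]:
    """Simulate a labeled cohort; a pure function of the spec.

    Returns ``n_bl + n_nbl`` ``(record, label)`` pairs, blood-loss records
    first.  Per-record seeds and parameter draws derive deterministically
    from the master seed.
    """
    param_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xC0,)))
    out: list[tuple[PPGRecord, str]] = []
    plan = [("BL", spec.n_bl, spec.bl_decay_range),
            ("NBL", spec.n_nbl, spec.nbl_decay_range)]
    index = 0
    for label, count, decay_range in plan:
        for i in range(count):
            hr = param_rng.uniform(*spec.hr_hz_range)
            decay = param_rng.uniform(*decay_range)
            cfg = replace(spec.base, duration_s=spec.duration_s, hr_hz=hr,
                          amp_decay_frac=decay,
                          seed=_record_seed(spec.seed, index))
            rec = simulate_record(cfg, record_id=f"{label.lower()}_{i:03d}",
                                  label=label)
            out.append((rec, label))
            index += 1
    return out


def clinical_cohort(seed: int = 0, **overrides) -> CohortSpec:
    """Preset mirroring the clinical class imbalance: 65 NBL vs 29 BL."""
    return CohortSpec(n_bl=29, n_nbl=65, seed=seed, **overrides)
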