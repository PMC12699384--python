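"""Seeded noise synthesis, level calibration and stimulus assembly.

All maskers are generated as pure functions of a :class:`NoiseSpec`, so a
session only needs to store per-trial seeds to be able to rebuild every
waveform bit-for-bit later.  Levels are handled on a dB-full-scale (dBFS)
convention: a waveform with RMS 1.0 is said to play back at ``dbfs_ref`` dB
SPL (default 100 dB), so ``set_level(w, 65)`` scales to RMS ``10**(-35/20)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as sps

__all__ = [
    "Waveform",
    "NoiseSpec",
    "NOISE_KINDS",
    "generate_noise",
    "set_level",
    "mix_at_snr",
    "rove_level",
    "apply_ramps",
    "pure_tone",
]

DEFAULT_DBFS = 100.0  # full-scale calibration: RMS 1.0 <-> 100 dB SPL


@dataclass(frozen=True)
class Waveform:
    """Calibrated mono audio buffer.

    Parameters
    ----------
    samples : ndarray
        Sample values in full-scale units.
    rate : float
        Sampling rate in Hz.
    dbfs_ref : float
        SPL (dB) at which an RMS of 1.0 is presented.
    """

    samples: np.ndarray
    rate: float
    dbfs_ref: float = DEFAULT_DBFS

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def __len__(self) -> int:
        return self.samples.size


NOISE_KINDS = ("white", "pink", "bump", "mps")


@dataclass(frozen=True)
class NoiseSpec:
    """Recipe for one reproducible masker waveform.

    ``kind_params`` carries kind-specific knobs: bump noise accepts
    ``n_bumps``, ``bump_db`` (peak gain, default 10 dB), ``sigma_f_erb`` and
    ``sigma_t_s``; MPS noise accepts ``fm_cutoff_hz`` (temporal-modulation
    low-pass, default 40 Hz) and ``sm_cutoff_cpo`` (spectral modulation,
    cycles/octave).
    """

    kind: str
    duration_s: float
    rate: float
    seed: int
    kind_params: Mapping[str, float] = field(default_factory=dict)
    dbfs_ref: float = DEFAULT_DBFS

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(
                f"unknown noise kind {self.kind!r}; supported kinds: {NOISE_KINDS}"
            )
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "duration_s": self.duration_s,
            "rate": self.rate,
            "seed": int(self.seed),
            "kind_params": dict(self.kind_params),
            "dbfs_ref": self.dbfs_ref,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseSpec":
        return cls(
            kind=d["kind"],
            duration_s=float(d["duration_s"]),
            rate=float(d["rate"]),
            seed=int(d["seed"]),
            kind_params=dict(d.get("kind_params", {})),
            dbfs_ref=float(d.get("dbfs_ref", DEFAULT_DBFS)),
        )


def generate_noise(spec: NoiseSpec) -> Waveform:
    """Synthesize the masker described by ``spec``.

    Deterministic: the same spec always yields bitwise-identical samples.
    The output is zero-mean with RMS 1.0 (i.e. at the full-scale reference
    level); use :func:`set_level` to calibrate.
    """
    n = int(round(spec.duration_s * spec.rate))
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "white":
        x = rng.standard_normal(n)
    elif spec.kind == "pink":
        x = _spectrally_shaped(rng, n, slope=-0.5)
    elif spec.kind == "bump":
        x = _bump_noise(rng, n, spec.rate, spec.kind_params)
    elif spec.kind == "mps":
        x = _mps_noise(rng, n, spec.rate, spec.kind_params)
    else:  # pragma: no cover - guarded by NoiseSpec
        raise ValueError(spec.kind)
    x = x - x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x / rms
    return Waveform(x, spec.rate, spec.dbfs_ref)


def _spectrally_shaped(rng, n, slope):
    """White Gaussian noise with amplitude spectrum ~ f**slope (f > 0)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** slope
    return np.fft.irfft(spec * gain, n)


def _stft_frames(rate):
    # 512-point Hann frames with 75% overlap: ~23 ms analysis windows at 16 kHz
    nper = min(512, 256)
    return dict(nperseg=nper, noverlap=3 * nper // 4, window="hann")


def _bump_noise(rng, n, rate, params):
    """White-spectrum masker with sparse 2-D Gaussian envelope bumps.

    The short-time log-magnitude of a white-noise seed is boosted by a sparse
    sum of 2-D Gaussians (peak gain ``bump_db``, default 10 dB), then the
    signal is rebuilt with the original phases.  Bump centers are drawn
    uniformly over the time-frequency plane, so the long-term averaged
    spectrum stays flat in expectation while envelope fluctuations grow.
    """
    n_bumps = int(params.get("n_bumps", 30))
    bump_db = float(params.get("bump_db", 10.0))
    sigma_t = float(params.get("sigma_t_s", 0.02))
    sigma_f = float(params.get("sigma_f_hz", rate / 40.0))

    x = rng.standard_normal(n)
    kw = _stft_frames(rate)
    f, t, Z = sps.stft(x, fs=rate, **kw)
    gain_db = np.zeros((f.size, t.size))
    for _ in range(n_bumps):
        fc = rng.uniform(f[1], f[-1])
        tc = rng.uniform(t[0], t[-1])
        gain_db += bump_db * np.exp(
            -0.5 * (((f[:, None] - fc) / sigma_f) ** 2 + ((t[None, :] - tc) / sigma_t) ** 2)
        )
    Z = Z * 10 ** (gain_db / 20.0)
    _, y = sps.istft(Z, fs=rate, **kw)
    return y[:n] if y.size >= n else np.pad(y, (0, n - y.size))


def _mps_noise(rng, n, rate, params, n_griffin_lim=8):
    """Masker low-pass filtered in the modulation-power-spectrum domain.

    The 2-D Fourier transform of the log short-time magnitude of a white
    noise seed is low-passed below ``fm_cutoff_hz`` temporal and
    ``sm_cutoff_cpo`` spectral modulation; the waveform is rebuilt by a few
    Griffin–Lim phase-reconstruction iterations.  An approximation to the
    original "sMPS" generator (property-matched, not bit-matched).
    """
    fm_cut = float(params.get("fm_cutoff_hz", 40.0))
    sm_cut = float(params.get("sm_cutoff_cpo", 2.0))

    x = rng.standard_normal(n)
    kw = _stft_frames(rate)
    f, t, Z = sps.stft(x, fs=rate, **kw)
    logmag = np.log(np.abs(Z) + 1e-12)
    M = np.fft.fft2(logmag)
    # modulation axes: temporal (Hz) from frame spacing, spectral (cyc/oct approx
    # via cycles per kHz scaled) from channel spacing
    dt = t[1] - t[0] if t.size > 1 else 1.0
    df = f[1] - f[0] if f.size > 1 else 1.0
    wm_t = np.fft.fftfreq(t.size, d=dt)  # Hz
    wm_f = np.fft.fftfreq(f.size, d=df)  # cycles per Hz
    sm_cut_cphz = sm_cut / 1000.0  # coarse cycles/octave -> cycles/Hz near 1 kHz
    mask = (np.abs(wm_t)[None, :] <= fm_cut) & (np.abs(wm_f)[:, None] <= sm_cut_cphz)
    logmag_lp = np.real(np.fft.ifft2(M * mask))
    target_mag = np.exp(logmag_lp)

    # Griffin-Lim: iterate magnitude substitution / phase re-estimation
    phase = np.exp(1j * rng.uniform(0, 2 * np.pi, size=target_mag.shape))
    for _ in range(n_griffin_lim):
        Z = target_mag * phase
        _, y = sps.istft(Z, fs=rate, **kw)
        _, _, Z2 = sps.stft(y[:n] if y.size >= n else np.pad(y, (0, n - y.size)), fs=rate, **kw)
        Z2 = Z2[:, : target_mag.shape[1]]
        if Z2.shape != target_mag.shape:
            pad = target_mag.shape[1] - Z2.shape[1]
            Z2 = np.pad(Z2, ((0, 0), (0, pad)))
        phase = np.exp(1j * np.angle(Z2))
    _, y = sps.istft(target_mag * phase, fs=rate, **kw)
    return y[:n] if y.size >= n else np.pad(y, (0, n - y.size))


def set_level(w: Waveform, level_db_spl: float, dbfs_ref: float | None = None) -> Waveform:
    """Scale ``w`` so it plays back at ``level_db_spl`` dB SPL.

    Output RMS is ``10**((level_db_spl - dbfs_ref) / 20)``.  Idempotent on the
    final level and invariant to any prior scaling of the input.
    """
    if dbfs_ref is None:
        dbfs_ref = w.dbfs_ref
    rms = w.rms
    if rms == 0:
        raise ValueError("cannot set the level of a silent waveform")
    target = 10 ** ((level_db_spl - dbfs_ref) / 20.0)
    return replace(w, samples=w.samples * (target / rms), dbfs_ref=dbfs_ref)


def pure_tone(freq_hz: float, duration_s: float, rate: float,
              dbfs_ref: float = DEFAULT_DBFS, ramp_s: float = 0.0) -> Waveform:
    """Unit-RMS sine tone, optionally with raised-cosine on/off ramps."""
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    x = np.sqrt(2.0) * np.sin(2 * np.pi * freq_hz * t)
    w = Waveform(x, rate, dbfs_ref)
    if ramp_s > 0:
        w = apply_ramps(w, ramp_s)
    return w


def apply_ramps(w: Waveform, ramp_s: float = 0.01) -> Waveform:
    """Apply raised-cosine fade-in/fade-out ramps of ``ramp_s`` seconds."""
    n_r = int(round(ramp_s * w.rate))
    if n_r == 0:
        return w
    if 2 * n_r > len(w):
        raise ValueError("ramps longer than the waveform")
    env = np.ones(len(w))
    r = 0.5 * (1 - np.cos(np.pi * np.arange(n_r) / n_r))
    env[:n_r] = r
    env[-n_r:] = r[::-1]
    return replace(w, samples=w.samples * env)


def mix_at_snr(target: Waveform, noise: Waveform, snr_db: float,
               mode: str = "broadband_rms", offset_s: float | None = None
               ) -> Waveform:
    """Add ``target`` into ``noise`` at a fixed signal-to-noise ratio.

    ``mode='broadband_rms'`` scales the target so the RMS ratio over the
    target's support equals ``snr_db``.  ``mode='es_over_n0'`` interprets
    ``snr_db`` as 10·log10(Es/N0), with Es the target energy (sum of squared
    samples over the sampling rate) and N0 the noise power spectral density
    (noise power divided by the Nyquist bandwidth) — the classic tone-in-noise
    convention.  The target is centered in time unless ``offset_s`` is given.
    """
    if target.rate != noise.rate:
        raise ValueError("target and noise sampling rates differ")
    if len(target) > len(noise):
        raise ValueError("target longer than noise")
    if mode not in ("broadband_rms", "es_over_n0"):
        raise ValueError(f"unknown mode {mode!r}")

    if offset_s is None:
        start = (len(noise) - len(target)) // 2
    else:
        start = int(round(offset_s * noise.rate))
        if start < 0 or start + len(target) > len(noise):
            raise ValueError("target does not fit in noise at this offset")

    t_rms = target.rms
    if t_rms == 0:
        return replace(noise, samples=noise.samples.copy())

    if mode == "broadband_rms":
        seg = noise.samples[start:start + len(target)]
        n_rms = np.sqrt(np.mean(seg**2))
        scale = 10 ** (snr_db / 20.0) * n_rms / t_rms
    else:
        es = float(np.sum(target.samples**2)) / target.rate
        n0 = float(np.mean(noise.samples**2)) / (noise.rate / 2.0)
        scale = np.sqrt(10 ** (snr_db / 10.0) * n0 / es)

    out = noise.samples.copy()
    out[start:start + len(target)] += scale * target.samples
    return replace(noise, samples=out)


def rove_level(w: Waveform, range_db: float, rng: np.random.Generator
               ) -> tuple[Waveform, float]:
    """Apply a random level rove uniform on [-range_db, +range_db]."""
    if range_db < 0:
        raise ValueError("range_db must be >= 0")
    offset = float(rng.uniform(-range_db, range_db)) if range_db > 0 else 0.0
    return replace(w, samples=w.samples * 10 ** (offset / 20.0)), offset
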