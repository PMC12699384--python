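"""Time-frequency representations of waveforms for observers and estimators.

The default front-end is a gammatone spectrogram: a 4th-order gammatone
filterbank on an ERB-number axis (0.5-ERB spacing from 45.8 Hz to 8 kHz gives
64 channels), followed by a simplified inner-hair-cell envelope stage
(half-wave rectification plus a first-order 1-kHz low-pass), averaged into
10-ms frames.  A coarse band/segment energy grid (the classic 5x5 layout of
early tone-in-noise reverse-correlation work) is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signals import Waveform

__all__ = [
    "erb_scale",
    "erb_to_hz",
    "erb_centers",
    "gammatone_spectrogram",
    "coarse_energy_grid",
    "ReprSpec",
    "StimulusTensor",
    "dataload",
    "zscore_pixels",
    "represent",
]

# Glasberg & Moore ERB-rate constants
_ERB_A = 21.4
_ERB_B = 0.00437


def erb_scale(f_hz):
    """ERB-number of frequency ``f_hz`` (Glasberg-Moore ERB-rate scale)."""
    f = np.asarray(f_hz, dtype=float)
    out = _ERB_A * np.log10(_ERB_B * f + 1.0)
    return float(out) if np.isscalar(f_hz) else out


def erb_to_hz(erb):
    e = np.asarray(erb, dtype=float)
    out = (10 ** (e / _ERB_A) - 1.0) / _ERB_B
    return float(out) if np.isscalar(erb) else out


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth (Hz) of the auditory filter at f_hz."""
    return 24.7 * (_ERB_B * np.asarray(f_hz, dtype=float) + 1.0)


def erb_centers(f_min_hz: float, f_max_hz: float, step_erb: float = 0.5) -> np.ndarray:
    """Filterbank center frequencies spaced every ``step_erb`` ERB-numbers.

    Centers start at the ERB-number of ``f_min_hz`` and step upward without
    exceeding the ERB-number of ``f_max_hz``.  The default grid (45.8 Hz to
    8 kHz, 0.5 ERB) has 64 centers, the last at ERB-number
    ``erb_scale(45.8) + 63 * 0.5``.
    """
    if not (0 < f_min_hz < f_max_hz):
        raise ValueError("need 0 < f_min_hz < f_max_hz")
    if not step_erb > 0:
        raise ValueError("step_erb must be positive")
    e0, e1 = erb_scale(f_min_hz), erb_scale(f_max_hz)
    n = int(np.floor((e1 - e0) / step_erb + 1e-9)) + 1
    return erb_to_hz(e0 + step_erb * np.arange(n))


def gammatone_spectrogram(w: Waveform, centers: Sequence[float],
                          binwidth_s: float = 0.01,
                          ihc_cutoff_hz: float = 1000.0) -> np.ndarray:
    """Gammatone-filterbank envelope spectrogram, shape (n_f, n_t).

    Each channel is a 4th-order gammatone filter (spectral-domain magnitude
    response ``[1 + ((f - fc)/b)^2]^-2`` with ``b = 1.019 ERB(fc)``), followed
    by half-wave rectification and a first-order low-pass at
    ``ihc_cutoff_hz`` (simplified inner hair cell).  Envelopes are averaged
    in half-open ``binwidth_s`` bins.
    """
    centers = np.asarray(centers, dtype=float)
    if w.rate < 2 * centers.max():
        raise ValueError("sampling rate below Nyquist for the highest channel")
    x = w.samples
    n = x.size
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / w.rate)
    b_lp, a_lp = sps.butter(1, ihc_cutoff_hz / (w.rate / 2.0))

    n_t = int(np.floor(n / (binwidth_s * w.rate) + 1e-9))
    frame = int(round(binwidth_s * w.rate))
    out = np.empty((centers.size, n_t))
    for i, fc in enumerate(centers):
        b = 1.019 * float(erb_bandwidth(fc))
        H = (1.0 + ((f - fc) / b) ** 2) ** -2.0
        y = np.fft.irfft(X * H, n)
        env = sps.lfilter(b_lp, a_lp, np.maximum(y, 0.0))
        out[i] = env[: n_t * frame].reshape(n_t, frame).mean(axis=1)
    return out


def coarse_energy_grid(w: Waveform, f_edges: Sequence[float],
                       t_edges: Sequence[float]) -> np.ndarray:
    """Band x segment energy matrix over a coarse time-frequency grid.

    ``f_edges`` (Hz) and ``t_edges`` (s) are monotone cell boundaries; the
    result has shape ``(len(f_edges)-1, len(t_edges)-1)``.  Energies are
    summed from a magnitude-squared STFT, so scaling the waveform by ``k``
    scales every cell by ``k**2``.
    """
    f_edges = np.asarray(f_edges, dtype=float)
    t_edges = np.asarray(t_edges, dtype=float)
    if f_edges.size < 2 or np.any(np.diff(f_edges) <= 0):
        raise ValueError("f_edges must be increasing with >= 2 values")
    if t_edges.size < 2 or np.any(np.diff(t_edges) <= 0):
        raise ValueError("t_edges must be increasing with >= 2 values")
    if f_edges[-1] > w.rate / 2 + 1e-9:
        raise ValueError("f_edges exceed Nyquist")
    if t_edges[-1] > w.duration + 1e-9:
        raise ValueError("t_edges exceed waveform duration")

    nper = max(16, min(256, len(w) // 8))
    f, t, Z = sps.stft(w.samples, fs=w.rate, nperseg=nper, noverlap=nper // 2)
    P = np.abs(Z) ** 2
    out = np.empty((f_edges.size - 1, t_edges.size - 1))
    for i in range(f_edges.size - 1):
        fi = (f >= f_edges[i]) & (f < f_edges[i + 1])
        for j in range(t_edges.size - 1):
            tj = (t >= t_edges[j]) & (t < t_edges[j + 1])
            out[i, j] = P[np.ix_(fi, tj)].sum()
    return out


@dataclass(frozen=True)
class ReprSpec:
    """Options for converting waveforms to analysis matrices.

    Keys mirror the post-processing conventions of the field: ``tf_type``
    ("gammatone", "spect" or "coarse_grid"), ``bwmul`` (channel spacing in
    ERB), ``binwidth`` (s), ``f_limits``/``t_limits`` crop windows, and
    ``zscore`` (apply per-pixel z-scoring downstream).
    """

    tf_type: str = "gammatone"
    bwmul: float = 0.5
    binwidth: float = 0.01
    f_limits: tuple[float, float] = (45.8, 8000.0)
    t_limits: tuple[float, float] | None = None
    zscore: bool = True
    # coarse_grid only:
    f_edges: tuple[float, ...] | None = None
    t_edges: tuple[float, ...] | None = None
    ihc_cutoff_hz: float = 1000.0

    def to_dict(self) -> dict:
        d = {
            "tf_type": self.tf_type, "bwmul": self.bwmul,
            "binwidth": self.binwidth, "f_limits": list(self.f_limits),
            "t_limits": list(self.t_limits) if self.t_limits else None,
            "zscore": self.zscore, "ihc_cutoff_hz": self.ihc_cutoff_hz,
            "f_edges": list(self.f_edges) if self.f_edges else None,
            "t_edges": list(self.t_edges) if self.t_edges else None,
        }
        return d

    @classmethod
    def from_dict(cls, d) -> "ReprSpec":
        return cls(
            tf_type=d.get("tf_type", "gammatone"),
            bwmul=float(d.get("bwmul", 0.5)),
            binwidth=float(d.get("binwidth", 0.01)),
            f_limits=tuple(d.get("f_limits", (45.8, 8000.0))),
            t_limits=tuple(d["t_limits"]) if d.get("t_limits") else None,
            zscore=bool(d.get("zscore", True)),
            f_edges=tuple(d["f_edges"]) if d.get("f_edges") else None,
            t_edges=tuple(d["t_edges"]) if d.get("t_edges") else None,
            ihc_cutoff_hz=float(d.get("ihc_cutoff_hz", 1000.0)),
        )


def represent(w: Waveform, spec: ReprSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the front-end in ``spec`` to one waveform.

    Returns ``(matrix, freq_axis, time_axis)`` with matrix shape (n_f, n_t),
    cropped to the spec's t/f limits.
    """
    if spec.tf_type == "gammatone":
        f_lo, f_hi = spec.f_limits
        centers = erb_centers(f_lo, min(f_hi, w.rate / 2 * 0.999), spec.bwmul)
        mat = gammatone_spectrogram(w, centers, spec.binwidth, spec.ihc_cutoff_hz)
        t_axis = (np.arange(mat.shape[1]) + 0.5) * spec.binwidth
        f_axis = centers
    elif spec.tf_type == "spect":
        nper = 512 if len(w) >= 512 else len(w)
        f_axis, t_axis, Z = sps.stft(w.samples, fs=w.rate, nperseg=nper, noverlap=0)
        mat = np.abs(Z)
        f_lo, f_hi = spec.f_limits
        keep = (f_axis >= f_lo) & (f_axis <= f_hi)
        mat, f_axis = mat[keep], f_axis[keep]
    elif spec.tf_type == "coarse_grid":
        if spec.f_edges is None or spec.t_edges is None:
            raise ValueError("coarse_grid requires f_edges and t_edges")
        mat = coarse_energy_grid(w, spec.f_edges, spec.t_edges)
        f_axis = 0.5 * (np.asarray(spec.f_edges[:-1]) + np.asarray(spec.f_edges[1:]))
        t_axis = 0.5 * (np.asarray(spec.t_edges[:-1]) + np.asarray(spec.t_edges[1:]))
        return mat, f_axis, t_axis
    else:
        raise ValueError(f"unknown tf_type {spec.tf_type!r}")

    if spec.t_limits is not None:
        t_lo, t_hi = spec.t_limits
        keep = (t_axis - 0.5 * spec.binwidth >= t_lo - 1e-12) & \
               (t_axis + 0.5 * spec.binwidth <= t_hi + 1e-12)
        mat, t_axis = mat[:, keep], t_axis[keep]
    return mat, f_axis, t_axis


@dataclass
class StimulusTensor:
    """trials x frequency x time noise representation.

    The first axis follows presentation order.  ``zscored`` marks per-pixel
    standardization across trials; ``const_mask`` flags pixels that were
    constant (set to zero by z-scoring).
    """

    data: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    zscored: bool = False
    source: str = "noise_alone"
    const_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x n_f x n_t")
        if self.data.shape[1] != len(self.freq_axis) or \
           self.data.shape[2] != len(self.time_axis):
            raise ValueError("axis lengths do not match data shape")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def as_matrix(self) -> np.ndarray:
        """Flatten to (n_trials, n_f * n_t) with C pixel ordering."""
        return self.data.reshape(self.n_trials, -1)

    def subset(self, idx) -> "StimulusTensor":
        return StimulusTensor(self.data[idx], self.freq_axis, self.time_axis,
                              self.zscored, self.source, self.const_mask)


def dataload(session, repr_spec: ReprSpec | None = None,
             source: str = "noise_alone") -> StimulusTensor:
    """Build the trials x freq x time tensor for a recorded session.

    Waveforms are regenerated from the per-trial noise seeds stored in the
    session (``source='noise_alone'``, the default) or reassembled with the
    target (``source='noisy_stimulus'``); trials are ordered by presentation.
    """
    from .experiment import rebuild_noise, rebuild_stimulus  # lazy: avoid cycle

    if repr_spec is None:
        repr_spec = ReprSpec()
    mats = []
    for i in range(session.n_trials):
        w = rebuild_noise(session, i) if source == "noise_alone" \
            else rebuild_stimulus(session, i)
        mat, f_axis, t_axis = represent(w, repr_spec)
        mats.append(mat)
    return StimulusTensor(np.stack(mats), f_axis, t_axis, source=source)


def zscore_pixels(t: StimulusTensor) -> StimulusTensor:
    """Standardize each pixel independently across trials.

    After the call every non-constant pixel has mean 0 and SD 1 along the
    trial axis; constant pixels are set to 0 and flagged in ``const_mask``.
    Idempotent.
    """
    if t.n_trials < 2:
        raise ValueError("z-scoring requires at least 2 trials")
    mu = t.data.mean(axis=0)
    sd = t.data.std(axis=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    z = (t.data - mu) / sd_safe
    z[:, const] = 0.0
    return StimulusTensor(z, t.freq_axis, t.time_axis, zscored=True,
                          source=t.source, const_mask=const)
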