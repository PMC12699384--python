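"""Persistence: session archives, seed-based waveform regeneration, results.

A session archive is a directory holding ``config.json`` (the experiment
protocol, a version tag and per-waveform checksums), ``trials.csv`` (the
presentation-order trial table) and ``schedule.json`` (stim order / target
assignment).  Because every masker is a pure function of its stored seed,
the ``NoiseStim`` WAV folder can be deleted at any time and regenerated
bit-exactly; checksums guard against seed tampering.  Classification-image
results are stored as HDF5 (weights, axes, lambda path, validation) with a
JSON metadata attribute.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import (ExperimentConfig, SessionData, noise_seed,
                         rebuild_noise)
from .signals import Waveform

__all__ = [
    "save_session",
    "load_session",
    "regenerate_waveforms",
    "write_wav",
    "read_wav",
    "save_aci",
    "load_aci",
    "ARCHIVE_VERSION",
]

ARCHIVE_VERSION = "revaci-session-1"


def write_wav(path, w: Waveform) -> None:
    from scipy.io import wavfile
    wavfile.write(str(path), int(round(w.rate)), w.samples.astype(np.float32))


def read_wav(path, dbfs_ref: float = 100.0) -> Waveform:
    from scipy.io import wavfile
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":  # integer PCM -> full scale floats
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(data.astype(np.float64), float(rate), dbfs_ref)


def _waveform_checksum(w: Waveform) -> str:
    return hashlib.sha256(np.ascontiguousarray(
        w.samples.astype(np.float64)).tobytes()).hexdigest()[:16]


def save_session(session: SessionData, path, n_completed: int | None = None
                 ) -> Path:
    """Write a session archive (possibly partial) under directory ``path``.

    ``n_completed`` limits the trial table to the first completed trials so
    an interrupted run can be resumed later; the protocol and schedule are
    always stored in full.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = session.n_trials if n_completed is None else int(n_completed)
    cfg = session.config
    checksums = {str(k): _waveform_checksum(rebuild_noise(session, i))
                 for i, k in list(enumerate(session.noise_id))[: min(n, 16)]}
    meta = {
        "version": ARCHIVE_VERSION,
        "n_completed": n,
        "config": cfg.to_dict(),
        "noise_seeds_scheme": "SeedSequence((master_seed, 0, noise_id))",
        "noise_checksums": checksums,
    }
    (path / "config.json").write_text(json.dumps(meta, indent=1))
    (path / "schedule.json").write_text(json.dumps({
        "stim_order": session.stim_order.tolist(),
        "target_assignment": session.target_assignment.tolist(),
    }))
    session.to_frame().iloc[:n].to_csv(path / "trials.csv", index=False,
                                       float_format="%.17g")
    return path


def load_session(path) -> tuple[SessionData, int]:
    """Load a session archive; returns ``(session, n_completed)``.

    Trailing (not-yet-run) trials are zero-filled, so a partial session can
    be resumed with ``run_experiment(config, responder,
    start_trial=n_completed, prior=session)``.
    """
    path = Path(path)
    try:
        meta = json.loads((path / "config.json").read_text())
    except FileNotFoundError as e:
        raise FileNotFoundError(f"no session archive at {path}") from e
    if meta.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"archive version {meta.get('version')!r} not supported "
            f"(expected {ARCHIVE_VERSION!r})")
    cfg = ExperimentConfig.from_dict(meta["config"])
    sched = json.loads((path / "schedule.json").read_text())
    df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    n_total, n = cfg.n_trials, int(meta["n_completed"])

    def full(col, dtype=float):
        arr = np.zeros(n_total, dtype=dtype)
        arr[:len(df)] = df[col].to_numpy().astype(dtype)
        return arr

    stim_order = np.asarray(sched["stim_order"], dtype=int)
    probe_flags = np.zeros(n_total, dtype=bool)
    if cfg.probe_periodicity > 0:
        probe_flags[cfg.probe_periodicity - 1::cfg.probe_periodicity] = True
    session = SessionData(
        config=cfg, stim_order=stim_order,
        target_assignment=np.asarray(sched["target_assignment"], dtype=int),
        noise_id=stim_order.copy(),
        n_target=full("n_target", int), n_response=full("n_response", int),
        expvar=full("expvar"), is_correct=full("is_correct", bool),
        is_probe=probe_flags, rove_offset=full("rove_offset"),
        reversal_count=full("reversal_count", int))
    return session, n


def regenerate_waveforms(path, out_dir: str | Path | None = None,
                         verify: bool = True, trials=None) -> Path:
    """Rebuild the masker WAV files of an archived session from their seeds.

    ``trials`` restricts regeneration to specific presentation indices (any
    single waveform is regenerable in isolation).  With ``verify`` the
    stored checksums are compared and a mismatch raises.
    """
    session, n = load_session(path)
    out = Path(out_dir) if out_dir is not None else Path(path) / "NoiseStim"
    out.mkdir(parents=True, exist_ok=True)
    meta = json.loads((Path(path) / "config.json").read_text())
    checksums = meta.get("noise_checksums", {})
    indices = range(n) if trials is None else trials
    for i in indices:
        w = rebuild_noise(session, i)
        k = int(session.noise_id[i])
        if verify and str(k) in checksums:
            got = _waveform_checksum(w)
            if got != checksums[str(k)]:
                raise ValueError(
                    f"checksum mismatch for noise {k}: stored "
                    f"{checksums[str(k)]}, regenerated {got}")
        write_wav(out / f"noise_{k:05d}.wav", w)
    return out


# --------------------------------------------------------------------------
# ACI results (HDF5)
# --------------------------------------------------------------------------

def save_aci(result, path) -> Path:
    """Persist an :class:`~revaci.estimation.ACIResult` to HDF5."""
    import h5py
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=result.weights)
        f.create_dataset("freq_axis", data=np.asarray(result.freq_axis, float))
        f.create_dataset("time_axis", data=np.asarray(result.time_axis, float))
        if result.lambda_path:
            f.create_dataset("lambda_path", data=np.asarray(result.lambda_path))
        if result.coef_basis is not None:
            f.create_dataset("coef_basis", data=result.coef_basis)
        for name, arr in result.per_pixel_stats.items():
            f.create_dataset(f"per_pixel/{name}", data=np.asarray(arr, float))
        if result.validation:
            g = f.create_group("validation")
            for key, rep in result.validation.items():
                gg = g.create_group(key)
                gg.create_dataset("per_fold", data=np.asarray(rep.per_fold))
                gg.attrs["mean_accuracy"] = rep.mean_accuracy
                gg.attrs["mean_deviance"] = rep.mean_deviance
        f.attrs["meta"] = json.dumps({
            "method": result.method,
            "intercept": result.intercept,
            "lambda": result.lambda_,
            "converged": bool(result.converged),
            "n_trials": int(result.n_trials),
            "sign_convention": result.sign_convention,
        })
    return path


def load_aci(path):
    import h5py

    from .estimation import ACIResult
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        res = ACIResult(
            weights=f["weights"][()], intercept=float(meta["intercept"]),
            method=meta["method"], freq_axis=f["freq_axis"][()],
            time_axis=f["time_axis"][()],
            lambda_=meta.get("lambda"),
            lambda_path=[tuple(row) for row in f["lambda_path"][()]]
            if "lambda_path" in f else [],
            coef_basis=f["coef_basis"][()] if "coef_basis" in f else None,
            converged=bool(meta.get("converged", True)),
            n_trials=int(meta.get("n_trials", 0)))
        if "per_pixel" in f:
            res.per_pixel_stats = {k: f[f"per_pixel/{k}"][()]
                                   for k in f["per_pixel"]}
    return res
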