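"""Tabular I/O, run manifests, and the synthetic fixture generator.

All interchange is plain tabular text (tab-separated, header row) so that
runs can be consumed from R/Julia/spreadsheets without binary readers:
signal tables (time column + named state columns), beat tables
(beat_time_s, RR_s, SAP_mmHg, DAP_mmHg), and an annotation-style beat list
(sample index + beat time) for waveform-database-style tooling.

The fixture generator produces signal pairs with known ground truth (written
to a JSON sidecar) so that every analysis operation can be tested without
external recordings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .params import ModelParameters
from .model import ModelRun

__all__ = [
    "write_signals", "read_signals", "write_beats", "read_beats",
    "write_beat_annotations", "read_two_column", "write_manifest",
    "write_run", "FixtureSpec", "generate_fixture",
]

_FLOAT_FMT = "%.17g"    # exact binary round trip


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_signals(run: ModelRun, path) -> None:
    """Signal table: time_s column plus every stored state variable."""
    df = run.states.copy()
    df.insert(0, "time_s", run.time)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_signals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_beats(beats: pd.DataFrame, path) -> None:
    beats.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_beats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_beat_annotations(beats: pd.DataFrame, path, fs: float = 250.0) -> None:
    """Annotation-style beat list: sample index at ``fs`` plus beat time."""
    ann = pd.DataFrame({
        "sample": np.round(beats["beat_time_s"].to_numpy() * fs).astype(int),
        "time_s": beats["beat_time_s"].to_numpy(),
        "symbol": "N",
    })
    ann.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    """External recording as two-column text (time, value); a header row is
    detected and skipped automatically."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    try:
        float(df.columns[0])
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         header=None)
    except ValueError:
        pass
    return (df.iloc[:, 0].to_numpy(dtype=float),
            df.iloc[:, 1].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, *, command: str, seeds, config: dict) -> Path:
    """Write a manifest sufficient to reproduce the run exactly (package
    version, full configuration, seeds, config hash)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "tiltsim",
        "version": _pkg_version,
        "command": command,
        "seeds": list(np.atleast_1d(seeds).tolist()),
        "config": config,
        "config_hash": _config_hash(config),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path


def write_run(run: ModelRun, outdir, command: str = "simulate") -> dict:
    """Write one run: signals, beats, beat annotations and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_signals(run, outdir / "signals.tsv")
    write_beats(run.beats, outdir / "beats.tsv")
    write_beat_annotations(run.beats, outdir / "beats.ann.tsv")
    config = {
        "dt": run.dt, "store_stride": run.store_stride,
        "duration_s": run.duration,
        "posture_times": run.posture.times.tolist(),
        "posture_angles": run.posture.angles.tolist(),
        "parameters": run.params.as_dict(),
    }
    write_manifest(outdir, command=command, seeds=run.seed, config=config)
    return config


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("locked-pair", "unlocked-pair", "piecewise-locked-pair",
                 "tachogram-tone", "model-targets")


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic fixture.

    ``band_freq`` is the oscillation frequency (Hz) of the pair / tone;
    ``locked_fraction`` applies to the piecewise kind; ``noise_level`` is
    the SD of the additive observation noise relative to unit amplitude.
    """

    kind: str
    duration_s: float = 600.0
    band_freq: float = 0.10
    locked_fraction: float = 0.5
    noise_level: float = 0.05   # keeps the phase oracle sharp
    seed: int = 0
    freq_offset: float = 0.03       # detuning of the unlocked segment/pair
    fs: float = 4.0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")
        if not 0.0 <= self.locked_fraction <= 1.0:
            raise ValueError("locked_fraction must be within [0, 1]")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")


def generate_fixture(spec: FixtureSpec, outdir=None
                     ) -> tuple[dict[str, np.ndarray], dict]:
    """Generate fixture signals plus a ground-truth sidecar.

    Returns ``(signals, truth)`` where ``signals`` maps names to arrays
    (with a shared ``"t"`` time base) and ``truth`` records the generating
    parameters and the known answer (true S fraction, true band powers).
    If ``outdir`` is given, signals are written as two-column text and the
    truth as ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    f0 = spec.band_freq
    truth: dict = {"spec": asdict(spec)}
    signals: dict[str, np.ndarray] = {"t": t}

    if spec.kind == "locked-pair":
        phase = 2 * np.pi * f0 * t
        signals["x"] = np.sin(phase) + spec.noise_level * rng.normal(size=n)
        signals["y"] = np.sin(phase + 0.8) + spec.noise_level * rng.normal(size=n)
        truth["s_true_percent"] = 100.0
    elif spec.kind == "unlocked-pair":
        signals["x"] = np.sin(2 * np.pi * f0 * t) \
            + spec.noise_level * rng.normal(size=n)
        signals["y"] = np.sin(2 * np.pi * (f0 + spec.freq_offset) * t) \
            + spec.noise_level * rng.normal(size=n)
        truth["s_true_percent"] = 0.0
    elif spec.kind == "piecewise-locked-pair":
        t_switch = spec.locked_fraction * spec.duration_s
        phase_x = 2 * np.pi * f0 * t
        # y follows x up to the switch, then detunes by freq_offset
        phase_y = phase_x + 0.8 + 2 * np.pi * spec.freq_offset \
            * np.clip(t - t_switch, 0.0, None)
        signals["x"] = np.sin(phase_x) + spec.noise_level * rng.normal(size=n)
        signals["y"] = np.sin(phase_y) + spec.noise_level * rng.normal(size=n)
        truth["s_true_percent"] = 100.0 * spec.locked_fraction
        truth["t_switch_s"] = t_switch
    elif spec.kind == "tachogram-tone":
        amp_ms = 30.0
        mean_ms = 850.0
        signals["rr_ms"] = mean_ms + amp_ms * np.sin(2 * np.pi * f0 * t)
        truth["tone_freq_hz"] = f0
        truth["tone_amplitude_ms"] = amp_ms
        truth["tone_power_ms2"] = amp_ms ** 2 / 2.0
        truth["band"] = "LF" if f0 < 0.15 else "HF"
    elif spec.kind == "model-targets":
        from .params import default_parameters
        from .fitting import model_indexes
        from .protocol import TiltProtocol
        params = default_parameters()
        proto = TiltProtocol()
        idx = model_indexes(params, n_realizations=3, seed0=spec.seed,
                            protocol=proto)
        truth["targets"] = idx
        truth["n_realizations"] = 3
        truth["seed0"] = spec.seed
        signals = {"t": np.array([])}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in signals.items():
            if name == "t" or arr.size == 0:
                continue
            pd.DataFrame({"time_s": t, name: arr}).to_csv(
                outdir / f"{name}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, default=float)
            fh.write("\n")
    return signals, truth
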