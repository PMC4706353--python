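"""Reading and writing the toolkit's data products.

Formats are deliberately boring: multi-trial signals go into a ``.npz``
array container with a JSON sidecar carrying the metadata (sampling rate,
seed, configuration echo); tables (spike events, coherence spectra,
locking summaries, per-sample signal dumps) are tab-separated text via
pandas; configurations round-trip through TOML (read with ``tomllib``,
written as flat key = value).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import CoherenceSpectrum, LockingEstimate, bias_correct_coh2
from .networks import NetworkPairConfig, SpikeRaster
from .oscillators import OscillatorPairConfig, TrialSignalSet

__all__ = [
    "save_signals",
    "load_signals",
    "export_signals_text",
    "export_raster_events",
    "export_coherence_spectrum",
    "locking_summary",
    "write_config",
    "read_config",
]


def save_signals(
    signals: TrialSignalSet, path: str | Path, extra_meta: dict | None = None
) -> None:
    """Write signals to ``<path>.npz`` plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), x=signals.x, y=signals.y)
    meta = {
        "fs": signals.fs,
        "n_trials": signals.n_trials,
        "n_samples": signals.n_samples,
        "snr_requested": (
            "inf" if np.isinf(signals.snr_requested) else signals.snr_requested
        ),
        "noise_kind": signals.noise_kind,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_signals(path: str | Path) -> TrialSignalSet:
    """Load a signal container written by :func:`save_signals`."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        x, y = data["x"], data["y"]
    with open(path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    snr = meta.get("snr_requested", "inf")
    return TrialSignalSet(
        x,
        y,
        fs=float(meta["fs"]),
        snr_requested=np.inf if snr == "inf" else float(snr),
        noise_kind=meta.get("noise_kind", "none"),
    )


def export_signals_text(signals: TrialSignalSet, path: str | Path) -> None:
    """Delimited-text export: one row per sample (trial, t, x, y)."""
    nt, ns = signals.x.shape
    t = np.tile(np.arange(ns) / signals.fs, nt)
    trial = np.repeat(np.arange(nt), ns)
    pd.DataFrame(
        {"trial": trial, "t": t, "x": signals.x.ravel(), "y": signals.y.ravel()}
    ).to_csv(path, sep="\t", index=False)


def export_raster_events(
    raster: SpikeRaster, path: str | Path, network: str = "X"
) -> None:
    """Spike events as delimited text (network, neuron, type, trial, t_ms)."""
    raster.events(network).to_csv(path, sep="\t", index=False)


def export_coherence_spectrum(cohspec: CoherenceSpectrum, path: str | Path) -> None:
    """Coherence spectrum as delimited text with corrected squared values."""
    coh2 = cohspec.coh**2
    corrected = np.array(
        [
            bias_correct_coh2(c2, int(n)) if n >= 2 else np.nan
            for c2, n in zip(coh2, cohspec.n_trials)
        ]
    )
    pd.DataFrame(
        {
            "freq": cohspec.freqs,
            "coh": cohspec.coh,
            "coh2": coh2,
            "coh2_corrected": corrected,
            "N": cohspec.n_trials,
        }
    ).to_csv(path, sep="\t", index=False)


def locking_summary(estimates: list[LockingEstimate]) -> pd.DataFrame:
    """One-row-per-estimate summary table of locking results."""
    return pd.DataFrame(
        [
            {
                "estimator": e.estimator,
                "value": e.value,
                "bias_corrected": e.bias_corrected,
                "n_units": e.n_units,
                "peak_freq": e.peak_freq,
            }
            for e in estimates
        ]
    )


_CONFIG_TYPES = {
    "oscillator": OscillatorPairConfig,
    "network": NetworkPairConfig,
}


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    return repr(float(value)) if isinstance(value, float) else repr(value)


def write_config(
    config: OscillatorPairConfig | NetworkPairConfig, path: str | Path
) -> None:
    """Write a config as a flat TOML file with a ``kind`` discriminator."""
    kind = "oscillator" if isinstance(config, OscillatorPairConfig) else "network"
    lines = [f'kind = "{kind}"']
    for field in dataclasses.fields(config):
        lines.append(f"{field.name} = {_toml_scalar(getattr(config, field.name))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> OscillatorPairConfig | NetworkPairConfig:
    """Read a TOML config written by :func:`write_config` (or by hand)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kind = data.pop("kind", "oscillator")
    try:
        cls = _CONFIG_TYPES[kind]
    except KeyError:
        raise ValueError(f"unknown config kind {kind!r}") from None
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if isinstance(value, list):
            data[key] = tuple(value)
    return cls(**data)
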