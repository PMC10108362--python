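"""Configuration round-trip, result writers, and run manifests.

Run configurations are YAML documents.  An empty document means "the pyruvate
preset": six spins, the published J set, tau_Ir = 31 ms, B0 = 121 uT.  Keys:

    spins:        list of {label, isotope, chemical_shift_ppm[, gamma_mhz_per_t]}
    roles:        map label -> role (hydride_a, hydride_b, carbon, methyl_*)
    couplings_hz: list of [label_a, label_b, J]
    tau_ir_s:     hydrogen-exchange lifetime, s
    b0_ut:        static field, uT
    singlet_fraction: parahydrogen singlet fraction of the fed hydrogen

Unknown keys are rejected by name.  Numeric CSV output keeps full double
precision so that determinism checks on re-runs are byte-for-byte meaningful.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import yaml

from .exchange import ExchangeModel
from .spin_core import (
    CouplingNetwork,
    Preset,
    SpinSpec,
    SpinSystem,
    StaticField,
    preset_pyruvate_sabre,
)

__all__ = ["ConfigError", "RunManifest", "load_config", "save_config", "write_outputs"]

logger = logging.getLogger("sabrespin")

_ALLOWED_KEYS = {
    "spins",
    "roles",
    "couplings_hz",
    "tau_ir_s",
    "b0_ut",
    "singlet_fraction",
}


class ConfigError(ValueError):
    """A configuration document failed validation."""


def _preset_to_dict(preset: Preset) -> dict:
    system, couplings = preset.system, preset.couplings
    pairs = []
    for i in range(system.n_spins):
        for j in range(i + 1, system.n_spins):
            if couplings.J[i, j] != 0.0:
                pairs.append(
                    [system.labels[i], system.labels[j], float(couplings.J[i, j])]
                )
    return {
        "spins": [
            {
                "label": s.label,
                "isotope": s.isotope,
                "chemical_shift_ppm": s.chemical_shift,
                "gamma_mhz_per_t": s.gyromagnetic_ratio,
            }
            for s in system.spins
        ],
        "roles": dict(system.roles),
        "couplings_hz": pairs,
        "tau_ir_s": preset.exchange.tau_ir,
        "b0_ut": preset.field.b0_ut,
        "singlet_fraction": preset.exchange.singlet_fraction,
    }


def save_config(preset: Preset, path) -> None:
    """Write a preset as a YAML configuration document."""
    with open(path, "w") as fh:
        yaml.safe_dump(_preset_to_dict(preset), fh, sort_keys=True)


def load_config(path) -> Preset:
    """Load and validate a YAML run configuration.

    Missing keys default to the pyruvate preset; an empty file yields the full
    preset.  Unknown keys raise :class:`ConfigError` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(doc) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

    defaults = _preset_to_dict(preset_pyruvate_sabre())
    merged = {**defaults, **doc}

    try:
        spins = tuple(
            SpinSpec(
                label=s["label"],
                isotope=s["isotope"],
                gyromagnetic_ratio=s.get("gamma_mhz_per_t"),
                chemical_shift=float(s.get("chemical_shift_ppm", 0.0)),
            )
            for s in merged["spins"]
        )
    except (KeyError, TypeError) as err:
        raise ConfigError(f"invalid 'spins' entry: {err}") from err
    roles = merged["roles"]
    if "spins" in doc and "roles" not in doc:
        raise ConfigError("'roles' must accompany a custom 'spins' list")
    system = SpinSystem(spins, roles)

    try:
        couplings = CouplingNetwork.from_pairs(
            system, [(a, b, float(v)) for a, b, v in merged["couplings_hz"]]
        )
    except (KeyError, ValueError, TypeError) as err:
        raise ConfigError(f"invalid 'couplings_hz': {err}") from err

    tau = merged["tau_ir_s"]
    if not (isinstance(tau, (int, float)) and tau > 0):
        raise ConfigError(f"'tau_ir_s' must be a positive number, got {tau!r}")
    f = merged["singlet_fraction"]
    if not (isinstance(f, (int, float)) and 0.0 <= f <= 1.0):
        raise ConfigError(f"'singlet_fraction' must lie in [0, 1], got {f!r}")
    b0 = merged["b0_ut"]
    if not (isinstance(b0, (int, float)) and b0 >= 0):
        raise ConfigError(f"'b0_ut' must be non-negative, got {b0!r}")

    exchange = ExchangeModel(
        tau_ir=float(tau),
        hydride_pair=system.hydride_pair,
        singlet_fraction=float(f),
    )
    return Preset(system, couplings, exchange, StaticField(float(b0)))


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit with the same build."""

    config: dict
    seed: int | None = None
    tool_version: str = ""
    created_unix: float = field(default_factory=time.time)
    outputs: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "tool_version": self.tool_version,
                "created_unix": self.created_unix,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def write_outputs(results: Dict[str, object], manifest: RunManifest, out_dir) -> List[Path]:
    """Write tabular results as CSV and dict-like results as JSON.

    ``results`` maps output names to pandas DataFrames (written as
    ``<name>.csv`` with repr-round-trip float precision) or JSON-serializable
    objects (written as ``<name>.json``).  The manifest, updated with the file
    list, goes to ``manifest.json``.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False, float_format="%.17g")
        else:
            p = out_dir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        logger.info("wrote %s", p)
        written.append(p)
    manifest.outputs = [p.name for p in written]
    mp = out_dir / "manifest.json"
    with open(mp, "w") as fh:
        fh.write(manifest.to_json())
    logger.info("wrote %s", mp)
    written.append(mp)
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
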