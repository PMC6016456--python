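"""Run configuration: every analysis constant in one place.

The defaults carry the study conditions (3.0 Å contact cutoff, 10 Å
interface definition, 30-pose ensembles) together with the package's own
operational thresholds (top-k, localization, funnel criteria); nothing is
hard-coded inside the stages. The config round-trips losslessly through a
plain-text ``key = value`` file.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

from .errors import InputError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    cutoff_contact: float = 3.0  # Å, residue-contact cutoff
    cutoff_interface: float = 10.0  # Å, interface-residue definition for iRMSD
    n_poses: int = 30  # poses per docking ensemble
    top_k: int = 20  # residues ranked for domain localization
    localized_threshold: float = 0.8
    funnel_rho_threshold: float = 0.4
    funnel_low_fraction: float = 0.1
    equil_window: int = 10  # frames
    equil_band: float = 0.5  # Å
    fit_model: str = "single-site"
    seed: int = 0
    out_dir: str = "iface-out"

    def __post_init__(self) -> None:
        for name in ("cutoff_contact", "cutoff_interface", "equil_band"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            for field in dataclasses.fields(self):
                handle.write(f"{field.name} = {getattr(self, field.name)}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        kwargs = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise InputError(f"{path}: line {lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in types:
                    raise InputError(f"{path}: line {lineno}: unknown key {key!r}")
                kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)
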