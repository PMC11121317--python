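"""Configuration and amino-acid feature tables.

The rendering pipeline colours each residue circle by three side-chain
properties mapped to the RGB channels: polarizability (P, Charton & Charton),
isoelectric point (I, Zimmerman), and hydrophobicity (H, Kyte-Doolittle
hydropathy).  Each scale is min-max normalised to [0, 1] over the 20 standard
amino acids.  Circle radii derive from mean residue volumes V (Zamyatnin /
Chothia) as the radius of the equivalent sphere, r = (3V / 4 pi)^(1/3).

All tables are plain dicts so they can be overridden from a YAML config file.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import yaml

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Side-chain polarizability (Charton & Charton scale).
POLARIZABILITY = {
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128,
    "Q": 0.180, "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186,
    "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.290, "P": 0.131,
    "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.140,
}

#: Isoelectric point (Zimmerman scale).
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.66, "W": 5.89, "Y": 5.66, "V": 5.96,
}

#: Hydropathy (Kyte-Doolittle).
HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Mean residue volume in cubic Angstrom (Zamyatnin / Chothia).
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


def minmax_scale(table: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalise a per-amino-acid table to [0, 1]."""
    vals = [table[a] for a in STANDARD_AA]
    lo, hi = min(vals), max(vals)
    return {a: (table[a] - lo) / (hi - lo) for a in STANDARD_AA}


def residue_radius(aa: str, volumes: Mapping[str, float] = RESIDUE_VOLUME) -> float:
    """Radius in Angstrom of the sphere with the residue's mean volume."""
    return (3.0 * volumes[aa] / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclasses.dataclass
class FeatureTable:
    """Scaled P/I/H values and circle radii for the 20 standard amino acids."""

    polarizability: dict[str, float] = dataclasses.field(
        default_factory=lambda: minmax_scale(POLARIZABILITY))
    isoelectric: dict[str, float] = dataclasses.field(
        default_factory=lambda: minmax_scale(ISOELECTRIC_POINT))
    hydrophobicity: dict[str, float] = dataclasses.field(
        default_factory=lambda: minmax_scale(HYDROPHOBICITY))
    radius: dict[str, float] = dataclasses.field(
        default_factory=lambda: {a: residue_radius(a) for a in STANDARD_AA})


@dataclasses.dataclass
class ImagingConfig:
    """Rendering parameters.

    ``size`` is the final (cropped) square image size in pixels; rendering
    happens on a canvas of twice that size which is then cropped centrally.
    ``scale`` is pixels per Angstrom, so the default 100 px field of view
    covers 50 A.  ``d_max``/``alpha_min`` parametrise the linear
    depth-to-transparency map; ``distance_feature=False`` renders every circle
    fully opaque (ablation of the distance channel).
    """

    size: int = 100
    scale: float = 2.0
    mode: str = "residue"            # "residue" | "atom"
    scheme: str = "PIH"              # "PIH" | "four_color"
    knockout: tuple[str, ...] = ()   # subset of {"P","I","H"}
    d_max: float = 6.0
    alpha_min: float = 0.1
    distance_feature: bool = True
    atom_radius: float = 1.0
    features: FeatureTable = dataclasses.field(default_factory=FeatureTable)


@dataclasses.dataclass
class InterfaceConfig:
    cutoff: float = 6.0       # Cmu-Cmu contact cutoff, Angstrom
    cdr_radius: float = 40.0  # maximum distance from the CDR centre, Angstrom


@dataclasses.dataclass
class TrainConfig:
    """Optimiser / schedule hyperparameters for one cross-validation fold."""

    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.1
    min_delta: float = 1e-4
    val_loss_floor: float = 0.0   # stop once validation BCE falls below this
    dropout: float = 0.75
    n_kernels: int = 32
    pool_window: int = 4
    eps_clip: float = 1e-7


def desk_train_config(**overrides) -> TrainConfig:
    """Training schedule sized for small synthetic tasks on a single CPU.

    Same optimiser, tighter schedule: few hundred samples converge within a
    couple of dozen epochs, so the patience windows are shortened accordingly.
    """
    cfg = TrainConfig(max_epochs=25, early_stop_patience=5, plateau_patience=3,
                      val_loss_floor=5e-3)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclasses.dataclass
class Config:
    imaging: ImagingConfig = dataclasses.field(default_factory=ImagingConfig)
    interface: InterfaceConfig = dataclasses.field(default_factory=InterfaceConfig)
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    seed: int = 0


def _update(obj, data: Mapping) -> None:
    for key, val in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key: {key!r}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, Mapping):
            _update(cur, val)
        elif isinstance(cur, dict) and isinstance(val, Mapping):
            cur.update(val)
        elif isinstance(cur, tuple) and isinstance(val, Sequence):
            setattr(obj, key, tuple(val))
        else:
            setattr(obj, key, val)


def load_config(path: str | None = None) -> Config:
    """Load a :class:`Config`, optionally overriding defaults from YAML."""
    cfg = Config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _update(cfg, data)
    return cfg
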