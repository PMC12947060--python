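"""YAML run configuration: defaults, validation, echo.

Sections: ``scanner`` (n_rings, n_crystals_per_ring, pitch_t, pitch_z,
radius), ``sparsity`` (block_rings, block_crystals, phase), ``sim``
(n_phantoms, count_level, seed, n_pixels, hot_contrast), ``train`` (NetConfig
and TrainConfig fields), ``eval`` (n_sample).  Every violated constraint is
reported by name before any compute starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .binning import MichelogramScheme, default_n_radial, plane_count
from .geometry import ChessboardPattern, ScannerGeometry
from .nn import NetConfig, TrainConfig
from .simulate import SimulationConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_DEFAULTS: dict = {
    "scanner": {
        "n_rings": 16,
        "n_crystals_per_ring": 64,
        "pitch_t": 4.0,
        "pitch_z": 5.3,
        "radius": 80.0,
    },
    "sparsity": {"block_rings": 1, "block_crystals": 1, "phase": "standard"},
    "sim": {
        "n_phantoms": 3,
        "count_level": 2.0e4,
        "seed": 0,
        "n_pixels": 64,
        "hot_contrast": 6.0,
    },
    "train": {
        "depth": 2,
        "base_filters": 8,
        "res_blocks_per_level": [1, 2],
        "lr0": 1.0e-3,
        "decay_rate": 0.96,
        "max_epochs": 200,
        "batch_size": 64,
        "patience": 20,
        "seed": 0,
    },
    "eval": {"n_sample": 100000},
}


@dataclass
class RunConfig:
    scanner: dict
    sparsity: dict
    sim: dict
    train: dict
    eval: dict

    # resolved domain objects ------------------------------------------------

    @property
    def geometry(self) -> ScannerGeometry:
        s = self.scanner
        return ScannerGeometry(
            n_rings=s["n_rings"],
            n_crystals_per_ring=s["n_crystals_per_ring"],
            crystal_pitch_transaxial=s["pitch_t"],
            crystal_pitch_axial=s["pitch_z"],
            ring_radius=s["radius"],
        )

    @property
    def pattern(self) -> ChessboardPattern:
        p = self.sparsity
        return ChessboardPattern(p["block_rings"], p["block_crystals"], p["phase"])

    @property
    def scheme(self) -> MichelogramScheme:
        return MichelogramScheme(self.scanner["n_rings"])

    @property
    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_phantoms=self.sim["n_phantoms"],
            count_level=self.sim["count_level"],
            seed=self.sim["seed"],
            n_pixels=self.sim["n_pixels"],
            hot_contrast=self.sim["hot_contrast"],
            geometry=self.geometry,
            pattern=self.pattern,
        )

    @property
    def net_config(self) -> NetConfig:
        t = self.train
        return NetConfig(t["depth"], t["base_filters"], tuple(t["res_blocks_per_level"]))

    @property
    def train_config(self) -> TrainConfig:
        t = self.train
        return TrainConfig(
            lr0=t["lr0"], decay_rate=t["decay_rate"], max_epochs=t["max_epochs"],
            batch_size=t["batch_size"], patience=t["patience"], seed=t["seed"],
        )

    def summary(self) -> dict:
        """Fully-resolved configuration echo, including derived quantities."""
        g = self.geometry
        return {
            "scanner": dict(self.scanner),
            "sparsity": dict(self.sparsity),
            "sim": dict(self.sim),
            "train": dict(self.train),
            "eval": dict(self.eval),
            "derived": {
                "plane_count": plane_count(self.scheme),
                "n_radial": default_n_radial(g.n_crystals_per_ring),
                "n_angles": g.n_crystals_per_ring // 2,
            },
        }


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = dict(defaults)
    for k, v in (user or {}).items():
        if k not in defaults:
            errors.append(f"unknown key {path}.{k}")
        else:
            out[k] = v
    return out


def load_config(source) -> RunConfig:
    """Load, default-fill and validate a YAML run configuration.  ``source``
    is a path or a YAML string/dict.  Each violated constraint is named."""
    if isinstance(source, dict):
        raw = source
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")

    errors: list[str] = []
    for key in raw:
        if key not in _DEFAULTS:
            errors.append(f"unknown section {key!r}")
    sections = {
        name: _merge(_DEFAULTS[name], raw.get(name, {}), name, errors)
        for name in _DEFAULTS
    }
    cfg = RunConfig(**sections)

    sc = sections["scanner"]
    if sc["n_rings"] < 1:
        errors.append("scanner.n_rings must be >= 1")
    if sc["n_crystals_per_ring"] < 2 or sc["n_crystals_per_ring"] % 2 != 0:
        errors.append("scanner.n_crystals_per_ring must be a positive even integer")
    for k in ("pitch_t", "pitch_z", "radius"):
        if sc[k] <= 0:
            errors.append(f"scanner.{k} must be > 0")
    sp = sections["sparsity"]
    if sp["block_rings"] < 1 or sp["block_crystals"] < 1:
        errors.append("sparsity block sizes must be >= 1")
    if sp["phase"] not in ("standard", "complementary"):
        errors.append("sparsity.phase must be 'standard' or 'complementary'")
    if (
        sc["n_crystals_per_ring"] % 2 == 0
        and sc["n_crystals_per_ring"] % (2 * max(sp["block_crystals"], 1)) != 0
    ):
        errors.append(
            "sparsity.block_crystals: chessboard does not tile seamlessly "
            "(n_crystals_per_ring must be divisible by 2*block_crystals)"
        )
    sim = sections["sim"]
    if sim["count_level"] <= 0:
        errors.append("sim.count_level must be > 0")
    if sim["n_phantoms"] < 1:
        errors.append("sim.n_phantoms must be >= 1")
    tr = sections["train"]
    if len(tr["res_blocks_per_level"]) != tr["depth"]:
        errors.append("train.res_blocks_per_level must have one entry per level")
    if tr["patience"] >= tr["max_epochs"]:
        errors.append("train.patience must be smaller than train.max_epochs")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg
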