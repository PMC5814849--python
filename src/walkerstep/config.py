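"""Run configuration: schema, validation and object builders.

Configs are YAML with nested sections (walker, track, kinetics, fret,
hairpin, sampling, output). Validation is strict — unknown keys are errors
with a did-you-mean suggestion, units are checked on load — and a validated
config deterministically builds the domain objects used by the pipeline.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .fret import PopulationModel
from .kinetics import DEFAULT_K_FB
from .mechanics import Calibration, HairpinModel, TrackGeometry, WalkerDesign
from .polymer import SegmentSpec
from .units import parse_concentration

__all__ = ["ConfigError", "RunConfig", "default_config", "load_config", "loads_config", "write_config"]


class ConfigError(ValueError):
    """Configuration validation failure, naming the offending key."""


# section -> allowed keys (True marks required keys).
_SCHEMA: dict[str, dict[str, bool]] = {
    "walker": {"constants": True, "capture_radius_nm": True, "bound_arm": True, "fuel_arm": True},
    "walker.constants": {
        "ss_contour_nm_per_nt": True,
        "ss_kuhn_nm": True,
        "ds_rise_nm_per_bp": True,
    },
    "track": {"kind": True, "cylinder_radius_nm": False},
    "kinetics": {"k_FB": True, "fuel_concentrations": True, "reference": True},
    "kinetics.reference": {"d_ref_nm": True, "k_s_ref": True},
    "fret": {
        "E_LP": True,
        "E_Trap": True,
        "sd_LP": True,
        "sd_Trap": True,
        "n_bursts": True,
        "n_bootstrap": False,
        "true_stepping_rates": True,
    },
    "hairpin": {"enabled": True, "dG_hp_kBT": False, "sequestered_nt": False},
    "sampling": {
        "n_conformations": True,
        "seed": True,
        "step_grid_nm": True,
        "grid_spacing_nm": False,
        "bandwidth_nm": False,
        "n_bootstrap": False,
    },
    "output": {"directory": True},
}
_TOP_LEVEL = {"walker", "track", "kinetics", "fret", "hairpin", "sampling", "output"}
_SEGMENT_KEYS = {"name", "kind", "n_units"}


def _suggest(key: str, candidates) -> str:
    close = difflib.get_close_matches(key, list(candidates), n=1)
    return f"; did you mean {close[0]!r}?" if close else ""


def _check_keys(section: str, mapping: dict, allowed: dict[str, bool]) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in section {section!r}{_suggest(key, allowed)}")
    for key, required in allowed.items():
        if required and key not in mapping:
            raise ConfigError(f"missing required key {key!r} in section {section!r}")


def _check_number(section: str, key: str, value, minimum=None, strict=False) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{section}.{key} must be a number, got {value!r}")
    v = float(value)
    if minimum is not None and (v <= minimum if strict else v < minimum):
        op = ">" if strict else ">="
        raise ConfigError(f"{section}.{key} must be {op} {minimum}, got {value!r}")
    return v


def _validate_segments(section: str, segments) -> None:
    if not isinstance(segments, list) or not segments:
        raise ConfigError(f"{section} must be a non-empty list of segments")
    for i, seg in enumerate(segments):
        where = f"{section}[{i}]"
        if not isinstance(seg, dict):
            raise ConfigError(f"{where} must be a mapping")
        for key in seg:
            if key not in _SEGMENT_KEYS:
                raise ConfigError(f"unknown key {key!r} in {where}{_suggest(key, _SEGMENT_KEYS)}")
        if seg.get("kind") not in ("single_stranded", "duplex"):
            raise ConfigError(
                f"{where}.kind must be 'single_stranded' or 'duplex', got {seg.get('kind')!r}"
            )
        n = seg.get("n_units")
        if isinstance(n, bool) or not isinstance(n, int) or n < 1:
            raise ConfigError(f"{where}.n_units must be a positive integer, got {n!r}")


def _validate(raw: dict) -> None:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in raw:
        if key not in _TOP_LEVEL:
            raise ConfigError(f"unknown section {key!r}{_suggest(key, _TOP_LEVEL)}")
    for key in _TOP_LEVEL:
        if key not in raw:
            raise ConfigError(f"missing section {key!r}")
    for section in _TOP_LEVEL:
        _check_keys(section, raw[section], _SCHEMA[section])
    _check_keys("walker.constants", raw["walker"]["constants"], _SCHEMA["walker.constants"])
    _check_keys("kinetics.reference", raw["kinetics"]["reference"], _SCHEMA["kinetics.reference"])

    wc = raw["walker"]["constants"]
    _check_number("walker.constants", "ss_contour_nm_per_nt", wc["ss_contour_nm_per_nt"], 0, strict=True)
    _check_number("walker.constants", "ss_kuhn_nm", wc["ss_kuhn_nm"], 0, strict=True)
    _check_number("walker.constants", "ds_rise_nm_per_bp", wc["ds_rise_nm_per_bp"], 0, strict=True)
    _check_number("walker", "capture_radius_nm", raw["walker"]["capture_radius_nm"], 0, strict=True)
    _validate_segments("walker.bound_arm", raw["walker"]["bound_arm"])
    _validate_segments("walker.fuel_arm", raw["walker"]["fuel_arm"])

    track = raw["track"]
    if track["kind"] not in ("flat", "cylinder"):
        raise ConfigError(f"track.kind must be 'flat' or 'cylinder', got {track['kind']!r}")
    if "cylinder_radius_nm" in track:
        _check_number("track", "cylinder_radius_nm", track["cylinder_radius_nm"], 0, strict=True)
    elif track["kind"] == "cylinder":
        raise ConfigError("track.cylinder_radius_nm is required for cylinder tracks")

    kin = raw["kinetics"]
    _check_number("kinetics", "k_FB", kin["k_FB"], 0, strict=True)
    concs = kin["fuel_concentrations"]
    if not isinstance(concs, list) or not concs:
        raise ConfigError("kinetics.fuel_concentrations must be a non-empty list")
    for c in concs:
        try:
            parse_concentration(c)
        except ValueError as err:
            raise ConfigError(f"kinetics.fuel_concentrations: {err}") from err
    _check_number("kinetics.reference", "d_ref_nm", kin["reference"]["d_ref_nm"], 0, strict=True)
    _check_number("kinetics.reference", "k_s_ref", kin["reference"]["k_s_ref"], 0, strict=True)

    fret = raw["fret"]
    for key in ("E_LP", "E_Trap"):
        v = _check_number("fret", key, fret[key], 0)
        if v > 1:
            raise ConfigError(f"fret.{key} must lie in [0, 1], got {v}")
    for key in ("sd_LP", "sd_Trap"):
        _check_number("fret", key, fret[key], 0, strict=True)
    if not isinstance(fret["n_bursts"], int) or fret["n_bursts"] < 1:
        raise ConfigError(f"fret.n_bursts must be a positive integer, got {fret['n_bursts']!r}")
    rates = fret["true_stepping_rates"]
    if not isinstance(rates, dict) or not rates:
        raise ConfigError("fret.true_stepping_rates must be a non-empty mapping of step -> rate")
    for d, k in rates.items():
        if isinstance(d, bool) or not isinstance(d, (int, float)):
            raise ConfigError(f"fret.true_stepping_rates: step size {d!r} must be a number")
        _check_number("fret.true_stepping_rates", str(d), k, 0)

    hp = raw["hairpin"]
    if not isinstance(hp["enabled"], bool):
        raise ConfigError(f"hairpin.enabled must be true/false, got {hp['enabled']!r}")
    if hp["enabled"]:
        for key in ("dG_hp_kBT", "sequestered_nt"):
            if key not in hp:
                raise ConfigError(f"hairpin.{key} is required when hairpin.enabled is true")
        if not isinstance(hp["sequestered_nt"], int) or hp["sequestered_nt"] < 0:
            raise ConfigError("hairpin.sequestered_nt must be a non-negative integer")

    smp = raw["sampling"]
    for key in ("n_conformations", "seed"):
        if isinstance(smp[key], bool) or not isinstance(smp[key], int):
            raise ConfigError(f"sampling.{key} must be an integer, got {smp[key]!r}")
    if smp["n_conformations"] < 1:
        raise ConfigError("sampling.n_conformations must be >= 1")
    grid = smp["step_grid_nm"]
    if not isinstance(grid, list) or not grid:
        raise ConfigError("sampling.step_grid_nm must be a non-empty list")
    for d in grid:
        if isinstance(d, bool) or not isinstance(d, (int, float)) or d < 0:
            raise ConfigError(f"sampling.step_grid_nm entries must be numbers >= 0, got {d!r}")

    if not isinstance(raw["output"]["directory"], str) or not raw["output"]["directory"]:
        raise ConfigError("output.directory must be a non-empty string")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; builds the pipeline's domain objects."""

    raw: dict

    # -- builders -----------------------------------------------------------

    def _segment(self, seg: dict) -> SegmentSpec:
        wc = self.raw["walker"]["constants"]
        if seg["kind"] == "duplex":
            return SegmentSpec(
                "duplex", seg["n_units"], wc["ds_rise_nm_per_bp"], None, seg.get("name", "")
            )
        return SegmentSpec(
            "single_stranded",
            seg["n_units"],
            wc["ss_contour_nm_per_nt"],
            wc["ss_kuhn_nm"],
            seg.get("name", ""),
        )

    def design(self) -> WalkerDesign:
        w = self.raw["walker"]
        return WalkerDesign(
            arm_bound=tuple(self._segment(s) for s in w["bound_arm"]),
            arm_fuel=tuple(self._segment(s) for s in w["fuel_arm"]),
            capture_radius=float(w["capture_radius_nm"]),
        )

    def track(self, kind: str | None = None, separation: float = 0.0) -> TrackGeometry:
        t = self.raw["track"]
        kind = kind or t["kind"]
        radius = float(t.get("cylinder_radius_nm", 0.0)) if kind == "cylinder" else None
        return TrackGeometry(kind=kind, separation=separation, radius=radius)

    def calibration(self) -> Calibration:
        kin = self.raw["kinetics"]
        return Calibration(
            d_ref=float(kin["reference"]["d_ref_nm"]),
            k_s_ref=float(kin["reference"]["k_s_ref"]),
            k_FB=float(kin["k_FB"]),
        )

    def fuel_concentrations(self) -> list[float]:
        return [parse_concentration(c) for c in self.raw["kinetics"]["fuel_concentrations"]]

    def population_model(self, f_LP: float = 1.0) -> PopulationModel:
        f = self.raw["fret"]
        return PopulationModel(
            E_LP=float(f["E_LP"]),
            E_Trap=float(f["E_Trap"]),
            sd_LP=float(f["sd_LP"]),
            sd_Trap=float(f["sd_Trap"]),
            f_LP=f_LP,
        )

    def true_stepping_rates(self) -> dict[float, float]:
        return {float(d): float(k) for d, k in self.raw["fret"]["true_stepping_rates"].items()}

    def hairpin(self) -> HairpinModel | None:
        hp = self.raw["hairpin"]
        if not hp["enabled"]:
            return None
        return HairpinModel(dG_hp=float(hp["dG_hp_kBT"]), sequestered_units=hp["sequestered_nt"])

    # -- scalar accessors ---------------------------------------------------

    @property
    def n_conformations(self) -> int:
        return self.raw["sampling"]["n_conformations"]

    @property
    def seed(self) -> int:
        return self.raw["sampling"]["seed"]

    @property
    def step_grid(self) -> list[float]:
        return [float(d) for d in self.raw["sampling"]["step_grid_nm"]]

    @property
    def grid_spacing(self) -> float:
        return float(self.raw["sampling"].get("grid_spacing_nm", 1.0))

    @property
    def bandwidth(self) -> float:
        return float(self.raw["sampling"].get("bandwidth_nm", 0.5))

    @property
    def sampling_bootstrap(self) -> int:
        return int(self.raw["sampling"].get("n_bootstrap", 64))

    @property
    def fret_bootstrap(self) -> int:
        return int(self.raw["fret"].get("n_bootstrap", 200))

    @property
    def n_bursts(self) -> int:
        return self.raw["fret"]["n_bursts"]

    @property
    def output_directory(self) -> Path:
        return Path(self.raw["output"]["directory"])

    def config_hash(self) -> str:
        """SHA-256 of the canonicalized config (stable across key order)."""
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


def default_config() -> dict:
    """Deep copy of the packaged default configuration."""
    text = resources.files("walkerstep").joinpath("data/default.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def loads_config(raw: dict) -> RunConfig:
    """Validate an in-memory config mapping."""
    _validate(raw)
    return RunConfig(raw=copy.deepcopy(raw))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return loads_config(raw)
    except ConfigError as err:
        raise ConfigError(f"{path}: {err}") from err


def write_config(config: RunConfig | dict, path: str | Path) -> Path:
    """Write a config to YAML; load(write(c)) round-trips exactly."""
    raw = config.raw if isinstance(config, RunConfig) else config
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return path
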