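"""Configuration files, release-data I/O and the synthetic-data generator.

Conventions: SI units inside the package; release is a fraction in memory and
a percentage on disk; YAML configuration keys map 1:1 onto the spec
dataclasses and unknown keys are rejected (typo safety).  A bundled
``reference`` profile encodes the benchmark chloride/POPC system.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimConfig, simulate
from .equilibria import CarrierSpec
from .errors import ConfigError
from .fitting import ReleaseDataset
from .geometry import DispersionSpec, MembraneSpec
from .observables import release_curve

__all__ = [
    "RunConfig",
    "SyntheticSpec",
    "load_config",
    "loads_config",
    "dump_config",
    "dumps_config",
    "reference_config",
    "read_release_data",
    "write_release_data",
    "generate_synthetic",
]

RELEASE_COLUMNS = ["dose_molpct", "time_s", "release_pct"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run simulations: system + protocol."""

    carrier: CarrierSpec
    membrane: MembraneSpec
    dispersion: DispersionSpec
    guest_in: float
    doses: tuple[float, ...] = (1.0,)
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.guest_in < 0:
            raise ConfigError("guest_in must be >= 0")
        if not self.doses:
            raise ConfigError("doses must be nonempty")
        if any(d < 0 for d in self.doses):
            raise ConfigError("doses must be >= 0")


_SECTIONS = {
    "carrier": CarrierSpec,
    "membrane": MembraneSpec,
    "dispersion": DispersionSpec,
    "sim": SimConfig,
}
_TOP_KEYS = set(_SECTIONS) | {"guest_in", "doses"}


def _build_section(name: str, cls, raw: dict):
    if not isinstance(raw, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    try:
        return cls(**raw)
    except ConfigError as exc:
        raise ConfigError(f"{name}: {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def loads_config(text: str) -> RunConfig:
    """Parse a YAML configuration string into a validated :class:`RunConfig`."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    missing = {"carrier", "membrane", "dispersion", "guest_in"} - set(raw)
    if missing:
        raise ConfigError(f"missing required key(s): {sorted(missing)}")
    sections = {
        name: _build_section(name, cls, raw.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    doses = raw.get("doses", [1.0])
    if not isinstance(doses, (list, tuple)):
        raise ConfigError("doses must be a list")
    return RunConfig(
        carrier=sections["carrier"],
        membrane=sections["membrane"],
        dispersion=sections["dispersion"],
        guest_in=float(raw["guest_in"]),
        doses=tuple(float(d) for d in doses),
        sim=sections["sim"],
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    return loads_config(Path(path).read_text())


def dumps_config(cfg: RunConfig) -> str:
    """Serialise a :class:`RunConfig` back to YAML (round-trips with load)."""
    data = {
        "carrier": asdict(cfg.carrier),
        "membrane": asdict(cfg.membrane),
        "dispersion": asdict(cfg.dispersion),
        "guest_in": cfg.guest_in,
        "doses": list(cfg.doses),
        "sim": asdict(cfg.sim),
    }
    return yaml.safe_dump(data, sort_keys=False)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(dumps_config(cfg))


def reference_config() -> RunConfig:
    """The bundled benchmark profile (chloride/POPC, 200 nm vesicles)."""
    text = importlib.resources.files("uniportsim").joinpath("profiles/reference.yaml").read_text()
    return loads_config(text)


def read_release_data(path: str | Path) -> ReleaseDataset:
    """Read delimited release data (header ``dose_molpct,time_s,release_pct``).

    Percentages on disk become fractions in memory.  Malformed rows are
    reported with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != RELEASE_COLUMNS:
        raise ConfigError(
            f"{path}: expected header {','.join(RELEASE_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    bad_lines = []
    for col in RELEASE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((df.index[coerced.isna()] + 2).tolist())
        df[col] = coerced
    bad_lines.extend((df.index[df["time_s"] < 0] + 2).tolist())
    bad_lines.extend((df.index[(df["release_pct"] < -5) | (df["release_pct"] > 105)] + 2).tolist())
    if bad_lines:
        raise ConfigError(f"{path}: malformed row(s) at line(s) {sorted(set(bad_lines))}")
    out = pd.DataFrame(
        {
            "dose_molpct": df["dose_molpct"],
            "time_s": df["time_s"],
            "release": df["release_pct"] / 100.0,
        }
    )
    return ReleaseDataset(frame=out, metadata={"source": str(path)})


def write_release_data(dataset: ReleaseDataset, path: str | Path) -> None:
    """Write a dataset as delimited text, release in percent."""
    df = pd.DataFrame(
        {
            "dose_molpct": dataset.frame["dose_molpct"],
            "time_s": dataset.frame["time_s"],
            "release_pct": dataset.frame["release"] * 100.0,
        }
    )
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for noisy synthetic release curves.

    The truth system is simulated at each dose, sampled at ``times`` (default:
    the dwell grid from ``dwell`` to ``t_total``), and i.i.d. Gaussian noise
    with standard deviation ``noise_sd`` *percentage points* is added, the
    result being clipped to [0, 100]%.
    """

    config: RunConfig
    noise_sd: float = 1.0
    seed: int = 0
    times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def generate_synthetic(spec: SyntheticSpec) -> ReleaseDataset:
    """Simulate the truth system and add measurement noise; reproducible."""
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    rows = []
    for dose in cfg.doses:
        curve = release_curve(
            simulate(cfg.carrier, cfg.membrane, cfg.dispersion, dose, cfg.guest_in, cfg.sim)
        )
        if spec.times is None:
            mask = curve.times > 0
            times = curve.times[mask]
            clean = curve.release[mask]
        else:
            times = np.asarray(spec.times, dtype=float)
            clean = np.interp(times, curve.times, curve.release)
        noisy = clean + rng.normal(0.0, spec.noise_sd / 100.0, size=clean.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
        for t, r in zip(times, noisy):
            rows.append((dose, float(t), float(r)))
    frame = pd.DataFrame(rows, columns=["dose_molpct", "time_s", "release"])
    meta = {
        "truth_D": cfg.carrier.D,
        "truth_Dc": cfg.carrier.Dc,
        "noise_sd_pct": spec.noise_sd,
        "seed": spec.seed,
    }
    return ReleaseDataset(frame=frame, metadata=meta)
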