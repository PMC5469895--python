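"""File formats, rate binning and run configuration.

CSV is used throughout: stretch trajectories (time_s, length_L0,
velocity_L0_per_s), joint trajectories (time_s, theta_deg,
theta_dot_deg_per_s; degrees at the file boundary, radians in memory),
spike trains (time_s, unit_id) and binned rates.  Configurations are
structured key-value files in JSON or YAML; unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fusimotor import SpikeTrain
from .geometry import JointTrajectory, ThreeLinkGeometry, TwoLinkGeometry
from .model_core import FiberParameters, StretchInput
from .params import SpindleParameters, named_parameter_set

__all__ = [
    "RateTrace",
    "RunConfig",
    "bin_rates",
    "read_stretch_csv",
    "write_stretch_csv",
    "read_spike_train",
    "write_spike_train",
    "read_joint_csv",
    "write_joint_csv",
    "write_rate_csv",
    "load_config",
]


@dataclass
class RateTrace:
    """Mean per-unit firing rate in contiguous fixed-width bins."""

    bin_start: np.ndarray
    bin_width: float
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.bin_start = np.asarray(self.bin_start, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.bin_start.shape != self.rate.shape:
            raise ValueError("bin_start and rate must have equal shapes")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")


def bin_rates(train: SpikeTrain, n_units: int, bin_width: float = 0.030) -> RateTrace:
    """Mean per-unit rate per bin: count / (n_units * bin_width).

    Bins tile [0, duration]; a spike exactly at the duration falls in the
    last bin, so binning conserves the total spike count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    n_bins = max(1, int(math.ceil(train.duration / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    # np.histogram is right-exclusive except the last edge; spikes beyond the
    # final edge (duration not a bin multiple) are clipped into the last bin
    overflow = int(np.sum(train.times >= edges[-1]))
    counts[-1] += overflow
    return RateTrace(
        bin_start=edges[:-1], bin_width=bin_width,
        rate=counts / (n_units * bin_width),
    )


# ---------------------------------------------------------------------------
# CSV readers/writers

def _read_numeric_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path.name}: malformed value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path.name}: empty value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_stretch_csv(path) -> StretchInput:
    df = _read_numeric_csv(path, ["time_s", "length_L0", "velocity_L0_per_s"])
    return StretchInput(
        times=df["time_s"].to_numpy(),
        length=df["length_L0"].to_numpy(),
        velocity=df["velocity_L0_per_s"].to_numpy(),
    )


def write_stretch_csv(stretch: StretchInput, path) -> None:
    pd.DataFrame(
        {
            "time_s": stretch.times,
            "length_L0": stretch.length,
            "velocity_L0_per_s": stretch.velocity,
        }
    ).to_csv(path, index=False, float_format="%.9f")


def read_spike_train(path, duration: float | None = None) -> SpikeTrain:
    df = _read_numeric_csv(path, ["time_s", "unit_id"])
    times = df["time_s"].to_numpy()
    if duration is None:
        duration = float(times[-1]) if times.size else 0.0
    return SpikeTrain(
        times=times, unit_ids=df["unit_id"].to_numpy(dtype=int), duration=duration
    )


def write_spike_train(train: SpikeTrain, path) -> None:
    pd.DataFrame({"time_s": train.times, "unit_id": train.unit_ids}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_joint_csv(path) -> JointTrajectory:
    df = _read_numeric_csv(path, ["time_s", "theta_deg", "theta_dot_deg_per_s"])
    return JointTrajectory(
        times=df["time_s"].to_numpy(),
        theta=np.radians(df["theta_deg"].to_numpy()),
        theta_dot=np.radians(df["theta_dot_deg_per_s"].to_numpy()),
    )


def write_joint_csv(trajectory: JointTrajectory, path) -> None:
    pd.DataFrame(
        {
            "time_s": trajectory.times,
            "theta_deg": np.degrees(trajectory.theta),
            "theta_dot_deg_per_s": np.degrees(trajectory.theta_dot),
        }
    ).to_csv(path, index=False, float_format="%.9f")


def write_rate_csv(traces: dict[str, RateTrace], path) -> None:
    """Write aligned rate traces (e.g. Ia and II) as one CSV."""
    if not traces:
        raise ValueError("no rate traces to write")
    first = next(iter(traces.values()))
    data = {"bin_start_s": first.bin_start}
    for name, tr in traces.items():
        if tr.bin_start.shape != first.bin_start.shape:
            raise ValueError("rate traces must share binning")
        data[f"rate_{name}"] = tr.rate
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Run configuration

_FIBER_KEYS = {f for f in FiberParameters.__dataclass_fields__}
_FUSIMOTOR_KEYS = {
    "r_dynamic", "tau_dynamic_ms", "r_static", "tau_static_ms", "chain_scale",
}
_POPULATION_KEYS = {"n_units", "primary_fraction", "shared_tension", "seed"}
_PROTOCOL_KEYS = {
    "kind", "l_start", "ramp_speed", "phase_durations", "pin_plateau",
    "peak_to_peak", "frequency", "center", "hold_at_extremes", "duration",
}
_DRIVE_KEYS = {"gamma_dynamic", "gamma_static", "kind"}
_GEOMETRY_KEYS = {
    "kind", "l1", "l2", "l3", "s_attach", "alpha_deg", "theta_rest_deg",
    "muscle", "side",
}
_TOP_KEYS = {
    "seed", "dt", "n_substeps", "parameter_set", "s_occl", "fibers",
    "fusimotor", "population", "protocol", "drive", "geometry",
}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    """Validated simulation configuration with defaults filled in."""

    seed: int = 0
    dt: float = 1e-3
    n_substeps: int = 10
    parameter_set: str = "cat_soleus"
    s_occl: float | None = None
    fibers: dict = field(default_factory=dict)
    fusimotor: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    drive: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "config")
        for name, allowed in [
            ("fusimotor", _FUSIMOTOR_KEYS),
            ("population", _POPULATION_KEYS),
            ("protocol", _PROTOCOL_KEYS),
            ("drive", _DRIVE_KEYS),
            ("geometry", _GEOMETRY_KEYS),
        ]:
            if name in raw:
                _check_keys(raw[name], allowed, name)
        for fiber, overrides in raw.get("fibers", {}).items():
            if fiber not in ("bag1", "bag2", "chain"):
                raise ValueError(f"unknown fiber {fiber!r} in fibers section")
            _check_keys(overrides, _FIBER_KEYS, f"fibers.{fiber}")
        cfg = cls(**raw)
        if cfg.dt <= 0:
            raise ValueError("dt must be positive")
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "dt": self.dt, "n_substeps": self.n_substeps,
            "parameter_set": self.parameter_set, "s_occl": self.s_occl,
            "fibers": self.fibers, "fusimotor": self.fusimotor,
            "population": self.population, "protocol": self.protocol,
            "drive": self.drive, "geometry": self.geometry,
        }

    def spindle_parameters(self) -> SpindleParameters:
        """Resolve the named set plus any per-fiber/fusimotor overrides."""
        from dataclasses import replace

        base = named_parameter_set(self.parameter_set)
        fibers = {}
        for name in ("bag1", "bag2", "chain"):
            fiber = getattr(base, name)
            if name in self.fibers:
                fiber = replace(fiber, **self.fibers[name])
            fibers[name] = fiber
        extra = dict(self.fusimotor)
        if self.s_occl is not None:
            extra["s_occl"] = self.s_occl
        return replace(base, **fibers, **extra)

    def geometry_object(self):
        g = dict(self.geometry)
        kind = g.pop("kind", None)
        g.pop("muscle", None)
        g.pop("side", None)
        if kind == "two_link":
            return TwoLinkGeometry(
                l1=g["l1"], l2=g["l2"], s_attach=g.get("s_attach", g["l1"] * g["l2"] / 2),
                theta_rest=math.radians(g.get("theta_rest_deg", 125.0)),
            )
        if kind == "three_link":
            return ThreeLinkGeometry(
                l1=g["l1"], l2=g["l2"], l3=g["l3"],
                alpha=math.radians(g.get("alpha_deg", 90.0)),
                theta_rest=math.radians(g.get("theta_rest_deg", 0.0)),
            )
        raise ValueError(f"unknown geometry kind {kind!r}")


def load_config(path) -> RunConfig:
    """Load a JSON or YAML run configuration, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path.name}: config root must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
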