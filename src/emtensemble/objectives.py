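"""Training objectives: measurement series and residual scoring.

Band/transcript intensities from blots or qPCR carry no absolute units,
so simulated readouts are gauge-matched to each series by a least-squares
scale factor before the weighted sum-of-squares residual is formed.  The
training data are organized into 11 objective functions that are
minimized simultaneously during ensemble estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    CompiledModel,
    Condition,
    IntegrationError,
    ParameterSet,
    compile_model,
    simulate,
)

FAILURE_SENTINEL = np.inf
DEFAULT_SD_FRACTION = 0.10  # fallback: 10% of the series maximum


@dataclass
class MeasurementSeries:
    """One measured time series: a species readout under one condition."""

    series_id: str
    species: str
    condition_id: str
    times: np.ndarray  # h
    values: np.ndarray  # intensities, a.u.
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if self.sd is not None and len(self.sd) != len(self.values):
            raise ValueError("sd length mismatch")
        if np.any(self.values < 0):
            raise ValueError("intensities must be nonnegative")

    def effective_sd(self) -> np.ndarray:
        if self.sd is not None and np.all(self.sd > 0):
            return self.sd
        scale = self.values.max()
        if scale <= 0:
            scale = 1.0
        return np.full_like(self.values, DEFAULT_SD_FRACTION * scale)


@dataclass
class Objective:
    """A group of measurement series scored together (ids 1..11)."""

    id: int
    series: list[MeasurementSeries]
    weight: float = 1.0

    def condition_ids(self) -> list[str]:
        return sorted({s.condition_id for s in self.series})


def scale_to_data(sim: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares gauge: scale sim by s* = <sim,data>/<sim,sim>.

    Returns (scaled sim, s*); s* = 0 for an identically zero simulation.
    """
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    if sim.shape != data.shape:
        raise ValueError("sim and data must have the same length")
    denom = float(np.dot(sim, sim))
    if denom == 0.0:
        return np.zeros_like(sim), 0.0
    s = float(np.dot(sim, data)) / denom
    return s * sim, s


class SimulationCache:
    """Caches one trajectory per (parameter set, condition)."""

    def __init__(self, model: CompiledModel, conditions: dict[str, Condition]):
        self.model = model
        self.conditions = conditions
        self._cache: dict[str, object] = {}

    def trajectory(self, params: ParameterSet, condition_id: str):
        if condition_id not in self._cache:
            cond = self.conditions[condition_id]
            self._cache[condition_id] = simulate(self.model, params, cond)
        return self._cache[condition_id]

    def reset(self):
        self._cache.clear()


def _series_error(traj, series: MeasurementSeries) -> float:
    sim = np.interp(series.times, traj.times, traj.series(series.species))
    scaled, _ = scale_to_data(sim, series.values)
    z = (scaled - series.values) / series.effective_sd()
    return float(np.dot(z, z))


def objective_error(
    params: ParameterSet,
    objective: Objective,
    model,
    conditions: dict[str, Condition],
    cache: SimulationCache | None = None,
) -> float:
    """Weighted SSE of one objective; failed integrations map to +inf."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    own_cache = cache or SimulationCache(cm, conditions)
    total = 0.0
    for s in objective.series:
        try:
            traj = own_cache.trajectory(params, s.condition_id)
        except IntegrationError:
            return FAILURE_SENTINEL
        total += _series_error(traj, s)
    return objective.weight * total


def evaluate_objectives(
    params: ParameterSet,
    objectives: list[Objective],
    model,
    conditions: dict[str, Condition],
) -> np.ndarray:
    """Error vector over the objectives; one simulation per unique condition."""
    if not objectives:
        raise ValueError("objectives list is empty")
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    cache = SimulationCache(cm, conditions)
    return np.array(
        [objective_error(params, o, cm, conditions, cache) for o in objectives]
    )


# ---------------------------------------------------------------------------
# CSV round-trip (objective_id, series_id, species, condition_id, time_h, value, sd)
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "objective_id", "series_id", "species", "condition_id",
    "time_h", "value", "sd",
]


def objectives_to_frame(objectives: list[Objective]) -> pd.DataFrame:
    rows = []
    for o in objectives:
        for s in o.series:
            sd = s.effective_sd()
            for t, v, e in zip(s.times, s.values, sd):
                rows.append((o.id, s.series_id, s.species, s.condition_id, t, v, e))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_objectives_csv(objectives: list[Objective], path) -> None:
    objectives_to_frame(objectives).to_csv(path, index=False)


def read_objectives_csv(path_or_buf) -> list[Objective]:
    df = pd.read_csv(path_or_buf)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"objectives CSV missing columns {sorted(missing)}")
    objectives = []
    for oid, og in df.groupby("objective_id", sort=True):
        series = []
        for sid, sg in og.groupby("series_id", sort=True):
            sg = sg.sort_values("time_h")
            series.append(
                MeasurementSeries(
                    series_id=str(sid),
                    species=sg["species"].iloc[0],
                    condition_id=sg["condition_id"].iloc[0],
                    times=sg["time_h"].to_numpy(),
                    values=sg["value"].to_numpy(),
                    sd=sg["sd"].to_numpy(),
                )
            )
        objectives.append(Objective(id=int(oid), series=series))
    return objectives
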