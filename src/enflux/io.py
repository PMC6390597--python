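"""Persistence of cohort, trajectory, calorimetry and report artifacts.

Formats are deliberately plain: individuals as a JSON array (field names
exactly as on :class:`~enflux.model.VirtualIndividual`), trajectories as
tidy CSV ``(individual_id, time_day, variable, value)``, gas-exchange
records as CSV ``(animal_id, time_min, vo2_L_per_day, vco2_L_per_day)``,
stratification reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calorimetry import GasExchangeRecord
from .model import (
    Trajectory,
    VirtualIndividual,
    individual_from_dict,
    individual_to_dict,
)

__all__ = [
    "save_cohort",
    "load_cohort",
    "trajectory_to_tidy",
    "save_trajectories",
    "load_trajectories",
    "save_gas_records",
    "load_gas_records",
    "save_json",
    "load_json",
]


def save_cohort(cohort: list[VirtualIndividual], path: str | Path) -> None:
    payload = [individual_to_dict(ind) for ind in cohort]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_cohort(path: str | Path) -> list[VirtualIndividual]:
    payload = json.loads(Path(path).read_text())
    return [individual_from_dict(d) for d in payload]


def trajectory_to_tidy(trajectory: Trajectory) -> pd.DataFrame:
    """Long-format frame with columns individual_id, time_day, variable, value."""
    frames = []
    for block in (trajectory.pools, trajectory.fluxes):
        df = block.copy()
        df["time_day"] = trajectory.time
        frames.append(df.melt(id_vars="time_day", var_name="variable", value_name="value"))
    tidy = pd.concat(frames, ignore_index=True)
    tidy.insert(0, "individual_id", trajectory.individual_id)
    return tidy


def save_trajectories(trajectories: dict[str, Trajectory], path: str | Path) -> None:
    tidy = pd.concat(
        [trajectory_to_tidy(t) for t in trajectories.values()], ignore_index=True
    )
    tidy.to_csv(path, index=False)


def load_trajectories(path: str | Path) -> dict[str, Trajectory]:
    tidy = pd.read_csv(path)
    from .model import FLUX_NAMES, STATE_NAMES

    out: dict[str, Trajectory] = {}
    for iid, grp in tidy.groupby("individual_id", sort=False):
        wide = grp.pivot_table(index="time_day", columns="variable", values="value", sort=True)
        out[str(iid)] = Trajectory(
            individual_id=str(iid),
            time=wide.index.to_numpy(dtype=float),
            pools=wide[list(STATE_NAMES)].reset_index(drop=True),
            fluxes=wide[list(FLUX_NAMES)].reset_index(drop=True),
        )
    return out


def save_gas_records(records: list[GasExchangeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": r.animal_id,
                    "time_min": r.time_min,
                    "vo2_L_per_day": r.vo2,
                    "vco2_L_per_day": r.vco2,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def load_gas_records(path: str | Path) -> list[GasExchangeRecord]:
    df = pd.read_csv(path)
    records = []
    for aid, grp in df.groupby("animal_id", sort=False):
        records.append(
            GasExchangeRecord(
                animal_id=str(aid),
                time_min=grp["time_min"].to_numpy(),
                vo2=grp["vo2_L_per_day"].to_numpy(),
                vco2=grp["vco2_L_per_day"].to_numpy(),
            )
        )
    return records


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, cls=_NumpyEncoder))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
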