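"""Per-population environmental tables with climate-scenario bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class EnvTable:
    """Populations x environmental variables for one climate scenario.

    ``data`` is indexed by population; ``climatic_vars`` names the columns
    that move under future scenarios (non-climatic predictors such as soil
    properties stay at present values).
    """

    data: pd.DataFrame
    scenario: str = "current"
    climatic_vars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.climatic_vars) - set(self.data.columns)
        if unknown:
            raise ValueError(f"climatic_vars not in table: {sorted(unknown)}")

    @property
    def populations(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "population", out.index)
        out["scenario"] = self.scenario
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, climatic_vars: list[str] | None = None) -> "EnvTable":
        df = pd.read_csv(path)
        if "population" not in df.columns:
            raise ValueError(f"{path}: missing 'population' column")
        scenario = "current"
        if "scenario" in df.columns:
            scenarios = df["scenario"].unique()
            if len(scenarios) != 1:
                raise ValueError(f"{path}: mixed scenarios {scenarios}")
            scenario = str(scenarios[0])
            df = df.drop(columns="scenario")
        df = df.set_index("population")
        return cls(data=df, scenario=scenario, climatic_vars=climatic_vars or [])


def shift_climate(env: EnvTable, delta_by_pop: pd.DataFrame | dict, scenario: str = "future") -> EnvTable:
    """Apply per-population deltas to the climatic variables.

    ``delta_by_pop`` is a populations x climatic-variables frame (or a dict
    ``{variable: {population: delta}}``); variables absent from the delta
    table, and all non-climatic variables, are copied unchanged.
    """
    if isinstance(delta_by_pop, dict):
        delta_by_pop = pd.DataFrame(delta_by_pop)
    missing = set(env.populations) - set(delta_by_pop.index)
    if missing:
        raise ValueError(f"delta table missing populations: {sorted(missing)[:5]}")
    non_climatic_touched = set(delta_by_pop.columns) - set(env.climatic_vars)
    if non_climatic_touched:
        raise ValueError(
            f"deltas supplied for non-climatic variables: {sorted(non_climatic_touched)}"
        )
    data = env.data.copy()
    for var in delta_by_pop.columns:
        data[var] = data[var] + delta_by_pop[var].reindex(data.index)
    return EnvTable(data=data, scenario=scenario, climatic_vars=list(env.climatic_vars))
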