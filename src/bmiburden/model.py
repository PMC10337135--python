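"""Model/Results interface over the projection pipeline.

``BurdenProjection`` is built from a validated input bundle (CSV directory
or the synthetic generator); ``fit()`` runs the four scenario trajectories
plus the TMREL counterfactual through the multistate life table, optionally
with Monte Carlo uncertainty, and returns a ``BurdenProjectionResults``
carrying the burden tables, intervals, aggregations and plots.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import SCENARIOS, TOTAL, ModelConfig, ModelInputs
from .engine import MsltRun, RunContext, run_mslt
from .io import load_inputs
from .reporting import aggregate_totals, averted, plot_trends, shares, trend_series
from .scenarios import build_canonical_scenarios, tmrel_trajectory
from .synthetic import SyntheticParams, generate_bundle
from .uncertainty import DrawSpec, UncertaintyResult, run_monte_carlo

__all__ = ["BurdenProjection", "BurdenProjectionResults"]


class BurdenProjection:
    """Proportional multistate life-table projection of overweight burden."""

    def __init__(self, inputs: ModelInputs):
        self.inputs = inputs

    @classmethod
    def from_config(cls, config_path) -> "BurdenProjection":
        """Build from a YAML config referencing the four input CSVs."""
        return cls(load_inputs(config_path))

    @classmethod
    def from_synthetic(
        cls, seed: int = 0, scale: float = 1e5, config: ModelConfig | None = None
    ) -> "BurdenProjection":
        """Build from the anchored synthetic Chilean-style bundle."""
        params = SyntheticParams(seed=seed, scale=scale)
        return cls(generate_bundle(params, config))

    def fit(
        self, draws: int = 0, seed: int | None = None
    ) -> "BurdenProjectionResults":
        """Run all scenarios; with draws > 0 add Monte Carlo 95% UIs."""
        cfg = self.inputs.config
        ctx = RunContext(self.inputs)
        trajectories = build_canonical_scenarios(cfg, self.inputs.bmi_baseline)
        tmrel_run = run_mslt(self.inputs, tmrel_trajectory(cfg, self.inputs.bmi_baseline), ctx)
        runs = {sid: run_mslt(self.inputs, traj, ctx) for sid, traj in trajectories.items()}

        key = ["outcome", "disease_id", "year"]
        tmrel_values = tmrel_run.burden.set_index(key)["value"]
        attr_frames = []
        for sid, run in runs.items():
            df = run.burden.copy()
            df["value"] = df["value"].to_numpy() - tmrel_values.reindex(
                pd.MultiIndex.from_frame(df[key])
            ).to_numpy()
            attr_frames.append(df)
        attributable = pd.concat(attr_frames, ignore_index=True)

        uncertainty = None
        if draws > 0:
            spec = DrawSpec(n_draws=draws, seed=cfg.seed if seed is None else seed)
            uncertainty = run_monte_carlo(self.inputs, spec)

        return BurdenProjectionResults(
            model=self,
            runs=runs,
            tmrel_run=tmrel_run,
            attributable=attributable,
            uncertainty=uncertainty,
        )


@dataclass
class BurdenProjectionResults:
    """Scenario burden tables and their aggregations."""

    model: BurdenProjection
    runs: dict[str, MsltRun]
    tmrel_run: MsltRun
    attributable: pd.DataFrame  # per outcome/disease/scenario/year, vs TMREL
    uncertainty: UncertaintyResult | None = None

    def totals(self) -> pd.DataFrame:
        """Period-total attributable burden per scenario with cancer subtotal."""
        return aggregate_totals(self.attributable)

    def averted(self) -> pd.DataFrame:
        """BAU-minus-scenario attributable burden (cases/deaths prevented)."""
        return averted(self.attributable)

    def shares(self, grouping=None) -> pd.DataFrame:
        return shares(self.attributable, grouping)

    def trend(self, cumulative: bool = True) -> pd.DataFrame:
        return trend_series(self.attributable, cumulative=cumulative)

    def plot_trends(self, path: str) -> str:
        return plot_trends(self.trend(), path)

    def summary(self) -> str:
        """Plain-text summary of period totals and averted burden."""
        totals = self.totals()
        pivot = totals[totals["disease_id"] == TOTAL].pivot(
            index="outcome", columns="scenario_id", values="value"
        )[list(SCENARIOS)]
        av = self.averted()
        av_tot = av[av["disease_id"] == TOTAL].pivot(
            index="outcome", columns="scenario_id", values="averted"
        )[[s for s in SCENARIOS if s != "BAU"]]
        lines = [
            "Attributable NCD burden projection "
            f"({self.model.inputs.config.start_year}-{self.model.inputs.config.end_year})",
            "",
            "Period-total attributable burden (persons):",
            pivot.round(0).to_string(),
            "",
            "Averted vs BAU (persons):",
            av_tot.round(0).to_string(),
        ]
        if self.uncertainty is not None:
            lines += ["", f"95% UIs from {self.uncertainty.n_draws} Monte Carlo draws."]
        return "\n".join(lines)
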