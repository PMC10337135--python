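"""Monte Carlo propagation of parameter uncertainty.

Each draw samples the relative risks (lognormal, median at the point
estimate, log-sd from the printed 95% CI, one shared draw per disease across
its age/BMI bands) and the baseline stratum BMI means (a common normal shift
per sex), rebuilds the scenario trajectories from the shifted baseline, and
re-evaluates the attributable burden for every trajectory against the same
draw's TMREL run.  Draws are therefore paired across scenarios, and averted
burden intervals come from per-draw differences, never from differencing two
marginal intervals.  95% uncertainty intervals are the 2.5th/97.5th
percentiles across draws; disease rates are held fixed (their uncertainty is
not propagated).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    DISEASES,
    SCENARIOS,
    SEXES,
    ModelInputs,
    ParameterError,
    RRSpec,
)
from .engine import RunContext, attributable_burden, run_mslt
from .scenarios import build_canonical_scenarios, tmrel_trajectory

__all__ = ["DrawSpec", "sample_rr", "run_monte_carlo", "UncertaintyResult"]

_Z95 = 2.0 * 1.959963984540054  # CI span in standard normal units


@dataclass(frozen=True)
class DrawSpec:
    """What is sampled, how often, and from which seed."""

    n_draws: int = 1000
    seed: int = 0
    sample_rr: bool = True
    sample_bmi_mean: bool = True
    bmi_mean_se: float = 0.1  # kg/m2, common shift per sex per draw

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ParameterError("n_draws must be >= 1")
        if self.bmi_mean_se < 0:
            raise ParameterError("bmi_mean_se must be non-negative")


def sample_rr(spec: RRSpec, rng: np.random.Generator) -> RRSpec:
    """One lognormal draw of a disease's RR bands.

    A single standard-normal deviate is shared by all bands of the disease
    (they derive from one meta-analysis, so within-disease correlation is
    taken as perfect); each band's log-sd is (ln rr_high - ln rr_low)/3.92.
    A degenerate CI (low == point == high) always returns the point.
    """
    z = rng.standard_normal()
    bands = []
    for b in spec.bands:
        if b.rr_low <= 0:
            raise ParameterError(f"{spec.disease_id}: rr_low must be positive")
        sdlog = (np.log(b.rr_high) - np.log(b.rr_low)) / _Z95
        drawn = float(b.rr * np.exp(z * sdlog))
        bands.append(replace(b, rr=drawn, rr_low=min(drawn, b.rr_low), rr_high=max(drawn, b.rr_high)))
    return replace(spec, bands=tuple(bands))


@dataclass
class UncertaintyResult:
    """Point estimates with percentile uncertainty intervals.

    ``attributable`` carries per (outcome, disease, scenario, year) the
    central-parameter point estimate and the 95% UI across draws;
    ``averted`` the same for BAU-minus-scenario differences.  The point
    estimate is the central run, so percentile intervals may exclude it in
    skewed settings; that is recorded, not corrected.
    """

    attributable: pd.DataFrame
    averted: pd.DataFrame
    n_draws: int
    seed: int


def _attributable_frame(
    inputs: ModelInputs,
    trajectories: dict[str, pd.DataFrame],
    rr_specs,
    baseline,
) -> dict[str, pd.DataFrame]:
    ctx = RunContext(inputs, rr_specs=rr_specs, bmi_baseline=baseline)
    tmrel_run = run_mslt(inputs, tmrel_trajectory(inputs.config, baseline), ctx)
    return {
        sid: attributable_burden(inputs, traj, tmrel_run=tmrel_run, context=ctx)
        for sid, traj in trajectories.items()
    }


def run_monte_carlo(
    inputs: ModelInputs,
    draw_spec: DrawSpec | None = None,
) -> UncertaintyResult:
    """Propagate RR and exposure uncertainty through the full projection.

    Fixed seed implies bit-identical output.  Any draw failure aborts with
    the draw index attached.
    """
    spec = draw_spec or DrawSpec(n_draws=inputs.config.n_draws, seed=inputs.config.seed)
    rng = np.random.default_rng(spec.seed)

    central = _attributable_frame(
        inputs,
        build_canonical_scenarios(inputs.config, inputs.bmi_baseline),
        inputs.rr_specs,
        inputs.bmi_baseline,
    )
    key = ["outcome", "disease_id", "year"]
    template = {sid: df.set_index(key)["value"] for sid, df in central.items()}
    cell_index = template["BAU"].index

    draws = {sid: np.empty((spec.n_draws, len(cell_index))) for sid in SCENARIOS}
    for j in range(spec.n_draws):
        try:
            rr_specs = (
                {d: sample_rr(inputs.rr_specs[d], rng) for d in DISEASES}
                if spec.sample_rr
                else inputs.rr_specs
            )
            baseline = inputs.bmi_baseline.copy()
            if spec.sample_bmi_mean:
                for sex in SEXES:
                    shift = rng.normal(0.0, spec.bmi_mean_se)
                    baseline.loc[sex, "mean_bmi"] = (
                        baseline.loc[sex, "mean_bmi"] + shift
                    ).to_numpy()
            trajectories = build_canonical_scenarios(inputs.config, baseline)
            attr = _attributable_frame(inputs, trajectories, rr_specs, baseline)
            for sid in SCENARIOS:
                draws[sid][j] = (
                    attr[sid].set_index(key)["value"].reindex(cell_index).to_numpy()
                )
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"Monte Carlo draw {j} failed: {exc}") from exc

    def percentile_frame(point: pd.Series, sample: np.ndarray, sid: str) -> pd.DataFrame:
        lo, hi = np.percentile(sample, [2.5, 97.5], axis=0)
        out = point.rename("value").reset_index()
        out.insert(2, "scenario_id", sid)
        out["ci_low"] = lo
        out["ci_high"] = hi
        return out

    attr_frames = [
        percentile_frame(template[sid], draws[sid], sid) for sid in SCENARIOS
    ]
    averted_frames = [
        percentile_frame(
            template["BAU"] - template[sid], draws["BAU"] - draws[sid], sid
        )
        for sid in SCENARIOS
        if sid != "BAU"
    ]
    return UncertaintyResult(
        attributable=pd.concat(attr_frames, ignore_index=True),
        averted=pd.concat(averted_frames, ignore_index=True),
        n_draws=spec.n_draws,
        seed=spec.seed,
    )
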