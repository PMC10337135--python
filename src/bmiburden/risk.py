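"""Relative-risk curves and potential impact fractions.

The potential impact fraction (PIF) compares a reference BMI distribution
P_ref with a counterfactual P_cf through a relative-risk curve RR(x):

    PIF = 1 - sum_x P_cf(x) RR(x) / sum_x P_ref(x) RR(x)

and the complementary incidence multiplier sum P_cf RR / sum P_ref RR is
what the multistate life table applies to disease inflow.  Distributions are
discretised on a BMI grid (10-60 kg/m2, 0.1 steps, midpoint rule, truncated
mass renormalised); point masses (sd == 0) are evaluated exactly.
"""
from __future__ import annotations

import numpy as np

from .datatypes import (
    MAX_RR_AGE,
    RRBand,
    RRSpec,
    BMIDistribution,
    ModelConfig,
    SpecificationGapError,
)

__all__ = [
    "bmi_grid",
    "rr_at_bmi",
    "rr_on_grid",
    "normal_weights",
    "pif_from_weights",
    "pif",
    "incidence_multiplier",
]


def bmi_grid(config: ModelConfig | None = None) -> np.ndarray:
    """Midpoints of the BMI discretisation cells."""
    cfg = config or ModelConfig()
    n = int(round((cfg.bmi_grid_hi - cfg.bmi_grid_lo) / cfg.bmi_grid_step))
    return cfg.bmi_grid_lo + cfg.bmi_grid_step * (np.arange(n) + 0.5)


def _age_band(spec: RRSpec, sex: str, age: int) -> RRBand | None:
    """Band matching (sex, age) for a log-linear spec.

    Returns None when the spec restricts applicability (outside_window_rr set)
    and the stratum falls outside every band; otherwise extends to the nearest
    band in age, raising only when no band exists for the sex at all.
    """
    age = min(age, MAX_RR_AGE)
    candidates = [b for b in spec.bands if b.sex in ("both", sex)]
    for b in candidates:
        if b.age_lo <= age <= b.age_hi:
            return b
    if spec.outside_window_rr is not None:
        return None
    if not candidates:
        raise SpecificationGapError(
            f"{spec.disease_id}: no RR band for sex={sex!r}, age={age}"
        )
    return min(
        candidates, key=lambda b: min(abs(age - b.age_lo), abs(age - b.age_hi))
    )


def _categorical_value(spec: RRSpec, bmi: float) -> float:
    bands = sorted(spec.bands, key=lambda b: b.bmi_lo)
    for b in bands:
        if b.bmi_lo <= bmi < b.bmi_hi:
            return b.rr
    return bands[0].rr if bmi < bands[0].bmi_lo else bands[-1].rr


def rr_at_bmi(spec: RRSpec, sex: str, age: int, bmi: float) -> float:
    """Relative risk at a single BMI value for one (sex, age) stratum."""
    if spec.form == "categorical":
        return _categorical_value(spec, bmi)
    band = _age_band(spec, sex, age)
    if band is None:
        return spec.outside_window_rr
    if bmi <= spec.tmrel:
        return 1.0
    return float(band.rr ** ((bmi - spec.tmrel) / 5.0))


def rr_on_grid(
    spec: RRSpec, sex: str, age: int, grid: np.ndarray
) -> np.ndarray:
    """Relative risk evaluated on the whole BMI grid (vectorised rr_at_bmi)."""
    if spec.form == "categorical":
        bands = sorted(spec.bands, key=lambda b: b.bmi_lo)
        out = np.full_like(grid, bands[-1].rr, dtype=float)
        out[grid < bands[0].bmi_lo] = bands[0].rr
        for b in bands:
            out[(grid >= b.bmi_lo) & (grid < b.bmi_hi)] = b.rr
        return out
    band = _age_band(spec, sex, age)
    if band is None:
        return np.full_like(grid, spec.outside_window_rr, dtype=float)
    out = np.ones_like(grid, dtype=float)
    above = grid > spec.tmrel
    out[above] = band.rr ** ((grid[above] - spec.tmrel) / 5.0)
    return out


def normal_weights(
    means: np.ndarray, sds: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Discretised normal probability masses, one row per stratum.

    Tails outside the grid are truncated and the remaining mass renormalised
    to 1, so the rows are proper probability vectors on the grid.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    z = (grid[None, :] - means[:, None]) / sds[:, None]
    w = np.exp(-0.5 * z * z)
    w /= w.sum(axis=1, keepdims=True)
    return w


def pif_from_weights(
    w_ref: np.ndarray, w_cf: np.ndarray, rr: np.ndarray
) -> float:
    """PIF from explicit probability vectors and an RR vector on one grid."""
    denom = float(np.dot(w_ref, rr))
    if denom <= 0:
        raise ArithmeticError("reference RR-weighted mass is not positive")
    return 1.0 - float(np.dot(w_cf, rr)) / denom


def _mean_rr(
    dist: BMIDistribution,
    spec: RRSpec,
    sex: str,
    age: int,
    grid: np.ndarray,
) -> float:
    if dist.sd == 0.0:
        return rr_at_bmi(spec, sex, age, dist.mean)
    w = normal_weights(dist.mean, dist.sd, grid)[0]
    return float(np.dot(w, rr_on_grid(spec, sex, age, grid)))


def incidence_multiplier(
    reference: BMIDistribution,
    counterfactual: BMIDistribution,
    spec: RRSpec,
    sex: str,
    age: int,
    grid: np.ndarray | None = None,
) -> float:
    """Ratio of RR-weighted mass, counterfactual over reference (= 1 - PIF)."""
    if grid is None:
        grid = bmi_grid()
    denom = _mean_rr(reference, spec, sex, age, grid)
    if denom <= 0:
        raise ArithmeticError("reference RR-weighted mass is not positive")
    return _mean_rr(counterfactual, spec, sex, age, grid) / denom


def pif(
    reference: BMIDistribution,
    counterfactual: BMIDistribution,
    spec: RRSpec,
    sex: str,
    age: int,
    grid: np.ndarray | None = None,
) -> float:
    """Potential impact fraction of moving reference to counterfactual.

    Zero when the two distributions coincide, positive when the
    counterfactual shifts mass toward lower risk, and complementary to
    :func:`incidence_multiplier` by construction (pif + multiplier == 1).
    """
    return 1.0 - incidence_multiplier(reference, counterfactual, spec, sex, age, grid)
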