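"""Deterministic (tornado) and probabilistic sensitivity analyses.

One-way analysis re-runs the full two-arm pipeline with each uncertain
parameter at its low and high bound, everything else at base case, and ranks
parameters by the ICER swing. The probabilistic analysis draws every
uncertain parameter from its assigned distribution (beta for probabilities
and utilities, gamma for costs; no correlations) in each iteration, re-runs
both arms, and summarises the incremental cloud against the willingness-to-
pay threshold, including a cost-effectiveness acceptability curve.

Each parameter gets its own random stream derived from the master seed, so
adding or removing a parameter does not perturb the others' draws.

The cohort shares of MCI and mild dementia carry uncertainty intervals while
the SCD share does not; whenever a share is varied, the SCD share absorbs the
change so the cohort stays a unit mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import PathwayId
from .econ import compare_strategies
from .fixtures import FixtureBundle
from .parameters import ParameterSet

__all__ = ["TornadoEntry", "PSAResult", "one_way_dsa", "run_psa", "set_parameter"]

_SHARE_PATHS = {"population.share_mci", "population.share_mild_dem"}


def set_parameter(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Replace one parameter, renormalising the SCD share if a cohort share
    was changed (SCD is the residual category)."""
    if path in _SHARE_PATHS:
        other = (_SHARE_PATHS - {path}).pop()
        scd = 1.0 - value - params.get(other)
        return params.replace_many(
            {path: value, "population.share_scd": scd}
        )
    return params.replace(path, value)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_dsa(
    params: ParameterSet,
    fixtures: FixtureBundle,
    param_list: list[str] | None = None,
    reference: PathwayId = PathwayId.SOC,
    intervention: PathwayId = PathwayId.BBM_PHC,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Returns one row per parameter, sorted by ICER swing descending. A
    parameter without low/high bounds is skipped with a warning. An ICER
    undefined at a bound (zero QALY increment) is recorded as NaN.
    """
    if param_list is None:
        param_list = [p for p, _ in params.iter_uncertain()]

    rows = []
    for path in param_list:
        spec = params.distributions.get(path)
        if spec is None or spec.family == "fixed" or spec.low is None:
            warnings.warn(f"parameter {path!r} has no bounds; skipped", stacklevel=2)
            continue
        icers = {}
        for bound in ("low", "high"):
            value = getattr(spec, bound)
            varied = set_parameter(params, path, value)
            _, _, ce = compare_strategies(
                reference, intervention, varied, fixtures
            )
            icers[bound] = np.nan if ce.icer is None else ce.icer
        entry = TornadoEntry(
            parameter=path,
            low_value=spec.low,
            high_value=spec.high,
            icer_at_low=icers["low"],
            icer_at_high=icers["high"],
        )
        rows.append(
            {
                "parameter": entry.parameter,
                "low_value": entry.low_value,
                "high_value": entry.high_value,
                "icer_at_low": entry.icer_at_low,
                "icer_at_high": entry.icer_at_high,
                "swing": entry.swing,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "parameter", "low_value", "high_value",
            "icer_at_low", "icer_at_high", "swing",
        ],
    )
    return df.sort_values("swing", ascending=False, ignore_index=True)


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis output."""

    iterations: pd.DataFrame  # columns: delta_cost, delta_qaly, icer
    draws: pd.DataFrame  # sampled parameter values, one column per parameter
    fraction_above_wtp: float
    fraction_below_wtp: float
    ceac: pd.DataFrame  # columns: wtp, probability_cost_effective
    wtp: float
    seed: int


def parameter_draws(
    params: ParameterSet, n_iter: int, seed: int
) -> pd.DataFrame:
    """Sample every uncertain parameter ``n_iter`` times.

    One child random stream per parameter (keyed by its sorted position under
    the master seed), so streams are stable against adding parameters.
    """
    paths = sorted(p for p, _ in params.iter_uncertain())
    cols = {}
    for i, path in enumerate(paths):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        cols[path] = params.distributions[path].sample(rng, size=n_iter)
    return pd.DataFrame(cols, index=range(n_iter))


def run_psa(
    params: ParameterSet,
    fixtures: FixtureBundle,
    n_iter: int = 10_000,
    seed: int = 0,
    reference: PathwayId = PathwayId.SOC,
    intervention: PathwayId = PathwayId.BBM_PHC,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis of one pairwise comparison.

    ``fraction_above_wtp`` / ``fraction_below_wtp`` partition the iterations
    that gained QALYs by whether their ICER exceeds the threshold (cost-saving
    QALY-gaining iterations count as below); iterations that lost QALYs are in
    neither. The CEAC reports, per threshold on the grid, the fraction of
    iterations with positive incremental net monetary benefit.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    wtp = params.econ.wtp
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 150_001.0, 10_000.0)

    draws = parameter_draws(params, n_iter, seed)
    records = []
    for i in range(n_iter):
        varied = params
        for path, value in draws.iloc[i].items():
            varied = set_parameter(varied, str(path), float(value))
        _, _, ce = compare_strategies(reference, intervention, varied, fixtures, wtp)
        records.append(
            {
                "delta_cost": ce.delta_cost,
                "delta_qaly": ce.delta_qaly,
                "icer": np.nan if ce.icer is None else ce.icer,
            }
        )
    iters = pd.DataFrame(records)

    gained = iters["delta_qaly"] > 0
    above = gained & (iters["delta_cost"] > 0) & (iters["icer"] > wtp)
    below = gained & ~above
    nmb = wtp_grid[None, :] * iters["delta_qaly"].to_numpy()[:, None] - iters[
        "delta_cost"
    ].to_numpy()[:, None]
    ceac = pd.DataFrame(
        {"wtp": wtp_grid, "probability_cost_effective": (nmb > 0).mean(axis=0)}
    )
    return PSAResult(
        iterations=iters,
        draws=draws,
        fraction_above_wtp=float(above.mean()),
        fraction_below_wtp=float(below.mean()),
        ceac=ceac,
        wtp=wtp,
        seed=seed,
    )
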