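"""Monte Carlo uncertainty and sensitivity analysis over the input table.

The probabilistic analysis re-evaluates the Year-20 per-patient cost metrics
on thousands of parameter draws.  Non-fixed inputs are sampled independently
from their published distributions: triangular rows with the base as mode,
uniform rows on [low, high], and "variable" rows as triangular with bounds
resolved from an analogue row.  For every metric the summary reports the
*certainty to base* (fraction of draws at or above the deterministic base
case), the mean, median and the 10th/90th percentiles.

Sensitivity uses signed contribution-to-variance indices: the normalised
squared Spearman rank correlation of each sampled input with the output,
carrying the correlation's sign (the spreadsheet-PSA convention, which is why
published indices sum near +/-100 %).

Epidemiology growth inputs are held at base during the cost-metric analysis
(the metrics are per-patient costs, not national totals); pass
``include_epidemiology=True`` to sample them jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cost_model import (
    accrual_pre_lt_kernel,
    admission_kernel,
    is_severe,
    post_lt_kernel,
    severe_pre_lt_kernel,
)
from .epidemiology import CATEGORY_WAIT_BAND
from .parameters import (
    ADMISSION_COMPONENTS,
    CASEMIX_CHARACTERISTICS,
    COMPLICATIONS,
    MELD_CATEGORIES,
    DistributionKind,
    DistributionSpec,
    DomainError,
    ParameterTable,
)

__all__ = [
    "MetricSpec",
    "SampledScenario",
    "MonteCarloResult",
    "sample",
    "sample_table",
    "sampled_scenarios",
    "default_cost_metrics",
    "run_monte_carlo",
    "sensitivity_indices",
    "sensitivity_report",
]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
    bounds: tuple[float, float] | None = None,
):
    """Draw from one input distribution.

    ``fixed`` returns the base; ``triangular`` draws with mode = base;
    ``uniform`` draws on [low, high] (the base is reported, not used);
    ``variable`` requires resolved ``bounds`` (see
    :meth:`ParameterTable.sampling_bounds`) and draws triangular.
    """
    kind = spec.kind
    if kind is DistributionKind.FIXED:
        return spec.base if size is None else np.full(size, spec.base)
    if kind is DistributionKind.TRIANGULAR:
        return rng.triangular(spec.low, spec.base, spec.high, size)
    if kind is DistributionKind.UNIFORM:
        return rng.uniform(spec.low, spec.high, size)
    if bounds is None:
        raise DomainError(
            "sampling a 'variable' distribution requires resolved bounds"
        )
    low, high = bounds
    return rng.triangular(low, spec.base, high, size)


def _varied_names(params: ParameterTable, include_epidemiology: bool) -> list[str]:
    names = []
    for name in params.names():
        p = params[name]
        if p.spec.kind is DistributionKind.FIXED:
            continue
        if p.psa or include_epidemiology:
            names.append(name)
    return names


def draw_matrix(
    params: ParameterTable,
    names: Sequence[str],
    n_draws: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """n_draws x len(names) matrix of independent samples (registry order)."""
    cols = {}
    for name in names:
        spec = params[name].spec
        cols[name] = np.asarray(
            sample(spec, rng, size=n_draws, bounds=params.sampling_bounds(name)),
            dtype=float,
        )
    return pd.DataFrame(cols)


def sample_table(
    params: ParameterTable,
    rng: np.random.Generator,
    include_epidemiology: bool = False,
) -> ParameterTable:
    """One full sampled parameter table (fixed inputs untouched)."""
    names = _varied_names(params, include_epidemiology)
    overrides = {
        name: float(sample(params[name].spec, rng, bounds=params.sampling_bounds(name)))
        for name in names
    }
    return params.with_values(overrides)


@dataclass(frozen=True)
class SampledScenario:
    draw_index: int
    table: ParameterTable
    rng_seed: int


def sampled_scenarios(
    params: ParameterTable,
    n_draws: int,
    seed: int,
    include_epidemiology: bool = False,
):
    """Yield :class:`SampledScenario` objects (one RNG stream, in order)."""
    rng = np.random.default_rng(seed)
    for i in range(n_draws):
        yield SampledScenario(
            draw_index=i,
            table=sample_table(params, rng, include_epidemiology),
            rng_seed=seed,
        )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

class _Values:
    """Name -> sampled column, falling back to the base value."""

    def __init__(self, params: ParameterTable, overrides: Mapping[str, np.ndarray]):
        self._params = params
        self._overrides = overrides

    def __call__(self, name: str):
        if name in self._overrides:
            return self._overrides[name]
        return self._params.value(name)


@dataclass(frozen=True)
class MetricSpec:
    """A scalar cost metric with the named inputs that feed it."""

    name: str
    label: str
    inputs: tuple[str, ...]
    evaluate: Callable[[_Values], np.ndarray | float]


def default_cost_metrics(
    params: ParameterTable, listing_year: int = 20
) -> list[MetricSpec]:
    """The seven per-patient cost metrics: pre-transplant per MELD category,
    admission, and 10-year post-transplant, at the given listing year."""
    rates = ("rates.cost_increase", "rates.discount")
    metrics: list[MetricSpec] = []

    for c in MELD_CATEGORIES:
        monthly = f"cost.monthly_pre_lt.{c.slug}"
        band = CATEGORY_WAIT_BAND[c]
        if is_severe(params, c):
            inputs = (monthly, *rates)

            def ev(v, _monthly=monthly):
                return severe_pre_lt_kernel(
                    v(_monthly), v("rates.cost_increase"), v("rates.discount"),
                    listing_year,
                )
        else:
            inputs = (monthly, band, "growth.time_to_transplant",
                      "cost.last30d_adjustment", *rates)

            def ev(v, _monthly=monthly, _band=band):
                return accrual_pre_lt_kernel(
                    v(_monthly), v(_band), v("growth.time_to_transplant"),
                    v("cost.last30d_adjustment"), v("rates.cost_increase"),
                    v("rates.discount"), listing_year,
                )
        metrics.append(
            MetricSpec(
                name=f"pre_lt_{c.slug}",
                label=f"Discounted pre-transplant cost, MELD {c.value}, Year-{listing_year} listing",
                inputs=inputs,
                evaluate=ev,
            )
        )

    share_names = tuple(f"cost.admission_share.{s}" for s in ADMISSION_COMPONENTS)
    uplift_names = tuple(f"cost.casemix_uplift.{s}" for s in CASEMIX_CHARACTERISTICS)
    share_base_sum = sum(params.value(s) for s in share_names)

    def ev_admission(v):
        # The published line-item shares compose the fixed hospital charge, so
        # their draws scale that component; the ratio is 1 at base.
        share_sum = sum(v(s) for s in share_names)
        hospital = v("cost.hospital_admission") * share_sum / share_base_sum
        uplift = sum(
            params.value(f"admission.frac.{s}") * v(f"cost.casemix_uplift.{s}")
            for s in CASEMIX_CHARACTERISTICS
        )
        return admission_kernel(
            v("cost.organ_procurement"), v("cost.physician_fees"), hospital,
            uplift, v("rates.cost_increase"), v("rates.discount"), listing_year,
        )

    metrics.append(
        MetricSpec(
            name="admission",
            label=f"Discounted transplant-to-discharge cost, Year-{listing_year} listing",
            inputs=("cost.organ_procurement", "cost.physician_fees",
                    *share_names, *uplift_names, *rates),
            evaluate=ev_admission,
        )
    )

    freq_names = tuple(f"complication.{c}.frequency" for c in COMPLICATIONS)
    cost_names = tuple(f"complication.{c}.cost" for c in COMPLICATIONS)

    def ev_post(v):
        comp = sum(
            v(f"complication.{c}.frequency") * v(f"complication.{c}.cost")
            for c in COMPLICATIONS
        )
        return post_lt_kernel(
            v("cost.post90d_base"), comp, v("cost.immunosuppression_annual"),
            v("rates.cost_increase"), v("rates.discount"), listing_year,
        )

    metrics.append(
        MetricSpec(
            name="post_lt",
            label=f"Discounted 10-year post-transplant cost, Year-{listing_year} listing",
            inputs=("cost.post90d_base", *freq_names, *cost_names, *rates),
            evaluate=ev_post,
        )
    )
    return metrics


# ---------------------------------------------------------------------------
# Monte Carlo driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloResult:
    summaries: pd.DataFrame
    draws: pd.DataFrame
    outputs: pd.DataFrame
    base_case: dict[str, float]
    metrics: tuple[MetricSpec, ...]
    n_draws: int
    seed: int


def run_monte_carlo(
    params: ParameterTable,
    metrics: Sequence[MetricSpec] | None = None,
    n_draws: int = 30_000,
    seed: int = 0,
    include_epidemiology: bool = False,
) -> MonteCarloResult:
    """Evaluate cost metrics over sampled parameter sets.

    All varied inputs are drawn once per iteration (a single seeded stream,
    sampled in registry order, so results are bit-reproducible for a given
    seed and n_draws); each metric reads the subset of columns feeding it.
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    if metrics is None:
        metrics = default_cost_metrics(params)
    rng = np.random.default_rng(seed)
    names = _varied_names(params, include_epidemiology)
    draws = draw_matrix(params, names, n_draws, rng)
    cols = {name: draws[name].to_numpy() for name in draws.columns}
    view = _Values(params, cols)
    base_view = _Values(params, {})

    outputs = {}
    base_case = {}
    rows = []
    for m in metrics:
        try:
            out = np.asarray(m.evaluate(view), dtype=float)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"metric {m.name!r} failed during evaluation") from exc
        if out.shape != (n_draws,):
            out = np.broadcast_to(out, (n_draws,)).astype(float)
        base = float(m.evaluate(base_view))
        outputs[m.name] = out
        base_case[m.name] = base
        rows.append(
            {
                "metric": m.name,
                "label": m.label,
                "base_case": base,
                "certainty_at_or_above_base": float(np.mean(out >= base)),
                "mean": float(np.mean(out)),
                "median": float(np.median(out)),
                "p10": float(np.quantile(out, 0.10)),
                "p90": float(np.quantile(out, 0.90)),
                "n_draws": n_draws,
                "seed": seed,
            }
        )
    return MonteCarloResult(
        summaries=pd.DataFrame(rows),
        draws=draws,
        outputs=pd.DataFrame(outputs),
        base_case=base_case,
        metrics=tuple(metrics),
        n_draws=n_draws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

def sensitivity_indices(
    draws: pd.DataFrame,
    output: np.ndarray | pd.Series,
    inputs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Signed contribution-to-variance indices for one output metric.

    index_i = sign(rho_i) * rho_i**2 / sum_j rho_j**2, with rho the Spearman
    rank correlation of input i with the output over the draws.  A constant
    output has no rank variance; its indices are undefined and returned NaN.
    """
    out = np.asarray(output, dtype=float)
    if out.ndim != 1 or len(out) != len(draws):
        raise DomainError("output must be one value per draw")
    if len(out) < 100:
        raise DomainError("sensitivity indices require at least 100 draws")
    names = list(inputs) if inputs is not None else list(draws.columns)
    rows = []
    constant_output = np.ptp(out) == 0.0
    for name in names:
        x = draws[name].to_numpy()
        if constant_output or np.ptp(x) == 0.0:
            rho = np.nan
        else:
            rho = float(stats.spearmanr(x, out).statistic)
        rows.append({"input": name, "rho": rho})
    df = pd.DataFrame(rows)
    denom = np.nansum(df["rho"] ** 2)
    if constant_output or denom == 0.0:
        df["index"] = np.nan
    else:
        df["index"] = np.sign(df["rho"]) * df["rho"] ** 2 / denom
    df = df.sort_values("index", key=lambda s: s.abs(), ascending=False, kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def sensitivity_report(result: MonteCarloResult) -> dict[str, pd.DataFrame]:
    """Per-metric contribution-to-variance tables from a Monte Carlo run."""
    report = {}
    for m in result.metrics:
        cols = [n for n in m.inputs if n in result.draws.columns]
        report[m.name] = sensitivity_indices(
            result.draws, result.outputs[m.name].to_numpy(), cols
        )
    return report
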