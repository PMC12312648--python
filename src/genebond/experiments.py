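"""Resource sweeps, heterogeneity screens and the full-vs-reduced benchmark.

These drive the circuit builders over grids of energy/ribosome availability
and over sampled cell-to-cell parameter distributions, mirroring how one
would screen a synthetic circuit design across operating conditions before
building it.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy import stats

from .circuits import CircuitSpec, build_gene_expression, build_repressilator
from .errors import ConfigurationError, GenebondError, NoLimitCycleError, NoSteadyStateError
from .network import NetworkSpec
from .simulate import (
    find_steady_state,
    integrate,
    limit_cycle_metrics,
    switching_time,
)
from .translation import (
    TranslationParams,
    build_full_translation,
    build_reduced_translation,
    translation_rate,
)

_METRICS = (
    "steady_state",
    "switching_time",
    "bistability_index",
    "amplitude",
    "period",
    "translation_rate",
)


@dataclass
class SweepSpec:
    """Grid of shared-pool conditions over which circuit metrics are measured."""

    circuit: CircuitSpec
    axis_A: Sequence[float]
    axis_R: Sequence[float]
    metrics: Sequence[str] = ("steady_state",)

    def __post_init__(self):
        # YAML configs may deliver numbers as strings (e.g. "5.8e6")
        self.axis_A = [float(v) for v in self.axis_A]
        self.axis_R = [float(v) for v in self.axis_R]
        if len(self.axis_A) == 0 or len(self.axis_R) == 0:
            raise ConfigurationError("sweep axes must be non-empty")
        if min(self.axis_A) <= 0 or min(self.axis_R) <= 0:
            raise ConfigurationError("sweep axes must be positive")
        unknown = set(self.metrics) - set(_METRICS)
        if unknown:
            raise ConfigurationError(f"unknown sweep metrics {sorted(unknown)}")


@dataclass
class HeterogeneitySpec:
    """Sampling plan for cell-to-cell variability of one parameter.

    ``parameter`` is one of energy / ribosomes / protein_halflife;
    ``distribution`` is a record like
    ``{"kind": "truncated_normal", "mean": ..., "sd": ..., "minimum": ...}``,
    ``{"kind": "lognormal_cv", "median": ..., "cv": ...}`` or
    ``{"kind": "lognormal_ci95", "median": ..., "ci95_fold": ...}``.
    Half-life draws are applied identically to every gene (perfectly
    correlated global fluctuation).
    """

    parameter: str
    distribution: Dict
    n_samples: int = 1000
    seed: int = 0
    correlation: str = "perfectly_correlated_across_proteins"

    def __post_init__(self):
        if self.parameter not in ("energy", "ribosomes", "protein_halflife"):
            raise ConfigurationError(f"unknown heterogeneity parameter {self.parameter!r}")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")


# ------------------------------------------------------------------ samplers
def sample_truncated_normal(
    mean: float, sd: float, minimum: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Left-truncated normal via the inverse CDF (exact and rejection-free)."""
    if sd == 0:
        return np.full(n, max(mean, minimum))
    a = (minimum - mean) / sd
    u = rng.random(n)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def lognormal_sigma_from_cv(cv: float) -> float:
    """Log-scale sd of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv**2))


def lognormal_sigma_from_ci95_fold(fold: float) -> float:
    """Log-scale sd whose central 95% interval spans median/fold .. median*fold."""
    return math.log(fold) / stats.norm.ppf(0.975)


def sample_lognormal(
    median: float, sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sigma == 0:
        return np.full(n, median)
    return np.exp(rng.normal(math.log(median), sigma, size=n))


def draw_parameter_samples(h: HeterogeneitySpec) -> np.ndarray:
    """Reproducible samples of the varied parameter (natural units)."""
    rng = np.random.default_rng(h.seed)
    d = dict(h.distribution)
    kind = d.pop("kind")
    if kind == "truncated_normal":
        return sample_truncated_normal(d["mean"], d["sd"], d["minimum"], h.n_samples, rng)
    if kind == "lognormal_cv":
        return sample_lognormal(
            d["median"], lognormal_sigma_from_cv(d["cv"]), h.n_samples, rng
        )
    if kind == "lognormal_ci95":
        return sample_lognormal(
            d["median"], lognormal_sigma_from_ci95_fold(d["ci95_fold"]), h.n_samples, rng
        )
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


# ------------------------------------------------------------ unit conversion
def molecules_to_concentration(count: float, volume_litres: float = 1e-15) -> float:
    """Molecule count to molar concentration (default volume: 1 µm³ = 1e-15 L)."""
    if count < 0 or volume_litres <= 0:
        raise ConfigurationError("count must be >= 0 and volume > 0")
    return count / (_const.Avogadro * volume_litres)


def concentration_to_molecules(molar: float, volume_litres: float = 1e-15) -> float:
    """Molar concentration to molecule count (inverse of the above)."""
    if molar < 0 or volume_litres <= 0:
        raise ConfigurationError("concentration must be >= 0 and volume > 0")
    return molar * _const.Avogadro * volume_litres


# ------------------------------------------------------------------- sweeps
def _single_gene_translation_rate(circuit: CircuitSpec, pools: Dict[str, float]) -> float:
    g = circuit.genes[0]
    net = build_gene_expression(g, pools=pools)
    x = find_steady_state(net)
    return translation_rate(net, x, prefix=f"{g.name}_")


def resource_sweep(
    s: SweepSpec,
    build: Optional[Callable[[CircuitSpec], NetworkSpec]] = None,
    ic_active: Optional[Dict[str, float]] = None,
    ic_inactive: Optional[Dict[str, float]] = None,
    t_cycle: float = 2000.0,
    readout: Optional[str] = None,
) -> pd.DataFrame:
    """Measure the requested metrics at every (A, R) grid point.

    Failures at individual grid points (no steady state, no limit cycle) are
    recorded as NaN with the error message in the ``status`` column; an error
    is raised only if every grid point fails.
    """
    rows = []
    any_ok = False
    for A in s.axis_A:
        for R in s.axis_R:
            pools = {**s.circuit.pools, "A": float(A), "R": float(R)}
            row: Dict[str, object] = {"A": float(A), "R": float(R), "status": "ok"}
            try:
                if "translation_rate" in s.metrics:
                    row["translation_rate"] = _single_gene_translation_rate(s.circuit, pools)
                needs_net = set(s.metrics) - {"translation_rate"}
                if needs_net:
                    from dataclasses import replace

                    spec = replace(s.circuit, pools=pools)
                    net = build(spec) if build else build_repressilator(spec)
                    _grid_point_metrics(
                        net, s.metrics, row, ic_active, ic_inactive, t_cycle, readout
                    )
                any_ok = True
            except GenebondError as exc:
                row["status"] = f"{type(exc).__name__}: {exc}"
                for m in s.metrics:
                    row.setdefault(m, np.nan)
            rows.append(row)
    if not any_ok:
        raise GenebondError("every grid point of the resource sweep failed")
    return pd.DataFrame(rows)


def _grid_point_metrics(net, metrics, row, ic_active, ic_inactive, t_cycle, readout):
    readout = readout or f"{net.species[0].name.split('_')[0]}_P"
    if "bistability_index" in metrics or "switching_time" in metrics or "steady_state" in metrics:
        x_active = find_steady_state(net, net.initial_state(ic_active))
        if "steady_state" in metrics:
            row["steady_state"] = float(x_active[net.species_index(readout)])
        if "bistability_index" in metrics:
            x_inactive = find_steady_state(net, net.initial_state(ic_inactive))
            row["bistability_index"] = float(
                x_active[net.species_index(readout)]
                / x_inactive[net.species_index(readout)]
            )
        if "switching_time" in metrics:
            p1, p2 = readout, readout.replace("g1", "g2")
            tc = integrate(
                net,
                net.initial_state(ic_active),
                t_span=(0.0, t_cycle),
                t_eval=np.linspace(0.0, t_cycle, 2001),
            )
            row["switching_time"] = switching_time(
                tc,
                float(x_active[net.species_index(p1)]),
                float(x_active[net.species_index(p2)]),
                p1=p1,
                p2=p2,
            )
    if "amplitude" in metrics or "period" in metrics:
        tc = integrate(
            net,
            net.initial_state(ic_active),
            t_span=(0.0, t_cycle),
            t_eval=np.linspace(0.0, t_cycle, 4001),
        )
        amplitude, period = limit_cycle_metrics(tc, readout)
        if "amplitude" in metrics:
            row["amplitude"] = amplitude
        if "period" in metrics:
            row["period"] = period


# ------------------------------------------------------------ heterogeneity
@dataclass
class HeterogeneityResult:
    table: pd.DataFrame
    excluded: int
    summary: Dict
    percentile_timecourses: Dict[float, pd.DataFrame] = field(default_factory=dict)


def heterogeneity_experiment(
    h: HeterogeneitySpec,
    circuit: CircuitSpec,
    ic: Optional[Dict[str, float]] = None,
    t_cycle: float = 2000.0,
    readout: str = "g1_P",
    percentiles: Sequence[float] = (5, 25, 50, 75, 95),
) -> HeterogeneityResult:
    """Per-sample repressilator amplitude/period under parameter heterogeneity.

    Samples that do not oscillate are excluded and counted.  The summary
    holds the requested percentiles of the sampled parameter; the timecourses
    simulated at those percentile values are returned alongside.
    """
    samples = draw_parameter_samples(h)
    rows = []
    excluded = 0
    for value in samples:
        try:
            amplitude, period = _run_sampled(h.parameter, float(value), circuit, ic, t_cycle, readout)
            rows.append({"value": float(value), "amplitude": amplitude, "period": period})
        except (NoLimitCycleError, NoSteadyStateError, GenebondError):
            excluded += 1
            rows.append({"value": float(value), "amplitude": np.nan, "period": np.nan})
    if excluded > 0.5 * h.n_samples:
        raise GenebondError(
            f"{excluded}/{h.n_samples} heterogeneity samples failed to oscillate"
        )
    table = pd.DataFrame(rows)
    pct_values = {p: float(np.percentile(samples, p)) for p in percentiles}
    timecourses = {}
    for p, value in pct_values.items():
        try:
            tc = _simulate_sampled(h.parameter, value, circuit, ic, t_cycle)
            timecourses[p] = tc.to_dataframe()
        except GenebondError:
            pass
    summary = {
        "parameter": h.parameter,
        "n_samples": h.n_samples,
        "excluded": excluded,
        "analysed": h.n_samples - excluded,
        "percentile_values": pct_values,
    }
    return HeterogeneityResult(table, excluded, summary, timecourses)


def _apply_sample(parameter: str, value: float, circuit: CircuitSpec, ic):
    from dataclasses import replace

    pools = dict(circuit.pools)
    genes = list(circuit.genes)
    if parameter == "energy":
        pools["A"] = value
    elif parameter == "ribosomes":
        pools["R"] = value
    elif parameter == "protein_halflife":
        from .rate_laws import DegradationParams

        r_deg = math.log(2.0) / value
        genes = [
            replace(g, deg_p=DegradationParams(r_deg=r_deg, sink_potential=g.deg_p.sink_potential))
            for g in genes
        ]
    spec = replace(circuit, genes=genes, pools=pools)
    return build_repressilator(spec)


def _simulate_sampled(parameter, value, circuit, ic, t_cycle):
    net = _apply_sample(parameter, value, circuit, ic)
    return integrate(
        net,
        net.initial_state(ic),
        t_span=(0.0, t_cycle),
        t_eval=np.linspace(0.0, t_cycle, 4001),
    )


def _run_sampled(parameter, value, circuit, ic, t_cycle, readout):
    tc = _simulate_sampled(parameter, value, circuit, ic, t_cycle)
    return limit_cycle_metrics(tc, readout)


# --------------------------------------------------------------- benchmark
def benchmark_models(
    p: TranslationParams,
    n_values: Sequence[int],
    repetitions: int = 3,
    t_span=(0.0, 10.0),
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """State dimensions (exact) and runtime ratio full/reduced (informational).

    Runtimes are hardware-dependent and reported only as a smoke-level
    comparison; the structural claim is the dimension scaling (full grows
    with n, reduced stays constant).
    """
    from dataclasses import replace

    rows = []
    for n in n_values:
        if n < 2:
            raise ConfigurationError("benchmark requires n >= 2")
        pn = replace(p, n=int(n))
        full = build_full_translation(pn)
        reduced = build_reduced_translation(pn)
        t_full = _time_integration(full, repetitions, t_span, rtol, atol)
        t_reduced = _time_integration(reduced, repetitions, t_span, rtol, atol)
        rows.append(
            {
                "n": int(n),
                "dim_full": full.n_species,
                "dim_reduced": reduced.n_species,
                "time_full_s": t_full,
                "time_reduced_s": t_reduced,
                "runtime_ratio": t_full / t_reduced,
            }
        )
    return pd.DataFrame(rows)


def _time_integration(net, repetitions, t_span, rtol, atol):
    best = math.inf
    for _ in range(repetitions):
        start = time.perf_counter()
        integrate(net, t_span=t_span, rtol=rtol, atol=atol)
        best = min(best, time.perf_counter() - start)
    return best
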