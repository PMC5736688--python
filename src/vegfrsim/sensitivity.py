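"""Concentration sweeps and Monte Carlo uncertainty propagation.

One-at-a-time adapter-concentration sweeps run on a log-spaced grid over
[1e2, 1e5] molecules/cell, re-simulating the model at every grid point with
only the swept adapter's pool changed.  Monte Carlo analysis perturbs
kinetic rates around their nominal values (default: log-uniform within one
decade of kon and koff, per adapter) and reports the mean and standard
deviation of every response summary over the draws; a fixed seed makes the
whole analysis bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ode import DEFAULT_N_POINTS, DEFAULT_T_END, phospho_trace, run_model
from .params import ModelParameters, RESPONSES
from .responses import ResponseSummary, compute_responses, summarize

SWEEP_LO = 1e2  # molecules/cell
SWEEP_HI = 1e5


@dataclass
class SweepResult:
    """Per-grid-point response and adapter summaries for one swept adapter."""

    swept_adapter: str
    grid: np.ndarray  # molecules/cell
    summaries: list[ResponseSummary]
    adapter_integrated: list[dict[str, float]]  # per grid point, per adapter
    adapter_amplitude: list[dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x, summ, ai, aa in zip(
            self.grid, self.summaries, self.adapter_integrated, self.adapter_amplitude
        ):
            for resp in RESPONSES:
                rows.append(
                    {
                        "swept_adapter": self.swept_adapter,
                        "concentration": x,
                        "output": resp,
                        "integrated": summ.integrated[resp],
                        "amplitude": summ.amplitude[resp],
                    }
                )
            for aname in ai:
                rows.append(
                    {
                        "swept_adapter": self.swept_adapter,
                        "concentration": x,
                        "output": f"adapter:{aname}",
                        "integrated": ai[aname],
                        "amplitude": aa[aname],
                    }
                )
        return pd.DataFrame(rows)


def sweep_concentration(
    params: ModelParameters,
    adapter: str,
    n_grid: int = 10,
    variant: str = "specific",
    lo: float = SWEEP_LO,
    hi: float = SWEEP_HI,
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
) -> SweepResult:
    """One-at-a-time concentration sweep of a single adapter.

    The grid is log-spaced and includes the endpoints exactly.
    """
    params.adapter(adapter)  # raise early on unknown name
    if n_grid < 2:
        raise ConfigurationError("n_grid must be >= 2")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    grid[0], grid[-1] = lo, hi  # exact endpoints
    summaries, adapter_integrated, adapter_amplitude = [], [], []
    for conc in grid:
        p = params.copy()
        p.adapter(adapter).concentration = float(conc)
        result = run_model(p, variant=variant, t_end=t_end, n_points=n_points)
        summaries.append(summarize(compute_responses(result, p)))
        ai, aa = {}, {}
        for a in p.adapters:
            tr = phospho_trace(result, a.name)
            ai[a.name] = float(np.trapezoid(tr, result.times))
            aa[a.name] = float(np.max(tr))
        adapter_integrated.append(ai)
        adapter_amplitude.append(aa)
    return SweepResult(adapter, grid, summaries, adapter_integrated, adapter_amplitude)


@dataclass
class PerturbationSpec:
    """How Monte Carlo draws perturb the nominal parameterization.

    ``targets`` selects which adapter rates are perturbed; each draw
    multiplies the rate by 10**U(-decades, +decades) (log-uniform).
    ``decades = 0`` gives zero-width perturbation (every draw is nominal).
    """

    targets: tuple[str, ...] = ("kon", "koff")
    decades: float = 1.0

    def validate(self) -> None:
        allowed = {"kon", "koff", "concentration"}
        bad = set(self.targets) - allowed
        if bad:
            raise ConfigurationError(f"unknown perturbation targets: {sorted(bad)}")
        if self.decades < 0:
            raise ConfigurationError("decades must be >= 0")


def sample_perturbation_factors(
    spec: PerturbationSpec, seed: int, n: int
) -> np.ndarray:
    """Draw n multiplicative factors from the perturbation distribution.

    Factors are 10**U(-decades, decades); log10 of a factor therefore has
    mean 0 and standard deviation decades/sqrt(3).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    return 10.0 ** rng.uniform(-spec.decades, spec.decades, size=n)


@dataclass
class MonteCarloResult:
    """Mean and standard deviation of each output over the draws."""

    n_draws: int
    seed: int
    spec: PerturbationSpec
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    draws: pd.DataFrame | None = None


def _summary_outputs(summary: ResponseSummary) -> dict[str, float]:
    out = {}
    for resp in RESPONSES:
        out[f"integrated:{resp}"] = summary.integrated[resp]
        out[f"amplitude:{resp}"] = summary.amplitude[resp]
    return out


def monte_carlo(
    params: ModelParameters,
    n_draws: int,
    seed: int,
    perturbation: PerturbationSpec | None = None,
    variant: str = "specific",
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
    keep_draws: bool = False,
) -> MonteCarloResult:
    """Propagate kinetic-parameter uncertainty through the model.

    Deterministic for a fixed seed.  Standard deviations use the population
    convention (ddof=0) so a single draw reports sd = 0.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    spec = perturbation or PerturbationSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    records: list[dict[str, float]] = []
    for _ in range(n_draws):
        p = params.copy()
        for a in p.adapters:
            for target in spec.targets:
                factor = 10.0 ** rng.uniform(-spec.decades, spec.decades)
                setattr(a, target, getattr(a, target) * factor)
        result = run_model(p, variant=variant, t_end=t_end, n_points=n_points)
        records.append(_summary_outputs(summarize(compute_responses(result, p))))
    frame = pd.DataFrame(records)
    # moments computed around the first draw so identical draws give sd == 0
    mean, sd = {}, {}
    for col in frame.columns:
        x = frame[col].to_numpy()
        shifted = x - x[0]
        m = shifted.mean()
        mean[col] = float(x[0] + m)
        sd[col] = float(np.sqrt(np.mean((shifted - m) ** 2)))
    return MonteCarloResult(
        n_draws=n_draws,
        seed=seed,
        spec=spec,
        mean=mean,
        sd=sd,
        draws=frame if keep_draws else None,
    )
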