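"""Cell-response readouts, inhibitor predictions, and goodness of fit.

Migration and proliferation are weighted sums of adapter phosphorylation
traces; degradation is by definition identical to c-Cbl phosphorylation.
Summaries are the integrated response (trapezoidal area under the
response-time curve), the amplitude (peak value), and each response's
fraction of the three-response integrated total.

Inhibitors are modeled as complete blocks of the target adapter's
phosphorylation path (its kp is scaled to zero) while binding is retained,
so competition for receptor sites persists — appropriate for catalytic
inhibitors such as Wortmannin, U73122 and Imatinib.  An alternative mode
removes the adapter pool entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .errors import ConfigurationError, ParameterValidationError, UnknownEntityError
from .ode import SimulationResult, phospho_trace
from .params import ModelParameters, RESPONSES

WEIGHTED_RESPONSES = ("migration", "proliferation")


@dataclass
class CellResponseTrace:
    """Migration/proliferation/degradation time courses (weighted molecules/cell)."""

    times: np.ndarray
    migration: np.ndarray
    proliferation: np.ndarray
    degradation: np.ndarray

    def get(self, response: str) -> np.ndarray:
        try:
            return getattr(self, response)
        except AttributeError:
            raise UnknownEntityError(f"unknown response {response!r}") from None


@dataclass
class ResponseSummary:
    """Integrated (AUC), amplitude, and relative-integrated summaries."""

    integrated: dict[str, float] = field(default_factory=dict)
    amplitude: dict[str, float] = field(default_factory=dict)
    relative_integrated: dict[str, float] = field(default_factory=dict)


@dataclass
class GofReport:
    """Chi-square goodness-of-fit verdict for one predicted time course."""

    chi2: float
    dof: int
    critical: float
    passed: bool
    residuals: np.ndarray


def compute_responses(result: SimulationResult, params: ModelParameters) -> CellResponseTrace:
    """Map phospho-adapter traces to the three cell-response channels.

    Every adapter must carry weights for migration and proliferation (zero
    is a valid weight).  Degradation is the phospho trace of the
    degradation adapter (c-Cbl); if that adapter is not in the model the
    degradation channel is identically zero.
    """
    n = len(result.times)
    traces = {a.name: phospho_trace(result, a.name) for a in params.adapters}
    sums = {r: np.zeros(n) for r in WEIGHTED_RESPONSES}
    for a in params.adapters:
        for resp in WEIGHTED_RESPONSES:
            if resp not in a.weights:
                raise ConfigurationError(
                    f"adapter {a.name} is missing a {resp} weight"
                )
            sums[resp] = sums[resp] + a.weights[resp] * traces[a.name]
    if params.degradation_adapter in traces:
        degradation = traces[params.degradation_adapter]
    else:
        degradation = np.zeros(n)
    return CellResponseTrace(
        times=result.times,
        migration=sums["migration"],
        proliferation=sums["proliferation"],
        degradation=degradation,
    )


def summarize(trace: CellResponseTrace) -> ResponseSummary:
    """AUC (trapezoid on the stored grid), peak amplitude, relative fractions."""
    if len(trace.times) < 2:
        raise ConfigurationError("need at least 2 time points to summarize")
    integrated = {
        r: float(np.trapezoid(trace.get(r), trace.times)) for r in RESPONSES
    }
    amplitude = {r: float(np.max(trace.get(r))) for r in RESPONSES}
    total = sum(integrated.values())
    if total > 0:
        relative = {r: integrated[r] / total for r in RESPONSES}
    else:
        relative = {r: 0.0 for r in RESPONSES}
    return ResponseSummary(integrated=integrated, amplitude=amplitude,
                           relative_integrated=relative)


def apply_inhibitor(
    params: ModelParameters, adapter: str, mode: str = "kp"
) -> ModelParameters:
    """Return parameters with the named adapter completely inhibited.

    ``mode='kp'`` (default) removes the adapter's phosphorylation path but
    keeps its binding, preserving site competition; ``mode='deplete'`` sets
    its concentration to zero instead.
    """
    params.adapter(adapter)  # raise early on unknown name
    treated = params.copy()
    for a in treated.adapters:
        if a.name == adapter:
            if mode == "kp":
                a.kp_scale = 0.0
            elif mode == "deplete":
                a.concentration = 0.0
            else:
                raise ConfigurationError(f"unknown inhibitor mode {mode!r}")
    return treated


def percent_reduction(
    baseline: ResponseSummary, treated: ResponseSummary, response: str
) -> float:
    """Percent drop of the integrated response under treatment."""
    base = baseline.integrated.get(response)
    if base is None:
        raise UnknownEntityError(f"unknown response {response!r}")
    if base <= 0:
        raise ParameterValidationError(
            f"baseline integrated {response} must be > 0, got {base}"
        )
    return 100.0 * (1.0 - treated.integrated[response] / base)


def significance_band(
    baseline: ResponseSummary, response: str, fraction: float = 0.1
) -> tuple[float, float]:
    """Interval of ±10% variation around the untreated integrated response.

    A treated value strictly outside the (inclusive) band is flagged as a
    model-significant change.
    """
    base = baseline.integrated.get(response)
    if base is None:
        raise UnknownEntityError(f"unknown response {response!r}")
    if base <= 0:
        raise ParameterValidationError(f"baseline {response} must be > 0")
    return ((1.0 - fraction) * base, (1.0 + fraction) * base)


def is_significant(value: float, band: tuple[float, float]) -> bool:
    lo, hi = band
    return value < lo or value > hi


def chi2_gof(
    predicted: np.ndarray,
    observed: np.ndarray,
    sem: np.ndarray | None = None,
    alpha: float = 0.05,
    pearson: bool = False,
) -> GofReport:
    """Chi-square goodness of fit of a predicted time course to measurements.

    Default scaling uses the measurement SEM: chi2 = sum(((obs-pred)/sem)^2).
    With ``pearson=True`` the classic expected-value scaling
    sum((obs-pred)^2 / pred) is used instead.  The model passes when chi2
    is below the chi-square critical value at ``dof = n - 1``.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ConfigurationError("predicted and observed must be equal-length 1-D")
    if len(predicted) < 2:
        raise ConfigurationError("need at least 2 points for goodness of fit")
    if pearson:
        if np.any(predicted <= 0):
            raise ConfigurationError("Pearson scaling requires positive predictions")
        residuals = (observed - predicted) / np.sqrt(predicted)
    else:
        if sem is None:
            raise ConfigurationError("sem is required unless pearson=True")
        sem = np.asarray(sem, dtype=float)
        if sem.shape != predicted.shape:
            raise ConfigurationError("sem must match predicted length")
        if np.any(sem <= 0):
            raise ConfigurationError("sem values must be > 0")
        residuals = (observed - predicted) / sem
    stat = float(np.sum(residuals**2))
    dof = len(predicted) - 1
    critical = float(chi2_dist.ppf(1.0 - alpha, dof))
    return GofReport(chi2=stat, dof=dof, critical=critical,
                     passed=bool(stat < critical), residuals=residuals)


def receptor_fold(
    params: ModelParameters,
    response: str,
    variant: str = "specific",
    t_end: float | None = None,
    n_points: int | None = None,
) -> float:
    """Ratio of single-receptor integrated responses (first / second receptor).

    Each receptor is simulated alone (the other's concentration zeroed,
    adapter pools unchanged) and the integrated response ratio is returned.
    """
    from .ode import DEFAULT_N_POINTS, DEFAULT_T_END, receptor_contribution

    if len(params.receptors) != 2:
        raise ConfigurationError("receptor_fold requires exactly two receptors")
    t_end = DEFAULT_T_END if t_end is None else t_end
    n_points = DEFAULT_N_POINTS if n_points is None else n_points
    integrated = []
    for rec in params.receptors:
        result = receptor_contribution(
            params, rec.name, variant=variant, t_end=t_end, n_points=n_points
        )
        summary = summarize(compute_responses(result, params))
        integrated.append(summary.integrated[response])
    if integrated[1] <= 0:
        raise ParameterValidationError(
            f"degenerate fold: {params.receptors[1].name} integrated {response} is 0"
        )
    return integrated[0] / integrated[1]
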