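"""Mass-action ODE integration of a :class:`~vegfrsim.network.ReactionNetwork`.

The system is dx/dt = S v(x) with elementary mass-action propensities
v_j(x) = k_j * prod(x_i over reactants).  Boundary species (bath ligand,
phosphatase reservoir) have their rows of S zeroed so they stay constant.
Integration uses the stiff BDF method of :func:`scipy.integrate.solve_ivp`
with an analytic Jacobian assembled from the reaction list; tolerances
default to rtol=1e-8, atol=1e-10.  Small negative excursions above -1e-9
are clamped to zero; moiety conservation is verified over the whole grid
after every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConservationError, SimulationError, UnknownEntityError
from .network import (
    ReactionNetwork,
    build_nonspecific_network,
    build_specific_network,
    moiety_vector,
    stoichiometry_matrix,
)
from .params import ModelParameters

#: default simulation horizon, s (order of the ELISA observation window)
DEFAULT_T_END = 3600.0
#: default number of output grid points
DEFAULT_N_POINTS = 601

RTOL = 1e-8
ATOL = 1e-10
NEGATIVE_CLAMP = -1e-9
CONSERVATION_RTOL = 1e-6


@dataclass
class SimulationResult:
    """Time grid plus per-species trajectories in molecules/cell."""

    times: np.ndarray  # (n_times,), strictly increasing, s
    values: np.ndarray  # (n_species, n_times)
    network: ReactionNetwork
    params_digest: str = ""

    def trajectory(self, species_id: str) -> np.ndarray:
        return self.values[self.network.index(species_id)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy trajectory table: time_s, species, value."""
        n = len(self.times)
        return pd.DataFrame(
            {
                "time_s": np.tile(self.times, self.network.n_species),
                "species": np.repeat([s.id for s in self.network.species], n),
                "value": self.values.ravel(),
            }
        )


def _rate_arrays(network: ReactionNetwork):
    """Precompute per-reaction rate constants and reactant index lists."""
    ks = np.array([r.rate_constant for r in network.reactions])
    idx = [tuple(network.index(s) for s in r.reactants) for r in network.reactions]
    return ks, idx


def _make_rhs_jac(network: ReactionNetwork):
    ks, reactant_idx = _rate_arrays(network)
    S = stoichiometry_matrix(network).astype(float)
    const_rows = np.array([s.constant for s in network.species])
    S[const_rows, :] = 0.0
    n_sp, n_rx = S.shape

    uni = [(j, i[0]) for j, i in enumerate(reactant_idx) if len(i) == 1]
    bi = [(j, i[0], i[1]) for j, i in enumerate(reactant_idx) if len(i) == 2]
    uni_j = np.array([j for j, _ in uni], dtype=int)
    uni_i = np.array([i for _, i in uni], dtype=int)
    bi_j = np.array([j for j, _, _ in bi], dtype=int)
    bi_a = np.array([a for _, a, _ in bi], dtype=int)
    bi_b = np.array([b for _, _, b in bi], dtype=int)

    def rates(x: np.ndarray) -> np.ndarray:
        v = np.zeros(n_rx)
        if uni_j.size:
            v[uni_j] = ks[uni_j] * x[uni_i]
        if bi_j.size:
            v[bi_j] = ks[bi_j] * x[bi_a] * x[bi_b]
        return v

    def rhs(_t, x):
        return S @ rates(x)

    def jac(_t, x):
        # dv_j/dx_i assembled reaction by reaction
        dv = np.zeros((n_rx, n_sp))
        if uni_j.size:
            dv[uni_j, uni_i] = ks[uni_j]
        if bi_j.size:
            dv[bi_j, bi_a] += ks[bi_j] * x[bi_b]
            dv[bi_j, bi_b] += ks[bi_j] * x[bi_a]
        return S @ dv

    return rhs, jac, rates


def check_conservation(
    result: SimulationResult, params: ModelParameters, rtol: float = CONSERVATION_RTOL
) -> float:
    """Max relative drift of any adapter/receptor moiety total; raises on breach.

    Moieties with zero initial total are required to stay exactly below
    absolute tolerance instead.
    """
    net = result.network
    worst = 0.0
    moieties = [("adapter", a.name) for a in params.adapters] + [
        ("receptor", r.name) for r in params.receptors
    ]
    for kind, name in moieties:
        v = moiety_vector(net, kind, name)
        totals = v @ result.values
        ref = totals[0]
        if ref <= 0:
            drift = float(np.max(np.abs(totals)))
            if drift > 1e-6:
                raise ConservationError(f"{kind} {name}: zero moiety drifted to {drift}")
            continue
        drift = float(np.max(np.abs(totals - ref)) / ref)
        worst = max(worst, drift)
        if drift > rtol:
            raise ConservationError(
                f"{kind} {name}: conservation violated (relative drift {drift:.3e})"
            )
    return worst


def simulate(
    network: ReactionNetwork,
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
    params: ModelParameters | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> SimulationResult:
    """Integrate the network ODEs on a uniform output grid.

    When ``params`` is given, moiety conservation is verified after the run.
    """
    if t_end <= 0:
        raise SimulationError(f"t_end must be > 0, got {t_end}")
    if n_points < 2:
        raise SimulationError("n_points must be >= 2")
    network.validate()
    rhs, jac, _ = _make_rhs_jac(network)
    x0 = np.array([network.initial_state.get(s.id, 0.0) for s in network.species])
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs, (0.0, t_end), x0, method="BDF", jac=jac, t_eval=times,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    values = sol.y
    if values.min() < NEGATIVE_CLAMP:
        raise SimulationError(
            f"solution went negative beyond tolerance (min {values.min():.3e})"
        )
    values = np.clip(values, 0.0, None)
    result = SimulationResult(
        times=times, values=values, network=network,
        params_digest=network.params_digest,
    )
    if params is not None:
        check_conservation(result, params)
    return result


def phospho_trace(result: SimulationResult, adapter: str) -> np.ndarray:
    """Total phosphorylated copies of one adapter over time.

    Sums every species containing the adapter in chemically phosphorylated
    form, including phosphatase-bound phospho intermediates still awaiting
    catalysis.
    """
    net = result.network
    known = {a for sp in net.species for a in sp.adapter_content}
    if adapter not in known:
        raise UnknownEntityError(f"adapter {adapter!r} not in network")
    weights = np.array([sp.phospho_content.get(adapter, 0) for sp in net.species], dtype=float)
    return weights @ result.values


def run_model(
    params: ModelParameters,
    variant: str = "specific",
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
) -> SimulationResult:
    """Build the requested model variant and simulate it."""
    if variant == "specific":
        network = build_specific_network(params)
    elif variant == "nonspecific":
        network = build_nonspecific_network(params)
    else:
        raise SimulationError(f"unknown model variant {variant!r}")
    return simulate(network, t_end=t_end, n_points=n_points, params=params)


def receptor_contribution(
    params: ModelParameters,
    receptor: str,
    variant: str = "specific",
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
) -> SimulationResult:
    """Simulate with only the named receptor active.

    Other receptors' concentrations are zeroed; all adapter pools are left
    unchanged, so adapter competition within the remaining receptor is
    preserved.
    """
    params.receptor(receptor)  # raise early on unknown name
    solo = params.copy()
    for rec in solo.receptors:
        if rec.name != receptor:
            rec.concentration = 0.0
    return run_model(solo, variant=variant, t_end=t_end, n_points=n_points)
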