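"""Steady-state solver for the beta-oxidation model.

Strategy: stiff time integration to quiescence followed by a Newton
(root-finding) polish on the reduced state.  Pure root finding can land on
non-physical branches of moiety-conserved networks, so integration always
precedes a cold polish; warm starts (continuation along a substrate grid,
or the tiny Vmax perturbations used for control coefficients) go straight
to the polish and fall back to integration if it strays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ..errors import ConvergenceError, DomainError
from .model import (
    N_STATE,
    CompiledModel,
    ModelState,
    ParameterSet,
)

#: relative derivative-norm convergence target
REL_TOL = 1e-9
#: concentration floor used in the relative norm (uM)
FLOOR = 1e-12


@dataclass
class SteadyStateResult:
    """Converged state, flux readout and solver diagnostics.

    ``flux`` is the steady-state CPT1 rate in umol min^-1 (mg total
    protein)^-1 — the pathway flux readout.  ``flux_uM`` is the same rate in
    internal concentration units (uM min^-1).
    """

    state: ModelState
    flux: float
    flux_uM: float
    acylcarnitine_c16: float
    residual_norm: float
    converged: bool
    s_cyt: float
    malonyl: float

    @property
    def x(self) -> np.ndarray:
        """Reduced state vector (for warm starts)."""
        return self.state.to_vector()


def _rel_norm(dx: np.ndarray, x: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(x))), FLOOR)
    return float(np.max(np.abs(dx))) / scale


def _finish(cm: CompiledModel, x: np.ndarray, s: float, m: float) -> SteadyStateResult:
    x = np.maximum(x, 0.0)
    dx = cm.rhs(x, s, m)
    res = _rel_norm(dx, x)
    v = cm.cpt1_rate(x, s, m)
    return SteadyStateResult(
        state=ModelState.from_vector(x, cm.params, s, m),
        flux=v * cm.vol * 1e-6,
        flux_uM=v,
        acylcarnitine_c16=float(x[0]),
        residual_norm=res,
        converged=res < REL_TOL,
        s_cyt=s,
        malonyl=m,
    )


def _polish(cm: CompiledModel, x0: np.ndarray, s: float, m: float) -> Optional[np.ndarray]:
    """Newton polish; returns the refined vector or None if it failed/strayed."""
    sol = root(lambda x: cm.rhs(x, s, m), x0, method="hybr", tol=1e-14)
    x = sol.x
    if not np.all(np.isfinite(x)) or np.any(x < -1e-6):
        return None
    x = np.maximum(x, 0.0)
    if _rel_norm(cm.rhs(x, s, m), x) < REL_TOL:
        return x
    return None


def _integrate(cm: CompiledModel, x0: np.ndarray, s: float, m: float) -> np.ndarray:
    """Integrate towards quiescence with an expanding horizon."""
    x = x0.copy()
    t_end = 1.0
    for _ in range(8):
        sol = solve_ivp(
            lambda t, y: cm.rhs(y, s, m),
            (0.0, t_end),
            x,
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
        )
        x = np.maximum(sol.y[:, -1], 0.0)
        if _rel_norm(cm.rhs(x, s, m), x) < 1e-5:
            break
        t_end *= 10.0
    return x


def steady_state(
    params: ParameterSet,
    s_cyt: float,
    malonyl: float = 0.0,
    x0: Optional[np.ndarray] = None,
    _compiled: Optional[CompiledModel] = None,
) -> SteadyStateResult:
    """Solve for the steady state at clamped substrate/inhibitor levels.

    Deterministic for fixed inputs.  A non-converged solve is returned with
    ``converged=False`` rather than raised, so scans can report the offending
    grid point.
    """
    if s_cyt < 0 or malonyl < 0:
        raise DomainError("s_cyt and malonyl must be >= 0")
    cm = _compiled if _compiled is not None else CompiledModel(params)
    if s_cyt == 0.0:
        # zero-input fixed point: the all-zero acyl state, exactly
        return _finish(cm, np.zeros(N_STATE), 0.0, malonyl)

    if x0 is not None:
        x = _polish(cm, np.asarray(x0, dtype=float), s_cyt, malonyl)
        if x is not None:
            return _finish(cm, x, s_cyt, malonyl)

    start = np.asarray(x0, dtype=float) if x0 is not None else np.zeros(N_STATE)
    x = _integrate(cm, start, s_cyt, malonyl)
    polished = _polish(cm, x, s_cyt, malonyl)
    if polished is not None:
        x = polished
    return _finish(cm, x, s_cyt, malonyl)


def default_substrate_grid(
    lo: float = 0.1, hi: float = 10.0, points: int = 25
) -> np.ndarray:
    """Logarithmic palmitoyl-CoA grid, uM."""
    return np.geomspace(lo, hi, points)


def flux_scan(
    params: ParameterSet,
    substrate_grid: Sequence[float],
    malonyl: float = 0.0,
    raise_on_failure: bool = False,
) -> list[SteadyStateResult]:
    """Steady states over a substrate grid, warm-starting each point from the
    previous one (continuation)."""
    grid = np.asarray(substrate_grid, dtype=float)
    if np.any(grid < 0):
        raise DomainError("substrate grid values must be >= 0")
    cm = CompiledModel(params)
    results: list[SteadyStateResult] = []
    x_prev: Optional[np.ndarray] = None
    for s in grid:
        res = steady_state(params, float(s), malonyl, x0=x_prev, _compiled=cm)
        if not res.converged and raise_on_failure:
            raise ConvergenceError(
                f"steady state did not converge at S_cyt={s:g} uM "
                f"(malonyl-CoA {malonyl:g} uM, residual {res.residual_norm:.2e})"
            )
        results.append(res)
        x_prev = res.x if res.converged and s > 0 else None
    return results
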