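"""Local geometry relaxation under the MM model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy import CompiledSystem
from .forcefield import ForceField
from .structure import Structure

__all__ = ["MinimizationResult", "MinimizationError", "minimize", "minimize_compiled"]


class MinimizationError(RuntimeError):
    """Minimization diverged (non-finite energy)."""


@dataclass
class MinimizationResult:
    structure: Structure
    energy: float
    grad_rms: float
    converged: bool
    n_steps: int

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords


def minimize_compiled(
    system: CompiledSystem,
    coords: np.ndarray,
    max_steps: int = 500,
    grad_tol: float = 0.01,
) -> tuple[np.ndarray, float, float, bool, int]:
    """L-BFGS relaxation on a compiled system; returns raw arrays.

    Convergence is declared on the RMS gradient component (kJ·mol⁻¹·Å⁻¹).
    """
    x0 = np.asarray(coords, dtype=float).reshape(-1)
    if not np.all(np.isfinite(x0)):
        raise MinimizationError("non-finite starting coordinates")

    def fun(x):
        e, g = system.energy_and_gradient(x)
        return e, g.reshape(-1)

    e0, g0 = fun(x0)
    if not np.isfinite(e0):
        raise MinimizationError("non-finite energy at starting geometry")
    rms0 = float(np.sqrt(np.mean(g0 ** 2)))
    if rms0 <= grad_tol:
        return x0.reshape(-1, 3), e0, rms0, True, 0

    res = _scipy_minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": max_steps,
            "gtol": grad_tol * 0.1,  # gtol is max|g|; tighter than the RMS target
            "ftol": 1e-14,
            "maxcor": 20,
        },
    )
    e, g = fun(res.x)
    if not np.isfinite(e):
        raise MinimizationError("minimization diverged to non-finite energy")
    rms = float(np.sqrt(np.mean(np.asarray(g) ** 2)))
    return res.x.reshape(-1, 3), float(e), rms, rms <= grad_tol, int(res.nit)


def minimize(
    s: Structure,
    ff: ForceField,
    max_steps: int = 500,
    grad_tol: float = 0.01,
) -> MinimizationResult:
    """Relax ``s`` under ``ff`` to RMS gradient ≤ ``grad_tol`` or ``max_steps``."""
    system = CompiledSystem(s, ff)
    x, e, rms, ok, nit = minimize_compiled(system, s.coords, max_steps, grad_tol)
    return MinimizationResult(s.with_coords(x), e, rms, ok, nit)
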