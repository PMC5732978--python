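"""Per-cell conductance scale-factor estimation.

Two estimators mirror the two experiment families:

* ``estimate_peak_scale`` — the inward currents (I_Na, I_CaL) are scaled by
  the ratio of measured to simulated extremal peak current, kinetics
  untouched.
* ``fit_decomposition`` — the lumped outward-protocol current is fitted as
  a non-negative weighted sum of unit-scale simulated component currents by
  minimizing the sum of squared errors over the unmasked samples of all
  sweeps. The production route is CMA-ES in a log-scale parameterization
  (which enforces s >= 0); because the objective is an exact quadratic in
  the scale vector, non-negative least squares (``scipy.optimize.nnls``)
  provides an independent closed-form oracle the CMA-ES fit must agree
  with.

Contribution scores quantify each fitted component's share of the total
end-of-step current magnitude: c_i = |I_final,i| / sum_j |I_final,j|, with
I_final,i the scaled component current at the last unmasked sample of the
final (+50 mV) step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from . import _paci2013 as _k
from ._cmaes import minimize_cmaes
from .clamp import (
    ClampConditions,
    CurrentTraceSet,
    StepProtocol,
    make_outward_protocol,
    outward_solution,
    simulate_voltage_clamp,
)
from .model import PaciModel

__all__ = [
    "DEFAULT_COMPONENTS",
    "DASH_THRESHOLD",
    "ComponentMatrix",
    "DecompositionResult",
    "estimate_peak_scale",
    "build_component_matrix",
    "fit_decomposition",
    "repeat_fit_convergence",
    "contribution_scores",
]

# The eight currents fitted to the outward-protocol recording
DEFAULT_COMPONENTS = (
    "I_Na",
    "I_CaL",
    "I_K1",
    "I_Kr",
    "I_Ks",
    "I_to",
    "I_f",
    "I_NaCa",
)

# Scale factors below this are reported as absent (printed as a dash)
DASH_THRESHOLD = 1e-10

_LOG_FLOOR = 1e-13  # smallest representable scale in the log parameterization


@dataclass
class ComponentMatrix:
    """Unit-scale simulated component currents of the outward protocol.

    ``matrix_full`` holds every sample (one row per component, columns
    sweep-major over the concatenated time grids); ``mask`` flags the
    capacitance-window columns that are excluded from fitting. ``column_map``
    maps each column back to (step potential mV, time ms).
    """

    component_names: tuple
    matrix_full: np.ndarray  # (n_components, n_all_samples)
    mask: np.ndarray  # (n_all_samples,) bool
    column_map: np.ndarray  # (n_all_samples, 2): step mV, time ms
    protocol: StepProtocol
    conditions: ClampConditions
    final_currents: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        """Design matrix over unmasked samples only."""
        return self.matrix_full[:, ~self.mask]

    def subset(self, names) -> "ComponentMatrix":
        idx = [self.component_names.index(n) for n in names]
        return ComponentMatrix(
            component_names=tuple(names),
            matrix_full=self.matrix_full[idx],
            mask=self.mask,
            column_map=self.column_map,
            protocol=self.protocol,
            conditions=self.conditions,
            final_currents={n: self.final_currents[n] for n in names},
        )


@dataclass
class DecompositionResult:
    """Fitted scale factors with diagnostics.

    ``s`` maps component name to its non-negative scale factor; components
    below ``dash_threshold`` are effectively absent. ``c`` holds the
    contribution scores (sum 1 over the fitted set). ``seed_l2`` is filled
    by :func:`repeat_fit_convergence`.
    """

    s: dict
    sse: float
    c: dict
    method: str
    seed: int | None = None
    seed_l2: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    dash_threshold: float = DASH_THRESHOLD

    def s_vector(self, names) -> np.ndarray:
        return np.array([self.s[n] for n in names])

    def absent(self) -> set:
        return {n for n, v in self.s.items() if v < self.dash_threshold}


def estimate_peak_scale(measured_peak_iv: np.ndarray,
                        simulated_peak_iv: np.ndarray) -> float:
    """Scale factor matching the extremal simulated peak to the measured one.

    Both IV relations must be on the same step grid; the scalar returned is
    measured/simulated at the step where the simulated current is extremal
    (largest magnitude). Kinetics are untouched.
    """
    measured = np.asarray(measured_peak_iv, dtype=float)
    simulated = np.asarray(simulated_peak_iv, dtype=float)
    if measured.shape != simulated.shape:
        raise ValueError("measured and simulated IV are on different grids")
    k = int(np.argmax(np.abs(simulated)))
    if simulated[k] == 0.0:
        raise ZeroDivisionError("simulated peak current is zero")
    return float(measured[k] / simulated[k])


def build_component_matrix(
    model: PaciModel,
    conditions: ClampConditions | None = None,
    protocol: StepProtocol | None = None,
    components: tuple = DEFAULT_COMPONENTS,
) -> ComponentMatrix:
    """Simulate the unit-scale response of each component to the protocol.

    The model's scale factors are ignored (components are simulated at unit
    scale); with clamped potential and concentrations the gating trajectory
    is scale-independent, so any measured trace is exactly linear in the
    scale vector over these rows.
    """
    protocol = protocol or make_outward_protocol()
    conditions = conditions or outward_solution()
    unit_model = PaciModel(model.params.with_scales(
        **{name: 1.0 for name in _k.CURRENT_NAMES}))
    traces, _ = simulate_voltage_clamp(unit_model, protocol, conditions,
                                       components=tuple(components))
    n_t = traces[components[0]].time_ms.size
    n_steps = protocol.n_steps
    full = np.stack([traces[name].data.T.ravel() for name in components])
    mask = np.tile(traces[components[0]].mask, n_steps)
    col_steps = np.repeat(protocol.step_potentials, n_t)
    col_times = np.tile(traces[components[0]].time_ms, n_steps)
    column_map = np.column_stack([col_steps, col_times])
    # unit current at the last unmasked sample of the final (highest) step
    final_currents = {name: float(traces[name].data[-1, -1]) for name in components}
    return ComponentMatrix(
        component_names=tuple(components),
        matrix_full=full,
        mask=mask,
        column_map=column_map,
        protocol=protocol,
        conditions=conditions,
        final_currents=final_currents,
    )


def _measured_vector(matrix: ComponentMatrix,
                     measured: CurrentTraceSet | np.ndarray) -> np.ndarray:
    if isinstance(measured, CurrentTraceSet):
        flat = measured.data.T.ravel()
        if flat.size != matrix.matrix_full.shape[1]:
            raise ValueError("measured trace is not on the matrix sample grid")
        return flat[~matrix.mask]
    vec = np.asarray(measured, dtype=float).ravel()
    if vec.size == matrix.matrix_full.shape[1]:
        return vec[~matrix.mask]
    if vec.size == matrix.matrix.shape[1]:
        return vec
    raise ValueError("measured vector length matches neither full nor unmasked grid")


def fit_decomposition(
    matrix: ComponentMatrix,
    measured: CurrentTraceSet | np.ndarray,
    method: str = "cmaes",
    seed: int = 0,
    *,
    sigma0: float = 0.5,
    max_iter: int = 3000,
    tol_params: float = 1e-8,
) -> DecompositionResult:
    """Fit non-negative scale factors minimizing the SSE over unmasked samples.

    ``method='nnls'`` solves the non-negative least-squares problem in
    closed form (deterministic; the oracle). ``method='cmaes'`` optimizes
    log-scale factors with CMA-ES, initialized at a seed-perturbed NNLS
    solution, and must agree with the oracle since the objective is an
    exact quadratic in the scale vector.
    """
    A = matrix.matrix  # (k, M)
    b = _measured_vector(matrix, measured)

    s_nnls, _ = nnls(A.T, b)

    if method == "nnls":
        s = s_nnls
        n_iter, converged = 0, True
    elif method == "cmaes":
        # exact quadratic: ||A^T s - b||^2 = s'Gs - 2 c's + b'b
        G = A @ A.T
        cvec = A @ b
        btb = float(b @ b)

        def objective(z):
            s_ = np.exp(z)
            return float(s_ @ G @ s_ - 2.0 * (cvec @ s_) + btb)

        rng = np.random.default_rng(seed)
        z0 = np.log(np.maximum(s_nnls, _LOG_FLOOR)) + 0.25 * rng.standard_normal(
            len(s_nnls)
        )
        res = minimize_cmaes(
            objective,
            z0,
            sigma0,
            seed=seed,
            max_iter=max_iter,
            tol_fun=0.0,
            tol_x=0.0,
            param_transform=np.exp,
            tol_params=tol_params,
        )
        s = np.exp(res.x)
        n_iter, converged = res.n_iter, res.converged
        if not converged:
            raise RuntimeError(
                f"CMA-ES did not converge in {max_iter} generations; "
                f"best SSE {res.fun_best:.6g}"
            )
    else:
        raise ValueError("method must be 'cmaes' or 'nnls'")

    resid = A.T @ s - b
    sse = float(resid @ resid)
    s_map = {name: float(v) for name, v in zip(matrix.component_names, s)}
    c_map = contribution_scores(s_map, matrix.final_currents)
    return DecompositionResult(
        s=s_map,
        sse=sse,
        c=c_map,
        method=method,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
    )


def repeat_fit_convergence(
    matrix: ComponentMatrix,
    measured: CurrentTraceSet | np.ndarray,
    n_seeds: int = 10,
    method: str = "cmaes",
    base_seed: int = 0,
    **options,
) -> list[float]:
    """L2 distance of each repeated fit's scale vector from the first fit's.

    Repeats the optimization from ``n_seeds`` different random seeds
    (different CMA-ES sampling streams and perturbed starting points) and
    returns n_seeds - 1 distances.
    """
    if n_seeds < 2:
        raise ValueError("need at least two seeds")
    names = matrix.component_names
    first = fit_decomposition(matrix, measured, method=method,
                              seed=base_seed, **options)
    ref = first.s_vector(names)
    out = []
    for k in range(1, n_seeds):
        fit = fit_decomposition(matrix, measured, method=method,
                                seed=base_seed + k, **options)
        out.append(float(np.linalg.norm(fit.s_vector(names) - ref)))
    return out


def contribution_scores(s: dict, final_currents: dict) -> dict:
    """Share of end-of-final-step current magnitude per fitted component.

    c_i = |s_i * I_final,i| / sum_j |s_j * I_final,j| over the fitted set;
    invariant under a common positive rescaling of all s.
    """
    vals = {name: abs(s[name] * final_currents[name]) for name in s}
    denom = sum(vals.values())
    if denom == 0.0:
        raise ZeroDivisionError("all end-of-step currents are zero")
    return {name: v / denom for name, v in vals.items()}
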