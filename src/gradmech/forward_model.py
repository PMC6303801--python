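"""Reaction-diffusion model of CCL21 gradient formation and its observation.

Model
-----
Three concentration fields on the tissue domain: soluble CCL21 ``u1``
(secreted at rate ``alpha`` inside lymphatic vessels, diffusing with
coefficient ``D``, degraded at rate ``gamma``), free heparan sulfate ``u2``
and the immobilized CCL21-heparan-sulfate complex ``u3``, coupled by the
reversible binding ``u1 + u2 <-> u3`` with rates ``k1`` / ``k_minus1``.
Heparan sulfate is not transported, so ``u2 + u3 = s0(x)`` is conserved
pointwise, where ``s0(x)`` is the total heparan sulfate field (uniform, or
vessel-dependent under the alternative hypotheses).

At steady state the binding terms cancel (``k1*u1*u2 = k_minus1*u3``), so u1
satisfies the linear screened-Poisson equation

    D * lap(u1) - gamma * u1 + alpha * sum_l q_l(x) = 0

with no-flux boundaries, and u3 follows algebraically:
``u3 = s0(x) * (k1*u1/k_minus1) / (1 + k1*u1/k_minus1)``.

Only the reduced combination (D/gamma, rho = alpha*k1/(gamma*k_minus1),
s*S0, bg) is identifiable from a single equilibrium image; the raw
eight-parameter vector is structurally non-identifiable.

Discretization: 5-point finite-difference Laplacian on the pixel grid with
reflective ghost nodes for the no-flux condition. That operator is exactly
diagonalized by the type-II discrete cosine transform, which is the default
solve path; an explicit sparse-matrix path is kept for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.sparse
import scipy.sparse.linalg

from .geometry import PixelGrid, VesselGeometry


@dataclass(frozen=True)
class RawParameters:
    """Mechanistic and observation parameters on their natural scale.

    alpha: secretion rate (conc / time); D: diffusion coefficient
    (um^2 / time); gamma: degradation rate (1 / time); k1: binding rate
    (1 / (conc * time)); k_minus1: unbinding rate (1 / time); S0: total
    heparan sulfate concentration (conc); s: intensity scaling
    (intensity / conc); b: background (conc).
    """

    alpha: float
    D: float
    gamma: float
    k1: float
    k_minus1: float
    S0: float
    s: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D", "gamma", "k1", "k_minus1", "S0", "s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        # alpha = 0 is the (degenerate but well-posed) zero-secretion case
        if self.alpha < 0 or self.b < 0:
            raise ValueError("alpha and b must be non-negative")


@dataclass(frozen=True)
class ReducedParameters:
    """Identifiable parameter combination for equilibrium images.

    d_over_gamma: D/gamma (um^2, squared gradient decay length);
    rho: alpha*k1/(gamma*k_minus1) (dimensionless saturation gain);
    s_s0: s*S0 (intensity scale of the immobilized signal);
    bg: background on the observed-intensity scale (bg = s*b).
    """

    d_over_gamma: float
    rho: float
    s_s0: float
    bg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_over_gamma", "rho", "s_s0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bg < 0:
            raise ValueError("bg must be non-negative")


def reduce_parameters(raw: RawParameters) -> ReducedParameters:
    """Map the raw eight-parameter vector to its identifiable reduction.

    Two raw vectors with equal reductions produce identical observed
    equilibrium images (structural non-identifiability). The background is
    returned on the observed-intensity scale, bg = s*b.
    """
    return ReducedParameters(
        d_over_gamma=raw.D / raw.gamma,
        rho=(raw.alpha * raw.k1) / (raw.gamma * raw.k_minus1),
        s_s0=raw.s * raw.S0,
        bg=raw.s * raw.b,
    )


@dataclass(frozen=True)
class HeparanFieldSpec:
    """Hypothesis on the spatial heparan sulfate field s0(x).

    model 1: uniform level everywhere; model 2: one tissue level and one
    shared vessel level; model 3: one tissue level and one level per vessel.
    Levels are interpreted on whatever scale the caller works on (raw
    concentration S, or intensity-scaled s*S in the reduced pipeline).
    """

    model: int
    tissue_level: float
    vessel_levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        if self.tissue_level < 0 or any(v < 0 for v in self.vessel_levels):
            raise ValueError("heparan levels must be non-negative")
        if self.model == 1 and self.vessel_levels:
            raise ValueError("model 1 takes a single uniform level")
        if self.model == 2 and len(self.vessel_levels) != 1:
            raise ValueError("model 2 takes exactly one vessel level")
        if self.model == 3 and len(self.vessel_levels) < 1:
            raise ValueError("model 3 takes one level per vessel")

    @classmethod
    def uniform(cls, level: float) -> "HeparanFieldSpec":
        return cls(model=1, tissue_level=level)

    @property
    def n_levels(self) -> int:
        return 1 + len(self.vessel_levels)


def heparan_field(spec: HeparanFieldSpec, vessels: VesselGeometry) -> np.ndarray:
    """Evaluate s0(x) on the grid for the given hypothesis.

    model 2: s0(x) = S_T + (S_L - S_T) * sum_l q_l(x);
    model 3: s0(x) = S_T + sum_l (S_{L,l} - S_T) * q_l(x).
    """
    if spec.model == 1:
        return np.full(vessels.grid.shape, float(spec.tissue_level))
    if spec.model == 2:
        levels = [spec.vessel_levels[0]] * vessels.n_vessels
    else:
        if len(spec.vessel_levels) != vessels.n_vessels:
            raise ValueError(
                f"model 3 needs {vessels.n_vessels} vessel levels, "
                f"got {len(spec.vessel_levels)}"
            )
        levels = list(spec.vessel_levels)
    out = np.full(vessels.grid.shape, float(spec.tissue_level))
    for lvl, mask in zip(levels, vessels.masks):
        out[mask] = lvl
    return out


@dataclass
class StateField:
    """Equilibrium (or instantaneous) state (u1, u2, u3) on a grid."""

    grid: PixelGrid
    u1: np.ndarray = field(repr=False)
    u2: np.ndarray = field(repr=False)
    u3: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Discrete Laplacian solvers (5-point stencil, reflective-ghost Neumann BCs)
# ---------------------------------------------------------------------------


def _neumann_eigenvalues(n: int, h: float) -> np.ndarray:
    """Eigenvalues of minus the 1D second-difference operator with
    reflective ghost nodes, in the DCT-II basis."""
    return (2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n)) / h**2


def solve_screened_poisson(
    grid: PixelGrid,
    source: np.ndarray,
    lam2: float,
    method: str = "dct",
) -> np.ndarray:
    """Solve ``v - lam2 * lap(v) = source`` with no-flux boundaries.

    ``lam2`` is the squared screening length (um^2). The "dct" method
    diagonalizes the 5-point reflective-ghost Laplacian exactly via the
    type-II DCT; "sparse" assembles the same operator as a sparse matrix and
    factorizes it (kept for validation and as a reference path).
    """
    if not lam2 > 0:
        raise ValueError("lam2 must be strictly positive (D, gamma > 0)")
    source = grid.check_image(np.asarray(source, dtype=float))
    h = grid.pixel_size
    if method == "dct":
        er = _neumann_eigenvalues(grid.n_rows, h)
        ec = _neumann_eigenvalues(grid.n_cols, h)
        denom = 1.0 + lam2 * (er[:, None] + ec[None, :])
        shat = scipy.fft.dctn(source, type=2, norm="ortho")
        return scipy.fft.idctn(shat / denom, type=2, norm="ortho")
    if method == "sparse":
        A = _screened_operator(grid, lam2)
        return scipy.sparse.linalg.spsolve(A.tocsc(), source.ravel()).reshape(grid.shape)
    raise ValueError(f"unknown method {method!r}")


def _laplacian_1d(n: int, h: float) -> scipy.sparse.spmatrix:
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0  # reflective ghost node
    off = np.ones(n - 1)
    return scipy.sparse.diags([off, main, off], [-1, 0, 1]) / h**2


def _screened_operator(grid: PixelGrid, lam2: float) -> scipy.sparse.spmatrix:
    h = grid.pixel_size
    Lr = _laplacian_1d(grid.n_rows, h)
    Lc = _laplacian_1d(grid.n_cols, h)
    Ir = scipy.sparse.identity(grid.n_rows)
    Ic = scipy.sparse.identity(grid.n_cols)
    lap = scipy.sparse.kron(Lr, Ic) + scipy.sparse.kron(Ir, Lc)
    return scipy.sparse.identity(grid.n_pixels) - lam2 * lap


def _u3_from_u1(u1_scaled: np.ndarray, s0: np.ndarray) -> np.ndarray:
    """Algebraic equilibrium of the binding reaction.

    ``u1_scaled`` is k1*u1/k_minus1 (equivalently rho*v in reduced form).
    """
    return s0 * u1_scaled / (1.0 + u1_scaled)


def solve_steady_state_2d(
    grid: PixelGrid,
    vessels: VesselGeometry,
    params: RawParameters,
    spec: HeparanFieldSpec | None = None,
    method: str = "dct",
) -> StateField:
    """Equilibrium of the full model for raw parameters.

    u1 solves the linear screened-Poisson equation (the nonlinear binding
    terms cancel at equilibrium); u3 and u2 follow algebraically, conserving
    u2 + u3 = s0(x).
    """
    if spec is None:
        spec = HeparanFieldSpec.uniform(params.S0)
    s0 = heparan_field(spec, vessels)
    q = vessels.union_mask.astype(float)
    v = solve_screened_poisson(grid, q, params.D / params.gamma, method=method)
    u1 = (params.alpha / params.gamma) * v
    u3 = _u3_from_u1(params.k1 * u1 / params.k_minus1, s0)
    return StateField(grid=grid, u1=u1, u2=s0 - u3, u3=u3)


def steady_state_image(
    grid: PixelGrid,
    vessels: VesselGeometry,
    reduced: ReducedParameters,
    spec: HeparanFieldSpec | None = None,
    v: np.ndarray | None = None,
) -> np.ndarray:
    """Observed equilibrium image from reduced parameters only.

    ``y = s*s0(x) * rho*v/(1 + rho*v) + bg`` where v solves
    ``v - (D/gamma)*lap(v) = sum_l q_l``. For heparan hypotheses 2/3, the
    spec levels are interpreted on the intensity scale (s*S). A precomputed
    ``v`` may be passed to avoid re-solving when only algebraic parameters
    change.
    """
    if spec is None:
        spec = HeparanFieldSpec.uniform(reduced.s_s0)
    if v is None:
        v = solve_screened_poisson(
            grid, vessels.union_mask.astype(float), reduced.d_over_gamma
        )
    field_s = heparan_field(spec, vessels)
    return _u3_from_u1(reduced.rho * v, field_s) + reduced.bg


def observe_pixels(state: StateField, s: float, b: float = 0.0) -> np.ndarray:
    """Pixel observation y_j = s * (u3 + b), midpoint quadrature per pixel.

    Solver nodes coincide with pixel centres, so the per-pixel integral of
    the readout reduces to centre-point evaluation.
    """
    if s < 0:
        raise ValueError("scaling must be non-negative")
    return s * (state.u3 + b)


@dataclass
class TransientResult:
    state: StateField
    t_end: float
    converged: bool
    residual: float
    trajectory_times: np.ndarray | None = None
    trajectory: list[StateField] | None = None


def simulate_transient_2d(
    grid: PixelGrid,
    vessels: VesselGeometry,
    params: RawParameters,
    spec: HeparanFieldSpec | None = None,
    t_end: float = 50.0,
    dt: float = 0.02,
    equilibrium_tol: float = 1e-8,
    store_every: int | None = None,
) -> TransientResult:
    """Time-march the full nonlinear system from u1 = 0, u2 = s0(x), u3 = 0.

    IMEX scheme: diffusion of u1 implicit (DCT solve per step), reactions
    explicit. u2 + u3 = s0(x) is conserved exactly by construction. The run
    stops early once the maximum relative state change per unit time drops
    below ``equilibrium_tol``; otherwise the (flagged) partial result is
    returned. Retained primarily as an independent oracle for the algebraic
    steady-state reduction.
    """
    if spec is None:
        spec = HeparanFieldSpec.uniform(params.S0)
    s0 = heparan_field(spec, vessels)
    q = vessels.union_mask.astype(float)
    h = grid.pixel_size
    er = _neumann_eigenvalues(grid.n_rows, h)
    ec = _neumann_eigenvalues(grid.n_cols, h)
    denom = 1.0 + dt * params.D * (er[:, None] + ec[None, :])

    u1 = np.zeros(grid.shape)
    u2 = s0.copy()
    u3 = np.zeros(grid.shape)
    times, states = [], []
    if store_every:
        times.append(0.0)
        states.append(StateField(grid, u1.copy(), u2.copy(), u3.copy()))

    n_steps = int(round(t_end / dt)) if t_end > 0 else 0
    converged = n_steps == 0 and t_end == 0
    residual = np.inf if n_steps else 0.0
    scale = max(params.alpha / params.gamma, float(s0.max()), 1e-300)
    for step in range(1, n_steps + 1):
        bind = params.k1 * u1 * u2 - params.k_minus1 * u3
        f1 = params.alpha * q - bind - params.gamma * u1
        rhs = u1 + dt * f1
        u1_new = scipy.fft.idctn(
            scipy.fft.dctn(rhs, type=2, norm="ortho") / denom, type=2, norm="ortho"
        )
        u3_new = u3 + dt * bind
        u2_new = s0 - u3_new  # exact conservation
        residual = max(
            np.abs(u1_new - u1).max(), np.abs(u3_new - u3).max()
        ) / (dt * scale)
        u1, u2, u3 = u1_new, u2_new, u3_new
        if store_every and (step % store_every == 0 or step == n_steps):
            times.append(step * dt)
            states.append(StateField(grid, u1.copy(), u2.copy(), u3.copy()))
        if residual < equilibrium_tol:
            converged = True
            t_end = step * dt
            break
    return TransientResult(
        state=StateField(grid, u1, u2, u3),
        t_end=t_end,
        converged=converged,
        residual=residual,
        trajectory_times=np.array(times) if store_every else None,
        trajectory=states if store_every else None,
    )


def solve_steady_state_1d(
    alpha: float,
    D: float,
    gamma: float,
    length: float,
    n_nodes: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady state of the 1D analogue on [0, length].

    ``D*u1'' - gamma*u1 = 0`` with an influx boundary ``-D*u1'(0) = alpha``
    (secretion concentrated at the vessel at x = 0) and no flux at
    x = length. Finite differences on a node-centred grid; the analytic
    solution is ``u1(x) = (alpha*lam/D) * cosh((length-x)/lam)/sinh(length/lam)``
    with ``lam = sqrt(D/gamma)``. Returns (x, u1).
    """
    if not (length > 0 and D > 0 and gamma > 0):
        raise ValueError("length, D and gamma must be positive")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    x = np.linspace(0.0, length, n_nodes)
    h = x[1] - x[0]
    main = np.full(n_nodes, -2.0 * D / h**2 - gamma)
    off = np.full(n_nodes - 1, D / h**2)
    rhs = np.zeros(n_nodes)
    # ghost-node Neumann closures: at x=0 an influx alpha, at x=L zero flux
    main[0] = -2.0 * D / h**2 - gamma
    off_u = off.copy()
    off_l = off.copy()
    off_u[0] = 2.0 * D / h**2
    rhs[0] = -2.0 * alpha / h
    main[-1] = -2.0 * D / h**2 - gamma
    off_l[-1] = 2.0 * D / h**2
    A = scipy.sparse.diags([off_l, main, off_u], [-1, 0, 1], format="csc")
    u1 = scipy.sparse.linalg.spsolve(A, rhs)
    return x, u1


def u3_profile_1d(
    u1: np.ndarray, rho_times_inv_u1scale: float, s0: float
) -> np.ndarray:
    """Immobilized profile from a 1D soluble profile via the same algebraic
    binding equilibrium as in 2D. ``rho_times_inv_u1scale`` multiplies u1 to
    give the dimensionless k1*u1/k_minus1."""
    w = rho_times_inv_u1scale * u1
    return s0 * w / (1.0 + w)
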