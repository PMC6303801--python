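"""Maximum-likelihood estimation, profile likelihoods, model selection.

Estimation follows the multi-start local optimization recipe: starting
points are drawn by latin hypercube sampling from the (transformed) bounds
box and each start is refined with a bounded quasi-Newton optimizer
(L-BFGS-B) using central finite-difference gradients. All positive
parameters are estimated on log10 scale (bounds span four or more decades),
the outlier weight on logit scale, and the outlier location shift on a
linear scale since its sign is unconstrained.

Uncertainty is quantified with profile likelihoods: for a grid of fixed
values of one parameter all others are re-optimized; the chi-square
(1 d.o.f.) level sets of twice the profiled log-likelihood difference give
pointwise confidence intervals. A parameter is flagged practically
non-identifiable ("n.i.") when its profile fails to cross the highest
requested threshold before reaching a bound, or when its interval spans
more decades than carry usable information (see ProfileResult).

Hypotheses about the heparan sulfate field are compared with the Bayesian
information criterion, BIC = 2*nll + n_theta*log(n_data); differences of 10
or more are treated as substantial. Models are only comparable when fitted
to the identical dataset with the same statistical approach, which
``compare_models`` enforces.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.stats import qmc

from . import noise_likelihood as nl
from .filtering import mser_detect, regions_to_mask
from .forward_model import solve_screened_poisson, solve_steady_state_1d
from .geometry import (
    PixelGrid,
    VesselGeometry,
    boundary_margin_mask,
    distance_average,
    distance_map,
)
from .noise_likelihood import NoiseModel

# ---------------------------------------------------------------------------
# Parameter transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Param:
    """One free parameter with bounds on its natural scale and a transform
    ('log10', 'logit' or 'linear') used for optimization."""

    name: str
    lo: float
    hi: float
    scale: str = "log10"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"degenerate bounds for {self.name}")
        if self.scale not in ("log10", "logit", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "log10" and self.lo <= 0:
            raise ValueError(f"log10 parameter {self.name} needs positive bounds")
        if self.scale == "logit" and not (0 < self.lo < self.hi < 1):
            raise ValueError(f"logit parameter {self.name} needs bounds in (0,1)")

    def to_internal(self, value: float) -> float:
        if self.scale == "log10":
            return float(np.log10(value))
        if self.scale == "logit":
            return float(np.log(value / (1.0 - value)))
        return float(value)

    def to_external(self, z: float) -> float:
        if self.scale == "log10":
            return float(10.0**z)
        if self.scale == "logit":
            return float(1.0 / (1.0 + np.exp(-z)))
        return float(z)

    @property
    def internal_bounds(self) -> tuple[float, float]:
        return (self.to_internal(self.lo), self.to_internal(self.hi))


class ParameterSpace:
    """Ordered collection of free parameters with transform bookkeeping."""

    def __init__(self, params: list[Param]):
        if len({p.name for p in params}) != len(params):
            raise ValueError("duplicate parameter names")
        self.params = list(params)
        self.names = [p.name for p in params]

    @property
    def dim(self) -> int:
        return len(self.params)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_external(self, x: np.ndarray) -> dict[str, float]:
        return {p.name: p.to_external(z) for p, z in zip(self.params, x)}

    def to_internal(self, values: dict[str, float]) -> np.ndarray:
        return np.array([p.to_internal(values[p.name]) for p in self.params])

    def internal_bounds(self) -> list[tuple[float, float]]:
        return [p.internal_bounds for p in self.params]


#: Default bounds boxes (natural scale); mechanistic boxes span >= 4 decades.
DEFAULT_BOUNDS: dict[str, tuple[float, float, str]] = {
    "d_over_gamma": (1.0, 1e4, "log10"),
    "rho": (1e-2, 1e2, "log10"),
    # the intensity-scale boxes are wider than the mechanistic ones so that
    # the structural rho*sS0 ridge is never truncated by a box corner (a
    # truncated ridge would fake identifiability of its members)
    "s_s0": (1e-1, 1e5, "log10"),
    "s_st": (1e-1, 1e5, "log10"),
    "s_sl": (1e-1, 1e5, "log10"),
    "bg": (1e-1, 1e3, "log10"),
    "sigma": (1e-3, 10.0, "log10"),
    "w_o": (1e-6, 1.0 - 1e-6, "logit"),
    "mu_o": (-2.0, 5.0, "linear"),
    "sigma_o": (1e-2, 10.0, "log10"),
}


def default_param(name: str) -> Param:
    base = name.rsplit("_", 1)[0] if name.startswith("s_sl_") else name
    if name.startswith("s_sl_"):
        base = "s_sl"
    lo, hi, scale = DEFAULT_BOUNDS[base]
    return Param(name, lo, hi, scale)


# ---------------------------------------------------------------------------
# Multi-start optimization
# ---------------------------------------------------------------------------


def lhs_starts(
    space: ParameterSpace, n_starts: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Latin hypercube sample of start points in the transformed bounds box.

    Each coordinate's ``n_starts`` values occupy distinct equal strata.
    Returns an (n_starts, dim) array of internal coordinates.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    unit = sampler.random(n_starts)
    bounds = np.array(space.internal_bounds())
    return bounds[:, 0] + unit * (bounds[:, 1] - bounds[:, 0])


def _fd_gradient(fun, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient on the transformed scale."""
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (fun(xp) - fun(xm)) / (2.0 * step)
    return g


_BIG = 1e300


def _safe(fun):
    def wrapped(x):
        try:
            v = fun(x)
        except (ValueError, FloatingPointError):
            return _BIG
        return v if np.isfinite(v) else _BIG

    return wrapped


@dataclass
class FitResult:
    """Multi-start outcome: per-start trajectories plus the best estimate."""

    space: ParameterSpace
    starts: np.ndarray
    solutions: np.ndarray
    nlls: np.ndarray
    converged: np.ndarray
    seed: int | None = None
    trace: pd.DataFrame | None = None

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.nlls)

    @property
    def ladder(self) -> np.ndarray:
        """Final objective values sorted non-decreasingly."""
        return np.sort(self.nlls)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.nlls))

    @property
    def best_nll(self) -> float:
        return float(self.nlls[self.best_index])

    @property
    def best_internal(self) -> np.ndarray:
        return self.solutions[self.best_index]

    @property
    def best_external(self) -> dict[str, float]:
        return self.space.to_external(self.best_internal)


def multistart_fit(
    objective,
    space: ParameterSpace,
    n_starts: int = 20,
    seed: int = 0,
    maxiter: int = 200,
    fd_step: float = 1e-5,
    x_extra: np.ndarray | None = None,
    record_trace: bool = False,
) -> FitResult:
    """Bounded multi-start local optimization of a scalar objective.

    ``objective`` maps an internal (transformed) parameter vector to a
    negative log-likelihood. Gradients are central finite differences unless
    the objective exposes an analytic ``gradient(x)`` attribute. ``x_extra``
    optionally appends deterministic extra start points (e.g. warm starts)
    to the latin hypercube draw. With ``record_trace`` every iterate of
    every start is logged as a (start, iteration, nll, parameters) row.
    """
    fun = _safe(objective)
    grad = getattr(objective, "gradient", None)
    jac = grad if grad is not None else (lambda x: _fd_gradient(fun, x, fd_step))
    starts = lhs_starts(space, n_starts, seed)
    if x_extra is not None:
        starts = np.vstack([starts, np.atleast_2d(x_extra)])
    bounds = space.internal_bounds()
    xs, fs, ok = [], [], []
    rows: list[dict] = []
    for k, x0 in enumerate(starts):
        callback = None
        if record_trace:
            counter = iter(range(1, 10**6))

            def callback(xk, _k=k, _c=counter):  # noqa: B023 - bound via defaults
                rows.append(
                    {"start": _k, "iteration": next(_c), "nll": fun(xk)}
                    | space.to_external(xk)
                )

        try:
            res = scipy.optimize.minimize(
                fun,
                x0,
                jac=jac,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
                callback=callback,
            )
            xs.append(res.x)
            fs.append(float(res.fun))
            ok.append(bool(res.success))
        except Exception:  # noqa: BLE001 - a failed start is data, not fatal
            xs.append(x0)
            fs.append(np.inf)
            ok.append(False)
    fs = np.array(fs)
    if not np.isfinite(fs).any():
        raise RuntimeError("all optimization starts failed")
    return FitResult(
        space=space,
        starts=starts,
        solutions=np.array(xs),
        nlls=fs,
        converged=np.array(ok),
        seed=seed,
        trace=pd.DataFrame(rows) if record_trace else None,
    )


# ---------------------------------------------------------------------------
# Profile likelihoods
# ---------------------------------------------------------------------------


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter with derived confidence intervals.

    ``intervals`` maps a confidence level to (lo, hi) on the natural scale;
    ``hit_bound`` records whether each endpoint ran into the bounds box
    before crossing the threshold (=> practically non-identifiable there).
    """

    parameter: str
    grid_internal: np.ndarray
    grid_external: np.ndarray
    profile_nll: np.ndarray
    best_nll: float
    intervals: dict[float, tuple[float, float]]
    hit_bound: dict[float, tuple[bool, bool]]
    node_converged: np.ndarray
    scale: str = "log10"
    #: a log10-scale CI wider than this many decades is treated as
    #: practically non-identifiable even if the profile technically crosses
    #: the threshold inside the box: along a structural product ridge the
    #: partner parameter's box always truncates the ridge somewhere, so a
    #: pure bound-hit rule could never flag both ridge members
    ni_span_decades: float = 2.0

    def identifiable(self, level: float | None = None) -> bool:
        level = max(self.intervals) if level is None else level
        lo_b, hi_b = self.hit_bound[level]
        if lo_b or hi_b:
            return False
        lo, hi = self.intervals[level]
        if self.scale == "log10" and np.log10(hi / lo) > self.ni_span_decades:
            return False
        return True

    @property
    def flag(self) -> str:
        return "ok" if self.identifiable() else "n.i."


class _FixedCoordinate:
    """Objective with one internal coordinate held fixed."""

    def __init__(self, fun, i: int, value: float, dim: int):
        self.fun = fun
        self.i = i
        self.value = value
        self.free = [j for j in range(dim) if j != i]

    def embed(self, x_free: np.ndarray) -> np.ndarray:
        x = np.empty(len(self.free) + 1)
        x[self.free] = x_free
        x[self.i] = self.value
        return x

    def __call__(self, x_free: np.ndarray) -> float:
        return self.fun(self.embed(x_free))


def _reoptimize(fun, space, i, value, x_warm, maxiter=150):
    sub = _FixedCoordinate(_safe(fun), i, value, space.dim)
    if not sub.free:  # one-parameter problem: nothing left to re-optimize
        x = sub.embed(np.empty(0))
        return _safe(fun)(x), x, True
    bounds = [b for j, b in enumerate(space.internal_bounds()) if j != i]
    x0 = x_warm[sub.free]
    res = scipy.optimize.minimize(
        sub,
        np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
        jac=lambda x: _fd_gradient(sub, x),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter},
    )
    return float(res.fun), sub.embed(res.x), bool(res.success)


def profile_likelihood(
    objective,
    space: ParameterSpace,
    fit: FitResult,
    parameter: str,
    levels: tuple[float, ...] = (0.75, 0.90, 0.99),
    step: float = 0.05,
    growth: float = 1.4,
    max_nodes: int = 40,
    maxiter: int = 150,
) -> ProfileResult:
    """Profile one parameter by constrained re-optimization on a walk-out grid.

    Starting at the ML estimate, the target coordinate is stepped outward
    (growing steps) while all other parameters are re-optimized with warm
    starts, until the profile exceeds the highest requested chi-square
    threshold or the bounds box is reached. Interval endpoints are then
    located by bisection between bracketing nodes; endpoints that reach a
    bound are flagged.
    """
    i = space.index(parameter)
    lo_b, hi_b = space.internal_bounds()[i]
    thresholds = {c: scipy.stats.chi2.ppf(c, df=1) / 2.0 for c in levels}
    t_max = max(thresholds.values())
    best_nll = fit.best_nll
    x_hat = fit.best_internal

    nodes: list[tuple[float, float, np.ndarray, bool]] = [
        (float(x_hat[i]), best_nll, x_hat.copy(), True)
    ]
    for direction in (+1.0, -1.0):
        x_warm = x_hat.copy()
        c = float(x_hat[i])
        width = step
        for _ in range(max_nodes):
            c_next = c + direction * width
            clipped = bool(c_next <= lo_b or c_next >= hi_b)
            c_next = float(np.clip(c_next, lo_b, hi_b))
            if c_next == c:
                break
            pnll, x_opt, ok = _reoptimize(
                objective, space, i, c_next, x_warm, maxiter
            )
            nodes.append((c_next, pnll, x_opt, ok))
            x_warm = x_opt
            c = c_next
            width *= growth
            if pnll - best_nll > t_max + 0.5 or clipped:
                break

    nodes.sort(key=lambda n: n[0])
    grid = np.array([n[0] for n in nodes])
    pnll = np.array([n[1] for n in nodes])
    node_ok = np.array([n[3] for n in nodes])
    warms = [n[2] for n in nodes]
    i_best = int(np.argmin(np.abs(grid - x_hat[i])))

    def crossing(side: int, thr: float) -> tuple[float, bool]:
        """Find where pnll - best_nll crosses thr walking away from the MLE.

        side = +1 walks right, -1 walks left. Returns (internal value,
        hit_bound flag).
        """
        idx = range(i_best, len(grid)) if side > 0 else range(i_best, -1, -1)
        prev = i_best
        for j in idx:
            if pnll[j] - best_nll > thr:
                a, b = (prev, j) if side > 0 else (j, prev)
                warm = warms[a if side > 0 else b]
                # bisection refinement with re-optimization; the bracket is
                # (left below threshold, right above) in walk direction
                left, right = grid[a], grid[b]
                f_left, f_right = pnll[a] - best_nll, pnll[b] - best_nll
                for _ in range(6):
                    if abs(right - left) < 1e-3:
                        break
                    mid = 0.5 * (left + right)
                    fm, xm, _ = _reoptimize(objective, space, i, mid, warm, maxiter)
                    fm -= best_nll
                    warm = xm
                    # keep the sub-interval containing the crossing
                    if (fm > thr) == (f_right > thr):
                        right, f_right = mid, fm
                    else:
                        left, f_left = mid, fm
                # linear interpolation on the final bracket
                if f_right == f_left:
                    return 0.5 * (left + right), False
                frac = (thr - f_left) / (f_right - f_left)
                return float(left + np.clip(frac, 0, 1) * (right - left)), False
            prev = j
        # never crossed: endpoint is the farthest node; bound flag if at box
        edge = grid[-1] if side > 0 else grid[0]
        at_bound = bool(np.isclose(edge, hi_b if side > 0 else lo_b, atol=1e-9))
        return float(edge), at_bound

    param = space.params[i]
    intervals: dict[float, tuple[float, float]] = {}
    hit_bound: dict[float, tuple[bool, bool]] = {}
    for level, thr in thresholds.items():
        hi_x, hi_flag = crossing(+1, thr)
        lo_x, lo_flag = crossing(-1, thr)
        intervals[level] = (param.to_external(lo_x), param.to_external(hi_x))
        hit_bound[level] = (lo_flag, hi_flag)
    return ProfileResult(
        parameter=parameter,
        grid_internal=grid,
        grid_external=np.array([param.to_external(g) for g in grid]),
        profile_nll=pnll,
        best_nll=best_nll,
        intervals=intervals,
        hit_bound=hit_bound,
        node_converged=node_ok,
        scale=param.scale,
    )


class ProductReparam:
    """Linear reparametrization exposing the product of two log10 parameters.

    The coordinate slot of ``name_a`` becomes log10(a*b); the slot of
    ``name_b`` keeps log10(b). Profiling the product coordinate re-optimizes
    the ratio, which is exactly the profile of a*b.
    """

    def __init__(self, fun, space: ParameterSpace, name_a: str, name_b: str):
        ia, ib = space.index(name_a), space.index(name_b)
        pa, pb = space.params[ia], space.params[ib]
        if pa.scale != "log10" or pb.scale != "log10":
            raise ValueError("product reparametrization needs log10 parameters")
        self.fun = fun
        self.ia, self.ib = ia, ib
        params = list(space.params)
        params[ia] = Param(
            f"{name_a}*{name_b}", pa.lo * pb.lo, pa.hi * pb.hi, "log10"
        )
        self.space = ParameterSpace(params)

    def to_original(self, y: np.ndarray) -> np.ndarray:
        x = np.array(y, dtype=float)
        x[self.ia] = y[self.ia] - y[self.ib]  # log10 a = log10(ab) - log10 b
        return x

    def map_best(self, x: np.ndarray) -> np.ndarray:
        y = np.array(x, dtype=float)
        y[self.ia] = x[self.ia] + x[self.ib]
        return y

    def __call__(self, y: np.ndarray) -> float:
        return self.fun(self.to_original(y))


def profile_product(
    objective,
    space: ParameterSpace,
    fit: FitResult,
    name_a: str,
    name_b: str,
    **kwargs,
) -> ProfileResult:
    """Profile likelihood of the product of two log10-scaled parameters."""
    rep = ProductReparam(objective, space, name_a, name_b)
    pseudo = FitResult(
        space=rep.space,
        starts=fit.starts,
        solutions=np.array([rep.map_best(x) for x in fit.solutions]),
        nlls=fit.nlls,
        converged=fit.converged,
    )
    return profile_likelihood(
        rep, rep.space, pseudo, f"{name_a}*{name_b}", **kwargs
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def bic(nll: float, n_theta: int, n_data: int) -> float:
    """Bayesian information criterion, 2*nll + n_theta*log(n_data)."""
    if n_data < 1:
        raise ValueError("n_data must be at least 1")
    return 2.0 * nll + n_theta * np.log(n_data)


#: BIC difference regarded as substantial evidence.
BIC_SUBSTANTIAL = 10.0


@dataclass
class ModelComparison:
    table: pd.DataFrame
    best_label: str


def compare_models(fits: list["ApproachFit"], labels: list[str]) -> ModelComparison:
    """BIC table over model hypotheses fitted to the same data.

    Refuses comparison across different datasets or statistical approaches
    (the filtering approach changes the dataset, so BIC values would not be
    commensurable).
    """
    if len(fits) != len(labels) or not fits:
        raise ValueError("need one label per fit")
    ids = {f.dataset_id for f in fits}
    if len(ids) > 1:
        raise ValueError("fits were computed on different datasets")
    approaches = {f.approach for f in fits}
    if len(approaches) > 1:
        raise ValueError("BIC comparison across statistical approaches is invalid")
    rows = []
    for label, f in zip(labels, fits):
        rows.append(
            {
                "model": label,
                "nll": f.fit.best_nll,
                "n_theta": f.space.dim,
                "n_data": f.n_data,
                "bic": bic(f.fit.best_nll, f.space.dim, f.n_data),
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    table["delta_bic"] = table["bic"] - table["bic"].min()
    table["substantial"] = table["delta_bic"] >= BIC_SUBSTANTIAL
    return ModelComparison(table=table, best_label=str(table["bic"].idxmin()))


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------


class _VCache:
    """Cache of screened-Poisson solutions keyed by the squared decay length.

    The PDE solve is the only expensive part of an objective evaluation and
    depends on a single parameter, so finite-difference gradients touch it
    for just one coordinate.
    """

    def __init__(self, grid: PixelGrid, source: np.ndarray, maxsize: int = 128):
        self.grid = grid
        self.source = source
        self.maxsize = maxsize
        self._cache: dict[float, np.ndarray] = {}

    def __call__(self, lam2: float) -> np.ndarray:
        v = self._cache.get(lam2)
        if v is None:
            v = solve_screened_poisson(self.grid, self.source, lam2)
            if len(self._cache) >= self.maxsize:
                self._cache.pop(next(iter(self._cache)))
            self._cache[lam2] = v
        return v


def _heparan_params(hypothesis: int, n_vessels: int) -> list[str]:
    if hypothesis == 1:
        return ["s_s0"]
    if hypothesis == 2:
        return ["s_st", "s_sl"]
    if hypothesis == 3:
        return ["s_st"] + [f"s_sl_{l}" for l in range(1, n_vessels + 1)]
    raise ValueError("hypothesis must be 1, 2 or 3")


def _build_space(
    hypothesis: int, n_vessels: int, approach: str, overrides: dict | None = None
) -> ParameterSpace:
    names = ["d_over_gamma", "rho", *_heparan_params(hypothesis, n_vessels), "bg"]
    names.append("sigma")
    if approach == "integrated":
        names += ["w_o", "mu_o", "sigma_o"]
    params = []
    for n in names:
        p = default_param(n)
        if overrides and n in overrides:
            lo, hi = overrides[n]
            p = replace(p, lo=lo, hi=hi)
        params.append(p)
    return ParameterSpace(params)


class WholeImageObjective:
    """Negative log-likelihood of a whole image under one approach.

    Evaluates the reduced steady-state model (decay-length solve cached),
    builds the intensity-scaled heparan field for the chosen hypothesis and
    scores the included pixels with the direct or mixture likelihood.
    """

    def __init__(
        self,
        data: np.ndarray,
        grid: PixelGrid,
        vessels: VesselGeometry,
        approach: str = "direct",
        hypothesis: int = 1,
        include: np.ndarray | None = None,
        space: ParameterSpace | None = None,
    ):
        if approach not in ("direct", "filtered", "integrated"):
            raise ValueError(f"unknown approach {approach!r}")
        self.grid = grid
        self.vessels = vessels
        self.approach = approach
        self.hypothesis = hypothesis
        self.include = (
            np.ones(grid.shape, dtype=bool) if include is None else include.astype(bool)
        )
        if not self.include.any():
            raise ValueError("no pixels included in the objective")
        self.data = grid.check_image(np.asarray(data, dtype=float))
        if np.any(self.data[self.include] <= 0):
            raise ValueError("included data pixels must be strictly positive")
        self.space = space or _build_space(
            hypothesis, vessels.n_vessels, "integrated" if approach == "integrated" else "direct"
        )
        self._vcache = _VCache(grid, vessels.union_mask.astype(float))
        self._labels = vessels.labels()
        self._union = vessels.union_mask
        self._log_data = np.log(self.data[self.include])
        self._data_m = self.data[self.include]
        self.n_data = int(self.include.sum())
        self.dataset_id = hashlib.sha1(self._data_m.tobytes()).hexdigest()

    def _field(self, theta: dict[str, float]) -> np.ndarray:
        if self.hypothesis == 1:
            return np.full(self.grid.shape, theta["s_s0"])
        out = np.full(self.grid.shape, theta["s_st"])
        if self.hypothesis == 2:
            out[self._union] = theta["s_sl"]
        else:
            for l, mask in enumerate(self.vessels.masks, start=1):
                out[mask] = theta[f"s_sl_{l}"]
        return out

    def model_image(self, theta: dict[str, float]) -> np.ndarray:
        v = self._vcache(theta["d_over_gamma"])
        w = theta["rho"] * v
        return self._field(theta) * w / (1.0 + w) + theta["bg"]

    def nll_external(self, theta: dict[str, float]) -> float:
        m = self.model_image(theta)[self.include]
        if self.approach == "integrated":
            noise = NoiseModel(
                sigma=theta["sigma"],
                w_o=theta["w_o"],
                mu_o=theta["mu_o"],
                sigma_o=theta["sigma_o"],
            )
            return nl.nll_integrated(self._data_m, m, noise)
        return nl.nll_direct(self._data_m, m, theta["sigma"])

    def __call__(self, x: np.ndarray) -> float:
        return self.nll_external(self.space.to_external(x))


class SummaryObjective2D:
    """Likelihood of the distance-binned mean-intensity profile under the 2D
    model: the model prediction per bin is the bin mean of the model image,
    each defined bin is one data point with log-normal noise."""

    def __init__(
        self,
        data: np.ndarray,
        grid: PixelGrid,
        vessels: VesselGeometry,
        bin_width: float = 1.0,
        hypothesis: int = 1,
        include: np.ndarray | None = None,
        space: ParameterSpace | None = None,
    ):
        self.grid = grid
        self.vessels = vessels
        self.hypothesis = hypothesis
        self.approach = "direct"
        dmap = distance_map(grid, vessels)
        self.profile = distance_average(data, dmap, bin_width, include=include)
        keep = self.profile.defined
        self._data_means = self.profile.mean_intensity[keep]
        if np.any(self._data_means <= 0):
            raise ValueError("bin means must be strictly positive")
        d = dmap.values if include is None else dmap.values[include.astype(bool)]
        idx = np.floor(d.ravel() / bin_width).astype(np.int64)
        self._bin_idx = idx
        self._counts = np.bincount(idx)
        self._keep = keep[: len(self._counts)]
        self.n_data = int(keep.sum())
        self._include = include
        self.space = space or _build_space(hypothesis, vessels.n_vessels, "direct")
        self._vcache = _VCache(grid, vessels.union_mask.astype(float))
        self._union = vessels.union_mask
        self.dataset_id = hashlib.sha1(self._data_means.tobytes()).hexdigest()

    def _field(self, theta):
        return WholeImageObjective._field(self, theta)

    def model_profile(self, theta: dict[str, float]) -> np.ndarray:
        v = self._vcache(theta["d_over_gamma"])
        w = theta["rho"] * v
        y = self._field(theta) * w / (1.0 + w) + theta["bg"]
        vals = y if self._include is None else y[self._include.astype(bool)]
        sums = np.bincount(self._bin_idx, weights=vals.ravel())
        return (sums / np.maximum(self._counts, 1))[self._keep]

    def nll_external(self, theta: dict[str, float]) -> float:
        return nl.nll_direct(self._data_means, self.model_profile(theta), theta["sigma"])

    def __call__(self, x: np.ndarray) -> float:
        return self.nll_external(self.space.to_external(x))


class SummaryObjective1D:
    """Likelihood of the distance profile under the 1D approximation.

    The vessel is collapsed to the boundary x = 0 of an interval; secretion
    enters via an influx boundary condition and the immobilized profile
    follows from the same binding equilibrium. Amplitude conventions are
    absorbed by rho and s_s0.
    """

    def __init__(
        self,
        profile_means: np.ndarray,
        profile_centres: np.ndarray,
        space: ParameterSpace | None = None,
        n_nodes: int = 400,
    ):
        means = np.asarray(profile_means, dtype=float)
        centres = np.asarray(profile_centres, dtype=float)
        keep = np.isfinite(means)
        self._means = means[keep]
        self._centres = centres[keep]
        if np.any(self._means <= 0):
            raise ValueError("bin means must be strictly positive")
        self.length = float(self._centres.max() * 1.05 + 1.0)
        self.n_nodes = n_nodes
        self.n_data = int(self._means.size)
        self.approach = "direct"
        self.space = space or ParameterSpace(
            [default_param(n) for n in ("d_over_gamma", "rho", "s_s0", "bg", "sigma")]
        )
        self._gcache: dict[float, np.ndarray] = {}
        self.dataset_id = hashlib.sha1(self._means.tobytes()).hexdigest()

    def _g(self, lam2: float) -> np.ndarray:
        g = self._gcache.get(lam2)
        if g is None:
            x, u1 = solve_steady_state_1d(
                alpha=1.0, D=lam2, gamma=1.0, length=self.length, n_nodes=self.n_nodes
            )
            g = np.interp(self._centres, x, u1)
            if len(self._gcache) > 128:
                self._gcache.pop(next(iter(self._gcache)))
            self._gcache[lam2] = g
        return g

    def model_profile(self, theta: dict[str, float]) -> np.ndarray:
        w = theta["rho"] * self._g(theta["d_over_gamma"])
        return theta["s_s0"] * w / (1.0 + w) + theta["bg"]

    def nll_external(self, theta: dict[str, float]) -> float:
        return nl.nll_direct(self._means, self.model_profile(theta), theta["sigma"])

    def __call__(self, x: np.ndarray) -> float:
        return self.nll_external(self.space.to_external(x))


# ---------------------------------------------------------------------------
# Fitting driver
# ---------------------------------------------------------------------------


@dataclass
class ApproachFit:
    """A fitted objective: estimation outcome plus everything needed for
    profiles and model comparison."""

    fit: FitResult
    objective: object
    space: ParameterSpace
    approach: str
    hypothesis: int
    n_data: int
    dataset_id: str
    filter_mask: np.ndarray | None = None

    @property
    def estimate(self) -> dict[str, float]:
        return self.fit.best_external

    @property
    def bic(self) -> float:
        return bic(self.fit.best_nll, self.space.dim, self.n_data)


def fit_approach(
    data: np.ndarray,
    grid: PixelGrid,
    vessels: VesselGeometry,
    approach: str = "integrated",
    hypothesis: int = 1,
    n_starts: int = 20,
    seed: int = 0,
    boundary_depth: float = 0.0,
    mser_params: dict | None = None,
    mask_dilation: int = 1,
    bounds_overrides: dict | None = None,
    maxiter: int = 200,
    record_trace: bool = False,
) -> ApproachFit:
    """Fit one statistical approach to a single image.

    Boundary-margin pixels are excluded from every objective; the filtering
    approach additionally removes MSER-detected bright-spot pixels
    (dilated by ``mask_dilation``). Returns the multi-start fit together
    with the objective for downstream profiling.
    """
    include = (
        ~boundary_margin_mask(grid, boundary_depth)
        if boundary_depth > 0
        else np.ones(grid.shape, dtype=bool)
    )
    filter_mask = None
    if approach == "filtered":
        regions = mser_detect(data, **(mser_params or {}))
        filter_mask = regions_to_mask(regions, grid.shape, dilation=mask_dilation)
        include = include & ~filter_mask
        if not include.any():
            raise ValueError("filter set covers every included pixel")
    space = _build_space(hypothesis, vessels.n_vessels, approach, bounds_overrides)
    obj = WholeImageObjective(
        data,
        grid,
        vessels,
        approach=approach,
        hypothesis=hypothesis,
        include=include,
        space=space,
    )
    fit = multistart_fit(
        obj, space, n_starts=n_starts, seed=seed, maxiter=maxiter,
        record_trace=record_trace,
    )
    return ApproachFit(
        fit=fit,
        objective=obj,
        space=space,
        approach=approach,
        hypothesis=hypothesis,
        n_data=obj.n_data,
        dataset_id=obj.dataset_id,
        filter_mask=filter_mask,
    )


class JointImageObjective:
    """Joint likelihood over several images of the same tissue type.

    Mechanistic parameters, the concentration-scale background and sigma are
    shared; the semi-quantitative intensity scaling differs per image, so
    image i >= 2 carries a free multiplier ``scale_i`` applied to both the
    heparan intensity level and the background (both are proportional to
    the per-image scaling s). Uniform-heparan hypothesis only.
    """

    def __init__(
        self,
        datas: list[np.ndarray],
        grids: list[PixelGrid],
        vessels_list: list[VesselGeometry],
        approach: str = "direct",
        includes: list[np.ndarray] | None = None,
    ):
        if not (len(datas) == len(grids) == len(vessels_list)) or len(datas) < 2:
            raise ValueError("need at least two images with matching geometry lists")
        self.approach = approach
        self.parts = [
            WholeImageObjective(
                d,
                g,
                v,
                approach=approach,
                hypothesis=1,
                include=None if includes is None else includes[i],
            )
            for i, (d, g, v) in enumerate(zip(datas, grids, vessels_list))
        ]
        params = list(self.parts[0].space.params)
        for i in range(2, len(datas) + 1):
            params.append(Param(f"scale_{i}", 1e-2, 1e2, "log10"))
        self.space = ParameterSpace(params)
        self.n_data = sum(p.n_data for p in self.parts)
        self.dataset_id = hashlib.sha1(
            b"".join(p.dataset_id.encode() for p in self.parts)
        ).hexdigest()

    def nll_external(self, theta: dict[str, float]) -> float:
        total = 0.0
        for i, part in enumerate(self.parts, start=1):
            c = 1.0 if i == 1 else theta[f"scale_{i}"]
            local = dict(theta)
            local["s_s0"] = c * theta["s_s0"]
            local["bg"] = c * theta["bg"]
            total += part.nll_external(local)
        return total

    def __call__(self, x: np.ndarray) -> float:
        return self.nll_external(self.space.to_external(x))


def fit_images_jointly(
    datas: list[np.ndarray],
    grids: list[PixelGrid],
    vessels_list: list[VesselGeometry],
    approach: str = "direct",
    n_starts: int = 20,
    seed: int = 0,
    maxiter: int = 300,
) -> ApproachFit:
    """Multi-start joint fit of several images with shared mechanistic
    parameters and per-image intensity scalings."""
    obj = JointImageObjective(datas, grids, vessels_list, approach=approach)
    fit = multistart_fit(obj, obj.space, n_starts=n_starts, seed=seed, maxiter=maxiter)
    return ApproachFit(
        fit=fit,
        objective=obj,
        space=obj.space,
        approach=approach,
        hypothesis=1,
        n_data=obj.n_data,
        dataset_id=obj.dataset_id,
    )


# ---------------------------------------------------------------------------
# Paired test
# ---------------------------------------------------------------------------


def paired_onesided_test(errors_a, errors_b) -> float:
    """One-sided paired t-test of H1: mean(a - b) > 0.

    Degenerate zero-variance differences return 0, 1 or 0.5 according to the
    sign of the mean difference.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        m = d.mean()
        return 0.0 if m > 0 else (1.0 if m < 0 else 0.5)
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(scipy.stats.t.sf(t, df=d.size - 1))
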