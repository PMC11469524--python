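"""Weighted least-squares estimation of coefficient-path values.

The free parameters are the identifiable coordinates of a
:class:`~mranet.identifiability.Parametrisation` — one pivot edge
coefficient per coefficient path plus the inhibitor strengths (constrained
negative).  The objective is the weighted sum of squared residuals (WSSR)
between measured and simulated log2 fold changes, each cell weighted by its
standard error.  Optimization uses Latin-hypercube-sampled multi-start
initialization followed by damped least squares (trust-region reflective,
which reduces to Levenberg-Marquardt steps in the unbounded directions);
the best restart is returned.

Goodness of fit is summarized by the reduced chi-square
``X_r = WSSR_fit / (n_datapoints - n_identifiable)``, which approaches 1
when the model fits the data down to the noise level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .identifiability import (
    CoefficientPath,
    Parametrisation,
    derive_parametrisation,
)
from .network import (
    DesignError,
    PerturbationDataset,
    PerturbationDesign,
    SignalingNetwork,
)
from .simulator import (
    SingularNetworkError,
    build_local_response_matrix,
    simulate_design,
)

__all__ = [
    "FitConfig",
    "MRAModel",
    "FitResult",
    "wssr",
    "reduced_chi_square",
    "fit_model",
    "refit_with_fixed_inhibitors",
]

logger = logging.getLogger(__name__)

_BIG_RESIDUAL = 1e6


@dataclass(frozen=True)
class FitConfig:
    """Multi-start fitting configuration.

    ``n_starts`` Latin-hypercube restarts; pivot coefficients are
    initialized with log-uniform magnitude in ``mag_range`` and random
    sign, inhibitor strengths uniform in ``l_init_range`` (strictly
    negative, bounded by ``l_bounds`` during optimization).  Per-cell
    standard errors are floored at ``error_floor`` log2 units.
    """

    n_starts: int = 100
    seed: int = 0
    mag_range: tuple[float, float] = (0.01, 100.0)
    l_init_range: tuple[float, float] = (-5.0, -0.01)
    l_bounds: tuple[float, float] = (-30.0, -1e-9)
    ftol: float = 1e-8
    xtol: float = 1e-10
    max_iter: int = 1000
    coarse_max_iter: int = 80
    n_polish: int = 3
    sign_flip_rounds: int = 6
    regression_start: bool = True
    error_floor: float = 0.05
    plateau_rtol: float = 1e-6


@dataclass
class MRAModel:
    """A network + design with its identifiable parameterization and values.

    ``raw`` holds the value of every raw symbol (edge coefficients and
    inhibitor strengths) in the parametrisation's symbol order; non-pivot
    edge coefficients are gauge-fixed to 1.  ``fixed`` names parameters
    held constant during fitting.
    """

    network: SignalingNetwork
    design: PerturbationDesign
    param: Parametrisation
    raw: np.ndarray
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return self.param.n_identifiable - len(self.fixed)

    def local_response_matrix(self) -> np.ndarray:
        return build_local_response_matrix(
            self.network, self.param.edge_values(self.raw)
        )

    def l_values(self) -> dict[str, float]:
        return self.param.l_values(self.raw)

    def edge_value(self, source: str, target: str) -> float:
        from .identifiability import Symbol

        return float(self.raw[self.param.symbols.index(Symbol.edge(source, target))])

    def path_values(self) -> dict[str, float]:
        return self.param.path_values(self.raw)

    def simulate(self, design: PerturbationDesign | None = None) -> np.ndarray:
        design = design if design is not None else self.design
        return simulate_design(
            self.network, self.local_response_matrix(), self.l_values(), design
        )


@dataclass
class FitResult:
    model: MRAModel
    wssr_fit: float
    n_datapoints: int
    n_parameters: int
    n_free_parameters: int
    reduced_chi_square: float
    n_restarts: int
    converged_restarts: int
    seed: int

    def summary(self) -> str:
        return (
            f"WSSR {self.wssr_fit:.4g} over {self.n_datapoints} points, "
            f"{self.n_parameters} identifiable parameters, "
            f"X_r = {self.reduced_chi_square:.4g} "
            f"({self.converged_restarts}/{self.n_restarts} restarts at optimum)"
        )


# ---------------------------------------------------------------------------
# statistics


def wssr(data: PerturbationDataset, sim: np.ndarray) -> float:
    """Weighted sum of squared residuals over all jointly observed cells."""
    sim = np.asarray(sim, dtype=float)
    if sim.shape != data.values.shape:
        raise DesignError(f"shape mismatch: {sim.shape} vs {data.values.shape}")
    obs = data.observed_mask() & np.isfinite(sim)
    errs = data.errors[obs]
    if np.any(~(errs > 0)):
        raise DesignError("zero or negative error on an observed cell")
    res = (data.values[obs] - sim[obs]) / errs
    return float(np.sum(res**2))


def reduced_chi_square(wssr_fit: float, n_datapoints: int, n_params: int) -> float:
    """``WSSR / (n_datapoints - n_params)``; requires an overdetermined model."""
    dof = n_datapoints - n_params
    if dof <= 0:
        raise ValueError(
            f"model not overdetermined: {n_datapoints} data points, "
            f"{n_params} parameters"
        )
    return wssr_fit / dof


# ---------------------------------------------------------------------------
# compiled steady-state simulation with analytic parameter sensitivities


class _CompiledSim:
    """Precompiled per-condition structure for fast repeated simulation.

    The steady state in a condition solves ``A x = -b`` where ``A`` is the
    local response matrix with inhibited columns dampened and ``b``
    collects stimulus entries and basal inhibitor offsets.  One multi-RHS
    solve per condition yields both ``x`` and all parameter sensitivities:
    for an edge coefficient at position (t, s), ``dx = -A^{-1} e_t xt_s``
    with ``xt_s`` the transmitted signal of the source; for an inhibitor
    strength, ``dx = -A^{-1} c_k (exp(l_k) x_k + 1)`` with ``c_k`` the
    outgoing column of the target.
    """

    def __init__(self, param: Parametrisation):
        self.param = param
        network, design = param.network, param.design
        self.n = len(network.nodes)
        idx = {node: i for i, node in enumerate(network.nodes)}
        self.edge_pos = []  # (target_idx, source_idx, raw_idx)
        self.l_node = {}  # node_idx -> raw_idx
        for j, sym in enumerate(param.symbols):
            if sym.kind == "r":
                self.edge_pos.append((idx[sym.target], idx[sym.source], j))
            else:
                self.l_node[idx[sym.target]] = j
        self.edge_t = np.array([t for t, _, _ in self.edge_pos], dtype=int)
        self.edge_s = np.array([s for _, s, _ in self.edge_pos], dtype=int)
        self.edge_raw = np.array([j for _, _, j in self.edge_pos], dtype=int)
        self.conditions = []
        for cond in design.conditions:
            stim = np.zeros(self.n)
            for s in cond.stimulated:
                stim[idx[s]] += 1.0
            inh = np.array(sorted(idx[k] for k in cond.inhibited), dtype=int)
            self.conditions.append((stim, inh))
        self.readout_idx = np.array(
            [idx[node] for _, node in design.measured], dtype=int
        )
        self.mask = design.mask_matrix()

    def r_matrix(self, raw: np.ndarray) -> np.ndarray:
        r = -np.eye(self.n)
        r[self.edge_t, self.edge_s] = raw[self.edge_raw]
        return r

    def _condition_system(self, r, raw, stim, inh):
        a = r.copy()
        b = stim.copy()
        expl = {}
        for k in inh:
            lk = raw[self.l_node[k]]
            col = r[:, k].copy()
            col[k] = 0.0
            b += col * lk
            a[:, k] = col * np.exp(lk)
            a[k, k] = r[k, k]
            expl[k] = np.exp(lk)
        return a, b, expl

    def responses(self, raw: np.ndarray) -> np.ndarray:
        """[condition x readout] matrix; masked cells NaN; raises on
        singular systems."""
        r = self.r_matrix(raw)
        out = np.empty((len(self.conditions), len(self.readout_idx)))
        for i, (stim, inh) in enumerate(self.conditions):
            a, b, _ = self._condition_system(r, raw, stim, inh)
            x = np.linalg.solve(a, -b)
            out[i] = x[self.readout_idx]
        out[self.mask] = np.nan
        return out

    def responses_and_jac(self, raw: np.ndarray, theta_cols: list[int]):
        """Responses plus d(response)/d(theta) for the given raw indices.

        ``theta_cols`` lists raw-symbol indices (edge coefficients or
        inhibitor strengths); returns (sim, jac) with jac of shape
        [condition, readout, len(theta_cols)].
        """
        r = self.r_matrix(raw)
        n_c, n_ro, n_p = len(self.conditions), len(self.readout_idx), len(theta_cols)
        sim = np.empty((n_c, n_ro))
        jac = np.zeros((n_c, n_ro, n_p))
        col_info = []
        for j in theta_cols:
            sym = self.param.symbols[j]
            if sym.kind == "r":
                m = int(np.flatnonzero(self.edge_raw == j)[0])
                col_info.append(("r", int(self.edge_t[m]), int(self.edge_s[m])))
            else:
                node = next(k for k, jj in self.l_node.items() if jj == j)
                col_info.append(("l", node, node))
        for i, (stim, inh) in enumerate(self.conditions):
            a, b, expl = self._condition_system(r, raw, stim, inh)
            rhs = np.empty((self.n, 1 + n_p))
            rhs[:, 0] = -b
            sol0 = np.linalg.solve(a, rhs[:, :1])
            x = sol0[:, 0]
            inh_set = set(int(k) for k in inh)
            for m, (kind, t, s) in enumerate(col_info):
                col = np.zeros(self.n)
                if kind == "r":
                    if s in inh_set:
                        xt = expl[s] * x[s] + raw[self.l_node[s]]
                    else:
                        xt = x[s]
                    col[t] = xt
                else:
                    if t not in inh_set:
                        rhs[:, 1 + m] = 0.0
                        continue
                    c = r[:, t].copy()
                    c[t] = 0.0
                    col = c * (expl[t] * x[t] + 1.0)
                rhs[:, 1 + m] = -col
            dx = np.linalg.solve(a, rhs[:, 1:])
            sim[i] = x[self.readout_idx]
            jac[i] = dx[self.readout_idx, :]
        sim[self.mask] = np.nan
        jac[self.mask, :] = 0.0
        return sim, jac


# ---------------------------------------------------------------------------
# the optimization problem


class _FitProblem:
    def __init__(
        self,
        param: Parametrisation,
        data: PerturbationDataset,
        fixed: dict[str, float],
        path_constraint: tuple[CoefficientPath, float] | None = None,
    ):
        self.param = param
        self.data = data
        self.obs = data.observed_mask()
        self.values = data.values[self.obs]
        self.errors = data.errors[self.obs]
        if np.any(~(self.errors > 0)):
            raise DesignError("zero or negative error on an observed cell")
        self.path_constraint = path_constraint
        self.sim = _CompiledSim(param)

        names = param.theta_names
        all_symbols = {s.name for s in param.symbols}
        fixed_idx: dict[int, float] = {}
        for name, val in fixed.items():
            if name in names:
                fixed_idx[names.index(name)] = float(val)
            elif name in all_symbols:
                continue  # parameter exists but never appears in a response
            else:
                fixed_idx[self._theta_index_of_path(name)] = float(val)
        self.fixed_idx = fixed_idx

        constrained = set(fixed_idx)
        if path_constraint is not None:
            path, _ = path_constraint
            constrained.add(self._pivot_theta_index(path))
        self.free = [i for i in range(param.n_theta) if i not in constrained]

        l_lo = slice(len(param.free_r), param.n_theta)
        self.is_l = np.zeros(param.n_theta, dtype=bool)
        self.is_l[l_lo] = True

    def _theta_index_of_path(self, name: str) -> int:
        path = self.param.find_path(name)  # KeyError if absent
        if path.support() != (path.pivot,) or path.exponents[path.pivot] != 1:
            raise KeyError(
                f"{name!r} is a composite coefficient path; only simple "
                "(single-symbol) paths or raw parameter names can be fixed"
            )
        return self._pivot_theta_index(path)

    def _pivot_theta_index(self, path: CoefficientPath) -> int:
        sym = self.param.symbols[path.pivot]
        try:
            return self.param.theta_names.index(sym.name)
        except ValueError:
            raise KeyError(f"path pivot {sym.name!r} is not a free parameter")

    # -- parameter plumbing ---------------------------------------------
    def theta_full(self, theta_active: np.ndarray) -> np.ndarray | None:
        theta = np.empty(self.param.n_theta)
        theta[self.free] = theta_active
        for i, v in self.fixed_idx.items():
            theta[i] = v
        if self.path_constraint is not None:
            path, target = self.path_constraint
            piv_theta = self._pivot_theta_index(path)
            raw = self.param.raw_from_theta(theta)  # pivot entry is garbage here
            t = target
            g = int(path.exponents[path.pivot])
            for j in path.support():
                if j == path.pivot:
                    continue
                denom = float(raw[j]) ** int(path.exponents[j])
                if denom == 0:
                    return None
                t /= denom
            if g % 2 == 0 and t < 0:
                return None
            piv = float(np.sign(t) * np.abs(t) ** (1.0 / g)) if g != 1 else t
            sym = self.param.symbols[path.pivot]
            if sym.kind == "i" and piv >= 0:
                return None
            theta[piv_theta] = piv
        return theta

    def residuals(self, theta_active: np.ndarray) -> np.ndarray:
        theta = self.theta_full(theta_active)
        if theta is None:
            return np.full(self.values.size, _BIG_RESIDUAL)
        raw = self.param.raw_from_theta(theta)
        try:
            sim = self.sim.responses(raw)
        except (np.linalg.LinAlgError, SingularNetworkError):
            return np.full(self.values.size, _BIG_RESIDUAL)
        simv = sim[self.obs]
        res = (simv - self.values) / self.errors
        bad = ~np.isfinite(res)
        if bad.any():
            res = np.where(bad, _BIG_RESIDUAL, res)
        return res

    def jacobian(self, theta_active: np.ndarray) -> np.ndarray:
        """Analytic residual Jacobian (only valid without a path constraint)."""
        theta = self.theta_full(theta_active)
        raw = self.param.raw_from_theta(theta)
        raw_cols = self.param.free_r + self.param.free_l
        active_cols = [raw_cols[i] for i in self.free]
        try:
            _sim, jac = self.sim.responses_and_jac(raw, active_cols)
        except (np.linalg.LinAlgError, SingularNetworkError):
            return np.zeros((self.values.size, len(self.free)))
        jr = jac[self.obs] / self.errors[:, None]
        jr[~np.isfinite(jr)] = 0.0
        return jr

    def cost(self, theta_active: np.ndarray) -> float:
        return float(np.sum(self.residuals(theta_active) ** 2))

    def bounds(self, config: FitConfig):
        lo = np.full(len(self.free), -np.inf)
        hi = np.full(len(self.free), np.inf)
        for k, i in enumerate(self.free):
            if self.is_l[i]:
                lo[k], hi[k] = config.l_bounds
        return lo, hi

    def sample_starts(self, n: int, config: FitConfig, rng: np.random.Generator):
        d = len(self.free)
        if d == 0:
            return np.zeros((max(n, 1), 0))
        sampler = qmc.LatinHypercube(d=d, seed=rng)
        u = sampler.random(n)
        starts = np.empty((n, d))
        lo_m, hi_m = np.log10(config.mag_range[0]), np.log10(config.mag_range[1])
        for k, i in enumerate(self.free):
            if self.is_l[i]:
                a, b = config.l_init_range
                starts[:, k] = a + u[:, k] * (b - a)
            else:
                mag = 10.0 ** (lo_m + u[:, k] * (hi_m - lo_m))
                sign = rng.choice([-1.0, 1.0], size=n)
                starts[:, k] = sign * mag
        return starts

    def minimize_from(self, x0: np.ndarray, config: FitConfig):
        lo, hi = self.bounds(config)
        x0 = np.clip(x0, lo, hi)
        if len(self.free) == 0:
            return x0, self.cost(x0), True
        jac = "2-point" if self.path_constraint is not None else self.jacobian
        try:
            sol = least_squares(
                self.residuals,
                x0,
                jac=jac,
                bounds=(lo, hi),
                method="trf",
                ftol=config.ftol,
                xtol=config.xtol,
                max_nfev=config.max_iter
                if self.path_constraint is None
                else config.max_iter * (len(self.free) + 1),
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("restart failed: %s", exc)
            return x0, np.inf, False
        return sol.x, 2.0 * sol.cost, sol.success


# ---------------------------------------------------------------------------
# data-driven initialization

def _heuristic_theta(param: Parametrisation, data: PerturbationDataset):
    """Initial parameter estimate by regression on the measured responses.

    In the steady state each node's response is (approximately, ignoring
    inhibitor dampening) a linear combination of its parents' responses.
    For every measured node the observed responses are regressed on the
    responses of its nearest measured or stimulus ancestors — unmeasured
    intermediates are collapsed, so the regression coefficient estimates
    the *product* of coefficients along the connecting chain, which is
    assigned to the chain's free pivot coordinate (non-pivot coefficients
    are gauge-fixed at 1).  Conditions inhibiting an involved node are
    excluded from each regression.  Returns None when nothing is
    estimable.
    """
    net, design = param.network, param.design
    conds = design.conditions
    vals = data.values
    node_col: dict[str, int] = {}
    for j, (_ro, node) in enumerate(design.measured):
        node_col.setdefault(node, j)
    known: dict[str, np.ndarray] = {
        node: vals[:, j] for node, j in node_col.items()
    }
    for s in net.stimuli:
        known.setdefault(
            s,
            np.array([1.0 if s in c.stimulated else 0.0 for c in conds]),
        )
    parents: dict[str, list[str]] = {n: [] for n in net.nodes}
    for s, t in net.edges:
        parents[t].append(s)

    def expand(p: str, stack: frozenset, depth: int):
        """Chains from the nearest known ancestors down to ``p``."""
        if p in known:
            return [(p, ())]
        if p in stack or depth > 4:
            return []
        out = []
        for q in parents[p]:
            for u, ch in expand(q, stack | {p}, depth + 1):
                out.append((u, ch + ((q, p),)))
        return out

    estimates: dict[tuple, float] = {}
    for t, jt in node_col.items():
        by_u: dict[str, tuple] = {}
        for p in parents[t]:
            for u, ch in expand(p, frozenset({t}), 0):
                chain = ch + ((p, t),)
                if u not in by_u or len(chain) < len(by_u[u]):
                    by_u[u] = chain
        if not by_u:
            continue
        us = sorted(by_u)
        involved = set(us)
        for ch in by_u.values():
            for e in ch:
                involved.update(e)
        rows = [
            i
            for i, c in enumerate(conds)
            if np.isfinite(vals[i, jt])
            and all(np.isfinite(known[u][i]) for u in us)
            and not (c.inhibited & involved)
        ]
        if len(rows) <= len(us):
            continue
        x = np.column_stack([known[u][rows] for u in us])
        y = vals[rows, jt]
        try:
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            continue
        for u, cf in zip(us, coef):
            if np.isfinite(cf):
                estimates[by_u[u]] = float(cf)

    if not estimates:
        return None

    def clipmag(v: float) -> float:
        sign = -1.0 if v < 0 else 1.0
        return sign * float(np.clip(abs(v), 0.05, 20.0))

    theta = np.array(
        [1.0] * len(param.free_r) + [-1.0] * len(param.free_l)
    )
    edge_theta = {}
    for i, j in enumerate(param.free_r):
        sym = param.symbols[j]
        edge_theta[(sym.source, sym.target)] = i
    assigned = np.zeros(len(theta), dtype=bool)
    for ch in sorted(estimates, key=lambda c: (len(c), c)):
        v = estimates[ch]
        free_es = [e for e in ch if e in edge_theta]
        if not free_es:
            continue
        unassigned = [e for e in free_es if not assigned[edge_theta[e]]]
        if not unassigned:
            continue
        denom = 1.0
        for e in free_es:
            if assigned[edge_theta[e]]:
                denom *= theta[edge_theta[e]]
        if denom != 0:
            theta[edge_theta[unassigned[0]]] = clipmag(v / denom)
        for e in unassigned:
            assigned[edge_theta[e]] = True

    # rough inhibitor strengths from single-inhibitor basal conditions
    off = len(param.free_r)
    for i, j in enumerate(param.free_l):
        k = param.symbols[j].target
        ratios = []
        for ci, c in enumerate(conds):
            if c.inhibited != frozenset({k}) or c.stimulated:
                continue
            for t in net.nodes:
                e = (k, t)
                if e in edge_theta and t in node_col:
                    y = vals[ci, node_col[t]]
                    r_est = theta[edge_theta[e]]
                    if np.isfinite(y) and abs(r_est) > 1e-6:
                        ratios.append(y / r_est)
        if ratios:
            theta[off + i] = float(np.clip(np.median(ratios), -4.0, -0.05))
    return theta


def _node_flip_groups(param: Parametrisation, free: list[int]) -> list[list[int]]:
    """Joint sign-flip moves: all free in/out edge coordinates of one node.

    A wrong sign guess for a node's activity manifests as a coherent sign
    error on every edge touching it; single-coordinate flips cannot cross
    such basins."""
    sym_of = {}
    for k, ti in enumerate(free):
        if ti < len(param.free_r):
            sym_of[k] = param.symbols[param.free_r[ti]]
    groups = []
    for n in param.network.nodes:
        ks = [k for k, sym in sym_of.items() if n in (sym.source, sym.target)]
        if len(ks) > 1:
            groups.append(ks)
    return groups


# ---------------------------------------------------------------------------
# public fitting entry points


def _prepare_data(
    design: PerturbationDesign, data: PerturbationDataset, config: FitConfig
) -> PerturbationDataset:
    return data.masked_like(design).with_error_floor(config.error_floor)


def fit_model(
    network: SignalingNetwork,
    design: PerturbationDesign,
    data: PerturbationDataset,
    config: FitConfig | None = None,
    fixed: dict[str, float] | None = None,
    param: Parametrisation | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Estimate coefficient-path values by multi-start weighted least squares.

    ``fixed`` clamps named parameters (inhibitor strengths ``i_<node>`` or
    single-symbol coefficient paths) at given values; clamped parameters
    are excluded from the identifiable-parameter count.  ``theta0`` adds a
    warm start to the Latin-hypercube restarts.
    """
    config = config or FitConfig()
    fixed = dict(fixed or {})
    if not any(c.is_perturbed for c in design.conditions):
        raise DesignError("design has no perturbed conditions; nothing to fit")
    if param is None:
        param = derive_parametrisation(network, design)
    prepared = _prepare_data(design, data, config)
    problem = _FitProblem(param, prepared, fixed)

    n_datapoints = int(problem.obs.sum())
    if fixed:
        fixed_syms = [n for n in fixed if n in [s.name for s in param.symbols]]
        fixed_syms += [
            param.symbols[param.find_path(n).pivot].name
            for n in fixed
            if n not in fixed_syms
        ]
        n_params = param.rank_excluding(fixed_syms)
    else:
        n_params = param.n_identifiable
    if n_datapoints <= n_params:
        raise ValueError(
            f"model not overdetermined: {n_datapoints} data points for "
            f"{n_params} identifiable parameters"
        )

    rng = np.random.default_rng(config.seed)
    starts = list(problem.sample_starts(config.n_starts, config, rng))

    # stage 1: damped least squares from every start, iteration-capped
    coarse_cfg = replace(config, max_iter=config.coarse_max_iter, ftol=1e-6)
    results = [problem.minimize_from(x0, coarse_cfg) for x0 in starts]
    costs = [c for _x, c, _ok in results]

    # stage 2: polish the best restarts and the informed starts to tolerance
    polish_idx = list(np.argsort(costs)[: config.n_polish])
    best_x, best_cost = None, np.inf
    solutions: list[tuple[float, np.ndarray]] = []
    for i in polish_idx:
        x, c, _ok = problem.minimize_from(results[i][0], config)
        costs[i] = c
        solutions.append((c, x))
        if c < best_cost:
            best_x, best_cost = x, c
    informed = []
    if theta0 is not None:
        informed.append(np.asarray(theta0, dtype=float)[problem.free])
    if config.regression_start and problem.path_constraint is None:
        heur = _heuristic_theta(param, prepared)
        if heur is not None:
            x0 = heur[problem.free]
            informed.append(x0)
            # jittered copies: the regression start usually lands in the
            # right sign basin but can polish into a neighboring one
            for _ in range(3):
                informed.append(x0 * np.exp(rng.normal(0.0, 0.3, size=x0.shape)))
    for x0 in informed:
        x, c, _ok = problem.minimize_from(x0, config)
        costs.append(c)
        solutions.append((c, x))
        if c < best_cost:
            best_x, best_cost = x, c
    if best_x is None or not np.isfinite(best_cost):
        raise RuntimeError("all restarts failed to converge")

    # stage 3: greedy sign-flip refinement — the residual landscape of an
    # MRA model is organized in sign basins (one per coefficient sign
    # assignment) that random restarts rarely sample completely.  Moves:
    # single coefficients, and all edges of one node jointly (a wrong
    # guess for a node's activity sign flips every edge that touches it).
    if config.sign_flip_rounds > 0 and len(problem.free) > 0:
        quick_cfg = replace(config, max_iter=60, ftol=1e-6)
        lmask = problem.is_l[np.array(problem.free, dtype=int)]
        moves = [[k] for k in range(len(problem.free)) if not lmask[k]]
        moves += _node_flip_groups(param, problem.free)
        # refine from the two best distinct stage-2 basins, not only the
        # very best: the runner-up occasionally sits nearer the optimum
        solutions.sort(key=lambda t: t[0])
        seeds_x = [solutions[0][1]] if solutions else [best_x]
        for c, x in solutions[1:]:
            if not np.allclose(x, seeds_x[0], rtol=1e-3, atol=1e-6):
                seeds_x.append(x)
                break
        for x_seed in seeds_x:
            x_cur, _c_cur, _ = problem.minimize_from(x_seed, config)
            c_cur = float(np.sum(problem.residuals(x_cur) ** 2))
            for _round in range(config.sign_flip_rounds):
                improved = False
                for mv in moves:
                    x_try = x_cur.copy()
                    x_try[mv] = -x_try[mv]
                    if np.array_equal(x_try, x_cur):
                        continue
                    xq, cq, _ = problem.minimize_from(x_try, quick_cfg)
                    if cq < c_cur - 1e-9:
                        xp, cp, _ = problem.minimize_from(xq, config)
                        if cp < c_cur:
                            x_cur, c_cur = xp, cp
                            improved = True
                if not improved:
                    break
            if c_cur < best_cost:
                best_x, best_cost = x_cur, c_cur

    converged = int(
        np.sum(np.asarray(costs) <= best_cost * (1 + config.plateau_rtol) + 1e-12)
    )
    if converged < 2 and len(starts) > 1:
        warnings.warn(
            f"optimum plateau reached by only {converged} of {len(starts)} "
            "restarts; the fit may be a local optimum",
            stacklevel=2,
        )

    theta = problem.theta_full(best_x)
    raw = param.raw_from_theta(theta)
    model = MRAModel(network, design, param, raw, fixed=fixed)
    xr = reduced_chi_square(best_cost, n_datapoints, n_params)
    return FitResult(
        model=model,
        wssr_fit=float(best_cost),
        n_datapoints=n_datapoints,
        n_parameters=n_params,
        n_free_parameters=n_datapoints - n_params,
        reduced_chi_square=xr,
        n_restarts=len(starts),
        converged_restarts=converged,
        seed=config.seed,
    )


def refit_with_fixed_inhibitors(
    fit: FitResult,
    fixed_values: dict[str, float],
    data: PerturbationDataset,
    config: FitConfig | None = None,
) -> FitResult:
    """Refit with inhibitor strengths clamped to externally supplied values.

    Used for cross-model comparison: inhibitor doses are shared between
    experiments, so their strengths are fixed to a common value (reference
    model or mean across models) and the remaining coefficient paths are
    allowed to compensate.  The clamped strengths no longer count as
    identifiable parameters.
    """
    model = fit.model
    valid = {s.name for s in model.param.symbols if s.kind == "i"}
    for name in fixed_values:
        if name not in valid:
            raise KeyError(
                f"{name!r} is not an inhibitor strength of this model "
                f"(known: {sorted(valid)})"
            )
    config = config or FitConfig()
    return fit_model(
        model.network,
        model.design,
        data,
        config=config,
        fixed=dict(fixed_values),
        param=model.param,
        theta0=model.param.theta_from_raw(model.raw),
    )
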