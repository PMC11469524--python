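"""Profile-likelihood confidence intervals, model comparison, structure
transfer, and consensus core-network extraction.

The 95% pointwise confidence interval of a coefficient path is found by
scanning its value away from the optimum while re-optimizing all other
parameters, until the WSSR exceeds the optimum by the chi-square(1)
quantile (3.841 for alpha = 0.05).  A direction in which the threshold is
never crossed before the parameter bound is flagged non-identifiable
("ni"): changes of the coefficient can be compensated by the rest of the
model.

For cross-model comparison the inhibitor strengths are first fixed to
common values (doses were shared between experiments), after which two
models differ significantly in a path when their confidence intervals do
not overlap.  A consensus core network keeps the edges present in at least
``k`` of the member models, with coefficients binned into five qualitative
states (amplification, dampening/neutral relay, no link, attenuation,
enforced inhibition).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
from scipy.stats import chi2

from .fitting import (
    FitConfig,
    FitResult,
    MRAModel,
    _FitProblem,
    _prepare_data,
    fit_model,
)
from .network import (
    PerturbationDataset,
    PerturbationDesign,
    SignalingNetwork,
    validate_design,
)

__all__ = [
    "ProfileResult",
    "profile_likelihood",
    "ModelComparison",
    "compare_models",
    "transfer_structure",
    "bin_coefficient",
    "compose_path",
    "ConsensusEdge",
    "ConsensusNetwork",
    "consensus_network",
    "BIN_LABELS",
]

logger = logging.getLogger(__name__)


@dataclass
class ProfileResult:
    """Pointwise profile-likelihood confidence interval for one path."""

    name: str
    estimate: float
    lower: float
    upper: float
    ni_lower: bool
    ni_upper: bool
    alpha: float = 0.05
    points: list[tuple[float, float]] = field(default_factory=list)

    def contains(self, value: float) -> bool:
        lo = -np.inf if self.ni_lower else self.lower
        hi = np.inf if self.ni_upper else self.upper
        return lo <= value <= hi

    def overlaps(self, other: "ProfileResult") -> bool:
        lo_a = -np.inf if self.ni_lower else self.lower
        hi_a = np.inf if self.ni_upper else self.upper
        lo_b = -np.inf if other.ni_lower else other.lower
        hi_b = np.inf if other.ni_upper else other.upper
        return lo_a <= hi_b and lo_b <= hi_a


def _profile_cost(problem: _FitProblem, config: FitConfig, theta_warm: np.ndarray):
    x0 = theta_warm[problem.free]
    x, cost, _ok = problem.minimize_from(x0, config)
    theta = problem.theta_full(x)
    return cost, theta


def profile_likelihood(
    fit: FitResult,
    data: PerturbationDataset,
    path_name: str,
    alpha: float = 0.05,
    bound: float = 1e4,
    config: FitConfig | None = None,
) -> ProfileResult:
    """Profile one coefficient path and return its (1-alpha) CI.

    Stepping is adaptive: initial step 10% of the estimate's magnitude
    (floored at 0.01), doubled until the threshold is bracketed, then
    bisected; the crossing is interpolated linearly.  If the scan passes
    ``bound`` in magnitude without crossing, the direction is flagged
    non-identifiable.
    """
    config = config or FitConfig()
    model = fit.model
    param = model.param
    path = param.find_path(path_name)
    pivot_name = param.symbols[path.pivot].name
    if pivot_name in model.fixed:
        raise ValueError(f"path {path_name!r} is fixed, not free; cannot profile")

    prepared = _prepare_data(model.design, data, config)
    threshold = fit.wssr_fit + float(chi2.ppf(1.0 - alpha, 1))
    increment = threshold - fit.wssr_fit
    theta_best = param.theta_from_raw(model.raw)
    v0 = param.path_value(path, model.raw)

    points: list[tuple[float, float]] = [(v0, fit.wssr_fit)]

    def cost_at(v: float, warm: np.ndarray):
        problem = _FitProblem(
            param, prepared, dict(model.fixed), path_constraint=(path, v)
        )
        try:
            c, theta = _profile_cost(problem, config, warm)
        except Exception as exc:  # refit failure: skip the point
            warnings.warn(f"profile point {v:.4g} skipped: {exc}", stacklevel=2)
            return np.inf, warm
        if theta is None:
            return np.inf, warm
        points.append((v, c))
        return c, theta

    def scan(direction: int):
        step = max(0.1 * abs(v0), 0.01)
        v_in, c_in, warm = v0, fit.wssr_fit, theta_best.copy()
        while True:
            v_out = v_in + direction * step
            if abs(v_out) > bound:
                return None  # non-identifiable in this direction
            c_out, warm_new = cost_at(v_out, warm)
            if c_out > threshold:
                break
            v_in, c_in, warm = v_out, c_out, warm_new
            step *= 2.0
        # bisect the bracket [v_in, v_out]
        for _ in range(60):
            if abs(c_out - threshold) <= 1e-3 * increment:
                break
            v_mid = 0.5 * (v_in + v_out)
            c_mid, warm_mid = cost_at(v_mid, warm)
            if c_mid > threshold:
                v_out, c_out = v_mid, c_mid
            else:
                v_in, c_in, warm = v_mid, c_mid, warm_mid
            if abs(v_out - v_in) < 1e-12 * (1 + abs(v0)):
                break
        if np.isfinite(c_out) and c_out > c_in:
            frac = (threshold - c_in) / (c_out - c_in)
            frac = min(max(frac, 0.0), 1.0)
            return v_in + frac * (v_out - v_in)
        return v_out

    upper = scan(+1)
    lower = scan(-1)
    return ProfileResult(
        name=path_name,
        estimate=v0,
        lower=-np.inf if lower is None else float(lower),
        upper=np.inf if upper is None else float(upper),
        ni_lower=lower is None,
        ni_upper=upper is None,
        alpha=alpha,
        points=sorted(points),
    )


# ---------------------------------------------------------------------------
# cross-model comparison


@dataclass
class ModelComparison:
    shared: dict[str, tuple[ProfileResult, ProfileResult]]
    significant: dict[str, bool]
    individual: tuple[tuple[str, ...], tuple[str, ...]]

    def significantly_different(self) -> list[str]:
        return [n for n, sig in self.significant.items() if sig]


def compare_models(
    fits: list[FitResult],
    datasets: list[PerturbationDataset],
    alpha: float = 0.05,
    config: FitConfig | None = None,
) -> ModelComparison:
    """Flag coefficient paths whose CIs do not overlap between two models.

    The models are expected to share a path naming scheme (same structure,
    inhibitor strengths fixed to common values beforehand).  Paths present
    in only one model are reported separately as individual links, not
    flagged.
    """
    if len(fits) != 2 or len(datasets) != 2:
        raise ValueError("compare_models expects exactly two fitted models")
    names = [set(f.model.path_values()) for f in fits]
    shared_names = sorted(names[0] & names[1])
    if not shared_names:
        raise ValueError("models share no coefficient paths")
    shared: dict[str, tuple[ProfileResult, ProfileResult]] = {}
    significant: dict[str, bool] = {}
    for name in shared_names:
        profiles = []
        for f, d in zip(fits, datasets):
            pivot = f.model.param.symbols[f.model.param.find_path(name).pivot].name
            if pivot in f.model.fixed:
                break  # fixed in one model: not comparable as a free path
            profiles.append(profile_likelihood(f, d, name, alpha=alpha, config=config))
        if len(profiles) < 2:
            continue
        shared[name] = (profiles[0], profiles[1])
        significant[name] = not profiles[0].overlaps(profiles[1])
    individual = (
        tuple(sorted(names[0] - names[1])),
        tuple(sorted(names[1] - names[0])),
    )
    return ModelComparison(shared, significant, individual)


def transfer_structure(
    structure: SignalingNetwork,
    design: PerturbationDesign,
    data: PerturbationDataset,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit a foreign dataset on a fixed network structure.

    Runs the full identifiability analysis and fit on the new data; the
    returned statistics use the same reduced chi-square convention as a
    natively adapted fit and are directly comparable.
    """
    validate_design(structure, design, data)
    return fit_model(structure, design, data, config=config)


# ---------------------------------------------------------------------------
# consensus core network

BIN_LABELS = (
    "amplification",
    "dampening to neutral relay",
    "no link",
    "attenuating to neutral inhibition",
    "enforced inhibition",
)


def bin_coefficient(value: float, zero_tol: float = 1e-9) -> str:
    """Five-state qualitative bin of a response coefficient.

    amplification (r > 1), dampening to neutral relay (0 < r <= 1),
    no link (r = 0), attenuating to neutral inhibition (-1 <= r < 0),
    enforced inhibition (r < -1).  Boundary values fall to the neutral
    side; |r| below ``zero_tol`` counts as no link.
    """
    if abs(value) < zero_tol:
        return "no link"
    if value > 1:
        return "amplification"
    if value > 0:
        return "dampening to neutral relay"
    if value >= -1:
        return "attenuating to neutral inhibition"
    return "enforced inhibition"


def compose_path(values) -> float:
    """Overall response along a chain of edges: the product of coefficients.

    Signs propagate multiplicatively — two inhibitory links in series give
    an overall positive response.
    """
    values = list(values)
    if not values:
        raise ValueError("compose_path requires at least one coefficient")
    return float(np.prod(values))


@dataclass
class ConsensusEdge:
    source: str
    target: str
    votes: int
    states: tuple[str | None, ...]
    consensus_state: str


@dataclass
class ConsensusNetwork:
    members: tuple[str, ...]
    min_votes: int
    edges: list[ConsensusEdge]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


def consensus_network(
    models: list[MRAModel],
    k: int = 3,
    labels: list[str] | None = None,
) -> ConsensusNetwork:
    """Core network of edges present in at least ``k`` member models.

    Each retained edge carries the per-model binned coefficient states and
    a consensus state (the majority bin among the models containing the
    edge; ties are reported as "unresolved").  ``k=1`` yields the union of
    the member networks, ``k=len(models)`` their intersection.
    """
    if k > len(models):
        raise ValueError(f"k={k} exceeds the number of models ({len(models)})")
    if k < 1:
        raise ValueError("k must be at least 1")
    labels = labels or [f"model{i}" for i in range(len(models))]
    all_edges: list[tuple[str, str]] = []
    for m in models:
        for e in m.network.edges:
            if e not in all_edges:
                all_edges.append(e)
    edges: list[ConsensusEdge] = []
    for s, t in all_edges:
        states: list[str | None] = []
        for m in models:
            if m.network.has_edge(s, t):
                states.append(bin_coefficient(m.edge_value(s, t)))
            else:
                states.append(None)
        votes = sum(st is not None for st in states)
        if votes < k:
            continue
        counts = Counter(st for st in states if st is not None)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            consensus = "unresolved"
        else:
            consensus = top[0][0]
        edges.append(ConsensusEdge(s, t, votes, tuple(states), consensus))
    return ConsensusNetwork(tuple(labels), k, edges)
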