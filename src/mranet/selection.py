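"""Greedy network-structure adaptation with held-out consistency checks.

Starting from a literature-derived network, the structure is adapted one
edge at a time: links whose removal does not significantly worsen the fit
(likelihood-ratio test, p > alpha) are pruned, and links whose addition
significantly improves it (p < alpha) are introduced.  Each candidate
change is additionally gated by a consistency check on held-out data (in
the study design: the unstimulated inhibitor conditions, which were never
used for fitting): the model's error reduction over the all-zero null
prediction, ``100 * (WSSR_null - WSSR_sim) / WSSR_null``, must not drop by
more than a small tolerance relative to the previous accepted step.
Candidates are tried in rank order until one passes or none remain.

The likelihood-ratio degrees of freedom are the change in *identifiable*
parameter count (coefficient paths), not the raw edge count: removing an
edge that was only identifiable inside a larger combination can cost zero
degrees of freedom, in which case it is accepted as a pure simplification
whenever the fit is unchanged.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2

from .fitting import FitConfig, FitResult, MRAModel, fit_model, wssr
from .network import (
    PerturbationDataset,
    PerturbationDesign,
    SignalingNetwork,
)

__all__ = [
    "ConsistencyResult",
    "AdaptConfig",
    "Candidate",
    "AdaptationStep",
    "AdaptationTrace",
    "lrt_pvalue",
    "scan_removals",
    "scan_additions",
    "consistency_check",
    "adapt_network",
    "split_by_stimulation",
]

logger = logging.getLogger(__name__)

_DF0_WSSR_TOL = 1e-6  # zero-df removals accepted when the fit is unchanged


@dataclass
class ConsistencyResult:
    """Held-out prediction quality relative to the all-zero null model."""

    wssr_simulation: float
    wssr_nullmodel: float
    error_reduction_pct: float


@dataclass(frozen=True)
class AdaptConfig:
    alpha_remove: float = 0.05
    alpha_add: float = 0.05
    delta_pct: float = 2.0
    fit_config: FitConfig = field(default_factory=lambda: FitConfig(n_starts=30))
    scan_starts: int = 12
    max_iterations: int = 25
    error_floor: float = 0.05


@dataclass
class Candidate:
    action: str  # "remove" | "add"
    edge: tuple[str, str]
    fit: FitResult
    p_value: float
    delta_df: int

    @property
    def name(self) -> str:
        return f"{self.action} {self.edge[0]}->{self.edge[1]}"


@dataclass
class AdaptationStep:
    action: str
    edge: tuple[str, str]
    p_value: float
    delta_df: int
    wssr_before: float
    wssr_after: float
    xr_before: float
    xr_after: float
    error_reduction_before: float | None
    error_reduction_after: float | None
    accepted: bool
    reason: str = ""


@dataclass
class AdaptationTrace:
    steps: list[AdaptationStep] = field(default_factory=list)

    def accepted_steps(self) -> list[AdaptationStep]:
        return [s for s in self.steps if s.accepted]

    def replay(self, network: SignalingNetwork) -> SignalingNetwork:
        """Apply the accepted actions to ``network`` in order."""
        for s in self.accepted_steps():
            if s.action == "remove":
                network = network.without_edge(*s.edge)
            else:
                network = network.with_edge(*s.edge)
        return network


# ---------------------------------------------------------------------------
# statistics


def lrt_pvalue(wssr_small: float, wssr_big: float, delta_df: int) -> float:
    """Likelihood-ratio p-value for nested weighted-least-squares models.

    ``wssr_small`` is the WSSR of the smaller (nested) model, ``wssr_big``
    of the larger one; the difference is chi-square distributed with
    ``delta_df`` degrees of freedom (the change in identifiable parameter
    count) under the null that the extra parameters are superfluous.
    """
    if delta_df < 0:
        raise ValueError("delta_df must be non-negative")
    d = wssr_small - wssr_big
    slack = 1e-6 * (1.0 + abs(wssr_small))
    if d < -slack:
        raise ValueError(
            f"larger model fits worse (dWSSR={d:.3g}); upstream fit failure"
        )
    if delta_df == 0:
        return 1.0
    return float(chi2.sf(max(d, 0.0), delta_df))


def _scan_config(config: AdaptConfig, tag: str) -> FitConfig:
    seed = zlib.crc32(f"{tag}:{config.fit_config.seed}".encode()) & 0x7FFFFFFF
    return replace(config.fit_config, n_starts=config.scan_starts, seed=seed)


def _candidate_fit(
    network, design, data, config: AdaptConfig, tag: str, warm_from: MRAModel | None = None
):
    """Fit a candidate structure, warm-started from the current model.

    Warm starting makes the nested comparison honest: the candidate's
    optimizer begins at the current optimum (shared coefficients copied,
    a newly added edge starting inert at 0), so the WSSR difference
    reflects the structural change rather than restart luck.
    """
    try:
        from .identifiability import derive_parametrisation

        param = derive_parametrisation(network, design)
        theta0 = None
        if warm_from is not None:
            current = dict(zip(warm_from.param.symbols, warm_from.raw))
            raw = param.default_raw()
            for j, sym in enumerate(param.symbols):
                if sym in current:
                    raw[j] = current[sym]
                elif sym.kind == "r":
                    raw[j] = 0.0  # new edge starts with no effect
            theta0 = param.theta_from_raw(raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fit_model(
                network,
                design,
                data,
                config=_scan_config(config, tag),
                param=param,
                theta0=theta0,
            )
    except Exception as exc:
        logger.warning("candidate %s failed: %s", tag, exc)
        return None


def scan_removals(
    fit: FitResult,
    data: PerturbationDataset,
    config: AdaptConfig | None = None,
    alpha: float | None = None,
) -> list[Candidate]:
    """Refit once per removable edge and rank insignificant edges.

    Returns candidates with p > alpha (edges the data cannot justify),
    ranked by descending p; ties broken by smaller candidate WSSR, then
    fewer identifiable parameters, then edge name.
    """
    config = config or AdaptConfig()
    alpha = config.alpha_remove if alpha is None else alpha
    model = fit.model
    out: list[Candidate] = []
    for edge in model.network.edges:
        tag = f"rm:{edge[0]}->{edge[1]}"
        reduced = model.network.without_edge(*edge)
        cand_fit = _candidate_fit(
            reduced, model.design, data, config, tag, warm_from=model
        )
        if cand_fit is None:
            continue
        ddf = fit.n_parameters - cand_fit.n_parameters
        if ddf < 0:
            logger.warning("%s increased the parameter count; skipped", tag)
            continue
        d = max(cand_fit.wssr_fit - fit.wssr_fit, 0.0)
        if ddf == 0:
            p = 1.0 if d < _DF0_WSSR_TOL * (1 + fit.wssr_fit) else 0.0
        else:
            p = float(chi2.sf(d, ddf))
        if p > alpha:
            out.append(Candidate("remove", edge, cand_fit, p, ddf))
    out.sort(
        key=lambda c: (-c.p_value, c.fit.wssr_fit, c.fit.n_parameters, c.edge)
    )
    return out


def scan_additions(
    fit: FitResult,
    data: PerturbationDataset,
    config: AdaptConfig | None = None,
    alpha: float | None = None,
) -> list[Candidate]:
    """Refit once per addable edge and rank significant improvements.

    Candidate edges are all ordered node pairs absent from the network,
    excluding self-loops and edges into stimulus nodes.  Returns candidates
    with p < alpha ranked by ascending p.
    """
    config = config or AdaptConfig()
    alpha = config.alpha_add if alpha is None else alpha
    model = fit.model
    net = model.network
    existing = set(net.edges)
    out: list[Candidate] = []
    for s in net.nodes:
        for t in net.nodes:
            if s == t or t in net.stimuli or (s, t) in existing:
                continue
            tag = f"add:{s}->{t}"
            extended = net.with_edge(s, t)
            cand_fit = _candidate_fit(
                extended, model.design, data, config, tag, warm_from=model
            )
            if cand_fit is None:
                continue
            ddf = cand_fit.n_parameters - fit.n_parameters
            if ddf <= 0:
                continue  # the new edge adds no identifiable freedom
            d = max(fit.wssr_fit - cand_fit.wssr_fit, 0.0)
            p = float(chi2.sf(d, ddf))
            if p < alpha:
                out.append(Candidate("add", (s, t), cand_fit, p, ddf))
    out.sort(
        key=lambda c: (c.p_value, c.fit.wssr_fit, c.fit.n_parameters, c.edge)
    )
    return out


def consistency_check(
    model: MRAModel,
    heldout_data: PerturbationDataset,
    heldout_design: PerturbationDesign | None = None,
    error_floor: float = 0.05,
) -> ConsistencyResult:
    """Error reduction of the model's held-out prediction over the null model.

    The null model predicts no response at all (unperturbed control);
    ``error_reduction_pct = 100 * (WSSR_null - WSSR_sim) / WSSR_null``.
    """
    design = heldout_design if heldout_design is not None else model.design
    data = heldout_data.masked_like(design).with_error_floor(error_floor)
    sim = model.simulate(design)
    wssr_sim = wssr(data, sim)
    wssr_null = wssr(data, np.zeros_like(data.values))
    if wssr_null == 0:
        raise ValueError("held-out null WSSR is zero; no signal to explain")
    er = 100.0 * (wssr_null - wssr_sim) / wssr_null
    return ConsistencyResult(wssr_sim, wssr_null, er)


def split_by_stimulation(design: PerturbationDesign, data: PerturbationDataset):
    """Study-design split: stimulated conditions for training, unstimulated
    inhibitor conditions as the held-out consistency set."""
    train_rows = [i for i, c in enumerate(design.conditions) if c.stimulated]
    held_rows = [
        i
        for i, c in enumerate(design.conditions)
        if not c.stimulated and c.inhibited
    ]
    train = design.subset(lambda c: bool(c.stimulated))
    held = design.subset(lambda c: not c.stimulated and bool(c.inhibited))
    return (
        train,
        data.subset_rows(train_rows),
        held,
        data.subset_rows(held_rows),
    )


def adapt_network(
    start_network: SignalingNetwork,
    design: PerturbationDesign,
    train_data: PerturbationDataset,
    heldout_design: PerturbationDesign | None = None,
    heldout_data: PerturbationDataset | None = None,
    config: AdaptConfig | None = None,
) -> tuple[FitResult, AdaptationTrace]:
    """Iterative greedy structure adaptation (fit -> adapt -> consistency).

    Each iteration fits the current structure, scans removals first and
    additions second, and accepts the best-ranked candidate that (a) keeps
    the reduced chi-square from increasing and (b) keeps the held-out error
    reduction within ``delta_pct`` percentage points of the previous
    accepted step.  Stops when no candidate is accepted.
    """
    config = config or AdaptConfig()
    if (heldout_data is None) != (heldout_design is None):
        raise ValueError("provide heldout_design and heldout_data together")
    gate_consistency = heldout_data is not None
    if not gate_consistency:
        warnings.warn(
            "no held-out data: adaptation runs with the consistency gate disabled",
            stacklevel=2,
        )

    def consistency_of(model: MRAModel) -> float | None:
        if not gate_consistency:
            return None
        return consistency_check(
            model, heldout_data, heldout_design, config.error_floor
        ).error_reduction_pct

    current = fit_model(start_network, design, train_data, config=config.fit_config)
    prev_er = consistency_of(current.model)
    trace = AdaptationTrace()

    for _ in range(config.max_iterations):
        candidates = scan_removals(current, train_data, config) + scan_additions(
            current, train_data, config
        )
        accepted = None
        for cand in candidates:
            er = consistency_of(cand.fit.model)
            # "better or equally good fit with every network alteration":
            # an accepted change must not worsen the per-dof fit statistic
            ok_xr = cand.fit.reduced_chi_square <= current.reduced_chi_square + 1e-9
            ok_er = (
                True
                if (er is None or prev_er is None)
                else er >= prev_er - config.delta_pct
            )
            step = AdaptationStep(
                action=cand.action,
                edge=cand.edge,
                p_value=cand.p_value,
                delta_df=cand.delta_df,
                wssr_before=current.wssr_fit,
                wssr_after=cand.fit.wssr_fit,
                xr_before=current.reduced_chi_square,
                xr_after=cand.fit.reduced_chi_square,
                error_reduction_before=prev_er,
                error_reduction_after=er,
                accepted=bool(ok_xr and ok_er),
                reason="" if (ok_xr and ok_er) else
                ("fit statistic increased" if not ok_xr else "consistency dropped"),
            )
            trace.steps.append(step)
            if step.accepted:
                accepted = cand
                break
            logger.warning("rejected %s: %s", cand.name, step.reason)
        if accepted is None:
            break
        # every iteration starts from a fully converged fit of the new
        # structure: the scan fit is only a ranking device, and an
        # under-converged current optimum would inflate the next scan's
        # likelihood-ratio statistics
        model = accepted.fit.model
        try:
            current = fit_model(
                model.network,
                design,
                train_data,
                config=config.fit_config,
                param=model.param,
                theta0=model.param.theta_from_raw(model.raw),
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("post-acceptance refit failed: %s", exc)
            current = accepted.fit
        prev_er = consistency_of(current.model)
    return current, trace
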