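"""Ground-truth models and noisy synthetic perturbation datasets.

The generator emulates the B-cell-receptor perturbation experiments the
analysis is designed for: a literature-style starting network of BCR
signaling, 14 phospho-readouts, 8 kinase inhibitors applied with and
without alpha-IgM stimulation, log2 fold-change readouts as means of
replicate measurements with replicate noise, and masking of readouts whose
own node is inhibited (AKT and Btk inhibitors act on the readout site).

Edge coefficients are sampled log-uniformly in magnitude with configurable
signs, inhibitor strengths uniformly negative; replicates are generated
explicitly and averaged so that standard-error-based weighting is
exercised exactly as with real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import MRAModel
from .identifiability import derive_parametrisation
from .network import (
    Condition,
    PerturbationDataset,
    PerturbationDesign,
    SignalingNetwork,
)
from .simulator import SingularNetworkError, simulate_design

__all__ = [
    "GroundTruthConfig",
    "bcr_network",
    "bcr_design_fixture",
    "systematic_design",
    "random_network",
    "generate_ground_truth",
    "generate_dataset",
    "BCR_EDGES",
    "BCR_READOUTS",
    "BCR_INHIBITOR_TARGETS",
]


# ---------------------------------------------------------------------------
# the BCR literature fixture (representative, editable encoding)

# Literature-style starting wiring of BCR signaling.  Deliberately contains
# proximal redundancy around PI3K and couplings later found dispensable in
# Burkitt lymphoma cells, and none of the crosstalks the adaptation is
# meant to discover (mTORC1->JNK, GSK3->ZAP70, p38->RAF).
BCR_EDGES: tuple[tuple[str, str], ...] = (
    ("BCR", "SYK"),
    ("SYK", "ZAP70"),
    ("SYK", "Btk"),
    ("ZAP70", "Btk"),
    ("SYK", "PI3K"),
    ("Btk", "PI3K"),
    ("PI3K", "Btk"),
    ("PI3K", "AKT"),
    ("AKT", "mTORC1"),
    ("mTORC1", "RPS6"),
    ("p90RSK", "RPS6"),
    ("AKT", "BAD"),
    ("AKT", "GSK3"),
    ("ERK", "GSK3"),
    ("Btk", "RAF"),
    ("ERK", "RAF"),
    ("RAF", "MEK"),
    ("MEK", "ERK"),
    ("ERK", "p90RSK"),
    ("Btk", "JNK"),
    ("JNK", "cJun"),
    ("Btk", "IKK"),
    ("IKK", "NFkB"),
    ("Btk", "p38"),
    ("p38", "HSP27"),
)

# The ERK->RAF negative feedback is the one canonically inhibitory edge in
# the starting wiring; all other literature edges are activating.
BCR_EDGE_SIGNS: dict[tuple[str, str], float] = {("ERK", "RAF"): -1.0}

BCR_READOUTS: tuple[tuple[str, str], ...] = (
    ("SYK", "SYK"),
    ("ZAP70", "ZAP70"),
    ("Btk", "Btk"),
    ("AKT", "AKT"),
    ("RPS6", "RPS6"),
    ("BAD", "BAD"),
    ("ERK", "ERK"),
    ("MEK", "MEK"),
    ("p90RSK", "p90RSK"),
    ("GSK3", "GSK3"),
    ("NFkB-p65", "NFkB"),
    ("HSP27", "HSP27"),
    ("JNK", "JNK"),
    ("cJun", "cJun"),
)

BCR_INHIBITOR_TARGETS: tuple[str, ...] = (
    "JNK",
    "MEK",
    "PI3K",
    "Btk",
    "AKT",
    "mTORC1",
    "IKK",
    "p38",
)

# AKT and Btk inhibitors act on the measured phosphosite of their own
# target, so that readout is withheld whenever the inhibitor is applied.
BCR_MASKED: frozenset[tuple[str, str]] = frozenset(
    {("AKT", "AKT"), ("Btk", "Btk")}
)


def bcr_network() -> SignalingNetwork:
    """The packaged 20-node BCR literature starting network."""
    nodes: list[str] = []
    for s, t in BCR_EDGES:
        for n in (s, t):
            if n not in nodes:
                nodes.append(n)
    return SignalingNetwork(tuple(nodes), BCR_EDGES, frozenset({"BCR"}))


def bcr_design_fixture(variant: str = "bl") -> tuple[SignalingNetwork, PerturbationDesign]:
    """Network and perturbation design emulating the study layout.

    ``variant="bl"`` (Burkitt lymphoma): each of the 8 inhibitors with and
    without alpha-IgM stimulation plus the stimulation alone — 17
    conditions over 14 readouts.  ``variant="dlbcl"``: chronically active
    BCR signaling, inhibitors only, no stimulated condition.
    """
    network = bcr_network()
    conditions: list[Condition] = []
    if variant == "bl":
        conditions.append(Condition("aIgM", stimulated=frozenset({"BCR"})))
        for t in BCR_INHIBITOR_TARGETS:
            conditions.append(Condition(f"{t}i", inhibited=frozenset({t})))
            conditions.append(
                Condition(
                    f"{t}i+aIgM",
                    stimulated=frozenset({"BCR"}),
                    inhibited=frozenset({t}),
                )
            )
    elif variant == "dlbcl":
        for t in BCR_INHIBITOR_TARGETS:
            conditions.append(Condition(f"{t}i", inhibited=frozenset({t})))
    else:
        raise ValueError(f"unknown variant {variant!r} (expected 'bl' or 'dlbcl')")
    design = PerturbationDesign(tuple(conditions), BCR_READOUTS, BCR_MASKED)
    return network, design


# ---------------------------------------------------------------------------
# generic designs and random networks for simulation studies


def systematic_design(
    network: SignalingNetwork,
    inhibited=None,
    with_stimulation: bool = True,
    masked=frozenset(),
) -> PerturbationDesign:
    """Single-inhibitor design over a network: every inhibitor with and
    without each stimulus, plus each stimulus alone; every non-stimulus
    node measured under its own name."""
    inhibited = tuple(
        inhibited
        if inhibited is not None
        else [n for n in network.nodes if n not in network.stimuli]
    )
    stimuli = sorted(network.stimuli) if with_stimulation else []
    conditions: list[Condition] = []
    for s in stimuli:
        conditions.append(Condition(f"{s}", stimulated=frozenset({s})))
    for t in inhibited:
        conditions.append(Condition(f"{t}i", inhibited=frozenset({t})))
        for s in stimuli:
            conditions.append(
                Condition(
                    f"{t}i+{s}",
                    stimulated=frozenset({s}),
                    inhibited=frozenset({t}),
                )
            )
    measured = tuple(
        (n, n) for n in network.nodes if n not in network.stimuli
    )
    return PerturbationDesign(tuple(conditions), measured, frozenset(masked))


def random_network(
    n_nodes: int,
    n_extra_edges: int = 2,
    seed: int = 0,
    acyclic: bool = True,
    n_stimuli: int = 1,
) -> SignalingNetwork:
    """Random connected signaling network with one or more stimulus nodes.

    A random spanning arborescence rooted in the stimuli guarantees every
    node is reachable; ``n_extra_edges`` additional random edges are
    layered on top (forward-only when ``acyclic``)."""
    rng = np.random.default_rng(seed)
    stim = ["S"] if n_stimuli == 1 else [f"S{i}" for i in range(n_stimuli)]
    names = [f"N{i}" for i in range(n_nodes - n_stimuli)]
    nodes = stim + names
    edges: set[tuple[str, str]] = set()
    order = {n: i for i, n in enumerate(nodes)}
    for i, n in enumerate(names):
        parent = nodes[int(rng.integers(0, n_stimuli + i))]
        edges.add((parent, n))
    attempts = 0
    added = 0
    stimset = set(stim)
    while added < n_extra_edges and attempts < 200:
        attempts += 1
        s, t = rng.choice(nodes, size=2, replace=False)
        if t in stimset or (s, t) in edges:
            continue
        if acyclic and order[s] > order[t]:
            s, t = t, s
            if t in stimset or (s, t) in edges:
                continue
        edges.add((s, t))
        added += 1
    ordered = tuple(sorted(edges, key=lambda e: (order[e[0]], order[e[1]])))
    return SignalingNetwork(tuple(nodes), ordered, frozenset(stimset))


# ---------------------------------------------------------------------------
# ground truth and datasets


@dataclass(frozen=True)
class GroundTruthConfig:
    """Sampling ranges for ground-truth model coefficients.

    Edge magnitudes are log-uniform in ``mag_range`` (a typical edge
    neither heavily dampens nor amplifies); signs follow ``edge_signs``
    (defaulting to +1) or are random when ``sign_policy="random"``.
    Inhibitor strengths are uniform in ``l_range``.
    """

    mag_range: tuple[float, float] = (0.5, 2.0)
    sign_policy: str = "fixed"  # "fixed" (edge_signs, default +) | "random"
    edge_signs: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(BCR_EDGE_SIGNS)
    )
    l_range: tuple[float, float] = (-2.0, -0.5)
    max_resample: int = 50
    max_response: float = 1e3


def generate_ground_truth(
    network: SignalingNetwork,
    design: PerturbationDesign,
    config: GroundTruthConfig | None = None,
    seed: int = 0,
) -> MRAModel:
    """Sample a ground-truth model (full raw coefficients, no gauge).

    Deterministic under ``seed``.  Draws are rejected and resampled when a
    sampled feedback configuration makes some condition singular or wildly
    unstable; persistent failure raises.
    """
    config = config or GroundTruthConfig()
    param = derive_parametrisation(network, design)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(config.mag_range[0]), np.log(config.mag_range[1])
    for _ in range(config.max_resample):
        raw = np.empty(len(param.symbols))
        for j, sym in enumerate(param.symbols):
            if sym.kind == "r":
                mag = float(np.exp(rng.uniform(lo, hi)))
                if config.sign_policy == "random":
                    sign = float(rng.choice([-1.0, 1.0]))
                else:
                    sign = config.edge_signs.get((sym.source, sym.target), 1.0)
                raw[j] = sign * mag
            else:
                raw[j] = float(rng.uniform(*config.l_range))
        model = MRAModel(network, design, param, raw)
        try:
            sim = model.simulate()
        except SingularNetworkError:
            continue
        if np.nanmax(np.abs(sim)) <= config.max_response:
            return model
    raise SingularNetworkError(
        "could not sample a stable ground-truth model "
        f"after {config.max_resample} attempts"
    )


def generate_dataset(
    model: MRAModel,
    design: PerturbationDesign | None = None,
    noise_sd: float | np.ndarray = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    error_mode: str = "sem",
) -> PerturbationDataset:
    """Simulate a noisy perturbation dataset from a ground-truth model.

    Per cell, ``n_replicates`` replicate measurements are drawn with
    Gaussian noise (``noise_sd`` scalar or per-readout vector, log2 units)
    and averaged; the stored error is the sample standard error of the
    mean (``error_mode="sem"``, as estimated from real replicates) or the
    exact ``noise_sd/sqrt(n)`` (``error_mode="exact"``).  Masked cells are
    generated and then flagged missing.
    """
    design = design if design is not None else model.design
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 to estimate errors")
    if error_mode not in ("sem", "exact"):
        raise ValueError(f"unknown error_mode {error_mode!r}")
    rng = np.random.default_rng(seed)
    truth = model.simulate(design)
    sd = np.broadcast_to(
        np.asarray(noise_sd, dtype=float), (design.n_readouts,)
    ).astype(float)
    reps = truth[None, :, :] + rng.normal(
        0.0, 1.0, size=(n_replicates,) + truth.shape
    ) * sd[None, None, :]
    values = reps.mean(axis=0)
    if error_mode == "sem":
        errors = reps.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    else:
        errors = np.broadcast_to(
            sd[None, :] / np.sqrt(n_replicates), truth.shape
        ).copy()
    mask = ~np.isfinite(truth)
    values = np.where(mask, np.nan, values)
    errors = np.where(mask, np.nan, errors)
    return PerturbationDataset(values, errors, n_replicates)
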