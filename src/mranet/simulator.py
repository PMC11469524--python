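"""Steady-state response simulation for Modular Response Analysis models.

The global response of the network to a perturbation vector ``p`` is the
solution of the linear steady state ``R = -r^{-1} p`` where ``r`` is the
local response matrix (diagonal normalized to -1, ``r[i, j]`` the direct
effect of node ``j`` on node ``i``).  Model space is log2 fold change, the
same space as the data, so simulated responses are directly comparable to
measured log2 fold changes.

Inhibitors act twofold on the signal their target ``k`` *transmits* (never
on the target's own measured response): the transmitted signal becomes
``exp(l_k) * x_k + l_k`` with strength ``l_k < 0`` — a multiplicative
dampening ``exp(l_k)`` of the incoming (e.g. stimulated) signal plus a
negative basal offset ``l_k``.  Stimulated nodes receive a perturbation
entry of 1; their outgoing coefficients absorb the stimulation strength.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from .network import Condition, PerturbationDesign, SignalingNetwork

__all__ = [
    "SingularNetworkError",
    "build_local_response_matrix",
    "local_to_global",
    "simulate_condition",
    "simulate_design",
]


class SingularNetworkError(ValueError):
    """The effective local response matrix is singular (e.g. a feedback
    loop product equals 1), so no steady state exists."""


def build_local_response_matrix(
    network: SignalingNetwork, edge_values: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """Dense local response matrix with diagonal -1 and the network's sparsity.

    ``edge_values`` maps ``(source, target)`` to the local response
    coefficient of that edge; edges absent from the mapping raise.
    """
    n = len(network.nodes)
    idx = {node: i for i, node in enumerate(network.nodes)}
    r = -np.eye(n)
    for (s, t) in network.edges:
        r[idx[t], idx[s]] = edge_values[(s, t)]
    return r


def local_to_global(r: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Solve ``x = -r^{-1} p`` (the MRA global response relation)."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    try:
        cond_ok = np.isfinite(r).all()
        if not cond_ok:
            raise SingularNetworkError("non-finite local response matrix")
        x = np.linalg.solve(r, -p)
    except np.linalg.LinAlgError as exc:
        raise SingularNetworkError(
            f"singular local response matrix (det={np.linalg.det(r):g})"
        ) from exc
    return x


def simulate_condition(
    network: SignalingNetwork,
    r: np.ndarray,
    l_values: Mapping[str, float],
    condition: Condition,
) -> np.ndarray:
    """Steady-state node responses (log2 fold change) for one condition.

    Each stimulated node gets a perturbation entry of 1.  Each inhibited
    node ``k`` transmits ``exp(l_k) x_k + l_k`` to its targets: the
    effective coefficient into ``j`` becomes ``r[j,k] exp(l_k)`` and node
    ``j`` gains a constant input ``r[j,k] l_k``.  The inhibited node's own
    response is not directly altered.
    """
    n = len(network.nodes)
    idx = {node: i for i, node in enumerate(network.nodes)}
    a = np.array(r, dtype=float)
    b = np.zeros(n)
    for s in condition.stimulated:
        b[idx[s]] += 1.0
    for k in condition.inhibited:
        lk = l_values.get(k)
        if lk is None:
            raise KeyError(f"no inhibitor strength for inhibited node {k!r}")
        kk = idx[k]
        col = np.array(r[:, kk])
        col[kk] = 0.0  # diagonal untouched: inhibition acts on transmission only
        b += col * lk
        a[:, kk] = col * np.exp(lk)
        a[kk, kk] = r[kk, kk]
    try:
        x = np.linalg.solve(a, -b)
    except np.linalg.LinAlgError as exc:
        raise SingularNetworkError(
            f"singular effective response matrix in condition "
            f"{condition.condition_id!r}"
        ) from exc
    return x


def simulate_design(
    network: SignalingNetwork,
    r: np.ndarray,
    l_values: Mapping[str, float],
    design: PerturbationDesign,
) -> np.ndarray:
    """Predicted [condition x readout] log2 fold-change matrix.

    Node responses are projected onto the design's readouts; masked cells
    are returned as NaN.
    """
    idx = {node: i for i, node in enumerate(network.nodes)}
    ro_idx = [idx[node] for _, node in design.measured]
    out = np.empty((design.n_conditions, design.n_readouts))
    for i, cond in enumerate(design.conditions):
        x = simulate_condition(network, r, l_values, cond)
        out[i] = x[ro_idx]
    out[design.mask_matrix()] = np.nan
    return out
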