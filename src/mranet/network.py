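"""Domain types for signaling networks, perturbation designs and datasets.

A :class:`SignalingNetwork` is a directed graph whose nodes stand for the
measured phospho-signal of a protein (e.g. ``GSK3`` means pGSK3 S21/S9) and
whose edges carry signed local response coefficients.  External stimuli
(e.g. the BCR entry node activated by alpha-IgM) are explicit nodes without
incoming edges; their outgoing coefficients absorb the stimulation strength.

A :class:`PerturbationDesign` lists the experimental conditions (which
stimuli are applied, which nodes are inhibited), maps antibody readouts to
network nodes, and records readouts that must be masked whenever their own
node is inhibited (inhibitors that act on the readout site itself).

A :class:`PerturbationDataset` holds the measured log2 fold changes versus
solvent control together with per-cell standard errors.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "NetworkError",
    "DesignError",
    "SignalingNetwork",
    "Condition",
    "PerturbationDesign",
    "PerturbationDataset",
    "ValidationReport",
    "load_network",
    "write_network",
    "validate_design",
]


class NetworkError(ValueError):
    """Raised when a network violates a structural invariant."""


class DesignError(ValueError):
    """Raised when a design or dataset violates a structural invariant."""


@dataclass(frozen=True)
class SignalingNetwork:
    """Directed signaling network with declared stimulus nodes.

    Parameters
    ----------
    nodes
        Unique node names in a deterministic order (order of first
        appearance when loaded from an edge list).
    edges
        Ordered ``(source, target)`` pairs; no self-loops or duplicates.
    stimuli
        Subset of ``nodes`` representing external stimuli.  Stimulus nodes
        must not have incoming edges.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    stimuli: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple((s, t) for s, t in self.edges))
        object.__setattr__(self, "stimuli", frozenset(self.stimuli))
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node names")
        nodeset = set(self.nodes)
        seen = set()
        for s, t in self.edges:
            if s == t:
                raise NetworkError(f"self-loop on node {s!r}")
            if (s, t) in seen:
                raise NetworkError(f"duplicate edge {s}->{t}")
            seen.add((s, t))
            if s not in nodeset or t not in nodeset:
                raise NetworkError(f"edge {s}->{t} references undeclared node")
        for st in self.stimuli:
            if st not in nodeset:
                raise NetworkError(f"stimulus {st!r} is not a declared node")
        for s, t in self.edges:
            if t in self.stimuli:
                raise NetworkError(f"edge {s}->{t} points into stimulus node {t!r}")

    # -- basic accessors -------------------------------------------------
    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in set(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- structural edits (used by the greedy adaptation) ----------------
    def with_edge(self, source: str, target: str) -> "SignalingNetwork":
        return replace(self, edges=self.edges + ((source, target),))

    def without_edge(self, source: str, target: str) -> "SignalingNetwork":
        if (source, target) not in self.edges:
            raise NetworkError(f"edge {source}->{target} not in network")
        return replace(
            self, edges=tuple(e for e in self.edges if e != (source, target))
        )

    def topological_rank(self) -> dict[str, int]:
        """Deterministic node ordering compatible with the edge direction.

        Cycles are collapsed to their strongly connected components for the
        ordering; nodes inside a component keep their declaration order.
        Used only for canonical naming, never for numerics.
        """
        g = self.to_networkx()
        cond = nx.condensation(g)
        order: list[str] = []
        for comp in nx.topological_sort(cond):
            members = sorted(cond.nodes[comp]["members"], key=self.nodes.index)
            order.extend(members)
        return {n: i for i, n in enumerate(order)}


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a set of stimuli and a set of inhibited nodes."""

    condition_id: str
    stimulated: frozenset[str] = frozenset()
    inhibited: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "stimulated", frozenset(self.stimulated))
        object.__setattr__(self, "inhibited", frozenset(self.inhibited))

    @property
    def is_perturbed(self) -> bool:
        return bool(self.stimulated or self.inhibited)


@dataclass(frozen=True)
class PerturbationDesign:
    """Conditions, readout-to-node mapping and masking rules.

    ``measured`` maps each antibody readout name to one network node.
    ``masked`` contains ``(inhibited_node, readout_name)`` pairs whose cells
    are dropped in every condition where that node is inhibited.
    """

    conditions: tuple[Condition, ...]
    measured: tuple[tuple[str, str], ...]
    masked: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "measured", tuple(tuple(m) for m in self.measured))
        object.__setattr__(self, "masked", frozenset(tuple(m) for m in self.masked))
        names = [r for r, _ in self.measured]
        if len(set(names)) != len(names):
            raise DesignError("readout names are not unique")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise DesignError("condition ids are not unique")

    @property
    def readout_names(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.measured)

    @property
    def readout_nodes(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.measured)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_readouts(self) -> int:
        return len(self.measured)

    def inhibited_nodes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.conditions:
            for n in sorted(c.inhibited):
                if n not in seen:
                    seen.append(n)
        return tuple(seen)

    def stimulated_nodes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.conditions:
            for n in sorted(c.stimulated):
                if n not in seen:
                    seen.append(n)
        return tuple(seen)

    def mask_matrix(self) -> np.ndarray:
        """Boolean [condition x readout] matrix, True where the cell is masked."""
        mask = np.zeros((self.n_conditions, self.n_readouts), dtype=bool)
        ro_index = {r: j for j, r in enumerate(self.readout_names)}
        for i, cond in enumerate(self.conditions):
            for node, readout in self.masked:
                if node in cond.inhibited and readout in ro_index:
                    mask[i, ro_index[readout]] = True
        return mask

    def subset(self, predicate) -> "PerturbationDesign":
        """Design restricted to conditions satisfying ``predicate``."""
        keep = tuple(c for c in self.conditions if predicate(c))
        return replace(self, conditions=keep)


@dataclass
class PerturbationDataset:
    """Measured log2 fold changes (vs. control) with per-cell standard errors.

    Missing or masked cells are encoded as NaN in ``values``.  ``errors``
    must be strictly positive on every non-missing cell once the error
    floor has been applied.
    """

    values: np.ndarray
    errors: np.ndarray
    n_replicates: int = 3

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.values.shape != self.errors.shape:
            raise DesignError(
                f"values shape {self.values.shape} != errors shape {self.errors.shape}"
            )
        if self.values.ndim != 2:
            raise DesignError("values must be a [condition x readout] matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_error_floor(self, floor: float = 0.05) -> "PerturbationDataset":
        """Floor per-cell errors at ``floor`` log2 units (prevents infinite weights)."""
        errs = np.where(np.isfinite(self.errors), np.maximum(self.errors, floor), np.nan)
        obs = self.observed_mask()
        if np.any(obs & ~(errs > 0)):
            raise DesignError("non-positive error on an observed cell after flooring")
        return PerturbationDataset(self.values.copy(), errs, self.n_replicates)

    def masked_like(self, design: PerturbationDesign) -> "PerturbationDataset":
        """Copy with the design's masked cells set to NaN."""
        vals = self.values.copy()
        vals[design.mask_matrix()] = np.nan
        return PerturbationDataset(vals, self.errors.copy(), self.n_replicates)

    def subset_rows(self, rows) -> "PerturbationDataset":
        rows = list(rows)
        return PerturbationDataset(
            self.values[rows], self.errors[rows], self.n_replicates
        )


# ---------------------------------------------------------------------------
# loading / writing


def _open_text(source):
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        return open(source, "r", newline=""), True
    if isinstance(source, str):
        return io.StringIO(source), True
    return source, False


def load_network(source, stimuli=()) -> SignalingNetwork:
    """Read a network from a two-column ``source,target`` CSV.

    Lines of the form ``# stimuli: A,B`` preceding the header declare
    stimulus nodes; the ``stimuli`` argument adds to those.  Node order is
    the order of first appearance in the edge list.
    """
    fh, close = _open_text(source)
    try:
        stim = set(stimuli)
        rows = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("stimuli:"):
                    stim.update(
                        s.strip() for s in body.split(":", 1)[1].split(",") if s.strip()
                    )
                continue
            rows.append(line)
    finally:
        if close:
            fh.close()
    if not rows:
        raise NetworkError("empty network file")
    reader = csv.reader(rows)
    header = next(reader)
    if [h.strip().lower() for h in header[:2]] != ["source", "target"]:
        raise NetworkError(f"expected header 'source,target', got {header!r}")
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    for row in reader:
        if not row or not any(c.strip() for c in row):
            continue
        s, t = row[0].strip(), row[1].strip()
        edges.append((s, t))
        for n in (s, t):
            if n not in nodes:
                nodes.append(n)
    for st in sorted(stim):
        if st not in nodes:
            nodes.append(st)
    return SignalingNetwork(tuple(nodes), tuple(edges), frozenset(stim))


def write_network(network: SignalingNetwork, path_or_buf) -> None:
    """Write the edge list (with a stimulus declaration line) as CSV."""
    lines = []
    if network.stimuli:
        lines.append("# stimuli: " + ",".join(sorted(network.stimuli)))
    lines.append("source,target")
    lines.extend(f"{s},{t}" for s, t in network.edges)
    text = "\n".join(lines) + "\n"
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    n_conditions: int
    n_readouts: int
    perturbed_unmeasured: tuple[str, ...]
    measured_unperturbed: tuple[str, ...]
    n_masked_cells: int
    messages: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [f"{self.n_conditions} conditions x {self.n_readouts} readouts"]
        if self.perturbed_unmeasured:
            lines.append(
                "perturbed but unmeasured: " + ", ".join(self.perturbed_unmeasured)
            )
        if self.measured_unperturbed:
            lines.append(
                "measured but never perturbed directly: "
                + ", ".join(self.measured_unperturbed)
            )
        lines.append(f"masked cells: {self.n_masked_cells}")
        lines.extend(self.messages)
        return "\n".join(lines)


def validate_design(
    network: SignalingNetwork,
    design: PerturbationDesign,
    data: PerturbationDataset | None = None,
) -> ValidationReport:
    """Cross-check network, design and (optionally) data for conformability.

    Side-effect free; raises :class:`DesignError` on hard violations and
    returns a report of soft findings otherwise.
    """
    if not design.conditions:
        raise DesignError("design has no conditions")
    nodeset = set(network.nodes)
    for cond in design.conditions:
        if not cond.stimulated <= network.stimuli:
            raise DesignError(
                f"condition {cond.condition_id!r} stimulates non-stimulus node(s) "
                f"{sorted(cond.stimulated - network.stimuli)}"
            )
        if not cond.inhibited <= nodeset:
            raise DesignError(
                f"condition {cond.condition_id!r} inhibits unknown node(s) "
                f"{sorted(cond.inhibited - nodeset)}"
            )
    for readout, node in design.measured:
        if node not in nodeset:
            raise DesignError(f"readout {readout!r} maps to unknown node {node!r}")
    inhibited = set(design.inhibited_nodes())
    readouts = set(design.readout_names)
    for node, readout in design.masked:
        if node not in inhibited:
            raise DesignError(
                f"masked pair references {node!r} which is never inhibited"
            )
        if readout not in readouts:
            raise DesignError(f"masked pair references unknown readout {readout!r}")
    if data is not None:
        if data.shape != (design.n_conditions, design.n_readouts):
            raise DesignError(
                f"data shape {data.shape} does not match design "
                f"({design.n_conditions} conditions x {design.n_readouts} readouts)"
            )
    perturbed = inhibited | set(design.stimulated_nodes())
    measured_nodes = set(design.readout_nodes)
    report = ValidationReport(
        n_conditions=design.n_conditions,
        n_readouts=design.n_readouts,
        perturbed_unmeasured=tuple(sorted(perturbed - measured_nodes)),
        measured_unperturbed=tuple(sorted(measured_nodes - perturbed)),
        n_masked_cells=int(design.mask_matrix().sum()),
    )
    return report
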