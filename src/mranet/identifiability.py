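"""Structural identifiability analysis of an MRA model before fitting.

With an incomplete perturbation/measurement design, individual local
response coefficients are generally not identifiable — only certain
multiplicative combinations of them are.  Every steady-state response is a
rational function whose numerator terms are products of coefficients along
a simple perturbation-to-readout path (times the inhibitor strength when
the perturbation is an inhibition) and whose denominator terms are products
of vertex-disjoint simple cycles.  Collecting the exponent vectors of these
monomials and running exact Gaussian elimination over the rationals yields
a basis of identifiable parameter combinations, the *coefficient paths*.

The basis is rendered with canonical, human-readable names such as
``r_MEK_RAF*r_RAF_p38`` (``r_<target>_<source>`` per factor, inhibitor
strengths as ``i_<target>``), stable across runs and orderings.

Feedback loops make responses rational rather than polynomial, so the
symbolic count is cross-checked numerically: :func:`verify_rank` evaluates
the Jacobian of all simulated responses with respect to the log-magnitude
raw parameters at random points and compares its rank with the symbolic
path count.  On disagreement the numerical rank is authoritative for the
degrees-of-freedom bookkeeping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd, lcm

import networkx as nx
import numpy as np

from .network import PerturbationDesign, SignalingNetwork
from .simulator import SingularNetworkError, build_local_response_matrix, simulate_design

__all__ = [
    "Symbol",
    "CoefficientPath",
    "Parametrisation",
    "build_monomial_matrix",
    "reduce_to_identifiable_paths",
    "derive_parametrisation",
    "verify_rank",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Symbol:
    """A raw model parameter: an edge coefficient or an inhibitor strength.

    ``kind`` is ``"r"`` (local response coefficient of edge source->target)
    or ``"i"`` (inhibitor strength acting on ``target``; ``source`` equals
    ``target`` for uniformity).
    """

    kind: str
    target: str
    source: str

    @property
    def name(self) -> str:
        if self.kind == "r":
            return f"r_{self.target}_{self.source}"
        return f"i_{self.target}"

    @staticmethod
    def edge(source: str, target: str) -> "Symbol":
        return Symbol("r", target, source)

    @staticmethod
    def inhibitor(target: str) -> "Symbol":
        return Symbol("i", target, target)


@dataclass
class CoefficientPath:
    """One identifiable combination of raw parameters.

    ``exponents`` is an integer vector over the parametrisation's symbol
    list (primitive: gcd 1, pivot entry positive); ``pivot`` the column
    index of the leading symbol used as the free coordinate.
    """

    name: str
    exponents: tuple[int, ...]
    pivot: int
    value: float | None = None

    def support(self) -> tuple[int, ...]:
        return tuple(j for j, e in enumerate(self.exponents) if e != 0)


def _symbol_order(network: SignalingNetwork):
    """Canonical column order: edge coefficients (source-major topological
    order, then lexicographic), then inhibitor strengths."""
    rank = network.topological_rank()

    def key(sym: Symbol):
        return (
            0 if sym.kind == "r" else 1,
            rank.get(sym.source, len(rank)),
            sym.source,
            sym.target,
        )

    return key


def _collect_monomials(
    network: SignalingNetwork, design: PerturbationDesign
) -> tuple[list[tuple[tuple[int, ...], tuple[int, ...]]], list[Symbol], list[str]]:
    """Exponent vectors of all response monomials, with dampening factors.

    Each monomial is a pair ``(multiplicative, dampening)``: the first part
    holds integer exponents over the raw symbols (edge coefficients, and
    the inhibitor strength when the perturbation is an inhibition), the
    second the occurrences of ``exp(l_k)`` — the factor an inhibited node
    applies to the signal it relays — one column per inhibitor.
    """
    g = network.to_networkx()
    symbols: list[Symbol] = [Symbol.edge(s, t) for s, t in network.edges]
    inhibitors = list(design.inhibited_nodes())
    symbols += [Symbol.inhibitor(t) for t in inhibitors]
    symbols.sort(key=_symbol_order(network))
    col = {sym: j for j, sym in enumerate(symbols)}
    ecol = {t: j for j, t in enumerate(inhibitors)}

    rows: dict[tuple[tuple[int, ...], tuple[int, ...]], None] = {}
    reachable_readouts: set[str] = set()

    def add_monomial(edges, extra: Symbol | None, relaying, inhibited):
        vec = [0] * len(symbols)
        for s, t in edges:
            vec[col[Symbol.edge(s, t)]] += 1
        if extra is not None:
            vec[col[extra]] += 1
        evec = [0] * len(inhibitors)
        for n in relaying:
            if n in inhibited:
                evec[ecol[n]] += 1
        rows.setdefault((tuple(vec), tuple(evec)), None)

    path_cache: dict[tuple[str, str], list[list[str]]] = {}

    def simple_paths(src: str, dst: str) -> list[list[str]]:
        key = (src, dst)
        if key not in path_cache:
            if src == dst:
                path_cache[key] = []
            else:
                path_cache[key] = sorted(nx.all_simple_paths(g, src, dst))
        return path_cache[key]

    for cond in design.conditions:
        masked_here = {ro for node, ro in design.masked if node in cond.inhibited}
        inhibited = cond.inhibited
        for readout, node in design.measured:
            if readout in masked_here:
                continue
            for s in cond.stimulated:
                if s == node:
                    reachable_readouts.add(readout)  # trivial unit self-response
                    continue
                for path in simple_paths(s, node):
                    # every node before the readout relays the signal onward
                    add_monomial(
                        zip(path[:-1], path[1:]), None, path[:-1], inhibited
                    )
                    reachable_readouts.add(readout)
            for k in inhibited:
                if k == node:
                    continue  # inhibition never alters its target's own response
                for path in simple_paths(k, node):
                    # the basal offset l_k is injected directly into k's
                    # targets; only the downstream interior nodes relay
                    add_monomial(
                        zip(path[:-1], path[1:]),
                        Symbol.inhibitor(k),
                        path[1:-1],
                        inhibited,
                    )
                    reachable_readouts.add(readout)
        # simple cycles enter the determinant of every condition's
        # steady-state system; inhibited cycle nodes relay dampened signal
        if rows:
            for cycle in nx.simple_cycles(g):
                edges = list(zip(cycle, cycle[1:] + cycle[:1]))
                add_monomial(edges, None, cycle, inhibited)

    unreachable = [r for r in design.readout_names if r not in reachable_readouts]
    if unreachable:
        warnings.warn(
            "readouts unreachable from every perturbation (responses are "
            "structurally zero): " + ", ".join(unreachable),
            stacklevel=2,
        )
    return sorted(rows), symbols, inhibitors


def build_monomial_matrix(
    network: SignalingNetwork, design: PerturbationDesign
) -> tuple[np.ndarray, list[Symbol]]:
    """Integer exponent matrix of the response monomials.

    Rows are the deduplicated multiplicative exponent vectors of (a) every
    simple path from a perturbed node to a measured, unmasked readout in
    some condition (inhibitions contribute their ``i_<target>`` factor)
    and (b) every simple cycle of the network (cycle products enter the
    determinant of the steady-state system).  Columns are raw symbols in
    canonical order.

    Readout nodes unreachable from every perturbation are reported with a
    warning; their predicted responses are structurally zero.
    """
    rows, symbols, _ = _collect_monomials(network, design)
    dedup = sorted({mult for mult, _damp in rows})
    matrix = np.array(dedup, dtype=int).reshape(len(dedup), len(symbols))
    return matrix, symbols


def _generic_rank(
    rows: list[tuple[tuple[int, ...], tuple[int, ...]]],
    symbols: list[Symbol],
    inhibitors: list[str],
) -> int:
    """Identifiable parameter count including the dampening action.

    The log of a monomial is linear in log|r|, log|l| and (through the
    relay factors exp(l)) in l itself, so the column of inhibitor k in the
    parameter Jacobian is the multiplicative exponent plus l_k times the
    dampening exponent.  The generic rank of that pencil is evaluated
    exactly over the rationals at fixed non-special values of l; two
    distinct value sets are used and the larger rank kept.
    """
    if not rows:
        return 0
    icol = {t: j for j, sym in enumerate(symbols) if sym.kind == "i" for t in [sym.target]}
    best = 0
    for salt in (0, 1):
        lam = {
            t: Fraction(104729 + 7919 * (k + 1) + 13 * salt, 99991 + 101 * salt)
            for k, t in enumerate(inhibitors)
        }
        folded = []
        for mult, damp in rows:
            row = [Fraction(x) for x in mult]
            for k, t in enumerate(inhibitors):
                if damp[k]:
                    row[icol[t]] += lam[t] * damp[k]
            folded.append(row)
        basis, _ = _rref_rows(folded)
        best = max(best, len(basis))
    return best


def _rref(matrix: np.ndarray) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form of an integer matrix over exact rationals."""
    rows = [[Fraction(int(x)) for x in row] for row in matrix]
    return _rref_rows(rows)


def _rref_rows(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form over exact rationals.

    Pivot rows are chosen among candidates with the fewest non-zero
    entries (shortest monomials), keeping path names human-readable and
    the reduction deterministic.
    """
    n_cols = len(rows[0]) if rows else 0
    basis: list[list[Fraction]] = []
    pivots: list[int] = []
    remaining = rows
    for c in range(n_cols):
        cands = [r for r in remaining if r[c] != 0]
        if not cands:
            continue
        cands.sort(key=lambda r: (sum(1 for x in r if x != 0), r))
        piv = cands[0]
        remaining = [r for r in remaining if r is not piv]
        inv = Fraction(1) / piv[c]
        piv = [x * inv for x in piv]
        for r in remaining:
            if r[c] != 0:
                f = r[c]
                for j in range(c, n_cols):
                    r[j] -= f * piv[j]
        for b in basis:
            if b[c] != 0:
                f = b[c]
                for j in range(n_cols):
                    b[j] -= f * piv[j]
        basis.append(piv)
        pivots.append(c)
    return basis, pivots


def _primitive_int_row(row: list[Fraction], pivot: int) -> tuple[int, ...]:
    mult = lcm(*[f.denominator for f in row]) if row else 1
    ints = [int(f * mult) for f in row]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    if ints[pivot] < 0:
        ints = [-x for x in ints]
    return tuple(ints)


def path_name(
    exponents, symbols: list[Symbol], network: SignalingNetwork
) -> str:
    """Canonical name: factors ordered by topological order of the source
    node then lexicographically; exponents other than 1 rendered ``^e``."""
    rank = network.topological_rank()
    factors = []
    for j, e in enumerate(exponents):
        if e == 0:
            continue
        sym = symbols[j]
        key = (rank.get(sym.source, len(rank)), sym.source, sym.target, sym.kind)
        txt = sym.name if e == 1 else f"{sym.name}^{e}"
        factors.append((key, txt))
    return "*".join(txt for _, txt in sorted(factors))


def reduce_to_identifiable_paths(
    matrix: np.ndarray,
    symbols: list[Symbol],
    network: SignalingNetwork,
) -> list[CoefficientPath]:
    """Basis of identifiable coefficient paths by exact Gaussian elimination.

    The number of paths equals the rank of the monomial matrix; an all-zero
    (or empty) matrix yields an empty basis.
    """
    if matrix.size == 0:
        return []
    basis, pivots = _rref(matrix)
    paths = []
    for row, piv in zip(basis, pivots):
        ints = _primitive_int_row(row, piv)
        paths.append(
            CoefficientPath(
                name=path_name(ints, symbols, network),
                exponents=ints,
                pivot=piv,
            )
        )
    return paths


@dataclass
class Parametrisation:
    """Identifiable parameterization of a network + design.

    Free coordinates are the pivot edge coefficients (one per coefficient
    path whose pivot is an ``r`` symbol) plus every inhibitor strength that
    appears in some monomial.  All non-pivot edge coefficients are
    gauge-fixed to 1; they carry no identifiable information of their own.
    """

    network: SignalingNetwork
    design: PerturbationDesign
    symbols: list[Symbol]
    matrix: np.ndarray
    paths: list[CoefficientPath]
    ext_rows: list[tuple[tuple[int, ...], tuple[int, ...]]] = field(
        default_factory=list
    )
    inhibitor_order: list[str] = field(default_factory=list)
    rank: int | None = None
    rank_symbolic: int | None = None
    free_r: list[int] = field(init=False)
    free_l: list[int] = field(init=False)

    def __post_init__(self):
        pivots = {p.pivot for p in self.paths}
        self.free_r = sorted(
            j for j in pivots if self.symbols[j].kind == "r"
        )
        active = set(np.flatnonzero(np.any(self.matrix != 0, axis=0))) if self.matrix.size else set()
        damped = {
            t
            for _mult, damp in self.ext_rows
            for k, t in enumerate(self.inhibitor_order)
            if damp[k]
        }
        self.free_l = sorted(
            j
            for j, sym in enumerate(self.symbols)
            if sym.kind == "i" and (j in active or sym.target in damped)
        )
        if self.rank is None:
            self.rank = len(self.paths)
        if self.rank_symbolic is None:
            self.rank_symbolic = self.rank

    # -- bookkeeping -----------------------------------------------------
    @property
    def n_identifiable(self) -> int:
        """Identifiable parameter count (degrees of freedom of the model).

        Set to the symbolic generic rank of the monomial analysis, unless
        the numerical Jacobian rank disagrees — additive degeneracies
        (parallel routes from a never-separately-perturbed intermediate)
        are invisible to any multiplicative exponent analysis, so the
        numerical rank is authoritative.
        """
        return self.rank

    @property
    def n_theta(self) -> int:
        return len(self.free_r) + len(self.free_l)

    @property
    def theta_names(self) -> list[str]:
        return [self.symbols[j].name for j in self.free_r + self.free_l]

    def l_theta_slice(self) -> slice:
        return slice(len(self.free_r), self.n_theta)

    def symbol_index(self, name: str) -> int:
        for j, sym in enumerate(self.symbols):
            if sym.name == name:
                return j
        raise KeyError(name)

    # -- raw parameter vector --------------------------------------------
    def default_raw(self) -> np.ndarray:
        """Gauge values: 1 for every edge coefficient, -1 for inhibitors."""
        return np.array(
            [1.0 if s.kind == "r" else -1.0 for s in self.symbols], dtype=float
        )

    def raw_from_theta(self, theta: np.ndarray) -> np.ndarray:
        raw = self.default_raw()
        for i, j in enumerate(self.free_r):
            raw[j] = theta[i]
        off = len(self.free_r)
        for i, j in enumerate(self.free_l):
            raw[j] = theta[off + i]
        return raw

    def theta_from_raw(self, raw: np.ndarray) -> np.ndarray:
        return np.array(
            [raw[j] for j in self.free_r] + [raw[j] for j in self.free_l]
        )

    def edge_values(self, raw: np.ndarray) -> dict[tuple[str, str], float]:
        return {
            (s.source, s.target): raw[j]
            for j, s in enumerate(self.symbols)
            if s.kind == "r"
        }

    def l_values(self, raw: np.ndarray) -> dict[str, float]:
        return {
            s.target: raw[j] for j, s in enumerate(self.symbols) if s.kind == "i"
        }

    # -- path values -----------------------------------------------------
    def path_value(self, path: CoefficientPath, raw: np.ndarray) -> float:
        v = 1.0
        for j in path.support():
            v *= float(raw[j]) ** int(path.exponents[j])
        return v

    def path_values(self, raw: np.ndarray) -> dict[str, float]:
        return {p.name: self.path_value(p, raw) for p in self.paths}

    def find_path(self, name: str) -> CoefficientPath:
        for p in self.paths:
            if p.name == name:
                return p
        raise KeyError(f"no coefficient path named {name!r}")

    def rank_excluding(self, symbol_names) -> int:
        """Identifiable count once the named parameters are fixed.

        Fixing a parameter removes its column (for inhibitors both the
        multiplicative and the relay-dampening occurrence) from the
        Jacobian before the rank is taken; as for the full rank, a
        numerical disagreement overrides the symbolic count.
        """
        symbol_names = list(symbol_names)
        sym_rank = self._symbolic_rank_excluding(symbol_names)
        num_rank = numeric_rank(self, exclude=symbol_names)
        if num_rank != sym_rank:
            logger.info(
                "identifiable count with %s fixed: symbolic %d, numerical %d "
                "(numerical kept)",
                symbol_names,
                sym_rank,
                num_rank,
            )
        return num_rank

    def _symbolic_rank_excluding(self, symbol_names) -> int:
        drop = {self.symbol_index(n) for n in symbol_names}
        dropped_inhibitors = {
            self.symbols[j].target for j in drop if self.symbols[j].kind == "i"
        }
        keep = [j for j in range(len(self.symbols)) if j not in drop]
        keep_symbols = [self.symbols[j] for j in keep]
        keep_inhib = [t for t in self.inhibitor_order if t not in dropped_inhibitors]
        ecol = {t: k for k, t in enumerate(self.inhibitor_order)}
        sub_rows = []
        for mult, damp in self.ext_rows:
            sub_rows.append(
                (
                    tuple(mult[j] for j in keep),
                    tuple(damp[ecol[t]] for t in keep_inhib),
                )
            )
        if not sub_rows:
            return 0
        return _generic_rank(sorted(set(sub_rows)), keep_symbols, keep_inhib)


def derive_parametrisation(
    network: SignalingNetwork,
    design: PerturbationDesign,
    numeric_dof: bool = True,
) -> Parametrisation:
    """Full identifiability analysis: monomials, exact elimination, paths.

    With ``numeric_dof`` (default) the symbolic identifiable count is
    cross-checked against the numerical Jacobian rank and replaced by it
    on disagreement (the symbolic analysis cannot see additive
    degeneracies between parallel routes).
    """
    ext_rows, symbols, inhibitors = _collect_monomials(network, design)
    dedup = sorted({mult for mult, _damp in ext_rows})
    matrix = np.array(dedup, dtype=int).reshape(len(dedup), len(symbols))
    paths = reduce_to_identifiable_paths(matrix, symbols, network)
    rank_sym = _generic_rank(ext_rows, symbols, inhibitors)
    param = Parametrisation(
        network,
        design,
        symbols,
        matrix,
        paths,
        ext_rows=ext_rows,
        inhibitor_order=inhibitors,
        rank=rank_sym,
        rank_symbolic=rank_sym,
    )
    if numeric_dof and matrix.size:
        rank_num = numeric_rank(param)
        if rank_num != rank_sym:
            logger.info(
                "identifiable count: symbolic %d vs numerical %d (numerical kept)",
                rank_sym,
                rank_num,
            )
            param.rank = rank_num
    return param


# ---------------------------------------------------------------------------
# numerical cross-check


def _response_vector(param: Parametrisation, raw: np.ndarray) -> np.ndarray:
    r = build_local_response_matrix(param.network, param.edge_values(raw))
    sim = simulate_design(param.network, r, param.l_values(raw), param.design)
    return sim[np.isfinite(sim)]


def _sample_point(param: Parametrisation, seed: int) -> np.ndarray:
    """Random raw parameter point with moderate magnitudes (rejecting
    singular feedback configurations)."""
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        raw = np.empty(len(param.symbols))
        for j, sym in enumerate(param.symbols):
            if sym.kind == "r":
                raw[j] = rng.choice([-1.0, 1.0]) * np.exp(
                    rng.uniform(np.log(0.3), np.log(2.0))
                )
            else:
                raw[j] = -np.exp(rng.uniform(np.log(0.3), np.log(2.0)))
        try:
            _response_vector(param, raw)
        except SingularNetworkError:
            continue
        return raw
    raise SingularNetworkError("could not sample an invertible model")


def _jacobian_rank(
    param: Parametrisation,
    raw: np.ndarray,
    columns,
    svd_rtol: float,
) -> int:
    """Rank of d(responses)/d(log-magnitude raw parameters) at ``raw``."""
    h = 1e-6
    cols = []
    for j in columns:
        step = np.zeros_like(raw)
        step[j] = raw[j] * h  # d/d log|theta_j|
        fp = _response_vector(param, raw + step)
        fm = _response_vector(param, raw - step)
        cols.append((fp - fm) / (2 * h))
    if not cols:
        return 0
    jac = np.column_stack(cols)
    sv = np.linalg.svd(jac, compute_uv=False)
    if sv.size == 0 or sv[0] <= 0:
        return 0
    return int(np.sum(sv > svd_rtol * sv[0]))


def numeric_rank(
    param: Parametrisation,
    exclude=(),
    seeds=(0, 1),
    svd_rtol: float = 1e-8,
) -> int:
    """Numerical Jacobian rank of the response map, maximized over seeds.

    The rank at a random parameter point equals the generic rank almost
    surely, and special points can only lower it, so the maximum over
    sampled points is the authoritative identifiable-parameter count.
    ``exclude`` names raw symbols held fixed (their columns dropped).
    """
    drop = {param.symbol_index(n) for n in exclude}
    columns = [j for j in range(len(param.symbols)) if j not in drop]
    best = 0
    for seed in seeds:
        raw = _sample_point(param, seed)
        best = max(best, _jacobian_rank(param, raw, columns, svd_rtol))
    return best


def verify_rank(
    network: SignalingNetwork,
    design: PerturbationDesign,
    paths: list[CoefficientPath] | Parametrisation,
    seeds=(0, 1),
    svd_rtol: float = 1e-8,
) -> bool:
    """Check the symbolic path count against the numerical Jacobian rank.

    Simulated responses are differentiated with respect to the
    log-magnitude of every raw parameter (signs held fixed, inhibitor
    strengths via log(-l)) at one random parameter point per seed.  Returns
    True iff the numerical rank (singular values above ``svd_rtol`` times
    the largest) equals the symbolic path count at every point.
    """
    if isinstance(paths, Parametrisation):
        param = paths
        n_paths = param.rank_symbolic
    else:
        param = derive_parametrisation(network, design, numeric_dof=False)
        n_paths = len(paths)
    all_cols = range(len(param.symbols))
    ok = True
    for seed in seeds:
        raw = _sample_point(param, seed)
        rank = _jacobian_rank(param, raw, all_cols, svd_rtol)
        if rank != n_paths:
            logger.warning(
                "identifiability mismatch at seed %s: symbolic %d vs numerical %d",
                seed,
                n_paths,
                rank,
            )
            ok = False
    return ok
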