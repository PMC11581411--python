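"""Linear structural equation models over causal diagrams with correlated errors.

This module is the identification layer of the package.  A causal diagram is
a directed acyclic graph (DAG) of direct effects, augmented with bidirected
edges representing covariances between error terms (unmodelled confounding,
or linkage disequilibrium between genetic variants).  The diagram defines a
linear SEM

    X_i = sum_j c_ij X_j + U_i,      Cov(U_i, U_j) = Psi_ij,

whose implied covariance matrix is Sigma = (I - C)^-1 Psi (I - C^T)^-1.

Three classical results are implemented:

* the path-tracing rule: for standardized variables, the covariance of two
  nodes equals the sum over unblocked (collider-free) simple paths of the
  product of edge parameters along each path;
* marginal d-separation: two nodes are d-separated iff no unblocked path
  connects them, in which case their model covariance vanishes;
* the instrumental-set criterion of Brito and Pearl, under which K
  instruments jointly identify the direct effects of K exposures on an
  outcome even when the instruments are mutually correlated, via the linear
  system Sigma_EX c = Sigma_EY.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "CausalGraph",
    "LinearSEM",
    "PathCertificate",
    "Refusal",
    "IdentificationError",
    "UnderdeterminedError",
    "PathExplosionError",
    "implied_covariance",
    "wright_path_sum",
    "d_separated",
    "check_instrumental_set",
    "identify_effects",
    "build_mvmr_sem",
    "random_standardized_sem",
]

# node roles used by the MVMR construction helpers; plain nodes are allowed
ROLE_INSTRUMENT = "instrument"
ROLE_EXPOSURE = "exposure"
ROLE_OUTCOME = "outcome"

DEFAULT_MAX_PATHS = 100_000


class IdentificationError(RuntimeError):
    """Raised when causal effects cannot be identified from the model."""


class UnderdeterminedError(IdentificationError):
    """Raised when the instrument-exposure covariance matrix is rank deficient."""


class PathExplosionError(RuntimeError):
    """Raised when path enumeration exceeds the configured path limit."""


class GraphInputError(ValueError):
    """Raised for malformed graph input (unknown nodes, duplicate edges...)."""


class CausalGraph:
    """Mixed graph of directed (causal) and bidirected (covariance) edges.

    Directed edges carry a path coefficient, bidirected edges an error
    covariance, and every node carries an error variance (default 1).
    """

    def __init__(self) -> None:
        self._roles: dict[str, str | None] = {}
        self._error_variance: dict[str, float] = {}
        self._directed: dict[tuple[str, str], float] = {}
        self._bidirected: dict[tuple[str, str], float] = {}

    # -- construction ---------------------------------------------------
    def add_node(self, name: str, role: str | None = None, error_variance: float = 1.0):
        if name in self._roles:
            raise GraphInputError(f"duplicate node {name!r}")
        self._roles[name] = role
        self._error_variance[name] = float(error_variance)
        return self

    def add_edge(self, src: str, dst: str, coefficient: float):
        """Add the directed edge ``src -> dst`` with the given path coefficient."""
        self._require(src)
        self._require(dst)
        if (src, dst) in self._directed:
            raise GraphInputError(f"duplicate edge {src}->{dst}")
        self._directed[(src, dst)] = float(coefficient)
        return self

    def add_bidirected(self, a: str, b: str, covariance: float):
        """Add the bidirected edge ``a <-> b`` (error covariance)."""
        self._require(a)
        self._require(b)
        key = (min(a, b), max(a, b))
        if key in self._bidirected:
            raise GraphInputError(f"duplicate bidirected edge {a}<->{b}")
        self._bidirected[key] = float(covariance)
        return self

    def _require(self, name: str) -> None:
        if name not in self._roles:
            raise GraphInputError(f"unknown node {name!r}")

    # -- views -----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._roles)

    @property
    def directed_edges(self) -> dict[tuple[str, str], float]:
        return dict(self._directed)

    @property
    def bidirected_edges(self) -> dict[tuple[str, str], float]:
        return dict(self._bidirected)

    def role(self, name: str) -> str | None:
        self._require(name)
        return self._roles[name]

    def nodes_with_role(self, role: str) -> list[str]:
        return [n for n, r in self._roles.items() if r == role]

    def error_variance(self, name: str) -> float:
        self._require(name)
        return self._error_variance[name]

    # -- structure -------------------------------------------------------
    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._roles)
        g.add_edges_from(self._directed)
        return g

    def validate_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self._digraph()):
            raise GraphInputError("directed part of the causal diagram is cyclic")

    def topological_order(self) -> list[str]:
        self.validate_acyclic()
        # stable: break ties by insertion order
        order_index = {n: i for i, n in enumerate(self._roles)}
        return list(
            nx.lexicographical_topological_sort(self._digraph(), key=order_index.get)
        )

    def descendants(self, node: str) -> set[str]:
        self._require(node)
        return nx.descendants(self._digraph(), node)

    def without_directed_edges(self, edges) -> "CausalGraph":
        """Copy of the graph with the listed directed edges removed."""
        out = CausalGraph()
        out._roles = dict(self._roles)
        out._error_variance = dict(self._error_variance)
        drop = set(edges)
        out._directed = {e: v for e, v in self._directed.items() if e not in drop}
        out._bidirected = dict(self._bidirected)
        return out

    def copy(self) -> "CausalGraph":
        return self.without_directed_edges([])

    # -- SEM conversion ---------------------------------------------------
    def to_sem(self) -> "LinearSEM":
        order = self.topological_order()
        idx = {n: i for i, n in enumerate(order)}
        p = len(order)
        C = np.zeros((p, p))
        for (src, dst), coef in self._directed.items():
            C[idx[dst], idx[src]] = coef
        Psi = np.zeros((p, p))
        for n, v in self._error_variance.items():
            Psi[idx[n], idx[n]] = v
        for (a, b), cov in self._bidirected.items():
            Psi[idx[a], idx[b]] = cov
            Psi[idx[b], idx[a]] = cov
        return LinearSEM(C=C, Psi=Psi, node_order=order)

    # -- serialization ----------------------------------------------------
    def to_edgelist(self) -> str:
        """Edge-list text: one line per node/edge.

        ``node <name> [role] [error_variance]`` lines declare nodes, then
        ``src -> dst parameter`` and ``a <-> b parameter`` lines declare edges.
        """
        lines = []
        for n, r in self._roles.items():
            lines.append(f"node\t{n}\t{r or '.'}\t{self._error_variance[n]!r}")
        for (s, d), v in self._directed.items():
            lines.append(f"{s}\t->\t{d}\t{v!r}")
        for (a, b), v in self._bidirected.items():
            lines.append(f"{a}\t<->\t{b}\t{v!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edgelist(cls, text: str) -> "CausalGraph":
        g = cls()
        for ln, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "node":
                if len(parts) < 2:
                    raise GraphInputError(f"line {ln}: malformed node line")
                role = None if len(parts) < 3 or parts[2] == "." else parts[2]
                ev = float(parts[3]) if len(parts) > 3 else 1.0
                g.add_node(parts[1], role=role, error_variance=ev)
            elif len(parts) == 4 and parts[1] in ("->", "<->"):
                src, kind, dst, param = parts
                for n in (src, dst):
                    if n not in g._roles:
                        g.add_node(n)
                if kind == "->":
                    g.add_edge(src, dst, float(param))
                else:
                    g.add_bidirected(src, dst, float(param))
            else:
                raise GraphInputError(f"line {ln}: cannot parse {raw!r}")
        return g

    # -- adjacency for path walking ---------------------------------------
    def _adjacency(self):
        """For each node a list of traversal options.

        Each option is ``(neighbor, head_at_self, head_at_neighbor, param)``
        where the head flags say on which endpoints the edge carries an
        arrowhead.  A bidirected edge has heads at both ends.
        """
        adj: dict[str, list[tuple[str, bool, bool, float]]] = {
            n: [] for n in self._roles
        }
        for (src, dst), coef in self._directed.items():
            adj[src].append((dst, False, True, coef))
            adj[dst].append((src, True, False, coef))
        for (a, b), cov in self._bidirected.items():
            adj[a].append((b, True, True, cov))
            adj[b].append((a, True, True, cov))
        return adj


@dataclass
class LinearSEM:
    """Coefficient matrix ``C`` (row = child) and error covariance ``Psi``.

    ``C[i, j]`` is the direct effect of node ``j`` on node ``i`` in
    ``node_order``; the directed part must be acyclic and ``Psi`` symmetric
    positive semi-definite.
    """

    C: np.ndarray
    Psi: np.ndarray
    node_order: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        p = len(self.node_order)
        if self.C.shape != (p, p) or self.Psi.shape != (p, p):
            raise GraphInputError("C/Psi dimensions do not match node_order")
        if not np.allclose(self.Psi, self.Psi.T, atol=1e-10):
            raise GraphInputError("Psi must be symmetric")
        w = np.linalg.eigvalsh(self.Psi)
        scale = max(abs(w).max(), 1.0)
        if w.min() < -1e-10 * scale:
            raise GraphInputError("Psi must be positive semi-definite")
        g = nx.DiGraph(
            [(j, i) for i in range(p) for j in range(p) if self.C[i, j] != 0.0]
        )
        g.add_nodes_from(range(p))
        if not nx.is_directed_acyclic_graph(g):
            raise GraphInputError("coefficient matrix C encodes a cyclic graph")

    def index(self, name: str) -> int:
        return self.node_order.index(name)

    def to_graph(self, roles: dict[str, str] | None = None) -> CausalGraph:
        g = CausalGraph()
        roles = roles or {}
        for i, n in enumerate(self.node_order):
            g.add_node(n, role=roles.get(n), error_variance=self.Psi[i, i])
        p = len(self.node_order)
        for i in range(p):
            for j in range(p):
                if self.C[i, j] != 0.0:
                    g.add_edge(self.node_order[j], self.node_order[i], self.C[i, j])
        for i in range(p):
            for j in range(i + 1, p):
                if self.Psi[i, j] != 0.0:
                    g.add_bidirected(
                        self.node_order[i], self.node_order[j], self.Psi[i, j]
                    )
        return g


def implied_covariance(sem: LinearSEM) -> np.ndarray:
    """Model-implied covariance matrix ``(I - C)^-1 Psi (I - C^T)^-1``."""
    p = sem.C.shape[0]
    A = np.eye(p) - sem.C
    try:
        M = np.linalg.solve(A, sem.Psi)
        Sigma = np.linalg.solve(A, M.T).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - acyclic C is safe
        raise IdentificationError("(I - C) is singular") from exc
    return (Sigma + Sigma.T) / 2.0


# ---------------------------------------------------------------------------
# path enumeration


def _iter_unblocked_paths(graph: CausalGraph, a: str, b: str, max_paths: int):
    """Yield unblocked simple paths from ``a`` to ``b``.

    A path is a list of steps ``(u, v, head_at_u, head_at_v, param)`` in
    traversal order; it is unblocked when no intermediate node is a collider
    (two arrowheads meeting at the node).
    """
    graph._require(a)
    graph._require(b)
    adj = graph._adjacency()
    count = 0

    # DFS over (current node, arrowhead-at-current-from-previous-step);
    # recursion is fine, graphs here are small
    def dfs(cur, head_into_cur, steps, visited):
        nonlocal count
        if cur == b and steps:
            count += 1
            if count > max_paths:
                raise PathExplosionError(
                    f"more than {max_paths} unblocked paths between {a} and {b}"
                )
            yield list(steps)
            return
        for nbr, head_at_cur, head_at_nbr, param in adj[cur]:
            if nbr in visited:
                continue
            if head_into_cur is not None and head_into_cur and head_at_cur:
                continue  # collider at cur
            steps.append((cur, nbr, head_at_cur, head_at_nbr, param))
            visited.add(nbr)
            yield from dfs(nbr, head_at_nbr, steps, visited)
            visited.remove(nbr)
            steps.pop()

    yield from dfs(a, None, [], {a})


def _path_root(steps) -> str | None:
    """Node without arrowheads along the path, or None for a bidirected top."""
    if any(hu and hv for (_, _, hu, hv, _) in steps):
        return None  # path runs through a bidirected edge; covariance is its top
    heads: dict[str, bool] = {}
    for u, v, hu, hv, _ in steps:
        heads[u] = heads.get(u, False) or hu
        heads[v] = heads.get(v, False) or hv
    roots = [n for n, h in heads.items() if not h]
    if len(roots) != 1:  # pragma: no cover - impossible on collider-free paths
        raise RuntimeError("collider-free path must have exactly one root")
    return roots[0]


def wright_path_sum(
    graph: CausalGraph,
    a: str,
    b: str,
    node_variances: dict[str, float] | None = None,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> float:
    """Covariance of ``a`` and ``b`` by the path-tracing rule.

    Sums, over all unblocked simple paths, the product of edge parameters.
    For standardized variables (unit variances, the default) this equals the
    model covariance.  For unstandardized variables pass ``node_variances``:
    each path is multiplied by the variance of its root node (the unique node
    with no arrowhead on the path); paths through a bidirected edge carry the
    error covariance instead and need no root correction.
    """
    graph.validate_acyclic()
    if a == b:
        raise GraphInputError("path sum is defined for distinct nodes")
    total = 0.0
    for steps in _iter_unblocked_paths(graph, a, b, max_paths):
        t = 1.0
        for _, _, _, _, param in steps:
            t *= param
        if node_variances is not None:
            root = _path_root(steps)
            if root is not None:
                t *= node_variances[root]
        total += t
    return total


def d_separated(graph: CausalGraph, a: str, b: str) -> bool:
    """True iff no unblocked (collider-free) path connects ``a`` and ``b``."""
    graph.validate_acyclic()
    if a == b:
        raise GraphInputError("d-separation is defined for distinct nodes")
    for _ in _iter_unblocked_paths(graph, a, b, DEFAULT_MAX_PATHS):
        return False
    return True


# ---------------------------------------------------------------------------
# instrumental sets


@dataclass(frozen=True)
class PathCertificate:
    """Witness that an instrument set satisfies the three graphical conditions.

    ``pairing`` holds, per instrument in the certified order, the matched
    exposure and the node sequence of its unblocked path to the outcome.
    """

    pairing: tuple[tuple[str, str, tuple[str, ...]], ...]
    satisfied_conditions: tuple[tuple[bool, bool, bool], ...]

    def __post_init__(self):
        seen = [e for e, _, _ in self.pairing]
        if len(seen) != len(set(seen)):
            raise GraphInputError("each instrument may appear once in a pairing")


@dataclass(frozen=True)
class Refusal:
    """Names the first instrumental-set condition that could not be satisfied."""

    condition: int
    message: str

    def __bool__(self) -> bool:
        return False


def _path_nodes(steps) -> tuple[str, ...]:
    return tuple([steps[0][0]] + [s[1] for s in steps])


def _side_heads(steps, nodes, v: str, side: str) -> bool:
    """Does the truncation of the path at ``v`` point to ``v``?

    ``side == 'to_end'`` looks at the edge leaving ``v`` toward the path end
    (vacuously true when ``v`` is the last node, e.g. the outcome itself);
    ``side == 'from_start'`` looks at the edge entering ``v`` from the start.
    """
    i = nodes.index(v)
    if side == "to_end":
        if i == len(nodes) - 1:
            return True
        step = steps[i]  # step from nodes[i] to nodes[i+1]
        return step[2]  # head at nodes[i]
    if i == 0:
        return True
    step = steps[i - 1]  # step from nodes[i-1] to nodes[i]
    return step[3]  # head at nodes[i]


def _condition3_ok(early, late) -> bool:
    """Check condition 3 for an ordered pair of (instrument, steps) entries."""
    (e_i, steps_i) = early
    (e_j, steps_j) = late
    nodes_i = _path_nodes(steps_i)
    nodes_j = _path_nodes(steps_j)
    if e_j in nodes_i:
        return False
    for v in set(nodes_i) & set(nodes_j):
        if not _side_heads(steps_i, list(nodes_i), v, "to_end"):
            return False
        if not _side_heads(steps_j, list(nodes_j), v, "from_start"):
            return False
    return True


def check_instrumental_set(
    graph: CausalGraph,
    instruments,
    exposures,
    outcome: str,
    max_exhaustive: int = 6,
    max_paths: int = DEFAULT_MAX_PATHS,
):
    """Search for a Brito–Pearl certificate for ``instruments`` vs ``exposures``.

    Returns a :class:`PathCertificate` when a pairing of instruments with
    unblocked paths through distinct ``exposure -> outcome`` edges satisfies
    the three conditions, else a :class:`Refusal` naming the first condition
    that failed.  All instrument orderings are tried for up to
    ``max_exhaustive`` instruments (condition 3 is order dependent); beyond
    that a single heuristic ordering (fewest candidate paths first) is used.
    """
    instruments = list(instruments)
    exposures = list(exposures)
    if len(instruments) != len(exposures):
        raise GraphInputError(
            f"need equally many instruments ({len(instruments)}) and exposures "
            f"({len(exposures)})"
        )
    graph.validate_acyclic()
    for x in exposures:
        if (x, outcome) not in graph.directed_edges:
            return Refusal(1, f"no edge {x} -> {outcome} to identify")

    # condition 1a: instruments are non-descendants of the outcome
    desc = graph.descendants(outcome)
    for e in instruments:
        if e in desc or e == outcome:
            return Refusal(1, f"{e} is a descendant of {outcome}")

    # condition 2: d-separation in the graph without the exposure->outcome edges
    g_bar = graph.without_directed_edges([(x, outcome) for x in exposures])
    for e in instruments:
        if not d_separated(g_bar, e, outcome):
            return Refusal(
                2, f"{e} is not d-separated from {outcome} once exposure "
                "effects are removed"
            )

    # condition 1b: candidate unblocked paths ending with an X_i -> Y edge
    exposure_set = set(exposures)
    candidates: dict[str, list[tuple[str, list]]] = {}
    for e in instruments:
        opts = []
        for steps in _iter_unblocked_paths(graph, e, outcome, max_paths):
            u, v, hu, hv, _ = steps[-1]
            if v == outcome and hv and not hu and u in exposure_set:
                opts.append((u, steps))
        if not opts:
            return Refusal(
                1, f"no unblocked path from {e} to {outcome} through an "
                "exposure edge"
            )
        candidates[e] = opts

    def backtrack(order):
        chosen: list[tuple[str, str, list]] = []
        used_exposures: set[str] = set()

        def rec(i):
            if i == len(order):
                return True
            e = order[i]
            for x, steps in candidates[e]:
                if x in used_exposures:
                    continue
                ok = all(
                    _condition3_ok((pe, ps), (e, steps)) for pe, _, ps in chosen
                )
                if not ok:
                    continue
                chosen.append((e, x, steps))
                used_exposures.add(x)
                if rec(i + 1):
                    return True
                chosen.pop()
                used_exposures.remove(x)
            return False

        return chosen if rec(0) else None

    if len(instruments) <= max_exhaustive:
        orderings = itertools.permutations(instruments)
    else:  # heuristic: most constrained instruments first
        orderings = [sorted(instruments, key=lambda e: len(candidates[e]))]
    for order in orderings:
        res = backtrack(list(order))
        if res is not None:
            return PathCertificate(
                pairing=tuple((e, x, _path_nodes(s)) for e, x, s in res),
                satisfied_conditions=tuple((True, True, True) for _ in res),
            )
    return Refusal(3, "no instrument ordering satisfies the pairwise path condition")


# ---------------------------------------------------------------------------
# identification


def identify_effects(
    sigma_EX: np.ndarray, sigma_EY: np.ndarray, rank_tol: float = 1e-8
) -> np.ndarray:
    """Solve ``Sigma_EX c = Sigma_EY`` for the direct effects ``c``.

    Uses the least-squares (generalized left inverse) solution
    ``c = (Sigma_EX^T Sigma_EX)^-1 Sigma_EX^T Sigma_EY``, which is exact when
    the covariances come from an SEM whose instruments form an instrumental
    set.  Raises :class:`UnderdeterminedError` when ``Sigma_EX`` has
    (numerical) rank below the number of exposures — the situation with fewer
    causal variants than exposures.
    """
    B = np.atleast_2d(np.asarray(sigma_EX, dtype=float))
    y = np.asarray(sigma_EY, dtype=float).ravel()
    if B.shape[0] != y.shape[0]:
        raise GraphInputError("sigma_EX and sigma_EY have inconsistent lengths")
    K = B.shape[1]
    sv = np.linalg.svd(B, compute_uv=False)
    if sv.size == 0 or sv[-1] <= rank_tol * sv[0]:
        rank = int(np.sum(sv > rank_tol * sv[0])) if sv.size else 0
        raise UnderdeterminedError(
            f"instrument-exposure covariance has rank {rank} < {K} exposures; "
            "effects are not identifiable from this instrument set"
        )
    c, *_ = np.linalg.lstsq(B, y, rcond=None)
    return c


def build_mvmr_sem(
    ld: np.ndarray,
    instrument_effects: np.ndarray,
    causal_effects: np.ndarray,
    exposure_error_variance: float = 1.0,
    outcome_error_variance: float = 1.0,
) -> LinearSEM:
    """SEM for the canonical MVMR diagram.

    L instruments with error covariance ``ld`` (their LD matrix, since they
    are exogenous), an L x K matrix of instrument effects on the exposures,
    and a length-K vector of direct exposure effects on the outcome.
    Node order is ``E1..EL, X1..XK, Y``.
    """
    ld = np.atleast_2d(np.asarray(ld, dtype=float))
    A = np.atleast_2d(np.asarray(instrument_effects, dtype=float))
    c = np.asarray(causal_effects, dtype=float).ravel()
    L, K = A.shape
    if ld.shape != (L, L):
        raise GraphInputError("LD matrix shape does not match instrument count")
    if c.shape != (K,):
        raise GraphInputError("causal effect vector does not match exposure count")
    p = L + K + 1
    C = np.zeros((p, p))
    C[L : L + K, :L] = A.T
    C[p - 1, L : L + K] = c
    Psi = np.zeros((p, p))
    Psi[:L, :L] = ld
    Psi[L : L + K, L : L + K] = np.eye(K) * exposure_error_variance
    Psi[p - 1, p - 1] = outcome_error_variance
    order = (
        [f"E{i + 1}" for i in range(L)] + [f"X{j + 1}" for j in range(K)] + ["Y"]
    )
    return LinearSEM(C=C, Psi=Psi, node_order=order)


def random_standardized_sem(
    rng: np.random.Generator,
    n_nodes: int = 6,
    edge_prob: float = 0.4,
    bidirected_prob: float = 0.3,
):
    """Random acyclic SEM whose variables all have unit variance.

    Exogenous nodes come first; bidirected edges are placed only between
    exogenous pairs (keeping the standardization algebra exact), and error
    variances of endogenous nodes are set to one minus their explained
    variance.  Returns ``(graph, sem)``; useful as a test oracle because the
    implied covariance then equals the standardized path-tracing sum
    entrywise.
    """
    if n_nodes < 2:
        raise GraphInputError("need at least two nodes")
    n_roots = int(rng.integers(1, n_nodes))
    names = [f"X{i + 1}" for i in range(n_nodes)]
    p = n_nodes
    C = np.zeros((p, p))
    for j in range(n_roots, p):
        parents = [i for i in range(j) if rng.random() < edge_prob]
        if not parents and j >= n_roots:
            parents = [int(rng.integers(0, j))]
        for i in parents:
            C[j, i] = rng.uniform(0.1, 0.5) * rng.choice([-1.0, 1.0])
    Psi = np.eye(p)
    roots = list(range(n_roots))
    rng.shuffle(roots)
    for a, b in zip(roots[::2], roots[1::2]):
        if rng.random() < bidirected_prob:
            val = rng.uniform(-0.5, 0.5)
            Psi[a, b] = Psi[b, a] = val
    # standardize endogenous nodes: Sigma built incrementally in topo order
    Sigma = np.zeros((p, p))
    Sigma[:n_roots, :n_roots] = Psi[:n_roots, :n_roots]
    for j in range(n_roots, p):
        explained = C[j, :j] @ Sigma[:j, :j] @ C[j, :j]
        if explained >= 0.9:
            C[j, :j] *= np.sqrt(0.8 / explained)
            explained = 0.8
        Psi[j, j] = 1.0 - explained
        Sigma[j, :j] = C[j, :j] @ Sigma[:j, :j]
        Sigma[:j, j] = Sigma[j, :j]
        Sigma[j, j] = 1.0
    sem = LinearSEM(C=C, Psi=Psi, node_order=names)
    return sem.to_graph(), sem
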