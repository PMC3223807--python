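"""Discrete Bayesian networks: structures, scores, K2 search, inference.

The scoring machinery is the workhorse of the whole toolkit.  Two scores are
provided, both decomposable into per-family terms:

* the Cooper–Herskovits (K2) marginal likelihood of a family under a uniform
  Dirichlet parameter prior,

      score(i) = prod_j (r_i - 1)! / (F_ij + r_i - 1)! * prod_k F_ijk!

  evaluated entirely in log space with log-Gamma (raw factorials overflow for
  any realistic count), and combined into the joint structure/data score
  log p(G, D) = log c + sum_i score(i) with a constant structure prior c;

* the Bayesian information criterion, log-likelihood at the maximum-likelihood
  parameters minus (Dim_G / 2) * log M, where Dim_G = sum_i q_i (r_i - 1)
  counts free parameters and penalizes overly connected structures.

Structure search is the classic K2 greedy scheme: given a total node order,
each node greedily acquires the single predecessor parent that most improves
its family score, stopping at no improvement or the parent cap.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .data_model import DiscreteDataset

__all__ = [
    "DAGStructure",
    "SufficientStats",
    "CPTSet",
    "ScoredNetwork",
    "collect_stats",
    "k2_family_score",
    "bic_family_score",
    "family_score",
    "k2_network_score",
    "bic_score",
    "k2_search",
    "fit_parameters",
    "log_likelihood",
    "infer_posterior",
]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class DAGStructure:
    """Directed acyclic graph given as per-node parent sets.

    ``node_order`` records the total order used by K2-style search (defaults
    to ``nodes``); it is metadata, not a constraint on the parent sets.
    """

    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    node_order: list[str] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for n in self.nodes:
            self.parents.setdefault(n, ())
        for child, pars in self.parents.items():
            if child not in node_set:
                raise ValueError(f"parent entry for unknown node {child!r}")
            self.parents[child] = tuple(pars)
            if child in pars:
                raise ValueError(f"self-loop on {child!r}")
            unknown = set(pars) - node_set
            if unknown:
                raise ValueError(f"unknown parents {unknown} of {child!r}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("structure contains a directed cycle")
        if self.node_order is None:
            self.node_order = list(self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, pars in self.parents.items():
            g.add_edges_from((p, child) for p in pars)
        return g

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c in self.nodes for p in self.parents[c]]

    @property
    def n_edges(self) -> int:
        return sum(len(self.parents[c]) for c in self.nodes)

    def relabel(self, mapping: Mapping[str, str]) -> "DAGStructure":
        """Rename nodes through ``mapping`` (identity for absent names)."""
        f = lambda n: mapping.get(n, n)
        return DAGStructure(
            nodes=[f(n) for n in self.nodes],
            parents={f(c): tuple(f(p) for p in ps)
                     for c, ps in self.parents.items()},
            node_order=[f(n) for n in self.node_order],
        )

    # -- serialization ------------------------------------------------------

    def to_edge_list(self) -> str:
        """Tab-separated ``parent<TAB>child`` lines (isolated nodes omitted)."""
        return "\n".join(f"{p}\t{c}" for p, c in self.edges())

    @classmethod
    def from_edge_list(cls, text: str,
                       nodes: Sequence[str] | None = None) -> "DAGStructure":
        parents: dict[str, list[str]] = {}
        seen: list[str] = list(nodes) if nodes else []
        for line in text.strip().splitlines():
            if not line.strip():
                continue
            p, c = line.split("\t")
            for n in (p, c):
                if n not in seen:
                    seen.append(n)
            parents.setdefault(c, []).append(p)
        return cls(nodes=seen,
                   parents={c: tuple(ps) for c, ps in parents.items()})

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dict(self) -> dict:
        return {"nodes": self.nodes,
                "parents": {c: list(p) for c, p in self.parents.items()},
                "node_order": self.node_order}

    @classmethod
    def from_dict(cls, d: dict) -> "DAGStructure":
        return cls(nodes=list(d["nodes"]),
                   parents={c: tuple(p) for c, p in d["parents"].items()},
                   node_order=list(d.get("node_order") or d["nodes"]))


@dataclass
class SufficientStats:
    """Per-family counts: ``counts[node]`` has shape (q_i, r_i)."""

    counts: dict[str, np.ndarray]
    parent_arities: dict[str, tuple[int, ...]]
    n_records: int


@dataclass
class CPTSet:
    """Conditional probability tables matching a :class:`DAGStructure`.

    ``tables[node]`` has shape ``(q_i, r_i)``: one row per parent
    instantiation (mixed-radix encoding of parent states, first parent most
    significant), each row a distribution over the node's states.
    """

    structure: DAGStructure
    tables: dict[str, np.ndarray]
    arities: dict[str, int]
    estimator: str = "mle"

    def __post_init__(self) -> None:
        for node, tab in self.tables.items():
            if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")

    @property
    def dimension(self) -> int:
        """Dim_G = sum_i q_i (r_i - 1): free parameters of the model."""
        return sum(t.shape[0] * (t.shape[1] - 1) for t in self.tables.values())

    def relabel(self, mapping: Mapping[str, str]) -> "CPTSet":
        f = lambda n: mapping.get(n, n)
        return CPTSet(
            structure=self.structure.relabel(mapping),
            tables={f(n): t.copy() for n, t in self.tables.items()},
            arities={f(n): r for n, r in self.arities.items()},
            estimator=self.estimator,
        )

    def to_json(self, path) -> None:
        payload = {
            "structure": self.structure.to_dict(),
            "arities": self.arities,
            "estimator": self.estimator,
            "tables": {n: t.tolist() for n, t in self.tables.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CPTSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(structure=DAGStructure.from_dict(d["structure"]),
                   tables={n: np.asarray(t) for n, t in d["tables"].items()},
                   arities={n: int(r) for n, r in d["arities"].items()},
                   estimator=d["estimator"])


@dataclass
class ScoredNetwork:
    structure: DAGStructure
    score_value: float
    score_kind: str
    structure_prior_c: float = 1.0


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _parent_config_index(records: np.ndarray, parent_idx: Sequence[int],
                         arities: np.ndarray) -> tuple[np.ndarray, int]:
    """Mixed-radix encoding of parent states; returns (index per record, q)."""
    if not parent_idx:
        return np.zeros(records.shape[0], dtype=np.int64), 1
    j = np.zeros(records.shape[0], dtype=np.int64)
    q = 1
    for p in parent_idx:
        j = j * arities[p] + records[:, p]
        q *= int(arities[p])
    return j, q


def family_counts(dataset: DiscreteDataset, node: str,
                  parents: Sequence[str]) -> np.ndarray:
    """F_ijk tally for one family, shape (q_i, r_i)."""
    ci = dataset.index_of(node)
    pidx = [dataset.index_of(p) for p in parents]
    r = int(dataset.arities[ci])
    j, q = _parent_config_index(dataset.records, pidx, dataset.arities)
    flat = np.bincount(j * r + dataset.records[:, ci], minlength=q * r)
    return flat.reshape(q, r)


def collect_stats(dataset: DiscreteDataset, dag: DAGStructure) -> SufficientStats:
    """Sufficient statistics F_ijk for every family of ``dag``."""
    missing = set(dag.nodes) - set(dataset.variables)
    if missing:
        raise ValueError(f"nodes absent from dataset: {sorted(missing)}")
    counts = {n: family_counts(dataset, n, dag.parents[n]) for n in dag.nodes}
    pa = {n: tuple(dataset.arity_of(p) for p in dag.parents[n])
          for n in dag.nodes}
    return SufficientStats(counts, pa, dataset.n_records)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def k2_family_score_from_counts(counts: np.ndarray) -> float:
    """Cooper–Herskovits family score from an F_ijk table, in log space."""
    r = counts.shape[1]
    f_ij = counts.sum(axis=1)
    return float(
        np.sum(gammaln(r) - gammaln(f_ij + r))
        + np.sum(gammaln(counts + 1.0))
    )


def k2_family_score(dataset: DiscreteDataset, node: str,
                    parents: Sequence[str] = ()) -> float:
    """log of prod_j [(r-1)!/(F_ij+r-1)!] prod_k F_ijk! for one family."""
    return k2_family_score_from_counts(family_counts(dataset, node, parents))


def ll_from_counts(counts: np.ndarray) -> float:
    """Maximized log-likelihood of one family; empty cells contribute 0."""
    f_ij = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * (np.log(counts) - np.log(f_ij))
    return float(np.sum(term[counts > 0]))


def bic_family_score(dataset: DiscreteDataset, node: str,
                     parents: Sequence[str] = ()) -> float:
    """Decomposed BIC term: family LL minus q_i (r_i - 1)/2 * log M."""
    counts = family_counts(dataset, node, parents)
    q, r = counts.shape
    return ll_from_counts(counts) - 0.5 * q * (r - 1) * np.log(dataset.n_records)


def family_score(dataset: DiscreteDataset, node: str,
                 parents: Sequence[str], score_kind: str) -> float:
    if score_kind == "k2":
        return k2_family_score(dataset, node, parents)
    if score_kind == "bic":
        return bic_family_score(dataset, node, parents)
    raise ValueError(f"unknown score kind {score_kind!r}")


def k2_network_score(dataset: DiscreteDataset, dag: DAGStructure,
                     c: float = 1.0) -> ScoredNetwork:
    """Joint structure/data score log p(G, D) = log c + sum of family scores."""
    if c <= 0:
        raise ValueError("structure prior constant c must be positive")
    total = np.log(c) + sum(
        k2_family_score(dataset, n, dag.parents[n]) for n in dag.nodes
    )
    return ScoredNetwork(dag, float(total), "k2", c)


def bic_score(dataset: DiscreteDataset, dag: DAGStructure) -> float:
    """BIC of ``dag``: maximized log-likelihood minus (Dim_G/2) log M."""
    return float(sum(
        bic_family_score(dataset, n, dag.parents[n]) for n in dag.nodes
    ))


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def k2_search(
    dataset: DiscreteDataset,
    node_order: Sequence[str] | None = None,
    max_parents: int = 3,
    score_kind: str = "k2",
) -> DAGStructure:
    """Greedy K2 structure search under a fixed total node order.

    Starting from the empty graph, each node considers only nodes earlier in
    the order as candidate parents and repeatedly adds the one that most
    improves its family score, stopping when nothing improves or
    ``max_parents`` is reached.  Deterministic: score ties are broken in
    favour of the earlier node in the order.
    """
    if node_order is None:
        node_order = list(dataset.variables)
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    parents: dict[str, tuple[str, ...]] = {}
    for pos, node in enumerate(node_order):
        current: list[str] = []
        best = family_score(dataset, node, current, score_kind)
        candidates = list(node_order[:pos])
        while len(current) < max_parents and candidates:
            gains = [
                (family_score(dataset, node, current + [c], score_kind), c)
                for c in candidates
            ]
            top_score = max(g for g, _ in gains)
            if top_score <= best:
                break
            # earliest-in-order winner among ties
            winner = next(c for _, c in sorted(
                ((g, c) for g, c in gains if g == top_score),
                key=lambda gc: candidates.index(gc[1])))
            current.append(winner)
            candidates.remove(winner)
            best = top_score
        parents[node] = tuple(current)
    return DAGStructure(nodes=list(node_order), parents=parents,
                        node_order=list(node_order))


# ---------------------------------------------------------------------------
# parameters and likelihood
# ---------------------------------------------------------------------------

def fit_parameters(dataset: DiscreteDataset, dag: DAGStructure,
                   estimator: str = "mle") -> CPTSet:
    """CPTs by maximum likelihood or add-one (Laplace) smoothing.

    MLE rows with no observations fall back to uniform; Laplace rows are
    strictly positive everywhere.
    """
    if estimator not in ("mle", "laplace"):
        raise ValueError(f"unknown estimator {estimator!r}")
    stats = collect_stats(dataset, dag)
    tables: dict[str, np.ndarray] = {}
    for node, counts in stats.counts.items():
        q, r = counts.shape
        if estimator == "laplace":
            num = counts + 1.0
        else:
            num = counts.astype(float)
            empty = num.sum(axis=1) == 0
            num[empty] = 1.0  # uniform fallback for unseen parent configs
        tables[node] = num / num.sum(axis=1, keepdims=True)
    arities = {n: dataset.arity_of(n) for n in dag.nodes}
    return CPTSet(dag, tables, arities, estimator)


def log_likelihood(dataset: DiscreteDataset, dag: DAGStructure,
                   cpts: CPTSet) -> float:
    """Sum over records and nodes of log theta(state | parent states).

    Returns ``-inf`` honestly if an MLE table assigns probability zero to an
    observed event; callers needing finiteness should fit with Laplace.
    """
    total = 0.0
    for node in dag.nodes:
        ci = dataset.index_of(node)
        pidx = [dataset.index_of(p) for p in dag.parents[node]]
        j, _ = _parent_config_index(dataset.records, pidx, dataset.arities)
        theta = cpts.tables[node][j, dataset.records[:, ci]]
        with np.errstate(divide="ignore"):
            total += float(np.sum(np.log(theta)))
    return total


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

class _Factor:
    """Dense factor over a tuple of variables (used by variable elimination)."""

    __slots__ = ("vars", "card", "values")

    def __init__(self, vars_: tuple[str, ...], card: dict[str, int],
                 values: np.ndarray):
        self.vars = vars_
        self.card = card
        self.values = values  # shape: tuple(card[v] for v in vars_)

    def reduce(self, var: str, state: int) -> "_Factor":
        ax = self.vars.index(var)
        taken = np.take(self.values, state, axis=ax)
        rest = tuple(v for v in self.vars if v != var)
        return _Factor(rest, self.card, taken)

    def marginalize(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        rest = tuple(v for v in self.vars if v != var)
        return _Factor(rest, self.card, self.values.sum(axis=ax))

    def multiply(self, other: "_Factor") -> "_Factor":
        all_vars = self.vars + tuple(v for v in other.vars
                                     if v not in self.vars)
        a = self._broadcast(all_vars)
        b = other._broadcast(all_vars)
        return _Factor(all_vars, {**self.card, **other.card}, a * b)

    def _broadcast(self, all_vars: tuple[str, ...]) -> np.ndarray:
        shape = [self.card[v] if v in self.vars else 1 for v in all_vars]
        perm = [self.vars.index(v) for v in all_vars if v in self.vars]
        return self.values.transpose(perm).reshape(shape)


def _cpt_factor(node: str, cpts: CPTSet) -> _Factor:
    pars = cpts.structure.parents[node]
    card = {n: cpts.arities[n] for n in (*pars, node)}
    shape = tuple(card[p] for p in pars) + (card[node],)
    vals = cpts.tables[node].reshape(shape)
    return _Factor((*pars, node), card, vals)


def infer_posterior(
    dag: DAGStructure,
    cpts: CPTSet,
    evidence: Mapping[str, int] | None = None,
    query: Iterable[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Exact posterior over ``query`` given ``evidence``, by variable elimination.

    Elimination order is the min-size heuristic (cheapest intermediate factor
    first).  Returns the ordered query variables and the joint posterior
    array over their states (sums to 1).  Evidence with probability zero
    raises ``ValueError("impossible evidence")``.
    """
    evidence = dict(evidence or {})
    if query is None:
        query = [n for n in dag.nodes if n not in evidence]
    query = list(query)
    overlap = set(query) & set(evidence)
    if overlap:
        raise ValueError(f"query and evidence overlap: {sorted(overlap)}")
    for var, state in evidence.items():
        if not 0 <= state < cpts.arities[var]:
            raise ValueError(f"evidence state {state} out of range for {var!r}")

    factors = [_cpt_factor(n, cpts) for n in dag.nodes]
    for var, state in evidence.items():
        factors = [f.reduce(var, state) if var in f.vars else f
                   for f in factors]

    to_eliminate = set(dag.nodes) - set(evidence) - set(query)
    while to_eliminate:
        # min-size heuristic: eliminate the variable whose product factor
        # would be smallest
        def cost(v: str) -> int:
            involved = {u for f in factors if v in f.vars for u in f.vars}
            size = 1
            for u in involved:
                size *= cpts.arities[u]
            return size
        var = min(sorted(to_eliminate), key=cost)
        to_eliminate.discard(var)
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]

    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    # collapse any scalar factors and order axes by the query list
    if result.vars != tuple(query):
        perm = [result.vars.index(v) for v in query]
        values = result.values.transpose(perm) if result.vars else result.values
    else:
        values = result.values
    z = values.sum()
    if z <= 0:
        raise ValueError("impossible evidence")
    return query, values / z


def enumerate_joint(cpts: CPTSet) -> tuple[list[str], np.ndarray]:
    """Full joint table by brute-force enumeration (small networks only)."""
    nodes = list(cpts.structure.nodes)
    cards = [cpts.arities[n] for n in nodes]
    joint = np.zeros(cards)
    for assign in itertools.product(*(range(c) for c in cards)):
        state = dict(zip(nodes, assign))
        p = 1.0
        for n in nodes:
            pars = cpts.structure.parents[n]
            j = 0
            for par in pars:
                j = j * cpts.arities[par] + state[par]
            p *= cpts.tables[n][j, state[n]]
        joint[assign] = p
    return nodes, joint
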