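"""Simulated-annealing search for functionally equivalent species.

A network learned in one community (the *donor* model) defines structural
roles — slots — for its species.  Given a second community's data, the search
asks which of its species best fill those slots: an injective assignment of
slots to candidate species is scored by how well the donor structure,
relabelled onto the assigned columns, fits the second dataset (BIC by
default, with parameters re-fit on the second dataset; the K2 joint score is
selectable).  The assignment space is explored by simulated annealing with a
geometric cooling schedule: single-slot replacements are proposed uniformly,
uphill moves always accepted, downhill moves accepted with probability
exp(dscore / t).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bn_core import (
    CPTSet,
    DAGStructure,
    bic_family_score,
    k2_family_score,
)
from .data_model import DiscreteDataset

__all__ = [
    "EquivalenceProblem",
    "AnnealingSchedule",
    "EquivalenceResult",
    "score_assignment",
    "accept_move",
    "update_temperature",
    "functional_equivalence_search",
]

TEMPERATURE_FLOOR = 1e-12


@dataclass
class EquivalenceProblem:
    """Donor structure, target data and the candidate species pool.

    ``slot_arities`` (from the donor model's discretization vocabulary) is
    checked against assigned columns when given; assignments to columns of a
    different arity are rejected.
    """

    bn1_structure: DAGStructure
    data2: DiscreteDataset
    candidate_pool: list[str]
    score_kind: str = "bic"
    bn1_cpts: CPTSet | None = None
    slot_arities: dict[str, int] | None = None
    structure_prior_c: float = 1.0
    tied_prev_suffix: str | None = None

    def __post_init__(self) -> None:
        required = set(self.candidate_pool)
        if self.tied_prev_suffix:
            required |= {c + self.tied_prev_suffix for c in self.candidate_pool}
        unknown = required - set(self.data2.variables)
        if unknown:
            raise ValueError(
                f"candidates absent from target data: {sorted(unknown)}")
        if len(self.candidate_pool) < len(self.slots):
            raise ValueError(
                f"candidate pool ({len(self.candidate_pool)}) smaller than "
                f"the number of model slots ({len(self.slots)})")
        if self.score_kind not in ("bic", "k2", "transfer_ll"):
            raise ValueError(f"unknown score kind {self.score_kind!r}")
        if self.score_kind == "transfer_ll" and self.bn1_cpts is None:
            raise ValueError("transfer_ll scoring needs the donor CPTs")
        if self.slot_arities is None and self.bn1_cpts is not None:
            self.slot_arities = dict(self.bn1_cpts.arities)

    @property
    def slots(self) -> list[str]:
        """Assignable slots: one per donor species.

        For a two-slice (temporal) donor structure whose previous-slice
        twin nodes carry ``tied_prev_suffix``, the twins are tied to their
        base slot — one species fills both — and are not listed here.
        """
        if not self.tied_prev_suffix:
            return list(self.bn1_structure.nodes)
        return [n for n in self.bn1_structure.nodes
                if not n.endswith(self.tied_prev_suffix)]

    def _full_mapping(self, vars2: dict[str, str]) -> dict[str, str]:
        if not self.tied_prev_suffix:
            return dict(vars2)
        sfx = self.tied_prev_suffix
        full = dict(vars2)
        full.update({s + sfx: c + sfx for s, c in vars2.items()})
        return full


@dataclass
class AnnealingSchedule:
    """Geometric cooling schedule; defaults are the reference settings
    (t_start = 1000, 1000 iterations, cooling factor 0.9)."""

    t_start: float = 1000.0
    iterations: int = 1000
    cooling_factor: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_start <= 0:
            raise ValueError("t_start must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must be in (0, 1)")


@dataclass
class EquivalenceResult:
    """Final and best-ever assignments plus the full annealing trace.

    With restarts, ``score_trace``/``final_*`` describe the restart whose
    best-ever score won and ``restart_scores`` lists every restart's
    best-ever score.
    """

    final_vars2: dict[str, str]
    final_score: float
    best_ever_vars2: dict[str, str]
    best_ever_score: float
    score_trace: np.ndarray = field(repr=False)
    accepted_moves: int = 0
    restart_scores: list[float] = field(default_factory=list)
    best_restart: int = 0

    def to_json(self, path) -> None:
        payload = {
            "final_vars2": self.final_vars2,
            "final_score": self.final_score,
            "best_ever_vars2": self.best_ever_vars2,
            "best_ever_score": self.best_ever_score,
            "accepted_moves": self.accepted_moves,
            "score_trace": np.asarray(self.score_trace).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def mapping_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(
            {"slot_species": list(self.best_ever_vars2),
             "assigned_species": list(self.best_ever_vars2.values())}
        ).to_csv(path, index=False)


def score_assignment(problem: EquivalenceProblem,
                     vars2: dict[str, str]) -> float:
    """Score one injective slot -> species assignment (higher is better).

    The donor structure is relabelled onto the assigned target columns and
    scored on the target data.  Three scores are available:

    ``bic`` (default)
        BIC with parameters re-fit on the target data by maximum
        likelihood — pure structure transfer; the fit is judged on the new
        community.
    ``k2``
        The joint structure/data score, likewise re-fit semantics.
    ``transfer_ll``
        Log-likelihood of the target data under the donor structure *and*
        the donor's own parameters, relabelled verbatim.  Re-fit scores see
        only topology, so structurally isomorphic slots (e.g. the interior
        of a chain) are anonymous to them; carrying the donor parameters is
        what makes distinct functional roles identifiable.  No dimension
        penalty applies because nothing is fitted.
    """
    slots = problem.slots
    missing = set(slots) - set(vars2)
    if missing:
        raise ValueError(f"assignment misses slots: {sorted(missing)}")
    assigned = [vars2[s] for s in slots]
    if len(set(assigned)) != len(assigned):
        raise ValueError("assignment must be injective")
    unknown = set(assigned) - set(problem.candidate_pool)
    if unknown:
        raise ValueError(f"assigned species outside pool: {sorted(unknown)}")
    if problem.slot_arities is not None:
        for s in slots:
            want = problem.slot_arities[s]
            got = problem.data2.arity_of(vars2[s])
            if got != want:
                raise ValueError(
                    f"arity mismatch: slot {s!r} has {want} states but "
                    f"{vars2[s]!r} has {got}")
    full = problem._full_mapping({s: vars2[s] for s in slots})
    total = sum(
        _family_term(problem, node, full)
        for node in problem.bn1_structure.nodes
    )
    if problem.score_kind == "k2":
        total += np.log(problem.structure_prior_c)
    return float(total)


def _family_term(problem: EquivalenceProblem, node: str,
                 full: Mapping[str, str],
                 cache: dict | None = None) -> float:
    """Score contribution of one donor family under the given relabelling.

    Decomposability makes this the annealer's unit of caching: a single-slot
    replacement touches only the families containing that slot, and repeated
    visits to an assignment cost one dictionary lookup per family.
    """
    parents = problem.bn1_structure.parents[node]
    mapped_child = full[node]
    mapped_parents = tuple(full[p] for p in parents)
    if cache is not None:
        key = (node, mapped_child, mapped_parents)
        hit = cache.get(key)
        if hit is not None:
            return hit
    if problem.score_kind == "bic":
        value = bic_family_score(problem.data2, mapped_child, mapped_parents)
    elif problem.score_kind == "k2":
        value = k2_family_score(problem.data2, mapped_child, mapped_parents)
    else:  # transfer_ll: donor CPT applied to the assigned columns
        tab = problem.bn1_cpts.tables[node]
        ds = problem.data2
        child = ds.column(mapped_child)
        j = np.zeros(ds.n_records, dtype=np.int64)
        for p, mp in zip(parents, mapped_parents):
            j = j * problem.bn1_cpts.arities[p] + ds.column(mp)
        theta = tab[j, child]
        with np.errstate(divide="ignore"):
            value = float(np.sum(np.log(theta)))
    if cache is not None:
        cache[key] = value
    return value


def accept_move(dscore: float, t: float, u: float) -> bool:
    """Metropolis-style acceptance: dscore >= 0, or u < exp(dscore / t)."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if dscore >= 0:
        return True
    ratio = dscore / t
    if ratio < -745.0:  # exp underflows to exactly 0: never accepted
        return False
    return u < np.exp(ratio)


def update_temperature(t: float, cooling_factor: float = 0.9,
                       floor: float = TEMPERATURE_FLOOR) -> float:
    """Geometric cooling with a positive floor (late schedule = greedy)."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    return max(t * cooling_factor, floor)


def functional_equivalence_search(
    problem: EquivalenceProblem,
    schedule: AnnealingSchedule | None = None,
    n_restarts: int = 10,
) -> EquivalenceResult:
    """Anneal over injective slot assignments to the candidate pool.

    Each restart runs the full schedule from an independent random
    assignment (restart r seeds its generator with ``schedule.seed + r``)
    and the restart with the best ever-visited score wins; the geometric
    schedule spends only a few dozen iterations in the temperature range
    where score differences matter, so independent restarts — not a longer
    single run — are what buys reliability.

    Within a run, each iteration proposes replacing one uniformly chosen
    slot's species with a uniformly chosen different candidate — if that
    candidate currently fills another slot the two slots swap, keeping the
    assignment injective (and making pure permutations reachable when the
    pool has no spare species).  Acceptance follows :func:`accept_move`
    against the current score; the temperature cools geometrically each
    iteration.  Returns both the final assignment of the winning restart
    and the best assignment ever visited (the recommended output).
    """
    schedule = schedule or AnnealingSchedule()
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    results = [
        _anneal_once(problem, schedule, schedule.seed + r)
        for r in range(n_restarts)
    ]
    scores = [r.best_ever_score for r in results]
    best_idx = int(np.argmax(scores))
    winner = results[best_idx]
    winner.restart_scores = [float(s) for s in scores]
    winner.best_restart = best_idx
    return winner


def _anneal_once(problem: EquivalenceProblem, schedule: AnnealingSchedule,
                 seed: int) -> EquivalenceResult:
    rng = np.random.default_rng(seed)
    slots = problem.slots
    pool = list(problem.candidate_pool)
    slot_ar = problem.slot_arities or {}

    def fits(candidate: str, slot: str) -> bool:
        return (slot not in slot_ar
                or problem.data2.arity_of(candidate) == slot_ar[slot])

    # random initial injective assignment, respecting slot arities
    shuffled = [pool[i] for i in rng.permutation(len(pool))]
    vars2: dict[str, str] = {}
    used: set[str] = set()
    for slot in slots:
        pick = next((c for c in shuffled if c not in used and fits(c, slot)),
                    None)
        if pick is None:
            raise ValueError(
                f"no arity-compatible candidate left for slot {slot!r}")
        vars2[slot] = pick
        used.add(pick)

    cache: dict = {}

    def rescore_fn(assign: dict[str, str]) -> float:
        full = problem._full_mapping(assign)
        total = sum(_family_term(problem, node, full, cache)
                    for node in problem.bn1_structure.nodes)
        if problem.score_kind == "k2":
            total += np.log(problem.structure_prior_c)
        return float(total)

    current = score_assignment(problem, vars2)  # validates the start state
    best_vars = dict(vars2)
    best_score = current

    t = schedule.t_start
    trace = np.empty(schedule.iterations)
    accepted = 0
    for i in range(schedule.iterations):
        slot = slots[rng.integers(len(slots))]
        old = vars2[slot]
        others = [c for c in pool if c != old and fits(c, slot)]
        if not others:
            trace[i] = current
            t = update_temperature(t, schedule.cooling_factor)
            continue
        candidate = others[rng.integers(len(others))]
        holder = next((s for s, c in vars2.items() if c == candidate), None)
        if holder is not None and not fits(old, holder):
            trace[i] = current  # swap would break the holder's arity
            t = update_temperature(t, schedule.cooling_factor)
            continue
        vars2[slot] = candidate
        if holder is not None:
            vars2[holder] = old
        rescore = rescore_fn(vars2)
        dscore = rescore - current
        if accept_move(dscore, t, float(rng.uniform())):
            current = rescore
            accepted += 1
            if rescore > best_score:
                best_score = rescore
                best_vars = dict(vars2)
        else:  # undo the switch
            vars2[slot] = old
            if holder is not None:
                vars2[holder] = candidate
        trace[i] = current
        t = update_temperature(t, schedule.cooling_factor)

    return EquivalenceResult(
        final_vars2=vars2,
        final_score=current,
        best_ever_vars2=best_vars,
        best_ever_score=best_score,
        score_trace=trace,
        accepted_moves=accepted,
    )
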