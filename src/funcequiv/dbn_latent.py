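"""Dynamic Bayesian network with one binary latent regime node.

The model couples a two-slice DBN over the observed (discretized) species
with a single hidden chain H:

* every observable node has parents in the previous time slice only
  (found by REVEAL-style greedy search, BIC by default);
* the hidden node is binary with the autoregressive link H_{t-1} -> H_t,
  an initial distribution P(H_1) and transition matrix P(H_t | H_{t-1});
* H_t additionally feeds a configurable child set — by default only the
  target species (the "cod" node), whose conditional table is
  P(target_t | previous-slice parents, H_t).

The hidden chain is fitted by expectation-maximization (forward-backward in
the E-step, add-one smoothed expected-count M-step), observables without a
hidden parent are fitted by direct counting of consecutive-year pairs.
Survey gaps are handled without imputation: emission terms are skipped when
the previous year is missing and the hidden chain bridges a k-year gap with
the k-step transition matrix.

The fitted model supports one-step-ahead prediction of the target (causal
filtering), smoothed hidden-state posteriors with a Viterbi MAP path, and
cross-region transfer: structure *and* parameters are relabelled onto the
functionally equivalent species of another region and applied there without
re-fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_core import _parent_config_index, family_score
from .data_model import DiscreteDataset

__all__ = [
    "TransitionDataset",
    "DBNModel",
    "PredictionSeries",
    "EMReport",
    "make_transition_dataset",
    "reveal_search",
    "fit_em",
    "predict_one_step",
    "infer_hidden_states",
    "transfer_model",
    "align_hidden_labels",
]

PREV_SUFFIX = "__prev"


# ---------------------------------------------------------------------------
# transition pairs
# ---------------------------------------------------------------------------

@dataclass
class TransitionDataset:
    """(slice t-1, slice t) record pairs built from consecutive years only."""

    variables: list[str]
    arities: np.ndarray
    prev: np.ndarray
    cur: np.ndarray
    years_cur: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.prev.shape[0]

    def to_dataset(self) -> DiscreteDataset:
        """Stack both slices into one dataset (previous-slice copies get the
        ``__prev`` suffix) so static family scoring applies unchanged."""
        return DiscreteDataset(
            variables=[v + PREV_SUFFIX for v in self.variables]
            + list(self.variables),
            arities=np.concatenate([self.arities, self.arities]),
            records=np.hstack([self.prev, self.cur]),
        )


def make_transition_dataset(dataset: DiscreteDataset,
                            years: Sequence[int]) -> TransitionDataset:
    """Pair each year with its immediate successor; survey gaps are skipped."""
    years = np.asarray(years, dtype=int)
    if years.shape != (dataset.n_records,):
        raise ValueError("years must align one-to-one with records")
    consec = np.where(np.diff(years) == 1)[0]
    if consec.size < 1:
        raise ValueError("need at least two consecutive years")
    return TransitionDataset(
        variables=list(dataset.variables),
        arities=dataset.arities.copy(),
        prev=dataset.records[consec],
        cur=dataset.records[consec + 1],
        years_cur=years[consec + 1],
    )


def reveal_search(
    tdata: TransitionDataset,
    targets: Sequence[str] | None = None,
    max_parents: int = 3,
    score_kind: str = "bic",
    min_parents: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Greedy inter-slice parent search, one family at a time.

    For each slice-t target the previous-slice variables (including the
    target's own past) are candidate parents; the single best-scoring
    addition is made repeatedly until nothing improves or ``max_parents``
    is hit.  All edges cross slices, so acyclicity is automatic.

    ``min_parents=1`` forces the best-scoring single parent even when no
    parent clears the score penalty — useful when the structure's *shape*
    is needed downstream (e.g. to embed every node in some dependence for
    an equivalence search) and a weak edge is better than none.
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if min_parents > max_parents:
        raise ValueError("min_parents cannot exceed max_parents")
    targets = list(targets) if targets is not None else list(tdata.variables)
    stacked = tdata.to_dataset()
    candidates_all = [v + PREV_SUFFIX for v in tdata.variables]
    result: dict[str, tuple[str, ...]] = {}
    for node in targets:
        current: list[str] = []
        best = family_score(stacked, node, current, score_kind)
        candidates = list(candidates_all)
        while len(current) < max_parents and candidates:
            scored = [(family_score(stacked, node, current + [c], score_kind), c)
                      for c in candidates]
            top = max(s for s, _ in scored)
            if top <= best and len(current) >= min_parents:
                break
            winner = next(c for s, c in scored if s == top)
            current.append(winner)
            candidates.remove(winner)
            best = top
        result[node] = tuple(
            p[: -len(PREV_SUFFIX)] for p in current)
    return result


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class DBNModel:
    """Two-slice DBN with one binary latent regime node.

    ``tables[node]`` has shape ``(q, r)`` for hidden-free observables and
    ``(q, n_hidden, r)`` for hidden children, with ``q`` the mixed-radix
    count of previous-slice parent configurations (parent order as listed in
    ``inter_parents``).  ``transition`` is P(H_t | H_{t-1}) (rows = H_{t-1}),
    ``initial`` is P(H_1).
    """

    variables: list[str]
    arities: dict[str, int]
    inter_parents: dict[str, tuple[str, ...]]
    target: str
    hidden_children: tuple[str, ...] = ()
    n_hidden: int = 2
    transition: np.ndarray | None = None
    initial: np.ndarray | None = None
    tables: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target not in self.variables:
            raise ValueError("target must be an observable variable")
        if not self.hidden_children:
            self.hidden_children = (self.target,)
        unknown = set(self.hidden_children) - set(self.variables)
        if unknown:
            raise ValueError(f"hidden children not observable: {unknown}")
        for node, pars in self.inter_parents.items():
            bad = set(pars) - set(self.variables)
            if bad:
                raise ValueError(f"unknown parents {bad} for {node!r}")
        if self.transition is not None:
            self._check_stochastic(np.atleast_2d(self.transition), "transition")
        if self.initial is not None:
            self._check_stochastic(np.atleast_2d(self.initial), "initial")
        for node, tab in self.tables.items():
            self._check_stochastic(tab.reshape(-1, tab.shape[-1]),
                                   f"table[{node}]")

    @staticmethod
    def _check_stochastic(rows: np.ndarray, what: str) -> None:
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"{what} rows must sum to 1")

    @property
    def is_fitted(self) -> bool:
        return (self.transition is not None and self.initial is not None
                and len(self.tables) == len(self.variables))

    def q_of(self, node: str) -> int:
        q = 1
        for p in self.inter_parents.get(node, ()):
            q *= self.arities[p]
        return q

    def skeleton_copy(self) -> "DBNModel":
        return DBNModel(
            variables=list(self.variables),
            arities=dict(self.arities),
            inter_parents={n: tuple(p) for n, p in self.inter_parents.items()},
            target=self.target,
            hidden_children=tuple(self.hidden_children),
            n_hidden=self.n_hidden,
        )

    def relabel(self, mapping: Mapping[str, str]) -> "DBNModel":
        """Rename observables through ``mapping``; parameters travel along."""
        f = lambda n: mapping.get(n, n)
        return DBNModel(
            variables=[f(n) for n in self.variables],
            arities={f(n): r for n, r in self.arities.items()},
            inter_parents={f(n): tuple(f(p) for p in ps)
                           for n, ps in self.inter_parents.items()},
            target=f(self.target),
            hidden_children=tuple(f(n) for n in self.hidden_children),
            n_hidden=self.n_hidden,
            transition=None if self.transition is None
            else self.transition.copy(),
            initial=None if self.initial is None else self.initial.copy(),
            tables={f(n): t.copy() for n, t in self.tables.items()},
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "variables": self.variables,
            "arities": self.arities,
            "inter_parents": {n: list(p)
                              for n, p in self.inter_parents.items()},
            "target": self.target,
            "hidden_children": list(self.hidden_children),
            "n_hidden": self.n_hidden,
            "transition": None if self.transition is None
            else self.transition.tolist(),
            "initial": None if self.initial is None else self.initial.tolist(),
            "tables": {n: t.tolist() for n, t in self.tables.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DBNModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            variables=list(d["variables"]),
            arities={k: int(v) for k, v in d["arities"].items()},
            inter_parents={n: tuple(p)
                           for n, p in d["inter_parents"].items()},
            target=d["target"],
            hidden_children=tuple(d["hidden_children"]),
            n_hidden=int(d["n_hidden"]),
            transition=None if d["transition"] is None
            else np.asarray(d["transition"]),
            initial=None if d["initial"] is None else np.asarray(d["initial"]),
            tables={n: np.asarray(t) for n, t in d["tables"].items()},
        )


@dataclass
class EMReport:
    """Fitting diagnostics for one EM run (best restart).

    ``objective_trace`` is the quantity EM provably never decreases: the data
    log-likelihood of the hidden-chain part plus the Dirichlet add-``alpha``
    log-prior of the smoothed parameters (for ``alpha = 0`` it is the plain
    log-likelihood).  ``ll_trace`` records the raw data log-likelihood at the
    same iterations for inspection.
    """

    objective_trace: np.ndarray
    ll_trace: np.ndarray
    converged: bool
    n_restarts: int
    best_restart: int
    seed: int
    restart_final_objectives: np.ndarray | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.objective_trace)


@dataclass
class PredictionSeries:
    """Per-year one-step-ahead target predictions and hidden-state inference.

    ``flagged`` marks years whose prediction could not condition on the
    previous year's observations (the first year, and years after a survey
    gap): those use the hidden-state prior marginalized over parent
    configurations.
    """

    target: str
    years: np.ndarray
    observed: np.ndarray
    predicted_dist: np.ndarray
    predicted_state: np.ndarray
    expected_state: np.ndarray
    flagged: np.ndarray
    smoothed_hidden: np.ndarray
    map_path: np.ndarray

    def accuracy(self, include_flagged: bool = False) -> float:
        keep = np.ones(len(self.years), bool) if include_flagged \
            else ~self.flagged
        if not keep.any():
            return float("nan")
        return float(np.mean(self.predicted_state[keep] == self.observed[keep]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years,
            "observed": self.observed,
            "predicted": self.predicted_state,
            "p_hidden_state1": self.smoothed_hidden[:, 1],
            "map_state": self.map_path,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# emission bookkeeping
# ---------------------------------------------------------------------------

def _series_layout(model: DBNModel, dataset: DiscreteDataset,
                   years: np.ndarray):
    """Per-year parent-configuration indices and validity for hidden children.

    Returns (gaps, valid, configs, child_states): ``gaps[t]`` is the calendar
    distance to the previous record (0 for t = 0); ``valid[node][t]`` is True
    when ``node``'s conditional is defined at year t — always, for a node
    with no previous-slice parents; only when the previous calendar year was
    observed, otherwise; ``configs[node][t]`` is the mixed-radix parent
    configuration of ``node`` at year t (from slice t-1), defined only where
    valid.
    """
    missing = set(model.variables) - set(dataset.variables)
    if missing:
        raise ValueError(f"dataset lacks model variables: {sorted(missing)}")
    for v in model.variables:
        if dataset.arity_of(v) != model.arities[v]:
            raise ValueError(
                f"arity mismatch for {v!r}: model {model.arities[v]}, "
                f"data {dataset.arity_of(v)}")
    years = np.asarray(years, dtype=int)
    t_len = dataset.n_records
    gaps = np.zeros(t_len, dtype=int)
    gaps[1:] = np.diff(years)
    if np.any(gaps[1:] < 1):
        raise ValueError("years must be strictly increasing")
    consecutive = gaps == 1

    arities = dataset.arities
    valid: dict[str, np.ndarray] = {}
    configs: dict[str, np.ndarray] = {}
    child_states: dict[str, np.ndarray] = {}
    for node in model.variables:
        parents = model.inter_parents.get(node, ())
        pidx = [dataset.index_of(p) for p in parents]
        j, _ = _parent_config_index(dataset.records, pidx, arities)
        cfg = np.zeros(t_len, dtype=np.int64)
        cfg[1:] = j[:-1]  # parents live in the previous slice
        configs[node] = cfg
        child_states[node] = dataset.column(node)
        valid[node] = (np.ones(t_len, dtype=bool) if not parents
                       else consecutive)
    return gaps, valid, configs, child_states


def _emissions(model: DBNModel, valid: dict[str, np.ndarray],
               configs: dict[str, np.ndarray],
               child_states: dict[str, np.ndarray]) -> np.ndarray:
    """e[t, h] = prod over hidden children of P(x_t | parents_{t-1}, H_t = h);
    a node contributes 1 at years where its conditional is undefined."""
    t_len = next(iter(valid.values())).shape[0]
    e = np.ones((t_len, model.n_hidden))
    for node in model.hidden_children:
        tab = model.tables[node]  # (q, n_hidden, r)
        idx = np.where(valid[node])[0]
        e[idx] *= tab[configs[node][idx], :, child_states[node][idx]]
    return e


def _forward_backward(model: DBNModel, gaps: np.ndarray, e: np.ndarray):
    """Scaled forward-backward over the hidden chain.

    Survey gaps are bridged with the multi-step transition matrix.  Returns
    (log-likelihood, filtered, smoothed, xi) where ``xi[t]`` holds the joint
    P(H_{t-1}, H_t | all data) for single-year steps (zeros across gaps, so
    transition counts only accrue from real year-to-year steps).
    """
    a = model.transition
    t_len, n_h = e.shape
    alpha = np.zeros((t_len, n_h))
    scale = np.zeros(t_len)

    step = [None] * t_len  # transition matrix into slice t
    for t in range(1, t_len):
        step[t] = np.linalg.matrix_power(a, int(gaps[t]))

    raw = model.initial * e[0]
    scale[0] = raw.sum()
    alpha[0] = raw / scale[0]
    for t in range(1, t_len):
        raw = (alpha[t - 1] @ step[t]) * e[t]
        scale[t] = raw.sum()
        if scale[t] <= 0:
            raise ValueError("impossible observation sequence under model")
        alpha[t] = raw / scale[t]
    ll = float(np.sum(np.log(scale)))

    beta = np.zeros((t_len, n_h))
    beta[-1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[t] = step[t + 1] @ (e[t + 1] * beta[t + 1])
        beta[t] /= beta[t].max()  # guard underflow; gamma renormalizes

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.zeros((t_len, n_h, n_h))
    for t in range(1, t_len):
        if gaps[t] != 1:
            continue
        m = (alpha[t - 1][:, None] * a) * (e[t] * beta[t])[None, :]
        xi[t] = m / m.sum()
    return ll, alpha, gamma, xi


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _fit_static_tables(model: DBNModel, valid, configs, child_states,
                       alpha_smooth: float) -> tuple[dict[str, np.ndarray], float]:
    """Count-based conditionals for hidden-free observables, plus their LL."""
    tables: dict[str, np.ndarray] = {}
    ll = 0.0
    for node in model.variables:
        if node in model.hidden_children:
            continue
        idx = np.where(valid[node])[0]
        q, r = model.q_of(node), model.arities[node]
        counts = np.zeros((q, r))
        np.add.at(counts, (configs[node][idx], child_states[node][idx]), 1.0)
        tab = (counts + alpha_smooth)
        tab /= tab.sum(axis=1, keepdims=True)
        tables[node] = tab
        ll += float(np.sum(np.log(tab[configs[node][idx],
                                      child_states[node][idx]])))
    return tables, ll


def _log_prior(model: DBNModel, alpha_smooth: float, sticky: float) -> float:
    """Log-prior of the hidden-chain parameters: Dirichlet add-``alpha``
    everywhere plus ``sticky`` extra pseudo-counts on the transition
    diagonal (persistent-regime prior)."""
    lp = 0.0
    if alpha_smooth > 0:
        lp += alpha_smooth * float(np.sum(np.log(model.initial)))
        lp += alpha_smooth * float(np.sum(np.log(model.transition)))
        for node in model.hidden_children:
            lp += alpha_smooth * float(np.sum(np.log(model.tables[node])))
    if sticky > 0:
        lp += sticky * float(np.sum(np.log(np.diag(model.transition))))
    return lp


def fit_em(
    skeleton: DBNModel,
    dataset: DiscreteDataset,
    years: Sequence[int],
    init: str = "auto",
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int = 0,
    alpha_smooth: float = 1.0,
    sticky: float = 25.0,
) -> tuple[DBNModel, EMReport]:
    """Baum-Welch-style EM for the hidden chain and its children.

    Hidden-free observable conditionals are closed-form counts and fitted
    once.  Each restart ascends the penalized likelihood — add-
    ``alpha_smooth`` Dirichlet smoothing everywhere plus ``sticky`` extra
    pseudo-counts on the transition diagonal — until the relative change
    drops below ``tol`` or ``max_iter`` is reached; the restart with the
    best final objective wins.

    The sticky prior encodes that the latent state is a *regime*: persistent
    by definition, switching rarely.  Without it the binary hidden node is
    free enough at these sample sizes to chase record-level noise with a
    fast-switching path; the diagonal pseudo-counts make such solutions pay
    for every switch while a genuine regime (a handful of switches per
    series) is barely taxed.

    ``init="auto"`` (default) mixes deterministic segmented starts — the
    hidden path initialized as a step function at several candidate split
    points, the natural basin for a one-shot regime change — with random
    Dirichlet starts; ``"random"`` and ``"uniform-perturbed"`` use only
    random starts.  Restart r derives its generator from ``seed + r``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if init not in ("auto", "random", "uniform-perturbed"):
        raise ValueError(f"unknown init {init!r}")
    years = np.asarray(years, dtype=int)
    gaps, valid, configs, child_states = _series_layout(
        skeleton, dataset, years)
    if not np.any(gaps == 1):
        raise ValueError("need at least two consecutive years to fit")
    static_tables, static_ll = _fit_static_tables(
        skeleton, valid, configs, child_states, alpha_smooth)

    n_h = skeleton.n_hidden
    t_len = dataset.n_records
    n_seg = min(4, n_restarts - 1) if init == "auto" and n_h == 2 else 0
    seg_fracs = np.linspace(0.25, 0.75, n_seg) if n_seg else []

    best: tuple[float, DBNModel, list[float], list[float], int, bool] | None = None
    finals = np.zeros(n_restarts)

    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        model = skeleton.skeleton_copy()
        model.tables = dict(static_tables)
        if r < n_seg:
            # segmented start: M-step from a soft step-function hidden path
            split = int(round(seg_fracs[r] * t_len))
            gamma0 = np.full((t_len, 2), 0.1)
            gamma0[:split, 0] = 0.9
            gamma0[split:, 1] = 0.9
            _m_step(model, gamma0, _soft_xi(gamma0, gaps), valid, configs,
                    child_states, alpha_smooth, sticky)
        elif init == "uniform-perturbed":
            jitter = 0.01
            model.initial = _normalize(
                np.ones(n_h) + jitter * rng.random(n_h))
            model.transition = _normalize(
                np.ones((n_h, n_h)) + jitter * rng.random((n_h, n_h)))
            for node in model.hidden_children:
                q, rr = model.q_of(node), model.arities[node]
                model.tables[node] = _normalize(
                    np.ones((q, n_h, rr)) + jitter * rng.random((q, n_h, rr)))
        else:
            model.initial = rng.dirichlet(np.ones(n_h))
            model.transition = rng.dirichlet(np.ones(n_h), size=n_h)
            for node in model.hidden_children:
                q, rr = model.q_of(node), model.arities[node]
                model.tables[node] = rng.dirichlet(
                    np.ones(rr), size=(q, n_h))

        obj_trace: list[float] = []
        ll_trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            e = _emissions(model, valid, configs, child_states)
            ll, _, gamma, xi = _forward_backward(model, gaps, e)
            obj = ll + _log_prior(model, alpha_smooth, sticky)
            ll_trace.append(ll + static_ll)
            obj_trace.append(obj)
            if len(obj_trace) > 1:
                prev = obj_trace[-2]
                if abs(obj - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
            _m_step(model, gamma, xi.sum(axis=0), valid, configs,
                    child_states, alpha_smooth, sticky)
        final = obj_trace[-1]
        finals[r] = final
        if best is None or final > best[0]:
            best = (final, model, obj_trace, ll_trace, r, converged)

    _, model, obj_trace, ll_trace, r_best, converged = best
    report = EMReport(
        objective_trace=np.asarray(obj_trace),
        ll_trace=np.asarray(ll_trace),
        converged=converged,
        n_restarts=n_restarts,
        best_restart=r_best,
        seed=seed,
        restart_final_objectives=finals,
    )
    return model, report


def _soft_xi(gamma: np.ndarray, gaps: np.ndarray) -> np.ndarray:
    """Expected transition counts implied by an (independent) soft path."""
    xi = np.zeros((gamma.shape[1], gamma.shape[1]))
    for t in range(1, gamma.shape[0]):
        if gaps[t] == 1:
            xi += np.outer(gamma[t - 1], gamma[t])
    return xi


def _m_step(model: DBNModel, gamma: np.ndarray, xi_sum: np.ndarray,
            valid, configs, child_states,
            alpha_smooth: float, sticky: float) -> None:
    n_h = model.n_hidden
    model.initial = _normalize(gamma[0] + alpha_smooth)
    model.transition = _normalize(
        xi_sum + alpha_smooth + sticky * np.eye(n_h))
    for node in model.hidden_children:
        idx = np.where(valid[node])[0]
        q, rr = model.q_of(node), model.arities[node]
        counts = np.zeros((q, n_h, rr))
        np.add.at(
            counts,
            (configs[node][idx], slice(None), child_states[node][idx]),
            gamma[idx],
        )
        model.tables[node] = _normalize(counts + alpha_smooth)


def _normalize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x / x.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# prediction and hidden-state inference
# ---------------------------------------------------------------------------

def predict_one_step(model: DBNModel, dataset: DiscreteDataset,
                     years: Sequence[int]) -> PredictionSeries:
    """Causal one-step-ahead prediction of the target plus hidden inference.

    The filtered hidden posterior P(H_{t-1} | obs up to t-1) is propagated
    one step and combined with the target's conditional given the previous
    year's observed parent states; the first year (and any year after a
    survey gap) cannot condition on its predecessor and falls back to the
    parent-marginalized prior prediction, marked in ``flagged``.  Point
    predictions are the argmax state with ties to the lower state.
    """
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    years = np.asarray(years, dtype=int)
    gaps, valid, configs, child_states = _series_layout(model, dataset, years)
    e = _emissions(model, valid, configs, child_states)
    t_len = dataset.n_records
    n_h = model.n_hidden
    r_t = model.arities[model.target]
    tab = model.tables[model.target]  # (q, n_h, r)
    tab_marg = tab.mean(axis=0)       # parent-marginalized fallback (n_h, r)

    pred_dist = np.zeros((t_len, r_t))
    flagged = np.zeros(t_len, dtype=bool)
    filtered = np.zeros((t_len, n_h))

    for t in range(t_len):
        if t == 0:
            h_pred = model.initial.copy()
        else:
            step = np.linalg.matrix_power(model.transition, int(gaps[t]))
            h_pred = filtered[t - 1] @ step
        if t > 0 and valid[model.target][t]:
            pred_dist[t] = h_pred @ tab[configs[model.target][t]]
        else:
            flagged[t] = True
            pred_dist[t] = h_pred @ tab_marg
        raw = h_pred * e[t]
        z = raw.sum()
        if z <= 0:
            raise ValueError("impossible observation sequence under model")
        filtered[t] = raw / z

    smoothed, map_path = infer_hidden_states(model, dataset, years)
    observed = child_states[model.target]
    return PredictionSeries(
        target=model.target,
        years=years,
        observed=observed,
        predicted_dist=pred_dist,
        predicted_state=np.argmax(pred_dist, axis=1),
        expected_state=pred_dist @ np.arange(r_t),
        flagged=flagged,
        smoothed_hidden=smoothed,
        map_path=map_path,
    )


def infer_hidden_states(model: DBNModel, dataset: DiscreteDataset,
                        years: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed posteriors P(H_t | obs_{1:T}) and the Viterbi MAP path."""
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    years = np.asarray(years, dtype=int)
    gaps, valid, configs, child_states = _series_layout(model, dataset, years)
    e = _emissions(model, valid, configs, child_states)
    _, _, gamma, _ = _forward_backward(model, gaps, e)

    # Viterbi in log space
    t_len, n_h = e.shape
    with np.errstate(divide="ignore"):
        log_e = np.log(e)
        log_pi = np.log(model.initial)
    delta = np.zeros((t_len, n_h))
    back = np.zeros((t_len, n_h), dtype=int)
    delta[0] = log_pi + log_e[0]
    for t in range(1, t_len):
        step = np.linalg.matrix_power(model.transition, int(gaps[t]))
        with np.errstate(divide="ignore"):
            log_a = np.log(step)
        cand = delta[t - 1][:, None] + log_a
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], np.arange(n_h)] + log_e[t]
    path = np.zeros(t_len, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(t_len - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return gamma, path


def align_hidden_labels(path: np.ndarray, years: Sequence[int],
                        collapse_year: int) -> np.ndarray:
    """Resolve EM label switching: state 1 = "collapsed-like".

    Flips the binary labelling if the majority MAP state over the
    post-collapse span is 0, so that 1 means the post-collapse regime.
    """
    path = np.asarray(path, dtype=int)
    years = np.asarray(years, dtype=int)
    post = path[years >= collapse_year]
    if post.size and post.mean() < 0.5:
        return 1 - path
    return path


def transfer_model(
    donor: DBNModel,
    mapping: Mapping[str, str] | "EquivalenceResultLike",
    target_data: DiscreteDataset,
    years: Sequence[int],
) -> PredictionSeries:
    """Apply a donor-region model to another region via a species mapping.

    ``mapping`` sends every donor observable to a species of the target
    region (an equivalence-search result object with ``best_ever_vars2`` is
    accepted directly).  Structure *and* donor parameters are carried over
    verbatim — no re-fitting — and one-step-ahead prediction plus
    hidden-state inference run on the target region's data.
    """
    if hasattr(mapping, "best_ever_vars2"):
        mapping = mapping.best_ever_vars2
    mapping = dict(mapping)
    missing = set(donor.variables) - set(mapping)
    if missing:
        raise ValueError(f"mapping misses donor slots: {sorted(missing)}")
    if len(set(mapping.values())) != len(donor.variables):
        raise ValueError("mapping must be injective over donor slots")
    relabelled = donor.relabel(mapping)
    return predict_one_step(relabelled, target_data, years)
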