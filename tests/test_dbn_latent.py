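"""Latent-regime DBN: transition pairing, REVEAL, EM, filtering, transfer."""

import itertools

import numpy as np
import pytest

from funcequiv.data_model import DiscreteDataset
from funcequiv.dbn_latent import (
    DBNModel,
    align_hidden_labels,
    fit_em,
    infer_hidden_states,
    make_transition_dataset,
    predict_one_step,
    reveal_search,
    transfer_model,
    _emissions,
    _forward_backward,
    _series_layout,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def path_enumeration_posteriors(model, dataset, years):
    """Smoothed hidden posteriors by explicit summation over all 2^T paths."""
    years = np.asarray(years, dtype=int)
    gaps, valid, configs, child_states = _series_layout(model, dataset, years)
    e = _emissions(model, valid, configs, child_states)
    t_len = dataset.n_records
    n_h = model.n_hidden
    probs = {}
    total = 0.0
    marg = np.zeros((t_len, n_h))
    for path in itertools.product(range(n_h), repeat=t_len):
        p = model.initial[path[0]] * e[0, path[0]]
        for t in range(1, t_len):
            step = np.linalg.matrix_power(model.transition, int(gaps[t]))
            p *= step[path[t - 1], path[t]] * e[t, path[t]]
        probs[path] = p
        total += p
        for t in range(t_len):
            marg[t, path[t]] += p
    best = max(probs, key=probs.get)
    return marg / total, np.array(best), np.log(total)


def _simple_model(tables_e, a, pi, n_states=3):
    """One parentless observable 'x' driven by the hidden node."""
    return DBNModel(
        variables=["x"], arities={"x": n_states}, inter_parents={"x": ()},
        target="x", hidden_children=("x",),
        transition=np.asarray(a), initial=np.asarray(pi),
        tables={"x": np.asarray(tables_e)[None, :, :]},
    )


# ---------------------------------------------------------------------------
# transition pairing
# ---------------------------------------------------------------------------

class TestMakeTransitionDataset:
    def test_complete_span_counts(self, rng):
        ds = make_dataset({"x": rng.integers(0, 3, 46)})
        td = make_transition_dataset(ds, np.arange(1963, 2009))
        assert td.n_pairs == 45

    def test_gap_skipped(self, rng):
        ds = make_dataset({"x": rng.integers(0, 2, 4)})
        td = make_transition_dataset(ds, [2000, 2001, 2003, 2004])
        assert td.n_pairs == 2
        assert list(td.years_cur) == [2001, 2004]

    def test_single_year_rejected(self):
        ds = make_dataset({"x": [1]})
        with pytest.raises(ValueError):
            make_transition_dataset(ds, [2000])

    def test_pairs_are_lagged_copies(self, rng):
        col = rng.integers(0, 3, 10)
        ds = make_dataset({"x": col})
        td = make_transition_dataset(ds, np.arange(10))
        assert np.array_equal(td.prev[:, 0], col[:-1])
        assert np.array_equal(td.cur[:, 0], col[1:])


# ---------------------------------------------------------------------------
# REVEAL
# ---------------------------------------------------------------------------

class TestRevealSearch:
    def test_ar1_self_edges_recovered(self):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            n, t_len = 3, 201
            states = np.zeros((t_len, n), dtype=int)
            states[0] = g.integers(0, 2, n)
            for t in range(1, t_len):
                keep = g.random(n) > 0.1
                states[t] = np.where(keep, states[t - 1],
                                     g.integers(0, 2, n))
            ds = DiscreteDataset([f"s{i}" for i in range(n)],
                                 np.full(n, 2), states)
            td = make_transition_dataset(ds, np.arange(t_len))
            found = reveal_search(td, max_parents=2)
            if all(found[f"s{i}"] == (f"s{i}",) for i in range(n)):
                hits += 1
        assert hits >= 18

    def test_max_parents_zero(self, rng):
        ds = make_dataset({"x": rng.integers(0, 2, 30),
                           "y": rng.integers(0, 2, 30)})
        td = make_transition_dataset(ds, np.arange(30))
        assert all(v == () for v in reveal_search(td, max_parents=0).values())

    def test_min_parents_forces_best_single(self, rng):
        ds = make_dataset({"x": rng.integers(0, 2, 30),
                           "y": rng.integers(0, 2, 30)})
        td = make_transition_dataset(ds, np.arange(30))
        found = reveal_search(td, max_parents=2, min_parents=1)
        assert all(len(v) >= 1 for v in found.values())

    def test_greedy_not_worse_than_exhaustive_singletons_pairs(self, rng):
        """Greedy family score >= every <=2-subset's score would be false in
        general; assert it at least matches the best single parent."""
        from funcequiv.bn_core import family_score
        g = np.random.default_rng(5)
        cols = {f"v{i}": g.integers(0, 2, 120) for i in range(5)}
        cols["t"] = np.roll(cols["v0"], 1) ^ (g.random(120) < 0.05)
        ds = make_dataset({k: v.astype(int) for k, v in cols.items()})
        td = make_transition_dataset(ds, np.arange(120))
        stacked = td.to_dataset()
        found = reveal_search(td, targets=["t"], max_parents=2)
        got = family_score(stacked, "t",
                           [p + "__prev" for p in found["t"]], "bic")
        best_single = max(
            family_score(stacked, "t", [c], "bic")
            for c in stacked.variables if c.endswith("__prev"))
        assert got >= best_single - 1e-9


# ---------------------------------------------------------------------------
# forward-backward and Viterbi vs enumeration
# ---------------------------------------------------------------------------

class TestExactness:
    @pytest.mark.parametrize("t_len", [4, 6, 8])
    def test_smoothed_match_enumeration(self, t_len, rng):
        e_tab = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
        model = _simple_model(e_tab, [[0.85, 0.15], [0.2, 0.8]], [0.6, 0.4])
        obs = rng.integers(0, 3, t_len)
        ds = make_dataset({"x": obs}, arities=[3])
        years = np.arange(2000, 2000 + t_len)
        smoothed, _ = infer_hidden_states(model, ds, years)
        want, best, ll_want = path_enumeration_posteriors(model, ds, years)
        assert np.allclose(smoothed, want, atol=1e-9)

    def test_viterbi_matches_enumeration_argmax(self, rng):
        e_tab = np.array([[0.8, 0.15, 0.05], [0.05, 0.15, 0.8]])
        model = _simple_model(e_tab, [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        obs = np.array([0, 0, 2, 2, 0, 2])
        ds = make_dataset({"x": obs}, arities=[3])
        years = np.arange(6)
        _, path = infer_hidden_states(model, ds, years)
        _, best, _ = path_enumeration_posteriors(model, ds, years)
        assert np.array_equal(path, best)

    def test_gap_bridged_with_matrix_power(self, rng):
        """A two-year gap uses the squared transition matrix: posteriors
        must match enumeration run with the same convention."""
        e_tab = np.array([[0.7, 0.3], [0.2, 0.8]])
        model = _simple_model(e_tab, [[0.8, 0.2], [0.3, 0.7]], [0.5, 0.5],
                              n_states=2)
        obs = np.array([0, 1, 1, 0])
        ds = make_dataset({"x": obs})
        years = np.array([2000, 2001, 2003, 2004])  # gap before 2003
        smoothed, _ = infer_hidden_states(model, ds, years)
        want, _, _ = path_enumeration_posteriors(model, ds, years)
        assert np.allclose(smoothed, want, atol=1e-9)

    def test_deterministic_emissions_pin_posteriors(self):
        e_tab = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = _simple_model(e_tab, [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5],
                              n_states=2)
        obs = np.array([0, 0, 1, 1, 1])
        ds = make_dataset({"x": obs})
        smoothed, path = infer_hidden_states(model, ds, np.arange(5))
        assert np.allclose(smoothed[np.arange(5), obs], 1.0)
        assert np.array_equal(path, obs)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

class TestEM:
    def _sample_hmm(self, g, t_len, a, e_tab, pi):
        h = np.zeros(t_len, int)
        x = np.zeros(t_len, int)
        h[0] = g.choice(len(pi), p=pi)
        x[0] = g.choice(e_tab.shape[1], p=e_tab[h[0]])
        for t in range(1, t_len):
            h[t] = g.choice(len(pi), p=a[h[t]-h[t]] if False else a[h[t-1]])
            x[t] = g.choice(e_tab.shape[1], p=e_tab[h[t]])
        return h, x

    def test_transition_recovery_deterministic_emissions(self, rng):
        a = np.array([[0.9, 0.1], [0.15, 0.85]])
        e_tab = np.array([[0.97, 0.02, 0.01], [0.01, 0.02, 0.97]])
        pi = np.array([0.5, 0.5])
        h, x = self._sample_hmm(np.random.default_rng(3), 200, a, e_tab, pi)
        ds = make_dataset({"x": x}, arities=[3])
        skel = DBNModel(variables=["x"], arities={"x": 3},
                        inter_parents={"x": ()}, target="x")
        model, rep = fit_em(skel, ds, np.arange(200), seed=0, sticky=0.0)
        est = model.transition
        if est[0, 0] < est[0, 1]:  # label switching
            est = est[::-1, ::-1]
        assert np.abs(est - a).max() < 0.05

    def test_objective_trace_monotone_many_seeds(self, rng):
        for seed in range(50):
            g = np.random.default_rng(seed)
            x = g.integers(0, 3, 40)
            ds = make_dataset({"x": x}, arities=[3])
            skel = DBNModel(variables=["x"], arities={"x": 3},
                            inter_parents={"x": ()}, target="x")
            model, rep = fit_em(skel, ds, np.arange(40), seed=seed,
                                n_restarts=2, max_iter=60)
            assert np.all(np.diff(rep.objective_trace) >= -1e-9)

    def test_hmmlearn_cross_check(self, rng):
        """Forward log-likelihood of a fitted parentless-emission model
        agrees with hmmlearn's independent implementation."""
        from hmmlearn.hmm import CategoricalHMM
        x = rng.integers(0, 3, 80)
        ds = make_dataset({"x": x}, arities=[3])
        skel = DBNModel(variables=["x"], arities={"x": 3},
                        inter_parents={"x": ()}, target="x")
        model, rep = fit_em(skel, ds, np.arange(80), seed=1)
        ref = CategoricalHMM(n_components=2, init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.emissionprob_ = model.tables["x"][0]
        assert rep.ll_trace[-1] == pytest.approx(
            ref.score(x.reshape(-1, 1)), abs=1e-8)

    def test_best_restart_selection(self, rng):
        x = rng.integers(0, 2, 30)
        ds = make_dataset({"x": x})
        skel = DBNModel(variables=["x"], arities={"x": 2},
                        inter_parents={"x": ()}, target="x")
        _, rep = fit_em(skel, ds, np.arange(30), seed=0, n_restarts=6,
                        max_iter=40)
        assert rep.best_restart == int(np.argmax(
            rep.restart_final_objectives))
        assert rep.objective_trace[-1] == pytest.approx(
            rep.restart_final_objectives[rep.best_restart])


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

class TestPrediction:
    def test_copy_dynamics_predicts_lagged_observation(self, rng):
        """Near-deterministic copy dynamics: the point prediction at every
        year is last year's state, and on data actually produced by the
        copy process (a constant series) accuracy is 1."""
        eps = 1e-6
        copy = np.full((3, 3), eps / 2) + (1 - 1.5 * eps) * np.eye(3)
        copy /= copy.sum(axis=1, keepdims=True)
        tab = np.stack([copy, copy], axis=1)  # (q=3, h=2, r=3)
        model = DBNModel(
            variables=["x"], arities={"x": 3}, inter_parents={"x": ("x",)},
            target="x", transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
            initial=np.array([0.5, 0.5]), tables={"x": tab})
        col = rng.integers(0, 3, 30)
        series = predict_one_step(model, make_dataset({"x": col},
                                                      arities=[3]),
                                  np.arange(30))
        assert np.array_equal(series.predicted_state[1:], col[:-1])
        assert series.flagged[0] and not series.flagged[1:].any()
        const = np.full(30, 2)
        series2 = predict_one_step(model, make_dataset({"x": const},
                                                       arities=[3]),
                                   np.arange(30))
        assert series2.accuracy() == 1.0

    def test_hidden_irrelevant_matches_hfree_computation(self, rng):
        """Emissions identical across hidden states: predictions equal the
        direct conditional prediction with no latent variable."""
        g = np.random.default_rng(0)
        col = g.integers(0, 2, 40)
        ds = make_dataset({"x": col})
        cond = np.array([[0.8, 0.2], [0.3, 0.7]])
        tab = np.stack([cond, cond], axis=1)
        model = DBNModel(
            variables=["x"], arities={"x": 2}, inter_parents={"x": ("x",)},
            target="x", transition=np.array([[0.6, 0.4], [0.2, 0.8]]),
            initial=np.array([0.3, 0.7]), tables={"x": tab})
        series = predict_one_step(model, ds, np.arange(40))
        for t in range(1, 40):
            assert series.predicted_dist[t] == pytest.approx(
                cond[col[t - 1]], abs=1e-12)

    def test_predictions_causal_under_future_shuffle(self, rng):
        """Shuffling observations after year t never changes the
        prediction at t."""
        col = rng.integers(0, 3, 25)
        ds = make_dataset({"x": col}, arities=[3])
        e_tab = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        q_tab = np.stack([e_tab[0:1].repeat(3, 0), e_tab[1:2].repeat(3, 0)],
                         axis=1)
        model = DBNModel(
            variables=["x"], arities={"x": 3}, inter_parents={"x": ("x",)},
            target="x", transition=np.array([[0.8, 0.2], [0.2, 0.8]]),
            initial=np.array([0.5, 0.5]), tables={"x": q_tab})
        base = predict_one_step(model, ds, np.arange(25))
        cut = 12
        col2 = col.copy()
        col2[cut:] = col[cut:][::-1]
        ds2 = make_dataset({"x": col2}, arities=[3])
        other = predict_one_step(model, ds2, np.arange(25))
        assert np.allclose(base.predicted_dist[: cut + 1],
                           other.predicted_dist[: cut + 1], atol=1e-12)

    def test_filtered_prediction_matches_enumeration(self, rng):
        """One-step-ahead target distribution equals the brute-force
        conditional P(x_t | x_{1:t-1}) for a short series."""
        e_tab = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
        model = _simple_model(e_tab, [[0.85, 0.15], [0.2, 0.8]], [0.6, 0.4])
        obs = rng.integers(0, 3, 7)
        ds = make_dataset({"x": obs}, arities=[3])
        years = np.arange(7)
        series = predict_one_step(model, ds, years)
        # brute force: joint over paths and x values
        for t in range(1, 7):
            num = np.zeros(3)
            for x_t in range(3):
                o2 = obs.copy()
                o2[t] = x_t
                total = 0.0
                for path in itertools.product(range(2), repeat=t + 1):
                    p = model.initial[path[0]] * e_tab[path[0], o2[0]]
                    for u in range(1, t + 1):
                        p *= model.transition[path[u - 1], path[u]] \
                            * e_tab[path[u], o2[u]]
                    total += p
                num[x_t] = total
            want = num / num.sum()
            assert np.allclose(series.predicted_dist[t], want, atol=1e-9)


# ---------------------------------------------------------------------------
# transfer and label alignment
# ---------------------------------------------------------------------------

class TestTransfer:
    def _fitted_toy_model(self, rng):
        col = rng.integers(0, 2, 40)
        ds = make_dataset({"u": col, "v": 1 - col})
        skel = DBNModel(variables=["u", "v"], arities={"u": 2, "v": 2},
                        inter_parents={"u": ("u",), "v": ("u",)},
                        target="u")
        model, _ = fit_em(skel, ds, np.arange(40), seed=0, n_restarts=3,
                          max_iter=50)
        return model, ds

    def test_identity_transfer_is_noop(self, rng):
        model, ds = self._fitted_toy_model(rng)
        direct = predict_one_step(model, ds, np.arange(40))
        via = transfer_model(model, {"u": "u", "v": "v"}, ds, np.arange(40))
        assert np.allclose(direct.predicted_dist, via.predicted_dist)
        assert np.array_equal(direct.map_path, via.map_path)

    def test_unmapped_slot_rejected(self, rng):
        model, ds = self._fitted_toy_model(rng)
        with pytest.raises(ValueError, match="misses"):
            transfer_model(model, {"u": "u"}, ds, np.arange(40))

    def test_relabel_round_trip(self, rng):
        model, ds = self._fitted_toy_model(rng)
        fwd = model.relabel({"u": "a", "v": "b"})
        back = fwd.relabel({"a": "u", "b": "v"})
        assert back.variables == model.variables
        assert np.allclose(back.tables["u"], model.tables["u"])

    def test_align_hidden_labels_flips_inverted(self):
        years = np.arange(1980, 2000)
        path = (years < 1990).astype(int)  # inverted labelling
        aligned = align_hidden_labels(path, years, 1990)
        assert np.array_equal(aligned, (years >= 1990).astype(int))

    def test_model_json_round_trip(self, rng, tmp_path):
        model, _ = self._fitted_toy_model(rng)
        p = tmp_path / "m.json"
        model.to_json(p)
        back = DBNModel.from_json(p)
        assert back.variables == model.variables
        assert np.allclose(back.transition, model.transition)
        assert np.allclose(back.tables["v"], model.tables["v"])
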