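"""End-to-end cross-region workflow.

Chains the individual steps in the order the analysis runs: discretize both
regions, wrapper-select collapse-relevant species in the donor region, learn
a donor network and a latent-regime DBN over the selected species, search
the other region for functionally equivalent species by simulated annealing,
and transfer the donor DBN onto them for one-step-ahead prediction and
hidden-state inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bn_core import CPTSet, DAGStructure, fit_parameters, k2_search
from .data_model import BiomassTable, DiscreteDataset, discretize, label_collapse
from .dbn_latent import (
    PREV_SUFFIX,
    DBNModel,
    EMReport,
    PredictionSeries,
    fit_em,
    make_transition_dataset,
    predict_one_step,
    reveal_search,
    transfer_model,
)
from .feature_selection import FeatureRanking, wrapper_select
from .functional_equivalence import (
    AnnealingSchedule,
    EquivalenceProblem,
    EquivalenceResult,
    functional_equivalence_search,
)

__all__ = ["TransferResult", "run_transfer_pipeline",
           "temporal_equivalence_problem"]


def temporal_equivalence_problem(
    inter_parents: dict[str, tuple[str, ...]],
    variables: list[str],
    slot_arities: dict[str, int],
    data_b: DiscreteDataset,
    years_b,
    candidate_pool: list[str] | None = None,
    score_kind: str = "bic",
    data_a: DiscreteDataset | None = None,
    years_a=None,
) -> EquivalenceProblem:
    """Equivalence problem imposing a two-slice (DBN) donor structure.

    The donor's inter-slice parent sets are unrolled into a two-slice DAG
    whose previous-slice twin of each slot is tied to it (one species fills
    both), and the target region's data become the stacked consecutive-year
    transition pairs, so an assignment is scored by how well the donor's
    *dynamics* fit the candidate species.  With ``score_kind="transfer_ll"``
    (donor-parameterized scoring) the donor region's data must be supplied
    so the two-slice conditionals can be parametrized there.
    """
    nodes = [v + PREV_SUFFIX for v in variables] + list(variables)
    parents = {v: tuple(p + PREV_SUFFIX for p in inter_parents.get(v, ()))
               for v in variables}
    two_slice = DAGStructure(nodes, parents)
    stacked = make_transition_dataset(data_b, years_b).to_dataset()
    cpts = None
    if score_kind == "transfer_ll":
        if data_a is None or years_a is None:
            raise ValueError("transfer_ll scoring needs the donor data")
        stacked_a = make_transition_dataset(
            data_a.subset(variables), years_a).to_dataset()
        cpts = fit_parameters(stacked_a, two_slice, estimator="laplace")
    if candidate_pool is None:
        candidate_pool = [v for v in data_b.variables
                          if data_b.arity_of(v) in set(slot_arities.values())]
    return EquivalenceProblem(
        bn1_structure=two_slice,
        data2=stacked,
        candidate_pool=candidate_pool,
        score_kind=score_kind,
        bn1_cpts=cpts,
        slot_arities=dict(slot_arities),
        tied_prev_suffix=PREV_SUFFIX,
    )


@dataclass
class TransferResult:
    """Everything the cross-region workflow produces."""

    selected_species: list[str]
    ranking: FeatureRanking
    donor_structure: DAGStructure
    donor_cpts: CPTSet
    dbn: DBNModel
    em_report: EMReport
    equivalence: EquivalenceResult
    donor_predictions: PredictionSeries
    transfer_predictions: PredictionSeries


def run_transfer_pipeline(
    table_a: BiomassTable,
    table_b: BiomassTable,
    collapse_year_a: int,
    target: str | None = None,
    n_select: int = 10,
    n_bins: int = 3,
    n_boot: int = 1000,
    max_parents: int = 3,
    dbn_max_parents: int = 2,
    schedule: AnnealingSchedule | None = None,
    em_restarts: int = 10,
    sa_restarts: int = 50,
    seed: int = 0,
) -> TransferResult:
    """Run the full donor-to-target analysis.

    ``target`` is the donor-region species whose biomass the DBN predicts
    (the "cod" role); by default the top wrapper-ranked species.  The donor
    network over the ``n_select`` wrapper-selected species (always including
    the target) defines the slots the annealing search fills with the other
    region's species; the latent DBN fitted on the donor region is then
    carried over the recovered mapping, parameters and all.
    """
    disc_a = discretize(table_a, n_bins=n_bins)
    disc_b = discretize(table_b, n_bins=n_bins)
    labeled = label_collapse(disc_a, table_a.years, collapse_year_a)

    ranking = wrapper_select(labeled, n_boot=n_boot, seed=seed,
                             max_parents=max_parents)
    selected = ranking.top(n_select)
    if target is None:
        target = selected[0]
    elif target not in selected:
        selected = [target] + selected[: n_select - 1]

    data_sel = disc_a.subset(selected)
    donor_structure = k2_search(data_sel, node_order=selected,
                                max_parents=max_parents, score_kind="bic")
    donor_cpts = fit_parameters(data_sel, donor_structure, estimator="laplace")

    tdata = make_transition_dataset(data_sel, table_a.years)
    inter = reveal_search(tdata, max_parents=dbn_max_parents,
                          score_kind="bic")
    # the regime node feeds every modelled species: a functional collapse is
    # a community-wide change of the dependence structure, not a single
    # species' anomaly
    skeleton = DBNModel(
        variables=selected,
        arities={s: data_sel.arity_of(s) for s in selected},
        inter_parents=inter,
        target=target,
        hidden_children=tuple(selected),
    )
    dbn, em_report = fit_em(skeleton, data_sel, table_a.years,
                            n_restarts=em_restarts, seed=seed)
    donor_predictions = predict_one_step(dbn, data_sel, table_a.years)

    # impose the donor DBN's inter-slice structure on the other region's
    # transition pairs; every slot is forced at least one parent so no slot
    # is role-less in the search, and only species sharing the slots' state
    # vocabulary are eligible (quantile ties can shrink a species' arity)
    inter_eq = reveal_search(tdata, max_parents=dbn_max_parents,
                             score_kind="bic", min_parents=1)
    problem = temporal_equivalence_problem(
        inter_parents=inter_eq,
        variables=selected,
        slot_arities={s: data_sel.arity_of(s) for s in selected},
        data_b=disc_b,
        years_b=table_b.years,
        score_kind="transfer_ll",
        data_a=data_sel,
        years_a=table_a.years,
    )
    schedule = schedule or AnnealingSchedule(seed=seed)
    equivalence = functional_equivalence_search(problem, schedule,
                                                n_restarts=sa_restarts)

    transfer_predictions = transfer_model(
        dbn, equivalence, disc_b, table_b.years)

    return TransferResult(
        selected_species=selected,
        ranking=ranking,
        donor_structure=donor_structure,
        donor_cpts=donor_cpts,
        dbn=dbn,
        em_report=em_report,
        equivalence=equivalence,
        donor_predictions=donor_predictions,
        transfer_predictions=transfer_predictions,
    )
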