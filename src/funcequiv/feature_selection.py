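"""Bootstrap filter/wrapper selection of collapse-relevant species.

Both selectors ask which species carry information about the binary collapse
class, but at different granularity.  The *filter* scores each species
independently: the Cooper–Herskovits likelihood of the one-edge family
class -> species, averaged over bootstrap resamples of the records.  The
*wrapper* learns a full BN classifier by K2 greedy search on every resample
and reports, per species, the proportion of resamples in which any edge links
it with the class node (the *confidence*) — so it credits species whose
relevance only shows through interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn_core import (
    CPTSet,
    DAGStructure,
    fit_parameters,
    infer_posterior,
    k2_family_score,
    k2_search,
)
from .data_model import ClassLabeledDataset, bootstrap_resample

__all__ = [
    "FeatureRanking",
    "BNClassifier",
    "filter_select",
    "wrapper_select",
    "build_classifier",
    "classify",
]


@dataclass
class FeatureRanking:
    """Species ranked by relevance to the collapse class.

    ``scores`` holds the method's raw statistic (mean bootstrap family score
    for the filter; confidence in [0, 1] for the wrapper); ``delta_scores``
    is the filter's baseline-corrected version (score minus the parentless
    family score, positive = informative), ``None`` for the wrapper.
    """

    species: list[str]
    scores: np.ndarray
    method: str
    n_boot: int
    seed: int
    delta_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.argsort(-self.scores, kind="stable")
        self.species = [self.species[i] for i in order]
        self.scores = self.scores[order]
        if self.delta_scores is not None:
            self.delta_scores = self.delta_scores[order]

    def top(self, k: int) -> list[str]:
        return self.species[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"species": self.species, "score": self.scores})
        if self.delta_scores is not None:
            df["delta_score"] = self.delta_scores
        if self.method == "wrapper":
            df = df.rename(columns={"score": "confidence"})
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class BNClassifier:
    """A learned BN with a distinguished binary class node."""

    structure: DAGStructure
    cpts: CPTSet
    class_name: str

    def __post_init__(self) -> None:
        if self.cpts.arities[self.class_name] != 2:
            raise ValueError("class node must be binary")


def _resample_seeds(seed: int, n_boot: int) -> list[int]:
    # replicate b uses seed + b: independent, reproducible streams
    return [seed + b for b in range(n_boot)]


def filter_select(
    labeled: ClassLabeledDataset,
    n_boot: int = 1000,
    seed: int = 0,
    class_as_parent: bool = True,
) -> FeatureRanking:
    """Filter selection: mean bootstrap K2 score of the class–species family.

    Each species s is scored as the family {class -> s} (class as parent by
    default; set ``class_as_parent=False`` for the s -> class orientation) on
    every bootstrap resample, and the mean over resamples is reported.  The
    baseline-corrected delta (score minus the same species' parentless score
    on the same resample) is recorded alongside: positive means the class
    genuinely explains the species.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    data = labeled.as_dataset()
    cname = labeled.class_name
    species = list(labeled.base.variables)
    raw = np.zeros(len(species))
    delta = np.zeros(len(species))
    for b_seed in _resample_seeds(seed, n_boot):
        boot = bootstrap_resample(data, b_seed)
        for i, s in enumerate(species):
            if class_as_parent:
                with_link = k2_family_score(boot, s, [cname])
                baseline = k2_family_score(boot, s, [])
            else:
                with_link = k2_family_score(boot, cname, [s])
                baseline = k2_family_score(boot, cname, [])
            raw[i] += with_link
            delta[i] += with_link - baseline
    raw /= n_boot
    delta /= n_boot
    return FeatureRanking(species, raw, "filter", n_boot, seed,
                          delta_scores=delta)


def _classifier_order(labeled: ClassLabeledDataset,
                      species: list[str] | None = None) -> list[str]:
    """K2 node order for classifier search: species first, class node last.

    With the class last, class–species links surface as species -> class
    edges, i.e. the class node selects its own predictive parents.
    """
    sp = list(species) if species is not None else list(labeled.base.variables)
    return sp + [labeled.class_name]


def wrapper_select(
    labeled: ClassLabeledDataset,
    n_boot: int = 1000,
    seed: int = 0,
    max_parents: int = 3,
) -> FeatureRanking:
    """Wrapper selection: bootstrap confidence of class-node adjacency.

    On each resample a BN classifier is learned by K2 greedy search; a
    species earns a count whenever any edge (either direction) links it with
    the class node.  Confidence = count / n_boot.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    data = labeled.as_dataset()
    cname = labeled.class_name
    species = list(labeled.base.variables)
    order = _classifier_order(labeled)
    counts = dict.fromkeys(species, 0)
    for b_seed in _resample_seeds(seed, n_boot):
        boot = bootstrap_resample(data, b_seed)
        dag = k2_search(boot, node_order=order, max_parents=max_parents,
                        score_kind="k2")
        linked = set(dag.parents[cname])
        linked |= {c for c in dag.nodes if cname in dag.parents[c]}
        for s in linked:
            if s in counts:
                counts[s] += 1
    conf = np.array([counts[s] / n_boot for s in species])
    return FeatureRanking(species, conf, "wrapper", n_boot, seed)


def build_classifier(
    labeled: ClassLabeledDataset,
    selected_species: list[str],
    max_parents: int = 3,
) -> BNClassifier:
    """Learn a BN classifier over the class node plus the selected species.

    Structure by K2 greedy search (species first, class last in the order),
    Laplace parametrization so inference never meets a zero.
    """
    unknown = set(selected_species) - set(labeled.base.variables)
    if unknown:
        raise ValueError(f"selected species not in dataset: {sorted(unknown)}")
    cname = labeled.class_name
    if not selected_species:
        warnings.warn("empty selection: classifier reduces to the class prior",
                      stacklevel=2)
        data = labeled.as_dataset().subset([cname])
        dag = DAGStructure(nodes=[cname], parents={cname: ()})
    else:
        data = labeled.as_dataset().subset(list(selected_species) + [cname])
        dag = k2_search(
            data, node_order=_classifier_order(labeled, list(selected_species)),
            max_parents=max_parents, score_kind="k2")
    cpts = fit_parameters(data, dag, estimator="laplace")
    return BNClassifier(dag, cpts, cname)


def classify(classifier: BNClassifier,
             observation: dict[str, int] | None = None) -> np.ndarray:
    """Posterior over the class states given a (possibly partial) observation."""
    observation = dict(observation or {})
    observation.pop(classifier.class_name, None)
    _, post = infer_posterior(
        classifier.structure, classifier.cpts,
        evidence=observation, query=[classifier.class_name])
    return post
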