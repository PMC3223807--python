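"""Biomass tables, discretization, collapse labelling and bootstrap resampling.

The raw inputs are species-by-year biomass matrices (one region per CSV, one
row per survey year).  All downstream network scoring is categorical, so the
continuous biomass series are discretized per species into a small ordinal
vocabulary ("low / medium / high" for the default three quantile bins).  A
binary *collapse* class is attached by splitting the year axis at a collapse
year, and bootstrap resampling of records underpins the filter/wrapper
feature-selection confidences.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiomassTable",
    "DiscreteDataset",
    "ClassLabeledDataset",
    "read_biomass_table",
    "discretize",
    "label_collapse",
    "bootstrap_resample",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BiomassTable:
    """Continuous species x year biomass matrix for one region.

    Parameters
    ----------
    region_id
        Free-text label for the region (e.g. ``"GB"``).
    years
        Strictly increasing calendar years, one per row of ``values``.
    species
        Unique species names, one per column of ``values``.
    values
        ``(len(years), len(species))`` array of non-negative biomass in
        survey units.
    """

    region_id: str
    years: np.ndarray
    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1:
            raise ValueError("years must be one-dimensional")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        if self.values.shape != (len(self.years), len(self.species)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.years)} years x {len(self.species)} species"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError("biomass values must not be NaN")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative biomass for species {self.species[c]!r} "
                f"in year {self.years[r]}"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "year", self.years)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DiscreteDataset:
    """Categorical records with a per-variable arity.

    ``records[m, i]`` is the state index of variable ``i`` in record ``m``,
    in ``[0, arities[i])``.  ``state_labels[i]`` carries the ordered labels
    of variable ``i``'s states (bin descriptions for discretized biomass).
    """

    variables: list[str]
    arities: np.ndarray
    records: np.ndarray
    state_labels: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.arities = np.asarray(self.arities, dtype=int)
        self.records = np.asarray(self.records, dtype=int)
        n = len(self.variables)
        if self.records.ndim != 2 or self.records.shape[1] != n:
            raise ValueError("records must be an M x n_variables matrix")
        if self.records.shape[0] < 1:
            raise ValueError("dataset must contain at least one record")
        if self.arities.shape != (n,):
            raise ValueError("arities length must match variables")
        if np.any(self.arities < 2):
            raise ValueError("every variable needs arity >= 2")
        if not self.state_labels:
            self.state_labels = [
                [str(k) for k in range(r)] for r in self.arities
            ]
        if [len(lbl) for lbl in self.state_labels] != list(self.arities):
            raise ValueError("state_labels lengths must match arities")
        if np.any(self.records < 0) or np.any(self.records >= self.arities):
            raise ValueError("record entries out of range for arities")

    @property
    def n_records(self) -> int:
        return self.records.shape[0]

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def index_of(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in dataset") from None

    def column(self, name: str) -> np.ndarray:
        return self.records[:, self.index_of(name)]

    def arity_of(self, name: str) -> int:
        return int(self.arities[self.index_of(name)])

    def subset(self, names: Sequence[str]) -> "DiscreteDataset":
        idx = [self.index_of(n) for n in names]
        return DiscreteDataset(
            variables=list(names),
            arities=self.arities[idx],
            records=self.records[:, idx],
            state_labels=[self.state_labels[i] for i in idx],
        )

    def with_variable(
        self, name: str, states: np.ndarray, arity: int,
        labels: list[str] | None = None,
    ) -> "DiscreteDataset":
        """Return a copy with one extra variable appended."""
        if name in self.variables:
            raise ValueError(f"variable {name!r} already present")
        states = np.asarray(states, dtype=int).reshape(-1, 1)
        return DiscreteDataset(
            variables=self.variables + [name],
            arities=np.append(self.arities, arity),
            records=np.hstack([self.records, states]),
            state_labels=self.state_labels
            + [labels if labels is not None else [str(k) for k in range(arity)]],
        )

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write integer states as CSV, plus a JSON sidecar of the vocabulary."""
        pd.DataFrame(self.records, columns=self.variables).to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {
                "variables": self.variables,
                "arities": self.arities.tolist(),
                "state_labels": self.state_labels,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1)


@dataclass
class ClassLabeledDataset:
    """A discrete dataset plus the binary collapse class per record."""

    base: DiscreteDataset
    class_name: str
    class_values: np.ndarray
    collapse_year: int

    def __post_init__(self) -> None:
        self.class_values = np.asarray(self.class_values, dtype=int)
        if self.class_values.shape != (self.base.n_records,):
            raise ValueError("class_values length must equal record count")
        if np.any((self.class_values < 0) | (self.class_values > 1)):
            raise ValueError("class variable must be binary")

    def as_dataset(self) -> DiscreteDataset:
        """Species variables plus the class node, as one discrete dataset."""
        return self.base.with_variable(
            self.class_name, self.class_values, 2, labels=["pre", "post"]
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_biomass_table(source, region_id: str) -> BiomassTable:
    """Read a region's biomass CSV (``year`` column plus species columns).

    Years are sorted ascending; duplicate years, non-numeric cells and
    negative biomass are rejected.
    """
    if isinstance(source, (str, bytes)) and not isinstance(source, bytes) \
            and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ValueError("CSV needs a year column plus at least one species")
    year_col = df.columns[0]
    if year_col.strip().lower() != "year":
        raise ValueError(f"first column must be 'year', got {year_col!r}")
    years = pd.to_numeric(df[year_col], errors="raise").astype(int).to_numpy()
    if len(np.unique(years)) != len(years):
        dup = int(pd.Series(years)[pd.Series(years).duplicated()].iloc[0])
        raise ValueError(f"duplicate year {dup} in {region_id!r}")
    species = [str(c) for c in df.columns[1:]]
    try:
        vals = df[df.columns[1:]].apply(
            pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric biomass cell: {exc}") from exc
    if np.any(vals < 0):
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative biomass at year {years[r]}, species {species[c]!r}"
        )
    order = np.argsort(years)
    return BiomassTable(region_id, years[order], species, vals[order])


def _quantile_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior cut points at equal-frequency quantiles (may collapse)."""
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(x, qs)
    return np.unique(edges)


def _equal_width_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    return np.unique(np.linspace(x.min(), x.max(), n_bins + 1)[1:-1])


def discretize(
    table: BiomassTable,
    n_bins: int = 3,
    method: str = "quantile",
    drop_constant: bool = False,
) -> DiscreteDataset:
    """Bin each species' biomass independently into ordinal states.

    Quantile binning (default) gives equal-frequency "low/medium/high"
    states robust to the heavy right skew of survey biomass; equal-width
    binning splits the observed range evenly.  Bin edges are recorded in
    ``state_labels`` as half-open intervals.  A species whose values are
    all identical carries no information and is rejected unless
    ``drop_constant`` is set.

    Ordinality is preserved: larger biomass never maps to a lower state.
    If ties collapse quantile edges, that species' arity is reduced.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if method not in ("quantile", "equal_width"):
        raise ValueError(f"unknown discretization method {method!r}")

    keep: list[str] = []
    cols: list[np.ndarray] = []
    arities: list[int] = []
    labels: list[list[str]] = []
    for s_idx, name in enumerate(table.species):
        x = table.values[:, s_idx]
        if np.all(x == x[0]):
            if drop_constant:
                continue
            raise ValueError(f"constant variable {name!r} (zero information)")
        edges = (_quantile_edges if method == "quantile"
                 else _equal_width_edges)(x, n_bins)
        states = np.searchsorted(edges, x, side="right")
        arity = len(edges) + 1
        if arity < 2:  # all edges collapsed onto the extremes
            if drop_constant:
                continue
            raise ValueError(
                f"variable {name!r} cannot support 2 states under {method}"
            )
        bounds = np.concatenate([[-np.inf], edges, [np.inf]])
        labels.append([
            f"[{bounds[k]:.6g}, {bounds[k + 1]:.6g})" for k in range(arity)
        ])
        keep.append(name)
        cols.append(states)
        arities.append(arity)
    if not keep:
        raise ValueError("no usable species after discretization")
    return DiscreteDataset(
        variables=keep,
        arities=np.array(arities),
        records=np.column_stack(cols),
        state_labels=labels,
    )


def label_collapse(
    dataset: DiscreteDataset,
    years: Sequence[int],
    collapse_year: int,
    class_name: str = "collapse",
) -> ClassLabeledDataset:
    """Attach the binary collapse class: 0 before the collapse year, 1 from it on.

    The collapse year itself is "post": the year a system is said to have
    collapsed is the first year of the collapsed state.
    """
    years = np.asarray(years, dtype=int)
    if years.shape != (dataset.n_records,):
        raise ValueError("years must align one-to-one with records")
    if collapse_year < years.min() or collapse_year > years.max():
        warnings.warn(
            f"collapse year {collapse_year} outside observed span "
            f"[{years.min()}, {years.max()}]; labelling is one-class",
            stacklevel=2,
        )
    cls = (years >= collapse_year).astype(int)
    if cls.min() == cls.max():
        raise ValueError(
            f"collapse year {collapse_year} leaves one class empty"
        )
    return ClassLabeledDataset(dataset, class_name, cls, collapse_year)


def bootstrap_resample(
    dataset: DiscreteDataset, seed: int | np.random.Generator
) -> DiscreteDataset:
    """Resample the M records with replacement (nonparametric bootstrap).

    Arity and vocabulary are untouched so scores on resamples stay
    comparable.  Deterministic given the seed / generator state.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    m = dataset.n_records
    rows = rng.integers(0, m, size=m)
    return DiscreteDataset(
        variables=list(dataset.variables),
        arities=dataset.arities.copy(),
        records=dataset.records[rows],
        state_labels=[list(l) for l in dataset.state_labels],
    )
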