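"""Rich-get-richer growth models for annotation counts across releases.

Each release adds ``delta = max(0, n_{j+1} - n_j)`` annotations, distributed
over genes by a weight model applied to the *initial* release's annotation
shares ``p0_i = n_i0 / n_0``:

==================  =============================================
model               raw weight for gene i
==================  =============================================
exp_initial         exp(p0_i)
cubic_initial       p0_i ** 3
squared_weight      (previous round's probability_i) ** 2
squared_initial     p0_i ** 2
initial             p0_i
initial_random_focus p0 values permuted anew each release
equal               1 (every baseline gene)
==================  =============================================

Raw weights are normalised to a probability simplex each step so the
release's annotation total is conserved.  The update is
``counts_{j+1} = counts_j + delta * p`` (deterministic) or a multinomial
allocation of ``delta`` draws (stochastic).  Candidate models are ranked
against an observed Gini trajectory by RMS distance;
:class:`AnnotationGrowthModel` wraps simulation and ranking in a
model/results pair.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inequality import gini_from_counts
from .io import AnnotationCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthModel",
    "ALL_MODELS",
    "GrowthModelSpec",
    "GrowthState",
    "ReleaseSeries",
    "TrajectoryResult",
    "model_weights",
    "step",
    "simulate_series",
    "observed_gini_series",
    "compare_trajectories",
    "AnnotationGrowthModel",
    "GrowthModelResults",
    "read_series_long",
    "write_series_long",
]


class GrowthModel(str, Enum):
    exp_initial = "exp_initial"
    cubic_initial = "cubic_initial"
    squared_weight = "squared_weight"
    squared_initial = "squared_initial"
    initial = "initial"
    initial_random_focus = "initial_random_focus"
    equal = "equal"


ALL_MODELS: tuple[GrowthModel, ...] = tuple(GrowthModel)


@dataclass(frozen=True)
class GrowthModelSpec:
    """A weight model plus its execution mode.

    `stochastic` switches the update from the exact fractional product to a
    multinomial draw; `seed` is required whenever randomness is involved
    (stochastic mode, or the random-focus model's per-release permutation).
    """

    model: GrowthModel
    stochastic: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        model = GrowthModel(self.model)
        object.__setattr__(self, "model", model)
        needs_seed = self.stochastic or model is GrowthModel.initial_random_focus
        if needs_seed and self.seed is None:
            raise ValueError(f"seed required for {model.value} / stochastic mode")


@dataclass
class GrowthState:
    """Evolving per-gene counts and probabilities during a simulation."""

    genes: tuple[str, ...]
    counts: np.ndarray  # current counts, aligned to genes
    p0: np.ndarray  # initial annotation shares
    p_prev: np.ndarray  # previous round's probabilities (squared_weight)
    version_index: int = 0

    @classmethod
    def from_table(cls, table: AnnotationCountTable) -> "GrowthState":
        genes = tuple(sorted(table.counts))
        counts = np.asarray([table.counts[g] for g in genes], dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("baseline table has no annotations")
        p0 = counts / total
        return cls(genes=genes, counts=counts, p0=p0, p_prev=p0.copy())

    def validate(self) -> None:
        if abs(self.p0.sum() - 1.0) > 1e-9 or abs(self.p_prev.sum() - 1.0) > 1e-9:
            raise ValueError("probability vectors must sum to 1")
        if (self.counts < 0).any():
            raise ValueError("negative counts in growth state")

    def to_table(self, version_label: str = "", source_label: str = "simulated") -> AnnotationCountTable:
        return AnnotationCountTable(
            {g: c for g, c in zip(self.genes, self.counts) if c > 0},
            source_label=source_label,
            version_label=version_label,
        )


@dataclass
class ReleaseSeries:
    """Version-ordered count tables for one annotation source."""

    versions: list[tuple[str, AnnotationCountTable]]

    def __post_init__(self) -> None:
        if len(self.versions) < 2:
            raise ValueError("a release series needs at least two versions")
        labels = [v for v, _ in self.versions]
        if len(set(labels)) != len(labels):
            raise ValueError("version labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [v for v, _ in self.versions]

    @property
    def tables(self) -> list[AnnotationCountTable]:
        return [t for _, t in self.versions]

    @property
    def totals(self) -> list[float]:
        return [t.total() for t in self.tables]

    def __len__(self) -> int:
        return len(self.versions)


@dataclass
class TrajectoryResult:
    """A simulated Gini trajectory, and its distance to the observed one."""

    spec: GrowthModelSpec
    gini_series: list[float]
    distance_to_observed: float | None = None


def _focus_rng(spec: GrowthModelSpec, version_index: int) -> np.random.Generator:
    # independent substream per release, so trajectory j does not depend on
    # whether earlier releases were simulated
    return np.random.default_rng([int(spec.seed), int(version_index)])


def model_weights(spec: GrowthModelSpec, state: GrowthState) -> np.ndarray:
    """Normalised allocation probabilities for the next release."""
    model = spec.model
    p0 = state.p0
    if model is GrowthModel.exp_initial:
        raw = np.exp(p0)
    elif model is GrowthModel.cubic_initial:
        raw = p0**3
    elif model is GrowthModel.squared_weight:
        raw = state.p_prev**2
    elif model is GrowthModel.squared_initial:
        raw = p0**2
    elif model is GrowthModel.initial:
        raw = p0.copy()
    elif model is GrowthModel.initial_random_focus:
        rng = _focus_rng(spec, state.version_index)
        raw = p0[rng.permutation(p0.size)]
    elif model is GrowthModel.equal:
        raw = np.ones_like(p0)
    else:  # pragma: no cover
        raise ValueError(f"unknown growth model: {model}")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all model weights are zero")
    return raw / total


def step(
    spec: GrowthModelSpec,
    state: GrowthState,
    delta: float,
    rng: np.random.Generator | None = None,
) -> GrowthState:
    """Advance one release, adding `delta` annotations under the model.

    Deterministic mode adds the exact fractional allocation ``delta * p``;
    stochastic mode draws ``round(delta)`` annotations from a multinomial.
    `delta` must already be clamped to >= 0 by the caller.
    """
    if delta < 0:
        raise ValueError("negative delta: clamp release-to-release decreases to 0")
    p = model_weights(spec, state)
    if spec.stochastic:
        if rng is None:
            rng = _focus_rng(spec, state.version_index)
        added = rng.multinomial(int(round(delta)), p).astype(float)
    else:
        added = delta * p
    return GrowthState(
        genes=state.genes,
        counts=state.counts + added,
        p0=state.p0,
        p_prev=p,
        version_index=state.version_index + 1,
    )


def simulate_series(spec: GrowthModelSpec, series: ReleaseSeries) -> TrajectoryResult:
    """Replay a release series under one model, from the series' baseline.

    The baseline (version 0) counts seed the state; each later release adds
    the observed total increase (clamped at zero) distributed by the model.
    The Gini at each version is computed over genes with positive simulated
    count.
    """
    totals = series.totals
    state = GrowthState.from_table(series.tables[0])
    rng = (
        np.random.default_rng([int(spec.seed), 0x5E1F])
        if spec.stochastic
        else None
    )
    series_gini = [gini_from_counts(state.counts[state.counts > 0])]
    for v in range(1, len(series)):
        delta = max(0.0, totals[v] - totals[v - 1])
        state = step(spec, state, delta, rng=rng)
        series_gini.append(gini_from_counts(state.counts[state.counts > 0]))
    return TrajectoryResult(spec=spec, gini_series=series_gini)


def observed_gini_series(series: ReleaseSeries) -> list[float]:
    """Gini of each observed release, over its annotated genes."""
    return [gini_from_counts(t.positive_counts()) for t in series.tables]


def compare_trajectories(
    observed: Sequence[float], candidates: Iterable[TrajectoryResult]
) -> list[TrajectoryResult]:
    """Rank candidates by RMS distance to the observed Gini trajectory.

    The shared baseline point is excluded from the distance.  Returns new
    result objects sorted ascending by distance.
    """
    observed = np.asarray(observed, dtype=float)
    ranked = []
    for cand in candidates:
        sim = np.asarray(cand.gini_series, dtype=float)
        if sim.shape != observed.shape:
            raise ValueError(
                f"trajectory length {sim.size} != observed length {observed.size}"
            )
        dist = float(np.sqrt(np.mean((sim[1:] - observed[1:]) ** 2)))
        ranked.append(replace(cand, distance_to_observed=dist))
    ranked.sort(key=lambda r: r.distance_to_observed)
    return ranked


class AnnotationGrowthModel:
    """Growth-model comparison for one release series.

    Fits nothing in the parametric sense: each candidate weight model is
    simulated forward from the series' first release, and candidates are
    ranked by RMS distance between simulated and observed Gini trajectories.

    Parameters
    ----------
    series : ReleaseSeries
        Version-ordered observed count tables.
    models : sequence of GrowthModel or str, optional
        Candidate models (default: all seven).
    stochastic : bool
        Use multinomial allocation instead of exact fractional updates.
    seed : int, optional
        Required for stochastic mode or the random-focus model.
    """

    def __init__(
        self,
        series: ReleaseSeries,
        models: Sequence[GrowthModel | str] | None = None,
        stochastic: bool = False,
        seed: int | None = None,
    ):
        self.series = series
        self.models = tuple(GrowthModel(m) for m in (models or ALL_MODELS))
        self.stochastic = stochastic
        self.seed = seed

    def fit(self) -> "GrowthModelResults":
        observed = observed_gini_series(self.series)
        trajectories = {}
        for m in self.models:
            needs_seed = self.stochastic or m is GrowthModel.initial_random_focus
            spec = GrowthModelSpec(
                model=m,
                stochastic=self.stochastic,
                seed=self.seed if needs_seed else None,
            )
            trajectories[m] = simulate_series(spec, self.series)
        ranking = compare_trajectories(observed, trajectories.values())
        return GrowthModelResults(
            model=self, observed_gini=observed, ranking=ranking
        )


@dataclass
class GrowthModelResults:
    """Ranked growth-model trajectories for one release series."""

    model: AnnotationGrowthModel
    observed_gini: list[float]
    ranking: list[TrajectoryResult]

    @property
    def best_model(self) -> GrowthModel:
        return self.ranking[0].spec.model

    @property
    def trajectories(self) -> dict[GrowthModel, TrajectoryResult]:
        return {r.spec.model: r for r in self.ranking}

    def trajectory_frame(self) -> pd.DataFrame:
        """Long-format (version, model, gini) including the observed series."""
        labels = self.model.series.labels
        rows = [
            {"version": v, "model": "observed", "gini": g}
            for v, g in zip(labels, self.observed_gini)
        ]
        for r in self.ranking:
            rows += [
                {"version": v, "model": r.spec.model.value, "gini": g}
                for v, g in zip(labels, r.gini_series)
            ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Ranking table: model, RMS distance to observed, final Gini."""
        return pd.DataFrame(
            {
                "model": [r.spec.model.value for r in self.ranking],
                "distance": [r.distance_to_observed for r in self.ranking],
                "final_gini": [r.gini_series[-1] for r in self.ranking],
            }
        )

    def __str__(self) -> str:
        obs = self.observed_gini
        head = (
            f"Annotation growth-model comparison "
            f"({len(obs)} versions; observed Gini {obs[0]:.4f} -> {obs[-1]:.4f})\n"
        )
        return head + self.summary().to_string(index=False)


def read_series_long(stream: Iterable[str]) -> ReleaseSeries:
    """Read a long-format (version, gene, count) TSV into a ReleaseSeries.

    Version order follows first appearance in the file.
    """
    df = pd.read_csv(stream, sep="\t", dtype={0: str, 1: str})
    df.columns = [c.lower() for c in df.columns]
    required = {"version", "gene", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"long series TSV needs columns {sorted(required)}")
    order = list(dict.fromkeys(df["version"]))
    versions = []
    for v in order:
        sub = df[df["version"] == v]
        counts = dict(zip(sub["gene"], sub["count"].astype(float)))
        versions.append((v, AnnotationCountTable(counts, version_label=v)))
    return ReleaseSeries(versions)


def write_series_long(series: ReleaseSeries, stream) -> None:
    stream.write("version\tgene\tcount\n")
    for label, table in series.versions:
        for gene in sorted(table.counts):
            c = table.counts[gene]
            out = int(c) if float(c).is_integer() else c
            stream.write(f"{label}\t{gene}\t{out}\n")
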