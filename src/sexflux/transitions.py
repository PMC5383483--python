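"""Year-to-year sex-expression transition counting and summaries.

A transition pair (year t, year t+1) is counted iff both years are present in
the trajectory, are consecutive calendar years, and both states are expressed;
a non-flowering or unobserved year breaks that pair but not later pairs.  An
optional pooling map (e.g. all hermaphrodite categories -> ``HALL``) is
applied to states *before* counting; pooling commutes with counting, so this
equals aggregating the unpooled count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .census_io import EXPRESSED_STATES, Trajectory, is_expressed


@dataclass(frozen=True)
class TransitionCounts:
    """K x K integer matrix of observed transitions, rows = origin state."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("negative transition count")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probability matrix.

    Rows with zero observed origin counts are undefined and filled with NaN;
    ``row_totals`` is preserved so bootstrap schemes can resample at the
    original sample sizes.
    """

    labels: tuple[str, ...]
    probs: np.ndarray
    row_totals: np.ndarray

    @property
    def undefined_rows(self) -> tuple[str, ...]:
        return tuple(
            label for label, total in zip(self.labels, self.row_totals) if total == 0
        )


@dataclass(frozen=True)
class TransitionSummary:
    """Structure of the observed transition graph (unpooled state space)."""

    n_observed_types: int
    never_observed: tuple[tuple[str, str], ...]
    max_offdiagonal_count: int
    max_offdiagonal_pairs: tuple[tuple[str, str], ...]


def consecutive_expressed_pairs(
    trajectory: Trajectory,
) -> list[tuple[int, int, str, str]]:
    """All (year_t, year_t+1, state_t, state_t+1) pairs that enter counting."""
    pairs = []
    obs = trajectory.observations
    for (y0, s0), (y1, s1) in zip(obs, obs[1:]):
        if y1 - y0 == 1 and is_expressed(s0) and is_expressed(s1):
            pairs.append((y0, y1, s0, s1))
    return pairs


def count_transitions(
    trajectories: Iterable[Trajectory],
    states: Sequence[str] = EXPRESSED_STATES,
    pooling: Mapping[str, str] | None = None,
) -> TransitionCounts:
    """Count consecutive-year transitions over ``states``.

    When ``pooling`` is given it is applied to both ends of every pair before
    tallying, and ``states`` must enumerate the pooled state space.  States
    outside the (pooled) state space raise ``ValueError``: silent dropping
    would corrupt row totals.
    """
    labels = tuple(states)
    index = {s: i for i, s in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for trajectory in trajectories:
        for _, _, s0, s1 in consecutive_expressed_pairs(trajectory):
            if pooling is not None:
                s0, s1 = pooling[s0], pooling[s1]
            try:
                counts[index[s0], index[s1]] += 1
            except KeyError as exc:
                raise ValueError(
                    f"state {exc.args[0]!r} not in state list {labels!r}"
                ) from exc
    return TransitionCounts(labels=labels, counts=counts)


def pool_counts(
    counts: TransitionCounts,
    pooling: Mapping[str, str],
    pooled_labels: Sequence[str],
) -> TransitionCounts:
    """Aggregate an unpooled count matrix onto a pooled state space."""
    labels = tuple(pooled_labels)
    index = {s: i for i, s in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)), dtype=int)
    for i, si in enumerate(counts.labels):
        for j, sj in enumerate(counts.labels):
            out[index[pooling[si]], index[pooling[sj]]] += counts.counts[i, j]
    return TransitionCounts(labels=labels, counts=out)


def to_probabilities(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalize counts into a transition probability matrix.

    Zero-total rows are flagged (NaN-filled), not fatal.  Probabilities are
    kept at full precision; 4-decimal rounding is display-only.
    """
    totals = counts.row_totals
    probs = np.full(counts.counts.shape, np.nan, dtype=float)
    positive = totals > 0
    probs[positive] = counts.counts[positive] / totals[positive, None]
    return TransitionMatrix(labels=counts.labels, probs=probs, row_totals=totals)


def observed_summaries(counts: TransitionCounts) -> TransitionSummary:
    """Summarize which ordered state pairs were ever observed.

    Returns the number of distinct off-diagonal transition types with at least
    one event, the ordered pairs never observed, and the off-diagonal maximum
    with every pair attaining it.
    """
    c = counts.counts
    labels = counts.labels
    off = ~np.eye(len(labels), dtype=bool)
    observed = (c > 0) & off
    never = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(len(labels))
        if off[i, j] and c[i, j] == 0
    ]
    max_count = int(c[off].max()) if off.any() else 0
    if max_count > 0:
        argmax = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(len(labels))
            if off[i, j] and c[i, j] == max_count
        ]
    else:
        argmax = []
    return TransitionSummary(
        n_observed_types=int(observed.sum()),
        never_observed=tuple(never),
        max_offdiagonal_count=max_count,
        max_offdiagonal_pairs=tuple(argmax),
    )
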