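"""Canonical classification of sex-expression trajectories.

An individual's history of expressed sexes is reduced to a *pattern string*:
consecutive repeats are collapsed, the distinct successive states are
relabelled A, B, C, ... in order of first appearance, and the letters are
joined by arrows.  ``[F, M, F]`` becomes ``A->B->A`` (written with a unicode
arrow); the pattern encodes the changes, not their durations, so ``[F, F, M]``
and ``[F, M, M]`` are both ``A->B``.  A trajectory is *constant* with no
change, *unidirectional* when it changes without ever returning to a
previously expressed sex, and *bidirectional* when some sex reappears after a
different one intervened -- equivalently, when a letter repeats in the
collapsed pattern.

Non-flowering and unobserved years are skipped by default
(``collapse_gaps=True``): the pattern is read off the expressed states only.
With ``collapse_gaps=False`` a gap instead splits the trajectory into
segments (joined by ``|`` in the pattern string); only within-segment steps
count as changes and cross-gap state differences count neither as changes nor
as reappearances.  Transition *events* (for cross-tabulation against the
transition-count matrix) always use the strict consecutive-calendar-year rule
shared with :mod:`sexflux.transitions`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .census_io import Trajectory, is_expressed
from .transitions import consecutive_expressed_pairs

ARROW = "→"
GAP = "|"

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class PatternResult:
    """Canonical pattern of one trajectory.

    ``pattern`` is None for trajectories with no expressed observation
    (direction ``"unclassifiable"``); such individuals are excluded from
    tabulation.  In the default gap mode ``n_changes`` equals the number of
    letters minus one.
    """

    individual_id: str
    pattern: str | None
    direction: str  # constant | unidirectional | bidirectional | unclassifiable
    n_changes: int
    n_expressed_years: int


@dataclass(frozen=True)
class ChangeEvent:
    """One consecutive-year sex change."""

    year_from: int
    year_to: int
    state_from: str
    state_to: str


def _segments(trajectory: Trajectory, collapse_gaps: bool) -> list[list[str]]:
    """Expressed-state runs; a single run when gaps are collapsed, otherwise
    split at NF/NA observations and at missing calendar years."""
    if collapse_gaps:
        seq = [s for _, s in trajectory.observations if is_expressed(s)]
        return [seq] if seq else []
    segments: list[list[str]] = []
    current: list[str] = []
    prev_year: int | None = None
    for year, state in trajectory.observations:
        broken = not is_expressed(state) or (
            prev_year is not None and year - prev_year != 1
        )
        if broken and current:
            segments.append(current)
            current = []
        if is_expressed(state):
            # a gap in calendar years also breaks the segment
            if prev_year is not None and year - prev_year != 1 and current:
                segments.append(current)
                current = []
            current.append(state)
        prev_year = year
    if current:
        segments.append(current)
    return segments


def canonicalize(trajectory: Trajectory, collapse_gaps: bool = True) -> PatternResult:
    """Classify one trajectory into its canonical sex-change pattern."""
    n_expressed = sum(1 for _, s in trajectory.observations if is_expressed(s))
    segments = _segments(trajectory, collapse_gaps)
    if not segments:
        return PatternResult(
            individual_id=trajectory.individual_id,
            pattern=None,
            direction="unclassifiable",
            n_changes=0,
            n_expressed_years=0,
        )
    # collapse consecutive repeats within each segment, then relabel states
    # A, B, C ... in order of first appearance across the whole trajectory
    collapsed: list[list[str]] = []
    for seg in segments:
        run = [seg[0]]
        for state in seg[1:]:
            if state != run[-1]:
                run.append(state)
        collapsed.append(run)
    letter_of: dict[str, str] = {}
    for seg in collapsed:
        for state in seg:
            if state not in letter_of:
                letter_of[state] = _LETTERS[len(letter_of)]
    pattern = GAP.join(ARROW.join(letter_of[s] for s in seg) for seg in collapsed)
    n_changes = sum(len(seg) - 1 for seg in collapsed)
    # bidirectional iff a letter reappears after an intervening different
    # letter; within-segment walks only, so cross-gap differences do not count
    letters_seen: set[str] = set()
    bidirectional = False
    for seg in collapsed:
        for prev, cur in zip(seg, seg[1:]):
            if letter_of[cur] in letters_seen and letter_of[cur] != letter_of[prev]:
                bidirectional = True
            letters_seen.add(letter_of[prev])
        letters_seen.add(letter_of[seg[-1]])
    if n_changes == 0:
        direction = "constant"
    elif bidirectional:
        direction = "bidirectional"
    else:
        direction = "unidirectional"
    return PatternResult(
        individual_id=trajectory.individual_id,
        pattern=pattern,
        direction=direction,
        n_changes=n_changes,
        n_expressed_years=n_expressed,
    )


@dataclass(frozen=True)
class PatternTable:
    """Population-level pattern tabulation."""

    table: pd.DataFrame  # pattern, direction, count, percent
    results: tuple[PatternResult, ...]
    n_classifiable: int
    n_changed: int
    changes_distribution: Mapping[int, int]  # n_changes -> individuals
    span_distribution: Mapping[int, int]  # expressed years -> individuals

    @property
    def proportion_changed(self) -> float:
        return self.n_changed / self.n_classifiable if self.n_classifiable else 0.0


def tabulate_patterns(
    trajectories: Iterable[Trajectory], collapse_gaps: bool = True
) -> PatternTable:
    """Tabulate canonical patterns over a population.

    Percentages are of classifiable individuals (those with at least one
    expressed observation).  The observation-span distribution is reported
    alongside because populations may pool plots censused for different
    numbers of years.
    """
    results = tuple(canonicalize(t, collapse_gaps=collapse_gaps) for t in trajectories)
    classifiable = [r for r in results if r.pattern is not None]
    n = len(classifiable)
    counter = Counter((r.pattern, r.direction) for r in classifiable)
    rows = [
        {
            "pattern": pattern,
            "direction": direction,
            "count": count,
            "percent": 100.0 * count / n if n else 0.0,
        }
        for (pattern, direction), count in counter.items()
    ]
    table = pd.DataFrame(rows, columns=["pattern", "direction", "count", "percent"])
    if len(table):
        table = table.sort_values(
            ["count", "pattern"], ascending=[False, True], ignore_index=True
        )
    return PatternTable(
        table=table,
        results=results,
        n_classifiable=n,
        n_changed=sum(1 for r in classifiable if r.n_changes > 0),
        changes_distribution=dict(Counter(r.n_changes for r in classifiable)),
        span_distribution=dict(Counter(r.n_expressed_years for r in classifiable)),
    )


def change_events(
    trajectory: Trajectory, pooling: Mapping[str, str] | None = None
) -> list[ChangeEvent]:
    """Sex-change events between consecutive expressed years.

    One event per consecutive-calendar-year pair whose states differ (after
    optional pooling); aggregated over a population these equal the
    off-diagonal cells of the transition count matrix on the same data.
    """
    events = []
    for y0, y1, s0, s1 in consecutive_expressed_pairs(trajectory):
        if pooling is not None:
            s0, s1 = pooling[s0], pooling[s1]
        if s0 != s1:
            events.append(
                ChangeEvent(year_from=y0, year_to=y1, state_from=s0, state_to=s1)
            )
    return events
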