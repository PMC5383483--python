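"""Synthetic sex-expression censuses and the published-tally fixtures.

The generator emulates the statistical structure the analysis pipeline
assumes: a multi-plot shrub population censused yearly, individuals switching
among sexual categories by a first-order Markov chain, occasional
non-flowering years masking the latent state, and -- in covariate mode -- a
change probability that is logistic in standardized covariates (stem
diameter, winter/summer relative light, yearly diameter growth) with a
Gaussian random intercept per plot.  Defaults mirror a five-year census of a
subdioecious *Eurya japonica* population: four 20 x 20 m plots of 74/81/102/52
monitored shrubs, observed mean category proportions as the initial state
distribution, the field transition matrix as the default chain, and a ~6%
non-flowering rate.

Two exact fixtures are also constructed here and shipped as package data:

* ``table2_pairs.csv`` -- one 2-year pseudo-individual per observed
  transition event, so that counting transitions reproduces the published
  6-state tally cell-for-cell (937 events, 1874 rows).
* ``table1_trajectories.csv`` -- 309 five-year trajectories whose canonical
  patterns reproduce the published pattern table (224 constant, 85 changed),
  using concrete states drawn only from transitions actually observed in the
  tally.

The two fixtures are deliberately independent reconstructions of two printed
summaries of the same unpublished census; they are not mutually consistent at
the individual level.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .census_io import (
    EXPRESSED_STATES,
    POOL_TO_HALL,
    POOLED_STATES,
    CensusRecord,
)
from .transitions import TransitionCounts, pool_counts

# ---------------------------------------------------------------------------
# the published field tally (rows = origin state, columns = destination)
# ---------------------------------------------------------------------------

#: Five-year transition tally of the field census, 6 expressed states.
#: 937 transition events in total; the printed H-origin total (57) disagrees
#: with its own cells, whose sum (58) is taken as authoritative.
FIELD_COUNTS_6STATE = np.array(
    [
        # F    M    H   HF   HM  HFM
        [300,   4,   1,  10,   0,   0],  # from F
        [  5, 274,   1,   1,  10,   3],  # from M
        [  0,   0,  30,  22,   3,   3],  # from H
        [ 22,   1,  10, 168,   3,   8],  # from HF
        [  1,   6,   1,   2,  22,   3],  # from HM
        [  0,   2,   1,   6,   4,  10],  # from HFM
    ],
    dtype=int,
)

#: Mean observed proportions of the six categories across census years.
FIELD_PROPORTIONS_6STATE = np.array([0.332, 0.301, 0.051, 0.226, 0.040, 0.024])


def field_counts(pooled: bool = False) -> TransitionCounts:
    """The field transition tally as a :class:`TransitionCounts`."""
    counts = TransitionCounts(labels=EXPRESSED_STATES, counts=FIELD_COUNTS_6STATE)
    if pooled:
        return pool_counts(counts, POOL_TO_HALL, POOLED_STATES)
    return counts


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _default_beta() -> dict[str, float]:
    # magnitudes echo the selected occurrence model on the standardized scale;
    # the intercept matches the observed ~14% yearly change rate
    return {
        "intercept": -1.8,
        "dbh": 0.0,
        "rppfd_winter": 0.34,
        "rppfd_summer": 0.03,
        "growth": 0.16,
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic census.

    ``mode="matrix"`` evolves states by an explicit row-stochastic matrix
    over ``states``; ``mode="covariate"`` draws a yearly change indicator from
    the logistic model and, on change, a destination from the origin state's
    conditional destination distribution.  Covariates are drawn once per
    individual (DBH start, both rPPFD seasons) except yearly growth, which is
    redrawn every year and accumulates onto DBH.
    """

    n_individuals: tuple[int, ...] = (74, 81, 102, 52)
    years: tuple[int, ...] = (2010, 2011, 2012, 2013, 2014)
    seed: int = 0
    mode: str = "matrix"
    states: tuple[str, ...] | None = None
    matrix: np.ndarray | None = None
    initial_dist: np.ndarray | None = None
    p_nonflower: float = 0.06
    sigma_plot: float = 0.5
    beta: Mapping[str, float] = field(default_factory=_default_beta)
    destination: Mapping[str, Mapping[str, float]] | None = None
    dbh_lognormal: tuple[float, float] = (0.9, 0.5)  # log-cm mean, sd
    rppfd_winter_beta: tuple[float, float] = (2.0, 5.0)
    rppfd_summer_beta: tuple[float, float] = (1.5, 8.0)
    growth_gamma: tuple[float, float] = (1.5, 1.0)  # shape, scale (mm/yr)


def config_hash(config: SimConfig) -> str:
    """Deterministic short hash of a configuration (embedded in outputs)."""
    parts = []
    for name in sorted(config.__dataclass_fields__):
        value = getattr(config, name)
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, Mapping):
            value = sorted(value.items())
        parts.append(f"{name}={value!r}")
    return hashlib.sha256(";".join(parts).encode()).hexdigest()[:16]


def _resolve_chain(config: SimConfig):
    """Fill in the state space, matrix/destinations and initial distribution."""
    if config.mode not in ("matrix", "covariate"):
        raise ValueError(f"unknown simulation mode {config.mode!r}")
    pooled = field_counts(pooled=True)
    pooled_probs = pooled.counts / pooled.counts.sum(axis=1, keepdims=True)
    if config.mode == "matrix":
        matrix = pooled_probs if config.matrix is None else np.asarray(config.matrix)
        if config.states is not None:
            states = tuple(config.states)
        elif matrix.shape[0] == 3:
            states = POOLED_STATES
        elif matrix.shape[0] == 6:
            states = EXPRESSED_STATES
        else:
            raise ValueError("states must be given for a non 3/6-state matrix")
        if matrix.shape != (len(states), len(states)):
            raise ValueError("matrix shape does not match states")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9) or (matrix < 0).any():
            raise ValueError("matrix rows must be probability distributions")
    else:
        states = tuple(config.states) if config.states else POOLED_STATES
        matrix = None
    if config.initial_dist is not None:
        initial = np.asarray(config.initial_dist, dtype=float)
    elif states == POOLED_STATES:
        raw = np.array(
            [
                FIELD_PROPORTIONS_6STATE[0],
                FIELD_PROPORTIONS_6STATE[1],
                FIELD_PROPORTIONS_6STATE[2:].sum(),
            ]
        )
        initial = raw / raw.sum()
    elif states == EXPRESSED_STATES:
        initial = FIELD_PROPORTIONS_6STATE / FIELD_PROPORTIONS_6STATE.sum()
    else:
        initial = np.full(len(states), 1.0 / len(states))
    if len(initial) != len(states) or not np.isclose(initial.sum(), 1.0):
        raise ValueError("initial_dist must be a distribution over states")
    destination = None
    if config.mode == "covariate":
        if config.destination is not None:
            destination = {
                s: dict(d) for s, d in config.destination.items()
            }
        else:
            destination = {}
            for i, s in enumerate(states):
                off = pooled_probs[i].copy()
                off[i] = 0.0
                off /= off.sum()
                destination[s] = {
                    t: float(off[j]) for j, t in enumerate(states) if j != i
                }
        for s, dist in destination.items():
            total = sum(dist.values())
            if not np.isclose(total, 1.0) or any(v < 0 for v in dist.values()):
                raise ValueError(f"destination distribution for {s!r} invalid")
    return states, matrix, initial, destination


def _covariate_moments(config: SimConfig) -> dict[str, tuple[float, float]]:
    """Theoretical mean/sd of the covariate generators (standardization)."""
    mu, sd = config.dbh_lognormal
    dbh_mean = np.exp(mu + sd**2 / 2.0)
    dbh_sd = dbh_mean * np.sqrt(np.exp(sd**2) - 1.0)
    out = {"dbh": (dbh_mean, dbh_sd)}
    for name, (a, b) in (
        ("rppfd_winter", config.rppfd_winter_beta),
        ("rppfd_summer", config.rppfd_summer_beta),
    ):
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        out[name] = (mean, np.sqrt(var))
    k, theta = config.growth_gamma
    out["growth"] = (k * theta, np.sqrt(k) * theta)
    return out


def simulate_census(config: SimConfig) -> list[CensusRecord]:
    """Simulate one census; deterministic for a fixed config (incl. seed)."""
    if not 0.0 <= config.p_nonflower < 1.0:
        raise ValueError("p_nonflower must lie in [0, 1)")
    states, matrix, initial, destination = _resolve_chain(config)
    moments = _covariate_moments(config)
    rng = np.random.default_rng(config.seed)
    years = tuple(config.years)
    records: list[CensusRecord] = []
    for plot_index, n_ind in enumerate(config.n_individuals):
        plot_id = f"P{plot_index + 1}"
        u_plot = rng.normal(0.0, config.sigma_plot)
        for ind in range(n_ind):
            individual_id = f"{plot_id}-{ind + 1:04d}"
            dbh = float(rng.lognormal(*config.dbh_lognormal))
            rw = float(rng.beta(*config.rppfd_winter_beta))
            rs = float(rng.beta(*config.rppfd_summer_beta))
            state = states[rng.choice(len(states), p=initial)]
            growth_mm = 0.0  # no growth measurement before the first year
            for t, year in enumerate(years):
                if t > 0:
                    # transition from last year's latent state
                    if config.mode == "matrix":
                        state = states[
                            rng.choice(len(states), p=matrix[states.index(state)])
                        ]
                    else:
                        z = {
                            "dbh": (dbh - moments["dbh"][0]) / moments["dbh"][1],
                            "rppfd_winter": (rw - moments["rppfd_winter"][0])
                            / moments["rppfd_winter"][1],
                            "rppfd_summer": (rs - moments["rppfd_summer"][0])
                            / moments["rppfd_summer"][1],
                            "growth": (growth_mm - moments["growth"][0])
                            / moments["growth"][1],
                        }
                        eta = config.beta["intercept"] + u_plot
                        for term, value in z.items():
                            eta += config.beta.get(term, 0.0) * value
                        if rng.random() < 1.0 / (1.0 + np.exp(-eta)):
                            dist = destination[state]
                            targets = list(dist)
                            state = targets[
                                rng.choice(
                                    len(targets), p=[dist[s] for s in targets]
                                )
                            ]
                        growth_mm = float(
                            rng.gamma(config.growth_gamma[0], config.growth_gamma[1])
                        )
                        dbh += growth_mm / 10.0
                    if config.mode == "matrix":
                        growth_mm = float(
                            rng.gamma(config.growth_gamma[0], config.growth_gamma[1])
                        )
                        dbh += growth_mm / 10.0
                observed = "NF" if rng.random() < config.p_nonflower else state
                records.append(
                    CensusRecord(
                        plot_id=plot_id,
                        individual_id=individual_id,
                        year=year,
                        state=observed,
                        dbh=round(dbh, 6),
                        rppfd_winter=round(rw, 6),
                        rppfd_summer=round(rs, 6),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# exact fixtures for the two published summaries
# ---------------------------------------------------------------------------


def make_fixture_table2() -> list[CensusRecord]:
    """One 2-year pseudo-individual per observed transition event.

    Counting transitions over the result reproduces the 6-state field tally
    cell-for-cell (937 events).  Pseudo-individuals cycle through four plots;
    no covariates are attached.
    """
    records = []
    plot_cycle = ("P1", "P2", "P3", "P4")
    serial = 0
    for i, origin in enumerate(EXPRESSED_STATES):
        for j, dest in enumerate(EXPRESSED_STATES):
            for k in range(int(FIELD_COUNTS_6STATE[i, j])):
                individual_id = f"t2-{origin}-{dest}-{k + 1:03d}"
                plot_id = plot_cycle[serial % len(plot_cycle)]
                serial += 1
                records.append(
                    CensusRecord(plot_id, individual_id, 2010, origin)
                )
                records.append(CensusRecord(plot_id, individual_id, 2011, dest))
    return records


#: (pattern code, 5-year state sequence, count) for the trajectory fixture.
#: Sequences use only transitions with positive cells in the field tally.
_TABLE1_SEQUENCES: tuple[tuple[str, tuple[str, ...], int], ...] = (
    ("a", ("F",) * 5, 76),
    ("a", ("M",) * 5, 69),
    ("a", ("H",) * 5, 12),
    ("a", ("HF",) * 5, 52),
    ("a", ("HM",) * 5, 9),
    ("a", ("HFM",) * 5, 6),
    ("ab", ("F", "F", "F", "F", "HF"), 10),
    ("ab", ("M", "M", "M", "M", "HM"), 9),
    ("ab", ("HF", "HF", "HF", "HF", "F"), 9),
    ("ab", ("HM", "HM", "HM", "HM", "M"), 9),
    ("abc", ("F", "F", "F", "HF", "H"), 7),
    ("abc", ("M", "M", "M", "HM", "HFM"), 6),
    ("abcd", ("F", "HF", "H", "HM", "HM"), 1),
    ("abcd", ("M", "HM", "HFM", "HF", "HF"), 1),
    ("aba", ("F", "HF", "F", "F", "F"), 9),
    ("aba", ("M", "HM", "M", "M", "M"), 8),
    ("abab", ("F", "HF", "F", "HF", "HF"), 6),
    ("abab", ("M", "HM", "M", "HM", "HM"), 5),
    ("abac", ("F", "HF", "F", "M", "M"), 2),
    ("abac", ("M", "HM", "M", "F", "F"), 1),
    ("abacd", ("F", "HF", "F", "M", "HM"), 1),
    ("abcdc", ("F", "HF", "H", "HM", "H"), 1),
)


def make_fixture_table1() -> list[CensusRecord]:
    """309 five-year trajectories reproducing the published pattern counts.

    224 constant individuals (split across the six categories in roughly the
    observed proportions) and 85 changers: 37 with one change, 30 with two,
    16 with three and 2 changing every year.  Individuals alternate between
    two plots; no covariates are attached.
    """
    records = []
    serial = 0
    years = (2010, 2011, 2012, 2013, 2014)
    for code, sequence, count in _TABLE1_SEQUENCES:
        for k in range(count):
            serial += 1
            individual_id = f"t1-{code}-{serial:03d}"
            plot_id = "P2" if serial % 2 else "P3"
            for year, state in zip(years, sequence):
                records.append(CensusRecord(plot_id, individual_id, year, state))
    return records


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV (e.g. ``table2_pairs``)."""
    resource = resources.files("sexflux") / "data" / f"{name}.csv"
    return Path(str(resource))


def write_fixtures(directory: str | Path) -> None:
    """Regenerate both fixture CSVs into ``directory`` (used at build time)."""
    from .census_io import write_census

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_census(make_fixture_table2(), directory / "table2_pairs.csv")
    write_census(make_fixture_table1(), directory / "table1_trajectories.csv")
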