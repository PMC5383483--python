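"""Stationary distributions and bootstrap inference for sex-state chains.

The long-run expected sex ratio of a population whose individuals switch
sexual phenotype by a time-homogeneous Markov chain is the stationary
distribution pi of the transition matrix P (pi P = pi).  Sampling uncertainty
is propagated by a nonparametric bootstrap of the observed transition events:
each replicate redraws the events, row-normalizes the resampled counts and
recomputes pi, giving percentile confidence intervals per state.  A state's
long-run share is called significantly above (below) a null share -- by
default the uniform 1/3 -- iff its whole interval lies above (below) it; no
p-value is attached, the interval *is* the criterion.

Two resampling schemes are provided:

``pooled``
    All ``n_pairs`` (origin, destination) events are treated as one
    exchangeable multiset and redrawn by a single multinomial.  Default.
``row-stratified``
    Each origin row is redrawn by its own multinomial at its observed row
    total, conditioning on the number of times each origin state was seen.

Replicates with an empty row or a reducible chain have no stationary
distribution and are rejected and redrawn; a run of 1000 consecutive
rejections aborts with an error (degenerate counts), and the total redraw
count is reported in the result metadata rather than silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .transitions import TransitionCounts, TransitionMatrix

#: Abort after this many consecutive rejected bootstrap replicates.
DEFAULT_REJECTION_CAP = 1000

_RESIDUAL_TOL = 1e-10


class ReducibleChainError(ValueError):
    """The chain is not irreducible on its label set."""


def _irreducible_mask(probs: np.ndarray) -> np.ndarray:
    """Vectorized irreducibility check for a batch of K x K matrices.

    A chain is irreducible iff every state reaches every other along the
    positive-support graph, i.e. (I + B)^(K-1) is all-positive for the boolean
    adjacency B.
    """
    k = probs.shape[-1]
    adj = ((probs > 0) | np.eye(k, dtype=bool)).astype(np.int32)
    reach = adj
    for _ in range(k - 2):
        reach = np.minimum(reach @ adj, 1)
    return (reach > 0).all(axis=(-2, -1))


def _unreachable_states(probs: np.ndarray, labels: tuple[str, ...]) -> list[str]:
    """States outside the single closed communicating class (if any)."""
    n_comp, assignment = connected_components(
        csr_matrix(probs > 0), directed=True, connection="strong"
    )
    if n_comp == 1:
        return []
    sizes = np.bincount(assignment, minlength=n_comp)
    main = int(np.argmax(sizes))
    return [label for label, comp in zip(labels, assignment) if comp != main]


def _stationary_batch(probs: np.ndarray) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1 for a batch of row-stochastic matrices.

    Replaces the last equation of (P^T - I) pi = 0 with the normalization
    constraint and solves the dense linear system; no validity checks.
    """
    k = probs.shape[-1]
    a = np.swapaxes(probs, -1, -2) - np.eye(k)
    a[..., k - 1, :] = 1.0
    b = np.zeros(probs.shape[:-2] + (k, 1))
    b[..., k - 1, 0] = 1.0
    return np.linalg.solve(a, b)[..., 0]


def stationary(matrix: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix.

    Computed by the direct linear solve; the result satisfies pi >= 0,
    sum(pi) = 1 and ``max|pi P - pi| <= 1e-10`` (checked).  Raises
    :class:`ReducibleChainError` naming the states outside the closed
    communicating class when the chain is reducible or has undefined rows.
    """
    if isinstance(matrix, TransitionMatrix):
        labels = matrix.labels
        probs = matrix.probs
    else:
        probs = np.asarray(matrix, dtype=float)
        labels = tuple(str(i) for i in range(probs.shape[0]))
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.isnan(probs).any():
        bad = [labels[i] for i in np.where(np.isnan(probs).any(axis=1))[0]]
        raise ReducibleChainError(
            f"rows undefined (no observed transitions) for states {bad}"
        )
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows do not sum to 1")
    bad = _unreachable_states(probs, labels)
    if bad:
        raise ReducibleChainError(
            f"chain is reducible; states outside the closed class: {bad}"
        )
    pi = _stationary_batch(probs[None])[0]
    residual = np.abs(pi @ probs - pi).max()
    if residual > _RESIDUAL_TOL:
        raise ArithmeticError(f"stationary solve residual {residual:.2e}")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class BootstrapReplicates:
    """Resampled transition matrices plus the scheme metadata."""

    labels: tuple[str, ...]
    matrices: np.ndarray  # (n_boot, K, K) row-stochastic
    scheme: str
    seed: int
    n_redraws: int


def bootstrap_matrices(
    counts: TransitionCounts,
    n_boot: int,
    seed: int,
    scheme: str = "pooled",
    rejection_cap: int = DEFAULT_REJECTION_CAP,
) -> BootstrapReplicates:
    """Draw ``n_boot`` resampled transition probability matrices.

    See the module docstring for the two schemes.  Deterministic for a given
    ``seed``: the same seed yields a bit-identical replicate set.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if scheme not in ("pooled", "row-stratified"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    c = counts.counts
    n = counts.n_pairs
    if n == 0:
        raise ValueError("cannot bootstrap all-zero counts")
    k = len(counts.labels)
    rng = np.random.default_rng(seed)
    row_totals = counts.row_totals
    row_probs = np.where(
        row_totals[:, None] > 0, c / np.maximum(row_totals[:, None], 1), 0.0
    )

    def draw(size: int) -> np.ndarray:
        if scheme == "pooled":
            flat = rng.multinomial(n, (c / n).ravel(), size=size)
            return flat.reshape(size, k, k)
        rows = [
            rng.multinomial(int(row_totals[i]), row_probs[i], size=size)
            for i in range(k)
        ]
        return np.stack(rows, axis=1)

    accepted = np.empty((n_boot, k, k))
    n_accepted = 0
    n_redraws = 0
    consecutive_rejections = 0
    while n_accepted < n_boot:
        batch = draw(n_boot - n_accepted)
        totals = batch.sum(axis=2, keepdims=True)
        valid = (totals[:, :, 0] > 0).all(axis=1)
        probs = np.where(totals > 0, batch / np.maximum(totals, 1), np.nan)
        valid &= _irreducible_mask(np.nan_to_num(probs))
        n_new = int(valid.sum())
        rejected = len(batch) - n_new
        n_redraws += rejected
        consecutive_rejections = 0 if n_new else consecutive_rejections + rejected
        if consecutive_rejections >= rejection_cap:
            raise ValueError(
                f"bootstrap rejected {consecutive_rejections} consecutive "
                "replicates (empty row or reducible chain); counts are too "
                "degenerate to resample"
            )
        accepted[n_accepted : n_accepted + n_new] = probs[valid]
        n_accepted += n_new
    return BootstrapReplicates(
        labels=counts.labels,
        matrices=accepted,
        scheme=scheme,
        seed=seed,
        n_redraws=n_redraws,
    )


@dataclass(frozen=True)
class SteadyStateResult:
    """Point and bootstrap inference for the stationary sex ratio."""

    labels: tuple[str, ...]
    point: np.ndarray
    boot_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int
    level: float
    null_value: float
    exceeds_null: np.ndarray  # per state: ci_low > null_value
    below_null: np.ndarray  # per state: ci_high < null_value
    scheme: str
    n_redraws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.labels,
                "point": self.point,
                "boot_mean": self.boot_mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "exceeds_null": self.exceeds_null,
                "below_null": self.below_null,
            }
        )


def _replicate_stationaries(replicates: BootstrapReplicates) -> np.ndarray:
    """Stationary distribution of every replicate (all irreducible by
    construction); tiny negative round-off is clipped and renormalized."""
    pis = _stationary_batch(replicates.matrices)
    pis = np.clip(pis, 0.0, None)
    return pis / pis.sum(axis=1, keepdims=True)


def steady_state_test(
    counts: TransitionCounts,
    n_boot: int = 5000,
    seed: int = 0,
    null_value: float = 1.0 / 3.0,
    level: float = 0.95,
    scheme: str = "pooled",
) -> SteadyStateResult:
    """Bootstrap the stationary distribution and compare it to a uniform null.

    Returns the observed-matrix point estimate, the replicate mean, the
    percentile interval at ``level`` per state, and the two significance
    calls ``exceeds_null`` (interval entirely above the null share) and
    ``below_null`` (entirely below).
    """
    from .transitions import to_probabilities

    point = stationary(to_probabilities(counts))
    replicates = bootstrap_matrices(counts, n_boot=n_boot, seed=seed, scheme=scheme)
    pis = _replicate_stationaries(replicates)
    alpha = (1.0 - level) / 2.0
    ci_low = np.quantile(pis, alpha, axis=0)
    ci_high = np.quantile(pis, 1.0 - alpha, axis=0)
    boot_mean = pis.mean(axis=0)
    return SteadyStateResult(
        labels=counts.labels,
        point=point,
        boot_mean=boot_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        level=level,
        null_value=null_value,
        exceeds_null=ci_low > null_value,
        below_null=ci_high < null_value,
        scheme=scheme,
        n_redraws=replicates.n_redraws,
    )


def transition_prob_cis(
    counts: TransitionCounts,
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    scheme: str = "pooled",
) -> pd.DataFrame:
    """Bootstrap mean and percentile CI for every transition probability.

    One row per ordered state pair with columns ``from``, ``to``, ``observed``,
    ``boot_mean``, ``ci_low``, ``ci_high``.  Replicate cells from rows with no
    resampled events are undefined and excluded from that cell's statistics.
    """
    from .transitions import to_probabilities

    observed = to_probabilities(counts).probs
    replicates = bootstrap_matrices(counts, n_boot=n_boot, seed=seed, scheme=scheme)
    mats = replicates.matrices
    alpha = (1.0 - level) / 2.0
    rows = []
    for i, origin in enumerate(counts.labels):
        for j, dest in enumerate(counts.labels):
            cell = mats[:, i, j]
            cell = cell[np.isfinite(cell)]
            rows.append(
                {
                    "from": origin,
                    "to": dest,
                    "observed": observed[i, j],
                    "boot_mean": cell.mean(),
                    "ci_low": np.quantile(cell, alpha),
                    "ci_high": np.quantile(cell, 1.0 - alpha),
                }
            )
    return pd.DataFrame(rows)
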