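"""Cluster-aware permutation test for group lineage richness.

Compares the total symbiont richness (number of distinct lineages in the
union of a set of samples) hosted by caged insects against wild insects.
Because bugs within a cage are not independent, each iteration resamples
one bug per cage before computing the richness difference, and the null
distribution is built by re-randomizing the caged/wild labels within that
iteration's pooled selection.  The p-value is the proportion of iterations
in which the null difference is at least as extreme as the paired observed
difference, doubled for the two-tailed test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import LineageMatrix
from .profiles import _counts_of
from .seeds import as_rng

__all__ = [
    "PermConfig",
    "PermResult",
    "select_one_per_cage",
    "permutation_richness_test",
    "exact_small_oracle",
    "cages_from_bug_table",
]

TAILS = ("two_sided", "caged_lower", "caged_higher")


@dataclass(frozen=True)
class PermConfig:
    """Settings for the richness permutation test."""

    n_iter: int = 10_000
    seed: int | None = None
    tail: str = "two_sided"
    #: add-one finite-sample correction, p = (1 + k) / (n_iter + 1);
    #: False reports the raw proportion k / n_iter instead.
    correction: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")


@dataclass
class PermResult:
    """Observed and null richness-difference distributions with p-values.

    ``observed_diffs[i]`` is the signed statistic (caged - wild richness)
    for iteration i's one-per-cage selection; ``null_diffs[i]`` is the same
    statistic after randomizing origin labels within that iteration's pool.
    """

    p_two: float
    p_one: float
    p_lower: float
    p_higher: float
    observed_diffs: np.ndarray = field(repr=False)
    null_diffs: np.ndarray = field(repr=False)
    n_caged_selected: int = 0
    n_wild: int = 0
    n_iter: int = 0
    seed: int | None = None
    tail: str = "two_sided"

    def to_dict(self) -> dict:
        return {
            "p_two": self.p_two,
            "p_one": self.p_one,
            "p_lower": self.p_lower,
            "p_higher": self.p_higher,
            "mean_observed_diff": float(np.mean(self.observed_diffs)),
            "mean_null_diff": float(np.mean(self.null_diffs)),
            "n_caged_selected": self.n_caged_selected,
            "n_wild": self.n_wild,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "tail": self.tail,
        }


def cages_from_bug_table(
    bugs: pd.DataFrame, sample_ids: Sequence[str]
) -> dict[str, list[str]]:
    """Group the caged bugs among ``sample_ids`` by cage.

    Convenience for feeding the permutation test from a metadata table:
    returns cage_id -> list of bug ids, restricted to caged bugs whose id
    appears in ``sample_ids`` (e.g. the samples surviving rarefaction).
    """
    present = set(sample_ids)
    caged = bugs[(bugs["origin"] == "caged") & bugs["bug_id"].isin(present)]
    return {
        cage: sorted(grp["bug_id"]) for cage, grp in caged.groupby("cage_id", sort=True)
    }


def select_one_per_cage(
    cages: Mapping[str, Sequence[str]],
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Select one sample uniformly at random from each cage."""
    if not cages:
        raise ValueError("no cages to select from")
    rng = as_rng(seed)
    out = []
    for cage in sorted(cages):
        members = list(cages[cage])
        if not members:
            raise ValueError(f"cage {cage!r} has no bugs")
        out.append(members[int(rng.integers(len(members)))])
    return out


def _presence_and_indices(
    matrix: LineageMatrix | pd.DataFrame,
    cages: Mapping[str, Sequence[str]],
    wild_ids: Sequence[str],
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    counts = _counts_of(matrix)
    if not cages:
        raise ValueError("at least one cage required")
    if not len(wild_ids):
        raise ValueError("at least one wild bug required")
    pos = {s: i for i, s in enumerate(counts.index)}
    all_ids = [m for c in sorted(cages) for m in cages[c]] + list(wild_ids)
    unknown = [s for s in all_ids if s not in pos]
    if unknown:
        raise KeyError(f"sample ids absent from the lineage matrix: {unknown}")
    cage_members = []
    for cage in sorted(cages):
        members = list(cages[cage])
        if not members:
            raise ValueError(f"cage {cage!r} has no bugs")
        cage_members.append(np.array([pos[m] for m in members], dtype=np.intp))
    wild_idx = np.array([pos[s] for s in wild_ids], dtype=np.intp)
    presence = counts.to_numpy() > 0
    return presence, cage_members, wild_idx


def permutation_richness_test(
    matrix: LineageMatrix | pd.DataFrame,
    cages: Mapping[str, Sequence[str]],
    wild_ids: Sequence[str],
    config: PermConfig = PermConfig(),
) -> PermResult:
    """Cluster-aware permutation test of caged vs wild group richness.

    Per iteration: (1) draw one bug per cage, compute
    ``d_obs = richness(selected caged) - richness(wild)``; (2) pool the
    selected caged bugs with all wild bugs, randomly reassign the caged
    labels within the pool, and recompute the difference as ``d_null``.
    One-tailed p-values count iterations where ``d_null`` is at least as
    extreme as the paired ``d_obs`` (``<=`` for the caged-lower tail,
    ``>=`` for caged-higher), with an add-one correction by default; the
    two-tailed p doubles the smaller tail, capped at 1.
    """
    presence, cage_members, wild_idx = _presence_and_indices(matrix, cages, wild_ids)
    rng = as_rng(config.seed)
    n_iter = config.n_iter
    n_cages = len(cage_members)
    n_wild = len(wild_idx)

    # one-per-cage selection for every iteration at once: (n_iter, n_cages)
    sel = np.empty((n_iter, n_cages), dtype=np.intp)
    for j, members in enumerate(cage_members):
        sel[:, j] = members[rng.integers(len(members), size=n_iter)]

    wild_rich = int(presence[wild_idx].any(axis=0).sum())
    caged_rich = presence[sel].any(axis=1).sum(axis=1)
    d_obs = caged_rich - wild_rich

    pool = np.concatenate([sel, np.broadcast_to(wild_idx, (n_iter, n_wild))], axis=1)
    pool = rng.permuted(pool, axis=1)
    null_caged = presence[pool[:, :n_cages]].any(axis=1).sum(axis=1)
    null_wild = presence[pool[:, n_cages:]].any(axis=1).sum(axis=1)
    d_null = null_caged - null_wild

    k_lower = int(np.sum(d_null <= d_obs))
    k_higher = int(np.sum(d_null >= d_obs))
    if config.correction:
        p_lower = (1 + k_lower) / (n_iter + 1)
        p_higher = (1 + k_higher) / (n_iter + 1)
    else:
        p_lower = k_lower / n_iter
        p_higher = k_higher / n_iter
    p_two = min(1.0, 2.0 * min(p_lower, p_higher))
    if config.tail == "caged_lower":
        p_one = p_lower
    elif config.tail == "caged_higher":
        p_one = p_higher
    else:
        p_one = min(p_lower, p_higher)
    return PermResult(
        p_two=p_two,
        p_one=p_one,
        p_lower=p_lower,
        p_higher=p_higher,
        observed_diffs=d_obs.astype(np.int64),
        null_diffs=d_null.astype(np.int64),
        n_caged_selected=n_cages,
        n_wild=n_wild,
        n_iter=n_iter,
        seed=config.seed,
        tail=config.tail,
    )


def exact_small_oracle(
    matrix: LineageMatrix | pd.DataFrame,
    caged_ids: Sequence[str],
    wild_ids: Sequence[str],
    tail: str = "two_sided",
    max_pool: int = 12,
) -> float:
    """Exact permutation p over all label assignments of a small pool.

    For a fixed one-per-cage selection, enumerates every way of labelling
    ``len(caged_ids)`` of the pooled bugs as caged and computes the exact
    proportion of assignments whose richness difference is at least as
    extreme as the observed one — the same statistic and tail convention as
    the Monte-Carlo test.  Enumeration is limited to pools of ``max_pool``
    bugs.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    counts = _counts_of(matrix)
    pool_ids = list(caged_ids) + list(wild_ids)
    n = len(pool_ids)
    k = len(caged_ids)
    if n > max_pool:
        raise ValueError(f"pool of {n} bugs exceeds enumeration bound {max_pool}")
    unknown = [s for s in pool_ids if s not in counts.index]
    if unknown:
        raise KeyError(f"sample ids absent from the lineage matrix: {unknown}")
    presence = counts.loc[pool_ids].to_numpy() > 0

    def rich(idx: tuple[int, ...]) -> int:
        if not idx:
            return 0
        return int(presence[list(idx)].any(axis=0).sum())

    d_obs = rich(tuple(range(k))) - rich(tuple(range(k, n)))
    diffs = []
    for combo in itertools.combinations(range(n), k):
        rest = tuple(i for i in range(n) if i not in combo)
        diffs.append(rich(combo) - rich(rest))
    diffs = np.asarray(diffs)
    p_lower = float(np.mean(diffs <= d_obs))
    p_higher = float(np.mean(diffs >= d_obs))
    if tail == "caged_lower":
        return p_lower
    if tail == "caged_higher":
        return p_higher
    return min(1.0, 2.0 * min(p_lower, p_higher))
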