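"""Synthetic cage-experiment generator.

Emulates the moving parts of a field cage study of environmental symbiont
acquisition: a phylogeny of ASVs with a known partition into lineages, a
cage-structured insect experiment (per-treatment acquisition, development
coupled to symbiont status, per-cage mortality), per-bug amplicon read
counts with one dominant lineage, two-year climate series, and the
per-cage diagnostic-PCR subsampling rule.  Everything is seeded and
deterministic so every downstream stage is testable without external data.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    SimConfig,
    lineages_per_bug_sampler,
    validate_bug_table,
)
from .seeds import as_rng, substream

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_phylogeny",
    "simulate_experiment",
    "simulate_reads",
    "simulate_climate",
    "subsample_bugs",
]


# ---------------------------------------------------------------------------
# phylogeny

def _random_subtree(parent: dendropy.Node, labels: Sequence[str],
                    within_scale: float, rng: np.random.Generator) -> list[dendropy.Node]:
    """Grow a random binary subtree under ``parent`` with the given tip labels.

    Edge lengths are drawn uniformly and then rescaled so the maximum
    tip-to-tip path within the subtree equals ``within_scale`` exactly,
    which makes the within-lineage diameter a construction guarantee rather
    than a statistical one.
    """
    if len(labels) == 1:
        leaf = parent.new_child(edge_length=0.0)
        leaf.label = labels[0]
        return [leaf]
    # grow by repeatedly splitting a random current leaf into a cherry
    root = parent.new_child(edge_length=0.0)
    leaves = []
    first = root.new_child(edge_length=float(rng.uniform(0.5, 1.0)))
    second = root.new_child(edge_length=float(rng.uniform(0.5, 1.0)))
    leaves = [first, second]
    for _ in range(len(labels) - 2):
        pick = leaves.pop(int(rng.integers(len(leaves))))
        a = pick.new_child(edge_length=float(rng.uniform(0.5, 1.0)))
        b = pick.new_child(edge_length=float(rng.uniform(0.5, 1.0)))
        leaves.extend([a, b])
    # depth of each leaf below the subtree root
    def depth(node: dendropy.Node) -> float:
        d = 0.0
        while node is not root:
            d += node.edge.length
            node = node.parent_node
        return d

    # max tip-tip distance = max over pairs of depth_i + depth_j - 2*depth_lca;
    # with small trees a brute-force pass is cheapest and obviously right
    max_d = 0.0
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            anc_i = {id(n) for n in _ancestors(leaves[i], root)}
            lca = leaves[j]
            while id(lca) not in anc_i:
                lca = lca.parent_node
            d = depth(leaves[i]) + depth(leaves[j]) - 2.0 * depth(lca)
            max_d = max(max_d, d)
    scale = within_scale / max_d
    for node in root.preorder_iter():
        if node is not root and node.edge.length is not None:
            node.edge.length *= scale
    for leaf, lab in zip(leaves, labels):
        leaf.label = lab
    return leaves


def _ancestors(node: dendropy.Node, stop: dendropy.Node) -> list[dendropy.Node]:
    out = [node]
    while node is not stop:
        node = node.parent_node
        out.append(node)
    return out


def simulate_phylogeny(
    n_lineages: int,
    asvs_per_lineage: int,
    within_scale: float = 0.02,
    between_scale: float = 1.0,
    seed: int | np.random.Generator | None = None,
    lineage_labels: Sequence[str] | None = None,
) -> tuple[dendropy.Tree, dict[str, list[str]]]:
    """Simulate a rooted ASV phylogeny with a known lineage partition.

    The tree is a pectinate backbone of long inter-lineage stems (each at
    least ``between_scale / 2``, so any two tips of different lineages are
    at least ``between_scale`` apart) carrying compact random subtrees
    whose within-lineage diameter equals ``within_scale`` exactly.  With
    ``within_scale < h < between_scale`` the partition is therefore
    recoverable by cophenetic agglomeration at threshold ``h`` by
    construction.

    Returns the tree (tips labelled ``ASV_<lineage>_<index>``) together
    with the true lineage -> tip-label partition.
    """
    if n_lineages < 1 or asvs_per_lineage < 1:
        raise ConfigError("n_lineages and asvs_per_lineage must be >= 1")
    if within_scale <= 0 or between_scale <= 0:
        raise ConfigError("branch-length scales must be positive")
    rng = as_rng(seed)
    if lineage_labels is None:
        lineage_labels = [f"L{i + 1:02d}" for i in range(n_lineages)]
    elif len(lineage_labels) != n_lineages:
        raise ConfigError("lineage_labels length must equal n_lineages")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    partition: dict[str, list[str]] = {}

    def stem_length() -> float:
        return float(between_scale * (0.5 + 0.5 * rng.uniform()))

    spine = tree.seed_node
    for i, lab in enumerate(lineage_labels):
        tip_labels = [f"ASV_{lab}_{j + 1:03d}" for j in range(asvs_per_lineage)]
        partition[lab] = tip_labels
        if n_lineages == 1:
            attach = spine
        elif i < n_lineages - 1:
            stem = spine.new_child(edge_length=stem_length())
            attach = stem
            if i < n_lineages - 2:
                spine = spine.new_child(edge_length=float(0.1 * between_scale * rng.uniform()))
        else:
            attach = spine.new_child(edge_length=stem_length())
        if asvs_per_lineage == 1:
            if attach is tree.seed_node:
                leaf = attach.new_child(edge_length=0.0)
            else:
                leaf = attach
            leaf.label = tip_labels[0]
        else:
            _random_subtree(attach, tip_labels, within_scale, rng)

    for leaf in tree.leaf_node_iter():
        leaf.taxon = taxa.new_taxon(leaf.label)
        leaf.label = None
    return tree, partition


# ---------------------------------------------------------------------------
# cage experiment

def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cage experiment described by ``config``.

    Per cage, ``bugs_per_cage`` nymphs are released; each acquires the
    symbiont with its treatment's ``acquisition_prob``; the probability of
    reaching a late stage (fifth instar or adult) depends on symbiont
    status; the number of deaths per cage is Poisson with the treatment's
    ``mortality_rate`` (capped at the census).  ``n_wild`` free-roaming
    adults, all symbiont-positive, are appended.

    Returns ``(cages, bugs)`` DataFrames.
    """
    rng = substream(config.seed, "experiment")
    cage_rows = []
    bug_rows = []
    for treatment, spec in config.treatments.items():
        for c in range(config.n_cages):
            cage_id = f"{config.year}_{treatment}_c{c + 1:02d}"
            cage_rows.append(
                {"cage_id": cage_id, "treatment": treatment, "year": config.year,
                 "n_added": config.bugs_per_cage}
            )
            n = config.bugs_per_cage
            positive = rng.random(n) < spec.acquisition_prob
            p_late = np.where(
                positive, config.p_late_given_symbiotic, config.p_late_given_aposymbiotic
            )
            late = rng.random(n) < p_late
            stage = np.where(
                late,
                rng.choice(["instar5", "adult"], size=n),
                rng.choice(["instar3", "instar4"], size=n),
            )
            n_dead = min(int(rng.poisson(spec.mortality_rate)), n)
            dead_idx = rng.choice(n, size=n_dead, replace=False)
            alive = np.ones(n, dtype=bool)
            alive[dead_idx] = False
            sex = np.where(
                stage == "adult", rng.choice(["M", "F"], size=n), "unknown"
            )
            for b in range(n):
                bug_rows.append(
                    {
                        "bug_id": f"{cage_id}_b{b + 1:02d}",
                        "cage_id": cage_id,
                        "origin": "caged",
                        "treatment": treatment,
                        "year": config.year,
                        "stage": stage[b],
                        "sex": sex[b],
                        "alive": bool(alive[b]),
                        "symbiont_positive": bool(positive[b]),
                    }
                )
    for w in range(config.n_wild):
        bug_rows.append(
            {
                "bug_id": f"wild_{config.year}_{w + 1:03d}",
                "cage_id": pd.NA,
                "origin": "wild",
                "treatment": pd.NA,
                "year": config.year,
                "stage": "adult",
                "sex": str(rng.choice(["M", "F"])),
                "alive": True,
                "symbiont_positive": True,
            }
        )
    cages = pd.DataFrame(cage_rows)
    bugs = pd.DataFrame(bug_rows)
    return cages, validate_bug_table(bugs)


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    bugs: pd.DataFrame,
    partition: Mapping[str, Sequence[str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-bug ASV read counts.

    Each symbiont-positive bug hosts ``k ~ lineages_per_bug`` lineages
    drawn without replacement from its origin's pool; the dominant lineage
    receives at least ``dominant_fraction`` of the bug's reads, the
    remainder is split over the minor lineages with Dirichlet weights, and
    each lineage's reads are spread uniformly-multinomially over its ASVs.
    Aposymbiotic bugs get all-zero rows.  Row sums equal the drawn depth
    exactly.
    """
    if rng is None:
        rng = substream(config.seed, "reads")
    for pool, name in ((config.caged_pool, "caged"), (config.wild_pool, "wild")):
        missing = [lin for lin in pool if lin not in partition]
        if missing:
            raise ConfigError(f"{name} pool lineages missing from partition: {missing}")
    asv_ids = [a for lin in sorted(partition) for a in partition[lin]]
    col_of = {a: i for i, a in enumerate(asv_ids)}
    ks, kp = lineages_per_bug_sampler(config.lineages_per_bug)
    counts = np.zeros((len(bugs), len(asv_ids)), dtype=np.int64)
    lo, hi = config.read_depth
    for row, rec in enumerate(bugs.itertuples(index=False)):
        if not rec.symbiont_positive:
            continue
        pool = config.caged_pool if rec.origin == "caged" else config.wild_pool
        k = int(rng.choice(ks, p=kp))
        if k > len(pool):
            logger.info(
                "bug %s: requested %d lineages, pool has %d; clamping",
                rec.bug_id, k, len(pool),
            )
            k = len(pool)
        chosen = rng.choice(len(pool), size=k, replace=False)
        lineages = [pool[i] for i in chosen]  # first drawn is the dominant
        depth = int(rng.integers(lo, hi + 1))
        if k == 1:
            lineage_reads = [depth]
        else:
            dom = int(math.ceil(config.dominant_fraction * depth))
            rest = depth - dom
            if rest >= k - 1:
                # every hosted minor lineage is detectable: >= 1 read each
                w = rng.dirichlet(np.ones(k - 1))
                minor = 1 + rng.multinomial(rest - (k - 1), w)
            else:
                minor = np.zeros(k - 1, dtype=np.int64)
                minor[:rest] = 1
            lineage_reads = [dom, *minor.tolist()]
        for lin, n_reads in zip(lineages, lineage_reads):
            members = partition[lin]
            split = rng.multinomial(n_reads, np.full(len(members), 1.0 / len(members)))
            for a, c in zip(members, split):
                counts[row, col_of[a]] += c
    return pd.DataFrame(counts, index=list(bugs["bug_id"]), columns=asv_ids)


# ---------------------------------------------------------------------------
# climate

def simulate_climate(
    n_days: int,
    temp_max_mean: float = 34.0,
    rh_max_mean: float = 75.0,
    temp_daily_sd: float = 1.5,
    rh_daily_sd: float = 5.0,
    reading_sd: float = 0.0,
    readings_per_day: int = 24,
    temp_amplitude: float = 12.0,
    rh_amplitude: float = 40.0,
    start: str = "2019-09-01",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a logger series with a sinusoidal daily cycle.

    Temperature peaks at 15:00 local, humidity at 05:00 (the two are
    anti-phased as in desert orchards).  Each day's peak is drawn around
    ``temp_max_mean`` / ``rh_max_mean`` with the daily SDs, so with hourly
    or 5-minute cadence (both sample the peak hour exactly) the daily
    maxima have the configured mean up to the per-reading noise.  Humidity
    is clipped to [0, 100].
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    rng = as_rng(seed)
    step = pd.Timedelta(days=1) / readings_per_day
    ts = pd.date_range(start=start, periods=n_days * readings_per_day, freq=step)
    hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    day_idx = np.repeat(np.arange(n_days), readings_per_day)
    t_peak = temp_max_mean + rng.normal(0.0, temp_daily_sd, size=n_days)
    rh_peak = rh_max_mean + rng.normal(0.0, rh_daily_sd, size=n_days)
    temp = (
        t_peak[day_idx]
        - temp_amplitude * (1.0 - np.cos(2 * np.pi * (hours - 15.0) / 24.0)) / 2.0
    )
    rh = (
        rh_peak[day_idx]
        - rh_amplitude * (1.0 - np.cos(2 * np.pi * (hours - 5.0) / 24.0)) / 2.0
    )
    if reading_sd > 0:
        temp = temp + rng.normal(0.0, reading_sd, size=len(ts))
        rh = rh + rng.normal(0.0, reading_sd, size=len(ts))
    rh = np.clip(rh, 0.0, 100.0)
    return pd.DataFrame({"timestamp": ts, "temperature": temp, "humidity": rh})


# ---------------------------------------------------------------------------
# diagnostic-PCR subsampling

def subsample_bugs(
    bugs: pd.DataFrame,
    max_per_cage: int = 7,
    min_per_instar: int = 2,
    min_per_adult_sex: int = 2,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Select survivors per cage for diagnostic testing.

    Mirrors the field protocol: up to ``max_per_cage`` surviving insects per
    cage, aiming for at least ``min_per_instar`` per juvenile instar present
    and ``min_per_adult_sex`` adults per sex.  When the quotas cannot all
    fit within the cap they are relaxed round-robin (one pick per class per
    round), which keeps every class represented; relaxation is logged.
    Selection among eligible bugs is uniform under the given seed.
    """
    rng = as_rng(seed)
    selected: list[pd.DataFrame] = []
    caged = bugs[bugs["cage_id"].notna()]
    for cage_id, grp in caged.groupby("cage_id", sort=True):
        alive = grp[grp["alive"]]
        if len(alive) <= max_per_cage:
            selected.append(alive)
            continue
        classes: dict[str, list[int]] = {}
        for idx, rec in alive.iterrows():
            key = f"adult_{rec['sex']}" if rec["stage"] == "adult" else str(rec["stage"])
            classes.setdefault(key, []).append(idx)
        quotas = {
            key: min(min_per_adult_sex if key.startswith("adult") else min_per_instar,
                     len(members))
            for key, members in classes.items()
        }
        for members in classes.values():
            rng.shuffle(members)
        picks: list[int] = []
        if sum(quotas.values()) > max_per_cage:
            logger.info(
                "cage %s: quotas (%s) exceed cap %d; relaxing round-robin",
                cage_id, quotas, max_per_cage,
            )
            order = sorted(classes)
            rng.shuffle(order)
            rounds = 0
            while len(picks) < max_per_cage:
                progressed = False
                for key in order:
                    if len(picks) >= max_per_cage:
                        break
                    if rounds < len(classes[key]):
                        picks.append(classes[key][rounds])
                        progressed = True
                rounds += 1
                if not progressed:
                    break
        else:
            for key in sorted(classes):
                picks.extend(classes[key][: quotas[key]])
            remaining = [i for members in classes.values() for i in members if i not in picks]
            n_fill = min(max_per_cage - len(picks), len(remaining))
            if n_fill > 0:
                fill = rng.choice(len(remaining), size=n_fill, replace=False)
                picks.extend(remaining[i] for i in fill)
        selected.append(alive.loc[sorted(picks)])
    if not selected:
        return caged.iloc[0:0]
    return pd.concat(selected).sort_index()
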