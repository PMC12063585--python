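"""Shared data containers and configuration.

Tabular data (bug metadata, cage tables, climate series, ASV read counts)
are plain pandas DataFrames with documented schemas, validated by the
helpers here.  Trees are dendropy ``Tree`` objects whose tip labels are ASV
ids.  ``LineageMatrix`` bundles an agglomerated count table with the
ASV-to-lineage partition that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# enumerations and schemas

#: Developmental stages recorded at harvest.  Second instars are the stage
#: released into cages, so they can appear in metadata, but the early/late
#: coding used by the stage analyses only accepts instar3..adult.
STAGES = ("instar2", "instar3", "instar4", "instar5", "adult")

SEXES = ("M", "F", "unknown")

ORIGINS = ("caged", "wild")

#: Required columns of a bug-metadata table, one row per insect.
BUG_COLUMNS = (
    "bug_id",
    "cage_id",
    "origin",
    "treatment",
    "year",
    "stage",
    "sex",
    "alive",
    "symbiont_positive",
)


class SchemaError(ValueError):
    """A tabular input violates its declared schema."""


def validate_bug_table(bugs: pd.DataFrame) -> pd.DataFrame:
    """Validate a bug-metadata table against the BugRecord schema.

    Checks required columns, unique bug ids, enumerated stage/sex/origin
    values, and the wild-bug constraint (wild bugs carry neither a cage nor
    a treatment).  Returns the table unchanged on success.
    """
    missing = [c for c in BUG_COLUMNS if c not in bugs.columns]
    if missing:
        raise SchemaError(f"bug table missing required columns: {missing}")
    dup = bugs["bug_id"][bugs["bug_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate bug ids: {sorted(dup.unique().tolist())}")
    bad_stage = bugs.loc[~bugs["stage"].isin(STAGES), "bug_id"]
    if len(bad_stage):
        raise SchemaError(
            f"unknown stage label for bugs {bad_stage.tolist()}; "
            f"allowed: {STAGES}"
        )
    bad_sex = bugs.loc[~bugs["sex"].isin(SEXES), "bug_id"]
    if len(bad_sex):
        raise SchemaError(f"unknown sex for bugs {bad_sex.tolist()}; allowed: {SEXES}")
    bad_origin = bugs.loc[~bugs["origin"].isin(ORIGINS), "bug_id"]
    if len(bad_origin):
        raise SchemaError(
            f"unknown origin for bugs {bad_origin.tolist()}; allowed: {ORIGINS}"
        )
    wild = bugs[bugs["origin"] == "wild"]
    bad_wild = wild.loc[wild["cage_id"].notna() | wild["treatment"].notna(), "bug_id"]
    if len(bad_wild):
        raise SchemaError(
            f"wild bugs must have no cage_id or treatment: {bad_wild.tolist()}"
        )
    return bugs


def validate_read_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x ASVs count table: unique ids, non-negative ints."""
    if counts.index.duplicated().any():
        raise SchemaError("duplicate sample ids in read matrix")
    if counts.columns.duplicated().any():
        raise SchemaError("duplicate ASV ids in read matrix")
    arr = counts.to_numpy()
    if arr.size:
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr - np.floor(arr)
            if np.any(frac != 0):
                r, c = np.argwhere(frac != 0)[0]
                raise SchemaError(
                    f"non-integer count at (sample={counts.index[r]!r}, "
                    f"asv={counts.columns[c]!r}): {arr[r, c]}"
                )
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"negative count at (sample={counts.index[r]!r}, "
                f"asv={counts.columns[c]!r}): {arr[r, c]}"
            )
    return counts


def validate_climate(series: pd.DataFrame) -> pd.DataFrame:
    """Validate a climate series: strictly increasing timestamps, RH in [0,100]."""
    for col in ("timestamp", "temperature", "humidity"):
        if col not in series.columns:
            raise SchemaError(f"climate series missing column {col!r}")
    ts = pd.to_datetime(series["timestamp"])
    if len(ts) > 1 and not ts.is_monotonic_increasing:
        raise SchemaError("climate timestamps must be increasing")
    if len(ts) > 1 and ts.duplicated().any():
        raise SchemaError("climate timestamps must be strictly increasing (duplicates)")
    rh = series["humidity"].to_numpy(dtype=float)
    if rh.size and (np.nanmin(rh) < 0 or np.nanmax(rh) > 100):
        raise SchemaError("relative humidity must lie in [0, 100]")
    return series


# ---------------------------------------------------------------------------
# lineage matrix

@dataclass
class LineageMatrix:
    """Samples x lineages count table plus the ASV partition behind it.

    Attributes
    ----------
    counts
        Integer counts, index = sample ids, columns = lineage ids.
    mapping
        asv_id -> lineage_id for every ASV that entered agglomeration.
    archetypes
        lineage_id -> the member ASV with the largest total count across
        samples (ties broken by lexicographically smallest ASV id).
        Lineages are named after their archetype ASV.
    """

    counts: pd.DataFrame
    mapping: dict[str, str] = field(default_factory=dict)
    archetypes: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lineage_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# simulation configuration

class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class TreatmentSpec:
    """Per-treatment parameters of the cage experiment.

    acquisition_prob
        Probability that a nymph in this treatment acquires the symbiont
        over the course of the experiment.
    mortality_rate
        Expected number of deaths per cage (Poisson mean); deaths are capped
        at the cage census.
    """

    acquisition_prob: float
    mortality_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.acquisition_prob <= 1.0:
            raise ConfigError(
                f"acquisition_prob must be in [0,1], got {self.acquisition_prob}"
            )
        if self.mortality_rate < 0:
            raise ConfigError(f"mortality_rate must be >= 0, got {self.mortality_rate}")


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated cage experiment.

    The defaults mirror the field design: 10 replicate trees (cages) per
    treatment, 12 second-instar nymphs added per cage, a symbiont-fed
    control acquiring at ~0.75 versus ~0.30 in open treatments, development
    to the late stages strongly coupled to symbiont status, wild bugs all
    symbiotic with a 14-lineage pool against a 3-lineage caged pool, and
    per-bug communities of 1-5 lineages with one dominant.
    """

    n_cages: int = 10
    treatments: Mapping[str, TreatmentSpec] = field(
        default_factory=lambda: {
            "caballeronia": TreatmentSpec(acquisition_prob=0.75, mortality_rate=0.5),
            "burst_fruit": TreatmentSpec(acquisition_prob=0.30, mortality_rate=1.0),
            "adult": TreatmentSpec(acquisition_prob=0.30, mortality_rate=2.0),
            "phyllosphere": TreatmentSpec(acquisition_prob=0.30, mortality_rate=1.0),
        }
    )
    bugs_per_cage: int = 12
    p_late_given_symbiotic: float = 0.9
    p_late_given_aposymbiotic: float = 0.15
    n_wild: int = 29
    caged_pool: tuple[str, ...] = ("L01", "L02", "L03")
    wild_pool: tuple[str, ...] = tuple(f"L{i:02d}" for i in range(1, 15))
    lineages_per_bug: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}
    )
    dominant_fraction: float = 0.85
    read_depth: tuple[int, int] = (12000, 30000)
    year: int = 2019
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cages < 1:
            raise ConfigError("n_cages must be >= 1")
        if self.bugs_per_cage < 1:
            raise ConfigError("bugs_per_cage must be >= 1")
        if not self.treatments:
            raise ConfigError("at least one treatment required")
        for name, t in self.treatments.items():
            if not isinstance(t, TreatmentSpec):
                raise ConfigError(f"treatment {name!r} is not a TreatmentSpec")
        for p in (self.p_late_given_symbiotic, self.p_late_given_aposymbiotic):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"late-stage probability must be in [0,1], got {p}")
        if not self.caged_pool or not self.wild_pool:
            raise ConfigError("lineage pools must be non-empty")
        support = set(self.lineages_per_bug)
        if not support or not support <= {1, 2, 3, 4, 5}:
            raise ConfigError(
                f"lineages_per_bug support must be within {{1..5}}, got {sorted(support)}"
            )
        weights = np.asarray(list(self.lineages_per_bug.values()), dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ConfigError("lineages_per_bug weights must be non-negative, sum > 0")
        if not 0.5 < self.dominant_fraction <= 1.0:
            raise ConfigError("dominant_fraction must lie in (0.5, 1]")
        lo, hi = self.read_depth
        if not (1 <= lo <= hi):
            raise ConfigError(f"read_depth range must satisfy 1 <= lo <= hi, got {self.read_depth}")

    @property
    def lineage_labels(self) -> tuple[str, ...]:
        """Sorted union of the caged and wild lineage pools."""
        return tuple(sorted(set(self.caged_pool) | set(self.wild_pool)))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        """Build a config from a plain mapping (e.g. parsed YAML)."""
        raw = dict(raw)
        if "treatments" in raw:
            raw["treatments"] = {
                name: TreatmentSpec(**spec) if not isinstance(spec, TreatmentSpec) else spec
                for name, spec in raw["treatments"].items()
            }
        for key in ("caged_pool", "wild_pool"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "lineages_per_bug" in raw:
            raw["lineages_per_bug"] = {int(k): float(v) for k, v in raw["lineages_per_bug"].items()}
        if "read_depth" in raw:
            raw["read_depth"] = tuple(int(v) for v in raw["read_depth"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "n_cages": self.n_cages,
            "treatments": {
                name: {"acquisition_prob": t.acquisition_prob, "mortality_rate": t.mortality_rate}
                for name, t in self.treatments.items()
            },
            "bugs_per_cage": self.bugs_per_cage,
            "p_late_given_symbiotic": self.p_late_given_symbiotic,
            "p_late_given_aposymbiotic": self.p_late_given_aposymbiotic,
            "n_wild": self.n_wild,
            "caged_pool": list(self.caged_pool),
            "wild_pool": list(self.wild_pool),
            "lineages_per_bug": {int(k): float(v) for k, v in self.lineages_per_bug.items()},
            "dominant_fraction": self.dominant_fraction,
            "read_depth": list(self.read_depth),
            "year": self.year,
            "seed": self.seed,
        }


def lineages_per_bug_sampler(
    dist: Mapping[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a lineages-per-bug distribution into (values, probabilities)."""
    ks = np.asarray(sorted(dist), dtype=int)
    ps = np.asarray([dist[int(k)] for k in ks], dtype=float)
    return ks, ps / ps.sum()
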