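"""Vertical/horizontal transfer classification from presence/absence sets.

A taxon found in a later host generation is called *vertically
transferred* when it was already present in the seed (founder)
generation, and *horizontally acquired* when it first appears later
(environmental recruitment).  Presence is decided on RAW counts with a
detection rule (at least ``min_count`` reads in at least
``min_prevalence`` samples of the group); the default — one read in one
sample — is the weakest rule consistent with reporting plain set sizes.

Two baselines are supported for "vertical":

* ``seed_baseline`` — present at generation g and in the seed set
  (per-generation vertical/horizontal percentages);
* ``chain`` — present at g and in *every* earlier generation
  (taxa "transferred across all generations"; this is the default for
  flow/Sankey-style retention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    GENERATIONS,
    NO_FIELD,
    Dataset,
    GroupKey,
    group_samples,
)

__all__ = [
    "PresenceMap",
    "GenerationTransfer",
    "TransferClassification",
    "StageFlow",
    "FlowResult",
    "presence_sets",
    "classify_transfer",
    "flow_proportions",
    "shared_unique",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (presentation rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class PresenceMap:
    """Per-group detected-taxon sets under a fixed detection rule."""

    groups: dict[GroupKey, frozenset[str]]
    min_count: int = 1
    min_prevalence: int = 1

    def get(self, key: GroupKey) -> frozenset[str]:
        return self.groups.get(key, frozenset())

    def lookup(self, key: GroupKey) -> frozenset[str]:
        """Present set for a key, tolerating field mismatches.

        Seed (and, in single-field designs, daughter) groups carry the
        explicit no-field level; when a context names a field the lookup
        falls back to the no-field group and finally to the union of all
        groups matching on the remaining components (one seed lot feeds
        every field).
        """
        if key in self.groups:
            return self.groups[key]
        nofield = key.replace(field=NO_FIELD)
        if nofield in self.groups:
            return self.groups[nofield]
        matches = [
            s
            for k, s in self.groups.items()
            if k.generation == key.generation
            and k.compartment == key.compartment
            and k.cultivar == key.cultivar
        ]
        out: set[str] = set()
        for s in matches:
            out |= s
        return frozenset(out)


def presence_sets(
    ds: Dataset,
    by: Sequence[str] = ("generation", "compartment", "cultivar", "field"),
    min_count: int = 1,
    min_prevalence: int = 1,
) -> PresenceMap:
    """Detected-taxon set per design cell, computed on raw counts."""
    if min_count < 1 or min_prevalence < 1:
        raise ValueError("min_count and min_prevalence must be >= 1")
    groups = group_samples(ds, list(by))
    col_of = {s: j for j, s in enumerate(ds.table.sample_ids)}
    counts = ds.table.counts
    taxa = np.asarray(ds.table.taxon_ids)
    out: dict[GroupKey, frozenset[str]] = {}
    for key, sample_ids in groups.items():
        cols = [col_of[s] for s in sample_ids]
        hits = (counts[:, cols] >= min_count).sum(axis=1)
        out[key] = frozenset(taxa[hits >= min_prevalence])
    return PresenceMap(out, min_count=min_count, min_prevalence=min_prevalence)


@dataclass
class GenerationTransfer:
    """Classification of one later generation's taxa against the baseline."""

    generation: str
    present: frozenset[str]
    vertical_set: frozenset[str]
    horizontal_set: frozenset[str]
    vertical_pct: float  # NaN when the generation's set is empty
    horizontal_pct: float


@dataclass
class TransferClassification:
    """Vertical/horizontal split for one (compartment, cultivar, field)."""

    compartment: str
    cultivar: str
    field: Optional[str]
    mode: str
    seed_set: frozenset[str]
    per_generation: dict[str, GenerationTransfer]


def classify_transfer(
    presence: PresenceMap,
    context: tuple[str, str, Optional[str]],
    mode: str = "seed_baseline",
    generations: Sequence[str] = GENERATIONS,
) -> TransferClassification:
    """Split each later generation's taxa into vertical vs horizontal.

    ``context`` is (compartment, cultivar, field); ``field`` may be None
    for single-field or pooled designs.  The seed baseline is always the
    no-field seed group of the same cultivar and compartment.
    """
    if mode not in ("seed_baseline", "chain"):
        raise ValueError(f"mode must be 'seed_baseline' or 'chain', got {mode!r}")
    compartment, cultivar, field = context
    keys = [
        GroupKey(generation=g, compartment=compartment, cultivar=cultivar, field=field)
        for g in generations
    ]
    sets = [presence.lookup(k) for k in keys]
    seed_set = sets[0]
    if not seed_set:
        raise ValueError(
            f"seed-generation taxon set is empty for context "
            f"({compartment}, {cultivar}, {field})"
        )
    per_gen: dict[str, GenerationTransfer] = {}
    chain_core = seed_set
    for g, present in zip(generations[1:], sets[1:]):
        chain_core = chain_core & present
        vertical = (present & seed_set) if mode == "seed_baseline" else chain_core
        horizontal = present - vertical
        if present:
            v_pct = 100.0 * len(vertical) / len(present)
            h_pct = 100.0 * len(horizontal) / len(present)
        else:
            warnings.warn(
                f"no taxa detected at generation {g!r} for context "
                f"({compartment}, {cultivar}, {field}); percentages are NA"
            )
            v_pct = h_pct = float("nan")
        per_gen[g] = GenerationTransfer(
            generation=g,
            present=present,
            vertical_set=frozenset(vertical),
            horizontal_set=frozenset(horizontal),
            vertical_pct=v_pct,
            horizontal_pct=h_pct,
        )
    return TransferClassification(
        compartment=compartment,
        cultivar=cultivar,
        field=field,
        mode=mode,
        seed_set=seed_set,
        per_generation=per_gen,
    )


@dataclass
class StageFlow:
    """One stage of a retention (Sankey) flow."""

    key: GroupKey
    entering: frozenset[str]
    retained: frozenset[str]
    pct_exact: float  # NaN when the entering set is empty
    pct_rounded: Optional[int]


@dataclass
class FlowResult:
    """Ordered retention flow; each stage's percentage is relative to the
    previously retained group."""

    stages: list[StageFlow]


def flow_proportions(presence: PresenceMap, stage_keys: Sequence[GroupKey]) -> FlowResult:
    """Chain retention across ordered stages.

    The first stage's set enters unchanged (100%); each later stage
    retains the intersection of the previous stage's retained set with
    the taxa present at that stage, and reports
    ``|retained| / |entering| * 100`` exactly and rounded to the nearest
    integer (halves away from zero).
    """
    if len(stage_keys) < 2:
        raise ValueError("flow requires at least 2 stages")
    first = presence.lookup(stage_keys[0])
    stages = [StageFlow(stage_keys[0], first, first, 100.0, 100)]
    current = first
    for key in stage_keys[1:]:
        entering = current
        retained = entering & presence.lookup(key)
        if entering:
            pct = 100.0 * len(retained) / len(entering)
            stages.append(StageFlow(key, entering, retained, pct, round_half_away(pct)))
        else:
            warnings.warn(f"empty entering set at stage {key}; percentage is NA")
            stages.append(StageFlow(key, entering, retained, float("nan"), None))
        current = retained
    return FlowResult(stages)


def shared_unique(
    presence: PresenceMap, keys: Sequence[GroupKey]
) -> dict[frozenset[GroupKey], int]:
    """Venn-style membership counts over 2-6 groups.

    For every nonempty subset of ``keys``, the number of taxa present in
    exactly those groups; the counts sum to the size of the union.
    """
    if not 2 <= len(keys) <= 6:
        raise ValueError(f"shared_unique supports 2-6 groups, got {len(keys)}")
    sets = {k: presence.lookup(k) for k in keys}
    union: set[str] = set()
    for s in sets.values():
        union |= s
    out: dict[frozenset[GroupKey], int] = {}
    for taxon in union:
        members = frozenset(k for k in keys if taxon in sets[k])
        out[members] = out.get(members, 0) + 1
    return out
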