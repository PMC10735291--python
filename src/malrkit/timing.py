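"""Insertion timing from orthologous presence/absence across species splits.

A retroelement fixed before a speciation event is expected at the
orthologous locus of both daughter lineages; one that inserted between two
successive splits is found only in the lineages that diverged after it.
With two comparison species whose splits from the focal lineage bracket an
interval (e.g. bushbaby before tarsier), presence in both places an
insertion before the first split, presence only in the younger species
places it between the splits, and absence from both leaves it unresolved
(or lineage-specific).

The workflow: keep entities whose best fragment reaches the minimum
Smith-Waterman score; lift the 300 bp flanks on each side of the entity
span through each species' chain and require at least 200 aligned bases per
side in *every* comparison species ("properly aligned", the denominator of
all counts); then lift the entity span itself and call presence when more
than 50 bases align.  Aligned-base counts are summed across chains and
sub-intervals -- the criteria are base counts, not contiguity.  A
present-in-older/absent-in-younger pattern is biologically discordant
(hemiplasy or lineage deletion) and is reported as such, never silently
binned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .formats import ChainAlignment, RepeatEntity, lifted_aligned_bases

log = logging.getLogger(__name__)

CALL_PRE_FIRST = "pre_first_split"
CALL_BETWEEN = "between_splits"
CALL_POST = "post_second_split_or_unresolved"
CALL_DISCORDANT = "discordant"
CALLS = (CALL_PRE_FIRST, CALL_BETWEEN, CALL_POST, CALL_DISCORDANT)


@dataclass(frozen=True)
class TimingThresholds:
    """Filtering and presence criteria (score / bases)."""

    min_sw_score: int = 100
    flank_length: int = 300
    min_flank_aligned: int = 200
    min_presence: int = 50  # strict: aligned bases must exceed this

    def __post_init__(self) -> None:
        if min(self.min_sw_score, self.flank_length,
               self.min_flank_aligned, self.min_presence) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_flank_aligned > self.flank_length:
            raise ValueError("min_flank_aligned cannot exceed flank_length")


@dataclass
class FlankAssessment:
    left_aligned: int
    right_aligned: int
    element_aligned: int
    flank_ok: bool


def filter_entities(
    entities: Sequence[RepeatEntity], thresholds: TimingThresholds
) -> list[RepeatEntity]:
    """Keep entities whose maximum fragment score reaches the minimum."""
    return [e for e in entities if e.max_sw >= thresholds.min_sw_score]


def assess_alignment(
    entity: RepeatEntity,
    chains_per_species: Mapping[str, Sequence[ChainAlignment]],
    thresholds: TimingThresholds,
) -> dict[str, FlankAssessment]:
    """Flank and element aligned-base counts per comparison species.

    Flanks extend from the entity's outermost fragment boundaries (internal
    nesting gaps are part of the span, not of the flanks) and are clipped at
    the sequence ends.
    """
    s, t = entity.span
    chrom = entity.query_name
    out: dict[str, FlankAssessment] = {}
    for sp, chains in chains_per_species.items():
        size = chains[0].target_size if chains else t + thresholds.flank_length
        ls, le = max(0, s - thresholds.flank_length), s
        rs, re = t, min(size, t + thresholds.flank_length)
        left = lifted_aligned_bases(chains, chrom, ls, le) if le > ls else 0
        right = lifted_aligned_bases(chains, chrom, rs, re) if re > rs else 0
        elem = lifted_aligned_bases(chains, chrom, s, t)
        out[sp] = FlankAssessment(
            left_aligned=left, right_aligned=right, element_aligned=elem,
            flank_ok=(left >= thresholds.min_flank_aligned
                      and right >= thresholds.min_flank_aligned),
        )
    return out


def classify_timing(presence_older: bool, presence_younger: bool) -> str:
    """Map the two presence bits to a timing call.

    ``older`` is the species with the deeper split from the focal lineage.
    """
    if presence_older and presence_younger:
        return CALL_PRE_FIRST
    if presence_younger:
        return CALL_BETWEEN
    if presence_older:
        return CALL_DISCORDANT
    return CALL_POST


def run_timing(
    entities: Sequence[RepeatEntity],
    chains_per_species: Mapping[str, Sequence[ChainAlignment]],
    thresholds: TimingThresholds | None = None,
    species_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Full per-entity timing table.

    ``species_order`` names the (older, younger) comparison species; by
    default the two mapping keys in iteration order.  An entity is properly
    aligned only when the flank test passes in *all* comparison species;
    calls are made only for properly aligned entities.
    """
    thresholds = thresholds or TimingThresholds()
    species = list(chains_per_species)
    if species_order is None:
        if len(species) != 2:
            raise ValueError("species_order required unless exactly 2 species")
        species_order = (species[0], species[1])
    older, younger = species_order
    for sp in species_order:
        if sp not in chains_per_species:
            raise ValueError(f"no chains configured for species {sp!r}")

    kept = filter_entities(entities, thresholds)
    rows = []
    for e in kept:
        ass = assess_alignment(e, chains_per_species, thresholds)
        properly = all(a.flank_ok for a in ass.values())
        presence = {sp: a.element_aligned > thresholds.min_presence
                    for sp, a in ass.items()}
        call = (classify_timing(presence[older], presence[younger])
                if properly else None)
        row = {
            "repeat_id": e.repeat_id,
            "family": e.family,
            "chrom": e.query_name,
            "start": e.span[0],
            "end": e.span[1],
            "n_fragments": len(e.fragments),
            "max_sw": e.max_sw,
            "properly_aligned": properly,
            "call": call,
        }
        for sp in species:
            row[f"{sp}_left_aligned"] = ass[sp].left_aligned
            row[f"{sp}_right_aligned"] = ass[sp].right_aligned
            row[f"{sp}_element_aligned"] = ass[sp].element_aligned
            row[f"{sp}_present"] = presence[sp]
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "start", "repeat_id"]).reset_index(drop=True)
    return df


def timing_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-family counts of the timing categories.

    ``frac_younger_only`` is the between-splits fraction of properly
    aligned entities (the statistic that singles out a family active
    between the two splits).
    """
    if calls.empty:
        return pd.DataFrame(columns=["family", "n_total", "n_properly_aligned",
                                     *CALLS, "frac_younger_only"])
    rows = []
    for fam, grp in calls.groupby("family", sort=True):
        aligned = grp[grp["properly_aligned"]]
        counts = {c: int((aligned["call"] == c).sum()) for c in CALLS}
        n_pa = len(aligned)
        rows.append({
            "family": fam,
            "n_total": len(grp),
            "n_properly_aligned": n_pa,
            **counts,
            "frac_younger_only": counts[CALL_BETWEEN] / n_pa if n_pa else 0.0,
        })
    return pd.DataFrame(rows)
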