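"""Consensus-anchored structural-variant genotyping of LTR copies.

Named indel variants (e.g. ``204del``, ``186ins``, ``226_235del``,
``303_312delinsTT``) are defined by 1-based coordinates on a reference LTR
consensus.  Each element's two LTRs are located by aligning the consensus
to both ends, genotyped per variant, and the per-LTR pattern is matched
against the precursor/intermediate/canonical stage definitions of the
THE1B-to-THE1A transition.  LTR replication logic (5' R/U5 and 3' U3 are
the segments a progeny inherits) then predicts the variant pattern after
one replication round, which is what orders the structural changes in time.

Variant presence is decided from the alignment's length signature between
two anchor columns flanking the locus: the number of element bases between
the nearest aligned consensus positions on each side is invariant to where
the aligner places gaps, so calls are robust to gap-placement ambiguity in
diverged copies.  An anchor must exist within 15 consensus bases of the
locus on each side, otherwise the variant is uncallable there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .phylo import AlignParams, global_align_free_end_gaps

log = logging.getLogger(__name__)

#: the four variants that separate the canonical THE1A pattern from THE1B
THE1A_VARIANTS = ("186ins", "204del", "226_235del", "303_312delinsTT")

MAX_ANCHOR_DIST = 15


class SoloLTRError(ValueError):
    """Element has fewer than two detectable LTRs (solo or partial)."""


@dataclass(frozen=True)
class StructuralVariantDef:
    """A named indel on the reference consensus (1-based coordinates).

    ``insertion`` kind: ``start`` is the consensus base after which element
    bases are inserted.  ``deletion``: consensus ``start..end`` absent from
    the element.  ``delins``: consensus ``start..end`` replaced by
    ``replacement`` on the element side.
    """

    name: str
    kind: str
    start: int
    end: int | None = None
    replacement: str | None = None
    insert_seq: str = "C"
    reference: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "delins"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind != "insertion":
            if self.end is None or self.start > self.end:
                raise ValueError(f"{self.name}: need start <= end")
        if self.kind == "delins" and not self.replacement:
            raise ValueError(f"{self.name}: delins needs a replacement")

    @property
    def span(self) -> tuple[float, float]:
        if self.kind == "insertion":
            return (self.start + 0.5, self.start + 0.5)
        return (float(self.start), float(self.end))


def load_variant_defs(path=None) -> dict[str, StructuralVariantDef]:
    """Load variant definitions from YAML; the packaged file by default."""
    if path is None:
        text = (resources.files("malrkit") / "data" / "variants.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    defs = {}
    for item in doc["variants"]:
        item = dict(item)
        item.setdefault("reference", doc.get("reference"))
        d = StructuralVariantDef(**item)
        defs[d.name] = d
    return defs


@dataclass(frozen=True)
class LTRModel:
    """U3/R/U5 boundaries on the consensus; TSS at the U3|R junction.

    Segments are 1-based and contiguous: U3 = 1..u3_end,
    R = u3_end+1..r_end, U5 = r_end+1..length.  During replication a progeny
    inherits R/U5 from the parental 5' LTR and U3 from the parental 3' LTR,
    so a variant's segment decides which parental LTR it is copied from.
    """

    length: int
    u3_end: int
    r_end: int

    def __post_init__(self) -> None:
        if not 0 < self.u3_end < self.r_end < self.length:
            raise ValueError("segments must be ordered and contiguous")

    @property
    def tss(self) -> int:
        return self.u3_end + 1

    def segment_of(self, vdef: StructuralVariantDef) -> str:
        lo, hi = vdef.span
        if hi <= self.u3_end + 0.5:
            return "U3"
        if lo >= self.u3_end + 0.5:
            return "R/U5"  # R and U5 travel together in replication
        raise ValueError(
            f"{vdef.name} spans the U3|R boundary; assign a segment explicitly"
        )


def load_ltr_model(path=None) -> LTRModel:
    if path is None:
        text = (resources.files("malrkit") / "data" / "ltr_model.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return LTRModel(length=doc["length"], u3_end=doc["u3_end"], r_end=doc["r_end"])


# ---------------------------------------------------------------------------
# Applying variants to a consensus (used by the simulator)
# ---------------------------------------------------------------------------

def apply_variants(
    consensus: str,
    variant_defs: Mapping[str, StructuralVariantDef],
    names: Sequence[str] | frozenset,
) -> str:
    """Rewrite the consensus to carry the named variants.

    Definitions are applied from the highest coordinate down so earlier
    coordinates stay valid; overlapping selections are an error.
    """
    chosen = [variant_defs[n] for n in sorted(names)]
    for d in chosen:
        lo, hi = d.span
        if hi > len(consensus):
            raise ValueError(f"{d.name} exceeds consensus length")
    for a in chosen:
        for b in chosen:
            if a.name < b.name:
                if a.span[0] <= b.span[1] and b.span[0] <= a.span[1]:
                    raise ValueError(f"variants {a.name} and {b.name} overlap")
    seq = consensus
    for d in sorted(chosen, key=lambda d: d.span[0], reverse=True):
        if d.kind == "deletion":
            seq = seq[: d.start - 1] + seq[d.end:]
        elif d.kind == "insertion":
            seq = seq[: d.start] + d.insert_seq + seq[d.start:]
        else:
            seq = seq[: d.start - 1] + d.replacement + seq[d.end:]
    return seq


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    """Per-LTR genotype: status of every named variant on one LTR copy."""

    element_id: str
    side: str  # "5p" or "3p"
    status: dict[str, str] = field(default_factory=dict)  # present/absent/uncallable
    delta: dict[str, int | None] = field(default_factory=dict)
    segment_content: dict[str, str | None] = field(default_factory=dict)
    anchor_dist: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    @property
    def present(self) -> frozenset[str]:
        return frozenset(n for n, s in self.status.items() if s == "present")

    @property
    def callable(self) -> bool:
        return all(s != "uncallable" for s in self.status.values())


def _consensus_index(consensus: str, ltr_seq: str,
                     params: AlignParams | None = None):
    """Align an LTR copy to the consensus and map consensus positions.

    Returns (eidx, aln): ``eidx[p]`` (1-based p) is the 0-based element index
    aligned to consensus position p, or -1 where the consensus base aligns
    to a gap.
    """
    aln = global_align_free_end_gaps(consensus, ltr_seq, params)
    eidx = np.full(len(consensus) + 1, -1, dtype=int)
    cpos = 0
    epos = 0
    for a, b in zip(aln.aligned_a, aln.aligned_b):
        if a != "-" and b != "-":
            eidx[cpos + 1] = epos
        if a != "-":
            cpos += 1
        if b != "-":
            epos += 1
    return eidx, aln


def _find_anchor(eidx: np.ndarray, pos: int, direction: int,
                 max_dist: int = MAX_ANCHOR_DIST) -> int | None:
    """Nearest aligned consensus position at or beyond ``pos``."""
    L = len(eidx) - 1
    for step in range(max_dist):
        p = pos + direction * step
        if p < 1 or p > L:
            return None
        if eidx[p] >= 0:
            return p
    return None


def _variant_windows(
    variant_defs: Mapping[str, StructuralVariantDef],
    consensus_len: int,
    margin: int = 20,
) -> dict[str, tuple[int, int]]:
    """Measurement compartment per variant, bounded at midpoints between
    neighbouring variants (or ``margin`` bases when isolated).

    An optimal alignment of a diverged copy may slide an indel gap a few
    columns away from the locus when nearby substitutions make the shifted
    placement score equally well; the element-base count over a compartment
    is invariant to any drift that stays inside it, so compartments as wide
    as possible -- but never containing two variants -- give the most
    robust length signatures.
    """
    edges = {}
    for name, d in variant_defs.items():
        if d.kind == "insertion":
            edges[name] = (d.start, d.start + 1)
        else:
            edges[name] = (d.start - 1, d.end + 1)
    order = sorted(edges, key=lambda n: edges[n][0])
    windows = {}
    for i, name in enumerate(order):
        lo_edge, hi_edge = edges[name]
        lo = max(1, lo_edge - margin)
        hi = min(consensus_len, hi_edge + margin)
        if i > 0:
            prev_hi = edges[order[i - 1]][1]
            lo = max(lo, (prev_hi + lo_edge) // 2)
        if i + 1 < len(order):
            next_lo = edges[order[i + 1]][0]
            hi = min(hi, (hi_edge + next_lo + 1) // 2)
        windows[name] = (lo, hi)
    return windows


def call_variants(
    ltr_seq: str,
    consensus: str,
    variant_defs: Mapping[str, StructuralVariantDef],
    element_id: str = "",
    side: str = "5p",
    params: AlignParams | None = None,
) -> VariantCall:
    """Genotype one LTR copy against the reference consensus.

    For each variant, the element bases between two aligned anchor columns
    bracketing its compartment are counted; the observed-minus-expected
    length difference is the call: a k-base deletion shows -k, an insertion
    shows >= +1, a delins shows len(replacement) - k.  Any other signature,
    or a missing anchor, makes the locus uncallable.  Replacement content is
    recorded but substitutions in it do not flip the call.
    """
    eidx, _ = _consensus_index(consensus, ltr_seq, params)
    call = VariantCall(element_id=element_id, side=side)
    windows = _variant_windows(variant_defs, len(consensus))
    for name, d in variant_defs.items():
        lo, hi = windows[name]
        pa = _find_anchor(eidx, lo, -1)
        pb = _find_anchor(eidx, hi, +1)
        if pa is None or pb is None:
            call.status[name] = "uncallable"
            call.delta[name] = None
            call.segment_content[name] = None
            call.anchor_dist[name] = None
            continue
        call.anchor_dist[name] = (lo - pa, pb - hi)
        seg = ltr_seq[eidx[pa] + 1: eidx[pb]]
        expected = pb - pa - 1  # consensus bases strictly between anchors
        delta = len(seg) - expected
        call.delta[name] = delta
        call.segment_content[name] = seg
        if d.kind == "deletion":
            k = d.end - d.start + 1
            # anchors may sit short of the locus edge; the reference bases
            # between anchor and locus are still expected on the element
            call.status[name] = ("present" if delta == -k
                                 else "absent" if delta == 0 else "uncallable")
        elif d.kind == "insertion":
            call.status[name] = ("present" if delta >= 1
                                 else "absent" if delta == 0 else "uncallable")
        else:
            k = d.end - d.start + 1
            want = len(d.replacement) - k
            call.status[name] = ("present" if delta == want
                                 else "absent" if delta == 0 else "uncallable")
    return call


def find_ltrs(
    element_seq: str,
    ltr_consensus: str,
    min_coverage: float = 0.8,
    params: AlignParams | None = None,
) -> tuple[str, str]:
    """Locate the 5' and 3' LTRs of a full-length element.

    The LTR consensus is aligned (free end gaps) against a window at each
    end of the element; the aligned element stretch is the LTR copy.  If
    either end covers less than ``min_coverage`` of the consensus, the
    element is treated as solo/partial and a :class:`SoloLTRError` is
    raised.
    """
    L = len(ltr_consensus)
    w = min(len(element_seq), int(1.5 * L))
    if len(element_seq) < L // 2:
        raise SoloLTRError(f"{len(element_seq)} bp element too short for two LTRs")

    def one_end(window: str) -> tuple[int, int]:
        aln = global_align_free_end_gaps(ltr_consensus, window, params)
        first = last = None
        epos = 0
        for a, b in zip(aln.aligned_a, aln.aligned_b):
            if a != "-" and b != "-":
                if first is None:
                    first = epos
                last = epos
            if b != "-":
                epos += 1
        covered = sum(1 for a, b in zip(aln.aligned_a, aln.aligned_b)
                      if a != "-" and b != "-")
        if first is None or covered < min_coverage * L:
            raise SoloLTRError("LTR consensus does not cover this end")
        return first, last + 1

    s5, e5 = one_end(element_seq[:w])
    s3, e3 = one_end(element_seq[-w:])
    off = len(element_seq) - w
    if off + s3 < e5:
        raise SoloLTRError("the two LTR hits overlap; not a full-length element")
    return element_seq[s5:e5], element_seq[off + s3: off + e3]


def call_element(
    element_seq: str,
    ltr_consensus: str,
    variant_defs: Mapping[str, StructuralVariantDef],
    element_id: str = "",
    params: AlignParams | None = None,
) -> tuple[VariantCall, VariantCall]:
    ltr5, ltr3 = find_ltrs(element_seq, ltr_consensus, params=params)
    return (
        call_variants(ltr5, ltr_consensus, variant_defs, element_id, "5p", params),
        call_variants(ltr3, ltr_consensus, variant_defs, element_id, "3p", params),
    )


# ---------------------------------------------------------------------------
# Stage classification and replication logic
# ---------------------------------------------------------------------------

THREE_INDELS = frozenset({"186ins", "226_235del", "303_312delinsTT"})

#: stage -> (5' LTR variant set, 3' LTR variant set) over THE1A_VARIANTS
STAGE_DEFS: dict[str, tuple[frozenset, frozenset]] = {
    "precursor": (THREE_INDELS, THREE_INDELS),
    "intermediate": (THREE_INDELS | {"204del"}, THREE_INDELS),
    "canonical": (frozenset(THE1A_VARIANTS), frozenset(THE1A_VARIANTS)),
}


@dataclass
class StageCall:
    element_id: str
    stage: str  # precursor | intermediate | canonical | other | solo_or_partial
    pattern_5p: frozenset[str]
    pattern_3p: frozenset[str]
    reason: str = ""


def classify_stage(call5: VariantCall, call3: VariantCall) -> StageCall:
    """Match the per-LTR pattern of the four named variants to a stage."""
    names = THE1A_VARIANTS
    unc = [n for n in names
           for c in (call5, call3) if c.status.get(n, "uncallable") == "uncallable"]
    p5 = frozenset(n for n in names if call5.status.get(n) == "present")
    p3 = frozenset(n for n in names if call3.status.get(n) == "present")
    if unc:
        return StageCall(call5.element_id, "other", p5, p3,
                         reason="uncallable: " + ",".join(sorted(set(unc))))
    for stage, (s5, s3) in STAGE_DEFS.items():
        if p5 == s5 and p3 == s3:
            return StageCall(call5.element_id, stage, p5, p3)
    return StageCall(call5.element_id, "other", p5, p3,
                     reason="pattern matches no named stage")


def predict_progeny_ltr(
    pattern_5p: frozenset[str] | set[str],
    pattern_3p: frozenset[str] | set[str],
    variant_defs: Mapping[str, StructuralVariantDef],
    ltr_model: LTRModel,
) -> frozenset[str]:
    """Variant pattern both progeny LTRs carry after one replication round.

    The progeny LTR is a composite: U3 from the parental 3' LTR, R/U5 from
    the parental 5' LTR; at birth the two progeny LTRs are identical.
    """
    out = set()
    for name in set(pattern_5p) | set(pattern_3p):
        seg = ltr_model.segment_of(variant_defs[name])
        src = pattern_3p if seg == "U3" else pattern_5p
        if name in src:
            out.add(name)
    return frozenset(out)


def scan_for_stage(
    elements: Mapping[str, str],
    ltr_consensus: str,
    variant_defs: Mapping[str, StructuralVariantDef] | None = None,
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Stage table over a population of full-length elements.

    Elements whose two LTRs cannot both be located are reported as
    ``solo_or_partial`` and excluded from stage counting.  Candidate
    non-canonical (precursor/intermediate) elements are what the chronology
    argument rests on, so their ids are the interesting output.
    """
    if variant_defs is None:
        variant_defs = {n: d for n, d in load_variant_defs().items()
                        if n in THE1A_VARIANTS}
    rows = []
    for eid in sorted(elements):
        try:
            c5, c3 = call_element(elements[eid], ltr_consensus, variant_defs,
                                  eid, params)
        except SoloLTRError as exc:
            rows.append({"element_id": eid, "stage": "solo_or_partial",
                         "pattern_5p": "", "pattern_3p": "", "reason": str(exc)})
            continue
        sc = classify_stage(c5, c3)
        rows.append({
            "element_id": eid, "stage": sc.stage,
            "pattern_5p": "+".join(sorted(sc.pattern_5p)),
            "pattern_3p": "+".join(sorted(sc.pattern_3p)),
            "reason": sc.reason,
        })
    return pd.DataFrame(rows)


def stage_summary(table: pd.DataFrame) -> pd.Series:
    return table["stage"].value_counts()


# ---------------------------------------------------------------------------
# Uniquely shared consensus features
# ---------------------------------------------------------------------------

@dataclass
class SharedBlock:
    """Run of consensus-a columns where a and b agree and all backgrounds
    differ (1-based inclusive coordinates on consensus a)."""

    start: int
    end: int
    violations: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def shared_features(
    consensus_a: str,
    consensus_b: str,
    background: Mapping[str, str],
    min_len: int = 10,
    max_violation_frac: float = 0.1,
    params: AlignParams | None = None,
) -> list[SharedBlock]:
    """Blocks uniquely shared by two consensuses against a background set.

    Every sequence is mapped onto consensus a's coordinate frame by pairwise
    alignment.  A column is diagnostic when b carries a's residue while
    every background consensus carries a different residue or a gap there;
    maximal runs of diagnostic columns are merged across short interruptions
    as long as violations stay below ``max_violation_frac`` of the block.
    Features that exist only as extra sequence in b (absent from a) have no
    columns in this frame and are not reported.
    """
    if not background:
        raise ValueError("uniqueness needs at least one background consensus")
    if params is None:
        # near-prohibitive gap costs: the projection must preserve positional
        # homology between near-colinear consensuses, not let a diverged
        # background region micro-shift to collect coincidental matches; a
        # genuine length difference still forces a gap, paid once
        params = AlignParams(gap_open=-30.0, gap_extend=-10.0)

    def profile(seq: str) -> list[str | None]:
        eidx, _ = _consensus_index(consensus_a, seq, params)
        return [seq[eidx[p]] if eidx[p] >= 0 else None
                for p in range(1, len(consensus_a) + 1)]

    prof_b = profile(consensus_b)
    prof_bg = [profile(s) for s in background.values()]
    good = []
    for i, a_res in enumerate(consensus_a):
        ok = prof_b[i] == a_res and all(
            p[i] is None or p[i] != a_res for p in prof_bg
        )
        good.append(ok)

    runs: list[tuple[int, int]] = []
    i = 0
    n = len(good)
    while i < n:
        if good[i]:
            j = i
            while j + 1 < n and good[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    blocks: list[SharedBlock] = []
    i = 0
    while i < len(runs):
        s, e = runs[i]
        j = i
        while j + 1 < len(runs):
            ns, ne = runs[j + 1]
            span = ne - s + 1
            viol = span - sum(r[1] - r[0] + 1 for r in runs[i:j + 2])
            if viol / span <= max_violation_frac:
                j += 1
                e = ne
            else:
                break
        viol = (e - s + 1) - sum(r[1] - r[0] + 1 for r in runs[i:j + 1])
        if e - s + 1 >= min_len:
            blocks.append(SharedBlock(start=s + 1, end=e + 1, violations=viol))
        i = j + 1
    return blocks


def succession_support(
    family_chain: Sequence[str],
    consensuses: Mapping[str, str],
    min_len: int = 10,
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Uniquely shared feature support for each adjacent pair of a chain.

    For every adjacent pair, the remaining chain members form the
    background; a pair is "supported" when at least one uniquely shared
    block survives.  A correct succession order should support every
    adjacent pair; shuffled orders should support fewer.
    """
    missing = [f for f in family_chain if f not in consensuses]
    if missing:
        raise ValueError(f"no consensus for chain member(s): {missing}")
    if len(family_chain) < 2:
        raise ValueError("chain needs at least two members")
    rows = []
    for a, b in zip(family_chain, family_chain[1:]):
        # all remaining consensuses (chain members and any extra context
        # families supplied) form the background the pair must beat
        bg = {f: s for f, s in consensuses.items() if f not in (a, b)}
        blocks = shared_features(consensuses[a], consensuses[b], bg,
                                 min_len=min_len, params=params)
        rows.append({
            "predecessor": a, "successor": b,
            "n_blocks": len(blocks),
            "total_shared_len": sum(bl.length for bl in blocks),
            "supported": len(blocks) > 0,
        })
    return pd.DataFrame(rows)


def count_supported_pairs(
    order: Sequence[str],
    consensuses: Mapping[str, str],
    min_len: int = 10,
    params: AlignParams | None = None,
) -> int:
    """Number of supported adjacent pairs under a proposed chain order."""
    return int(succession_support(order, consensuses, min_len, params)
               ["supported"].sum())
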