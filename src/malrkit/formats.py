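"""Readers, writers and core containers for the annotation formats the pipeline touches.

Supported on-disk formats: RepeatMasker ``.out`` (UCSC dialect with trailing
repeat ID column) and ``.align`` headers, UCSC pairwise ``chain``, FASTA,
Newick and BED.  All readers accept plain or gzip-compressed files.

Coordinate conventions
----------------------
Internally every genomic interval is 0-based half-open.  Conversion happens
only at the format boundary: ``.out`` genomic coordinates are 1-based
inclusive on disk, chain files are already 0-based half-open.  Repeat
(consensus) coordinates keep the 1-based inclusive convention of ``.out``
because that is how the field quotes them (e.g. "204del" on a consensus).
Rows reported on the ``C`` (complement) strand are normalised to strand
``-`` with ``rep_start <= rep_end`` at parse time.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "RepeatCopy",
    "RepeatEntity",
    "ChainAlignment",
    "LiftResult",
    "read_rmsk_out",
    "write_rmsk_out",
    "read_rmsk_align",
    "group_entities",
    "family_census",
    "read_chain",
    "write_chain",
    "lift_interval",
    "lifted_aligned_bases",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "write_bed",
]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

@dataclass
class RepeatCopy:
    """One annotated repeat interval (one row of a RepeatMasker ``.out`` file).

    ``query_start``/``query_end`` are 0-based half-open; ``rep_start``/
    ``rep_end`` are 1-based inclusive consensus coordinates with
    ``rep_start <= rep_end`` for both strands.  ``rep_left`` is the
    parenthesised remaining-consensus count from the file.  ``repeat_id``
    links fragments of one original insertion.
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    query_name: str
    query_start: int
    query_end: int
    query_left: int
    strand: str
    rep_name: str
    rep_class_family: str
    rep_start: int
    rep_end: int
    rep_left: int
    repeat_id: int

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError(
                f"empty genomic interval {self.query_start}..{self.query_end}"
            )
        if self.sw_score < 0:
            raise ValueError("negative Smith-Waterman score")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.rep_start > self.rep_end:
            raise ValueError("rep_start must not exceed rep_end")

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclass
class RepeatEntity:
    """Fragments sharing one repeat ID: the remains of a single insertion."""

    repeat_id: int
    fragments: list[RepeatCopy]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("entity needs at least one fragment")
        self.fragments = sorted(self.fragments, key=lambda c: c.query_start)
        names = {c.query_name for c in self.fragments}
        if len(names) > 1:
            raise ValueError("fragments of one entity must share query_name")

    @property
    def query_name(self) -> str:
        return self.fragments[0].query_name

    @property
    def span(self) -> tuple[int, int]:
        return self.fragments[0].query_start, self.fragments[-1].query_end

    @property
    def family(self) -> str:
        return Counter(c.rep_name for c in self.fragments).most_common(1)[0][0]

    @property
    def max_sw(self) -> int:
        return max(c.sw_score for c in self.fragments)


class RmskParseError(ValueError):
    pass


class RmskDialectError(RmskParseError):
    pass


def _parse_left(token: str, lineno: int) -> int:
    if token.startswith("(") and token.endswith(")"):
        return int(token[1:-1])
    raise RmskParseError(f"line {lineno}: expected parenthesised value, got {token!r}")


def read_rmsk_out(path) -> list[RepeatCopy]:
    """Parse a RepeatMasker ``.out`` file (UCSC dialect, trailing ID column)."""
    copies: list[RepeatCopy] = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            try:
                int(fields[0])
            except ValueError:
                if lineno <= 3:  # header block
                    continue
                raise RmskParseError(f"line {lineno}: cannot parse score field")
            if fields and fields[-1] == "*":  # optional overlap marker
                fields = fields[:-1]
            if len(fields) == 14:
                raise RmskDialectError(
                    f"line {lineno}: 14 columns, missing trailing repeat ID -- "
                    "this looks like a non-UCSC RepeatMasker run; the pipeline "
                    "needs the ID column to group fragments into entities"
                )
            if len(fields) != 15:
                raise RmskParseError(
                    f"line {lineno}: expected 15 columns, found {len(fields)}"
                )
            strand = fields[8]
            if strand == "+":
                rep_start = int(fields[11])
                rep_end = int(fields[12])
                rep_left = _parse_left(fields[13], lineno)
            elif strand in ("C", "-"):
                # complement rows carry "(left) end begin"
                strand = "-"
                rep_left = _parse_left(fields[11], lineno)
                rep_end = int(fields[12])
                rep_start = int(fields[13])
            else:
                raise RmskParseError(f"line {lineno}: bad strand {fields[8]!r}")
            copies.append(
                RepeatCopy(
                    sw_score=int(fields[0]),
                    pct_div=float(fields[1]),
                    pct_del=float(fields[2]),
                    pct_ins=float(fields[3]),
                    query_name=fields[4],
                    query_start=int(fields[5]) - 1,
                    query_end=int(fields[6]),
                    query_left=_parse_left(fields[7], lineno),
                    strand=strand,
                    rep_name=fields[9],
                    rep_class_family=fields[10],
                    rep_start=rep_start,
                    rep_end=rep_end,
                    rep_left=rep_left,
                    repeat_id=int(fields[14]),
                )
            )
    return copies


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def write_rmsk_out(copies: Iterable[RepeatCopy], path) -> None:
    """Write copies back out in the same dialect :func:`read_rmsk_out` reads."""
    with _open(path, "wt") as fh:
        fh.write(_OUT_HEADER)
        for c in copies:
            if c.strand == "+":
                rep_cols = f"{c.rep_start} {c.rep_end} ({c.rep_left})"
                strand = "+"
            else:
                rep_cols = f"({c.rep_left}) {c.rep_end} {c.rep_start}"
                strand = "C"
            fh.write(
                f"{c.sw_score:>6} {c.pct_div:4.1f} {c.pct_del:4.1f} "
                f"{c.pct_ins:4.1f} {c.query_name} {c.query_start + 1} "
                f"{c.query_end} ({c.query_left}) {strand} {c.rep_name} "
                f"{c.rep_class_family} {rep_cols} {c.repeat_id}\n"
            )


def read_rmsk_align(path) -> list[RepeatCopy]:
    """Extract copy records from the header lines of a ``.align`` file.

    The per-base alignment text is skipped; only the summary line of each
    alignment block is returned, in the same container as ``.out`` rows.
    ``.align`` headers lack the query_left column and percentage breakdown,
    so pct_del/pct_ins are zero and query_left is -1.
    """
    copies: list[RepeatCopy] = []
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if len(fields) < 13:
                continue
            try:
                score = int(fields[0])
                float(fields[1])
            except ValueError:
                continue
            # score div del ins query begin end (left) [C] repeat begin end (left) id
            try:
                qname, qs, qe = fields[4], int(fields[5]), int(fields[6])
                rest = fields[8:]
                if rest[0] in ("C", "+"):
                    strand = "-" if rest[0] == "C" else "+"
                    rest = rest[1:]
                else:
                    strand = "+"
                rep_name = rest[0].split("#")[0]
                if strand == "+":
                    rs, re_, rl = int(rest[1]), int(rest[2]), _parse_left(rest[3], lineno)
                else:
                    rl, re_, rs = _parse_left(rest[1], lineno), int(rest[2]), int(rest[3])
                rid = int(rest[4]) if len(rest) > 4 else -1
            except (ValueError, IndexError, RmskParseError):
                continue
            copies.append(
                RepeatCopy(
                    sw_score=score,
                    pct_div=float(fields[1]),
                    pct_del=0.0,
                    pct_ins=0.0,
                    query_name=qname,
                    query_start=qs - 1,
                    query_end=qe,
                    query_left=-1,
                    strand=strand,
                    rep_name=rep_name,
                    rep_class_family="",
                    rep_start=rs,
                    rep_end=re_,
                    rep_left=rl,
                    repeat_id=rid,
                )
            )
    return copies


def group_entities(copies: Sequence[RepeatCopy]) -> list[RepeatEntity]:
    """Partition copies into entities by ``(query_name, repeat_id)``.

    Fragments of one repeat ID that land on different sequences are split
    into separate entities (with a warning): a single insertion cannot span
    two chromosomes.
    """
    buckets: "OrderedDict[tuple[str, int], list[RepeatCopy]]" = OrderedDict()
    seen_ids: dict[int, set[str]] = {}
    for c in copies:
        buckets.setdefault((c.query_name, c.repeat_id), []).append(c)
        seen_ids.setdefault(c.repeat_id, set()).add(c.query_name)
    for rid, names in seen_ids.items():
        if len(names) > 1:
            log.warning(
                "repeat_id %d appears on %d sequences; split into separate entities",
                rid, len(names),
            )
    return [RepeatEntity(repeat_id=rid, fragments=frags)
            for (_, rid), frags in buckets.items()]


def family_census(
    copies: Sequence[RepeatCopy],
    families: Sequence[str],
    species_label: str,
) -> pd.DataFrame:
    """Per-family fragment and entity counts for one species' annotation.

    Both counts are reported because public annotations are sometimes quoted
    as raw rows and sometimes as repeat-ID entities.
    """
    fam_set = set(families)
    frag = Counter(c.rep_name for c in copies if c.rep_name in fam_set)
    ent = Counter(
        e.family for e in group_entities([c for c in copies if c.rep_name in fam_set])
    )
    return pd.DataFrame(
        {
            "species": species_label,
            "family": list(families),
            "fragments": [frag.get(f, 0) for f in families],
            "entities": [ent.get(f, 0) for f in families],
        }
    )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

@dataclass
class ChainAlignment:
    """A UCSC chain: gapped pairwise alignment between target and query.

    ``blocks`` is a list of ``(size, dt, dq)`` triples; the final triple has
    ``dt == dq == 0``.  Coordinates are 0-based half-open on the stated
    strand, per the chain spec.
    """

    chain_id: int
    score: float
    target_name: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    query_name: str
    query_size: int
    query_strand: str
    query_start: int
    query_end: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        tspan = sum(s + dt for s, dt, _ in self.blocks)
        qspan = sum(s + dq for s, _, dq in self.blocks)
        if self.blocks:
            if any(s <= 0 for s, _, _ in self.blocks):
                raise ValueError("chain block sizes must be positive")
            if tspan != self.target_end - self.target_start:
                raise ValueError("chain blocks do not cover the target span")
            if qspan != self.query_end - self.query_start:
                raise ValueError("chain blocks do not cover the query span")

    @property
    def aligned_bases(self) -> int:
        return sum(s for s, _, _ in self.blocks)


def read_chain(path) -> list[ChainAlignment]:
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def flush():
        if header is None:
            return
        (_, score, tn, ts, tstr, t0, t1, qn, qs, qstr, q0, q1, cid) = header
        chains.append(
            ChainAlignment(
                chain_id=int(cid), score=float(score),
                target_name=tn, target_size=int(ts), target_strand=tstr,
                target_start=int(t0), target_end=int(t1),
                query_name=qn, query_size=int(qs), query_strand=qstr,
                query_start=int(q0), query_end=int(q1),
                blocks=list(blocks),
            )
        )

    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                flush()
                header = line.split()
                if len(header) != 13:
                    raise ValueError(f"line {lineno}: malformed chain header")
                blocks = []
            else:
                parts = line.split()
                if header is None:
                    raise ValueError(f"line {lineno}: block outside chain")
                if len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ValueError(f"line {lineno}: malformed block line")
    flush()
    return chains


def write_chain(chains: Iterable[ChainAlignment], path) -> None:
    with _open(path, "wt") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.target_name} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} "
                f"{c.query_name} {c.query_size} {c.query_strand} "
                f"{c.query_start} {c.query_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


@dataclass
class LiftResult:
    """Mapping of one target interval through one chain.

    ``intervals`` are merged query intervals on the forward strand;
    ``aligned_bases`` counts target bases of the input interval that fall in
    aligned blocks (the quantity the presence/flank thresholds are stated in).
    """

    chain_id: int
    query_name: str
    query_strand: str
    intervals: list[tuple[int, int]]
    aligned_bases: int


def _merge(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out: list[tuple[int, int]] = []
    for s, e in iv:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def lift_interval(
    chains: Sequence[ChainAlignment],
    target_name: str,
    start: int,
    end: int,
) -> list[LiftResult]:
    """Lift a target interval through every overlapping chain.

    Returns one :class:`LiftResult` per chain that overlaps the interval with
    at least one aligned base; an interval outside all chains yields an empty
    list.  Query coordinates are reported on the forward strand regardless of
    the chain's query strand.
    """
    if start >= end:
        raise ValueError("empty interval")
    results: list[LiftResult] = []
    for chain in chains:
        if chain.target_name != target_name:
            continue
        if chain.target_end <= start or chain.target_start >= end:
            continue
        tpos = chain.target_start
        qpos = chain.query_start
        mapped: list[tuple[int, int]] = []
        aligned = 0
        for size, dt, dq in chain.blocks:
            os_, oe = max(start, tpos), min(end, tpos + size)
            if oe > os_:
                aligned += oe - os_
                qs = qpos + (os_ - tpos)
                qe = qpos + (oe - tpos)
                if chain.query_strand == "-":
                    qs, qe = chain.query_size - qe, chain.query_size - qs
                mapped.append((qs, qe))
            tpos += size + dt
            qpos += size + dq
            if tpos >= end:
                break
        if aligned:
            results.append(
                LiftResult(
                    chain_id=chain.chain_id,
                    query_name=chain.query_name,
                    query_strand=chain.query_strand,
                    intervals=_merge(mapped),
                    aligned_bases=aligned,
                )
            )
    return results


def lifted_aligned_bases(
    chains: Sequence[ChainAlignment], target_name: str, start: int, end: int
) -> int:
    """Total aligned target bases of an interval, summed over chains and
    sub-intervals (the thresholds are base counts, not contiguity)."""
    return sum(r.aligned_bases for r in lift_interval(chains, target_name, start, end))


# ---------------------------------------------------------------------------
# FASTA / Newick / BED
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(s), id=n, description="") for n, s in records.items()),
            fh,
            "fasta",
        )


def write_newick(newick: str, path) -> None:
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    with _open(path, "wt") as fh:
        fh.write(newick + "\n")


def write_bed(entities: Sequence[RepeatEntity], path, name_fmt: str = "{family}.{rid}") -> None:
    """Write entity spans as BED6 (0-based half-open, as BED requires)."""
    with _open(path, "wt") as fh:
        for e in entities:
            s, t = e.span
            name = name_fmt.format(family=e.family, rid=e.repeat_id)
            strand = e.fragments[0].strand
            fh.write(f"{e.query_name}\t{s}\t{t}\t{name}\t{e.max_sw}\t{strand}\n")
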