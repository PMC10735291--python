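"""Genome-evolution simulator for successive transposon-family activity.

The generator plays the succession model forward: families are active in
(truncated-normal) windows on a pseudo-time axis that increases toward the
present, insertions land on the branch of a rooted species tree spanning
their draw, and every copy is materialised in all species descending from
that branch.  A configurable fraction of insertions nests inside an older,
still-contiguous copy, splitting the host annotation into two fragments that
share one repeat ID -- exactly the evidence pattern the nesting detector
consumes.

Outputs are RepeatMasker-style ``.out`` annotations per species, UCSC chains
from the focal species to every other species (derived exactly from the
simulated coordinate maps, so lifting is ground truth by construction),
consensus and per-element FASTA, and a machine-readable truth table.
Genomes are coordinate systems plus element sequences; a small "toy genome"
mode can materialise full FASTA for end-to-end runs.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import structvar
from .formats import ChainAlignment, RepeatCopy, write_chain, write_fasta, write_rmsk_out

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with the given probability.

    A substituted base is always changed (drawn from the three alternatives),
    so ``rate`` is the realised per-base divergence in expectation.
    """
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alts = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([alts[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def synthetic_ltr_consensus(length: int = 360, seed: int = 20231204) -> str:
    """Deterministic synthetic LTR consensus (stand-in for a Dfam model)."""
    return random_seq(np.random.default_rng(seed), length)


def synthetic_internal_consensus(length: int = 480, seed: int = 4111979) -> str:
    """Deterministic synthetic gag-only internal-region consensus."""
    return random_seq(np.random.default_rng(seed), length)


def make_succession_consensuses(
    n: int,
    length: int = 400,
    region_len: int = 40,
    subst_rate: float = 0.005,
    seed: int = 1729,
    names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Consensus chain produced by sequential mutation of a founder.

    Member ``i`` and its direct successor ``i+1`` share a diagnostic sequence
    block that is overwritten again two steps later, so every adjacent pair
    in the true order carries at least one uniquely shared feature while
    non-adjacent pairs do not.  A light sprinkle of independent
    substitutions mimics post-divergence drift.
    """
    if n < 2:
        raise ValueError("need at least two chain members")
    spacer = (length - (n - 1) * region_len) // n
    if spacer < 10:
        raise ValueError("consensus too short for the requested chain")
    rng = np.random.default_rng(seed)
    base = random_seq(rng, length)
    if names is None:
        names = [f"fam{i + 1}" for i in range(n)]
    # diagnostic region j sits between conserved spacers (anchoring the
    # alignment frame on both sides); its three content versions
    # (ancestral, shared-by-the-pair, later) differ at every column, as a
    # saturating burst of change would leave them
    shift = str.maketrans("ACGT", "CGTA")
    regions: dict[int, tuple[int, int]] = {}
    versions = {}
    for j in range(1, n):
        lo = spacer + (j - 1) * (region_len + spacer)
        regions[j] = (lo, lo + region_len)
        orig = base[lo:lo + region_len]
        va = orig.translate(shift)
        versions[j] = (va, va.translate(shift))
    out: dict[str, str] = {}
    for i in range(1, n + 1):
        seq = list(base)
        for j in range(1, n):
            if i < j:
                continue  # ancestral content
            lo, hi = regions[j]
            va, vb = versions[j]
            seq[lo:hi] = va if i <= j + 1 else vb
        out[names[i - 1]] = mutate_seq(rng, "".join(seq), subst_rate)
    return out


def succession_region(j: int, n: int, length: int = 400,
                      region_len: int = 40) -> tuple[int, int]:
    """1-based inclusive coordinates of diagnostic region j (1..n-1), the
    block uniquely shared by chain members j and j+1."""
    spacer = (length - (n - 1) * region_len) // n
    lo = spacer + (j - 1) * (region_len + spacer)
    return lo + 1, lo + region_len


# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted species tree encoded by split times on the focal lineage.

    ``splits`` maps each non-focal species to the pseudo-time at which its
    lineage diverged from the focal lineage; pseudo-time increases toward
    the present, so smaller split times are deeper splits.  An insertion at
    time ``t`` is shared with species ``s`` iff ``t < splits[s]``.
    """

    focal: str = "human"
    splits: dict[str, float] = field(
        default_factory=lambda: {"bushbaby": 0.35, "tarsier": 0.55}
    )

    def __post_init__(self) -> None:
        if self.focal in self.splits:
            raise ValueError("focal species cannot have a split time")
        if len(set(self.splits.values())) != len(self.splits):
            raise ValueError("split times must be distinct (binary tree)")

    @property
    def species(self) -> list[str]:
        return [self.focal] + sorted(self.splits, key=self.splits.get)

    def shared_with(self, t: float) -> list[str]:
        return [self.focal] + [s for s, ts in self.splits.items() if t < ts]

    def newick(self) -> str:
        """Ladderised rooted newick; branch lengths in pseudo-time units."""
        order = sorted(self.splits, key=self.splits.get)  # deepest first
        node = self.focal
        depth = 1.0
        for sp in reversed(order):
            ts = self.splits[sp]
            node = f"({node}:{depth - ts:g},{sp}:{depth - ts:g})"
            depth = ts
        return node + ";"


@dataclass
class FamilyActivity:
    """Activity window and copy parameters for one transposon family.

    ``mu``/``sigma`` parameterise a truncated normal on pseudo-time [0, 1];
    ``copies`` is the number of insertions to draw; ``subst_rate`` is the
    expected per-base divergence of each copy from the consensus.
    ``indel_rate`` perturbs only the emitted element FASTA (small 1-3 bp
    indels), never genomic coordinates, so annotations and chains remain
    exact coordinate truth.
    """

    name: str
    mu: float
    sigma: float
    copies: int
    consensus: str
    subst_rate: float = 0.02
    indel_rate: float = 0.0
    rep_class_family: str = "LTR/ERVL-MaLR"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.copies < 0:
            raise ValueError("copy budget must be nonnegative")
        if not self.consensus:
            raise ValueError("consensus sequence required")


def default_scenario() -> tuple[SpeciesTree, list[FamilyActivity]]:
    """Five-family succession straddling both comparison splits.

    Consensus sequences form a sequential-mutation chain (each family derived
    from its predecessor), activity windows succeed each other along
    pseudo-time, and the middle family straddles the younger split so the
    timing workflow sees all three outcome classes.
    """
    cons = make_succession_consensuses(
        5, length=400, region_len=40,
        names=["MSTD", "MSTC", "MSTA1", "MSTB1", "THE1B"],
    )
    mus = {"MSTD": 0.12, "MSTC": 0.22, "MSTA1": 0.30, "MSTB1": 0.45, "THE1B": 0.68}
    fams = [
        FamilyActivity(name=n, mu=mus[n], sigma=0.06, copies=100,
                       consensus=cons[n], subst_rate=0.03)
        for n in cons
    ]
    return SpeciesTree(), fams


def tint_scenario(
    copies: int = 320,
    nest_prob: float = 0.35,
) -> tuple[SpeciesTree, list[FamilyActivity], list[str]]:
    """Five-family succession with disjoint activity windows plus an ancient
    anchor family.

    The anchor (an abundant, old SINE-like family active before the whole
    succession) plays the role AluJo/AluSc play in nesting analyses: it
    guarantees that even the oldest focal family appears as the *inner*
    partner of events, without which that family's placement is
    unidentifiable (its event row would be empty and a multinomial row with
    zero total carries no information).  Returns (tree, families,
    focal_family_names) with focal families in true succession order.
    """
    names = ["F1", "F2", "F3", "F4", "F5"]
    cons = make_succession_consensuses(5, names=names)
    anchor = FamilyActivity(
        name="AluAnc", mu=0.02, sigma=0.015, copies=450,
        consensus=random_seq(np.random.default_rng(99), 300),
        subst_rate=0.08, rep_class_family="SINE/Alu",
    )
    fams = [anchor] + [
        FamilyActivity(name=n, mu=m, sigma=0.025, copies=copies,
                       consensus=cons[n], subst_rate=0.03)
        for n, m in zip(names, [0.1, 0.25, 0.4, 0.55, 0.7])
    ]
    return SpeciesTree(), fams, names


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

@dataclass
class _Seg:
    owner: int          # -1 = ancestral background, else insertion id
    src_start: int      # coordinates within the owner sequence (genome strand)
    src_end: int

    @property
    def length(self) -> int:
        return self.src_end - self.src_start


@dataclass
class _Insertion:
    iid: int
    family: FamilyActivity
    t: float
    strand: str
    seq: str            # element sequence, consensus orientation
    mismatch: np.ndarray
    parent: int | None = None
    depth: int = 0
    split: bool = False


@dataclass
class SimulationBundle:
    """Everything one simulated scenario produced, plus its truth table."""

    tree: SpeciesTree
    families: list[FamilyActivity]
    seed: int
    copies: dict[str, list[RepeatCopy]]
    chains: dict[str, list[ChainAlignment]]
    truth: pd.DataFrame
    consensus: dict[str, str]
    elements: dict[str, str]
    chrom: str = "chr1"
    genome_fasta: dict[str, str] | None = None

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for sp, rows in self.copies.items():
            p = outdir / f"{sp}.fa.out"
            write_rmsk_out(rows, p)
            written.append(p)
        for sp, chains in self.chains.items():
            p = outdir / f"{self.tree.focal}To{sp.capitalize()}.chain"
            write_chain(chains, p)
            written.append(p)
        p = outdir / "consensus.fa"
        write_fasta(self.consensus, p)
        written.append(p)
        p = outdir / "elements.fa"
        write_fasta(self.elements, p)
        written.append(p)
        p = outdir / "truth.tsv"
        self.truth.to_csv(p, sep="\t", index=False)
        written.append(p)
        if self.genome_fasta is not None:
            p = outdir / "genomes.fa"
            write_fasta(self.genome_fasta, p)
            written.append(p)
        return written


def _fragment_score(elem_mism: np.ndarray, src_start: int, src_end: int) -> tuple[int, float]:
    n = src_end - src_start
    mism = int(elem_mism[src_start:src_end].sum())
    score = max(0, 2 * (n - mism) - 5 * mism)
    return score, 100.0 * mism / n


def simulate_succession(
    tree: SpeciesTree,
    families: Sequence[FamilyActivity],
    seed: int,
    nest_prob: float = 0.25,
    bg_length: int = 150_000,
    chrom: str = "chr1",
    toy_genome: bool = False,
) -> SimulationBundle:
    """Run the succession model and emit annotations, chains and truth.

    Each insertion draws a pseudo-time from its family's truncated-normal
    activity window, lands either in ancestral background sequence or (with
    probability ``nest_prob``) strictly inside an older, still-unsplit copy,
    and is inherited by every species whose split postdates the draw.
    Nesting splits the host into exactly two fragments sharing the host's
    repeat ID; nesting depth is capped at 2.
    """
    if not 0 <= nest_prob < 1:
        raise ValueError("nest_prob must be in [0, 1)")
    total_elem = sum(f.copies * len(f.consensus) for f in families)
    if total_elem > 50 * bg_length:
        raise ValueError("copy budget vastly exceeds background genome size")
    rng = np.random.default_rng(seed)

    # draw insertion times per family, then interleave chronologically
    draws: list[tuple[float, FamilyActivity]] = []
    for fam in families:
        a, b = (0.0 - fam.mu) / fam.sigma, (1.0 - fam.mu) / fam.sigma
        ts = truncnorm.rvs(a, b, loc=fam.mu, scale=fam.sigma,
                           size=fam.copies, random_state=rng)
        draws.extend((float(t), fam) for t in np.atleast_1d(ts))
    draws.sort(key=lambda x: x[0])

    segments: list[_Seg] = [_Seg(-1, 0, bg_length)]
    insertions: dict[int, _Insertion] = {}

    for iid, (t, fam) in enumerate(draws, start=1):
        seq = mutate_seq(rng, fam.consensus, fam.subst_rate)
        mism = np.frombuffer(seq.encode(), "S1") != np.frombuffer(
            fam.consensus.encode(), "S1")
        strand = "+" if rng.random() < 0.5 else "-"
        ins = _Insertion(iid=iid, family=fam, t=t, strand=strand,
                         seq=seq, mismatch=mism)
        hosts = [h for h in insertions.values()
                 if not h.split and h.depth < 2 and len(h.seq) >= 2]
        if hosts and rng.random() < nest_prob:
            # the landing family follows total copy abundance (insertions hit
            # a family's sequence in proportion to how much of it exists);
            # the two-fragment cap only restricts which copy can still host
            fam_total: dict[str, int] = {}
            for h in insertions.values():
                fam_total[h.family.name] = fam_total.get(h.family.name, 0) + 1
            by_fam: dict[str, list[_Insertion]] = {}
            for h in hosts:
                by_fam.setdefault(h.family.name, []).append(h)
            fam_names = sorted(by_fam)
            w = np.array([fam_total[f] for f in fam_names], dtype=float)
            fam = fam_names[int(rng.choice(len(fam_names), p=w / w.sum()))]
            cands = by_fam[fam]
            host = cands[int(rng.integers(0, len(cands)))]
            idx = next(i for i, s in enumerate(segments) if s.owner == host.iid)
            seg = segments[idx]
            cut = seg.src_start + int(rng.integers(1, seg.length))
            segments[idx:idx + 1] = [
                _Seg(host.iid, seg.src_start, cut),
                _Seg(iid, 0, len(seq)),
                _Seg(host.iid, cut, seg.src_end),
            ]
            host.split = True
            ins.parent = host.iid
            ins.depth = host.depth + 1
        else:
            bg_idx = [i for i, s in enumerate(segments) if s.owner == -1]
            lens = np.array([segments[i].length for i in bg_idx], dtype=float)
            pick = bg_idx[int(rng.choice(len(bg_idx), p=lens / lens.sum()))]
            seg = segments[pick]
            off = int(rng.integers(0, seg.length + 1))
            new = _Seg(iid, 0, len(seq))
            if off == 0:
                segments.insert(pick, new)
            elif off == seg.length:
                segments.insert(pick + 1, new)
            else:
                cut = seg.src_start + off
                segments[pick:pick + 1] = [
                    _Seg(-1, seg.src_start, cut),
                    new,
                    _Seg(-1, cut, seg.src_end),
                ]
        insertions[iid] = ins

    tree_species = tree.species
    present = {
        sp: {iid: (sp == tree.focal or ins.t < tree.splits[sp])
             for iid, ins in insertions.items()}
        for sp in tree_species
    }

    # per-species annotation rows and focal coordinates
    copies: dict[str, list[RepeatCopy]] = {}
    focal_span: dict[int, tuple[int, int]] = {}
    genome_len: dict[str, int] = {}
    for sp in tree_species:
        rows: list[RepeatCopy] = []
        pos = 0
        # merge adjacent same-owner segments with contiguous source
        pending: _Seg | None = None
        pend_start = 0
        frag_ranges: dict[int, list[tuple[int, int, int, int]]] = {}

        def flush():
            nonlocal pending
            if pending is not None and pending.owner != -1:
                frag_ranges.setdefault(pending.owner, []).append(
                    (pend_start, pend_start + pending.length,
                     pending.src_start, pending.src_end)
                )
            pending = None

        for seg in segments:
            if seg.owner != -1 and not present[sp][seg.owner]:
                continue
            if (pending is not None and pending.owner == seg.owner
                    and pending.src_end == seg.src_start):
                pending = _Seg(pending.owner, pending.src_start, seg.src_end)
            else:
                flush()
                pending = _Seg(seg.owner, seg.src_start, seg.src_end)
                pend_start = pos
            pos += seg.length
        flush()
        genome_len[sp] = pos

        for iid in sorted(frag_ranges):
            ins = insertions[iid]
            elen = len(ins.seq)
            for qs, qe, ss, se in frag_ranges[iid]:
                if ins.strand == "+":
                    rep_start, rep_end = ss + 1, se
                else:  # genome-left piece comes from the consensus 3' end
                    rep_start, rep_end = elen - se + 1, elen - ss
                score, pdiv = _fragment_score(ins.mismatch, ss, se)
                rows.append(RepeatCopy(
                    sw_score=score, pct_div=round(pdiv, 1), pct_del=0.0,
                    pct_ins=0.0, query_name=chrom, query_start=qs,
                    query_end=qe, query_left=genome_len[sp] - qe,
                    strand=ins.strand, rep_name=ins.family.name,
                    rep_class_family=ins.family.rep_class_family,
                    rep_start=rep_start, rep_end=rep_end,
                    rep_left=elen - rep_end, repeat_id=iid,
                ))
                if sp == tree.focal:
                    s0, s1 = focal_span.get(iid, (qs, qe))
                    focal_span[iid] = (min(s0, qs), max(s1, qe))
        rows.sort(key=lambda c: (c.query_start, c.repeat_id))
        copies[sp] = rows

    # chains focal -> other species (exact, from the shared-segment walk)
    chains: dict[str, list[ChainAlignment]] = {}
    for sp in tree_species:
        if sp == tree.focal:
            continue
        runs: list[tuple[bool, int]] = []  # (shared, length)
        for seg in segments:
            shared = seg.owner == -1 or present[sp][seg.owner]
            if runs and runs[-1][0] == shared:
                runs[-1] = (shared, runs[-1][1] + seg.length)
            else:
                runs.append((shared, seg.length))
        while runs and not runs[0][0]:
            runs.pop(0)
        lead = genome_len[tree.focal] - sum(l for _, l in runs)
        while runs and not runs[-1][0]:
            runs.pop()
        blocks: list[tuple[int, int, int]] = []
        for shared, length in runs:
            if shared:
                blocks.append((length, 0, 0))
            else:
                size, _, _ = blocks[-1]
                blocks[-1] = (size, length, 0)
        aligned = sum(s for s, _, _ in blocks)
        chains[sp] = [ChainAlignment(
            chain_id=1, score=float(aligned),
            target_name=chrom, target_size=genome_len[tree.focal],
            target_strand="+", target_start=lead,
            target_end=lead + sum(s + dt for s, dt, _ in blocks),
            query_name=chrom, query_size=genome_len[sp],
            query_strand="+", query_start=0, query_end=aligned,
            blocks=blocks,
        )] if blocks else []

    # truth table
    rows = []
    for iid in sorted(insertions):
        ins = insertions[iid]
        shared = tree.shared_with(ins.t)
        span = focal_span[iid]
        rows.append({
            "insertion_id": iid,
            "family": ins.family.name,
            "pseudo_time": round(ins.t, 6),
            "branch": ",".join(sorted(shared)),
            "strand": ins.strand,
            "chrom": chrom,
            f"{tree.focal}_start": span[0],
            f"{tree.focal}_end": span[1],
            "element_length": len(ins.seq),
            "nesting_parent": ins.parent if ins.parent is not None else 0,
            "nesting_depth": ins.depth,
            **{f"present_{sp}": present[sp][iid] for sp in tree_species},
        })
    truth = pd.DataFrame(rows)

    elements = {}
    for iid in sorted(insertions):
        ins = insertions[iid]
        seq = ins.seq
        if ins.family.indel_rate > 0:  # FASTA-only perturbation
            n_indel = rng.binomial(len(seq), ins.family.indel_rate)
            for _ in range(n_indel):
                p = int(rng.integers(0, len(seq)))
                if rng.random() < 0.5 and len(seq) > 10:
                    seq = seq[:p] + seq[p + int(rng.integers(1, 4)):]
                else:
                    seq = seq[:p] + random_seq(rng, int(rng.integers(1, 4))) + seq[p:]
        elements[f"{ins.family.name}.{iid}"] = seq

    genome_fasta = None
    if toy_genome:
        if genome_len[tree.focal] > 1_000_000:
            raise ValueError("toy genome mode is limited to 1 Mb")
        bg = random_seq(np.random.default_rng(seed + 101), bg_length)
        genome_fasta = {}
        for sp in tree_species:
            parts = []
            for seg in segments:
                if seg.owner == -1:
                    parts.append(bg[seg.src_start:seg.src_end])
                elif present[sp][seg.owner]:
                    ins = insertions[seg.owner]
                    placed = ins.seq if ins.strand == "+" else revcomp(ins.seq)
                    parts.append(placed[seg.src_start:seg.src_end])
            genome_fasta[f"{sp}_{chrom}"] = "".join(parts)

    return SimulationBundle(
        tree=tree, families=list(families), seed=seed, copies=copies,
        chains=chains, truth=truth,
        consensus={f.name: f.consensus for f in families},
        elements=elements, chrom=chrom, genome_fasta=genome_fasta,
    )


# ---------------------------------------------------------------------------
# Chain degradation (lineage-specific deletions)
# ---------------------------------------------------------------------------

def degrade_chain(
    chain: ChainAlignment,
    deletion_fraction: float,
    seed: int,
    chunk: int = 100,
) -> ChainAlignment:
    """Remove aligned blocks covering ~``deletion_fraction`` of target bases.

    Models lineage-specific deletions in the non-focal genome so that the
    presence thresholds are exercised.  Aligned blocks are exploded into
    chunks of at most ``chunk`` bases; a seed-determined permutation of
    chunks is removed until the budget is met, so for a fixed seed the
    removed set grows monotonically with ``deletion_fraction``.
    """
    if not 0 <= deletion_fraction < 1:
        raise ValueError("deletion_fraction must be in [0, 1)")
    if deletion_fraction == 0 or not chain.blocks:
        return chain
    pieces: list[list] = []  # [t_len, q_len, aligned_bool]
    for size, dt, dq in chain.blocks:
        off = 0
        while off < size:
            step = min(chunk, size - off)
            pieces.append([step, step, True])
            off += step
        if dt or dq:
            pieces.append([dt, dq, False])
    aligned_idx = [i for i, p in enumerate(pieces) if p[2]]
    total = sum(pieces[i][0] for i in aligned_idx)
    budget = int(round(deletion_fraction * total))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(aligned_idx))
    removed = 0
    n_aligned = len(aligned_idx)
    for j in order:
        if removed >= budget or n_aligned <= 1:
            break
        i = aligned_idx[j]
        pieces[i][2] = False
        removed += pieces[i][0]
        n_aligned -= 1

    # rebuild, trimming unaligned leading/trailing pieces into the header
    while pieces and not pieces[0][2]:
        pieces.pop(0)
    lead_t = chain.target_end - chain.target_start - sum(p[0] for p in pieces)
    lead_q = chain.query_end - chain.query_start - sum(p[1] for p in pieces)
    while pieces and not pieces[-1][2]:
        pieces.pop()
    t0 = chain.target_start + lead_t
    q0 = chain.query_start + lead_q
    t1 = t0 + sum(p[0] for p in pieces)
    q1 = q0 + sum(p[1] for p in pieces)
    blocks: list[tuple[int, int, int]] = []
    pend_gap = [0, 0]
    for t_len, q_len, ok in pieces:
        if ok:
            if blocks and pend_gap == [0, 0]:
                size, dt, dq = blocks[-1]
                if dt == 0 and dq == 0:
                    blocks[-1] = (size + t_len, 0, 0)
                    continue
            blocks.append((t_len, 0, 0))
            if pend_gap != [0, 0]:
                prev = blocks[-2]
                blocks[-2] = (prev[0], pend_gap[0], pend_gap[1])
                pend_gap = [0, 0]
        else:
            pend_gap[0] += t_len
            pend_gap[1] += q_len
    return ChainAlignment(
        chain_id=chain.chain_id, score=float(sum(s for s, _, _ in blocks)),
        target_name=chain.target_name, target_size=chain.target_size,
        target_strand=chain.target_strand, target_start=t0, target_end=t1,
        query_name=chain.query_name, query_size=chain.query_size,
        query_strand=chain.query_strand, query_start=q0, query_end=q1,
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Structural-variant element population
# ---------------------------------------------------------------------------

STAGE_THREE = frozenset({"186ins", "226_235del", "303_312delinsTT"})
STAGE_FOUR = STAGE_THREE | {"204del"}

STAGE_PATTERNS: dict[str, tuple[frozenset, frozenset]] = {
    "ancestral": (frozenset(), frozenset()),
    "precursor": (STAGE_THREE, STAGE_THREE),
    "intermediate": (STAGE_FOUR, STAGE_THREE),
    "canonical": (STAGE_FOUR, STAGE_FOUR),
}


def plant_structural_variants(
    ltr_consensus: str,
    internal_consensus: str,
    variant_defs: dict[str, "structvar.StructuralVariantDef"],
    stage_spec: Sequence[str] | dict[str, int],
    seed: int,
    subst_rate: float = 0.05,
    id_prefix: str = "elem",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Emit full-length elements whose LTRs carry stage-defined variant sets.

    ``stage_spec`` is either an ordered list of stage names (one element
    each) or a mapping stage -> count.  Elements are 5'LTR-internal-3'LTR,
    each diverged by ``subst_rate`` substitutions after variant planting.
    Returns the element FASTA mapping and a per-LTR truth table.
    """
    if isinstance(stage_spec, dict):
        stages = [s for s, k in stage_spec.items() for _ in range(k)]
    else:
        stages = list(stage_spec)
    for s in stages:
        if s not in STAGE_PATTERNS:
            raise ValueError(f"unknown stage {s!r}")
    rng = np.random.default_rng(seed)
    elements: dict[str, str] = {}
    rows = []
    for i, stage in enumerate(stages, start=1):
        set5, set3 = STAGE_PATTERNS[stage]
        ltr5 = structvar.apply_variants(ltr_consensus, variant_defs, set5)
        ltr3 = structvar.apply_variants(ltr_consensus, variant_defs, set3)
        seq = mutate_seq(rng, ltr5 + internal_consensus + ltr3, subst_rate)
        eid = f"{id_prefix}{i:03d}"
        elements[eid] = seq
        row = {"element_id": eid, "stage": stage}
        for v in sorted(STAGE_FOUR):
            row[f"{v}_5p"] = v in set5
            row[f"{v}_3p"] = v in set3
        rows.append(row)
    return elements, pd.DataFrame(rows)
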