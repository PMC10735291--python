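# Methods

This note records the models implemented in `malrkit`, the defaults and why
they were chosen, what the synthetic data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Coordinate conventions

Everything internal is 0-based half-open. Conversions happen only at format
boundaries: RepeatMasker `.out` genomic coordinates are 1-based inclusive on
disk; UCSC chains are already 0-based half-open. Repeat-consensus
coordinates keep the 1-based inclusive convention of `.out` and of the
variant nomenclature (a "204del" is the deletion of consensus base 204).
Complement (`C`) rows are normalised at parse time to strand `-` with
`rep_start <= rep_end`; the `(left) end begin` column order is restored on
writing, so read ∘ write is the identity on parsed fields. Fragments of one
repeat ID on different sequences are split into separate entities with a
logged warning — one insertion cannot span two chromosomes, and the case is
otherwise undefined.

## Insertion timing

An entity passes the score filter when its best fragment reaches
Smith–Waterman score 100 (inclusive). Flanks of 300 bp are taken from the
entity's outermost fragment boundaries — internal nesting gaps belong to
the span, not the flanks, matching the single-insertion reading of a repeat
ID — and clipped at sequence ends. A flank side passes with ≥ 200 aligned
bases; an entity is *properly aligned* only when both sides pass in **all**
comparison species. The conjunctive reading is forced by the arithmetic of
a single per-family denominator: each entity must be in or out of the
denominator once, not once per species. Element presence requires strictly
more than 50 lifted bases (50 → absent). Aligned bases are summed over
chains and sub-intervals; the criteria are base counts, and requiring
contiguity would make calls depend on how a chain happens to be fragmented.
The defaults (100 / 300 bp / 200 bp / > 50 bp) are the standard
comparative-genomics criteria for this analysis and are all exposed as
flags. A present-in-older/absent-in-younger pattern is biologically
discordant (hemiplasy, incomplete lineage sorting or lineage deletion); it
is reported as `discordant`, never silently folded into a timing bin.

## Transposition-in-transposition

**Detection.** An event requires (i) an outer entity with two consecutive
fragments on the same sequence, (ii) consensus-coordinate continuity of
those fragments — the downstream fragment resumes within 30 consensus bases
of where the upstream one stopped (strand-aware; 30 because RepeatMasker
fragment endpoints jitter by a few tens of bases; exposed as a flag), and
(iii) an inner entity of a different repeat ID fully contained in the
genomic gap. Events are counted per inner entity, not per fragment pair.
When several inner entities occupy one gap (depth-2 nesting), a candidate
contained in another candidate's span is attributed to that nearer host
only; without this rule every deep nesting would double-count against the
outermost host and detector precision would degrade with nesting depth.

**Inference.** Family *f* has a normal activity window N(μ_f, σ_f²) on an
uncalibrated pseudo-time axis that increases toward the present. The
probability that a random active moment of family *i* postdates one of
family *j* is Φ((μ_i − μ_j)/√(σ_i² + σ_j²)). Weighting target *j* by its
abundance c_j (entity counts by default; annotated-base totals are
equivalent up to rescaling) gives the multinomial target distribution
p_ij = q_ij / Σ_j′ q_ij′ with q_ij = c_j·Φ(·), and the log-likelihood
Σ N[i][j]·log p_ij over off-diagonal counts. Self-nestings are excluded:
they carry no ordering information. Identifiability is fixed by anchoring
the first family's μ at 0 and the geometric mean of the σ's at 1; the
likelihood is maximised by multi-start L-BFGS-B (bounds |μ| ≤ 30,
|log σ| ≤ 2.5; 12 seeded restarts plus one start ordered by each family's
net inner-minus-outer event excess). Reported 75/95/99 % intervals are the
central quantiles μ ± z·σ with z = 1.1503, 1.9600, 2.5758. This likelihood
is this package's own concrete definition of the nesting-inference model —
a minimal two-parameter-per-family formulation consistent with symmetric
unimodal activity periods — not a port of any existing service's internal
numerics.

A family with no off-diagonal events in either direction is reported as
*unconstrained* (flagged, with a deliberately wide interval) rather than
silently placed: a multinomial row with zero total contributes nothing to
the likelihood. The same logic dictates a design point of the synthetic
scenario used to validate inference: the oldest focal family never appears
as an inner element, so its placement is only identified when an even older
abundant *anchor* family is present in the analysis (the role old SINE
families such as AluJo/AluSc play in practice). The bundled
`tint_scenario()` therefore includes one.

## Consensus phylogeny

Pairwise distances, not a multiple alignment, drive the tree. Alignment is
global with affine gap costs and zero-cost terminal gaps (match +1,
mismatch −1, gap open −4, gap extend −1; an optional transition score,
default −0.5 when enabled, softens transitions — the aligner options are
standard, the exact values are package defaults and all are flags). The
observed mismatch fraction p is computed over internal columns with a
residue in both sequences; end-gap and internal gap columns are excluded.
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) is applied to raw p even
when the aligner used transition weighting, as the JC model assumes equal
rates; p ≥ 0.75 is flagged saturated and refused by tree building unless
explicitly capped. Neighbor-joining is the classic Q-matrix algorithm with
ties broken by lexicographic order of the clusters' smallest leaf labels
and negative branch lengths clamped to zero with a log note. Tree-level
questions are answered on splits of the unrooted tree: a taxon set is a
clade on some rooting iff it is one side of an edge bipartition, and the
reported sister is the smallest adjacent subtree on the far side.

## Structural-variant genotyping

LTR copies are located by aligning the reference LTR consensus against a
window at each element end (free end gaps; the hit must cover ≥ 80 % of the
consensus, otherwise the element is set aside as solo/partial). Each copy
is genotyped by alignment to the consensus, and each variant is called from
the **length signature over its compartment**: the number of element bases
between two aligned anchor columns bracketing the locus. Compartment
boundaries sit at the midpoints between neighbouring variant loci (at most
±20 bases for isolated variants); anchors must exist within 15 consensus
bases of the compartment edge, else the locus is uncallable. The count of
element bases between two fixed aligned columns is invariant to where the
aligner places gaps, which matters because an optimal alignment of a
diverged copy can slide a 1-bp gap several columns when nearby
substitutions make the shifted placement score equally — a nearest-anchor
rule mis-calls a few percent of 5 %-diverged copies, the compartment rule
essentially none. A k-base deletion shows delta −k, an insertion ≥ +1
(inserted content is not matched; it is not part of the variant's
definition), a delins len(replacement) − k. Replacement content (the `TT`
of `303_312delinsTT`) is recorded and reported but substitutions within it
do not flip the call; keying the call on content would make stage
classification of diverged copies non-deterministic for no information
gain, since the 10-to-2 length signature is already unambiguous.

Stages are exact per-LTR patterns over the four THE1A variants: *precursor*
= the three indels in both LTRs without `204del`; *intermediate* = the
three indels in both plus `204del` in the 5′ LTR only; *canonical* = all
four in both. Anything else, including any uncallable locus, is `other`
with the observed pattern attached. Replication logic: a progeny LTR is the
composite of the parental 3′-LTR U3 segment and the parental 5′-LTR R/U5
segment, identical in both progeny LTRs at birth; a variant is routed by
which segment its coordinates fall in, and a variant spanning the U3|R
boundary is an error demanding explicit assignment. The shipped
`ltr_model.yaml` places the TSS (the U3|R junction) at 191 on the synthetic
360-bp consensus so that 204 is downstream of it; segment boundaries are
explicit configuration, never hidden defaults, because they are not
derivable from the consensus itself. Applying the replication map to the
intermediate pattern yields the full canonical pattern in both LTRs — the
argument that the 5′-only `204del` state is one replication round away from
the canonical family, i.e. chronologically last.

**Uniquely shared features.** All sequences are projected onto consensus
*a*'s coordinate frame by pairwise alignment; a column is diagnostic when
*b* carries *a*'s residue and every background consensus carries a
different residue or a gap. Maximal diagnostic runs are merged across
interruptions while violations stay ≤ 10 % of the block (absorbing
post-divergence drift; exposed as a flag) and reported at ≥ `min_len`
(default 10) columns. The projection uses near-prohibitive gap costs (open
−30, extend −10): between near-colinear consensus models the frame must be
positional homology, and permissive gaps would let a fully diverged
background region micro-shift to collect coincidental matches,
destroying column-wise uniqueness. Consequences: genuine length differences
still force (expensive, single) gaps, and features that exist only as extra
sequence in *b* have no columns in *a*'s frame and are not reported.
Succession support runs `shared_features` for each adjacent pair of a
proposed chain with all remaining supplied consensuses as background; edge
pairs may show an extra block where they uniquely retain an ancestral state
— that is a correct consequence of uniqueness being relative to the
sampled set.

## The synthetic data generator

`simulate_succession` plays the succession model forward on one focal
chromosome: each family draws insertion pseudo-times from a truncated
normal on [0, 1], insertions land in ancestral background sequence or, with
probability `nest_prob` (default 0.25), strictly inside an older
still-unsplit copy, splitting the host into exactly two fragments sharing
its repeat ID (nesting depth ≤ 2; a copy hosts at most one direct
insertion, so the detector's two-fragment evidence pattern is exact). The
nesting *family* is chosen in proportion to total copy abundance — the
assumption the inference model makes about target weights — and the copy
uniformly among that family's still-unsplit copies. Species on the tree
(default human focal; bushbaby split 0.35, tarsier split 0.55) inherit
every insertion drawn before their split. Chains from the focal species to
each other species are derived exactly from the shared-segment walk, so
lifting is coordinate truth by construction; `degrade_chain` then models
lineage-specific deletions by removing a seed-determined set of ≤ 100-bp
aligned chunks covering a requested fraction of aligned bases (monotone in
the fraction for a fixed seed).

Copies diverge from their consensus by iid substitutions (default 2–3 % in
the bundled scenarios; the per-family rates are testing placeholders, not
biological estimates — no per-family divergence calibration exists to copy).
Smith–Waterman scores and divergence percentages are synthesised from the
realised mismatch counts (2·matches − 5·mismatches, floored at 0). The
per-family indel rate perturbs only the emitted element FASTA, never
genomic coordinates, so annotations and chains remain exact; indel-diverged
LTR genotyping is exercised separately through
`plant_structural_variants`. Genomes are coordinate systems plus element
sequences; a toy-genome mode (≤ 1 Mb) materialises full FASTA.

What the generator does **not** emulate — and hence what green tests do not
certify about real data: RepeatMasker's fragmentation heuristics and
annotation errors, recombination between repeats (solo-LTR formation,
mosaic elements), per-branch substitution-rate variation and CpG
hypermutability, segmental duplications, independent insertions in
non-focal lineages (chains carry no query-side novel sequence before
degradation), and alignment-chain artefacts. Timing truth recovery is 100 %
on undegraded chains *by construction* — the value of the test is that the
thresholds, lifting arithmetic and bookkeeping introduce no errors of their
own, and that under degradation every error is confined to the presence
rule crossing.

`make_succession_consensuses` builds the consensus chain for the phylogeny
and shared-feature tracks: a founder sequence with n−1 diagnostic regions
(default 40 bp) interleaved with conserved spacers; region *j* switches
content when member *j* arises and again two members later, so members *j*
and *j*+1 uniquely share it. The three content versions of a region differ
at every column (cyclic base rotation), the signature a saturating burst of
change leaves; spacers anchor the alignment frame so projection cannot
slide. Light iid drift (0.5 %) is sprinkled per member.

`plant_structural_variants` emits 5′LTR–internal–3′LTR elements whose LTRs
carry the stage-defined variant subsets, then diverges each element by a
stated substitution rate (5 % in the bundled conditions, the point at which
per-LTR recovery is still expected to be exact under the compartment
rule). The synthetic LTR (360 bp) and internal (480 bp) consensuses are
deterministic stand-ins generated from fixed seeds; they are labelled
synthetic and carry no homology to any real model.

## Numerical and policy choices

- Alignment tie-breaks take the aligner's first reported path (highroad);
  all stochastic steps take an explicit seed and the end-to-end driver
  records seed, config hash and output checksums in a manifest.
- `lift_interval` returns per-chain aligned-base counts and merged
  forward-strand intervals; an interval outside all chains is an empty
  result, not an error.
- Empty inputs return empty outputs everywhere (empty entity list, empty
  event list, zero matrix); degenerate statistics raise
  (`jc_distance` with no comparable columns, NJ with < 3 taxa, activity
  inference with no off-diagonal counts).
- Problem sizes in the bundled study conditions — 500 insertions for the
  timing track, 5 × 320 copies plus a 450-copy anchor for the nesting
  track, 50 random additive matrices up to 8 taxa for the tree track, 100
  elements for the stage scan, 6 chain members and 20 shuffles for
  succession support — are the package's chosen desk-scale conditions;
  each completes in seconds while leaving every statistic far from its
  decision boundary.

## Known limitations

- Pseudo-time is relative; no calibration to absolute ages is attempted
  (anchor families can be given known ages downstream if desired).
- The activity model assumes static target abundances c_j; in reality (and
  in the simulator) hosts accumulate over time, which slightly skews
  target proportions for middle-aged families. Ordering is robust to this;
  the σ estimates are not interpretable as literal window widths.
- Variant genotyping assumes declared variants; it does not discover
  structural changes de novo.
- `shared_features` is blind to features absent from the reference frame
  (deletions shared by the pair relative to backgrounds appear only as
  missing columns).
- The `.align` reader parses block headers only; per-base alignment text
  is skipped. Element sequences should enter via FASTA.
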