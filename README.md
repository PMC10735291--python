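# malrkit

Tools for reconstructing the **succession history of LTR retrotransposon
families** — which family descended from which, when each was active, and
which single mutation preceded each expansion — from standard repeat
annotations, pairwise genome alignments and consensus sequences.

The motivating system is the primate ERVL-MaLR superfamily (MLT → MST →
THE1 members), whose members each replicated for a limited window before
being succeeded by a derived family, but every component works on any
LTR-element family set. `malrkit` is written for molecular-evolution and
genome-biology researchers who have RepeatMasker `.out` files, UCSC `chain`
files and Dfam-style consensus models and want the four classic lines of
evidence computed reproducibly:

1. **Insertion timing** (`malrkit.timing`) — an element fixed before a
   speciation event is present at the orthologous locus of both daughter
   lineages. Entities with Smith–Waterman score ≥ 100 whose 300 bp flanks
   each lift with ≥ 200 aligned bases per side in every comparison species
   are "properly aligned"; the element itself is called present where more
   than 50 bases lift. Presence in (older, younger) comparison species maps
   to `pre_first_split` / `between_splits` / `post_second_split_or_unresolved`
   (bushbaby + tarsier bracket the Haplorhini–Strepsirrhini and
   Simiiformes–Tarsiiformes splits in the primate case).
2. **Transposition-in-transposition** (`malrkit.tint`) — a copy nested
   inside an older copy splits the host annotation into two fragments with
   one repeat ID; directed nesting counts N[i][j] constrain relative
   activity times. Activity windows are N(μ_f, σ_f²) on pseudo-time, and
   the target of an insertion of family *i* is multinomial with weights
   q_ij = c_j · Φ((μ_i − μ_j)/√(σ_i² + σ_j²)); maximum likelihood over
   (μ, σ) yields activity centers with 75/95/99 % intervals.
3. **Consensus phylogeny** (`malrkit.phylo`) — pairwise global alignment
   with free end gaps, Jukes–Cantor correction
   d = −(3/4)·ln(1 − 4p/3), and neighbor-joining, plus split/clade tests
   (e.g. "do all primate-specific families form one clade, and who is the
   sister?").
4. **Structural-variant chronology** (`malrkit.structvar`) — genotypes
   named consensus-anchored indels (`186ins`, `204del`, `226_235del`,
   `303_312delinsTT`, `227_242del`) per LTR, classifies THE1A-lineage
   stages (precursor / intermediate / canonical), and applies LTR
   replication logic (progeny 5′ = parental 3′-U3 ⊕ parental 5′-R/U5) to
   order the changes; `shared_features` finds sequence blocks uniquely
   shared by a family and its direct predecessor.

A fully deterministic genome-evolution simulator (`malrkit.simulate`)
generates per-species `.out` annotations, exact chains, element FASTA and a
machine-readable truth table, so every stage of the pipeline is testable
end to end without downloading a genome.

## Worked example

Simulate the default five-family succession (500 insertions on a
human/tarsier/bushbaby tree, splits at pseudo-times 0.35 and 0.55) and run
the timing workflow:

```bash
malrkit simulate --seed 11 --out demo
malrkit timing --rmsk demo/human.fa.out \
    --chains bushbaby=demo/humanToBushbaby.chain,tarsier=demo/humanToTarsier.chain \
    --report demo/calls.tsv --summary demo/summary.tsv
# 500 entities, 342 properly aligned
```

`demo/summary.tsv`:

```
family  n_total  n_properly_aligned  pre_first_split  between_splits  post_second_split_or_unresolved  discordant  frac_younger_only
MSTA1   100      68                  53               15              0                                0           0.221
MSTB1   100      69                  6                62              1                                0           0.899
MSTC    100      72                  71               1               0                                0           0.014
MSTD    100      70                  70               0               0                                0           0.0
THE1B   100      63                  0                0               63                               0           0.0
```

Read: the two oldest families (MSTD, MSTC) are present in both comparison
species (active before the first split); MSTB1, whose simulated activity
window straddles the splits, is mostly tarsier-only (`between_splits`);
the youngest family (THE1B) is absent from both (it expanded after the
second split). That per-family profile is exactly how the relative
activity order is read off real annotations. The other tracks follow the
same pattern:

```bash
malrkit tint detect --rmsk demo/human.fa.out --out demo/matrix.tsv   # nesting counts
malrkit tree --consensus demo/consensus.fa --out demo/nj.nwk          # NJ of consensuses
malrkit run-all --seed 11 --out demo_all                              # everything + manifest
```

`run-all` writes a `manifest.json` with the seed, a config hash and sha256
checksums of every output, so two runs with the same seed are
byte-identical.

## Layout

| module | contents |
| --- | --- |
| `malrkit.formats` | RepeatMasker `.out`/`.align`, UCSC chain, FASTA/Newick/BED IO; entity grouping; interval lifting; family census |
| `malrkit.simulate` | succession simulator, chain degradation, structural-variant element generator, consensus-chain generator |
| `malrkit.timing` | SW filter, flank test, presence calls, per-family summary |
| `malrkit.tint` | nesting detector, count matrix, ML activity periods, youngest-family report |
| `malrkit.phylo` | free-end-gap alignment, JC distances, neighbor-joining, clade checks |
| `malrkit.structvar` | variant genotyping, stage scan, LTR replication logic, uniquely shared features |
| `malrkit.config` / `malrkit.cli` | run configuration, `run-all` driver with manifest, `malrkit` command |

See `docs/methods.md` for the models, parameter choices and limitations.
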