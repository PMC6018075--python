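# Methods

## Scope and model

`gliadinscan` characterizes wheat gliadin protein sequences by exact
string computation and rule cascades; there is no probabilistic scoring,
fuzzy matching or machine learning anywhere in the pipeline. The package
assumes clean deduced protein sequences (20 canonical residues plus X) —
it does not model sequencing error, peptide digestion, spectra or gel
physics.

## Counting conventions

Motif and epitope counting is **overlapping at distinct start positions**.
This convention is fixed by the 33-mer peptide
`LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF`: it contains `PQPQLPYPQ` at offsets
6, 13 and 20 and `PFPQPQLPY` at offset 4, which is exactly the epitope
complement reported for 33-mer-bearing α-gliadins. A greedy
non-overlapping mode is provided alongside. Note that under overlapping
counting `PYPQPQLPY` occurs twice in the 33-mer although the published
tables list one copy for that core; the counting convention behind that
one published value is ambiguous, both modes are exposed, and no headline
quantity depends on it. Coordinates are 0-based, half-open everywhere.

The degenerate γ-repeat `PFPQ{1,2}(PQQ){1,2}` is matched by expanding all
four literal forms; at each start position the longest matching expansion
wins and exactly one hit is recorded, so nested expansions are never
double-counted.

## Epitope catalog

The shipped catalog (`data/default_epitopes.yaml`) holds 19 entries: five
α-gliadin CD cores, eight γ cores, two ω cores, and four ω5/WDEIA cores.
Cores whose sequence is pinned by in-package primary data — `PFPQPQLPY`
and `PQPQLPYPQ` by the 33-mer decomposition, `QQIPQQQ` and `QQFPQQQ` as
the dominant WDEIA epitopes — are marked `verified: true`; the remainder
follow the standard published CD-epitope nomenclature and are flagged
`verified: false`, i.e. they are configuration, not code, and can be
replaced by editing the YAML. Deamidated cores must equal the native core
up to Q→E substitutions; the scanner defaults to `native_only` because
deposited sequences are native (deamidation happens in the gut, not in
the genome).

## Maturation

Signal peptides are removed by signature search, not by a prediction
model: the earliest occurrence of any known mature-start signature
(`ARE, ARQ, KEL, SRL, GRL, VRV, NMQ, ISQ, SHI`; 40-residue search window)
marks the mature N-terminus. `NMQ` (the γ-gliadin mature start) is
included so γ precursors mature under the same rule as the other
families. Initiator-Met-stripped variants need no special casing because
the search keys on the earliest occurrence. When no signature is found
the sequence is left untrimmed, flagged `unknown`, and a warning logged.

## Classification cascade

Deterministic and total, evaluated in order on the mature sequence:

1. **omega** — at most 1 cysteine and ω-motif coverage (union of
   `PQQPFP`, `FPQQQ`, `QQIPQQ` matches) ≥ 20 % of the sequence. Subtype
   follows the **dominant repeat motif**, not the N-terminal signature:
   `omega_5` iff count(`FPQQQ`) + count(`QQIPQQ`) > count(`PQQPFP`). The
   precedent for ignoring the signature is the documented ω-gliadin that
   opens with the ω5-typical SRLL- yet carries 12 `PQQPFP` copies and is
   therefore ω1,2.
2. **gamma** — ≥ 4 γ-repeat matches and cysteine count in 8 ± 1 (the
   band admits the observed 9-Cys variants).
3. **alpha** — α repeat content (`PQPQPFP`, `PQQPYP`, `PQPQLPY` ≥ 3
   total), a 33-mer, or the VRV- mature start, and cysteine count in
   6 ± 1 (admits the observed 7-Cys variant).
4. otherwise **unclassified** — LMW glutenin subunits and non-gluten
   proteins deliberately land here; the census still runs on them.

The chain-terminator flag is pure parity: true iff the cysteine count is
odd and positive (an even count pairs into intramolecular disulfide
bonds; an odd count leaves one thiol free to cap glutenin polymer
growth).

## Domain segmentation

Family-motif matches closer than `max_gap` (8 residues) merge into
candidate repetitive segments; candidates at least `window` (30) residues
long with motif coverage ≥ `density_threshold` (0.4) are kept.
Interval-merging rather than a fixed sliding window was chosen so that
segment boundaries land exactly on the first/last motif residue instead
of being quantized to window edges; the window length and density
threshold keep their role as minimum-size and minimum-saturation
parameters. Polyglutamine runs (≥ 6 Q) outside repetitive segments become
`polyglutamine` segments; a leading known signature is labelled
`nterm_signature`; everything else is `nonrepetitive`. Segments always
tile the mature sequence exactly. No quantitative published boundary
definition exists for the γ-gliadin domains I–V, so segmentation is a
density construct and exact boundaries are only guaranteed on synthetic
sequences built from pure motif blocks.

## Genome assignment

Motif rules fire first: ω1,2 + ARE- → D; ω1,2 + ARQ-/KEL- → A; ω5 +
SRL-/GRL- → B; α containing `CSTT` → B. Everything else falls back to
nearest-reference assignment against a genome-labelled panel, which
replaces the usual multiple-alignment + tree step with its actual
decision content ("which labelled cluster is nearest").

Pairwise identity is computed by global dynamic programming with
identity scoring (match +1, mismatch 0, linear gap −1, all configurable
integers) and reported as matches / alignment length × 100. Co-optimal
alignments can differ in identity, so the traceback objective is the
lexicographic maximum of (score, matches, −length); this makes identity a
well-defined function of the sequence pair and lets tests compare against
exhaustive alignment enumeration exactly. The kernel is a numba-compiled
O(nm) loop. If the two best references come from different genomes within
a 0.5-point tie margin the call is `unknown` — 0.5 points is below the
resolution of the within-cluster similarities such studies report
(≈99.0–99.7 %). Because the underlying studies do not state their
similarity measure, printed similarity percentages are not treated as
reproducible quantities.

## Spot aggregation

Spot volumes are percentages of total gel volume (0–100 scale), stored at
full precision and printed with two decimals. Raw per-table listings may
mention one spot several times (a predominant listing plus
minor-component listings, the ∗-marked rows of the published tables);
`resolve_listings` collapses them by the non-minor-wins rule and treats
conflicting non-minor listings as an input error. `summarize_spots`
conserves volume exactly (tolerance 1e-9); `count_predominant_spots`
counts distinct spots and excludes minor listings, and per-genome volume
shares likewise exclude minor listings (whether the published shares
include them is unstated; excluding them is the conservative default).

The shipped `keumkang_spot_listings` table transcribes the published
spot/protein assignments of a 98-spot 2-DE separation: 31 α, 28 γ and one
ω predominant spot, six α-minor and two γ-minor listings. Per-spot
volumes are not published (only per-category totals), so each category's
total is split equally over its predominant spots — category sums are
exact, the within-category split is synthetic. LMW-GS, non-gluten and
unidentified spot ids are synthetic placeholders since only their counts
are published; one spot that is minor in both gliadin tables is carried
among the LMW-GS spots. The file header documents all of this.

## Synthetic data

The generator assembles proteins the way the real families are built:
signal peptide + mature-start signature + repetitive domain (family
repeat units with planted epitope copies, shuffled) + polyglutamine runs
+ non-repetitive blocks carrying exactly the requested number of
cysteines. Default blueprints (`example_spec`) mirror canonical
architectures: a 6-Cys α-gliadin with two polyQ domains, an 8-Cys
γ-gliadin with eight repeat units, an ω5 with SRLL- start and 28/10
scannable `FPQQQ`/`QQIPQQ` copies, an ω1,2 with ARQL- start and 12
scannable `PQQPFP` copies.

Exactness is structural, not statistical. All blocks are separated by
3-residue spacers drawn from `{T, N, V, H, K, D}` — an alphabet disjoint
from every residue of every repeat motif and catalog core — so no motif
or epitope occurrence can span a block boundary. (A spacer alphabet
containing A/S/G/L/I would not give this guarantee, because those letters
occur inside catalog cores such as `IQPQQPAQL` and `QGSFQPSQQ`.) Ground
truth is then computed analytically per planted block with a naive
substring counter, independent of the motif engine, and includes
cross-containment (e.g. each planted `QQFPQQQ` contributes one `FPQQQ`
count, each `QQPQQPFPQ` one `PQQPFP`). The signal-peptide template is
cysteine-free and signature-free, so precursor and mature cysteine
censuses agree and trimming is unambiguous.

What the generator does **not** emulate: real repeat-unit sequence
drift, pseudogene-derived stops, tandem repeats without spacers,
post-translational modification, gel migration (MW/pI), and MS/MS
coverage gaps. Passing the recovery tests therefore demonstrates that
the pipeline's bookkeeping is exact on in-model sequences, not that the
classifier thresholds are optimal for every deposited sequence.

Spot tables are generated with symmetric-Dirichlet volumes normalized to
100 and categories sampled by weight; ground truth carries the exact
group sums.

Reference panels (`make_reference_panel`) hold one synthetic mature
sequence per genome per family with genome-consistent diagnostic
features; cross-genome identities land well below 90 %, so 2 %-mutated
copies re-assign to their source genome with a wide margin.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds; the same
seed gives byte-identical output. The test suite works at desk scale:
1000 random strings against the brute-force counting oracle, 200 random
synthetic proteins for full census recovery, exhaustive alignment
enumeration up to length 8 (beyond that the alignment count explodes
combinatorially), and 100 mutation trials for genome recovery — the
whole suite runs in a few seconds on one core.

## Known limitations

* Family thresholds (coverage 0.2, γ-repeats ≥ 4, cysteine bands ± 1)
  are rule-of-thumb encodings of the observed variants, tunable via
  `ClassifierConfig`; heavily degenerate or truncated deposited sequences
  may land in `unclassified`.
* Maturation is signature-based only; a precursor whose mature start is
  not in the signature set is left untrimmed.
* γ- and several ω-epitope cores ship unverified (see catalog section).
* The α-gliadin genome call implements only the `CSTT` hard rule; other
  genome-specific α motifs are not encoded and those sequences rely on
  the reference panel.
* Per-genome volume shares and gel-derived percentages depend on the
  study's gels; the package reproduces their bookkeeping, not their
  measurement.
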