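# Methods

This note documents the model behind `sigiscan`, the parameters that
matter, the design decisions that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Promoter model

A σ<sup>I</sup>-dependent promoter is modelled as three motifs on one
strand:

1. **A-tract** — a homopolymeric run of adenines closing the −35 element.
   The scanner anchors on *maximal* runs of length ≥ the −35 core (default
   `AAA`), so one biological site yields exactly one report regardless of
   run length. This reconciles the triad used for genome searches with the
   tetrad seen in curated alignments: a maximal run of 4+ contains both.
2. **Spacer** — 12–15 nt (inclusive) measured from the 3′ end of the
   maximal A-tract to the 5′ start of the −10 core. The literature fixes
   only "between the −10 and −35 elements"; tract-end-to-core-start is this
   package's convention, configurable through `MotifSpec`.
3. **−10 core** — `CGHH` by default (`H` = A/C/T), i.e. the CG dyad
   delimited by the requirement that the two following bases are not G.

Around the cores, every match carries a `specificity_window` (default 6 nt
5′ of the A-tract — the *region of specificity*) and a `downstream_window`
(default 6 nt 3′ of the core, holding the conserved AT dyad three
nucleotides after the tetrad). `N` never matches a concrete pattern
symbol: assembly gaps are treated conservatively.

`background_hit_rate` gives the closed-form i.i.d. expectation
Σ<sub>spacers</sub> Π p(−35 positions) · Π p(−10 positions) per position
per strand. Because it counts core *occurrences* while the scanner reports
maximal runs once, it is an upper bound; for an all-A core the realized
rate is lower by roughly a factor (1 − p<sub>A</sub>). Calibration checks
therefore use short contigs (2.5 kb per GC value), where this deterministic
deficit (~1–1.5 Poisson SD) sits well inside a 3-SD band; on long contigs
the deficit grows linearly while the band grows as √L and the bound would
dominate.

## Profiles and scoring

Curated promoters are stacked on two anchors — the A-tract 3′ end and the
−10 core 5′ start — with the variable spacer excluded from columns (its
length distribution is stored separately as a categorical over 12–15).
Columns a record does not reach hold a gap that is ignored in counts, so
short A-tracts never dilute long-tract columns.

Frequencies use f(b,j) = (count + κ) / (n<sub>eff</sub> + 4κ) with
pseudocount κ = 0.5 by default: curated sets are small (a handful of
promoters per σ), so zero counts are common; κ is configurable and tests
that need exact point estimates use κ = 0. The default background is
uniform; per-column information content is the relative entropy versus the
background, which under a uniform background is 2 + Σ f log₂ f ∈ [0, 2]
bits. A logo-style small-sample correction (3/(2 ln2 · n)) is available
behind a flag and off by default — with 3–6 records it would erase real
conservation. Zero-support columns hold the background exactly and score
zero.

`score_window` lays a scanned candidate onto the same dual-anchored
columns and sums log₂(f/background) over covered positions; uncovered
positions (edge truncation, N) contribute 0. Scores therefore depend only
on element sequences, never on coordinates or strand.

Consensus strings report the majority base when it reaches the threshold
(default 0.75), otherwise the minimal IUPAC code over bases above 1/4,
otherwise N.

## Regulon rules and classification

A `SpecificityRule` is the declarative form of "cytosine enrichment in the
region of specificity": a concrete triad whose 3′ end may sit 0–`offset`
nt upstream of the A-tract (σ<sup>I1</sup>: CTC at offset 0;
σ<sup>I3</sup>: CCC at offsets 0–2), a −10 tetrad (CGAA versus the CGTA of
the *sigI3* gene's own promoter) and an optional dyad three nucleotides
downstream of the tetrad (AT, or GT for *sigI3*). A count-based variant
(≥3 C in the 5 nt before the A-tract) is available behind a flag.

Classification is rule AND score ≥ `min_score` (default 0 bits, i.e.
better than background), applied per σ **without** argmax: a promoter
satisfying several σ rules keeps all labels and is flagged as cross-talk.
This is deliberate — multi-σ recognition of key cellulosomal promoters
(the `CCCCTCAAA`/CGAA "universal promoter" configuration) is a real
finding, not a classification error. No multiple-testing correction is
applied: the pipeline is rule-based, not p-value-based.

5′-UTR distances are measured from the 3′ end of the −10 core to the first
codon; the promoter-side endpoint is not fixed by the source descriptions
and is documented here as this package's convention. The upstream search
window defaults to 600 nt, covering the longest UTR classes plus the
promoter footprint; `whole_genome` scope scans both strands and assigns
each match to the nearest downstream same-strand gene within the window,
leaving unassigned matches in the output.

## In-silico mutagenesis

`mutscan` rebuilds the reporter-library experiment computationally: one
transversion (A↔T, C↔G) per position. Two decoupled behaviours mirror the
two behaviours of real mutant libraries:

* **ablation** — the mutant window no longer contains any bipartite core
  match (the "not detected" phenotype). For a σ<sup>I3</sup>-style
  analysis the scan spec must carry the σ-specific core `CGAA`; under the
  permissive genome-search core `CGHH`, A→T at tetrad position 3 would
  yield `CGTA`, still a valid match, and the known destroying mutation
  would be misread as tolerated.
* **graded effects** — for surviving mutants, Δscore = score(best mutant
  match) − score(wild type) with a neutral band of ±0.5 bits (the source
  data give qualitative classes plus a single quantitative outlier, so
  banded classification, not regression, is appropriate). Positions
  outside all scored columns (spacer interior, flanks) give exactly 0 and
  class `neutral`; extending the A-tract by mutating the base immediately
  5′ of it adds a high-frequency A column and classifies as `increased`,
  matching the direction of the known activity-increasing −35 mutation.

## Synthetic benchmark

`synthetic` generates what the analysis assumes and nothing more: an
i.i.d. background at configurable GC (default 0.38, clostridial-like),
planted promoters, and one annotation-only gene per plant at a sampled
5′-UTR distance (uniform 30–300 nt by default, gene length 300 nt).

Per-σ generators are parametric: a concrete triad, an IUPAC gap (the
σ<sup>I3</sup> default `YY` covers the pyrimidine gaps seen in real
promoters, CT and TC), a concrete tetrad, a downstream context with the
concrete AT dyad, and an A-tract length distribution (4:0.5, 5:0.3,
6:0.2). Degenerate positions are realized uniformly over their expansion;
cores are fully conserved, which mirrors the stringency of these promoters
and keeps rule-based recall/misassignment claims deterministic rather than
dependent on an arbitrary noise constant. The last gap symbol must exclude
A, otherwise the realized gap would merge into the A-tract and shift the
anchor.

Planted spacers are rejection-sampled until a self-scan of the assembled
plant yields exactly the intended match — this simultaneously forbids
accidental in-plant promoters and A-tract extension into gap or spacer, so
the truth table is exact. The background elsewhere is untouched:
background hits are *expected*, and all recall claims match on truth
coordinates, never on total counts. Each plant reserves a non-overlapping
zone covering promoter + UTR + gene, so the nearest downstream same-strand
gene of every planted promoter is provably its own gene; decoy genes are
placed outside all zones. Everything is seeded; an identical spec gives
byte-identical FASTA/GFF3/truth outputs.

What passing these benchmarks does **not** show about real data: real
promoter sets have correlated positions, indels and mislabeled members;
real genomes have skewed composition, repeats and operon structure; and
real σ–promoter recognition is quantitative (polymerase occupancy), not a
rule. The benchmarks validate the *machinery* — coordinates, anchoring,
counting, rule logic — under the stated statistical model.

## Problem sizes and fixed choices

The shipped checks use: 100 × 10 kb sequences for scanner/oracle
equivalence (exhaustive enumeration oracle, exact set equality); 2.5 kb
contigs × GC ∈ {0.3, 0.5, 0.7} for background calibration (|z| ≤ 3);
500 plants across five disjoint-triad σ classes on a 400 kb genome for
recall (100%) and misassignment (≤1%); n = 200 sampled promoters for
parameter recovery (L<sub>∞</sub> ≤ 0.05 against the generating profile).
Parameter recovery at n = 200 is checked on the fully concrete
σ<sup>I1</sup> generator, where the estimator is exact; degenerate columns
(true frequency 0.5) are checked at n = 2000, where the binomial standard
error (~0.011) sits far inside the band — at n = 200 a 0.5-frequency
column has SE ≈ 0.035, so a single-draw 0.05 bound on it would fail ~30%
of the time by chance, a property of the binomial rather than of the
estimator.

## Known limitations

* The scanner is exact-pattern, not probabilistic: no PWM-threshold
  scanning of the cores, no mismatch tolerance (a stated non-goal).
* Rules use concrete triads with exact offsets; promoters whose
  specificity region deviates from the curated consensus are missed at the
  rule stage even if their profile score is high.
* Ortholog mapping between σ factors across species is user-supplied; the
  transfer pipeline projects one source model onto one target genome.
* The ΔFU relative activity is a ratio of condition means, not a mean of
  per-replicate ratios; with the replicate SD already folded into the ND
  rule, the two differ only for noisy measurements.
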