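# Methods

`mitolong` is a desk-scale re-implementation of a long-read (Oxford
Nanopore MinION-style) workflow for detecting and quantifying large-scale
deletions of the human mitochondrial genome.  It covers the full chain:
simulation of reads from a heteroplasmic mixture of circular molecules,
circular-aware alignment, breakpoint calling, heteroplasmy and mtDNA
content estimation, naive point-variant calling, and the
protocol-selection rule that decides which library chemistry to use next.
This note records the models, the defaults, and the choices made where
the design was genuinely open.

## The biological setting

Human mtDNA is a 16,569-bp circle present in hundreds to thousands of
copies per cell.  In patients with single large-scale deletions
(Kearns-Sayre, Pearson, PEO) or with multiple deletions secondary to
nuclear maintenance-gene defects, a fraction *h* of the molecules — the
heteroplasmy — carries a multi-kilobase deletion.  A deletion is described
by two 1-based breakpoints `(start, end)` meaning bases `start..end-1`
are absent; its size is the circular forward distance `end − start
(mod L)`.  All coordinates in the package follow this convention; it is
the only one under which breakpoint pairs and sizes agree arithmetically
(e.g. 13,956 − 7,634 = 6,322).

Two library chemistries are modelled:

* **Ligation kit (endonuclease linearization).**  The circle must be cut
  once by a restriction enzyme (BamHI, G^GATCC, or PvuII, CAG^CTG) before
  adapter ligation.  If the enzyme site falls *inside* the deletion, the
  deleted molecules keep no site, stay circular, and are mostly not
  sequenced — deletion heteroplasmy is then underestimated.
* **Rapid kit (transposase tagmentation).**  Fragmentation is random, so
  deletions and complex rearrangements are sampled without positional
  bias; this also makes multiple-deletion samples analysable.

## Read simulator (`mitolong.simulate`)

A sample is a `MoleculePopulation`: species (deletion sets) with
fractions summing to one.  Each simulated molecule draw realizes the
species' circular sequence, fragments it, and corrupts each fragment:

* **Endonuclease mode** cuts at every recognition site found on the
  *realized* molecule (sites are recomputed after excision, so a deletion
  spanning the site removes it).  A molecule with no remaining site is
  emitted only with probability `p_uncut` (default 0.1), linearized at a
  uniform random phase.  `p_uncut` has no experimental
  measurement; 0.1 gives a strong but not total underestimation, matching
  the qualitative BamHI-vs-PvuII pattern, and is exposed as a knob.
  Fragments additionally suffer random degradation nicks at
  `breakage_rate` per internal bond (default 1.5e-4, making Ligation-kit
  reads average roughly 6 kb rather than full circle length, in line with
  typical Ligation-kit mtDNA read lengths).
* **Transposase mode** cuts the circle at a uniform phase and partitions
  it into fragments with log-normal lengths (default arithmetic mean
  4,403 bases, σ_log = 0.6 — a typical Rapid-kit average mtDNA read
  length).
  Fragments always partition the circle, so per molecule draw every
  surviving base is covered exactly once; this makes the coverage-ratio
  estimator unbiased by construction in this mode.

The error model is indel-dominated, as on R9.4.1 pores: per base,
mutually exclusive substitution (0.02), insertion (0.015) or deletion
(0.025), totalling ~6%, with the deletion probability doubled inside
homopolymer runs ≥ 4.  Quality is a constant Q12; reads are strand-flipped
with probability 0.5.  Fragments shorter than `min_read_length`
(200 bases) are dropped as unsequenceable.  Nuclear background reads are
i.i.d.-uniform random sequence — sufficient to exercise mapped/unmapped
classification and the mtDNA/nDNA ratio, but *not* a model of real
nuclear DNA or NUMTs (a stated limitation: real NUMT-derived reads share
sequence with the mt genome; random reads do not).

Every read carries ground truth (species, reference coordinates,
junctions spanned, nuclear flag), and a run is byte-reproducible given
its seed.

## Circular-aware aligner (`mitolong.align`)

The reference is indexed as a doubled sequence so alignments may cross
the origin; any chain spanning more than one full circle is rejected.
Per read:

1. k-mers (k = 15, masked above 20 circle occurrences) are sampled at an
   adaptive stride targeting ≤ 260 sampled positions and looked up
   exactly;
2. anchors are chained by dynamic programming; consecutive anchors pay
   `gap_open_scale · log2(1 + g)` for a reference-vs-read gap `g`.  The
   concave cost makes a 6-kb deletion barely more expensive than a 500-b
   one, which is the desired behaviour for large-deletion evidence, while
   co-linearity is enforced exactly.  `gap_open_scale = 4` balances two
   failure modes: a larger value discards true junctions whose shorter
   flank carries only a handful of anchors (biasing the spanning-read
   estimator down), a smaller one admits spurious chains through isolated
   random anchors;
3. the chain is split into blocks where the implied reference gap exceeds
   `min_seg_gap` (30 bases); each junction is refined by exhaustively
   scoring breakpoint placements (left-flank extension × right-flank
   extension, edit distance via edlib) with ties resolved to the
   *leftmost* reference position, so deletions flanked by direct repeats
   — common in mtDNA — are reported reproducibly;
4. segment ends not pinned by a junction are located by semi-global
   edit-distance alignment with a ±window (200 bases) pad.

A read is `mapped` when the best chain spans ≥ 40% of the read
(`min_cov_frac`) with at least three anchors; i.i.d.-random reads only
ever produce isolated anchors and fail this.  The chain *span* is used
rather than summed anchor lengths: at a ~6% error rate only ~40% of
15-mers are error-free, so an anchor-mass criterion would sit exactly at
the threshold and misclassify half of the genuine reads.  Only the best
single strand is reported; chimeric multi-strand reads are out of scope.
None of these values mimic any production aligner's scoring; they are
sized for a 16.6-kb circular reference and ~5%
error reads, and all are exposed in `AlignParams`.

## Deletion calling (`mitolong.svcall`)

Each reference gap ≥ `min_del_size` (100 bases; separates structural
deletions from nanopore indel noise) in a mapped read is one deletion
signal.  Signals are clustered by single linkage — two signals link when
both breakpoints are within `tol` (50 bases, the observed breakpoint
scatter under the default error model) by circular distance — and
clusters with fewer than `min_support = 2` reads are discarded — the
conventional SV-caller minimum-support setting for low-depth evidence.  Consensus
breakpoints are per-cluster leftmost medians computed after unwrapping
the cluster around its first member, so clusters straddling the origin
behave correctly.  Calls wrapping the origin are emitted as two VCF
records sharing an `_a`/`_b` ID suffix because a linear VCF record cannot
express a circular interval; the reader rejoins them.

## Heteroplasmy estimation (`mitolong.quantify`)

Two estimators per call:

* **Coverage ratio** — `h = 1 − mean(depth inside) / mean(depth
  outside)`, clamped to [0, 1].  `margin = 100` bases are trimmed on each
  side of both breakpoints (breakpoint scatter and soft ends), and ±300
  bases around any linearization site are excluded from the outside mean
  (the cut site shows a coverage spike because many reads start there).
  The margin scheme (which bases to trim) is this package's own choice.
* **Spanning reads** — `h = J / (J + W)` where `J` counts reads whose
  reference gap matches the call with ≥ `min_flank` (50) aligned bases on
  both sides, and `W` is the *average* of the two per-breakpoint counts
  of reads aligned contiguously across a breakpoint.  The average (rather
  than the count of reads crossing either breakpoint) is required for
  centring: an intact circle presents two breakpoint loci where a deleted
  molecule presents one junction, so summing the two wild-type counts
  would underestimate h by roughly a factor of `(2 − h)/1` — at h = 0.5
  the naive form returns ~0.33.  When no read qualifies the estimate is
  undefined and printed as `NA`, never 0.

For samples with several deletions only the spanning-read estimator is
reported per call; overlapping depth drops confound the coverage ratio.
Downsampling removes whole reads in a seeded random order until the mean
depth first reaches the target, mirroring a BAM-level random
downsampling check.  The mtDNA/nDNA read-count ratio is a plain quotient
of mapped-to-circle vs other reads — a relative mtDNA content indicator,
not an absolute copy number.

The protocol recommendation implements the decision workflow: no calls →
negative; one call not containing the enzyme site → done; one call
containing the site (endonuclease mode) → re-digest with PvuII; two or
more calls in endonuclease mode → re-sequence with the Rapid kit.
Transposase runs are always terminal; a transposase run with ≥ 2 calls
returns `done_multiple_deletions`, a status added here because the
four-outcome workflow has no name for that terminal case.

## Point variants (`mitolong.pointvar`)

A naive pileup counts matching/substituted bases per position from each
segment's edit-distance alignment; read indels and inserted bases are
excluded, and positions inside a read's deletion gap contribute nothing.
Site heteroplasmy is the alternate fraction with a Clopper–Pearson exact
two-sided interval — "asymmetric" at the boundary, where the upper bound
for zero alternate reads in n is `1 − (α/2)^(1/n)` (3.6% at 100x, 0.74%
at 500x).  The exact interval was chosen as the interpretation of an
otherwise unspecified asymmetric interval because of its coverage
guarantee and closed boundary form.  The mean of per-site upper bounds
over covered positions (only covered ones; averaging over all positions
would need a convention for zero-depth sites) is reported as the error
floor.  Strand bias and base qualities are ignored — the simulator emits
constant quality — which is a stated gap versus production mtDNA variant
servers.  The default detection threshold `min_h = 0.05` reflects the
practical nanopore point-variant floor.

## Visualization and CLI

`viz.circular_plot` draws the genome as a circle (12 o'clock origin,
clockwise), with an annotation ring, a coverage ring, and one chord per
deletion call whose width grows linearly with supporting reads between
0.5 pt and a 6 pt cap (so one dominant clone cannot blank the figure).
SVG output carries a fixed hash salt and no date metadata so identical
inputs give identical files.

The `mitolong` CLI exposes `simulate / align / call / quantify /
pointvar / plot / run`; exit codes are 0 (success), 2 (usage), 3 (data
error).  `--threads` is accepted for interface compatibility; results
never depend on it.  All outputs are byte-reproducible given inputs and
seed.

## Problem sizes and what the tests show

The test-suite and the acceptance script run the pipeline at the study's
own scales: a seeded random 16,569-bp circle (the real reference is
fetched from NCBI only in one opt-out-free network test), 300x error-free
coverage for breakpoint recovery of clinically observed deletion
coordinates,
and 500x with the default error model for heteroplasmy recovery and the
100x downsampling check.  The linearization-bias replicate study
(20 seeded replicates, endonuclease vs transposase with the site inside
the deletion) runs on a 6-kb circle at 60x — the bias mechanism is
scale-free, and the small circle keeps the replicate count high.

Because the synthetic reference is i.i.d.-random, it underrepresents the
repeat structure, NUMT homology and homopolymer composition of real
mtDNA; passing tests therefore demonstrate the correctness of the
algorithms under the modelled error process, not base-perfect
performance on real nanopore data.  The simulator also omits squiggle-
level artefacts, quality-score structure, adapters and barcodes.
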