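# Methods

This note records the models, numerical conventions and design choices behind
`archscan`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## Coordinates and alignment model

All public coordinates are 1-based and spans are inclusive, so
`span_length(280, 310) = 31` — the convention used when residue ranges of a
protein are printed.  An alignment is a set of rows over columns labelled
*match* (consensus positions of the domain model) or *insert*.  Match columns
hold uppercase residues or `-`; insert columns hold lowercase residues or `.`
(the Pfam/Stockholm case convention; Stockholm files must carry `#=GC RF` with
`x`/`.`).  Only this dialect is accepted — no guessing of other case
conventions.

`strip_insert_columns` removes insert columns but records, per row, the number
of insert residues between each pair of flanking match columns.  This matters
because region *lengths* are defined on the ungapped sequence: a variable
region can hold several hundred residues while the match-column span stays
fixed, and only an insert-inclusive length definition can express that.
Insert slots strictly between two match columns of one region belong to that
region; a slot falling exactly on a region boundary is assigned to the region
on its left (slot 0 to the first region).  This tie-break makes region lengths
partition the sequence exactly; the generator never places inserts on
boundaries, so the convention is only visible for adversarial alignments.

Reference maps number residues in the parent protein
(`number = offset + position − 1`, insert residues included in the numbering)
and map match-assigned residues to match columns, bijectively on their shared
support.  `X` is allowed in non-reference rows and counts as a gap in
conservation scoring; reference rows must be `X`-free.

## Profile alignment

The profile stores per-column log-base-2 odds `log2(f_c(a) / q(a))` with
column frequencies `f_c = (counts + w·q) / (n_c + w)` (pseudocount weight
`w = 1` by default, background `q` uniform or the BLOSUM62 marginals).
Alignment is global in both profile and sequence, with affine gap penalties in
bits shared by insertions and deletions: a run of length L costs
`open + (L−1)·ext`, defaults `open = 4`, `ext = 0.25`.  This is a deliberate
simplification of a profile HMM: no state-specific transition training, no
local/glocal modes, and no E-value statistics — candidate screening uses a
plain bit-score threshold instead of a database E-value.  Ties in the dynamic
program break deterministically (match > delete > insert).  `X` scores 0 bits
in every column.  Optional position-based (Henikoff) sequence weighting is
off by default.

The implementation is a Gotoh three-state recurrence; the delete state obeys a
prefix-max recurrence along each row and is computed with an accumulated
maximum, which keeps the inner loop vectorized.  Correctness is pinned by an
exhaustive path-enumeration oracle on all shapes up to 4 columns × 5 residues.

## Conservation scoring

Per match column: residue distribution over non-gap, non-`X` symbols;
gap fraction = (gaps + X) / rows; Jensen–Shannon divergence against the
background with mixture weight λ = 1/2 (bounded by 1, symmetric); gap penalty
multiplicative, `jsd_penalized = jsd_raw · (1 − gap_fraction)`; smoothing
`s'_i = (1−λ_w)·s_i + λ_w·Σ(flank)/2w` with w = 3 columns each side and
λ_w = 1/2.  The flank normalizer stays `2w` at the profile ends (missing
neighbours contribute 0), which is what the hand-computed case
`[0,1,0] → [0.25, 0.5, 0.25]` pins down; as a consequence end columns are
pulled toward zero and a constant track is a fixed point only where the flank
is complete.  These values are one published default set for JSD conservation
scoring; the background choice and weighting are exposed as options and
recorded in output metadata, since the original analysis does not state them.

Information content is `log2 20 − H(p_c)`, floored at 0; the small-sample
correction `19/(2·ln2·n)` is available but off by default — at the scale
where the 2-bit call is used (thousands of rows) it is ~0.003 bits and
immaterial.  Conserved columns are those with bits strictly above the
threshold (default 2.0).  Logo letter heights are `p_c(a)·bits(c)`; only the
numeric matrix is produced, no graphics.  Identity percentages count gaps in
the denominator and are reported rounded to the nearest integer with the raw
fraction retained.

## Architecture segmentation

The smoothed, gap-penalized JSD track is thresholded at τ = the midpoint of
its 20th and 80th percentiles (overridable); maximal above-threshold runs are
merged when separated by fewer than 5 columns and discarded when shorter than
10.  Exactly two super-blocks are expected — DNA-binding, then dimerization;
any other outcome raises a segmentation error carrying the run list, and a
user-supplied template (which always overrides inference) can be imposed
instead.  Columns before the first and after the last block are absorbed into
the flanking blocks so the template tiles all match columns.  Within the
dimerization block the same percentile-midpoint rule, applied block-locally,
defines a valley threshold; the lowest-mean internal run of width ≥ 5 below it
becomes the linker, splitting α from β.

Appending all-gap rows rescales the penalized track uniformly
(`(1 − g/n) → (n−g)/(n+k)` per column), so percentile thresholds scale with it
and segmentation is invariant — this is property-tested.

Range masses ("X% of sequences between a and b residues") use inclusive
bounds `[a, b]`, an interpretation recorded in output metadata.  Default bins:
width 20 from 0 for the variable region, width 5 for the linker, aligning bin
edges with the conventional reporting ranges.

## The synthetic generator

The generator emulates the statistical structure of a kingdom-wide velvet
collection with a planted architecture of 30 / 50 / 45 / 20 / 40 match columns
(DNA-binding / variable / α / linker / β).  Column residues follow a
Dirichlet-categorical model: per column, a distribution is drawn from
`Dirichlet(κ·m)` with class mean `m = identity·e_consensus + (1−identity)·q`,
then residues are i.i.d. across sequences.  Class defaults:

| class     | identity | κ    | role |
|-----------|----------|------|------|
| conserved | 0.50     | 400  | DNA-binding and α/β bulk: high JSD, bits < 2 |
| linker    | 0.48     | 150  | above the global threshold, below α/β — one super-block with an internal valley |
| variable  | 0.00     | 2000 | background-like |

The conserved-class parameters were chosen (by simulating the per-column bits
distribution at n = 5000) so that non-planted columns essentially never cross
the 2-bit call: the columns exceeding 2 bits are the planted near-invariant
sites.  Thirty such sites (15 in α, 15 in β) carry fixed residues at identity
0.95–0.98, including one glycine at 0.98 and one leucine at 0.95 — the
synthetic counterparts of the two most conserved dimerization residues, whose
identity across the real collection is reported as 98% and 95%.  Off-residues
at invariant sites are drawn from the background *excluding* the site residue,
so realized identity estimates the identity probability directly.  A `tight`
preset (conserved 0.95, linker 0.80) is used for boundary-recovery
experiments; the linker level scales with the block level because the
segmentation contract requires the linker to stay above the global threshold
while remaining the within-block valley.

Variable-region lengths are drawn from an explicit pmf on 0..450: an atom at 0
(2%), a discretized log-normal with mode 50 (σ = 0.28), and a power-law tail
(exponent 1.5) from 80 to 450; the log-normal weight is solved so the pmf mass
on [40, 60] is exactly 0.47.  Linker lengths are 20 + J with J a truncated
two-sided geometric on [−15, 30] whose decay is solved by bisection so that
P(|J| ≤ 5) = 0.63 — i.e. linker lengths 15–25 in 63% of sequences.  Both
calibrations are exact at the distribution level; realized family fractions
fluctuate binomially, which is what the 3-standard-error acceptance bands
check at n = 5000.

Length realization: a sequence shorter than the variable block deletes a
random contiguous window of variable columns; a longer one carries a single
contiguous insert run at the central slot (a single-loop simplification;
`insert_placement="random"` spreads the slot choice).  Linker jitter works
the same way.  Conserved blocks are insertion- and deletion-free.  There is
no phylogeny: columns are exchangeable given their class and sequences are
independent, so the generator does not reproduce the correlation structure of
real homolog sets (clade-specific residues, covarying positions, alignment
uncertainty).  Passing the synthetic acceptance checks therefore demonstrates
correctness of the pipeline's bookkeeping and statistics under known truth,
not robustness to real-data alignment error.

## Structure contacts

A "hydrogen bond" is operationalized as the minimum distance between polar
heavy atoms (N, O; backbone included, so glycine participates) of two
residues — no hydrogen placement, no angle criterion.  This matches the way a
single printed interface distance is measured in a viewer and keeps the check
dependency-light.  Structures are read with gemmi (first model, waters and
hydrogens removed, altlocs reduced to the highest-occupancy conformer); which
chains are which protein is a user input.  A synthetic two-residue fixture
(glycine 240 / serine 110 with an exact 3.50 Å N–OG separation, labelled
synthetic) exercises the check without any external download.

## Problem sizes and determinism

The study-scale experiments use n = 4999 sequences (the size of the
collection the generator emulates); boundary recovery uses 5 seeds × 200
sequences through the full align → conserve → segment pipeline; calibration
checks use 5000–10000 draws.  Every sampler consumes a single
`numpy.random.default_rng` stream seeded from the spec; identical
configuration and seed give byte-identical outputs, including the pipeline's
serialized summary.

## Known limitations

* The profile aligner is not a profile HMM; on real, deeply diverged families
  its column assignments will differ from HMMER's, so dataset-wide conserved
  counts on real collections are alignment-sensitive.
* The 47%/63% length masses are distribution-level calibrations to reported
  summary statistics, not fits to full empirical histograms (which are not
  published); the mixture shapes are package defaults, not claims.
* Segmentation assumes a two-block architecture with one internal valley; it
  reports a structured error (rather than guessing) on tracks that do not
  match this shape.
* Identity percentages treat rows as exchangeable; no phylogenetic
  down-weighting is applied by default.
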