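# Methods

This note documents the models, rules and numerical choices behind
`mtphylo`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Curation rules

Quality control operates on raw (unaligned) sequences and is entirely
threshold-driven (`QcConfig`):

- **Length classes.** The defaults encode the empirical length structure
  of complete human mtDNA in rCRS numbering: the *strict* band
  [16550, 16600] (closed on both ends, since both endpoints are quoted as
  attained), a hard maximum of 16600 bp beyond which a record is rejected
  as an intrusion, the *vacuum* [15600, 16300) in which no coherent genome
  occurs (a length there is itself suspicious and is marked for review),
  and a review band [16300, 16550) that is known to contain rare but
  legitimate large deletions. Review outliers are retained and flagged by
  default — dropping them requires `strict_exclude` — because completeness
  matters more than convenience and the flags keep them auditable.
  Non-strict intervals are half-open `[lo, hi)`; the colon-ranges the
  thresholds come from do not state openness, so the convention is fixed
  here once. `QcConfig.scaled(L, cr_len)` maps the same band structure
  onto a reference of any length so the identical rules run on the 2 kb
  synthetic genomes.
- **Composition.** Ambiguity is counted as residues outside {A,C,G,T}
  (gaps are illegal in raw sequences). The default static threshold is 5
  ambiguous positions — on large public snapshots a threshold of 1 already
  covers ~95 % of sequences and 5 covers ~99 % — with an optional
  fractional threshold. N-runs of ≥ 10 (`n_run_min`) are flagged; the
  value is chosen to sit far above isolated sequencing noise and below any
  biologically plausible feature, since real N-runs mark unsequenced
  stretches in formally "complete" records.
- **Identity.** Duplicates are exact raw-residue string matches;
  ambiguity-aware equality (N matching anything) is deliberately *not*
  used, because representative compression must be losslessly reversible.
  The lexicographically smallest id represents each group and an expansion
  map restores members in final outputs.

`run_qc` is idempotent (re-running on its own output changes neither tiers
nor the log) and every exclusion is justified by a provenance entry.

## Rotation handling

A circular genome linearized at a non-canonical start point shows up as a
sequence whose canonical position 1 sits mid-string. Detection is
k-mer-based (k = 12, one seed every 16 positions): each seed hit votes for
an offset, and a candidate must (a) lie outside a ±32 *drift window*
around zero — apparent offsets inside it are the signature of ordinary
indels, which shift all downstream positions by their length, not of
rotations; (b) dominate the vote (≥ 30 % of sampled k-mers and more mass
than the zero neighbourhood); and (c) improve ungapped identity by ≥ 5
percentage points. Correction rotates the string back; the provenance log
records the offset. Limitations: a genuine rotation smaller than the drift
window is not detectable (none are expected — real cases displace the
origin by thousands of positions), and a very large deletion early in the
genome could in principle masquerade as a rotation; the pipeline therefore
runs detection only on strict-tier (full-length) sequences, where no such
deletion can be present.

## Partitioned alignment

Multiple alignment of thousands of ~16.6 kb genomes is intractable
directly, but gene order in mtDNA is fixed, so homology can be localized
first: each sequence is aligned once, pairwise, against the reference
(affine costs — gap open 3, extend 1 — so missing regions stay contiguous
blocks; the alignment is cached and reused across reruns), and unit
boundaries are mapped through it. Insertions attach to the reference
position on their left; a cost-neutral normalization pulls residues
leftward across gap runs so that co-optimal gap placements are canonical.
Units that overlap in the annotation (e.g. overlapping genes such as
ATP8/ATP6) carry the shared interval in both slices; at merge time the
left unit's columns are kept and the right unit's copy must agree
residue-for-residue — disagreement is a hard error naming the sequence and
unit pair, rather than a silent preference, because it indicates an
alignment defect worth surfacing.

The internal per-unit aligner is a deterministic center-star progressive
aligner seeded on the reference slice (the reference-closest guide); it is
adequate for the closely related, structurally conserved sequences the
units contain, and an external aligner (e.g. MAFFT) is available behind a
subprocess adapter when higher quality is wanted. On synthetic units the
internal aligner's parsimony cost stays within 20 % of MAFFT's.

Indel classification inside coding units distinguishes codon-level events
(length divisible by 3 *and* starting on a codon boundary under the unit's
reading frame) from frameshifts; in non-coding units events are recorded
without biological classification.

Rows missing a unit entirely are gap-padded and masked *unsequenced*; for
flexible-tier sequences the same mask is applied to their control-region
gap columns. The mask is the mechanism that distinguishes legitimate
deletions from unsequenced regions: masked positions expand to the full
parsimony state set, so they never generate false indel events.

## Distances and outliers

Edit distances are unweighted parsimony counts on aligned rows. A column
contributes nothing when the IUPAC sets of the two symbols intersect (N is
compatible with everything), so ambiguity can only lower a distance, never
inflate it; `skip_ambiguous` additionally drops ambiguous columns per
pair. Gap runs count per column by default or as single events
(`single_event`), which is the mode that keeps control-region-less
sequences comparable with complete ones; alternatively the pipeline
restricts all pairs to coding-region columns whenever flexible sequences
are present.

Group-wise outlier detection computes, within each labeled group of ≥ 3,
each member's median intra-group distance, and flags a member when that
median exceeds the group's median-of-medians by more than k·MAD (k = 5)
**and** exceeds 4× the center. The relative guard is essential: legitimate
intraspecies mtDNA distance distributions spread to roughly 3× their
median (deep clades, long branches), while defective data — incomplete
sequences, intrusions — inflate distances several-fold. Groups smaller
than 3 are reported, not scored, and a separation report compares minimum
inter-group with maximum intra-group distances.

## Trees

Internal inference is Saitou–Nei neighbor joining: deterministic
(Q-criterion ties break toward the lexicographically smallest label pair),
exact on additive matrices, negative branch lengths clamped to zero. It is
the desk-scale engine; production-size maximum-likelihood runs go through
the external-engine adapter (FASTA in, newick out) and everything
downstream is engine-agnostic. Bootstrap resamples columns with
replacement under a fixed seed; majority-rule consensus retains
bipartitions with frequency strictly above the threshold (default 0.5,
which guarantees pairwise compatibility) and reports the exact frequency
as support; unresolved regions collapse to polytomies. Rooting is by
outgroup, which must form one side of a bipartition.

## Parsimony annotation

Ancestral states come from generalized Fitch parsimony over the five-state
alphabet {A,C,G,T,−}. The gap is a real state: each column is treated
independently, so a k-column indel contributes k point events (events are
*not* unified across columns). Leaf symbols enter as state subsets (IUPAC
codes; N = four bases; unsequenced positions = all five states), which
resolves compatible ambiguity implicitly. Top-down resolution is
deterministic: the root takes the first member of its set in the fixed
order A<C<G<T<−, children inherit the parent state when possible. On a
pendant branch an event exists only when the parent state is incompatible
with the leaf's observed symbol, and the recorded target state is that
observed symbol — this is what makes ambiguous events local to the leaves
and incapable of being back-mutations.

Event flags:

- **conserved**: column dominant fraction α > 0.95 (0.99 reported
  alongside). α's denominator excludes gaps and ambiguity codes so it
  reflects true polymorphic variation; a raw-row-count denominator is
  available via `count_all_rows`.
- **back-mutation**: default *path* scope — some earlier event on the
  root-to-branch path at the same column had `from_state` equal to this
  event's `to_state` (the change restores a previously replaced state).
  The stricter root-state-only variant (`scope='root'`) is provided; it is
  never larger than the path-scoped count.
- **ambiguous** / **indel** follow from the event's states.

Statistics: the cross-tabulation of events by
{unambiguous, ungapped, ambiguous} × {conserved, back-mutation, both,
remaining}, whose rows satisfy the inclusion–exclusion identity
`total = conserved + back − both + remaining` (checked at construction);
per-branch counts with an outlier threshold of 50 events per branch
(branches above it have always turned out to be defective leaves or known
deep clade stems — internal-branch outliers are reported in the stats but
not converted to sequence flags); generation points per mutation (grouped
by position, or position + states); the perfect-phylogeny bound
Σ(distinct unambiguous symbols − 1) per column, a hard lower bound on any
tree's parsimony score; and per-leaf / per-character / per-branch rates
(rounded to two decimals only in reports).

## Synthetic data: what it emulates and what it does not

The generator's defaults define the study conditions: a 2000 bp reference
with two control-region parts flanking the origin, six coding genes and
two non-coding spacers (10 units — structurally faithful, at 1/8 scale, to
the 50-unit human partition); a Yule tree (uniform random leaf splits)
with Exp(1) branch lengths; substitutions at Poisson rate 1.5 per unit
branch length under a uniform substitution model; indels at rate 0.15,
codon-sized with probability 0.85 inside genes and 1–4 bp in non-coding
units. These rates give leaf-to-leaf distances of roughly 0.5–2 % of the
genome, matching the high conservation regime the pipeline targets. Leaves
are forced to be pairwise distinct (a recorded extra pendant substitution
repairs chance collisions) so injected duplicates are unambiguous.

With recurrence disabled, no column is touched twice anywhere in the tree,
which makes the true event count equal both the perfect-phylogeny bound
and the Fitch score of the truth — the identity the acceptance checks
exploit. The defect battery (rotations, truncations, N-runs, duplicates,
divergent intruders with 60 extra substitutions, overlong padding,
ambiguity excess) is injected *beyond* the QC thresholds by construction.

What passing these tests shows: the rules, the bookkeeping and the
algorithms are internally correct and the flag logic separates the defect
classes from clean data under realistic conservation levels. What it does
not show: performance under model misspecification (the generator is
uniform-rate, not GTR+Γ; real mtDNA has strong site-rate heterogeneity and
hypervariable control-region positions), heteroplasmy-driven ambiguity
patterns, or the behaviour of the internal aligner on diverged
(interspecies) data — for those, the external ML and alignment adapters
exist.

## Numerical and degenerate-input choices

- Pairwise alignment delegates to a C-backed global aligner with negated
  costs; of co-optimal alignments the aligner's canonical first
  enumeration is used (deterministic for fixed input), followed by the
  gap-placement normalization above. Alignment of empty sequences is an
  error.
- Distance matrices validate symmetry, zero diagonal and non-negativity at
  construction; bootstrap replicates carry no column map (column identity
  is not preserved under resampling).
- Conservation α is NaN (flagged undefined) at zero effective depth;
  summary statistics ignore undefined columns.
- An empty event list yields an all-zero cross-tab and zero rates; rate
  computation with zero leaves or columns is an error rather than a NaN.
- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  fixed seeds give byte-identical FASTA, registries and newick.

## Problem sizes in the standard checks

The bundled verification batteries run at sizes chosen so the whole suite
exercises every path with exhaustive or analytic oracles: Fitch vs full
enumeration on 200 random instances (≤ 6 leaves, ≤ 8 columns, 5-state
alphabet plus ambiguity codes), bound checks on 500 instances, NJ recovery
on 100 random additive matrices (n ≤ 12), split/merge round trips and the
full defect-recovery pipeline on 20 seeded datasets (20 leaves, 2 kb), and
bootstrap calibration at 1000 columns × 40 replicates.
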