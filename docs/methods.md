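# Methods

## Reference model

A heterozygous locus is modelled as a pair of amplicon reference windows of
length `2*flank + 1` (default flank 40 bp) centred on the discriminating
single-nucleotide variant: the *target* allele carries the alternate base,
the *non-target* allele the reference base, and the two sequences are
otherwise identical.  Coordinates are 0-based half-open; cut sites and
insertion positions are inter-base coordinates.  HGVS-style labels are
display-only metadata.

Guides are specified by protospacer, IUPAC PAM pattern, ortholog and strand
and must match the target reference exactly once on the stated strand.  The
blunt Cas9 cut is placed `cut_offset` (default 3) inter-base steps 5′ of
the PAM for all orthologs (SpCas9/SaCas9/SauriCas9/SlugCas9); cleavage
geometry is not ortholog-specific in this model, but the offset is
configurable.  The editing window of `half_width` (default 5) bases on each
side of the cut is read as the half-open 10-base interval
`[cut-5, cut+5)` for substitutions/deletions and the closed inter-base
interval `[cut-5, cut+5]` for insertions — symmetric, unambiguous, and
containing both cut flanks.  Whether the window should instead span 11
bases is genuinely open; `half_width` exposes the choice.

## Alignment and canonicalization

Reads are aligned globally with Gotoh's three-state affine-gap dynamic
programme.  A gap of length L scores `gap_open + (L-1)*gap_extend`;
defaults (+2 match, −3 mismatch, −8 open, −1 extend) prefer one long gap
over scattered mismatches, matching the dominant single-indel outcomes of
Cas9 repair.  End gaps are penalized by default because the indicator
filter guarantees full-span amplicons; a `free_ends` policy is available
for truncated-read experiments.  The traceback is deterministic: at equal
scores diagonal beats deletion beats insertion.

Residual ambiguity (an indel sliding inside a repeat) is removed by
canonicalization: ops are merged (contiguous same-kind runs) and indels are
left-aligned, iterated to a fixed point, because a left-shifted indel can
become mergeable with its left neighbour.  The result is the unique
canonical representative of the edit-equivalence class; tests verify
idempotence and invariance over *all* optimal alignments enumerated by an
independent recursive oracle.

Allele of origin is decided by the higher alignment score; on a tie, the
read base aligned opposite the discriminating position decides, and if that
base is deleted (or matches neither allele) the read is *ambiguous*.
Ambiguous reads stay in the filtered-read denominator, are excluded from
both allele tallies, and are reported separately.  A consequence worth
stating plainly: an indel that deletes the discriminating base is
inherently unassignable from sequence alone.  At the motivating locus the
discriminating T *is* part of the cryptic donor GT, so the clinically
interesting donor-destroying deletions are exactly the ambiguous ones.

## Classification rules

Reads qualify when both indicator sequences — the terminal 15-mers of the
reference window (configurable length, exact or ≤1-mismatch matching) —
occur in order; this enforces the full ±40 bp span that the reference model
assumes.  A minimum-length filter (reference length − 30) guards degenerate
fragments; base qualities are carried but not used.  Samples below 10,000
filtered reads trigger a warning, not an abort.

Within-window ops determine the mutation class (deletion + insertion →
deletion_plus_insertion; deletion; insertion; substitutions only →
base_pair_exchange; none → WT).  Out-of-window substitutions are counted as
sequencing artifacts.  Out-of-window indels are not ruled on by the
artifact convention for substitutions; the package treats reads whose only
ops are out-of-window indels as WT-with-flag, reported in a separate tally
and excluded from edited counts — conservative symmetry with the artifact
rule, fully visible in the output.  The discriminating substitution itself
is never counted as an edit on either allele.

Editing efficiency counts reads in the indel classes; within-window
base-pair exchanges are tallied as their own outcome class but are not part
of the headline indel frequency.  Both denominators are always reported:
out of all filtered alleles and within the target allele.  Under the
diploid, uni-allelic-target assumption the all-allele efficiency doubles to
an implied edited-cell fraction, capped at 100%.

## Spectra and comparisons

The indel spectrum maps canonical variant keys
(`kind|offset|ref_len|alt`, offsets relative to the cut) of edited
target-allele reads to counts and percentages; panels are emitted both as
percent of filtered reads and percent of edited reads because either
denominator is defensible.  Spectrum comparisons report Pearson *r* over
the union of keys (missing = 0) and total variation distance
`0.5 * Σ|a-b| / 100`; neither statistic is canonical for this problem —
they were chosen for interpretability and are both reported.  Predicted
profiles (two-column TSV, `del{n}@{offset}` / `ins{bases}@{offset}`
descriptors, inDelphi-style) are renormalized to 100% and left-normalized
onto the same key space before comparison.

## Splice impact

The splice comparator needs only a monotone donor-site score.  The package
does not reimplement deep-learning splice predictors; it accepts externally
computed scores keyed by variant, and ships a PWM log-odds donor scorer as
the desk-scale stand-in: weights
`log2(((count + 0.5) / (N + 2)) / background)` over the 9 boundary
positions −3..+6, trained on donor-site sequences (a synthetic training-set
generator draws sites from an idealized human U2 donor base-frequency
table).  For each spectrum variant the post-edit target sequence is
reconstructed and the best motif score in a search interval around the
cryptic site is taken.  Categories: *disrupting* if the score falls below
the wild-type allele's best score (strict by default; margin configurable),
*enhancing* if it reaches the pathological allele's score, *neutral*
otherwise.  Acceptor-site scoring uses the same machinery with a second PWM
and is disabled by default.

## Prevalence aggregation

Frequencies from three population datasets are parsed as decimals
(decimal-comma input is normalized), "not detected" counts as 0 in the
mean, and rows undetected in all three datasets keep a missing mean rather
than 0 — preserving the published table's own distinction.  Means are
rounded half-up to 8 decimal places, the print precision of the source
table, and reproduce every bundled row exactly.  Ranking is by descending
mean, missing last, ties by label.

## Synthetic data and what passing tests show

The generator draws, per read: allele (Bernoulli, default share 0.5 —
slightly more than half of real alleles were maternal, so 0.5 is the
neutral choice), edited status on the target allele (default rate 0.3, the
upper end of the reported 21–30% range), a variant from the spectrum
(default del9 0.49 / insA 0.27 / insT 0.12 / del2 0.12, mirroring the
dominant reported outcomes), and independent per-base substitution errors
(default 1e-3, constant Q30).  Output is deterministic per seed.

The bundled synthetic locus is an 81-nt window whose C>T centre base
creates a near-consensus donor site (CAG|GTAAGT).  Guide A cuts immediately
3′ of the variant — the published geometry, where del9 removes the entire
donor motif; it is used for splice-impact demonstrations, since its
deletions span the discriminating base and are allele-ambiguous by
construction.  Guide B cuts 5 bp downstream and is the simulator default,
so every default spectrum variant leaves the discriminating base intact and
allele-resolved parameter recovery is testable end to end.

What the simulation does *not* model: PCR amplification bias, paired-end
structure and merging errors, platform-specific error profiles, indel
sequencing errors (off by default; an optional rate exercises the
off-window-indel rule), and chimeric reads.  Passing recovery tests
therefore demonstrate correctness of the classification logic under the
stated error model, not robustness to every real-world artifact.

## Problem sizes and numerical choices

Recovery tests use 10–21 simulated samples of 20,000 reads; alignment
oracle checks use 10,000 random pairs up to length 12 plus an independent
biopython cross-check; the PWM is trained on 500 synthetic sites.  The DP
fill runs under numba; per-sample alignment results are memoized by read
sequence, which deep amplicon data makes very effective.  Spectrum
probabilities must sum to 1 within 1e-9; comparisons of degenerate
(constant) spectra define r = 1 for identical and 0 otherwise rather than
propagating an undefined correlation.

## Known limitations

* Equivalence with the web tools used in the original analyses
  (Cas-analyzer, inDelphi, SpliceAI) is not claimed; their parameters or
  models are not public or not reimplemented, by design.
* Reads whose edits delete the discriminating base cannot be assigned an
  allele from sequence alone; downstream efficiency estimates for guides
  cutting directly at the SNV must account for the reported ambiguous
  fraction.
* The PWM donor model is position-independent and desk-scale; it orders
  motif-destroying edits correctly but its absolute scores are not
  calibrated probabilities.
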