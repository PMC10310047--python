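# Methods

## Pipeline model

`tagsieve` assumes each MS/MS spectrum yields up to five candidate sequence
tags — a run of 4 residues read from the fragmentation ladder, flanked by an
N-terminal and a C-terminal mass gap.  A gap is modelled as the plain sum of
monoisotopic residue masses of the unsequenced flank *within the peptide*:
no water or proton terms, with terminal-group offsets exposed as
configurable constants defaulting to 0.  This residue-sum convention is used
consistently by the matcher and the simulator, which share one pinned
monoisotopic mass table (printed below).  Tags cannot distinguish isoleucine
from leucine (isobaric residues), so sequences are canonicalized I→L for
identity and matching; gap masses are rounded to 4 decimal places for tag
identity only, with full precision retained for matching.  Charge handling
is assumed to have happened upstream in the de novo engine: gap masses in
the input table are neutral quantities.

Matching proceeds per canonical tag: exact k-mer lookup of the tag sequence,
then a depth-first extension of each flank one residue at a time.  Fixed
modifications apply unconditionally (default: carbamidomethyl C,
+57.02146 Da); variable modifications branch per instance (default:
oxidation M +15.99491 Da; acetylation +42.01057 Da admissible only when the
leftward extension reaches protein residue 0, including an empty flank at
the N-terminus).  A branch is pruned as soon as its accumulated mass exceeds
gap + tolerance — valid because residue and modification masses are
positive, so flank mass is monotone in extension length; this also
guarantees termination.  Branches that meet a residue without a defined
monoisotopic mass (B, Z, X, U, O) are abandoned rather than guessed at.
A peptide is reported once per (protein, start, end) even when several
modification assignments satisfy the gaps; spectral counting needs peptide
identity, not a modification enumeration.

Both gaps share a single tolerance parameter (default 0.02 Da — the
benchmark configuration sets fragment and precursor tolerance to the same
value, and the two flanks are not treated differently).  Candidate peptides
must be fully tryptic under the rule "cleavage after all K or R" (no proline
suppression — the rule is applied as glossed, not as the conventional
Trypsin/P exclusion), with at most 2 internal missed cleavages.  Fully
specific termini are enforced; semi-tryptic matching is out of scope.

## Ranking and filtering

Spectral counts per protein and sample are turned into SAF (count/length),
NSAF (per-sample normalization to 1), summed NSAF across samples, and a
protein marginal probability (share of total summed NSAF).  The greedy
filter walks the ranked list accumulating the set of spectra seen above;
a protein is retained iff it contributes an unseen spectrum.  Two
equivalent predecessor semantics exist ("all proteins above" vs "retained
proteins above"); they provably coincide — a protein rejected earlier
contributed no new spectra, so the seen sets agree — and the test suite
checks the equivalence on randomized instances as an implementation
self-check.

Ties in the sort key are broken by descending summed NSAF, then ascending
sequence length, then ascending accession, making runs reproducible and
guaranteeing that exact-duplicate isoforms collapse to the shortest member.
Organism probabilities for the second pass come exclusively from the pass-1
retained set; proteins of organisms absent there carry a joint probability
of 0 but remain in the pass-2 list (sorting last), so a protein that alone
explains a spectrum is always retained and spectrum coverage is preserved.
Pass 2 reuses the pass-1 protein marginals — only the organism term is new.
The "maximum value of 1" property of the protein marginal is an assertion,
not a clamp: under the stated normalization the value cannot exceed 1.
Samples with zero mapped spectra contribute zero NSAF rather than failing.

Chunked and threaded execution partitions the tag set and merges per-chunk
spectral counts by set union; since the computation per tag is independent
and the merge is commutative, the output is a pure function of (database,
tag set, parameters), which the suite verifies byte-for-byte on the emitted
FASTA and report.

## Taxonomic benchmarking

The benchmark layer consumes an externally produced peptide→taxon
lowest-common-ancestor table (computing LCAs is out of scope).  Spurious
taxa are removed by a stringency filter retaining taxa strictly above 0.5%
of characterised counts, applied separately per taxonomic level; the
pre-filter total is preserved so downstream percentages stay relative to
all characterised counts including misassignments.  The mean-squared-error
score averages squared deviations of observed from expected percentages
over the *expected* taxa only; unexpected mass is penalized implicitly
through the all-inclusive denominator.  Misassignment rates count taxa
outside the expected set, with an explicit whitelist argument for post-hoc
plausible taxa, and an explicit relabelling mapping (applied before
aggregation) for merging congeneric assignments.

## Synthetic data

The generator emulates the pipeline's inputs with known ground truth.
Proteins are concatenations of tryptic segments (≥ tag length + 1 non-K/R
residues followed by K or R), guaranteeing at least three fully tryptic
peptides long enough to carry a tag window; sequences are otherwise uniform
over the 20 standard residues, so homology between proteins is accidental
only.  Defaults model the benchmark community: 5 organisms ×
20 proteins of 120–400 residues (a typical bacterial protein-length range),
Dirichlet(1) abundance fractions, 2000 spectra split over 2 samples, 5 tags
of length 4 per spectrum, Gaussian gap noise with sd 0.005 Da (comfortably
inside the 0.02 Da tolerance: 3·sd < tolerance), a 20% decoy-tag fraction,
10000 distractor proteins from never-sampled organisms, and 5 isoform pairs
(a duplicated protein with one appended residue) to exercise the
shortest-sequence collapse.  Decoy tags are uniform random 4-mers with gap
masses uniform on [0, 500] Da — the scale of a 1–4 residue flank — filling
every non-rank-1 tag slot and, with the decoy fraction, rank 1 as well.
Tag letters are never corrupted: the noise model deliberately isolates the
matcher's mass-tolerance logic, so passing recovery tests demonstrates
correct gap arithmetic and ranking, not robustness to sequencing errors,
real homology structure, or engine-specific tag quality.

`evaluate_recovery` scores a finished run: protein recall over the
accessions actually sampled by spectra (an isoform twin counts as a hit for
its partner), precision of the retained set, database reduction factor,
Spearman rank correlation between true and estimated organism fractions,
and coverage of the non-decoy spectra by the retained set.

## Numerical and design choices

* Randomness: all synthetic artifacts derive from `numpy.random.default_rng`
  seeded with `[seed, stream]`, so database generation and tag simulation
  are independently reproducible bit-for-bit.
* Tolerance comparisons are inclusive (`|Δm| ≤ tol`).  Flank masses are
  accumulated incrementally; the cross-checking oracle in the test suite
  recomputes them with compensated summation, and agreement at the 0.02 Da
  scale is unaffected by the ~1e-13 Da representation differences.
* Duplicate FASTA accessions are both kept (UniProt concatenations can
  collide); the second copy is keyed with an ordinal suffix.  Output FASTA
  wraps at 60 columns with LF endings.
* Organism parsing follows the UniProt `OS=…` convention terminated by the
  next ` XX=` key; any header without it (e.g. metagenome ORF databases)
  falls into an `"unknown"` bucket, which participates in ranking like any
  other organism.
* The spec-level operation surface is kept, with small signature
  extensions where a lookup was otherwise unavailable: organism aggregation
  and joint ranking take an accession→organism mapping, and recovery
  scoring takes the organism profile and spectral counts it scores.
* Problem sizes in the test suite: the matcher is validated against an
  exhaustive brute-force oracle on 200 random databases of ≤ 20 proteins ×
  ≤ 60 residues (exhaustive enumeration is only tractable at this scale);
  filter properties run on 500 random instances; recovery runs use the full
  default conditions above.

## Pinned monoisotopic residue masses (Da)

G 57.02146, A 71.03711, S 87.03203, P 97.05276, V 99.06841, T 101.04768,
C 103.00919, L/I 113.08406, N 114.04293, D 115.02694, Q 128.05858,
K 128.09496, E 129.04259, M 131.04049, H 137.05891, F 147.06841,
R 156.10111, Y 163.06333, W 186.07931.

## Known limitations

* No spectrum-level simulation (peaks, charge states, intensities) and no
  tag-letter error model; DirecTag-style engines are consumed conceptually
  through the tag table, never executed.
* No semi-tryptic or non-specific digestion; no proline-suppressed trypsin
  variant.
* No FDR estimation or decoy generation — the output database is the input
  to a downstream target-decoy search, not a replacement for one.
* Organism recovery depends on UniProt-style headers; arbitrary headers
  degrade gracefully to a single `"unknown"` organism, which weakens the
  second-pass re-ranking.
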