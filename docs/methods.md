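# Methods

## Evaluation model

The package evaluates a per-substitution pathogenicity score s ∈ [0, 1]
against binary clinical labels.  Scores are banded three ways with cutoffs
b = 0.340 and p = 0.564:

* likely benign: s < b
* ambiguous: b ≤ s < p
* likely pathogenic: s ≥ p

The boundary conventions (lower cutoff inclusive into the ambiguous band,
upper cutoff inclusive into the pathogenic band) are fixed by the published
per-variant calls the package reproduces: a pathogenic-labeled variant
scored 0.5637 counts as an ambiguous mis-call, and the pathogenic color
band of the reference visualization starts at 0.564.  Both cutoffs are
configurable (`ThresholdScheme`).

Against binary labels the three-way call is reduced to a 2×2 confusion
table under one of two policies.  The default, `ambiguous_as_error`, counts
an ambiguous call as an error of the labeled class (FN on pathogenic, FP on
benign); it is the convention that reproduces the reference worked-example
row (TPR = 98/102 = 0.961 requires the ambiguous calls in the denominator).
`ambiguous_excluded` removes ambiguous calls before counting and reports
them separately, matching the alternative convention used for
prediction-distribution summaries.

Metrics are the standard point estimates: PPV, TPR, their harmonic mean F1,
MCC, and a rank-based aucROC (midrank tie handling, pathogenic positive,
equivalent to the Mann–Whitney statistic).  Any metric whose denominator
vanishes is reported as 0 and flagged `degenerate` rather than raised:
sparse subsets (tiny region sets, single-class joins) must not abort a
batch run.  aucROC on a single-class join is likewise flagged, but calling
`auc_roc` directly on single-class input is an error, since the quantity is
undefined.

## Restrictions and frequencies

Filters apply in the fixed order protein set → region → confidence, so
report rows are comparable across configurations.  Region membership is
residue-level and boundary-inclusive; accessions with no region annotation
of the requested type are excluded from both the inside and the outside
subset (they belong to neither), mirroring how transmembrane-annotated and
soluble protein sets are kept disjoint in practice.  The confidence filter
drops residues with pLDDT strictly below the cutoff (default 50, the usual
intrinsic-disorder proxy); residues without confidence data are dropped and
counted.

Mutation frequencies divide variant counts by the summed length of the
proteins in the evaluated set — the same accessions `n_protein` counts,
i.e. those contributing at least one joined variant.  Clinical (CV)
frequencies count labeled variants per side; predicted (AM) frequencies
count three-way classes, with ambiguous predictions contributing to
neither side, optionally restricted to SNV-reachable substitutions.

## Genetic-code reachability

A substitution ref→alt is SNV-reachable when some sense codon of ref has a
single-nucleotide sense neighbour coding alt (standard code, stops
excluded).  This generic per-pair mode — rather than a per-genome-position
mode — is the default because the package consumes protein-keyed tables
without genomic coordinates; a codon-specific helper
(`reachable_from_codon`) exists for when the actual coding sequence is
known, and the synthetic generator uses it.  Reachability is symmetric
(single-nucleotide changes are reversible) and covers 150 of the 380
ordered pairs.

## Substitution-matrix analytics

Cell (ref, alt) of the 20×20 matrix is the unweighted arithmetic mean over
matching records — each substitution instance counts once, with no
per-protein reweighting.  Asymmetric pairs are unordered pairs with
|mean(a→b) − mean(b→a)| ≥ 0.2 (inclusive), reported once each with the
higher-mean direction as "forward" so output is independent of input
orientation.  Label flips require likely-pathogenic one way and
likely-benign the reverse; an ambiguous side is not a flip.  The BLOSUM62
fit regresses the per-*ordered*-pair means on the symmetric BLOSUM62 value
of the unordered pair (both directions enter as separate points); Pearson r
with the usual two-sided t-test p-value and an OLS line.  BLOSUM62 comes
from Biopython's substitution-matrix collection.

## Structure annotation

Per-residue profiles average record scores per position in two modes: `snv`
(SNV-reachable substitutions only) and `all`.  Region means average the
per-residue means, not the raw records — the two differ when per-residue
coverage is uneven, and the two-stage definition matches how per-residue
summaries are built first and then aggregated.

Annotation rewrites only the fixed-width occupancy (columns 55–60) and
B-factor (columns 61–66) fields of ATOM/HETATM records, format `%6.2f`;
every other byte is preserved, so the operation is idempotent and
coordinates round-trip exactly.  Two layouts: `snv_both` (SNV mean in both
fields) and the default `qb` (B-factor = SNV mean, occupancy =
all-substitution mean).  Residues absent from the profile are written as
0.00 (counted and logged) rather than left untouched, so downstream
coloring is deterministic.  Only single-model, single-chain files are
accepted, the monomer-model convention.  The rewrite is done by direct
column editing precisely because the byte-preservation contract forbids a
parse/serialize round trip; tests confirm the output still parses with a
standard reader.

## Synthetic cohorts

The generator emulates the five pipeline inputs.  Its statistical model: a
fraction φ of residues is functionally critical (default 0.3, consistent
with the observed ≈30–35 % pathogenic share among all possible missense
substitutions); substitutions at critical residues draw scores from a
pathogenic distribution, others from a benign one.  Score coverage per
residue is exactly the SNV-reachable alternatives of a codon sampled
uniformly from the residue's codons (`all` mode: all 19).  Clinical labels
equal ground truth with probability κ (default 0.9) and are star-rated from
a 0–4 distribution centred on 1–2 stars.  Default score model is a Beta
mixture, Beta(2, 8) benign vs Beta(8, 2) pathogenic — bounded support like
real scores, overlapping enough that default-cohort metrics land in the
realistic 0.6–0.9 range.  A truncated-Gaussian model exists because it has
the closed-form AUC oracle Φ((μ_p−μ_b)/√(σ_b²+σ_p²)); at the recovery
settings (μ 0.2/0.8, σ 0.15) truncation to [0, 1] perturbs the true AUC by
≈10⁻³, negligible against the Monte-Carlo standard error at the cohort
sizes used (≈2 500 joined variants, ~3 000–9 000 residues across 30
proteins — sizes chosen to make the standard error small while the whole
suite stays fast).  Transmembrane-like segments (19–23 residues, spaced
40–90 apart) are emitted for half the proteins; low-confidence stretches
(pLDDT ~ U(20, 49), lengths 10–40, ≈15 % of residues; U(60, 95) elsewhere)
feed the confidence filter; toy CA-trace helix structures carry the pLDDT
in their B-factor column.  All randomness flows from one explicit seed
through a single generator — no global state — so bundles are
byte-reproducible.

What passing tests on synthetic data do *not* show: the generator makes no
attempt at real mutational spectra, codon-usage bias, ascertainment bias of
clinical databases, or correlated scores along the sequence; recovery
results validate the pipeline's arithmetic, not any predictor's real-world
accuracy.  Whole-dataset published quantities (full benchmark rows, the
BLOSUM62 correlation of r = −0.678, real region means) require the external
score and clinical downloads; the readers accept those files, but no test
depends on them.

## Numerical and degenerate-input choices

* MCC is computed in floating point with the product of marginals under one
  square root; counts up to ~10⁷ are exact in doubles.
* Duplicate clinical rows (same accession, position, ref, alt) keep the
  highest star count; every dropped or deduplicated row is counted in the
  read report.
* Review-status → star mapping ships as an overridable table (practice
  guideline = 4, expert panel = 3, multiple submitters without conflicts =
  2, single submitter or conflicting = 1, no assertion = 0); "likely"
  clinical calls merge into the binary labels by default, overridable via
  `label_map`.
* Reports format metrics and frequencies at 3 decimals, making reruns on
  identical inputs byte-identical.
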