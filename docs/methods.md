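# Methods

`strainprot` implements a strain-resolved metaproteomics analysis for
communities of binned metagenome-assembled genomes: it consumes predicted
proteomes, an identified-peptide (PSM) table and per-contig read counts, and
produces peptide-uniqueness-aware protein detection, community composition
by reads and by peptides, their divergence, pathway
expression-over-potential ratios and two-strain comparative profiles. This
note documents the model, the parameter choices, the synthetic world used
for testing, and the numerical decisions.

## Digestion and canonicalization

Trypsin specificity is the standard "cleave after K/R, not before P" rule.
Peptides are emitted for 0..`max_missed_cleavages` internal missed sites and
then length-filtered; defaults are 2 missed cleavages and 6–50 residues, the
common identifiable range for LC-MS/MS search engines. These are decisions,
not reconstructions of any particular search: they are configurable and
logged per run. The protein N-terminal methionine is not optionally removed
(simplicity; a future toggle).

Isoleucine and leucine are isobaric and indistinguishable by standard MS/MS,
so all peptide comparisons operate on canonical sequences with I mapped to L
(`collapse_IL`, on by default). Uniqueness — in particular any claim that a
peptide discriminates one strain from another — is therefore never based on
an I/L difference. The canonical symbol is L; the map is idempotent.

## Peptide uniqueness and PSM assignment

Every canonical peptide of the digested database is assigned its full parent
sets (genes, organisms) and one of four classes: `protein_unique` (one
gene), `organism_unique` (one organism, several genes),
`shared_within_strain_pair` (parents span exactly the two members of a
declared strain pair), `shared_across_organisms` (anything broader). Strain
pairs are declared in configuration, not auto-detected — in practice the
pair is known a priori from genome curation.

PSMs are assigned by exact canonical lookup. Shared peptides keep their full
parent sets; no razor/parsimony winner-takes-all is applied, so downstream
quantification can choose its policy (below). Unmatched peptides are
reported per sample and excluded from quantification; spectral counts are
conserved exactly between the assigned and unmatched partitions.

## Detection, QC and composition

A protein is *detected* in a sample when its protein-unique spectral count
reaches `detection_min` (default 1 — deliberately permissive, matching
summary tables that report single-sample detections). Samples whose total
organism-unique spectral count falls strictly below `qc_min_unique_spectra`
(default 500) are excluded from composition and ratio outputs but still
reported; the default separates a failed extraction (a few hundred unique
spectra) from informative deep samples (thousands).

Peptide-based composition is NSAF-style: per-gene counts are divided by
protein length (longer proteins yield more peptides), summed per organism,
divided by the organism's protein count (a proteome-size correction), and
closed per sample. The normalization order — length first, protein count
second, closure last — is fixed and logged.

Shared-peptide policy (`share_mode`):

- `unique` (default): protein-unique counts only. Faithful to
  "unique-peptide" reporting, but structurally biased against a
  near-identical strain pair: at 99% amino-acid identity roughly 90% of a
  strain's tryptic peptides are shared with its partner and are discarded,
  so the pair's activity is underestimated several-fold. This is a property
  of unique-only counting itself, not of this implementation.
- `fractional`: shared counts split equally among parent genes. Unbiased
  only when the strains are equally active.
- `proportional`: shared counts split among parent organisms in proportion
  to each organism's organism-unique signal in that sample (standard
  distributed spectral counting), then equally among that organism's parent
  genes. In expectation this recovers organism-level activity exactly when
  unique signal is informative, and it is the mode the recovery analyses
  use. With no unique signal at all it degrades to the equal split.

Read-based composition divides per-organism summed contig counts by genome
length (bp) before closure, converting DNA share into a cell-fraction
estimate; genome-length normalization is on by default and toggleable.
Genome length is taken from the gene map as the per-contig maximum gene end,
a lower bound that is exact for the simulator's contigs.

The divergence table reports `log2(peptide_fraction / read_fraction)` per
(sample, organism), finite only when both fractions are positive; cells with
|ratio| > 0.5 carry a `discordant` flag, which is a reporting convenience
with no inferential claim.

## Pathway ratios

A "feature" is a gene; lists are inputs (curated gene-id sets), never
derived from ontologies here. The potential matrix counts list genes per
organism (zeros kept). The expression-over-potential ratio is the
non-redundant count of an organism's list genes detected in a sample,
divided by the organism's list-gene count; cells with zero potential are
omitted. A pooled-across-samples variant (detected in any kept sample) is
available and labelled `pooled`.

## Strain comparison

Ortholog pairing is bidirectional best match under global alignment
identity. Scoring is identity-based (match 1, mismatch 0, linear gap −1) —
at ~99% identity the substitution matrix is immaterial. Identity is
identical columns over aligned (both non-gap) columns; a pair must reach
`min_identity` (default 0.8) with the alignment covering `min_coverage`
(default 0.8) of the shorter protein. Candidates are pre-screened by shared
8-mers (top 5 per gene by shared-count): true orthologs at strain-level
divergence share hundreds of 8-mers while unrelated random proteins
essentially never collide, so the screen only removes hopeless alignments.
Unpaired genes form the strain-unique sets; ties in identity break on
partner id so pairing is deterministic and symmetric.

Contig profiles are dense per-gene tracks (unique spectral count / protein
length, ordered by contig and start, strain-unique genes flagged), using
protein-unique counts only so shared-between-strain signal never inflates
either strain's track.

## The synthetic world

The generator emulates the structure of a preterm-infant gut colonization
community at desk scale: 4 organism bins of 150–250 genes each (gene
lengths log-normal, median 300 aa, σ = 0.35), of which two are a strain
pair — the partner proteome is the base with i.i.d. substitutions at rate
ρ (default 0.01 per site, hard cap 0.2 beyond which "strain" is a
misnomer) plus ~5% entirely novel strain-unique genes per strain (novel
sequences guarantee no accidental homology). Residue frequencies are
uniform over the 20 amino acids, so K+R jointly occur at 0.1 and tryptic
peptides average ~10 residues. 6 samples, 10^5 reads and 2×10^4 PSMs per
sample mirror a deep spectral-counting study at reduced scale.

Truth vectors are defined *on the scale the estimators estimate*:

- `abundance_truth` is the cell-fraction simplex; reads are drawn per
  contig ∝ abundance × contig length (cells × genome size), so the
  genome-length-normalized read composition is unbiased for it.
- `activity_truth` is the simplex the NSAF-style peptide composition
  estimates; spectra are drawn per gene ∝ activity × weight × protein
  length (per-gene weights log-normal, σ = 0.5; ortholog partners share
  their base gene's weight), then uniformly over the gene's tryptic
  peptides of 7–30 residues (a hard detectability window — the simplest
  mechanism producing realistic shared/unique peptide mixtures).

Defining truth on the estimator's scale is what makes recovery tests
meaningful: any residual error is sampling noise plus estimator defects,
not a units mismatch. Mean abundance/activity profiles are fixed (one
read-dominant organism with middling activity; a strain pair with similar,
high activity) and per-sample vectors are Dirichlet-jittered around them
(concentration 150). The strains' similar mean activities reflect the
coexisting-strain scenario under study; they also keep the proportional
split's residual blending error well inside noise.

All randomness derives from a single seed (child streams for database,
reads, PSMs); identical parameters give byte-identical outputs.

What the generator does **not** emulate: chimeric or misidentified spectra,
post-translational modifications, retention-time effects, protein-level FDR,
sequencing error, uneven coverage within genomes. A green recovery test
therefore establishes correctness of the bookkeeping and the normalization
chain under ideal identification, not robustness to search-engine noise.

## Known limitations

- Unique-only quantification (the default, faithful to unique-peptide
  reporting) underestimates near-identical strains; use `proportional` when
  organism-level activity is the target.
- Ortholog pairing is a stand-in for manual strain curation; at identities
  far below 99% the identity-scored alignment and the BBH heuristic would
  need a proper substitution matrix and synteny support.
- Nucleotide-level identity is out of scope (amino-acid only).
- The pipeline consumes identified peptides and mapped read counts; search
  and alignment quality are upstream concerns it cannot repair.
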