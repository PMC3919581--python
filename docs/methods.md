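# Methods

## Model

The unit of inference is a *binding site*: a set of residues of a
reference protein annotated, via solved protein–ligand structures, as
contacting a ligand of one category (NUC = nucleic acid, PEP =
peptide, SMI = small molecule or ion). The question asked of each site
is whether the missense mutations observed for that protein across
patient samples concentrate in the site more than expected if they
were placed at random over the residues for which structural
information exists.

### Coordinate mapping and reference sequences

Mutations arrive in genomic coordinates (1-based, top strand, MAF
convention). For each isoform, the spliced CDS is assembled from its
segments (reverse-complemented for minus-strand genes), the mutated
codon is translated before and after the substitution, and the variant
class is derived from the amino-acid pair: synonymous iff the residues
are equal, "other" (and excluded downstream) if a stop codon is
created or lost. A record whose stated reference allele disagrees with
the genome is an error, never silently re-complemented — this
deliberately surfaces strand bookkeeping mistakes in the inputs.

Per gene, one isoform is selected as the reference sequence: the one
mapping the largest number of **distinct mutated protein positions**
(events at the same position count once; missense and synonymous are
pooled), with ties broken by assembly order. Selection pools all
cohorts, so one gene has one reference sequence everywhere; a
per-cohort selection would make per-cohort results incomparable across
cohorts of the same gene.

### Annotation transfer

Homology hits between reference sequences and structure chains are
consumed from files (tabular hits + aligned-FASTA pairs) rather than
computed internally; identity and coverage are recomputed from each
alignment on load so the filters cannot be gamed by stale columns.
The acceptance filter is the strict triple: E-value < 1e-6, identity
> 0.60 over aligned columns, coverage > 0.80 of the chain length.
A binding annotation is transferred only when the identity restricted
to its binding residues is strictly > 0.90; a binding residue aligned
to a gap counts as a mismatch (and cannot map). Transferred sites of
the same ligand category on one reference sequence are merged by
transitive overlap (union–find); cross-category overlaps are kept as
separate sites so the per-category breakdown survives merging.

### Binding scores

Residue weight b_i is the fraction of the residue's heavy atoms within
4.0 Å (inclusive, Euclidean) of any ligand atom, averaged over the
accepted structures that both cover the position in their alignment
and resolve the residue in their coordinates; unresolved residues are
excluded from the average, not zero-filled. Annotated binding residues
with no atom in range keep b_i = 0 and stay in the site: the contact
fraction is a weight on the annotation, not a redefinition of it.
Hydrogens are dropped on input and only the highest-occupancy altloc
is kept, making the score deterministic.

### Site test

Observed score: s_b = Σ over site residues of b_i × (number of
distinct samples with a missense mutation at that residue). The null
redistributes the sequence's m missense events — counted with sample
multiplicity over its structurally covered positions — uniformly with
replacement over those positions, summing b over drawn positions
(zero off-site). Defaults: R = 100 000 replicates; p = #{replicate
score ≥ observed}/R. Ties count toward the tail (conservative; the
degenerate all-binding sequence then gets p = 1 exactly) and a zero
count is floored at 1/R so p ∈ (0, 1] and Benjamini–Hochberg is
well-defined. Both conventions are switchable
(`tie_convention`, `m_mode`) and recorded in the output provenance
header. Note one asymmetry, kept deliberately: the observed score
collapses repeated mutations of one residue in the same sample, while
replicates count every drawn event; with realistic per-sample mutation
loads the effect is negligible and conservative.

Per-site RNG streams are derived from (master seed, reference id, site
id), so results are independent of the order in which sites are
tested and reproducible across runs.

When all b_i in a site are equal and off-site weights are zero, the
null score is b times a binomial count with success probability
|site| / |structural positions| — a useful analytic limit that the
test suite checks.

### Cohort-level tests

For a variant class, positions are counted once regardless of
recurrence: N structural positions, K binding positions, n positions
hit, k binding positions hit, pooled over all reference sequences.
The exact hypergeometric upper tail P(X ≥ k) is used for cancer
missense (enrichment), the lower tail P(X ≤ k) for population SNPs
(avoidance). Category-specific runs restrict K and k to one ligand
category while keeping N and n global. The frequency-aware companion
is a binomial upper tail on event counts with success probability
q = K/N; it is not applied to SNPs, whose observation counts are not
available. The known-cancer-gene enrichment curve selects, at each
p-value threshold, genes with ≥ 1 site at p ≤ threshold and reports
(CCG fraction among selected) / (CCG fraction in the background of
mutated binding sites). The background is counted in sites by default
(`background_unit="sites"`), matching how the published selection
counts combine gene-level selection with a site-level background;
gene-level counting is available.

## Synthetic cohorts

The generator emulates the statistical structure of a tumor-cohort
study: multi-exon genes on both strands with two isoforms (the shorter
one a single-exon truncation, so isoform selection has real work to
do), one ligand-bound structure per gene covering 80–100% of the
protein, planted binding sites with prescribed per-residue contact
fractions, a missense track in which each event targets a uniformly
chosen binding residue of a designated driver gene with probability
`enrichment_effect` (else a uniform coding position), a uniform
synonymous track, and a SNP track biased away from binding residues.
Decoy homology hits at ~55% identity exercise the filters.

Geometry is schematic by design: residues sit 20 Å apart with heavy
atoms spaced 8 Å, and ligand atoms are placed 3 Å from exactly the
atoms meant to be in contact, so every planted b_i is exact and the
annotation stage can be validated against the manifest to machine
precision. What the generator does **not** emulate: trinucleotide
mutational signatures, copy-number events, germline contamination,
alignment errors, non-exact homology (chains are exact subsequences),
or realistic protein geometry. Passing tests therefore demonstrate the
correctness of the bookkeeping and statistics, not robustness to noisy
homology or biased mutation processes in real data.

Default study conditions (one choice, used throughout): 20 genes of
60–100 residues, 3 driver genes, enrichment effect 0.8, one cohort of
100 samples, 0.5 missense and 0.15 synonymous events per coding
residue, 0.15 SNPs per residue with 0.8 off-site bias. The event rates
describe a deliberately dense toy cohort so that every binding site
receives mutations and null p-values are informative; they are much
higher per-gene than a real exome cohort, which matters for power
calibration only, not for correctness.

## Problem sizes used in validation

Null calibration uses 125 genes × 4 disjoint sites = 500 sites with
`enrichment_effect = 0` and R = 2000 (p-value granularity 5·10⁻⁴ is
ample for a Kolmogorov–Smirnov uniformity check; note that empirical
p-values of a discrete, conservative test carry a small atom at 1 from
sites with no observed hit). Planted-signal recovery runs 20 generator
seeds at R = 20 000. Exact-oracle agreement for the permutation engine
enumerates all draws on instances with ≤ 6 structural positions and
m ≤ 4 at R = 100 000; hypergeometric and binomial tails are checked
against brute-force enumeration for all instances up to population
size 12.

## Numerical and design notes

- Replicate scores are compared to the observed score with a 1e-9
  absolute tolerance so floating-point addition order cannot flip a
  tie.
- The 4.0 Å contact threshold is inclusive (≤); boundary atoms count.
- BH FDR is delegated to statsmodels (`fdr_bh`) behind a validating
  wrapper; hypergeometric and binomial tails are scipy's exact
  distributions.
- Chains are renumbered 1..L on load (insertion codes and author
  numbering do not leak into binding-residue indices); peptide and
  nucleic-acid ligands may be named as whole chains (`chain:X`) in the
  binding TSV, small molecules by HETATM residue name.
- Output TSVs have deterministic row order and carry a provenance
  header (version, seed, hash of the scientific parameters only, so
  identical analyses are byte-identical regardless of file paths).
- Stage composition is exact: running the subcommands in sequence
  writes byte-identical files to the monolithic `run`.

## Known limitations

- Only single-nucleotide missense/synonymous variants are interpreted;
  indels, splice-site, nonsense and non-coding variants are recorded
  as unmapped or excluded.
- Protein–protein interfaces are out of scope (interfaces routinely
  cover large fractions of a protein surface, which would dilute the
  site-level signal the method is built to detect).
- No covariate-adjusted background mutation model: the null is uniform
  over structurally covered positions of the same protein, so
  gene-level mutation-rate covariates (expression, replication timing)
  cancel, but within-protein rate heterogeneity does not.
- Overlapping genes are resolved by assigning a mutation to the
  lexicographically first gene whose CDS contains it.
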