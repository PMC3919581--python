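# mutbind

Interaction-aware prioritisation of cancer genes: find proteins whose
**ligand-binding sites** carry more somatic missense mutations across
patient samples than chance allows.

Most somatic mutations observed in tumor exomes are passengers. A gene
can matter for tumorigenesis even when it is rarely mutated overall —
if the few mutations it does carry cluster in the residues the protein
uses to bind DNA/RNA, peptides, small molecules or ions. `mutbind`
implements a complete pipeline for this idea, aimed at computational
cancer-genomics and structural-bioinformatics researchers:

1. **map** — somatic mutations (MAF-like TSV, genomic coordinates) are
   placed into transcript models, translated, and assigned protein
   coordinates; per gene, the isoform that maps the largest number of
   distinct mutated positions becomes the *reference sequence* (ties go
   to the first isoform in the assembly).
2. **annotate** — binding annotations from ligand-bound structures
   (BioLip-style TSV + PDB coordinate files) are transferred to each
   reference sequence through precomputed homology hits that pass
   E-value < 1e-6, sequence identity > 60% and structure coverage
   > 80%; a site is transferred only when > 90% of its binding residues
   align to identical amino acids. Overlapping sites of one ligand
   category are merged. Each binding residue *i* gets a weight

       b_i = mean over structures j of |Ã_ij| / |A_ij|

   where A_ij are the residue's heavy atoms in structure j and Ã_ij
   those within 4.0 Å of any ligand atom.
3. **site-test** — each binding site is scored
   `s_b = Σ_i b_i · (#samples with a missense mutation at residue i)`
   and compared with a resampling null: the sequence's m missense
   events at structurally covered positions are redistributed uniformly
   (with replacement, 100 000 replicates by default); empirical
   p-values are converted to FDRs by Benjamini–Hochberg within each
   cohort run.
4. **cohort-test** — position-wise hypergeometric tails over the
   quadruple (N structural positions, K binding positions, n positions
   hit, k binding positions hit): upper tail for cancer missense, lower
   tail for population SNPs, plus a frequency-aware binomial test.
5. **enrich** — enrichment of known cancer genes (CCG-style list) among
   the genes selected at progressively smaller p-value thresholds.

A first-class synthetic-data generator (`mutbind simulate` /
`mutbind.simulate`) emits a complete, self-consistent input bundle —
genome, transcripts, structures with ligands placed to realise exact
contact fractions, homology files, mutation/SNP cohorts and a
ground-truth manifest — so the whole pipeline is testable offline.

## Worked example

```sh
mutbind simulate --out-dir demo/bundle --seed 1 --genes 6
mutbind run \
  --mutations demo/bundle/mutations.tsv \
  --transcripts demo/bundle/transcripts.tsv \
  --genome demo/bundle/genome.fa \
  --biolip demo/bundle/biolip.tsv \
  --pdb-dir demo/bundle/structures \
  --homology demo/bundle/homology/homology_hits.tsv \
  --snps demo/bundle/snps.tsv \
  --ccg demo/bundle/ccg_genes.txt \
  --out-dir demo/out --replicates 5000 --seed 7
```

`demo/out/site_results_ALL.tsv` then contains (provenance header
omitted):

```
gene    site_id category n_binding_residues mutated_binding_positions  m    s_b     p_empirical fdr      cohort
GENE001 SMI_1   SMI      6                  1                          1    0.5     0.085       0.1275   ALL
GENE002 PEP_1   PEP      9                  9                          85   41.2238 0.0002      0.0004   ALL
GENE003 SMI_1   SMI      8                  8                          69   25.7417 0.0002      0.0004   ALL
GENE004 SMI_1   SMI      8                  0                          2    0       1           1        ALL
GENE005 PEP_1   PEP      7                  7                          63   42.0357 0.0002      0.0004   ALL
GENE006 SMI_1   SMI      8                  1                          11   0.125   0.6304      0.75648  ALL
```

The generator planted three driver genes (GENE002, GENE003, GENE005)
whose binding sites attract 80% of missense events; all three reach
the p-value floor (p = 1/R = 2·10⁻⁴) and FDR 4·10⁻⁴, while the
passenger genes stay null. `global_counts.tsv` shows the cohort-level
contrast on the same bundle: missense mutations hit binding positions
far more often than chance (hypergeometric upper tail 1.6·10⁻¹⁵ at
N=414, K=46, n=50, k=26), SNPs avoid them (lower tail 0.011), and
synonymous mutations are unremarkable (upper tail 0.51).

Real inputs use the same formats: a TCGA-style MAF (via the
column-name mapping), GRCh37-style transcript models, BioLip binding
annotations with the corresponding PDB files, and BLASTP/Clustal
results in the tabular + aligned-FASTA carrier format.

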