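"""Self-consistent synthetic inputs with planted binding-site enrichment.

The generator emits a complete toy input bundle — genome FASTA,
transcript models, structure coordinate files with ligands, binding
annotations, homology hits with alignments, mutation and SNP tables,
and a known-cancer-gene list — together with a ground-truth manifest,
so the whole pipeline can be exercised and validated without any
external downloads.

Geometry is deliberately schematic: residues are laid out on a wide
grid (20 A apart) with their heavy atoms spaced 8 A along z, so a
ligand atom placed 3 A from a residue atom is in contact with exactly
that atom and no other. This makes the per-residue contact fraction —
and hence every planted binding score — exact by construction.

The emulated study: a tumor cohort in which a chosen fraction of
missense events is redirected onto the binding residues of designated
driver genes while the remainder (and all synonymous mutations) land
uniformly in coding sequence, and a population-SNP track biased away
from binding residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from mutbind import io as mio
from mutbind.types import GenomicMutation, ProteinMutation, TranscriptModel

_AA = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# residue grid spacing (x), atom spacing within a residue (z), and the
# ligand offset (y): contacts are unambiguous because 3.0 < 4.0 <
# sqrt(3^2 + 8^2) < 20.
_RESIDUE_SPACING = 20.0
_ATOM_SPACING = 8.0
_CONTACT_OFFSET = 3.0
_FAR_OFFSET = 100.0

_BACKTABLE: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _BACKTABLE.setdefault(aa, []).append(codon)
for aa in _BACKTABLE:
    _BACKTABLE[aa].sort()


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic cohort.

    The defaults describe a dense toy cohort: 20 genes of 60-100
    residues, two isoforms each, one ligand-bound structure per gene,
    three driver genes whose binding sites receive 80% of missense
    events, 100 patient samples, and half a missense event per coding
    residue so that every binding site sees mutations.
    """

    n_genes: int = 20
    isoforms_per_gene: int = 2
    protein_length: tuple[int, int] = (60, 100)
    n_structures_per_gene: int = 1
    sites_per_gene: int = 1
    site_sizes: dict = field(
        default_factory=lambda: {"SMI": (4, 8), "PEP": (6, 10), "NUC": (6, 10)}
    )
    category_weights: dict = field(
        default_factory=lambda: {"SMI": 0.7, "PEP": 0.15, "NUC": 0.15}
    )
    chain_span_fraction: tuple[float, float] = (0.8, 1.0)
    n_driver_genes: int = 3
    enrichment_effect: float = 0.8
    cohorts: dict = field(default_factory=lambda: {"SIM": 100})
    background_rate: float = 0.5  # missense events per coding residue
    synonymous_rate: float = 0.15  # synonymous events per coding residue
    snp_rate: float = 0.15  # SNPs per coding residue
    snp_offsite_bias: float = 0.8  # probability a SNP avoids binding residues
    decoy_hits: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("enrichment_effect", "snp_offsite_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "isoforms_per_gene", "n_structures_per_gene",
                     "sites_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes cannot exceed n_genes")


def place_ligand_for_fraction(n_atoms: int, fraction: float) -> np.ndarray:
    """Ligand coordinates giving a residue at the local origin exactly
    ``fraction`` of its heavy atoms within 4.0 A.

    The residue's atoms are assumed at (0, 0, k * 8) for k < n_atoms
    (the generator's layout). fraction * n_atoms must be integral.
    """
    target = fraction * n_atoms
    n_contact = round(target)
    if abs(target - n_contact) > 1e-9:
        raise ValueError(
            f"fraction {fraction} * {n_atoms} atoms is not an integer"
        )
    if not 0 <= n_contact <= n_atoms:
        raise ValueError("fraction must lie in [0, 1]")
    if n_contact == 0:
        return np.array([[0.0, _FAR_OFFSET, 0.0]])
    return np.array(
        [[0.0, _CONTACT_OFFSET, k * _ATOM_SPACING] for k in range(n_contact)]
    )


# ---------------------------------------------------------------------------
# internal gene construction


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    protein: str
    cds: str  # spliced, 5'->3'
    transcripts: list[TranscriptModel]
    cds_genomic: list[int]  # genomic position of each CDS base (isoform 1)
    sites: list[dict]  # {category, positions, scores, atoms}
    chain_start: int
    chain_end: int
    is_driver: bool
    structure_ids: list[str]

    @property
    def structural_positions(self) -> set[int]:
        return set(range(self.chain_start, self.chain_end + 1))

    @property
    def binding_positions(self) -> set[int]:
        out: set[int] = set()
        for s in self.sites:
            out.update(s["positions"])
        return out


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_BACKTABLE[aa]) for aa in protein)


def _build_gene(
    rng: np.random.Generator,
    spec: FixtureSpec,
    index: int,
    chrom: str,
    offset: int,
    is_driver: bool,
) -> tuple[_Gene, str, int]:
    """Construct one gene; returns (gene, genomic sequence of its
    locus, next free offset)."""
    gene_id = f"GENE{index + 1:03d}"
    length = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
    protein = _random_protein(rng, length)
    cds = _back_translate(rng, protein)
    strand = "+" if index % 2 == 0 else "-"

    # two exons split at a codon boundary, 20 nt intron
    split_codon = int(rng.integers(max(1, length // 4), max(2, 3 * length // 4)))
    exon1, exon2 = cds[: split_codon * 3], cds[split_codon * 3 :]
    intron = "".join(rng.choice(list("ACGT"), size=20))
    start = offset + 1
    if strand == "+":
        locus = exon1 + intron + exon2
        seg1 = (start, start + len(exon1) - 1)
        seg2 = (seg1[1] + 21, seg1[1] + 20 + len(exon2))
        segments = (seg1, seg2)
        cds_genomic = list(range(seg1[0], seg1[1] + 1)) + list(range(seg2[0], seg2[1] + 1))
    else:
        rc = lambda s: s.translate(_COMPLEMENT)[::-1]
        locus = rc(exon2) + intron + rc(exon1)
        segA = (start, start + len(exon2) - 1)  # exon2, rc'd, low coords
        segB = (segA[1] + 21, segA[1] + 20 + len(exon1))
        segments = (segB, segA)  # transcript order: exon1 first
        cds_genomic = list(range(segB[1], segB[0] - 1, -1)) + list(
            range(segA[1], segA[0] - 1, -1)
        )

    transcripts = [
        TranscriptModel(
            gene_id=gene_id, isoform_id=f"{gene_id}.1", assembly_rank=1,
            chrom=chrom, strand=strand, cds_segments=segments,
        )
    ]
    if spec.isoforms_per_gene > 1:
        # shorter isoform: first exon only
        short = (segments[0],)
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id, isoform_id=f"{gene_id}.2", assembly_rank=2,
                chrom=chrom, strand=strand, cds_segments=short,
            )
        )

    # structure chain span (contiguous), then binding sites inside it
    lo, hi = spec.chain_span_fraction
    span = max(10, int(round(length * rng.uniform(lo, hi))))
    span = min(span, length)
    chain_start = int(rng.integers(1, length - span + 2))
    chain_end = chain_start + span - 1

    sites = []
    used: set[int] = set()
    categories = list(spec.category_weights)
    weights = np.array([spec.category_weights[c] for c in categories], dtype=float)
    weights /= weights.sum()
    for _ in range(spec.sites_per_gene):
        category = str(rng.choice(categories, p=weights))
        size_lo, size_hi = spec.site_sizes[category]
        size = int(rng.integers(size_lo, size_hi + 1))
        free = sorted(set(range(chain_start, chain_end + 1)) - used)
        if len(free) < size:
            break
        positions = sorted(rng.choice(free, size=size, replace=False).tolist())
        used.update(positions)
        atoms = {p: int(rng.integers(4, 9)) for p in positions}
        contacts = {p: int(rng.integers(1, atoms[p] + 1)) for p in positions}
        sites.append(
            {
                "category": category,
                "positions": positions,
                "atoms": atoms,
                "contacts": contacts,
                "scores": {p: contacts[p] / atoms[p] for p in positions},
            }
        )

    gene = _Gene(
        gene_id=gene_id, chrom=chrom, strand=strand, protein=protein, cds=cds,
        transcripts=transcripts, cds_genomic=cds_genomic, sites=sites,
        chain_start=chain_start, chain_end=chain_end, is_driver=is_driver,
        structure_ids=[f"{gene_id.lower()}s{j + 1}" for j in range(spec.n_structures_per_gene)],
    )
    return gene, locus, offset + len(locus) + 50


# ---------------------------------------------------------------------------
# structures


def _atom_count(gene: _Gene, pos: int) -> int:
    for s in gene.sites:
        if pos in s["atoms"]:
            return s["atoms"][pos]
    return 4  # non-binding residues get a fixed small complement


def _write_structure(gene: _Gene, structure_id: str, path: Path) -> list[dict]:
    """Write one synthetic PDB file; returns the binding-annotation
    rows it supports."""
    builder = StructureBuilder()
    builder.init_structure(structure_id)
    builder.init_model(0)
    builder.init_seg("    ")
    builder.init_chain("A")
    chain_len = gene.chain_end - gene.chain_start + 1
    for j in range(1, chain_len + 1):
        protein_pos = gene.chain_start + j - 1
        aa = gene.protein[protein_pos - 1]
        builder.init_residue(seq3(aa).upper(), " ", j, " ")
        for k in range(_atom_count(gene, protein_pos)):
            name = f"C{k + 1}"
            coord = np.array([j * _RESIDUE_SPACING, 0.0, k * _ATOM_SPACING])
            builder.init_atom(name, coord, 0.0, 1.0, " ", name, element="C")

    rows = []
    builder.init_chain("Z")
    for si, site in enumerate(gene.sites):
        ligand_id = f"L{si + 1:02d}"
        builder.init_residue(ligand_id, f"H_{ligand_id}", si + 1, " ")
        atom_no = 0
        for pos in site["positions"]:
            j = pos - gene.chain_start + 1
            local = place_ligand_for_fraction(site["atoms"][pos], site["scores"][pos])
            for xyz in local:
                atom_no += 1
                coord = xyz + np.array([j * _RESIDUE_SPACING, 0.0, 0.0])
                builder.init_atom(f"O{atom_no}", coord, 0.0, 1.0, " ", f"O{atom_no}", element="O")
        rows.append(
            {
                "structure_id": structure_id,
                "chain_id": "A",
                "ligand_id": ligand_id,
                "category": site["category"],
                "binding_residues": ";".join(
                    str(p - gene.chain_start + 1) for p in site["positions"]
                ),
            }
        )
    pdb_io = PDBIO()
    pdb_io.set_structure(builder.get_structure())
    pdb_io.save(str(path))
    return rows


# ---------------------------------------------------------------------------
# mutation planting


def _codon_change(
    rng: np.random.Generator, gene: _Gene, protein_pos: int, want: str
) -> Optional[tuple[int, str, str]]:
    """A single-base CDS change at a residue realizing the wanted
    class; returns (cds offset 1-based, ref base, alt base) or None."""
    codon = gene.cds[(protein_pos - 1) * 3 : protein_pos * 3]
    ref_aa = str(Seq(codon).translate())
    options = []
    for within in range(3):
        for alt in "ACGT":
            if alt == codon[within]:
                continue
            alt_codon = codon[:within] + alt + codon[within + 1 :]
            alt_aa = str(Seq(alt_codon).translate())
            if want == "missense" and alt_aa not in ("*", ref_aa):
                options.append((within, alt))
            elif want == "synonymous" and alt_aa == ref_aa:
                options.append((within, alt))
    if not options:
        return None
    within, alt = options[int(rng.integers(len(options)))]
    offset = (protein_pos - 1) * 3 + within + 1
    return offset, codon[within], alt


def _genomic_record(
    gene: _Gene, offset: int, cds_ref: str, cds_alt: str,
    sample_id: str, cohort: str, var_class: str,
) -> GenomicMutation:
    pos = gene.cds_genomic[offset - 1]
    ref, alt = cds_ref, cds_alt
    if gene.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return GenomicMutation(
        chrom=gene.chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        sample_id=sample_id, cohort=cohort, var_class=var_class,
    )


def plant_cohort(
    rng: np.random.Generator,
    spec: FixtureSpec,
    genes: list[_Gene],
    cohort: str,
    n_samples: int,
) -> tuple[list[GenomicMutation], list[dict]]:
    """Draw one cohort's somatic mutations.

    Each missense event targets, with probability ``enrichment_effect``,
    a uniformly chosen binding residue of a driver gene; otherwise a
    uniformly chosen coding residue. Synonymous events are always
    uniform. Returns the records plus the planted ground truth.
    """
    total_residues = sum(len(g.protein) for g in genes)
    lengths = np.array([len(g.protein) for g in genes], dtype=float)
    gene_p = lengths / lengths.sum()
    driver_targets = [
        (g, p) for g in genes if g.is_driver for p in sorted(g.binding_positions)
    ]
    samples = [f"{cohort}_{i + 1:03d}" for i in range(n_samples)]

    records: list[GenomicMutation] = []
    truth: list[dict] = []
    n_missense = int(rng.poisson(spec.background_rate * total_residues))
    n_syn = int(rng.poisson(spec.synonymous_rate * total_residues))

    for _ in range(n_missense):
        on_target = (
            bool(driver_targets) and rng.random() < spec.enrichment_effect
        )
        for _attempt in range(50):
            if on_target:
                gene, pos = driver_targets[int(rng.integers(len(driver_targets)))]
            else:
                gene = genes[int(rng.choice(len(genes), p=gene_p))]
                pos = int(rng.integers(1, len(gene.protein) + 1))
            change = _codon_change(rng, gene, pos, "missense")
            if change is not None:
                break
        else:  # pragma: no cover - 20 standard aa always admit a missense
            continue
        offset, ref, alt = change
        sample = samples[int(rng.integers(n_samples))]
        records.append(_genomic_record(gene, offset, ref, alt, sample, cohort, "missense"))
        truth.append(
            {"gene": gene.gene_id, "protein_pos": pos, "sample": sample,
             "cohort": cohort, "class": "missense", "on_driver_site": on_target}
        )

    for _ in range(n_syn):
        for _attempt in range(50):
            gene = genes[int(rng.choice(len(genes), p=gene_p))]
            pos = int(rng.integers(1, len(gene.protein) + 1))
            change = _codon_change(rng, gene, pos, "synonymous")
            if change is not None:
                break
        else:
            continue
        offset, ref, alt = change
        sample = samples[int(rng.integers(n_samples))]
        records.append(_genomic_record(gene, offset, ref, alt, sample, cohort, "synonymous"))
        truth.append(
            {"gene": gene.gene_id, "protein_pos": pos, "sample": sample,
             "cohort": cohort, "class": "synonymous", "on_driver_site": False}
        )
    return records, truth


def _plant_snps(
    rng: np.random.Generator, spec: FixtureSpec, genes: list[_Gene]
) -> list[ProteinMutation]:
    """Population SNPs in protein coordinates, biased away from binding
    residues."""
    snps = []
    for gene in genes:
        n = int(rng.poisson(spec.snp_rate * len(gene.protein)))
        binding = gene.binding_positions
        non_binding = sorted(set(range(1, len(gene.protein) + 1)) - binding)
        for i in range(n):
            if non_binding and rng.random() < spec.snp_offsite_bias:
                pos = int(non_binding[int(rng.integers(len(non_binding)))])
            else:
                pos = int(rng.integers(1, len(gene.protein) + 1))
            ref_aa = gene.protein[pos - 1]
            alt_aa = str(rng.choice([a for a in _AA if a != ref_aa]))
            snps.append(
                ProteinMutation(
                    gene_id=gene.gene_id, isoform_id=f"{gene.gene_id}.1",
                    protein_pos=pos, ref_aa=ref_aa, alt_aa=alt_aa,
                    sample_id=f"snp_{gene.gene_id}_{i + 1}", cohort="dbsnp",
                    var_class="missense",
                )
            )
    return snps


# ---------------------------------------------------------------------------
# bundle assembly


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the full input bundle and return the ground-truth manifest
    (also stored as ``manifest.json``). Identical specs produce
    byte-identical bundles."""
    rng = np.random.default_rng(spec.rng_seed)
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    (out / "homology").mkdir(exist_ok=True)

    driver_ids = set(rng.choice(spec.n_genes, size=spec.n_driver_genes, replace=False).tolist())
    genes: list[_Gene] = []
    chrom_seqs: dict[str, str] = {}
    genes_per_chrom = 10
    offsets: dict[str, int] = {}
    for i in range(spec.n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        offset = offsets.get(chrom, 0)
        gene, locus, next_offset = _build_gene(rng, spec, i, chrom, offset, i in driver_ids)
        pad = next_offset - offset - len(locus)
        chrom_seqs[chrom] = chrom_seqs.get(chrom, "") + locus + "N" * pad
        offsets[chrom] = next_offset
        genes.append(gene)

    with open(out / "genome.fa", "w") as fh:
        for chrom in sorted(chrom_seqs):
            fh.write(f">{chrom}\n")
            seq = chrom_seqs[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    mio.write_transcripts(
        [tx for g in genes for tx in g.transcripts], out / "transcripts.tsv"
    )

    biolip_rows = []
    pdb_paths = []
    for gene in genes:
        for structure_id in gene.structure_ids:
            path = out / "structures" / f"{structure_id}.pdb"
            biolip_rows.extend(_write_structure(gene, structure_id, path))
            pdb_paths.append(str(path))
    with open(out / "biolip.tsv", "w") as fh:
        fh.write("structure_id\tchain_id\tligand_id\tcategory\tbinding_residues\n")
        for row in biolip_rows:
            fh.write(
                f"{row['structure_id']}\t{row['chain_id']}\t{row['ligand_id']}\t"
                f"{row['category']}\t{row['binding_residues']}\n"
            )

    hits = []
    for gene in genes:
        length = len(gene.protein)
        chain_seq = gene.protein[gene.chain_start - 1 : gene.chain_end]
        chain_aln = "-" * (gene.chain_start - 1) + chain_seq + "-" * (length - gene.chain_end)
        for structure_id in gene.structure_ids:
            hits.append((gene.gene_id, structure_id, "A", 1e-50, gene.protein, chain_aln))
        if spec.decoy_hits:
            # a scrambled near-duplicate that fails the 60% identity gate
            decoy = list(chain_seq)
            n_mut = int(0.45 * len(decoy))
            idx = rng.choice(len(decoy), size=n_mut, replace=False)
            for j in idx:
                decoy[j] = _AA[(_AA.index(decoy[j]) + 1) % len(_AA)]
            decoy_aln = "-" * (gene.chain_start - 1) + "".join(decoy) + "-" * (length - gene.chain_end)
            hits.append((gene.gene_id, f"{gene.gene_id.lower()}decoy", "A", 1e-8,
                         gene.protein, decoy_aln))
    mio.write_homology_hits(hits, out / "homology")

    mutations: list[GenomicMutation] = []
    truth_events: list[dict] = []
    for cohort in sorted(spec.cohorts):
        recs, truth = plant_cohort(rng, spec, genes, cohort, spec.cohorts[cohort])
        mutations.extend(recs)
        truth_events.extend(truth)
    mio.write_mutations(mutations, out / "mutations.tsv")

    snps = _plant_snps(rng, spec, genes)
    mio.write_protein_mutations(snps, out / "snps.tsv")

    mio.write_gene_list([g.gene_id for g in genes if g.is_driver], out / "ccg_genes.txt")

    manifest = {
        "seed": spec.rng_seed,
        "spec": asdict(spec),
        "driver_genes": sorted(g.gene_id for g in genes if g.is_driver),
        "genes": {
            g.gene_id: {
                "protein": g.protein,
                "strand": g.strand,
                "chosen_isoform": f"{g.gene_id}.1",
                "chain_range": [g.chain_start, g.chain_end],
                "structural_positions": sorted(g.structural_positions),
                "structures": g.structure_ids,
                "sites": [
                    {
                        "category": s["category"],
                        "positions": s["positions"],
                        "scores": {str(p): s["scores"][p] for p in s["positions"]},
                    }
                    for s in g.sites
                ],
            }
            for g in genes
        },
        "events": truth_events,
        "n_mutations": len(mutations),
        "n_snps": len(snps),
        "files": {
            "genome": "genome.fa",
            "transcripts": "transcripts.tsv",
            "mutations": "mutations.tsv",
            "snps": "snps.tsv",
            "biolip": "biolip.tsv",
            "structures": sorted(Path(p).name for p in pdb_paths),
            "homology": "homology/homology_hits.tsv",
            "ccg": "ccg_genes.txt",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
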