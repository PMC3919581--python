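"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV with a single header row; lines
starting with ``#`` are provenance/comment lines and are skipped on
read. Genomic and protein coordinates are 1-based inclusive.

Dialects
--------
mutation TSV (maf_like)
    chrom, pos, ref_allele, alt_allele, sample_id, cohort, var_class.
    Full TCGA-style MAFs are accepted by passing a column-name mapping.
protein-coordinate variant TSV (protein_coords)
    gene_id, isoform_id, protein_pos, ref_aa, alt_aa, sample_id,
    cohort, var_class (the last four optional; used for dbSNP-style
    variants already mapped to reference transcripts and for the
    pipeline's own mapped-mutation output).
transcript TSV
    gene_id, isoform_id, assembly_rank, chrom, strand, cds_segments
    ("start-end" intervals comma-separated, in transcript order).
binding-annotation TSV (BioLip dialect)
    structure_id, chain_id, ligand_id, category, binding_residues
    (semicolon-separated indices against the chain renumbered 1..L).
homology hits TSV
    refseq_id, structure_id, chain_id, e_value, pct_identity,
    structure_coverage, alignment_file (aligned-FASTA pair, refseq
    record first).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from pyfaidx import Fasta

from mutbind.types import (
    AlignmentColumn,
    BindingRecord,
    ChainResidue,
    EnrichmentPoint,
    FormatError,
    GenomicMutation,
    HomologyHit,
    LigandRecord,
    MappedBindingSite,
    ProteinMutation,
    SiteTestResult,
    StructureChain,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_MAF_COLUMNS = ("chrom", "pos", "ref_allele", "alt_allele", "sample_id", "cohort")
_PROT_REQUIRED = ("gene_id", "protein_pos", "ref_aa", "alt_aa")

# Accepted spellings of variant classes (TCGA MAF uses Missense_Mutation
# and Silent); anything else is retained but tagged "other".
_CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "synonymous": "synonymous",
    "silent": "synonymous",
}


def normalize_var_class(raw: str) -> str:
    return _CLASS_ALIASES.get(raw.strip().lower(), "other")


def _data_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(1-based physical line number, fields), ...])."""
    rows: list[tuple[int, list[str]]] = []
    header: Optional[list[str]] = None
    with open(path, newline="") as fh:
        for lineno, line in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not line or line[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line]
            else:
                rows.append((lineno, line))
    if header is None:
        raise FormatError(f"{path}: empty file, expected a header row")
    return header, rows


def _column_index(
    header: list[str], required: Sequence[str], column_map: Optional[dict] = None,
    path: str | Path = "",
) -> dict[str, int]:
    """Map canonical column names to indices, honouring a rename map."""
    column_map = column_map or {}
    idx = {}
    for name in required:
        file_name = column_map.get(name, name)
        if file_name not in header:
            raise FormatError(f"{path}: missing required column {file_name!r}")
        idx[name] = header.index(file_name)
    return idx


def _optional_index(header: list[str], name: str, column_map: Optional[dict]) -> Optional[int]:
    file_name = (column_map or {}).get(name, name)
    return header.index(file_name) if file_name in header else None


def read_mutations(
    path: str | Path,
    dialect: str = "maf_like",
    column_map: Optional[dict[str, str]] = None,
) -> list[GenomicMutation] | list[ProteinMutation]:
    """Read a variant table.

    ``maf_like`` yields :class:`GenomicMutation`; ``protein_coords``
    yields :class:`ProteinMutation` (variants already in protein
    coordinates, e.g. dbSNP entries mapped to reference transcripts).
    Rows whose class is neither missense nor synonymous are retained
    and tagged ``other``; the row count is always preserved.
    """
    if dialect not in ("maf_like", "protein_coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header, rows = _data_rows(path)
    if dialect == "maf_like":
        idx = _column_index(header, _MAF_COLUMNS, column_map, path)
        class_idx = _optional_index(header, "var_class", column_map)
        out: list[GenomicMutation] = []
        for lineno, row in rows:
            try:
                pos = int(row[idx["pos"]])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric position {row[idx['pos']]!r} "
                    f"on line {lineno}"
                ) from None
            out.append(
                GenomicMutation(
                    chrom=row[idx["chrom"]],
                    pos=pos,
                    ref_allele=row[idx["ref_allele"]].upper(),
                    alt_allele=row[idx["alt_allele"]].upper(),
                    sample_id=row[idx["sample_id"]],
                    cohort=row[idx["cohort"]],
                    var_class=normalize_var_class(row[class_idx])
                    if class_idx is not None
                    else "other",
                )
            )
        return out

    idx = _column_index(header, _PROT_REQUIRED, column_map, path)
    opt = {
        name: _optional_index(header, name, column_map)
        for name in ("isoform_id", "sample_id", "cohort", "var_class")
    }
    result: list[ProteinMutation] = []
    for lineno, row in rows:
        try:
            pos = int(row[idx["protein_pos"]])
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric position {row[idx['protein_pos']]!r} "
                f"on line {lineno}"
            ) from None
        ref_aa = row[idx["ref_aa"]].upper()
        alt_aa = row[idx["alt_aa"]].upper()
        if opt["var_class"] is not None:
            var_class = normalize_var_class(row[opt["var_class"]])
        elif "*" in (ref_aa, alt_aa):
            var_class = "other"
        else:
            var_class = "synonymous" if ref_aa == alt_aa else "missense"
        result.append(
            ProteinMutation(
                gene_id=row[idx["gene_id"]],
                isoform_id=row[opt["isoform_id"]] if opt["isoform_id"] is not None else "",
                protein_pos=pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                sample_id=row[opt["sample_id"]] if opt["sample_id"] is not None else "",
                cohort=row[opt["cohort"]] if opt["cohort"] is not None else "",
                var_class=var_class,
            )
        )
    return result


def write_mutations(
    mutations: Iterable[GenomicMutation],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAF_COLUMNS + ("var_class",))
        for m in mutations:
            w.writerow(
                [m.chrom, m.pos, m.ref_allele, m.alt_allele, m.sample_id, m.cohort, m.var_class]
            )


def write_protein_mutations(
    mutations: Iterable[ProteinMutation],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene_id", "isoform_id", "protein_pos", "ref_aa", "alt_aa",
             "sample_id", "cohort", "var_class"]
        )
        for m in mutations:
            w.writerow(
                [m.gene_id, m.isoform_id, m.protein_pos, m.ref_aa, m.alt_aa,
                 m.sample_id, m.cohort, m.var_class]
            )


# ---------------------------------------------------------------------------
# Transcript models and genome


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    header, rows = _data_rows(path)
    idx = _column_index(
        header,
        ("gene_id", "isoform_id", "assembly_rank", "chrom", "strand", "cds_segments"),
        path=path,
    )
    out = []
    for lineno, row in rows:
        try:
            segments = tuple(
                (int(s.split("-")[0]), int(s.split("-")[1]))
                for s in row[idx["cds_segments"]].split(",")
            )
            out.append(
                TranscriptModel(
                    gene_id=row[idx["gene_id"]],
                    isoform_id=row[idx["isoform_id"]],
                    assembly_rank=int(row[idx["assembly_rank"]]),
                    chrom=row[idx["chrom"]],
                    strand=row[idx["strand"]],
                    cds_segments=segments,
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad transcript row on line {lineno}: {exc}") from None
    ranks: dict[str, set[int]] = {}
    for tx in out:
        seen = ranks.setdefault(tx.gene_id, set())
        if tx.assembly_rank in seen:
            raise FormatError(
                f"{path}: duplicate assembly_rank {tx.assembly_rank} for gene {tx.gene_id}"
            )
        seen.add(tx.assembly_rank)
    return out


def write_transcripts(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "isoform_id", "assembly_rank", "chrom", "strand", "cds_segments"])
        for tx in transcripts:
            segs = ",".join(f"{s}-{e}" for s, e in tx.cds_segments)
            w.writerow([tx.gene_id, tx.isoform_id, tx.assembly_rank, tx.chrom, tx.strand, segs])


class GenomeStore:
    """Random access to a genome FASTA (1-based inclusive coordinates)."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def base(self, chrom: str, pos: int) -> str:
        return str(self._fasta[chrom][pos - 1 : pos])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Top-strand sequence of chrom[start..end], 1-based inclusive."""
        return str(self._fasta[chrom][start - 1 : end])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta


# ---------------------------------------------------------------------------
# Structures and binding annotations


def _chain_from_pdb(structure_id: str, chain) -> Optional[StructureChain]:
    residues = []
    seq_index = 0
    for res in chain:
        if res.id[0] != " ":  # heteroatoms / waters are not chain residues
            continue
        seq_index += 1
        atoms = []
        for atom in res:
            if atom.is_disordered():
                # keep highest-occupancy alternate location only
                atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
            if (atom.element or "").upper() == "H":
                continue
            atoms.append(atom.get_coord())
        if not atoms:
            continue
        aa = seq1(res.get_resname(), undef_code="X")
        residues.append(
            ChainResidue(
                sequence_index=seq_index,
                amino_acid=aa,
                heavy_atoms=np.array(atoms, dtype=float),
            )
        )
    if not residues:
        return None
    return StructureChain(structure_id=structure_id, chain_id=chain.id, residues=tuple(residues))


def _ligand_atoms(structure, ligand_id: str) -> np.ndarray:
    """Heavy-atom coordinates of a ligand.

    ``ligand_id`` is either a HETATM residue name (small molecules,
    ions) or ``chain:<id>`` naming a whole chain (peptide and nucleic
    acid ligands).
    """
    coords = []
    if ligand_id.startswith("chain:"):
        chain_id = ligand_id.split(":", 1)[1]
        for chain in structure.get_chains():
            if chain.id != chain_id:
                continue
            for atom in chain.get_atoms():
                if (atom.element or "").upper() != "H":
                    coords.append(atom.get_coord())
    else:
        for res in structure.get_residues():
            if res.id[0] == " " or res.get_resname().strip() != ligand_id:
                continue
            for atom in res:
                if (atom.element or "").upper() != "H":
                    coords.append(atom.get_coord())
    return np.array(coords, dtype=float) if coords else np.empty((0, 3))


def read_structures(
    pdb_paths: Iterable[str | Path],
    biolip_tsv_path: str | Path,
) -> tuple[list[StructureChain], list[BindingRecord]]:
    """Load PDB coordinate files and the binding-annotation TSV.

    Chains are renumbered 1..L in order of appearance (the BioLip
    convention), hydrogens are dropped, and every annotated binding
    residue is validated against the chain.
    """
    parser = PDBParser(QUIET=True)
    structures = {}
    chains: dict[tuple[str, str], StructureChain] = {}
    for p in pdb_paths:
        p = Path(p)
        structure_id = p.stem
        structure = parser.get_structure(structure_id, str(p))
        structures[structure_id] = structure
        for chain in structure.get_chains():
            sc = _chain_from_pdb(structure_id, chain)
            if sc is not None:
                chains[sc.key] = sc

    header, rows = _data_rows(biolip_tsv_path)
    idx = _column_index(
        header,
        ("structure_id", "chain_id", "ligand_id", "category", "binding_residues"),
        path=biolip_tsv_path,
    )
    records = []
    for lineno, row in rows:
        key = (row[idx["structure_id"]], row[idx["chain_id"]])
        if key not in chains:
            raise FormatError(
                f"{biolip_tsv_path}: line {lineno} references unknown chain "
                f"{key[0]}/{key[1]}"
            )
        chain = chains[key]
        residues = frozenset(int(x) for x in row[idx["binding_residues"]].split(";"))
        known = {r.sequence_index for r in chain.residues}
        missing = sorted(residues - known)
        if missing:
            raise FormatError(
                f"{biolip_tsv_path}: line {lineno}: residue(s) "
                f"{', '.join(map(str, missing))} not in chain {key[0]}/{key[1]}"
            )
        ligand_id = row[idx["ligand_id"]]
        atoms = _ligand_atoms(structures[key[0]], ligand_id)
        if atoms.shape[0] == 0:
            raise FormatError(
                f"{biolip_tsv_path}: line {lineno}: ligand {ligand_id!r} has no "
                f"heavy atoms in structure {key[0]}"
            )
        records.append(
            BindingRecord(
                structure_id=key[0],
                chain_id=key[1],
                ligand=LigandRecord(
                    ligand_id=ligand_id, category=row[idx["category"]], heavy_atoms=atoms
                ),
                binding_residues=residues,
            )
        )
    return list(chains.values()), records


# ---------------------------------------------------------------------------
# Homology hits


def alignment_from_pair(ref_aln: str, chain_aln: str) -> tuple[AlignmentColumn, ...]:
    """Column list of an aligned pair; gaps are '-' and encode as None."""
    if len(ref_aln) != len(chain_aln):
        raise FormatError(
            f"aligned pair lengths differ: {len(ref_aln)} vs {len(chain_aln)}"
        )
    columns: list[AlignmentColumn] = []
    ref_pos = chain_pos = 0
    for a, b in zip(ref_aln, chain_aln):
        ref_gap, chain_gap = a == "-", b == "-"
        if ref_gap and chain_gap:
            continue
        if not ref_gap:
            ref_pos += 1
        if not chain_gap:
            chain_pos += 1
        columns.append((None if ref_gap else ref_pos, None if chain_gap else chain_pos))
    return tuple(columns)


def identity_and_coverage(ref_aln: str, chain_aln: str) -> tuple[float, float]:
    """Identity over aligned (both non-gap) columns; coverage = aligned
    columns / chain length."""
    aligned = matches = 0
    chain_len = sum(1 for c in chain_aln if c != "-")
    for a, b in zip(ref_aln, chain_aln):
        if a != "-" and b != "-":
            aligned += 1
            if a.upper() == b.upper():
                matches += 1
    identity = matches / aligned if aligned else 0.0
    coverage = aligned / chain_len if chain_len else 0.0
    return identity, coverage


def read_homology_hits(path: str | Path) -> list[HomologyHit]:
    """Read a hits TSV plus its companion aligned-FASTA pairs.

    Identity and coverage are recomputed from each alignment; stated
    values that disagree are replaced with a logged warning.
    """
    path = Path(path)
    header, rows = _data_rows(path)
    idx = _column_index(
        header,
        ("refseq_id", "structure_id", "chain_id", "e_value",
         "pct_identity", "structure_coverage", "alignment_file"),
        path=path,
    )
    hits = []
    for lineno, row in rows:
        aln_path = path.parent / row[idx["alignment_file"]]
        records = list(SeqIO.parse(str(aln_path), "fasta"))
        if len(records) != 2:
            raise FormatError(f"{aln_path}: expected exactly 2 aligned records")
        ref_aln, chain_aln = str(records[0].seq), str(records[1].seq)
        columns = alignment_from_pair(ref_aln, chain_aln)
        identity, coverage = identity_and_coverage(ref_aln, chain_aln)
        stated_id = float(row[idx["pct_identity"]])
        stated_cov = float(row[idx["structure_coverage"]])
        if not math.isclose(stated_id, identity, abs_tol=1e-3) or not math.isclose(
            stated_cov, coverage, abs_tol=1e-3
        ):
            logger.warning(
                "%s line %d: stated identity/coverage (%.3f/%.3f) disagree with "
                "alignment (%.3f/%.3f); recomputed values kept",
                path, lineno, stated_id, stated_cov, identity, coverage,
            )
        hits.append(
            HomologyHit(
                refseq_id=row[idx["refseq_id"]],
                structure_id=row[idx["structure_id"]],
                chain_id=row[idx["chain_id"]],
                e_value=float(row[idx["e_value"]]),
                pct_identity=identity,
                structure_coverage=coverage,
                alignment=columns,
            )
        )
    return hits


def write_homology_hits(
    hits: Iterable[tuple[str, str, str, float, str, str]],
    out_dir: str | Path,
    tsv_name: str = "homology_hits.tsv",
) -> Path:
    """Write hits given as (refseq_id, structure_id, chain_id, e_value,
    ref_aln, chain_aln) tuples; one aligned-FASTA pair per hit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / tsv_name
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["refseq_id", "structure_id", "chain_id", "e_value",
             "pct_identity", "structure_coverage", "alignment_file"]
        )
        for i, (refseq_id, structure_id, chain_id, e_value, ref_aln, chain_aln) in enumerate(hits):
            identity, coverage = identity_and_coverage(ref_aln, chain_aln)
            aln_name = f"aln_{i:04d}_{refseq_id}_{structure_id}_{chain_id}.fasta"
            with open(out_dir / aln_name, "w") as afh:
                afh.write(f">{refseq_id}\n{ref_aln}\n>{structure_id}_{chain_id}\n{chain_aln}\n")
            w.writerow(
                [refseq_id, structure_id, chain_id, f"{e_value:.3g}",
                 f"{identity:.6f}", f"{coverage:.6f}", aln_name]
            )
    return tsv_path


# ---------------------------------------------------------------------------
# Binding sites, structural positions, results


def write_sites(
    sites: Iterable[MappedBindingSite],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["refseq_id", "site_id", "category", "positions", "source_structures"])
        for s in sorted(sites, key=lambda s: (s.refseq_id, s.site_id)):
            pos_field = ";".join(
                f"{p}:{s.binding_scores[p]:.6f}" for p in sorted(s.positions)
            )
            w.writerow([s.refseq_id, s.site_id, s.category, pos_field,
                        ",".join(s.source_structures)])


def read_sites(path: str | Path) -> list[MappedBindingSite]:
    header, rows = _data_rows(path)
    idx = _column_index(
        header, ("refseq_id", "site_id", "category", "positions"), path=path
    )
    src_idx = _optional_index(header, "source_structures", None)
    sites = []
    for _, row in rows:
        scores = {}
        for pair in row[idx["positions"]].split(";"):
            pos, b = pair.split(":")
            scores[int(pos)] = float(b)
        sources = ()
        if src_idx is not None and row[src_idx]:
            sources = tuple(row[src_idx].split(","))
        sites.append(
            MappedBindingSite(
                refseq_id=row[idx["refseq_id"]],
                site_id=row[idx["site_id"]],
                category=row[idx["category"]],
                positions=frozenset(scores),
                binding_scores=scores,
                source_structures=sources,
            )
        )
    return sites


def write_structural_positions(
    positions: dict[str, set[int]], path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["refseq_id", "positions"])
        for refseq_id in sorted(positions):
            w.writerow([refseq_id, ";".join(map(str, sorted(positions[refseq_id])))])


def read_structural_positions(path: str | Path) -> dict[str, set[int]]:
    header, rows = _data_rows(path)
    idx = _column_index(header, ("refseq_id", "positions"), path=path)
    out = {}
    for _, row in rows:
        field = row[idx["positions"]]
        out[row[idx["refseq_id"]]] = {int(x) for x in field.split(";")} if field else set()
    return out


_RESULT_COLUMNS = (
    "gene", "site_id", "category", "n_binding_residues",
    "mutated_binding_positions", "m", "s_b", "p_empirical", "fdr", "cohort",
)


def write_site_results(
    results: Iterable[SiteTestResult],
    path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write the per-site test results TSV (deterministic row order:
    gene, then site_id)."""
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RESULT_COLUMNS)
        for r in sorted(results, key=lambda r: (r.refseq_id, r.site_id)):
            w.writerow(
                [r.refseq_id, r.site_id, r.category, r.n_binding_residues,
                 r.mutated_binding_positions, r.m, f"{r.s_b:.6g}",
                 f"{r.p_empirical:.6g}", f"{r.fdr:.6g}", r.cohort]
            )


def read_site_results(path: str | Path) -> list[SiteTestResult]:
    header, rows = _data_rows(path)
    idx = _column_index(header, _RESULT_COLUMNS, path=path)
    return [
        SiteTestResult(
            refseq_id=row[idx["gene"]],
            site_id=row[idx["site_id"]],
            category=row[idx["category"]],
            cohort=row[idx["cohort"]],
            n_binding_residues=int(row[idx["n_binding_residues"]]),
            mutated_binding_positions=int(row[idx["mutated_binding_positions"]]),
            m=int(row[idx["m"]]),
            s_b=float(row[idx["s_b"]]),
            p_empirical=float(row[idx["p_empirical"]]),
            fdr=float(row[idx["fdr"]]),
        )
        for _, row in rows
    ]


def write_enrichment_curve(
    points: Iterable[EnrichmentPoint], path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["p_threshold", "selected_genes", "ccg_in_selected",
             "total_genes", "ccg_total", "enrichment_ratio"]
        )
        for pt in points:
            ratio = "NA" if pt.enrichment_ratio is None else f"{pt.enrichment_ratio:.6g}"
            w.writerow(
                [f"{pt.p_threshold:.6g}", pt.selected_genes, pt.ccg_in_selected,
                 pt.total_genes, pt.ccg_total, ratio]
            )


def write_refseqs(refseqs: dict[str, str], path: str | Path) -> None:
    """Reference protein sequences as FASTA, sorted by id."""
    with open(path, "w") as fh:
        for refseq_id in sorted(refseqs):
            fh.write(f">{refseq_id}\n")
            seq = refseqs[refseq_id]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_refseqs(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_unmapped(
    unmapped: Iterable[tuple[GenomicMutation, str]], path: str | Path,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref_allele", "alt_allele", "sample_id", "cohort", "reason"])
        for mut, reason in unmapped:
            w.writerow([mut.chrom, mut.pos, mut.ref_allele, mut.alt_allele,
                        mut.sample_id, mut.cohort, reason])


def write_isoform_mappings(mappings, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "chosen_isoform_id", "mapped_mutated_positions", "per_isoform_counts"])
        for im in sorted(mappings, key=lambda im: im.gene_id):
            counts = ";".join(f"{iso}:{n}" for iso, n in sorted(im.per_isoform_counts.items()))
            w.writerow([im.gene_id, im.chosen_isoform_id, im.mapped_mutated_positions, counts])


def write_global_counts(rows: Iterable[dict], path: str | Path,
                        header_comments: Sequence[str] = ()) -> None:
    """Burden-test table: one row per (variant class, ligand category)
    with the (N, K, n, k) quadruple and its tail p-values."""
    columns = ["var_class", "category", "N", "K", "n", "k",
               "p_upper", "p_lower", "events_binding", "events_total", "p_binomial"]
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow([
                row["var_class"], row["category"], row["N"], row["K"], row["n"], row["k"],
                f"{row['p_upper']:.6g}", f"{row['p_lower']:.6g}",
                row.get("events_binding", ""), row.get("events_total", ""),
                f"{row['p_binomial']:.6g}" if row.get("p_binomial") is not None else "",
            ])


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line (Cancer Gene Census style)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_config(path: str | Path) -> dict:
    """JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
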