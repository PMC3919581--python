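"""Genomic-to-protein coordinate mapping and reference-isoform selection.

Each somatic mutation is placed into the spliced coding sequence of an
isoform (strand-aware), its codon is translated before and after the
substitution, and the variant class (missense / synonymous / other) is
derived from the amino-acid pair. For every gene a single reference
isoform is chosen: the one onto which the largest number of distinct
mutated positions can be mapped, ties broken by assembly order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import Seq

from mutbind.io import GenomeStore
from mutbind.types import (
    GenomicMutation,
    IsoformMapping,
    ProteinMutation,
    ReferenceMismatchError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

NOT_IN_CDS = "not in CDS"


def spliced_cds(tx: TranscriptModel, genome: GenomeStore) -> str:
    """The 5'->3' coding sequence of an isoform.

    Minus-strand segments are reverse-complemented from the top strand.
    """
    parts = []
    for start, end in tx.cds_segments:
        seq = genome.slice(tx.chrom, start, end)
        if tx.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        parts.append(seq)
    return "".join(parts)


def cds_offset(tx: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """1-based offset of a genomic position within the spliced CDS, or
    None when the position falls outside every CDS segment."""
    consumed = 0
    for start, end in tx.cds_segments:
        if start <= genomic_pos <= end:
            if tx.strand == "+":
                return consumed + (genomic_pos - start + 1)
            return consumed + (end - genomic_pos + 1)
        consumed += end - start + 1
    return None


def _classify(ref_aa: str, alt_aa: str) -> str:
    if "*" in (ref_aa, alt_aa):
        return "other"  # stop gained/lost: excluded downstream
    return "synonymous" if ref_aa == alt_aa else "missense"


def map_mutation_to_isoform(
    mut: GenomicMutation,
    tx: TranscriptModel,
    genome: GenomeStore,
    cds_seq: Optional[str] = None,
) -> Optional[ProteinMutation]:
    """Map one genomic mutation onto one isoform.

    Returns None when the position is not in the CDS. Raises
    :class:`ReferenceMismatchError` when the record's reference allele
    disagrees with the genome (top strand); mismatches are never
    silently re-complemented, so strand bookkeeping bugs surface.
    """
    offset = cds_offset(tx, mut.pos)
    if offset is None:
        return None
    genome_base = genome.base(mut.chrom, mut.pos)
    if genome_base != mut.ref_allele:
        raise ReferenceMismatchError(genome_base, mut.ref_allele, mut.chrom, mut.pos)
    if cds_seq is None:
        cds_seq = spliced_cds(tx, genome)
    codon_index = (offset - 1) // 3  # 0-based codon
    within = (offset - 1) % 3
    codon = cds_seq[codon_index * 3 : codon_index * 3 + 3]
    alt_base = mut.alt_allele
    if tx.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return ProteinMutation(
        gene_id=tx.gene_id,
        isoform_id=tx.isoform_id,
        protein_pos=codon_index + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        sample_id=mut.sample_id,
        cohort=mut.cohort,
        var_class=_classify(ref_aa, alt_aa),
    )


def select_isoform(
    gene_id: str,
    per_isoform_mapped: dict[str, int],
    ranks: dict[str, int],
) -> IsoformMapping:
    """Choose the isoform mapping the most distinct mutated positions;
    ties go to the isoform listed first in the assembly."""
    if not per_isoform_mapped:
        raise ValueError(f"no isoforms for gene {gene_id}")
    chosen = min(
        per_isoform_mapped,
        key=lambda iso: (-per_isoform_mapped[iso], ranks[iso]),
    )
    return IsoformMapping(
        gene_id=gene_id,
        chosen_isoform_id=chosen,
        mapped_mutated_positions=per_isoform_mapped[chosen],
        per_isoform_counts=dict(per_isoform_mapped),
    )


@dataclass
class ReferenceSet:
    """Mutations mapped onto the chosen reference isoforms, plus the
    ledger of mutations that could not be mapped."""

    mapped: list[ProteinMutation]
    isoform_mappings: list[IsoformMapping]
    unmapped: list[tuple[GenomicMutation, str]]


def reference_sequences(
    transcripts: Iterable[TranscriptModel],
    genome: GenomeStore,
    isoform_mappings: Iterable[IsoformMapping],
) -> dict[str, str]:
    """Translate the chosen isoform of every gene in the reference set."""
    chosen = {im.gene_id: im.chosen_isoform_id for im in isoform_mappings}
    out = {}
    for tx in transcripts:
        if chosen.get(tx.gene_id) == tx.isoform_id:
            cds = spliced_cds(tx, genome)
            protein = str(Seq(cds).translate()).rstrip("*")
            out[tx.gene_id] = protein
    return out


def build_reference_set(
    mutations: Iterable[GenomicMutation],
    transcripts: Iterable[TranscriptModel],
    genome: GenomeStore,
) -> ReferenceSet:
    """Map a mutation cohort onto one reference isoform per gene.

    Isoform selection pools all cohorts, so every gene has a single
    reference sequence throughout the analysis. Counting for the
    selection uses distinct protein positions (not events), missense
    and synonymous pooled. Every input mutation ends up either mapped
    or in the unmapped ledger with a reason.
    """
    mutations = list(mutations)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    # Assign each mutation to the gene(s) whose CDS contains it.
    gene_mutations: dict[str, list[GenomicMutation]] = {g: [] for g in by_gene}
    unmapped: list[tuple[GenomicMutation, str]] = []
    for mut in mutations:
        owners = sorted(
            tx.gene_id
            for txs in by_gene.values()
            for tx in txs
            if tx.chrom == mut.chrom and cds_offset(tx, mut.pos) is not None
        )
        if not owners:
            unmapped.append((mut, NOT_IN_CDS))
            continue
        gene_mutations[owners[0]].append(mut)

    mapped: list[ProteinMutation] = []
    isoform_mappings: list[IsoformMapping] = []
    for gene_id in sorted(gene_mutations):
        muts = gene_mutations[gene_id]
        if not muts:
            continue
        txs = by_gene[gene_id]
        cds_cache = {tx.isoform_id: spliced_cds(tx, genome) for tx in txs}
        per_isoform: dict[str, set[int]] = {tx.isoform_id: set() for tx in txs}
        for tx in txs:
            for mut in muts:
                try:
                    pm = map_mutation_to_isoform(
                        mut, tx, genome, cds_seq=cds_cache[tx.isoform_id]
                    )
                except ReferenceMismatchError:
                    continue
                if pm is not None and pm.var_class in ("missense", "synonymous"):
                    per_isoform[tx.isoform_id].add(pm.protein_pos)
        mapping = select_isoform(
            gene_id,
            {iso: len(pos) for iso, pos in per_isoform.items()},
            {tx.isoform_id: tx.assembly_rank for tx in txs},
        )
        isoform_mappings.append(mapping)
        chosen_tx = next(tx for tx in txs if tx.isoform_id == mapping.chosen_isoform_id)
        for mut in muts:
            try:
                pm = map_mutation_to_isoform(
                    mut, chosen_tx, genome, cds_seq=cds_cache[chosen_tx.isoform_id]
                )
            except ReferenceMismatchError as exc:
                unmapped.append((mut, str(exc)))
                continue
            if pm is None:
                unmapped.append((mut, NOT_IN_CDS))
            else:
                mapped.append(pm)

    n_in, n_out = len(mutations), len(mapped) + len(unmapped)
    if n_in != n_out:
        raise AssertionError(f"mutation conservation violated: {n_in} in, {n_out} out")
    return ReferenceSet(mapped=mapped, isoform_mappings=isoform_mappings, unmapped=unmapped)
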