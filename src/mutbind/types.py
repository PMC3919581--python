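"""Domain types shared across the pipeline.

Coordinate conventions: genomic and protein positions are 1-based
inclusive everywhere; alignment columns are 1-based with gaps encoded
as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

NUCLEOTIDES = frozenset("ACGT")

#: Ligand categories: nucleic acid, peptide, small molecule or ion.
LIGAND_CATEGORIES = ("NUC", "PEP", "SMI")

VAR_CLASSES = ("missense", "synonymous", "other")


class MutbindError(Exception):
    """Base class for pipeline errors."""


class FormatError(MutbindError):
    """An input file violates its format contract."""


class ReferenceMismatchError(MutbindError):
    """The reported reference allele disagrees with the genome base."""

    def __init__(self, expected: str, observed: str, chrom: str, pos: int):
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"reference mismatch at {chrom}:{pos}: genome has "
            f"{expected!r}, mutation record claims {observed!r}"
        )


@dataclass(frozen=True)
class GenomicMutation:
    """One observed somatic variant in genomic coordinates."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    sample_id: str
    cohort: str
    var_class: str = "other"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")


@dataclass(frozen=True)
class ProteinMutation:
    """One variant mapped onto a protein reference sequence.

    ``var_class`` is derived from codon translation for mapped somatic
    mutations; for variants supplied directly in protein coordinates
    (dbSNP-style) it is inferred from the amino-acid pair.
    """

    gene_id: str
    isoform_id: str
    protein_pos: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    sample_id: str
    cohort: str
    var_class: str

    def __post_init__(self):
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")
        syn = self.ref_aa == self.alt_aa
        if self.var_class == "synonymous" and not syn:
            raise ValueError("synonymous mutation must have ref_aa == alt_aa")
        if self.var_class == "missense" and syn:
            raise ValueError("missense mutation must have ref_aa != alt_aa")


@dataclass(frozen=True)
class TranscriptModel:
    """One protein-coding isoform of a gene.

    ``cds_segments`` are genomic intervals (1-based, inclusive) listed in
    5'->3' transcript order; for minus-strand isoforms the intervals run
    in decreasing genomic coordinate.
    """

    gene_id: str
    isoform_id: str
    assembly_rank: int
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise ValueError("cds_segments must be non-empty")
        for start, end in self.cds_segments:
            if start < 1 or end < start:
                raise ValueError(f"invalid CDS segment ({start}, {end})")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.isoform_id} "
                "not divisible by 3"
            )
        spans = sorted(self.cds_segments)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("CDS segments overlap")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


@dataclass(frozen=True)
class ChainResidue:
    """One residue of a structure chain with its heavy-atom coordinates."""

    sequence_index: int  # 1-based, BioLip-style renumbering 1..L
    amino_acid: str  # one-letter
    heavy_atoms: np.ndarray  # (n_atoms, 3), Angstrom

    def __post_init__(self):
        coords = np.asarray(self.heavy_atoms, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("heavy_atoms must be an (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("heavy-atom coordinates must be finite")
        object.__setattr__(self, "heavy_atoms", coords)


@dataclass(frozen=True)
class StructureChain:
    """A protein chain extracted from a coordinate file (heavy atoms only)."""

    structure_id: str
    chain_id: str
    residues: tuple[ChainResidue, ...]

    def __post_init__(self):
        idx = [r.sequence_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue sequence_index must be strictly increasing")

    @property
    def one_letter_sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)

    def residue(self, sequence_index: int) -> Optional[ChainResidue]:
        for r in self.residues:
            if r.sequence_index == sequence_index:
                return r
        return None


@dataclass(frozen=True)
class LigandRecord:
    """A bound ligand: nucleic acid (NUC), peptide (PEP), or small
    molecule / ion (SMI)."""

    ligand_id: str
    category: str
    heavy_atoms: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        if self.category not in LIGAND_CATEGORIES:
            raise ValueError(
                f"ligand category must be one of {LIGAND_CATEGORIES}, "
                f"got {self.category!r}"
            )
        coords = np.asarray(self.heavy_atoms, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("ligand must have >= 1 heavy atom as (n, 3) array")
        object.__setattr__(self, "heavy_atoms", coords)


@dataclass(frozen=True)
class BindingRecord:
    """Binding annotation for one (chain, ligand) pair: which chain
    residues contact the ligand, in chain numbering 1..L."""

    structure_id: str
    chain_id: str
    ligand: LigandRecord
    binding_residues: frozenset[int]

    def __post_init__(self):
        if not self.binding_residues:
            raise ValueError("binding_residues must be non-empty")
        object.__setattr__(
            self, "binding_residues", frozenset(self.binding_residues)
        )


# Alignment columns: (refseq_pos | None, chain_pos | None), 1-based.
AlignmentColumn = tuple[Optional[int], Optional[int]]


@dataclass(frozen=True)
class HomologyHit:
    """One sequence-to-structure-chain homology search hit with its
    pairwise alignment. Identity and coverage are recomputed from the
    alignment on load."""

    refseq_id: str
    structure_id: str
    chain_id: str
    e_value: float
    pct_identity: float  # fraction of aligned (both non-gap) columns identical
    structure_coverage: float  # fraction of chain residues aligned
    alignment: tuple[AlignmentColumn, ...]

    def __post_init__(self):
        ref_prev = chain_prev = 0
        for ref_pos, chain_pos in self.alignment:
            if ref_pos is not None:
                if ref_pos <= ref_prev:
                    raise ValueError("alignment not monotone in refseq positions")
                ref_prev = ref_pos
            if chain_pos is not None:
                if chain_pos <= chain_prev:
                    raise ValueError("alignment not monotone in chain positions")
                chain_prev = chain_pos


@dataclass(frozen=True)
class StructuralMatch:
    """A homology hit with the acceptance decision of the triple filter
    (E-value < 1e-6, identity > 60%, structure coverage > 80%)."""

    hit: HomologyHit
    accepted: bool
    reject_reason: Optional[str] = None

    @property
    def refseq_id(self) -> str:
        return self.hit.refseq_id

    @property
    def structure_id(self) -> str:
        return self.hit.structure_id

    @property
    def chain_id(self) -> str:
        return self.hit.chain_id


@dataclass(frozen=True)
class MappedBindingSite:
    """A merged binding site on a reference sequence: the residue
    positions of one ligand category, each weighted by a binding score
    b_i in [0, 1] (mean heavy-atom contact fraction over structures)."""

    refseq_id: str
    site_id: str
    category: str
    positions: frozenset[int]
    binding_scores: dict[int, float]
    source_structures: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.positions:
            raise ValueError("binding site must have >= 1 position")
        if self.category not in LIGAND_CATEGORIES:
            raise ValueError(f"unknown ligand category {self.category!r}")
        if set(self.binding_scores) != set(self.positions):
            raise ValueError("binding_scores keys must equal positions")
        for pos, b in self.binding_scores.items():
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"binding score b_{pos}={b} outside [0, 1]")
        object.__setattr__(self, "positions", frozenset(self.positions))


@dataclass(frozen=True)
class SiteTestResult:
    """Permutation-test outcome for one binding site in one cohort."""

    refseq_id: str
    site_id: str
    category: str
    cohort: str
    n_binding_residues: int
    mutated_binding_positions: int
    m: int  # mutation events at structural positions (sample multiplicity)
    s_b: float  # observed site score
    p_empirical: float
    fdr: float = float("nan")

    def __post_init__(self):
        if self.s_b < 0:
            raise ValueError("s_b must be >= 0")
        if not (0.0 < self.p_empirical <= 1.0):
            raise ValueError("p_empirical must lie in (0, 1]")


@dataclass(frozen=True)
class IsoformMapping:
    """Outcome of choosing one reference isoform for a gene."""

    gene_id: str
    chosen_isoform_id: str
    mapped_mutated_positions: int
    per_isoform_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class GlobalCounts:
    """Cohort-level burden quadruple for the hypergeometric test.

    N: positions with structural information; K: binding positions;
    n: structural positions hit by >= 1 variant of the class under
    test; k: binding positions hit.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.K <= self.N):
            raise ValueError(f"need 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"need 0 <= k <= min(K, n), got k={self.k}, "
                f"K={self.K}, n={self.n}"
            )

    def __add__(self, other: "GlobalCounts") -> "GlobalCounts":
        return GlobalCounts(
            self.N + other.N, self.K + other.K, self.n + other.n, self.k + other.k
        )


@dataclass(frozen=True)
class EnrichmentPoint:
    """One point of the known-cancer-gene enrichment curve."""

    p_threshold: float
    selected_genes: int
    ccg_in_selected: int
    total_genes: int
    ccg_total: int
    enrichment_ratio: Optional[float]
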