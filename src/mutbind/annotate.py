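"""Transfer of binding-site annotations onto reference sequences.

Homology hits against ligand-bound structure chains pass a triple
filter (E-value < 1e-6, sequence identity > 60%, coverage of the
matching structure > 80%). Binding residues are carried through the
pairwise alignment onto the reference sequence only when more than 90%
of them align to an identical amino acid (a binding residue aligned to
a gap counts as non-identical). Sites of the same ligand category that
share at least one residue are merged transitively; each residue gets
a binding score b_i: the fraction of its heavy atoms within 4.0 A of
any ligand atom, averaged over the structures that resolve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from mutbind.types import (
    BindingRecord,
    ChainResidue,
    HomologyHit,
    LIGAND_CATEGORIES,
    MappedBindingSite,
    StructuralMatch,
    StructureChain,
)

#: Defaults of the homology filters and the contact threshold.
E_VALUE_MAX = 1e-6
IDENTITY_MIN = 0.60
COVERAGE_MIN = 0.80
BINDING_IDENTITY_MIN = 0.90
CONTACT_DISTANCE = 4.0  # Angstrom, inclusive


def filter_hits(
    hits: Iterable[HomologyHit],
    e_value_max: float = E_VALUE_MAX,
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = COVERAGE_MIN,
) -> list[StructuralMatch]:
    """Apply the triple filter; all thresholds are strict inequalities.

    Rejected hits are retained with a reason so coverage bookkeeping
    stays complete.
    """
    matches = []
    for hit in hits:
        reasons = []
        if not hit.e_value < e_value_max:
            reasons.append(f"e_value {hit.e_value:.3g} >= {e_value_max:.3g}")
        if not hit.pct_identity > identity_min:
            reasons.append(f"identity {hit.pct_identity:.3f} <= {identity_min:.2f}")
        if not hit.structure_coverage > coverage_min:
            reasons.append(f"coverage {hit.structure_coverage:.3f} <= {coverage_min:.2f}")
        matches.append(
            StructuralMatch(
                hit=hit,
                accepted=not reasons,
                reject_reason="; ".join(reasons) or None,
            )
        )
    return matches


def _chain_to_ref(hit: HomologyHit) -> dict[int, Optional[int]]:
    """chain position -> aligned refseq position (None when the chain
    residue aligns to a gap)."""
    out: dict[int, Optional[int]] = {}
    for ref_pos, chain_pos in hit.alignment:
        if chain_pos is not None:
            out[chain_pos] = ref_pos
    return out


def transfer_binding_site(
    match: StructuralMatch,
    rec: BindingRecord,
    refseq: str,
    chain: StructureChain,
    binding_identity_min: float = BINDING_IDENTITY_MIN,
) -> Optional[frozenset[int]]:
    """Map one binding annotation through the alignment.

    Returns the refseq positions of the binding residues, or None when
    the identity over the binding residues is not strictly above the
    gate (default 90%).
    """
    if not match.accepted:
        raise ValueError("transfer requires an accepted match")
    chain_to_ref = _chain_to_ref(match.hit)
    chain_aa = {r.sequence_index: r.amino_acid for r in chain.residues}
    identical = 0
    mapped: set[int] = set()
    for chain_pos in rec.binding_residues:
        ref_pos = chain_to_ref.get(chain_pos)
        if ref_pos is None:
            continue  # aligned to a gap: counts as non-identical, cannot map
        if refseq[ref_pos - 1].upper() == chain_aa.get(chain_pos, "?").upper():
            identical += 1
        mapped.add(ref_pos)
    identity = identical / len(rec.binding_residues)
    if not identity > binding_identity_min:
        return None
    return frozenset(mapped) if mapped else None


@dataclass(frozen=True)
class MergedGroup:
    category: str
    positions: frozenset[int]
    members: tuple[int, ...]  # indices into the input list


def merge_sites(sites: Sequence[tuple[str, frozenset[int]]]) -> list[MergedGroup]:
    """Merge sites of the same ligand category that share a residue
    (transitive closure of the overlap relation, via union-find).

    Sites of different categories are never merged. The output order is
    deterministic: by category, then smallest position.
    """
    parent = list(range(len(sites)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if sites[i][0] == sites[j][0] and sites[i][1] & sites[j][1]:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(sites)):
        groups.setdefault(find(i), []).append(i)
    merged = [
        MergedGroup(
            category=sites[members[0]][0],
            positions=frozenset().union(*(sites[i][1] for i in members)),
            members=tuple(sorted(members)),
        )
        for members in groups.values()
    ]
    merged.sort(key=lambda g: (LIGAND_CATEGORIES.index(g.category), min(g.positions)))
    return merged


def contact_fraction(
    residue: ChainResidue,
    ligand_atoms: np.ndarray,
    contact_distance: float = CONTACT_DISTANCE,
) -> tuple[int, int]:
    """(atoms within the contact distance of any ligand atom, total
    heavy atoms) for one residue; the threshold is inclusive."""
    if residue.heavy_atoms.shape[0] == 0:
        raise ValueError("residue has no heavy atoms")
    d = cdist(residue.heavy_atoms, np.asarray(ligand_atoms, dtype=float))
    n_close = int(np.sum(d.min(axis=1) <= contact_distance))
    return n_close, int(residue.heavy_atoms.shape[0])


@dataclass
class ResidueContactProfile:
    """Per-structure heavy-atom contact counts for one refseq position."""

    refseq_id: str
    protein_pos: int
    entries: list[tuple[str, int, int]] = field(default_factory=list)
    # entries: (structure_id, total heavy atoms |A_ij|, atoms in contact |~A_ij|)

    def add(self, structure_id: str, n_total: int, n_close: int) -> None:
        if not (0 <= n_close <= n_total) or n_total < 1:
            raise ValueError(f"invalid contact counts ({n_close}, {n_total})")
        self.entries.append((structure_id, n_total, n_close))


def binding_score(profile: ResidueContactProfile) -> float:
    """b_i: mean over structures of the residue's contact fraction."""
    if not profile.entries:
        raise ValueError(
            f"no structures resolve position {profile.protein_pos} of "
            f"{profile.refseq_id}"
        )
    return float(np.mean([n_close / n_total for _, n_total, n_close in profile.entries]))


def annotate_reference(
    refseqs: dict[str, str],
    matches: Iterable[StructuralMatch],
    binding_records: Iterable[BindingRecord],
    chains: Iterable[StructureChain],
    binding_identity_min: float = BINDING_IDENTITY_MIN,
    contact_distance: float = CONTACT_DISTANCE,
) -> tuple[list[MappedBindingSite], dict[str, set[int]]]:
    """Run the full annotation for every reference sequence.

    Returns the merged, scored binding sites and the per-refseq set of
    structural positions (residues covered by >= 1 accepted match),
    which is the sampling universe of the downstream statistics.
    Reference sequences with no accepted match yield no sites and no
    structural positions.
    """
    chain_map = {c.key: c for c in chains}
    records_by_chain: dict[tuple[str, str], list[BindingRecord]] = {}
    for rec in binding_records:
        records_by_chain.setdefault((rec.structure_id, rec.chain_id), []).append(rec)

    sites: list[MappedBindingSite] = []
    structural: dict[str, set[int]] = {}
    matches = list(matches)
    for refseq_id in sorted(refseqs):
        seq = refseqs[refseq_id]
        accepted = [m for m in matches if m.accepted and m.refseq_id == refseq_id]
        if not accepted:
            continue
        covered: set[int] = set()
        for m in accepted:
            covered.update(
                ref_pos
                for ref_pos, chain_pos in m.hit.alignment
                if ref_pos is not None and chain_pos is not None
            )
        structural[refseq_id] = covered

        transferred: list[tuple[str, frozenset[int]]] = []
        provenance: list[tuple[StructuralMatch, BindingRecord]] = []
        for m in accepted:
            chain = chain_map.get((m.structure_id, m.chain_id))
            if chain is None:
                raise ValueError(
                    f"no coordinates for chain {m.structure_id}/{m.chain_id}"
                )
            for rec in records_by_chain.get((m.structure_id, m.chain_id), []):
                positions = transfer_binding_site(
                    m, rec, seq, chain, binding_identity_min=binding_identity_min
                )
                if positions is not None:
                    transferred.append((rec.ligand.category, positions))
                    provenance.append((m, rec))

        counters: dict[str, int] = {}
        for group in merge_sites(transferred):
            counters[group.category] = counters.get(group.category, 0) + 1
            site_id = f"{group.category}_{counters[group.category]}"
            scores = _score_group(refseq_id, group, provenance, chain_map, contact_distance)
            structures = tuple(
                sorted({provenance[i][0].structure_id for i in group.members})
            )
            sites.append(
                MappedBindingSite(
                    refseq_id=refseq_id,
                    site_id=site_id,
                    category=group.category,
                    positions=group.positions,
                    binding_scores=scores,
                    source_structures=structures,
                )
            )
    return sites, structural


def _score_group(
    refseq_id: str,
    group: MergedGroup,
    provenance: Sequence[tuple[StructuralMatch, BindingRecord]],
    chain_map: dict[tuple[str, str], StructureChain],
    contact_distance: float = CONTACT_DISTANCE,
) -> dict[int, float]:
    """Binding scores for one merged site.

    For each contributing structure, the ligand atoms of all its
    records in the group are pooled; a position's per-structure
    fraction uses the chain residue it aligns to in that structure's
    match. Structures whose alignment does not cover the position, or
    whose coordinates do not resolve the residue, are left out of the
    average rather than zero-filled.
    """
    by_structure: dict[str, list[tuple[StructuralMatch, BindingRecord]]] = {}
    for i in group.members:
        m, rec = provenance[i]
        by_structure.setdefault(m.structure_id, []).append((m, rec))

    scores: dict[int, float] = {}
    for pos in sorted(group.positions):
        profile = ResidueContactProfile(refseq_id=refseq_id, protein_pos=pos)
        for structure_id, pairs in sorted(by_structure.items()):
            ligand_atoms = np.vstack([rec.ligand.heavy_atoms for _, rec in pairs])
            # the same structure may appear via several records; the
            # alignment is per match, identical matches collapse here
            chain_positions = set()
            for m, _ in pairs:
                for ref_pos, chain_pos in m.hit.alignment:
                    if ref_pos == pos and chain_pos is not None:
                        chain_positions.add((m.chain_id, chain_pos))
            for chain_id, chain_pos in sorted(chain_positions):
                residue = chain_map[(structure_id, chain_id)].residue(chain_pos)
                if residue is None or residue.heavy_atoms.shape[0] == 0:
                    continue
                n_close, n_total = contact_fraction(residue, ligand_atoms, contact_distance)
                profile.add(structure_id, n_total, n_close)
                break  # one entry per structure
        scores[pos] = binding_score(profile) if profile.entries else 0.0
    return scores


# ---------------------------------------------------------------------------
# Structure geometry helper (used for spot checks on real complexes)


def min_residue_distance(
    pdb_path: str,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> float:
    """Minimum heavy-atom distance (A) between two residues of a PDB
    file, selected by (chain id, author residue number)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", pdb_path)
    model = next(structure.get_models())

    def heavy_coords(chain_id: str, resseq: int) -> np.ndarray:
        chain = model[chain_id]
        coords = []
        for res in chain:
            if res.id[1] != resseq:
                continue
            for atom in res:
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(),
                        key=lambda a: a.get_occupancy() or 0.0,
                    )
                if (atom.element or "").upper() != "H":
                    coords.append(atom.get_coord())
        if not coords:
            raise ValueError(f"no heavy atoms for {chain_id}:{resseq}")
        return np.array(coords, dtype=float)

    a = heavy_coords(*residue_a)
    b = heavy_coords(*residue_b)
    return float(cdist(a, b).min())
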