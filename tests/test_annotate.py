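"""Homology filtering, binding-site transfer, merging, contact scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutbind.annotate import (
    ResidueContactProfile,
    annotate_reference,
    binding_score,
    contact_fraction,
    filter_hits,
    merge_sites,
    min_residue_distance,
    transfer_binding_site,
)
from mutbind.io import alignment_from_pair
from mutbind.types import (
    BindingRecord,
    ChainResidue,
    HomologyHit,
    LigandRecord,
    StructureChain,
    StructuralMatch,
)


def hit(e=1e-20, identity=1.0, coverage=1.0, alignment=((1, 1),), refseq_id="R", sid="s1"):
    return HomologyHit(refseq_id, sid, "A", e, identity, coverage, tuple(alignment))


def make_chain(seq, sid="s1", atoms_per_residue=1, spacing=20.0):
    residues = tuple(
        ChainResidue(
            i + 1, aa,
            np.array([[i * spacing, 0.0, k * 8.0] for k in range(atoms_per_residue)]),
        )
        for i, aa in enumerate(seq)
    )
    return StructureChain(sid, "A", residues)


class TestFilter:
    @pytest.mark.parametrize(
        "e,identity,coverage,accepted,reason_part",
        [
            (1e-7, 0.75, 0.85, True, None),
            (1e-7, 0.60, 0.85, False, "identity"),  # exactly 60%: strict >
            (1e-5, 0.99, 0.99, False, "e_value"),
            (1e-7, 0.75, 0.80, False, "coverage"),  # exactly 80%: strict >
        ],
    )
    def test_triple_filter_is_strict(self, e, identity, coverage, accepted, reason_part):
        (match,) = filter_hits([hit(e, identity, coverage)])
        assert match.accepted is accepted
        if reason_part:
            assert reason_part in match.reject_reason

    def test_rejected_hits_are_retained(self):
        matches = filter_hits([hit(1e-5), hit(1e-9)])
        assert len(matches) == 2
        assert [m.accepted for m in matches] == [False, True]


class TestTransfer:
    def test_full_identity_transfers(self):
        chain = make_chain("MKLV")
        aln = alignment_from_pair("MKLV", "MKLV")
        match = StructuralMatch(hit(alignment=aln), accepted=True)
        rec = BindingRecord("s1", "A", LigandRecord("L", "SMI", np.zeros((1, 3))), frozenset({2, 3}))
        assert transfer_binding_site(match, rec, "MKLV", chain) == {2, 3}

    def test_ninety_percent_exactly_is_rejected(self):
        # 10 binding residues, 9 identical -> identity 0.90, gate is strict
        chain_seq = "AAAAAAAAAA"
        refseq = "AAAAAAAAAC"
        aln = alignment_from_pair(refseq, chain_seq)
        match = StructuralMatch(hit(alignment=aln), accepted=True)
        rec = BindingRecord(
            "s1", "A", LigandRecord("L", "SMI", np.zeros((1, 3))), frozenset(range(1, 11))
        )
        assert transfer_binding_site(match, rec, refseq, chain_seq and make_chain(chain_seq)) is None

    def test_binding_residue_on_gap_counts_as_mismatch(self):
        # chain residue 2 aligns to a refseq gap: identity 3/4 -> rejected
        chain = make_chain("MKLV")
        aln = alignment_from_pair("M-LVE", "MKLV-")
        match = StructuralMatch(hit(alignment=aln), accepted=True)
        rec = BindingRecord(
            "s1", "A", LigandRecord("L", "SMI", np.zeros((1, 3))), frozenset({1, 2, 3, 4})
        )
        assert transfer_binding_site(match, rec, "MLVE", chain) is None

    def test_positions_map_through_alignment_offsets(self):
        # chain is a suffix of the refseq: chain pos i -> refseq pos i+2
        chain = make_chain("LVWK")
        aln = alignment_from_pair("MKLVWK", "--LVWK")
        match = StructuralMatch(hit(alignment=aln), accepted=True)
        rec = BindingRecord("s1", "A", LigandRecord("L", "SMI", np.zeros((1, 3))), frozenset({1, 4}))
        assert transfer_binding_site(match, rec, "MKLVWK", chain) == {3, 6}


def brute_force_merge(sites):
    """Oracle: transitive closure on the overlap graph by fixpoint union."""
    groups = [(c, set(p)) for c, p in sites]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if groups[i][0] == groups[j][0] and groups[i][1] & groups[j][1]:
                groups[i] = (groups[i][0], groups[i][1] | groups[j][1])
                del groups[j]
                changed = True
                break
    return sorted((c, tuple(sorted(p))) for c, p in groups)


class TestMerge:
    def test_shared_residue_merges(self):
        merged = merge_sites([("SMI", frozenset({1, 2, 3})), ("SMI", frozenset({3, 4}))])
        assert [(g.category, set(g.positions)) for g in merged] == [("SMI", {1, 2, 3, 4})]

    def test_disjoint_sites_stay_separate(self):
        merged = merge_sites([("SMI", frozenset({1, 2})), ("SMI", frozenset({4, 5}))])
        assert len(merged) == 2

    def test_chain_of_overlaps_collapses(self):
        merged = merge_sites(
            [("SMI", frozenset({1, 2})), ("SMI", frozenset({2, 3})), ("SMI", frozenset({3, 4}))]
        )
        assert [set(g.positions) for g in merged] == [{1, 2, 3, 4}]

    def test_categories_never_merge(self):
        merged = merge_sites([("SMI", frozenset({1, 2})), ("NUC", frozenset({2, 3}))])
        assert len(merged) == 2

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["SMI", "PEP", "NUC"]),
                st.frozensets(st.integers(1, 12), min_size=1, max_size=5),
            ),
            min_size=1,
            max_size=8,
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_oracle_and_order_independent(self, sites, rnd):
        canon = lambda groups: sorted(
            (g.category, tuple(sorted(g.positions))) for g in groups
        )
        expected = brute_force_merge(sites)
        assert canon(merge_sites(sites)) == expected
        shuffled = list(sites)
        rnd.shuffle(shuffled)
        assert canon(merge_sites(shuffled)) == expected

    def test_idempotent(self):
        once = merge_sites([("SMI", frozenset({1, 2})), ("SMI", frozenset({2, 5}))])
        again = merge_sites([(g.category, g.positions) for g in once])
        assert sorted(g.positions for g in again) == sorted(g.positions for g in once)


class TestContacts:
    def test_four_angstrom_boundary_is_inclusive(self):
        res = ChainResidue(1, "A", np.array([[0.0, 0.0, 0.0]]))
        assert contact_fraction(res, np.array([[0.0, 0.0, 4.0]])) == (1, 1)
        assert contact_fraction(res, np.array([[0.0, 0.0, 4.001]])) == (0, 1)

    def test_fraction_counts_nearest_distances(self):
        res = ChainResidue(
            1, "A", np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 5.0], [0.0, 0.0, 3.9]])
        )
        ligand = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        # nearest-ligand distances: 0.0, 5.0, 3.9 -> two in contact
        assert contact_fraction(res, ligand) == (2, 3)

    def test_binding_score_is_mean_over_structures(self):
        profile = ResidueContactProfile("R", 5)
        profile.add("s1", 8, 4)
        assert binding_score(profile) == pytest.approx(0.5)
        profile.add("s2", 3, 3)
        assert binding_score(profile) == pytest.approx(0.75)

    def test_zero_contact_binding_residue_scores_zero(self):
        profile = ResidueContactProfile("R", 5)
        profile.add("s1", 6, 0)
        assert binding_score(profile) == 0.0

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError, match="no structures"):
            binding_score(ResidueContactProfile("R", 5))


def simple_scenario(contacts=(2, 4), atoms=4, sid="s1", seq="MKLVWKYR"):
    """One chain identical to the refseq, ligand touching residues 3 and 4
    with the given contact counts."""
    chain = make_chain(seq, sid, atoms_per_residue=atoms)
    ligand_atoms = []
    for pos, n in zip((3, 4), contacts):
        for k in range(n):
            ligand_atoms.append([(pos - 1) * 20.0, 3.0, k * 8.0])
    rec = BindingRecord(
        sid, "A", LigandRecord("LIG", "SMI", np.array(ligand_atoms)), frozenset({3, 4})
    )
    aln = alignment_from_pair(seq, seq)
    match = StructuralMatch(hit(alignment=aln, sid=sid), accepted=True)
    return chain, rec, match


class TestAnnotateReference:
    def test_single_structure_site(self):
        chain, rec, match = simple_scenario()
        sites, structural = annotate_reference({"R": "MKLVWKYR"}, [match], [rec], [chain])
        (site,) = sites
        assert site.positions == {3, 4}
        assert site.binding_scores == {3: pytest.approx(0.5), 4: pytest.approx(1.0)}
        assert structural["R"] == set(range(1, 9))

    def test_rejected_match_yields_nothing(self):
        chain, rec, match = simple_scenario()
        rejected = StructuralMatch(match.hit, accepted=False, reject_reason="identity")
        sites, structural = annotate_reference({"R": "MKLVWKYR"}, [rejected], [rec], [chain])
        assert sites == [] and structural == {}

    def test_two_structures_average_scores(self):
        c1, r1, m1 = simple_scenario(contacts=(2, 4), sid="s1")
        c2, r2, m2 = simple_scenario(contacts=(4, 2), sid="s2")
        sites, _ = annotate_reference({"R": "MKLVWKYR"}, [m1, m2], [r1, r2], [c1, c2])
        (site,) = sites
        assert site.binding_scores == {3: pytest.approx(0.75), 4: pytest.approx(0.75)}
        assert site.source_structures == ("s1", "s2")

    def test_mean_fixed_point_when_duplicate_structure_added(self):
        c1, r1, m1 = simple_scenario(sid="s1")
        c2, r2, m2 = simple_scenario(sid="s2")  # identical fractions
        (site_one,), _ = annotate_reference({"R": "MKLVWKYR"}, [m1], [r1], [c1])
        (site_two,), _ = annotate_reference({"R": "MKLVWKYR"}, [m1, m2], [r1, r2], [c1, c2])
        assert site_two.binding_scores == pytest.approx(site_one.binding_scores)

    def test_scores_stay_in_unit_interval(self):
        chain, rec, match = simple_scenario(contacts=(1, 3))
        sites, _ = annotate_reference({"R": "MKLVWKYR"}, [match], [rec], [chain])
        for b in sites[0].binding_scores.values():
            assert 0.0 <= b <= 1.0


def test_min_residue_distance_on_synthetic_structure(tmp_path):
    pdb = tmp_path / "pair.pdb"
    pdb.write_text(
        "ATOM      1  C1  ALA A  10       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  C2  ALA A  10       1.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C1  SER B  20       0.000   3.400   0.000  1.00  0.00           C\n"
        "END\n"
    )
    assert min_residue_distance(str(pdb), ("A", 10), ("B", 20)) == pytest.approx(3.4)
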