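import numpy as np
import pytest

from conftest import brute_force_contacts, random_homolog_spec

from serpinvar.benchmark import (
    AlignedPair,
    AlignmentError,
    BenchmarkConfig,
    ContactMap,
    ResidueNotResolvableError,
    StructureError,
    align_homolog,
    build_neutral_set,
    contact_map,
    contact_map_for_query,
    contacts_conserved,
    extract_substitutions,
    flank_conserved,
    gap_ok,
    percent_identity,
)
from serpinvar.synthetic import build_structure, gen_homolog_pair, gen_toy_structure
from serpinvar.variants import ReferenceSequence


def _pair(q: str, s: str, sid: str = "subj") -> AlignedPair:
    return AlignedPair("query", sid, q, s)


# ---------------------------------------------------------------------------
# alignment columns
# ---------------------------------------------------------------------------

class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(_pair("AKLM", "AKLM")) == 100.0

    def test_three_of_four(self):
        assert percent_identity(_pair("AKLM", "AKIM")) == 75.0

    def test_gap_column_excluded_from_denominator(self):
        assert percent_identity(_pair("AK-LM", "AKQLM")) == 100.0

    def test_no_ungapped_columns_is_error(self):
        with pytest.raises(AlignmentError):
            percent_identity(_pair("A-", "-A"))

    def test_rows_validated(self):
        with pytest.raises(AlignmentError):
            _pair("AK", "AKL")
        with pytest.raises(AlignmentError):
            _pair("A-K", "A-K")


class TestExtractSubstitutions:
    def test_single_substitution_in_query_coordinates(self):
        cands = extract_substitutions(_pair("AKLM", "AKIM"))
        assert [str(c.variant) for c in cands] == ["L3I"]

    def test_identity_yields_nothing(self):
        assert extract_substitutions(_pair("AKLM", "AKLM")) == []

    def test_indels_are_not_substitutions(self):
        assert extract_substitutions(_pair("A-KL", "AQKL")) == []
        assert extract_substitutions(_pair("AQKL", "A-KL")) == []

    def test_position_skips_query_gaps(self):
        # query gap before the substitution must not advance query numbering
        cands = extract_substitutions(_pair("AK-LM", "AKQIM"))
        assert [str(c.variant) for c in cands] == ["L3I"]


class TestFlankAndGapFilters:
    def test_flank_conserved(self):
        assert flank_conserved(_pair("ANCDE", "ANWDE"), 2, k=2) is True
        # left flank differs in the subject row
        assert flank_conserved(_pair("ANCDE", "AYWDE"), 2, k=2) is False

    def test_flank_requires_full_window_on_both_sides(self):
        # only one column left of the substitution
        assert flank_conserved(_pair("NCDE", "NWDE"), 1, k=2) is False
        # right flank not conserved
        assert flank_conserved(_pair("ANCDE", "ANWDF"), 2, k=2) is False

    def test_flank_gap_breaks_conservation(self):
        assert flank_conserved(_pair("ANCDE", "A-WDE"), 2, k=2) is False

    def test_gap_ok_window(self):
        assert gap_ok(_pair("ANCDEFG", "ANWDEFG"), 2, window=3) is True
        # gap exactly three columns away trips the filter
        assert gap_ok(_pair("ANCDE-G", "ANWDEFG"), 2, window=3) is False
        # gap four columns away does not
        assert gap_ok(_pair("ANCDEF-HI", "ANWDEFGHI"), 2, window=3) is True


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

class TestContactMap:
    def test_line_geometry(self):
        st = build_structure(
            [(1, "A", [(0.0, 0.0, 0.0)]), (2, "G", [(4.0, 0.0, 0.0)]), (3, "L", [(8.0, 0.0, 0.0)])]
        )
        cmap = contact_map(st, 5.0)
        assert cmap.contacts == {1: frozenset({2}), 2: frozenset({1, 3}), 3: frozenset({2})}

    def test_exact_cutoff_distance_is_not_a_contact(self):
        st = build_structure([(1, "A", [(0.0, 0.0, 0.0)]), (2, "G", [(5.0, 0.0, 0.0)])])
        cmap = contact_map(st, 5.0)
        assert cmap.contacts == {1: frozenset(), 2: frozenset()}

    def test_min_over_atom_pairs(self):
        # residue centres 7 apart, but one side-chain atom bridges the gap
        st = build_structure(
            [(1, "A", [(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)]), (2, "G", [(7.0, 0.0, 0.0)])]
        )
        assert contact_map(st, 5.0).contacts[1] == frozenset({2})

    @pytest.mark.parametrize("atoms", [1, 3])
    def test_matches_brute_force_on_random_toys(self, atoms):
        for seed in range(15):
            st, _ = gen_toy_structure(
                int(np.random.default_rng(seed).integers(2, 21)),
                seed=seed, mode="random", atoms_per_residue=atoms,
            )
            assert dict(contact_map(st, 5.0).contacts) == brute_force_contacts(st, 5.0)

    def test_symmetry_enforced(self):
        with pytest.raises(StructureError):
            ContactMap(5.0, {1: frozenset({2}), 2: frozenset()})
        with pytest.raises(StructureError):
            ContactMap(5.0, {1: frozenset({1})})

    def test_tightening_cutoff_never_adds_contacts(self):
        st, _ = gen_toy_structure(15, seed=4, mode="random")
        wide = contact_map(st, 5.0)
        tight = contact_map(st, 4.0)
        for pos, nbrs in tight.contacts.items():
            assert nbrs <= wide.contacts[pos]

    def test_waters_and_ligands_excluded(self):
        import gemmi

        st = build_structure([(1, "A", [(0.0, 0.0, 0.0)]), (2, "G", [(4.0, 0.0, 0.0)])])
        water = gemmi.Residue()
        water.name = "HOH"
        water.seqid = gemmi.SeqId(3, " ")
        atom = gemmi.Atom()
        atom.name = "O"
        atom.pos = gemmi.Position(2.0, 0.0, 0.0)
        atom.element = gemmi.Element("O")
        st[0][0].add_residue(water)
        cmap = contact_map(st, 5.0)
        assert 3 not in cmap.positions

    def test_altloc_resolved_to_highest_occupancy(self):
        import gemmi

        st = build_structure([(1, "A", [(0.0, 0.0, 0.0)]), (2, "G", [(20.0, 0.0, 0.0)])])
        # add an alternate CA for residue 2: low occupancy near residue 1
        alt = gemmi.Atom()
        alt.name = "CA"
        alt.pos = gemmi.Position(3.0, 0.0, 0.0)
        alt.element = gemmi.Element("C")
        alt.occ = 0.2
        st[0][0][1].add_atom(alt)
        # the kept conformer (occ 1.0) is 20 A away: no contact
        assert contact_map(st, 5.0).contacts[1] == frozenset()

    def test_structure_without_atoms_is_error(self):
        import gemmi

        with pytest.raises(StructureError):
            contact_map(gemmi.Structure())


class TestContactsConserved:
    CMAP = ContactMap(5.0, {
        2: frozenset({5}), 5: frozenset({2, 7}), 7: frozenset({5}),
        1: frozenset(), 3: frozenset(), 4: frozenset(), 6: frozenset(),
    })

    def test_identical_contacts_pass(self):
        pair = _pair("ANCDEFG", "ANCDWFG")  # substitution at query position 5
        assert contacts_conserved(pair, 5, self.CMAP) is True

    def test_single_differing_contact_fails(self):
        pair = _pair("ANCDEFG", "AYCDWFG")  # contact residue 2 differs
        assert contacts_conserved(pair, 5, self.CMAP) is False

    def test_contact_aligned_to_gap_fails(self):
        pair = _pair("ANCDEFG", "A-CDWFG")
        assert contacts_conserved(pair, 5, self.CMAP) is False

    def test_isolated_residue_passes_vacuously(self):
        pair = _pair("ANCDEFG", "ANWDEFG")
        assert contacts_conserved(pair, 3, self.CMAP) is True

    def test_unresolved_position_raises_distinct_signal(self):
        pair = _pair("ANCDEFGHI", "ANCDEFGWI")
        with pytest.raises(ResidueNotResolvableError):
            contacts_conserved(pair, 8, self.CMAP)


def test_contact_map_for_query_by_author_numbering_and_by_alignment():
    seq = "ACDEFGHIKL"
    query = ReferenceSequence("q", seq)
    residues = [(i + 1, aa, [(4.0 * i, 0.0, 0.0)]) for i, aa in enumerate(seq)]
    st = build_structure(residues)
    direct = contact_map_for_query(st, query, 5.0)
    assert direct.contacts[1] == frozenset({2})
    # same structure renumbered with an offset: falls back to alignment mapping
    shifted = build_structure([(i + 101, aa, [(4.0 * i, 0.0, 0.0)]) for i, aa in enumerate(seq)])
    remapped = contact_map_for_query(shifted, query, 5.0)
    assert dict(remapped.contacts) == dict(direct.contacts)


# ---------------------------------------------------------------------------
# neutral-set construction
# ---------------------------------------------------------------------------

def _empty_cmap(n: int) -> ContactMap:
    return ContactMap(5.0, {i: frozenset() for i in range(1, n + 1)})


QUERY40 = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"


def _sub_at(query: str, pos: int, alt: str, extra: dict = None) -> str:
    out = list(query)
    out[pos - 1] = alt
    for p, a in (extra or {}).items():
        out[p - 1] = a
    return "".join(out)


class TestBuildNeutralSet:
    def test_highest_identity_pair_wins_for_shared_substitution(self):
        query = ReferenceSequence("q", QUERY40)
        hi = _pair(QUERY40, _sub_at(QUERY40, 10, "I"), "close_homolog")
        lo = _pair(QUERY40, _sub_at(QUERY40, 10, "I", {30: "S"}), "far_homolog")
        accepted = build_neutral_set(query, [lo, hi], _empty_cmap(40))
        l10 = [c for c in accepted if c.variant.position == 10]
        assert len(l10) == 1
        assert l10[0].subject_id == "close_homolog"
        assert l10[0].source_identity == pytest.approx(97.5)

    def test_equal_identity_tie_breaks_on_smaller_subject_id(self):
        query = ReferenceSequence("q", QUERY40)
        a = _pair(QUERY40, _sub_at(QUERY40, 10, "I"), "zeta")
        b = _pair(QUERY40, _sub_at(QUERY40, 10, "I"), "alpha")
        accepted = build_neutral_set(query, [a, b], _empty_cmap(40))
        assert accepted[0].subject_id == "alpha"

    def test_identity_threshold_is_strictly_greater(self):
        query = ReferenceSequence("q", QUERY40)
        # 4 mismatches in 40 columns -> exactly 90%: excluded
        at90 = _pair(QUERY40, _sub_at(QUERY40, 10, "I", {20: "C", 25: "A", 30: "S"}), "s")
        assert percent_identity(at90) == 90.0
        assert build_neutral_set(query, [at90], _empty_cmap(40)) == []

    def test_failing_one_filter_excludes_with_outcome_recorded(self):
        query = ReferenceSequence("q", QUERY40)
        # substitutions at adjacent positions break each other's flanks
        pair = _pair(QUERY40, _sub_at(QUERY40, 10, "I", {11: "C"}), "s")
        accepted, candidates = build_neutral_set(
            query, [pair], _empty_cmap(40), return_all=True
        )
        assert accepted == []
        assert all(c.flank_ok is False for c in candidates)
        assert all(c.gap_ok and c.contacts_ok for c in candidates)

    def test_accepted_set_deduplicated_and_sorted(self):
        rng = np.random.default_rng(17)
        res = gen_homolog_pair(random_homolog_spec(rng))
        accepted = build_neutral_set(res.query, [res.pair, res.pair], res.structure)
        keys = [(c.variant.ref_aa, c.variant.position, c.variant.alt_aa) for c in accepted]
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys, key=lambda k: (k[1], k[2]))

    def test_removing_any_filter_only_enlarges_the_accepted_set(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            res = gen_homolog_pair(random_homolog_spec(rng))
            base = {str(c.variant) for c in
                    build_neutral_set(res.query, [res.pair], res.structure)}
            relaxed_configs = [
                BenchmarkConfig(flank_k=0),
                BenchmarkConfig(gap_window=0),
                BenchmarkConfig(identity_min=0.0),
            ]
            for cfg in relaxed_configs:
                bigger = {str(c.variant) for c in
                          build_neutral_set(res.query, [res.pair], res.structure, cfg)}
                assert base <= bigger
            # neutralising the contact filter via an empty contact map
            no_contacts = _empty_cmap(res.pair.query_row.count("-") + len(res.query))
            bigger = {str(c.variant) for c in
                      build_neutral_set(res.query, [res.pair], no_contacts)}
            assert base <= bigger

    def test_no_pairs_is_error(self):
        with pytest.raises(AlignmentError):
            build_neutral_set(ReferenceSequence("q", QUERY40), [], _empty_cmap(40))


def test_align_homolog_recovers_indel():
    pair = align_homolog("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKMNPQRSTVWY", "del_L10")
    assert pair.query_row.replace("-", "") == "ACDEFGHIKLMNPQRSTVWY"
    assert pair.subject_row.count("-") == 1
    assert percent_identity(pair) == 100.0
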