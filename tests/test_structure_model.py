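"""Structure I/O, role assignment, dyad frame and coverage reporting."""

import numpy as np
import pytest

from nucdeform import sequences as sq
from nucdeform.errors import AnchorError, RoleError, StructureParseError
from nucdeform.model import (
    AtomRecord,
    NucleosomeModel,
    assign_nucleosome_roles,
    build_coordinate_frame,
    coverage_report,
    read_structure,
    write_structure,
)

MINI_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
END
"""


class TestReadWrite:
    def test_minimal_pdb_snippet(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        m = read_structure(p)
        assert len(m.chains) == 1
        assert len(m.chains[0].residues) == 1
        assert m.n_atoms() == 3

    def test_round_trip_preserves_atoms(self, ideal, tmp_path):
        p = tmp_path / "m.pdb"
        write_structure(ideal.structure, p)
        m2 = read_structure(p)
        assert m2.n_atoms() == ideal.structure.n_atoms()
        names1 = [a.name for _, a in ideal.structure.iter_atoms()]
        names2 = [a.name for _, a in m2.iter_atoms()]
        assert names1 == names2
        x1 = np.array([a.xyz for _, a in ideal.structure.iter_atoms()])
        x2 = np.array([a.xyz for _, a in m2.iter_atoms()])
        # PDB coordinate columns carry 3 decimals
        assert np.max(np.abs(x1 - x2)) < 1.5e-3

    def test_generated_dna_atom_count(self, ideal, params):
        n_dna = sum(
            len(r.atoms)
            for role in ("strand_top", "strand_bottom")
            for r in ideal.chain_for_role(role).residues
        )
        # 11 backbone atoms per nucleotide, 5' termini missing P/OP1/OP2
        assert n_dna == 2 * (params.n_bp * 11 - 3)

    def test_mmcif_read_matches_pdb(self, small_ideal, tmp_path):
        import gemmi

        pdb_path = tmp_path / "m.pdb"
        write_structure(small_ideal.structure, pdb_path)
        st = gemmi.read_pdb(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "m.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        m_cif = read_structure(cif_path)  # auto-detects mmcif by suffix
        assert m_cif.n_atoms() == small_ideal.structure.n_atoms()
        assert m_cif.source_format == "mmcif"

    def test_missing_file_and_bad_format(self, tmp_path):
        with pytest.raises(StructureParseError):
            read_structure(tmp_path / "nope.pdb")
        p = tmp_path / "x.pdb"
        p.write_text(MINI_PDB)
        with pytest.raises(Exception):
            read_structure(p, format="xyzzy")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(pdb)
        m = read_structure(p)
        res = m.chains[0].residues[0]
        assert len(res.atoms) == 1
        assert res.atoms[0].xyz[0] == pytest.approx(5.0)


class TestBfactorChannel:
    def test_zero_channel(self, ideal, tmp_path):
        channel = {r.ref: 0.0 for r in ideal.structure.iter_residues()}
        p = write_structure(ideal.structure, tmp_path / "b0.pdb", bfactor_channel=channel)
        m2 = read_structure(p)
        assert all(a.bfactor == 0.0 for _, a in m2.iter_atoms())

    def test_clamp_and_round_trip(self, small_ideal, tmp_path):
        residues = list(small_ideal.structure.iter_residues())
        channel = {r.ref: 1234.5 for r in residues[:1]}
        channel.update({r.ref: 7.25 for r in residues[1:]})
        p = write_structure(small_ideal.structure, tmp_path / "b.pdb", bfactor_channel=channel)
        m2 = read_structure(p)
        out = list(m2.iter_residues())
        assert all(a.bfactor == pytest.approx(999.99, abs=0.01) for a in out[0].atoms)
        for r in out[1:]:
            mean_b = np.mean([a.bfactor for a in r.atoms])
            assert mean_b == pytest.approx(7.25, abs=0.01)


class TestRoles:
    def test_explicit_config(self, ideal):
        config = dict(ideal.roles)
        nm = assign_nucleosome_roles(ideal.structure, config)
        assert nm.roles == config

    def test_duplicate_strand_role_conflict(self, ideal):
        config = dict(ideal.roles)
        config["I"] = "strand_bottom"  # J already is
        with pytest.raises(RoleError):
            assign_nucleosome_roles(ideal.structure, config)

    def test_auto_assigns_histone_classes(self, ideal):
        nm = assign_nucleosome_roles(ideal.structure, "auto")
        by_role = {r: cid for cid, r in nm.roles.items()}
        # H3-class goes to the ~135-residue chains
        assert len(nm.structure.chain(by_role["H3"])) == 135
        assert len(nm.structure.chain(by_role["H4"])) == 102
        assert sorted(set(nm.roles.values())) == sorted(
            {"H3", "H4", "H2A", "H2B", "H3'", "H4'", "H2A'", "H2B'",
             "strand_top", "strand_bottom"}
        )

    def test_auto_needs_enough_chains(self, small_ideal):
        import copy

        m = copy.deepcopy(small_ideal.structure)
        m.chains = m.chains[:5]
        with pytest.raises(RoleError):
            assign_nucleosome_roles(m, "auto")


class TestFrame:
    def test_partner_convention(self, ideal):
        top = ideal.strand_residues("strand_top")
        bottom = ideal.strand_residues("strand_bottom")
        assert set(top) == {-p for p in bottom}
        # increasing 5'->3' within each strand
        for role in ("strand_top", "strand_bottom"):
            chain = ideal.chain_for_role(role)
            pos = [ideal.frame[r.ref.key()] for r in chain.residues]
            assert pos == sorted(pos)

    def test_dyad_at_terminal_degenerate(self, small_ideal):
        nm = NucleosomeModel(structure=small_ideal.structure.copy(), roles=dict(small_ideal.roles))
        first = {role: nm.chain_for_role(role).residues[0].ref.auth_seq
                 for role in ("strand_top", "strand_bottom")}
        build_coordinate_frame(nm, first)
        for role in ("strand_top", "strand_bottom"):
            pos = sorted(nm.strand_residues(role))
            assert pos[0] == 0 and pos[-1] == len(pos) - 1

    def test_unresolvable_dyad(self, small_ideal):
        nm = NucleosomeModel(structure=small_ideal.structure.copy(), roles=dict(small_ideal.roles))
        with pytest.raises(AnchorError):
            build_coordinate_frame(nm, {"strand_top": 9999, "strand_bottom": 9999})


class TestPrintedSequences:
    def test_top_strand_length(self):
        assert len(sq.WIDOM601_TOP) == 152

    def test_affine_index_map_integer_exact(self):
        a, b, resid = sq.fit_affine_index_map()
        assert resid < 1e-9
        assert a == pytest.approx(1.0) and b == pytest.approx(-78.0)

    @pytest.mark.parametrize("pos", [-30, -50, -53, -55])
    def test_inosine_maps_to_stated_position(self, pos):
        s = sq.WIDOM601_BOTTOM_DI[pos]
        assert len(s) == 152
        assert sq.bottom_index_to_position(sq.inosine_index(s)) == pos

    def test_strands_complementary_except_at_lesion(self):
        # top index j pairs bottom index 153-j; the top strand keeps the
        # undamaged base opposite the inosine, so each variant differs from
        # perfect complementarity at exactly that one partner site
        for s in sq.WIDOM601_BOTTOM_DI.values():
            paired = "".join(sq.complement(b) for b in reversed(s))
            mism = [i + 1 for i, (x, y) in enumerate(zip(paired, sq.WIDOM601_TOP))
                    if x != y]
            assert mism == [153 - sq.inosine_index(s)]


class TestCoverage:
    def test_complete_fixture_one_span(self, ideal, params):
        half = params.half_span
        rep = coverage_report(ideal, expected={r: (-half, half) for r in
                                               ("strand_top", "strand_bottom")})
        for role in ("strand_top", "strand_bottom"):
            assert rep.spans[role] == [(-half, half)]
            assert rep.gaps[role] == []
            assert rep.terminal_truncations[role] == []

    def test_terminal_deletion_flagged(self, ideal, params):
        m = ideal.copy()
        for role in ("strand_top", "strand_bottom"):
            chain = m.chain_for_role(role)
            doomed = {r.ref.key() for r in chain.residues
                      if -77 <= m.frame[r.ref.key()] <= -61}
            chain.residues = [r for r in chain.residues if r.ref.key() not in doomed]
        half = params.half_span
        rep = coverage_report(m, expected={r: (-half, half) for r in
                                           ("strand_top", "strand_bottom")})
        for role in ("strand_top", "strand_bottom"):
            assert len(rep.terminal_truncations[role]) == 1
            start, end, length = rep.terminal_truncations[role][0]
            assert (start, end, length) == (-73, -61, 13)

    def test_partial_model_span(self, ideal):
        # emulate a model whose damaged strand is resolved only from -59 to +72
        m = ideal.copy()
        chain = m.chain_for_role("strand_bottom")
        chain.residues = [r for r in chain.residues
                          if -59 <= m.frame[r.ref.key()] <= 72]
        rep = coverage_report(m)
        assert rep.spans["strand_bottom"] == [(-59, 72)]

    def test_atom_record_invariants(self):
        with pytest.raises(ValueError):
            AtomRecord("CA", "C", np.array([np.nan, 0, 0]))
        with pytest.raises(ValueError):
            AtomRecord("CA", "C", np.zeros(3), occupancy=1.5)
        with pytest.raises(ValueError):
            AtomRecord("", "C", np.zeros(3))
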