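"""Structure parsing, interface identification and curation rules."""

import numpy as np
import pytest

from parepi.structio import (CurationInput, NoInterfaceError, PDBParseError,
                             StructureError, curate, deduplicate,
                             find_interface, parse_complex, sequence_identity)

from conftest import make_record


def atom_line(serial, name, resname, chain, resseq, xyz, altloc=" ", occ=1.0):
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:>3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.00:6.2f}           C")


SPEC = {"H": "H", "L": "L", "A": "A"}


def minimal_pdb(extra_lines=()):
    lines = [
        atom_line(1, "CA", "ALA", "H", 1, (0, 0, 0)),
        atom_line(2, "CB", "ALA", "H", 1, (2, 0, 0)),
        atom_line(3, "CA", "GLY", "L", 1, (1, 1, 1)),
        atom_line(4, "CB", "LYS", "A", 1, (0, 0, 0)),
        atom_line(5, "CG", "LYS", "A", 1, (2, 0, 0)),
        atom_line(6, "CD", "LYS", "A", 1, (4, 0, 0)),
    ]
    return "\n".join(list(lines) + list(extra_lines) + ["END"]) + "\n"


class TestParseComplex:
    def test_c_mu_rules(self):
        """Single side-chain atom, glycine C-alpha rule, and the 3-atom mean."""
        rec = parse_complex(minimal_pdb(), SPEC)
        ala = rec.heavy_chain[0]
        assert np.allclose(ala.c_mu, (2, 0, 0))          # own single side atom
        gly = rec.light_chain[0]
        assert np.allclose(gly.c_mu, (1, 1, 1))          # C-alpha for Gly
        lys = rec.antigen_chains["A"][0]
        assert np.allclose(lys.c_mu, (2, 0, 0))          # arithmetic mean

    def test_missing_declared_chain(self):
        with pytest.raises(StructureError, match="Z"):
            parse_complex(minimal_pdb(), {"H": "H", "L": "L", "Z": "A"})

    def test_bad_chain_spec(self):
        with pytest.raises(StructureError):
            parse_complex(minimal_pdb(), {"H": "H", "A": "A"})

    def test_unparseable_atom_record_reports_line(self):
        bad = minimal_pdb().replace("   2.000", "   x.bad", 1)
        with pytest.raises(PDBParseError, match="line 2"):
            parse_complex(bad, SPEC)

    def test_unk_residues_reported_not_dropped(self):
        extra = [atom_line(7, "CB", "UNK", "A", 2, (0, 0, 3))]
        rec = parse_complex(minimal_pdb(extra), SPEC)
        assert rec.unk_residues == ["A2"]
        assert len(rec.antigen_chains["A"]) == 2

    def test_altloc_highest_occupancy(self):
        extra = [
            atom_line(7, "CB", "SER", "A", 2, (0, 0, 1), altloc="A", occ=0.4),
            atom_line(8, "CB", "SER", "A", 2, (0, 0, 2), altloc="B", occ=0.6),
        ]
        rec = parse_complex(minimal_pdb(extra), SPEC)
        ser = rec.antigen_chains["A"][1]
        assert np.allclose(ser.c_mu, (0, 0, 2))

    def test_altloc_tie_prefers_a(self):
        extra = [
            atom_line(7, "CB", "SER", "A", 2, (0, 0, 1), altloc="A", occ=0.5),
            atom_line(8, "CB", "SER", "A", 2, (0, 0, 2), altloc="B", occ=0.5),
        ]
        rec = parse_complex(minimal_pdb(extra), SPEC)
        assert np.allclose(rec.antigen_chains["A"][1].c_mu, (0, 0, 1))

    def test_c_mu_within_side_chain_bounding_box(self):
        rec = parse_complex(minimal_pdb(), SPEC)
        for res in rec.antibody_residues() + rec.antigen_residues():
            side = [c for _, c in res.side_chain_atoms()]
            if not side:
                continue
            side = np.array(side)
            assert np.all(res.c_mu >= side.min(axis=0) - 1e-12)
            assert np.all(res.c_mu <= side.max(axis=0) + 1e-12)


def brute_force_interface(ab_pts, ag_pts, cutoff=6.0, radius=40.0):
    para, epi = set(), set()
    for i, a in enumerate(ab_pts):
        for j, g in enumerate(ag_pts):
            if np.linalg.norm(np.asarray(a) - np.asarray(g)) <= cutoff:
                para.add(i)
                epi.add(j)
    if not para:
        return None
    center = np.mean([ab_pts[i] for i in sorted(para)], axis=0)
    para = {i for i in para if np.linalg.norm(ab_pts[i] - center) <= radius}
    epi = {j for j in epi if np.linalg.norm(ag_pts[j] - center) <= radius}
    return (para, epi) if para and epi else None


class TestFindInterface:
    def test_boundary_inclusion(self):
        rec = make_record([(0, 0, 0)], [(0, 0, 5.9)])
        para, epi = find_interface(rec)
        assert len(para.members) == 1 and len(epi.members) == 1

    def test_boundary_exclusion(self):
        rec = make_record([(0, 0, 0)], [(0, 0, 6.1)])
        with pytest.raises(NoInterfaceError):
            find_interface(rec)

    def test_cdr_centre_filter_removes_remote_contacts(self):
        """A secondary contact 100 A from the main site is filtered out."""
        ab = [(0, 0, 0), (3, 0, 0), (0, 3, 0), (100, 0, 0)]
        ag = [(0, 0, 5), (3, 0, 5), (0, 3, 5), (100, 0, 5)]
        rec = make_record(ab, ag)
        para, epi = find_interface(rec)
        assert {r.c_mu[0] for r in para.members} == {0.0, 3.0}
        assert {r.c_mu[0] for r in epi.members} == {0.0, 3.0}

    def test_matches_brute_force_on_random_complexes(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(30):
            ab = rng.uniform(-12, 12, (15, 3))
            ag = rng.uniform(-12, 12, (15, 3)) + np.array([0, 0, 4.0])
            rec = make_record(list(ab), list(ag))
            expected = brute_force_interface(ab, ag)
            if expected is None:
                with pytest.raises(NoInterfaceError):
                    find_interface(rec)
                continue
            para, epi = find_interface(rec)
            got_p = {r.number - 1 if r.chain_id == "H" else 14 for r in para.members}
            got_e = {r.number - 1 for r in epi.members}
            assert got_p == expected[0]
            assert got_e == expected[1]
            checked += 1
        assert checked >= 10

    def test_membership_symmetry(self):
        """a within cutoff of b iff b within cutoff of a, on random complexes."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            ab = rng.uniform(-10, 10, (8, 3))
            ag = rng.uniform(-10, 10, (8, 3))
            d = np.linalg.norm(ab[:, None] - ag[None], axis=-1)
            assert np.array_equal((d <= 6.0), (d.T <= 6.0).T)


class TestCurate:
    def _toy(self, rec_id="c1", n_ag=60):
        rng = np.random.default_rng(3)
        ab_xy = rng.uniform(-8, 8, (6, 2))
        ab = [(x, y, 0) for x, y in ab_xy]
        ag = [(x, y, 4.5) for x, y in ab_xy + rng.normal(0, .2, (6, 2))]
        ag += [(x, y, 30.0) for x, y in rng.uniform(-8, 8, (n_ag - 6, 2))]
        return make_record(ab, ag, rec_id=rec_id)

    def test_valid_complex_kept(self):
        rep = curate([CurationInput(self._toy())])
        assert rep.kept == ["c1"] and rep.discarded == []

    def test_small_antigen_discarded(self):
        rep = curate([CurationInput(self._toy(n_ag=49))])
        assert rep.discarded == [("c1", "antigen_size")]

    def test_nonprotein_antigen_discarded(self):
        rep = curate([CurationInput(self._toy(), is_protein_antigen=False)])
        assert rep.discarded == [("c1", "antigen_size")]

    def test_missing_residues_rule(self):
        rep = curate([CurationInput(self._toy(), n_missing_residues=51)])
        assert rep.discarded == [("c1", "missing_residues")]
        rep = curate([CurationInput(self._toy(), n_missing_residues=50)])
        assert rep.kept == ["c1"]

    def test_unk_rule(self):
        rec = self._toy()
        rec.unk_residues = ["A7"]
        rep = curate([CurationInput(rec)])
        assert rep.discarded == [("c1", "unk_residues")]

    def test_first_failing_rule_cited(self):
        rec = self._toy(n_ag=49)
        rec.unk_residues = ["A1"]
        rep = curate([CurationInput(rec, n_missing_residues=99)])
        assert rep.discarded == [("c1", "antigen_size")]

    def test_interface_size_rule(self):
        rec = make_record([(0, 0, 0), (3, 0, 0), (90, 0, 0)],
                          [(0, 0, 5)] + [(x, 0, 40) for x in range(60)])
        rep = curate([CurationInput(rec)])
        assert rep.discarded == [(rec.id, "interface_size")]

    def test_partition_covers_input_disjointly(self):
        inputs = [CurationInput(self._toy(f"c{i}", n_ag=49 + i)) for i in range(4)]
        rep = curate(inputs)
        assert sorted(rep.kept + [i for i, _ in rep.discarded]) == \
            [f"c{i}" for i in range(4)]
        assert not set(rep.kept) & {i for i, _ in rep.discarded}


def lcs_length(a, b):
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            dp[i, j] = max(dp[i - 1, j], dp[i, j - 1],
                           dp[i - 1, j - 1] + (a[i - 1] == b[j - 1]))
    return int(dp[len(a), len(b)])


class TestDeduplicate:
    def test_identical_pair_keeps_longest_antigen(self):
        out = deduplicate([("c1", "ARNDC", "G" * 20), ("c2", "ARNDC", "G" * 21)])
        assert out == ["c2"]

    def test_and_rule_keeps_dissimilar_cdrs(self):
        out = deduplicate([("c1", "AAAAAA", "GGGGG"), ("c2", "AAARRR", "GGGGG")])
        assert sorted(out) == ["c1", "c2"]

    def test_empty_input(self):
        assert deduplicate([]) == []

    def test_identity_matches_lcs_oracle(self):
        rng = np.random.default_rng(2)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(20):
            a = "".join(rng.choice(aas, rng.integers(5, 15)))
            b = "".join(rng.choice(aas, rng.integers(5, 15)))
            expected = lcs_length(a, b) / max(len(a), len(b))
            assert sequence_identity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_grouping_matches_exhaustive_oracle(self):
        items = [
            ("a", "ARNDKK", "GGGGGGGGGG"),
            ("b", "ARNDKK", "GGGGGGGGGGG"),  # same cluster as a (longer antigen)
            ("c", "WWYYFF", "GGGGGGGGGG"),   # different CDR -> own cluster
            ("d", "ARNDKR", "GGGGGGGGG"),    # CDR id 5/6 > 0.8, ag id 9/10 = .9 -> kept
            ("e", "ARNDKK", "PPPPPPPPPP"),   # different antigen -> own cluster
        ]

        def oid(x, y):
            return lcs_length(x, y) / max(len(x), len(y))

        order = sorted(items, key=lambda c: (-len(c[2]), c[0]))
        assigned, kept = set(), []
        for i, (cid, cdr, ag) in enumerate(order):
            if cid in assigned:
                continue
            assigned.add(cid)
            kept.append(cid)
            for cid2, cdr2, ag2 in order[i + 1:]:
                if cid2 not in assigned and oid(cdr, cdr2) > 0.8 and oid(ag, ag2) > 0.9:
                    assigned.add(cid2)
        assert deduplicate(items) == kept
        assert set(kept) == {"b", "c", "d", "e"}

    def test_permutation_invariance(self):
        items = [("a", "ARNDKK", "GGGGGGGGGG"), ("b", "ARNDKK", "GGGGGGGGGA"),
                 ("c", "WWYYFF", "GGGGGGGGGG")]
        out1 = deduplicate(items)
        out2 = deduplicate(items[::-1])
        assert sorted(out1) == sorted(out2)
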