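import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etgating.structure import (AtomLookupError, HBondCriteria, MotifHit,
                                StructureParseError, ca_distance,
                                find_small_motifs, hbond_occupancy,
                                interface_profile, read_structure,
                                read_trajectory_pdb, tally_conservation)
from etgating.scales import SMALL_RESIDUES
from etgating.synth import gen_alignment, gen_trajectory

from conftest import make_multimodel_pdb_text, make_pdb_text


class TestReadStructure:
    def test_minimal_fixture_parsed(self):
        text = make_pdb_text([("A", 1, "GLY", "CA", (0.0, 0.0, 0.0)),
                              ("A", 2, "ALA", "CA", (3.8, 0.0, 0.0))])
        model = read_structure(text)
        assert model.residue_numbers("A") == [1, 2]
        np.testing.assert_allclose(model.ca_coord("A", 2), [3.8, 0.0, 0.0])

    def test_multi_model_selection(self):
        atoms1 = [("A", 1, "GLY", "CA", (0.0, 0.0, 0.0))]
        atoms2 = [("A", 1, "GLY", "CA", (1.0, 2.0, 3.0))]
        text = make_multimodel_pdb_text([atoms1, atoms2])
        model2 = read_structure(text, model_index=2)
        np.testing.assert_allclose(model2.ca_coord("A", 1), [1.0, 2.0, 3.0])

    def test_empty_content_rejected(self):
        with pytest.raises(StructureParseError):
            read_structure("REMARK nothing here\n")


class TestCaDistance:
    def test_three_four_five_triangle(self):
        text = make_pdb_text([("A", 208, "GLY", "CA", (0.0, 0.0, 0.0)),
                              ("D", 208, "ALA", "CA", (3.0, 4.0, 0.0))])
        model = read_structure(text)
        assert ca_distance(model, ("A", 208), ("D", 208)) == pytest.approx(5.0)

    def test_symmetry(self, two_helix_model):
        d1 = ca_distance(two_helix_model, ("A", 205), ("D", 207))
        d2 = ca_distance(two_helix_model, ("D", 207), ("A", 205))
        assert d1 == d2 >= 0

    def test_missing_ca_named_in_error(self):
        text = make_pdb_text([("A", 208, "GLY", "CA", (0.0, 0.0, 0.0)),
                              ("D", 208, "ALA", "CB", (3.0, 4.0, 0.0))])
        model = read_structure(text)
        with pytest.raises(AtomLookupError, match="D/208"):
            ca_distance(model, ("A", 208), ("D", 208))


class TestInterfaceProfile:
    def test_matches_brute_force_minimum(self, two_helix_model):
        range_a = range(201, 213)
        range_b = range(201, 213)
        profile = interface_profile(two_helix_model, "A", range_a, "D", range_b)
        for pair in profile:
            na = pair.res_a[1]
            brute = min(ca_distance(two_helix_model, ("A", na), ("D", nb))
                        for nb in range_b)
            assert pair.ca_distance == pytest.approx(brute)

    def test_single_partner_range(self, two_helix_model):
        profile = interface_profile(two_helix_model, "A", [203, 204], "D", [205])
        for pair in profile:
            assert pair.res_b[1] == 205
            assert pair.ca_distance == pytest.approx(
                ca_distance(two_helix_model, ("A", pair.res_a[1]), ("D", 205)))

    def test_empty_range_rejected(self, two_helix_model):
        with pytest.raises(ValueError):
            interface_profile(two_helix_model, "A", [], "D", [205])


def brute_force_motifs(seq):
    small = set(SMALL_RESIDUES)
    gxxxg = [(i + 1, i + 5) for i in range(len(seq) - 4)
             if seq[i] in small and seq[i + 4] in small]
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] in small:
            j = i
            while j + 1 < len(seq) and seq[j + 1] in small:
                j += 1
            if j - i + 1 >= 3:
                runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return gxxxg, runs


class TestMotifs:
    def test_all_small_sequence(self):
        hits = find_small_motifs("AAAAA")
        kinds = {(h.kind, h.start, h.end) for h in hits}
        assert ("gxxxg_like", 1, 5) in kinds
        assert ("consecutive_small", 1, 5) in kinds

    def test_no_small_residues_no_hits(self):
        assert find_small_motifs("LLLLL") == []

    def test_d1_helix_fragment_matches_exhaustive_scan(self):
        seq = "LGVAGVFGGSLFSAM"
        hits = find_small_motifs(seq)
        gxxxg, runs = brute_force_motifs(seq)
        assert {(h.start, h.end) for h in hits if h.kind == "gxxxg_like"} == set(gxxxg)
        assert {(h.start, h.end) for h in hits
                if h.kind == "consecutive_small"} == set(runs)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            find_small_motifs("AXA")

    @settings(max_examples=150, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
    def test_agrees_with_brute_force_on_random_sequences(self, seq):
        hits = find_small_motifs(seq)
        gxxxg, runs = brute_force_motifs(seq)
        assert {(h.start, h.end) for h in hits if h.kind == "gxxxg_like"} == set(gxxxg)
        assert {(h.start, h.end) for h in hits
                if h.kind == "consecutive_small"} == set(runs)
        for h in hits:
            assert h.sequence == seq[h.start - 1:h.end]


class TestConservation:
    def test_exact_counting(self):
        seqs = ["LLVPFWGGSLLVPFW"] * 9 + ["LLVPFWGGALLVPFW"]
        tally = tally_conservation(seqs, window=(7, 8, 9))
        assert tally.fractions() == {"GGS": 0.9, "GGA": 0.1}
        assert tally.fraction_all_small == 1.0
        assert sum(tally.fractions().values()) == 1.0

    def test_single_sequence(self):
        tally = tally_conservation(["LLVPFWGGSLLVPFW"], window=(7, 8, 9))
        assert tally.fractions() == {"GGS": 1.0}

    def test_out_of_bounds_window_lists_offenders(self):
        with pytest.raises(ValueError, match="indices"):
            tally_conservation(["GGS", "GG"], window=(1, 2, 3))

    def test_generator_probabilities_recovered_within_binomial_error(self):
        n = 5000
        seqs, truth = gen_alignment(n, {"GGS": 0.894, "GGA": 0.106}, seed=17)
        tally = tally_conservation(seqs, window=(7, 8, 9))
        sd = np.sqrt(0.894 * 0.106 / n)
        assert tally.fractions()["GGS"] == pytest.approx(0.894, abs=4 * sd)
        assert tally.fraction_all_small == 1.0
        assert tally.triplet_counts == truth["counts"]


class TestHBond:
    def test_counting_nine_of_ten(self):
        frames, _ = gen_trajectory(10, 0.9, seed=1, exact_count=True)
        occ = hbond_occupancy(frames, ("A", 209, "OG"), ("D", 204, "O"))
        assert occ == 0.9

    def test_never_bonded(self):
        frames, _ = gen_trajectory(50, 0.0, seed=2)
        assert hbond_occupancy(frames, ("A", 209, "OG"), ("D", 204, "O")) == 0.0

    def test_stochastic_occupancy_within_binomial_error(self):
        n = 2000
        frames, truth = gen_trajectory(n, 0.32, seed=3)
        occ = hbond_occupancy(frames, ("A", 209, "OG"), ("D", 204, "O"))
        assert occ == truth["n_bonded"] / n
        assert occ == pytest.approx(0.32, abs=4 * np.sqrt(0.32 * 0.68 / n))

    def test_invariant_under_frame_order(self):
        frames, _ = gen_trajectory(40, 0.5, seed=4)
        occ = hbond_occupancy(frames, ("A", 209, "OG"), ("D", 204, "O"))
        assert hbond_occupancy(frames[::-1], ("A", 209, "OG"),
                               ("D", 204, "O")) == occ

    def test_angle_criterion_with_hydrogen(self):
        donor, hyd, acc = ("A", 1, "N"), ("A", 1, "H"), ("B", 2, "O")
        linear = {donor: np.array([0.0, 0.0, 0.0]),
                  hyd: np.array([1.0, 0.0, 0.0]),
                  acc: np.array([2.9, 0.0, 0.0])}
        bent = {donor: np.array([0.0, 0.0, 0.0]),
                hyd: np.array([1.0, 0.0, 0.0]),
                acc: np.array([1.0, 2.0, 0.0])}  # 90 degrees at H
        crit = HBondCriteria(require_hydrogens=True)
        assert hbond_occupancy([linear], donor, acc, crit, hyd) == 1.0
        assert hbond_occupancy([bent], donor, acc, crit, hyd) == 0.0

    def test_missing_atom_names_frame(self):
        frames, _ = gen_trajectory(5, 1.0, seed=5)
        del frames[3][("A", 209, "OG")]
        with pytest.raises(AtomLookupError, match="frame 3"):
            hbond_occupancy(frames, ("A", 209, "OG"), ("D", 204, "O"))


def test_trajectory_pdb_round_trip(tmp_path):
    models = [[("A", 1, "SER", "OG", (0.0, 0.0, 0.0)),
               ("D", 2, "ILE", "O", (d, 0.0, 0.0))]
              for d in (2.9, 5.5, 3.0, 6.0)]
    path = tmp_path / "traj.pdb"
    path.write_text(make_multimodel_pdb_text(models))
    frames = read_trajectory_pdb(path)
    assert len(frames) == 4
    occ = hbond_occupancy(frames, ("A", 1, "OG"), ("D", 2, "O"))
    assert occ == 0.5
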