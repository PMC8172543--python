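"""Structure parsing, edge detection, and network assembly."""

import numpy as np
import pytest

from vetflow import (
    Atom,
    Edge,
    EnergyNetwork,
    HEATER_POOL,
    SOLVENT,
    HeaterSpec,
    Residue,
    Structure,
    TransportParams,
    apply_quantum_correction,
    assemble_network,
    detect_heater_contacts,
    detect_hydrogen_bonds,
    integrate_master_equation,
    make_idealized_hairpin,
    parse_pdb,
    prune_contacts,
    sensor_peak_time,
    write_pdb,
)
from vetflow.structure_net import _amide_h_position, hydrogen_bond_distance

from conftest import build_hairpin_network, make_diamond


def _chain_structure(n, spacing=3.8):
    """Straight chain of backbone-only residues along x."""
    residues = []
    for i in range(1, n + 1):
        x = spacing * (i - 1)
        residues.append(Residue(i, "GLY", (
            Atom("N", "N", (x - 1.2, 0.8, 0.0)),
            Atom("CA", "C", (x, 0.0, 0.0)),
            Atom("C", "C", (x + 1.2, 0.8, 0.0)),
            Atom("O", "O", (x + 1.2, 2.0, 0.0)),
        )))
    return Structure(tuple(residues))


# ---------------------------------------------------------------------- PDB

class TestParsePDB:
    def test_round_trip_of_minimal_chain(self):
        s = _chain_structure(2)
        parsed = parse_pdb(write_pdb(s))
        assert len(parsed) == 2
        assert parsed.indices == [1, 2]

    def test_round_trip_of_idealized_hairpin(self, v1_structure):
        parsed = parse_pdb(write_pdb(v1_structure))
        assert [r.index for r in parsed.residues] == \
            [r.index for r in v1_structure.residues]
        assert [r.name for r in parsed.residues] == \
            [r.name for r in v1_structure.residues]
        for ra, rb in zip(parsed.residues, v1_structure.residues):
            assert [a.name for a in ra.atoms] == [a.name for a in rb.atoms]
            np.testing.assert_allclose(
                [a.xyz for a in ra.atoms], [a.xyz for a in rb.atoms],
                atol=1e-3)  # PDB fixed-point coordinates

    def test_missing_backbone_atom_is_hard_error(self):
        s = _chain_structure(2)
        text = "\n".join(line for line in write_pdb(s).splitlines()
                         if " N  " not in line) + "\n"
        with pytest.raises(ValueError, match="missing backbone atom"):
            parse_pdb(text)

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            parse_pdb("")

    def test_residue_indices_must_increase(self):
        r = _chain_structure(2).residues
        with pytest.raises(ValueError, match="strictly increasing"):
            Structure((r[1], r[0]))


# ------------------------------------------------------------ HB detection

def brute_force_hb(structure, cutoff, angle_min):
    """Independent all-pairs scan over donor/acceptor geometry."""
    found = set()
    for ra in structure.residues:
        for rb in structure.residues:
            if ra.index >= rb.index or abs(ra.index - rb.index) < 3:
                continue
            for donor, acceptor in ((ra, rb), (rb, ra)):
                if not acceptor.has_atom("O"):
                    continue
                n = donor.coord("N")
                o = acceptor.coord("O")
                if np.linalg.norm(n - o) > cutoff:
                    continue
                h = _amide_h_position(structure, donor)
                v1, v2 = n - h, o - h
                cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                    found.add((ra.index, rb.index))
    return found


class TestHydrogenBonds:
    def test_hairpin_pairs_match_brute_force(self, v1_structure):
        got = set(detect_hydrogen_bonds(v1_structure, 3.5, 120.0))
        assert got == brute_force_hb(v1_structure, 3.5, 120.0)

    def test_cross_strand_register_found_and_turn_excluded(self, v1_structure):
        pairs = set(detect_hydrogen_bonds(v1_structure))
        assert (1, 12) in pairs
        assert all(abs(i - j) >= 3 for i, j in pairs)

    def test_distant_residues_give_empty_list(self):
        s = _chain_structure(6, spacing=20.0)
        assert detect_hydrogen_bonds(s) == []

    def test_donor_sensor_terminal_pair_exists_for_v1(self, v1_structure):
        # efficient interstrand contact of the sensor with the heater terminus
        assert (1, 12) in detect_hydrogen_bonds(v1_structure)


class TestHeaterContacts:
    def test_v1_heater_contacts_opposite_strand(self, v1_structure):
        pairs = detect_heater_contacts(v1_structure, 1, 4.5)
        assert (1, 12) in pairs
        assert all(i == 1 and abs(i - j) >= 3 for i, j in pairs)

    def test_backbone_only_heater_has_no_contacts(self):
        s = _chain_structure(12)
        assert detect_heater_contacts(s, 1, 4.5) == []

    def test_tiny_cutoff_gives_empty_list(self, v1_structure):
        assert detect_heater_contacts(v1_structure, 1, 0.1) == []

    def test_invalid_heater_index_is_hard_error(self, v1_structure):
        with pytest.raises(ValueError, match="heater index"):
            detect_heater_contacts(v1_structure, 99, 4.5)


# --------------------------------------------------------------- assembly

class TestAssembly:
    def test_backbone_rate_scaling_rule(self):
        s = _chain_structure(3, spacing=3.8)
        params = TransportParams(D_B=8.66, D_C=0.0)
        net = assemble_network(s, [], [], params, heater_index=1)
        bb = [e.rate for e in net.edges if e.edge_class == "BB"]
        np.testing.assert_allclose(bb, [8.66 / 3.8**2] * 2, rtol=1e-12)
        np.testing.assert_allclose(bb[0], 0.5997, atol=5e-5)

    def test_contact_rate_scaling_rule(self, v1_structure):
        params = TransportParams(D_C=9.0, contact_exponent=2.0)
        net = assemble_network(v1_structure, [(1, 12)], [], params,
                               heater_index=1)
        r = hydrogen_bond_distance(v1_structure, 1, 12)
        (k_hb,) = [e.rate for e in net.edges if e.edge_class == "HB"]
        assert k_hb == pytest.approx(9.0 / r**2, rel=1e-12)

    def test_zero_contact_coefficient_matches_bb_only_solution(self, v1):
        full = build_hairpin_network(v1, TransportParams(D_C=0.0))
        bb_only = EnergyNetwork(
            full.nodes,
            [e for e in full.edges if e.edge_class not in ("HB", "HC")],
            full.dof)
        t1 = integrate_master_equation(full)
        t2 = integrate_master_equation(bb_only)
        np.testing.assert_allclose(t1.energies, t2.energies, atol=1e-12)

    def test_symmetry_of_intramolecular_rates(self, v1_network):
        K, idx = v1_network.rate_matrix()
        for e in v1_network.edges:
            if e.edge_class in ("BB", "HB", "HC"):
                assert K[idx[e.j], idx[e.i]] == K[idx[e.i], idx[e.j]]

    def test_scaling_homogeneity(self, v1):
        c = 2.5
        base = build_hairpin_network(v1, TransportParams())
        scaled = build_hairpin_network(
            v1, TransportParams(D_B=57.8 * c, D_C=1.7 * c))
        for e0, e1 in zip(base.edges, scaled.edges):
            if e0.edge_class in ("BB", "HB", "HC"):
                assert e1.rate == pytest.approx(c * e0.rate, rel=1e-12)
            else:
                assert e1.rate == e0.rate

    def test_unknown_pair_is_error(self, v1_structure):
        with pytest.raises(ValueError, match="unknown residue"):
            assemble_network(v1_structure, [(1, 99)], [], TransportParams())

    def test_network_json_round_trip(self, v1_network):
        back = EnergyNetwork.from_json(v1_network.to_json())
        assert back.nodes == v1_network.nodes
        assert [(e.i, e.j, e.edge_class, e.rate) for e in back.edges] == \
            [(e.i, e.j, e.edge_class, e.rate) for e in v1_network.edges]


# ------------------------------------------------------ quantum correction

class TestQuantumCorrection:
    def test_identity_at_q_one(self, v1_network):
        out = apply_quantum_correction(v1_network, 1.0)
        assert [e.rate for e in out.edges] == \
            [e.rate for e in v1_network.edges]

    def test_scales_all_but_cooling(self, v1_network):
        out = apply_quantum_correction(v1_network, 2.0)
        for e0, e1 in zip(v1_network.edges, out.edges):
            expected = e0.rate if e0.edge_class == "COOL" else 2.0 * e0.rate
            assert e1.rate == pytest.approx(expected, rel=1e-15)

    def test_reference_factor(self, v1_network):
        out = apply_quantum_correction(v1_network, 3.1)
        bb0 = next(e for e in v1_network.edges if e.edge_class == "BB")
        bb1 = next(e for e in out.edges if e.edge_class == "BB")
        assert bb1.rate == pytest.approx(3.1 * bb0.rate)
        cool0 = next(e for e in v1_network.edges if e.edge_class == "COOL")
        cool1 = next(e for e in out.edges if e.edge_class == "COOL")
        assert cool1.rate == cool0.rate

    def test_q_below_one_is_hard_error(self, v1_network):
        with pytest.raises(ValueError):
            apply_quantum_correction(v1_network, 0.9)

    def test_commutes_with_assembly(self, v1):
        q = 3.1
        via_params = build_hairpin_network(
            v1, TransportParams(D_B=57.8 * q, D_C=1.7 * q, k_h=1.0 * q))
        via_correction = apply_quantum_correction(
            build_hairpin_network(v1, TransportParams()), q)
        for e0, e1 in zip(via_params.edges, via_correction.edges):
            assert (e0.i, e0.j, e0.edge_class) == (e1.i, e1.j, e1.edge_class)
            assert e0.rate == pytest.approx(e1.rate, rel=1e-12)


# ----------------------------------------------------------------- pruning

class TestPruneContacts:
    def test_zero_fraction_is_identity(self, v1_network):
        out = prune_contacts(v1_network, fraction=0.0, seed=3)
        assert [e.rate for e in out.edges] == \
            [e.rate for e in v1_network.edges]

    def test_full_pruning_zeroes_contacts_and_delays_peak(self, v1_network):
        out = prune_contacts(v1_network, fraction=1.0, seed=3)
        for e in out.edges:
            if e.edge_class in ("HB", "HC"):
                assert e.rate == 0.0
        assert sensor_peak_time(out, 12) > sensor_peak_time(v1_network, 12)

    def test_explicit_shortcut_removal_delays_diamond_sensor(self):
        net = make_diamond()
        cut = prune_contacts(net, edges_to_remove=[(1, 4)])
        assert sensor_peak_time(cut, 4) > sensor_peak_time(net, 4)

    def test_reproducible_under_seed(self, v1_network):
        a = prune_contacts(v1_network, fraction=0.5, seed=11)
        b = prune_contacts(v1_network, fraction=0.5, seed=11)
        assert [e.rate for e in a.edges] == [e.rate for e in b.edges]

    def test_removing_donor_sensor_contacts_never_speeds_up_sensor(self, v1_network):
        # contacts that carry flux toward the sensor (incident to the donor or
        # the sensor) can only delay its peak when cut; distant contacts act as
        # parallel drains and are exempt from this monotonicity
        base = sensor_peak_time(v1_network, 12)
        contacts = [(e.i, e.j) for e in v1_network.edges
                    if e.edge_class in ("HB", "HC") and {1, 12} & {e.i, e.j}]
        assert contacts
        for pair in contacts:
            cut = prune_contacts(v1_network, edges_to_remove=[pair])
            assert sensor_peak_time(cut, 12) >= base - 1e-9


# ------------------------------------------------------------- heater spec

def test_heater_temperature_jump_near_600K():
    spec = HeaterSpec()
    assert spec.delta_T == pytest.approx(600.0, rel=0.10)
    assert HeaterSpec(E_exc=4.0).delta_T == pytest.approx(2 * spec.delta_T)


def test_edge_class_constraints():
    with pytest.raises(ValueError):
        Edge(1, 2, "XX", 1.0)
    with pytest.raises(ValueError, match="HEATER_POOL"):
        EnergyNetwork([HEATER_POOL, 1, SOLVENT], [Edge(1, HEATER_POOL, "HEAT", 1.0)])
    with pytest.raises(ValueError, match="SOLVENT"):
        EnergyNetwork([HEATER_POOL, 1, SOLVENT],
                      [Edge(SOLVENT, 1, "COOL", 1.0)])
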