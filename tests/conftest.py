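"""Shared fixtures: toy rate networks and idealized hairpin variants."""

import numpy as np
import pytest

from vetflow import (
    Edge,
    EnergyNetwork,
    HEATER_POOL,
    SOLVENT,
    TransportParams,
    VariantSpec,
    assemble_network,
    detect_heater_contacts,
    detect_hydrogen_bonds,
    make_idealized_hairpin,
)


def make_two_node() -> EnergyNetwork:
    """Two residues coupled at 0.5/ps, no heater, no sink rate."""
    return EnergyNetwork(
        [HEATER_POOL, 1, 2, SOLVENT],
        [Edge(HEATER_POOL, 1, "HEAT", 0.0), Edge(1, 2, "BB", 0.5)],
    )


def make_heater_chain(k_h=1.0, k_s=1.0 / 6.0) -> EnergyNetwork:
    """HEATER_POOL -> residue -> SOLVENT; peak time ln(kh/ks)/(kh-ks)."""
    return EnergyNetwork(
        [HEATER_POOL, 1, SOLVENT],
        [Edge(HEATER_POOL, 1, "HEAT", k_h), Edge(1, SOLVENT, "COOL", k_s)],
    )


def make_bb_chain(n: int, k: float = 1.0, k_s: float = 0.0) -> EnergyNetwork:
    """Linear backbone-only chain of n residues fed by the heater pool."""
    edges = [Edge(HEATER_POOL, 1, "HEAT", 1.0)]
    edges += [Edge(i, i + 1, "BB", k) for i in range(1, n)]
    if k_s > 0:
        edges += [Edge(i, SOLVENT, "COOL", k_s) for i in range(1, n + 1)]
    return EnergyNetwork([HEATER_POOL, *range(1, n + 1), SOLVENT], edges)


def make_toy_parallel(k_hb=1.0, k_bb=1.0, k_s=0.0) -> EnergyNetwork:
    """Source(1)–sensor(3) direct HB edge in parallel with a 1–2–3 BB chain."""
    edges = [
        Edge(HEATER_POOL, 1, "HEAT", 1.0),
        Edge(1, 3, "HB", k_hb),
        Edge(1, 2, "BB", k_bb),
        Edge(2, 3, "BB", k_bb),
    ]
    if k_s > 0:
        edges += [Edge(i, SOLVENT, "COOL", k_s) for i in (1, 2, 3)]
    return EnergyNetwork([HEATER_POOL, 1, 2, 3, SOLVENT], edges)


def make_diamond(k_s=1.0 / 6.0) -> EnergyNetwork:
    """Donor 1 and sensor 4 joined by an HB shortcut and a BB path 1–2–3–4."""
    return EnergyNetwork(
        [HEATER_POOL, 1, 2, 3, 4, SOLVENT],
        [
            Edge(HEATER_POOL, 1, "HEAT", 1.0),
            Edge(1, 4, "HB", 0.3),
            Edge(1, 2, "BB", 2.0),
            Edge(2, 3, "BB", 2.0),
            Edge(3, 4, "BB", 2.0),
            *(Edge(i, SOLVENT, "COOL", k_s) for i in (1, 2, 3, 4)),
        ],
    )


def build_hairpin_network(variant: VariantSpec,
                          params: TransportParams | None = None,
                          n_res: int = 12) -> EnergyNetwork:
    params = params or TransportParams()
    s = make_idealized_hairpin(n_res, variant=variant)
    hb = detect_hydrogen_bonds(s, params.hb_cutoff, params.hb_angle_min)
    hc = detect_heater_contacts(s, variant.donor, params.hc_cutoff)
    return assemble_network(s, hb, hc, params, heater_index=variant.donor)


@pytest.fixture(scope="session")
def v1():
    return VariantSpec("V1", 1, 12, "opposite")


@pytest.fixture(scope="session")
def v4():
    return VariantSpec("V4", 1, 5, "same")


@pytest.fixture(scope="session")
def v1_structure(v1):
    return make_idealized_hairpin(12, variant=v1)


@pytest.fixture(scope="session")
def v1_network(v1):
    return build_hairpin_network(v1)


@pytest.fixture(scope="session")
def v4_network(v4):
    return build_hairpin_network(v4)


def random_symmetric_network(rng: np.random.Generator, n_res: int,
                             p_edge: float = 0.4,
                             with_sink: bool = True) -> EnergyNetwork:
    """Random connected symmetric residue network for property tests."""
    edges = [Edge(HEATER_POOL, 1, "HEAT", float(rng.uniform(0.2, 2.0)))]
    for i in range(1, n_res):
        edges.append(Edge(i, i + 1, "BB", float(rng.uniform(0.1, 3.0))))
    for i in range(1, n_res + 1):
        for j in range(i + 2, n_res + 1):
            if rng.random() < p_edge:
                cls = "HB" if rng.random() < 0.5 else "HC"
                edges.append(Edge(i, j, cls, float(rng.uniform(0.05, 1.0))))
    if with_sink:
        edges += [Edge(i, SOLVENT, "COOL", float(rng.uniform(0.05, 0.3)))
                  for i in range(1, n_res + 1)]
    return EnergyNetwork([HEATER_POOL, *range(1, n_res + 1), SOLVENT], edges)
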