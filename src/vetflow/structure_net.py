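"""Build inter-residue energy-transport networks from peptide structure.

A peptide structure is reduced to a residue-level network whose edges carry
energy-transport rates (1/ps). Three intramolecular edge classes are
distinguished:

``BB``
    backbone edges between sequence neighbours, rate ``D_B / d²`` with ``d``
    the Cα–Cα distance;
``HB``
    interstrand backbone hydrogen bonds, rate ``D_C / r^p`` with ``r`` the
    donor–acceptor (N···O) distance;
``HC``
    heater contacts — side-chain heavy-atom contacts of the heater residue
    with sequence-distant residues, rate ``D_C / r^p`` with ``r`` the minimum
    heavy-atom distance.

Two further one-way channels complete the open system: a ``HEAT`` edge feeds
the photo-deposited quantum from a heater pool node into the heater residue
(rate ``k_h``), and ``COOL`` edges drain every residue into a solvent sink
(rate ``k_s``). Energies are tracked per degree of freedom, so symmetric
intramolecular rates make the uniform distribution stationary (equipartition).
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: Boltzmann constant in eV/K, used to convert heater excitation energy to ΔT.
K_B_EV = 8.617333262e-5

BACKBONE_ATOMS = ("N", "CA", "C")

HEATER_POOL = "HEATER_POOL"
SOLVENT = "SOLVENT"

EDGE_CLASSES = ("BB", "HB", "HC", "HEAT", "COOL")
#: Edge classes rescaled by the quantum correction (COOL is exempt: solvent
#: dissipation is slow compared to intramolecular steps and stays classical).
QUANTUM_SCALED = ("BB", "HB", "HC", "HEAT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    index: int          # 1-based sequence index
    name: str           # 3-letter code
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.index} ({self.name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coord(self, name: str) -> np.ndarray:
        return np.asarray(self.atom(name).xyz, dtype=float)

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of all non-hydrogen atoms, shape (n, 3)."""
        pts = [a.xyz for a in self.atoms if a.element.upper() != "H"]
        return np.asarray(pts, dtype=float)

    def sidechain_heavy_coords(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms
               if a.element.upper() != "H" and a.name not in ("N", "CA", "C", "O", "OXT")]
        return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class Structure:
    """Ordered residues of a single chain/model, coordinates in Å."""

    residues: tuple[Residue, ...]
    chain_id: str = "A"

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        for r in self.residues:
            for name in BACKBONE_ATOMS:
                if not r.has_atom(name):
                    raise ValueError(
                        f"missing backbone atom {name} in residue {r.index} ({r.name})"
                    )
            for a in r.atoms:
                if not np.all(np.isfinite(a.xyz)):
                    raise ValueError(f"non-finite coordinate in residue {r.index}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")


@dataclass
class TransportParams:
    """Free parameters of the transport model.

    ``D_B``/``D_C`` in Å²/ps scale backbone and contact rates, ``k_h``/``k_s``
    in 1/ps are the heater-release and solvent-cooling rates, ``Q`` ≥ 1 is the
    dimensionless quantum correction applied to all intramolecular channels.
    Geometry cutoffs select hydrogen bonds and heater contacts.
    """

    D_B: float = 57.8
    D_C: float = 1.7
    k_h: float = 1.0
    k_s: float = 1.0 / 6.0
    Q: float = 1.0
    hb_cutoff: float = 3.5        # Å, donor–acceptor N···O
    hb_angle_min: float = 120.0   # degrees, N–H···O
    hc_cutoff: float = 4.5        # Å, heavy-atom
    contact_exponent: float = 2.0

    def __post_init__(self):
        for name in ("D_B", "D_C", "k_h", "k_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        for name in ("hb_cutoff", "hc_cutoff", "contact_exponent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kw) -> "TransportParams":
        return replace(self, **kw)


@dataclass
class HeaterSpec:
    """Instantaneous temperature jump deposited by the photoexcited heater.

    The excess energy k_B·ΔT per heater degree of freedom matches the
    electronic excitation energy: ΔT = E_exc / (k_B · n_dof_h). The defaults
    (2 eV over 39 degrees of freedom) give ΔT ≈ 595 K.
    """

    E_exc: float = 2.0       # eV
    n_dof_h: int = 39
    T_0: float = 300.0       # K

    def __post_init__(self):
        if self.E_exc <= 0 or self.n_dof_h <= 0:
            raise ValueError("E_exc and n_dof_h must be positive")

    @property
    def delta_T(self) -> float:
        return self.E_exc / (K_B_EV * self.n_dof_h)


@dataclass(frozen=True)
class Edge:
    i: object            # node id (residue index or pool/sink label)
    j: object
    edge_class: str
    rate: float          # 1/ps

    def __post_init__(self):
        if self.edge_class not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {self.edge_class!r}")
        if self.rate < 0:
            raise ValueError("edge rate must be >= 0")


class EnergyNetwork:
    """Residue network plus heater pool and solvent sink.

    Nodes are residue indices plus the labels ``HEATER_POOL`` and ``SOLVENT``.
    Intramolecular edges (BB/HB/HC) are symmetric (stored once, applied both
    ways); HEAT and COOL edges are directed. ``dof`` maps each node to its
    degree-of-freedom count (informational; energies are per-DOF).
    """

    def __init__(self, nodes: Sequence, edges: Iterable[Edge],
                 dof: dict | None = None):
        self.nodes = list(nodes)
        self.edges = list(edges)
        self.dof = dict(dof) if dof else {n: 1 for n in self.nodes}
        self._validate()

    def _validate(self):
        node_set = set(self.nodes)
        for e in self.edges:
            if e.i not in node_set or e.j not in node_set:
                raise ValueError(f"edge {e} references unknown node")
            if e.i == e.j:
                raise ValueError("self-edges are not allowed")
            if e.edge_class == "HEAT" and e.i != HEATER_POOL:
                raise ValueError("HEAT edges must originate at HEATER_POOL")
            if e.edge_class == "COOL" and e.j != SOLVENT:
                raise ValueError("COOL edges must terminate at SOLVENT")
            if e.i == SOLVENT:
                raise ValueError("SOLVENT must have no outgoing edges")

    # -- queries ----------------------------------------------------------
    @property
    def residue_nodes(self) -> list:
        return [n for n in self.nodes if n not in (HEATER_POOL, SOLVENT)]

    def node_index(self) -> dict:
        return {n: k for k, n in enumerate(self.nodes)}

    def directed_edges(self) -> list[tuple]:
        """All directed (i, j, class, rate) transitions, symmetrizing BB/HB/HC."""
        out = []
        for e in self.edges:
            out.append((e.i, e.j, e.edge_class, e.rate))
            if e.edge_class in ("BB", "HB", "HC"):
                out.append((e.j, e.i, e.edge_class, e.rate))
        return out

    def rate_matrix(self) -> tuple[np.ndarray, dict]:
        """Generator matrix K with dE/dt = K @ E; columns sum to zero."""
        idx = self.node_index()
        n = len(self.nodes)
        K = np.zeros((n, n))
        for i, j, _cls, k in self.directed_edges():
            if k < 0:
                raise ValueError("negative rate in network")
            K[idx[j], idx[i]] += k
            K[idx[i], idx[i]] -= k
        return K, idx

    def is_connected_from_heater(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for i, j, _cls, k in self.directed_edges():
            if k > 0:
                g.add_edge(i, j)
        reach = nx.descendants(g, HEATER_POOL) if HEATER_POOL in g else set()
        return all(r in reach for r in self.residue_nodes)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "nodes": [str(n) for n in self.nodes],
            "dof": {str(n): int(d) for n, d in self.dof.items()},
            "edges": [
                {"i": str(e.i), "j": str(e.j), "class": e.edge_class, "rate": e.rate}
                for e in self.edges
            ],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EnergyNetwork":
        def _node(s: str):
            return int(s) if s.lstrip("-").isdigit() else s
        d = json.loads(text)
        nodes = [_node(s) for s in d["nodes"]]
        edges = [Edge(_node(e["i"]), _node(e["j"]), e["class"], float(e["rate"]))
                 for e in d["edges"]]
        dof = {_node(k): v for k, v in d.get("dof", {}).items()}
        return cls(nodes, edges, dof or None)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.i, e.j, e.edge_class, e.rate) for e in self.edges],
            columns=["i", "j", "class", "rate_per_ps"],
        )

    def copy_with_edges(self, edges: Iterable[Edge]) -> "EnergyNetwork":
        return EnergyNetwork(self.nodes, edges, self.dof)


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr: AtomArray, chain_id: str) -> Structure:
    residues: list[Residue] = []
    res_ids = sorted(set(int(r) for r in arr.res_id))
    for rid in res_ids:
        mask = arr.res_id == rid
        names = arr.atom_name[mask]
        elements = arr.element[mask]
        coords = arr.coord[mask]
        atoms = tuple(
            Atom(str(n), str(el) if el else str(n)[0], tuple(float(x) for x in xyz))
            for n, el, xyz in zip(names, elements, coords)
        )
        resname = str(arr.res_name[mask][0])
        residues.append(Residue(rid, resname, atoms))
    return Structure(tuple(residues), chain_id=chain_id)


def parse_pdb(pdb_text: str) -> Structure:
    """Parse ATOM records of the first model / first chain into a Structure.

    NMR ensembles are reduced to model 1. Raises on empty input or on any
    residue missing an N, CA or C backbone atom.
    """
    if not pdb_text or not pdb_text.strip():
        raise ValueError("empty PDB input")
    pdb = PDBFile.read(io.StringIO(pdb_text))
    arr = pdb.get_structure(model=1)
    arr = arr[np.isin(arr.hetero, [False])] if len(arr) else arr
    if len(arr) == 0:
        raise ValueError("no ATOM records found in PDB input")
    chain = str(arr.chain_id[0])
    arr = arr[arr.chain_id == chain]
    return _structure_from_atom_array(arr, chain)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure to PDB text (round-trips through parse_pdb)."""
    n_atoms = sum(len(r.atoms) for r in structure.residues)
    arr = AtomArray(n_atoms)
    k = 0
    for r in structure.residues:
        for a in r.atoms:
            arr.chain_id[k] = structure.chain_id
            arr.res_id[k] = r.index
            arr.res_name[k] = r.name
            arr.atom_name[k] = a.name
            arr.element[k] = a.element
            arr.coord[k] = a.xyz
            k += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# edge detection
# ---------------------------------------------------------------------------

def _amide_h_position(structure: Structure, res: Residue) -> np.ndarray | None:
    """Infer the backbone amide H from local geometry if not present.

    The H sits 1.0 Å from N, opposite the bisector of N→CA and N→C(prev)
    (N→C of the same residue for the N-terminus).
    """
    for a in res.atoms:
        if a.name in ("H", "HN"):
            return np.asarray(a.xyz, dtype=float)
    n = res.coord("N")
    v1 = res.coord("CA") - n
    prev = [r for r in structure.residues if r.index == res.index - 1]
    v2 = (prev[0].coord("C") if prev else res.coord("C")) - n
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bis = v1 + v2
    nrm = np.linalg.norm(bis)
    if nrm < 1e-9:
        return None
    return n - bis / nrm * 1.0


def detect_hydrogen_bonds(structure: Structure, hb_cutoff: float = 3.5,
                          hb_angle_min: float = 120.0) -> list[tuple[int, int]]:
    """Backbone N–H···O=C hydrogen bonds between sequence-distant residues.

    Returns unordered residue pairs (i < j) with |i−j| ≥ 3 for which either
    N(i)···O(j) or N(j)···O(i) is within ``hb_cutoff`` Å and the N–H···O angle
    is at least ``hb_angle_min`` degrees. The amide hydrogen is taken from the
    structure if present, otherwise inferred from N/CA/C geometry.
    """
    pairs: list[tuple[int, int]] = []
    residues = structure.residues
    for a_pos, ra in enumerate(residues):
        for rb in residues[a_pos + 1:]:
            if abs(ra.index - rb.index) < 3:
                continue
            if _is_hbonded(structure, ra, rb, hb_cutoff, hb_angle_min) or \
               _is_hbonded(structure, rb, ra, hb_cutoff, hb_angle_min):
                pairs.append((ra.index, rb.index))
    return pairs


def _is_hbonded(structure: Structure, donor: Residue, acceptor: Residue,
                cutoff: float, angle_min: float) -> bool:
    if not acceptor.has_atom("O"):
        return False
    n = donor.coord("N")
    o = acceptor.coord("O")
    if np.linalg.norm(n - o) > cutoff:
        return False
    h = _amide_h_position(structure, donor)
    if h is None:
        return False
    v1 = n - h
    v2 = o - h
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angle >= angle_min


def hydrogen_bond_distance(structure: Structure, i: int, j: int) -> float:
    """Minimum donor–acceptor N···O distance between residues i and j (Å)."""
    ri, rj = structure.residue(i), structure.residue(j)
    d = np.inf
    for donor, acceptor in ((ri, rj), (rj, ri)):
        if acceptor.has_atom("O"):
            d = min(d, float(np.linalg.norm(donor.coord("N") - acceptor.coord("O"))))
    return d


def detect_heater_contacts(structure: Structure, heater_index: int,
                           hc_cutoff: float = 4.5) -> list[tuple[int, int]]:
    """Side-chain contacts of the heater residue with sequence-distant residues.

    A contact exists when any heater side-chain heavy atom lies within
    ``hc_cutoff`` Å of any heavy atom of a residue with |heater−j| ≥ 3. A
    residue pair may carry both an HB and an HC edge.
    """
    try:
        heater = structure.residue(heater_index)
    except KeyError as exc:
        raise ValueError(f"invalid heater index {heater_index}") from exc
    sc = heater.sidechain_heavy_coords()
    if sc.size == 0:
        return []
    pairs = []
    for r in structure.residues:
        if abs(r.index - heater_index) < 3:
            continue
        other = r.heavy_coords()
        dmin = np.min(np.linalg.norm(sc[:, None, :] - other[None, :, :], axis=-1))
        if dmin <= hc_cutoff:
            pairs.append((heater_index, r.index))
    return pairs


def heater_contact_distance(structure: Structure, heater_index: int, j: int) -> float:
    """Minimum heater-side-chain to residue-j heavy-atom distance (Å)."""
    sc = structure.residue(heater_index).sidechain_heavy_coords()
    other = structure.residue(j).heavy_coords()
    if sc.size == 0 or other.size == 0:
        return np.inf
    return float(np.min(np.linalg.norm(sc[:, None, :] - other[None, :, :], axis=-1)))


# ---------------------------------------------------------------------------
# network assembly and transformations
# ---------------------------------------------------------------------------

def assemble_network(structure: Structure,
                     hb_pairs: Sequence[tuple[int, int]],
                     hc_pairs: Sequence[tuple[int, int]],
                     params: TransportParams,
                     heater_index: int | None = None) -> EnergyNetwork:
    """Assemble the full rate network from detected edges and scaling rules.

    Backbone rates follow k = D_B / d(Cα,Cα)²; hydrogen-bond and
    heater-contact rates follow k = D_C / r^p with r the relevant minimum
    heavy-atom distance and p ``params.contact_exponent``. A HEAT edge (rate
    k_h) connects the heater pool to the heater residue — by default the first
    residue of the first hc pair, else the first residue — and every residue
    is drained by a COOL edge (rate k_s).
    """
    valid = set(structure.indices)
    for (i, j) in list(hb_pairs) + list(hc_pairs):
        if i not in valid or j not in valid:
            raise ValueError(f"pair ({i}, {j}) references an unknown residue")
    if heater_index is None:
        heater_index = hc_pairs[0][0] if hc_pairs else structure.indices[0]
    if heater_index not in valid:
        raise ValueError(f"invalid heater index {heater_index}")

    edges: list[Edge] = []
    idxs = structure.indices
    for a, b in zip(idxs, idxs[1:]):
        d = float(np.linalg.norm(structure.residue(a).coord("CA")
                                 - structure.residue(b).coord("CA")))
        if d == 0:
            raise ValueError(f"zero Cα–Cα distance between residues {a} and {b}")
        edges.append(Edge(a, b, "BB", params.D_B / d**2))

    for (i, j) in hb_pairs:
        r = hydrogen_bond_distance(structure, i, j)
        if r == 0:
            raise ValueError(f"zero HB distance between residues {i} and {j}")
        edges.append(Edge(min(i, j), max(i, j), "HB",
                          params.D_C / r**params.contact_exponent))
    for (i, j) in hc_pairs:
        r = heater_contact_distance(structure, i, j)
        if r == 0:
            raise ValueError(f"zero contact distance between residues {i} and {j}")
        edges.append(Edge(min(i, j), max(i, j), "HC",
                          params.D_C / r**params.contact_exponent))

    edges.append(Edge(HEATER_POOL, heater_index, "HEAT", params.k_h))
    for i in idxs:
        edges.append(Edge(i, SOLVENT, "COOL", params.k_s))

    dof = {i: 3 * len(structure.residue(i).heavy_coords()) for i in idxs}
    dof[HEATER_POOL] = 1
    dof[SOLVENT] = 1
    net = EnergyNetwork([HEATER_POOL, *idxs, SOLVENT], edges, dof)
    if not net.is_connected_from_heater():
        msg = "network is not connected from the heater pool to every residue"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return net


def apply_quantum_correction(network: EnergyNetwork, Q: float) -> EnergyNetwork:
    """Scale all intramolecular and heater rates by Q; cooling stays classical.

    The quantum correction compensates the classical underestimation of
    intramolecular vibrational energy transfer; solvent dissipation is slow
    and taken from experiment, so COOL rates are left untouched.
    """
    if Q < 1:
        raise ValueError("quantum correction Q must be >= 1")
    edges = [
        Edge(e.i, e.j, e.edge_class,
             e.rate * Q if e.edge_class in QUANTUM_SCALED else e.rate)
        for e in network.edges
    ]
    return network.copy_with_edges(edges)


def prune_contacts(network: EnergyNetwork,
                   fraction: float | None = None,
                   edges_to_remove: Sequence[tuple] | None = None,
                   seed: int = 0) -> EnergyNetwork:
    """Rupture HB/HC contacts, emulating partial unfolding by denaturant.

    Either a ``fraction`` of the HB/HC edges is removed at random
    (reproducibly under ``seed``) or an explicit list of (i, j) pairs is
    removed. Removal sets the rate to 0; BB and COOL edges are untouched.
    """
    contact_ids = [k for k, e in enumerate(network.edges)
                   if e.edge_class in ("HB", "HC")]
    if edges_to_remove is not None:
        remove_pairs = {frozenset(p) for p in edges_to_remove}
        selected = {k for k in contact_ids
                    if frozenset((network.edges[k].i, network.edges[k].j))
                    in remove_pairs}
    else:
        if fraction is None:
            raise ValueError("provide either fraction or edges_to_remove")
        if not 0 <= fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        rng = np.random.default_rng(seed)
        n_remove = int(round(fraction * len(contact_ids)))
        selected = set(rng.choice(contact_ids, size=n_remove, replace=False)) \
            if n_remove else set()
    edges = [
        Edge(e.i, e.j, e.edge_class, 0.0) if k in selected else e
        for k, e in enumerate(network.edges)
    ]
    return network.copy_with_edges(edges)
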