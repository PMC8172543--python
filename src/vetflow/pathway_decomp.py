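"""Decompose sensor-arriving energy into backbone / H-bond / contact pathways.

Energy flow under the master equation can be read as a continuous-time Markov
jump process of independent energy quanta (the equation is linear, so one
quantum is an unbiased sample of the flow). A pathway is the edge-class
sequence a quantum traverses from the source to its first passage at the
sensor; it is classified

    HC  if any heater-contact edge was traversed,
    HB  else if any interstrand hydrogen-bond edge was traversed,
    BB  otherwise (solely backbone).

Two routes compute the class-resolved arrival fractions: an exact one that
augments the node space with (seen-HB, seen-HC) flags and integrates the
expanded linear system with the sensor made absorbing, and a Monte Carlo one
that samples the jump chain directly. They must agree (the MC within binomial
noise) — a disagreement indicates a bug, not statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .structure_net import SOLVENT, EnergyNetwork

CLASSES = ("BB", "HB", "HC")

_OUTCOMES = ("sensor", "solvent", "t_max")


def classify_path(edge_classes: Sequence[str]) -> str:
    """Class of a traversed edge sequence; precedence HC > HB > BB.

    HEAT and COOL labels are ignored (they mark entry/exit, not transport
    between residues). An empty sequence — a source-equals-sensor degenerate
    walk — counts as BB.
    """
    seen_hb = seen_hc = False
    for c in edge_classes:
        if c == "HC":
            seen_hc = True
        elif c == "HB":
            seen_hb = True
        elif c not in ("BB", "HEAT", "COOL"):
            raise ValueError(f"unknown edge class {c!r}")
    return "HC" if seen_hc else ("HB" if seen_hb else "BB")


@dataclass(frozen=True)
class PathRecord:
    edge_classes: tuple[str, ...]
    arrival_time: float          # ps; NaN unless outcome == "sensor"
    outcome: str                 # sensor | solvent | t_max

    def __post_init__(self):
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class PathwayFractions:
    """Cumulative per-class fractions of the energy arrived at the sensor.

    ``bb + hb + hc == 1`` wherever ``total_arrived > 0``; before the first
    arrival the class fractions are NaN (undefined, not zero).
    """

    times: np.ndarray
    bb: np.ndarray
    hb: np.ndarray
    hc: np.ndarray
    total_arrived: np.ndarray    # fraction of injected quanta arrived by t

    def at(self, t: float) -> dict:
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        return {"BB": float(self.bb[k]), "HB": float(self.hb[k]),
                "HC": float(self.hc[k]), "total_arrived": float(self.total_arrived[k])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "BB": self.bb, "HB": self.hb,
                             "HC": self.hc, "total_arrived": self.total_arrived})


# ---------------------------------------------------------------------------
# exact route: flag-augmented master equation
# ---------------------------------------------------------------------------

def _directed_transitions(network: EnergyNetwork):
    return [(i, j, cls, k) for (i, j, cls, k) in network.directed_edges() if k > 0]


def _check_reachable(network: EnergyNetwork, source, sensor):
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from((i, j) for i, j, _c, _k in _directed_transitions(network))
    if source != sensor and not nx.has_path(g, source, sensor):
        raise ValueError(f"sensor {sensor!r} is unreachable from source {source!r}")


def _flag_update(flags: tuple[bool, bool], cls: str) -> tuple[bool, bool]:
    hb, hc = flags
    return (hb or cls == "HB", hc or cls == "HC")


def exact_pathway_fractions(network: EnergyNetwork, source, sensor,
                            grid: np.ndarray) -> PathwayFractions:
    """Class-resolved first-passage fractions from the expanded linear system.

    Each transient state is (node, seen-HB, seen-HC); the sensor is split into
    four absorbing states, one per flag combination, and the solvent sink
    absorbs lost quanta. Integrating the expanded master equation gives the
    exact cumulative arrival mass per class at every grid time.
    """
    _check_reachable(network, source, sensor)
    grid = np.asarray(grid, dtype=float)
    flagset = [(False, False), (True, False), (False, True), (True, True)]
    transient = [(n, f) for n in network.nodes
                 if n not in (sensor, SOLVENT) for f in flagset]
    absorb_sensor = {f: len(transient) + k for k, f in enumerate(flagset)}
    i_solvent = len(transient) + 4
    n_states = i_solvent + 1
    s_idx = {s: k for k, s in enumerate(transient)}

    K = np.zeros((n_states, n_states))
    for i, j, cls, k in _directed_transitions(network):
        if i in (sensor, SOLVENT):
            continue
        for f in flagset:
            a = s_idx[(i, f)]
            g = _flag_update(f, cls)
            if j == sensor:
                b = absorb_sensor[g]
            elif j == SOLVENT:
                b = i_solvent
            else:
                b = s_idx[(j, g)]
            K[b, a] += k
            K[a, a] -= k

    e0 = np.zeros(n_states)
    if source == sensor:
        # degenerate: everything has arrived at t = 0 with an empty (BB) path
        e0[absorb_sensor[(False, False)]] = 1.0
    else:
        e0[s_idx[(source, (False, False))]] = 1.0

    arrived = np.empty((4, grid.size))
    props: dict[float, np.ndarray] = {}
    e = e0.copy()
    t_prev = 0.0
    for k, t in enumerate(grid):
        dt = float(t - t_prev)
        if dt > 0:
            P = props.get(dt)
            if P is None:
                P = expm(K * dt)
                props[dt] = P
            e = P @ e
        t_prev = t
        arrived[:, k] = [e[absorb_sensor[f]] for f in flagset]

    total = arrived.sum(axis=0)
    mass = {
        "BB": arrived[0],
        "HB": arrived[1],
        "HC": arrived[2] + arrived[3],   # HC precedence over HB
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {c: np.where(total > 0, mass[c] / np.where(total > 0, total, 1.0),
                            np.nan) for c in CLASSES}
    return PathwayFractions(grid, frac["BB"], frac["HB"], frac["HC"], total)


# ---------------------------------------------------------------------------
# Monte Carlo route: jump-chain sampling
# ---------------------------------------------------------------------------

class PathEnsemble:
    """Array-backed sequence of :class:`PathRecord`.

    Stores the per-walker arrival time, outcome and seen-class flags in flat
    arrays so that millions of walkers stay cheap; indexing materializes a
    PathRecord view. Without ``record_paths`` the edge-class sequence of each
    record is compressed to the distinct classes in first-traversal order,
    which is what :func:`classify_path` needs.
    """

    def __init__(self, arrival_time, outcome_code, hb_seen, hc_seen,
                 paths: list | None = None):
        self.arrival_time = np.asarray(arrival_time, dtype=float)
        self.outcome_code = np.asarray(outcome_code, dtype=np.int8)
        self.hb_seen = np.asarray(hb_seen, dtype=bool)
        self.hc_seen = np.asarray(hc_seen, dtype=bool)
        self.paths = paths

    def __len__(self) -> int:
        return self.arrival_time.size

    def __getitem__(self, k: int) -> PathRecord:
        if self.paths is not None:
            seq = tuple(self.paths[k])
        elif self.outcome_code[k] == 0 and self.arrival_time[k] == 0:
            seq = ()   # degenerate source == sensor walk
        else:
            seq = tuple(c for c, seen in
                        (("HB", self.hb_seen[k]), ("HC", self.hc_seen[k]))
                        if seen) or ("BB",)
        return PathRecord(seq, float(self.arrival_time[k]),
                          _OUTCOMES[self.outcome_code[k]])

    def __iter__(self):
        return (self[k] for k in range(len(self)))

    @property
    def classes(self) -> np.ndarray:
        """Per-record class label (precedence HC > HB > BB)."""
        out = np.full(len(self), "BB", dtype="<U2")
        out[self.hb_seen] = "HB"
        out[self.hc_seen] = "HC"
        return out


def sample_jump_chain(network: EnergyNetwork, source, sensor,
                      n_walkers: int, t_max: float = 50.0,
                      seed: int = 0, record_paths: bool = False) -> PathEnsemble:
    """Sample energy-quantum walks from source to first passage at the sensor.

    Each walker waits at node i an exponential time with rate Σ_j k_ij
    (cooling included) and jumps to j with probability ∝ k_ij. It terminates
    at its first sensor arrival, at solvent absorption, or at ``t_max``.
    Reproducible under ``seed``.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    nodes = list(network.nodes)
    n_idx = {n: k for k, n in enumerate(nodes)}
    if source not in n_idx or sensor not in n_idx:
        raise KeyError("source/sensor not in network")

    if source == sensor:
        z = np.zeros(n_walkers)
        return PathEnsemble(z, np.zeros(n_walkers, dtype=np.int8),
                            np.zeros(n_walkers, bool), np.zeros(n_walkers, bool),
                            paths=[[] for _ in range(n_walkers)]
                            if record_paths else None)

    # per-node branch tables
    n_nodes = len(nodes)
    branches: list[list[tuple[int, int, float]]] = [[] for _ in range(n_nodes)]
    cls_code = {"BB": 0, "HB": 1, "HC": 2, "HEAT": 3, "COOL": 4}
    for i, j, cls, k in _directed_transitions(network):
        branches[n_idx[i]].append((n_idx[j], cls_code[cls], k))
    total_rate = np.array([sum(b[2] for b in br) for br in branches])
    max_deg = max((len(br) for br in branches), default=1) or 1
    cum = np.ones((n_nodes, max_deg))
    tgt = np.zeros((n_nodes, max_deg), dtype=np.int64)
    ccd = np.zeros((n_nodes, max_deg), dtype=np.int8)
    for i, br in enumerate(branches):
        if not br:
            continue
        rates = np.array([b[2] for b in br])
        cum[i, :len(br)] = np.cumsum(rates) / rates.sum()
        cum[i, len(br):] = 1.0
        tgt[i, :len(br)] = [b[0] for b in br]
        ccd[i, :len(br)] = [b[1] for b in br]

    i_sensor, i_solvent = n_idx[sensor], n_idx.get(SOLVENT, -1)
    rng = np.random.default_rng(seed)

    node = np.full(n_walkers, n_idx[source], dtype=np.int64)
    t = np.zeros(n_walkers)
    hb = np.zeros(n_walkers, bool)
    hc = np.zeros(n_walkers, bool)
    arrival = np.full(n_walkers, np.nan)
    outcome = np.full(n_walkers, 2, dtype=np.int8)   # default: censored at t_max
    active = np.arange(n_walkers)
    paths: list[list[str]] | None = \
        [[] for _ in range(n_walkers)] if record_paths else None
    inv_code = {v: k for k, v in cls_code.items()}

    while active.size:
        cur = node[active]
        rates = total_rate[cur]
        if np.any(rates <= 0):
            bad = nodes[int(cur[rates <= 0][0])]
            raise ValueError(f"non-absorbing node {bad!r} has zero outgoing rate")
        t[active] += rng.exponential(1.0 / rates)
        alive = t[active] <= t_max
        active = active[alive]
        if not active.size:
            break
        cur = node[active]
        u = rng.random(active.size)
        b = (u[:, None] > cum[cur]).sum(axis=1)
        nxt = tgt[cur, b]
        cls = ccd[cur, b]
        hb[active] |= cls == 1
        hc[active] |= cls == 2
        if paths is not None:
            for w, c in zip(active, cls):
                paths[w].append(inv_code[int(c)])
        node[active] = nxt
        hit = nxt == i_sensor
        lost = nxt == i_solvent
        arrival[active[hit]] = t[active[hit]]
        outcome[active[hit]] = 0
        outcome[active[lost]] = 1
        active = active[~(hit | lost)]

    return PathEnsemble(arrival, outcome, hb, hc, paths)


def mc_pathway_fractions(records, grid: np.ndarray) -> PathwayFractions:
    """Empirical class-resolved arrival fractions from sampled walks.

    Accepts a :class:`PathEnsemble` or any iterable of :class:`PathRecord`.
    Fractions are cumulative per-class arrival counts over total arrivals up
    to each grid time; times with zero arrivals yield NaN fractions.
    """
    if isinstance(records, PathEnsemble):
        arrived = records.outcome_code == 0
        times = records.arrival_time[arrived]
        labels = records.classes[arrived]
        n_total = len(records)
    else:
        records = list(records)
        n_total = len(records)
        times, labels = [], []
        for r in records:
            if r.outcome == "sensor":
                times.append(r.arrival_time)
                labels.append(classify_path(r.edge_classes))
        times = np.asarray(times, dtype=float)
        labels = np.asarray(labels)
    if n_total == 0:
        raise ValueError("no records given")

    grid = np.asarray(grid, dtype=float)
    counts = {}
    for c in CLASSES:
        tc = np.sort(times[labels == c])
        counts[c] = np.searchsorted(tc, grid, side="right").astype(float)
    total = sum(counts.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {c: np.where(total > 0, counts[c] / np.where(total > 0, total, 1.0),
                            np.nan) for c in CLASSES}
    return PathwayFractions(grid, frac["BB"], frac["HB"], frac["HC"],
                            total / n_total)


def edge_flux_table(network: EnergyNetwork, source, sensor,
                    n_walkers: int = 100_000, t_max: float = 50.0,
                    seed: int = 0) -> pd.DataFrame:
    """Per-edge traversal counts among sensor-arriving walkers.

    The table behind arrow-thickness pathway diagrams: for each directed edge,
    how many arriving walkers traversed it, normalized per arrival.
    """
    nodes = list(network.nodes)
    flux: dict[tuple, int] = {}
    walks = _sample_with_nodes(network, source, sensor, n_walkers, t_max, seed)
    for node_seq, cls_seq, arrived in walks:
        if not arrived:
            continue
        for a, b, c in zip(node_seq, node_seq[1:], cls_seq):
            flux[(nodes[a], nodes[b], c)] = flux.get((nodes[a], nodes[b], c), 0) + 1
    n_arr = max(sum(1 for *_, a in walks if a), 1)
    rows = [(i, j, c, n, n / n_arr) for (i, j, c), n in sorted(flux.items(),
            key=lambda kv: -kv[1])]
    return pd.DataFrame(rows, columns=["i", "j", "class", "count",
                                       "per_arrival"])


def _sample_with_nodes(network: EnergyNetwork, source, sensor,
                       n_walkers: int, t_max: float, seed: int):
    """Plain per-walker sampler retaining node sequences (small n only)."""
    nodes = list(network.nodes)
    n_idx = {n: k for k, n in enumerate(nodes)}
    adj: dict[int, list[tuple[int, str, float]]] = {k: [] for k in range(len(nodes))}
    for i, j, cls, k in _directed_transitions(network):
        adj[n_idx[i]].append((n_idx[j], cls, k))
    rng = np.random.default_rng(seed)
    i_sensor, i_solvent = n_idx[sensor], n_idx.get(SOLVENT, None)
    out = []
    for _ in range(n_walkers):
        cur, t = n_idx[source], 0.0
        node_seq, cls_seq = [cur], []
        arrived = False
        while True:
            br = adj[cur]
            tot = sum(b[2] for b in br)
            if tot <= 0:
                raise ValueError(f"non-absorbing node {nodes[cur]!r} has zero "
                                 "outgoing rate")
            t += rng.exponential(1.0 / tot)
            if t > t_max:
                break
            r = rng.random() * tot
            acc = 0.0
            for j, cls, k in br:
                acc += k
                if r <= acc:
                    break
            node_seq.append(j)
            cls_seq.append(cls)
            cur = j
            if cur == i_sensor:
                arrived = True
                break
            if i_solvent is not None and cur == i_solvent:
                break
        out.append((node_seq, cls_seq, arrived))
    return out
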