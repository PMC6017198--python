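"""Molecular constraint graph and rigid-cluster decomposition.

The molecule is modelled as a body-bar framework: every atom is a rigid body
with 6 degrees of freedom, and interactions are bundles of bars, each bar
removing one relative degree of freedom.  Rotatable covalent bonds place 5
bars (one residual torsion), resonant/partial-double bonds 6, hydrogen bonds
5, and hydrophobic tethers 2.  Rigid clusters are found with the (6,6)
pebble game; a numerical rank oracle over the generic body-bar rigidity
matrix provides an independent check at test scale.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .structure import Structure
from .topology import (BACKBONE_ATOMS, LOCKED_BONDS, RESIDUE_BONDS,
                       THREE_TO_ONE, vdw_radius)

logger = logging.getLogger(__name__)

EDGE_KINDS = ("covalent", "hbond", "hydrophobic")


@dataclass(frozen=True)
class Edge:
    body_a: int
    body_b: int
    bars: int
    kind: str

    def __post_init__(self):
        if self.body_a == self.body_b:
            raise ValueError("self-loop edge")
        if not 1 <= self.bars <= 6:
            raise ValueError(f"bars must be in [1, 6], got {self.bars}")
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")


@dataclass
class ConstraintGraph:
    """Bodies (each owning a set of atom ids) joined by bar bundles."""
    bodies: dict[int, tuple[int, ...]]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self):
        seen: set[int] = set()
        for members in self.bodies.values():
            for atom in members:
                if atom in seen:
                    raise ValueError(f"atom {atom} assigned to two bodies")
                seen.add(atom)

    @property
    def n_bodies(self) -> int:
        return len(self.bodies)

    def total_atoms(self) -> int:
        return sum(len(m) for m in self.bodies.values())


@dataclass
class RigidClusterDecomposition:
    clusters: list[frozenset[int]]  # atom-id sets

    def __post_init__(self):
        self.clusters = sorted(self.clusters, key=lambda c: (-len(c), min(c)))

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def lrc(self) -> int:
        return max(self.sizes)

    def body_partition(self, graph: ConstraintGraph) -> frozenset[frozenset[int]]:
        """Cluster partition expressed over body ids (for comparisons)."""
        atom_to_body = {a: b for b, mem in graph.bodies.items() for a in mem}
        return frozenset(frozenset(atom_to_body[a] for a in c)
                         for c in self.clusters)


@dataclass
class ClusterHistogram:
    """Rigid-cluster size distribution: size (atoms) -> count."""
    counts: dict[int, int]
    total_atoms: int

    def __post_init__(self):
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("histogram counts must be >= 1")
        mass = sum(size * count for size, count in self.counts.items())
        if mass != self.total_atoms:
            raise ValueError(
                f"histogram mass {mass} != total atoms {self.total_atoms}")

    @classmethod
    def from_sizes(cls, sizes) -> "ClusterHistogram":
        sizes = list(sizes)
        return cls(counts=dict(Counter(sizes)), total_atoms=sum(sizes))

    @classmethod
    def from_decomposition(cls, d: RigidClusterDecomposition) -> "ClusterHistogram":
        return cls.from_sizes(d.sizes)

    @property
    def lrc(self) -> int:
        return max(self.counts)

    @property
    def smallest(self) -> int:
        return min(self.counts)

    def get(self, size: int) -> int:
        return self.counts.get(size, 0)


# ---------------------------------------------------------------------------
# Constraint-graph construction
# ---------------------------------------------------------------------------

@dataclass
class RigidityParams:
    """Detection thresholds and bar counts (all config-overridable)."""
    hbond_max_da: float = 3.6          # donor-acceptor distance cutoff (A)
    hbond_min_angle: float = 100.0     # donor-H-acceptor angle cutoff (deg)
    hbond_require_hydrogen: bool = True
    hydrophobic_margin: float = 0.25   # added to vdW-sum (A)
    rotatable_bars: int = 5
    locked_bars: int = 6
    hbond_bars: int = 5
    hydrophobic_bars: int = 2
    hydrophobic_residues: frozenset = frozenset("ACFGILMPVWY")
    disulfide_max: float = 2.5
    peptide_max: float = 1.8
    hydrogen_bond_max: float = 1.6     # H to parent heavy atom (A)


def build_constraint_graph(s: Structure,
                           params: RigidityParams | None = None) -> ConstraintGraph:
    """Build the molecular constraint graph: one body per atom, covalent
    edges from residue topology plus peptide/disulfide bonds, geometric
    hydrogen bonds and hydrophobic tethers."""
    params = params or RigidityParams()
    atoms = s.atoms
    n = len(atoms)
    bodies = {i: (i,) for i in range(n)}
    bonded: set[frozenset[int]] = set()
    edges: list[Edge] = []

    def add_edge(i: int, j: int, bars: int, kind: str):
        pair = frozenset((i, j))
        if pair in bonded:
            return
        bonded.add(pair)
        edges.append(Edge(min(i, j), max(i, j), bars, kind))

    residues = s.residues()
    res_keys = list(residues)
    index_of = {id(a): i for i, a in enumerate(atoms)}

    def idx(atom):
        return index_of[id(atom)]

    # Intra-residue covalent bonds from topology; hydrogens attach to the
    # nearest heavy atom of the same residue.
    for key, res_atoms in residues.items():
        resname = res_atoms[0].residue_name
        topo = RESIDUE_BONDS.get(resname)
        if topo is None:
            logger.warning("unknown residue type %s at %s; topology skipped",
                           resname, key)
            continue
        locked = LOCKED_BONDS[resname]
        by_name = {}
        for a in res_atoms:
            by_name.setdefault(a.atom_name, a)
        for n1, n2 in topo:
            if n1 in by_name and n2 in by_name:
                bars = (params.locked_bars
                        if frozenset((n1, n2)) in locked
                        else params.rotatable_bars)
                add_edge(idx(by_name[n1]), idx(by_name[n2]), bars, "covalent")
        heavies = [a for a in res_atoms if not a.is_hydrogen()]
        for a in res_atoms:
            if not a.is_hydrogen() or not heavies:
                continue
            d = [np.linalg.norm(a.coords - h.coords) for h in heavies]
            k = int(np.argmin(d))
            if d[k] <= params.hydrogen_bond_max:
                add_edge(idx(a), idx(heavies[k]),
                         params.rotatable_bars, "covalent")

    # Peptide bonds between consecutive residues of a chain (resonant: 6 bars).
    for k1, k2 in zip(res_keys, res_keys[1:]):
        if k1[0] != k2[0]:
            continue
        c_atom = next((a for a in residues[k1] if a.atom_name == "C"), None)
        n_atom = next((a for a in residues[k2] if a.atom_name == "N"), None)
        if c_atom is None or n_atom is None:
            continue
        if np.linalg.norm(c_atom.coords - n_atom.coords) <= params.peptide_max:
            add_edge(idx(c_atom), idx(n_atom), params.locked_bars, "covalent")

    # Disulfide bridges.
    sgs = [a for a in atoms if a.atom_name == "SG" and a.residue_name == "CYS"]
    for a, b in itertools.combinations(sgs, 2):
        if np.linalg.norm(a.coords - b.coords) <= params.disulfide_max:
            add_edge(idx(a), idx(b), params.rotatable_bars, "covalent")

    # Adjacency for donor-H lookup and bonded-pair exclusion.
    neighbors: dict[int, list[int]] = defaultdict(list)
    for e in edges:
        neighbors[e.body_a].append(e.body_b)
        neighbors[e.body_b].append(e.body_a)

    _add_hydrogen_bonds(atoms, neighbors, bonded, add_edge, params)
    _add_hydrophobic_tethers(atoms, bonded, add_edge, params)
    return ConstraintGraph(bodies=bodies, edges=edges)


def _add_hydrogen_bonds(atoms, neighbors, bonded, add_edge, params):
    donors = []   # (donor_idx, [h_idx, ...])
    acceptors = []
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el in ("N", "O"):
            hs = [j for j in neighbors[i] if atoms[j].is_hydrogen()]
            if hs:
                donors.append((i, hs))
            elif not params.hbond_require_hydrogen and el == "N":
                donors.append((i, []))
            if el == "O" or (el == "N" and not hs):
                acceptors.append(i)
    for d, hs in donors:
        for acc in acceptors:
            if acc == d or frozenset((d, acc)) in bonded:
                continue
            if atoms[d].residue_key == atoms[acc].residue_key:
                continue
            dist = np.linalg.norm(atoms[d].coords - atoms[acc].coords)
            if dist > params.hbond_max_da:
                continue
            if hs:
                ok = False
                for h in hs:
                    v1 = atoms[d].coords - atoms[h].coords
                    v2 = atoms[acc].coords - atoms[h].coords
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if angle >= params.hbond_min_angle:
                        ok = True
                        break
                if not ok:
                    continue
            elif params.hbond_require_hydrogen:
                continue
            add_edge(d, acc, params.hbond_bars, "hbond")


def _add_hydrophobic_tethers(atoms, bonded, add_edge, params):
    candidates = [
        i for i, a in enumerate(atoms)
        if a.element.upper() in ("C", "S")
        and a.atom_name not in BACKBONE_ATOMS
        and THREE_TO_ONE.get(a.residue_name) in params.hydrophobic_residues
    ]
    for i, j in itertools.combinations(candidates, 2):
        if atoms[i].residue_key == atoms[j].residue_key:
            continue
        if frozenset((i, j)) in bonded:
            continue
        cutoff = (vdw_radius(atoms[i].element) + vdw_radius(atoms[j].element)
                  + params.hydrophobic_margin)
        if np.linalg.norm(atoms[i].coords - atoms[j].coords) <= cutoff:
            add_edge(i, j, params.hydrophobic_bars, "hydrophobic")


# ---------------------------------------------------------------------------
# (6,6) pebble game
# ---------------------------------------------------------------------------

class _PebbleGame:
    """The (6,6) body-bar pebble game over an indexed body set.

    Every body holds 6 pebbles.  A bar between u and v is independent iff 7
    pebbles can be gathered onto {u, v}; accepting it pins one pebble from an
    endpoint and orients the bar away from it.  Pebble searches are
    deterministic lowest-index-first DFS.
    """

    K = 6
    L = 6

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [self.K] * n
        self.out: list[dict[int, int]] = [defaultdict(int) for _ in range(n)]

    def _find_pebble_path(self, sources: tuple[int, int]) -> list[int] | None:
        """Directed path from a source to any body outside `sources` holding
        a free pebble; lowest-index-first DFS."""
        parent: dict[int, int] = {}
        stack = sorted(sources, reverse=True)
        visited = set(sources)
        while stack:
            u = stack.pop()
            if u not in sources and self.pebbles[u] > 0:
                path = [u]
                while path[-1] in parent:
                    path.append(parent[path[-1]])
                path.reverse()
                return path
            for v in sorted(self.out[u], reverse=True):
                if self.out[u][v] > 0 and v not in visited:
                    visited.add(v)
                    parent[v] = u
                    stack.append(v)
        return None

    def _reverse_path(self, path: list[int]) -> None:
        # Move one pebble from the end of the path back to its start.
        w = path[-1]
        self.pebbles[w] -= 1
        self.pebbles[path[0]] += 1
        for a, b in zip(path, path[1:]):
            self.out[a][b] -= 1
            if self.out[a][b] == 0:
                del self.out[a][b]
            self.out[b][a] += 1

    def can_collect(self, u: int, v: int, target: int) -> bool:
        while self.pebbles[u] + self.pebbles[v] < target:
            path = self._find_pebble_path((u, v))
            if path is None:
                return False
            self._reverse_path(path)
        return True

    def insert_bar(self, u: int, v: int) -> bool:
        """True if the bar is independent (and inserted)."""
        if not self.can_collect(u, v, self.L + 1):
            return False
        src = u if self.pebbles[u] > 0 else v
        dst = v if src == u else u
        self.pebbles[src] -= 1
        self.out[src][dst] += 1
        return True

    def mutually_rigid(self, u: int, v: int) -> bool:
        """Bodies u, v have zero residual relative freedom iff a further bar
        between them would be redundant."""
        return not self.can_collect(u, v, self.L + 1)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _clusters_from_body_partition(g: ConstraintGraph, body_ids, uf) -> RigidClusterDecomposition:
    groups: dict[int, set[int]] = defaultdict(set)
    for i, b in enumerate(body_ids):
        groups[uf.find(i)].update(g.bodies[b])
    return RigidClusterDecomposition(
        clusters=[frozenset(v) for v in groups.values()])


def pebble_game_decompose(g: ConstraintGraph) -> RigidClusterDecomposition:
    """Rigid-cluster decomposition of a body-bar constraint graph.

    Plays the (6,6) pebble game over all bars, then merges every adjacent
    body pair with zero residual relative freedom; clusters are the
    transitive closure, mapped to atom sets.  The result is independent of
    edge insertion order.
    """
    body_ids = sorted(g.bodies)
    index = {b: i for i, b in enumerate(body_ids)}
    game = _PebbleGame(len(body_ids))
    pairs: set[tuple[int, int]] = set()
    for e in sorted(g.edges, key=lambda e: (e.body_a, e.body_b, e.kind)):
        u, v = index[e.body_a], index[e.body_b]
        pairs.add((min(u, v), max(u, v)))
        for _ in range(e.bars):
            game.insert_bar(u, v)
    uf = _UnionFind(len(body_ids))
    for u, v in sorted(pairs):
        if game.mutually_rigid(u, v):
            uf.union(u, v)
    return _clusters_from_body_partition(g, body_ids, uf)


# ---------------------------------------------------------------------------
# Rank oracle (generic body-bar rigidity matrix)
# ---------------------------------------------------------------------------

def rigidity_rank_oracle(g: ConstraintGraph, seed: int = 0,
                         max_bodies: int = 80,
                         tol: float = 1e-7) -> RigidClusterDecomposition:
    """Rigid clusters by numerical rank of a generic body-bar rigidity matrix.

    Each body gets a random generic placement; every bar becomes one row
    constraining the relative velocity of its random endpoints along the bar
    direction.  Two bodies are mutually rigid when every null-space motion
    gives them identical rigid-body velocities.  Intended as a test-time
    oracle for small graphs, not for production use.
    """
    body_ids = sorted(g.bodies)
    n = len(body_ids)
    if n > max_bodies:
        raise ValueError(f"oracle limited to {max_bodies} bodies, got {n}")
    index = {b: i for i, b in enumerate(body_ids)}

    for attempt in range(5):
        rng = np.random.default_rng(seed + 7919 * attempt)
        part = _oracle_partition(g, body_ids, index, rng, tol)
        part2 = _oracle_partition(g, body_ids, index, rng, tol)
        if part == part2:
            break
    uf = _UnionFind(n)
    for group in part:
        members = sorted(group)
        for m in members[1:]:
            uf.union(members[0], m)
    return _clusters_from_body_partition(g, body_ids, uf)


def _oracle_partition(g, body_ids, index, rng, tol) -> frozenset[frozenset[int]]:
    n = len(body_ids)
    pos = rng.uniform(-5.0, 5.0, size=(n, 3))
    rows = []
    for e in g.edges:
        u, v = index[e.body_a], index[e.body_b]
        for _ in range(e.bars):
            pu = pos[u] + rng.uniform(-1.0, 1.0, 3)
            pv = pos[v] + rng.uniform(-1.0, 1.0, 3)
            d = pv - pu
            d = d / np.linalg.norm(d)
            row = np.zeros(6 * n)
            # velocity of point p on body i: v_i + w_i x p; constraint
            # d . (vel_u(pu) - vel_v(pv)) = 0, block layout (w_i, v_i).
            row[6 * u: 6 * u + 3] = np.cross(pu, d)
            row[6 * u + 3: 6 * u + 6] = d
            row[6 * v: 6 * v + 3] = -np.cross(pv, d)
            row[6 * v + 3: 6 * v + 6] = -d
            rows.append(row)
    if rows:
        ns = null_space(np.array(rows))
    else:
        ns = np.eye(6 * n)
    uf = _UnionFind(n)
    scale = max(1.0, float(np.abs(ns).max())) if ns.size else 1.0
    for i in range(n):
        for j in range(i + 1, n):
            diff = ns[6 * i: 6 * i + 6, :] - ns[6 * j: 6 * j + 6, :]
            if ns.shape[1] == 0 or np.abs(diff).max() <= tol * scale:
                uf.union(i, j)
    groups: dict[int, set[int]] = defaultdict(set)
    for i in range(n):
        groups[uf.find(i)].add(i)
    return frozenset(frozenset(v) for v in groups.values())


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

def write_clusters_tsv(d: RigidClusterDecomposition, path) -> None:
    with open(path, "w") as fh:
        fh.write("atom_id\tcluster_id\n")
        for cid, cluster in enumerate(d.clusters):
            for atom in sorted(cluster):
                fh.write(f"{atom}\t{cid}\n")


def read_clusters_tsv(path) -> RigidClusterDecomposition:
    groups: dict[str, set[int]] = defaultdict(set)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("atom_id"):
            raise ValueError(f"{path}: expected 'atom_id\\tcluster_id' header")
        for line in fh:
            if not line.strip():
                continue
            atom, cid = line.split("\t")
            groups[cid.strip()].add(int(atom))
    return RigidClusterDecomposition(clusters=[frozenset(v) for v in groups.values()])


def write_histogram_tsv(h: ClusterHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("size\tcount\n")
        for size in sorted(h.counts):
            fh.write(f"{size}\t{h.counts[size]}\n")


def read_histogram_tsv(path) -> ClusterHistogram:
    counts: dict[int, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("size"):
            raise ValueError(f"{path}: expected 'size\\tcount' header")
        for line in fh:
            if not line.strip():
                continue
            size, count = line.split("\t")
            counts[int(size)] = int(count)
    total = sum(s * c for s, c in counts.items())
    return ClusterHistogram(counts=counts, total_atoms=total)
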