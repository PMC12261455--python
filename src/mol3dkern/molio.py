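"""Molecule I/O and synthetic fixtures.

Molecules are handled as :class:`MoleculeGraph` objects: a labeled undirected
graph ``G = (V, E)`` with an atom element symbol ``l(v)`` and a 3D position
(in Angstrom) attached to every node.  Bond orders, charges and aromaticity
are deliberately discarded — the kernels in this package use only the atom
labels, the connectivity and the interatomic distances.

SDF/MOL (V2000) reading and writing is delegated to RDKit; parsing is done
with sanitization switched off so that records are taken verbatim (no valence
model, no re-perception).  A small set of generators produces deterministic
synthetic molecules so the whole package is testable without any external
dataset.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MoleculeGraph",
    "read_sdf",
    "write_sdf",
    "read_labels",
    "write_labels",
    "make_chain_fixture",
    "sample_molecule",
]


@dataclass
class MoleculeGraph:
    """Labeled undirected molecular graph with 3D coordinates.

    Parameters
    ----------
    labels : sequence of str
        Atom element symbol per node; node ids are the positions ``0..n-1``.
    coords : (n, 3) array_like of float
        Cartesian coordinates in Angstrom.
    edges : iterable of (int, int)
        Unordered bonds; stored sorted, without duplicates or self-loops.
    name : str
        Record identifier.
    """

    labels: tuple[str, ...]
    coords: np.ndarray
    edges: tuple[tuple[int, int], ...]
    name: str = ""

    def __init__(
        self,
        labels: Sequence[str],
        coords,
        edges: Iterable[tuple[int, int]],
        name: str = "",
    ):
        self.labels = tuple(str(s) for s in labels)
        n = len(self.labels)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(
                f"coords must have shape ({n}, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.coords = coords
        seen: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) references a missing node")
            seen.add((min(u, v), max(u, v)))
        self.edges = tuple(sorted(seen))
        self.name = name

    # -- derived quantities -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    @property
    def n_bonds(self) -> int:
        return len(self.edges)

    def neighbor_lists(self) -> list[list[int]]:
        """Adjacency lists, sorted for determinism."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for u, v in self.edges:
            nbrs[u].append(v)
            nbrs[v].append(u)
        for lst in nbrs:
            lst.sort()
        return nbrs

    @property
    def max_degree(self) -> int:
        if self.n_atoms == 0:
            return 0
        deg = np.zeros(self.n_atoms, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return int(deg.max())

    def distance(self, u: int, v: int) -> float:
        """Euclidean distance between two atoms, in Angstrom."""
        return float(np.linalg.norm(self.coords[u] - self.coords[v]))

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        nbrs = self.neighbor_lists()
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for w in nbrs[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_atoms

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` with ``label``/``coord`` data."""
        import networkx as nx

        g = nx.Graph(name=self.name)
        for i, lab in enumerate(self.labels):
            g.add_node(i, label=lab, coord=self.coords[i])
        g.add_edges_from(self.edges)
        return g

    def transformed(self, rotation=None, translation=None) -> "MoleculeGraph":
        """Copy with coordinates mapped through ``x -> R x + t``."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return MoleculeGraph(self.labels, xyz, self.edges, name=self.name)


# ---------------------------------------------------------------------------
# SDF I/O (via RDKit)
# ---------------------------------------------------------------------------


def _graph_from_rdkit(mol, index: int, hydrogen_policy: str) -> MoleculeGraph:
    name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
    if not name:
        name = f"record{index}"
    if mol.GetNumConformers() == 0:
        raise ValueError(f"record {index} ({name!r}): no coordinate block")
    conf = mol.GetConformer()
    n = mol.GetNumAtoms()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z] for i in range(n)]
    )
    if n > 0 and not conf.Is3D() and np.allclose(coords[:, 2], 0.0):
        warnings.warn(
            f"record {index} ({name!r}) is flagged 2D with an all-zero z column; "
            "kept, but its torsion features are degenerate",
            stacklevel=3,
        )
    labels = [a.GetSymbol() for a in mol.GetAtoms()]
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    g = MoleculeGraph(labels, coords, edges, name=name)
    if hydrogen_policy == "strip":
        g = strip_hydrogens(g)
    return g


def strip_hydrogens(g: MoleculeGraph) -> MoleculeGraph:
    """Drop H atoms and incident bonds; node ids are compacted."""
    keep = [i for i, lab in enumerate(g.labels) if lab != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    edges = [
        (remap[u], remap[v]) for u, v in g.edges if u in remap and v in remap
    ]
    return MoleculeGraph(
        [g.labels[i] for i in keep], g.coords[keep], edges, name=g.name
    )


def read_sdf(path, hydrogen_policy: str = "strip") -> list[MoleculeGraph]:
    """Read a multi-record SDF/MOL V2000 file into :class:`MoleculeGraph` objects.

    Parameters
    ----------
    path : path-like
        SDF file with a 3D coordinate block per record.
    hydrogen_policy : {"strip", "keep"}
        With ``"strip"`` (default) hydrogen atoms and their bonds are removed
        and node ids compacted to the heavy-atom skeleton.

    Returns
    -------
    list of MoleculeGraph, in file order.  Duplicate record names are
    disambiguated with a ``#<index>`` suffix.  A malformed record raises
    :class:`ValueError` naming the record index; records flagged 2D are kept
    but reported via :class:`UserWarning`.
    """
    if hydrogen_policy not in ("strip", "keep"):
        raise ValueError(f"unknown hydrogen_policy {hydrogen_policy!r}")
    from rdkit import Chem

    path = Path(path)
    if path.stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out: list[MoleculeGraph] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"record {i}: malformed atom/bond block")
        out.append(_graph_from_rdkit(mol, i, hydrogen_policy))
    counts = Counter(g.name for g in out)
    for i, g in enumerate(out):
        if counts[g.name] > 1:
            g.name = f"{g.name}#{i}"
    return out


def write_sdf(molecules: Iterable[MoleculeGraph], path) -> None:
    """Write molecules as a multi-record V2000 SDF (single bonds only)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    try:
        for g in molecules:
            rw = Chem.RWMol()
            for lab in g.labels:
                atom = Chem.Atom(lab)
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
            for u, v in g.edges:
                rw.AddBond(u, v, Chem.BondType.SINGLE)
            conf = Chem.Conformer(g.n_atoms)
            for i, (x, y, z) in enumerate(g.coords):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            conf.Set3D(True)
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", g.name)
            mol.UpdatePropertyCache(strict=False)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Label files
# ---------------------------------------------------------------------------


def read_labels(path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column ``name<TAB>label`` file into a dict.

    Conflicting duplicate names raise; labels are taken verbatim (the
    screening harness expects ``active`` / ``inactive``).
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, lab = parts[0].strip(), parts[1].strip()
            if name in out and out[name] != lab:
                raise ValueError(f"{path}:{lineno}: conflicting label for {name!r}")
            out[name] = lab
    return out


def write_labels(labels: dict[str, str], path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for name in labels:
            fh.write(f"{name}{delimiter}{labels[name]}\n")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def make_chain_fixture(
    n_atoms: int,
    bond_length: float = 1.0,
    labels: Sequence[str] | None = None,
    geometry: str = "collinear",
    coords=None,
    name: str = "chain",
) -> MoleculeGraph:
    """Deterministic path-graph molecule A-B-C-... for worked examples.

    ``geometry="collinear"`` places atoms on the x-axis at ``bond_length``
    spacing; ``"zigzag"`` alternates the bond direction in the xy-plane with a
    120 degree internal angle; ``"coords"`` takes the coordinate list verbatim.
    """
    if n_atoms < 2:
        raise ValueError("a chain needs at least 2 atoms")
    if labels is None:
        labels = ["C"] * n_atoms
    if len(labels) != n_atoms:
        raise ValueError("label list length must equal n_atoms")
    if geometry == "collinear":
        xyz = np.zeros((n_atoms, 3))
        xyz[:, 0] = bond_length * np.arange(n_atoms)
    elif geometry == "zigzag":
        xyz = np.zeros((n_atoms, 3))
        ang = np.deg2rad(30.0)  # +/-30 deg off the x-axis -> 120 deg internal angle
        pos = np.zeros(3)
        for i in range(1, n_atoms):
            step = np.array(
                [np.cos(ang), np.sin(ang) * (1 if i % 2 else -1), 0.0]
            )
            pos = pos + bond_length * step
            xyz[i] = pos
    elif geometry == "coords":
        if coords is None:
            raise ValueError("geometry='coords' requires an explicit coordinate list")
        xyz = np.asarray(coords, dtype=float)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    edges = [(i, i + 1) for i in range(n_atoms - 1)]
    return MoleculeGraph(labels, xyz, edges, name=name)


def sample_molecule(
    rng_seed,
    n_atoms: int,
    ring_prob: float = 0.0,
    label_alphabet: Sequence[str] = ("C", "C", "C", "N", "O"),
    bond_length: float = 1.5,
    name: str | None = None,
) -> MoleculeGraph:
    """Random connected synthetic molecule: spanning tree plus ring closures.

    Atom ``i > 0`` attaches to a uniformly chosen earlier atom and is placed at
    ``bond_length`` (default 1.5 A, a typical single-bond length) from its
    parent in a uniformly random direction; every non-tree pair then closes a
    ring independently with probability ``ring_prob``.  Bit-identical output
    for a given seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(rng_seed)
    labels = [str(rng.choice(label_alphabet)) for _ in range(n_atoms)]
    coords = np.zeros((n_atoms, 3))
    edges: list[tuple[int, int]] = []
    for i in range(1, n_atoms):
        parent = int(rng.integers(0, i))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[parent] + bond_length * direction
        edges.append((parent, i))
    tree = {(min(u, v), max(u, v)) for u, v in edges}
    if ring_prob > 0:
        for u in range(n_atoms):
            for v in range(u + 1, n_atoms):
                if (u, v) in tree:
                    continue
                if rng.random() < ring_prob:
                    edges.append((u, v))
    if name is None:
        name = f"synth{rng_seed}"
    return MoleculeGraph(labels, coords, edges, name=name)
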