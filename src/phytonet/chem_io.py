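"""Small-molecule structures as heavy-atom graphs, with MOL/SDF I/O.

The pipeline works entirely at 2D topology level: a molecule is an
undirected graph of heavy atoms with bond orders and a per-atom implicit
hydrogen count derived from a fixed valence model.  Explicit hydrogens in
the input are folded into the implicit counts; stereochemistry and 3D
coordinates are ignored.

Valence model
-------------
Default valences: C=4, N=3, O=2, S=2 (6 when the bond-order sum exceeds 2),
P=3 (5 when the bond-order sum exceeds 3), halogens=1.  A +1 formal charge
on nitrogen adds one to the valence; any other charge subtracts its
magnitude.  Aromatic-flagged bonds count 1.5 toward the valence sum, which
is floored after summing, so a benzene carbon (two aromatic bonds) uses 3
of its 4 valences and carries one implicit hydrogen.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "MolecularGraph",
    "SDFRecord",
    "MolParseError",
    "parse_molfile",
    "write_molfile",
    "read_sdf",
    "write_sdf",
    "topological_distances",
]

AROMATIC = 1.5  # sentinel bond order for aromatic-flagged bonds

DEFAULT_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


class MolParseError(ValueError):
    """Raised for malformed MOL/SDF input; message names the line or record."""


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph.

    atoms      -- list of (element symbol, formal charge)
    bonds      -- list of (i, j, order) with i < j, order in {1, 2, 3, 1.5}
    implicit_h -- per-atom implicit hydrogen count (valence model)
    """

    atoms: list[tuple[str, int]]
    bonds: list[tuple[int, int, float]]
    implicit_h: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm = []
        for i, j, order in self.bonds:
            if i == j or not (0 <= i < n) or not (0 <= j < n):
                raise ValueError(f"invalid bond endpoints ({i}, {j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], float(order)))
        self.bonds = norm
        if not self.implicit_h:
            self.implicit_h = [self._implicit_h(i) for i in range(n)]

    # -- valence model -------------------------------------------------

    def bond_order_sum(self, i: int) -> float:
        return sum(o for a, b, o in self.bonds if i in (a, b))

    def _implicit_h(self, i: int) -> int:
        element, charge = self.atoms[i]
        if element == "H":
            return 0
        if element not in DEFAULT_VALENCE:
            raise ValueError(f"no valence model for element {element!r}")
        order_sum = self.bond_order_sum(i)
        valence = DEFAULT_VALENCE[element]
        if element == "S" and order_sum > 2:
            valence = 6
        elif element == "P" and order_sum > 3:
            valence = 5
        if element == "N" and charge > 0:
            valence += charge
        else:
            valence -= abs(charge)
        return max(0, valence - math.floor(order_sum))

    # -- topology helpers ----------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return True
        return len(self._component(0)) == self.n_atoms

    def _component(self, start: int) -> set[int]:
        adj = self.adjacency()
        seen = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return seen

    def fragments(self) -> list["MolecularGraph"]:
        """Split into connected components (new graphs, reindexed)."""
        remaining = set(range(self.n_atoms))
        out = []
        while remaining:
            comp = sorted(self._component(next(iter(remaining))) & remaining)
            remaining -= set(comp)
            index = {old: new for new, old in enumerate(comp)}
            out.append(MolecularGraph(
                atoms=[self.atoms[i] for i in comp],
                bonds=[(index[i], index[j], o) for i, j, o in self.bonds
                       if i in index and j in index],
            ))
        return out

    def ring_bonds(self) -> set[tuple[int, int]]:
        """Bonds that lie on at least one cycle (bridge detection by removal)."""
        rings = set()
        for i, j, _ in self.bonds:
            # bond is in a ring iff endpoints stay connected without it
            adj = self.adjacency()
            adj[i].remove(j)
            adj[j].remove(i)
            seen = {i}
            queue = deque([i])
            while queue:
                u = queue.popleft()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        queue.append(v)
            if j in seen:
                rings.add((i, j))
        return rings


@dataclass
class SDFRecord:
    """One molecule record of an SDF file: id, graph and its data items."""

    id: str
    graph: MolecularGraph
    properties: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MOL V2000 parsing


def parse_molfile(text: str, split_fragments: bool = False) -> MolecularGraph:
    """Parse a MOL V2000 block into a heavy-atom :class:`MolecularGraph`.

    Explicit hydrogen atoms are removed and re-expressed as implicit counts.
    Multi-fragment records raise unless ``split_fragments`` is set, in which
    case the largest fragment is kept.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolParseError("molfile shorter than 4 lines")
    counts = lines[3]
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolParseError(f"malformed counts line (line 4): {counts!r}") from None
    if natoms < 1:
        raise MolParseError("counts line declares no atoms (line 4)")

    atoms: list[tuple[str, int]] = []
    for k in range(natoms):
        lineno = 5 + k
        try:
            line = lines[4 + k]
        except IndexError:
            raise MolParseError(f"truncated atom block (line {lineno})") from None
        element = line[31:34].strip()
        if element != "H" and element not in DEFAULT_VALENCE:
            raise MolParseError(f"unknown element {element!r} (line {lineno})")
        atoms.append((element, 0))

    bonds: list[tuple[int, int, float]] = []
    for k in range(nbonds):
        lineno = 5 + natoms + k
        try:
            line = lines[4 + natoms + k]
        except IndexError:
            raise MolParseError(f"truncated bond block (line {lineno})") from None
        try:
            i = int(line[0:3]) - 1
            j = int(line[3:6]) - 1
            btype = int(line[6:9])
        except ValueError:
            raise MolParseError(f"malformed bond line (line {lineno})") from None
        if not (0 <= i < natoms and 0 <= j < natoms):
            raise MolParseError(f"bond index out of range (line {lineno})")
        order = AROMATIC if btype == 4 else float(btype)
        if btype not in (1, 2, 3, 4):
            raise MolParseError(f"unsupported bond type {btype} (line {lineno})")
        bonds.append((i, j, order))

    # property block: formal charges
    charges: dict[int, int] = {}
    for line in lines[4 + natoms + nbonds:]:
        if line.startswith("M  CHG"):
            fields = line.split()
            n = int(fields[2])
            for t in range(n):
                idx = int(fields[3 + 2 * t]) - 1
                charges[idx] = int(fields[4 + 2 * t])
        elif line.startswith("M  END"):
            break
    atoms = [(el, charges.get(i, 0)) for i, (el, ch) in enumerate(atoms)]

    graph = _fold_explicit_hydrogens(atoms, bonds)
    if not graph.is_connected():
        if not split_fragments:
            raise MolParseError(
                "record contains multiple fragments; enable fragment splitting "
                "to keep the largest"
            )
        graph = max(graph.fragments(), key=lambda g: g.n_atoms)
    return graph


def _fold_explicit_hydrogens(
    atoms: list[tuple[str, int]], bonds: list[tuple[int, int, float]]
) -> MolecularGraph:
    heavy = [k for k, (el, _) in enumerate(atoms) if el != "H"]
    if len(heavy) == len(atoms):
        return MolecularGraph(atoms=atoms, bonds=bonds)
    index = {old: new for new, old in enumerate(heavy)}
    kept_bonds = [
        (index[i], index[j], o)
        for i, j, o in bonds
        if i in index and j in index
    ]
    return MolecularGraph(atoms=[atoms[k] for k in heavy], bonds=kept_bonds)


def write_molfile(graph: MolecularGraph, title: str = "") -> str:
    """Serialize a graph as a MOL V2000 block (zero coordinates, 2D)."""
    lines = [title, "  phytonet", ""]
    lines.append(f"{graph.n_atoms:>3}{len(graph.bonds):>3}  0  0  0  0  0  0  0  0999 V2000")
    for element, _charge in graph.atoms:
        lines.append(f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in graph.bonds:
        btype = 4 if order == AROMATIC else int(order)
        lines.append(f"{i + 1:>3}{j + 1:>3}{btype:>3}  0  0  0  0")
    charged = [(i + 1, ch) for i, (_, ch) in enumerate(graph.atoms) if ch != 0]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        entry = "".join(f"{idx:>4}{ch:>4}" for idx, ch in chunk)
        lines.append(f"M  CHG{len(chunk):>3}{entry}")
    lines.append("M  END")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# SDF


def read_sdf(stream: TextIO | str, split_fragments: bool = False) -> list[SDFRecord]:
    """Read a $$$$-delimited SDF into a list of :class:`SDFRecord`.

    The record id is the title line, falling back to a ``<name>``-like data
    item, then to the 1-based ordinal.  Duplicate ids raise.
    """
    text = stream if isinstance(stream, str) else stream.read()
    records: list[SDFRecord] = []
    ids: set[str] = set()
    chunks = text.split("$$$$")
    for ordinal, chunk in enumerate(chunks, start=1):
        block = chunk.strip("\n")
        if not block.strip():
            continue
        if "M  END" not in block:
            raise MolParseError(f"truncated record {ordinal}: missing M  END")
        mol_part, _, prop_part = block.partition("M  END")
        try:
            graph = parse_molfile(mol_part + "M  END", split_fragments=split_fragments)
        except MolParseError as exc:
            raise MolParseError(f"record {ordinal}: {exc}") from None
        properties = _parse_data_items(prop_part)
        rec_id = mol_part.splitlines()[0].strip() or properties.get("name", "") or str(ordinal)
        if rec_id in ids:
            raise MolParseError(f"duplicate record id {rec_id!r} (record {ordinal})")
        ids.add(rec_id)
        records.append(SDFRecord(id=rec_id, graph=graph, properties=properties))
    return records


def _parse_data_items(text: str) -> dict[str, str]:
    props: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if key is not None:
                props[key] = "\n".join(buf).strip()
            lt, gt = line.find("<"), line.rfind(">")
            key = line[lt + 1:gt] if 0 <= lt < gt else line[1:].strip()
            buf = []
        elif key is not None:
            buf.append(line)
    if key is not None:
        props[key] = "\n".join(buf).strip()
    return props


def write_sdf(records: Iterable[SDFRecord]) -> str:
    out = []
    for rec in records:
        block = write_molfile(rec.graph, title=rec.id)
        for key, value in sorted(rec.properties.items()):
            block += f"\n>  <{key}>\n{value}\n"
        out.append(block + "\n$$$$\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Topology


def topological_distances(graph: MolecularGraph) -> list[list[int]]:
    """All-pairs shortest-path bond counts by per-atom BFS.

    Raises on disconnected graphs; callers split fragments first.
    """
    if not graph.is_connected():
        raise ValueError("graph is disconnected; split fragments before computing distances")
    n = graph.n_atoms
    adj = graph.adjacency()
    dist = [[0] * n for _ in range(n)]
    for source in range(n):
        row = dist[source]
        seen = [False] * n
        seen[source] = True
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    row[v] = row[u] + 1
                    queue.append(v)
    return dist
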