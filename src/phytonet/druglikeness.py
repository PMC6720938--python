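"""Lipinski rule-of-five descriptors and the strict oral drug-likeness filter.

A compound is considered orally drug-like only when it satisfies ALL five
rules strictly: molecular weight < 500 Da, H-bond donors < 5, H-bond
acceptors < 10, rotatable bonds < 10 and logP < 5.  This is the strict
five-way conjunction, not the common "at most one violation" relaxation.

Descriptor conventions (documented because commercial descriptor packages
differ): HBA is the nitrogen+oxygen atom count, HBD the hydrogen count on
nitrogen and oxygen (the classic "sum of OHs and NHs").  logP defaults to a
packaged additive atom-contribution estimate (Wildman–Crippen-style classes
simplified to element + aromaticity + heteroatom neighbourhood); a supplied
logP column from any external estimator bypasses it.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from statistics import mean as _mean

import pandas as pd

from .chem_io import ATOMIC_MASS, AROMATIC, MolecularGraph

__all__ = [
    "CompoundDescriptors",
    "DescriptorSummary",
    "RO5_THRESHOLDS",
    "molecular_weight",
    "count_hba",
    "count_hbd",
    "count_rotatable_bonds",
    "logp",
    "compute_descriptors",
    "ro5_pass",
    "summarize_descriptors",
    "read_descriptor_table",
    "write_descriptor_table",
]

HETEROATOMS = {"N", "O", "S", "P", "F", "Cl", "Br", "I"}

RO5_THRESHOLDS = {"weight": 500.0, "a_don": 5, "a_acc": 10, "b_rotN": 10, "logP": 5.0}

#: Additive logP contributions keyed by (element, aromatic?, heteroatom
#: neighbour?); "=O" is carbonyl-like oxygen.  Values follow the magnitude
#: and sign structure of published atom-contribution schemes.
LOGP_CONTRIBUTIONS = {
    ("C", False, False): 0.1441,
    ("C", False, True): -0.2035,
    ("C", True, False): 0.1581,
    ("C", True, True): 0.1129,
    ("N", False, False): -1.0190,
    ("N", False, True): -1.0190,
    ("N", True, False): -0.3239,
    ("N", True, True): -0.3239,
    ("O", False, False): -0.2893,
    ("O", False, True): -0.2893,
    ("O", True, False): 0.1552,
    ("O", True, True): 0.1552,
    ("=O", False, False): -0.1526,
    ("S", False, False): 0.6482,
    ("S", True, False): 0.6237,
    ("P", False, False): 0.8612,
    ("F", False, False): 0.4202,
    ("Cl", False, False): 0.6895,
    ("Br", False, False): 0.8456,
    ("I", False, False): 0.8857,
    ("H", "on_C"): 0.1230,
    ("H", "on_het"): -0.2677,
}


@dataclass
class CompoundDescriptors:
    """The five Ro5 descriptors for one compound."""

    compound_id: str
    weight: float
    a_acc: int
    a_don: int
    b_rotN: int
    logP: float
    logP_source: str = "computed"  # or "supplied"

    def __post_init__(self) -> None:
        if not (self.weight > 0 and math.isfinite(self.weight)):
            raise ValueError(f"{self.compound_id}: weight must be positive and finite")
        for name in ("a_acc", "a_don", "b_rotN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.compound_id}: {name} must be >= 0")
        if not math.isfinite(self.logP):
            raise ValueError(f"{self.compound_id}: logP must be finite")


@dataclass
class DescriptorSummary:
    """Per-descriptor median / mean / standard deviation over a compound set."""

    median: dict[str, float]
    mean: dict[str, float]
    std: dict[str, float]
    n: int


def molecular_weight(graph: MolecularGraph) -> float:
    """Molecular weight in Da: heavy atoms plus implicit hydrogens."""
    total = 0.0
    for (element, _), h in zip(graph.atoms, graph.implicit_h):
        if element not in ATOMIC_MASS:
            raise ValueError(f"no atomic mass tabulated for {element!r}")
        total += ATOMIC_MASS[element] + h * ATOMIC_MASS["H"]
    return total


def count_hba(graph: MolecularGraph) -> int:
    """H-bond acceptors: number of N and O atoms (Lipinski convention)."""
    return sum(1 for element, _ in graph.atoms if element in ("N", "O"))


def count_hbd(graph: MolecularGraph) -> int:
    """H-bond donors: hydrogens on N and O (sum of OHs and NHs)."""
    return sum(
        h for (element, _), h in zip(graph.atoms, graph.implicit_h)
        if element in ("N", "O")
    )


def count_rotatable_bonds(graph: MolecularGraph, exclude_amide: bool = False) -> int:
    """Single non-ring bonds between two non-terminal heavy atoms.

    Amide C–N bonds count as rotatable unless ``exclude_amide``.
    """
    rings = graph.ring_bonds()
    count = 0
    for i, j, order in graph.bonds:
        if order != 1.0 or (i, j) in rings:
            continue
        if graph.degree(i) < 2 or graph.degree(j) < 2:
            continue
        if exclude_amide and _is_amide_bond(graph, i, j):
            continue
        count += 1
    return count


def _is_amide_bond(graph: MolecularGraph, i: int, j: int) -> bool:
    for c, n in ((i, j), (j, i)):
        if graph.atoms[c][0] == "C" and graph.atoms[n][0] == "N":
            for a, b, order in graph.bonds:
                if order == 2.0 and c in (a, b):
                    other = b if a == c else a
                    if graph.atoms[other][0] == "O":
                        return True
    return False


def logp(graph: MolecularGraph | None = None, supplied: float | None = None) -> tuple[float, str]:
    """Octanol/water partition estimate; a supplied value always wins.

    Returns (value, source) with source "supplied" or "computed".
    """
    if supplied is not None:
        return float(supplied), "supplied"
    if graph is None:
        raise ValueError("need either a molecular graph or a supplied logP value")
    aromatic_atoms = set()
    carbonyl_oxygens = set()
    for i, j, order in graph.bonds:
        if order == AROMATIC:
            aromatic_atoms.update((i, j))
        if order == 2.0:
            for o, c in ((i, j), (j, i)):
                if graph.atoms[o][0] == "O" and graph.atoms[c][0] == "C":
                    carbonyl_oxygens.add(o)
    adj = graph.adjacency()
    total = 0.0
    for idx, ((element, _), h) in enumerate(zip(graph.atoms, graph.implicit_h)):
        aromatic = idx in aromatic_atoms
        het_neighbor = any(graph.atoms[v][0] in HETEROATOMS for v in adj[idx])
        if idx in carbonyl_oxygens:
            candidates = [("=O", False, False)]
        else:
            # most → least specific; table distinguishes neighbourhood only
            # where the class is tabulated
            candidates = [
                (element, aromatic, het_neighbor),
                (element, aromatic, False),
                (element, False, False),
            ]
        key = next((k for k in candidates if k in LOGP_CONTRIBUTIONS), None)
        if key is None:
            raise ValueError(f"no logP contribution for atom class {candidates[0]}")
        total += LOGP_CONTRIBUTIONS[key]
        h_key = ("H", "on_het" if element in HETEROATOMS else "on_C")
        total += h * LOGP_CONTRIBUTIONS[h_key]
    return total, "computed"


def compute_descriptors(
    compound_id: str,
    graph: MolecularGraph,
    supplied_logp: float | None = None,
    exclude_amide: bool = False,
) -> CompoundDescriptors:
    value, source = logp(graph, supplied_logp)
    return CompoundDescriptors(
        compound_id=compound_id,
        weight=molecular_weight(graph),
        a_acc=count_hba(graph),
        a_don=count_hbd(graph),
        b_rotN=count_rotatable_bonds(graph, exclude_amide=exclude_amide),
        logP=value,
        logP_source=source,
    )


def ro5_pass(d: CompoundDescriptors) -> bool:
    """True iff all five rules hold with strict inequality."""
    return (
        d.weight < RO5_THRESHOLDS["weight"]
        and d.a_don < RO5_THRESHOLDS["a_don"]
        and d.a_acc < RO5_THRESHOLDS["a_acc"]
        and d.b_rotN < RO5_THRESHOLDS["b_rotN"]
        and d.logP < RO5_THRESHOLDS["logP"]
    )


_COLUMNS = ("weight", "a_acc", "a_don", "b_rotN", "logP")


def summarize_descriptors(table: list[CompoundDescriptors], ddof: int = 1) -> DescriptorSummary:
    """Column-wise median (lower-middle for even n), mean and std (n−ddof).

    A single row yields std 0 rather than dividing by zero.
    """
    if not table:
        raise ValueError("cannot summarize an empty descriptor table")
    medians, means, stds = {}, {}, {}
    n = len(table)
    for col in _COLUMNS:
        values = sorted(float(getattr(d, col)) for d in table)
        medians[col] = values[(n - 1) // 2]
        mu = _mean(values)
        means[col] = mu
        if n <= ddof:
            stds[col] = 0.0
        else:
            stds[col] = math.sqrt(sum((v - mu) ** 2 for v in values) / (n - ddof))
    return DescriptorSummary(median=medians, mean=means, std=stds, n=n)


# ---------------------------------------------------------------------------
# TSV interface


def read_descriptor_table(path_or_buffer) -> list[CompoundDescriptors]:
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"compound_id": str})
    required = {"compound_id", *_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    return [
        CompoundDescriptors(
            compound_id=row.compound_id,
            weight=float(row.weight),
            a_acc=int(row.a_acc),
            a_don=int(row.a_don),
            b_rotN=int(row.b_rotN),
            logP=float(row.logP),
            logP_source=getattr(row, "logP_source", "supplied"),
        )
        for row in df.itertuples(index=False)
    ]


def write_descriptor_table(table: list[CompoundDescriptors], path=None) -> str | None:
    df = pd.DataFrame(
        [
            {
                "compound_id": d.compound_id,
                "weight": round(d.weight, 4),
                "a_acc": d.a_acc,
                "a_don": d.a_don,
                "b_rotN": d.b_rotN,
                "logP": round(d.logP, 4),
                "logP_source": d.logP_source,
            }
            for d in table
        ]
    )
    if path is None:
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    df.to_csv(path, sep="\t", index=False)
    return None
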