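"""Ligand-based target fishing with atom-pair fingerprints.

A compound's fingerprint is the multiset of features (type_i, type_j, d) —
one per unordered pair of heavy atoms, where d is their topological
(bond-count) distance and the atom type defaults to element symbol plus
heavy-atom degree.  Similarity between two fingerprints is the Tanimoto
coefficient c/(a+b+c): c shared features, a and b the features unique to
each side, counted with multiplicity.

A compound is fished to a target when its best similarity to any of the
target's known ligands exceeds the threshold (study default 0.8, strict >).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .chem_io import AROMATIC, MolecularGraph, topological_distances

__all__ = [
    "AtomPairFingerprint",
    "ReferenceLibrary",
    "CandidatePair",
    "TYPING_SCHEMES",
    "atom_pair_fingerprint",
    "tanimoto",
    "screen",
]

logger = logging.getLogger(__name__)

TYPING_SCHEMES = ("element", "element+degree", "element+degree+aromatic")
DEFAULT_SCHEME = "element+degree"


@dataclass(frozen=True)
class AtomPairFingerprint:
    """Multiset of typed atom-pair features with their topological distance."""

    features: Counter
    typing_scheme: str = DEFAULT_SCHEME

    @property
    def size(self) -> int:
        """Feature count with multiplicity: C(n_heavy, 2)."""
        return sum(self.features.values())


def _atom_types(graph: MolecularGraph, scheme: str) -> list[str]:
    if scheme not in TYPING_SCHEMES:
        raise ValueError(f"unknown typing scheme {scheme!r}; choose from {TYPING_SCHEMES}")
    aromatic_atoms = set()
    for i, j, order in graph.bonds:
        if order == AROMATIC:
            aromatic_atoms.update((i, j))
    types = []
    for idx, (element, _) in enumerate(graph.atoms):
        t = element
        if scheme != "element":
            t += str(graph.degree(idx))
        if scheme == "element+degree+aromatic" and idx in aromatic_atoms:
            t += "a"
        types.append(t)
    return types


def atom_pair_fingerprint(
    graph: MolecularGraph, typing_scheme: str = DEFAULT_SCHEME
) -> AtomPairFingerprint:
    """One feature per unordered heavy-atom pair; requires a connected graph."""
    types = _atom_types(graph, typing_scheme)
    dist = topological_distances(graph)
    features: Counter = Counter()
    n = graph.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = sorted((types[i], types[j]))
            features[(ti, tj, dist[i][j])] += 1
    return AtomPairFingerprint(features=features, typing_scheme=typing_scheme)


def tanimoto(fpA: AtomPairFingerprint, fpB: AtomPairFingerprint, counted: bool = True) -> float:
    """Tanimoto coefficient c/(a+b+c) over (multi)sets of atom-pair features.

    counted=True uses multiset (minimum-multiplicity) intersection; False
    collapses to plain sets.  Two empty fingerprints are identical nothing
    (similarity 1); one empty against one non-empty is 0.
    """
    if fpA.typing_scheme != fpB.typing_scheme:
        raise ValueError(
            f"typing scheme mismatch: {fpA.typing_scheme!r} vs {fpB.typing_scheme!r}"
        )
    a_feats, b_feats = fpA.features, fpB.features
    if not counted:
        a_feats = Counter(set(a_feats))
        b_feats = Counter(set(b_feats))
    c = sum(min(a_feats[k], b_feats[k]) for k in a_feats.keys() & b_feats.keys())
    size_a = sum(a_feats.values())
    size_b = sum(b_feats.values())
    union = size_a + size_b - c  # a + b + c
    if union == 0:
        return 1.0
    return c / union


@dataclass
class ReferenceLibrary:
    """Known-ligand sets per target, emulating a ChEMBL-style reference.

    entries: (target_id, gene_symbol, ligand_id, fingerprint) tuples;
    every target has at least one ligand and ligand ids are unique per target.
    """

    entries: list[tuple[str, str, str, AtomPairFingerprint]]
    _by_target: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_target: dict[str, list[tuple[str, str, AtomPairFingerprint]]] = {}
        genes: dict[str, str] = {}
        for target_id, gene, ligand_id, fp in self.entries:
            bucket = by_target.setdefault(target_id, [])
            if any(lid == ligand_id for lid, _, _ in bucket):
                raise ValueError(f"duplicate ligand id {ligand_id!r} for target {target_id!r}")
            bucket.append((ligand_id, gene, fp))
            genes[target_id] = gene
        self._by_target = by_target
        self.genes = genes

    @property
    def targets(self) -> list[str]:
        return sorted(self._by_target)

    def ligands(self, target_id: str) -> list[tuple[str, str, AtomPairFingerprint]]:
        return self._by_target[target_id]


@dataclass
class CandidatePair:
    """A compound fished to a target, with the best-matching known ligand."""

    compound_id: str
    target_id: str
    gene_symbol: str
    best_similarity: float
    best_ligand_id: str


def screen(
    compounds: list[tuple[str, AtomPairFingerprint]],
    library: ReferenceLibrary,
    threshold: float = 0.8,
    counted: bool = True,
) -> list[CandidatePair]:
    """Fish targets for each compound: retain pairs with best similarity > threshold.

    Similarity to a target is the max over its known ligands.  Output is
    sorted by compound id, then descending similarity, then target id.
    """
    if not library.entries:
        raise ValueError("reference library is empty")
    out: list[CandidatePair] = []
    for compound_id, fp in compounds:
        if fp is None:
            logger.warning("compound %s has no fingerprint; skipped", compound_id)
            continue
        for target_id in library.targets:
            best_sim, best_ligand = -1.0, None
            for ligand_id, _gene, lig_fp in library.ligands(target_id):
                sim = tanimoto(fp, lig_fp, counted=counted)
                if sim > best_sim:
                    best_sim, best_ligand = sim, ligand_id
            if best_sim > threshold:
                out.append(CandidatePair(
                    compound_id=compound_id,
                    target_id=target_id,
                    gene_symbol=library.genes[target_id],
                    best_similarity=best_sim,
                    best_ligand_id=best_ligand,
                ))
    out.sort(key=lambda p: (p.compound_id, -p.best_similarity, p.target_id))
    return out


def write_candidate_pairs(pairs: list[CandidatePair], path=None) -> str | None:
    df = pd.DataFrame(
        [
            {
                "compound_id": p.compound_id,
                "target_id": p.target_id,
                "gene_symbol": p.gene_symbol,
                "best_similarity": round(p.best_similarity, 6),
                "best_ligand_id": p.best_ligand_id,
            }
            for p in pairs
        ],
        columns=["compound_id", "target_id", "gene_symbol", "best_similarity", "best_ligand_id"],
    )
    if path is None:
        import io

        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    df.to_csv(path, sep="\t", index=False)
    return None


def read_candidate_pairs(path) -> list[CandidatePair]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_id": str})
    return [
        CandidatePair(
            compound_id=row.compound_id,
            target_id=row.target_id,
            gene_symbol=row.gene_symbol,
            best_similarity=float(row.best_similarity),
            best_ligand_id=str(row.best_ligand_id),
        )
        for row in df.itertuples(index=False)
    ]
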