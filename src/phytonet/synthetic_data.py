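"""Synthetic inputs with planted, recoverable signal, plus packaged fixtures.

Every input class the pipeline consumes can be generated here with known
ground truth: random valence-valid molecules (SDF), a per-target known-ligand
library whose planted actives are light perturbations of chosen compounds
(guaranteed above the similarity threshold) and whose decoys sit below it,
an interaction-score table separating planted-true pairs from the rest
around the score cutoff, and a pathway annotation with one deliberately
over-represented pathway.  All generators are pure functions of the config:
the seed fully determines the emitted bytes (stdlib MT19937 streams, one
independently-derived stream per generator, no global state).

The module also loads the packaged study fixtures: the descriptor summary
of the 181 drug-like compounds, the 49-target table (gene, protein, degree,
betweenness) and the 17-pathway enrichment table.  Because the study's edge
list was never published, :func:`fixture_target_network` builds a *synthetic*
degree-consistent realization of the target degree sequence (target of
degree d joins compounds 1..d); node/edge counts and every target-side
degree are exact, compound-side degrees are one admissible realization.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem_io import DEFAULT_VALENCE, MolecularGraph, SDFRecord, write_sdf
from .druglikeness import compute_descriptors, ro5_pass
from .enrichment import PathwayAnnotation, write_gmt
from .interaction_filter import InteractionScore, write_score_table
from .target_fishing import (
    AtomPairFingerprint,
    ReferenceLibrary,
    atom_pair_fingerprint,
    tanimoto,
)
from .ct_network import CTNetwork, build_network

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_molecules",
    "gen_reference_library",
    "gen_scores",
    "gen_annotation",
    "emit_bundle",
    "load_study_fixtures",
    "StudyFixtures",
    "fixture_target_network",
    "fixture_pathway_annotation",
]

_FIXTURE_SHA256 = {
    "descriptor_summary.tsv": "8087c1b3ad23bf962974816e21ecb2448ba7b9574f4aff5024ba6fd71a01c167",
    "target_table.tsv": "d84befa2824307a8bf2a5a1964a5b2b639d40d10410fc5e8e5270407ddd989d1",
    "pathway_table.tsv": "f242b4b5fc36d8780effbe50aeca1f9274123994898b5bd309003bf4a28de78f",
}


@dataclass
class SimulationConfig:
    """Study-shaped defaults: thresholds 0.8 / −8.0 / 0.01, 20 planted pairs,
    80 decoy ligands, 1-edit actives, 200-gene universe, one planted pathway."""

    seed: int = 0
    n_compounds: int = 30
    atom_count_range: tuple[int, int] = (10, 22)
    elements: tuple[str, ...] = ("C", "N", "O", "S")
    element_weights: tuple[float, ...] = (0.62, 0.12, 0.22, 0.04)
    n_targets: int = 10
    actives_per_target: int = 2
    perturbation_edits: int = 1
    decoy_count: int = 80
    similarity_threshold: float = 0.8
    score_cutoff: float = -8.0
    alpha: float = 0.01
    universe_size: int = 200
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (8, 16)
    planted_overlap_fraction: float = 0.6
    max_retries: int = 200

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_targets", "actives_per_target", "decoy_count",
                     "universe_size", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.similarity_threshold < 1:
            raise ValueError("similarity_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def rng(self, stream: str) -> random.Random:
        """Independent deterministic stream derived from (seed, stream name)."""
        return random.Random(f"{self.seed}:{stream}")


@dataclass
class GroundTruth:
    """What was planted: active pairs, true interactions, enriched pathway."""

    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_pathway: str = ""
    decoy_ligands: list[str] = field(default_factory=list)
    target_genes: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Molecules


def _random_molecule(rng: random.Random, n_atoms: int, config: SimulationConfig) -> MolecularGraph:
    """Random connected valence-valid heavy-atom graph.

    Grown as a random attachment tree (first atom forced to carbon so growth
    never dead-ends immediately), then decorated with up to two ring-closing
    edges and up to two bond-order upgrades where free valence allows.
    """
    while True:
        elements = ["C"] + rng.choices(config.elements, weights=config.element_weights,
                                       k=n_atoms - 1)
        capacity = [DEFAULT_VALENCE[e] for e in elements]
        used = [0] * n_atoms
        bonds: list[tuple[int, int, float]] = []
        ok = True
        for k in range(1, n_atoms):
            open_atoms = [i for i in range(k) if used[i] < capacity[i]]
            if not open_atoms:
                ok = False
                break
            parent = rng.choice(open_atoms)
            bonds.append((parent, k, 1.0))
            used[parent] += 1
            used[k] += 1
        if not ok:
            continue
        bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        # ring closures
        for _ in range(rng.randint(0, 2)):
            candidates = [
                (i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)
                if (i, j) not in bonded and used[i] < capacity[i] and used[j] < capacity[j]
            ]
            if not candidates:
                break
            i, j = rng.choice(candidates)
            bonds.append((i, j, 1.0))
            bonded.add((i, j))
            used[i] += 1
            used[j] += 1
        # bond-order upgrades
        for _ in range(rng.randint(0, 2)):
            upgradable = [
                idx for idx, (i, j, o) in enumerate(bonds)
                if o == 1.0 and used[i] < capacity[i] and used[j] < capacity[j]
            ]
            if not upgradable:
                break
            idx = rng.choice(upgradable)
            i, j, _ = bonds[idx]
            bonds[idx] = (i, j, 2.0)
            used[i] += 1
            used[j] += 1
        return MolecularGraph(atoms=[(e, 0) for e in elements], bonds=bonds)


def gen_molecules(config: SimulationConfig) -> list[SDFRecord]:
    """Generate the compound library; deterministic given the config seed."""
    rng = config.rng("molecules")
    lo, hi = config.atom_count_range
    records = []
    width = len(str(config.n_compounds))
    for idx in range(1, config.n_compounds + 1):
        graph = _random_molecule(rng, rng.randint(lo, hi), config)
        records.append(SDFRecord(id=f"cmpd_{idx:0{width}d}", graph=graph))
    return records


# ---------------------------------------------------------------------------
# Reference library


_VALENCE_CLASSES = [("O", "S"), ("F", "Cl", "Br", "I")]


def _perturb(rng: random.Random, graph: MolecularGraph, edits: int) -> MolecularGraph:
    """Apply up to `edits` valence-preserving local edits to a copy."""
    atoms = list(graph.atoms)
    bonds = list(graph.bonds)
    for _ in range(edits):
        moves = ["swap_terminal", "add_terminal"]
        if len(atoms) > 2:
            moves.append("remove_terminal")
        move = rng.choice(moves)
        degree = [0] * len(atoms)
        for i, j, _ in bonds:
            degree[i] += 1
            degree[j] += 1
        terminals = [i for i in range(len(atoms)) if degree[i] == 1]
        if move == "swap_terminal":
            swappable = [
                i for i in terminals
                if any(atoms[i][0] in cls for cls in _VALENCE_CLASSES)
            ]
            if swappable:
                i = rng.choice(swappable)
                cls = next(c for c in _VALENCE_CLASSES if atoms[i][0] in c)
                choices = [e for e in cls if e != atoms[i][0]]
                atoms[i] = (rng.choice(choices), atoms[i][1])
                continue
            move = "add_terminal"
        if move == "remove_terminal" and terminals:
            victim = rng.choice(terminals)
            keep = [k for k in range(len(atoms)) if k != victim]
            index = {old: new for new, old in enumerate(keep)}
            atoms = [atoms[k] for k in keep]
            bonds = [(index[i], index[j], o) for i, j, o in bonds
                     if i != victim and j != victim]
            continue
        # add_terminal (also the fallback)
        capacity = [DEFAULT_VALENCE[e] for e, _ in atoms]
        used = [0.0] * len(atoms)
        for i, j, o in bonds:
            used[i] += o
            used[j] += o
        open_atoms = [i for i in range(len(atoms)) if used[i] < capacity[i]]
        if open_atoms:
            parent = rng.choice(open_atoms)
            atoms.append((rng.choice(("C", "O")), 0))
            bonds.append((parent, len(atoms) - 1, 1.0))
    return MolecularGraph(atoms=atoms, bonds=bonds)


def gen_reference_library(
    config: SimulationConfig, molecules: list[SDFRecord]
) -> tuple[ReferenceLibrary, GroundTruth, list[SDFRecord]]:
    """Build per-target known-ligand sets around planted active pairs.

    Actives are perturbed copies of drug-like compounds, re-generated with
    fewer edits until their similarity to the source compound exceeds the
    threshold (zero edits gives an identical copy, similarity 1).  Decoys
    are fresh random molecules verified to sit at or below the threshold
    against every compound.  Returns (library, ground truth, ligand records).
    """
    rng = config.rng("library")
    fingerprints = {rec.id: atom_pair_fingerprint(rec.graph) for rec in molecules}
    druglike = [
        rec for rec in molecules
        if ro5_pass(compute_descriptors(rec.id, rec.graph))
    ]
    if len(druglike) < 2:
        raise ValueError(
            "too few drug-like compounds to plant actives; "
            "increase n_compounds or adjust the atom-count range"
        )
    truth = GroundTruth()
    entries = []
    ligand_records = []
    targets = [f"T{i:02d}" for i in range(1, config.n_targets + 1)]
    truth.target_genes = {t: f"GENE{i:02d}" for i, t in enumerate(targets, start=1)}

    for target in targets:
        sources = rng.sample(druglike, min(config.actives_per_target, len(druglike)))
        for a_idx, src in enumerate(sources, start=1):
            ligand_id = f"{target}_active_{a_idx}"
            for edits in range(config.perturbation_edits, -1, -1):
                candidate = _perturb(rng, src.graph, edits)
                if candidate.is_connected():
                    sim = tanimoto(fingerprints[src.id], atom_pair_fingerprint(candidate))
                    if sim > config.similarity_threshold:
                        break
            else:  # pragma: no cover - edits=0 always yields similarity 1
                raise RuntimeError("could not plant an active above the threshold")
            entries.append((target, truth.target_genes[target], ligand_id,
                            atom_pair_fingerprint(candidate)))
            ligand_records.append(SDFRecord(id=ligand_id, graph=candidate))
            truth.planted_pairs.append((src.id, target))

    lo, hi = config.atom_count_range
    per_target = max(1, config.decoy_count // config.n_targets)
    decoy_idx = 0
    for target in targets:
        for _ in range(per_target):
            decoy_idx += 1
            ligand_id = f"{target}_decoy_{decoy_idx:03d}"
            for _attempt in range(config.max_retries):
                graph = _random_molecule(rng, rng.randint(lo, hi), config)
                fp = atom_pair_fingerprint(graph)
                if all(
                    tanimoto(fp, cfp) <= config.similarity_threshold
                    for cfp in fingerprints.values()
                ):
                    break
            else:
                raise RuntimeError(
                    "could not generate a decoy below the similarity threshold; "
                    "lower the threshold or shrink the atom-count range"
                )
            entries.append((target, truth.target_genes[target], ligand_id, fp))
            ligand_records.append(SDFRecord(id=ligand_id, graph=graph))
            truth.decoy_ligands.append(ligand_id)

    truth.planted_pairs = sorted(set(truth.planted_pairs))
    return ReferenceLibrary(entries=entries), truth, ligand_records


# ---------------------------------------------------------------------------
# Interaction scores


def gen_scores(
    config: SimulationConfig,
    truth: GroundTruth,
    compound_ids: list[str],
    target_ids: list[str],
) -> list[InteractionScore]:
    """Score every (compound, target) combination around the cutoff.

    Planted-true pairs draw uniformly from [cutoff−3, cutoff]; all other
    pairs from (cutoff, cutoff+4], strictly excluding the boundary.
    """
    rng = config.rng("scores")
    planted = set(truth.planted_pairs)
    cutoff = config.score_cutoff
    scores = []
    for cid in compound_ids:
        for tid in target_ids:
            if (cid, tid) in planted:
                value = rng.uniform(cutoff - 3.0, cutoff)
            else:
                value = cutoff + 4.0 * (1.0 - rng.random())  # in (cutoff, cutoff+4]
            scores.append(InteractionScore(cid, tid, value))
    return scores


# ---------------------------------------------------------------------------
# Pathway annotation


def gen_annotation(
    config: SimulationConfig, query_genes: list[str]
) -> tuple[PathwayAnnotation, str]:
    """Universe + pathways with one planted over-represented pathway.

    The planted pathway draws ceil(overlap_fraction × size) of its members
    from the query genes; the remaining pathways are uniform draws from the
    universe.  Returns (annotation, planted pathway id).
    """
    rng = config.rng("annotation")
    query = sorted(set(query_genes))
    if len(query) > config.universe_size:
        raise ValueError("universe_size smaller than the query gene list")
    filler = [f"FILL{i:04d}" for i in range(1, config.universe_size - len(query) + 1)]
    universe = frozenset(query) | frozenset(filler)
    lo, hi = config.pathway_size_range

    planted_size = rng.randint(lo, hi)
    overlap = math.ceil(config.planted_overlap_fraction * planted_size)
    if overlap > len(query):
        raise ValueError(
            f"planted overlap {overlap} exceeds query size {len(query)}; "
            "shrink pathway_size_range or planted_overlap_fraction"
        )
    planted_genes = set(rng.sample(query, overlap))
    planted_genes |= set(rng.sample(filler, planted_size - overlap))
    planted_id = "PW01"

    pathways = [(planted_id, "planted pathway", frozenset(planted_genes))]
    pool = sorted(universe)
    for i in range(2, config.n_pathways + 1):
        size = rng.randint(lo, hi)
        genes = frozenset(rng.sample(pool, size))
        pathways.append((f"PW{i:02d}", f"background pathway {i}", genes))
    return PathwayAnnotation(pathways=pathways, universe=universe), planted_id


# ---------------------------------------------------------------------------
# Bundle emission


def emit_bundle(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Write every pipeline input to ``outdir``; deterministic per seed.

    Files: compounds.sdf, library.tsv + ligands.sdf, scores.tsv,
    pathways.gmt, universe.txt, query_genes.txt, ground_truth.json,
    config.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    molecules = gen_molecules(config)
    library, truth, ligand_records = gen_reference_library(config, molecules)

    (outdir / "compounds.sdf").write_text(write_sdf(molecules))
    (outdir / "ligands.sdf").write_text(write_sdf(ligand_records))
    lib_rows = [
        {"target_id": t, "gene_symbol": g, "ligand_id": lid, "structure_ref": "ligands.sdf"}
        for t, g, lid, _ in library.entries
    ]
    pd.DataFrame(lib_rows).to_csv(outdir / "library.tsv", sep="\t", index=False)

    targets = library.targets
    scores = gen_scores(config, truth, [m.id for m in molecules], targets)
    write_score_table(scores, outdir / "scores.tsv")

    query_genes = sorted(truth.target_genes.values())
    annotation, planted_id = gen_annotation(config, query_genes)
    truth.planted_pathway = planted_id
    (outdir / "pathways.gmt").write_text(write_gmt(annotation))
    (outdir / "universe.txt").write_text("\n".join(sorted(annotation.universe)) + "\n")
    (outdir / "query_genes.txt").write_text("\n".join(query_genes) + "\n")

    (outdir / "ground_truth.json").write_text(json.dumps({
        "planted_pairs": truth.planted_pairs,
        "planted_pathway": truth.planted_pathway,
        "decoy_ligands": truth.decoy_ligands,
        "target_genes": truth.target_genes,
    }, indent=2))
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2))
    return truth


# ---------------------------------------------------------------------------
# Packaged study fixtures


@dataclass
class StudyFixtures:
    """Transcribed study tables: descriptor summary, targets, pathways."""

    descriptor_summary: pd.DataFrame  # descriptor, median, mean, std (181 drug-like compounds)
    targets: pd.DataFrame  # 49 targets: uniprot, protein, betweenness, degree, gene
    pathways: pd.DataFrame  # 17 pathways: name, common genes, Nr, %associated, p


def _load_checked(name: str) -> pd.DataFrame:
    ref = resources.files("phytonet.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    return pd.read_csv(ref.open("r"), sep="\t")


def load_study_fixtures() -> StudyFixtures:
    """Load the packaged fixture tables, verifying their checksums."""
    summary = _load_checked("descriptor_summary.tsv")
    targets = _load_checked("target_table.tsv")
    pathways = _load_checked("pathway_table.tsv")
    if len(targets) != 49:
        raise ValueError(f"target fixture must have 49 rows, found {len(targets)}")
    if len(pathways) != 17:
        raise ValueError(f"pathway fixture must have 17 rows, found {len(pathways)}")
    return StudyFixtures(descriptor_summary=summary, targets=targets, pathways=pathways)


def fixture_target_network(n_compounds: int = 63) -> CTNetwork:
    """Synthetic degree-consistent realization of the 49-target network.

    The study's edge list is unpublished; this nested construction joins a
    target of degree d to compounds 1..d, exactly reproducing the fixture's
    target-side degree sequence (and hence node/edge counts and every
    handshake-lemma quantity) on 63 compound nodes.
    """
    fixtures = load_study_fixtures()
    compounds = [f"compound_{i:02d}" for i in range(1, n_compounds + 1)]
    pairs = []
    for row in fixtures.targets.itertuples(index=False):
        degree = int(row.degree)
        if degree > n_compounds:
            raise ValueError(f"target {row.gene_name} degree {degree} exceeds compound count")
        pairs.extend((compounds[i], row.gene_name) for i in range(degree))
    return build_network(pairs, compounds=compounds)


def fixture_pathway_annotation(padding_prefix: str = "SYNPAD") -> PathwayAnnotation:
    """Pathway annotation reconstructed from the 17-pathway fixture.

    Pathway sizes are back-derived as K = round(100·Nr/pct); members beyond
    the printed overlap genes are synthetic padding symbols (the study's
    KEGG release is unrecoverable).  The universe is the union of pathway
    genes plus the 49 target genes.
    """
    fixtures = load_study_fixtures()
    query = set(fixtures.targets["gene_name"])
    pathways = []
    for row in fixtures.pathways.itertuples(index=False):
        common = [g.strip() for g in row.common_genes.split(",")]
        size = round(100 * int(row.nr) / float(row.pct_associated))
        padding = [f"{padding_prefix}_{row.rank}_{i:03d}" for i in range(1, size - len(common) + 1)]
        pathways.append((f"fixture_{row.rank}", row.pathway_name, frozenset(common + padding)))
    union = frozenset().union(*(g for _, _, g in pathways))
    return PathwayAnnotation(pathways=pathways, universe=union | frozenset(query))
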