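"""Synthetic strain proteomes and metagenome samples with planted truth.

Strain proteomes carry a planted pangenome structure — core families present
in every strain, dispensable families present in a proper subset of size
>= 2, and per-strain unique genes — evolved along a planted binary tree by a
per-branch substitution process.  Metagenome samples are deterministic
mixtures of strain gene subsets plus unrelated noise proteins.  Everything
is seed-deterministic and accompanied by machine-readable truth.

Conventions (documented design decisions):

* residue alphabet = 20 standard amino acids with uniform ancestral
  composition, which keeps the expected p-distance closed-form;
* along a branch of length ``b`` each site substitutes once with
  probability ``1 - exp(-b * divergence)``, the new residue drawn uniformly
  from the other 19;
* sample inclusion takes ``floor(fraction * n)`` genes per strain, chosen
  by a seeded shuffle;
* noise genes are i.i.d. uniform-residue sequences (≈5% identity to any
  family, far below all clustering thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml

from panmeta.phylogeny import DistanceMatrix
from panmeta.seqio import GeneRecord, write_fasta

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_ARR = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

CORE = "core"
DISPENSABLE = "dispensable"
STRAIN_SPECIFIC = "strain_specific"
NOISE = "noise"

__all__ = [
    "PlantedPangenomeSpec",
    "PlantedTruth",
    "Pangenome",
    "generate_planted_tree",
    "evolve_family",
    "generate_pangenome",
    "generate_metagenome_sample",
    "expected_leaf_pair_pdistance",
]


def strain_name(i: int) -> str:
    return f"strain_{i}"


@dataclass(frozen=True)
class PlantedPangenomeSpec:
    """Parameters of a planted pangenome.

    ``dispensable_strain_subsets`` may be ``None``, in which case subsets
    of random size in [2, n_strains - 1] are drawn from the spec seed.
    Subsets are given as frozensets of strain names.
    """

    n_strains: int
    n_core: int
    n_dispensable: int
    n_unique_per_strain: int
    dispensable_strain_subsets: tuple[frozenset, ...] | None = None
    protein_length_mean: int = 120
    protein_length_jitter: int = 30
    divergence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        for name in ("n_core", "n_dispensable", "n_unique_per_strain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.protein_length_mean - self.protein_length_jitter < 10:
            raise ValueError("protein length mean - jitter must be >= 10")
        if self.dispensable_strain_subsets is not None:
            subsets = tuple(frozenset(s) for s in self.dispensable_strain_subsets)
            if len(subsets) != self.n_dispensable:
                raise ValueError(
                    "number of dispensable subsets must equal n_dispensable"
                )
            strains = set(self.strains)
            for sub in subsets:
                if not 2 <= len(sub) < self.n_strains:
                    raise ValueError(
                        "every dispensable subset must be a proper subset "
                        "with size >= 2"
                    )
                if not sub <= strains:
                    raise ValueError(f"unknown strain in subset: {sorted(sub)}")
            object.__setattr__(self, "dispensable_strain_subsets", subsets)

    @property
    def strains(self) -> list[str]:
        return [strain_name(i + 1) for i in range(self.n_strains)]

    @classmethod
    def from_yaml(cls, path) -> "PlantedPangenomeSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        subsets = data.pop("dispensable_strain_subsets", None)
        if subsets is not None:
            subsets = tuple(frozenset(s) for s in subsets)
        return cls(dispensable_strain_subsets=subsets, **data)

    def to_yaml(self, path) -> None:
        data = {
            "n_strains": self.n_strains,
            "n_core": self.n_core,
            "n_dispensable": self.n_dispensable,
            "n_unique_per_strain": self.n_unique_per_strain,
            "protein_length_mean": self.protein_length_mean,
            "protein_length_jitter": self.protein_length_jitter,
            "divergence": self.divergence,
            "seed": self.seed,
        }
        if self.dispensable_strain_subsets is not None:
            data["dispensable_strain_subsets"] = [
                sorted(s) for s in self.dispensable_strain_subsets
            ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class FamilyTruth:
    family_id: str
    class_label: str
    members: dict[str, str]  # gene_id -> strain


@dataclass
class SampleTruth:
    sample: str
    mixture: dict[str, float]       # strain -> inclusion fraction
    noise_count: int
    origins: dict[str, str | None]  # sample gene id -> source gene id (None = noise)


@dataclass
class PlantedTruth:
    """Machine-readable ground truth for a generated pangenome."""

    families: dict[str, FamilyTruth]
    tree: dendropy.Tree
    samples: dict[str, SampleTruth] = field(default_factory=dict)

    @property
    def gene_index(self) -> dict[str, tuple[str, str, str]]:
        """gene_id -> (family_id, class, strain)."""
        index = {}
        for fam in self.families.values():
            for gene_id, strain in fam.members.items():
                index[gene_id] = (fam.family_id, fam.class_label, strain)
        return index

    def family_partition(self) -> dict[str, set[str]]:
        """family_id -> set of member gene ids."""
        return {
            fid: set(fam.members) for fid, fam in self.families.items()
        }

    def class_counts(self) -> dict[str, int]:
        counts = {CORE: 0, DISPENSABLE: 0, STRAIN_SPECIFIC: 0}
        for fam in self.families.values():
            counts[fam.class_label] += 1
        return counts

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tfamily_id\tclass\tstrain\tsample\n")
            for fam in self.families.values():
                for gene_id, strain in sorted(fam.members.items()):
                    fh.write(
                        f"{gene_id}\t{fam.family_id}\t{fam.class_label}\t{strain}\t-\n"
                    )
            for st in self.samples.values():
                for gid, origin in sorted(st.origins.items()):
                    fam_id, cls = "-", NOISE
                    if origin is not None:
                        for fam in self.families.values():
                            if origin in fam.members:
                                fam_id, cls = fam.family_id, fam.class_label
                                break
                    fh.write(f"{gid}\t{fam_id}\t{cls}\t-\t{st.sample}\n")


@dataclass
class Pangenome:
    """Generated strain proteomes plus planted truth."""

    spec: PlantedPangenomeSpec
    proteomes: dict[str, list[GeneRecord]]  # strain -> records
    truth: PlantedTruth

    def all_records(self) -> list[GeneRecord]:
        return [rec for strain in self.spec.strains for rec in self.proteomes[strain]]

    def write_fastas(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for strain in self.spec.strains:
            path = out_dir / f"{strain}.faa"
            write_fasta(self.proteomes[strain], path)
            paths.append(path)
        return paths


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def generate_planted_tree(
    n_strains: int, seed: int
) -> tuple[dendropy.Tree, DistanceMatrix]:
    """Random unrooted binary tree with positive branch lengths.

    Built by random sequential addition: each new leaf bisects a uniformly
    chosen edge.  Leaves are labeled ``strain_1 .. strain_N``.  Returns the
    tree together with its leaf-to-leaf path-length matrix.  Deterministic
    for a fixed seed.
    """
    if n_strains < 3:
        raise ValueError("too few taxa: need n_strains >= 3")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace([strain_name(i + 1) for i in range(n_strains)])
    tree = dendropy.Tree(taxon_namespace=taxa)

    def blen() -> float:
        return float(rng.uniform(0.05, 0.5))

    # start from the unique unrooted 3-leaf topology (central trifurcation)
    for i in range(3):
        child = tree.seed_node.new_child(edge_length=blen())
        child.taxon = taxa.get_taxon(strain_name(i + 1))

    for i in range(3, n_strains):
        # bisect a uniformly chosen existing edge
        edges = [
            nd.edge
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        ]
        edge = edges[int(rng.integers(0, len(edges)))]
        child = edge.head_node
        parent = edge.tail_node
        split = dendropy.Node(edge_length=edge.length * float(rng.uniform(0.25, 0.75)))
        remaining = edge.length - split.edge_length
        parent.remove_child(child)
        parent.add_child(split)
        child.edge.length = remaining
        split.add_child(child)
        leaf = split.new_child(edge_length=blen())
        leaf.taxon = taxa.get_taxon(strain_name(i + 1))

    labels = [strain_name(i + 1) for i in range(n_strains)]
    pdm = tree.phylogenetic_distance_matrix()
    values = np.zeros((n_strains, n_strains))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i < j:
                d = pdm.patristic_distance(
                    taxa.get_taxon(la), taxa.get_taxon(lb)
                )
                values[i, j] = values[j, i] = d
    return tree, DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET_ARR[rng.integers(0, 20, size=length)].tobytes().decode()


def evolve_family(
    ancestral_sequence: str,
    tree: dendropy.Tree,
    divergence: float,
    seed: int,
) -> dict[str, str]:
    """Evolve one ancestral sequence to every leaf of the tree.

    Along each branch of length ``b`` every site substitutes independently
    with probability ``1 - exp(-b * divergence)``; the replacement residue
    is drawn uniformly from the other 19 amino acids.  Children inherit
    independently.  Returns ``{leaf_label: sequence}``.
    """
    if not ancestral_sequence:
        raise ValueError("ancestral sequence must be nonempty")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed)
    anc = np.frombuffer(ancestral_sequence.encode(), dtype=np.uint8).copy()
    idx = {code: i for i, code in enumerate(_ALPHABET_ARR)}
    try:
        anc_idx = np.array([idx[c] for c in anc], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"ancestral sequence contains non-standard residue {chr(exc.args[0])!r}"
        ) from exc

    leaves: dict[str, str] = {}

    def descend(node, seq_idx: np.ndarray) -> None:
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            p_sub = 1.0 - np.exp(-b * divergence)
            mask = rng.random(seq_idx.size) < p_sub
            child_idx = seq_idx.copy()
            n_sub = int(mask.sum())
            if n_sub:
                offsets = rng.integers(1, 20, size=n_sub)
                child_idx[mask] = (child_idx[mask] + offsets) % 20
            if child.is_leaf():
                leaves[child.taxon.label] = (
                    _ALPHABET_ARR[child_idx].tobytes().decode()
                )
            else:
                descend(child, child_idx)
        if node.is_leaf() and node.parent_node is None:  # degenerate single-node tree
            leaves[node.taxon.label] = _ALPHABET_ARR[seq_idx].tobytes().decode()

    descend(tree.seed_node, anc_idx)
    return leaves


def expected_leaf_pair_pdistance(
    branch_lengths: Sequence[float], divergence: float
) -> float:
    """Closed-form expected p-distance between two leaves.

    The path between the leaves is the given sequence of branch lengths,
    each applying one substitution round with probability
    ``q = 1 - exp(-b * divergence)`` and uniform replacement over the other
    19 residues.  Per branch the 20-state chain has eigenvalue
    ``1 - 20 q / 19`` on the non-uniform subspace, so

        P(same) = 1/20 + (19/20) * prod_k (1 - 20 q_k / 19).
    """
    prod = 1.0
    for b in branch_lengths:
        q = 1.0 - np.exp(-b * divergence)
        prod *= 1.0 - 20.0 * q / 19.0
    return float(1.0 - (1.0 / 20.0 + (19.0 / 20.0) * prod))


# ---------------------------------------------------------------------------
# Pangenome generation
# ---------------------------------------------------------------------------

def _family_length(rng: np.random.Generator, spec: PlantedPangenomeSpec) -> int:
    jitter = int(rng.integers(-spec.protein_length_jitter, spec.protein_length_jitter + 1))
    return spec.protein_length_mean + jitter


def generate_pangenome(spec: PlantedPangenomeSpec) -> Pangenome:
    """Generate strain proteomes with the planted pangenome structure.

    Core and dispensable families evolve an ancestral random sequence along
    the planted tree (dispensable families keep only their subset's
    leaves); unique genes are unrelated random sequences.  Byte-identical
    for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    tree, _ = generate_planted_tree(max(spec.n_strains, 3), seed=spec.seed)

    subsets = spec.dispensable_strain_subsets
    if subsets is None and spec.n_dispensable:
        strains = spec.strains
        if spec.n_strains < 3:
            raise ValueError(
                "dispensable families require n_strains >= 3 (proper subset "
                "of size >= 2)"
            )
        drawn = []
        for _ in range(spec.n_dispensable):
            size = int(rng.integers(2, spec.n_strains))
            members = rng.choice(spec.n_strains, size=size, replace=False)
            drawn.append(frozenset(strains[i] for i in members))
        subsets = tuple(drawn)
    elif subsets is None:
        subsets = ()

    proteomes: dict[str, list[GeneRecord]] = {s: [] for s in spec.strains}
    families: dict[str, FamilyTruth] = {}

    def plant_family(family_id: str, class_label: str, member_strains: Iterable[str]) -> None:
        length = _family_length(rng, spec)
        ancestor = _random_sequence(rng, length)
        fam_seed = int(rng.integers(0, 2**31 - 1))
        leaf_seqs = evolve_family(ancestor, tree, spec.divergence, seed=fam_seed)
        members: dict[str, str] = {}
        for strain in member_strains:
            gene_id = f"{strain}|{family_id}"
            proteomes[strain].append(
                GeneRecord(id=gene_id, source=strain, sequence=leaf_seqs[strain])
            )
            members[gene_id] = strain
        families[family_id] = FamilyTruth(family_id, class_label, members)

    width = max(4, len(str(spec.n_core + spec.n_dispensable)))
    for i in range(spec.n_core):
        plant_family(f"core_{i + 1:0{width}d}", CORE, spec.strains)
    for i, subset in enumerate(subsets):
        plant_family(
            f"disp_{i + 1:0{width}d}", DISPENSABLE, sorted(subset)
        )
    for strain in spec.strains:
        for i in range(spec.n_unique_per_strain):
            family_id = f"uniq_{strain}_{i + 1:03d}"
            length = _family_length(rng, spec)
            gene_id = f"{strain}|{family_id}"
            rec = GeneRecord(
                id=gene_id, source=strain, sequence=_random_sequence(rng, length)
            )
            proteomes[strain].append(rec)
            families[family_id] = FamilyTruth(
                family_id, STRAIN_SPECIFIC, {gene_id: strain}
            )

    truth = PlantedTruth(families=families, tree=tree)
    return Pangenome(spec=spec, proteomes=proteomes, truth=truth)


# ---------------------------------------------------------------------------
# Metagenome samples
# ---------------------------------------------------------------------------

def generate_metagenome_sample(
    pangenome: Pangenome,
    mixture: Sequence[str],
    noise_count: int,
    inclusion_fraction: float,
    seed: int,
    sample_name: str = "sample_1",
) -> tuple[list[GeneRecord], SampleTruth]:
    """Build a metagenome sample as a mixture of strain gene subsets + noise.

    For each strain in ``mixture`` exactly ``floor(inclusion_fraction * n)``
    of its genes are included (selected by a seeded shuffle of the
    id-sorted gene list) and relabeled ``<sample>|<original id>``.
    ``noise_count`` unrelated random proteins are appended.  The sample is
    registered in the pangenome truth.
    """
    if not 0.0 <= inclusion_fraction <= 1.0:
        raise ValueError("inclusion_fraction must be within [0, 1]")
    if noise_count < 0:
        raise ValueError("noise_count must be >= 0")
    for strain in mixture:
        if strain not in pangenome.proteomes:
            raise ValueError(f"unknown strain {strain!r} in mixture")

    rng = np.random.default_rng(seed)
    records: list[GeneRecord] = []
    origins: dict[str, str | None] = {}
    for strain in mixture:
        genes = sorted(pangenome.proteomes[strain], key=lambda r: r.id)
        n_take = int(np.floor(inclusion_fraction * len(genes)))
        order = rng.permutation(len(genes))
        for k in order[:n_take]:
            src = genes[int(k)]
            new_id = f"{sample_name}|{src.id}"
            records.append(
                GeneRecord(id=new_id, source=sample_name, sequence=src.sequence)
            )
            origins[new_id] = src.id
    spec = pangenome.spec
    for i in range(noise_count):
        length = _family_length(rng, spec)
        new_id = f"{sample_name}|noise_{i + 1:04d}"
        records.append(
            GeneRecord(
                id=new_id, source=sample_name, sequence=_random_sequence(rng, length)
            )
        )
        origins[new_id] = None

    truth = SampleTruth(
        sample=sample_name,
        mixture={s: inclusion_fraction for s in mixture},
        noise_count=noise_count,
        origins=origins,
    )
    pangenome.truth.samples[sample_name] = truth
    return records, truth
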