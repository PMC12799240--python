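"""Synthetic genomes, gene families and gated sequences with known truth.

Every downstream stage of the pipeline (profile search, neighborhood
classification, coevolution statistics, gate detection, end-to-end
ranking) is tested against cohorts produced here.  The generator emulates
the evolutionary regime the discovery procedure targets:

* protein families evolved along birth-death trees under a uniform
  (Jukes-Cantor-style, 20-letter) replacement model, optionally with
  joint horizontal co-transfer events that move a nuclease/protease leaf
  pair to a new lineage together;
* genomes assembled from a shuffled-sequence background pool (composition
  preserved, positional signal destroyed) with implanted defense loci in
  each known architecture -- nuclease upstream of a trypsin-protease
  fusion gene (Hachiman / AVAST / Lamassu / DRT) or a caspase gene
  upstream of the nuclease (canu) -- plus decoy loci carrying an ungated
  nuclease with no defense context;
* gated pro-nuclease sequences built by implanting insertions into an
  ungated reference nuclease, each insertion carrying a conserved
  cleavage residue (Ile for trypsin-partner systems, Gly for canu).

Coordinates are 1-based closed residue intervals throughout.  A single
master seed drives everything; child streams are derived by stable
hashing of (component, index), so equal seeds give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .errors import ConfigError, InputError
from .io_formats import (
    STANDARD_AA,
    GeneFeature,
    GenomeAnnotation,
    ProteinRecord,
    newick_string,
    write_fasta,
    write_gff3,
    write_newick,
)
from .profile_search import AA_INDEX

_N_AA = 20
_AA_ARR = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)

#: disorder-promoting residues; gating insertions are disordered loops, so
#: their content is drawn from this pool (minus the cleavage residue)
DISORDER_RESIDUES = "AEGKPQRS"


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Derive a reproducible child stream from (seed, component tags)."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tags
    ]
    return np.random.default_rng(entropy)


def _decode(idx: np.ndarray) -> str:
    out = np.where(idx >= 0, _AA_ARR[np.clip(idx, 0, _N_AA - 1)], ord("-"))
    return out.astype(np.uint8).tobytes().decode()


def _encode_strict(seq: str, what: str = "sequence") -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise InputError(f"non-standard residue {exc.args[0]!r} in {what}") from exc


def random_protein(rng: np.random.Generator, length: int) -> str:
    return _decode(rng.integers(0, _N_AA, size=length))


def mutate_sequence(seq: str, sub_rate: float, rng: np.random.Generator) -> str:
    """Apply the uniform replacement model at branch length ``sub_rate``."""
    idx = _encode_strict(seq)
    p = (19.0 / 20.0) * (1.0 - math.exp(-sub_rate * 20.0 / 19.0))
    mask = rng.random(idx.size) < p
    shifts = rng.integers(1, _N_AA, size=int(mask.sum()))
    idx[mask] = (idx[mask] + shifts) % _N_AA
    return _decode(idx)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Fisher-Yates shuffle: same composition, no positional signal."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Evolution along trees


@dataclass
class EvolutionConfig:
    """Regime of a simulated gene family.

    ``sub_rate`` is the expected substitutions/site from root to tip;
    ``transfer_rate`` the expected number of (co-)transfer events per tree
    (``n_transfers`` forces an exact count); ``indel_rate`` a per-site
    deletion-to-gap rate per unit branch length.
    """

    n_taxa: int = 16
    sub_rate: float = 0.15
    transfer_rate: float = 0.0
    indel_rate: float = 0.0
    tree_newick: Optional[str] = None
    n_transfers: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ConfigError("n_taxa must be >= 3")
        if min(self.sub_rate, self.transfer_rate, self.indel_rate) < 0:
            raise ConfigError("rates must be >= 0")


def sample_species_tree(config: EvolutionConfig) -> dendropy.Tree:
    """Species tree: fixed Newick, or a pure-birth tree scaled so the
    root-to-tip depth equals ``sub_rate`` substitutions/site."""
    if config.tree_newick is not None:
        tree = dendropy.Tree.get(
            data=config.tree_newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    else:
        crng = child_rng(config.seed, "tree")
        rng = random.Random(int(crng.integers(0, 2**31)))
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0,
            num_extant_tips=config.n_taxa, rng=rng,
        )
        # leaf names are assigned in randomized order: traversal order is
        # correlated with tree structure, which would couple the labels of
        # independently simulated trees
        perm = crng.permutation(config.n_taxa)
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"t{perm[i] + 1:02d}"
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if depth > 0 and config.tree_newick is None:
        scale = config.sub_rate / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def apply_transfers(
    tree: dendropy.Tree,
    n_events: int,
    rng: np.random.Generator,
    leaf_labels: Optional[dict[str, str]] = None,
    cross_label: bool = False,
) -> list[tuple[str, str]]:
    """Apply ``n_events`` leaf SPR moves in place (leaf a regrafted onto
    leaf b's branch).  With ``cross_label`` the pair must carry different
    labels, emulating transfer between defense systems.  Returns the
    (moved, target) leaf pairs."""
    events: list[tuple[str, str]] = []
    for _ in range(n_events):
        leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        for _attempt in range(100):
            a, b = rng.choice(len(leaves), size=2, replace=False)
            la, lb = leaves[int(a)], leaves[int(b)]
            if lb.parent_node is la.parent_node:
                continue
            if cross_label and leaf_labels is not None:
                if leaf_labels[la.taxon.label] == leaf_labels[lb.taxon.label]:
                    continue
            break
        else:
            break
        pa = la.parent_node
        pa.remove_child(la)
        if len(pa.child_nodes()) == 1:
            only = pa.child_nodes()[0]
            gp = pa.parent_node
            pa.remove_child(only)
            if gp is None:
                only.edge.length = None
                tree.seed_node = only
                only.parent_node = None
            else:
                only.edge.length = (only.edge.length or 0.0) + (pa.edge.length or 0.0)
                gp.remove_child(pa)
                gp.add_child(only)
        pb = lb.parent_node
        el = lb.edge.length or 0.0
        pb.remove_child(lb)
        mid = dendropy.Node()
        mid.edge.length = el / 2.0
        lb.edge.length = el / 2.0
        la.edge.length = el / 2.0
        mid.add_child(lb)
        mid.add_child(la)
        pb.add_child(mid)
        events.append((la.taxon.label, lb.taxon.label))
    return events


def evolve_along_tree(
    tree: dendropy.Tree,
    root_seq: str,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> list[ProteinRecord]:
    """Evolve ``root_seq`` down the tree; one record per leaf, aligned.

    Substitutions follow the 20-letter uniform replacement model; with
    ``indel_rate`` > 0, sites are deleted to gap at that rate per unit
    branch length (gaps are inherited), yielding a gapped alignment.
    """
    root_idx = _encode_strict(root_seq, "root_seq")
    L = root_idx.size
    if L == 0:
        raise InputError("root_seq must be non-empty")
    seqs: dict[int, np.ndarray] = {}
    records: list[ProteinRecord] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            cur = root_idx.copy()
        else:
            parent = seqs[id(nd.parent_node)]
            b = nd.edge.length or 0.0
            cur = parent.copy()
            alive = cur >= 0
            p_sub = (19.0 / 20.0) * (1.0 - math.exp(-b * 20.0 / 19.0))
            mask = alive & (rng.random(L) < p_sub)
            shifts = rng.integers(1, _N_AA, size=int(mask.sum()))
            cur[mask] = (cur[mask] + shifts) % _N_AA
            if indel_rate > 0:
                p_del = 1.0 - math.exp(-indel_rate * b)
                cur[alive & (rng.random(L) < p_del)] = -1
        seqs[id(nd)] = cur
        if nd.is_leaf():
            records.append(ProteinRecord(id=nd.taxon.label, sequence=_decode(cur)))
    records.sort(key=lambda r: r.id)
    return records


def simulate_gene_family(
    config: EvolutionConfig, root_seq: str
) -> tuple[list[ProteinRecord], dendropy.Tree]:
    """Simulate one family: (leaf alignment, true -- possibly
    transfer-modified -- genealogy).

    With ``transfer_rate`` = 0 (and no forced transfers) the true tree is
    the species tree ``sample_species_tree(config)``.
    """
    _encode_strict(root_seq, "root_seq")
    tree = sample_species_tree(config)
    rng_t = child_rng(config.seed, "transfers")
    k = (
        config.n_transfers
        if config.n_transfers is not None
        else int(rng_t.poisson(config.transfer_rate))
    )
    if k:
        apply_transfers(tree, k, rng_t)
    records = evolve_along_tree(
        tree, root_seq, child_rng(config.seed, "seq"), indel_rate=config.indel_rate
    )
    return records, tree


def simulate_linked_families(
    config: EvolutionConfig, roots: dict[str, str]
) -> tuple[dict[str, list[ProteinRecord]], dendropy.Tree]:
    """Co-simulate several families on one shared genealogy (joint
    transfers): the co-transfer regime of a nuclease-protease pair.  Leaf
    placements are identical across families by construction."""
    tree = sample_species_tree(config)
    rng_t = child_rng(config.seed, "transfers")
    k = (
        config.n_transfers
        if config.n_transfers is not None
        else int(rng_t.poisson(config.transfer_rate))
    )
    if k:
        apply_transfers(tree, k, rng_t)
    out: dict[str, list[ProteinRecord]] = {}
    for name in sorted(roots):
        out[name] = evolve_along_tree(
            tree, roots[name], child_rng(config.seed, "seq", name),
            indel_rate=config.indel_rate,
        )
    return out, tree


# ---------------------------------------------------------------------------
# Gated sequences


@dataclass
class InsertionSpec:
    """One gating insertion, positioned in ungated-reference coordinates.

    ``position`` is the 1-based reference residue the insertion is placed
    before; ``cleavage_offset`` the 1-based index of the cleavage residue
    inside the insertion.
    """

    position: int
    length: int
    cleavage_residue: str = "I"
    cleavage_offset: Optional[int] = None
    insert_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InputError("insertion length must be >= 1")
        if self.cleavage_offset is None:
            self.cleavage_offset = (self.length + 1) // 2
        if not (1 <= self.cleavage_offset <= self.length):
            raise InputError("cleavage_offset must lie inside the insertion")
        if self.cleavage_residue not in AA_INDEX:
            raise InputError(f"bad cleavage residue {self.cleavage_residue!r}")


def make_gated_sequence(
    reference: str,
    insertion_specs: Sequence[InsertionSpec],
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, list[tuple[int, int]], list[int]]:
    """Implant gating insertions into an ungated reference sequence.

    Returns (gated sequence, insertion intervals, cut-site positions),
    intervals and positions 1-based in the coordinates of the NEW
    sequence.  Removing the intervals restores the reference exactly.
    """
    positions = [s.position for s in insertion_specs]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise InputError("insertion positions must be strictly increasing (no overlap)")
    if positions and (positions[0] < 1 or positions[-1] > len(reference)):
        raise InputError("insertion positions must lie within the reference")
    pieces: list[str] = []
    intervals: list[tuple[int, int]] = []
    cut_sites: list[int] = []
    prev = 0
    offset = 0
    for spec in insertion_specs:
        pieces.append(reference[prev: spec.position - 1])
        if spec.insert_seq is not None:
            ins = spec.insert_seq
            if len(ins) != spec.length:
                raise InputError("insert_seq length disagrees with spec length")
        else:
            if rng is None:
                raise InputError("an RNG is required to draw insertion content")
            pool = [a for a in DISORDER_RESIDUES if a != spec.cleavage_residue]
            ins_list = [pool[int(k)] for k in rng.integers(0, len(pool), size=spec.length)]
            ins_list[spec.cleavage_offset - 1] = spec.cleavage_residue
            ins = "".join(ins_list)
        if ins[spec.cleavage_offset - 1] != spec.cleavage_residue:
            raise InputError("insert_seq lacks the cleavage residue at its offset")
        start = spec.position + offset
        end = start + spec.length - 1
        intervals.append((start, end))
        cut_sites.append(start + spec.cleavage_offset - 1)
        pieces.append(ins)
        prev = spec.position - 1
        offset += spec.length
    pieces.append(reference[prev:])
    return "".join(pieces), intervals, cut_sites


# ---------------------------------------------------------------------------
# Cohorts


#: length (residues) of each synthetic family's root sequence
FAMILY_LENGTHS: dict[str, int] = {
    "nuclease": 300,
    "trypsin": 180,
    "caspase": 220,
    "HamA": 220,
    "HamB": 250,
    "STAND": 260,
    "LmuA": 200,
    "LmuB": 240,
    "RT": 230,
    "transposase": 200,
    "CanB": 150,
}

#: families with seed alignments / search profiles (CanB stays unannotated,
#: matching the "gene of unknown function" in caspase-nuclease loci)
PROFILED_FAMILIES: tuple[str, ...] = (
    "nuclease", "trypsin", "caspase", "HamA", "HamB",
    "STAND", "LmuA", "LmuB", "RT", "transposase",
)

#: catalytic-motif columns of the ungated reference nuclease (1-based)
NUCLEASE_ACTIVE_SITE: tuple[int, ...] = (95, 98, 205)
_NUCLEASE_ACTIVE_RESIDUES = "DHK"

#: HamA nuclease catalytic motif implanted in the standalone root; knocked
#: out in protease-fusion copies (pattern D-GEXK, '-'/'X' = any residue)
HAMA_MOTIF_PATTERN = "D-GEXK"
HAMA_MOTIF_START = 120  # 1-based position of the motif in the HamA root
_HAMA_MOTIF_SEQ = "DAGELK"
_HAMA_MOTIF_KNOCKOUT = "NSAQLT"

SYSTEM_LABELS = ("Hachiman", "AVAST", "Lamassu", "DRT", "canu")
TRYPSIN_SYSTEMS = ("Hachiman", "AVAST", "Lamassu", "DRT")
_PARTNER = {"Hachiman": "HamA", "AVAST": "STAND", "Lamassu": "LmuA", "DRT": "RT"}
_MARKER = {"Hachiman": "HamB", "Lamassu": "LmuB"}


def default_insertions(cleavage_residue: str) -> list[InsertionSpec]:
    """The canonical two-insertion gate geometry: one insertion flanking
    each active-site cluster, each carrying a central cleavage residue."""
    return [
        InsertionSpec(position=100, length=20, cleavage_residue=cleavage_residue,
                      cleavage_offset=10),
        InsertionSpec(position=200, length=22, cleavage_residue=cleavage_residue,
                      cleavage_offset=11),
    ]


@dataclass
class ImplantSpec:
    """One locus to implant: a system architecture plus gate geometry."""

    system_label: str
    gene_order: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    insertion_specs: list[InsertionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_order:
            self.gene_order = default_gene_order(self.system_label)
        if not self.insertion_specs and self.system_label in SYSTEM_LABELS:
            residue = "G" if self.system_label == "canu" else "I"
            self.insertion_specs = default_insertions(residue)
        fams = [g[0] for g in self.gene_order]
        if self.system_label in TRYPSIN_SYSTEMS:
            if any(s.cleavage_residue != "I" for s in self.insertion_specs):
                raise ConfigError("trypsin-partner systems use Ile cleavage residues")
            fusion = next((i for i, g in enumerate(self.gene_order) if g[2]), None)
            nuc = fams.index("nuclease") if "nuclease" in fams else None
            if fusion is not None and nuc is not None and nuc > fusion:
                raise ConfigError("nuclease must sit upstream of the protease fusion")
        elif self.system_label == "canu":
            if any(s.cleavage_residue != "G" for s in self.insertion_specs):
                raise ConfigError("canu systems use Gly cleavage residues")
            if "caspase" in fams and "nuclease" in fams:
                if fams.index("caspase") > fams.index("nuclease"):
                    raise ConfigError("canu places the caspase upstream of the nuclease")


def default_gene_order(system_label: str) -> list[tuple[str, str, tuple[str, ...]]]:
    if system_label in TRYPSIN_SYSTEMS:
        partner = _PARTNER[system_label]
        order = [
            ("nuclease", "+", ()),
            (f"trypsin-{partner}", "+", ("trypsin", partner)),
        ]
        if system_label in _MARKER:
            order.append((_MARKER[system_label], "+", ()))
        return order
    if system_label == "canu":
        return [("caspase", "+", ()), ("CanB", "+", ()), ("nuclease", "+", ())]
    if system_label == "decoy":
        return [("nuclease", "+", ())]
    raise ConfigError(f"unknown system label {system_label!r}")


def default_implants() -> list[ImplantSpec]:
    """Ten implants: two per architecture across the five system classes."""
    return [ImplantSpec(system_label=s) for s in SYSTEM_LABELS for _ in range(2)]


@dataclass
class CohortConfig:
    """Study conditions of the default synthetic cohort."""

    genes_per_genome: int = 20
    locus_sub_rate: float = 0.2       # root-to-tip divergence of implanted loci
    seed_aln_taxa: int = 8            # members per family seed alignment
    seed_aln_sub_rate: float = 0.1
    decoy_sub_rate: float = 0.15
    insertion_divergence: float = 0.1  # divergence of insertion content
    cleavage_conservation: float = 1.0  # prob. the cleavage residue is retained
    transfer_rate: float = 1.0        # expected co-transfer events on the joint tree
    intergenic_min: int = 50
    intergenic_max: int = 200


def family_roots(seed: int) -> dict[str, str]:
    """Root sequence per family; nuclease catalytic residues and the HamA
    motif are pinned so motif/active-site logic has ground truth."""
    roots: dict[str, str] = {}
    for fam in sorted(FAMILY_LENGTHS):
        roots[fam] = random_protein(child_rng(seed, "root", fam), FAMILY_LENGTHS[fam])
    nuc = list(roots["nuclease"])
    for pos, res in zip(NUCLEASE_ACTIVE_SITE, _NUCLEASE_ACTIVE_RESIDUES):
        nuc[pos - 1] = res
    roots["nuclease"] = "".join(nuc)
    ham = list(roots["HamA"])
    ham[HAMA_MOTIF_START - 1: HAMA_MOTIF_START - 1 + len(_HAMA_MOTIF_SEQ)] = _HAMA_MOTIF_SEQ
    roots["HamA"] = "".join(ham)
    return roots


@dataclass
class SyntheticCohort:
    genomes: list[GenomeAnnotation]
    proteomes: dict[str, dict[str, ProteinRecord]]
    truth: pd.DataFrame
    decoys: pd.DataFrame
    trees: dict[str, dendropy.Tree]
    families: dict[str, list[ProteinRecord]]
    reference_nuclease: ProteinRecord
    active_site_columns: tuple[int, ...]
    seed: int

    def proteome_of(self, genome_id: str) -> list[ProteinRecord]:
        return [self.proteomes[genome_id][k] for k in sorted(self.proteomes[genome_id])]

    def digest(self) -> str:
        h = hashlib.sha256()
        for g in self.genomes:
            h.update(g.genome_id.encode())
            for f in g.features():
                h.update(
                    f"{f.gene_id}|{f.contig}|{f.start}|{f.end}|{f.strand}|{f.protein_id}".encode()
                )
            for pid in sorted(self.proteomes[g.genome_id]):
                h.update(self.proteomes[g.genome_id][pid].sequence.encode())
        h.update(self.truth.to_csv(index=False).encode())
        h.update(self.decoys.to_csv(index=False).encode())
        for name in sorted(self.trees):
            h.update(newick_string(self.trees[name]).encode())
        h.update(self.reference_nuclease.sequence.encode())
        return h.hexdigest()


def _evolved_locus_members(
    implants: list[ImplantSpec], cohort_cfg: CohortConfig, seed: int
) -> tuple[dict[int, dict[str, str]], dict[str, dendropy.Tree], dict[int, str]]:
    """Per-implant evolved core sequences for the co-evolving pair members.

    Trypsin-type implants share one joint genealogy for (nuclease, trypsin);
    canu implants share another for (nuclease, caspase).  Returns
    (implant index -> family -> sequence, named trees, implant index ->
    joint-tree leaf label)."""
    roots = family_roots(seed)
    members: dict[int, dict[str, str]] = {i: {} for i in range(len(implants))}
    trees: dict[str, dendropy.Tree] = {}
    leaf_of: dict[int, str] = {}
    groups = {
        "trypsin_loci": [i for i, im in enumerate(implants) if im.system_label in TRYPSIN_SYSTEMS],
        "canu_loci": [i for i, im in enumerate(implants) if im.system_label == "canu"],
    }
    pair_family = {"trypsin_loci": "trypsin", "canu_loci": "caspase"}
    for gname, idxs in groups.items():
        fam = pair_family[gname]
        if len(idxs) >= 3:
            cfg = EvolutionConfig(
                n_taxa=len(idxs),
                sub_rate=cohort_cfg.locus_sub_rate,
                transfer_rate=cohort_cfg.transfer_rate,
                seed=int(child_rng(seed, "joint", gname).integers(0, 2**31)),
            )
            fams, tree = simulate_linked_families(
                cfg, {"nuclease": roots["nuclease"], fam: roots[fam]}
            )
            trees[gname] = tree
            leaves = sorted(r.id for r in fams["nuclease"])
            by_id_n = {r.id: r.sequence for r in fams["nuclease"]}
            by_id_p = {r.id: r.sequence for r in fams[fam]}
            for leaf, i in zip(leaves, idxs):
                members[i]["nuclease"] = by_id_n[leaf]
                members[i][fam] = by_id_p[leaf]
                leaf_of[i] = leaf
        else:
            for i in idxs:
                rng = child_rng(seed, "indep", gname, i)
                members[i]["nuclease"] = mutate_sequence(
                    roots["nuclease"], cohort_cfg.locus_sub_rate, rng
                )
                members[i][fam] = mutate_sequence(
                    roots[fam], cohort_cfg.locus_sub_rate, rng
                )
    return members, trees, leaf_of


def generate_cohort(
    n_genomes: int = 50,
    implants: Optional[list[ImplantSpec]] = None,
    n_decoys: int = 10,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a deterministic cohort of annotated genomes with implanted
    defense loci, decoy loci and a shuffled-sequence background."""
    cfg = config or CohortConfig()
    if implants is None:
        implants = default_implants()
    for im in implants:
        for fam, _, fused in im.gene_order:
            for f in (fam.split("-") if not fused else fused):
                if f not in FAMILY_LENGTHS and fam not in FAMILY_LENGTHS:
                    raise ConfigError(f"implant family {fam!r} has no seed family")
    if n_genomes < len(implants) + n_decoys:
        raise ConfigError("n_genomes must accommodate all implants and decoys")

    roots = family_roots(seed)
    reference = ProteinRecord(id="nuclease_reference", sequence=roots["nuclease"],
                              description="ungated reference nuclease")

    # seed alignments per profiled family
    families: dict[str, list[ProteinRecord]] = {}
    for fam in PROFILED_FAMILIES:
        fcfg = EvolutionConfig(
            n_taxa=cfg.seed_aln_taxa,
            sub_rate=cfg.seed_aln_sub_rate,
            seed=int(child_rng(seed, "seedaln", fam).integers(0, 2**31)),
        )
        recs, _ = simulate_gene_family(fcfg, roots[fam])
        families[fam] = [
            ProteinRecord(id=f"{fam}_{r.id}", sequence=_conserve_sites(fam, r.sequence))
            for r in recs
        ]

    members, trees, leaf_of = _evolved_locus_members(implants, cfg, seed)

    # shared insertion templates (conserved content; cleavage residue pinned)
    templates: dict[tuple[str, int], str] = {}
    for im in implants:
        for k, spec in enumerate(im.insertion_specs):
            key = (spec.cleavage_residue, k)
            if key not in templates:
                rng = child_rng(seed, "ins_template", *key)
                pool = [a for a in DISORDER_RESIDUES if a != spec.cleavage_residue]
                tmpl = [pool[int(x)] for x in rng.integers(0, len(pool), size=spec.length)]
                tmpl[spec.cleavage_offset - 1] = spec.cleavage_residue
                templates[key] = "".join(tmpl)

    layout_rng = child_rng(seed, "layout")
    order = layout_rng.permutation(n_genomes)
    implant_genomes = {int(order[i]): i for i in range(len(implants))}
    decoy_genomes = {int(order[len(implants) + j]): j for j in range(n_decoys)}

    seed_pool = [r for fam in PROFILED_FAMILIES for r in families[fam]]

    genomes: list[GenomeAnnotation] = []
    proteomes: dict[str, dict[str, ProteinRecord]] = {}
    truth_rows: list[dict] = []
    decoy_rows: list[dict] = []

    for gi in range(n_genomes):
        gid = f"g{gi + 1:03d}"
        contig = f"{gid}_c1"
        grng = child_rng(seed, "genome", gi)
        gene_seqs: list[tuple[str, str]] = []  # (sequence, strand)
        locus_entry: Optional[dict] = None
        for _ in range(cfg.genes_per_genome):
            src = seed_pool[int(grng.integers(0, len(seed_pool)))]
            strand = "+" if grng.random() < 0.5 else "-"
            gene_seqs.append((shuffle_sequence(src.sequence, grng), strand))
        insert_block: list[tuple[str, str, Optional[str]]] = []  # (seq, strand, role)
        if gi in implant_genomes:
            ii = implant_genomes[gi]
            im = implants[ii]
            block: list[tuple[str, str, Optional[str]]] = []
            for fam, strand, fused in im.gene_order:
                if fused:
                    parts = []
                    for f in fused:
                        if f in members[ii]:
                            parts.append(members[ii][f])
                        else:
                            part = mutate_sequence(
                                roots[f], cfg.locus_sub_rate,
                                child_rng(seed, "partner", ii, f),
                            )
                            if f == "HamA":
                                part = (
                                    part[: HAMA_MOTIF_START - 1]
                                    + _HAMA_MOTIF_KNOCKOUT
                                    + part[HAMA_MOTIF_START - 1 + len(_HAMA_MOTIF_KNOCKOUT):]
                                )
                            parts.append(part)
                    block.append(("".join(parts), strand, "fusion"))
                elif fam == "nuclease":
                    ins_specs = [
                        replace(
                            s,
                            insert_seq=_diverged_insertion(
                                templates[(s.cleavage_residue, k)], s, cfg,
                                child_rng(seed, "ins", ii, k),
                            ),
                        )
                        for k, s in enumerate(im.insertion_specs)
                    ]
                    gated, intervals, cuts = make_gated_sequence(
                        members[ii]["nuclease"], ins_specs
                    )
                    block.append((gated, strand, "anchor"))
                    locus_entry = {
                        "system_label": im.system_label,
                        "gate_intervals": ";".join(f"{a}-{b}" for a, b in intervals),
                        "cut_sites": ";".join(str(c) for c in cuts),
                    }
                elif fam in members[ii]:
                    block.append((members[ii][fam], strand, None))
                else:
                    part = mutate_sequence(
                        roots[fam], cfg.locus_sub_rate, child_rng(seed, "marker", ii, fam)
                    )
                    block.append((part, strand, None))
            # a transposase next to the locus: the defense-island signature
            block.append(
                (
                    mutate_sequence(
                        roots["transposase"], cfg.locus_sub_rate,
                        child_rng(seed, "island", ii),
                    ),
                    "+",
                    "island",
                )
            )
            insert_block = block
        elif gi in decoy_genomes:
            dj = decoy_genomes[gi]
            decoy_seq = mutate_sequence(
                roots["nuclease"], cfg.decoy_sub_rate, child_rng(seed, "decoy", dj)
            )
            insert_block = [(decoy_seq, "+", "decoy")]

        slot = int(grng.integers(0, cfg.genes_per_genome + 1))
        combined: list[tuple[str, str, Optional[str]]] = (
            [(s, st, None) for s, st in gene_seqs[:slot]]
            + insert_block
            + [(s, st, None) for s, st in gene_seqs[slot:]]
        )
        feats: list[GeneFeature] = []
        prots: dict[str, ProteinRecord] = {}
        pos = 1
        for k, (pseq, strand, role) in enumerate(combined):
            gene_id = f"{gid}_g{k + 1:03d}"
            pid = f"{gid}_p{k + 1:03d}"
            length_nt = 3 * len(pseq)
            feats.append(
                GeneFeature(
                    gene_id=gene_id, contig=contig, start=pos,
                    end=pos + length_nt - 1, strand=strand, protein_id=pid,
                )
            )
            prots[pid] = ProteinRecord(id=pid, sequence=pseq)
            pos += length_nt + int(
                grng.integers(cfg.intergenic_min, cfg.intergenic_max + 1)
            )
            if role == "anchor":
                assert locus_entry is not None
                truth_rows.append(
                    {
                        "genome": gid,
                        "contig": contig,
                        "gene_id": gene_id,
                        "protein_id": pid,
                        "joint_leaf": leaf_of.get(implant_genomes[gi], ""),
                        **locus_entry,
                    }
                )
            elif role == "decoy":
                decoy_rows.append(
                    {"genome": gid, "contig": contig, "gene_id": gene_id,
                     "protein_id": pid}
                )
        genomes.append(GenomeAnnotation(genome_id=gid, contigs={contig: feats}))
        proteomes[gid] = prots

    truth_cols = ["genome", "contig", "gene_id", "protein_id", "system_label",
                  "gate_intervals", "cut_sites", "joint_leaf"]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    truth = truth.sort_values("gene_id").reset_index(drop=True)
    decoys = pd.DataFrame(decoy_rows, columns=["genome", "contig", "gene_id", "protein_id"])
    decoys = decoys.sort_values("gene_id").reset_index(drop=True)
    return SyntheticCohort(
        genomes=genomes,
        proteomes=proteomes,
        truth=truth,
        decoys=decoys,
        trees=trees,
        families=families,
        reference_nuclease=reference,
        active_site_columns=NUCLEASE_ACTIVE_SITE,
        seed=seed,
    )


def _conserve_sites(family: str, seq: str) -> str:
    """Re-impose functionally constrained residues after neutral evolution:
    catalytic sites are under purifying selection in active family members."""
    chars = list(seq)
    if family == "nuclease":
        for pos, res in zip(NUCLEASE_ACTIVE_SITE, _NUCLEASE_ACTIVE_RESIDUES):
            chars[pos - 1] = res
    elif family == "HamA":
        chars[HAMA_MOTIF_START - 1: HAMA_MOTIF_START - 1 + len(_HAMA_MOTIF_SEQ)] = (
            _HAMA_MOTIF_SEQ
        )
    return "".join(chars)


def _diverged_insertion(
    template: str, spec: InsertionSpec, cfg: CohortConfig, rng: np.random.Generator
) -> str:
    ins = mutate_sequence(template, cfg.insertion_divergence, rng)
    chars = list(ins)
    if rng.random() < cfg.cleavage_conservation:
        chars[spec.cleavage_offset - 1] = spec.cleavage_residue
    else:
        pool = [a for a in STANDARD_AA if a != spec.cleavage_residue]
        chars[spec.cleavage_offset - 1] = pool[int(rng.integers(0, len(pool)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Writing


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort as plain-text FASTA/GFF3/Newick/TSV plus metadata."""
    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "families").mkdir(exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    for g in cohort.genomes:
        write_fasta(cohort.proteome_of(g.genome_id), out / "genomes" / f"{g.genome_id}.faa")
        write_gff3(g, out / "genomes" / f"{g.genome_id}.gff3")
    for fam in sorted(cohort.families):
        write_fasta(cohort.families[fam], out / "families" / f"{fam}.afa")
    write_fasta([cohort.reference_nuclease], out / "reference_nuclease.faa")
    for name in sorted(cohort.trees):
        write_newick(cohort.trees[name], out / "trees" / f"{name}.nwk")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cohort.decoys.to_csv(out / "decoys.tsv", sep="\t", index=False)
    meta = {
        "seed": cohort.seed,
        "active_site_columns": list(cohort.active_site_columns),
        "hamA_motif_pattern": HAMA_MOTIF_PATTERN,
        "n_genomes": len(cohort.genomes),
        "digest": cohort.digest(),
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
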