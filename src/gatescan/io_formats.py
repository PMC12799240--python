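"""Shared genomic/phylogenetic data model and FASTA / GFF3 / Newick I/O.

The pipeline's substrate is a set of annotated genomes: per-contig ordered,
stranded protein-coding gene models (:class:`GeneFeature` inside a
:class:`GenomeAnnotation`) linked to protein sequences
(:class:`ProteinRecord`).  Trees are handled as :class:`dendropy.Tree`
objects throughout; bootstrap-style supports are carried as internal-node
labels, the most widespread Newick convention.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinRecord:
    """One protein sequence; ``X`` is tolerated as an unknown residue."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A protein-coding gene model on a contig (1-based inclusive coords)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"feature {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class GenomeAnnotation:
    """Ordered, stranded gene models per contig for one genome."""

    genome_id: str
    contigs: dict[str, list[GeneFeature]] = field(default_factory=dict)
    taxon_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig, feats in self.contigs.items():
            feats.sort(key=lambda f: (f.start, f.end, f.gene_id))
            for f in feats:
                if f.gene_id in seen:
                    raise FormatError(
                        f"duplicate gene_id {f.gene_id!r} in genome {self.genome_id}"
                    )
                seen.add(f.gene_id)

    def features(self) -> Iterable[GeneFeature]:
        for contig in sorted(self.contigs):
            yield from self.contigs[contig]

    def n_genes(self) -> int:
        return sum(len(v) for v in self.contigs.values())

    def feature_by_gene_id(self, gene_id: str) -> GeneFeature:
        for f in self.features():
            if f.gene_id == gene_id:
                return f
        raise InputError(f"gene {gene_id!r} not found in genome {self.genome_id}")

    def feature_by_protein_id(self, protein_id: str) -> GeneFeature:
        for f in self.features():
            if f.protein_id == protein_id:
                return f
        raise InputError(
            f"protein {protein_id!r} not annotated in genome {self.genome_id}"
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file; duplicate ids raise :class:`FormatError`."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path,
    proteins: Optional[Mapping[str, ProteinRecord]] = None,
    genome_id: Optional[str] = None,
    taxon_label: str = "",
) -> GenomeAnnotation:
    """Read CDS features from a GFF3 file into a :class:`GenomeAnnotation`.

    Each CDS must carry an ``ID`` attribute; an optional ``protein_id``
    attribute links it to a protein record (defaults to the ID).  When a
    protein mapping is supplied, CDS whose protein cannot be resolved are
    skipped with a logged warning.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    contigs: dict[str, list[GeneFeature]] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        protein_id = feat.attributes.get("protein_id", [gene_id])[0]
        if proteins is not None and protein_id not in proteins:
            log.warning(
                "skipping CDS %s: protein %s not in supplied FASTA", gene_id, protein_id
            )
            continue
        contigs.setdefault(feat.seqid, []).append(
            GeneFeature(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                protein_id=protein_id,
            )
        )
    gid = genome_id if genome_id is not None else Path(path).stem
    return GenomeAnnotation(genome_id=gid, contigs=contigs, taxon_label=taxon_label)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for feat in annotation.features():
            attrs = f"ID={feat.gene_id};protein_id={feat.protein_id}"
            fh.write(
                f"{feat.contig}\tgatescan\tCDS\t{feat.start}\t{feat.end}\t."
                f"\t{feat.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(source: str | Path, *, from_string: bool = False) -> dendropy.Tree:
    """Parse a Newick tree; internal-node labels are kept as supports.

    Missing supports remain ``None`` (absent, not 0).
    """
    try:
        if from_string:
            tree = dendropy.Tree.get(
                data=str(source), schema="newick",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
        else:
            tree = dendropy.Tree.get(
                path=str(source), schema="newick",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
    except Exception as exc:  # dendropy raises several parse-error classes
        raise FormatError(f"invalid Newick input: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path), schema="newick",
        suppress_rooting=True, unquoted_underscores=True,
    )


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_support(node: dendropy.Node) -> Optional[float]:
    """Support value of the branch subtending ``node`` (None when absent)."""
    if node.label is None or node.label == "":
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract every internal branch with support below ``threshold``.

    Mirrors the common display/analysis filter of deleting branches with
    support < 60 before interpretation.  The input tree is not modified.
    Contraction treats the unsupported branch as length 0 (children keep
    their own branch lengths), the usual polytomy-merge convention.
    Branches without a support value are kept.  Idempotent.
    """
    if not (0 <= threshold <= 100):
        raise InputError(f"support threshold must be in [0, 100], got {threshold}")
    out = tree.clone(depth=1)
    targets = [
        nd
        for nd in out.postorder_node_iter()
        if (not nd.is_leaf())
        and nd.parent_node is not None
        and node_support(nd) is not None
        and node_support(nd) < threshold
    ]
    for nd in targets:
        parent = nd.parent_node
        for child in list(nd.child_nodes()):
            nd.remove_child(child)
            parent.add_child(child)
        parent.remove_child(nd)
    return out
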