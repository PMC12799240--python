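"""Genomic-context mining: neighborhoods, fusions, motifs and locus calls.

A candidate nuclease gene is classified by the annotated families of its
chromosomal neighbors.  The defense-system grammar implemented here:

* trypsin-like protease fused to the N-terminus of a partner enzyme,
  with the nuclease as a separate (typically upstream) gene ->
  Hachiman (HamA/HamB context), AVAST (STAND ATPase), Lamassu
  (LmuA/LmuB), DRT (reverse transcriptase);
* a standalone caspase gene upstream of the nuclease -> canu;
* no rule fired -> unknown.

Additional defense/transposase markers within an extended window give a
defense-island score; co-orientation is not required (strand-agnostic
co-occurrence).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import InputError
from .io_formats import GeneFeature, GenomeAnnotation
from .profile_search import HitRecord

log = logging.getLogger(__name__)

SYSTEM_LABELS = ("Hachiman", "AVAST", "Lamassu", "DRT", "canu")
UNKNOWN = "unknown"

PROTEASE_FAMILIES = frozenset({"trypsin", "caspase"})

#: partner/marker families that vote for each system
SYSTEM_PARTNERS: dict[str, frozenset[str]] = {
    "Hachiman": frozenset({"HamA", "HamB"}),
    "AVAST": frozenset({"STAND"}),
    "Lamassu": frozenset({"LmuA", "LmuB"}),
    "DRT": frozenset({"RT"}),
}

#: marker families counted by the defense-island score
ISLAND_MARKER_FAMILIES = frozenset(
    {"transposase", "HamA", "HamB", "STAND", "LmuA", "LmuB", "RT",
     "trypsin", "caspase", "nuclease"}
)


@dataclass
class Neighborhood:
    anchor: GeneFeature
    members: list[GeneFeature]
    window_genes: int
    window_kb: float
    hits: dict[str, list[HitRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if all(m.gene_id != self.anchor.gene_id for m in self.members):
            raise InputError("anchor must be a member of its own neighborhood")
        self.members.sort(key=lambda f: (f.start, f.end))

    def hits_for(self, feature: GeneFeature) -> list[HitRecord]:
        return self.hits.get(feature.protein_id, [])


@dataclass
class FusionCall:
    protein_id: str
    n_terminal_family: str
    c_terminal_family: str
    boundary: int  # residue index separating the two hit spans
    motif_checks: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.boundary < 1:
            raise InputError("fusion boundary must be >= 1")


@dataclass
class LocusCall:
    genome_id: str
    anchor: GeneFeature
    system_label: str
    evidence_families: list[str]
    evidence_genes: list[str]
    fusion_calls: list[FusionCall]
    nuclease_upstream: Optional[bool]
    island_score: int = 0
    evidence_bit_score: float = 0.0
    competing_labels: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def extract_neighborhood(
    annotation: GenomeAnnotation,
    anchor_hit: HitRecord | str,
    window_genes: int = 10,
    window_kb: float = 10.0,
    hits_by_protein: Optional[Mapping[str, list[HitRecord]]] = None,
) -> Neighborhood:
    """Genes within min(±window_genes, ±window_kb) of the anchor on its contig."""
    protein_id = anchor_hit.protein_id if isinstance(anchor_hit, HitRecord) else anchor_hit
    anchor = annotation.feature_by_protein_id(protein_id)
    contig_feats = annotation.contigs[anchor.contig]
    idx = next(i for i, f in enumerate(contig_feats) if f.gene_id == anchor.gene_id)
    lo = max(0, idx - window_genes)
    hi = min(len(contig_feats), idx + window_genes + 1)
    span = window_kb * 1000.0
    members = [
        f
        for f in contig_feats[lo:hi]
        if f.gene_id == anchor.gene_id
        or (f.start <= anchor.end + span and f.end >= anchor.start - span)
    ]
    hits = {}
    if hits_by_protein is not None:
        hits = {f.protein_id: list(hits_by_protein.get(f.protein_id, [])) for f in members}
    return Neighborhood(
        anchor=anchor, members=members, window_genes=window_genes,
        window_kb=window_kb, hits=hits,
    )


def _resolve_overlaps(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """Greedy by bit score: overlapping hits lose to the higher-scoring one."""
    kept: list[HitRecord] = []
    for h in sorted(hits, key=lambda h: (-h.bit_score, h.family_name)):
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def detect_fusion(
    protein_hits: Sequence[HitRecord],
    protein_length: Optional[int] = None,
    n_margin_fraction: float = 0.4,
    n_margin_max: int = 200,
) -> Optional[FusionCall]:
    """Call an N-terminal protease fused to a C-terminal partner domain.

    A fusion requires a protease-family hit starting within the N-terminal
    margin (min of 40% of the protein or 200 residues) and a
    non-overlapping partner-family hit entirely C-terminal to it.
    Overlapping hits are resolved by bit score first.
    """
    if not protein_hits:
        return None
    hits = _resolve_overlaps(protein_hits)
    if protein_length is None:
        protein_length = max(h.end for h in hits)
    margin = min(int(n_margin_fraction * protein_length), n_margin_max)
    proteases = [
        h for h in hits if h.family_name in PROTEASE_FAMILIES and h.start <= margin
    ]
    if not proteases:
        return None
    prot = max(proteases, key=lambda h: h.bit_score)
    partners = [
        h
        for h in hits
        if h.family_name not in PROTEASE_FAMILIES and h.start > prot.end
    ]
    if not partners:
        return None
    partner = max(partners, key=lambda h: h.bit_score)
    return FusionCall(
        protein_id=prot.protein_id,
        n_terminal_family=prot.family_name,
        c_terminal_family=partner.family_name,
        boundary=prot.end,
    )


_MOTIF_TOKEN = re.compile(r"[A-Z]|-")


def check_motif(
    sequence: str,
    motif_pattern: str,
    region: Optional[tuple[int, int]] = None,
) -> bool:
    """Degenerate motif presence within a 1-based closed region.

    Pattern letters match exactly; ``X`` and ``-`` match any residue
    (e.g. ``D-GEXK``).  ``region`` defaults to the whole sequence.
    """
    tokens = _MOTIF_TOKEN.findall(motif_pattern.upper())
    if not tokens or "".join(tokens) != motif_pattern.upper():
        raise InputError(f"malformed motif pattern {motif_pattern!r}")
    regex = "".join("." if t in ("X", "-") else re.escape(t) for t in tokens)
    if region is None:
        region = (1, len(sequence))
    lo, hi = region
    if lo < 1 or hi > len(sequence) or lo > hi:
        return False
    return re.search(regex, sequence[lo - 1: hi]) is not None


def _is_upstream(candidate: GeneFeature, of: GeneFeature) -> bool:
    """Strand-aware 'upstream of': relative to ``of``'s reading direction."""
    if of.strand == "+":
        return candidate.end < of.start
    return candidate.start > of.end


def classify_locus(
    neighborhood: Neighborhood,
    fusion_calls: Optional[Sequence[FusionCall]] = None,
) -> LocusCall:
    """Assign a defense-system label to an anchored neighborhood.

    Rules: trypsin fusion with a HamA/HamB context -> Hachiman; STAND
    partner -> AVAST; LmuA/LmuB context -> Lamassu; RT partner -> DRT;
    standalone caspase upstream of the nuclease -> canu; otherwise
    unknown.  Ties are broken by the highest total marker bit score, with
    competitors recorded.  The nuclease-upstream expectation is logged as
    a boolean, never required.
    """
    if fusion_calls is None:
        fusion_calls = []
        for m in neighborhood.members:
            fc = detect_fusion(neighborhood.hits_for(m))
            if fc is not None:
                fusion_calls.append(fc)
    anchor = neighborhood.anchor
    votes: dict[str, float] = {}
    evidence: dict[str, tuple[set[str], set[str]]] = {
        s: (set(), set()) for s in SYSTEM_LABELS
    }

    feature_of = {m.protein_id: m for m in neighborhood.members}
    bit_of: dict[tuple[str, str], float] = {}
    for m in neighborhood.members:
        for h in neighborhood.hits_for(m):
            key = (m.protein_id, h.family_name)
            bit_of[key] = max(bit_of.get(key, 0.0), h.bit_score)

    # trypsin-fusion rules
    for fc in fusion_calls:
        if fc.n_terminal_family != "trypsin":
            continue
        for system, partners in SYSTEM_PARTNERS.items():
            if fc.c_terminal_family in partners:
                score = bit_of.get((fc.protein_id, "trypsin"), 0.0) + bit_of.get(
                    (fc.protein_id, fc.c_terminal_family), 0.0
                )
                votes[system] = votes.get(system, 0.0) + score
                evidence[system][0].update({"trypsin", fc.c_terminal_family})
                evidence[system][1].add(feature_of[fc.protein_id].gene_id)

    # standalone marker context (e.g. HamB helicase, LmuB) reinforces/fires
    fused_pids = {fc.protein_id for fc in fusion_calls}
    for m in neighborhood.members:
        if m.gene_id == anchor.gene_id or m.protein_id in fused_pids:
            continue
        for h in neighborhood.hits_for(m):
            for system, partners in SYSTEM_PARTNERS.items():
                if h.family_name in partners:
                    votes[system] = votes.get(system, 0.0) + h.bit_score
                    evidence[system][0].add(h.family_name)
                    evidence[system][1].add(m.gene_id)

    # canu: standalone caspase upstream of the nuclease anchor
    for m in neighborhood.members:
        if m.gene_id == anchor.gene_id or m.protein_id in fused_pids:
            continue
        caspase_hits = [
            h for h in neighborhood.hits_for(m) if h.family_name == "caspase"
        ]
        if caspase_hits and _is_upstream(m, anchor):
            score = max(h.bit_score for h in caspase_hits)
            votes["canu"] = votes.get("canu", 0.0) + score
            evidence["canu"][0].add("caspase")
            evidence["canu"][1].add(m.gene_id)

    if not votes:
        label = UNKNOWN
        fams: list[str] = []
        genes: list[str] = []
        best_score = 0.0
        competing: list[str] = []
    else:
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        label, best_score = ranked[0]
        fams = sorted(evidence[label][0])
        genes = sorted(evidence[label][1])
        competing = [s for s, _ in ranked[1:]]
        if competing:
            log.info(
                "locus %s: label %s wins over %s by bit score",
                anchor.gene_id, label, competing,
            )

    nuclease_upstream: Optional[bool] = None
    if label in SYSTEM_PARTNERS:  # trypsin-partner systems
        fusion_feats = [
            feature_of[fc.protein_id]
            for fc in fusion_calls
            if fc.n_terminal_family == "trypsin" and fc.protein_id in feature_of
        ]
        if fusion_feats:
            nuclease_upstream = _is_upstream(anchor, fusion_feats[0])

    return LocusCall(
        genome_id="",
        anchor=anchor,
        system_label=label,
        evidence_families=fams,
        evidence_genes=genes,
        fusion_calls=list(fusion_calls),
        nuclease_upstream=nuclease_upstream,
        evidence_bit_score=best_score,
        competing_labels=competing,
    )


def island_score(
    annotation: GenomeAnnotation,
    locus: LocusCall,
    extended_window_kb: float = 20.0,
    hits_by_protein: Optional[Mapping[str, list[HitRecord]]] = None,
    marker_families: frozenset[str] = ISLAND_MARKER_FAMILIES,
) -> int:
    """Count distinct additional defense/transposase marker families within
    an extended window around the locus (locus genes excluded).

    Monotonically non-decreasing in the window size.
    """
    if hits_by_protein is None:
        return 0
    anchor = locus.anchor
    locus_genes = {anchor.gene_id} | set(locus.evidence_genes)
    span = extended_window_kb * 1000.0
    found: set[str] = set()
    for f in annotation.contigs.get(anchor.contig, []):
        if f.gene_id in locus_genes:
            continue
        if f.start > anchor.end + span or f.end < anchor.start - span:
            continue
        for h in hits_by_protein.get(f.protein_id, []):
            if h.family_name in marker_families:
                found.add(h.family_name)
    return len(found)
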