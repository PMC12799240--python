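"""End-to-end discovery: scan -> classify -> gate -> coevolution -> rank.

The discovery strategy ranks candidate protease-coupled effector loci by
combining the hallmarks of functional coupling: residence in a marker-rich
defense context, a gated-proenzyme signature in the nuclease, and
coevolution of the nuclease with its partner protease.  The combined rank
score -- the mean of min-max-normalized island score, gate score, marker
evidence count and (when computable) Mantel congruence -- is declared
plumbing: a deterministic, monotone way to order candidates, not a
published statistic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .coevolution import (
    CongruenceResult,
    TransferSignal,
    mantel_congruence,
    nj_tree,
    poisson_distance,
    transfer_signal,
)
from .errors import ConfigError
from .gate_detection import GateParams, call_gate
from .io_formats import GenomeAnnotation, ProteinRecord, read_fasta, read_gff3
from .neighborhood import (
    SYSTEM_PARTNERS,
    UNKNOWN,
    classify_locus,
    extract_neighborhood,
    island_score,
)
from .profile_search import (
    PositionProfile,
    build_profile,
    calibrate_evalue,
    scan_proteome,
)
from .synthetic_data import NUCLEASE_ACTIVE_SITE, SyntheticCohort, child_rng

log = logging.getLogger(__name__)

TRYPSIN_SYSTEMS = tuple(SYSTEM_PARTNERS)


@dataclass
class DiscoveryParams:
    """All tunable knobs of the discovery pipeline."""

    window_genes: int = 10
    window_kb: float = 10.0
    island_window_kb: float = 20.0
    evalue_max: float = 1e-3
    n_shuffles: int = 200
    min_pairs_for_congruence: int = 4
    n_permutations: int = 999
    gate: GateParams = field(default_factory=GateParams)


@dataclass
class DiscoveryConfig:
    """File-based configuration for CLI runs (paths must exist)."""

    genomes_dir: str
    families_dir: str
    reference_fasta: str
    out_dir: str
    active_site_columns: tuple[int, ...] = NUCLEASE_ACTIVE_SITE
    anchor_family: str = "nuclease"
    seed: int = 0
    params: DiscoveryParams = field(default_factory=DiscoveryParams)


@dataclass
class CandidateReport:
    table: pd.DataFrame
    congruence: dict[str, CongruenceResult]
    transfer: dict[str, TransferSignal]
    metadata: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def body_bytes(self) -> bytes:
        return self.table.to_csv(index=False, float_format="%.6g").encode()


def build_profiles(
    families: dict[str, list[ProteinRecord]],
    params: DiscoveryParams,
    seed: int,
) -> list[PositionProfile]:
    """Profiles from seed alignments, each calibrated against a shuffled null."""
    profiles = []
    for fam in sorted(families):
        prof = build_profile(families[fam], family_name=fam)
        calibrate_evalue(
            prof, n_shuffles=params.n_shuffles,
            seed=int(child_rng(seed, "calibrate", fam).integers(0, 2**31)),
        )
        profiles.append(prof)
    return profiles


def _rank_scores(components: pd.DataFrame) -> pd.Series:
    """Mean of min-max-normalized evidence components (NaN-aware).

    A constant column normalizes to 0, so it cannot reorder candidates;
    the mean is over the components available for each row, which keeps
    the score monotone in every component.
    """
    normed = {}
    for col in components.columns:
        v = components[col].astype(float)
        lo, hi = v.min(skipna=True), v.max(skipna=True)
        if pd.isna(lo) or hi == lo:
            normed[col] = pd.Series(np.where(v.notna(), 0.0, np.nan), index=v.index)
        else:
            normed[col] = (v - lo) / (hi - lo)
    return pd.DataFrame(normed).mean(axis=1, skipna=True).fillna(0.0)


def discover(
    genomes: list[GenomeAnnotation],
    proteomes: dict[str, dict[str, ProteinRecord]],
    families: dict[str, list[ProteinRecord]],
    reference: ProteinRecord,
    active_site_columns: tuple[int, ...] = NUCLEASE_ACTIVE_SITE,
    params: Optional[DiscoveryParams] = None,
    seed: int = 0,
    anchor_family: str = "nuclease",
) -> CandidateReport:
    """Run the full discovery strategy on in-memory genomes."""
    p = params or DiscoveryParams()
    profiles = build_profiles(families, p, seed)
    rows: list[dict] = []
    anchor_proteins: dict[str, ProteinRecord] = {}
    protease_proteins: dict[str, tuple[str, str]] = {}  # anchor gene -> (pid, subseq)

    for genome in sorted(genomes, key=lambda g: g.genome_id):
        prots = proteomes[genome.genome_id]
        proteome = [prots[k] for k in sorted(prots)]
        hits = scan_proteome(
            profiles, proteome, evalue_max=p.evalue_max, database_size=len(proteome)
        )
        hits_by_protein: dict[str, list] = {}
        for h in hits:
            hits_by_protein.setdefault(h.protein_id, []).append(h)
        anchors = sorted(
            {h.protein_id for h in hits if h.family_name == anchor_family}
        )
        if not anchors:
            continue
        for pid in anchors:
            nb = extract_neighborhood(
                genome, pid, window_genes=p.window_genes, window_kb=p.window_kb,
                hits_by_protein=hits_by_protein,
            )
            call = classify_locus(nb)
            call.genome_id = genome.genome_id
            isl = island_score(
                genome, call, extended_window_kb=p.island_window_kb,
                hits_by_protein=hits_by_protein,
            )
            expected = (
                frozenset("G") if call.system_label == "canu"
                else frozenset("I") if call.system_label in TRYPSIN_SYSTEMS
                else frozenset("IG")
            )
            gate = call_gate(
                prots[pid], reference, active_site_columns,
                expected_residues=expected, params=p.gate,
            )
            anchor_proteins[call.anchor.gene_id] = prots[pid]
            for fc in call.fusion_calls:
                if fc.n_terminal_family in ("trypsin", "caspase"):
                    fh = [
                        h for h in hits_by_protein.get(fc.protein_id, [])
                        if h.family_name == fc.n_terminal_family
                    ]
                    if fh:
                        best = max(fh, key=lambda h: h.bit_score)
                        sub = prots[fc.protein_id].sequence[best.start - 1: best.end]
                        protease_proteins[call.anchor.gene_id] = (fc.protein_id, sub)
            rows.append(
                {
                    "genome": genome.genome_id,
                    "contig": call.anchor.contig,
                    "anchor_gene": call.anchor.gene_id,
                    "anchor_protein": pid,
                    "system_label": call.system_label,
                    "evidence": ",".join(call.evidence_families),
                    "n_marker_families": len(call.evidence_families),
                    "nuclease_upstream": call.nuclease_upstream,
                    "island_score": isl,
                    "n_insertions": len(gate.insertions),
                    "gate_intervals": ";".join(f"{a}-{b}" for a, b in gate.insertions),
                    "cut_sites": ";".join(str(k) for k, _ in gate.cut_sites),
                    "gate_score": gate.gate_score,
                    "gated": gate.gated,
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "genome", "contig", "anchor_gene", "anchor_protein", "system_label",
            "evidence", "n_marker_families", "nuclease_upstream", "island_score",
            "n_insertions", "gate_intervals", "cut_sites", "gate_score", "gated",
        ],
    )
    congruence: dict[str, CongruenceResult] = {}
    transfer: dict[str, TransferSignal] = {}
    table["mantel_r"] = np.nan
    if len(table):
        _coevolution_block(
            table, anchor_proteins, protease_proteins, congruence, transfer, p, seed
        )
        comps = table[["island_score", "gate_score", "n_marker_families", "mantel_r"]]
        table["rank_score"] = _rank_scores(comps)
        table = table.sort_values(
            ["rank_score", "anchor_gene"], ascending=[False, True]
        ).reset_index(drop=True)
    else:
        table["rank_score"] = pd.Series(dtype=float)
        log.warning("discovery produced zero anchor hits: empty report")

    meta = {
        "seed": seed,
        "version": __version__,
        "params_digest": hashlib.sha256(
            json.dumps(asdict(p), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_genomes": len(genomes),
        "n_candidates": int(len(table)),
    }
    return CandidateReport(
        table=table, congruence=congruence, transfer=transfer, metadata=meta
    )


def _coevolution_block(
    table: pd.DataFrame,
    anchor_proteins: dict[str, ProteinRecord],
    protease_proteins: dict[str, tuple[str, str]],
    congruence: dict[str, CongruenceResult],
    transfer: dict[str, TransferSignal],
    p: DiscoveryParams,
    seed: int,
) -> None:
    """Nuclease/protease tree congruence over loci with a protease partner.

    Loci enter when their protease domains share a common length with the
    group (the synthetic families are indel-free, so extracted domains are
    mutually aligned positionally); real data should supply alignments.
    """
    loci = [
        g for g in table["anchor_gene"]
        if g in protease_proteins and g in anchor_proteins
    ]
    if len(loci) < p.min_pairs_for_congruence:
        return
    nuc_lens = {len(anchor_proteins[g].sequence) for g in loci}
    pro_lens = {len(protease_proteins[g][1]) for g in loci}
    if len(nuc_lens) != 1 or len(pro_lens) != 1:
        log.warning("coevolution block skipped: unaligned member sequences")
        return
    nuc_recs = [
        ProteinRecord(id=g, sequence=anchor_proteins[g].sequence) for g in loci
    ]
    pro_recs = [
        ProteinRecord(id=f"p_{g}", sequence=protease_proteins[g][1]) for g in loci
    ]
    t_nuc = nj_tree(poisson_distance(nuc_recs))
    t_pro = nj_tree(poisson_distance(pro_recs))
    pairs = [(g, f"p_{g}") for g in loci]
    res = mantel_congruence(
        t_nuc, t_pro, pairs, n_perm=p.n_permutations,
        seed=int(child_rng(seed, "mantel").integers(0, 2**31)),
    )
    congruence["nuclease_vs_protease"] = res
    labels = dict(zip(table["anchor_gene"], table["system_label"]))
    group_labels = {g: labels[g] for g in loci}
    if len(set(group_labels.values())) >= 2:
        transfer["nuclease_tree_system_labels"] = transfer_signal(
            t_nuc, group_labels, n_perm=p.n_permutations,
            seed=int(child_rng(seed, "transfer").integers(0, 2**31)),
        )
    in_group = table["anchor_gene"].isin(loci)
    table.loc[in_group, "mantel_r"] = res.mantel_r


def discover_cohort(
    cohort: SyntheticCohort,
    params: Optional[DiscoveryParams] = None,
    seed: Optional[int] = None,
) -> CandidateReport:
    """Convenience wrapper: run discovery directly on a synthetic cohort."""
    return discover(
        cohort.genomes,
        cohort.proteomes,
        cohort.families,
        cohort.reference_nuclease,
        active_site_columns=cohort.active_site_columns,
        params=params,
        seed=cohort.seed if seed is None else seed,
    )


def run_discovery(config: DiscoveryConfig) -> CandidateReport:
    """File-based discovery run: load genomes/families, execute, write outputs."""
    gdir = Path(config.genomes_dir)
    fdir = Path(config.families_dir)
    ref_path = Path(config.reference_fasta)
    for path in (gdir, fdir, ref_path):
        if not path.exists():
            raise ConfigError(f"input path does not exist: {path}")
    genomes: list[GenomeAnnotation] = []
    proteomes: dict[str, dict[str, ProteinRecord]] = {}
    for faa in sorted(gdir.glob("*.faa")):
        gid = faa.stem
        gff = gdir / f"{gid}.gff3"
        if not gff.exists():
            log.warning("genome %s: no GFF3, skipped", gid)
            continue
        prots = {r.id: r for r in read_fasta(faa)}
        genomes.append(read_gff3(gff, proteins=prots, genome_id=gid))
        proteomes[gid] = prots
    families = {
        f.stem: read_fasta(f) for f in sorted(fdir.glob("*.afa"))
    }
    reference = read_fasta(ref_path)[0]
    report = discover(
        genomes, proteomes, families, reference,
        active_site_columns=tuple(config.active_site_columns),
        params=config.params, seed=config.seed,
        anchor_family=config.anchor_family,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_tsv(out / "candidates.tsv")
    sidecar = dict(report.metadata)
    sidecar["congruence"] = {k: asdict(v) for k, v in report.congruence.items()}
    sidecar["transfer"] = {k: asdict(v) for k, v in report.transfer.items()}
    (out / "run_metadata.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return report


def summarize(report: CandidateReport, top_n: int = 10) -> tuple[str, pd.DataFrame]:
    """Per-system counts, gated fraction per system, and the top-N table."""
    t = report.table
    systems = list(SYSTEM_PARTNERS) + ["canu", UNKNOWN]
    rows = []
    for s in systems:
        sub = t[t["system_label"] == s] if len(t) else t
        n = int(len(sub))
        gated_frac = float(sub["gated"].mean()) if n else 0.0
        rows.append({"system_label": s, "n_loci": n, "gated_fraction": gated_frac})
    summary = pd.DataFrame(rows, columns=["system_label", "n_loci", "gated_fraction"])
    lines = ["system_label\tn_loci\tgated_fraction"]
    for r in rows:
        lines.append(f"{r['system_label']}\t{r['n_loci']}\t{r['gated_fraction']:.3f}")
    lines.append("")
    lines.append(f"top {min(top_n, len(t))} candidates by rank score:")
    if len(t):
        head = t.head(top_n)[
            ["anchor_gene", "system_label", "island_score", "gate_score", "rank_score"]
        ]
        lines.append(head.to_string(index=False))
    return "\n".join(lines), summary
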