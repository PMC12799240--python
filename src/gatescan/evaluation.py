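"""Validation studies and exhaustive reference implementations.

The functions here recompute, from scratch, the quantitative properties
the package is expected to satisfy: oracle agreement of the dynamic-
programming aligner, Fitch counter and neighbor joining against
exhaustive/brute-force references; calibration and power of the Mantel
congruence test; recovery of implanted gating insertions; and locus
classification/ranking accuracy on synthetic cohorts.  The reference
implementations deliberately share no code path with the operations they
check.
"""

from __future__ import annotations

import math
import random
from typing import Optional, Sequence

import dendropy
import numpy as np

from .coevolution import (
    DistanceMatrix,
    fitch_parsimony,
    mantel_congruence,
    nj_tree,
    patristic_matrix,
    poisson_distance,
    robinson_foulds,
)
from .gate_detection import _BLOSUM62, call_insertions, global_align
from .pipeline import CandidateReport, discover_cohort
from .profile_search import AA_INDEX
from .synthetic_data import (
    EvolutionConfig,
    InsertionSpec,
    SyntheticCohort,
    child_rng,
    family_roots,
    generate_cohort,
    make_gated_sequence,
    mutate_sequence,
    random_protein,
    simulate_gene_family,
    simulate_linked_families,
)

# ---------------------------------------------------------------------------
# Brute-force references


def brute_force_global_score(
    query: str,
    reference: str,
    substitution_matrix: Optional[np.ndarray] = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal global affine-gap score by exhaustive path enumeration.

    Recursively enumerates every monotone alignment path (no memoization,
    no dynamic-programming matrices); exponential, so only usable for
    short sequences.  A length-k gap costs gap_open + k*gap_extend.
    """
    S = _BLOSUM62 if substitution_matrix is None else substitution_matrix
    qi = [AA_INDEX[c] for c in query]
    ri = [AA_INDEX[c] for c in reference]
    n, m = len(qi), len(ri)
    best = [-math.inf]

    def rec(i: int, j: int, state: str, score: float) -> None:
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            rec(i + 1, j + 1, "M", score + S[qi[i], ri[j]])
        if i < n:
            cost = gap_extend + (gap_open if state != "Y" else 0.0)
            rec(i + 1, j, "Y", score - cost)
        if j < m:
            cost = gap_extend + (gap_open if state != "X" else 0.0)
            rec(i, j + 1, "X", score - cost)

    rec(0, 0, "S", 0.0)
    return best[0]


def exhaustive_fitch(tree: dendropy.Tree, leaf_labels: dict[str, str]) -> int:
    """Minimum label changes by enumerating every internal-node labeling.

    Only feasible for small binary trees; the reference for the two-pass
    Fitch counter.
    """
    t = tree.clone(depth=1)
    t.resolve_polytomies(rng=random.Random(0))
    internals = [nd for nd in t.postorder_node_iter() if not nd.is_leaf()]
    states = sorted(set(leaf_labels.values()))
    k = len(internals)
    best = math.inf
    assignment: dict[int, str] = {}
    for code in range(len(states) ** k):
        c = code
        for nd in internals:
            assignment[id(nd)] = states[c % len(states)]
            c //= len(states)
        changes = 0
        for nd in t.postorder_node_iter():
            if nd.parent_node is None:
                continue
            lab = (
                leaf_labels[nd.taxon.label] if nd.is_leaf() else assignment[id(nd)]
            )
            if lab != assignment[id(nd.parent_node)]:
                changes += 1
        if changes < best:
            best = changes
    return int(best)


def random_additive_matrix(
    n_taxa: int, seed: int
) -> tuple[dendropy.Tree, DistanceMatrix]:
    """A random binary tree with positive lengths and its exact additive
    (patristic) distance matrix."""
    from dendropy.simulate import treesim

    rng = np.random.default_rng(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"x{i:02d}"
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.1, 1.0))
    labels, D = patristic_matrix(tree)
    return tree, DistanceMatrix(labels=labels, d=D)


# ---------------------------------------------------------------------------
# Oracle-agreement studies


def alignment_oracle_agreement(
    n_pairs: int = 500,
    max_len: int = 8,
    alphabet: str = "ACDE",
    seed: int = 0,
) -> float:
    """Fraction of random short pairs where the DP aligner's score equals
    the brute-force enumeration (4-letter test alphabet)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        lq = int(rng.integers(1, max_len + 1))
        lr = int(rng.integers(1, max_len + 1))
        q = "".join(alphabet[int(k)] for k in rng.integers(0, len(alphabet), lq))
        r = "".join(alphabet[int(k)] for k in rng.integers(0, len(alphabet), lr))
        dp = global_align(q, r).score
        bf = brute_force_global_score(q, r)
        agree += abs(dp - bf) < 1e-9
    return agree / n_pairs


def fitch_oracle_agreement(
    n_trees: int = 100, max_leaves: int = 7, max_labels: int = 4, seed: int = 0
) -> float:
    """Fraction of random binary trees where two-pass Fitch equals the
    exhaustive internal-labeling minimum."""
    from dendropy.simulate import treesim

    rng = np.random.default_rng(seed)
    agree = 0
    for t in range(n_trees):
        n = int(rng.integers(4, max_leaves + 1))
        k = int(rng.integers(2, max_labels + 1))
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            rng=random.Random(seed * 1000 + t),
        )
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        labels = {l: f"L{int(rng.integers(0, k))}" for l in leaves}
        if len(set(labels.values())) < 2:
            labels[leaves[0]] = "L0"
            labels[leaves[1]] = "L1"
        agree += fitch_parsimony(tree, labels) == exhaustive_fitch(tree, labels)
    return agree / n_trees


def nj_additive_exact_fraction(
    n_matrices: int = 100, max_taxa: int = 8, seed: int = 0
) -> float:
    """Fraction of random additive matrices on which neighbor joining
    recovers the generating topology and branch lengths exactly."""
    rng = np.random.default_rng(seed)
    exact = 0
    for t in range(n_matrices):
        n = int(rng.integers(4, max_taxa + 1))
        tree, dm = random_additive_matrix(n, seed * 1000 + t)
        inferred = nj_tree(dm)
        rf, _ = robinson_foulds(inferred, tree)
        _, D2 = patristic_matrix(inferred, dm.labels)
        exact += (rf == 0) and np.allclose(D2, dm.d, atol=1e-8)
    return exact / n_matrices


# ---------------------------------------------------------------------------
# Mantel calibration and power


def mantel_simulation_pvalue(
    seed: int,
    joint: bool,
    n_loci: int = 16,
    seq_len: int = 150,
    sub_rate: float = 0.3,
    transfer_rate: float = 2.0,
    n_perm: int = 999,
) -> float:
    """One replicate of the congruence study: co-simulated (joint
    transfers) or independently evolved nuclease/protease families, NJ
    trees on Poisson distances, Mantel p-value under locus-pairing
    permutation."""
    root_rng = child_rng(seed, "mantel_roots")
    if joint:
        cfg = EvolutionConfig(
            n_taxa=n_loci, sub_rate=sub_rate, transfer_rate=transfer_rate, seed=seed
        )
        fams, _ = simulate_linked_families(
            cfg,
            {
                "nuclease": random_protein(root_rng, seq_len),
                "protease": random_protein(root_rng, seq_len),
            },
        )
        ra, rb = fams["nuclease"], fams["protease"]
    else:
        ca = EvolutionConfig(n_taxa=n_loci, sub_rate=sub_rate, seed=2 * seed + 1)
        cb = EvolutionConfig(n_taxa=n_loci, sub_rate=sub_rate, seed=2 * seed + 2)
        ra, _ = simulate_gene_family(ca, random_protein(root_rng, seq_len))
        rb, _ = simulate_gene_family(cb, random_protein(root_rng, seq_len))
    ta = nj_tree(poisson_distance(ra))
    tb = nj_tree(poisson_distance(rb))
    pairs = [(r.id, r.id) for r in ra]
    return mantel_congruence(ta, tb, pairs, n_perm=n_perm, seed=seed).p_mantel


def mantel_type1_error(
    n_reps: int = 500, alpha: float = 0.05, seed: int = 0, **kwargs
) -> float:
    """Rejection rate at ``alpha`` under independent evolution (true null)."""
    ps = [
        mantel_simulation_pvalue(seed * 100_000 + k, joint=False, **kwargs)
        for k in range(n_reps)
    ]
    return float(np.mean([p <= alpha for p in ps]))


def mantel_power(
    n_reps: int = 100, alpha: float = 0.05, seed: int = 0, **kwargs
) -> float:
    """Rejection rate at ``alpha`` under joint-transfer co-simulation."""
    ps = [
        mantel_simulation_pvalue(seed * 100_000 + k, joint=True, **kwargs)
        for k in range(n_reps)
    ]
    return float(np.mean([p <= alpha for p in ps]))


# ---------------------------------------------------------------------------
# Gate recovery


def gate_recovery_study(
    n_gated: int = 200,
    n_ungated: int = 200,
    max_sub_rate: float = 0.2,
    min_insertion: int = 15,
    max_insertion: int = 30,
    boundary_tol: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Implant gates into diverged copies of the reference nuclease and
    measure insertion-boundary recovery, cut-site containment, and false
    insertion calls on ungated controls."""
    ref = family_roots(seed)["nuclease"]
    n_boundaries_ok = 0
    n_insertions = 0
    n_cuts = 0
    n_cuts_inside = 0
    for i in range(n_gated):
        rng = child_rng(seed, "gated", i)
        sub = float(rng.uniform(0.0, max_sub_rate))
        evolved = mutate_sequence(ref, sub, rng)
        l1 = int(rng.integers(min_insertion, max_insertion + 1))
        l2 = int(rng.integers(min_insertion, max_insertion + 1))
        p1 = int(rng.integers(60, 141))
        p2 = int(rng.integers(180, 261))
        # cleavage sites sit interior to the gating loop (mid-insertion),
        # mirroring the observed geometry of natural gated nucleases
        specs = [
            InsertionSpec(p1, l1, "I", int(rng.integers(4, l1 - 2))),
            InsertionSpec(p2, l2, "I", int(rng.integers(4, l2 - 2))),
        ]
        gated, truth_iv, truth_cuts = make_gated_sequence(evolved, specs, rng)
        called = call_insertions(global_align(gated, ref))
        for ts, te in truth_iv:
            n_insertions += 1
            if any(abs(cs - ts) <= boundary_tol and abs(ce - te) <= boundary_tol
                   for cs, ce in called):
                n_boundaries_ok += 1
        for cut in truth_cuts:
            n_cuts += 1
            if any(cs <= cut <= ce for cs, ce in called):
                n_cuts_inside += 1
    false_calls = 0
    for i in range(n_ungated):
        rng = child_rng(seed, "ungated", i)
        sub = float(rng.uniform(0.0, max_sub_rate))
        evolved = mutate_sequence(ref, sub, rng)
        false_calls += len(call_insertions(global_align(evolved, ref)))
    return {
        "boundary_recovery_fraction": n_boundaries_ok / n_insertions,
        "cut_sites_inside_fraction": n_cuts_inside / n_cuts,
        "false_insertion_calls": float(false_calls),
        "n_gated": float(n_gated),
        "n_ungated": float(n_ungated),
    }


# ---------------------------------------------------------------------------
# Cohort classification and ranking


def classification_metrics(
    cohort: SyntheticCohort, report: CandidateReport
) -> dict[str, float]:
    """Precision/recall of system labels on implanted loci and the
    unknown-rate on decoys, against the cohort truth table."""
    truth = dict(zip(cohort.truth["gene_id"], cohort.truth["system_label"]))
    decoy_genes = set(cohort.decoys["gene_id"])
    t = report.table
    predicted = dict(zip(t["anchor_gene"], t["system_label"]))
    labeled = {g: s for g, s in predicted.items() if s != "unknown"}
    tp = sum(1 for g, s in labeled.items() if truth.get(g) == s)
    precision = tp / len(labeled) if labeled else 0.0
    recall = (
        sum(1 for g, s in truth.items() if labeled.get(g) == s) / len(truth)
        if truth
        else 0.0
    )
    found_decoys = [g for g in decoy_genes if g in predicted]
    decoy_unknown = (
        sum(1 for g in found_decoys if predicted[g] == "unknown") / len(decoy_genes)
        if decoy_genes
        else 1.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "decoy_unknown_fraction": decoy_unknown,
        "n_truth": float(len(truth)),
        "n_decoys": float(len(decoy_genes)),
    }


def ranking_separation(cohort: SyntheticCohort, report: CandidateReport) -> float:
    """Fraction of truth loci ranked strictly above every decoy locus."""
    truth_genes = set(cohort.truth["gene_id"])
    decoy_genes = set(cohort.decoys["gene_id"])
    t = report.table
    scores = dict(zip(t["anchor_gene"], t["rank_score"]))
    decoy_scores = [scores[g] for g in decoy_genes if g in scores]
    worst_decoy = max(decoy_scores) if decoy_scores else -math.inf
    above = sum(1 for g in truth_genes if scores.get(g, -math.inf) > worst_decoy)
    return above / len(truth_genes) if truth_genes else 0.0


def default_cohort_study(seed: int = 1) -> dict[str, float]:
    """Classification + ranking metrics of a full discovery run on the
    default cohort (50 genomes, 10 implants, 10 decoys)."""
    cohort = generate_cohort(seed=seed)
    report = discover_cohort(cohort)
    out = classification_metrics(cohort, report)
    out["truth_above_all_decoys_fraction"] = ranking_separation(cohort, report)
    report2 = discover_cohort(cohort)
    out["repeat_run_identical"] = float(
        report.body_bytes() == report2.body_bytes()
    )
    if "nuclease_vs_protease" in report.congruence:
        res = report.congruence["nuclease_vs_protease"]
        out["cohort_mantel_r"] = res.mantel_r
        out["cohort_mantel_p"] = res.p_mantel
    return out
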