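"""Tree congruence and transfer statistics for nuclease-protease pairs.

The evolutionary argument the pipeline tests is twofold: (i) nuclease and
partner-protease gene trees should be congruent if the pair co-evolves and
moves as a unit (measured here by the Mantel correlation of patristic
distances with a locus-pairing permutation null, plus Robinson-Foulds
distance), and (ii) the scatter of defense-system labels across the
nuclease gene tree should exceed the vertical minimum if the pair was
acquired on multiple independent occasions (a Fitch label-parsimony excess
with a label-permutation null).

Distances are Poisson-corrected amino-acid distances; trees are built by
neighbor joining with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .errors import InputError
from .io_formats import ProteinRecord

log = logging.getLogger(__name__)

#: mismatch fraction beyond which a pair is considered saturated and capped
SATURATION_P = 0.95


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray = field(default=None)  # boolean mask of capped pairs

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise InputError("distances must be finite and non-negative")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)


@dataclass
class CongruenceResult:
    rf: int
    rf_normalized: float
    mantel_r: float
    p_mantel: float
    n_permutations: int
    seed: int
    degenerate: bool = False  # constant distances: r undefined, p = 1


@dataclass
class TransferSignal:
    observed_changes: int
    vertical_minimum: int
    excess: int
    p_perm: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# Distances


def poisson_distance(alignment: Sequence[ProteinRecord] | Sequence[str]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p) over ungapped columns.

    p is the mismatch fraction over columns where both sequences have a
    residue.  Pairs with p >= 0.95 are flagged saturated and capped at
    -ln(0.05); a pair with no comparable columns is an error.
    """
    labels = [r.id if isinstance(r, ProteinRecord) else f"s{i}" for i, r in enumerate(alignment)]
    seqs = [r.sequence if isinstance(r, ProteinRecord) else r for r in alignment]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise InputError("alignment sequences must have equal lengths")
    mat = np.array([list(s) for s in seqs])
    is_res = (mat != "-") & (mat != ".")
    n = len(seqs)
    d = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    cap = -math.log(1.0 - SATURATION_P)
    for i in range(n):
        for j in range(i + 1, n):
            both = is_res[i] & is_res[j]
            m = int(both.sum())
            if m == 0:
                raise InputError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no ungapped columns"
                )
            p = float((mat[i, both] != mat[j, both]).sum()) / m
            if p >= SATURATION_P:
                d[i, j] = d[j, i] = cap
                saturated[i, j] = saturated[j, i] = True
            else:
                d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(labels=labels, d=d, saturated=saturated)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved by the lexicographically smallest
    (label, label) pair, where a cluster is named by its smallest member
    leaf.  Negative branch lengths are clamped to 0 with the deficit
    logged.  Returns an unrooted tree (trifurcating seed node).
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        tx = dendropy.Taxon(label=lab)
        taxa.add_taxon(tx)
        nd = dendropy.Node(taxon=tx)
        nodes.append(nd)
    reps = list(dm.labels)  # representative (min) label per active cluster
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in cand
            if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)
        new = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        # distances from the new cluster
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dk
        D[:, i] = dk
        D[i, i] = 0.0
        nodes[i] = new
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].edge.length = lk
        root.add_child(nodes[k])
    if deficit > 0:
        log.info("nj_tree: clamped negative branch lengths totalling %.4g", deficit)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Tree comparison


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label frozensets."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(clade) < 2 or len(clade) > len(leaves) - 2:
            continue
        side = clade if ref not in clade else leaves - clade
        splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalization.

    rf is the size of the symmetric difference of non-trivial bipartitions;
    normalized by the attainable maximum (sum of bipartition counts; equal
    to 2(n-3) for two binary trees).  Leaf sets must match.
    """
    l1 = set(lf.taxon.label for lf in t1.leaf_node_iter())
    l2 = set(lf.taxon.label for lf in t2.leaf_node_iter())
    if l1 != l2:
        raise InputError("robinson_foulds requires identical leaf sets")
    b1 = _bipartitions(t1)
    b2 = _bipartitions(t2)
    rf = len(b1 ^ b2)
    max_rf = len(b1) + len(b2)
    return rf, (rf / max_rf if max_rf > 0 else 0.0)


def patristic_matrix(tree: dendropy.Tree, labels: Optional[Sequence[str]] = None) -> tuple[list[str], np.ndarray]:
    """Path-length (patristic) distances between leaves, in label order."""
    if labels is None:
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    dist_maps: dict[int, dict[int, float]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            if nd.taxon.label in idx:
                dist_maps[id(nd)] = {idx[nd.taxon.label]: 0.0}
            else:
                dist_maps[id(nd)] = {}
            continue
        children = nd.child_nodes()
        maps = []
        for ch in children:
            el = ch.edge.length or 0.0
            maps.append({k: v + el for k, v in dist_maps.pop(id(ch)).items()})
        merged: dict[int, float] = {}
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for ka, va in maps[a].items():
                    for kb, vb in maps[b].items():
                        D[ka, kb] = D[kb, ka] = va + vb
            merged.update(maps[a])
        dist_maps[id(nd)] = merged
    return list(labels), D


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def mantel_congruence(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    shared_pairs: Sequence[tuple[str, str]],
    n_perm: int = 999,
    seed: int = 0,
) -> CongruenceResult:
    """Mantel test of patristic-distance congruence between two gene trees.

    ``shared_pairs`` lists (leaf-in-t1, leaf-in-t2) same-locus pairings,
    e.g. a nuclease leaf with its co-encoded protease leaf.  The null
    permutes the locus pairing of the second matrix; the one-sided p-value
    is (1 + #{r_perm >= r_obs}) / (1 + n_perm).  Robinson-Foulds distance
    is computed on the pairing-relabeled trees restricted to shared loci.
    """
    if len(shared_pairs) < 4:
        raise InputError("mantel_congruence needs at least 4 shared locus pairs")
    labels1 = [a for a, _ in shared_pairs]
    labels2 = [b for _, b in shared_pairs]
    if len(set(labels1)) != len(labels1) or len(set(labels2)) != len(labels2):
        raise InputError("locus pairings must be unique on both sides")
    _, D1 = patristic_matrix(t1, labels1)
    _, D2 = patristic_matrix(t2, labels2)
    n = len(shared_pairs)
    v1 = _condensed(D1)
    rng = np.random.default_rng(seed)

    rf, rf_norm = _paired_rf(t1, t2, shared_pairs)

    if v1.std() == 0 or _condensed(D2).std() == 0:
        log.warning("mantel_congruence: constant distance matrix; r undefined")
        return CongruenceResult(
            rf=rf, rf_normalized=rf_norm, mantel_r=float("nan"), p_mantel=1.0,
            n_permutations=n_perm, seed=seed, degenerate=True,
        )

    iu_r, iu_c = np.triu_indices(n, k=1)

    def corr_with(D2v: np.ndarray) -> float:
        return float(np.corrcoef(v1, D2v)[0, 1])

    r_obs = corr_with(_condensed(D2))
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Dp = D2[perms[:, iu_r], perms[:, iu_c]]  # (n_perm, n_pairs)
    v1c = v1 - v1.mean()
    Dpc = Dp - Dp.mean(axis=1, keepdims=True)
    denom = np.sqrt((v1c**2).sum() * (Dpc**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        r_perm = (Dpc @ v1c) / denom
    r_perm = np.nan_to_num(r_perm, nan=-1.0)
    count = int((r_perm >= r_obs - 1e-12).sum())
    p = (1.0 + count) / (1.0 + n_perm)
    return CongruenceResult(
        rf=rf, rf_normalized=rf_norm, mantel_r=r_obs, p_mantel=p,
        n_permutations=n_perm, seed=seed,
    )


def _paired_rf(
    t1: dendropy.Tree, t2: dendropy.Tree, shared_pairs: Sequence[tuple[str, str]]
) -> tuple[int, float]:
    """RF between the trees restricted to shared loci, t2 relabeled via pairing."""
    mapping = {b: a for a, b in shared_pairs}
    keep1 = {a for a, _ in shared_pairs}
    c1 = t1.clone(depth=1)
    c1.retain_taxa_with_labels(list(keep1))
    c2 = t2.clone(depth=1)
    c2.retain_taxa_with_labels(list(mapping.keys()))
    for lf in c2.leaf_node_iter():
        lf.taxon.label = mapping[lf.taxon.label]
    return robinson_foulds(c1, c2)


# ---------------------------------------------------------------------------
# Label parsimony / transfer signal


def fitch_parsimony(tree: dendropy.Tree, leaf_labels: Mapping[str, str]) -> int:
    """Minimum label changes on the tree by two-pass Fitch counting.

    The tree is arbitrarily rooted and multifurcations are resolved with a
    fixed-seed arbitrary resolution; the count is exact for binary trees
    and a valid upper bound otherwise.
    """
    t = tree.clone(depth=1)
    t.resolve_polytomies(rng=random.Random(0))
    changes = 0
    state: dict[int, set[str]] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            lab = leaf_labels.get(nd.taxon.label)
            if lab is None:
                raise InputError(f"leaf {nd.taxon.label!r} has no label")
            state[id(nd)] = {lab}
            continue
        cur: Optional[set[str]] = None
        for ch in nd.child_nodes():
            s = state.pop(id(ch))
            if cur is None:
                cur = s
            else:
                inter = cur & s
                if inter:
                    cur = inter
                else:
                    cur = cur | s
                    changes += 1
        state[id(nd)] = cur
    return changes


def transfer_signal(
    gene_tree: dendropy.Tree,
    taxon_labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> TransferSignal:
    """Label-parsimony transfer statistic with a permutation null.

    ``excess`` = observed Fitch changes minus the vertical minimum
    (#labels - 1); each excess change is a candidate cross-lineage
    transfer.  ``p_perm`` is the fraction of random leaf-label
    permutations needing <= the observed number of changes: a small value
    means the labels are still more clustered than chance, a large excess
    with small p indicates repeated but clustered acquisitions.
    """
    leaves = [lf.taxon.label for lf in gene_tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in taxon_labels]
    if missing:
        raise InputError(f"leaves without labels: {missing[:3]}")
    labels = [taxon_labels[l] for l in leaves]
    distinct = sorted(set(labels))
    vertical_min = len(distinct) - 1
    if len(distinct) < 2:
        return TransferSignal(0, 0, 0, 1.0, n_perm, seed)
    observed = fitch_parsimony(gene_tree, dict(zip(leaves, labels)))
    rng = np.random.default_rng(seed)
    count = 0
    arr = np.array(labels)
    for _ in range(n_perm):
        perm = rng.permutation(len(arr))
        mapping = dict(zip(leaves, arr[perm]))
        if fitch_parsimony(gene_tree, mapping) <= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return TransferSignal(
        observed_changes=observed,
        vertical_minimum=vertical_min,
        excess=observed - vertical_min,
        p_perm=p,
        n_permutations=n_perm,
        seed=seed,
    )
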