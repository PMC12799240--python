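"""Gated-proenzyme signature calling.

A "gated" pro-nuclease carries polypeptide insertions, relative to an
ungated reference nuclease, that block the active site until a partner
protease cleaves inside them.  This module detects that signature at the
sequence level: global alignment of a candidate against the ungated
reference, insertion calling from reference-side gap runs, mapping of the
reference active-site columns into the candidate, conserved cleavage
residues inside the insertions (isoleucine for trypsin-partner systems,
glycine for caspase partners), and per-column sequence logos around the
cleavage site.

Proximity of an insertion to the active site is measured along the chain
(query coordinates), a deliberate 1-D proxy for the structural reading in
which the insertions physically occlude the catalytic pocket.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError
from .io_formats import STANDARD_AA, ProteinRecord
from .profile_search import AA_INDEX, encode_sequence

log = logging.getLogger(__name__)

_N_AA = 20
_X = _N_AA
_NEG = -1e30


def _blosum62_matrix() -> np.ndarray:
    """21x21 substitution matrix over STANDARD_AA + X; X scores are neutral 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    S = np.zeros((21, 21))
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            S[i, j] = blosum[a][b]
    return S


_BLOSUM62 = _blosum62_matrix()


@dataclass
class GateParams:
    """Tunable thresholds of the gate caller (all in residues/bits)."""

    min_len: int = 10          # minimum insertion length to count as a gate
    merge_gap: int = 3         # merge reference-gap runs closer than this (columns)
    prox_window: int = 30      # max chain distance insertion <-> active site
    gap_open: float = 11.0
    gap_extend: float = 1.0
    len_weight: float = 1.0
    prox_weight: float = 1.0
    residue_weight: float = 1.0


@dataclass
class AlignmentResult:
    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise InputError("aligned rows must have equal lengths")


@dataclass
class GateCall:
    query_id: str
    insertions: list[tuple[int, int]]
    active_site_query_positions: list[Optional[int]]
    cut_sites: list[tuple[int, str]]
    cleavage_residue_expected: frozenset[str]
    gate_score: float
    gated: bool
    alignment: Optional[AlignmentResult] = None


@dataclass
class CleavageLogo:
    """Residue frequencies and information content around a cut-site column."""

    description: str
    positions: list[int]            # 1-based alignment columns
    frequencies: np.ndarray         # (n_columns, 20)
    information: np.ndarray         # bits, in [0, log2 20]
    n_sequences: int
    anchor_column: int
    small_sample_correction: bool
    all_gap: np.ndarray = field(default=None)  # flagged undefined columns

    def anchor_index(self) -> int:
        return self.positions.index(self.anchor_column)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.frequencies, columns=list(STANDARD_AA))
        df.insert(0, "position", self.positions)
        df["bits"] = self.information
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Global alignment (affine-gap Needleman-Wunsch, vectorized per row)


def global_align(
    query: str | ProteinRecord,
    reference: str | ProteinRecord,
    substitution_matrix: Optional[np.ndarray] = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment with affine gaps (open+extend for a length-1 gap).

    Trace-back ties are resolved deterministically in the preference order
    match > insert-in-query (gap in the reference row) > insert-in-reference.
    Non-standard residues are treated as X with neutral (0) scores.
    """
    qid = query.id if isinstance(query, ProteinRecord) else "query"
    rid = reference.id if isinstance(reference, ProteinRecord) else "reference"
    q = query.sequence if isinstance(query, ProteinRecord) else query
    r = reference.sequence if isinstance(reference, ProteinRecord) else reference
    if not q or not r:
        raise InputError("global_align requires non-empty sequences")
    S = _BLOSUM62 if substitution_matrix is None else np.asarray(substitution_matrix, dtype=float)
    qi = encode_sequence(q)
    ri = encode_sequence(r)
    if (qi == _X).any() and any(c.upper() != "X" for c, k in zip(q, qi) if k == _X):
        log.info("global_align: non-standard residues in %s treated as X", qid)
    n, m = len(q), len(r)
    go, ge = float(gap_open), float(gap_extend)

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in query row (consumes reference)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in reference row (consumes query)
    M[0, 0] = 0.0
    if m >= 1:
        X[0, 1:] = -(go + ge * np.arange(1, m + 1))
    cols = np.arange(m)
    for i in range(1, n + 1):
        sc = S[qi[i - 1], ri]
        H_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = H_prev[:-1] + sc
        Y[i] = np.maximum(Y[i - 1] - ge, np.maximum(M[i - 1], X[i - 1]) - go - ge)
        A = np.maximum(M[i], Y[i])
        B = A[:-1] + ge * cols
        run = np.maximum.accumulate(B)
        X[i, 1:] = run - go - ge * np.arange(1, m + 1)
        X[i, 0] = _NEG

    eps = 1e-6
    i, j = n, m
    finals = (("M", M[n, m]), ("Y", Y[n, m]), ("X", X[n, m]))
    best = max(v for _, v in finals)
    state = next(s for s, v in finals if v >= best - eps)
    score = float(best)
    aq: list[str] = []
    ar: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            aq.append(q[i - 1])
            ar.append(r[j - 1])
            target = M[i, j] - S[qi[i - 1], ri[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, mat in (("M", M), ("Y", Y), ("X", X)):
                if abs(mat[i, j] - target) <= eps:
                    state = s
                    break
        elif state == "Y":
            aq.append(q[i - 1])
            ar.append("-")
            v = Y[i, j]
            i -= 1
            if abs(M[i, j] - go - ge - v) <= eps:
                state = "M"
            elif abs(Y[i, j] - ge - v) <= eps:
                state = "Y"
            else:
                state = "X"
        else:  # X
            aq.append("-")
            ar.append(r[j - 1])
            v = X[i, j]
            j -= 1
            if abs(M[i, j] - go - ge - v) <= eps:
                state = "M"
            elif abs(Y[i, j] - go - ge - v) <= eps:
                state = "Y"
            else:
                state = "X"
    return AlignmentResult(
        query_id=qid,
        reference_id=rid,
        aligned_query="".join(reversed(aq)),
        aligned_reference="".join(reversed(ar)),
        score=score,
        gap_open=go,
        gap_extend=ge,
    )


# ---------------------------------------------------------------------------
# Insertion calling and active-site mapping


def call_insertions(
    alignment: AlignmentResult, min_len: int = 10, merge_gap: int = 3
) -> list[tuple[int, int]]:
    """Insertions in the query relative to the reference, as 1-based closed
    intervals in query coordinates.

    Maximal runs of reference-row gaps are extracted; runs separated by
    fewer than ``merge_gap`` aligned columns are merged; merged intervals
    shorter than ``min_len`` query residues are dropped.
    """
    aq, ar = alignment.aligned_query, alignment.aligned_reference
    runs: list[tuple[int, int, int, int]] = []  # (col_start, col_end, q_start, q_end)
    qpos = 0
    run_start = None
    run_qstart = None
    for col, (cq, cr) in enumerate(zip(aq, ar)):
        if cq != "-":
            qpos += 1
        if cr == "-" and cq != "-":
            if run_start is None:
                run_start = col
                run_qstart = qpos
            run_end, run_qend = col, qpos
        else:
            if run_start is not None:
                runs.append((run_start, run_end, run_qstart, run_qend))
                run_start = None
    if run_start is not None:
        runs.append((run_start, run_end, run_qstart, run_qend))
    if not runs:
        return []
    merged = [list(runs[0])]
    for cs, ce, qs, qe in runs[1:]:
        if cs - merged[-1][1] - 1 < merge_gap:
            merged[-1][1], merged[-1][3] = ce, qe
        else:
            merged.append([cs, ce, qs, qe])
    return [(qs, qe) for _, _, qs, qe in merged if qe - qs + 1 >= min_len]


def map_active_site(
    alignment: AlignmentResult, reference_motif_columns: Sequence[int]
) -> list[Optional[int]]:
    """Map 1-based reference positions through the alignment to query
    positions; a position aligned to a query gap maps to None (absent)."""
    ar, aq = alignment.aligned_reference, alignment.aligned_query
    ref_len = sum(1 for c in ar if c != "-")
    for col in reference_motif_columns:
        if not (1 <= col <= ref_len):
            raise InputError(f"motif column {col} outside reference (1..{ref_len})")
    wanted = set(reference_motif_columns)
    mapping: dict[int, Optional[int]] = {}
    rpos = qpos = 0
    for cq, cr in zip(aq, ar):
        if cq != "-":
            qpos += 1
        if cr != "-":
            rpos += 1
            if rpos in wanted:
                mapping[rpos] = qpos if cq != "-" else None
    return [mapping[c] for c in reference_motif_columns]


def score_gate(
    insertions: Sequence[tuple[int, int]],
    active_site_positions: Sequence[Optional[int]],
    sequence: str,
    expected_residues: Sequence[str] | set[str] = ("I",),
    params: Optional[GateParams] = None,
) -> tuple[float, bool]:
    """Score the gated-proenzyme signature.

    Per insertion, three components: length >= min_len, chain distance to
    the nearest mapped active-site position <= prox_window, and presence of
    at least one expected cleavage residue.  gate_score is the weighted sum
    over insertions; ``gated`` requires one insertion passing all three.
    """
    p = params or GateParams()
    expected = frozenset(expected_residues)
    ins = sorted(insertions)
    for (s1, e1), (s2, e2) in zip(ins, ins[1:]):
        if s2 <= e1:
            raise InputError("insertions must not overlap")
    for s, e in ins:
        if s < 1 or e > len(sequence) or s > e:
            raise InputError(f"insertion ({s},{e}) inconsistent with sequence length")
    sites = [x for x in active_site_positions if x is not None]
    score = 0.0
    gated = False
    for s, e in ins:
        long_enough = (e - s + 1) >= p.min_len
        if sites:
            dist = min(max(0, s - x, x - e) for x in sites)
            proximal = dist <= p.prox_window
        else:
            proximal = False
        has_residue = any(sequence[k - 1] in expected for k in range(s, e + 1))
        score += (
            p.len_weight * long_enough
            + p.prox_weight * proximal
            + p.residue_weight * has_residue
        )
        gated = gated or (long_enough and proximal and has_residue)
    return score, gated


def find_cut_sites(
    sequence: str,
    insertions: Sequence[tuple[int, int]],
    expected_residues: Sequence[str] | set[str],
) -> list[tuple[int, str]]:
    """Candidate cleavage positions: expected residues inside insertions."""
    expected = set(expected_residues)
    out: list[tuple[int, str]] = []
    for s, e in insertions:
        for k in range(s, e + 1):
            if sequence[k - 1] in expected:
                out.append((k, sequence[k - 1]))
    return out


def call_gate(
    query: ProteinRecord,
    reference: ProteinRecord,
    reference_motif_columns: Sequence[int],
    expected_residues: Sequence[str] | set[str] = ("I",),
    params: Optional[GateParams] = None,
    keep_alignment: bool = False,
) -> GateCall:
    """End-to-end gate call for one candidate nuclease against the reference."""
    p = params or GateParams()
    aln = global_align(query, reference, gap_open=p.gap_open, gap_extend=p.gap_extend)
    insertions = call_insertions(aln, min_len=p.min_len, merge_gap=p.merge_gap)
    active = map_active_site(aln, reference_motif_columns)
    score, gated = score_gate(insertions, active, query.sequence, expected_residues, p)
    cuts = find_cut_sites(query.sequence, insertions, expected_residues)
    return GateCall(
        query_id=query.id,
        insertions=insertions,
        active_site_query_positions=active,
        cut_sites=cuts,
        cleavage_residue_expected=frozenset(expected_residues),
        gate_score=score,
        gated=gated,
        alignment=aln if keep_alignment else None,
    )


# ---------------------------------------------------------------------------
# Cleavage-site logos


def cut_site_logo(
    family_alignment: Sequence[ProteinRecord] | Sequence[str],
    anchor_column: int,
    flank: int = 5,
    small_sample_correction: bool = True,
    description: str = "",
) -> CleavageLogo:
    """Per-column residue frequencies and information content (bits) in a
    window around the aligned cut-site column.

    information = log2(20) - H(column) - e(n), with the small-sample
    correction e(n) = 19 / (2 ln2 n) over the n non-gap residues when
    enabled; clamped to [0, log2 20].  All-gap columns are flagged and
    carry zero information.
    """
    seqs = [r.sequence if isinstance(r, ProteinRecord) else r for r in family_alignment]
    if len(seqs) < 2:
        raise InputError("cut_site_logo needs at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise InputError("family alignment sequences must have equal lengths")
    if not (1 <= anchor_column <= L):
        raise InputError(f"anchor column {anchor_column} outside alignment (1..{L})")
    lo = max(1, anchor_column - flank)
    hi = min(L, anchor_column + flank)
    positions = list(range(lo, hi + 1))
    max_bits = math.log2(_N_AA)
    freqs = np.zeros((len(positions), _N_AA))
    info = np.zeros(len(positions))
    all_gap = np.zeros(len(positions), dtype=bool)
    for k, col in enumerate(positions):
        residues = [s[col - 1] for s in seqs if s[col - 1] in AA_INDEX]
        n = len(residues)
        if n == 0:
            all_gap[k] = True
            continue
        counts = np.bincount([AA_INDEX[c] for c in residues], minlength=_N_AA).astype(float)
        f = counts / n
        freqs[k] = f
        nz = f[f > 0]
        H = float(-(nz * np.log2(nz)).sum())
        bits = max_bits - H
        if small_sample_correction:
            bits -= (_N_AA - 1) / (2.0 * math.log(2.0) * n)
        info[k] = min(max(bits, 0.0), max_bits)
    return CleavageLogo(
        description=description,
        positions=positions,
        frequencies=freqs,
        information=info,
        n_sequences=len(seqs),
        anchor_column=anchor_column,
        small_sample_correction=small_sample_correction,
        all_gap=all_gap,
    )


def conserved_cleavage_fraction(
    logo: CleavageLogo, residue_set: Sequence[str] | set[str]
) -> float:
    """Summed frequency of ``residue_set`` at the logo's anchor column."""
    k = logo.anchor_index()
    return float(sum(logo.frequencies[k, AA_INDEX[r]] for r in residue_set if r in AA_INDEX))
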