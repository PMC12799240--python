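"""Position-specific scoring profiles and proteome scanning.

A :class:`PositionProfile` is a per-column log-odds matrix (bits) built
from a seed alignment of family members; it is the package's homology
search engine for nuclease, protease and defense-marker families.  Two
scanning modes are provided:

``best-window``
    slides the ungapped profile along the protein and reports the
    maximum-scoring placement (fast; the pipeline default), and
``glocal``
    aligns the whole profile to the protein with affine gaps (profile
    consumed entirely, protein flanks free).

Hit significance is calibrated against a shuffled-sequence null whose
best-window scores are fitted with a Gumbel (extreme-value) distribution
by the method of moments, yielding BLAST-style E-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import CalibrationError, FormatError, InputError
from .io_formats import STANDARD_AA, ProteinRecord

log = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_N_AA = 20
_X_INDEX = _N_AA  # unknown residue: scores 0 against every column

#: Euler-Mascheroni constant, used in the Gumbel method-of-moments fit.
EULER_GAMMA = 0.5772156649015329


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein string to integer indices; non-standard letters -> X."""
    idx = np.fromiter(
        (AA_INDEX.get(c, _X_INDEX) for c in seq.upper()), dtype=np.int64, count=len(seq)
    )
    return idx


@dataclass
class HitRecord:
    protein_id: str
    family_name: str
    bit_score: float
    start: int  # 1-based residue span on the protein
    end: int
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError("hit start must be <= end")
        if self.evalue is not None and self.evalue < 0:
            raise InputError("evalue must be >= 0")


@dataclass
class GumbelCalibration:
    """Location/scale of the best-window null-score distribution."""

    mu: float
    beta: float
    n_shuffles: int
    length: int
    seed: int

    def evalue(self, bit_score: float, database_size: int) -> float:
        e = database_size * math.exp(-(bit_score - self.mu) / self.beta)
        return float(min(max(e, 0.0), database_size))


@dataclass
class PositionProfile:
    """Log-odds profile (bits) over the 20 standard residues.

    ``scores`` has shape (L, 21): one row per retained alignment column,
    plus a zero-valued column for X/unknown residues.
    """

    family_name: str
    scores: np.ndarray
    background: np.ndarray
    min_coverage: float = 0.9
    pseudocount: float = 1.0
    consensus: str = ""
    calibration: Optional[GumbelCalibration] = None

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        return float(self.scores[:, :_N_AA].max(axis=1).sum())


def build_profile(
    seed_alignment: Sequence[ProteinRecord] | Sequence[str],
    family_name: str = "",
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
    max_gap_fraction: float = 0.5,
    score_floor: float = -10.0,
    min_coverage: float = 0.9,
) -> PositionProfile:
    """Build a log-odds profile from an aligned set of family sequences.

    score(col, aa) = log2( ((count + pc*bg) / (n + pc)) / bg ), where n is
    the number of non-gap residues in the column.  Columns with more than
    ``max_gap_fraction`` gaps are dropped (logged).  Scores are floored at
    ``score_floor`` bits to keep arithmetic finite.
    """
    seqs = [r.sequence if isinstance(r, ProteinRecord) else r for r in seed_alignment]
    if len(seqs) < 2:
        raise FormatError("a seed alignment needs at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise FormatError("ragged seed alignment: sequences differ in length")
    if background is None:
        background = np.full(_N_AA, 1.0 / _N_AA)
    background = np.asarray(background, dtype=float)
    if background.shape != (_N_AA,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
        raise InputError("background must be a 20-vector summing to 1")

    mat = np.array([encode_sequence(s.replace("-", "x").replace(".", "x")) for s in seqs])
    # '-'/'.'/'x'/'X' all land on _X_INDEX and are treated as missing here
    n_rows = len(seqs)
    kept_cols: list[int] = []
    col_scores: list[np.ndarray] = []
    consensus: list[str] = []
    for j in range(L):
        col = mat[:, j]
        observed = col[col < _N_AA]
        gap_frac = 1.0 - observed.size / n_rows
        if gap_frac > max_gap_fraction:
            continue
        counts = np.bincount(observed, minlength=_N_AA).astype(float)
        n = observed.size
        freq = (counts + pseudocount * background) / (n + pseudocount)
        with np.errstate(divide="ignore"):
            sc = np.log2(freq / background)
        sc = np.maximum(sc, score_floor)
        kept_cols.append(j)
        col_scores.append(sc)
        consensus.append(STANDARD_AA[int(counts.argmax())] if n else "X")
    dropped = L - len(kept_cols)
    if dropped:
        log.info("profile %s: dropped %d/%d gappy columns", family_name, dropped, L)
    if len(kept_cols) < 5:
        raise FormatError("profile needs at least 5 retained columns")
    scores = np.column_stack([np.array(col_scores), np.zeros(len(kept_cols))])
    return PositionProfile(
        family_name=family_name,
        scores=scores,
        background=background,
        pseudocount=pseudocount,
        min_coverage=min_coverage,
        consensus="".join(consensus),
    )


# ---------------------------------------------------------------------------
# Scanning


def _best_window(profile: PositionProfile, idx: np.ndarray) -> Optional[tuple[float, int, int]]:
    """(score, start, end) of the best ungapped placement, 1-based, or None."""
    L = profile.length
    N = idx.size
    if N >= L:
        windows = sliding_window_view(idx, L)  # (N-L+1, L)
        scores = profile.scores[np.arange(L)[None, :], windows].sum(axis=1)
        best = int(scores.argmax())
        return float(scores[best]), best + 1, best + L
    # short protein: slide it inside the profile, full protein must align
    if N < math.ceil(profile.min_coverage * L):
        return None
    offsets = np.arange(L - N + 1)
    rows = offsets[:, None] + np.arange(N)[None, :]
    scores = profile.scores[rows, idx[None, :]].sum(axis=1)
    best = int(scores.argmax())
    return float(scores[best]), 1, N


def _glocal(
    profile: PositionProfile,
    idx: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> Optional[tuple[float, int, int]]:
    """Align the whole profile to the protein with affine gaps.

    Profile columns skipped pay gap penalties; unaligned protein flanks are
    free.  Returns (score, start, end) of the consumed protein span.
    """
    L = profile.length
    N = idx.size
    if N == 0:
        return None
    NEG = -1e30
    go, ge = float(gap_open), float(gap_extend)
    # rows: profile columns 0..L; cols: protein 0..N
    M_prev = np.full(N + 1, NEG)
    Y_prev = np.full(N + 1, NEG)  # gap in protein (profile column skipped)
    X_prev = np.zeros(N + 1)  # gap in profile <=> protein residue unaligned; free at row 0
    col_sc = profile.scores  # (L, 21)
    M_rows = np.empty((L + 1, N + 1))
    X_rows = np.empty((L + 1, N + 1))
    Y_rows = np.empty((L + 1, N + 1))
    M_rows[0], X_rows[0], Y_rows[0] = M_prev, X_prev, Y_prev
    for i in range(1, L + 1):
        sc = col_sc[i - 1, idx]  # (N,)
        H_prev = np.maximum(np.maximum(M_prev, X_prev), Y_prev)
        M_cur = np.full(N + 1, NEG)
        M_cur[1:] = H_prev[:-1] + sc
        Y_cur = np.maximum(Y_prev - ge, np.maximum(M_prev, X_prev) - go - ge)
        # X: interior protein-residue skip (penalized); scan along the row
        A = np.maximum(M_cur, Y_cur)
        X_cur = np.full(N + 1, NEG)
        if N >= 1:
            B = A[:-1] + ge * np.arange(N)
            run = np.maximum.accumulate(B)
            X_cur[1:] = run - go - ge * np.arange(1, N + 1)
        M_rows[i], X_rows[i], Y_rows[i] = M_cur, X_cur, Y_cur
        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur
    # free protein suffix: best over last row of max(M, Y)
    last = np.maximum(M_rows[L], Y_rows[L])
    j_end = int(last.argmax())
    score = float(last[j_end])
    if score <= NEG / 2:
        return None
    # traceback to find the consumed protein span; stops at row 0 (the
    # remaining protein prefix is free)
    i, j = L, j_end
    state = "M" if M_rows[L][j_end] >= Y_rows[L][j_end] else "Y"
    end_j = j
    eps = 1e-9
    while i > 0:
        if state == "M":
            target = M_rows[i][j] - col_sc[i - 1, idx[j - 1]]
            i, j = i - 1, j - 1
            if i == 0:
                break
            for s, mat in (("M", M_rows), ("Y", Y_rows), ("X", X_rows)):
                if abs(mat[i][j] - target) <= eps:
                    state = s
                    break
        elif state == "Y":  # profile column skipped (gap in protein)
            v = Y_rows[i][j]
            i -= 1
            if i == 0:
                break
            if abs(M_rows[i][j] - go - ge - v) <= eps:
                state = "M"
            elif abs(Y_rows[i][j] - ge - v) <= eps:
                state = "Y"
            else:
                state = "X"
        else:  # X: interior protein residue skipped
            v = X_rows[i][j]
            j -= 1
            if abs(M_rows[i][j] - go - ge - v) <= eps:
                state = "M"
            elif abs(Y_rows[i][j] - go - ge - v) <= eps:
                state = "Y"
            else:
                state = "X"
    start_j = j + 1
    if start_j > end_j:
        return None
    return score, start_j, end_j


def scan_protein(
    profile: PositionProfile,
    protein: ProteinRecord,
    mode: str = "best-window",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    database_size: Optional[int] = None,
) -> Optional[HitRecord]:
    """Scan one protein with one profile; returns the best placement or None."""
    idx = encode_sequence(protein.sequence)
    if mode == "best-window":
        res = _best_window(profile, idx)
    elif mode == "glocal":
        res = _glocal(profile, idx, gap_open, gap_extend)
    else:
        raise InputError(f"unknown scan mode {mode!r}")
    if res is None:
        return None
    score, start, end = res
    evalue = None
    if profile.calibration is not None and database_size is not None:
        evalue = profile.calibration.evalue(score, database_size)
    return HitRecord(
        protein_id=protein.id,
        family_name=profile.family_name,
        bit_score=score,
        start=start,
        end=end,
        evalue=evalue,
    )


def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: beta = s*sqrt(6)/pi, mu = m - gamma*beta."""
    scores = np.asarray(scores, dtype=float)
    m = float(scores.mean())
    s = float(scores.std(ddof=1))
    if s <= 0:
        raise CalibrationError("null best-window scores have zero variance")
    beta = s * math.sqrt(6.0) / math.pi
    mu = m - EULER_GAMMA * beta
    return mu, beta


def calibrate_evalue(
    profile: PositionProfile,
    n_shuffles: int = 200,
    length: Optional[int] = None,
    seed: int = 0,
    composition: Optional[np.ndarray] = None,
) -> GumbelCalibration:
    """Fit a Gumbel null to best-window scores of shuffled sequences.

    Null sequences are drawn i.i.d. from ``composition`` (default: the
    profile's seed-consensus composition, which matches the shuffled
    backgrounds the synthetic cohorts use).  Method-of-moments fit:
    beta = s*sqrt(6)/pi, mu = m - gamma*beta.
    """
    if n_shuffles < 200:
        raise InputError("n_shuffles must be >= 200 for a stable fit")
    L = profile.length
    if length is None:
        length = 2 * L
    if length < L:
        length = L
    rng = np.random.default_rng(seed)
    if composition is None:
        cons = encode_sequence(profile.consensus)
        counts = np.bincount(cons[cons < _N_AA], minlength=_N_AA).astype(float)
        composition = (counts + 1.0) / (counts.sum() + _N_AA)
    composition = np.asarray(composition, dtype=float)
    composition = composition / composition.sum()
    scores = np.empty(n_shuffles)
    arange_L = np.arange(L)
    for k in range(n_shuffles):
        idx = rng.choice(_N_AA, size=length, p=composition)
        windows = sliding_window_view(idx, L)
        scores[k] = profile.scores[arange_L[None, :], windows].sum(axis=1).max()
    mu, beta = fit_gumbel_moments(scores)
    cal = GumbelCalibration(mu=mu, beta=beta, n_shuffles=n_shuffles, length=length, seed=seed)
    profile.calibration = cal
    return cal


def scan_proteome(
    profiles: Iterable[PositionProfile],
    proteins: Sequence[ProteinRecord],
    mode: str = "best-window",
    evalue_max: Optional[float] = None,
    database_size: Optional[int] = None,
) -> list[HitRecord]:
    """Scan every protein with every profile; keep hits passing ``evalue_max``.

    Results are independent of record order in the proteome (each hit is a
    per-protein maximum); output is sorted by (protein_id, family).
    """
    if database_size is None:
        database_size = len(proteins)
    hits: list[HitRecord] = []
    for profile in profiles:
        for prot in proteins:
            hit = scan_protein(profile, prot, mode=mode, database_size=database_size)
            if hit is None:
                continue
            if evalue_max is not None:
                if hit.evalue is None or hit.evalue > evalue_max:
                    continue
            hits.append(hit)
    hits.sort(key=lambda h: (h.protein_id, h.family_name))
    return hits
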