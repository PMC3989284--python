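"""Progressive multiple alignment and pairwise-identity summary.

The aligner is a classical progressive scheme: k-mer distances between the
input sequences feed a UPGMA guide tree; profiles are merged bottom-up with a
Gotoh affine-gap dynamic program over column-vs-column substitution scores.
Scoring defaults to match +1 / mismatch -1 with gap open 5 and gap extend 1,
which is adequate for families of 150-200 bp homologs. Tie-breaking in the
DP traceback prefers diagonal, then a gap in the second profile, then a gap
in the first, so alignments are bit-reproducible for fixed inputs.

Percent identity between two rows of the alignment is computed over
co-aligned columns (both rows non-gap); columns where either row is gapped do
not enter the denominator. A pair with zero co-aligned columns is reported
as missing (NaN), never as 0%.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core_types_io import Alignment, NucleotideSequence

__all__ = [
    "ScoringScheme",
    "IdentityMatrix",
    "needleman_wunsch",
    "align_family",
    "pairwise_identity",
    "alignment_score",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclasses.dataclass(frozen=True)
class ScoringScheme:
    """Substitution and affine gap parameters (all penalties positive)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 5.0
    gap_extend: float = 1.0

    def matrix(self) -> np.ndarray:
        m = np.full((5, 5), self.mismatch)
        np.fill_diagonal(m, self.match)
        # N scores 0 against everything (ambiguity carries no signal)
        m[4, :] = 0.0
        m[:, 4] = 0.0
        return m


@dataclasses.dataclass
class IdentityMatrix:
    """Square percent-identity matrix over family members (0-100, NaN=missing)."""

    ids: list[str]
    values: np.ndarray

    @property
    def min_off_diagonal(self) -> float:
        return float(np.nanmin(self._off_diag()))

    @property
    def max_off_diagonal(self) -> float:
        return float(np.nanmax(self._off_diag()))

    def _off_diag(self) -> np.ndarray:
        v = self.values.copy().astype(float)
        np.fill_diagonal(v, np.nan)
        return v

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# Profiles

def _seq_to_profile(seq: str) -> np.ndarray:
    """A profile is (n_cols, 6): counts of A,C,G,T,N,- per column."""
    prof = np.zeros((len(seq), 6))
    for j, c in enumerate(seq):
        prof[j, "ACGTN-".index(c)] = 1.0
    return prof


def _column_scores(pa: np.ndarray, pb: np.ndarray, sub: np.ndarray) -> np.ndarray:
    """Mean substitution score between residue pairs of two profile columns.

    Gap symbols in a profile column are excluded from the average (standard
    profile-sum-of-pairs with gaps ignored); an all-gap column scores 0.
    """
    ra, rb = pa[:, :5], pb[:, :5]
    na = ra.sum(axis=1, keepdims=True)
    nb = rb.sum(axis=1, keepdims=True)
    denom = na @ nb.T
    raw = ra @ sub @ rb.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, raw / np.maximum(denom, 1e-12), 0.0)
    return out


# ---------------------------------------------------------------------------
# Pairwise / profile DP (Gotoh, affine gaps)

_NEG = -1e30


def _gotoh(score_mat: np.ndarray, gap_open: float, gap_extend: float
           ) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global DP over a precomputed (la, lb) column-score matrix.

    Returns optimal score and a traceback path of moves, each move one of
    (1,1) diagonal, (1,0) gap in B, (0,1) gap in A. Traceback tie-break:
    diagonal first, then gap-in-B (consume A), then gap-in-A.
    """
    la, lb = score_mat.shape
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (A consumed)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A (B consumed)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        srow = score_mat[i - 1]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, lb + 1):
            best_prev = Mp[j - 1]
            if Xp[j - 1] > best_prev:
                best_prev = Xp[j - 1]
            if Yp[j - 1] > best_prev:
                best_prev = Yp[j - 1]
            Mi[j] = best_prev + srow[j - 1]
            xo = Mp[j] - gap_open
            xe = Xp[j] - gap_extend
            yo2 = Yp[j] - gap_open
            Xi[j] = xo if xo >= xe else xe
            if yo2 > Xi[j]:
                Xi[j] = yo2
            yo = Mi[j - 1] - gap_open
            ye = Yi[j - 1] - gap_extend
            xo2 = Xi[j - 1] - gap_open
            Yi[j] = yo if yo >= ye else ye
            if xo2 > Yi[j]:
                Yi[j] = xo2

    # traceback
    i, j = la, lb
    vals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(vals))  # 0=M, 1=X, 2=Y; argmax prefers M on ties
    total = float(vals[state])
    path: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                state = 2 if i == 0 else 1
                continue
            path.append((1, 1))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            target = M[i, j] - score_mat[i - 1, j - 1]
            state = _match_state(prev, target)
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((1, 0))
            if i == 1 and j == 0:
                i = 0
                break
            open_v = M[i - 1, j] - gap_open
            ext_v = X[i - 1, j] - gap_extend
            cross = Y[i - 1, j] - gap_open
            target = X[i, j]
            if abs(open_v - target) < 1e-9:
                state = 0
            elif abs(ext_v - target) < 1e-9:
                state = 1
            else:
                assert abs(cross - target) < 1e-9
                state = 2
            i -= 1
        else:
            path.append((0, 1))
            if j == 1 and i == 0:
                j = 0
                break
            open_v = M[i, j - 1] - gap_open
            ext_v = Y[i, j - 1] - gap_extend
            cross = X[i, j - 1] - gap_open
            target = Y[i, j]
            if abs(open_v - target) < 1e-9:
                state = 0
            elif abs(ext_v - target) < 1e-9:
                state = 2
            else:
                assert abs(cross - target) < 1e-9
                state = 1
            j -= 1
    path.reverse()
    return total, path


def _match_state(prev: tuple[float, float, float], target: float) -> int:
    # diagonal step came from the best of M/X/Y; prefer M, then X, then Y
    for s in (0, 1, 2):
        if abs(prev[s] - target) < 1e-9:
            return s
    return int(np.argmax(prev))


def needleman_wunsch(a: str, b: str, scoring: ScoringScheme | None = None
                     ) -> tuple[str, str, float]:
    """Global pairwise alignment of two sequences; returns gapped strings
    and the optimal affine-gap score."""
    scoring = scoring or ScoringScheme()
    pa, pb = _seq_to_profile(a.upper()), _seq_to_profile(b.upper())
    smat = _column_scores(pa, pb, scoring.matrix())
    score, path = _gotoh(smat, scoring.gap_open, scoring.gap_extend)
    ga, gb = [], []
    i = j = 0
    for di, dj in path:
        ga.append(a[i] if di else "-")
        gb.append(b[j] if dj else "-")
        i, j = i + di, j + dj
    return "".join(ga), "".join(gb), score


def alignment_score(aln: Alignment, scoring: ScoringScheme | None = None) -> float:
    """Sum-of-pairs affine-gap score of an existing alignment (diagnostic)."""
    scoring = scoring or ScoringScheme()
    sub = scoring.matrix()
    total = 0.0
    for (ia, sa), (ib, sb) in itertools.combinations(aln.records, 2):
        total += _pair_score(sa, sb, sub, scoring)
    return total


def _pair_score(sa: str, sb: str, sub: np.ndarray, scoring: ScoringScheme) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(sa, sb):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            score -= scoring.gap_extend if in_gap_a else scoring.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= scoring.gap_extend if in_gap_b else scoring.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += sub[_idx6(ca), _idx6(cb)]
            in_gap_a = in_gap_b = False
    return score


def _idx6(c: str) -> int:
    return "ACGTN-".index(c)


# ---------------------------------------------------------------------------
# Guide tree and progressive merge

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fractional shared k-mer count (common alignment-free distance)."""
    ka: dict[str, int] = {}
    kb: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        ka[a[i:i + k]] = ka.get(a[i:i + k], 0) + 1
    for i in range(len(b) - k + 1):
        kb[b[i:i + k]] = kb.get(b[i:i + k], 0) + 1
    shared = sum(min(ka[w], kb[w]) for w in ka.keys() & kb.keys())
    denom = min(len(a), len(b)) - k + 1
    if denom <= 0:
        return 1.0
    return 1.0 - shared / denom


def align_family(seqs: list[NucleotideSequence],
                 gap_open: float = 5.0,
                 gap_extend: float = 1.0,
                 match: float = 1.0,
                 mismatch: float = -1.0,
                 refine_rounds: int = 2) -> Alignment:
    """Progressive global alignment of a sequence family.

    A UPGMA (average-linkage) tree over pairwise k-mer distances fixes the
    merge order; each merge aligns two sub-alignments with the affine-gap
    profile DP. The progressive pass is followed by refine_rounds of
    leave-one-out refinement (each row realigned against the profile of the
    others), which corrects single-row drift that a greedy progressive merge
    cannot revisit. Deterministic for fixed inputs and parameters.
    """
    if len(seqs) < 2:
        raise ValueError("align_family needs at least 2 sequences")
    for s in seqs:
        if len(s) < 1:
            raise ValueError(f"empty sequence {s.id!r}")
    scoring = ScoringScheme(match, mismatch, gap_open, gap_extend)
    sub = scoring.matrix()

    if len(seqs) == 2:
        ga, gb, _ = needleman_wunsch(seqs[0].residues, seqs[1].residues, scoring)
        return Alignment([(seqs[0].id, ga), (seqs[1].id, gb)])

    n = len(seqs)
    dvec = np.array([
        _kmer_distance(seqs[i].residues, seqs[j].residues)
        for i in range(n) for j in range(i + 1, n)
    ])
    merges = linkage(dvec, method="average")

    # Each cluster holds (ids, gapped rows) in input order within the cluster.
    clusters: dict[int, list[tuple[str, str]]] = {
        i: [(seqs[i].id, seqs[i].residues)] for i in range(n)
    }
    nxt = n
    for a_idx, b_idx, _, _ in merges:
        left = clusters.pop(int(a_idx))
        right = clusters.pop(int(b_idx))
        clusters[nxt] = _merge(left, right, sub, scoring)
        nxt += 1
    (final,) = clusters.values()
    order = {s.id: k for k, s in enumerate(seqs)}
    final.sort(key=lambda rec: order[rec[0]])
    for _ in range(max(0, refine_rounds)):
        final = _refine_rows(final, sub, scoring)
    return Alignment(final)


def _refine_rows(rows: list[tuple[str, str]], sub: np.ndarray,
                 scoring: ScoringScheme) -> list[tuple[str, str]]:
    """One leave-one-out refinement sweep: realign each row to the profile
    of the remaining rows, keeping the existing columns (gap costs in
    columns that are mostly gaps elsewhere are proportionally discounted).
    All-gap columns are dropped afterwards."""
    current = list(rows)
    for k in range(len(current)):
        others = [s for i, (_, s) in enumerate(current) if i != k]
        rid, gapped = current[k]
        current[k] = (rid, _realign_row(gapped.replace("-", ""), others, sub,
                                        scoring))
    # drop columns that became all-gap
    keep = [j for j in range(len(current[0][1]))
            if any(s[j] != "-" for _, s in current)]
    return [(rid, "".join(s[j] for j in keep)) for rid, s in current]


def _realign_row(residues: str, others: list[str], sub: np.ndarray,
                 scoring: ScoringScheme) -> str:
    """Map a row's residues monotonically onto the fixed columns of the
    others' profile (residue-in-column or gap-in-column moves only).

    Gap costs here are linear and column-weighted (cheaper where the others
    are gapped too): the number of gapped bases per row is fixed by the
    column count, so linear costs make gap *placement* depend only on
    profile agreement. An affine merge bonus would instead pull nearby gaps
    together across short conserved anchors.
    """
    prof = _group_profile(others)
    n_cols = prof.shape[0]
    m = len(residues)
    if m > n_cols:
        raise ValueError("row longer than profile during refinement")
    w = prof[:, :5].sum(axis=1) / max(1, len(others))  # non-gap weight
    open_j = scoring.gap_extend * w
    ext_j = scoring.gap_extend * w
    rp = _seq_to_profile(residues)
    smat = _column_scores(rp, prof, sub)  # (m, n_cols)

    A = np.full((m + 1, n_cols + 1), _NEG)   # last move: residue in column
    G = np.full((m + 1, n_cols + 1), _NEG)   # last move: gap in column
    A[0, 0] = 0.0
    for j in range(1, n_cols + 1):
        G[0, j] = max(A[0, j - 1] - open_j[j - 1], G[0, j - 1] - ext_j[j - 1])
    for i in range(1, m + 1):
        Ai, Gi, Ap, Gp = A[i], G[i], A[i - 1], G[i - 1]
        srow = smat[i - 1]
        for j in range(1, n_cols + 1):
            d = Ap[j - 1] if Ap[j - 1] >= Gp[j - 1] else Gp[j - 1]
            Ai[j] = d + srow[j - 1]
            go = Ai[j - 1] - open_j[j - 1]
            ge = Gi[j - 1] - ext_j[j - 1]
            Gi[j] = go if go >= ge else ge
    # traceback, preferring residue placement on ties
    out = []
    i, j = m, n_cols
    state = 0 if A[i, j] >= G[i, j] else 1
    while j > 0:
        if state == 0:
            out.append(residues[i - 1])
            state = 0 if A[i - 1, j - 1] >= G[i - 1, j - 1] else 1
            i, j = i - 1, j - 1
        else:
            out.append("-")
            go = A[i, j - 1] - open_j[j - 1]
            ge = G[i, j - 1] - ext_j[j - 1]
            state = 0 if go >= ge else 1
            j -= 1
    assert i == 0
    out.reverse()
    return "".join(out)


def _merge(left: list[tuple[str, str]], right: list[tuple[str, str]],
           sub: np.ndarray, scoring: ScoringScheme) -> list[tuple[str, str]]:
    pa = _group_profile([s for _, s in left])
    pb = _group_profile([s for _, s in right])
    smat = _column_scores(pa, pb, sub)
    _, path = _gotoh(smat, scoring.gap_open, scoring.gap_extend)
    out_left = [[] for _ in left]
    out_right = [[] for _ in right]
    i = j = 0
    for di, dj in path:
        for r, (_, s) in enumerate(left):
            out_left[r].append(s[i] if di else "-")
        for r, (_, s) in enumerate(right):
            out_right[r].append(s[j] if dj else "-")
        i, j = i + di, j + dj
    merged = [(rid, "".join(row)) for (rid, _), row in zip(left, out_left)]
    merged += [(rid, "".join(row)) for (rid, _), row in zip(right, out_right)]
    return merged


def _group_profile(rows: list[str]) -> np.ndarray:
    prof = np.zeros((len(rows[0]), 6))
    for s in rows:
        for j, c in enumerate(s):
            prof[j, _idx6(c)] += 1.0
    return prof


# ---------------------------------------------------------------------------
# Identity

def pairwise_identity(aln: Alignment) -> IdentityMatrix:
    """Percent identity over co-aligned (both non-gap) columns for every pair.

    identity(i,j) = 100 * (# columns equal and both non-gap)
                        / (# columns both non-gap)
    Pairs with no co-aligned columns are NaN (missing), never 0.
    """
    rows = np.array([list(s) for _, s in aln.records])
    n = len(aln.records)
    values = np.full((n, n), 100.0)
    nongap = rows != "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            co = int(both.sum())
            if co == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            same = int(((rows[i] == rows[j]) & both).sum())
            values[i, j] = values[j, i] = 100.0 * same / co
    return IdentityMatrix(aln.ids, values)
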