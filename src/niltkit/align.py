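"""Pairwise and multiple alignment, identity/similarity, Shannon entropy.

Pairwise alignment is optimal global (Needleman-Wunsch) with affine gaps,
BLOSUM62 scores for proteins and +5/−4 for nucleotides (gap open 10, extend
0.5 — Clustal-style defaults).  Percent identity is computed over
residue-residue columns only (gap-excluded denominator); percent similarity
additionally counts positive-scoring substitutions.

The multiple aligner is a progressive profile aligner: a UPGMA guide tree on
pairwise identity distances, then profile-profile merges with sum-of-pairs
column scores and a linear gap penalty (two-sequence problems are solved with
the optimal affine-gap aligner directly).  No iterative refinement is
attempted, and bit-exact equivalence with any particular aligner is not a
goal.

Per-column variability is the Shannon entropy H = −Σ f·log2 f over the amino
acids observed in the column, gaps excluded from the frequencies; columns
with H above a threshold (default 1.3 bits) are called variable.  All-gap
columns have undefined entropy and are never called variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import NamedSequence

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
#: Linear gap penalty per column used by the profile aligner.
PROFILE_GAP = 8.0

MAX_ENTROPY_AA = float(np.log2(20))


def _matrix_for(alphabet: str):
    if alphabet == "aa":
        return substitution_matrices.load("BLOSUM62")
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 5.0 if a == b else -4.0
    return m


@dataclass
class PairwiseAlignment:
    """An optimal global alignment with identity/similarity percentages."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float


def global_align(a, b, alphabet: str | None = None, matrix=None,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch affine-gap alignment of two sequences."""
    sa = a.seq if isinstance(a, NamedSequence) else str(a)
    sb = b.seq if isinstance(b, NamedSequence) else str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if alphabet is None:
        alphabet = a.alphabet if isinstance(a, NamedSequence) else "aa"
    subst = matrix if matrix is not None else _matrix_for(alphabet)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subst
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    ident, simil, cols = 0, 0, 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            ident += 1
            simil += 1
        else:
            try:
                if subst[x, y] > 0:
                    simil += 1
            except (KeyError, IndexError):
                pass
    identity = 100.0 * ident / cols if cols else 0.0
    similarity = 100.0 * simil / cols if cols else 0.0
    return PairwiseAlignment(ga, gb, float(aln.score), identity, similarity)


@dataclass
class IdentityMatrix:
    """All-pairs identity and similarity percentages.

    ``table()`` renders the conventional combined layout: identity in the
    upper triangle, similarity in the lower, blank diagonal.
    """

    labels: list
    identity: pd.DataFrame
    similarity: pd.DataFrame

    def table(self) -> pd.DataFrame:
        n = len(self.labels)
        out = pd.DataFrame("", index=self.labels, columns=self.labels, dtype=object)
        for i in range(n):
            for j in range(n):
                if i < j:
                    out.iat[i, j] = round(self.identity.iat[i, j])
                elif i > j:
                    out.iat[i, j] = round(self.similarity.iat[i, j])
        return out


def identity_similarity_matrix(seqs, alphabet: str | None = None,
                               **align_kw) -> IdentityMatrix:
    """Pairwise-align all unordered pairs and tabulate identity/similarity."""
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = [s.id if isinstance(s, NamedSequence) else f"seq{i}"
              for i, s in enumerate(seqs)]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {', '.join(dup)}")
    n = len(seqs)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], alphabet=alphabet, **align_kw)
            ident[i, j] = ident[j, i] = aln.identity_pct
            simil[i, j] = simil[j, i] = aln.similarity_pct
    return IdentityMatrix(
        labels,
        pd.DataFrame(ident, index=labels, columns=labels),
        pd.DataFrame(simil, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def _profile_align(rows_a: list[str], rows_b: list[str], subst) -> tuple[list[str], list[str]]:
    """Align two profiles by Needleman-Wunsch with sum-of-pairs column scores
    (gap symbols contribute 0) and a linear gap penalty per column."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    cols_a = [[r[i] for r in rows_a] for i in range(la)]
    cols_b = [[r[j] for r in rows_b] for j in range(lb)]

    def colscore(ca, cb):
        tot, k = 0.0, 0
        for x in ca:
            for y in cb:
                k += 1
                if x != "-" and y != "-":
                    try:
                        tot += subst[x, y]
                    except (KeyError, IndexError):
                        pass
        return tot / k if k else 0.0

    g = PROFILE_GAP
    score = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = -g * np.arange(1, la + 1)
    score[0, 1:] = -g * np.arange(1, lb + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            d = score[i - 1, j - 1] + colscore(cols_a[i - 1], cols_b[j - 1])
            u = score[i - 1, j] - g
            l = score[i, j - 1] - g
            best = max(d, u, l)
            score[i, j] = best
            ptr[i, j] = 0 if best == d else (1 if best == u else 2)
    # traceback
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            i, j = i - 1, j - 1
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
        elif p == 1 and i > 0:
            i -= 1
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k in range(len(rows_b)):
                out_b[k].append("-")
        else:
            j -= 1
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def progressive_msa(seqs, alphabet: str | None = None) -> list[NamedSequence]:
    """Progressive multiple alignment along a UPGMA guide tree.

    Accepts :class:`NamedSequence` records or plain strings; returns aligned
    records of equal length whose ungapped sequences equal the inputs.
    """
    records = [
        s if isinstance(s, NamedSequence) else NamedSequence(f"seq{i}", str(s), "aa")
        for i, s in enumerate(seqs)
    ]
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    if alphabet is None:
        alphabet = records[0].alphabet
    if len(records) == 2:
        aln = global_align(records[0], records[1], alphabet=alphabet)
        return [
            NamedSequence(records[0].id, aln.aligned_a, alphabet),
            NamedSequence(records[1].id, aln.aligned_b, alphabet),
        ]
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], alphabet=alphabet)
            dist[i, j] = dist[j, i] = 1.0 - aln.identity_pct / 100.0
    guide = linkage(squareform(dist, checks=False), method="average")
    subst = _matrix_for(alphabet)
    # each cluster: (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].seq]) for i in range(n)
    }
    nxt = n
    for a, b, _, _ in guide:
        ia, ib = int(a), int(b)
        mem_a, rows_a = clusters.pop(ia)
        mem_b, rows_b = clusters.pop(ib)
        rows_a, rows_b = _profile_align(rows_a, rows_b, subst)
        clusters[nxt] = (mem_a + mem_b, rows_a + rows_b)
        nxt += 1
    members, rows = clusters.popitem()[1]
    ordered = [None] * n
    for idx, row in zip(members, rows):
        ordered[idx] = NamedSequence(records[idx].id, row, alphabet)
    return ordered


# ---------------------------------------------------------------------------
# Shannon entropy variability
# ---------------------------------------------------------------------------

@dataclass
class EntropyProfile:
    """Per-column Shannon entropy (bits) of an alignment.

    ``H`` is NaN for all-gap columns; ``variable_mask`` is True exactly where
    H exceeds the threshold (never for undefined columns).
    """

    H: np.ndarray
    variable_mask: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(1, len(self.H) + 1),
            "H": self.H,
            "variable": self.variable_mask,
        })


def entropy_profile(msa, threshold: float = 1.3) -> EntropyProfile:
    """Per-column Shannon entropy of an MSA, gaps excluded from frequencies."""
    rows = [s.seq if isinstance(s, NamedSequence) else str(s) for s in msa]
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    ncol = len(rows[0])
    H = np.empty(ncol)
    for j in range(ncol):
        col = [r[j] for r in rows if r[j] != "-"]
        if not col:
            H[j] = np.nan
            continue
        _, counts = np.unique(col, return_counts=True)
        f = counts / counts.sum()
        H[j] = float(-(f * np.log2(f)).sum()) + 0.0
    mask = np.zeros(ncol, dtype=bool)
    defined = ~np.isnan(H)
    mask[defined] = H[defined] > threshold
    return EntropyProfile(H, mask, threshold)
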