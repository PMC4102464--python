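"""Contig-to-gene assignment by score-thresholded reciprocal best hits.

An ungapped seed-and-extend aligner (word seeding, per-diagonal maximal
segment) stands in for a nucleotide BLAST search; significance uses
Karlin-Altschul statistics (E = K*m*n*exp(-lambda*S)) with lambda solved from
the base composition and K from the standard lattice approximation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

DEFAULT_WORD_SIZE = 11
DEFAULT_EVALUE_THRESHOLD = 1e-10


@dataclass(frozen=True)
class PairwiseHit:
    """An ungapped local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    score: int
    identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError("identity out of [0, 1]")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if (self.q_end - self.q_start) != (self.s_end - self.s_start):
            raise ValueError("ungapped hit intervals must have equal length")


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scoring with derived Karlin-Altschul parameters."""

    match: int = 1
    mismatch: int = 2  # penalty magnitude; applied as -mismatch
    lam: float = 0.0
    K: float = 0.0
    db_len: int = 0

    @classmethod
    def create(
        cls,
        match: int = 1,
        mismatch: int = 2,
        base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        db_len: int = 0,
    ) -> "ScoringScheme":
        lam, K = compute_lambda_K(match, mismatch, base_composition)
        return cls(match=match, mismatch=mismatch, lam=lam, K=K, db_len=db_len)


def compute_lambda_K(
    match: int,
    mismatch: int,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[float, float]:
    """Karlin-Altschul (lambda, K) for ungapped match/mismatch scoring.

    lambda solves sum_ij p_i p_j exp(lambda*s(i,j)) = 1 by bracketed
    root-finding; K uses the standard lattice-case series approximation.
    Raises if the expected score per aligned pair is non-negative (the
    statistics are undefined in that regime).
    """
    p = np.asarray(base_composition, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base composition must sum to 1")
    if match <= 0 or mismatch <= 0:
        raise ValueError("match reward and mismatch penalty must be positive")
    q_match = float(np.sum(p * p))  # P(two random letters agree)
    q_mis = 1.0 - q_match
    expected = q_match * match - q_mis * mismatch
    if expected >= 0:
        raise ValueError(
            f"expected score per pair is {expected:.4f} >= 0; "
            "Karlin-Altschul statistics undefined"
        )

    def f(lam: float) -> float:
        return q_match * math.exp(lam * match) + q_mis * math.exp(-lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-9, hi, xtol=1e-14, rtol=1e-15))
    assert abs(f(lam)) < 1e-10

    # lattice-case K: delta*exp(-2*Sigma) / ((1 - exp(-lam*delta)) * E[S e^{lam S}])
    # (checked against the published blastn constants: +1/-2 -> 0.621,
    #  +1/-1 -> 0.333, and against Monte-Carlo maximal-segment tails)
    delta = math.gcd(match, mismatch)
    e_s_exp = q_match * match * math.exp(lam * match) - q_mis * mismatch * math.exp(
        -lam * mismatch
    )
    # distribution of the k-step score sum via convolution on a score lattice
    lo_step, hi_step = -mismatch, match
    dist = np.zeros(hi_step - lo_step + 1)
    dist[0] = q_mis  # score -mismatch
    dist[-1] = q_match  # score +match
    step = dist.copy()
    sigma = 0.0
    cur = step.copy()
    cur_lo = lo_step
    for k in range(1, 400):
        scores = np.arange(cur_lo, cur_lo + len(cur))
        neg = scores < 0
        term = float(cur[~neg].sum()) + float(
            np.sum(cur[neg] * np.exp(lam * scores[neg]))
        )
        sigma += term / k
        if term / k < 1e-14:
            break
        cur = np.convolve(cur, step)
        cur_lo += lo_step
    K = delta * math.exp(-2.0 * sigma) / ((1.0 - math.exp(-lam * delta)) * e_s_exp)
    return lam, K


def evalue(score: float, query_len: int, db_len: int, lam: float, K: float) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return K * query_len * db_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# Seed-and-extend search
# ---------------------------------------------------------------------------


def _diagonal_best_segment(
    query: str, subject: str, diag: int, match: int, mismatch: int
) -> tuple[int, int, int, int] | None:
    """Maximal-scoring contiguous segment on diagonal q_i - s_j = diag.

    Returns (score, q_start, q_end, n_matches) or None if empty.  N (and any
    non-ACGT character) scores as a mismatch.
    """
    i0 = max(0, diag)
    i1 = min(len(query), len(subject) + diag)
    if i0 >= i1:
        return None
    best = None  # (score, q_start, q_end)
    run_score = 0
    run_start = i0
    best_score = -1
    best_bounds = (i0, i0)
    for i in range(i0, i1):
        qc, sc = query[i], subject[i - diag]
        s = match if (qc == sc and qc in "ACGT") else -mismatch
        if run_score <= 0:
            run_score = s
            run_start = i
        else:
            run_score += s
        if run_score > best_score:
            best_score = run_score
            best_bounds = (run_start, i + 1)
    if best_score < 0:
        return None
    qs, qe = best_bounds
    n_match = sum(
        1
        for i in range(qs, qe)
        if query[i] == subject[i - diag] and query[i] in "ACGT"
    )
    return best_score, qs, qe, n_match


def _word_index(seq: str, word_size: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - word_size + 1):
        w = seq[i : i + word_size]
        if set(w) <= set("ACGT"):
            idx[w].append(i)
    return idx


def seed_and_extend(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    scheme: ScoringScheme,
    word_size: int = DEFAULT_WORD_SIZE,
) -> PairwiseHit | None:
    """Best ungapped hit between two sequences, or None if no word is shared.

    All diagonals sharing at least one exact word are scanned for their
    maximal-scoring contiguous segment; the best segment over all such
    diagonals is returned.
    """
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    if not query or not subject:
        raise ValueError("empty sequence")
    sub_idx = _word_index(subject, word_size)
    diags: set[int] = set()
    for i in range(len(query) - word_size + 1):
        w = query[i : i + word_size]
        for j in sub_idx.get(w, ()):
            diags.add(i - j)
    return _best_hit_on_diagonals(
        query_id, query, subject_id, subject, sorted(diags), scheme
    )


def _best_hit_on_diagonals(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    diags: Sequence[int],
    scheme: ScoringScheme,
) -> PairwiseHit | None:
    best: tuple[int, int, int, int, int] | None = None
    for d in diags:
        seg = _diagonal_best_segment(query, subject, d, scheme.match, scheme.mismatch)
        if seg is None:
            continue
        score, qs, qe, n_match = seg
        cand = (score, -d, qs, qe, n_match)  # deterministic tie-break on diagonal
        if best is None or cand > best:
            best = cand
            best_d = d
    if best is None:
        return None
    score, _, qs, qe, n_match = best
    db_len = scheme.db_len if scheme.db_len > 0 else len(subject)
    return PairwiseHit(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        identity=n_match / (qe - qs),
        q_start=qs,
        q_end=qe,
        s_start=qs - best_d,
        s_end=qe - best_d,
        evalue=evalue(score, len(query), db_len, scheme.lam, scheme.K),
    )


def best_hits(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    word_size: int = DEFAULT_WORD_SIZE,
) -> dict[str, PairwiseHit]:
    """Best hit of each query against a subject database.

    The database is word-indexed once; per query, all (subject, diagonal)
    pairs sharing a word are scanned.  Ties between subjects are broken by
    (higher score, lower E-value, lexicographic subject id).
    """
    db_len = sum(len(s) for s in subjects.values())
    if scheme is None:
        scheme = ScoringScheme.create(db_len=db_len)
    elif scheme.db_len == 0:
        scheme = ScoringScheme(scheme.match, scheme.mismatch, scheme.lam, scheme.K, db_len)
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for sid, seq in subjects.items():
        for i in range(len(seq) - word_size + 1):
            w = seq[i : i + word_size]
            if set(w) <= set("ACGT"):
                index[w].append((sid, i))
    out: dict[str, PairwiseHit] = {}
    for qid, qseq in queries.items():
        cand: dict[str, set[int]] = defaultdict(set)
        for i in range(len(qseq) - word_size + 1):
            for sid, j in index.get(qseq[i : i + word_size], ()):
                cand[sid].add(i - j)
        best: PairwiseHit | None = None
        for sid in sorted(cand):
            hit = _best_hit_on_diagonals(
                qid, qseq, sid, subjects[sid], sorted(cand[sid]), scheme
            )
            if hit is None:
                continue
            if best is None or (hit.score, -hit.evalue, _neg_lex(hit.subject_id)) > (
                best.score,
                -best.evalue,
                _neg_lex(best.subject_id),
            ):
                best = hit
        if best is not None:
            out[qid] = best
    return out


class _neg_lex(str):
    """Orders lexicographically smaller strings as 'greater' for tie-breaks."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str(self) > str(other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str(self) < str(other)


def reciprocal_best_hit_filter(
    forward: Mapping[str, PairwiseHit],
    reverse: Mapping[str, PairwiseHit],
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> dict[str, list[str]]:
    """Ortholog assignment gene -> contigs from two best-hit tables.

    A contig is retained iff its best subject R satisfies E < threshold in
    both directions and R's best query is that contig.  Everything else is
    dropped.
    """
    assignment: dict[str, list[str]] = defaultdict(list)
    for contig_id, fwd in forward.items():
        if fwd.evalue >= threshold:
            continue
        rev = reverse.get(fwd.subject_id)
        if rev is None or rev.evalue >= threshold:
            continue
        if rev.subject_id != contig_id:
            continue
        assignment[fwd.subject_id].append(contig_id)
    return {g: sorted(cs) for g, cs in sorted(assignment.items())}


def hits_to_table(hits: Mapping[str, PairwiseHit]):
    """Hit table in blast outfmt-6-like column order (as a DataFrame)."""
    import pandas as pd

    rows = [
        (
            h.query_id,
            h.subject_id,
            h.score,
            round(h.identity, 4),
            h.q_start,
            h.q_end,
            h.s_start,
            h.s_end,
            h.evalue,
        )
        for h in hits.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "score", "identity",
            "q_start", "q_end", "s_start", "s_end", "evalue",
        ],
    )
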