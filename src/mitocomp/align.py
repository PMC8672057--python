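"""Pairwise local alignment (HSPs) and the identity definitions.

Two identity notions are used downstream and must not be conflated:

* ``hsp_identity`` — identical columns / alignment columns of ONE
  continuous local alignment.  The similarity network takes this index
  from the *longest* HSP of a genome pair.
* ``clustering_identity`` — identical columns of the best local
  alignment divided by the length of the SHORTER sequence (the global
  identity convention of greedy incremental clusterers such as CD-HIT).

For pairs where both sequences are at most ``exact_size_limit`` (2,000 bp
by default) the alignment is an exact affine-gap Smith–Waterman
(delegated to Biopython's C PairwiseAligner).  Longer pairs go through a
seed-and-extend path: exact 11-mer seeds, diagonal-band grouping,
collinear anchor chaining with exact alignment of the inter-anchor
segments, and ungapped X-drop end extension.  A gap of length L scores
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .annotation_io import reverse_complement


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap parameters (BLASTn-like analog knobs)."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass
class HSP:
    """One continuous local alignment, 0-based half-open coordinates.

    When ``strand`` is ``"-"`` the b coordinates refer to the reverse
    complement of the original b sequence.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aln_len: int
    matches: int
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        assert 0 <= self.matches <= self.aln_len


def hsp_identity(h: HSP) -> float:
    """Identical columns over alignment columns of one HSP."""
    if h.aln_len <= 0:
        raise ValueError("identity of an empty alignment is undefined")
    return h.matches / h.aln_len


def _aligner(s: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    # Biopython charges open_gap_score on the first gap position, so a
    # length-L gap costs open+ext + (L-1)*ext == gap_open + L*gap_extend.
    return Align.PairwiseAligner(
        mode=mode,
        match_score=s.match,
        mismatch_score=s.mismatch,
        open_gap_score=s.gap_open + s.gap_extend,
        extend_gap_score=s.gap_extend,
    )


def _walk_alignment(aln, a: str, b: str) -> tuple[int, int, tuple[int, int, int, int]]:
    """(matches, columns, coords) of a Biopython alignment."""
    ca, cb = aln.coordinates
    matches = 0
    cols = 0
    for k in range(len(ca) - 1):
        da = ca[k + 1] - ca[k]
        db = cb[k + 1] - cb[k]
        if da > 0 and db > 0:
            sa = a[ca[k] : ca[k + 1]]
            sb = b[cb[k] : cb[k + 1]]
            matches += sum(x == y for x, y in zip(sa, sb))
            cols += da
        else:
            cols += max(da, db)
    return matches, cols, (int(ca[0]), int(ca[-1]), int(cb[0]), int(cb[-1]))


def _exact_local(a: str, b: str, s: ScoringScheme) -> list[HSP]:
    alns = _aligner(s, "local").align(a, b)
    try:
        aln = alns[0]
    except IndexError:
        return []
    if aln.score <= 0:
        return []
    matches, cols, (a0, a1, b0, b1) = _walk_alignment(aln, a, b)
    if cols == 0:
        return []
    return [HSP(a0, a1, b0, b1, cols, matches, float(aln.score))]


# ---------------------------------------------------------------------------
# seed-and-extend path


_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _base in enumerate(b"ACGT"):
    _ENCODE_TABLE[_base] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int = 11) -> np.ndarray:
    """Integer codes of all k-mers (rolling 2-bit packing); k-mers
    containing non-ACGT bases are coded as -1."""
    arr = _encode(seq)
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        window = arr[t : t + n]
        codes = (codes << 2) | np.minimum(window, 3).astype(np.int64)
        bad |= window > 3
    codes[bad] = -1
    return codes


def _seeds(a: str, b: str, k: int, max_occ: int) -> list[tuple[int, int]]:
    codes_a = kmer_codes(a, k)
    codes_b = kmer_codes(b, k)
    if codes_a.size == 0 or codes_b.size == 0:
        return []
    order = np.argsort(codes_a, kind="stable")
    sorted_a = codes_a[order]
    left = np.searchsorted(sorted_a, codes_b, "left")
    right = np.searchsorted(sorted_a, codes_b, "right")
    counts = right - left
    hits = np.nonzero((counts > 0) & (counts <= max_occ) & (codes_b >= 0))[0]
    seeds: list[tuple[int, int]] = []
    for j in hits:
        for idx in range(left[j], right[j]):
            seeds.append((int(order[idx]), int(j)))
    return seeds


def _group_seeds(
    seeds: list[tuple[int, int]], band: int, max_i_gap: int
) -> list[list[tuple[int, int]]]:
    """Group seeds into diagonal bands, splitting on large positional gaps."""
    by_diag = sorted(seeds, key=lambda ij: (ij[0] - ij[1], ij[0]))
    bands: list[list[tuple[int, int]]] = []
    last_d = None
    for i, j in by_diag:
        d = i - j
        if last_d is None or d - last_d > band:
            bands.append([])
        bands[-1].append((i, j))
        last_d = d
    groups: list[list[tuple[int, int]]] = []
    for bandseeds in bands:
        bandseeds.sort()
        cur: list[tuple[int, int]] = []
        for i, j in bandseeds:
            if cur and i - cur[-1][0] > max_i_gap:
                groups.append(cur)
                cur = []
            cur.append((i, j))
        if cur:
            groups.append(cur)
    return groups


def _anchors(group: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Collapse same-diagonal consecutive seeds into maximal exact runs."""
    runs: list[tuple[int, int, int]] = []  # (i, j, length)
    for i, j in sorted(group, key=lambda ij: (ij[0] - ij[1], ij[0])):
        if runs:
            pi, pj, pl = runs[-1]
            if i - j == pi - pj and i <= pi + pl:
                runs[-1] = (pi, pj, max(pl, i + k - pi))
                continue
        runs.append((i, j, k))
    return runs


def _chain(
    anchors: list[tuple[int, int, int]], window: int = 64
) -> list[tuple[int, int, int]]:
    """Best collinear anchor chain (non-overlapping in both sequences).

    Windowed DP maximizing total anchored length with a penalty on
    diagonal jumps, so isolated spurious seeds sitting in the same
    diagonal band cannot hijack the chain.
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda t: (t[0], t[1]))
    n = len(anchors)
    best = [float(a[2]) for a in anchors]
    prev = [-1] * n
    for k in range(n):
        ik, jk, lk = anchors[k]
        dk = ik - jk
        for t in range(max(0, k - window), k):
            it, jt, lt = anchors[t]
            if it + lt <= ik and jt + lt <= jk:
                cand = best[t] + lk - 0.5 * abs(dk - (it - jt))
                if cand > best[k]:
                    best[k] = cand
                    prev[k] = t
    k = max(range(n), key=lambda idx: best[idx])
    chain: list[tuple[int, int, int]] = []
    while k != -1:
        chain.append(anchors[k])
        k = prev[k]
    chain.reverse()
    return chain


def _extend_ungapped(
    a: str, b: str, ai: int, bi: int, step: int, s: ScoringScheme, xdrop: float
) -> tuple[int, int, float]:
    """X-drop ungapped extension; returns (columns, matches, score) gained."""
    best = cur = 0.0
    best_k = best_m = m = 0
    k = 0
    while True:
        # (ai, bi) is the outermost column already in the HSP
        pa, pb = ai + step * (k + 1), bi + step * (k + 1)
        if not (0 <= pa < len(a) and 0 <= pb < len(b)):
            break
        if a[pa] == b[pb]:
            cur += s.match
            m += 1
        else:
            cur += s.mismatch
        k += 1
        if cur > best:
            best, best_k, best_m = cur, k, m
        if best - cur > xdrop:
            break
    return best_k, best_m, best


def _stitch_group(
    a: str,
    b: str,
    group: list[tuple[int, int]],
    s: ScoringScheme,
    k: int,
    gap_dp_limit: int,
    xdrop: float,
) -> list[HSP]:
    chain = _chain(_anchors(group, k))
    if not chain:
        return []
    glob = _aligner(s, "global")
    hsps: list[HSP] = []

    def flush(state):
        if state is None:
            return
        a0, b0, a1, b1, matches, cols, score = state
        lk, lm, ls = _extend_ungapped(a, b, a0, b0, -1, s, xdrop)
        rk, rm, rs = _extend_ungapped(a, b, a1 - 1, b1 - 1, +1, s, xdrop)
        hsps.append(
            HSP(
                a0 - lk,
                a1 + rk,
                b0 - lk,
                b1 + rk,
                cols + lk + rk,
                matches + lm + rm,
                score + ls + rs,
            )
        )

    state = None  # (a0, b0, a_end, b_end, matches, cols, score)
    for i, j, ln in chain:
        if state is None:
            state = (i, j, i + ln, j + ln, ln, ln, ln * s.match)
            continue
        a0, b0, ae, be, matches, cols, score = state
        ga, gb = a[ae:i], b[be:j]
        if max(len(ga), len(gb)) > gap_dp_limit:
            flush(state)  # segments too far apart: separate HSPs
            state = (i, j, i + ln, j + ln, ln, ln, ln * s.match)
            continue
        if not ga and not gb:
            gm, gc, gs = 0, 0, 0.0
        elif not ga or not gb:
            gap = max(len(ga), len(gb))
            gm, gc, gs = 0, gap, s.gap_open + gap * s.gap_extend
        elif len(ga) == 1 and len(gb) == 1:
            # single column: a match/mismatch beats paired gaps unless the
            # scheme says otherwise
            paired_gaps = 2 * (s.gap_open + s.gap_extend)
            if ga == gb:
                gm, gc, gs = 1, 1, s.match
            elif s.mismatch >= paired_gaps:
                gm, gc, gs = 0, 1, s.mismatch
            else:
                gm, gc, gs = 0, 2, paired_gaps
        else:
            aln = glob.align(ga, gb)[0]
            gm, gc, _ = _walk_alignment(aln, ga, gb)
            gs = float(aln.score)
        state = (
            a0,
            b0,
            i + ln,
            j + ln,
            matches + gm + ln,
            cols + gc + ln,
            score + gs + ln * s.match,
        )
    flush(state)
    return [h for h in hsps if h.score > 0]


def _window_hsp(
    a: str, b: str, group: list[tuple[int, int]], s: ScoringScheme, k: int, margin: int
) -> list[HSP]:
    a0 = max(0, min(i for i, _ in group) - margin)
    a1 = min(len(a), max(i for i, _ in group) + k + margin)
    b0 = max(0, min(j for _, j in group) - margin)
    b1 = min(len(b), max(j for _, j in group) + k + margin)
    out = []
    for h in _exact_local(a[a0:a1], b[b0:b1], s):
        out.append(
            HSP(
                h.a_start + a0,
                h.a_end + a0,
                h.b_start + b0,
                h.b_end + b0,
                h.aln_len,
                h.matches,
                h.score,
            )
        )
    return out


def _seeded_hsps(
    a: str,
    b: str,
    s: ScoringScheme,
    k: int = 11,
    band: int = 48,
    max_occ: int = 40,
    window_dp_limit: int = 500,
    gap_dp_limit: int = 500,
    margin: int = 60,
    xdrop: float = 20.0,
) -> list[HSP]:
    seeds = _seeds(a, b, k, max_occ)
    if not seeds:
        return []
    hsps: list[HSP] = []
    for group in _group_seeds(seeds, band, max_i_gap=3000):
        span_a = max(i for i, _ in group) - min(i for i, _ in group) + k + 2 * margin
        span_b = max(j for _, j in group) - min(j for _, j in group) + k + 2 * margin
        if span_a <= window_dp_limit and span_b <= window_dp_limit:
            hsps.extend(_window_hsp(a, b, group, s, k, margin))
        else:
            hsps.extend(_stitch_group(a, b, group, s, k, gap_dp_limit, xdrop))
    return hsps


def _dedupe(hsps: list[HSP]) -> list[HSP]:
    """Drop HSPs whose a-interval is mostly inside a longer kept HSP."""
    kept: list[HSP] = []
    for h in sorted(hsps, key=lambda h: (-h.aln_len, -h.matches, h.a_start)):
        redundant = False
        for g in kept:
            ov = min(h.a_end, g.a_end) - max(h.a_start, g.a_start)
            if ov > 0.5 * (h.a_end - h.a_start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def local_align(
    a: str,
    b: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    max_hsps: int = 25,
    method: str = "auto",
    exact_size_limit: int = 2000,
) -> list[HSP]:
    """Local alignments of a vs b, sorted by alignment length (desc).

    ``method`` is ``"exact"`` (full Smith-Waterman), ``"seed"``
    (seed-and-extend) or ``"auto"`` (exact when both sequences are at
    most ``exact_size_limit``).  Only the forward strand of ``b`` is
    searched; callers wanting both strands align against the reverse
    complement as well (see :func:`best_hsp`).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if method == "auto":
        method = (
            "exact"
            if max(len(a), len(b)) <= exact_size_limit
            else "seed"
        )
    if method == "exact":
        hsps = _exact_local(a, b, scoring)
    elif method == "seed":
        hsps = _dedupe(_seeded_hsps(a, b, scoring))
    else:
        raise ValueError(f"unknown method {method!r}")
    hsps.sort(key=lambda h: (-h.aln_len, -h.matches, h.a_start))
    return hsps[:max_hsps]


def best_hsp(
    a: str,
    b: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    rule: str = "longest",
    **kwargs,
) -> HSP | None:
    """Best HSP over both strands of b.

    ``rule`` is ``"longest"`` (maximal alignment length; ties broken by
    matches then by smaller a_start — the "longest continuous alignment"
    convention) or ``"best_score"``.
    """
    candidates: list[HSP] = []
    for strand, bseq in (("+", b), ("-", reverse_complement(b))):
        for h in local_align(a, bseq, scoring, **kwargs):
            h.strand = strand
            candidates.append(h)
    if not candidates:
        return None
    if rule == "longest":
        key = lambda h: (-h.aln_len, -h.matches, h.a_start)
    elif rule == "best_score":
        key = lambda h: (-h.score, -h.matches, h.a_start)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return sorted(candidates, key=key)[0]


def clustering_identity(
    a: str,
    b: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    early_exit: float | None = None,
    **kwargs,
) -> float:
    """Identical columns of the best local alignment over the shorter
    sequence length (both strands searched), capped at 1.0.

    When ``early_exit`` is given the reverse strand is skipped if the
    forward strand already reaches that identity (a threshold-decision
    shortcut for greedy clustering).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    min_len = min(len(a), len(b))
    best = 0
    for bseq in (b, reverse_complement(b)):
        for h in local_align(a, bseq, scoring, **kwargs):
            best = max(best, h.matches)
        if early_exit is not None and best / min_len >= early_exit:
            break
    return min(1.0, best / min_len)
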