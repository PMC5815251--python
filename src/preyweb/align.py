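"""Pairwise global alignment and the identity measure shared by clustering
and taxonomic assignment.

Identity is defined as: matching columns / alignment columns of the
optimal global alignment, with terminal (end) gaps excluded from the
column count — so a read that is a clean prefix of a longer template
scores identity 1.0.  Scoring is match +5, mismatch -4, interior gap -8
(linear); terminal gaps cost -1 per base, which keeps them cheap enough
for prefix/containment alignments while preventing the degenerate
short-overlap alignments that fully free ends would permit between
unrelated sequences.  When the optimal score is not positive the pair is
considered unalignable and identity is reported as 0.  Among
equal-score alignments the one with the most matching columns, then the
fewest columns, defines the reported identity — this pins the measure
to a single deterministic value.

A band limit makes the scan O(n*band) for the high-identity comparisons
the pipeline actually performs; `band=None` computes the exact full
matrix.
"""

from __future__ import annotations

import numpy as np

MATCH = 5
MISMATCH = -4
GAP = -8
TERM_GAP = -1

_NEG = -(10**9)


def _nw_stats_kernel(a, b, lo, hi):
    n = a.shape[0]
    m = b.shape[0]
    width = m + 1
    prev_s = np.full(width, _NEG, dtype=np.int64)
    prev_m = np.zeros(width, dtype=np.int64)
    prev_c = np.zeros(width, dtype=np.int64)
    cur_s = np.full(width, _NEG, dtype=np.int64)
    cur_m = np.zeros(width, dtype=np.int64)
    cur_c = np.zeros(width, dtype=np.int64)

    # row 0: leading terminal gap in B's frame; cheap, zero columns
    for j in range(0, min(m, hi) + 1):
        prev_s[j] = TERM_GAP * j
        prev_m[j] = 0
        prev_c[j] = 0

    # best alignment end; trailing terminal gap cost applied on the fly
    best_s, best_m, best_c = _NEG, 0, 0
    if m <= hi:  # end (0, m): everything is terminal gap
        best_s, best_m, best_c = TERM_GAP * (m + n), 0, 0

    for i in range(1, n + 1):
        jlo = i + lo
        jhi = i + hi
        if jlo < 0:
            jlo = 0
        if jhi > m:
            jhi = m
        # only the band fringe can hold stale values that later reads touch
        lo_clear = jlo - 2 if jlo >= 2 else 0
        hi_clear = jhi + 2 if jhi + 2 <= m else m
        for j in range(lo_clear, hi_clear + 1):
            cur_s[j] = _NEG
        if jlo == 0:
            cur_s[0] = TERM_GAP * i  # leading terminal gap in A's frame
            cur_m[0] = 0
            cur_c[0] = 0
            jstart = 1
        else:
            jstart = jlo
        for j in range(jstart, jhi + 1):
            # diagonal
            s = prev_s[j - 1]
            if s > _NEG:
                if a[i - 1] == b[j - 1]:
                    bs = s + MATCH
                    bm = prev_m[j - 1] + 1
                else:
                    bs = s + MISMATCH
                    bm = prev_m[j - 1]
                bc = prev_c[j - 1] + 1
            else:
                bs, bm, bc = _NEG, 0, 0
            # interior gap in B (consume a[i-1])
            s = prev_s[j]
            if s > _NEG:
                cs = s + GAP
                cm = prev_m[j]
                cc = prev_c[j] + 1
                if cs > bs or (cs == bs and (cm > bm or (cm == bm and cc < bc))):
                    bs, bm, bc = cs, cm, cc
            # interior gap in A (consume b[j-1])
            s = cur_s[j - 1]
            if s > _NEG:
                cs = s + GAP
                cm = cur_m[j - 1]
                cc = cur_c[j - 1] + 1
                if cs > bs or (cs == bs and (cm > bm or (cm == bm and cc < bc))):
                    bs, bm, bc = cs, cm, cc
            cur_s[j] = bs
            cur_m[j] = bm
            cur_c[j] = bc
        # ending at (i, m): the rest of A is a trailing terminal gap
        if jhi == m and cur_s[m] > _NEG:
            s = cur_s[m] + TERM_GAP * (n - i)
            mt, c = cur_m[m], cur_c[m]
            if s > best_s or (
                s == best_s and (mt > best_m or (mt == best_m and c < best_c))
            ):
                best_s, best_m, best_c = s, mt, c
        tmp_s, tmp_m, tmp_c = prev_s, prev_m, prev_c
        prev_s, prev_m, prev_c = cur_s, cur_m, cur_c
        cur_s, cur_m, cur_c = tmp_s, tmp_m, tmp_c

    # ending at (n, j): the rest of B is a trailing terminal gap; only the
    # last row's band holds live values
    jlo_n = n + lo
    if jlo_n < 0:
        jlo_n = 0
    jhi_n = n + hi
    if jhi_n > m:
        jhi_n = m
    for j in range(jlo_n, jhi_n + 1):
        s = prev_s[j]
        if s > _NEG:
            s = s + TERM_GAP * (m - j)
            mt, c = prev_m[j], prev_c[j]
            if s > best_s or (
                s == best_s and (mt > best_m or (mt == best_m and c < best_c))
            ):
                best_s, best_m, best_c = s, mt, c
    return best_s, best_m, best_c


try:  # numba is optional; the pure-python kernel is the reference behavior
    from numba import njit

    _nw_stats_fast = njit(cache=True, nogil=True)(_nw_stats_kernel)
except ImportError:  # pragma: no cover
    _nw_stats_fast = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def alignment_stats(
    a: str, b: str, band: int | None = None
) -> tuple[int, int, int]:
    """Return (score, matching_columns, columns) of the optimal alignment.

    `band` limits the explored diagonals to [min(0, m-n)-band,
    max(0, m-n)+band]; None means exact (unbounded).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0, 0, 0
    delta = m - n
    if band is None or band >= max(n, m):
        lo, hi = -n, m
    else:
        lo = min(0, delta) - band
        hi = max(0, delta) + band
    ea, eb = _encode(a), _encode(b)
    kernel = _nw_stats_fast if _nw_stats_fast is not None else _nw_stats_kernel
    s, mt, c = kernel(ea, eb, lo, hi)
    return int(s), int(mt), int(c)


def identity(a: str, b: str, band: int | None = None) -> float:
    """Pairwise identity: matching columns / columns, terminal gaps excluded.

    Pairs whose optimal alignment score is not positive are unalignable
    and score identity 0.0.
    """
    score, matches, columns = alignment_stats(a, b, band=band)
    if columns == 0 or score <= 0:
        return 0.0
    return matches / columns


def coverage_identity(
    a: str, b: str, band: int | None = None
) -> tuple[float, float]:
    """(identity, coverage) where coverage = columns / min(len_a, len_b)."""
    score, matches, columns = alignment_stats(a, b, band=band)
    if columns == 0 or score <= 0:
        return 0.0, 0.0
    return matches / columns, columns / min(len(a), len(b))


def band_for_cutoff(len_a: int, len_b: int, cutoff: float, slack: int = 8) -> int:
    """Band width guaranteeing exactness for alignments at or above `cutoff`.

    An alignment with identity >= cutoff over c columns contains at most
    (1-cutoff)*c <= (1-cutoff)*(len_a+len_b) non-matching columns,
    bounding how far its path strays off-diagonal beyond the length
    offset (which the band is already centered on).
    """
    return int(np.ceil((1.0 - cutoff) * (len_a + len_b))) + slack
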