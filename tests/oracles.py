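"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from the declared definitions,
without importing any package internals beyond plain data containers:
full-matrix alignment DP, naive read filtering, brute-force greedy
clustering, manual LCA, and closed-form rarefaction.
"""

from __future__ import annotations

from math import comb

# declared alignment scoring (restated here, not imported)
MATCH = 5
MISMATCH = -4
GAP = -8
TERM_GAP = -1


def nw_stats_oracle(a: str, b: str) -> tuple[int, int, int]:
    """Full-matrix DP for (score, matches, columns).

    Objective: maximize score, then matches, then fewest columns.
    Terminal gaps cost TERM_GAP per base and contribute no columns.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0, 0, 0
    NEG = (float("-inf"), 0, 0)

    def better(x, y):
        if x[0] != y[0]:
            return x if x[0] > y[0] else y
        if x[1] != y[1]:
            return x if x[1] > y[1] else y
        return x if x[2] <= y[2] else y

    dp = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        dp[0][j] = (TERM_GAP * j, 0, 0)
    for i in range(1, n + 1):
        dp[i][0] = (TERM_GAP * i, 0, 0)
        for j in range(1, m + 1):
            s, mt, c = dp[i - 1][j - 1]
            if a[i - 1] == b[j - 1]:
                best = (s + MATCH, mt + 1, c + 1)
            else:
                best = (s + MISMATCH, mt, c + 1)
            s, mt, c = dp[i - 1][j]
            best = better(best, (s + GAP, mt, c + 1))
            s, mt, c = dp[i][j - 1]
            best = better(best, (s + GAP, mt, c + 1))
            dp[i][j] = best
    end = NEG
    for i in range(n + 1):
        s, mt, c = dp[i][m]
        end = better(end, (s + TERM_GAP * (n - i), mt, c))
    for j in range(m + 1):
        s, mt, c = dp[n][j]
        end = better(end, (s + TERM_GAP * (m - j), mt, c))
    return int(end[0]), end[1], end[2]


def identity_oracle(a: str, b: str) -> float:
    score, matches, columns = nw_stats_oracle(a, b)
    if columns == 0 or score <= 0:
        return 0.0
    return matches / columns


def coverage_oracle(a: str, b: str) -> float:
    score, _, columns = nw_stats_oracle(a, b)
    if columns == 0 or score <= 0:
        return 0.0
    return columns / min(len(a), len(b))


# ---------------------------------------------------------------- filtering

def trim_oracle(quals: list[int], window: int = 5, min_q: int = 30) -> int:
    """Length after 3'-peeling; independent re-statement of the rule."""
    end = len(quals)
    while end >= window:
        if min(quals[end - window : end]) >= min_q:
            break
        end -= 1
    return end


def filter_label_oracle(
    bases: str,
    quals: list[int],
    fwd_index_quals: list[int],
    rev_index_quals: list[int],
    index_known: bool,
    min_index_q: int = 30,
    window: int = 5,
    trim_min_q: int = 30,
    min_len: int = 170,
    max_lowq_fraction: float = 0.10,
    q_thresh: int = 30,
) -> str:
    """One of: index_lowq, index_mismatch, length, quality_fraction, kept."""
    if any(q < min_index_q for q in fwd_index_quals + rev_index_quals):
        return "index_lowq"
    if not index_known:
        return "index_mismatch"
    end = trim_oracle(quals, window, trim_min_q)
    quals = quals[:end]
    if len(quals) < min_len:
        return "length"
    lowq = sum(1 for q in quals if q < q_thresh)
    if lowq / len(quals) >= max_lowq_fraction:
        return "quality_fraction"
    return "kept"


# ---------------------------------------------------------------- clustering

def greedy_cluster_oracle(
    sequences: list[str],
    cutoff: float = 0.97,
    min_coverage: float = 0.8,
) -> list[int]:
    """Cluster label per input sequence (inputs already in abundance order).

    Brute force: every sequence is aligned (full matrix) against every
    existing centroid; it joins the best identity >= cutoff with
    coverage >= min_coverage (earliest centroid on ties) or founds a
    new cluster.
    """
    labels: list[int] = []
    centroids: list[str] = []
    for seq in sequences:
        best_c, best_id = None, -1.0
        for ci, centroid in enumerate(centroids):
            score, matches, columns = nw_stats_oracle(seq, centroid)
            if columns == 0 or score <= 0:
                continue
            ident = matches / columns
            cov = columns / min(len(seq), len(centroid))
            if ident >= cutoff and cov >= min_coverage and ident > best_id:
                best_c, best_id = ci, ident
        if best_c is None:
            centroids.append(seq)
            labels.append(len(centroids) - 1)
        else:
            labels.append(best_c)
    return labels


# ---------------------------------------------------------------- taxonomy

def lca_oracle(lineages: list[tuple[str, ...]]) -> tuple[str, ...]:
    out = []
    for names in zip(*lineages):
        if len(set(names)) != 1:
            break
        out.append(names[0])
    return tuple(out)


def assign_oracle(
    query: str,
    refs: list[tuple[str, tuple[str, ...]]],
    epsilon: float = 0.01,
    min_identity: float = 0.8,
) -> tuple[str, ...] | None:
    idents = [identity_oracle(query, seq) for seq, _ in refs]
    best = max(idents)
    if best < min_identity:
        return None
    neighbors = [lin for (_, lin), i in zip(refs, idents) if i >= best - epsilon]
    consensus = lca_oracle(neighbors)
    return consensus if consensus else None


# ---------------------------------------------------------------- rarefaction

def rarefaction_oracle(counts: list[int], depth: int) -> float:
    """Exact hypergeometric expectation via integer binomials."""
    counts = [c for c in counts if c > 0]
    n_total = sum(counts)
    total = comb(n_total, depth)
    return sum(1.0 - comb(n_total - c, depth) / total for c in counts)
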