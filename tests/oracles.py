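"""Independent brute-force re-implementations used as test oracles.

Everything here is written with plain loops and top-down recursion,
deliberately sharing no code with the package, so agreement between the two
routes checks the vectorized/numba implementations against the committed
semantics.
"""

from __future__ import annotations

import sys

import numpy as np

from embedrepeat.alignment import AlignmentParams


def naive_cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            na = np.sqrt(sum(x * x for x in a[i]))
            nb = np.sqrt(sum(x * x for x in b[j]))
            out[i, j] = sum(a[i][k] * b[j][k] for k in range(a.shape[1])) / (na * nb)
    return out


def naive_moving_average(vals, window_length: int) -> list[float]:
    h = window_length // 2
    n = len(vals)
    out = []
    for k in range(n):
        lo, hi = max(k - h, 0), min(k + h + 1, n)
        out.append(sum(vals[lo:hi]) / (hi - lo))
    return out


def naive_windowed_score(pairs, s: np.ndarray, window_length: int) -> float:
    vals = [s[i, j] for i, j in pairs]
    ma = naive_moving_average(vals, window_length)
    return sum(ma) / len(ma)


def naive_diagonal_smooth(s: np.ndarray, window_length: int) -> np.ndarray:
    h = window_length // 2
    n, m = s.shape
    out = np.zeros_like(s)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            cnt = 0
            for t in range(-h, h + 1):
                if 0 <= i + t < n and 0 <= j + t < m:
                    acc += s[i + t, j + t]
                    cnt += 1
            out[i, j] = acc / cnt
    return out


def naive_local_traces(s_raw: np.ndarray, params: AlignmentParams,
                       self_mode: bool = True) -> list[tuple[tuple, float]]:
    """Plain-Python version of the whole suboptimal-trace extraction.

    Returns a sorted list of (pairs-tuple, score).
    """
    n, m = s_raw.shape
    if min(n, m) < params.min_span:
        return []
    smoothed = naive_diagonal_smooth(s_raw, params.window_length)
    band = params.diagonal_exclusion if self_mode else -1
    if self_mode:
        sel = [smoothed[i, j] for i in range(n) for j in range(m)
               if abs(i - j) > params.diagonal_exclusion]
    else:
        sel = list(smoothed.ravel())
    if not sel:
        return []
    theta = float(np.mean(sel) + params.sigma_factor * np.std(sel))
    sp = smoothed - theta
    if self_mode:
        for i in range(n):
            for j in range(m):
                if abs(i - j) <= band:
                    sp[i, j] = -1e9
    gap = params.gap_extension + max(theta, 0.0)

    sys.setrecursionlimit(100_000)
    memo: dict[tuple[int, int], float] = {}

    def H(i: int, j: int) -> float:  # 1-based, top-down
        if i == 0 or j == 0:
            return 0.0
        if band >= 0 and abs(i - j) <= band:
            return 0.0
        if (i, j) not in memo:
            best = H(i - 1, j - 1) + sp[i - 1, j - 1]
            best = max(best, H(i - 1, j) - gap, H(i, j - 1) - gap, 0.0)
            memo[(i, j)] = best
        return memo[(i, j)]

    core = np.array([[H(i, j) for j in range(1, m + 1)]
                     for i in range(1, n + 1)])

    def is_local_max(i: int, j: int) -> bool:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                a, b = i + di, j + dj
                neigh = core[a, b] if 0 <= a < n and 0 <= b < m else 0.0
                if core[i, j] < neigh:
                    return False
        return True

    seeds = [(i, j) for i in range(n) for j in range(m)
             if core[i, j] > 0 and is_local_max(i, j)
             and (not self_mode or j > i)]
    seeds.sort(key=lambda ij: (-core[ij[0], ij[1]], ij[0], ij[1]))

    def traceback(i: int, j: int) -> list[tuple[int, int]]:
        pairs = []
        while i > 0 and j > 0 and H(i, j) > 0.0:
            if H(i, j) == H(i - 1, j - 1) + sp[i - 1, j - 1]:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif H(i, j) == H(i - 1, j) - gap:
                i -= 1
            elif H(i, j) == H(i, j - 1) - gap:
                j -= 1
            else:
                break
        return pairs[::-1]

    raw, seen = [], set()
    for i, j in seeds:
        pairs = traceback(i + 1, j + 1)
        while pairs and s_raw[pairs[0]] < theta:
            pairs = pairs[1:]
        while pairs and s_raw[pairs[-1]] < theta:
            pairs = pairs[:-1]
        key = frozenset(pairs)
        if pairs and key not in seen:
            seen.add(key)
            raw.append(pairs)

    # filters
    filtered = []
    for pairs in raw:
        if len(pairs) < params.min_span:
            continue
        mean_sm = sum(smoothed[i, j] for i, j in pairs) / len(pairs)
        if mean_sm < theta:
            continue
        score = naive_windowed_score(pairs, s_raw, params.window_length)
        if score < params.score_cutoff:
            continue
        filtered.append((pairs, score))

    # strict-subset pruning
    sets = [frozenset(p) for p, _ in filtered]
    kept = [fp for k, fp in enumerate(filtered)
            if not any(sets[k] < sets[o] for o in range(len(filtered))
                       if o != k)]

    # redundancy (>=70% of either's pairs within Chebyshev distance 2)
    def redundant(p1, p2) -> bool:
        for a, b in ((p1, p2), (p2, p1)):
            bset = set(b)
            near = sum(
                1 for i, j in a
                if any((i + di, j + dj) in bset
                       for di in range(-2, 3) for dj in range(-2, 3)))
            if near >= 0.7 * len(a):
                return True
        return False

    kept.sort(key=lambda fp: (-fp[1], fp[0][0]))
    final = []
    for pairs, score in kept:
        if not any(redundant(pairs, q) for q, _ in final):
            final.append((pairs, score))
    final.sort(key=lambda fp: fp[0][0])
    return [(tuple(p), s) for p, s in final]


def best_chain_bruteforce(cells: list[tuple[int, int, float]],
                          gap_cost: float) -> tuple[float, tuple]:
    """Exhaustive search for the best strictly-increasing chain of cells.

    The chain objective mirrors the local DP: sum of cell weights minus
    gap_cost per skipped row/column between consecutive chain cells.  Only
    usable for small positive-cell sets (exponential recursion with memo on
    the last chain element).
    """
    cells = sorted(cells)
    memo: dict[int, tuple[float, tuple]] = {}

    def extend(k: int) -> tuple[float, tuple]:
        if k in memo:
            return memo[k]
        i, j, w = cells[k]
        best, chain = w, ((i, j),)
        for o in range(k + 1, len(cells)):
            i2, j2, _ = cells[o]
            if i2 > i and j2 > j:
                sub, subchain = extend(o)
                cost = gap_cost * ((i2 - i - 1) + (j2 - j - 1))
                if w + sub - cost > best:
                    best = w + sub - cost
                    chain = ((i, j),) + subchain
        memo[k] = (best, chain)
        return memo[k]

    best, chain = -np.inf, ()
    for k in range(len(cells)):
        sc, ch = extend(k)
        if sc > best:
            best, chain = sc, ch
    return best, chain


def naive_nw(s: np.ndarray, gap: float) -> float:
    """Top-down recursive global-alignment optimum (score only)."""
    n, m = s.shape
    memo: dict[tuple[int, int], float] = {}

    def F(i: int, j: int) -> float:
        if i == 0:
            return -gap * j
        if j == 0:
            return -gap * i
        if (i, j) not in memo:
            memo[(i, j)] = max(F(i - 1, j - 1) + s[i - 1, j - 1],
                               F(i - 1, j) - gap, F(i, j - 1) - gap)
        return memo[(i, j)]

    return F(n, m)


def naive_score_matrix(traces, length: int) -> np.ndarray:
    out = np.zeros((length, length))
    for t in traces:
        for i, j in t.pairs:
            out[i, j] += t.score
            out[j, i] += t.score
    return out


def naive_window_score(m: np.ndarray, weights, start: int) -> float:
    total = 0.0
    for i in range(m.shape[0]):
        for p, w in enumerate(weights):
            total += w * m[i, start + p]
    return total


def naive_weighted_embedding(m: np.ndarray, e: np.ndarray, start: int,
                             l: int) -> np.ndarray:
    L, d = e.shape
    out = np.zeros((l, d))
    for r in range(l):
        for i in range(L):
            for k in range(d):
                out[r, k] += m[i, start + r] * e[i, k]
        if not any(m[i, start + r] for i in range(L)):
            out[r] = e[start + r]
    return out
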