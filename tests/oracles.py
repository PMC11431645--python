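"""Naive enumeration oracles for texture matrices and the concordance index.

Everything here is deliberately written as plain Python loops, independent of
the vectorized implementations it checks.
"""

import numpy as np

from petfuse.features import DIRECTIONS_13


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_oracle(levels, ng, distance=1, symmetric=True):
    """Co-occurrence counts by exhaustive voxel-pair enumeration."""
    out = np.zeros((len(DIRECTIONS_13), ng, ng))
    shape = levels.shape
    for k, d in enumerate(DIRECTIONS_13):
        off = tuple(distance * c for c in d)
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = levels[x, y, z]
                    if a == 0:
                        continue
                    q = (x + off[0], y + off[1], z + off[2])
                    if not _inside(shape, q):
                        continue
                    b = levels[q]
                    if b == 0:
                        continue
                    out[k, a - 1, b - 1] += 1
                    if symmetric:
                        out[k, b - 1, a - 1] += 1
    return out


def glrlm_oracle_one_direction(levels, ng, direction):
    """Run-length counts by walking every maximal run in plain Python."""
    shape = levels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                prev = (x - direction[0], y - direction[1], z - direction[2])
                if _inside(shape, prev) and levels[prev] == g:
                    continue  # not the start of a run
                length = 1
                cur = (x, y, z)
                while True:
                    nxt = tuple(c + d for c, d in zip(cur, direction))
                    if not _inside(shape, nxt) or levels[nxt] != g:
                        break
                    length += 1
                    cur = nxt
                runs.append((g, length))
    if not runs:
        return np.zeros((ng, 1))
    max_len = max(l for _, l in runs)
    mat = np.zeros((ng, max_len))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def glszm_oracle(levels, ng):
    """Size-zone counts via BFS flood fill over 26-connected equal-level zones."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        q = tuple(c + o for c, o in zip(p, d))
                        if _inside(shape, q) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            stack.append(q)
                zones.append((g, size))
    if not zones:
        return np.zeros((ng, 1))
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def gldm_oracle(levels, ng, alpha=0):
    """Dependence counts per voxel by direct neighbour enumeration."""
    shape = levels.shape
    mat = np.zeros((ng, 27))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                dep = 0
                for d in NEIGHBORS_26:
                    q = tuple(c + o for c, o in zip((x, y, z), d))
                    if _inside(shape, q) and levels[q] != 0 and abs(int(levels[q]) - int(g)) <= alpha:
                        dep += 1
                mat[g - 1, dep] += 1
    return mat


def c_index_oracle(time, event, risk):
    """Harrell's C by exhaustive ordered-pair enumeration."""
    n = len(time)
    num = 0.0
    n_c = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                n_c += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if n_c == 0:
        return None, 0
    return num / n_c, n_c


def km_oracle(time, event):
    """Product-limit survival values at each distinct observed time."""
    times = sorted(set(time))
    s = 1.0
    out = {}
    for u in times:
        n_at = sum(1 for t in time if t >= u)
        d = sum(1 for t, e in zip(time, event) if t == u and e == 1)
        if d:
            s *= 1 - d / n_at
        out[u] = s
    return out
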