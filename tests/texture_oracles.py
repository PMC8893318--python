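"""Brute-force enumeration oracles for the texture-matrix builders.

Deliberately naive (per-voxel Python loops) and independent of the
vectorized builders they are checked against.
"""

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_counts_bruteforce(levels, directions):
    """Raw (unsymmetrized) co-occurrence counts by enumerating all voxel pairs."""
    ng = int(levels.max())
    counts = np.zeros((ng, ng), dtype=int)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for d in directions:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0:
                        counts[a - 1, levels[q] - 1] += 1
    return counts


def glrlm_counts_bruteforce(levels, directions):
    """Run-length counts by walking each run from its start voxel."""
    ng = int(levels.max())
    shape = levels.shape
    counts = np.zeros((ng, max(shape)), dtype=int)
    for d in directions:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    v = levels[x, y, z]
                    if v == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and levels[prev] == v:
                        continue  # not a run start
                    length = 1
                    cur = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, cur) and levels[cur] == v:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    counts[v - 1, length - 1] += 1
    return counts


def glszm_counts_bruteforce(levels):
    """Zone counts by BFS flood fill with 26-connectivity."""
    ng = int(levels.max())
    shape = levels.shape
    n_vox = int((levels > 0).sum())
    counts = np.zeros((ng, max(n_vox, 1)), dtype=int)
    seen = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, q) and not seen[q] and levels[q] == v:
                            seen[q] = True
                            stack.append(q)
                counts[v - 1, size - 1] += 1
    return counts


def ngtdm_table_bruteforce(levels):
    """(n_i, p_i, s_i) rows by per-voxel neighbourhood averaging."""
    ng = int(levels.max())
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                nbrs = [
                    levels[x + d[0], y + d[1], z + d[2]]
                    for d in NEIGHBORS_26
                    if _inside(shape, (x + d[0], y + d[1], z + d[2]))
                    and levels[x + d[0], y + d[1], z + d[2]] > 0
                ]
                if not nbrs:
                    continue
                n_i[v - 1] += 1
                s_i[v - 1] += abs(v - np.mean(nbrs))
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return np.stack([n_i, p_i, s_i], axis=1)


def gldm_counts_bruteforce(levels, alpha=0):
    """Dependence counts; size = 1 + dependent 26-neighbours."""
    ng = int(levels.max())
    shape = levels.shape
    counts = np.zeros((ng, 27), dtype=int)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                dep = 1
                for d in NEIGHBORS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(v)) <= alpha:
                        dep += 1
                counts[v - 1, dep - 1] += 1
    return counts
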