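"""Independent brute-force oracles used by the test suite.

Everything here is written as directly as possible (explicit loops,
hand-coded direction lists) so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np

# the 13 unique 26-connectivity offsets, written out by hand
DIRS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]


def _in(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def glcm_oracle(vol, roi, ng):
    """Direction-averaged symmetric normalized GLCM by explicit pair loops."""
    shape = vol.shape
    mats = []
    for d in DIRS_13:
        m = np.zeros((ng, ng))
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not roi[x, y, z]:
                        continue
                    q = (x + d[0], y + d[1], z + d[2])
                    if _in(shape, q) and roi[q]:
                        i, j = vol[x, y, z] - 1, vol[q] - 1
                        m[i, j] += 1
                        m[j, i] += 1
        if m.sum() > 0:
            mats.append(m / m.sum())
    if not mats:
        raise ValueError("no pairs")
    return np.mean(mats, axis=0)


def glrlm_oracle(vol, roi, ng, rmax):
    """Direction-averaged run-length matrix by explicit run walking."""
    shape = vol.shape
    acc = np.zeros((ng, rmax))
    for d in DIRS_13:
        m = np.zeros((ng, rmax))
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not roi[x, y, z]:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _in(shape, prev) and roi[prev] and vol[prev] == vol[x, y, z]:
                        continue  # interior of a run, not a start
                    length = 1
                    cur = (x, y, z)
                    while True:
                        nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                        if _in(shape, nxt) and roi[nxt] and vol[nxt] == vol[x, y, z]:
                            length += 1
                            cur = nxt
                        else:
                            break
                    m[vol[x, y, z] - 1, length - 1] += 1
        acc += m
    return acc / len(DIRS_13)


def glszm_oracle(vol, roi, ng, smax):
    """Size-zone matrix by breadth-first search over 26-neighbors."""
    shape = vol.shape
    seen = np.zeros(shape, dtype=bool)
    m = np.zeros((ng, smax))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not roi[x, y, z] or seen[x, y, z]:
                    continue
                g = vol[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (_in(shape, q) and roi[q] and not seen[q]
                                and vol[q] == g):
                            seen[q] = True
                            stack.append(q)
                m[g - 1, size - 1] += 1
    return m


def concordance_oracle(risk, time, event):
    """Harrell's C by an explicit all-pairs double loop."""
    n = len(risk)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def icc_anova_oracle(y):
    """ICC(2,1) from a hand-built two-way ANOVA table."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ms_rows = sum(k * (row.mean() - grand) ** 2 for row in y) / (n - 1)
    ms_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    ss_err = sum((y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
                 for i in range(n) for j in range(k))
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)


def random_discretized_volume(rng, max_side=6, ng_max=5):
    """Random small labeled volume + mask with at least one neighbor pair."""
    while True:
        shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
        roi = rng.random(shape) < 0.6
        if roi.sum() < 2:
            continue
        ng = int(rng.integers(1, ng_max + 1))
        vol = np.where(roi, rng.integers(1, ng + 1, size=shape), 0)
        ng_eff = int(vol.max())
        if ng_eff == 0:
            continue
        # require at least one in-ROI neighbor pair in some direction
        ok = False
        for d in DIRS_13:
            for p in np.argwhere(roi):
                q = tuple(p + d)
                if _in(shape, q) and roi[q]:
                    ok = True
                    break
            if ok:
                break
        if ok:
            return vol.astype(np.int64), roi, ng_eff
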