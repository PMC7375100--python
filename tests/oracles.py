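"""Independent brute-force reference implementations used only by tests.

Each oracle takes the literal definition of a quantity and computes it the
slow, obvious way (explicit loops, full correlation matrices, exhaustive
enumeration), deliberately sharing no code with the package.
"""

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = [
        o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
    ]
    if connectivity == 6:
        offs = [o for o in offs if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offs = [o for o in offs if sum(map(abs, o)) <= 2]
    return offs


def lfcd_oracle(data, mask, r_threshold, connectivity=26):
    """Per seed: correlate the seed with every voxel, then flood-fill the
    boolean exceedance grid from the seed."""
    shape = data.shape[:3]
    t = data.shape[-1]
    flat = data.reshape(-1, t)
    inc = np.asarray(mask, dtype=bool).ravel()
    # full voxel-by-voxel correlation matrix
    sd = flat.std(axis=1)
    inc = inc & (sd > 0)
    corr = np.corrcoef(flat)
    offs = neighbor_offsets(connectivity)
    values = np.zeros(len(flat))
    coords = [np.unravel_index(i, shape) for i in range(len(flat))]
    index = {c: i for i, c in enumerate(coords)}
    for seed in np.flatnonzero(inc):
        ok = inc & (corr[seed] > r_threshold)
        ok[seed] = True
        seen = {seed}
        q = deque([seed])
        while q:
            u = q.popleft()
            ci, cj, ck = coords[u]
            for dx, dy, dz in offs:
                c = (ci + dx, cj + dy, ck + dz)
                if c in index:
                    w = index[c]
                    if ok[w] and w not in seen:
                        seen.add(w)
                        q.append(w)
        values[seed] = len(seen)
    return values.reshape(shape)


def foca_oracle(data, mask, cube=3):
    """Literal double loops over neighborhood voxel pairs (temporal term)
    and consecutive frame pairs (spatial term)."""
    shape = data.shape[:3]
    t = data.shape[-1]
    mask = np.asarray(mask, dtype=bool)
    sd_ok = data.std(axis=-1) > 0
    incl = mask & sd_ok
    half = cube // 2
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not incl[i, j, k]:
                    continue
                members = []
                for di in range(-half, half + 1):
                    for dj in range(-half, half + 1):
                        for dk in range(-half, half + 1):
                            a, b, c = i + di, j + dj, k + dk
                            if (
                                0 <= a < shape[0]
                                and 0 <= b < shape[1]
                                and 0 <= c < shape[2]
                                and incl[a, b, c]
                            ):
                                members.append(data[a, b, c])
                n = len(members)
                if n < 3:
                    continue
                pair_corrs = []
                for a in range(n):
                    for b in range(a + 1, n):
                        pair_corrs.append(np.corrcoef(members[a], members[b])[0, 1])
                T = float(np.mean(pair_corrs))
                M = np.array(members)  # (n, t)
                step_corrs = []
                for s in range(t - 1):
                    pa, pb = M[:, s], M[:, s + 1]
                    if pa.std() == 0 or pb.std() == 0:
                        continue
                    step_corrs.append(np.corrcoef(pa, pb)[0, 1])
                S = float(np.mean(step_corrs)) if step_corrs else 0.0
                out[i, j, k] = (T + S) / 2.0
    return out


def ols_t_oracle(Y, X, j):
    """Per-column OLS via explicit normal equations; returns (t, p)."""
    from scipy import stats

    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    ts, ps = [], []
    for y in Y.T:
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - p)
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        tv = beta[j] / se
        ts.append(tv)
        ps.append(2 * stats.t.sf(abs(tv), n - p))
    return np.array(ts), np.array(ps)


def bh_oracle(pvals, q):
    """Benjamini-Hochberg by exhaustive scan of every cutoff k."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def components_oracle(mask, connectivity=26):
    """Connected components by union-find over the boolean grid."""
    mask = np.asarray(mask, dtype=bool)
    coords = list(map(tuple, np.argwhere(mask)))
    parent = {c: c for c in coords}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    offs = neighbor_offsets(connectivity)
    cs = set(coords)
    for c in coords:
        for dx, dy, dz in offs:
            d = (c[0] + dx, c[1] + dy, c[2] + dz)
            if d in cs:
                ra, rb = find(c), find(d)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for c in coords:
        groups.setdefault(find(c), set()).add(c)
    return list(groups.values())
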