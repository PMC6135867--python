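"""Independent brute-force reference implementations used only by tests.

Each oracle avoids the data structures of the implementation it checks:
dilation by explicit neighbour enumeration, surface distance by all-pairs
scans, component labelling by flood fill, and detection matching by
per-voxel set arithmetic with no joint histogram.
"""

from collections import deque
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist

FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _offsets(connectivity):
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        n_nonzero = sum(1 for x in d if x != 0)
        if connectivity == 6 and n_nonzero == 1:
            offs.append(d)
        elif connectivity == 18 and n_nonzero <= 2:
            offs.append(d)
        elif connectivity == 26:
            offs.append(d)
    return offs


def brute_dilate(mask, n_iter):
    """n_iter successive 6-neighbour growths by explicit enumeration."""
    cur = {tuple(c) for c in np.argwhere(mask)}
    shape = mask.shape
    for _ in range(n_iter):
        grown = set(cur)
        for (i, j, k) in cur:
            for di, dj, dk in FACE_OFFSETS:
                p = (i + di, j + dj, k + dk)
                if all(0 <= p[d] < shape[d] for d in range(3)):
                    grown.add(p)
        cur = grown
    out = np.zeros(shape, dtype=bool)
    for c in cur:
        out[c] = True
    return out


def brute_surface(mask):
    """Foreground voxels with a background face-neighbour or edge contact."""
    shape = mask.shape
    out = np.zeros(shape, dtype=bool)
    for (i, j, k) in np.argwhere(mask):
        for di, dj, dk in FACE_OFFSETS:
            p = (i + di, j + dj, k + dk)
            if not all(0 <= p[d] < shape[d] for d in range(3)) or not mask[p]:
                out[i, j, k] = True
                break
    return out


def brute_assd(mask_a, mask_g, spacing):
    """All-pairs average symmetric surface distance in mm."""
    sa = np.argwhere(brute_surface(mask_a)) * np.asarray(spacing)
    sg = np.argwhere(brute_surface(mask_g)) * np.asarray(spacing)
    d = cdist(sa, sg)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sg))


def flood_fill_components(mask, connectivity=18):
    """Connected components as a list of frozensets of voxel tuples (BFS)."""
    offs = _offsets(connectivity)
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for d in offs:
                p = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (all(0 <= p[k] < shape[k] for k in range(3))
                        and mask[p] and not seen[p]):
                    seen[p] = True
                    q.append(p)
        comps.append(frozenset(comp))
    return comps


def brute_count_detected(g_lesions, a_lesions, alpha_pct, gamma_pct, beta_pct,
                         beta_on_union=False):
    """Detection matching by explicit voxel-set arithmetic.

    ``g_lesions``/``a_lesions`` are lists of voxel-coordinate sets.
    Returns (tp, per-lesion booleans) for the reference lesions.
    """
    detected = []
    for gset in g_lesions:
        overlaps = [len(gset & aset) for aset in a_lesions]
        total = sum(overlaps)
        if total * 100.0 < alpha_pct * len(gset):
            detected.append(False)
            continue
        order = sorted(
            (i for i, o in enumerate(overlaps) if o > 0),
            key=lambda i: (-overlaps[i], i),
        )
        acc = 0
        chosen = []
        for i in order:
            chosen.append(i)
            acc += overlaps[i]
            if acc * 100.0 >= gamma_pct * total:
                break
        if beta_on_union:
            tot = sum(len(a_lesions[i]) for i in chosen)
            ins = sum(overlaps[i] for i in chosen)
            ok = (tot - ins) * 100.0 <= beta_pct * tot
        else:
            ok = all(
                (len(a_lesions[i]) - overlaps[i]) * 100.0
                <= beta_pct * len(a_lesions[i])
                for i in chosen
            )
        detected.append(ok)
    return sum(detected), detected


def lesion_sets(label_map):
    """Voxel-coordinate sets of a LesionLabelMap, ordered by label."""
    return [
        {tuple(c) for c in np.argwhere(label_map.labels == l)}
        for l in range(1, label_map.n_lesions + 1)
    ]


def naive_staple(D, prior, mode="staple", p0=0.9, q0=0.9, n_iter=100, tol=1e-6):
    """Reference binary STAPLE EM written with explicit per-voxel loops.

    ``D`` is an R x V list of 0/1 observations, ``prior`` a length-V list.
    The E-step multiplies raw per-rater likelihoods (classical) or their
    1/R-weighted geometric mean (log-opinion pool); the M-step re-estimates
    (p_r, q_r) from the posterior weights. Deliberately scalar and slow.
    """
    R = len(D)
    V = len(prior)
    p = [p0] * R
    q = [q0] * R
    W = [0.0] * V
    for _ in range(n_iter):
        for v in range(V):
            num = prior[v]
            den = 1.0 - prior[v]
            for r in range(R):
                f1 = p[r] if D[r][v] else 1.0 - p[r]
                f0 = (1.0 - q[r]) if D[r][v] else q[r]
                if mode == "lop_staple":
                    f1, f0 = f1 ** (1.0 / R), f0 ** (1.0 / R)
                num *= f1
                den *= f0
            W[v] = num / (num + den)
        new_p, new_q = [], []
        for r in range(R):
            sw = sum(W)
            sc = V - sw
            new_p.append(sum(W[v] for v in range(V) if D[r][v]) / sw)
            new_q.append(sum(1 - W[v] for v in range(V) if not D[r][v]) / sc)
        delta = max(
            max(abs(a - b) for a, b in zip(new_p, p)),
            max(abs(a - b) for a, b in zip(new_q, q)),
        )
        p, q = new_p, new_q
        if delta < tol:
            break
    return p, q, W
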