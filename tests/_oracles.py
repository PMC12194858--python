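"""Independent brute-force oracles for the image primitives.

Everything here is written as plainly as possible — per-pixel Python
loops, exhaustive searches, recursive flood fills — deliberately
sharing no code with the package, so agreement is meaningful.
"""

from itertools import product

import numpy as np


def grayscale_loop(img):
    h, w, _ = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            red, g, b = (float(v) for v in img[r, c])
            y = 0.299 * red + 0.587 * g + 0.114 * b
            out[r, c] = min(255, max(0, int(np.floor(y + 0.5))))
    return out


def otsu_exhaustive(img):
    """Smallest t in [0,255] maximizing w0*w1*(mu0-mu1)^2."""
    vals = np.asarray(img).ravel().astype(float)
    n = vals.size
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def _se_offsets(se):
    origin = (se.shape[0] // 2, se.shape[1] // 2)
    return [
        (r - origin[0], c - origin[1])
        for r, c in zip(*np.nonzero(np.asarray(se, dtype=bool)))
    ]


def dilate_loop(mask, se):
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = np.zeros_like(m)
    offs = _se_offsets(se)
    for r in range(h):
        for c in range(w):
            for dr, dc in offs:
                rr, cc = r - dr, c - dc
                if 0 <= rr < h and 0 <= cc < w and m[rr, cc]:
                    out[r, c] = True
                    break
    return out.astype(np.uint8)


def erode_loop(mask, se):
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = np.ones_like(m)
    offs = _se_offsets(se)
    for r in range(h):
        for c in range(w):
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w and m[rr, cc]):
                    out[r, c] = False
                    break
    return out.astype(np.uint8)


def _neighbors(r, c, h, w, connectivity):
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for dr, dc in steps:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            yield rr, cc


def label_flood(mask, connectivity=8):
    """Row-major-first flood-fill labeling."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    labels = np.zeros((h, w), dtype=int)
    n = 0
    for r0 in range(h):
        for c0 in range(w):
            if m[r0, c0] and not labels[r0, c0]:
                n += 1
                stack = [(r0, c0)]
                labels[r0, c0] = n
                while stack:
                    r, c = stack.pop()
                    for rr, cc in _neighbors(r, c, h, w, connectivity):
                        if m[rr, cc] and not labels[rr, cc]:
                            labels[rr, cc] = n
                            stack.append((rr, cc))
    return labels, n


def clear_border_flood(mask, connectivity=8):
    """Delete foreground reachable from any border foreground pixel."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    doomed = np.zeros_like(m)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if m[r, c] and (r in (0, h - 1) or c in (0, w - 1))
    ]
    for r, c in stack:
        doomed[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in _neighbors(r, c, h, w, connectivity):
            if m[rr, cc] and not doomed[rr, cc]:
                doomed[rr, cc] = True
                stack.append((rr, cc))
    return (m & ~doomed).astype(np.uint8)


def fill_holes_flood(mask):
    """Background 4-connected flood from the border; the rest fills."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    outside = np.zeros_like(m)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if not m[r, c] and (r in (0, h - 1) or c in (0, w - 1))
    ]
    for r, c in stack:
        outside[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in _neighbors(r, c, h, w, 4):
            if not m[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                stack.append((rr, cc))
    return (m | ~outside).astype(np.uint8)


def boundary_pixel_set(mask):
    """{p in mask : p has a background 4-neighbor or lies on border}."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = set()
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            if r in (0, h - 1) or c in (0, w - 1):
                out.add((r, c))
                continue
            if not (m[r - 1, c] and m[r + 1, c] and m[r, c - 1] and m[r, c + 1]):
                out.add((r, c))
    return out


def kmeans_exhaustive(points, k):
    """Globally optimal k-partition by enumerating all assignments."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = None
    best_cost = np.inf
    for assign in product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        cost = 0.0
        for j in range(k):
            sel = pts[[i for i in range(n) if assign[i] == j]]
            cost += ((sel - sel.mean(axis=0)) ** 2).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, assign
    return np.array(best), best_cost


def srgb_to_lab_reference(rgb):
    """CIE equations, written out: sRGB -> linear -> XYZ(D65) -> Lab."""
    c = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])  # D65
    t = xyz / white
    eps, kappa = 216 / 24389, 24389 / 27
    f = np.where(t > eps, np.cbrt(t), (kappa * t + 16) / 116)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    b = 200 * (f[1] - f[2])
    return np.array([L, a, b])
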