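"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written as a direct, slow, scalar re-statement of
the mathematical definition, sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def otsu_exhaustive(gray):
    """Search all 256 candidate thresholds for max omega0*omega1*(mu0-mu1)^2."""
    values = np.asarray(gray).ravel()
    n = len(values)
    best_t, best_score = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if len(lo) == 0 or len(hi) == 0:
            score = 0.0
        else:
            w0 = len(lo) / n
            w1 = len(hi) / n
            score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if score > best_score:  # strict: ties keep the lowest threshold
            best_score, best_t = score, t
    return best_t


def flood_fill_components(mask):
    """8-connected components by explicit BFS; returns (labels, sizes)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    sizes = {}
    nxt = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or labels[sy, sx]:
                continue
            nxt += 1
            stack = [(sy, sx)]
            labels[sy, sx] = nxt
            count = 0
            while stack:
                y, x = stack.pop()
                count += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx_ = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx_ < w and mask[ny, nx_] \
                                and not labels[ny, nx_]:
                            labels[ny, nx_] = nxt
                            stack.append((ny, nx_))
            sizes[nxt] = count
    return labels, sizes


def area_filter_bruteforce(mask, min_area):
    labels, sizes = flood_fill_components(mask)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for cid, size in sizes.items():
        if size >= min_area:
            out[labels == cid] = True
    return out


def point_in_polygon_evenodd(px, py, poly):
    """Scalar even-odd ray-casting test for one point."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 <= py < y2) or (y2 <= py < y1):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xin:
                inside = not inside
    return inside


def confusion_loop(pred, truth, k):
    cm = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        cm[t, p] += 1
    return cm


def metrics_loop(pred, truth, k):
    """mIoU and mPA from raw per-pixel counting, no confusion matrix."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    ious, recalls = [], []
    for c in range(k):
        tp = int(np.sum((pred == c) & (truth == c)))
        fp = int(np.sum((pred == c) & (truth != c)))
        fn = int(np.sum((pred != c) & (truth == c)))
        union = tp + fp + fn
        ious.append(tp / union if union else 1.0)
        recalls.append(tp / (tp + fn) if tp + fn else 1.0)
    return float(np.mean(ious)), float(np.mean(recalls))


def squeeze_loop(u):
    c, h, w = u.shape
    z = np.zeros(c)
    for ci in range(c):
        acc = 0.0
        for i in range(h):
            for j in range(w):
                acc += u[ci, i, j]
        z[ci] = acc / (h * w)
    return z


def excitation_loop(z, w1, w2):
    hdim = w1.shape[0]
    c = w2.shape[0]
    h = np.zeros(hdim)
    for i in range(hdim):
        acc = sum(w1[i, j] * z[j] for j in range(len(z)))
        h[i] = max(acc, 0.0)
    s = np.zeros(c)
    for i in range(c):
        acc = sum(w2[i, j] * h[j] for j in range(hdim))
        s[i] = 1.0 / (1.0 + np.exp(-acc))
    return s


def rescale_loop(u, s):
    out = np.zeros_like(np.asarray(u, dtype=float))
    c, h, w = u.shape
    for ci in range(c):
        for i in range(h):
            for j in range(w):
                out[ci, i, j] = s[ci] * u[ci, i, j]
    return out


def argmax_loop(logits):
    k, h, w = logits.shape
    out = np.zeros((h, w), dtype=int)
    for i in range(h):
        for j in range(w):
            best, best_v = 0, logits[0, i, j]
            for c in range(1, k):
                if logits[c, i, j] > best_v:
                    best, best_v = c, logits[c, i, j]
            out[i, j] = best
    return out


def conv1x1_loop(x, w, b):
    """Per-pixel dot product oracle for a 1x1 convolution, single map."""
    cin, h, wd = x.shape
    cout = w.shape[0]
    out = np.zeros((cout, h, wd))
    for co in range(cout):
        for i in range(h):
            for j in range(wd):
                acc = b[co]
                for ci in range(cin):
                    acc += w[co, ci, 0, 0] * x[ci, i, j]
                out[co, i, j] = acc
    return out
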