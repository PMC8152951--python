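"""Independent oracle implementations used by the acceptance checks.

These transcribe the estimator definitions directly (explicit loops over
pairs) without reusing the package's vectorised code paths.
"""

import numpy as np


def pcf_bruteforce(pattern, type_a, type_b, r, bandwidth):
    """O(n²) translation-corrected kernel PCF, straight from the definition."""
    pts_a = pattern.coords_of(type_a)
    pts_b = pattern.coords_of(type_b)
    same = type_a == type_b or (type_a is None and type_b is None)
    x0, y0, x1, y1 = pattern.window.bounds
    w_ext, h_ext = x1 - x0, y1 - y0
    area = pattern.area
    lam_a = len(pts_a) / area
    lam_b = len(pts_b) / area
    rows = []
    for i in range(len(pts_a)):
        for j in range(len(pts_b)):
            if same and i == j:
                continue
            dx = pts_b[j, 0] - pts_a[i, 0]
            dy = pts_b[j, 1] - pts_a[i, 1]
            d = np.sqrt(dx**2 + dy**2)
            ox = w_ext - np.abs(dx)
            oy = h_ext - np.abs(dy)
            w = area / (max(ox, 0.0) * max(oy, 0.0))
            u = r - d
            k = 0.75 * (1.0 - (u / bandwidth) ** 2) / bandwidth
            rows.append(np.where(np.abs(u) <= bandwidth, k, 0.0) * w)
    acc = np.zeros(len(r))
    if rows:
        acc = acc + np.vstack(rows).sum(axis=0)
    return acc / (2.0 * np.pi * r * lam_a * lam_b * area)


def greedy_merge_oracle(a_pts, b_pts, radius):
    """Nearest-first one-to-one matching by exhaustive scanning."""
    used_a, used_b, merges = set(), set(), []
    while True:
        best = None
        for i, pa in enumerate(a_pts):
            if i in used_a:
                continue
            for j, pb in enumerate(b_pts):
                if j in used_b:
                    continue
                d = float(np.hypot(pa[0] - pb[0], pa[1] - pb[1]))
                if d < radius and (best is None or (d, i, j) < best):
                    best = (d, i, j)
        if best is None:
            return merges
        _, i, j = best
        used_a.add(i)
        used_b.add(j)
        merges.append((i, j))
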