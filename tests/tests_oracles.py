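"""Independent brute-force oracles for texture statistics (test-only).

These deliberately use plain loops and literal formulas, sharing no code with
the implementation they check.
"""

import math

import numpy as np

# (row, col) steps per angle, rows increasing downward: offset = (sin a, cos a) * d
OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def brute_force_glcm(q, levels, angle_deg, distance=1, symmetric=True):
    """Direct pair counting over all pixel pairs at the given offset."""
    dr, dc = OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    m = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
    return m + m.T if symmetric else m


def brute_force_features(p):
    """The 13 texture statistics straight from their formulas."""
    L = p.shape[0]
    f = {}
    px = p.sum(1)
    py = p.sum(0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    pxy_sum = np.zeros(2 * L - 1)
    pxy_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            pxy_sum[i + j] += p[i, j]
            pxy_diff[abs(i - j)] += p[i, j]

    def ent(q):
        return -sum(v * math.log(v) for v in np.ravel(q) if v > 0)

    f["asm"] = (p ** 2).sum()
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    f["corr"] = ((sum(i * j * p[i, j] for i in range(L) for j in range(L))
                  - mu_x * mu_y) / (sd_x * sd_y)) if sd_x * sd_y > 0 else 0.0
    f["var"] = sum((i - mu_x) ** 2 * p[i, j] for i in range(L) for j in range(L))
    f["idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    f["sum_avg"] = sum(k * pxy_sum[k] for k in range(2 * L - 1))
    f["sum_var"] = sum((k - f["sum_avg"]) ** 2 * pxy_sum[k] for k in range(2 * L - 1))
    f["sum_ent"] = ent(pxy_sum)
    f["ent"] = ent(p)
    davg = sum(k * pxy_diff[k] for k in range(L))
    f["diff_var"] = sum((k - davg) ** 2 * pxy_diff[k] for k in range(L))
    f["diff_ent"] = ent(pxy_diff)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(p[i, j] * math.log(px[i] * py[j]) for i in range(L)
                for j in range(L) if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j]) for i in range(L)
                for j in range(L) if px[i] * py[j] > 0)
    f["imc1"] = (f["ent"] - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - f["ent"]))))
    return np.array(list(f.values()))
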