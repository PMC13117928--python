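"""Independent straight-line reference implementations used as oracles.

Everything here is written with explicit per-pixel loops and no shared code
with the package, so agreement with the vectorized implementations is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def _r(j: int, n: int) -> int:
    """Reflect an out-of-range index (mirror without edge repetition)."""
    if j < 0:
        return -j
    if j >= n:
        return 2 * n - 2 - j
    return j


def heaviside(z: float, eps: float) -> float:
    return 0.5 * (1.0 + (2.0 / math.pi) * math.atan(z / eps))


def delta(z: float, eps: float) -> float:
    return eps / (math.pi * (eps * eps + z * z))


def region_means_loops(u: np.ndarray, phi: np.ndarray, eps: float):
    num1 = num2 = den1 = den2 = 0.0
    h, w = u.shape
    for i in range(h):
        for j in range(w):
            hv = heaviside(phi[i, j], eps)
            num1 += u[i, j] * hv
            den1 += hv
            num2 += u[i, j] * (1.0 - hv)
            den2 += 1.0 - hv
    return num1 / den1, num2 / den2


def energy_loops(
    u: np.ndarray, phi: np.ndarray, c1: float, c2: float,
    mu: float, nu: float, lam1: float, lam2: float, eps: float,
) -> float:
    h, w = u.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            gy = 0.5 * (phi[_r(i + 1, h), j] - phi[_r(i - 1, h), j])
            gx = 0.5 * (phi[i, _r(j + 1, w)] - phi[i, _r(j - 1, w)])
            grad = math.hypot(gy, gx)
            hv = heaviside(phi[i, j], eps)
            total += mu * delta(phi[i, j], eps) * grad
            total += nu * hv
            total += lam1 * (u[i, j] - c1) ** 2 * hv
            total += lam2 * (u[i, j] - c2) ** 2 * (1.0 - hv)
    return total


def evolve_step_loops(
    u: np.ndarray, phi: np.ndarray, c1: float, c2: float,
    mu: float, nu: float, lam1: float, lam2: float,
    eps: float, dt: float, eta: float,
) -> np.ndarray:
    """One explicit update phi + dt*delta(phi)*[mu*kappa - nu - l1(u-c1)^2
    + l2(u-c2)^2] with two-stage central-difference curvature."""
    h, w = u.shape
    ny = np.zeros_like(phi)
    nx = np.zeros_like(phi)
    for i in range(h):
        for j in range(w):
            gy = 0.5 * (phi[_r(i + 1, h), j] - phi[_r(i - 1, h), j])
            gx = 0.5 * (phi[i, _r(j + 1, w)] - phi[i, _r(j - 1, w)])
            norm = math.hypot(gy, gx) + eta
            ny[i, j] = gy / norm
            nx[i, j] = gx / norm
    out = np.zeros_like(phi)
    for i in range(h):
        for j in range(w):
            kappa = 0.5 * (ny[_r(i + 1, h), j] - ny[_r(i - 1, h), j]) + 0.5 * (
                nx[i, _r(j + 1, w)] - nx[i, _r(j - 1, w)]
            )
            force = (
                mu * kappa
                - nu
                - lam1 * (u[i, j] - c1) ** 2
                + lam2 * (u[i, j] - c2) ** 2
            )
            out[i, j] = phi[i, j] + dt * delta(phi[i, j], eps) * force
    return out


def dice_sets(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def iou_sets(box_a, box_b, grid: int = 64) -> float:
    """Pixel-enumeration IoU on an integer-corner grid."""
    cells_a = {
        (x, y)
        for x in range(int(box_a[0]), int(box_a[2]))
        for y in range(int(box_a[1]), int(box_a[3]))
    }
    cells_b = {
        (x, y)
        for x in range(int(box_b[0]), int(box_b[2]))
        for y in range(int(box_b[1]), int(box_b[3]))
    }
    union = cells_a | cells_b
    return len(cells_a & cells_b) / len(union)


def hd95_brute(a: np.ndarray, b: np.ndarray, mode: str = "pooled") -> float:
    def boundary(mask):
        pts = []
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if not mask[i, j]:
                    continue
                edge = False
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if ii < 0 or jj < 0 or ii >= h or jj >= w or not mask[ii, jj]:
                        edge = True
                if edge:
                    pts.append((i, j))
        return pts

    if not a.any() and not b.any():
        return 0.0
    if not a.any() or not b.any():
        return math.hypot(*a.shape)
    pa, pb = boundary(a), boundary(b)
    d_ab = [min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in pb) for p in pa]
    d_ba = [min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in pa) for p in pb]
    if mode == "pooled":
        return float(np.percentile(d_ab + d_ba, 95))
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def average_precision_prefixes(confs, is_tp_flags, n_gt: int) -> float:
    """AP by explicit prefix PR points plus right-running precision envelope.

    ``is_tp_flags`` marks, for predictions already sorted by descending
    confidence, whether each one matches a still-unclaimed ground truth.
    """
    order = np.argsort(-np.asarray(confs), kind="stable")
    flags = [is_tp_flags[i] for i in order]
    precisions, recalls = [], []
    for k in range(1, len(flags) + 1):
        tp = sum(flags[:k])
        precisions.append(tp / k)
        recalls.append(tp / n_gt)
    ap = 0.0
    r_prev = 0.0
    for k in range(len(flags)):
        envelope = max(precisions[k:])
        ap += (recalls[k] - r_prev) * envelope
        r_prev = recalls[k]
    return ap
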