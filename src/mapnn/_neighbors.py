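"""Cell-list neighbor kernels for the continuous-space simulator.

Both kernels bin individuals into unit cells and scan the block of cells
covering the interaction radius, so expected cost is linear in population
size at fixed density.  Coordinates are passed in cell-sorted order
(contiguous per cell) for cache locality; the wrappers in this module
handle the reordering.  The mate kernel draws one weighted sample per
requested individual using single-pass weighted reservoir sampling; the
competition kernel accumulates symmetric pair interactions once per pair.
Results are contractually identical (in distribution, for the stochastic
mate draw) to brute-force all-pairs computation; the test-suite checks
both against NumPy references.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


def build_cells(x: np.ndarray, y: np.ndarray, width: float, cell_size: float):
    """Bin points into a regular grid; returns (order, cell_start, ncx, ncy).

    ``order`` lists point indices grouped by cell; ``cell_start`` has length
    ``ncx * ncy + 1`` with the usual CSR convention.
    """
    ncx = max(1, int(math.ceil(width / cell_size)))
    ncy = ncx
    cx = np.clip((x / cell_size).astype(np.int64), 0, ncx - 1)
    cy = np.clip((y / cell_size).astype(np.int64), 0, ncy - 1)
    cell = cy * ncx + cx
    order = np.argsort(cell, kind="stable")
    cell_start = np.searchsorted(cell[order], np.arange(ncx * ncy + 1))
    return order.astype(np.int64), cell_start.astype(np.int64), ncx, ncy


def mate_choice(x, y, need, width, sigma_m, seed):
    """Sample one mate (index into x/y) for each index in ``need``.

    Candidate j is selected with probability proportional to
    exp(-d^2 / (2 sigma_m^2)) among neighbors within 3 sigma_m; -1 where
    no neighbor is in range.
    """
    order, cell_start, ncx, ncy = build_cells(x, y, width, 1.0)
    pos_of = np.empty(x.size, dtype=np.int64)
    pos_of[order] = np.arange(x.size)
    xs = np.ascontiguousarray(x[order])
    ys = np.ascontiguousarray(y[order])
    need_sorted = pos_of[np.asarray(need, dtype=np.int64)]
    best = _mate_kernel(
        xs, ys, need_sorted, cell_start, ncx, ncy, 1.0, sigma_m, seed
    )
    out = np.where(best >= 0, order[np.clip(best, 0, None)], -1)
    return out


def competition(x, y, width, sigma_c, kernel_max):
    """Competition load per individual: truncated Gaussian kernel sum."""
    order, cell_start, ncx, ncy = build_cells(x, y, width, 1.0)
    xs = np.ascontiguousarray(x[order])
    ys = np.ascontiguousarray(y[order])
    eta_sorted = _eta_kernel(xs, ys, cell_start, ncx, ncy, 1.0, sigma_c, kernel_max)
    eta = np.empty(x.size)
    eta[order] = eta_sorted
    return eta


@njit(cache=True, fastmath=True)
def _mate_kernel(
    xs, ys, need, cell_start, ncx, ncy, cell_size, sigma_m, seed
):  # pragma: no cover - exercised via sim tests
    np.random.seed(seed)
    mate = np.full(need.size, -1, np.int64)
    rmax2 = 9.0 * sigma_m * sigma_m
    inv2s2 = 1.0 / (2.0 * sigma_m * sigma_m)
    reach = int(math.ceil(3.0 * sigma_m / cell_size))
    for t in range(need.size):
        i = need[t]
        xi = xs[i]
        yi = ys[i]
        cx = min(max(int(xi / cell_size), 0), ncx - 1)
        cy = min(max(int(yi / cell_size), 0), ncy - 1)
        total = 0.0
        best = -1
        for yy in range(max(0, cy - reach), min(ncy, cy + reach + 1)):
            row = yy * ncx
            for xx in range(max(0, cx - reach), min(ncx, cx + reach + 1)):
                c = row + xx
                for s in range(cell_start[c], cell_start[c + 1]):
                    if s == i:
                        continue
                    dx = xs[s] - xi
                    dy = ys[s] - yi
                    d2 = dx * dx + dy * dy
                    if d2 <= rmax2:
                        w = math.exp(-d2 * inv2s2)
                        total += w
                        if np.random.random() * total < w:
                            best = s
        mate[t] = best
    return mate


@njit(cache=True, fastmath=True)
def _eta_kernel(
    xs, ys, cell_start, ncx, ncy, cell_size, sigma_c, kernel_max
):  # pragma: no cover - exercised via sim tests
    n = xs.size
    eta = np.zeros(n)
    rmax2 = 9.0 * sigma_c * sigma_c
    inv2s2 = 1.0 / (2.0 * sigma_c * sigma_c)
    reach = int(math.ceil(3.0 * sigma_c / cell_size))
    ncells = ncx * ncy
    for c in range(ncells):
        c0 = cell_start[c]
        c1 = cell_start[c + 1]
        if c0 == c1:
            continue
        cy = c // ncx
        cx = c - cy * ncx
        # pairs within the cell
        for s in range(c0, c1):
            xi = xs[s]
            yi = ys[s]
            acc = 0.0
            for t in range(s + 1, c1):
                dx = xs[t] - xi
                dy = ys[t] - yi
                d2 = dx * dx + dy * dy
                if d2 <= rmax2:
                    w = math.exp(-d2 * inv2s2)
                    acc += w
                    eta[t] += w
            eta[s] += acc
        # pairs with forward neighbor cells: dy > 0, or dy == 0 and dx > 0
        for dyc in range(0, reach + 1):
            yy = cy + dyc
            if yy >= ncy:
                break
            x_lo = -reach if dyc > 0 else 1
            for dxc in range(x_lo, reach + 1):
                xx = cx + dxc
                if xx < 0 or xx >= ncx:
                    continue
                d = yy * ncx + xx
                d0 = cell_start[d]
                d1 = cell_start[d + 1]
                if d0 == d1:
                    continue
                for s in range(c0, c1):
                    xi = xs[s]
                    yi = ys[s]
                    acc = 0.0
                    for t in range(d0, d1):
                        dx = xs[t] - xi
                        dy = ys[t] - yi
                        d2 = dx * dx + dy * dy
                        if d2 <= rmax2:
                            w = math.exp(-d2 * inv2s2)
                            acc += w
                            eta[t] += w
                    eta[s] += acc
    return eta * kernel_max


def eta_bruteforce(x, y, sigma_c, kernel_max):
    """All-pairs reference for :func:`competition` (tests only)."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d2 = dx * dx + dy * dy
    w = kernel_max * np.exp(-d2 / (2 * sigma_c**2))
    w[d2 > 9 * sigma_c**2] = 0.0
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)
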