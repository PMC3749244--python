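"""Independent brute-force references for the spectral-detection primitives.

Everything here is written as plain double loops straight from the defining
formulas, deliberately sharing no code with the package, so the fast
implementations can be checked against them on small inputs.
"""

from __future__ import annotations

import math

import numpy as np


def laplacian_brute(values: np.ndarray) -> np.ndarray:
    """8-neighbor Laplacian (center 8, neighbors -1) with periodic wrap."""
    rows, cols = values.shape
    out = np.zeros_like(values, dtype=float)
    for i in range(rows):
        for j in range(cols):
            acc = 8.0 * values[i, j]
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    acc -= values[(i + di) % rows, (j + dj) % cols]
            out[i, j] = acc
    return out


def heterogeneity_brute(values: np.ndarray) -> np.ndarray:
    """H = normalized Laplacian x normalized intensity, elementwise."""
    L = laplacian_brute(values)
    lmin, lmax = L.min(), L.max()
    imin, imax = values.min(), values.max()
    out = np.zeros_like(values, dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            lf = (L[i, j] - lmin) / (lmax - lmin) if lmax > lmin else 0.0
            if_ = (values[i, j] - imin) / (imax - imin) if imax > imin else 0.0
            out[i, j] = lf * if_
    return out


def local_stats_brute(
    values: np.ndarray,
    excluded: np.ndarray,
    center: tuple[int, int],
    ns: int,
) -> tuple[float, float, int]:
    """Mean/population-variance over usable window pixels, clipped borders."""
    rows, cols = values.shape
    ic, jc = center
    samples = []
    for i in range(ic - ns, ic + ns + 1):
        for j in range(jc - ns, jc + ns + 1):
            if i < 0 or i >= rows or j < 0 or j >= cols:
                continue
            if (i, j) == (ic, jc) or excluded[i, j]:
                continue
            samples.append(values[i, j])
    n = len(samples)
    if n == 0:
        return float("nan"), float("nan"), 0
    ave = sum(samples) / n
    var = sum((s - ave) ** 2 for s in samples) / n
    return ave, var, n


def eig2_brute(a: float, b: float, c: float) -> tuple[float, float]:
    """Eigenvalues (descending) of the symmetric matrix [[a, b], [b, c]]."""
    half_tr = 0.5 * (a + c)
    disc = math.sqrt((0.5 * (a - c)) ** 2 + b * b)
    return half_tr + disc, half_tr - disc


def cvar_brute(
    values: np.ndarray,
    cn2: np.ndarray,
    pn2: np.ndarray,
    pn3: np.ndarray,
    ns: int = 1,
    restored0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reference constrained-variance restoration.

    Same contract as the package: central pixels tested independently
    against a frozen exclusion mask then relabeled, off-center clusters
    (8-connected, discovered in row-major order) eaten by repeated row-major
    sweeps with a live exclusion mask. Returns (values', replaced, skipped,
    restored).
    """
    rows, cols = values.shape
    out = values.copy()
    restored = (
        restored0.copy() if restored0 is not None else np.zeros_like(cn2)
    )
    replaced = np.zeros_like(cn2)
    skipped = np.zeros_like(cn2)
    noisy = cn2 | pn2

    def try_pixel(i, j, excluded):
        ave, var, n = local_stats_brute(out, excluded, (i, j), ns)
        if n == 0:
            return False
        if out[i, j] - ave > math.sqrt(var):
            out[i, j] = ave
            replaced[i, j] = True
        return True

    frozen = noisy & ~restored
    newly = []
    for i in range(rows):
        for j in range(cols):
            if cn2[i, j] and not restored[i, j]:
                if try_pixel(i, j, frozen):
                    newly.append((i, j))
                else:
                    skipped[i, j] = True
    for i, j in newly:
        restored[i, j] = True

    # flood-fill 8-connected clusters of pn3, in row-major discovery order
    seen = np.zeros_like(pn3)
    clusters = []
    for i in range(rows):
        for j in range(cols):
            if pn3[i, j] and not seen[i, j] and not restored[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                members = []
                while stack:
                    ci, cj = stack.pop()
                    members.append((ci, cj))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = ci + di, cj + dj
                            if (
                                0 <= ni < rows
                                and 0 <= nj < cols
                                and pn3[ni, nj]
                                and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                clusters.append(sorted(members))
    for members in clusters:
        pending = list(members)
        progress = True
        while pending and progress:
            progress = False
            still = []
            for i, j in pending:
                if try_pixel(i, j, noisy & ~restored):
                    restored[i, j] = True
                    progress = True
                else:
                    still.append((i, j))
            pending = still
        for i, j in pending:
            skipped[i, j] = True

    return out, replaced, skipped, restored
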