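"""Detection of potentially noisy spectral pixels in LogF.

The detection cascade narrows the whole spectrum down to a confirmed noisy
set in four stages:

1. a per-pixel heterogeneity score H in [0, 1] (normalized Laplacian times
   normalized log-intensity) flags pixels that are both bright and abruptly
   changing;
2. histogram-derived thresholds on H and intensity select the global
   candidate set ``Pn1``;
3. ``Pn1`` is split into a central disk ``C0`` (grown from the
   intensity-weighted inertia tensor of the candidates) and the off-center
   remainder ``Pn2``; the central intensity profile is modelled by an
   anisotropic 2D Gaussian and only pixels rising above it (``Cn1``) stay
   candidates;
4. a second histogram screen plus a run-length clustering rule (stripes map
   to straight pixel runs in the spectrum) confirm the noisy sets ``Cn2``
   (central) and ``Pn3`` (off-center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .spectrum import LogF

__all__ = [
    "HeterogeneityMap",
    "ThresholdSet",
    "InertiaSummary",
    "GaussianModel",
    "PixelLabelGrid",
    "laplacian_map",
    "heterogeneity_map",
    "threshold_from_histogram",
    "global_sampling",
    "inertia_summary",
    "grow_central_region",
    "fit_central_gaussian",
    "gaussian_deviation",
    "central_candidates",
    "screen_and_cluster",
]

# center 8, eight neighbors -1: a discrete Laplacian that responds to any
# deviation of a pixel from its 8-neighborhood mean
LAPLACIAN_KERNEL = np.array(
    [[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=float
)

LABEL_CODES = {
    "clean": 0,
    "Pn1": 1,
    "C0": 2,
    "Pn2": 3,
    "Cn1": 4,
    "Cn2": 5,
    "Pn3": 6,
    "restored": 7,
}


@dataclass
class HeterogeneityMap:
    """Heterogeneity score H plus the Laplacian map and normalization bounds."""

    H: np.ndarray
    L: np.ndarray
    L_min: float
    L_max: float
    I_min: float
    I_max: float


@dataclass
class ThresholdSet:
    """Thresholds derived from the heterogeneity histogram.

    ``var_ref`` is computed for diagnostics alongside ``ave_ref`` and
    ``max_ref`` but has no downstream consumer.
    """

    h_ref: float
    i_ref: float
    ave_ref: float
    max_ref: float
    var_ref: float
    bin_populations: list[int]
    threshold_bin: int | None


@dataclass
class InertiaSummary:
    """Intensity-weighted second moments of a candidate pixel set."""

    centroid: tuple[float, float]
    sigma_x: float  # larger eigenvalue
    sigma_y: float  # smaller eigenvalue
    eigvec_x: np.ndarray  # principal axis, unit vector in (row, col) coords
    eigvec_y: np.ndarray
    initial_radius: float


@dataclass
class GaussianModel:
    """Anisotropic 2D Gaussian fitted to the central-region log-intensities.

    The model surface is ``I0 * exp(-c1 (i-i0)^2 / sx' - c2 (j-j0)^2 / sy')``
    where (sx', sy') are the inertia eigenvalues rotated into the image axes
    by ``theta`` and (i0, j0) is the centroid pixel.
    """

    i0_value: float
    c1: float
    c2: float
    sigma_x_prime: float
    sigma_y_prime: float
    theta: float
    residual: float
    center: tuple[int, int]


class PixelLabelGrid:
    """Per-spectral-pixel membership in the named detection sets.

    Maintains the set algebra ``C0 | Pn2 == Pn1`` (disjoint),
    ``Cn2 <= Cn1 <= C0`` and ``Pn3 <= Pn2``, plus a ``restored`` overlay for
    pixels already tested during restoration. ``Pn2`` is derived as
    ``Pn1 & ~C0``.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        z = np.zeros(shape, dtype=bool)
        self.pn1 = z.copy()
        self.c0 = z.copy()
        self.cn1 = z.copy()
        self.cn2 = z.copy()
        self.pn3 = z.copy()
        self.restored = z.copy()

    @property
    def pn2(self) -> np.ndarray:
        return self.pn1 & ~self.c0

    def validate(self) -> None:
        if np.any(self.c0 & ~self.pn1):
            raise ValueError("C0 not a subset of Pn1")
        for sub, sup, names in (
            (self.cn1, self.c0, "Cn1 <= C0"),
            (self.cn2, self.cn1, "Cn2 <= Cn1"),
            (self.pn3, self.pn2, "Pn3 <= Pn2"),
        ):
            if np.any(sub & ~sup):
                raise ValueError(f"label invariant violated: {names}")

    def counts(self) -> dict[str, int]:
        return {
            "Pn1": int(self.pn1.sum()),
            "C0": int(self.c0.sum()),
            "Pn2": int(self.pn2.sum()),
            "Cn1": int(self.cn1.sum()),
            "Cn2": int(self.cn2.sum()),
            "Pn3": int(self.pn3.sum()),
            "restored": int(self.restored.sum()),
        }

    def label_codes(self) -> np.ndarray:
        """Deepest-set integer code per pixel, for the diagnostic raster dump."""
        codes = np.zeros(self.shape, dtype=np.int8)
        for name, mask in (
            ("Pn1", self.pn1),
            ("C0", self.c0),
            ("Pn2", self.pn2),
            ("Cn1", self.cn1),
            ("Cn2", self.cn2),
            ("Pn3", self.pn3),
            ("restored", self.restored),
        ):
            codes[mask] = LABEL_CODES[name]
        return codes


def laplacian_map(logf: LogF) -> np.ndarray:
    """Convolve LogF with the 8-neighbor Laplacian, periodic boundaries.

    Periodic wrap matches the inherent periodicity of the discrete spectrum.
    """
    return ndimage.convolve(logf.values, LAPLACIAN_KERNEL, mode="wrap")


def heterogeneity_map(logf: LogF) -> HeterogeneityMap:
    """H(i,j) = normalized Laplacian x normalized log-intensity, in [0, 1].

    Each factor is offset and scaled to [0, 1] over the whole image; a
    degenerate factor (max == min) is defined as 0 everywhere, so a flat map
    has no heterogeneous pixels.
    """
    L = laplacian_map(logf)
    I = logf.values
    L_min, L_max = float(L.min()), float(L.max())
    I_min, I_max = float(I.min()), float(I.max())
    if L_max > L_min:
        lf = (L - L_min) / (L_max - L_min)
    else:
        lf = np.zeros_like(L)
    if I_max > I_min:
        if_ = (I - I_min) / (I_max - I_min)
    else:
        if_ = np.zeros_like(I)
    return HeterogeneityMap(lf * if_, L, L_min, L_max, I_min, I_max)


def threshold_from_histogram(
    values: np.ndarray,
    n_bins: int,
    pop_ratio: float = 0.5,
) -> tuple[float, list[int], int | None]:
    """Histogram-based threshold for scores in [0, 1].

    Equal-width bins over [0, 1]. The longest run of consecutive non-empty
    bins is located (ties: larger total population, then lower value); within
    it, starting at its most populated bin and scanning toward higher values,
    the threshold bin is the first whose population is <= ``pop_ratio`` times
    the maximum bin population, and the threshold is its midpoint. If no bin
    qualifies the threshold is the upper edge of the run (selection above it
    is then empty) and the returned bin index is None.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("cannot build a histogram threshold from no values")
    if np.any(vals < 0.0) or np.any(vals > 1.0):
        raise ValueError("histogram values must lie in [0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))

    # maximal runs of consecutive non-empty bins
    runs: list[tuple[int, int]] = []  # [start, end] inclusive
    start = None
    for b in range(n_bins):
        if counts[b] > 0 and start is None:
            start = b
        elif counts[b] == 0 and start is not None:
            runs.append((start, b - 1))
            start = None
    if start is not None:
        runs.append((start, n_bins - 1))
    # most spreading run; ties broken by larger population, then lower value
    best = max(
        runs,
        key=lambda r: (r[1] - r[0], counts[r[0] : r[1] + 1].sum(), -r[0]),
    )
    seg = counts[best[0] : best[1] + 1]
    max_bin = best[0] + int(np.argmax(seg))
    max_pop = counts[max_bin]
    threshold_bin: int | None = None
    for b in range(max_bin, best[1] + 1):
        if counts[b] <= pop_ratio * max_pop:
            threshold_bin = b
            break
    if threshold_bin is None:
        threshold = float(edges[best[1] + 1])
    else:
        threshold = 0.5 * float(edges[threshold_bin] + edges[threshold_bin + 1])
    return threshold, [int(c) for c in counts], threshold_bin


def global_sampling(
    logf: LogF,
    het: HeterogeneityMap | None = None,
    n_bins: int = 20,
    pop_ratio: float = 0.5,
    h_ref_scale: float = 1.0,
) -> tuple[np.ndarray, ThresholdSet]:
    """Select the global candidate set Pn1 = {H > H_ref and I > I_ref}.

    ``H_ref`` comes from the 20-bin heterogeneity histogram; ``I_ref`` is the
    midpoint of the mean and max LogF intensity over the homogeneous pixels
    (H <= H_ref). ``h_ref_scale`` multiplies the computed H_ref (values < 1
    recruit more candidates when an image is under-denoised).
    """
    if het is None:
        het = heterogeneity_map(logf)
    h_ref, bins, threshold_bin = threshold_from_histogram(
        het.H, n_bins, pop_ratio=pop_ratio
    )
    h_ref *= h_ref_scale
    homog = het.H <= h_ref
    I = logf.values
    if np.any(homog):
        ave_ref = float(I[homog].mean())
        max_ref = float(I[homog].max())
        var_ref = float(I[homog].var())
    else:  # only possible for extreme h_ref_scale; nothing is trusted
        ave_ref = float(I.mean())
        max_ref = float(I.max())
        var_ref = float(I.var())
    i_ref = 0.5 * (max_ref + ave_ref)
    pn1 = (het.H > h_ref) & (I > i_ref)
    thresholds = ThresholdSet(
        h_ref=h_ref,
        i_ref=i_ref,
        ave_ref=ave_ref,
        max_ref=max_ref,
        var_ref=var_ref,
        bin_populations=bins,
        threshold_bin=threshold_bin,
    )
    return pn1, thresholds


def inertia_summary(pn1: np.ndarray, logf: LogF) -> InertiaSummary:
    """Intensity-weighted centroid and inertia eigensystem of Pn1.

    LogF values serve as masses; they are shifted so the minimum weight over
    Pn1 is >= 0 (LogF can be negative, and the tensor must stay positive
    semidefinite). Eigenvalues are returned in descending order; the initial
    search radius is sqrt(sigma_x + sigma_y), floored at one pixel.
    """
    idx = np.argwhere(pn1)
    if idx.shape[0] == 0:
        raise ValueError("Pn1 is empty; no inertia summary")
    w = logf.values[pn1].astype(float)
    shift = max(0.0, -float(w.min()))
    w = w + shift
    total = float(w.sum())
    if total <= 0.0:
        w = np.ones_like(w)
        total = float(w.sum())
    centroid = (w @ idx) / total
    d = idx - centroid
    tensor = (w[:, None] * d).T @ d / total
    eigvals, eigvecs = np.linalg.eigh(tensor)  # ascending
    sigma_y, sigma_x = float(eigvals[0]), float(eigvals[1])
    ex = eigvecs[:, 1]
    # deterministic sign: first non-zero component positive
    if ex[0] < 0 or (ex[0] == 0 and ex[1] < 0):
        ex = -ex
    ey = np.array([-ex[1], ex[0]])  # right-handed companion
    radius = max(1.0, float(np.sqrt(sigma_x + sigma_y)))
    return InertiaSummary(
        centroid=(float(centroid[0]), float(centroid[1])),
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        eigvec_x=ex,
        eigvec_y=ey,
        initial_radius=radius,
    )


def grow_central_region(
    pn1: np.ndarray,
    inertia: InertiaSummary,
    shape: tuple[int, int],
    grow_ratio: float = 0.85,
    grow_step_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Grow a disk about the centroid until the Pn1 density drops.

    The disk radius grows in increments of ``grow_step_frac`` of the initial
    inertia radius; growth stops at the first step where the fraction of disk
    pixels belonging to Pn1 is <= ``grow_ratio``. Returns ``(C0, Pn2,
    final_radius)`` where ``C0 = Pn1 & disk`` and ``Pn2`` is the remainder.
    Reaching the image bounds without ever diluting below the ratio stops the
    growth with a warning.
    """
    rows, cols = shape
    ci, cj = inertia.centroid
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dist = np.hypot(ii - ci, jj - cj)
    max_dist = float(dist.max())
    step = grow_step_frac * inertia.initial_radius
    r = 0.0
    disk = np.zeros(shape, dtype=bool)
    while True:
        r += step
        disk = dist <= r
        n_disk = int(disk.sum())
        if n_disk > 0:
            ratio = int((pn1 & disk).sum()) / n_disk
            if ratio <= grow_ratio:
                break
        if r >= max_dist:
            warnings.warn(
                "central region reached the image bounds before the density "
                "criterion was met",
                stacklevel=2,
            )
            break
    c0 = pn1 & disk
    pn2 = pn1 & ~disk
    return c0, pn2, r


def _rotated_sigmas(inertia: InertiaSummary) -> tuple[float, float, float]:
    """(sigma_x', sigma_y', theta): inertia eigenvalues in image-axis frame.

    theta is the counterclockwise angle between the principal eigenvector
    and the image row axis; only cos^2/sin^2 enter, so the quadrant is
    immaterial.
    """
    ex = inertia.eigvec_x
    theta = float(np.arctan2(ex[1], ex[0]))
    sx = inertia.sigma_x * np.cos(theta) ** 2 + inertia.sigma_y * np.sin(theta) ** 2
    if sx <= 0.0:
        return 0.0, 0.0, theta
    sy = inertia.sigma_x * inertia.sigma_y / sx
    return float(sx), float(sy), theta


def _gaussian_surface(
    params: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    center: tuple[int, int],
    sx: float,
    sy: float,
) -> np.ndarray:
    i0v, c1, c2 = params
    return i0v * np.exp(
        -c1 * (ii - center[0]) ** 2 / sx - c2 * (jj - center[1]) ** 2 / sy
    )


def gaussian_deviation(
    model: GaussianModel, logf: LogF, pixels: np.ndarray
) -> np.ndarray:
    """f(i,j) = I(i,j)/I0 - model envelope, for the given (n, 2) pixel array.

    Positive f means the measured log-intensity rises above the fitted
    Gaussian surface.
    """
    ii = pixels[:, 0].astype(float)
    jj = pixels[:, 1].astype(float)
    envelope = np.exp(
        -model.c1 * (ii - model.center[0]) ** 2 / model.sigma_x_prime
        - model.c2 * (jj - model.center[1]) ** 2 / model.sigma_y_prime
    )
    return logf.values[pixels[:, 0], pixels[:, 1]] / model.i0_value - envelope


def fit_central_gaussian(
    c0: np.ndarray, logf: LogF, inertia: InertiaSummary
) -> GaussianModel:
    """Fit the anisotropic Gaussian to the C0 log-intensities.

    Damped least squares on the normalized deviations f(i,j) with parameters
    (I0, c1, c2); the breadths (sigma_x', sigma_y') are fixed by the inertia
    eigensystem. Deterministic initialization: I0 = LogF at the centroid
    pixel, c1 = c2 = 1. Raises if C0 has fewer than 4 pixels or if the
    geometry or fitted peak degenerates (callers fall back to treating all
    of C0 as candidates).
    """
    pixels = np.argwhere(c0)
    if pixels.shape[0] < 4:
        raise ValueError(f"C0 has {pixels.shape[0]} pixels; need >= 4 to fit")
    sx, sy, theta = _rotated_sigmas(inertia)
    if sx <= 0.0 or sy <= 0.0:
        raise ValueError("degenerate inertia geometry: non-positive breadth")
    center = (int(round(inertia.centroid[0])), int(round(inertia.centroid[1])))
    ii = pixels[:, 0].astype(float)
    jj = pixels[:, 1].astype(float)
    data = logf.values[pixels[:, 0], pixels[:, 1]]
    i0_init = float(logf.values[center[0] % logf.shape[0], center[1] % logf.shape[1]])
    x0 = np.array([max(i0_init, 1e-6), 1.0, 1.0])

    def residuals(p: np.ndarray) -> np.ndarray:
        return data / p[0] - _gaussian_surface(
            np.array([1.0, p[1], p[2]]), ii, jj, center, sx, sy
        )

    sol = optimize.least_squares(
        residuals,
        x0,
        bounds=([1e-9, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    i0v, c1, c2 = sol.x
    if i0v <= 1e-8:
        raise ValueError("fit rejected: non-positive restored peak intensity")
    return GaussianModel(
        i0_value=float(i0v),
        c1=float(c1),
        c2=float(c2),
        sigma_x_prime=sx,
        sigma_y_prime=sy,
        theta=theta,
        residual=float(2.0 * sol.cost),
        center=center,
    )


def central_candidates(
    c0: np.ndarray, model: GaussianModel, logf: LogF
) -> np.ndarray:
    """Cn1: C0 pixels whose log-intensity exceeds the fitted Gaussian (f > 0)."""
    pixels = np.argwhere(c0)
    out = np.zeros_like(c0)
    if pixels.shape[0] == 0:
        return out
    f = gaussian_deviation(model, logf, pixels)
    keep = pixels[f > 0.0]
    out[keep[:, 0], keep[:, 1]] = True
    return out


def _qualifying_runs(
    kept: np.ndarray, roi_extent: int, run_min_len: int, roi_frac: float
) -> np.ndarray:
    """Pixels on qualifying horizontal/vertical line structures.

    Two independent catchments, applied along rows and along columns:

    * line-span criterion: the kept pixels on one line spread (first to
      last, gaps allowed) over more than ``roi_frac`` of the
      region-of-interest extent — the signature of a stripe band whose
      amplitude fluctuates along its length;
    * run criterion: a maximal gap-free run of kept pixels at least
      ``run_min_len`` long — a short dense stripe segment.

    Returns the union of pixels caught by either.
    """
    out = np.zeros_like(kept)
    span_min = roi_frac * roi_extent

    def scan(m: np.ndarray, o: np.ndarray) -> None:
        for r in range(m.shape[0]):
            cols = np.nonzero(m[r])[0]
            if cols.size == 0:
                continue
            if cols[-1] - cols[0] + 1 > span_min:
                o[r, cols] = True
            c = 0
            row = m[r]
            n = row.size
            while c < n:
                if row[c]:
                    c1 = c
                    while c < n and row[c]:
                        c += 1
                    if c - c1 >= run_min_len:
                        o[r, c1:c] = True
                else:
                    c += 1

    scan(kept, out)
    scan(kept.T, out.T)
    return out


def screen_and_cluster(
    candidates: np.ndarray,
    logf: LogF,
    roi_extent: int,
    het: HeterogeneityMap | None = None,
    n_bins: int = 10,
    pop_ratio: float = 0.5,
    run_min_len: int = 4,
    roi_frac: float = 2.0 / 3.0,
) -> np.ndarray:
    """Confirm noisy pixels by a second histogram screen plus run clustering.

    The heterogeneity values of the candidate pixels are thresholded with the
    same histogram rule (default 10 bins); surviving pixels are grouped into
    maximal horizontal and vertical runs, and a run is kept when its length
    exceeds ``roi_frac`` of the region-of-interest extent or reaches
    ``run_min_len`` consecutive pixels (stripe noise maps to straight runs in
    the spectrum). Empty input yields an empty set.
    """
    if not np.any(candidates):
        return np.zeros_like(candidates)
    if het is None:
        het = heterogeneity_map(logf)
    thr, _, _ = threshold_from_histogram(
        het.H[candidates], n_bins, pop_ratio=pop_ratio
    )
    kept = candidates & (het.H > thr)
    return _qualifying_runs(kept, roi_extent, run_min_len, roi_frac)
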