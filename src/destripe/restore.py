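"""Constrained-variance (CVAR) restoration of noisy spectral log-amplitudes.

A confirmed noisy pixel is compared against the mean of the non-noisy pixels
in its local (2*NS+1)^2 window: if it rises more than one local standard
deviation above that mean it is replaced by the mean, otherwise it is kept.
Suspected pixels (the whole off-center candidate set and the confirmed
central set) never contribute to the local statistics; pixels already tested
("restored") do, which lets clusters be eaten from their boundary inward.
Replacement can only ever lower a value, so the restored log-amplitude S'
satisfies S' <= S and the filter Phi = exp(S' - S) lies in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .detect import GaussianModel, PixelLabelGrid
from .spectrum import LogF, PhiImage

__all__ = ["RestoredLogF", "local_stats", "cvar_restore", "restore_dc", "build_phi"]


@dataclass
class RestoredLogF:
    """Restored log-amplitude S' with bookkeeping.

    ``replaced`` marks pixels whose value was lowered; ``skipped`` marks
    noisy pixels that never saw a single usable window neighbor.
    """

    values: np.ndarray
    replaced: np.ndarray
    skipped: np.ndarray


def _window_stats(
    values: np.ndarray,
    excluded: np.ndarray,
    center: tuple[int, int],
    ns: int,
) -> tuple[float, float, int]:
    rows, cols = values.shape
    ic, jc = center
    i_lo, i_hi = max(0, ic - ns), min(rows, ic + ns + 1)
    j_lo, j_hi = max(0, jc - ns), min(cols, jc + ns + 1)
    win = values[i_lo:i_hi, j_lo:j_hi]
    ok = ~excluded[i_lo:i_hi, j_lo:j_hi]
    ok = ok.copy()
    ok[ic - i_lo, jc - j_lo] = False  # the processed pixel never counts
    n = int(ok.sum())
    if n == 0:
        return float("nan"), float("nan"), 0
    vals = win[ok]
    ave = float(vals.mean())
    var = float(((vals - ave) ** 2).mean())  # population variance
    return ave, var, n


def local_stats(
    logf: LogF | np.ndarray,
    center: tuple[int, int],
    labels: PixelLabelGrid,
    ns: int = 1,
) -> tuple[float, float, int]:
    """Local mean/variance over non-noisy window pixels around ``center``.

    The window is the (2*ns+1)^2 square clipped at the image borders (no
    wrap: the window is a local smoothness estimate, and wrapping would mix
    opposite spectral corners). Excluded from the statistics are the center
    pixel itself and every pixel currently labeled noisy (in Cn2 or Pn2 and
    not yet restored). Returns ``(ave, sigma_var, n_var)``; ``n_var == 0``
    signals that no usable neighbor exists (``ave``/``sigma_var`` are NaN).
    """
    values = logf.values if isinstance(logf, LogF) else np.asarray(logf, dtype=float)
    excluded = (labels.cn2 | labels.pn2) & ~labels.restored
    return _window_stats(values, excluded, center, ns)


def cvar_restore(logf: LogF, labels: PixelLabelGrid, ns: int = 1) -> RestoredLogF:
    """Apply the CVAR replacement rule to all confirmed noisy pixels.

    Central pixels (Cn2) are tested point by point in row-major order against
    the original values (every suspected pixel is excluded from their
    statistics, so the order cannot matter) and then relabeled restored.
    Off-center pixels (Pn3) are grouped into 8-connected clusters, each
    processed by repeated row-major sweeps: a pixel is tested as soon as its
    window holds at least one usable value (n_var >= 1), relabeled restored,
    and its possibly-replaced value becomes usable by deeper cluster pixels.
    Pixels still untestable when a sweep makes no progress are skipped.

    ``labels.restored`` is updated in place.
    """
    values = logf.values.copy()
    replaced = np.zeros(logf.shape, dtype=bool)
    skipped = np.zeros(logf.shape, dtype=bool)
    noisy = labels.cn2 | labels.pn2  # exclusion base set

    def test(p: tuple[int, int], excluded: np.ndarray) -> bool:
        """CVAR-test pixel p in place; returns False when n_var == 0."""
        ave, var, n = _window_stats(values, excluded, p, ns)
        if n == 0:
            return False
        if values[p] - ave > np.sqrt(var):
            values[p] = ave
            replaced[p] = True
        return True

    # central region: point by point against a frozen exclusion mask, so the
    # result is independent of processing order; relabeling happens after.
    frozen = noisy & ~labels.restored
    tested_central = np.zeros(logf.shape, dtype=bool)
    for p in np.argwhere(labels.cn2 & ~labels.restored):
        p = (int(p[0]), int(p[1]))
        if test(p, frozen):
            tested_central[p] = True
        else:
            skipped[p] = True
    labels.restored |= tested_central

    # off-center region: cluster by cluster, boundary inward
    cluster_ids, n_clusters = ndimage.label(
        labels.pn3 & ~labels.restored, structure=np.ones((3, 3), dtype=int)
    )
    for cid in range(1, n_clusters + 1):
        pending = [
            (int(p[0]), int(p[1])) for p in np.argwhere(cluster_ids == cid)
        ]
        progress = True
        while pending and progress:
            progress = False
            still = []
            for p in pending:  # row-major by argwhere order
                if test(p, noisy & ~labels.restored):
                    labels.restored[p] = True
                    progress = True
                else:
                    still.append(p)
            pending = still
        for p in pending:
            skipped[p] = True

    return RestoredLogF(values=values, replaced=replaced, skipped=skipped)


def restore_dc(
    logf: LogF,
    model: GaussianModel,
    labels: PixelLabelGrid,
    confirmed_only: bool = True,
) -> LogF:
    """Replace a noisy spectral center pixel by the fitted Gaussian peak.

    Heavy whole-image stripes typically come from corruption of the
    zero-frequency pixel itself, whose true value no local window can
    estimate; the fitted peak intensity I0 is the model-based substitute,
    clamped to never exceed the measured value. With ``confirmed_only``
    (the default) the replacement fires only when the centroid pixel is in
    the confirmed noisy set Cn2; otherwise rising above the fitted envelope
    (membership in Cn1) suffices — but the center of any image with a
    nonzero mean towers over a smooth spectral envelope, so that looser gate
    strips the genuine scene mean from clean images too. The replaced pixel
    is marked restored so the local-window tests may use it.
    """
    center = model.center
    gate = labels.cn2 if confirmed_only else labels.cn1
    if not gate[center]:
        return logf
    out = logf.values.copy()
    out[center] = min(model.i0_value, out[center])
    labels.restored[center] = True
    return LogF(out, floor=logf.floor)


def build_phi(s: LogF, s_prime: RestoredLogF) -> PhiImage:
    """Phi = exp(S' - S): the fraction of spectral amplitude kept per pixel.

    Exactly 1 at unreplaced pixels; in (0, 1) where restoration lowered the
    log-amplitude. Any S' above S is an internal-consistency error.
    """
    diff = s_prime.values - s.values
    if np.any(diff > 1e-12):
        raise ValueError("restored log-amplitude exceeds the measured value")
    phi = np.ones_like(s.values)
    mask = s_prime.replaced
    phi[mask] = np.exp(np.minimum(diff[mask], 0.0))
    return PhiImage(phi)
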