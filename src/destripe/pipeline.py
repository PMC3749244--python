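"""End-to-end destriping pipeline.

Single pass: forward FFT -> log-amplitude -> heterogeneity -> global
sampling -> central-region formation and Gaussian modelling -> screening and
clustering -> center-pixel and CVAR restoration -> filter construction ->
inverse FFT split into restored and noise images. Fully deterministic; every
stage failure is reported with the stage name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import detect, restore, spectrum
from .detect import GaussianModel, PixelLabelGrid, ThresholdSet
from .image_io import HeightImage
from .spectrum import PhiImage

__all__ = ["DestripeParams", "DestripeResult", "StageError", "destripe"]

DIAGNOSTICS_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class DestripeParams:
    """Tunable parameters; the defaults are the ones every image is run with.

    h_bins : bins of the global heterogeneity histogram (width 0.05 on [0,1]).
    central_bins : bins of the second-stage candidate histogram.
    pop_ratio : population ratio defining the histogram threshold bin.
    grow_ratio : candidate-density stop criterion of central-region growth.
    grow_step_frac : growth increment as a fraction of the inertia radius.
    run_min_len : minimum consecutive-run length confirming stripe pixels.
    roi_frac : fraction of the region-of-interest extent a run may span
        to qualify regardless of ``run_min_len``.
    ns : local window half-width of the constrained-variance test
        (window side 2*ns + 1).
    amplitude_floor_frac : relative spectral amplitude floor before the log.
    h_ref_scale : multiplier on the computed heterogeneity threshold;
        values < 1 recruit more candidates for under-denoised images.
    """

    h_bins: int = 20
    central_bins: int = 10
    pop_ratio: float = 0.5
    grow_ratio: float = 0.85
    grow_step_frac: float = 0.1
    run_min_len: int = 4
    roi_frac: float = 2.0 / 3.0
    ns: int = 1
    amplitude_floor_frac: float = 1e-12
    h_ref_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.h_bins < 2 or self.central_bins < 2:
            raise ValueError("histogram bin counts must be >= 2")
        for name in ("pop_ratio", "grow_ratio", "roi_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.grow_step_frac <= 0:
            raise ValueError("grow_step_frac must be positive")
        if self.run_min_len < 1:
            raise ValueError("run_min_len must be >= 1")
        if self.ns < 1:
            raise ValueError("ns must be >= 1")
        if self.amplitude_floor_frac <= 0:
            raise ValueError("amplitude_floor_frac must be positive")
        if self.h_ref_scale <= 0:
            raise ValueError("h_ref_scale must be positive")


@dataclass
class DestripeResult:
    """Everything one destriping run produces.

    ``phi`` is the symmetrized filter actually applied to the spectrum;
    ``replaced`` marks spectral pixels whose log-amplitude was lowered
    (before symmetrization mirrors the attenuation onto reflected partners).
    """

    restored: HeightImage
    noise: HeightImage
    phi: PhiImage
    labels: PixelLabelGrid
    thresholds: ThresholdSet | None
    model: GaussianModel | None
    replaced: np.ndarray
    diagnostics: dict


def _negative_noise_fraction(noise: np.ndarray, dynamic_range: float) -> float:
    tol = 1e-6 * max(dynamic_range, 1e-300)
    return float((noise < -tol).mean())


def destripe(image: HeightImage, params: DestripeParams | None = None) -> DestripeResult:
    """Remove stripe noise from a height image; returns the full result.

    Deterministic: identical input and parameters give bit-identical output.
    When the global sampling finds no candidate the run short-circuits to the
    identity filter (restored == raw, noise == 0).
    """
    if params is None:
        params = DestripeParams()
    raw = image.data
    dyn = float(raw.max() - raw.min())

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    spec = stage("forward_spectrum", spectrum.forward_spectrum, image)

    def _logamp():
        amp = np.abs(spec.values)
        peak = float(amp.max())
        if peak == 0.0:
            raise ValueError("empty image: all-zero spectrum")
        floor = params.amplitude_floor_frac * peak
        return spectrum.LogF(np.log(np.maximum(amp, floor)), floor=floor)

    logf = stage("log_amplitude", _logamp)
    het = stage("heterogeneity_map", detect.heterogeneity_map, logf)
    pn1, thresholds = stage(
        "global_sampling",
        detect.global_sampling,
        logf,
        het,
        n_bins=params.h_bins,
        pop_ratio=params.pop_ratio,
        h_ref_scale=params.h_ref_scale,
    )

    labels = PixelLabelGrid(logf.shape)
    labels.pn1 = pn1.copy()
    model: GaussianModel | None = None

    if not np.any(pn1):
        # identity filter: return the raw data untouched (an FFT round
        # trip would re-introduce rounding noise for nothing)
        phi = PhiImage(np.ones(logf.shape))
        restored_img = HeightImage(raw.copy(), height_unit=image.height_unit)
        noise_img = HeightImage(np.zeros_like(raw), height_unit=image.height_unit)
        replaced = np.zeros(logf.shape, dtype=bool)
        skipped = np.zeros(logf.shape, dtype=bool)
    else:
        inertia = stage("inertia_summary", detect.inertia_summary, pn1, logf)
        c0, pn2, r_final = stage(
            "grow_central_region",
            detect.grow_central_region,
            pn1,
            inertia,
            logf.shape,
            grow_ratio=params.grow_ratio,
            grow_step_frac=params.grow_step_frac,
        )
        labels.c0 = c0

        try:
            model = detect.fit_central_gaussian(c0, logf, inertia)
            cn1 = detect.central_candidates(c0, model, logf)
        except ValueError as exc:
            warnings.warn(
                f"central Gaussian fit unavailable ({exc}); treating all "
                "central-region pixels as candidates",
                stacklevel=2,
            )
            model = None
            cn1 = c0.copy()
        labels.cn1 = cn1

        disk_diameter = max(1, int(round(2.0 * r_final)))
        cn2 = stage(
            "screen_and_cluster",
            detect.screen_and_cluster,
            cn1,
            logf,
            roi_extent=disk_diameter,
            het=het,
            n_bins=params.central_bins,
            pop_ratio=params.pop_ratio,
            run_min_len=params.run_min_len,
            roi_frac=params.roi_frac,
        )
        labels.cn2 = cn2
        pn3 = stage(
            "screen_and_cluster",
            detect.screen_and_cluster,
            pn2,
            logf,
            roi_extent=max(logf.shape),
            het=het,
            n_bins=params.central_bins,
            pop_ratio=params.pop_ratio,
            run_min_len=params.run_min_len,
            roi_frac=params.roi_frac,
        )
        labels.pn3 = pn3
        labels.validate()

        work = logf
        if model is not None:
            work = stage("restore_dc", restore.restore_dc, logf, model, labels)
        restored_logf = stage("cvar_restore", restore.cvar_restore, work, labels, params.ns)
        # a center pixel replaced by the model counts as replaced too
        dc_replaced = work.values < logf.values
        restored_logf.replaced |= dc_replaced
        phi_raw = stage("build_phi", restore.build_phi, logf, restored_logf)
        phi = stage("symmetrize_phi", spectrum.symmetrize_phi, phi_raw, logf.dc)
        replaced = restored_logf.replaced
        skipped = restored_logf.skipped
        if np.any(replaced):
            restored_img, noise_img = stage(
                "synthesize_images", spectrum.synthesize_images, spec, phi
            )
        else:  # nothing replaced: identity, bit-exact
            restored_img = HeightImage(raw.copy(), height_unit=image.height_unit)
            noise_img = HeightImage(np.zeros_like(raw), height_unit=image.height_unit)

    conservation = float(
        np.abs(raw - restored_img.data - noise_img.data).max()
    )
    if conservation > 1e-8 * max(dyn, 1e-300):
        raise StageError(
            "synthesize_images",
            ValueError(f"conservation residual {conservation:.3e} too large"),
        )
    restored_img.height_unit = image.height_unit
    noise_img.height_unit = image.height_unit
    diagnostics = {
        "schema_version": DIAGNOSTICS_SCHEMA_VERSION,
        **labels.counts(),
        "replaced": int(replaced.sum()),
        "skipped": int(skipped.sum()),
        "min_phi": float(phi.values.min()),
        "conservation_residual": conservation,
        "negative_noise_fraction": _negative_noise_fraction(noise_img.data, dyn),
        "h_ref": thresholds.h_ref if thresholds else None,
        "i_ref": thresholds.i_ref if thresholds else None,
    }
    return DestripeResult(
        restored=restored_img,
        noise=noise_img,
        phi=phi,
        labels=labels,
        thresholds=thresholds,
        model=model,
        replaced=replaced,
        diagnostics=diagnostics,
    )
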