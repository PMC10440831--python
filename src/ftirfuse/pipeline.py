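"""End-to-end orchestration: phantom -> preprocess -> register/fuse ->
quality -> cluster/ratio/unmix, driven by one validated JSON config and one
global seed.

Every stage's randomness is drawn from a named substream of the global seed,
so a rerun with the same config and seed is bit-identical; the run manifest
records SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import cubeio, fuse, phantom, preprocess, quality, unmix
from .cubeio import AffineTransform, HyperCube, PixelMask

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "save_artifacts"]


class PhantomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int] = (1012, 1012)
    class_fractions: Optional[dict[int, float]] = None
    pixel_size_hr: float = 0.25
    pixel_size_lr: float = 5.5
    psf_sigma: float = 2.75
    noise_sd: float = 0.01
    baseline_amp: float = 0.1
    scatter_amp: float = 0.02
    misregister_shift: tuple[float, float] = (3.0, -2.0)

    @model_validator(mode="after")
    def _check(self) -> "PhantomSection":
        if self.pixel_size_hr <= 0 or self.pixel_size_lr <= 0:
            raise ValueError("pixel sizes must be positive (um)")
        if self.pixel_size_lr <= self.pixel_size_hr:
            raise ValueError("FTIR pixel size must be coarser than optical")
        return self


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    amide_window: tuple[float, float] = (1600.0, 1700.0)
    quality_lo: float = 0.1
    quality_hi: float = 2.0
    paraffin_windows: tuple[tuple[float, float], ...] = (
        (1350.0, 1500.0),
        (2835.0, 3000.0),
    )
    fingerprint: tuple[float, float] = (900.0, 1800.0)
    denoise_components: int = 20
    emsc_iterations: int = 1

    @model_validator(mode="after")
    def _check(self) -> "PreprocessSection":
        if not self.quality_lo < self.quality_hi:
            raise ValueError("quality_lo must be below quality_hi")
        for lo, hi in (self.amide_window, self.fingerprint, *self.paraffin_windows):
            if not lo < hi:
                raise ValueError(f"window [{lo}, {hi}] must be increasing")
        return self

    def to_config(self) -> preprocess.PreprocessConfig:
        return preprocess.PreprocessConfig(
            amide_window=self.amide_window,
            quality_lo=self.quality_lo,
            quality_hi=self.quality_hi,
            paraffin_windows=self.paraffin_windows,
            fingerprint=self.fingerprint,
            denoise_components=self.denoise_components,
            emsc_iterations=self.emsc_iterations,
        )


class FusionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    # PSF applied when degrading the pan to the FTIR grid.  The default 0
    # (pure block average) keeps the degradation the exact adjoint of
    # upsampling: the FTIR cube already embodies the instrument PSF, so an
    # extra Gaussian would double-count blur and break Wald consistency.
    psf_sigma: float = 0.0


class UnmixSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_clusters: int = 3
    ratio_numerator: float = 1252.0
    ratio_denominator: float = 1285.0
    percentile: float = 95.0
    chi2_threshold: Optional[float] = None
    nonneg: bool = True


class QualitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rescale_p95: bool = True


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    phantom: PhantomSection = PhantomSection()
    preprocess: PreprocessSection = PreprocessSection()
    fusion: FusionSection = FusionSection()
    quality: QualitySection = QualitySection()
    unmix: UnmixSection = UnmixSection()


def validate_config(source: str | dict | None = None) -> PipelineConfig:
    """Normalise a JSON config file (or dict); unknown keys are rejected.

    An empty or missing document yields the full default config.
    """
    if source is None:
        payload: dict = {}
    elif isinstance(source, dict):
        payload = source
    else:
        with open(source) as fh:
            text = fh.read().strip()
        payload = json.loads(text) if text else {}
    return PipelineConfig.model_validate(payload)


def _substream(seed: int, name: str) -> int:
    """Derive a deterministic named substream seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig | dict | None = None) -> dict:
    """Execute every stage on the synthetic phantom; returns all results.

    Stages: phantom generation (scene, reference spectra, pseudo-H&E, FTIR
    cube, optional misregistration), control-point affine registration,
    preprocessing, regression fusion with equalisation, quality metrics,
    k-means clustering, the 1252/1285 ratio image, and molecular unmixing
    with the RGB composite.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    ph = cfg.phantom
    seed = cfg.seed

    # --- phantom -----------------------------------------------------------
    scene = phantom.make_scene(
        ph.shape, ph.class_fractions, seed=_substream(seed, "scene"),
        pixel_size_hr=ph.pixel_size_hr,
    )
    axis = phantom.default_axis()
    refs = phantom.make_reference_spectra(axis, seed=_substream(seed, "refs"))
    he = phantom.render_pseudo_he(scene)
    cube_raw = phantom.render_ftir(
        scene, refs,
        pixel_size_lr=ph.pixel_size_lr,
        psf_sigma=ph.psf_sigma,
        noise_sd=ph.noise_sd,
        baseline_amp=ph.baseline_amp,
        scatter_amp=ph.scatter_amp,
        seed=_substream(seed, "ftir"),
    )

    # --- registration ------------------------------------------------------
    shift = ph.misregister_shift
    registration: dict = {"applied": False}
    he_registered = he
    if shift != (0.0, 0.0):
        T = AffineTransform.translation(*shift)
        he_moved = phantom.misregister(he, T)
        # control points from the known correspondence (stands in for
        # manually clicked landmark pairs)
        rows, cols = he.shape[:2]
        src = np.array(
            [[10, 10], [cols - 11, 10], [10, rows - 11],
             [cols - 11, rows - 11], [cols / 2, rows / 2]],
            dtype=float,
        )
        dst = T.apply(src)
        fitted = cubeio.fit_affine(dst, src)  # maps moved -> original frame
        he_registered = phantom.misregister(he_moved, fitted)
        registration = {
            "applied": True,
            "true_shift": list(shift),
            "fitted_matrix": fitted.matrix.tolist(),
        }

    # --- preprocess --------------------------------------------------------
    pre_cfg = cfg.preprocess.to_config()
    cube_pre, mask, pre_report = preprocess.preprocess_pipeline(
        cube_raw, pre_cfg, constituents=refs.values
    )

    # --- fusion ------------------------------------------------------------
    factor = int(round(ph.pixel_size_lr / ph.pixel_size_hr))
    rows_hr = cube_pre.nrows * factor
    cols_hr = cube_pre.ncols * factor
    he_crop = he_registered[:rows_hr, :cols_hr]
    pan_hr = fuse.grayscale_standardise(he_crop, pixel_size=ph.pixel_size_hr)
    pan_lr = fuse.degrade_to_lowres(
        pan_hr, ph.pixel_size_lr, psf_sigma=cfg.fusion.psf_sigma
    )
    model = fuse.fit_fusion_model(cube_pre, pan_lr, mask)
    # the high-resolution stage runs in float32: ~1M px x ~166 bands
    cube_pre32 = HyperCube(
        cube_pre.data.astype(np.float32), cube_pre.axis, cube_pre.pixel_size
    )
    cube_up = fuse.upsample_bicubic(cube_pre32, ph.pixel_size_hr)
    fused = fuse.apply_fusion(model, cube_up, pan_hr)
    mask_hr = PixelMask(
        np.kron(mask.mask, np.ones((factor, factor), dtype=bool))
    )
    fused, flagged_bands = fuse.equalise_to_reference(fused, cube_up, mask_hr)
    fused = fuse.enforce_spectral_consistency(
        fused, cube_pre, psf_sigma=cfg.fusion.psf_sigma
    )

    # --- quality -----------------------------------------------------------
    qreport = quality.fusion_quality_report(
        fused, cube_up, pan=pan_hr.values, mask=mask_hr,
        rescale_p95=cfg.quality.rescale_p95,
    )
    amide_idx = fused.band_index(1650.0)
    amide_upsampled = cube_up.data[:, :, amide_idx].copy()
    del cube_up  # large at high resolution; the report retains what it needs
    wald = fuse.degrade_cube(fused, ph.pixel_size_lr, psf_sigma=cfg.fusion.psf_sigma)
    _, wald_sam = quality.sam(wald, cube_pre, mask)
    qreport["wald_sam_mean"] = wald_sam

    # --- cluster / ratio / unmix ------------------------------------------
    um = cfg.unmix
    cluster = unmix.kmeans_spectra(
        cube_pre, mask, k=um.k_clusters, seed=_substream(seed, "kmeans")
    )
    ratio, ratio_log = unmix.ratio_image(
        fused, um.ratio_numerator, um.ratio_denominator, mask_hr
    )
    refs_fp = phantom.ReferenceSpectra(
        cube_pre.axis, refs.names, refs.resample(cube_pre.axis).values
    )
    result = unmix.lsf_unmix(
        fused, refs_fp, mask_hr, chi2_threshold=um.chi2_threshold,
        nonneg=um.nonneg,
    )
    composite = unmix.rgb_composite(result, percentile=um.percentile)

    return {
        "config": cfg,
        "scene": scene,
        "refs": refs,
        "pseudo_he": he,
        "registration": registration,
        "cube_raw": cube_raw,
        "cube_pre": cube_pre,
        "mask": mask,
        "mask_hr": mask_hr,
        "preprocess_report": pre_report,
        "fusion_model": model,
        "amide_band_index": amide_idx,
        "amide_upsampled": amide_upsampled,
        "fused": fused,
        "equalise_flagged_bands": flagged_bands,
        "quality_report": qreport,
        "cluster": cluster,
        "ratio": ratio,
        "ratio_log": ratio_log,
        "unmix": result,
        "rgb_composite": composite,
        "pan_hr": pan_hr,
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_artifacts(results: dict, outdir: str) -> dict:
    """Write every pipeline artifact under ``outdir`` plus a hash manifest."""
    import imageio.v3 as iio
    import tifffile

    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []

    def p(name: str) -> str:
        full = os.path.join(outdir, name)
        paths.append(full)
        return full

    scene = results["scene"]
    iio.imwrite(p("label_map.png"), scene.label_map.astype(np.uint8))
    tifffile.imwrite(p("truth_abundance.tif"), scene.truth_abundance.astype(np.float32),
        photometric="minisblack")
    refs = results["refs"]
    pd.DataFrame(
        {"wavenumber": refs.axis}
        | {name: refs.values[:, j] for j, name in enumerate(refs.names)}
    ).to_csv(p("reference_spectra.csv"), index=False)
    iio.imwrite(
        p("pseudo_he.png"),
        (np.clip(results["pseudo_he"], 0, 1) * 255).astype(np.uint8),
    )
    cubeio.write_cube(results["cube_raw"], p("cube_raw.hdr"))
    paths.append(os.path.join(outdir, "cube_raw.dat"))
    cubeio.write_cube(results["cube_pre"], p("cube_preprocessed.hdr"))
    paths.append(os.path.join(outdir, "cube_preprocessed.dat"))
    iio.imwrite(
        p("mask.png"), (results["mask"].mask * 255).astype(np.uint8)
    )
    cubeio.write_cube(results["fused"], p("cube_fused.hdr"))
    paths.append(os.path.join(outdir, "cube_fused.dat"))

    q = results["quality_report"]
    with open(p("quality_report.json"), "w") as fh:
        json.dump(
            {
                "ssim_per_band": q["ssim_per_band"].tolist(),
                "psnr_per_band": q["psnr_per_band"].tolist(),
                "mse_per_band": q["mse_per_band"].tolist(),
                "sam_mean_rad": q["sam_mean"],
                "wald_sam_mean_rad": q["wald_sam_mean"],
            },
            fh,
            indent=2,
        )
    cluster = results["cluster"]
    iio.imwrite(
        p("cluster_labels.png"), (cluster.labels + 1).astype(np.uint8)
    )
    pd.DataFrame(
        cluster.centroids.T,
        columns=[f"cluster_{j}" for j in range(cluster.centroids.shape[0])],
    ).assign(wavenumber=results["cube_pre"].axis).to_csv(
        p("cluster_centroids.csv"), index=False
    )
    iio.imwrite(
        p("ratio_1252_1285.png"),
        (unmix.ratio_to_rgb(results["ratio"]) * 255).astype(np.uint8),
    )
    um = results["unmix"]
    tifffile.imwrite(p("abundance.tif"), um.abundance.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(p("chi2.tif"), um.chi2.astype(np.float32))
    iio.imwrite(
        p("rgb_composite.png"),
        (np.clip(results["rgb_composite"], 0, 1) * 255).astype(np.uint8),
    )

    manifest = {
        "seed": results["config"].seed,
        "config": json.loads(results["config"].model_dump_json()),
        "registration": results["registration"],
        "ratio_bands": results["ratio_log"],
        "preprocess_report": results["preprocess_report"],
        "artifacts": {
            os.path.basename(f): _sha256(f) for f in sorted(set(paths))
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
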