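"""Bootstrapped distribution summaries and end-to-end orchestration.

``run_analysis`` drives the full pipeline for every requested
(region x resolution) cell: render/load -> resample -> sample patches ->
normalize -> whiten -> ICA -> split -> fit Gabors -> disparity measures ->
bootstrap summaries.  Everything is deterministic given the seed block.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import gabor, ica, metrics, preprocessing, sampling, synthetic_data

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BootstrapHistogram:
    bin_edges: np.ndarray
    median_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int


def bootstrap_histogram(values, bin_edges, n_boot: int = 200,
                        seed: int = 0) -> BootstrapHistogram:
    """Per-bin median and 95% percentile envelope over ``n_boot``
    resamples (with replacement) of the value set; each resampled
    histogram is normalized to proportions."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("bootstrap of empty values")
    edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    hists = np.empty((n_boot, edges.size - 1))
    for b in range(n_boot):
        resample = v[rng.integers(0, v.size, size=v.size)]
        counts, _ = np.histogram(resample, bins=edges)
        hists[b] = counts / v.size
    return BootstrapHistogram(
        bin_edges=edges,
        median_curve=np.median(hists, axis=0),
        ci_low=np.percentile(hists, 2.5, axis=0),
        ci_high=np.percentile(hists, 97.5, axis=0),
        n_boot=n_boot, seed=seed,
    )


def spearman_dx_dy(dx, dy) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p value."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise ValueError("dx/dy length mismatch")
    if dx.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = sps.spearmanr(dx, dy)
    return float(rho), float(p)


@dataclasses.dataclass
class AnalysisConfig:
    """Configuration block for a full synthetic-scene analysis."""

    # scene / geometry
    interocular_mm: float = 65.0
    fixation_mm: float = 2000.0
    field_half_width_arcmin: float = 600.0
    eye_height_mm: float = 1600.0
    texture_alpha: float = 1.0
    vertical_gain: float = 0.0
    # sampling
    regions: Sequence[sampling.RegionSpec] = dataclasses.field(
        default_factory=lambda: [sampling.RegionSpec(b) for b in
                                 ("centre", "mid", "outer")])
    resolutions: Sequence[float] = (4.0,)
    patch_size: int = 16
    n_patches: int = 10_000
    # model
    n_components: int = 128
    ratio_threshold: float = 0.25
    max_residual: float = 0.5
    # statistics
    n_boot: int = 200
    disparity_bins: int = 21
    disparity_range_arcmin: float = 40.0
    phase_bins: int = 32
    orientation_bins: int = 18
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [[r.band, r.quadrant] for r in self.regions]
        d["resolutions"] = list(self.resolutions)
        return d


def _hist_dict(bh: BootstrapHistogram) -> dict:
    return {
        "bin_edges": [float(x) for x in bh.bin_edges],
        "median": [float(x) for x in bh.median_curve],
        "ci_low": [float(x) for x in bh.ci_low],
        "ci_high": [float(x) for x in bh.ci_high],
        "n_boot": bh.n_boot,
    }


def components_table(components, region: sampling.RegionSpec,
                     resolution: float) -> pd.DataFrame:
    """Tidy per-component fit table (one row per component)."""
    rows = []
    for c in components:
        row = {
            "region": region.band, "quadrant": region.quadrant,
            "resolution": resolution, "index": c.index,
            "left_energy": c.left_energy, "right_energy": c.right_energy,
            "binocular_ratio": c.binocular_ratio,
            "valid": c.valid, "rejection": c.rejection,
        }
        for eye, g in (("left", c.gabor_left), ("right", c.gabor_right)):
            for field in ("theta", "f", "phi", "sigma_w", "sigma_h", "psi",
                          "centre_x", "centre_y", "amplitude", "fit_error"):
                row[f"{eye}_{field}"] = getattr(g, field) if g else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def analyse_cell(
    pair: synthetic_data.BinocularImagePair,
    region: sampling.RegionSpec,
    resolution: float,
    cfg: AnalysisConfig,
    seed: int,
) -> dict:
    """One (region x resolution) cell of the analysis.

    Returns the per-cell report dict together with the fitted components
    under the ``"components"`` key (stripped before JSON serialization).
    """
    resampled = sampling.resample_pair(pair, resolution)
    geometry = sampling.PatchGeometry(cfg.patch_size, cfg.patch_size, resolution)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(3)]

    patches = sampling.sample_patches(resampled, region, geometry,
                                      cfg.n_patches, rng_seed=seeds[0])
    patches = preprocessing.normalize_patchset(patches)
    whitening = preprocessing.fit_whitening(patches, cfg.n_components)
    Z = preprocessing.whiten(whitening, patches)
    model = ica.fit_ica(Z, rng_seed=seeds[1])

    components = [
        gabor.fit_component(c, ratio_threshold=cfg.ratio_threshold,
                            max_residual=cfg.max_residual)
        for c in ica.split_all(model, whitening, geometry)
    ]
    ratios = np.array([c.binocular_ratio for c in components])
    monocular = float(np.mean(ratios < cfg.ratio_threshold))
    valid = [c for c in components if c.valid]
    cell: dict = {
        "region": [region.band, region.quadrant],
        "resolution": resolution,
        "n_components": len(components),
        "monocular_proportion": monocular,
        "binocular_proportion": 1.0 - monocular,
        "valid_proportion": len(valid) / len(components),
        "ica_converged": model.converged,
        "variance_fraction_retained": whitening.variance_fraction,
    }
    if valid:
        meas = [metrics.component_measures(c, resolution) for c in valid]
        dx = np.array([m.dx for m in meas])
        dy = np.array([m.dy for m in meas])
        dphi = np.array([m.dphi for m in meas])
        dtheta = np.array([m.dtheta for m in meas])
        freq = np.array([m.freq for m in meas])

        lim = cfg.disparity_range_arcmin
        d_edges = np.linspace(-lim, lim, cfg.disparity_bins + 1)
        phi_edges = np.linspace(0.0, np.pi, cfg.phase_bins + 1)
        th_edges = np.linspace(0.0, 90.0, cfg.orientation_bins + 1)
        f_edges = np.linspace(0.0, 0.5, 26)
        boot_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(4)]

        phase_counts, _ = np.histogram(dphi, bins=phi_edges)
        rho, p = (spearman_dx_dy(dx, dy) if dx.size >= 3
                  else (float("nan"), float("nan")))
        cell.update({
            "n_valid": len(valid),
            "median_dx": float(np.median(dx)),
            "median_dy": float(np.median(dy)),
            "mad_dx": metrics.mad(dx),
            "mad_dy": metrics.mad(dy),
            "mad_dtheta": metrics.mad(dtheta),
            "median_freq": float(np.median(freq)),
            "phase_asymmetry": metrics.asymmetry(
                phase_counts / phase_counts.sum()),
            "spearman_rho": rho,
            "spearman_p": p,
            "dx_hist": _hist_dict(bootstrap_histogram(
                np.clip(dx, -lim, lim), d_edges, cfg.n_boot, boot_seeds[0])),
            "dy_hist": _hist_dict(bootstrap_histogram(
                np.clip(dy, -lim, lim), d_edges, cfg.n_boot, boot_seeds[1])),
            "phase_hist": _hist_dict(bootstrap_histogram(
                dphi, phi_edges, cfg.n_boot, boot_seeds[2])),
            "freq_hist": _hist_dict(bootstrap_histogram(
                freq, f_edges, cfg.n_boot, boot_seeds[3])),
        })
    else:
        cell["n_valid"] = 0
    cell["components"] = components
    return cell


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Full pipeline over every (region x resolution) cell.

    Per-cell failures are recorded under an ``"error"`` key and the run
    continues.  The returned report echoes the configuration; strip the
    in-memory ``"components"`` entries with :func:`report_json` to
    serialize.
    """
    master = np.random.SeedSequence(cfg.seed)
    scene_ss, cells_ss = master.spawn(2)
    geometry = synthetic_data.ViewingGeometry(
        interocular_mm=cfg.interocular_mm,
        fixation_mm=cfg.fixation_mm,
        field_half_width_arcmin=cfg.field_half_width_arcmin,
    )
    scene = synthetic_data.SceneSpec(
        eye_height_mm=cfg.eye_height_mm,
        texture_alpha=cfg.texture_alpha,
        vertical_gain=cfg.vertical_gain,
        rng_seed=int(scene_ss.generate_state(1)[0]),
    )
    pair, _ = synthetic_data.render_stereo_pair(scene, geometry)

    n_cells = len(cfg.regions) * len(cfg.resolutions)
    cell_seeds = [int(s.generate_state(1)[0]) for s in cells_ss.spawn(n_cells)]
    report = {"config": cfg.to_dict(), "cells": []}
    i = 0
    for region in cfg.regions:
        for resolution in cfg.resolutions:
            t0 = time.perf_counter()
            try:
                cell = analyse_cell(pair, region, resolution, cfg, cell_seeds[i])
            except Exception as err:  # noqa: BLE001 - recorded per cell
                logger.exception("cell (%s, %s) failed", region, resolution)
                cell = {"region": [region.band, region.quadrant],
                        "resolution": resolution, "error": str(err)}
            cell["elapsed_s"] = round(time.perf_counter() - t0, 3)
            logger.info("cell (%s/%s @ %s arcmin/sample) done in %.1fs",
                        region.band, region.quadrant, resolution,
                        cell["elapsed_s"])
            report["cells"].append(cell)
            i += 1
    return report


def report_json(report: dict) -> str:
    """Canonical JSON form of a report (in-memory objects stripped)."""
    def strip(cell):
        return {k: v for k, v in cell.items()
                if k not in ("components", "elapsed_s")}

    clean = {"config": report["config"],
             "cells": [strip(c) for c in report["cells"]]}
    return json.dumps(clean, sort_keys=True, indent=1)
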