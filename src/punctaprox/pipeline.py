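"""End-to-end orchestration of the two analysis tracks.

The proximity track mirrors the two-channel STED quantification: render
(or load) a channel pair, detect puncta in each channel (blur →
rolling-ball background subtraction → Analyze-Particles-style
segmentation with centres of mass from the raw images), optionally
restrict to a junctional region, compute windowed nearest-neighbour
distances, and fit the two-component distance density with confidence
intervals and the degeneracy rule.

The morphometry track generates (or receives) junction images and
reports per-profile Gaussian FWHM widths, per-trace coefficients of
variance, and mask-normalised junctional intensities per group.

Every run report embeds the full configuration, its hash, the seed and
the package version, and reruns with the same configuration are
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import (RegionMask, apply_region_mask, gaussian_blur,
                     segment_particles, subtract_background)
from .distfit import fit_distance_model
from .image import Image, read_tiff, write_tiff
from .morpho import (extract_line_profile, gaussian_fwhm, mask_from_channel,
                     normalised_junctional_intensity, profile_cov)
from .proximity import build_histogram, nearest_neighbour_distances
from .synthgen import (FWHM_FACTOR, RenderSpec, SynthTruth,
                       generate_junction_image, generate_point_pattern,
                       render_image)

__all__ = [
    "DetectionConfig", "ProximityConfig", "MorphometryGroup", "PipelineConfig",
    "run_proximity_pipeline", "run_morphometry_pipeline",
]


@dataclass
class DetectionConfig:
    """Preprocessing and segmentation parameters (µm units).

    Defaults follow the standard STED puncta workflow: 0.015 µm blur,
    3 px rolling ball, areas up to 0.02 µm², circularity 0–1, Otsu
    threshold.
    """

    blur_sigma_um: float = 0.015
    background_radius_px: int = 3
    min_area_um2: float = 0.0
    max_area_um2: float = 0.02
    circ_min: float = 0.0
    circ_max: float = 1.0
    threshold: str | float = "otsu"


@dataclass
class ProximityConfig:
    """Nearest-neighbour window, binning and fit settings."""

    window_um: float = 0.5
    bin_width_um: float = 0.01
    n_components: int = 2
    pool_images: bool = True


@dataclass
class MorphometryGroup:
    """One synthetic morphometry condition (e.g. a treatment group)."""

    name: str
    ridge_fwhm_um: float = 0.5
    n_profiles: int = 50
    # SNR (amplitude/noise) 10, with the baseline well above the noise
    # floor so min-normalised CoV traces stay positive
    amplitude: float = 500.0
    baseline: float = 100.0
    noise_sd: float = 50.0


@dataclass
class PipelineConfig:
    """Complete configuration for a run; round-trips through YAML/JSON."""

    truth: SynthTruth = field(default_factory=SynthTruth)
    render: RenderSpec = field(default_factory=RenderSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    morphometry: list[MorphometryGroup] = field(default_factory=list)
    image_a: str | None = None
    image_b: str | None = None
    pixel_size: float | None = None
    junction_polygon: list | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.to_dict(),
            "render": self.render.to_dict(),
            "detection": dataclasses.asdict(self.detection),
            "proximity": dataclasses.asdict(self.proximity),
            "morphometry": [dataclasses.asdict(g) for g in self.morphometry],
            "image_a": self.image_a,
            "image_b": self.image_b,
            "pixel_size": self.pixel_size,
            "junction_polygon": self.junction_polygon,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .distfit import RicianMixtureParams
        t = dict(d.get("truth", {}))
        if "mixture" in t:
            t["mixture"] = RicianMixtureParams(**t["mixture"])
        if t.get("field_size") is not None:
            t["field_size"] = tuple(t["field_size"])
        if t.get("junction_path") is not None:
            t["junction_path"] = np.asarray(t["junction_path"], dtype=float)
        return cls(
            truth=SynthTruth(**t),
            render=RenderSpec(**d.get("render", {})),
            detection=DetectionConfig(**d.get("detection", {})),
            proximity=ProximityConfig(**d.get("proximity", {})),
            morphometry=[MorphometryGroup(**g) for g in d.get("morphometry", [])],
            image_a=d.get("image_a"),
            image_b=d.get("image_b"),
            pixel_size=d.get("pixel_size"),
            junction_polygon=d.get("junction_polygon"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (each < 2^31) from one base seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def _report_header(config: PipelineConfig) -> dict:
    return {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
    }


def _prepare_output(output_dir, force: bool) -> Path | None:
    if output_dir is None:
        return None
    outdir = Path(output_dir)
    report_path = outdir / "report.json"
    if report_path.exists() and not force:
        raise FileExistsError(
            f"{report_path} exists; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def detect_channel(raw: Image, det: DetectionConfig):
    """Run the full preprocessing + segmentation chain on one channel."""
    blurred = gaussian_blur(raw, det.blur_sigma_um)
    cleaned = subtract_background(blurred, det.background_radius_px)
    return segment_particles(cleaned, raw,
                             min_area_um2=det.min_area_um2,
                             max_area_um2=det.max_area_um2,
                             circ_min=det.circ_min, circ_max=det.circ_max,
                             threshold=det.threshold)


def run_proximity_pipeline(config: PipelineConfig, output_dir=None,
                           force: bool = False) -> dict:
    """Simulate/load a channel pair, detect puncta, and fit NN distances.

    Returns a JSON-serialisable report; when ``output_dir`` is given the
    particle tables, distances, histogram, fit and report are written
    there (refusing to overwrite an existing report unless ``force``).
    """
    outdir = _prepare_output(output_dir, force)
    report = _report_header(config)
    warnings_list: list[str] = []

    if config.image_a is not None and config.image_b is not None:
        raw_a = read_tiff(config.image_a, pixel_size=config.pixel_size,
                          channel_label="A")
        raw_b = read_tiff(config.image_b, pixel_size=config.pixel_size,
                          channel_label="B")
        field_size = (raw_a.width_um, raw_a.height_um)
        report["inputs"] = {"image_a": str(config.image_a),
                            "image_b": str(config.image_b)}
    else:
        truth_seed, seed_a, seed_b = _derive_seeds(config.seed, 3)
        truth = replace(config.truth, seed=truth_seed)
        pat_a, pat_b, truth = generate_point_pattern(truth)
        field_size = truth.field_size
        raw_a = render_image(pat_a, replace(config.render, seed=seed_a),
                             field_size=field_size, channel_label="A")
        raw_b = render_image(pat_b, replace(config.render, seed=seed_b),
                             field_size=field_size, channel_label="B")
        report["inputs"] = {"simulated": True, "truth": truth.to_dict(),
                            "n_points_a": len(pat_a), "n_points_b": len(pat_b)}

    particles = {}
    for label, raw in (("A", raw_a), ("B", raw_b)):
        particles[label] = detect_channel(raw, config.detection)

    if config.junction_polygon is not None:
        mask = RegionMask(polygon=np.asarray(config.junction_polygon, dtype=float))
        for label in particles:
            particles[label] = apply_region_mask(particles[label], mask)

    report["detection"] = {
        "n_particles_a": len(particles["A"]),
        "n_particles_b": len(particles["B"]),
        "parameters": dataclasses.asdict(config.detection),
    }

    sample = nearest_neighbour_distances(particles["A"], particles["B"],
                                         window_um=config.proximity.window_um)
    report["distances"] = sample.summary()
    if sample.n_excluded > 0:
        warnings_list.append(
            f"{sample.n_excluded} query puncta had no reference within the window")

    fit_dict = None
    hist = None
    if len(sample) >= 3 * config.proximity.n_components:
        hist = build_histogram(sample, config.proximity.bin_width_um)
        fit = fit_distance_model(hist, n_components=config.proximity.n_components)
        fit_dict = fit.to_dict()
        if fit.degenerate:
            warnings_list.append("distance-distribution fit is degenerate "
                                 "(CI half-width exceeds estimate)")
    else:
        warnings_list.append("too few distances to fit the distance model")
    report["fit"] = fit_dict
    report["warnings"] = warnings_list

    if outdir is not None:
        for label, raw in (("A", raw_a), ("B", raw_b)):
            write_tiff(outdir / f"channel_{label}.tif", raw)
            particles[label].to_dataframe().to_csv(
                outdir / f"particles_{label}.csv", index=False)
        pd.DataFrame({"distance_um": sample.distances}).to_csv(
            outdir / "distances.csv", index=False)
        if hist is not None:
            pd.DataFrame({"bin_left_um": hist.bin_edges[:-1],
                          "bin_right_um": hist.bin_edges[1:],
                          "density_per_um": hist.density}).to_csv(
                outdir / "histogram.csv", index=False)
        if fit_dict is not None:
            (outdir / "fit.json").write_text(json.dumps(fit_dict, indent=2))
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def run_morphometry_pipeline(config: PipelineConfig, output_dir=None,
                             force: bool = False) -> dict:
    """Generate per-group junction images and tabulate width/CoV/intensity.

    For each configured group, ``n_profiles`` junction images are
    simulated at the group's true FWHM; each contributes one
    perpendicular line profile (Gaussian-fitted width and CoV) and one
    mask-normalised junctional intensity.
    """
    if not config.morphometry:
        raise ValueError("config.morphometry lists no groups")
    outdir = _prepare_output(output_dir, force)
    report = _report_header(config)

    seeds = _derive_seeds(config.seed, sum(g.n_profiles for g in config.morphometry))
    seed_iter = iter(seeds)
    rows = []
    for group in config.morphometry:
        ridge_sigma = group.ridge_fwhm_um / FWHM_FACTOR
        for rep in range(group.n_profiles):
            spec = replace(config.render, seed=next(seed_iter))
            img, true_fwhm = generate_junction_image(
                ridge_sigma, amplitude=group.amplitude,
                baseline=group.baseline, noise_sd=group.noise_sd, spec=spec)
            h_um = img.height_um
            w_um = img.width_um
            profile = extract_line_profile(
                img, (0.0, h_um / 2.0), (w_um, h_um / 2.0), width_px=3)
            fit = gaussian_fwhm(profile)
            cov = profile_cov(profile, normalise="min")
            jmask = mask_from_channel(img)
            bmask_raster = ~jmask.as_raster(img.shape, img.pixel_size)
            bmask = RegionMask(raster=bmask_raster, kind="non_junctional",
                               pixel_size=img.pixel_size)
            nji = normalised_junctional_intensity(img, jmask, bmask)
            rows.append({
                "group": group.name, "replicate": rep,
                "true_fwhm_um": true_fwhm, "fwhm_um": fit.fwhm,
                "fit_converged": fit.converged, "cov": cov,
                "normalised_intensity": nji,
            })

    table = pd.DataFrame(rows)
    summary = (table.groupby("group")[["fwhm_um", "cov", "normalised_intensity"]]
               .agg(["median", "mean", "std"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    report["table"] = table.to_dict(orient="list")
    report["summary"] = {g: row.to_dict() for g, row in summary.iterrows()}

    if outdir is not None:
        table.to_csv(outdir / "morphometry.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report
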