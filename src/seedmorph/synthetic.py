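"""Synthetic seed populations with known ground truth.

Shape families are parameterized directly in elliptic-Fourier coefficient
space so that every downstream stage (outline tracing, Procrustes
alignment, harmonic decomposition, classification) can be tested against a
known generator.  The default design mirrors a reference collection of
seven poppy (*Papaver*) taxa, 30 seeds each: two elongated taxa, two
reniform taxa and three rounded, strongly overlapping taxa (the
*P. somniferum* group analogue, whose mean-shape separation is a single
scale factor).  Two extra 30-seed accessions of the two closest taxa can be
added to reproduce the unbalanced-class situation that motivates balanced
resampling, and repeated acquisitions of the same individuals emulate
positioning / cleaning / landmarking reproducibility tests.

Each seed is drawn as: coefficients ~ N(taxon mean, taxon covariance);
length and width log-normal; the reconstructed outline is rescaled to the
drawn bounding box, rotated by the positioning noise, point-jittered,
rasterized to a binary mask, and landmarked automatically.  Cell counts are
negative-binomial (Poisson in the large-dispersion limit).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon as draw_polygon

from .efa import EFTCoefficients, efourier, inverse_efourier, resample_outline
from .imaging import LandmarkSet, Outline, SeedRecord, write_landmarks_csv

__all__ = [
    "TaxonModel",
    "NoiseSpec",
    "SimulatedPopulation",
    "default_taxon_models",
    "extra_accession_models",
    "unknown_mixture_models",
    "repeatability_noise",
    "simulate_population",
    "simulate_repeats",
    "auto_landmarks",
    "render_mask",
]

N_HARMONICS = 5
_SHAPE_POINTS = 720

# per-coefficient SD of within-taxon shape variation, by harmonic
_COEFF_SD_BY_HARMONIC = np.array([0.015, 0.008, 0.006, 0.004, 0.003])


@dataclass
class TaxonModel:
    """Generative model of one taxon's seed population."""

    name: str
    mean_coeffs: np.ndarray           # flat (4H,) vector, a|b|c|d blocks
    coeff_sd: np.ndarray              # diagonal SD, same layout
    length_logmean: float             # natural-log mm
    length_logsd: float
    width_logmean: float
    width_logsd: float
    cell_mean: float
    cell_dispersion: float = 60.0
    n_seeds: int = 30

    def __post_init__(self) -> None:
        self.mean_coeffs = np.asarray(self.mean_coeffs, dtype=float)
        self.coeff_sd = np.broadcast_to(
            np.asarray(self.coeff_sd, dtype=float), self.mean_coeffs.shape
        ).copy()
        if np.any(self.coeff_sd < 0):
            raise ValueError("coeff_sd must be non-negative")
        if self.length_logsd < 0 or self.width_logsd < 0:
            raise ValueError("size log-SDs must be non-negative")
        if self.cell_mean <= 0:
            raise ValueError("cell_mean must be positive")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class NoiseSpec:
    """Acquisition-noise settings; a fixed seed makes output bit-identical.

    rotation_sd        radians of random in-plane re-positioning
    outline_jitter_sd  per-point radial noise, fraction of centroid size
    landmark_jitter_sd landmark placement noise, fraction of centroid size
    """

    rotation_sd: float = 0.0
    outline_jitter_sd: float = 0.0
    landmark_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_sd", "outline_jitter_sd", "landmark_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulatedPopulation:
    records: list
    masks: dict
    landmarks: dict
    px_per_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": r.id, "taxon": r.taxon, "length": r.length_mm,
              "width": r.width_mm, "cells": r.cells} for r in self.records])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        for rid, mask in self.masks.items():
            img = Image.fromarray((mask.astype(np.uint8)) * 255)
            img.save(outdir / "masks" / f"{rid}.png")
        write_landmarks_csv(self.landmarks, outdir / "landmarks.csv")
        self.to_frame().to_csv(outdir / "records.csv", index=False)


# ---------------------------------------------------------------------------
# base shape families

def _polar_shape(aspect: float, dent_depth: float = 0.0,
                 dent_width: float = 0.45, egg: float = 0.0,
                 lobe: float = 0.0, ripple3: float = 0.0,
                 ripple4: float = 0.0) -> EFTCoefficients:
    """Five-harmonic coefficients of a smooth seed-like closed curve.

    The curve is a radial deformation of an ellipse with the given
    width/length ``aspect``: ``dent_depth`` carves a hilum indentation on
    the right side, ``egg`` makes one end broader than the other, ``lobe``
    adds a gentle two-lobed modulation, and ``ripple3``/``ripple4`` add
    fine surface undulation (radial angular harmonics 3 and 4, i.e. shape
    content up to the fifth elliptic harmonic).
    """
    th = np.linspace(0.0, 2 * np.pi, _SHAPE_POINTS, endpoint=False)
    r = (1.0 + egg * np.sin(th) + lobe * np.cos(2 * th)
         + ripple3 * np.cos(3 * th) + ripple4 * np.sin(4 * th))
    if dent_depth:
        ang = np.angle(np.exp(1j * th))          # wrap to (-pi, pi], dent at 0
        r = r - dent_depth * np.exp(-(ang ** 2) / (2 * dent_width ** 2))
    x = aspect * r * np.cos(th)
    y = r * np.sin(th)
    out = Outline(points=np.column_stack([x, y]))
    bottom = out.points[np.argmin(out.points[:, 1])]
    rs = resample_outline(out, _SHAPE_POINTS, start=bottom)
    return efourier(rs, N_HARMONICS)


_ROUNDED_BASE = dict(aspect=0.93, dent_depth=0.28, dent_width=0.7, lobe=0.03,
                     ripple3=0.015, ripple4=0.012)


def _rounded_triple_deltas() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient-space offsets of the three rounded taxa at separation 1."""
    base = _polar_shape(**_ROUNDED_BASE).flatten()
    # two roughly orthogonal deformation directions (deeper hilum dent vs
    # egg-shaped asymmetry) so the middle taxon is not squeezed between the
    # other two along a single axis
    variant_a = _polar_shape(**{**_ROUNDED_BASE, "dent_depth": 0.50,
                                "ripple3": 0.032, "egg": 0.05}).flatten()
    variant_b = _polar_shape(**{**_ROUNDED_BASE, "dent_depth": 0.22,
                                "ripple4": 0.030, "egg": -0.15}).flatten()
    return np.zeros_like(base), variant_a - base, variant_b - base


def default_taxon_models(separation: float = 1.0) -> list:
    """Seven reference taxon models, 30 seeds each.

    ``separation`` linearly scales the pairwise mean-coefficient distances
    within the rounded triple (the *somniferum*-group analogue); at 0 the
    three rounded taxa share one mean shape.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    sd = _COEFF_SD_BY_HARMONIC
    coeff_sd = np.concatenate([sd, sd, sd, sd])

    def model(name, coeffs, l_mean, w_mean, cells, logsd=0.10):
        return TaxonModel(
            name=name, mean_coeffs=coeffs, coeff_sd=coeff_sd,
            length_logmean=float(np.log(l_mean)), length_logsd=logsd,
            width_logmean=float(np.log(w_mean)), width_logsd=logsd,
            cell_mean=cells)

    rounded_base = _polar_shape(**_ROUNDED_BASE).flatten()
    d_nig, d_set, d_som = _rounded_triple_deltas()
    return [
        model("P_argemone",
              _polar_shape(aspect=0.55, dent_depth=0.15, dent_width=0.7,
                           egg=0.10, lobe=0.04, ripple3=0.020,
                           ripple4=0.015).flatten(),
              0.75, 0.41, 95.0),
        model("P_hybridum",
              _polar_shape(aspect=0.62, dent_depth=0.12, dent_width=0.7,
                           egg=-0.08, lobe=0.06, ripple3=-0.018,
                           ripple4=0.020).flatten(),
              0.70, 0.43, 70.0),
        model("P_rhoeas",
              _polar_shape(aspect=0.84, dent_depth=0.35, dent_width=0.7,
                           egg=0.10, ripple3=0.022, ripple4=-0.015).flatten(),
              0.65, 0.53, 60.0),
        model("P_dubium",
              _polar_shape(aspect=0.74, dent_depth=0.50, dent_width=0.7,
                           egg=-0.08, ripple3=-0.020, ripple4=0.018).flatten(),
              0.70, 0.55, 65.0),
        model("P_nigrum", rounded_base + separation * d_nig,
              1.05, 0.98, 80.0),
        model("P_setigerum", rounded_base + separation * d_set,
              0.90, 0.85, 40.0),
        model("P_somniferum", rounded_base + separation * d_som,
              1.20, 1.09, 55.0),
    ]


def extra_accession_models(separation: float = 1.0) -> list:
    """Second 30-seed accessions of the two closest taxa.

    Same taxon labels and mean shapes as in :func:`default_taxon_models`,
    with slightly shifted size distributions (different collection of the
    same taxon), which makes those classes over-represented and motivates
    balanced resampling downstream.
    """
    base = {m.name: m for m in default_taxon_models(separation)}
    out = []
    for name, dlog in (("P_setigerum", 0.04), ("P_somniferum", -0.04)):
        m = base[name]
        out.append(TaxonModel(
            name=name, mean_coeffs=m.mean_coeffs.copy(),
            coeff_sd=m.coeff_sd.copy(),
            length_logmean=m.length_logmean + dlog,
            length_logsd=m.length_logsd,
            width_logmean=m.width_logmean + dlog,
            width_logsd=m.width_logsd,
            cell_mean=m.cell_mean, cell_dispersion=m.cell_dispersion))
    return out


def unknown_mixture_models(n_unknowns: int = 33,
                           separation: float = 1.0) -> list:
    """An archaeological-assemblage analogue: a close-taxa 50/50 mixture.

    Returns two models labelled ``unknown`` whose generative parameters are
    those of the two closest rounded taxa, splitting ``n_unknowns`` seeds
    as evenly as possible (odd counts give the first model one more seed).
    """
    base = {m.name: m for m in default_taxon_models(separation)}
    n_a = (n_unknowns + 1) // 2
    out = []
    for src, n in (("P_setigerum", n_a), ("P_somniferum", n_unknowns - n_a)):
        m = base[src]
        out.append(TaxonModel(
            name="unknown", mean_coeffs=m.mean_coeffs.copy(),
            coeff_sd=m.coeff_sd.copy(),
            length_logmean=m.length_logmean, length_logsd=m.length_logsd,
            width_logmean=m.width_logmean, width_logsd=m.width_logsd,
            cell_mean=m.cell_mean, cell_dispersion=m.cell_dispersion,
            n_seeds=n))
    return out


def repeatability_noise(seed: int = 0) -> dict:
    """Noise settings of the three reproducibility tests.

    position: the seed is physically re-positioned, re-photographed,
    re-cleaned and re-landmarked; cleaning: the same photo is re-cleaned and
    re-landmarked; landmark: only the landmarks are re-placed.
    """
    return {
        "position": NoiseSpec(rotation_sd=0.30, outline_jitter_sd=0.0008,
                              landmark_jitter_sd=0.001, seed=seed),
        "cleaning": NoiseSpec(rotation_sd=0.0, outline_jitter_sd=0.0008,
                              landmark_jitter_sd=0.001, seed=seed + 1),
        "landmark": NoiseSpec(rotation_sd=0.0, outline_jitter_sd=0.0,
                              landmark_jitter_sd=0.001, seed=seed + 2),
    }


# ---------------------------------------------------------------------------
# landmark auto-placement

_ARC_FRACTIONS = (0.45, 0.50, 0.55)   # landmarks 1-3, measured from the top


def auto_landmarks(outline: Outline, image_id: str = "",
                   rng: np.random.Generator | None = None,
                   jitter_sd: float = 0.0) -> LandmarkSet:
    """Place the 5 landmarks automatically on an outline.

    Landmarks 4 and 5 are the top and bottom y-extremes; landmarks 1-3 sit
    at fixed arc fractions (0.45, 0.50, 0.55 of the perimeter) from the top
    point, following the outline counterclockwise — a reproducible analogue
    of manually digitized hilum-arch points.  ``jitter_sd`` (fraction of
    centroid size) adds placement noise.
    """
    out = outline.as_ccw()
    dense = resample_outline(out, max(720, len(out.points)))
    pts = dense.points
    top_i = int(np.argmax(pts[:, 1]))
    bot_i = int(np.argmin(pts[:, 1]))
    k = len(pts)
    arc = [pts[(top_i + int(round(f * k))) % k] for f in _ARC_FRACTIONS]
    coords = np.array([arc[0], arc[1], arc[2], pts[top_i], pts[bot_i]])
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter requires an RNG")
        c = pts.mean(axis=0)
        size = float(np.sqrt(((pts - c) ** 2).sum()))
        coords = coords + rng.normal(0.0, jitter_sd * size, coords.shape)
    return LandmarkSet(coords=coords, image_id=image_id)


# ---------------------------------------------------------------------------
# rendering

def render_mask(outline_mm: Outline, px_per_mm: float = 100.0,
                margin_px: int = 8) -> tuple[np.ndarray, LandmarkSet | None,
                                             tuple[float, float, int]]:
    """Rasterize an outline (mm coordinates) to a binary mask.

    Returns (mask, None, transform) where transform = (x0, y0, height) maps
    mm to y-up pixel coordinates as ``px = (u - u0) * px_per_mm + margin``.
    """
    pts = outline_mm.points
    x0 = float(pts[:, 0].min())
    y0 = float(pts[:, 1].min())
    w_px = (pts[:, 0].max() - x0) * px_per_mm
    h_px = (pts[:, 1].max() - y0) * px_per_mm
    if w_px < 16 or h_px < 16:
        raise ValueError(
            f"rendering resolution too small: outline spans only "
            f"{w_px:.1f} x {h_px:.1f} px at {px_per_mm} px/mm")
    width = int(np.ceil(w_px)) + 2 * margin_px
    height = int(np.ceil(h_px)) + 2 * margin_px
    xp = (pts[:, 0] - x0) * px_per_mm + margin_px
    yp = (pts[:, 1] - y0) * px_per_mm + margin_px
    rows = (height - 1) - yp
    rr, cc = draw_polygon(rows, xp, shape=(height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True
    return mask, None, (x0, y0, height)


def _mm_to_px(pts_mm: np.ndarray, transform, px_per_mm: float,
              margin_px: int = 8) -> np.ndarray:
    x0, y0, _height = transform
    return np.column_stack([
        (pts_mm[:, 0] - x0) * px_per_mm + margin_px,
        (pts_mm[:, 1] - y0) * px_per_mm + margin_px,
    ])


# ---------------------------------------------------------------------------
# population simulation

def _radial_jitter(pts: np.ndarray, rng: np.random.Generator,
                   sd_frac: float) -> np.ndarray:
    """Smooth radial boundary perturbation of a closed outline.

    The field is a random combination of low angular frequencies (2..6)
    with marginal SD ``sd_frac`` times the centroid size — what re-tracing
    or re-cleaning a silhouette plausibly changes, as opposed to white
    per-point noise, which would roughen the contour and inflate its
    perimeter.
    """
    c = pts.mean(axis=0)
    rad = pts - c
    rho = np.hypot(rad[:, 0], rad[:, 1])
    rho[rho == 0] = 1.0
    theta = np.arctan2(rad[:, 1], rad[:, 0])
    freqs = np.arange(2, 7)
    amps = rng.normal(0.0, 1.0, (len(freqs), 2))
    f = np.zeros(len(pts))
    for m, (ac, as_) in zip(freqs, amps):
        f += ac * np.cos(m * theta) + as_ * np.sin(m * theta)
    f /= np.sqrt(len(freqs))
    size = float(np.sqrt((rad ** 2).sum()))
    return pts + (rad / rho[:, None]) * (f * sd_frac * size)[:, None]


def _rotate(pts: np.ndarray, theta: float) -> np.ndarray:
    c = pts.mean(axis=0)
    ct, st = np.cos(theta), np.sin(theta)
    r = np.array([[ct, -st], [st, ct]])
    return (pts - c) @ r.T + c


def _draw_seed_outline(model: TaxonModel, rng: np.random.Generator,
                       noise: NoiseSpec) -> tuple[Outline, float, float, float]:
    """One physical seed + acquisition: returns (outline_mm, L, W, theta)."""
    flat = rng.normal(model.mean_coeffs, model.coeff_sd)
    coeffs = EFTCoefficients.from_flat(flat)
    unit = inverse_efourier(coeffs, k=360)
    length = float(np.exp(rng.normal(model.length_logmean, model.length_logsd)))
    width = float(np.exp(rng.normal(model.width_logmean, model.width_logsd)))
    pts = unit.points.copy()
    ext_x = pts[:, 0].max() - pts[:, 0].min()
    ext_y = pts[:, 1].max() - pts[:, 1].min()
    pts[:, 0] *= width / ext_x
    pts[:, 1] *= length / ext_y
    theta = float(rng.normal(0.0, noise.rotation_sd)) if noise.rotation_sd else 0.0
    if theta:
        pts = _rotate(pts, theta)
    if noise.outline_jitter_sd > 0:
        pts = _radial_jitter(pts, rng, noise.outline_jitter_sd)
    return Outline(points=pts), length, width, theta


def _acquire(outline_mm: Outline, rid: str, rng: np.random.Generator,
             noise: NoiseSpec, px_per_mm: float):
    """Rasterize one outline and landmark it; returns (mask, landmarks)."""
    mask, _, transform = render_mask(outline_mm, px_per_mm=px_per_mm)
    lm_mm = auto_landmarks(outline_mm, image_id=rid)
    lm_px = _mm_to_px(lm_mm.coords, transform, px_per_mm)
    if noise.landmark_jitter_sd > 0:
        # jitter expressed against outline centroid size, in px
        pts_px = _mm_to_px(outline_mm.points, transform, px_per_mm)
        c = pts_px.mean(axis=0)
        osize = float(np.sqrt(((pts_px - c) ** 2).sum()))
        lm_px = lm_px + rng.normal(
            0.0, noise.landmark_jitter_sd * osize, lm_px.shape)
    return mask, LandmarkSet(coords=lm_px, image_id=rid)


def simulate_population(models, noise: NoiseSpec, px_per_mm: float = 100.0,
                        render: bool = True) -> SimulatedPopulation:
    """Simulate seeds for every model: records, masks and landmark sets.

    Fully reproducible from ``noise.seed``; models sharing a taxon name
    (extra accessions) simply contribute more seeds of that taxon.
    ``render=False`` skips rasterization and landmarking (records only),
    which is much faster for large population-moment checks.
    """
    rng = np.random.default_rng(noise.seed)
    records, masks, landmarks = [], {}, {}
    counter: dict = {}
    for model in models:
        for _ in range(model.n_seeds):
            i = counter.get(model.name, 0)
            counter[model.name] = i + 1
            rid = f"{model.name}_{i:03d}"
            outline, length, width, _ = _draw_seed_outline(model, rng, noise)
            if render:
                mask, lms = _acquire(outline, rid, rng, noise, px_per_mm)
            p = model.cell_dispersion / (model.cell_dispersion + model.cell_mean)
            cells = int(rng.negative_binomial(model.cell_dispersion, p))
            pts = outline.points
            records.append(SeedRecord(
                id=rid, taxon=model.name,
                length_mm=float(pts[:, 1].max() - pts[:, 1].min()),
                width_mm=float(pts[:, 0].max() - pts[:, 0].min()),
                cells=cells, outline_mm=outline))
            if render:
                masks[rid] = mask
                landmarks[rid] = lms
    return SimulatedPopulation(records=records, masks=masks,
                               landmarks=landmarks, px_per_mm=px_per_mm)


def simulate_repeats(record: SeedRecord, n_repeats: int, noise: NoiseSpec,
                     px_per_mm: float = 100.0) -> SimulatedPopulation:
    """Re-acquire one simulated individual ``n_repeats`` times.

    The individual's true outline is re-rotated and re-jittered, then
    re-rendered and re-landmarked under ``noise``; ids are suffixed
    ``_r<j>`` so repeats stay grouped by individual.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if record.outline_mm is None:
        raise ValueError("record has no ground-truth outline to re-acquire")
    child = (noise.seed + zlib.crc32(record.id.encode())) % (2 ** 31)
    rng = np.random.default_rng(child)
    base = record.outline_mm.points
    records, masks, landmarks = [], {}, {}
    for j in range(n_repeats):
        pts = base.copy()
        theta = float(rng.normal(0.0, noise.rotation_sd)) if noise.rotation_sd else 0.0
        if theta:
            pts = _rotate(pts, theta)
        if noise.outline_jitter_sd > 0:
            pts = _radial_jitter(pts, rng, noise.outline_jitter_sd)
        outline = Outline(points=pts)
        rid = f"{record.id}_r{j}"
        mask, lms = _acquire(outline, rid, rng, noise, px_per_mm)
        records.append(SeedRecord(
            id=rid, taxon=record.taxon,
            length_mm=float(pts[:, 1].max() - pts[:, 1].min()),
            width_mm=float(pts[:, 0].max() - pts[:, 0].min()),
            cells=record.cells, outline_mm=outline))
        masks[rid] = mask
        landmarks[rid] = lms
    return SimulatedPopulation(records=records, masks=masks,
                               landmarks=landmarks, px_per_mm=px_per_mm)
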