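"""Elliptic Fourier analysis of closed outlines and Procrustes normalization.

A closed outline is decomposed into a series of harmonic ellipses: with the
curve parameterized by arc length t in [0, T), the x and y coordinates are
approximated as

    x(t) = a0 + sum_n [ a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T) ]
    y(t) = c0 + sum_n [ c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T) ]

The coefficients are computed with the piecewise-linear (chain-sum)
formulation, which is exact for polygonal outlines, rather than an FFT on
sampled points.  Normalization for position, size and orientation is done by
generalized Procrustes alignment of landmark configurations (the transforms
estimated on the landmarks are applied to the full outlines), and the start
point of each outline is anchored to a designated landmark before the
transform, so all four coefficients of every harmonic remain meaningful
shape variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LinearRing

from .imaging import Outline

__all__ = [
    "EFTCoefficients",
    "AlignedOutlineSet",
    "resample_outline",
    "gpa_align",
    "efourier",
    "inverse_efourier",
    "harmonic_power",
    "cumulative_power",
    "choose_harmonics",
]


@dataclass
class EFTCoefficients:
    """Elliptic Fourier coefficients of one closed outline.

    ``a``, ``b``, ``c``, ``d`` hold one value per harmonic 1..H; ``a0`` and
    ``c0`` are the arc-length centroid (constant terms); ``perimeter`` is the
    curvilinear length T of the source outline.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    a0: float = 0.0
    c0: float = 0.0
    perimeter: float = 1.0

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if not (len(self.a) == len(self.b) == len(self.c) == len(self.d)):
            raise ValueError("coefficient vectors must share one length H")
        if len(self.a) < 1:
            raise ValueError("at least one harmonic required")

    @property
    def H(self) -> int:
        return len(self.a)

    def flatten(self) -> np.ndarray:
        """Coefficients as one vector (a1..aH, b1..bH, c1..cH, d1..dH)."""
        return np.concatenate([self.a, self.b, self.c, self.d])

    @classmethod
    def from_flat(cls, v: np.ndarray, perimeter: float = 1.0,
                  a0: float = 0.0, c0: float = 0.0) -> "EFTCoefficients":
        v = np.asarray(v, dtype=float)
        if v.size % 4:
            raise ValueError("flat coefficient vector length must be 4*H")
        H = v.size // 4
        return cls(a=v[:H], b=v[H:2 * H], c=v[2 * H:3 * H], d=v[3 * H:],
                   a0=a0, c0=c0, perimeter=perimeter)

    def truncated(self, H_use: int) -> "EFTCoefficients":
        if H_use > self.H:
            raise ValueError(f"H_use={H_use} exceeds available H={self.H}")
        return EFTCoefficients(self.a[:H_use], self.b[:H_use],
                               self.c[:H_use], self.d[:H_use],
                               a0=self.a0, c0=self.c0, perimeter=self.perimeter)


@dataclass
class AlignedOutlineSet:
    """Result of a generalized Procrustes superimposition.

    Outlines are translated, scaled and rotated by the parameters estimated
    on their landmark configurations; each aligned landmark configuration has
    centroid ~0 and centroid size ~1.
    """

    outlines: list
    landmarks: list
    mean_shape: np.ndarray
    iterations: int
    converged: bool
    rotations: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# resampling

def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return np.hypot(seg[:, 0], seg[:, 1])


def _nearest_on_curve(pts: np.ndarray, start: np.ndarray) -> float:
    """Arc-length position on the closed polyline nearest to ``start``.

    Ties are broken toward the lower arc-length position.
    """
    p0 = pts
    p1 = np.roll(pts, -1, axis=0)
    d = p1 - p0
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    t = np.clip(np.einsum("ij,ij->i", start - p0, d) / seg_len2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    dist = np.hypot(*(proj - start).T)
    i = int(np.argmin(dist))  # argmin takes the first == lowest arc position
    seg = np.hypot(*d.T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return float(cum[i] + t[i] * seg[i])


def resample_outline(outline: Outline, k: int, start=None) -> Outline:
    """Resample to ``k`` points equally spaced along the curvilinear abscissa.

    The first output point is the on-curve position nearest to ``start``
    (any 2-D point; commonly a landmark); orientation is forced
    counterclockwise before resampling.  Raises on self-intersecting
    outlines, for which arc-length parameterization is ill-defined.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    out = outline.as_ccw()
    pts = out.points
    if len(pts) >= 4 and not LinearRing(pts).is_valid:
        raise ValueError("outline is self-intersecting")
    seg = _arc_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    T = cum[-1]
    if T <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    if start is not None:
        t0 = _nearest_on_curve(pts, np.asarray(start, dtype=float))
    else:
        t0 = 0.0
    targets = (t0 + np.arange(k) * T / k) % T
    closed = np.vstack([pts, pts[:1]])
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return Outline(points=np.column_stack([x, y]), closed=True,
                   scale=out.scale, touches_border=out.touches_border)


# ---------------------------------------------------------------------------
# generalized Procrustes alignment

def _centroid_size(cfg: np.ndarray) -> float:
    c = cfg.mean(axis=0)
    return float(np.sqrt(((cfg - c) ** 2).sum()))


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares rotation (no reflection) taking src onto dst."""
    u, _, vt = np.linalg.svd(src.T @ dst)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def gpa_align(outlines, landmarks, tol: float = 1e-10,
              max_iter: int = 100) -> AlignedOutlineSet:
    """Generalized Procrustes alignment driven by landmark configurations.

    Translation (landmark centroid), scale (landmark centroid size -> 1) and
    rotation (iterative least-squares fit to the consensus) are estimated on
    the landmark configurations and applied to the full outlines.
    Non-convergence sets ``converged=False`` with a warning instead of
    raising.
    """
    if len(outlines) < 2:
        raise ValueError("GPA requires at least 2 outlines")
    if len(outlines) != len(landmarks):
        raise ValueError("one landmark configuration per outline required")

    lm = [np.asarray(getattr(l, "coords", l), dtype=float) for l in landmarks]
    cents = [cfg.mean(axis=0) for cfg in lm]
    sizes = [_centroid_size(cfg) for cfg in lm]
    if any(s <= 0 for s in sizes):
        raise ValueError("degenerate landmark configuration (zero size)")
    norm_lm = [(cfg - c) / s for cfg, c, s in zip(lm, cents, sizes)]

    rots = [np.eye(2) for _ in norm_lm]
    consensus = norm_lm[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rots = [_optimal_rotation(cfg, consensus) for cfg in norm_lm]
        aligned = [cfg @ r for cfg, r in zip(norm_lm, rots)]
        new_consensus = np.mean(aligned, axis=0)
        ns = _centroid_size(new_consensus)
        if ns > 0:
            new_consensus = new_consensus / ns
        shift = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("GPA did not converge within max_iter", RuntimeWarning)

    # canonical orientation: the consensus landmark 4 -> 5 axis (top and
    # bottom seed extremes) is rotated onto +y, so the aligned frame does
    # not depend on the orientation of the first input
    axis = consensus[3] - consensus[4]
    nrm = np.hypot(*axis)
    if nrm > 0:
        ct, st = axis[1] / nrm, -axis[0] / nrm
        canon = np.array([[ct, -st], [st, ct]])
        consensus = consensus @ canon
        rots = [r @ canon for r in rots]

    out_aligned, lm_aligned = [], []
    for o, cfg, c, s, r in zip(outlines, lm, cents, sizes, rots):
        pts = (np.asarray(o.points, dtype=float) - c) / s @ r
        out_aligned.append(replace(o, points=pts, scale=1.0))
        lm_aligned.append((cfg - c) / s @ r)
    return AlignedOutlineSet(outlines=out_aligned, landmarks=lm_aligned,
                             mean_shape=consensus, iterations=it,
                             converged=converged, rotations=rots)


# ---------------------------------------------------------------------------
# forward / inverse transform

def efourier(outline, H: int) -> EFTCoefficients:
    """Elliptic Fourier coefficients of a closed outline, harmonics 1..H.

    Uses the piecewise-linear chain-sum formulation on the polygon's own
    arc-length parameterization; deterministic and exact for polygons.
    """
    pts = np.asarray(outline.points if hasattr(outline, "points") else outline,
                     dtype=float)
    n = len(pts)
    if H < 1:
        raise ValueError("H must be >= 1")
    if H > n // 2:
        raise ValueError(f"H={H} too large for {n} points (need H <= n/2)")
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if np.any(dt == 0):
        keep = dt > 0
        pts = pts[keep]
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        dt = np.hypot(d[:, 0], d[:, 1])
        n = len(pts)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2 * np.pi * t / T           # length n+1
    harm = np.arange(1, H + 1)[:, None]
    cos_t = np.cos(harm * phi)        # H x (n+1)
    sin_t = np.sin(harm * phi)
    dcos = cos_t[:, 1:] - cos_t[:, :-1]
    dsin = sin_t[:, 1:] - sin_t[:, :-1]
    coef = T / (2 * (harm[:, 0] ** 2) * np.pi ** 2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = coef * (dcos @ dxdt)
    b = coef * (dsin @ dxdt)
    c = coef * (dcos @ dydt)
    dd = coef * (dsin @ dydt)
    # arc-length centroid (constant terms), exact for the polygon
    mid = (pts + np.roll(pts, -1, axis=0)) / 2
    a0 = float((mid[:, 0] * dt).sum() / T)
    c0 = float((mid[:, 1] * dt).sum() / T)
    return EFTCoefficients(a, b, c, dd, a0=a0, c0=c0, perimeter=float(T))


def inverse_efourier(coeffs: EFTCoefficients, k: int = 360,
                     H_use: int | None = None) -> Outline:
    """Reconstruct an outline from the truncated Fourier series."""
    if H_use is None:
        H_use = coeffs.H
    if H_use > coeffs.H:
        raise ValueError(f"H_use={H_use} exceeds available H={coeffs.H}")
    t = np.arange(k) / k
    harm = np.arange(1, H_use + 1)[:, None]
    ang = 2 * np.pi * harm * t[None, :]
    cos_t, sin_t = np.cos(ang), np.sin(ang)
    x = coeffs.a0 + coeffs.a[:H_use] @ cos_t + coeffs.b[:H_use] @ sin_t
    y = coeffs.c0 + coeffs.c[:H_use] @ cos_t + coeffs.d[:H_use] @ sin_t
    return Outline(points=np.column_stack([x, y]), closed=True, scale=1.0)


# ---------------------------------------------------------------------------
# harmonic power

def harmonic_power(coeffs: EFTCoefficients) -> np.ndarray:
    """Per-harmonic power (a^2 + b^2 + c^2 + d^2) / 2."""
    p = (coeffs.a ** 2 + coeffs.b ** 2 + coeffs.c ** 2 + coeffs.d ** 2) / 2
    if not np.any(p > 0):
        raise ValueError("all coefficients are zero; power undefined")
    return p


def cumulative_power(coeffs: EFTCoefficients) -> np.ndarray:
    """Cumulative power fractions over all computed harmonics (1 included)."""
    p = harmonic_power(coeffs)
    return np.cumsum(p) / p.sum()


def choose_harmonics(population, threshold: float = 0.95,
                     drop_first: bool = False) -> int:
    """Smallest H whose mean cumulative power fraction reaches ``threshold``.

    ``population`` is an iterable of EFTCoefficients, all with the same
    number of computed harmonics; the cumulative fraction is averaged over
    specimens before thresholding.

    With ``drop_first=True`` harmonic 1 is excluded from both numerator and
    denominator, the standard calibration in outline morphometrics: the
    first harmonic (the overall ellipse) always carries the overwhelming
    majority of the power, so including it makes the retention rule
    insensitive to the shape detail the later harmonics describe.  The
    returned H still counts from harmonic 1 (H = 1 + retained later
    harmonics), so it can be used directly as a truncation length.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    powers = np.vstack([harmonic_power(c) for c in population])
    if drop_first:
        if powers.shape[1] < 2:
            return 1
        powers = powers[:, 1:]
    tot = powers.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    fracs = np.cumsum(powers, axis=1) / tot
    mean_frac = fracs.mean(axis=0)
    hits = np.nonzero(mean_frac >= threshold - 1e-12)[0]
    h = int(hits[0]) + 1 if len(hits) else fracs.shape[1]
    return h + 1 if drop_first else h
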