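"""Synthetic fingerprint pairs with known ground truth.

Real latent prints and their inked controls cannot ship with a library, so
this module manufactures them: a smooth ridge orientation field with the
desired level-1 topology (arch, loop or whorl, built from the classical
zero-pole singularity model), an oriented-bandpass ridge rendering locked to
that field, deliberate local edits that create minutiae of known type and
position, and two appearance models — the inked control (dark ridges on a
light card, ink spread, uneven pressure) and the powder-developed sample
(bright fluorescing ridges on a dark textured substrate, powder grain,
smudges, partial occlusion) — related by a known rigid transform.

Every stage draws from substreams of one seeded generator, so a pair is
bit-reproducible from its parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import ConfigurationError
from .imgproc import BinaryImage, GrayImage
from .ridges import CorePoint, Minutia, MinutiaSet, OrientationField

__all__ = [
    "SynthParams",
    "Degradation",
    "RigidTransform",
    "GroundTruth",
    "SynthPair",
    "make_orientation_field",
    "render_ridge_image",
    "plant_minutiae",
    "simulate_control",
    "simulate_development",
    "generate_pair",
]

SUBSTRATES = ("paper", "metal", "plastic", "glass", "wood")


@dataclass(frozen=True)
class Degradation:
    """Degradation knobs of the powder-developed sample appearance.

    ``smudge_prob`` — chance of each of a handful of candidate patches being
    blurred out (powder smears); ``background_texture_amp`` — amplitude of
    the substrate texture and powder grain, as a fraction of full scale;
    ``contrast`` — ridge-to-background contrast retained (1 = full);
    ``occlusion_frac`` — fraction of the image hidden by opaque blobs.
    """

    smudge_prob: float = 0.05
    background_texture_amp: float = 0.15
    contrast: float = 0.8
    occlusion_frac: float = 0.1

    def __post_init__(self):
        if not (0 <= self.occlusion_frac < 1):
            raise ConfigurationError("occlusion_frac must lie in [0, 1)")
        if not (0 <= self.smudge_prob <= 1):
            raise ConfigurationError("smudge_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SynthParams:
    pattern: str = "whorl"  # arch | loop | whorl
    ridge_period: float = 9.0  # px between ridge centerlines
    image_size: int = 256
    n_minutiae: int = 12
    pore_rate: float = 0.0  # planted pores per 1000 ridge px (0 = none)
    substrate: str = "paper"
    degradation: Degradation = field(default_factory=Degradation)
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("arch", "loop", "whorl"):
            raise ConfigurationError(f"unknown pattern {self.pattern!r}")
        if self.substrate not in SUBSTRATES:
            raise ConfigurationError(f"unknown substrate {self.substrate!r}")
        if self.ridge_period < 4:
            raise ConfigurationError("ridge_period must be >= 4 px")


@dataclass(frozen=True)
class RigidTransform:
    """q = R_angle (p - center) + center + t, coordinates (x, y) in pixels."""

    angle: float = 0.0  # radians, counter-clockwise in (x, y-down)
    tx: float = 0.0
    ty: float = 0.0
    cx: float = 0.0
    cy: float = 0.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, dtype=float).reshape(-1, 2)
        c, s = math.cos(self.angle), math.sin(self.angle)
        d = p - (self.cx, self.cy)
        q = np.column_stack([c * d[:, 0] - s * d[:, 1], s * d[:, 0] + c * d[:, 1]])
        return q + (self.cx + self.tx, self.cy + self.ty)

    def inverse(self) -> "RigidTransform":
        c, s = math.cos(-self.angle), math.sin(-self.angle)
        # p = R_{-a}(q - c - t) + c  =>  new t = c - R_{-a}(c + t) ... expressed
        # in the same (center, t) parametrisation with the same center:
        # p = R_{-a}(q - center) + center + t'  with  t' = -R_{-a} @ (tx, ty)
        tpx = -(c * self.tx - s * self.ty)
        tpy = -(s * self.tx + c * self.ty)
        return RigidTransform(angle=-self.angle, tx=tpx, ty=tpy, cx=self.cx, cy=self.cy)

    def warp_image(self, img: np.ndarray, cval: float) -> np.ndarray:
        """Resample so that content at p appears at q = apply(p)."""
        a = -self.angle
        c, s = math.cos(a), math.sin(a)
        # inverse map in (y, x) index order for ndimage
        matrix = np.array([[c, s], [-s, c]])
        cyx = np.array([self.cy, self.cx])
        tyx = np.array([self.ty, self.tx])
        offset = cyx - matrix @ (cyx + tyx)
        return ndimage.affine_transform(
            img, matrix, offset=offset, order=1, mode="constant", cval=cval
        )


@dataclass(frozen=True)
class GroundTruth:
    minutiae: MinutiaSet  # in the control frame
    core: CorePoint
    delta: Optional[CorePoint]
    transform: RigidTransform  # control frame -> sample frame
    ridge_mask: BinaryImage  # control frame

    def sample_minutiae(self) -> MinutiaSet:
        """Ground-truth minutiae mapped into the sample frame."""
        if len(self.minutiae) == 0:
            return self.minutiae
        q = self.transform.apply(self.minutiae.coords())
        items = tuple(
            Minutia(float(x), float(y), m.type, m.quality)
            for (x, y), m in zip(q, self.minutiae)
        )
        return replace(self.minutiae, items=items)


@dataclass(frozen=True)
class SynthPair:
    control: GrayImage  # dark ridges, light background
    sample: GrayImage  # bright ridges, dark textured background
    truth: GroundTruth


# ---------------------------------------------------------------------------
# orientation fields (zero-pole construction)


def make_orientation_field(
    pattern: str,
    core: tuple[float, float] | None = None,
    delta: tuple[float, float] | None = None,
    size: int = 256,
    block_size: int = 1,
) -> OrientationField:
    """A smooth field with the prescribed singularity structure.

    whorl: theta = arg(z - core) + pi/2 (Poincaré index +1 — concentric
    flow); loop: theta = arg(z - core)/2 - arg(z - delta)/2 + pi/2 (+1/2 at
    the core, -1/2 at the delta); arch: level sets of a bumped horizontal
    stratification, no singularity.
    """
    margin = max(2 * block_size, 8)
    if core is not None and not (
        margin <= core[0] <= size - margin and margin <= core[1] <= size - margin
    ):
        raise ConfigurationError("core must lie inside the image, away from the boundary")
    n = size // block_size
    centers = (np.arange(n) + 0.5) * block_size
    X, Y = np.meshgrid(centers, centers)
    if pattern == "whorl":
        if core is None:
            core = (size / 2, size / 2)
        theta = np.arctan2(Y - core[1], X - core[0]) + np.pi / 2
    elif pattern == "loop":
        if core is None:
            core = (size / 2, size * 0.42)
        if delta is None:
            delta = (core[0] + size * 0.12, core[1] + size * 0.25)
        theta = (
            0.5 * np.arctan2(Y - core[1], X - core[0])
            - 0.5 * np.arctan2(Y - delta[1], X - delta[0])
            + np.pi / 2
        )
    elif pattern == "arch":
        amp, sig = size * 0.18, size * 0.25
        cx = size / 2
        # ridges are level sets of psi = y + amp*exp(-(x-cx)^2 / (2 sig^2))
        dpsi_dx = amp * (-(X - cx) / sig**2) * np.exp(-((X - cx) ** 2) / (2 * sig**2))
        dpsi_dy = np.ones_like(X)
        theta = np.arctan2(dpsi_dy, dpsi_dx) + np.pi / 2
    else:
        raise ConfigurationError(f"unknown pattern {pattern!r}")
    return OrientationField(
        theta=np.mod(theta, np.pi), block_size=block_size, coherence=np.ones_like(theta)
    )


def _pixel_theta(fld: OrientationField, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel orientation from a block field (doubled-angle interpolation)."""
    if fld.block_size == 1 and fld.theta.shape == shape:
        return fld.theta
    z = fld.block_size
    c2 = ndimage.zoom(np.cos(2 * fld.theta), z, order=1)
    s2 = ndimage.zoom(np.sin(2 * fld.theta), z, order=1)

    def fit(a):
        out = np.zeros(shape)
        h = min(shape[0], a.shape[0])
        w = min(shape[1], a.shape[1])
        out[:h, :w] = a[:h, :w]
        if h < shape[0]:
            out[h:, :w] = a[h - 1, :w]
        if w < shape[1]:
            out[:, w:] = out[:, w - 1 : w]
        return out

    return np.mod(0.5 * np.arctan2(fit(s2), fit(c2)), np.pi)


# ---------------------------------------------------------------------------
# ridge rendering


def _init_phase(pattern: str, shape, core, period) -> np.ndarray:
    h, w = shape
    Y, X = np.mgrid[0:h, 0:w].astype(float)
    if pattern in ("whorl", "loop"):
        r = np.hypot(X - core[0], Y - core[1])
        return 2 * np.pi * r / period
    amp, sig = w * 0.18, w * 0.25
    psi = Y + amp * np.exp(-((X - w / 2) ** 2) / (2 * sig**2))
    return 2 * np.pi * psi / period


def render_ridge_image(
    fld: OrientationField,
    ridge_period: float = 9.0,
    seed: int = 0,
    pattern: str = "whorl",
    core: tuple[float, float] | None = None,
    n_orientations: int = 16,
    n_iter: int = 4,
    noise_amp: float = 0.3,
) -> tuple[GrayImage, BinaryImage]:
    """Synthesize a ridge pattern locked to the orientation field.

    A seeded initial wave (analytic phase consistent with the pattern class,
    perturbed by noise) is iterated through a bank of even-symmetric oriented
    bandpass (Gabor) kernels at ``n_orientations`` discrete directions, each
    pixel taking the response of the kernel nearest its field orientation.
    The iteration converges to a quasi-stationary stripe pattern whose
    dominant spatial frequency sits at 1/ridge_period. Returns the rendered
    grayscale (dark ridges, light background, raw 0-255 stage) and the exact
    ridge mask.
    """
    nby, nbx = fld.theta.shape
    shape = (nby * fld.block_size, nbx * fld.block_size)
    theta = _pixel_theta(fld, shape)
    if core is None:
        core = (shape[1] / 2, shape[0] / 2)
    rng = np.random.default_rng(seed)
    img = np.cos(_init_phase(pattern, shape, core, ridge_period))
    img = img + noise_amp * rng.standard_normal(shape)

    # kernel bank: stripes along direction theta_k
    sigma = 0.55 * ridge_period
    L = int(2.5 * sigma)
    yy, xx = np.mgrid[-L : L + 1, -L : L + 1].astype(float)
    kernels = []
    for k in range(n_orientations):
        tk = np.pi * k / n_orientations
        u = xx * math.cos(tk + np.pi / 2) + yy * math.sin(tk + np.pi / 2)
        g = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) * np.cos(2 * np.pi * u / ridge_period)
        kernels.append(g - g.mean())
    idx = np.mod(np.rint(theta / np.pi * n_orientations).astype(int), n_orientations)

    for _ in range(n_iter):
        stack = np.empty((n_orientations,) + shape)
        for k, ker in enumerate(kernels):
            stack[k] = fftconvolve(img, ker, mode="same")
        img = np.take_along_axis(stack, idx[None], axis=0)[0]
        img = img / (img.std() + 1e-9)

    # equalize the local stripe amplitude (AM demodulation) so that regions
    # of destructive interference do not leave low-contrast patches that
    # would binarize into spurious ridge breaks downstream
    envelope = np.sqrt(ndimage.gaussian_filter(img**2, ridge_period) + 1e-12)
    img = img / envelope
    mask = (img > 0).astype(np.uint8)
    gray = np.clip(128.0 - 70.0 * np.tanh(1.5 * img), 0, 255)
    return GrayImage(gray, stage="raw"), BinaryImage(mask, ridge_is_one=True)


# ---------------------------------------------------------------------------
# minutiae planting


def _paint_rect(sel_x, sel_y, p, direction, length, width):
    u = np.array([math.cos(direction), math.sin(direction)])
    v = np.array([-u[1], u[0]])
    dx = sel_x - p[0]
    dy = sel_y - p[1]
    a = dx * u[0] + dy * u[1]
    b = dx * v[0] + dy * v[1]
    return (np.abs(a) <= length / 2) & (np.abs(b) <= width / 2)


def _paint_ellipse(sel_x, sel_y, p, direction, semi_u, semi_v):
    u = np.array([math.cos(direction), math.sin(direction)])
    v = np.array([-u[1], u[0]])
    dx = sel_x - p[0]
    dy = sel_y - p[1]
    a = dx * u[0] + dy * u[1]
    b = dx * v[0] + dy * v[1]
    return (a / semi_u) ** 2 + (b / semi_v) ** 2 <= 1.0


def plant_minutiae(
    gray: GrayImage,
    mask: BinaryImage,
    fld: OrientationField,
    n_minutiae: int,
    types: Sequence[str] = ("termination", "bifurcation", "eye"),
    seed: int = 0,
    ridge_period: float = 9.0,
    margin: int = 28,
    keepout: Sequence[tuple[float, float]] = (),
) -> tuple[GrayImage, BinaryImage, MinutiaSet]:
    """Edit the rendered pattern to create minutiae of known type and place.

    Events are drawn cyclically from ``types`` until at least ``n_minutiae``
    ground-truth points exist (a ridge cut contributes its two endpoints, a
    ridge bridge its two junctions; eyes, spurs and pores contribute one
    each). Sites are ridge pixels away from the border, from ``keepout``
    points (e.g. the core) and from each other. If the pattern runs out of
    room the set returned is honestly smaller than requested.
    """
    h, w = mask.pixels.shape
    theta = _pixel_theta(fld, (h, w))
    g = gray.pixels.copy()
    m = mask.pixels.astype(bool).copy()
    ridge_val = float(np.median(g[m])) if m.any() else 60.0
    bg_val = float(np.median(g[~m])) if (~m).any() else 200.0
    Y, X = np.mgrid[0:h, 0:w].astype(float)
    rng = np.random.default_rng(seed)
    placed: list[tuple[float, float]] = [tuple(p) for p in keepout]
    truth: list[Minutia] = []
    min_sep = 3.5 * ridge_period

    # sites on ridge centerlines (away from ridge edges, so erase edits like
    # pores stay fully enclosed)
    dist_bg = ndimage.distance_transform_edt(m)
    interior = dist_bg >= 1.8
    ridge_yx = np.argwhere(interior if interior.any() else m)

    def pick_site():
        for _ in range(300):
            yy, xx = ridge_yx[rng.integers(len(ridge_yx))]
            if not (margin <= xx < w - margin and margin <= yy < h - margin):
                continue
            if all((xx - px) ** 2 + (yy - py) ** 2 >= min_sep**2 for px, py in placed):
                return float(xx), float(yy)
        return None

    def apply(region, fg: bool):
        m[region] = fg
        g[region] = ridge_val if fg else bg_val

    ti = 0
    attempts = 0
    while len(truth) < n_minutiae:
        attempts += 1
        if attempts > 40 * max(n_minutiae, 1):
            break  # honestly report fewer than requested
        t = types[ti % len(types)]
        ti += 1
        site = pick_site()
        if site is None:
            break
        x0, y0 = site
        th = theta[int(y0), int(x0)]
        u = (math.cos(th), math.sin(th))
        v = (-u[1], u[0])
        if t == "termination":
            # gap comfortably wider than the break-merge radius, so the two
            # genuine endpoints are not mistaken for a ridge-break artifact
            gap = 20.0
            region = _paint_rect(X, Y, (x0, y0), th, gap, ridge_period * 0.8)
            apply(region, False)
            for sgn in (-1.0, 1.0):
                truth.append(
                    Minutia(x0 + sgn * (gap / 2) * u[0], y0 + sgn * (gap / 2) * u[1], "termination")
                )
        elif t == "bifurcation":
            pv = (x0 + ridge_period / 2 * v[0], y0 + ridge_period / 2 * v[1])
            region = _paint_rect(X, Y, pv, th + np.pi / 2, ridge_period + 3, 3.0)
            apply(region, True)
            truth.append(Minutia(x0, y0, "bifurcation"))
            truth.append(
                Minutia(x0 + ridge_period * v[0], y0 + ridge_period * v[1], "bifurcation")
            )
        elif t == "eye":
            # an enclosure needs room: clear a moat in the flanking valleys
            # (keeping a through-ridge corridor) so both arms of the annulus
            # are thicker than the ink-spread blur scale; requires locally
            # straight flow or the moat would clip curved neighbors
            the = theta[
                int(np.clip(y0 + 11 * u[1], 0, h - 1)), int(np.clip(x0 + 11 * u[0], 0, w - 1))
            ]
            bend = abs(math.remainder(the - th, math.pi))
            if bend > 0.15:
                continue  # too curved here; try another site
            moat = _paint_ellipse(X, Y, (x0, y0), th, 12.0, 8.5) & ~_paint_rect(
                X, Y, (x0, y0), th, 26.0, 4.6
            )
            apply(moat, False)
            apply(_paint_ellipse(X, Y, (x0, y0), th, 9.5, 5.4), True)
            apply(_paint_ellipse(X, Y, (x0, y0), th, 5.5, 2.3), False)
            truth.append(Minutia(x0, y0, "eye"))
        elif t == "spur":
            # long enough that the thinned arm survives noise pruning, at an
            # angle shallow enough to stay clear of the neighboring ridge
            ang = th + (0.6 if rng.random() < 0.5 else -0.6)
            wdir = (math.cos(ang), math.sin(ang))
            blen = 7.0
            center = (x0 + blen / 2 * wdir[0], y0 + blen / 2 * wdir[1])
            region = _paint_rect(X, Y, center, ang, blen + 1, 2.4)
            apply(region, True)
            truth.append(Minutia(x0, y0, "spur"))
        elif t == "pore":
            # elongated along the ridge: the lumen must stay enclosed by
            # ridge walls >= 1 px on the thin (cross-ridge) side
            if dist_bg[int(y0), int(x0)] < 2.0:
                continue  # too close to the ridge edge; try another site
            region = _paint_ellipse(X, Y, (x0, y0), th, 1.9, 0.95)
            apply(region, False)
            truth.append(Minutia(x0, y0, "pore"))
        else:
            raise ConfigurationError(f"cannot plant minutia type {t!r}")
        placed.append((x0, y0))

    truth = _snap_truth_to_skeleton(truth, m)
    return (
        GrayImage(g, stage="raw"),
        BinaryImage(m.astype(np.uint8), ridge_is_one=True),
        MinutiaSet(tuple(truth), image_shape=(h, w)),
    )


def _snap_truth_to_skeleton(truth: list[Minutia], mask: np.ndarray, reach: float = 8.0):
    """Refine planted coordinates onto the edited pattern's own skeleton.

    The paint/erase edits place features to within a few pixels; the exact
    minutia position is where the (noise-free) skeleton of the edited mask
    carries the corresponding crossing number. This is pure geometry of the
    generated image, independent of any extraction pipeline.
    """
    from skimage.morphology import skeletonize as _sk

    from .ridges import _cn_map

    skel = _sk(mask.astype(bool)).astype(np.uint8)
    cn = np.where(skel == 1, _cn_map(skel), -1)
    want = {"termination": (1,), "bifurcation": (3, 4), "spur": (3, 4)}
    coords = {k: np.argwhere(np.isin(cn, v)) for k, v in want.items()}
    out = []
    used: set[tuple[float, float, str]] = set()
    for m in truth:
        cand = coords.get(m.type)
        pick = m
        if cand is not None and len(cand) > 0:
            d = np.hypot(cand[:, 1] - m.x, cand[:, 0] - m.y)
            k = int(np.argmin(d))
            snapped = Minutia(float(cand[k, 1]), float(cand[k, 0]), m.type, m.quality)
            if d[k] <= reach and (snapped.x, snapped.y, snapped.type) not in used:
                pick = snapped
        out.append(pick)
        used.add((pick.x, pick.y, pick.type))
    return out


# ---------------------------------------------------------------------------
# appearance models


def simulate_control(gray: GrayImage, seed: int = 0) -> GrayImage:
    """Inked-card appearance: ink spread, uneven pressure, sensor noise."""
    rng = np.random.default_rng(seed)
    p = gray.pixels
    ink = (255.0 - ndimage.gaussian_filter(p, 0.7)) / 255.0
    pressure = ndimage.gaussian_filter(rng.standard_normal(p.shape), 40)
    pressure = 1.0 + 0.12 * pressure / (pressure.std() + 1e-9)
    out = 255.0 * (1.0 - ink * pressure) + 3.0 * rng.standard_normal(p.shape)
    return GrayImage(np.clip(out, 0, 255), stage="raw")


def _substrate_texture(substrate: str, shape, rng) -> np.ndarray:
    """Zero-mean texture field in roughly [-1, 1] per substrate archetype."""
    h, w = shape
    Y, X = np.mgrid[0:h, 0:w].astype(float)
    n = rng.standard_normal(shape)
    if substrate == "paper":
        t = ndimage.gaussian_filter(n, 3) * 4.0 + 0.3 * np.sin(2 * np.pi * Y / 17.0)
    elif substrate == "metal":
        t = ndimage.gaussian_filter(n, (0.5, 12)) * 6.0
    elif substrate == "plastic":
        t = ndimage.gaussian_filter(n, 12) * 14.0
    elif substrate == "glass":
        t = ndimage.gaussian_filter(n, 20) * 10.0
        for _ in range(2):
            gx, gy = rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h)
            t += 1.5 * np.exp(-((X - gx) ** 2 + (Y - gy) ** 2) / (2 * (0.08 * w) ** 2))
    elif substrate == "wood":
        drift = ndimage.gaussian_filter(rng.standard_normal(shape), 25)
        drift = drift / (drift.std() + 1e-9)
        t = np.sin(2 * np.pi * (X / 25.0 + 1.5 * drift))
    else:
        raise ConfigurationError(f"unknown substrate {substrate!r}")
    return t / (np.abs(t).max() + 1e-9)


def simulate_development(
    gray: GrayImage,
    substrate: str = "paper",
    degradation: Degradation | None = None,
    transform: RigidTransform | None = None,
    seed: int = 0,
    extras: dict | None = None,
) -> GrayImage:
    """Powder-developed appearance under UV: bright ridges, textured dark bg.

    With all degradation knobs at their degenerate values (amp 0, smudge 0,
    occlusion 0, contrast 1) the output is exactly the polarity-inverted
    rigid transform of the input rendering.
    """
    deg = degradation or Degradation()
    rng = np.random.default_rng(seed)
    p = 255.0 - gray.pixels  # bright ridges
    bgval = float(np.percentile(p, 10))
    if transform is not None:
        p = transform.warp_image(p, cval=bgval)
    out = p.copy()
    if deg.contrast != 1.0:
        out = bgval + deg.contrast * (out - bgval)
    amp = deg.background_texture_amp
    if amp > 0:
        out = out + 255.0 * amp * _substrate_texture(substrate, p.shape, rng)
        # powder granularity
        out = out + 255.0 * 0.15 * amp * rng.standard_normal(p.shape)
    if deg.smudge_prob > 0:
        h, w = p.shape
        for _ in range(6):
            if rng.random() < deg.smudge_prob:
                cx, cy = rng.uniform(0, w), rng.uniform(0, h)
                r = rng.uniform(10, 25)
                Y, X = np.mgrid[0:h, 0:w].astype(float)
                blob = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
                blurred = ndimage.gaussian_filter(out, 6)
                out[blob] = blurred[blob]
    if deg.occlusion_frac > 0:
        h, w = p.shape
        Y, X = np.mgrid[0:h, 0:w].astype(float)
        covered = np.zeros(p.shape, dtype=bool)
        target = deg.occlusion_frac
        while covered.mean() < target:
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            r = rng.uniform(10, 22)
            covered |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        occ_val = bgval + 255.0 * 0.5 * amp
        out[covered] = occ_val + (
            255.0 * 0.1 * amp * rng.standard_normal(p.shape)[covered] if amp > 0 else 0.0
        )
        if extras is not None:
            extras["occlusion_mask"] = covered
    return GrayImage(np.clip(out, 0, 255), stage="raw")


# ---------------------------------------------------------------------------
# full pair


def generate_pair(params: SynthParams) -> SynthPair:
    """Generate a control/sample pair with ground truth, end-to-end seeded."""
    size = params.image_size
    ss = np.random.SeedSequence(params.seed)
    s_geom, s_render, s_plant, s_ctrl, s_dev = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    rng = np.random.default_rng(s_geom)

    jitter = rng.uniform(-0.04 * size, 0.04 * size, size=2)
    if params.pattern == "whorl":
        core_xy = (size / 2 + jitter[0], size / 2 + jitter[1])
        delta_xy = None
    elif params.pattern == "loop":
        core_xy = (size / 2 + jitter[0], size * 0.42 + jitter[1])
        delta_xy = (core_xy[0] + size * 0.12, core_xy[1] + size * 0.25)
    else:
        core_xy = (size / 2, size / 2)  # nominal anchor; arch has no singularity
        delta_xy = None

    fld = make_orientation_field(
        params.pattern,
        core=core_xy if params.pattern != "arch" else None,
        delta=delta_xy,
        size=size,
        block_size=1,
    )
    gray, mask = render_ridge_image(
        fld, params.ridge_period, seed=s_render, pattern=params.pattern, core=core_xy
    )
    if params.pattern in ("whorl", "loop"):
        # the concentric phase leaves an isolated dot at the very centre;
        # erase it so the innermost ring is the first ridge structure
        h, w = mask.pixels.shape
        Y, X = np.mgrid[0:h, 0:w].astype(float)
        hole = (X - core_xy[0]) ** 2 + (Y - core_xy[1]) ** 2 <= (1.5 * params.ridge_period) ** 2
        mp = mask.pixels.copy()
        gp = gray.pixels.copy()
        bgv = float(np.median(gp[mask.pixels == 0]))
        mp[hole] = 0
        gp[hole] = bgv
        mask = BinaryImage(mp, ridge_is_one=True)
        gray = GrayImage(gp, stage="raw")
    # spurs are omitted from the default mix: at a 9 px ridge period a branch
    # short enough to read as a spur does not survive ink-spread blur intact
    # (it either bridges the valley or is absorbed by thinning)
    types = ("termination", "bifurcation", "eye")
    if params.pore_rate > 0:
        types = types + ("pore",)
    gray, mask, truth_ms = plant_minutiae(
        gray,
        mask,
        fld,
        params.n_minutiae,
        types=types,
        seed=s_plant,
        ridge_period=params.ridge_period,
        keepout=[core_xy] if params.pattern != "arch" else [],
    )
    control = simulate_control(gray, seed=s_ctrl)
    transform = RigidTransform(
        angle=rng.uniform(-np.deg2rad(4), np.deg2rad(4)),
        tx=rng.uniform(-5, 5),
        ty=rng.uniform(-5, 5),
        cx=size / 2,
        cy=size / 2,
    )
    sample = simulate_development(
        gray, params.substrate, params.degradation, transform, seed=s_dev
    )
    core_kind_idx = 1.0 if params.pattern == "whorl" else 0.5
    truth = GroundTruth(
        minutiae=truth_ms,
        core=CorePoint(a=core_xy[0], b=core_xy[1], kind="core", poincare_index=core_kind_idx),
        delta=(
            CorePoint(a=delta_xy[0], b=delta_xy[1], kind="delta", poincare_index=-0.5)
            if delta_xy
            else None
        ),
        transform=transform,
        ridge_mask=mask,
    )
    return SynthPair(control=control, sample=sample, truth=truth)
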