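"""Core-anchored similarity scoring between a latent print and its control.

The matcher compares two feature-point sets through their m x 2 coordinate
matrices: Z for the developed latent sample, X for the inked control. Each
point is reduced to its squared Euclidean distance from its image's core
point (a, b), and for every corresponding pair i the distance ratio

    rho_i = [(z_i1 - a_Z)^2 + (z_i2 - b_Z)^2] / [(x_i1 - a_X)^2 + (x_i2 - b_X)^2]

feeds the bounded per-point term 1 / (|rho_i - 1| + 1). The matching score

    P = (1/m) * sum_i 1 / (|rho_i - 1| + 1)

lies in (0, 1]; P = 1 exactly when every pair sits at the same core distance
(in particular when Z = X), and resemblance increases with P. The score is
reported as a percentage (100 * P).

Note the statistic is deliberately asymmetric: the sample-to-control
direction is fixed. Each matrix uses its *own* core, which makes the score
invariant to translation of either image and to rotation of the sample about
its core.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import imgproc, ridges
from .config import Config
from .errors import (
    DegenerateGeometryError,
    LfpError,
    NoFeaturesError,
    NoOverlapError,
    StageError,
)
from .imgproc import BinaryImage, GrayImage, RgbImage
from .ridges import CorePoint, MinutiaSet

__all__ = [
    "FeatureMatrix",
    "Correspondence",
    "MatchResult",
    "build_feature_matrix",
    "establish_correspondence",
    "similarity_score",
    "extract_features",
    "compare_images",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """The m x 2 coordinate matrix of one image plus its core anchor.

    Rows are (x, y) pixel coordinates of second-level minutiae, ordered
    canonically by polar angle about the core and then by radius, so the
    matrix does not depend on extraction order. ``core_is_fallback`` flags a
    centroid stand-in used when no flow singularity was found.
    """

    coords: np.ndarray
    core: CorePoint
    core_is_fallback: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        if c.shape[0] < 1:
            raise NoFeaturesError("feature matrix needs at least one row")
        d2 = (c[:, 0] - self.core.a) ** 2 + (c[:, 1] - self.core.b) ** 2
        if np.any(d2 == 0):
            raise DegenerateGeometryError("a feature point coincides with the core")
        object.__setattr__(self, "coords", c)

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, phi) of every row relative to the core."""
        dx = self.coords[:, 0] - self.core.a
        dy = self.coords[:, 1] - self.core.b
        return np.hypot(dx, dy), np.arctan2(dy, dx)


@dataclass(frozen=True)
class Correspondence:
    pairs: tuple[tuple[int, int], ...]  # (sample_index, control_index)
    unpaired_sample: tuple[int, ...] = ()
    unpaired_control: tuple[int, ...] = ()

    def __post_init__(self):
        zs = [i for i, _ in self.pairs]
        xs = [j for _, j in self.pairs]
        if len(set(zs)) != len(zs) or len(set(xs)) != len(xs):
            raise DegenerateGeometryError("an index appears in more than one pair")

    @classmethod
    def identity(cls, m: int) -> "Correspondence":
        return cls(tuple((i, i) for i in range(m)))


@dataclass(frozen=True)
class MatchResult:
    P: float
    percent: float
    m_used: int
    per_point_terms: tuple[float, ...]
    correspondence: Correspondence
    artifacts: dict = field(default_factory=dict, compare=False)


def build_feature_matrix(
    ms: MinutiaSet,
    r_min: float = 3.0,
    include_pores: bool = False,
) -> FeatureMatrix:
    """Assemble the m x 2 matrix from a typed minutia set.

    Level-3 pores are excluded by default (they serve as reference data, not
    primary identifiers). Points within ``r_min`` of the core are dropped to
    keep the distance ratios well-conditioned. Falls back to the minutiae
    centroid when the set carries no detected core.
    """
    excluded = {"core", "delta"} | (set() if include_pores else {"pore"})
    pts = [m for m in ms if m.type not in excluded]
    if not pts:
        raise NoFeaturesError("no usable feature points (set empty or pores only)")
    coords = np.array([(m.x, m.y) for m in pts], dtype=np.float64)
    if ms.core is not None:
        core, fallback = ms.core, False
    else:
        cx, cy = coords.mean(axis=0)
        core, fallback = CorePoint(a=float(cx), b=float(cy), kind="core", poincare_index=0.0), True
    d = np.hypot(coords[:, 0] - core.a, coords[:, 1] - core.b)
    coords = coords[d > r_min]
    if coords.shape[0] == 0:
        raise DegenerateGeometryError(f"all feature points within r_min={r_min} of the core")
    # canonical order: polar angle about the core, then radius
    dx, dy = coords[:, 0] - core.a, coords[:, 1] - core.b
    order = np.lexsort((np.hypot(dx, dy), np.arctan2(dy, dx)))
    return FeatureMatrix(coords[order], core=core, core_is_fallback=fallback)


def establish_correspondence(
    Zc: FeatureMatrix,
    Xc: FeatureMatrix,
    tol_r: float = 10.0,
    tol_phi: float = 0.3,
) -> Correspondence:
    """Pair sample and control points in core-centered polar coordinates.

    Candidate pairs must agree in radius within ``tol_r`` pixels and in
    angle within ``tol_phi`` radians; accepted greedily by ascending polar
    distance sqrt(dr^2 + (r_mean * dphi)^2), each index used at most once.
    The procedure is deterministic (ties broken by index order).
    """
    rz, pz = Zc.polar()
    rx, px = Xc.polar()
    dr = np.abs(rz[:, None] - rx[None, :])
    dphi = np.angle(np.exp(1j * (pz[:, None] - px[None, :])))
    rbar = 0.5 * (rz[:, None] + rx[None, :])
    dist = np.hypot(dr, rbar * dphi)
    ok = (dr <= tol_r) & (np.abs(dphi) <= tol_phi)
    cand = [(dist[i, j], i, j) for i, j in zip(*np.nonzero(ok))]
    cand.sort()
    used_z: set[int] = set()
    used_x: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_z or j in used_x:
            continue
        pairs.append((int(i), int(j)))
        used_z.add(i)
        used_x.add(j)
    if not pairs:
        raise NoOverlapError("no sample/control pair within tolerance")
    pairs.sort()
    return Correspondence(
        tuple(pairs),
        unpaired_sample=tuple(i for i in range(Zc.m) if i not in used_z),
        unpaired_control=tuple(j for j in range(Xc.m) if j not in used_x),
    )


def similarity_score(
    Zc: FeatureMatrix,
    Xc: FeatureMatrix,
    corr: Correspondence,
    penalize_unpaired: bool = False,
) -> MatchResult:
    """The matching score P between sample matrix Z and control matrix X.

    With ``penalize_unpaired`` the unmatched points of either side enter the
    mean as zero-valued terms (off by default: the score is the mean over
    accepted pairs only).
    """
    if len(corr.pairs) == 0:
        raise NoOverlapError("correspondence holds no pairs")
    az, bz = Zc.core.a, Zc.core.b
    ax, bx = Xc.core.a, Xc.core.b
    terms = []
    for i, j in corr.pairs:
        z = Zc.coords[i]
        x = Xc.coords[j]
        dz2 = (z[0] - az) ** 2 + (z[1] - bz) ** 2
        dx2 = (x[0] - ax) ** 2 + (x[1] - bx) ** 2
        if dx2 == 0 or dz2 == 0:
            raise DegenerateGeometryError("feature point at zero distance from its core")
        rho = dz2 / dx2
        terms.append(1.0 / (abs(rho - 1.0) + 1.0))
    m_used = len(terms)
    denom = m_used + (
        len(corr.unpaired_sample) + len(corr.unpaired_control) if penalize_unpaired else 0
    )
    P = float(np.sum(terms) / denom) if denom != m_used else float(np.mean(terms))
    return MatchResult(
        P=P,
        percent=100.0 * P,
        m_used=m_used,
        per_point_terms=tuple(float(t) for t in terms),
        correspondence=corr,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _stage(name: str, fn, reports: list, **params):
    t0 = time.perf_counter()
    try:
        out = fn()
    except LfpError as e:
        raise StageError(name, e) from e
    from .reportio import StageReport

    reports.append(
        StageReport(
            stage=name, params=params, elapsed_s=round(time.perf_counter() - t0, 4)
        ).to_dict()
    )
    return out


def extract_features(
    image, modality: str, cfg: Config | None = None, image_id: str = ""
) -> tuple[MinutiaSet, dict]:
    """Run the full enhancement + extraction chain on one image.

    ``image`` may be an RgbImage, a GrayImage, a 2-D or H x W x 3 uint8
    array. Returns the filtered minutia set (core attached) and a dict of
    stage artifacts (grayscale, normalized, binary, skeleton, orientation
    field, stage reports) for audit.
    """
    cfg = cfg or Config()
    reports: list[dict] = []
    if isinstance(image, RgbImage):
        gray = _stage("grayscale", lambda: imgproc.to_grayscale(image), reports)
    elif isinstance(image, GrayImage):
        gray = image
    else:
        arr = np.asarray(image)
        if arr.ndim == 3:
            gray = _stage("grayscale", lambda: imgproc.to_grayscale(RgbImage(arr)), reports)
        else:
            gray = GrayImage(arr, stage="raw")
    norm = _stage(
        "normalize",
        lambda: imgproc.normalize(gray, cfg.target_mean, cfg.target_variance),
        reports,
        target_mean=cfg.target_mean,
        target_variance=cfg.target_variance,
    )
    # light smoothing keeps powder grain and substrate texture from
    # shredding the threshold step
    from scipy.ndimage import gaussian_filter

    smoothed = (
        GrayImage(gaussian_filter(norm.pixels, cfg.smooth_sigma), stage="normalized")
        if cfg.smooth_sigma > 0
        else norm
    )
    if cfg.binarize_method == "adaptive":
        binary = _stage(
            "binarize", lambda: imgproc.binarize_adaptive(smoothed, cfg.adaptive_block), reports
        )
    else:
        binary = _stage(
            "binarize", lambda: imgproc.binarize(smoothed, cfg.binarize_method), reports
        )
    binary = _stage(
        "polarity",
        lambda: imgproc.ensure_ridge_polarity(binary, norm, modality),
        reports,
        modality=modality,
    )
    # small-speckle cleanup so the skeleton is not dominated by noise
    from skimage.morphology import remove_small_objects

    clean = remove_small_objects(binary.pixels.astype(bool), max_size=cfg.min_object_px)
    binary = BinaryImage(clean.astype(np.uint8), ridge_is_one=True)

    pores = _stage(
        "pores",
        lambda: ridges.detect_pores(
            norm,
            binary,
            ridges.PoreParams(cfg.pore_area_min, cfg.pore_area_max),
            source_image_id=image_id,
        ),
        reports,
    )
    # fill pore-sized holes before thinning so they do not skeletonize into
    # spurious enclosures
    from skimage.morphology import remove_small_holes

    filled = remove_small_holes(binary.pixels.astype(bool), max_size=cfg.pore_area_max)
    solid = BinaryImage(filled.astype(np.uint8), ridge_is_one=True)

    fld = _stage(
        "orientation",
        lambda: ridges.estimate_orientation(norm, cfg.orientation_block),
        reports,
        block=cfg.orientation_block,
    )
    cores = ridges.detect_core(fld)
    core = next((c for c in cores if c.kind == "core"), None)

    skel = _stage("skeletonize", lambda: ridges.skeletonize(solid), reports)
    ms = _stage("extract", lambda: ridges.extract_minutiae(skel, image_id), reports)
    ms = _stage(
        "compound",
        lambda: ridges.classify_compound(
            ms, skel, ridges.CompoundParams(cfg.l_eye, cfg.l_spur, cfg.l_short, cfg.l_prune)
        ),
        reports,
    )
    ms = _stage(
        "filter",
        lambda: ridges.filter_minutiae(ms, cfg.border_margin, cfg.min_separation),
        reports,
        border_margin=cfg.border_margin,
        min_separation=cfg.min_separation,
    )
    # minutiae in regions without ridge signal (occlusions, smudges, bare
    # substrate) or with incoherent flow are unreliable: gate on the
    # foreground segmentation and grade by block coherence
    seg = imgproc.segment_foreground(norm, cfg.orientation_block, cfg.seg_exclusion_px)
    coh = fld.coherence
    nby, nbx = coh.shape
    h_seg, w_seg = seg.shape

    graded = []
    for m in ms:
        yy = int(min(max(m.y, 0), h_seg - 1))
        xx = int(min(max(m.x, 0), w_seg - 1))
        if not seg[yy, xx]:
            continue
        bi = min(int(m.y // cfg.orientation_block), nby - 1)
        bj = min(int(m.x // cfg.orientation_block), nbx - 1)
        q = float(coh[bi, bj])
        if q >= cfg.min_quality:
            graded.append(ridges.Minutia(m.x, m.y, m.type, quality=q))
    ms = ridges.MinutiaSet(
        tuple(graded), source_image_id=image_id, image_shape=ms.image_shape
    )
    h_img, w_img = ms.image_shape
    items = ms.items + tuple(
        m
        for m in pores
        if cfg.border_margin <= m.x < w_img - cfg.border_margin
        and cfg.border_margin <= m.y < h_img - cfg.border_margin
        and seg[int(min(max(m.y, 0), h_seg - 1)), int(min(max(m.x, 0), w_seg - 1))]
    )
    ms = MinutiaSet(items, source_image_id=image_id, core=core, image_shape=ms.image_shape)
    artifacts = {
        "grayscale": gray,
        "normalized": norm,
        "binary": binary,
        "skeleton": skel,
        "orientation": fld,
        "cores": cores,
        "stage_reports": reports,
    }
    return ms, artifacts


def match_minutiae(
    sample: MinutiaSet, control: MinutiaSet, cfg: Config | None = None
) -> MatchResult:
    """Score two already-extracted minutia sets (sample against control)."""
    cfg = cfg or Config()
    Zc = build_feature_matrix(sample, r_min=cfg.r_min, include_pores=cfg.include_pores)
    Xc = build_feature_matrix(control, r_min=cfg.r_min, include_pores=cfg.include_pores)
    corr = establish_correspondence(Zc, Xc, tol_r=cfg.tol_r, tol_phi=cfg.tol_phi)
    return similarity_score(Zc, Xc, corr, penalize_unpaired=cfg.penalize_unpaired)


def compare_images(sample_img, control_img, cfg: Config | None = None) -> MatchResult:
    """Full pipeline: enhance, extract and score a sample/control image pair.

    The sample side is treated as a powder-developed fluorescent print
    (bright ridges), the control as an inked card (dark ridges). Stage
    artifacts of both sides ride along in ``result.artifacts``.
    """
    cfg = cfg or Config()
    sample_ms, sample_art = extract_features(
        sample_img, cfg.sample_modality, cfg, image_id="sample"
    )
    control_ms, control_art = extract_features(
        control_img, cfg.control_modality, cfg, image_id="control"
    )
    res = match_minutiae(sample_ms, control_ms, cfg)
    res.artifacts.update(
        {
            "sample": sample_art,
            "control": control_art,
            "sample_minutiae": sample_ms,
            "control_minutiae": control_ms,
        }
    )
    return res
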