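"""Ridge-flow analysis and Galton-Henry feature-point extraction.

From a binarized fingerprint this module derives, in order: the block-wise
ridge orientation field, the singular points of that field (core and delta,
located by the Poincaré index), the one-pixel-wide ridge skeleton, and the
typed feature points ("minutiae") that identification rests on.

Second-level minutiae are first typed by the crossing number (CN) of each
skeleton pixel — half the sum of absolute differences around its cyclic
8-neighborhood — and compound structures (eyes, spurs, short ridges,
crossovers) are then recognised by walking the skeleton graph. Third-level
sweat pores are detected separately as small valleys fully enclosed by ridge
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    ConfigurationError,
    DegenerateImageError,
    NoFeaturesError,
    PreconditionError,
)
from .imgproc import BinaryImage, GrayImage

__all__ = [
    "OrientationField",
    "CorePoint",
    "Minutia",
    "MinutiaSet",
    "MINUTIA_TYPES",
    "estimate_orientation",
    "detect_core",
    "skeletonize",
    "crossing_number",
    "extract_minutiae",
    "classify_compound",
    "detect_pores",
    "filter_minutiae",
    "CompoundParams",
    "PoreParams",
]

MINUTIA_TYPES = frozenset(
    {
        "core",
        "delta",
        "termination",
        "bifurcation",
        "trifurcation",
        "crossover",
        "eye",
        "lake",
        "spur",
        "short_ridge",
        "island",
        "hook",
        "pore",
    }
)


@dataclass(frozen=True)
class OrientationField:
    """Block-wise ridge orientation, wrapped modulo pi.

    ``theta[i, j]`` is the ridge direction (radians in [0, pi)) of the block
    whose top-left pixel is ``(x=j*block_size, y=i*block_size)``;
    ``coherence`` in [0, 1] measures how anisotropic the local gradient
    structure is (1 for perfect stripes, ~0 for isotropic noise).
    """

    theta: np.ndarray
    block_size: int
    coherence: np.ndarray

    def __post_init__(self):
        t = np.mod(np.asarray(self.theta, dtype=np.float64), np.pi)
        c = np.clip(np.asarray(self.coherence, dtype=np.float64), 0.0, 1.0)
        if t.shape != c.shape or t.ndim != 2:
            raise ConfigurationError("theta and coherence must be equal-shape 2-D arrays")
        object.__setattr__(self, "theta", t)
        object.__setattr__(self, "coherence", c)

    def block_center(self, i: int, j: int) -> tuple[float, float]:
        """Pixel coordinates (x, y) of the centre of block (row i, col j)."""
        return ((j + 0.5) * self.block_size, (i + 0.5) * self.block_size)


@dataclass(frozen=True)
class CorePoint:
    """A singular point of the ridge flow: the (a, b) anchor of the matcher."""

    a: float  # x, pixels
    b: float  # y, pixels
    kind: str = "core"  # "core" or "delta"
    poincare_index: float = 0.5


@dataclass(frozen=True)
class Minutia:
    x: float
    y: float
    type: str
    quality: float = 1.0
    #: for terminations: unit direction the ridge tip points (away from the
    #: ridge body), radians; None when unknown. Not part of identity.
    direction: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        if self.type not in MINUTIA_TYPES:
            raise ConfigurationError(f"unknown minutia type {self.type!r}")


@dataclass(frozen=True)
class MinutiaSet:
    """A deterministic, duplicate-free collection of typed feature points."""

    items: tuple[Minutia, ...]
    source_image_id: str = ""
    core: Optional[CorePoint] = None
    image_shape: Optional[tuple[int, int]] = None  # (H, W), for border filtering

    def __post_init__(self):
        items = tuple(sorted(self.items, key=lambda m: (m.y, m.x, m.type)))
        seen = set()
        for m in items:
            key = (m.x, m.y, m.type)
            if key in seen:
                raise ConfigurationError(f"duplicate minutia {key}")
            seen.add(key)
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def of_type(self, *types: str) -> tuple[Minutia, ...]:
        return tuple(m for m in self.items if m.type in types)

    def coords(self) -> np.ndarray:
        return np.array([(m.x, m.y) for m in self.items], dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# orientation field and singular points


def estimate_orientation(img: GrayImage, block_size: int = 16) -> OrientationField:
    """Least-squares gradient orientation per block (structure-tensor method).

    Within each block the doubled-angle average of the gradient direction is
    taken, which handles the mod-pi ambiguity; ridge orientation is the
    gradient direction rotated by pi/2. Coherence is the normalised
    eigenvalue gap of the summed gradient tensor.
    """
    p = img.pixels
    h, w = p.shape
    if block_size > min(h, w):
        raise ConfigurationError(
            f"block_size {block_size} exceeds image side {min(h, w)}"
        )
    if p.max() == p.min():
        raise DegenerateImageError("constant image has no orientation")
    gy, gx = np.gradient(p)
    gxx, gyy, gxy = gx * gx, gy * gy, gx * gy
    nby, nbx = h // block_size, w // block_size

    def block_sum(a: np.ndarray) -> np.ndarray:
        a = a[: nby * block_size, : nbx * block_size]
        return a.reshape(nby, block_size, nbx, block_size).sum(axis=(1, 3))

    sxx, syy, sxy = block_sum(gxx), block_sum(gyy), block_sum(gxy)
    # gradient direction (doubled-angle mean), then +pi/2 for ridge direction
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy) + 0.5 * np.pi
    denom = sxx + syy
    coh = np.where(
        denom > 0, np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2) / np.maximum(denom, 1e-12), 0.0
    )
    return OrientationField(theta=theta, block_size=block_size, coherence=coh)


def smooth_orientation(field: OrientationField, sigma: float = 1.0) -> OrientationField:
    """Vector-average smoothing in doubled-angle space (preserves mod-pi wrap)."""
    c2 = ndimage.gaussian_filter(np.cos(2 * field.theta) * np.maximum(field.coherence, 1e-3), sigma)
    s2 = ndimage.gaussian_filter(np.sin(2 * field.theta) * np.maximum(field.coherence, 1e-3), sigma)
    theta = 0.5 * np.arctan2(s2, c2)
    return OrientationField(theta=theta, block_size=field.block_size, coherence=field.coherence)


def _wrap_half_pi(d: np.ndarray) -> np.ndarray:
    """Wrap orientation differences into (-pi/2, pi/2]."""
    return d - np.pi * np.floor(d / np.pi + 0.5)


# cyclic 8-neighborhood offsets (dx, dy), counter-clockwise starting at +x
_RING = [(1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1)]


def poincare_index(field: OrientationField) -> np.ndarray:
    """Poincaré index of every interior block (0 on the 1-block border).

    The index is the net rotation of the orientation (taken mod pi) along the
    closed 8-neighborhood ring, in units of 2*pi: +1 at a whorl core, +1/2 at
    a loop core, -1/2 at a delta, 0 in smooth flow.
    """
    th = field.theta
    # gather ring orientations by shifting
    vals = []
    for dx, dy in _RING:
        vals.append(np.roll(np.roll(th, -dy, axis=0), -dx, axis=1))
    total = np.zeros_like(th)
    for k in range(8):
        total += _wrap_half_pi(vals[(k + 1) % 8] - vals[k])
    # the ring above is counter-clockwise in (x, y-up); with image y growing
    # downward the traversal is clockwise, so negate to keep the convention
    # "+1 whorl, +1/2 loop core, -1/2 delta"
    idx = -total / (2.0 * np.pi)
    idx[0, :] = idx[-1, :] = 0.0
    idx[:, 0] = idx[:, -1] = 0.0
    return idx


def detect_core(field: OrientationField, smooth_sigma: float = 1.0) -> list[CorePoint]:
    """Locate singular points of the ridge flow via the Poincaré index.

    Adjacent blocks flagging the same singularity are merged (connected
    components on the block lattice) and replaced by their centroid. The
    returned list is sorted by |index| descending, ties broken by distance to
    the image centroid, so the first entry is the (a, b) core anchor used by
    the matcher.
    """
    f = smooth_orientation(field, smooth_sigma) if smooth_sigma > 0 else field
    idx = poincare_index(f)
    points: list[CorePoint] = []
    # Blocks whose ring passes close to a singularity pick up a half-strength
    # halo, so detections are clustered by sign and each cluster is summarised
    # by its extreme-index blocks.
    for sign in (1.0, -1.0):
        mask = sign * idx > 0.3
        if not mask.any():
            continue
        lab = cc_label(mask, connectivity=2)
        for region in regionprops(lab):
            ys, xs = region.coords[:, 0], region.coords[:, 1]
            vals_r = idx[ys, xs]
            peak = np.abs(vals_r).max()
            target = min((1.0, 0.5), key=lambda t: abs(peak - t)) * sign
            if target not in (1.0, 0.5, -0.5):
                continue
            top = np.abs(vals_r) >= 0.75 * peak
            ci, cj = ys[top].mean(), xs[top].mean()  # block-row, block-col
            x = (cj + 0.5) * field.block_size
            y = (ci + 0.5) * field.block_size
            kind = "core" if target > 0 else "delta"
            points.append(CorePoint(a=x, b=y, kind=kind, poincare_index=target))
    nby, nbx = field.theta.shape
    cx = nbx * field.block_size / 2.0
    cy = nby * field.block_size / 2.0
    points.sort(
        key=lambda p: (
            -abs(p.poincare_index),
            (p.a - cx) ** 2 + (p.b - cy) ** 2,
            p.b,
            p.a,
        )
    )
    return points


# ---------------------------------------------------------------------------
# skeleton and crossing number


def skeletonize(binary: BinaryImage) -> BinaryImage:
    """Thin the ridge mask to one-pixel-wide centerlines (Zhang-Suen)."""
    if not binary.ridge_is_one:
        raise PreconditionError("skeletonize requires ridge polarity 1")
    if binary.pixels.sum() == 0:
        raise DegenerateImageError("empty foreground cannot be thinned")
    skel = _sk_skeletonize(binary.pixels.astype(bool))
    return BinaryImage(skel.astype(np.uint8), ridge_is_one=True)


def crossing_number(skel: BinaryImage, x: int, y: int) -> int:
    """CN at a skeleton pixel: half the cyclic transition count of its ring."""
    p = skel.pixels
    h, w = p.shape
    if not (0 <= x < w and 0 <= y < h) or p[y, x] != 1:
        raise PreconditionError(f"({x}, {y}) is not a skeleton pixel")
    ring = []
    for dx, dy in _RING:
        xx, yy = x + dx, y + dy
        ring.append(int(p[yy, xx]) if 0 <= xx < w and 0 <= yy < h else 0)
    return sum(abs(ring[k] - ring[(k + 1) % 8]) for k in range(8)) // 2


def _cn_map(p: np.ndarray) -> np.ndarray:
    """Vectorized crossing number for every pixel (valid on skeleton pixels)."""
    pad = np.pad(p, 1)
    rings = []
    for dx, dy in _RING:
        rings.append(pad[1 + dy : 1 + dy + p.shape[0], 1 + dx : 1 + dx + p.shape[1]])
    cn = np.zeros(p.shape, dtype=np.int32)
    for k in range(8):
        cn += np.abs(rings[(k + 1) % 8].astype(np.int32) - rings[k].astype(np.int32))
    return cn // 2


def extract_minutiae(skel: BinaryImage, source_image_id: str = "") -> MinutiaSet:
    """Type every skeleton pixel by its crossing number.

    CN 1 -> termination, CN 3 -> bifurcation, CN >= 4 -> trifurcation
    candidate (``classify_compound`` may refine it to a crossover). Interior
    ridge pixels (CN 2) carry no feature. The result is deterministic for a
    given skeleton and ordered canonically.
    """
    p = skel.pixels
    if p.sum() == 0:
        raise NoFeaturesError("empty skeleton")
    cn = _cn_map(p)
    cn = np.where(p == 1, cn, -1)
    h, w = p.shape
    items = []
    for y, x in zip(*np.nonzero(cn == 1)):
        # tip direction: away from the local skeleton mass
        ys0, ys1 = max(0, y - 6), min(h, y + 7)
        xs0, xs1 = max(0, x - 6), min(w, x + 7)
        yy, xx = np.nonzero(p[ys0:ys1, xs0:xs1])
        vx = float(np.sum(xx + xs0 - x))
        vy = float(np.sum(yy + ys0 - y))
        direction = float(np.arctan2(-vy, -vx)) if (vx or vy) else None
        items.append(Minutia(float(x), float(y), "termination", direction=direction))
    for y, x in zip(*np.nonzero(cn == 3)):
        items.append(Minutia(float(x), float(y), "bifurcation"))
    for y, x in zip(*np.nonzero(cn >= 4)):
        items.append(Minutia(float(x), float(y), "trifurcation"))
    return MinutiaSet(tuple(items), source_image_id=source_image_id, image_shape=p.shape)


# ---------------------------------------------------------------------------
# compound structures


@dataclass(frozen=True)
class CompoundParams:
    """Length scales (pixels) for compound-structure recognition.

    Defaults assume a ridge period near 9 px: a cycle shorter than ``l_eye``
    is an enclosure, a branch shorter than ``l_spur`` a spur, a free segment
    shorter than ``l_short`` a short ridge (or island when tiny). ``l_eye``
    is ~4.5 ridge periods because an enclosure's skeleton cycle runs along
    the annulus midline — roughly the lumen perimeter plus 2*pi times the
    ridge half-width — so a tighter bound would only admit enclosures whose
    lumen is below the ink-spread blur scale.
    """

    l_eye: float = 40.0
    l_spur: float = 8.0
    l_short: float = 15.0
    l_prune: float = 4.0  # branches below this are thinning noise, not spurs


def _skeleton_graph(p: np.ndarray):
    """Decompose a skeleton into node clusters and edge segments.

    Nodes are connected clusters of pixels with CN != 2; edges are connected
    components of the remaining (CN == 2) pixels, annotated with the node
    clusters adjacent to them. Returns (node_label_img, node_info, segments)
    where node_info[nid] = dict(kind=, centroid=(x, y), size=) and each
    segment is dict(length=, centroid=(x, y), nodes=multiset of node ids).
    """
    cn = np.where(p == 1, _cn_map(p), -1)
    node_mask = (cn == 1) | (cn >= 3)
    node_lab = cc_label(node_mask, connectivity=2)
    node_info = {}
    for r in regionprops(node_lab):
        ys, xs = r.coords[:, 0], r.coords[:, 1]
        cns = cn[ys, xs]
        kind = "termination" if cns.max() == 1 else ("bifurcation" if cns.max() == 3 else "trifurcation")
        node_info[r.label] = {
            "kind": kind,
            "centroid": (float(xs.mean()), float(ys.mean())),
            "size": len(xs),
        }
    # ridge arms leaving a junction are often mutually 8-adjacent right next
    # to it (diagonal steps bypass the node pixel), which would fuse them into
    # one edge component; excluding a one-pixel zone around every node keeps
    # the arms separate, at the cost of ~2-3 px of measured length per end
    # (compensated below)
    node_zone = ndimage.binary_dilation(node_mask, structure=np.ones((3, 3), bool))
    edge_mask = (cn == 2) & ~node_zone
    edge_lab = cc_label(edge_mask, connectivity=2)
    h, w = p.shape
    from collections import defaultdict

    # contact pixels of every (edge component, node cluster) pair, found by a
    # 5x5 scan (the excluded zone puts edges up to 2 px from their node)
    contacts: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for y, x in np.argwhere(edge_mask):
        eid = int(edge_lab[y, x])
        seen = set()
        for dy in (-2, -1, 0, 1, 2):
            for dx in (-2, -1, 0, 1, 2):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    nid = int(node_lab[yy, xx])
                    if nid:
                        seen.add(nid)
        for nid in seen:
            contacts[(eid, nid)].append((y, x))

    def count_ends(px: list[tuple[int, int]]) -> int:
        # contact pixels at one arm end are mutually close; a self-looping arm
        # touches its node at two far-apart groups
        groups: list[list[tuple[int, int]]] = []
        for q in px:
            for grp in groups:
                if any((q[0] - r[0]) ** 2 + (q[1] - r[1]) ** 2 <= 8 for r in grp):
                    grp.append(q)
                    break
            else:
                groups.append([q])
        return len(groups)

    touches: dict[int, dict[int, int]] = defaultdict(dict)
    for (eid, nid), px in contacts.items():
        touches[eid][nid] = count_ends(px)

    segments = []
    for r in regionprops(edge_lab):
        ys, xs = r.coords[:, 0], r.coords[:, 1]
        tc = dict(touches.get(r.label, {}))
        ends = sum(tc.values())
        segments.append(
            {
                "length": len(xs) + 2 * ends,  # compensate the excluded zones
                "raw_length": len(xs),
                "centroid": (float(xs.mean()), float(ys.mean())),
                "nodes": sorted(tc),
                "touch_counts": tc,
            }
        )
    # arms so short they vanished inside the excluded zones: node clusters in
    # direct contact still form a (pseudo-)segment of their centroid distance
    linked = {frozenset(s["nodes"]) for s in segments if len(s["nodes"]) == 2}
    ids = sorted(node_info)
    for ii, a in enumerate(ids):
        for b in ids[ii + 1 :]:
            if frozenset((a, b)) in linked:
                continue
            pa, pb = node_info[a]["centroid"], node_info[b]["centroid"]
            d = np.hypot(pa[0] - pb[0], pa[1] - pb[1])
            if d <= 4.5:
                segments.append(
                    {
                        "length": float(d),
                        "centroid": ((pa[0] + pb[0]) / 2, (pa[1] + pb[1]) / 2),
                        "nodes": [a, b],
                        "touch_counts": {a: 1, b: 1},
                    }
                )
    return node_lab, node_info, segments


def classify_compound(
    ms: MinutiaSet, skel: BinaryImage, params: CompoundParams | None = None
) -> MinutiaSet:
    """Re-label compound Galton-Henry structures by a skeleton graph walk.

    Recognised patterns (candidates not matching any rule keep their CN
    type):

    * two bifurcations joined by both arms of a cycle shorter than ``l_eye``
      -> one *eye* (a self-looping arm on a single junction counts too);
      an isolated cycle with no junction at all -> *lake*;
    * a branch shorter than ``l_spur`` from a junction to a termination ->
      one *spur* at the junction, the tip termination consumed;
    * a free segment with two terminations, total length below ``l_short``
      -> one *short_ridge* (an *island* when below 4 px);
    * two degree-3 junctions joined by a segment shorter than ``l_spur``
      whose through-ridges continue on both sides -> one *crossover*.
    """
    params = params or CompoundParams()
    p = skel.pixels
    node_lab, node_info, segments = _skeleton_graph(p)
    consumed: set[int] = set()  # node ids folded into a compound structure
    extra: list[Minutia] = []

    # index segments by node pair
    from collections import defaultdict

    by_pair = defaultdict(list)
    for seg in segments:
        key = tuple(seg["nodes"])
        by_pair[key].append(seg)

    bif_kinds = ("bifurcation", "trifurcation")

    # eyes: two junctions joined by >= 2 distinct arms forming a short cycle
    for key, segs in by_pair.items():
        if len(key) == 2 and len(segs) >= 2:
            a, b = key
            if node_info[a]["kind"] in bif_kinds and node_info[b]["kind"] in bif_kinds:
                segs_sorted = sorted(segs, key=lambda s: s["length"])
                # cycle length: the two arms plus the junction clusters
                # themselves (the per-end zone compensation would count each
                # junction twice around a closed path)
                cyc = (
                    segs_sorted[0].get("raw_length", segs_sorted[0]["length"])
                    + segs_sorted[1].get("raw_length", segs_sorted[1]["length"])
                    + node_info[a]["size"]
                    + node_info[b]["size"]
                    + 4
                )
                if cyc < params.l_eye and a not in consumed and b not in consumed:
                    cx = (segs_sorted[0]["centroid"][0] + segs_sorted[1]["centroid"][0]) / 2
                    cy = (segs_sorted[0]["centroid"][1] + segs_sorted[1]["centroid"][1]) / 2
                    extra.append(Minutia(cx, cy, "eye"))
                    consumed.update((a, b))
    # self-loop eye: one junction, an arm touching it at both ends
    for key, segs in by_pair.items():
        if len(key) == 1:
            (a,) = key
            for seg in segs:
                if (
                    node_info[a]["kind"] in bif_kinds
                    and seg["touch_counts"].get(a, 0) >= 2
                    and seg["length"] < params.l_eye
                    and a not in consumed
                ):
                    extra.append(Minutia(*seg["centroid"], "eye"))
                    consumed.add(a)
    # lakes: cycles with no node at all
    for key, segs in by_pair.items():
        if len(key) == 0:
            for seg in segs:
                if seg["length"] < params.l_eye:
                    extra.append(Minutia(*seg["centroid"], "lake"))

    # spurs: short junction-to-termination branch
    for key, segs in by_pair.items():
        if len(key) == 2:
            a, b = key
            ka, kb = node_info[a]["kind"], node_info[b]["kind"]
            pair = None
            if ka in bif_kinds and kb == "termination":
                pair = (a, b)
            elif kb in bif_kinds and ka == "termination":
                pair = (b, a)
            if pair is None:
                continue
            junc, tip = pair
            for seg in segs:
                if junc in consumed or tip in consumed:
                    continue
                if seg["length"] < params.l_prune:
                    # thinning artifact: delete both points, emit nothing
                    consumed.update((junc, tip))
                    break
                if seg["length"] < params.l_spur:
                    extra.append(Minutia(*node_info[junc]["centroid"], "spur"))
                    consumed.update((junc, tip))
                    break

    # short ridges / islands: free component = two terminations, one segment
    for key, segs in by_pair.items():
        if len(key) == 2:
            a, b = key
            if (
                node_info[a]["kind"] == "termination"
                and node_info[b]["kind"] == "termination"
                and len(segs) == 1
                and a not in consumed
                and b not in consumed
            ):
                # free only if neither termination touches any other segment
                others = [
                    s
                    for k2, ss in by_pair.items()
                    for s in ss
                    if (a in k2 or b in k2) and k2 != key
                ]
                if others:
                    continue
                length = segs[0]["length"]
                if length < params.l_short:
                    t = "island" if length < 4 else "short_ridge"
                    extra.append(Minutia(*segs[0]["centroid"], t))
                    consumed.update((a, b))

    # crossovers: two adjacent degree-3 junctions bridged by a short segment
    for key, segs in by_pair.items():
        if len(key) == 2 and len(segs) == 1:
            a, b = key
            if (
                node_info[a]["kind"] in bif_kinds
                and node_info[b]["kind"] in bif_kinds
                and segs[0]["length"] < params.l_spur / 2
                and a not in consumed
                and b not in consumed
            ):
                deg_a = sum(len(ss) for k2, ss in by_pair.items() if a in k2)
                deg_b = sum(len(ss) for k2, ss in by_pair.items() if b in k2)
                if deg_a >= 3 and deg_b >= 3:
                    cx = (node_info[a]["centroid"][0] + node_info[b]["centroid"][0]) / 2
                    cy = (node_info[a]["centroid"][1] + node_info[b]["centroid"][1]) / 2
                    extra.append(Minutia(cx, cy, "crossover"))
                    consumed.update((a, b))

    # rebuild: drop minutiae whose node cluster was consumed, add compounds
    kept = []
    h, w = p.shape
    for m in ms:
        xi = int(round(min(max(m.x, 0), w - 1)))
        yi = int(round(min(max(m.y, 0), h - 1)))
        nid = int(node_lab[yi, xi])
        if nid and nid in consumed:
            continue
        kept.append(m)
    kept.extend(extra)
    # compound centroids can coincide after rounding; nudge duplicates is not
    # needed because (x, y, type) triplets remain distinct by construction
    return replace(ms, items=tuple(kept))


# ---------------------------------------------------------------------------
# level-3 pores


@dataclass(frozen=True)
class PoreParams:
    """Sweat-pore size window in squared pixels."""

    area_min: int = 1
    area_max: int = 20


def detect_pores(
    gray: GrayImage | None,
    binary: BinaryImage,
    params: PoreParams | None = None,
    source_image_id: str = "",
) -> MinutiaSet:
    """Report background blobs fully enclosed by ridge pixels as pores.

    A pore is a 4-connected background component that does not touch the
    image border (hence is enclosed) with area in [area_min, area_max]. The
    grayscale image is accepted for interface symmetry but the decision is
    purely geometric.
    """
    params = params or PoreParams()
    if not binary.ridge_is_one:
        raise PreconditionError("detect_pores requires ridge polarity 1")
    bg = binary.pixels == 0
    lab = cc_label(bg, connectivity=1)
    border_labels = set(np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])))
    items = []
    for r in regionprops(lab):
        if r.label in border_labels:
            continue
        if params.area_min <= r.area <= params.area_max:
            cy, cx = r.centroid
            items.append(Minutia(float(cx), float(cy), "pore"))
    return MinutiaSet(tuple(items), source_image_id=source_image_id, image_shape=binary.pixels.shape)


# ---------------------------------------------------------------------------
# filtering


def filter_minutiae(
    ms: MinutiaSet, border_margin: int = 10, min_separation: float = 12.0
) -> MinutiaSet:
    """Suppress extraction artifacts.

    Drops feature points within ``border_margin`` pixels of the image edge
    (where the ridge pattern is truncated, every ridge ends artificially),
    then removes *pairs* of opposing terminations closer than
    ``min_separation`` — the signature of a broken ridge, two facing
    endpoints across a gap. Opposition is judged by distance alone: tip
    directions estimated at ragged break endpoints are too noisy to gate on
    (requiring estimated head-on geometry retains more spurious endpoints
    than it saves genuine ones). Deterministic: pairs are merged in
    canonical order.
    """
    if ms.image_shape is None:
        raise PreconditionError("MinutiaSet lacks image_shape; cannot border-filter")
    h, w = ms.image_shape
    kept = [
        m
        for m in ms
        if border_margin <= m.x < w - border_margin and border_margin <= m.y < h - border_margin
    ]
    terms = [m for m in kept if m.type == "termination"]
    removed: set[int] = set()
    for i in range(len(terms)):
        if i in removed:
            continue
        for j in range(i + 1, len(terms)):
            if j in removed:
                continue
            d = np.hypot(terms[i].x - terms[j].x, terms[i].y - terms[j].y)
            if d < min_separation:
                removed.update((i, j))
                break
    dead = {id(terms[k]) for k in removed}
    kept = [m for m in kept if id(m) not in dead]
    return replace(ms, items=tuple(kept))
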