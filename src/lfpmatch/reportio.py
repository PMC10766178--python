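"""Serialization: images, minutiae exchange files, match reports, overlays."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from dataclasses import field as dataclass_field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from PIL import Image, ImageDraw

from .errors import ConfigurationError, LfpError, PreconditionError
from .imgproc import BinaryImage, GrayImage, RgbImage
from .matching import Correspondence, MatchResult
from .ridges import MINUTIA_TYPES, CorePoint, Minutia, MinutiaSet

__all__ = [
    "StageReport",
    "read_image",
    "write_gray_png",
    "save_minutiae_json",
    "load_minutiae_json",
    "save_minutiae_csv",
    "load_minutiae_csv",
    "write_report",
    "read_report",
    "annotate_overlay",
]

REPORT_SCHEMA_VERSION = "1"


@dataclass
class StageReport:
    """Provenance record for one executed pipeline stage."""

    stage: str
    params: dict = dataclass_field(default_factory=dict)
    warnings: list = dataclass_field(default_factory=list)
    elapsed_s: float = 0.0
    inputs: Optional[str] = None
    outputs: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def read_image(path: str | Path):
    """Read PNG/TIFF/JPEG as RgbImage (color) or GrayImage (single channel)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P"):
                arr = np.asarray(im.convert("RGB"))
                return RgbImage(arr)
            arr = np.asarray(im.convert("L"))
            return GrayImage(arr.astype(float), stage="raw")
    except (OSError, ValueError) as e:
        raise LfpError(f"cannot read image {path}: {e}") from e


def write_gray_png(img: GrayImage | BinaryImage, path: str | Path) -> None:
    if isinstance(img, BinaryImage):
        arr = (img.pixels * 255).astype(np.uint8)
    else:
        p = img.pixels
        if img.stage == "normalized":  # rescale for display only
            lo, hi = p.min(), p.max()
            p = (p - lo) / (hi - lo + 1e-12) * 255.0
        arr = np.clip(p, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path), format="PNG")


# --- minutiae exchange -----------------------------------------------------


def _minutia_record(m: Minutia) -> dict:
    return {"x": m.x, "y": m.y, "type": m.type, "quality": m.quality}


def save_minutiae_json(ms: MinutiaSet, path: str | Path) -> None:
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "source_image_id": ms.source_image_id,
        "image_shape": list(ms.image_shape) if ms.image_shape else None,
        "core": (
            {"a": ms.core.a, "b": ms.core.b, "kind": ms.core.kind, "poincare_index": ms.core.poincare_index}
            if ms.core
            else None
        ),
        "minutiae": [_minutia_record(m) for m in ms],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def _validated_minutia(rec: dict) -> Minutia:
    t = rec["type"]
    if t not in MINUTIA_TYPES:
        raise ConfigurationError(f"unknown minutia type {t!r} in file")
    return Minutia(float(rec["x"]), float(rec["y"]), t, float(rec.get("quality", 1.0)))


def load_minutiae_json(path: str | Path) -> MinutiaSet:
    doc = json.loads(Path(path).read_text())
    core = None
    if doc.get("core"):
        c = doc["core"]
        core = CorePoint(float(c["a"]), float(c["b"]), c.get("kind", "core"), float(c.get("poincare_index", 0.5)))
    shape = tuple(doc["image_shape"]) if doc.get("image_shape") else None
    return MinutiaSet(
        tuple(_validated_minutia(r) for r in doc["minutiae"]),
        source_image_id=doc.get("source_image_id", ""),
        core=core,
        image_shape=shape,
    )


def save_minutiae_csv(ms: MinutiaSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "type", "quality"])
        for m in ms:
            w.writerow([m.x, m.y, m.type, m.quality])


def load_minutiae_csv(path: str | Path, source_image_id: str = "") -> MinutiaSet:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return MinutiaSet(
        tuple(_validated_minutia(r) for r in rows), source_image_id=source_image_id
    )


# --- match reports ---------------------------------------------------------


def write_report(
    result: MatchResult,
    stages: list[dict],
    path: str | Path,
    config: Optional[dict] = None,
) -> None:
    """Versioned JSON match report; percent printed with two decimals."""
    if stages is None:
        raise PreconditionError("a report requires the list of executed stages")
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "P": result.P,
        "percent": result.percent,
        "percent_str": f"{result.percent:.2f}",
        "m_used": result.m_used,
        "per_point_terms": list(result.per_point_terms),
        "correspondence": {
            "pairs": [list(p) for p in result.correspondence.pairs],
            "unpaired_sample": list(result.correspondence.unpaired_sample),
            "unpaired_control": list(result.correspondence.unpaired_control),
        },
        "stages": stages,
        "config": config or {},
    }
    try:
        Path(path).write_text(json.dumps(doc, indent=2))
    except OSError as e:
        raise LfpError(f"cannot write report {path}: {e}") from e


def read_report(path: str | Path) -> MatchResult:
    doc = json.loads(Path(path).read_text())
    corr = Correspondence(
        tuple((int(a), int(b)) for a, b in doc["correspondence"]["pairs"]),
        unpaired_sample=tuple(doc["correspondence"]["unpaired_sample"]),
        unpaired_control=tuple(doc["correspondence"]["unpaired_control"]),
    )
    return MatchResult(
        P=doc["P"],
        percent=doc["percent"],
        m_used=doc["m_used"],
        per_point_terms=tuple(doc["per_point_terms"]),
        correspondence=corr,
    )


# --- annotated overlays ----------------------------------------------------

_TYPE_COLORS = {
    "core": (255, 0, 0),
    "delta": (255, 128, 0),
    "termination": (0, 160, 255),
    "bifurcation": (0, 200, 0),
    "trifurcation": (160, 0, 200),
    "crossover": (200, 0, 120),
    "eye": (255, 200, 0),
    "lake": (255, 230, 120),
    "spur": (0, 255, 200),
    "short_ridge": (130, 130, 255),
    "island": (90, 90, 200),
    "hook": (0, 255, 120),
    "pore": (255, 90, 90),
}


def annotate_overlay(img: GrayImage, ms: MinutiaSet, path: str | Path) -> None:
    """Write a PNG with numbered, type-coloured markers at each feature point."""
    p = img.pixels
    h, w = p.shape
    for m in ms:
        if not (0 <= m.x < w and 0 <= m.y < h):
            raise PreconditionError(f"minutia ({m.x}, {m.y}) outside {w}x{h} image")
    if img.stage == "normalized":
        lo, hi = p.min(), p.max()
        p = (p - lo) / (hi - lo + 1e-12) * 255.0
    base = Image.fromarray(np.clip(p, 0, 255).astype(np.uint8), "L").convert("RGB")
    draw = ImageDraw.Draw(base)
    for i, m in enumerate(ms, start=1):
        color = _TYPE_COLORS.get(m.type, (255, 255, 255))
        r = 4
        draw.ellipse([m.x - r, m.y - r, m.x + r, m.y + r], outline=color, width=1)
        draw.text((m.x + r + 1, m.y - r - 1), str(i), fill=color)
    if ms.core is not None:
        a, b = ms.core.a, ms.core.b
        draw.line([a - 6, b, a + 6, b], fill=(255, 0, 0), width=1)
        draw.line([a, b - 6, a, b + 6], fill=(255, 0, 0), width=1)
    base.save(Path(path), format="PNG")
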