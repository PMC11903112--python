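"""Readers and writers for the artifacts a nuclear-morphometry study touches.

Supported formats:

* QuPath-dialect GeoJSON detection exports (RFC 7946 ``FeatureCollection``
  of nucleus boundary polygons with a ``classification`` property),
* integer label masks (TIFF/PNG; 0 = background, each positive label one
  nucleus) with a μm/pixel calibration,
* flat measurement CSV tables with a fixed header, and
* a cohort manifest CSV mapping case IDs to variant labels.

All geometry leaving this module is in calibrated micrometres. Coordinates
are kept in the image frame (y grows downward); every downstream measure is
reflection-invariant, so frame handedness never changes a result.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
from skimage import measure as skmeasure

__all__ = [
    "CELL_CLASSES",
    "VARIANT_LABELS",
    "NucleusShape",
    "CohortManifest",
    "MEASUREMENT_COLUMNS",
    "read_qupath_geojson",
    "write_qupath_geojson",
    "read_label_mask",
    "write_label_mask",
    "read_measurements_csv",
    "write_measurements_csv",
]

CELL_CLASSES = ("tumour", "lymphocyte", "normal_epithelium", "other")

#: Closed vocabulary of study groups for manifest variant labels.
VARIANT_LABELS = (
    "cLCIS",
    "pLCIS",
    "cILC_score1",
    "cILC_score2",
    "sILC_score2",
    "pILC",
    "IBC_NST_score1",
    "IBC_NST_score2",
    "IBC_NST_score3",
    "lymphocyte",
    "normal_epithelium",
)

#: Fixed measurement CSV header.
MEASUREMENT_COLUMNS = (
    "nucleus_id",
    "case_id",
    "cell_class",
    "area_um2",
    "perimeter_um",
    "min_feret_um",
    "max_feret_um",
)


@dataclass
class NucleusShape:
    """One nucleus boundary polygon in calibrated μm.

    ``vertices`` is an (n, 2) float array of ring vertices; the closing edge
    back to the first vertex is implied and the first vertex is not repeated.
    The stored ring is simple (non-self-intersecting) and oriented so its
    shoelace signed area is positive (counter-clockwise in a y-up frame).
    """

    nucleus_id: str
    case_id: str
    cell_class: str
    vertices: np.ndarray
    source_pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be an (n>=3, 2) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices contain non-finite coordinates")
        self.vertices = v

    @classmethod
    def from_ring(
        cls,
        ring,
        *,
        nucleus_id: str,
        case_id: str,
        cell_class: str = "tumour",
        source_pixel_size: float | None = None,
        repair: bool = True,
    ) -> "NucleusShape":
        """Build a shape from raw ring coordinates, cleaning the ring.

        Drops a repeated closing vertex and consecutive duplicates,
        normalizes orientation to positive signed area, and — when
        ``repair`` — fixes self-intersecting (bow-tie) rings by keeping the
        largest simple sub-polygon. Unrepairable rings raise ``ValueError``.
        """
        v = np.asarray(ring, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("ring must be an (n, 2) coordinate array")
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = np.any(v[1:] != v[:-1], axis=1)
        v = v[keep]
        if len(v) < 3:
            raise ValueError("degenerate ring: fewer than 3 distinct vertices")
        poly = sgeom.Polygon(v)
        if poly.is_valid and poly.area == 0:
            raise ValueError("zero-area polygon")
        if not poly.is_valid:
            if not repair:
                raise ValueError("self-intersecting ring")
            fixed = shapely.make_valid(poly)
            polys = (
                [g for g in fixed.geoms if isinstance(g, sgeom.Polygon)]
                if hasattr(fixed, "geoms")
                else ([fixed] if isinstance(fixed, sgeom.Polygon) else [])
            )
            polys = [p for p in polys if p.area > 0]
            if not polys:
                raise ValueError("ring could not be repaired to a simple polygon")
            poly = max(polys, key=lambda p: p.area)
            v = np.asarray(poly.exterior.coords[:-1], dtype=float)
        # normalize orientation: positive shoelace signed area
        x, y = v[:, 0], v[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if signed < 0:
            v = v[::-1]
        return cls(
            nucleus_id=nucleus_id,
            case_id=case_id,
            cell_class=cell_class,
            vertices=v,
            source_pixel_size=source_pixel_size,
        )


@dataclass
class CohortManifest:
    """Case-to-variant mapping with a lesion/reference role per case."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case_id, variant, role in self.entries:
            if case_id in seen:
                raise ValueError(f"duplicate case_id {case_id!r} in manifest")
            seen.add(case_id)
            if variant not in VARIANT_LABELS:
                raise ValueError(f"unknown variant label {variant!r}")
            if role not in ("lesion", "reference"):
                raise ValueError(f"unknown group_role {role!r}")

    @property
    def case_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def variant_of(self, case_id: str) -> str:
        for cid, variant, _ in self.entries:
            if cid == case_id:
                return variant
        raise KeyError(case_id)

    def cases_of(self, variant: str) -> list[str]:
        return [cid for cid, v, _ in self.entries if v == variant]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.entries, columns=["case_id", "variant_label", "group_role"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        df = pd.read_csv(path, dtype=str)
        for col in ("case_id", "variant_label", "group_role"):
            if col not in df.columns:
                raise ValueError(f"manifest is missing required column {col!r}")
        return cls(list(df[["case_id", "variant_label", "group_role"]].itertuples(index=False, name=None)))


def _classification_name(props: dict) -> str:
    """Map a QuPath classification property onto the cell-class vocabulary.

    Accepts both the plain string dialect (``"classification": "Tumor"``)
    and the nested object dialect (``{"classification": {"name": ...}}``).
    Absent or unrecognized classifications default to tumour / other.
    """
    raw = props.get("classification")
    if raw is None:
        return "tumour"
    name = raw.get("name", "") if isinstance(raw, dict) else str(raw)
    low = str(name).lower()
    if "lymph" in low or "immune" in low:
        return "lymphocyte"
    if "normal" in low or "epitheli" in low:
        return "normal_epithelium"
    if "tumor" in low or "tumour" in low:
        return "tumour"
    return "other"


_CLASS_EXPORT = {
    "tumour": "Tumor",
    "lymphocyte": "Lymphocyte",
    "normal_epithelium": "Normal epithelium",
    "other": "Other",
}
_CLASS_IMPORT = {v: k for k, v in _CLASS_EXPORT.items()}


def read_qupath_geojson(
    path,
    pixel_size: float | None = None,
    *,
    default_case_id: str | None = None,
) -> list[NucleusShape]:
    """Read nucleus boundaries from a QuPath-dialect GeoJSON export.

    Parameters
    ----------
    path
        A GeoJSON ``FeatureCollection`` of ``Polygon``/``MultiPolygon``
        detections.
    pixel_size
        μm/pixel calibration. When given, coordinates in the file are taken
        to be pixel units and are multiplied by it; when ``None`` the file
        is assumed to be in μm already and coordinates pass through
        unchanged.
    default_case_id
        Case label for features lacking a ``case_id`` property; defaults to
        the file stem.

    Only outer rings are kept (nucleus boundaries have no holes of
    interest); non-polygon geometries are skipped with a single summary
    warning. A feature that cannot be parsed at all raises ``ValueError``
    naming its index.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path.name}: not a GeoJSON FeatureCollection")
    if default_case_id is None:
        default_case_id = path.stem
    scale = 1.0 if pixel_size is None else float(pixel_size)

    shapes: list[NucleusShape] = []
    n_skipped = 0
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = feat["geometry"]
            gtype = geom["type"]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"unparseable feature at index {i}: {exc}") from exc
        if gtype == "Polygon":
            ring_sets = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            ring_sets = geom["coordinates"]
        else:
            n_skipped += 1
            continue
        props = feat.get("properties") or {}
        cell_class = _classification_name(props)
        base_id = str(props.get("nucleus_id", props.get("id", f"n{i:06d}")))
        case_id = str(props.get("case_id", default_case_id))
        for j, rings in enumerate(ring_sets):
            if not rings:
                continue
            outer = np.asarray(rings[0], dtype=float) * scale  # holes discarded
            nid = base_id if len(ring_sets) == 1 else f"{base_id}_p{j}"
            try:
                shapes.append(
                    NucleusShape.from_ring(
                        outer,
                        nucleus_id=nid,
                        case_id=case_id,
                        cell_class=cell_class,
                        source_pixel_size=pixel_size,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"unparseable feature at index {i}: {exc}") from exc
    if n_skipped:
        warnings.warn(
            f"{path.name}: skipped {n_skipped} non-polygon feature(s)",
            stacklevel=2,
        )
    return shapes


def write_qupath_geojson(shapes: list[NucleusShape], path) -> None:
    """Write shapes as a QuPath-readable GeoJSON ``FeatureCollection``.

    Output is byte-deterministic for a given shape list (sorted keys, fixed
    separators, ``repr`` floats), so identically seeded synthetic cohorts
    serialize identically.
    """
    features = []
    for s in shapes:
        ring = [[float(x), float(y)] for x, y in s.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "objectType": "detection",
                    "classification": {"name": _CLASS_EXPORT[s.cell_class]},
                    "nucleus_id": s.nucleus_id,
                    "case_id": s.case_id,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def _load_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_label_mask(mask: np.ndarray, path) -> None:
    """Write an integer label image as TIFF or PNG (by extension)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, mask)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, mask.astype(np.uint16 if mask.max() > 255 else np.uint8))


def read_label_mask(
    path,
    pixel_size: float,
    *,
    include_border: bool = False,
    default_case_id: str | None = None,
    simplify_tol_px: float = 0.05,
) -> list[NucleusShape]:
    """Extract nucleus boundary polygons from an integer label mask.

    Each positive label becomes one shape via a marching-squares contour at
    iso-level 0.5 on the label's binary image — vertices land at sub-pixel
    positions, which keeps perimeter staircase bias small — followed by
    vertex decimation at ``simplify_tol_px`` pixels. Labels touching the
    image border are incomplete nuclei and are excluded unless
    ``include_border``.
    """
    img = _load_mask(path) if not isinstance(path, np.ndarray) else path
    if img.ndim != 2:
        raise ValueError("label mask must be a 2-D image")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"label mask must have an integer dtype, got {img.dtype}")
    if default_case_id is None:
        default_case_id = Path(path).stem if not isinstance(path, np.ndarray) else "mask"

    labels = np.unique(img)
    labels = labels[labels > 0]
    border = set(np.unique(np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])))
    shapes: list[NucleusShape] = []
    n_border = 0
    for lab in labels:
        if lab in border and not include_border:
            n_border += 1
            continue
        binary = np.pad((img == lab).astype(float), 1)
        contours = skmeasure.find_contours(binary, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # (row, col) -> (x, y), undo the 1-pixel pad, calibrate
        xy = (contour[:, ::-1] - 1.0) * float(pixel_size)
        poly = sgeom.Polygon(xy).simplify(simplify_tol_px * float(pixel_size))
        if poly.is_empty or poly.area == 0:
            continue
        shapes.append(
            NucleusShape.from_ring(
                np.asarray(poly.exterior.coords[:-1]),
                nucleus_id=f"label_{int(lab)}",
                case_id=default_case_id,
                source_pixel_size=float(pixel_size),
            )
        )
    if n_border:
        warnings.warn(
            f"excluded {n_border} border-touching label(s)", stacklevel=2
        )
    return shapes


def write_measurements_csv(records, path) -> None:
    """Write morphometric records with the fixed documented header."""
    rows = [
        (
            r.nucleus_id,
            r.case_id,
            r.cell_class,
            r.area,
            r.perimeter,
            r.min_feret,
            r.max_feret,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(path, index=False)


def read_measurements_csv(path) -> list:
    """Read a measurement table; hard error naming any missing column."""
    from .morphometry import MorphometricRecord

    df = pd.read_csv(path, float_precision="round_trip")
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"measurements file is missing required column {col!r}")
    return [
        MorphometricRecord(
            nucleus_id=str(row.nucleus_id),
            case_id=str(row.case_id),
            cell_class=str(row.cell_class),
            area=float(row.area_um2),
            perimeter=float(row.perimeter_um),
            min_feret=float(row.min_feret_um),
            max_feret=float(row.max_feret_um),
        )
        for row in df.itertuples(index=False)
    ]
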