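"""Spherical ROI definitions and gray-matter volume extraction.

Each region of interest is a 5-mm-radius sphere in MNI space centered
on a published peak coordinate.  Given a subject's segmented gray-matter
probability (or modulated density) map in MNI space, the ROI volume is
the sum of GM values over the voxels whose centers fall inside the
sphere, times the voxel volume — no resampling, no thresholding: masks
are built in the map's native grid straight from its header affine.

The shipped catalogue contains the 61 unique peak coordinates collated
from earlier morphometry studies of tinnitus.  Three coordinates were
reported under two region labels (superior vs middle temporal gyrus);
they appear once each, under the first label, with the alternate label
recorded in ``also_reported_as``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .tables import META_COLUMNS, FeatureTable

__all__ = [
    "ROISpec",
    "ROICatalogue",
    "GMMap",
    "default_catalogue",
    "load_catalogue",
    "load_gm_map",
    "sphere_mask",
    "roi_volume",
    "extract_features",
    "make_synthetic_gm_map",
    "feature_id",
]


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI: name, hemisphere, MNI peak (mm) and radius (mm)."""

    region_name: str
    hemisphere: str
    peak_mni: tuple[float, float, float]
    radius: float = 5.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")


def feature_id(roi: ROISpec) -> str:
    """Stable feature-column name, e.g. ``R_hypothalamus_5_-5_-11``."""
    hemi = "R" if roi.hemisphere == "right" else "L"
    name = re.sub(r"[^A-Za-z0-9]+", "_", roi.region_name).strip("_")
    coords = "_".join(f"{c:g}" for c in roi.peak_mni)
    return f"{hemi}_{name}_{coords}"


@dataclass
class ROICatalogue:
    """Ordered collection of ROI specs with unique (name, peak) pairs."""

    rois: list[ROISpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.region_name, r.peak_mni) for r in self.rois]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (region_name, peak) in catalogue")
        for r in self.rois:
            x = r.peak_mni[0]
            if r.hemisphere == "right" and x < 0:
                raise ValueError(f"right-hemisphere ROI with x < 0: {r}")
            if r.hemisphere == "left" and x >= 0:
                raise ValueError(f"left-hemisphere ROI with x >= 0: {r}")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def feature_ids(self) -> list[str]:
        return [feature_id(r) for r in self.rois]


def load_catalogue(path) -> ROICatalogue:
    """Read an ROI catalogue CSV (region_name, hemisphere, x, y, z, radius)."""
    df = pd.read_csv(path)
    required = {"region_name", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    rois = [
        ROISpec(
            row.region_name,
            row.hemisphere,
            (float(row.x), float(row.y), float(row.z)),
            float(getattr(row, "radius_mm", 5.0)),
        )
        for row in df.itertuples()
    ]
    return ROICatalogue(rois)


def default_catalogue() -> ROICatalogue:
    """The shipped 61-region catalogue."""
    with resources.as_file(
        resources.files("tinnisel.data") / "roi_catalogue.csv"
    ) as p:
        return load_catalogue(p)


# ---------------------------------------------------------------------------
# GM maps


@dataclass
class GMMap:
    """A 3-D gray-matter map with its voxel-to-world (MNI mm) affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("GM map must be a non-empty 3-D grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("GM values must be finite and non-negative")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates over all voxel centers."""
        shape = np.array(self.values.shape)
        corners = np.array(
            [[i, j, k] for i in (0, shape[0] - 1)
             for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
            dtype=float,
        )
        world = corners @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world.min(axis=0), world.max(axis=0)


def load_gm_map(path) -> GMMap:
    """Load a NIfTI GM map; world coordinates come from the header affine."""
    img = nib.load(str(path))
    return GMMap(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)


# ---------------------------------------------------------------------------
# masks and volumes


def sphere_mask(gm_map: GMMap, roi: ROISpec) -> tuple[np.ndarray, ...]:
    """Indices of voxels whose center lies within ``radius`` of the peak.

    The inclusion rule is a closed ball (distance <= radius) on voxel
    centers in world space.  Returns an index tuple usable directly for
    fancy indexing of ``gm_map.values``.
    """
    lo, hi = gm_map.world_bounds()
    center = np.asarray(roi.peak_mni, dtype=np.float64)
    if (center < lo).any() or (center > hi).any():
        raise ValueError(
            f"ROI center {tuple(center)} outside map extent "
            f"[{lo.round(1)}, {hi.round(1)}]"
        )
    inv = np.linalg.inv(gm_map.affine)
    # bounding box: voxel-space image of the ball's world bounding cube
    offsets = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    cube = center + roi.radius * offsets
    vox = cube @ inv[:3, :3].T + inv[:3, 3]
    lo_idx = np.maximum(np.floor(vox.min(axis=0)).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil(vox.max(axis=0)).astype(int),
        np.array(gm_map.values.shape) - 1,
    )
    grids = [np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)]
    ii, jj, kk = np.meshgrid(*grids, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = idx @ gm_map.affine[:3, :3].T + gm_map.affine[:3, 3]
    inside = ((world - center) ** 2).sum(axis=1) <= roi.radius**2
    sel = idx[inside].astype(np.intp)
    return (sel[:, 0], sel[:, 1], sel[:, 2])


def roi_volume(gm_map: GMMap, roi: ROISpec) -> float:
    """GM volume of the ROI: sum of masked GM values x voxel volume."""
    mask = sphere_mask(gm_map, roi)
    return float(gm_map.values[mask].sum() * gm_map.voxel_volume)


def extract_features(
    subjects: list[tuple[dict, GMMap]], catalogue: ROICatalogue
) -> FeatureTable:
    """One feature row per subject, one ROI-volume column per catalogue entry.

    ``subjects`` pairs a metadata dict (``subject_id`` and ``group``
    required; ``age``, ``sex``, ``thi`` optional) with the subject's GM
    map.  Subject order is preserved.
    """
    if len(catalogue) == 0:
        raise ValueError("empty ROI catalogue")
    ids = catalogue.feature_ids()
    rows = []
    for meta, gm_map in subjects:
        row = {c: meta.get(c, np.nan) for c in META_COLUMNS}
        row["subject_id"] = meta["subject_id"]
        row["group"] = meta["group"]
        for fid, roi in zip(ids, catalogue):
            try:
                row[fid] = roi_volume(gm_map, roi)
            except ValueError as err:
                raise ValueError(
                    f"subject {meta['subject_id']!r}, ROI {fid}: {err}"
                ) from err
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + ids)
    return FeatureTable(df, ids, provenance="extracted")


# ---------------------------------------------------------------------------
# synthetic map fixture generator


def make_synthetic_gm_map(
    shape: tuple[int, int, int],
    voxel_size: float = 1.0,
    blobs: list[tuple[tuple[float, float, float], float, float]] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    origin: tuple[float, float, float] | None = None,
) -> GMMap:
    """Smooth synthetic GM field in [0, 1]: Gaussian blobs plus noise.

    ``blobs`` is a list of (world center, sigma mm, amplitude).  By
    default the world origin sits at the grid center so MNI-style
    coordinates near zero land inside the volume.  Deterministic in
    ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    if origin is None:
        origin = tuple(-voxel_size * (s - 1) / 2.0 for s in shape)
    affine[:3, 3] = origin
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    world = [affine[a, a] * grids[a] + affine[a, 3] for a in range(3)]
    values = np.zeros(shape)
    lo = np.array([w.min() for w in world])
    hi = np.array([w.max() for w in world])
    for center, sigma, amplitude in blobs or []:
        c = np.asarray(center, dtype=float)
        if (c < lo).any() or (c > hi).any():
            raise ValueError(f"blob center {center} outside map extent")
        d2 = sum((world[a] - c[a]) ** 2 for a in range(3))
        values += amplitude * np.exp(-d2 / (2.0 * sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values += noise_sd * rng.standard_normal(shape)
    return GMMap(np.clip(values, 0.0, 1.0), affine)
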