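"""Shape-index statistics: class partition, binned probabilities, descriptors.

Triangles are partitioned into three classes by their shape index S:

* spherical        S >= 0.99   (nearly perfect convex caps — free atomic surface)
* positive group   0 <= S < 0.99 (deformation where two atomic spheres fuse: bonds)
* negative group   S < 0       (deformation where several bonds meet, e.g. ring centres)

The signed groups are binned independently (64 uniform bins each by
default) and the per-bin probabilities p_i = k_i / k are normalized by the
total triangle count k of the mesh.  The surface descriptor collects the
three aggregates of the entropy model: the spherical area and the two
p·ln p-weighted deformation areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .surface import SurfaceMesh, mesh_area, mesh_volume

__all__ = [
    "ShapeHistogram",
    "SurfaceDescriptor",
    "classify_triangles",
    "histogram",
    "descriptor",
    "class_area_fractions",
    "descriptors_to_csv",
    "descriptors_from_csv",
]

SPHERICAL_THRESHOLD = 0.99

_LOG = {"e": np.log, "2": np.log2, "10": np.log10}


def _log_fn(log_base: str):
    try:
        return _LOG[str(log_base)]
    except KeyError:
        raise ValueError(f"log_base must be one of {sorted(_LOG)}, got {log_base!r}") from None


def _tri_values(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape index and area of the statistically valid triangles."""
    if mesh.triangle_shape_index is None:
        raise ValueError("mesh has no triangle shape index; run curvatures_on_mesh first")
    valid = mesh.triangle_valid
    if valid is None:
        valid = np.ones(mesh.n_triangles, dtype=bool)
    return mesh.triangle_shape_index[valid], mesh.triangle_area[valid]


def classify_triangles(
    mesh: SurfaceMesh, spherical_threshold: float = SPHERICAL_THRESHOLD
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint exhaustive index sets (spherical, positive, negative).

    S = 0 falls in the positive group; S = threshold in the spherical class.
    Indices refer to the valid triangles of the mesh in mesh order.
    """
    s, _ = _tri_values(mesh)
    idx = np.arange(len(s))
    spherical = idx[s >= spherical_threshold]
    positive = idx[(s >= 0) & (s < spherical_threshold)]
    negative = idx[s < 0]
    return spherical, positive, negative


@dataclass
class ShapeHistogram:
    """Sign-partitioned binned shape-index probabilities p_i = k_i / k."""

    n_bins: int
    pos_edges: np.ndarray
    neg_edges: np.ndarray
    pos_probs: np.ndarray
    neg_probs: np.ndarray
    spherical_count: int
    total_triangles: int
    spherical_threshold: float = SPHERICAL_THRESHOLD

    def probability_sum(self) -> float:
        """Sum of all probabilities plus the spherical mass; 1 by construction."""
        return float(
            self.pos_probs.sum() + self.neg_probs.sum() + self.spherical_count / self.total_triangles
        )


def histogram(
    mesh: SurfaceMesh,
    n_bins: int = 64,
    spherical_threshold: float = SPHERICAL_THRESHOLD,
) -> ShapeHistogram:
    """Uniform binning: ``n_bins`` over [0, threshold) and ``n_bins`` over [-1, 0)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    s, _ = _tri_values(mesh)
    if len(s) == 0:
        raise ValueError("mesh has no valid triangles")
    k = len(s)
    pos_edges = np.linspace(0.0, spherical_threshold, n_bins + 1)
    neg_edges = np.linspace(-1.0, 0.0, n_bins + 1)
    pos_counts, _ = np.histogram(s[(s >= 0) & (s < spherical_threshold)], bins=pos_edges)
    neg_counts, _ = np.histogram(s[s < 0], bins=neg_edges)
    spherical_count = int(np.count_nonzero(s >= spherical_threshold))
    return ShapeHistogram(
        n_bins=n_bins,
        pos_edges=pos_edges,
        neg_edges=neg_edges,
        pos_probs=pos_counts / k,
        neg_probs=neg_counts / k,
        spherical_count=spherical_count,
        total_triangles=k,
        spherical_threshold=spherical_threshold,
    )


@dataclass
class SurfaceDescriptor:
    """Per-molecule aggregates entering the area-law entropy model.

    ``sum_pos`` and ``sum_neg`` are Σ p(bin(S_t))·log p(bin(S_t))·A_t over
    the positive / negative deformation triangles (Å², always <= 0);
    ``area_spherical`` is the area with S above the spherical threshold.
    """

    area_spherical: float
    sum_pos: float
    sum_neg: float
    total_area: float
    total_volume: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if self.sum_pos > 1e-9 or self.sum_neg > 1e-9:
            raise ValueError("p·log p aggregates must be non-positive")
        if self.area_spherical > self.total_area * (1 + 1e-9):
            raise ValueError("spherical area cannot exceed total area")


def descriptor(
    mesh: SurfaceMesh,
    hist: ShapeHistogram,
    log_base: str = "e",
    mol_id: str | None = None,
    with_volume: bool = True,
) -> SurfaceDescriptor:
    """Evaluate the three model aggregates from a mesh and its histogram.

    The histogram must come from the same mesh (checked through the
    triangle count); p·log p is taken as 0 for empty bins.
    """
    log = _log_fn(log_base)
    s, areas = _tri_values(mesh)
    if hist.total_triangles != len(s):
        raise ValueError("histogram does not match mesh (triangle counts differ)")
    thr = hist.spherical_threshold
    spherical = s >= thr
    pos = (s >= 0) & (s < thr)
    neg = s < 0

    def _plogp_sum(sel: np.ndarray, edges: np.ndarray, probs: np.ndarray) -> float:
        if not np.any(sel):
            return 0.0
        bins = np.clip(np.digitize(s[sel], edges) - 1, 0, hist.n_bins - 1)
        p = probs[bins]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * log(np.where(p > 0, p, 1.0)), 0.0)
        return float((plogp * areas[sel]).sum())

    return SurfaceDescriptor(
        area_spherical=float(areas[spherical].sum()),
        sum_pos=_plogp_sum(pos, hist.pos_edges, hist.pos_probs),
        sum_neg=_plogp_sum(neg, hist.neg_edges, hist.neg_probs),
        total_area=float(areas.sum()),
        total_volume=mesh_volume(mesh) if with_volume else None,
        id=mol_id,
    )


def class_area_fractions(
    meshes: Iterable[SurfaceMesh],
    spherical_threshold: float = SPHERICAL_THRESHOLD,
    weight: str = "area",
) -> tuple[float, float, float]:
    """Pooled (positive, spherical, negative) class percentages across meshes.

    ``weight='area'`` weights by triangle area (default); ``'count'`` by
    triangle count.  Percentages sum to 100.
    """
    tot = np.zeros(3)
    n = 0
    for mesh in meshes:
        n += 1
        s, areas = _tri_values(mesh)
        w = areas if weight == "area" else np.ones_like(areas)
        tot[0] += w[(s >= 0) & (s < spherical_threshold)].sum()
        tot[1] += w[s >= spherical_threshold].sum()
        tot[2] += w[s < 0].sum()
    if n == 0:
        raise ValueError("no meshes given")
    frac = 100.0 * tot / tot.sum()
    return float(frac[0]), float(frac[1]), float(frac[2])


_CSV_COLUMNS = ["id", "area_spherical", "sum_pos", "sum_neg", "total_area", "total_volume"]


def descriptors_to_csv(descriptors: Sequence[SurfaceDescriptor], path: str | Path) -> None:
    rows = [
        {
            "id": d.id,
            "area_spherical": d.area_spherical,
            "sum_pos": d.sum_pos,
            "sum_neg": d.sum_neg,
            "total_area": d.total_area,
            "total_volume": d.total_volume,
        }
        for d in descriptors
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def descriptors_from_csv(path: str | Path) -> list[SurfaceDescriptor]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"descriptor CSV missing column(s): {sorted(missing)}")
    return [
        SurfaceDescriptor(
            area_spherical=row.area_spherical,
            sum_pos=row.sum_pos,
            sum_neg=row.sum_neg,
            total_area=row.total_area,
            total_volume=None if pd.isna(row.total_volume) else float(row.total_volume),
            id=str(row.id),
        )
        for row in df.itertuples()
    ]
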