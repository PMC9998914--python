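"""Per-seed location and size/shape measurements from a label volume.

Each labelled instance yields one record with its bounding box (half-open
[min, max) per axis, 0-based) and centroid per axis, followed by the
size/shape block:

  volume              voxel count
  bbox_volume         product of bounding-box edge lengths
  sphericity          pi^(1/3) * (6V)^(2/3) / surface_area
  surface_area        triangle area of the marching-cubes isosurface
  convex_volume       voxels inside the 3D convex hull
  equivalent_diameter (6V/pi)^(1/3), the equal-volume sphere's diameter
  extent              volume / bbox_volume
  major/minor axis    2*sqrt(5*lambda) from the voxel-coordinate
                      covariance eigenvalues (solid-ellipsoid relation)
  solidity            volume / convex_volume
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area
from skimage.morphology import convex_hull_image

from .io import ImageVolume, LabelVolume

__all__ = [
    "measure_instances",
    "export_instance_images",
    "sphericity",
    "equivalent_diameter",
    "surface_area",
]


def equivalent_diameter(volume: float) -> float:
    """Diameter of the sphere with the same volume: (6V/pi)^(1/3)."""
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def sphericity(volume: float, surface_area: float) -> float:
    """Ratio of the equal-volume sphere's surface area to the measured one:
    pi^(1/3) * (6V)^(2/3) / SA."""
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


def surface_area(mask: np.ndarray, smoothing_sigma: float = 0.5) -> float:
    """Total triangle area of the 0.5-level marching-cubes isosurface.

    The binary mask is padded (so the surface closes) and lightly Gaussian
    anti-aliased before meshing: a raw staircase isosurface overestimates
    the area of smooth bodies by ~9%, while sigma = 0.5 voxel recovers the
    analytic sphere area to ~4% without eroding genuine shape detail at
    the >=20-voxel seed scale.
    """
    padded = np.pad(np.asarray(mask, dtype=float), 2)
    if smoothing_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smoothing_sigma)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    return float(mesh_surface_area(verts, faces))


def _axis_lengths(coords: np.ndarray) -> tuple[float, float]:
    """Major/minor lengths via the solid-ellipsoid covariance relation.

    For a solid ellipsoid with semi-axis a the coordinate variance along
    that axis is a^2/5, so length = 2*sqrt(5*lambda).
    """
    cov = np.cov(coords.T, bias=True) if len(coords) > 1 else np.zeros((3, 3))
    eig = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))
    major = 2.0 * np.sqrt(5.0 * max(eig[-1], 0.0))
    minor = 2.0 * np.sqrt(5.0 * max(eig[0], 0.0))
    return float(major), float(minor)


def measure_instances(labels: LabelVolume) -> list[dict]:
    """One record per labelled instance, keyed by the report columns."""
    data = labels.data
    records: list[dict] = []
    objects = ndimage.find_objects(data)
    for lab in labels.ids():
        sl = objects[int(lab) - 1] if int(lab) - 1 < len(objects) else None
        if sl is None:
            continue
        sub = data[sl] == lab
        coords_local = np.argwhere(sub)
        offset = np.array([s.start for s in sl])
        coords = coords_local + offset
        volume = int(len(coords))
        bbox_min = coords.min(axis=0)
        bbox_max = coords.max(axis=0) + 1  # half-open
        bbox_volume = int(np.prod(bbox_max - bbox_min))
        centroid = coords.mean(axis=0)
        hull = convex_hull_image(sub)
        convex_volume = int(np.count_nonzero(hull))
        sa = surface_area(sub)
        major, minor = _axis_lengths(coords.astype(float))
        records.append(
            {
                "Seed ID Number": int(lab),
                "Z-axis minimum": int(bbox_min[0]),
                "Y-axis minimum": int(bbox_min[1]),
                "X-axis minimum": int(bbox_min[2]),
                "Z-axis maximum": int(bbox_max[0]),
                "Y-axis maximum": int(bbox_max[1]),
                "X-axis maximum": int(bbox_max[2]),
                "Z-axis centroid": float(centroid[0]),
                "Y-axis centroid": float(centroid[1]),
                "X-axis centroid": float(centroid[2]),
                "Volume": volume,
                "Bounding box volume": bbox_volume,
                "Sphericity": sphericity(volume, sa),
                "Surface area": sa,
                "Convex volume": convex_volume,
                "Equivalent diameter": equivalent_diameter(volume),
                "Extent": volume / bbox_volume,
                "Major axis length": major,
                "Minor axis length": minor,
                "Solidity": volume / convex_volume,
            }
        )
    return records


def export_instance_images(
    image: ImageVolume, labels: LabelVolume, seed_id: int
) -> dict[str, np.ndarray]:
    """Masked crop of one seed plus its orthogonal mid-slices.

    The sub-volume is the intensity image restricted to the instance's
    bounding box with background voxels zeroed; XY, YZ and XZ mid-slices
    pass through the centroid voxel (in crop coordinates).
    """
    data = labels.data
    mask = data == seed_id
    if not mask.any():
        raise KeyError(f"no instance with seed id {seed_id}")
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    box = tuple(slice(lo[i], hi[i]) for i in range(3))
    crop = np.where(mask[box], image.data[box], 0)
    cz, cy, cx = np.round(coords.mean(axis=0)).astype(int) - lo
    return {
        "volume": crop,
        "xy": crop[cz, :, :],
        "yz": crop[:, :, cx],
        "xz": crop[:, cy, :],
    }
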