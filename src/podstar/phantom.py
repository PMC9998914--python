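"""Synthetic micro-CT pod phantom.

Generates a 3D volume emulating a scanned seed pod: the pod's long axis
runs along Z, seeds sit in two rows (valves) on either side of a smooth
pseudoseptum curve in the (Z, X) plane, a thin pod wall surrounds them,
and CT-like additive Gaussian noise is applied.  Each seed is a
star-convex body by construction: its radius function is an ellipsoid
radius modulated by a smooth low-order directional series with bounded
amplitude, so radii stay positive and every boundary point is visible
from the center.

Ground truth (label volume, centroids, valve membership, sequence order)
is emitted alongside the intensities, which lets the detection,
evaluation, measurement and valve-sorting stages be exercised end to end
without any scan data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ImageVolume, LabelVolume, write_volume

__all__ = ["PhantomConfig", "PhantomTruth", "generate_pod", "generate_study"]


@dataclass
class PhantomConfig:
    """Configuration of one synthetic pod.

    Defaults target a pod that runs the full Z extent of a 256x128x128
    volume packed with rounded/ovate seeds of 20-36 voxel extent —
    the same structural regime as the real scans (505-1397 slices of
    512x512 with 1-34 seeds), scaled down so the full pipeline runs in
    seconds.  seed_axis_scale defaults to extents in ratio 32:31:29
    (Z:Y:X), reproducing the dataset-level anisotropy estimate.
    """

    shape: tuple[int, int, int] = (256, 128, 128)
    n_seeds: int = 6
    radius_range: tuple[float, float] = (10.0, 18.0)
    seed_axis_scale: tuple[float, float, float] = (1.0, 31.0 / 32.0, 29.0 / 32.0)
    perturbation: float = 0.15
    valve_offset: float = 12.0
    septum_coeffs: tuple[float, ...] = (0.0, 5.0, 6.0)
    wall_thickness: float = 2.0
    wall_clearance: float = 5.0
    intensity_background: float = 20.0
    intensity_wall: float = 90.0
    intensity_seed: float = 200.0
    noise_sd: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbation < 1.0:
            raise ValueError("perturbation amplitude must lie in [0, 1)")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius range")


@dataclass
class PhantomTruth:
    """Per-seed ground truth for one generated pod."""

    table: pd.DataFrame  # label, centroid z/y/x, valve, sequence_in_valve, base radius


def _septum_x(cfg: PhantomConfig, z: np.ndarray) -> np.ndarray:
    """Pseudoseptum X position as a polynomial in z normalized to [-1, 1]."""
    u = 2.0 * z / (cfg.shape[0] - 1) - 1.0
    x = np.full_like(np.asarray(u, dtype=float), cfg.shape[2] / 2.0)
    for p, c in enumerate(cfg.septum_coeffs):
        x = x + c * u**p
    return x


@dataclass
class _SeedSpec:
    center: np.ndarray  # (z, y, x)
    semi_axes: np.ndarray  # (az, ay, ax)
    pert_vecs: np.ndarray  # (m, 3) unit vectors
    pert_coeffs: np.ndarray  # (m,)
    amplitude: float
    valve: int

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        """Star-convex radius for unit directions (q, 3)."""
        a = self.semi_axes
        quad = (dirs / a) ** 2
        r_ell = 1.0 / np.sqrt(quad.sum(axis=1))
        if self.amplitude > 0 and len(self.pert_coeffs):
            # Smooth even low-order series in the direction components,
            # normalized so |perturbation| <= amplitude.
            proj = dirs @ self.pert_vecs.T  # (q, m)
            series = (proj**2 - 1.0 / 3.0) @ self.pert_coeffs
            norm = np.abs(self.pert_coeffs).sum() * (2.0 / 3.0)
            r_ell = r_ell * (1.0 + self.amplitude * series / norm)
        return r_ell

    @property
    def max_radius(self) -> float:
        return float(self.semi_axes.max() * (1.0 + self.amplitude))


def _place_seeds(cfg: PhantomConfig, rng: np.random.Generator) -> list[_SeedSpec]:
    """Pack seeds beak-to-pedicel along Z with non-overlap enforced.

    Seeds alternate valves (with occasional same-valve neighbors, as in
    real pods); consecutive Z positions advance just far enough that the
    pairwise center distance exceeds the sum of the two maximal radii
    plus a 2-voxel clearance, then every pair is re-checked.
    """
    nz, ny, nx = cfg.shape
    for _attempt in range(200):
        specs: list[_SeedSpec] = []
        z_cursor = None
        ok = True
        for i in range(cfg.n_seeds):
            r0 = rng.uniform(*cfg.radius_range)
            semi = r0 * np.asarray(cfg.seed_axis_scale) * rng.uniform(0.95, 1.05, size=3)
            if i == 0:
                valve = int(rng.integers(1, 3))
            elif rng.random() < 0.15:  # occasional same-valve neighbor
                valve = specs[-1].valve
            else:
                valve = 3 - specs[-1].valve
            sign = 1.0 if valve == 1 else -1.0
            y = ny / 2.0 + rng.uniform(-4, 4)
            m = 4
            spec = _SeedSpec(
                center=np.zeros(3),
                semi_axes=semi,
                pert_vecs=_random_units(rng, m),
                pert_coeffs=rng.uniform(-1.0, 1.0, size=m),
                amplitude=cfg.perturbation,
                valve=valve,
            )
            if z_cursor is None:
                z = spec.max_radius + 2.0 + rng.uniform(0, 3)
            else:
                prev = specs[-1]
                # Advance Z just enough given the cross-axis offsets.
                x_prev = prev.center[2]
                x_here = _septum_x(cfg, np.array([z_cursor]))[0] + sign * (
                    cfg.valve_offset + rng.uniform(-2, 2)
                )
                need = prev.max_radius + spec.max_radius + 2.5
                dyx2 = (y - prev.center[1]) ** 2 + (x_here - x_prev) ** 2
                dz = np.sqrt(max(need**2 - dyx2, 0.0)) + 0.5
                z = z_cursor + dz + rng.uniform(0, 2)
            x = _septum_x(cfg, np.array([z]))[0] + sign * (cfg.valve_offset + rng.uniform(-2, 2))
            spec.center = np.array([z, y, x])
            if z + spec.max_radius + 2.0 > nz - 1:
                ok = False
                break
            specs.append(spec)
            z_cursor = z
        if not ok:
            continue
        if all(
            np.linalg.norm(a.center - b.center) > a.max_radius + b.max_radius + 2.0
            for i, a in enumerate(specs)
            for b in specs[i + 1 :]
        ):
            return specs
    raise RuntimeError("could not place seeds without overlap; reduce n_seeds or radii")


def _random_units(rng: np.random.Generator, m: int) -> np.ndarray:
    v = rng.normal(size=(m, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rasterize_seed(spec: _SeedSpec, shape: tuple[int, int, int]) -> tuple[tuple, np.ndarray]:
    rmax = spec.max_radius
    lo = np.maximum(np.floor(spec.center - rmax).astype(int), 0)
    hi = np.minimum(np.ceil(spec.center + rmax).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1) - spec.center
    norms = np.linalg.norm(pts, axis=1)
    inside = norms <= 1e-9
    cand = ~inside & (norms <= rmax)
    if np.any(cand):
        dirs = pts[cand] / norms[cand, None]
        inside[cand] = norms[cand] <= spec.radius(dirs)
    box = tuple(slice(lo[i], hi[i]) for i in range(3))
    return box, inside.reshape(zz.shape)


def generate_pod(cfg: PhantomConfig) -> tuple[ImageVolume, LabelVolume, PhantomTruth]:
    """Generate one pod phantom: intensities, instance labels, truth table.

    Deterministic for a fixed cfg.rng_seed.  Seeds are labelled 1..n in
    beak-to-pedicel (ascending Z) order; valve truth is the side of the
    generating pseudoseptum curve each seed was placed on.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    specs = _place_seeds(cfg, rng)
    specs.sort(key=lambda s: s.center[0])

    nz, ny, nx = cfg.shape
    labels = np.zeros(cfg.shape, dtype=np.int32)
    for lab, spec in enumerate(specs, start=1):
        box, mask = _rasterize_seed(spec, cfg.shape)
        labels[box][mask] = lab

    image = np.full(cfg.shape, cfg.intensity_background, dtype=np.float32)

    # Pod wall: a tube following the septum curve, wide enough to clear
    # every seed.
    sept = _septum_x(cfg, np.arange(nz, dtype=float))
    max_r = max(s.max_radius for s in specs)
    tube_r = cfg.valve_offset + max_r + cfg.wall_clearance
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij")
    for z in range(nz):
        d = np.sqrt((yy - ny / 2.0) ** 2 + (xx - sept[z]) ** 2)
        ring = (d >= tube_r) & (d < tube_r + cfg.wall_thickness)
        image[z][ring] = cfg.intensity_wall
    image[labels > 0] = cfg.intensity_seed
    image += rng.normal(0.0, cfg.noise_sd, size=cfg.shape).astype(np.float32)

    rows = []
    seq: dict[int, int] = {1: 0, 2: 0}
    for lab, spec in enumerate(specs, start=1):
        coords = np.argwhere(labels == lab)
        centroid = coords.mean(axis=0)
        seq[spec.valve] += 1
        rows.append(
            {
                "label": lab,
                "centroid_z": centroid[0],
                "centroid_y": centroid[1],
                "centroid_x": centroid[2],
                "valve": spec.valve,
                "sequence_in_valve": seq[spec.valve],
                "base_radius": float(spec.semi_axes.max()),
            }
        )
    truth = PhantomTruth(pd.DataFrame(rows))
    return ImageVolume(image), LabelVolume(labels), truth


def generate_study(
    n_pods: int,
    out_dir: str | Path,
    n_seeds_range: tuple[int, int] = (1, 34),
    master_seed: int = 0,
    base_config: PhantomConfig | None = None,
) -> pd.DataFrame:
    """Generate a cohort of pods with per-pod derived RNG seeds.

    Per-pod seed counts are drawn uniformly from n_seeds_range (capped by
    what fits in the volume); volumes, labels and truth tables are written
    under out_dir and a manifest DataFrame (also written as CSV) lists pod
    id, seed count and file paths.
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    lo, hi = n_seeds_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid n_seeds range")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_config or PhantomConfig()
    # Taller stacks hold more seeds, as in real scans; grow Z with the
    # drawn seed count so packing always succeeds.
    rmax = base.radius_range[1] * max(base.seed_axis_scale) * (1 + base.perturbation)
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_pods + 1)]
    rng = np.random.default_rng(child_seeds[-1])
    records = []
    for p in range(n_pods):
        n_seeds = int(rng.integers(lo, hi + 1))
        z_needed = int(n_seeds * (2 * rmax + 4) + 2 * (rmax + 6))
        shape = (max(base.shape[0], z_needed), base.shape[1], base.shape[2])
        cfg = replace(base, n_seeds=n_seeds, shape=shape, rng_seed=child_seeds[p])
        image, labels, truth = generate_pod(cfg)
        pod_id = f"pod{p:03d}"
        img_path = out / f"{pod_id}_image.tif"
        lab_path = out / f"{pod_id}_labels.tif"
        truth_path = out / f"{pod_id}_truth.csv"
        write_volume(image, img_path)
        write_volume(labels, lab_path)
        truth.table.to_csv(truth_path, index=False)
        records.append(
            {
                "pod_id": pod_id,
                "n_seeds": n_seeds,
                "image": str(img_path),
                "labels": str(lab_path),
                "truth": str(truth_path),
            }
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
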