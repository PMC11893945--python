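"""Vial and cell geometry: an 8 mL water-equivalent blood volume containing
1000 randomly placed lymphocyte spheres (radius 3.75 µm) with concentric
nuclei (radius 3.1 µm), plus the geometric primitives the transport and
damage stages need (uniform cold-source sampling, ray–sphere chords, the
DNA sensitive-volume fraction).

Coordinates are right-handed Cartesian with the origin at the vial centre;
lengths are in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class VialGeometry:
    """Blood vial of a given volume (default 8 mL ≡ 8 cm³ ≡ 8e12 µm³).

    ``sphere`` (default): radius (3V/4π)^{1/3} ≈ 1.2407 cm. ``cylinder``:
    equilateral cylinder (height = diameter), radius (V/2π)^{1/3}.
    """

    volume_ml: float = 8.0
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("vial volume must be positive")
        if self.shape not in ("sphere", "cylinder"):
            raise ValueError(f"unknown vial shape {self.shape!r}")

    @property
    def volume_um3(self) -> float:
        return self.volume_ml * 1e12

    @property
    def radius_um(self) -> float:
        if self.shape == "sphere":
            return (3.0 * self.volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        return (self.volume_um3 / (2.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def half_height_um(self) -> float:
        """Cylinder half-height (equals radius for the equilateral cylinder)."""
        if self.shape != "cylinder":
            raise AttributeError("half_height_um is defined for cylinders only")
        return self.radius_um

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points at least ``margin`` inside the wall."""
        p = np.atleast_2d(points)
        if self.shape == "sphere":
            return np.linalg.norm(p, axis=1) <= self.radius_um - margin
        rho = np.hypot(p[:, 0], p[:, 1])
        return (rho <= self.radius_um - margin) & (
            np.abs(p[:, 2]) <= self.half_height_um - margin
        )

    def sample_uniform(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Uniform points in the vial, shape (size, 3)."""
        if self.shape == "sphere":
            r = self.radius_um * rng.random(size) ** (1.0 / 3.0)
            u = rng.uniform(-1.0, 1.0, size)
            phi = rng.uniform(0, 2 * np.pi, size)
            s = np.sqrt(1 - u * u)
            return np.column_stack([r * s * np.cos(phi), r * s * np.sin(phi), r * u])
        rho = self.radius_um * np.sqrt(rng.random(size))
        phi = rng.uniform(0, 2 * np.pi, size)
        z = rng.uniform(-self.half_height_um, self.half_height_um, size)
        return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    def distance_to_wall(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distance along each ray from an interior origin to the vial wall."""
        o = np.atleast_2d(origins)
        d = np.atleast_2d(directions)
        if self.shape == "sphere":
            b = np.einsum("ij,ij->i", o, d)
            c = np.einsum("ij,ij->i", o, o) - self.radius_um**2
            disc = np.maximum(b * b - c, 0.0)
            return -b + np.sqrt(disc)
        # cylinder: min of side-wall and cap intersections
        ox, oy, oz = o[:, 0], o[:, 1], o[:, 2]
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        a = dx * dx + dy * dy
        b = ox * dx + oy * dy
        c = ox * ox + oy * oy - self.radius_um**2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_side = np.where(
                a > 0, (-b + np.sqrt(np.maximum(b * b - a * c, 0.0))) / a, np.inf
            )
            t_cap = np.where(
                dz != 0,
                (np.sign(dz) * self.half_height_um - oz) / dz,
                np.inf,
            )
        return np.minimum(t_side, t_cap)


@dataclass
class CellPopulation:
    """Non-overlapping lymphocyte spheres with concentric nuclei."""

    centers: np.ndarray
    cell_radius: float = 3.75
    nucleus_radius: float = 3.1

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus radius must be smaller than cell radius")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def cell_volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.cell_radius**3

    @property
    def nucleus_volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.nucleus_radius**3

    def tree(self) -> cKDTree:
        return cKDTree(self.centers)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            self.centers,
            delimiter=",",
            header="x_um,y_um,z_um",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, cell_radius: float = 3.75, nucleus_radius: float = 3.1):
        centers = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(centers, cell_radius, nucleus_radius)


def place_cells(
    vial: VialGeometry,
    n: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    cell_radius: float = 3.75,
    nucleus_radius: float = 3.1,
) -> CellPopulation:
    """Place ``n`` non-overlapping cell spheres uniformly in the vial.

    Centres are i.i.d. uniform over the region where the whole cell fits;
    overlapping draws are rejected and resampled. Deterministic for a given
    seed. Raises if the packing fraction exceeds 0.1 (rejection would stall).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cell_volume = 4.0 / 3.0 * math.pi * cell_radius**3
    if n * cell_volume / vial.volume_um3 > 0.1:
        raise ValueError("packing fraction above 0.1; placement would stall")
    accepted = np.empty((0, 3))
    while len(accepted) < n:
        batch = vial.sample_uniform(rng, 2 * (n - len(accepted)) + 16)
        batch = batch[vial.contains(batch, margin=cell_radius)]
        for p in batch:
            if len(accepted) and np.min(
                np.linalg.norm(accepted - p, axis=1)
            ) < 2 * cell_radius:
                continue
            accepted = np.vstack([accepted, p])
            if len(accepted) == n:
                break
    return CellPopulation(accepted, cell_radius, nucleus_radius)


def sample_decay_position(
    vial: VialGeometry,
    cells: CellPopulation | None,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Uniform decay positions over the vial volume minus the cell spheres
    (cold-source condition: cells carry no activity), by rejection."""
    out = np.empty((0, 3))
    tree = cells.tree() if cells is not None and cells.n_cells else None
    while len(out) < size:
        batch = vial.sample_uniform(rng, size - len(out))
        if tree is not None:
            d, _ = tree.query(batch, k=1)
            batch = batch[d > cells.cell_radius]
        out = np.vstack([out, batch])
    return out


def ray_sphere_chord(origin, direction, center, radius):
    """Intersection of the ray origin + t·direction (t ≥ 0) with a sphere.

    Returns ``None`` when the ray misses or the sphere lies behind the
    origin; otherwise ``(entry_point, exit_point, chord_length)``. An origin
    inside the sphere yields entry at the origin itself.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    c = np.asarray(center, dtype=float)
    oc = c - o
    b = float(np.dot(oc, d))
    disc = b * b - (float(np.dot(oc, oc)) - radius * radius)
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    t1, t2 = b - sq, b + sq
    if t2 <= 0:
        return None  # sphere behind the origin
    t1 = max(t1, 0.0)
    entry = o + t1 * d
    exit_ = o + t2 * d
    return entry, exit_, t2 - t1


@dataclass
class SensitiveVolumeModel:
    """Homogeneous DNA sensitive-volume model of the nucleus.

    The genome is pictured as one cylinder of radius 1.1 nm and length
    (bp rise 0.34 nm) × (genome size 6.4e9 bp) ≈ 2.2 m; the ratio of that
    cylinder's volume (≈8.3 µm³) to the nucleus volume (≈124.8 µm³) gives the
    fraction of the nucleus occupied by DNA, ≈0.07, used to thin energy
    depositions into strand-break candidates.
    """

    dna_cylinder_radius_m: float = 1.1e-9
    bp_rise_m: float = 0.34e-9
    genome_size_bp: float = 6.4e9
    nucleus_radius_m: float = 3.1e-6

    @property
    def dna_length_m(self) -> float:
        return self.bp_rise_m * self.genome_size_bp

    @property
    def dna_volume_um3(self) -> float:
        return math.pi * self.dna_cylinder_radius_m**2 * self.dna_length_m * 1e18

    @property
    def nucleus_volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.nucleus_radius_m**3 * 1e18


def sensitive_fraction(model: SensitiveVolumeModel | None = None) -> float:
    """DNA volume / nucleus volume (≈0.0665 for the defaults; the damage model
    uses the conventional rounded value 0.07)."""
    m = model or SensitiveVolumeModel()
    if m.dna_cylinder_radius_m < 0 or m.genome_size_bp < 0:
        raise ValueError("model fields must be nonnegative")
    f = m.dna_volume_um3 / m.nucleus_volume_um3
    if not 0 <= f < 1:
        raise ValueError("sensitive fraction outside [0, 1)")
    return f
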