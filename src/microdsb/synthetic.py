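"""Synthetic inputs: fixture nuclide tables, planted SSB patterns with known
cluster counts, and phase-spaces with known chord statistics, so every stage
of the pipeline is testable offline with independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .macro import PS_COLUMNS

#: printed anchor values that the paper-anchored fixture table must carry
#: verbatim: nuclide → (particle code, energy string, intensity string)
PAPER_ANCHORS = {
    "Bi-212": ("A", "6.207", "0.3593"),
    "Po-212": ("A", "8.954", "1.0"),
    "Th-232": ("A", "4.081", "1.0"),
    "Cf-252": ("A", "6.219", "0.9691"),
    "Th-227": ("A", "5.9", "1.0"),
    "Th-228": ("A", "5.4", "1.0"),
}


def anchored_table_path() -> Path:
    return Path(str(resources.files("microdsb.data").joinpath("nuclides_anchored.tsv")))


def extended_table_path() -> Path:
    return Path(str(resources.files("microdsb.data").joinpath("nuclides_extended.tsv")))


def make_fixture_tables(out_dir) -> dict[str, Path]:
    """Write the paper-anchored and extended nuclide TSV tables into
    ``out_dir``; returns {'anchored': path, 'extended': path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, src in (
        ("anchored", anchored_table_path()),
        ("extended", extended_table_path()),
    ):
        dst = out / src.name
        dst.write_text(src.read_text(encoding="utf-8"), encoding="utf-8")
        written[name] = dst
    return written


@dataclass
class PlantedPatternSpec:
    """k well-separated opposite-strand SSB pairs plus isolated singletons.

    By construction the expected DSB count equals k (for clustering radius
    between the intra-pair and inter-cluster spacings)."""

    k: int = 3
    intra_pair_nm: float = 1.0
    inter_cluster_nm: float = 50.0
    singletons: int = 0
    same_strand: bool = False

    def validate(self, eps_nm: float = 3.4) -> None:
        if self.intra_pair_nm >= eps_nm:
            raise ValueError("intra-pair spacing must be below the cluster radius")
        if self.inter_cluster_nm <= eps_nm:
            raise ValueError("inter-cluster spacing must exceed the cluster radius")


def make_planted_ssb_pattern(
    spec: PlantedPatternSpec, rng: np.random.Generator, eps_nm: float = 3.4
) -> tuple[np.ndarray, np.ndarray, int]:
    """Returns (positions_nm (n,3), strands, expected DSB count).

    Pair clusters are laid along +x at multiples of the inter-cluster spacing
    with a small random transverse jitter (≪ eps); singletons continue on the
    same lattice beyond the pairs."""
    spec.validate(eps_nm)
    positions = []
    strands = []
    for i in range(spec.k):
        base = np.array([i * spec.inter_cluster_nm, 0.0, 0.0])
        jitter = rng.normal(scale=0.05, size=3)
        half = np.array([spec.intra_pair_nm / 2.0, 0.0, 0.0])
        positions.extend([base + jitter - half, base + jitter + half])
        strands.extend([0, 0] if spec.same_strand else [0, 1])
    for j in range(spec.singletons):
        base = np.array([(spec.k + j) * spec.inter_cluster_nm, 0.0, 0.0])
        positions.append(base + rng.normal(scale=0.05, size=3))
        strands.append(int(rng.integers(0, 2)))
    pos = np.array(positions) if positions else np.empty((0, 3))
    expected = 0 if spec.same_strand else spec.k
    return pos, np.array(strands, dtype=int), expected


@dataclass
class SyntheticPhaseSpaceSpec:
    particle: str = "alpha"
    energy_mev: float = 6.0
    count: int = 1000
    seed: int = 0


def make_isotropic_flux_phase_space(
    spec: SyntheticPhaseSpaceSpec,
    sphere_radius_um: float = 3.1,
    center_um: np.ndarray | None = None,
    cell_index: int = 0,
) -> pd.DataFrame:
    """Phase-space records emulating an isotropic external flux on a sphere:
    entry points uniform on the surface, directions cosine-law about the
    inward normal. Downstream chord lengths then follow the isotropic-flux
    chord law with mean 4r/3."""
    if spec.count <= 0:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(spec.seed)
    c = np.zeros(3) if center_um is None else np.asarray(center_um, dtype=float)
    # uniform points on the sphere
    n = rng.normal(size=(spec.count, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    entry = c + sphere_radius_um * n
    inward = -n
    # cosine-law direction about the inward normal: cosθ = sqrt(u)
    u = rng.random(spec.count)
    cos_t = np.sqrt(u)
    sin_t = np.sqrt(1.0 - u)
    phi = rng.uniform(0, 2 * np.pi, spec.count)
    # orthonormal frame (t1, t2) ⊥ inward
    a = np.where(np.abs(inward[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    t1 = np.cross(inward, a)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(inward, t1)
    d = (
        cos_t[:, None] * inward
        + (sin_t * np.cos(phi))[:, None] * t1
        + (sin_t * np.sin(phi))[:, None] * t2
    )
    df = pd.DataFrame(
        {
            "particle": spec.particle,
            "E_MeV": spec.energy_mev,
            "x_um": entry[:, 0],
            "y_um": entry[:, 1],
            "z_um": entry[:, 2],
            "dx": d[:, 0],
            "dy": d[:, 1],
            "dz": d[:, 2],
            "origin_volume": "blood",
            "process": "synthetic",
            "cell_index": cell_index,
            "weight": 1.0,
        }
    )
    return df[PS_COLUMNS]
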