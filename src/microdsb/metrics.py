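"""Dose-normalized damage metrics and cellular S-values.

S-values are absorbed dose rate in a target per unit activity in the source
region, in Gy·h⁻¹·MBq⁻¹: S = E[J per decay] / m[kg] × 3.6e9 decays/(MBq·h).
S_Blood←Blood is the blood self-dose (8 g of water-equivalent blood);
S_Lymph←Blood is the nucleus dose from activity in the surrounding blood
(cold-source cells), counting only alpha depositions for alpha chains.

Damage metrics are normalized per cell and per mGy of whole-blood absorbed
dose, mirroring how ex vivo irradiation experiments report γ-H2AX foci:
DSBs·cell⁻¹·mGy⁻¹, α-tracks·cell⁻¹·mGy⁻¹ (raw and after the experimental
selection threshold of track length > 0.75 µm with ≥ 7 DSBs), and the DSB
linear density DSBs/µm along alpha tracks, computed as a ratio of totals
(ΣDSB/Σlength), which is robust to very short tracks.

Uncertainties are the sample SD over independent seeds, reported with a
coverage factor k (default 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .constants import DECAYS_PER_MBQ_H, MEV_TO_J
from .macro import BloodDoseTally
from .micro import TrackDamageSummary


@dataclass
class DamageMetrics:
    dsb_per_cell_per_mgy: float | None
    tracks_per_cell_per_mgy_raw: float | None
    tracks_per_cell_per_mgy_thresholded: float | None
    dsb_per_um: float | None
    mean_path_um: float | None = None


@dataclass
class SValueResult:
    s_blood: float  # Gy·h⁻¹·MBq⁻¹
    s_lymph: float  # Gy·h⁻¹·MBq⁻¹
    alpha_only: bool = True


def s_value(mean_energy_mev_per_decay: float, target_mass_kg: float) -> float:
    """Gy·h⁻¹·MBq⁻¹ from mean energy deposited in the target per decay."""
    if target_mass_kg <= 0:
        raise ValueError("target mass must be positive")
    if mean_energy_mev_per_decay < 0:
        raise ValueError("energy per decay must be nonnegative")
    return mean_energy_mev_per_decay * MEV_TO_J / target_mass_kg * DECAYS_PER_MBQ_H


def blood_dose_per_decay(tally: BloodDoseTally, blood_mass_kg: float) -> float:
    """Gy per parent transformation; the mGy normalizer of all damage metrics."""
    if blood_mass_kg <= 0:
        raise ValueError("blood mass must be positive")
    return tally.mean_mev * MEV_TO_J / blood_mass_kg


def damage_metrics(
    summaries: list[TrackDamageSummary],
    n_cells: int,
    total_dose_mgy: float,
    particle_class: str = "alpha",
) -> DamageMetrics:
    """Normalize track damage summaries by cell count and whole-blood dose.

    ``total_dose_mgy`` is the blood dose corresponding to the same number of
    simulated transformations the summaries came from. Track weights are the
    phase-space statistical weights. Alpha track metrics are reported as
    absent (None) rather than zero when no alpha track reached a nucleus.
    """
    if total_dose_mgy <= 0:
        raise ValueError("total blood dose must be positive")
    sel = [s for s in summaries if s.particle == particle_class]
    w = np.array([s.weight for s in sel])
    if not len(sel):
        return DamageMetrics(None, None, None, None, None)
    ndsb = np.array([s.n_dsb for s in sel])
    lengths = np.array([s.path_um for s in sel])
    passes = np.array([s.passes_threshold for s in sel])
    denom = n_cells * total_dose_mgy
    total_dsb = float(np.sum(w * ndsb))
    total_tracks = float(np.sum(w))
    total_len = float(np.sum(w * lengths))
    return DamageMetrics(
        dsb_per_cell_per_mgy=total_dsb / denom,
        tracks_per_cell_per_mgy_raw=total_tracks / denom,
        tracks_per_cell_per_mgy_thresholded=float(np.sum(w * passes)) / denom,
        dsb_per_um=(total_dsb / total_len) if total_len > 0 else None,
        mean_path_um=(total_len / total_tracks) if total_tracks > 0 else None,
    )


@dataclass
class AggregatedValue:
    mean: float
    sd: float
    k: float = 2.0

    @property
    def half_width(self) -> float:
        return self.k * self.sd


def aggregate_seeds(runs: list, k: float = 2.0) -> dict[str, AggregatedValue]:
    """Mean and sample SD per numeric field over per-seed metric sets
    (dataclasses or dicts); reported intervals are mean ± k·SD.

    Requires at least 2 runs. Fields that are None in any run are skipped.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 seed runs to estimate an SD")

    def as_dict(r):
        if isinstance(r, dict):
            return r
        return {f.name: getattr(r, f.name) for f in fields(r)}

    dicts = [as_dict(r) for r in runs]
    out: dict[str, AggregatedValue] = {}
    for key in dicts[0]:
        vals = [d.get(key) for d in dicts]
        if any(v is None or isinstance(v, (bool, str)) for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        out[key] = AggregatedValue(
            mean=float(arr.mean()), sd=float(arr.std(ddof=1)), k=k
        )
    return out


def nucleus_mass_kg(nucleus_volume_um3: float = 124.8) -> float:
    """Mass of the nucleus at unit density (124.8 µm³ → 1.248e-13 kg)."""
    return nucleus_volume_um3 * 1e-15  # µm³ of water → kg


def check_uncertainty(
    values_over_seeds: list[float], target: float = 0.05
) -> tuple[float, bool]:
    """Relative uncertainty of the seed-mean (SEM/mean) vs the 5% stopping
    criterion; returns (relative uncertainty, met?)."""
    arr = np.asarray(values_over_seeds, dtype=float)
    if arr.mean() == 0:
        return math.inf, False
    rel = arr.std(ddof=1) / math.sqrt(len(arr)) / abs(arr.mean())
    return float(rel), rel < target
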