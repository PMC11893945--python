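"""Condensed physics stand-ins: stopping-power tables, CSDA ranges, beta
spectra and photon attenuation in water.

Charged-particle transport throughout the package uses the continuous
slowing-down approximation (CSDA): a particle of energy E travels a straight
path of length R(E) = ∫ dE'/S(E') and its residual energy after a path s is
E(R(E) − s). The stopping-power and attenuation tables are shipped TSV
fixtures (see the provenance headers in ``microdsb/data``); they are inputs to
the model, not outputs of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: transport cutoff: below this kinetic energy the particle is stopped and
#: its energy deposited locally (1 keV)
E_CUTOFF_MEV = 1e-3

_N_FINE = 4000  # fine grid size for the cumulative range integral


class EnergyOutOfRangeError(ValueError):
    """Requested energy lies outside the tabulated grid."""


@dataclass
class StoppingPowerTable:
    """Tabulated stopping power S(E) in water with precomputed CSDA ranges.

    ``energy_mev`` must be strictly increasing and ``stopping_mev_um``
    strictly positive. Interpolation is log-log linear; the range integral
    R(E) = ∫_cutoff^E dE'/S(E') is evaluated by trapezoidal quadrature on a
    dense logarithmic grid.
    """

    particle: str
    energy_mev: np.ndarray
    stopping_mev_um: np.ndarray
    provenance: str = ""
    _loge: np.ndarray = field(init=False, repr=False)
    _logs: np.ndarray = field(init=False, repr=False)
    _fine_e: np.ndarray = field(init=False, repr=False)
    _fine_r: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_mev, dtype=float)
        s = np.asarray(self.stopping_mev_um, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("stopping power must be strictly positive")
        self.energy_mev = e
        self.stopping_mev_um = s
        self._loge = np.log(e)
        self._logs = np.log(s)
        lo = max(e[0], E_CUTOFF_MEV)
        fine = np.geomspace(lo, e[-1], _N_FINE)
        inv_s = 1.0 / np.exp(np.interp(np.log(fine), self._loge, self._logs))
        r = np.concatenate(
            [[0.0], np.cumsum(0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(fine))]
        )
        self._fine_e = fine
        self._fine_r = r

    @property
    def e_min(self) -> float:
        return float(self._fine_e[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_mev[-1])

    def stopping(self, energy_mev):
        """S(E) in MeV/µm (log-log interpolation); clipped at the grid ends."""
        e = np.clip(np.asarray(energy_mev, dtype=float), self.energy_mev[0], self.e_max)
        return np.exp(np.interp(np.log(e), self._loge, self._logs))

    def range_um(self, energy_mev):
        """CSDA range R(E) in µm from the 1 keV cutoff up to E."""
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e > self.e_max * (1 + 1e-12)):
            raise EnergyOutOfRangeError(
                f"energy above tabulated maximum {self.e_max} MeV"
            )
        return np.interp(e, self._fine_e, self._fine_r)

    def energy_from_range(self, residual_range_um):
        """Inverse of :meth:`range_um`: energy whose CSDA range equals the
        residual range (≤ cutoff energy maps to 0)."""
        r = np.asarray(residual_range_um, dtype=float)
        e = np.interp(r, self._fine_r, self._fine_e)
        return np.where(r <= 0, 0.0, e)


@dataclass
class AttenuationTable:
    """Photon total mass attenuation µ/ρ in water, giving the linear
    attenuation coefficient µ per µm at unit density."""

    energy_mev: np.ndarray
    mu_per_um: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_mev, dtype=float)
        mu = np.asarray(self.mu_per_um, dtype=float)
        if np.any(np.diff(e) <= 0) or np.any(mu <= 0):
            raise ValueError("attenuation grid must be increasing and positive")
        self.energy_mev = e
        self.mu_per_um = mu

    def mu(self, energy_mev):
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e < self.energy_mev[0]) or np.any(e > self.energy_mev[-1]):
            raise EnergyOutOfRangeError("photon energy outside attenuation grid")
        return np.exp(
            np.interp(np.log(e), np.log(self.energy_mev), np.log(self.mu_per_um))
        )


def _read_two_column_tsv(name: str) -> tuple[np.ndarray, np.ndarray, str]:
    ref = resources.files("microdsb.data").joinpath(name)
    header: list[str] = []
    e, v = [], []
    for line in ref.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            header.append(line.lstrip("# "))
            continue
        if not line.strip():
            continue
        a, b = line.split("\t")
        e.append(float(a))
        v.append(float(b))
    return np.array(e), np.array(v), "\n".join(header)


def load_alpha_stopping_power() -> StoppingPowerTable:
    e, s, prov = _read_two_column_tsv("alpha_stopping_water.tsv")
    return StoppingPowerTable("alpha", e, s, prov)


def load_electron_stopping_power() -> StoppingPowerTable:
    e, s, prov = _read_two_column_tsv("electron_stopping_water.tsv")
    return StoppingPowerTable("electron", e, s, prov)


def load_photon_attenuation() -> AttenuationTable:
    e, mu_rho, prov = _read_two_column_tsv("photon_attenuation_water.tsv")
    # µ/ρ in cm²/g × ρ = 1 g/cm³ → per cm → per µm
    return AttenuationTable(e, mu_rho * 1e-4, prov)


def load_stopping_power(particle: str) -> StoppingPowerTable:
    if particle == "alpha":
        return load_alpha_stopping_power()
    if particle == "electron":
        return load_electron_stopping_power()
    raise ValueError(f"no stopping-power table for particle {particle!r}")


def alpha_range(energy_mev: float, table: StoppingPowerTable) -> float:
    """CSDA range of an alpha particle (µm); errors outside the table grid."""
    if energy_mev < E_CUTOFF_MEV:
        return 0.0
    if energy_mev > table.e_max:
        raise EnergyOutOfRangeError(
            f"{energy_mev} MeV above table maximum {table.e_max} MeV"
        )
    return float(table.range_um(energy_mev))


def beta_shape_exponent(mean_mev: float, endpoint_mev: float) -> float:
    """Exponent α of the analytic beta spectrum E^α (E_max − E)² chosen so the
    spectrum mean equals the tabulated mean energy.

    The shape is a scaled Beta(α+1, 3) law with mean E_max(α+1)/(α+4).
    """
    rho = mean_mev / endpoint_mev
    if not 0 < rho < 1:
        raise ValueError("beta mean must lie strictly inside (0, endpoint)")
    alpha = (4.0 * rho - 1.0) / (1.0 - rho)
    if alpha <= -1.0:
        raise ValueError("beta spectrum mean too low for the E^a(Emax-E)^2 shape")
    return alpha


def sample_beta_energy(
    mean_mev: float, endpoint_mev: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Sample beta kinetic energies (MeV) from the normalized
    E^α (E_max − E)² spectrum parameterized to reproduce ``mean_mev``."""
    alpha = beta_shape_exponent(mean_mev, endpoint_mev)
    return endpoint_mev * rng.beta(alpha + 1.0, 3.0, size=size)


def isotropic_directions(rng: np.random.Generator, size: int) -> np.ndarray:
    """Unit vectors uniform on the sphere, shape (size, 3)."""
    u = rng.uniform(-1.0, 1.0, size)
    phi = rng.uniform(0.0, 2.0 * np.pi, size)
    s = np.sqrt(1.0 - u * u)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
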