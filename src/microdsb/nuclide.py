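"""Radionuclide emission inventories and decay-chain truncation.

A *nuclear transformation* is one decay of the parent. In ex vivo blood
irradiation the retained short-lived daughters decay essentially promptly on
the experimental time scale, so a single simulated transformation emits the
inventory of the whole retained chain. Chains are truncated at daughters whose
half-life exceeds a cutoff (default 15 days: such daughters do not build up
during an experiment) and at an explicit list of conventional cut points
(Rn-222→Pb-210, Ra-226→Po-210, Th-232→Ra-228, Np-237→Pa-233, Pu-238→U-234,
Pu-239→U-235, Am-241→Np-237, Cm-244→Pu-240, Cf-252→Cm-248, Ra-228→Th-228,
Ac-225/Bi-213→Bi-209, At-211 excludes Bi-207).

Emission tables are read from a small TSV dialect, one row per emission line::

    nuclide_id  half_life_s  particle{A|B|G|CE}  energy_MeV  endpoint_MeV_or_dash  intensity
    nuclide_id  half_life_s  NONE  -  -  -          (declaration, no emission)
    nuclide_id  BRANCH  daughter_id  fraction       (decay-graph edge)

``half_life_s`` may be the word ``stable`` (treated as infinite). Comment
lines start with ``#``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .constants import DEFAULT_CHAIN_CUTOFF_S

ALPHA = "alpha"
BETA_MINUS = "beta_minus"
GAMMA = "gamma"
CONVERSION_ELECTRON = "conversion_electron"

_PARTICLE_CODES = {
    "A": ALPHA,
    "B": BETA_MINUS,
    "G": GAMMA,
    "CE": CONVERSION_ELECTRON,
}

#: conventional truncation points (daughters at which traversal stops);
#: each is consistent with the 15-day half-life rule
DEFAULT_EXPLICIT_CUTS = frozenset(
    {
        "Pb-210",
        "Po-210",
        "Ra-228",
        "Pa-233",
        "U-234",
        "U-235",
        "Np-237",
        "Pu-240",
        "Cm-248",
        "Th-228",
        "Bi-209",
        "Bi-207",
    }
)


class NuclideTableError(ValueError):
    """Malformed nuclide table or inconsistent decay graph."""


@dataclass(frozen=True)
class EmissionLine:
    """One emission line: particle kind, energy (MeV) and emissions/decay.

    ``energy`` is the mean energy for beta spectra and the line energy
    otherwise; ``endpoint_energy`` (MeV) is carried for betas so a spectrum
    shape can be attached downstream.
    """

    particle: str
    energy: float
    intensity: float
    endpoint_energy: float | None = None

    def __post_init__(self) -> None:
        if self.particle not in _PARTICLE_CODES.values():
            raise NuclideTableError(f"unknown particle kind {self.particle!r}")
        if not self.energy > 0:
            raise NuclideTableError(f"emission energy must be > 0, got {self.energy}")
        if not 0 < self.intensity <= 1:
            raise NuclideTableError(
                f"line intensity must be in (0, 1], got {self.intensity}"
            )
        if self.endpoint_energy is not None and self.endpoint_energy < self.energy:
            raise NuclideTableError("beta endpoint energy below mean energy")


@dataclass
class Nuclide:
    id: str
    half_life: float  # seconds; math.inf for stable
    lines: list[EmissionLine] = field(default_factory=list)
    branches: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise NuclideTableError(f"{self.id}: half-life must be > 0")
        if self.branches:
            total = sum(f for _, f in self.branches)
            if abs(total - 1.0) > 1e-6:
                raise NuclideTableError(
                    f"{self.id}: branching fractions sum to {total}, expected 1"
                )


@dataclass
class DecayChainSpec:
    """Per-transformation emission inventory of a parent plus retained chain.

    ``members`` maps nuclide id → occurrence factor (expected decays of that
    member per parent transformation, the product of branching fractions along
    the unique path from the parent). ``inventory`` is the flat list of
    (line, effective intensity) pairs, effective intensity = line intensity ×
    occurrence factor.
    """

    parent: str
    members: dict[str, float]
    truncated_at: set[str]
    inventory: list[tuple[EmissionLine, float]]


def _parse_half_life(token: str, lineno: int) -> float:
    if token.lower() == "stable":
        return math.inf
    try:
        value = float(token)
    except ValueError as exc:
        raise NuclideTableError(f"line {lineno}: bad half-life {token!r}") from exc
    if not value > 0:
        raise NuclideTableError(f"line {lineno}: half-life must be > 0")
    return value


def load_nuclide_table(path: str | Path) -> list[Nuclide]:
    """Parse a nuclide TSV table (dialect in the module docstring).

    Raises :class:`NuclideTableError` naming the offending line number for
    malformed rows, unknown particle codes, invalid energies/intensities, or
    the same nuclide id declared with conflicting half-lives.
    """
    nuclides: dict[str, Nuclide] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 2 and fields[1] == "BRANCH":
                if len(fields) != 4:
                    raise NuclideTableError(f"line {lineno}: malformed BRANCH row")
                nid, _, daughter, frac_s = fields
                try:
                    frac = float(frac_s)
                except ValueError as exc:
                    raise NuclideTableError(
                        f"line {lineno}: bad branching fraction {frac_s!r}"
                    ) from exc
                if nid not in nuclides:
                    raise NuclideTableError(
                        f"line {lineno}: BRANCH for undeclared nuclide {nid!r}"
                    )
                nuclides[nid].branches.append((daughter, frac))
                continue
            if len(fields) != 6:
                raise NuclideTableError(
                    f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            nid, hl_s, code, energy_s, endpoint_s, intensity_s = fields
            half_life = _parse_half_life(hl_s, lineno)
            if nid in nuclides:
                if nuclides[nid].half_life != half_life:
                    raise NuclideTableError(
                        f"line {lineno}: duplicate nuclide id {nid!r} with "
                        f"conflicting half-life"
                    )
                nuc = nuclides[nid]
            else:
                nuc = Nuclide(id=nid, half_life=half_life)
                nuclides[nid] = nuc
            if code == "NONE":
                continue
            if code not in _PARTICLE_CODES:
                raise NuclideTableError(
                    f"line {lineno}: unknown particle code {code!r}"
                )
            try:
                energy = float(energy_s)
                intensity = float(intensity_s)
                endpoint = None if endpoint_s == "-" else float(endpoint_s)
            except ValueError as exc:
                raise NuclideTableError(f"line {lineno}: malformed row") from exc
            try:
                em = EmissionLine(
                    particle=_PARTICLE_CODES[code],
                    energy=energy,
                    intensity=intensity,
                    endpoint_energy=endpoint,
                )
            except NuclideTableError as exc:
                raise NuclideTableError(f"line {lineno}: {exc}") from exc
            nuc.lines.append(em)
    # re-validate branch sums now that all rows are in
    for nuc in nuclides.values():
        if nuc.branches:
            total = sum(f for _, f in nuc.branches)
            if abs(total - 1.0) > 1e-6:
                raise NuclideTableError(
                    f"{nuc.id}: branching fractions sum to {total}, expected 1"
                )
    return list(nuclides.values())


def build_decay_chain(
    parent: str,
    table: list[Nuclide],
    cutoff_half_life: float = DEFAULT_CHAIN_CUTOFF_S,
    explicit_cuts: frozenset[str] | set[str] | None = None,
) -> DecayChainSpec:
    """Walk the decay graph breadth-first from ``parent`` and aggregate the
    per-transformation emission inventory of the retained (promptly decaying)
    chain.

    Traversal stops at any daughter in ``explicit_cuts`` (default: the
    conventional cut list) and at any daughter whose half-life exceeds
    ``cutoff_half_life`` (default 15 days). Occurrence factors multiply
    branching fractions along the path; the parent itself is never cut.
    """
    if explicit_cuts is None:
        explicit_cuts = DEFAULT_EXPLICIT_CUTS
    index = {n.id: n for n in table}
    if parent not in index:
        raise NuclideTableError(f"parent nuclide {parent!r} not in table")

    members: dict[str, float] = {parent: 1.0}
    truncated_at: set[str] = set()
    order: list[str] = [parent]
    # BFS over decay paths; each queue entry carries the occurrence of the
    # path ending at that nuclide so multi-path (DAG) daughters accumulate
    # correctly. A cycle would make the pop count blow past any DAG bound.
    queue: deque[tuple[str, float]] = deque([(parent, 1.0)])
    pops = 0
    max_pops = 4 * len(index) * max(1, len(index))
    while queue:
        nid, occ = queue.popleft()
        pops += 1
        if pops > max_pops:
            raise NuclideTableError(f"cycle detected in decay graph at {nid!r}")
        for daughter, frac in index[nid].branches:
            contribution = occ * frac
            if daughter in explicit_cuts:
                truncated_at.add(daughter)
                continue
            if daughter not in index:
                raise NuclideTableError(
                    f"daughter {daughter!r} of {nid!r} missing from table"
                )
            if index[daughter].half_life > cutoff_half_life:
                truncated_at.add(daughter)
                continue
            if daughter in members:
                members[daughter] += contribution
            else:
                members[daughter] = contribution
                order.append(daughter)
            queue.append((daughter, contribution))

    inventory: list[tuple[EmissionLine, float]] = []
    for nid in order:
        occ = members[nid]
        for line in index[nid].lines:
            inventory.append((line, line.intensity * occ))
    return DecayChainSpec(
        parent=parent,
        members=members,
        truncated_at=truncated_at,
        inventory=inventory,
    )


def mean_energy_per_decay(
    chain: DecayChainSpec, particle_filter: set[str] | None = None
) -> float:
    """Σ(effective intensity × energy) in MeV over inventory lines matching
    ``particle_filter`` (all particles when None). For beta lines this uses
    the mean spectrum energy, so the result is the expected emitted energy per
    parent transformation."""
    total = 0.0
    for line, eff in chain.inventory:
        if particle_filter is None or line.particle in particle_filter:
            total += eff * line.energy
    return total
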