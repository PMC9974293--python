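"""Arterial network data model: vessels, junctions, terminals, tube law.

The arterial tree is a rooted tree of 1D compliant vessels.  Each vessel is
discretised into ``n_cells`` axial cells with a linearly tapered reference
area A0(x).  Wall mechanics follow the standard beta tube law with an
optional Voigt viscoelastic term::

    P = P_ext + (beta / A0) * (sqrt(A) - sqrt(A0)) + Gamma / (A0 sqrt(A)) * dA/dt

which gives the closed-form wave speed c = sqrt(beta / (2 rho A0)) * A**(1/4):
the vessel stiffens with distension, so hydrostatic loading raises local wave
speed without any explicit stiffness rescaling.

Terminals carry three-element Windkessel (RCR) loads standing in for the
downstream microcirculation; the inflow source prescribes one periodic beat
of root flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, NumericalStateError, TopologyError

__all__ = [
    "SimConfig",
    "VesselSegment1D",
    "Junction",
    "TerminalWindkessel",
    "InflowSource",
    "NetworkTopology",
    "build_network",
    "tube_law",
    "analytic_wave_speed",
    "area_ratio_bifurcation",
    "network_mean_area_ratio",
]


@dataclass
class SimConfig:
    """Physical constants and solver controls.

    friction_coefficient is the viscous momentum source coefficient K_R in
    dQ/dt = ... - K_R * Q / A; the default 22*pi*mu/rho corresponds to the
    Womersley-motivated flat-core velocity profile (profile coefficient 22).
    """

    blood_density: float = 1050.0        # kg/m^3
    blood_viscosity: float = 0.004       # Pa s
    gravity: float = 9.81                # m/s^2
    momentum_correction: float = 1.0     # alpha
    friction_coefficient: float | None = None  # K_R, m^2/s; None -> 22 pi mu / rho
    cfl: float = 0.9
    max_beats: int = 30
    convergence_tol: float = 1e-3        # relative L2, beat to beat
    sample_rate: float = 1000.0          # Hz, output resampling

    def __post_init__(self):
        if self.blood_density <= 0 or self.blood_viscosity <= 0 or self.gravity < 0:
            raise ConfigurationError("rho, mu must be > 0 and g >= 0")
        if not 0.0 < self.cfl <= 1.0:
            raise ConfigurationError("CFL must lie in (0, 1]")
        if self.convergence_tol <= 0:
            raise ConfigurationError("convergence_tol must be > 0")
        if self.friction_coefficient is None:
            self.friction_coefficient = 22.0 * math.pi * self.blood_viscosity / self.blood_density


@dataclass
class VesselSegment1D:
    """One 1D arterial vessel with linear taper.

    phi is the inclination in degrees from horizontal for the upright body;
    positive when the distal end sits lower than the proximal end at 90 deg
    tilt.  z_prox is the proximal-end elevation below heart level (m, upright,
    positive downward); it may be left None and filled by tree accumulation.
    """

    id: int
    name: str
    length: float                 # m
    A0_prox: float                # m^2
    A0_dist: float                # m^2
    beta: float                   # Pa m
    gamma: float = 0.0            # Pa s m (viscoelastic)
    phi: float = 0.0              # deg
    z_prox: float | None = None   # m below heart, upright
    group: str = "other"          # aortic | cerebral | limb | other
    n_cells: int = 4

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigurationError(f"vessel {self.id}: length must be > 0")
        if self.A0_prox <= 0 or self.A0_dist <= 0:
            raise ConfigurationError(f"vessel {self.id}: reference areas must be > 0")
        if self.beta <= 0:
            raise ConfigurationError(f"vessel {self.id}: beta must be > 0")
        if self.gamma < 0:
            raise ConfigurationError(f"vessel {self.id}: Gamma must be >= 0")
        if self.n_cells < 2:
            raise ConfigurationError(f"vessel {self.id}: n_cells must be >= 2")
        if abs(self.phi) > 90.0:
            raise ConfigurationError(f"vessel {self.id}: |phi| must be <= 90 deg")
        if self.group not in ("aortic", "cerebral", "limb", "other"):
            raise ConfigurationError(f"vessel {self.id}: unknown group {self.group!r}")

    @property
    def dx(self) -> float:
        return self.length / self.n_cells

    def x_cells(self) -> np.ndarray:
        """Axial positions of cell midpoints, from the vessel inlet."""
        return (np.arange(self.n_cells) + 0.5) * self.dx

    def a0_at(self, x) -> np.ndarray:
        """Taper-interpolated reference area at axial position x."""
        frac = np.asarray(x) / self.length
        return self.A0_prox + (self.A0_dist - self.A0_prox) * frac

    def a0_cells(self) -> np.ndarray:
        return self.a0_at(self.x_cells())

    def da0_dx(self) -> float:
        return (self.A0_dist - self.A0_prox) / self.length

    @property
    def sin_phi(self) -> float:
        return math.sin(math.radians(self.phi))

    def z_at(self, x) -> np.ndarray:
        """Upright elevation below heart (m, positive downward) at position x."""
        if self.z_prox is None:
            raise ConfigurationError(f"vessel {self.id}: z_prox not resolved")
        return self.z_prox + np.asarray(x) * self.sin_phi

    @property
    def z_dist(self) -> float:
        return float(self.z_at(self.length))


@dataclass
class Junction:
    """Parent-to-daughter connection; one daughter encodes a continuation."""

    parent: int
    daughters: list[int]

    def __post_init__(self):
        if not 1 <= len(self.daughters) <= 2:
            raise ConfigurationError("junction must have 1 or 2 daughters")
        if self.parent in self.daughters:
            raise TopologyError(f"junction parent {self.parent} repeated as daughter")

    @property
    def is_bifurcation(self) -> bool:
        return len(self.daughters) == 2


@dataclass
class TerminalWindkessel:
    """RCR terminal load; R_down = R1 + R2 is the total downstream resistance."""

    R1: float                 # Pa s / m^3
    R2: float
    C: float                  # m^3 / Pa
    P_out: float = 0.0        # Pa

    def __post_init__(self):
        if self.R1 < 0 or self.R2 < 0 or self.C < 0:
            raise ConfigurationError("Windkessel elements must be >= 0")
        if self.R1 + self.R2 <= 0:
            raise ConfigurationError("R_down = R1 + R2 must be > 0")

    @property
    def R_down(self) -> float:
        return self.R1 + self.R2


@dataclass
class InflowSource:
    """Tabulated periodic inflow over one beat (first sample == last)."""

    RR: float                 # s
    t: np.ndarray             # s, ascending, t[0] = 0, t[-1] = RR
    Q: np.ndarray             # m^3/s

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.RR <= 0:
            raise ConfigurationError("RR must be > 0")
        if self.t.shape != self.Q.shape or self.t.ndim != 1 or self.t.size < 3:
            raise ConfigurationError("inflow table must be 1D with >= 3 samples")
        if abs(self.t[0]) > 1e-12 or abs(self.t[-1] - self.RR) > 1e-9 * self.RR:
            raise ConfigurationError("inflow table must span exactly [0, RR]")
        if abs(self.Q[0] - self.Q[-1]) > 1e-9 * (np.max(np.abs(self.Q)) + 1e-300):
            raise ConfigurationError("inflow must be periodic (first == last sample)")
        if self.stroke_volume <= 0:
            raise ConfigurationError("stroke volume must be > 0")

    @property
    def stroke_volume(self) -> float:
        """SV = integral of Q over one beat (m^3)."""
        return float(np.trapezoid(self.Q, self.t))

    def q_at(self, time) -> np.ndarray:
        """Periodic interpolation of the inflow at arbitrary times."""
        return np.interp(np.mod(time, self.RR), self.t, self.Q)


@dataclass
class NetworkTopology:
    """The 1D arterial tree: vessels, junctions, terminal loads, root inflow."""

    vessels: dict[int, VesselSegment1D]
    junctions: list[Junction]
    terminals: dict[int, TerminalWindkessel]
    root: int
    aortic_path: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structure queries -------------------------------------------------
    def parent_of(self, vid: int) -> int | None:
        for j in self.junctions:
            if vid in j.daughters:
                return j.parent
        return None

    def junction_at(self, parent: int) -> Junction | None:
        for j in self.junctions:
            if j.parent == parent:
                return j
        return None

    @property
    def leaves(self) -> list[int]:
        parents = {j.parent for j in self.junctions}
        return [vid for vid in self.vessels if vid not in parents]

    def vessels_by_group(self, group: str) -> list[int]:
        return [vid for vid, v in self.vessels.items() if v.group == group]

    def cerebral_terminals(self) -> list[int]:
        return [vid for vid in self.terminals if self.vessels[vid].group == "cerebral"]

    def total_peripheral_resistance(self) -> float:
        """Parallel total of all terminal R_down values."""
        return 1.0 / sum(1.0 / t.R_down for t in self.terminals.values())

    def path_distance(self, vid: int, x: float = 0.0) -> float:
        """Centreline distance from the root inlet to position x in vessel vid."""
        d = x
        cur = vid
        while cur != self.root:
            cur = self.parent_of(cur)
            d += self.vessels[cur].length
        return d

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        ids = list(self.vessels)
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate vessel ids")
        if self.root not in self.vessels:
            raise ConfigurationError(f"root vessel {self.root} not in network")

        seen_daughters: set[int] = set()
        for j in self.junctions:
            for vid in (j.parent, *j.daughters):
                if vid not in self.vessels:
                    raise ConfigurationError(f"junction references unknown vessel {vid}")
            for d in j.daughters:
                if d in seen_daughters:
                    raise TopologyError(f"vessel {d} is daughter of more than one junction")
                seen_daughters.add(d)
        if self.root in seen_daughters:
            raise TopologyError("root vessel cannot be a daughter")

        parents = {j.parent for j in self.junctions}
        if len(parents) != len(self.junctions):
            raise TopologyError("a vessel feeds more than one junction")

        # connectivity: walk down from the root
        reached = {self.root}
        stack = [self.root]
        while stack:
            j = self.junction_at(stack.pop())
            if j is None:
                continue
            for d in j.daughters:
                if d in reached:
                    raise TopologyError(f"cycle through vessel {d}")
                reached.add(d)
                stack.append(d)
        missing = set(self.vessels) - reached
        if missing:
            raise TopologyError(f"vessels not reachable from root: {sorted(missing)}")

        for leaf in self.leaves:
            if leaf not in self.terminals:
                raise ConfigurationError(f"leaf vessel {leaf} has no terminal Windkessel")
        for vid in self.terminals:
            if vid not in self.vessels:
                raise ConfigurationError(f"terminal attached to unknown vessel {vid}")
            if self.junction_at(vid) is not None:
                raise ConfigurationError(f"terminal attached to non-leaf vessel {vid}")

        if self.aortic_path:
            if self.aortic_path[0] != self.root:
                raise ConfigurationError("aortic path must start at the root")
            for up, down in zip(self.aortic_path, self.aortic_path[1:]):
                j = self.junction_at(up)
                if j is None or down not in j.daughters:
                    raise ConfigurationError(
                        f"aortic path step {up} -> {down} is not a junction edge")

        self._resolve_elevations()

    def _resolve_elevations(self) -> None:
        """Fill z_prox by accumulation from the root (root inlet at heart level
        unless its z_prox is given)."""
        rootv = self.vessels[self.root]
        if rootv.z_prox is None:
            rootv.z_prox = 0.0
        stack = [self.root]
        while stack:
            vid = stack.pop()
            j = self.junction_at(vid)
            if j is None:
                continue
            zd = self.vessels[vid].z_dist
            for d in j.daughters:
                dv = self.vessels[d]
                if dv.z_prox is None:
                    dv.z_prox = zd
                stack.append(d)

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            vessels={vid: replace(v) for vid, v in self.vessels.items()},
            junctions=[Junction(j.parent, list(j.daughters)) for j in self.junctions],
            terminals={vid: replace(t) for vid, t in self.terminals.items()},
            root=self.root,
            aortic_path=list(self.aortic_path),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_network(document) -> NetworkTopology:
    """Build and validate a NetworkTopology.

    ``document`` is either the name of a bundled network ("uniform_tube",
    "tapered_tube", "murray_tree", "mini_aorta", "single_reflector") or a
    parsed network description dict in file units (mmHg / cm / ml); see
    :mod:`pulsewave.io` for the on-disk schema.
    """
    if isinstance(document, str):
        from .fixtures import make_canonical_networks

        return make_canonical_networks(document)
    from .io import network_from_document

    return network_from_document(document)


def tube_law(A, dA_dt, vessel: VesselSegment1D, cell_index: int, p_ext: float = 0.0):
    """Transmural-inclusive pressure at one cell of a vessel (Pa)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise NumericalStateError(
            f"vessel {vessel.id} cell {cell_index}: non-positive area in tube law")
    a0 = float(vessel.a0_cells()[cell_index])
    p = p_ext + vessel.beta / a0 * (np.sqrt(A) - math.sqrt(a0))
    if vessel.gamma > 0.0:
        p = p + vessel.gamma / (a0 * np.sqrt(A)) * np.asarray(dA_dt, dtype=float)
    return p


def inverse_tube_law(P, vessel: VesselSegment1D, cell_index, p_ext: float = 0.0):
    """Elastic-branch area at pressure P (used for initialisation)."""
    a0 = vessel.a0_cells()[cell_index]
    root = np.sqrt(a0) + (np.asarray(P, dtype=float) - p_ext) * a0 / vessel.beta
    if np.any(root <= 0):
        raise NumericalStateError(f"vessel {vessel.id}: collapse pressure reached")
    return root**2


def analytic_wave_speed(A, vessel: VesselSegment1D, rho: float, cell_index=None):
    """Elastic wave speed c = sqrt((A/rho) dP/dA) = sqrt(beta/(2 rho A0)) A^(1/4).

    With ``cell_index=None``, ``A`` is interpreted per cell (array of length
    n_cells) using each cell's taper-interpolated A0.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise NumericalStateError(f"vessel {vessel.id}: non-positive area")
    a0 = vessel.a0_cells() if cell_index is None else float(vessel.a0_cells()[cell_index])
    return np.sqrt(vessel.beta / (2.0 * rho * a0)) * A**0.25


def area_ratio_bifurcation(junction: Junction, parent_A, daughter_As) -> float:
    """Beat-mean daughter/parent area ratio at one bifurcation.

    parent_A: area series at the parent distal cell; daughter_As: list of
    area series at each daughter proximal cell.  Continuation junctions are
    not bifurcations and are rejected by the caller (see
    :func:`network_mean_area_ratio`).
    """
    if not junction.is_bifurcation:
        raise ConfigurationError("area ratio is defined for bifurcations only")
    ap = float(np.mean(parent_A))
    ad = sum(float(np.mean(a)) for a in daughter_As)
    return ad / ap


def network_mean_area_ratio(network: NetworkTopology, area_of) -> float:
    """Mean forward area ratio over all bifurcations.

    ``area_of(vessel_id, cell_index)`` returns the beat area series at a cell;
    continuation junctions are excluded (with a logged notice).
    """
    import logging

    ratios = []
    for j in network.junctions:
        if not j.is_bifurcation:
            logging.getLogger(__name__).info(
                "junction at vessel %d is a continuation; excluded from area matching",
                j.parent)
            continue
        pa = area_of(j.parent, network.vessels[j.parent].n_cells - 1)
        das = [area_of(d, 0) for d in j.daughters]
        ratios.append(area_ratio_bifurcation(j, pa, das))
    if not ratios:
        raise ConfigurationError("network has no bifurcations")
    return float(np.mean(ratios))
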