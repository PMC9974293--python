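"""Canonical synthetic networks, inflows and waveform fixtures.

Every study input is generated here programmatically: a reflection-free
uniform tube, a tapered tube, a Murray-matched symmetric tree, a
single-reflector echo fixture, and ``mini_aorta`` — a 20-vessel adult
arterial tree with the numbered aortic path used in the posture study, a
cerebral (carotid) branch, an arm branch, a visceral trunk, and two
bifurcating legs.

Vessels are parameterised by their *operating* state: the nominal radius
and wave speed are prescribed at an anchor pressure (the supine mean
arterial pressure for mini_aorta) and converted to the reference area A0
and stiffness beta of the tube law, so that simulated loops reproduce the
intended speeds at pressure.  Terminal Windkessels are matched (R1 equals
the outlet characteristic impedance at the operating point) with R2 sized
to carry the prescribed mean flow share at the prescribed perfusion
pressure.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError
from .network import (InflowSource, Junction, NetworkTopology,
                      TerminalWindkessel, VesselSegment1D)
from .units import mmhg_to_pa

__all__ = [
    "make_canonical_networks",
    "default_inflow",
    "make_inflow_waveform",
    "make_superposed_waves",
    "make_wi_fixture",
    "CANONICAL_DEFAULTS",
]

RHO = 1050.0

CANONICAL_DEFAULTS = {
    "uniform_tube": dict(RR=0.8, SV_ml=20.0, p_mean_mmhg=50.0, p_out_mmhg=0.0),
    "tapered_tube": dict(RR=0.8, SV_ml=20.0, p_mean_mmhg=50.0, p_out_mmhg=0.0),
    "murray_tree": dict(RR=0.8, SV_ml=10.0, p_mean_mmhg=15.0, p_out_mmhg=0.0),
    "single_reflector": dict(RR=2.4, SV_ml=12.0, p_mean_mmhg=30.0, p_out_mmhg=0.0),
    "mini_aorta": dict(RR=0.8, SV_ml=70.0, p_mean_mmhg=93.0, p_out_mmhg=33.0),
}


def _operating_vessel(vid, name, length, r_prox, r_dist, c_op, p_anchor,
                      n_cells, phi=0.0, group="other", rho=RHO,
                      wall_viscosity=0.0) -> VesselSegment1D:
    """Vessel whose area and wave speed equal the given targets at p_anchor.

    The tube law gives c^2 = c0^2 + P/(2 rho) along one vessel cell, so the
    reference (zero-pressure) speed and area follow in closed form from the
    operating targets.
    """
    c0_sq = c_op**2 - p_anchor / (2.0 * rho)
    if c0_sq <= 0:
        raise ConfigurationError(
            f"vessel {vid}: operating speed {c_op} m/s unreachable at anchor "
            f"pressure {p_anchor:.0f} Pa")
    distension = (1.0 + p_anchor / (2.0 * rho * c0_sq)) ** 2
    a_prox = math.pi * r_prox**2
    a_dist = math.pi * r_dist**2
    a0_prox = a_prox / distension
    a0_dist = a_dist / distension
    beta = 2.0 * rho * c0_sq * math.sqrt(0.5 * (a0_prox + a0_dist))
    gamma = wall_viscosity * math.sqrt(0.5 * (a0_prox + a0_dist))
    return VesselSegment1D(id=vid, name=name, length=length,
                           A0_prox=a0_prox, A0_dist=a0_dist, beta=beta,
                           gamma=gamma, phi=phi, group=group, n_cells=n_cells)


def _zc_at(vessel: VesselSegment1D, p: float, rho=RHO) -> float:
    """Characteristic impedance of the vessel outlet at pressure p."""
    a0 = vessel.A0_dist
    a = (math.sqrt(a0) + p * a0 / vessel.beta) ** 2
    c = math.sqrt(vessel.beta / (2.0 * rho * a0)) * a**0.25
    return rho * c / a


def _matched_terminal(vessel: VesselSegment1D, p_mean: float, q_mean: float,
                      p_out: float, C: float | None = None, tau: float = 60.0,
                      rho=RHO) -> TerminalWindkessel:
    """Matched RCR load: R1 = outlet Zc, R2 sized for the mean flow share.

    With no explicit compliance, C is sized for a long time constant
    tau = R2*C so the compliance node is quasi-static and the load is
    reflection-free down to the beat fundamental (the oracle fixtures);
    physiological networks pass their compliance explicitly.
    """
    zc = _zc_at(vessel, p_mean, rho)
    r_down = (p_mean - p_out) / q_mean
    r2 = r_down - zc
    if r2 <= 0:
        raise ConfigurationError(
            f"vessel {vessel.id}: mean-flow share too large for a matched "
            f"terminal (R_down {r_down:.3g} <= Zc {zc:.3g})")
    if C is None:
        C = tau / r2
    return TerminalWindkessel(R1=zc, R2=r2, C=C, P_out=p_out)


# ---------------------------------------------------------------------------
# canonical networks
# ---------------------------------------------------------------------------

def make_canonical_networks(name: str, **overrides) -> NetworkTopology:
    """Build one of the bundled networks by name."""
    builders = {
        "uniform_tube": _uniform_tube,
        "tapered_tube": _tapered_tube,
        "murray_tree": _murray_tree,
        "single_reflector": _single_reflector,
        "mini_aorta": _mini_aorta,
    }
    if name not in builders:
        raise ConfigurationError(
            f"unknown bundled network {name!r}; choose from {sorted(builders)}")
    params = dict(CANONICAL_DEFAULTS[name])
    params.update(overrides)
    return builders[name](**params)


_DEFAULT_SHAPE = {
    # echo fixture: fast front, slow decay, long beat
    "single_reflector": dict(shape="sharp", ejection_fraction=0.17,
                             rise_fraction=0.012),
}


def default_inflow(name: str, **overrides) -> InflowSource:
    """The inflow waveform the bundled network's terminals were sized for."""
    params = dict(CANONICAL_DEFAULTS[name])
    params.update(_DEFAULT_SHAPE.get(name, {}))
    params.update(overrides)
    return make_inflow_waveform(
        RR=params["RR"], SV=params["SV_ml"] * 1e-6,
        shape=params.get("shape", "half_sine"),
        ejection_fraction=params.get("ejection_fraction", 0.35),
        rise_fraction=params.get("rise_fraction", 0.2))


def _uniform_tube(RR, SV_ml, p_mean_mmhg, p_out_mmhg, length=1.0,
                  radius=0.008, c_op=5.0, n_cells=20, terminal_tau=60.0):
    p_mean = mmhg_to_pa(p_mean_mmhg)
    p_out = mmhg_to_pa(p_out_mmhg)
    q_mean = SV_ml * 1e-6 / RR
    v = _operating_vessel(1, "uniform tube", length, radius, radius, c_op,
                          p_mean, n_cells)
    term = _matched_terminal(v, p_mean, q_mean, p_out, tau=terminal_tau)
    return NetworkTopology(vessels={1: v}, junctions=[], terminals={1: term},
                           root=1, aortic_path=[1])


def _tapered_tube(RR, SV_ml, p_mean_mmhg, p_out_mmhg, length=1.0,
                  radius=0.008, c_op=5.0, n_cells=20):
    """Reference area halves from inlet to outlet (radius / 2^0.5)."""
    p_mean = mmhg_to_pa(p_mean_mmhg)
    p_out = mmhg_to_pa(p_out_mmhg)
    q_mean = SV_ml * 1e-6 / RR
    v = _operating_vessel(1, "tapered tube", length, radius,
                          radius / math.sqrt(2.0), c_op, p_mean, n_cells)
    term = _matched_terminal(v, p_mean, q_mean, p_out)
    return NetworkTopology(vessels={1: v}, junctions=[], terminals={1: term},
                           root=1, aortic_path=[1])


def _murray_tree(RR, SV_ml, p_mean_mmhg, p_out_mmhg, depth=2, r_root=0.010,
                 c_root=8.0, length=0.15, n_cells=6):
    """Symmetric tree with Murray radii r_d = 2^(-1/3) r_p.

    Stiffness scales as beta_d = 2^(1/3) beta_p, which matches the parallel
    daughter characteristic impedance to the parent's at the reference
    state, so forward reflection is near zero at every junction.
    """
    p_mean = mmhg_to_pa(p_mean_mmhg)
    p_out = mmhg_to_pa(p_out_mmhg)
    q_mean = SV_ml * 1e-6 / RR
    vessels, junctions, terminals = {}, [], {}
    # reference-state construction: A0 set directly from the Murray radii
    beta_root = 2.0 * RHO * c_root**2 * math.sqrt(math.pi) * r_root
    n_leaves = 2**depth
    for level in range(depth + 1):
        r = r_root * 2.0 ** (-level / 3.0)
        a0 = math.pi * r**2
        beta = beta_root * 2.0 ** (level / 3.0)
        for k in range(2**level):
            vid = 2**level + k
            vessels[vid] = VesselSegment1D(
                id=vid, name=f"murray level {level} #{k}", length=length,
                A0_prox=a0, A0_dist=a0, beta=beta, n_cells=n_cells)
            if level < depth:
                junctions.append(Junction(vid, [2 * vid, 2 * vid + 1]))
            else:
                terminals[vid] = _matched_terminal(
                    vessels[vid], p_mean, q_mean / n_leaves, p_out)
    return NetworkTopology(vessels=vessels, junctions=junctions,
                           terminals=terminals, root=1, aortic_path=[])


def _single_reflector(RR, SV_ml, p_mean_mmhg, p_out_mmhg, distance=0.4,
                      zc_step=1.3, radius=0.008, c_op=5.0, n_cells=120,
                      distal_length=2.5, distal_cells=70):
    """Uniform tube with an abrupt Z_c step at the prescribed distance.

    The distal segment has the same lumen but a wave speed zc_step times
    higher at the operating point, so an incident wave reflects with
    R_p = (zc_step - 1)/(zc_step + 1) exactly at the known distance; the far
    end is matched and kept long so its residual echo arrives late and
    diffused.  This is the echo-timing oracle for ToR/PoR; drive it with the
    'sharp' inflow shape so the wavefront carries the WI energy.
    """
    p_mean = mmhg_to_pa(p_mean_mmhg)
    p_out = mmhg_to_pa(p_out_mmhg)
    q_mean = SV_ml * 1e-6 / RR
    v1 = _operating_vessel(1, "proximal segment", distance, radius, radius,
                           c_op, p_mean, n_cells)
    v2 = _operating_vessel(2, "distal stiff segment", distal_length, radius,
                           radius, c_op * zc_step, p_mean, distal_cells)
    term = _matched_terminal(v2, p_mean, q_mean, p_out)
    return NetworkTopology(vessels={1: v1, 2: v2},
                           junctions=[Junction(1, [2])],
                           terminals={2: term}, root=1, aortic_path=[1])


# geometry of the trimmed adult tree: (id, name, L_cm, r_prox_cm, r_dist_cm,
# c_op_supine m/s, n_cells, phi_deg, group).  Cell counts along the aortic
# path follow the per-vessel segment numbers implied by the posture study's
# paired-test pattern; elevations span head (-0.4 m) to ankle (+1.1 m).
_MINI_AORTA_GEOMETRY = [
    (1, "aortic root no. 1", 3, 1.45, 1.44, 4.00, 2, 0, "aortic"),
    (63, "ascending aorta no. 63", 6, 1.44, 1.40, 3.95, 6, -30, "aortic"),
    (2, "aortic arch A no. 2", 4, 1.40, 1.30, 4.10, 2, 0, "aortic"),
    (14, "aortic arch B no. 14", 8, 1.30, 1.15, 4.24, 8, 30, "aortic"),
    (18, "thoracic aorta no. 18", 10, 1.15, 1.00, 4.32, 10, 60, "aortic"),
    (27, "thoracic aorta no. 27", 6, 1.00, 0.95, 4.40, 3, 60, "aortic"),
    (28, "abdominal aorta no. 28", 6, 0.95, 0.90, 4.50, 3, 60, "aortic"),
    (35, "abdominal aorta no. 35", 6, 0.90, 0.85, 4.60, 3, 60, "aortic"),
    (37, "abdominal aorta no. 37", 8, 0.85, 0.80, 4.75, 4, 60, "aortic"),
    (39, "abdominal aorta no. 39", 10, 0.80, 0.70, 4.85, 10, 60, "aortic"),
    (41, "iliac bifurcation no. 41", 8, 0.70, 0.60, 5.06, 4, 60, "aortic"),
    (13, "cerebral branch (ext. carotid) no. 13", 45, 0.40, 0.30, 6.77, 6, -88, "cerebral"),
    (24, "arm (interosseous) no. 24", 40, 0.35, 0.30, 6.00, 4, 45, "limb"),
    # visceral bed off the upper abdominal aorta: carries the celiac +
    # renal + mesenteric flow share so the legs keep a realistic fraction
    (30, "visceral (celiac-renal) trunk no. 30", 8, 0.45, 0.35, 6.00, 2, 0, "other"),
    # each leg bifurcates (femoral -> two tibial-calibre daughters), giving
    # backward waves from the leg terminals two trapping junctions on the
    # way up, as in the real arterial tree; radii keep the daughters in
    # parallel close to the parent impedance in the forward direction
    (44, "femoral no. 44", 30, 0.45, 0.40, 6.00, 5, 80, "limb"),
    (45, "contralateral femoral no. 45", 30, 0.45, 0.40, 6.00, 3, 80, "limb"),
    (48, "leg (tibial) no. 48", 30, 0.32, 0.25, 7.42, 10, 80, "limb"),
    (50, "peroneal no. 50", 30, 0.32, 0.25, 7.42, 3, 80, "limb"),
    (49, "contralateral tibial no. 49", 30, 0.32, 0.25, 7.42, 4, 80, "limb"),
    (51, "contralateral peroneal no. 51", 30, 0.32, 0.25, 7.42, 3, 80, "limb"),
]

_MINI_AORTA_JUNCTIONS = [
    (1, [63]), (63, [2, 13]), (2, [14, 24]), (14, [18]), (18, [27]),
    (27, [28]), (28, [35, 30]), (35, [37]), (37, [39]), (39, [41]),
    (41, [44, 45]), (44, [48, 50]), (45, [49, 51]),
]

_MINI_AORTA_PATH = [1, 63, 2, 14, 18, 27, 28, 35, 37, 39, 41]

# mean-flow shares of the peripheral beds (cerebral ~13% of CO, visceral
# ~1/3, legs ~20% each)
_MINI_AORTA_FLOW_SHARE = {13: 0.13, 24: 0.12, 30: 0.33,
                          48: 0.105, 50: 0.105, 49: 0.105, 51: 0.105}
_MINI_AORTA_TOTAL_COMPLIANCE = 2.0e-8  # m^3/Pa, ~2.7 ml/mmHg arterial total


def _mini_aorta(RR, SV_ml, p_mean_mmhg, p_out_mmhg, wall_viscosity=100.0,
                peripheral_viscosity_factor=1.0):
    p_mean = mmhg_to_pa(p_mean_mmhg)
    p_out = mmhg_to_pa(p_out_mmhg)
    q_mean = SV_ml * 1e-6 / RR
    vessels = {}
    for vid, name, L, rp, rd, c_op, n, phi, group in _MINI_AORTA_GEOMETRY:
        # muscular (non-aortic) walls are markedly more viscous than the
        # elastic aorta
        wv = wall_viscosity * (1.0 if group == "aortic"
                               else peripheral_viscosity_factor)
        vessels[vid] = _operating_vessel(vid, name, L * 1e-2, rp * 1e-2,
                                         rd * 1e-2, c_op, p_mean, n,
                                         phi=phi, group=group,
                                         wall_viscosity=wv)
    junctions = [Junction(p, list(ds)) for p, ds in _MINI_AORTA_JUNCTIONS]
    terminals = {}
    for vid, share in _MINI_AORTA_FLOW_SHARE.items():
        # Zc-matched proximal resistor so the periphery absorbs rather than
        # re-reflects high-frequency wave energy (standard RCR practice)
        terminals[vid] = _matched_terminal(
            vessels[vid], p_mean, share * q_mean, p_out,
            C=share * _MINI_AORTA_TOTAL_COMPLIANCE)
    return NetworkTopology(vessels=vessels, junctions=junctions,
                           terminals=terminals, root=1,
                           aortic_path=list(_MINI_AORTA_PATH))


# ---------------------------------------------------------------------------
# waveform fixtures
# ---------------------------------------------------------------------------

def make_inflow_waveform(RR: float, SV: float, shape: str = "half_sine",
                         ejection_fraction: float = 0.35,
                         rise_fraction: float = 0.2,
                         n_samples: int = 1024) -> InflowSource:
    """Periodic one-beat inflow with exact (trapezoid-rule) stroke volume.

    shape 'half_sine': Q = Q_pk sin(pi t / T_ej) during ejection, zero in
    diastole; 'trapezoid': rise_fraction up, symmetric fall, 1 - 2*rise flat;
    'sharp': asymmetric triangle with a fast front (rise_fraction of T_ej)
    and a slow linear decay, used by echo-timing fixtures where the wavefront
    must carry nearly all of the wave-intensity energy.
    """
    if SV <= 0:
        raise ConfigurationError("stroke volume must be > 0")
    if shape not in ("half_sine", "trapezoid", "sharp"):
        raise ConfigurationError(f"unknown inflow shape {shape!r}")
    t = np.linspace(0.0, RR, n_samples + 1)
    t_ej = ejection_fraction * RR
    q = np.zeros_like(t)
    ej = t <= t_ej
    x = t[ej] / t_ej
    if shape == "half_sine":
        q[ej] = np.sin(np.pi * x)
    elif shape == "trapezoid":
        r = rise_fraction
        q[ej] = np.clip(np.minimum(x / r, (1.0 - x) / r), 0.0, 1.0)
    else:
        # smooth (cosine) front so dQ/dt peaks once at mid-rise, then a slow
        # linear decay: the wavefront carries nearly all the WI energy and
        # its WI peak time coincides with its WI energy centroid
        r = rise_fraction
        q[ej] = np.where(x < r, 0.5 * (1.0 - np.cos(np.pi * x / r)),
                         (1.0 - x) / (1.0 - r))
    q[0] = q[-1] = 0.0
    q *= SV / np.trapezoid(q, t)
    return InflowSource(RR=RR, t=t, Q=q)


def gaussian_pulse(t: np.ndarray, amp: float, t0: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def make_superposed_waves(forward: tuple[float, float, float],
                          backward: tuple[float, float, float],
                          Zc: float, RR: float = 0.8, n_samples: int = 2048,
                          p0: float = 0.0, A0: float = 3e-4):
    """Analysis-ready series with a known exact forward/backward split.

    ``forward``/``backward`` are (amplitude_Pa, centre_s, width_s) Gaussian
    pressure pulses; the emitted signals are P = p0 + P_f* + P_b* and
    Q = (P_f* - P_b*)/Zc, so linear separation with the same Zc recovers the
    constructed components exactly.  Returns (series, P_f*, P_b*).
    """
    from .solver import HemoTimeSeries

    t = np.linspace(0.0, RR, n_samples + 1)
    pf = gaussian_pulse(t, *forward)
    pb = gaussian_pulse(t, *backward)
    series = HemoTimeSeries(
        vessel_id=0, cell_index=0, x=0.0, elevation=0.0, t=t,
        P=p0 + pf + pb, Q=(pf - pb) / Zc, A=np.full_like(t, A0), RR=RR)
    return series, pf, pb


def make_wi_fixture(pulse_times, widths, weights, RR: float = 0.8,
                    n_samples: int = 4096, rho_c: float = 5e3,
                    forward_time: float = 0.05):
    """Synthetic wave-intensity series with WI_b as negative Gaussian pulses."""
    from .intensity import WaveIntensitySeries

    t = np.linspace(0.0, RR, n_samples + 1)
    wi_b = np.zeros_like(t)
    for t0, sig, w in zip(np.atleast_1d(pulse_times), np.atleast_1d(widths),
                          np.atleast_1d(weights)):
        wi_b -= gaussian_pulse(t, w, t0, sig)
    wi_f = gaussian_pulse(t, 1.0, forward_time, 0.01)
    return WaveIntensitySeries(t=t, wi_f=wi_f, wi_b=wi_b, rho_c=rho_c)
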