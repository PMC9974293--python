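"""Supine-to-standing posture transform.

Head-up tilt is represented statically: the converged set-points of the
short-term regulation loops (baroreflex, cardiopulmonary reflex, cerebral
autoregulation) are applied as scale factors on heart rate, stroke volume
and the terminal Windkessel elements, and the tilt angle is handed to the
solver so the hydrostatic field acts along every inclined vessel.  The
standing preset carries the steady-state shifts measured on passive head-up
tilt from 0 to 90 degrees: HR +23%, SV -32%, total peripheral resistance
+39%, cerebral arteriolar resistance -12%, cerebral compliance +65%,
venous/venular compliance -25%.

Arterial stiffness is deliberately not rescaled: the wave-speed rise below
heart level emerges from the pressure-dependent tube law under hydrostatic
loading (c grows with distension), and the carotid fall from the elevated,
autoregulation-dilated cerebral bed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .errors import ConfigurationError
from .network import InflowSource, NetworkTopology

__all__ = ["PostureState", "apply_posture", "SUPINE", "STANDING"]

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostureState:
    """Tilt angle plus the multiplicative haemodynamic factors.

    f_TPR is the target factor on the parallel total of all terminal
    R_down values; the uniform non-cerebral resistance factor implementing
    it is solved at application time (the cerebral factor f_Rc is fixed by
    autoregulation, so the non-cerebral beds absorb the remainder).
    """

    name: str = "custom"
    theta: float = 0.0        # deg
    f_HR: float = 1.0
    f_SV: float = 1.0
    f_TPR: float = 1.0
    f_Rc: float = 1.0         # cerebral terminal resistance
    f_Cc: float = 1.0         # cerebral terminal compliance
    f_Cv: float = 1.0         # non-cerebral terminal compliance

    def __post_init__(self):
        if not 0.0 <= self.theta <= 90.0:
            raise ConfigurationError("tilt angle must lie in [0, 90] deg")
        for f in (self.f_HR, self.f_SV, self.f_TPR, self.f_Rc, self.f_Cc, self.f_Cv):
            if f <= 0:
                raise ConfigurationError("posture factors must be > 0")


SUPINE = PostureState(name="supine", theta=0.0)
STANDING = PostureState(name="standing", theta=90.0, f_HR=1.23, f_SV=0.68,
                        f_TPR=1.39, f_Rc=0.88, f_Cc=1.65, f_Cv=0.75)


@dataclass
class PostureApplication:
    """Record of an applied posture (solved factors enable exact inversion)."""

    posture: PostureState
    f_R_noncerebral: float
    tpr_before: float
    tpr_after: float


def _scaled_r_down(t, f: float) -> float:
    """R_down when the distal (arteriolar) resistance R2 is scaled by f.

    The proximal resistor R1 represents the vessel-terminal interface
    impedance, not a regulated bed, so vasomotor factors act on R2 alone;
    the total is clipped at R1 from below.
    """
    return t.R1 + f * t.R2


def _tpr_with_factor(terminals, cerebral: set[int], f_Rc: float,
                     f: float) -> float:
    cond = 0.0
    for vid, t in terminals.items():
        cond += 1.0 / _scaled_r_down(t, f_Rc if vid in cerebral else f)
    return 1.0 / cond


def _solve_noncerebral_factor(network: NetworkTopology, posture: PostureState,
                              rel_tol: float = 1e-3) -> float:
    """Bisection for the uniform non-cerebral R2 factor hitting the TPR target."""
    cerebral = set(network.cerebral_terminals())
    terminals = network.terminals
    tpr0 = 1.0 / sum(1.0 / t.R_down for t in terminals.values())
    target = posture.f_TPR * tpr0
    if not any(vid not in cerebral for vid in terminals):
        raise ConfigurationError("network has no non-cerebral terminals to scale")
    # as f -> inf only the cerebral beds (plus bare R1's) conduct
    limit_cond = sum(1.0 / _scaled_r_down(t, posture.f_Rc) for vid, t in
                     terminals.items() if vid in cerebral)
    if limit_cond > 0 and 1.0 / limit_cond <= target:
        raise ConfigurationError(
            "requested TPR factor unreachable: cerebral conductance too large")

    lo, hi = 1e-6, 1.0
    while _tpr_with_factor(terminals, cerebral, posture.f_Rc, hi) < target:
        hi *= 2.0
        if hi > 1e12:
            raise ConfigurationError(
                "requested TPR factor unreachable with R1 fixed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _tpr_with_factor(terminals, cerebral, posture.f_Rc, mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < rel_tol * 1e-3 * mid:
            break
    return 0.5 * (lo + hi)


def apply_posture(network: NetworkTopology, inflow: InflowSource,
                  posture: PostureState):
    """Return (network, inflow, application record) for the given posture.

    The inputs are not modified.  The supine preset (all factors 1, theta 0)
    returns parameter-identical copies.
    """
    net = network.copy()
    tpr0 = net.total_peripheral_resistance()

    cerebral = set(net.cerebral_terminals())
    if (posture.f_Rc != 1.0 or posture.f_Cc != 1.0) and not cerebral:
        raise ConfigurationError(
            "posture prescribes cerebral factors but no terminal is tagged cerebral")

    identity = (posture.f_TPR == 1.0 and posture.f_Rc == 1.0)
    f = 1.0 if identity else _solve_noncerebral_factor(net, posture)

    for vid, t in net.terminals.items():
        if vid in cerebral:
            net.terminals[vid] = replace(t, R2=t.R2 * posture.f_Rc,
                                         C=t.C * posture.f_Cc)
        else:
            net.terminals[vid] = replace(t, R2=t.R2 * f,
                                         C=t.C * posture.f_Cv)

    # inflow: beat shortened by f_HR, volume scaled by f_SV
    new_rr = inflow.RR / posture.f_HR
    new_inflow = InflowSource(
        RR=new_rr,
        t=inflow.t / posture.f_HR,
        Q=inflow.Q * (posture.f_SV * posture.f_HR),
    )

    if posture.name == "standing":
        _log.info("standing preset: cardiac chamber elastance (+6%%) and venous "
                  "volume shifts are closed-loop quantities not represented by "
                  "this open arterial model; omitted")

    app = PostureApplication(posture=posture, f_R_noncerebral=f,
                             tpr_before=tpr0,
                             tpr_after=net.total_peripheral_resistance())
    return net, new_inflow, app
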