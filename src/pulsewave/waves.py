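"""Wave separation and pressure-flow wave analysis.

Given one periodic beat of pressure and flow at a node, the forward and
backward travelling components are

    P_f,b = (P +- Z_c Q) / 2        Q_f,b = (Q +- P / Z_c) / 2

with Z_c the local characteristic impedance.  Z_c is estimated with the
PQ-loop method and the local wave speed with the PU-loop method: the slope
of the early-systolic, nearly reflection-free linear tract of the P-Q
(resp. P-U) loop gives Z_c (resp. rho*c).

Reflection is quantified by the reflection magnitude RM = PP_b/PP_f, the
reflection index RI = PP_b/(PP_f+PP_b), the augmentation index AI = AP/PP,
and the pressure reflection coefficient R_p of each impedance discontinuity
(bifurcation, taper, terminal load).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import EstimationError, UndefinedIndexError
from .solver import HemoTimeSeries

__all__ = [
    "CharacteristicEstimate",
    "WaveSeparation",
    "ReflectionIndices",
    "ReflectionCoefficient",
    "ImpedanceSpectrum",
    "estimate_zc_pq",
    "estimate_c_pu",
    "separate_waves",
    "vessel_reflection_indices",
    "augmentation_index",
    "rp_bifurcation",
    "rp_taper",
    "rp_terminal",
    "input_impedance",
]

R2_GOOD = 0.98


@dataclass
class CharacteristicEstimate:
    Zc: float | None          # Pa s / m^3 (PQ slope)
    rho_c: float | None       # Pa s / m (PU slope)
    c: float | None           # m/s
    window: tuple[int, int]   # cyclic sample window of the fit
    r2: float
    flagged: bool = False


@dataclass
class WaveSeparation:
    P_f: np.ndarray
    P_b: np.ndarray
    Q_f: np.ndarray
    Q_b: np.ndarray

    @property
    def PP_f(self) -> float:
        return float(np.ptp(self.P_f))

    @property
    def PP_b(self) -> float:
        return float(np.ptp(self.P_b))

    @property
    def mean_P_f(self) -> float:
        return float(np.mean(self.P_f))

    @property
    def mean_P_b(self) -> float:
        return float(np.mean(self.P_b))


@dataclass
class ReflectionIndices:
    """Vessel-level reflection summary (PP_f, PP_b are means over cells)."""

    PP: float                 # total pulse pressure at the reference cell (Pa)
    PP_f: float
    PP_b: float
    RM: float
    RI: float
    AP: float | None = None   # signed augmentation pressure (Pa)
    AI: float | None = None
    AI_flagged: bool = False


@dataclass
class ReflectionCoefficient:
    kind: str                 # bifurcation_forward | bifurcation_backward | taper | terminal
    value: float
    impedances: dict = field(default_factory=dict)


@dataclass
class ImpedanceSpectrum:
    f: np.ndarray             # Hz, harmonics of 1/RR, index 0 = DC
    modulus: np.ndarray
    phase: np.ndarray
    defined: np.ndarray       # bool mask


# ---------------------------------------------------------------------------
# loop-slope estimators
# ---------------------------------------------------------------------------

def _foot_and_peak(P: np.ndarray) -> tuple[int, int, int]:
    """Cyclic indices of the pressure foot and systolic peak.

    The foot is found by walking back from the steepest point of the
    systolic upstroke (max dP/dt) until the slope falls below 8% of its
    maximum; this is robust to slow diastolic oscillations that sit within
    a percent of the diastolic minimum.  Returns (foot, peak, upstroke
    length in samples).
    """
    n = P.size
    i_pk = int(np.argmax(P))
    dP = np.roll(P, -1) - np.roll(P, 1)  # cyclic centred difference
    # steepest upstroke within the half beat preceding the peak
    half = n // 2
    pre_idx = (i_pk - half + np.arange(half)) % n
    i_steep = int(pre_idx[np.argmax(dP[pre_idx])])
    d_max = float(dP[i_steep])
    if d_max <= 0:
        raise EstimationError("no rising tract found (flat signal?)")
    foot = i_steep
    for back in range(1, half):
        j = (i_steep - back) % n
        if dP[j] <= 0.08 * d_max:
            foot = j
            break
    rise = (i_pk - foot) % n
    if rise < 3:
        raise EstimationError("upstroke too short to fit a loop slope")
    return foot, i_pk, rise


def _cyc(a: np.ndarray, start: int, length: int) -> np.ndarray:
    idx = (start + np.arange(length)) % a.size
    return a[idx]


def _loop_slope(P: np.ndarray, X: np.ndarray) -> CharacteristicEstimate:
    """Least-squares slope of P vs X over the early-systolic window.

    Window: foot to 30% of foot-to-peak time, widened in 5% steps until
    R^2 >= 0.98 or 60% is reached (then flagged).
    """
    scale = float(np.max(np.abs(X)))
    if np.ptp(X) < 1e-12 * max(scale, 1e-300) or scale == 0.0:
        raise EstimationError("flat signal: loop slope undefined")
    foot, _pk, rise = _foot_and_peak(P)
    best = None
    for frac in np.arange(0.30, 0.601, 0.05):
        m = max(int(round(frac * rise)) + 1, 3)
        p_w = _cyc(P, foot, m)
        x_w = _cyc(X, foot, m)
        if np.ptp(x_w) < 1e-12 * scale:
            continue
        slope, intercept = np.polyfit(x_w, p_w, 1)
        fit = slope * x_w + intercept
        ss_res = float(np.sum((p_w - fit) ** 2))
        ss_tot = float(np.sum((p_w - np.mean(p_w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        est = (float(slope), (foot, (foot + m) % P.size), float(r2))
        if best is None or r2 > best[2]:
            best = est
        if r2 >= R2_GOOD:
            best = est
            break
    if best is None:
        raise EstimationError("no usable fit window")
    slope, window, r2 = best
    if slope <= 0:
        raise EstimationError("non-positive loop slope: no identifiable upstroke")
    return CharacteristicEstimate(Zc=None, rho_c=None, c=None, window=window,
                                  r2=r2, flagged=r2 < R2_GOOD)


def estimate_zc_pq(series: HemoTimeSeries) -> CharacteristicEstimate:
    """Characteristic impedance from the PQ-loop slope."""
    est = _loop_slope(series.P, series.Q)
    slope = _refit(series.P, series.Q, est.window)
    est.Zc = slope
    return est


def estimate_c_pu(series: HemoTimeSeries, rho: float) -> CharacteristicEstimate:
    """Local wave speed from the PU-loop slope (slope = rho*c)."""
    est = _loop_slope(series.P, series.U)
    slope = _refit(series.P, series.U, est.window)
    est.rho_c = slope
    est.c = slope / rho
    return est


def _refit(P, X, window):
    start, stop = window
    m = (stop - start) % P.size
    if m == 0:
        m = P.size
    slope, _ = np.polyfit(_cyc(X, start, m), _cyc(P, start, m), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# separation and indices
# ---------------------------------------------------------------------------

def separate_waves(series: HemoTimeSeries, Zc: float) -> WaveSeparation:
    """Linear wave separation applied to the raw signals (means retained)."""
    if Zc <= 0:
        raise ValueError("Zc must be > 0")
    P, Q = series.P, series.Q
    return WaveSeparation(
        P_f=0.5 * (P + Zc * Q), P_b=0.5 * (P - Zc * Q),
        Q_f=0.5 * (Q + P / Zc), Q_b=0.5 * (Q - P / Zc))


def vessel_reflection_indices(separations: list[WaveSeparation],
                              reference: HemoTimeSeries | None = None,
                              ) -> ReflectionIndices:
    """RM/RI for one vessel from the cell-mean forward/backward pulse pressures."""
    if not separations:
        raise ValueError("need at least one cell separation")
    ppf = float(np.mean([s.PP_f for s in separations]))
    ppb = float(np.mean([s.PP_b for s in separations]))
    if ppf <= 0:
        raise UndefinedIndexError("PP_f is zero: RM undefined")
    rm = ppb / ppf
    ri = rm / (1.0 + rm)
    pp = float(np.ptp(reference.P)) if reference is not None else ppf + ppb
    ap = ai = None
    flagged = False
    if reference is not None:
        try:
            ap, ai = augmentation_index(reference)
        except UndefinedIndexError:
            flagged = True
    return ReflectionIndices(PP=pp, PP_f=ppf, PP_b=ppb, RM=rm, RI=ri,
                             AP=ap, AI=ai, AI_flagged=flagged)


def _smooth_lowpass(y: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = 0.5 * fs
    if cutoff >= 0.95 * nyq:
        return y
    b, a = _signal.butter(4, cutoff / nyq)
    return _signal.filtfilt(b, a, y)


def augmentation_index(series: HemoTimeSeries, cutoff_hz: float = 25.0,
                       prominence_frac: float = 0.005) -> tuple[float, float]:
    """Augmentation pressure and index from the shoulder of the pressure wave.

    The inflection point is located on the low-pass-filtered dP/dt: a local
    minimum of dP/dt that is still positive before the systolic peak marks an
    early shoulder (AP > 0); a local maximum that is still negative on the
    early downslope marks a late shoulder (AP < 0).  A single-humped pulse
    has neither and is signalled as undefined rather than reported as 0.
    """
    P, t = series.P, series.t
    fs = 1.0 / series.dt
    p_s = _smooth_lowpass(P, fs, cutoff_hz)
    dp = np.gradient(p_s, t)
    foot, i_pk, rise = _foot_and_peak(p_s)
    n = P.size
    pp = float(np.ptp(p_s))
    prom = prominence_frac * float(np.max(np.abs(dp)))

    # systolic search ranges (cyclic): upstroke, then 30% of the beat after peak
    up_idx = [(foot + k) % n for k in range(1, rise)]
    down_len = min(int(0.30 * n), n - rise - 1)
    down_idx = [(i_pk + k) % n for k in range(1, down_len)]

    def local_min(idx):
        seg = dp[np.asarray(idx)]
        found, _ = _signal.find_peaks(-seg, prominence=prom)
        return idx[found[0]] if found.size else None

    def local_max(idx):
        seg = dp[np.asarray(idx)]
        found, _ = _signal.find_peaks(seg, prominence=prom)
        return idx[found[0]] if found.size else None

    j_early = local_min(up_idx)
    if j_early is not None:
        ap = float(p_s[i_pk] - p_s[j_early])
        return ap, ap / pp
    j_late = local_max(down_idx)
    if j_late is not None:
        ap = -float(p_s[i_pk] - p_s[j_late])
        return ap, ap / pp
    raise UndefinedIndexError("no inflection point found in systole")


# ---------------------------------------------------------------------------
# reflection coefficients
# ---------------------------------------------------------------------------

def _parallel(zs) -> float:
    return 1.0 / sum(1.0 / z for z in zs)


def rp_bifurcation(zc_parent: float, zc_daughters: list[float],
                   direction: str = "forward") -> ReflectionCoefficient:
    """Pressure reflection coefficient at a junction.

    forward: R_p = (Z_d - Z_p)/(Z_d + Z_p) with Z_d the parallel combination
    of the daughters.  backward (per daughter): the wave sees the parent in
    parallel with its sibling(s); the junction-level value is the mean of the
    per-daughter magnitudes.
    """
    if zc_parent <= 0 or any(z <= 0 for z in zc_daughters):
        raise ValueError("impedances must be > 0")
    if direction == "forward":
        zd = _parallel(zc_daughters)
        val = (zd - zc_parent) / (zd + zc_parent)
        return ReflectionCoefficient(
            "bifurcation_forward", float(val),
            {"Zc_p": zc_parent, "Zc_d": list(zc_daughters), "Zc_d_parallel": zd})
    if direction == "backward":
        per = []
        for i, zi in enumerate(zc_daughters):
            others = [z for k, z in enumerate(zc_daughters) if k != i]
            zeff = _parallel([zc_parent, *others])
            per.append((zeff - zi) / (zeff + zi))
        return ReflectionCoefficient(
            "bifurcation_backward", float(np.mean(np.abs(per))),
            {"Zc_p": zc_parent, "Zc_d": list(zc_daughters), "per_daughter": per})
    raise ValueError(f"unknown direction {direction!r}")


def rp_taper(zc_cells: list[float]) -> ReflectionCoefficient:
    """Cumulative (telescoped) taper reflection coefficient of one vessel."""
    z = np.asarray(zc_cells, dtype=float)
    if z.size < 2:
        raise ValueError("taper R_p needs >= 2 cells")
    val = float(np.sum((z[1:] - z[:-1]) / (z[1:] + z[:-1])))
    return ReflectionCoefficient("taper", val, {"Zc_cells": list(z)})


def rp_terminal(r_down: float, zc_out: float) -> ReflectionCoefficient:
    """Reflection coefficient of a terminal Windkessel load."""
    if zc_out <= 0:
        raise ValueError("Zc_out must be > 0")
    if r_down < 0:
        raise ValueError("R_down must be >= 0")
    val = (r_down - zc_out) / (r_down + zc_out)
    return ReflectionCoefficient("terminal", float(val),
                                 {"R_down": r_down, "Zc_out": zc_out})


# ---------------------------------------------------------------------------
# input impedance
# ---------------------------------------------------------------------------

def input_impedance(series: HemoTimeSeries, p_reference: float = 0.0,
                    n_harmonics: int = 12) -> ImpedanceSpectrum:
    """Z_in at harmonics of 1/RR from Fourier decomposition of P and Q.

    DC uses (mean P - p_reference) / mean Q; harmonics with negligible flow
    content are marked undefined.
    """
    n_harmonics = max(int(n_harmonics), 12)
    P = series.P[:-1]  # drop the duplicated periodic endpoint
    Q = series.Q[:-1]
    Ph = np.fft.rfft(P) / P.size
    Qh = np.fft.rfft(Q) / Q.size
    k = np.arange(n_harmonics + 1)
    f = k / series.RR
    z = np.full(k.size, np.nan, dtype=complex)
    defined = np.zeros(k.size, dtype=bool)
    q_scale = float(np.max(np.abs(Qh))) + 1e-300
    q_mean = float(np.mean(series.Q))
    if abs(q_mean) > 1e-12 * q_scale:
        z[0] = (float(np.mean(series.P)) - p_reference) / q_mean
        defined[0] = True
    for i in k[1:]:
        if i < Ph.size and abs(Qh[i]) > 1e-12 * q_scale:
            z[i] = Ph[i] / Qh[i]
            defined[i] = True
    return ImpedanceSpectrum(f=f, modulus=np.abs(z),
                             phase=np.angle(np.where(defined, z, 1.0)),
                             defined=defined)
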