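"""Wave intensity analysis and the aortic wave-trapping moving horizon.

Wave intensity carried by forward and backward wavefronts is

    WI_f,b = +- (1 / 4 rho c) (dP/dt +- rho c dU/dt)^2

so WI_f >= 0, WI_b <= 0, and WI_f + WI_b = (dP/dt)(dU/dt) pointwise.  Peaks
of WI mark discrete wavefront arrivals; a peak is a compression wave when
the corresponding separated-pressure derivative is positive (FCW/BCW) and a
decompression wave otherwise (FDW/BDW).

At each aortic site the elapsed time between the first forward compression
wave and the energy-weighted mean arrival of backward waves,

    t_back = int t WI_b dt / int WI_b dt,       ToR = t_back - t_FCW,

locates the apparent distal reflection point PoR = ToR * c_down / 2, with
c_down the mean wave speed over the aortic sites from the current one down
to the end of the aortic path.  The downstream drift of PoR along the aorta
is the moving-horizon signature of backward wave trapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import UndefinedIndexError
from .solver import BeatResult, HemoTimeSeries
from .waves import WaveSeparation, estimate_c_pu, estimate_zc_pq, separate_waves

__all__ = [
    "WaveIntensitySeries",
    "WavefrontPeak",
    "AorticSite",
    "compute_wi",
    "classify_wavefronts",
    "backward_arrival_time",
    "mean_downstream_speed",
    "aortic_sites",
    "reflection_horizon",
]

PEAK_PROMINENCE = 0.02  # default fraction of the global |WI| maximum


@dataclass
class WaveIntensitySeries:
    t: np.ndarray
    wi_f: np.ndarray          # >= 0
    wi_b: np.ndarray          # <= 0
    rho_c: float

    def __post_init__(self):
        if np.any(self.wi_f < -1e-30) or np.any(self.wi_b > 1e-30):
            raise ValueError("wave-intensity sign structure violated")


@dataclass
class WavefrontPeak:
    time: float
    magnitude: float          # |WI| at the peak
    direction: str            # forward | backward
    wtype: str                # compression | decompression

    @property
    def label(self) -> str:
        return {"forward": "F", "backward": "B"}[self.direction] + \
            {"compression": "CW", "decompression": "DW"}[self.wtype]


def compute_wi(series: HemoTimeSeries, rho: float, c: float) -> WaveIntensitySeries:
    """Forward/backward wave intensity with centred time differences."""
    if c <= 0:
        raise ValueError("wave speed must be > 0")
    t = series.t
    dP = np.gradient(series.P, t)
    dU = np.gradient(series.U, t)
    rc = rho * c
    wi_f = (dP + rc * dU) ** 2 / (4.0 * rc)
    wi_b = -((dP - rc * dU) ** 2) / (4.0 * rc)
    return WaveIntensitySeries(t=t, wi_f=wi_f, wi_b=wi_b, rho_c=rc)


def classify_wavefronts(wi: WaveIntensitySeries, separation: WaveSeparation,
                        prominence_frac: float = PEAK_PROMINENCE,
                        ) -> list[WavefrontPeak]:
    """Detect and label WI peaks as F/B compression/decompression waves."""
    if not 0.0 < prominence_frac < 1.0:
        raise ValueError("prominence fraction must lie in (0, 1)")
    t = wi.t
    scale = max(float(np.max(wi.wi_f)), float(np.max(-wi.wi_b)))
    if scale <= 0:
        return []
    prom = prominence_frac * scale
    dpf = np.gradient(separation.P_f, t)
    dpb = np.gradient(separation.P_b, t)
    peaks: list[WavefrontPeak] = []
    for y, direction, dp in ((wi.wi_f, "forward", dpf), (-wi.wi_b, "backward", dpb)):
        idx, _ = _signal.find_peaks(y, prominence=prom)
        for i in idx:
            wtype = "compression" if dp[i] > 0 else "decompression"
            peaks.append(WavefrontPeak(time=float(t[i]), magnitude=float(y[i]),
                                       direction=direction, wtype=wtype))
    peaks.sort(key=lambda p: p.time)
    return peaks


def backward_arrival_time(wi: WaveIntensitySeries) -> float:
    """Energy-weighted mean arrival time of backward waves over the beat."""
    denom = float(np.trapezoid(wi.wi_b, wi.t))
    scale = float(np.trapezoid(wi.wi_f, wi.t))
    if abs(denom) <= 1e-12 * max(scale, 1e-300):
        raise UndefinedIndexError("WI_b vanishes: no backward wave visible")
    num = float(np.trapezoid(wi.t * wi.wi_b, wi.t))
    return num / denom


def first_fcw_time(wi: WaveIntensitySeries, separation: WaveSeparation,
                   prominence_frac: float = PEAK_PROMINENCE) -> float:
    """Arrival time of the first forward compression wave (first FCW WI peak)."""
    for p in classify_wavefronts(wi, separation, prominence_frac):
        if p.direction == "forward" and p.wtype == "compression":
            return p.time
    raise UndefinedIndexError("no forward compression wave detected")


def mean_downstream_speed(c_path: list[float], site_index: int,
                          inclusive: bool = True) -> float:
    """Mean wave speed over the aortic sites downstream of a site.

    ``inclusive`` (default) averages from the current site to the end of the
    path, which makes the last site's value equal its local wave speed; the
    exclusive variant averages strictly downstream sites, falling back to
    the local speed at the last site.
    """
    c = np.asarray(c_path, dtype=float)
    if not 0 <= site_index < c.size:
        raise IndexError("site index outside the aortic path")
    if inclusive:
        return float(np.mean(c[site_index:]))
    if site_index + 1 >= c.size:
        return float(c[-1])
    return float(np.mean(c[site_index + 1:]))


@dataclass
class AorticSite:
    """One analysis site along the aortic path."""

    site_id: int
    distance: float           # centreline distance from the root inlet (m)
    series: HemoTimeSeries
    c: float                  # site wave speed (PU-loop, vessel mean)


def aortic_sites(result: BeatResult, network, rho: float,
                 per: str = "vessel") -> list[AorticSite]:
    """Assemble the aortic-path analysis sites from a converged beat.

    per="vessel": one site per aortic-path vessel at its middle cell, with
    the vessel-mean PU-loop wave speed (the reported per-vessel convention);
    per="cell": one site per cell with its local speed (fixture studies).
    """
    sites = []
    for vid in network.aortic_path:
        v = network.vessels[vid]
        cells = result.vessel(vid)
        cs = [estimate_c_pu(s, rho).c for s in cells]
        if per == "vessel":
            mid = v.n_cells // 2
            s = cells[mid]
            sites.append(AorticSite(vid, network.path_distance(vid, s.x), s,
                                    float(np.mean(cs))))
        elif per == "cell":
            for s, c in zip(cells, cs):
                sites.append(AorticSite(vid, network.path_distance(vid, s.x),
                                        s, float(c)))
        else:
            raise ValueError("per must be 'vessel' or 'cell'")
    return sites


def reflection_horizon(sites: list[AorticSite], rho: float,
                       prominence_frac: float = PEAK_PROMINENCE,
                       inclusive: bool = True):
    """ToR/PoR moving-horizon table along the aortic path.

    Returns (DataFrame, points) where the frame has one row per usable site
    with columns site_id, distance_m, t_fcw_s, t_back_s, tor_s, c_down_m_s,
    por_m, and ``points`` holds the (distance, arrival-time) sets of the
    first FCW and of the mean backward arrival used for the regression-line
    comparison between postures.  Sites with no visible backward energy are
    excluded with a notice.
    """
    import logging

    rows = []
    fcw_pts, bcw_pts = [], []
    c_path = [s.c for s in sites]
    for i, site in enumerate(sites):
        zc = estimate_zc_pq(site.series).Zc
        sep = separate_waves(site.series, zc)
        wi = compute_wi(site.series, rho, site.c)
        try:
            t_back = backward_arrival_time(wi)
            t_fcw = first_fcw_time(wi, sep, prominence_frac)
        except UndefinedIndexError as err:
            logging.getLogger(__name__).info(
                "site %s excluded from trapping analysis: %s", site.site_id, err)
            continue
        tor = t_back - t_fcw
        c_down = mean_downstream_speed(c_path, i, inclusive=inclusive)
        rows.append({
            "site_id": site.site_id, "distance_m": site.distance,
            "t_fcw_s": t_fcw, "t_back_s": t_back, "tor_s": tor,
            "c_down_m_s": c_down, "por_m": tor * c_down / 2.0,
        })
        fcw_pts.append((site.distance, t_fcw))
        bcw_pts.append((site.distance, t_back))
    frame = pd.DataFrame(rows)
    return frame, {"fcw": fcw_pts, "bcw": bcw_pts}
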