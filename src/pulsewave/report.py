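"""Study-level reports built on the analysis primitives.

These functions turn a converged beat (supine or standing) into the tables
the study reads off: per-vessel wave speed / pulse pressures / reflection
indices, the reflection-coefficient family at bifurcations, tapers and
terminals, and the paired supine-vs-standing comparison with Wilcoxon
p-values over vessel segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError
from .network import NetworkTopology
from .solver import BeatResult
from .stats import percent_change, wilcoxon_signed_rank
from .units import pa_to_mmhg
from .waves import (estimate_c_pu, estimate_zc_pq, rp_bifurcation, rp_taper,
                    rp_terminal, separate_waves, vessel_reflection_indices)

__all__ = [
    "vessel_wave_report",
    "reflection_coefficient_report",
    "posture_comparison_report",
    "vessel_cell_speeds",
]


def vessel_cell_speeds(result: BeatResult, vid: int, rho: float) -> np.ndarray:
    """Per-cell PU-loop wave speeds of one vessel (m/s)."""
    return np.array([estimate_c_pu(s, rho).c for s in result.vessel(vid)])


def _vessel_row(result: BeatResult, network: NetworkTopology, vid: int,
                rho: float) -> dict:
    v = network.vessels[vid]
    cells = result.vessel(vid)
    zc = [estimate_zc_pq(s).Zc for s in cells]
    c = vessel_cell_speeds(result, vid, rho)
    seps = [separate_waves(s, z) for s, z in zip(cells, zc)]
    mid = v.n_cells // 2
    idx = vessel_reflection_indices(seps, reference=cells[mid])
    return {
        "vessel_id": vid,
        "name": v.name,
        "group": v.group,
        "c_m_s": float(np.mean(c)),
        "c_sd_m_s": float(np.std(c, ddof=1)) if len(c) > 1 else 0.0,
        "Zc": float(zc[mid]),
        "PPf_mmHg": pa_to_mmhg(idx.PP_f),
        "PPb_mmHg": pa_to_mmhg(idx.PP_b),
        "PP_mmHg": pa_to_mmhg(idx.PP),
        "RM": idx.RM,
        "RI": idx.RI,
        "AI": idx.AI if idx.AI is not None else np.nan,
        "Rp_taper": rp_taper(zc).value if len(zc) >= 2 else np.nan,
    }


def vessel_wave_report(result: BeatResult, network: NetworkTopology,
                       rho: float) -> pd.DataFrame:
    """One row of wave-analysis metrics per vessel."""
    rows = [_vessel_row(result, network, vid, rho)
            for vid in sorted(network.vessels)]
    return pd.DataFrame(rows)


def reflection_coefficient_report(result: BeatResult, network: NetworkTopology,
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """R_p at junctions (forward/backward) and at terminal branches.

    Impedances are PQ-loop estimates at the parent distal cell and daughter
    proximal cells; terminal R_down comes from the network parameters and
    Z_c,out from the outlet-cell loop estimate.
    """
    bif_rows = []
    for j in network.junctions:
        zc_p = estimate_zc_pq(
            result.node(j.parent, network.vessels[j.parent].n_cells - 1)).Zc
        zc_d = [estimate_zc_pq(result.node(d, 0)).Zc for d in j.daughters]
        fwd = rp_bifurcation(zc_p, zc_d, "forward")
        bwd = rp_bifurcation(zc_p, zc_d, "backward")
        bif_rows.append({
            "parent_id": j.parent,
            "n_daughters": len(j.daughters),
            "is_bifurcation": j.is_bifurcation,
            "rp_forward": fwd.value,
            "rp_backward": bwd.value,
        })
    term_rows = []
    for vid, term in sorted(network.terminals.items()):
        zc_out = estimate_zc_pq(
            result.node(vid, network.vessels[vid].n_cells - 1)).Zc
        term_rows.append({
            "vessel_id": vid,
            "group": network.vessels[vid].group,
            "R_down": term.R_down,
            "Zc_out": zc_out,
            "rp_terminal": rp_terminal(term.R_down, zc_out).value,
        })
    return pd.DataFrame(bif_rows), pd.DataFrame(term_rows)


def posture_comparison_report(supine: BeatResult, standing: BeatResult,
                              network_supine: NetworkTopology,
                              network_standing: NetworkTopology,
                              rho: float) -> pd.DataFrame:
    """Paired per-vessel supine/standing comparison.

    Wave speed is compared cell-by-cell with the exact Wilcoxon signed-rank
    test (n = number of cells of the vessel); RM/PPf/PPb are single
    per-vessel values compared by percent change only.
    """
    rep_sup = vessel_wave_report(supine, network_supine, rho).set_index("vessel_id")
    rep_std = vessel_wave_report(standing, network_standing, rho).set_index("vessel_id")
    rows = []
    for vid in rep_sup.index:
        c_sup = vessel_cell_speeds(supine, vid, rho)
        c_std = vessel_cell_speeds(standing, vid, rho)
        try:
            comp = wilcoxon_signed_rank(c_sup, c_std)
            p, n = comp.p, comp.n
        except UndefinedIndexError:
            p, n = np.nan, len(c_sup)
        rows.append({"vessel_id": vid, "name": rep_sup.loc[vid, "name"],
                     "metric": "c_m_s",
                     "supine": rep_sup.loc[vid, "c_m_s"],
                     "standing": rep_std.loc[vid, "c_m_s"],
                     "delta_pct": percent_change(rep_sup.loc[vid, "c_m_s"],
                                                 rep_std.loc[vid, "c_m_s"]),
                     "p_value": p, "n": n})
        for metric in ("PPf_mmHg", "PPb_mmHg", "RM"):
            a, b = rep_sup.loc[vid, metric], rep_std.loc[vid, metric]
            rows.append({"vessel_id": vid, "name": rep_sup.loc[vid, "name"],
                         "metric": metric, "supine": a, "standing": b,
                         "delta_pct": percent_change(a, b),
                         "p_value": np.nan, "n": 1})
    return pd.DataFrame(rows)
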