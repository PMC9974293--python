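"""File I/O: network descriptions, waveform tables, run manifests.

Network files are JSON (canonical) or YAML with top-level keys ``config``,
``vessels``, ``junctions``, ``terminals``, ``root``, ``aortic_path`` and
field names matching the in-memory types.  File units are clinical
(mmHg / cm / ml); everything is converted to SI on load.

Waveforms are written one CSV per node with header
``t_s,P_mmHg,Q_ml_s,A_cm2,U_cm_s`` plus a JSON sidecar carrying the node
location and beat metadata.  Externally supplied tables may omit the area
column, restricting analysis to PQ-based operations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .network import (InflowSource, Junction, NetworkTopology,
                      TerminalWindkessel, VesselSegment1D)
from .solver import BeatResult, ConvergenceReport, HemoTimeSeries
from .units import CM2_M2, CM_M, MMHG_PA, mmhg_to_pa, pa_to_mmhg

__all__ = [
    "read_network", "write_network", "network_from_document",
    "network_to_document", "read_inflow", "write_inflow",
    "write_waveforms", "read_waveforms", "write_manifest", "read_manifest",
]

FLOAT_FMT = "%.12g"

# file-unit -> SI multipliers per field
_VESSEL_SCALE = {"length": CM_M, "A0_prox": CM2_M2, "A0_dist": CM2_M2,
                 "beta": MMHG_PA * CM_M, "gamma": MMHG_PA * CM_M,
                 "z_prox": CM_M}
_TERMINAL_SCALE = {"R1": MMHG_PA / 1e-6, "R2": MMHG_PA / 1e-6,
                   "C": 1e-6 / MMHG_PA, "P_out": MMHG_PA}

_VESSEL_REQUIRED = ("id", "name", "length", "A0_prox", "A0_dist", "beta",
                    "n_cells")
_VESSEL_OPTIONAL = ("gamma", "phi", "z_prox", "group")
_TERMINAL_REQUIRED = ("R1", "R2", "C", "P_out")


def _check_keys(entry: dict, required, optional, what: str):
    for key in required:
        if key not in entry:
            raise ConfigurationError(f"{what}: missing required key {key!r}")
    unknown = set(entry) - set(required) - set(optional)
    if unknown:
        warnings.warn(f"{what}: unknown key(s) {sorted(unknown)} ignored",
                      stacklevel=3)


def network_from_document(doc: dict) -> NetworkTopology:
    """Validate a parsed network description (file units) into SI types."""
    for key in ("vessels", "terminals", "root"):
        if key not in doc:
            raise ConfigurationError(f"network document: missing key {key!r}")
    vessels = {}
    for entry in doc["vessels"]:
        _check_keys(entry, _VESSEL_REQUIRED, _VESSEL_OPTIONAL,
                    f"vessel {entry.get('id', '?')}")
        kw = {k: entry[k] for k in _VESSEL_REQUIRED + _VESSEL_OPTIONAL
              if k in entry}
        for k, s in _VESSEL_SCALE.items():
            if kw.get(k) is not None:
                kw[k] = kw[k] * s
        v = VesselSegment1D(**kw)
        if v.id in vessels:
            raise ConfigurationError(f"duplicate vessel id {v.id}")
        vessels[v.id] = v
    junctions = []
    for entry in doc.get("junctions", []):
        if isinstance(entry, dict):
            junctions.append(Junction(int(entry["parent"]),
                                      [int(d) for d in entry["daughters"]]))
        else:
            parent, daughters = entry
            junctions.append(Junction(int(parent), [int(d) for d in daughters]))
    terminals = {}
    for vid_str, entry in doc["terminals"].items():
        _check_keys(entry, _TERMINAL_REQUIRED, (), f"terminal {vid_str}")
        kw = {k: entry[k] * _TERMINAL_SCALE[k] for k in _TERMINAL_REQUIRED}
        terminals[int(vid_str)] = TerminalWindkessel(**kw)
    return NetworkTopology(vessels=vessels, junctions=junctions,
                           terminals=terminals, root=int(doc["root"]),
                           aortic_path=[int(v) for v in doc.get("aortic_path", [])])


def network_to_document(network: NetworkTopology) -> dict:
    """Serialize a network back to the file-unit document form."""
    vessels = []
    for vid in sorted(network.vessels):
        v = network.vessels[vid]
        entry = dataclasses.asdict(v)
        for k, s in _VESSEL_SCALE.items():
            if entry.get(k) is not None:
                entry[k] = entry[k] / s
        vessels.append(entry)
    terminals = {}
    for vid in sorted(network.terminals):
        t = network.terminals[vid]
        terminals[str(vid)] = {k: getattr(t, k) / _TERMINAL_SCALE[k]
                               for k in _TERMINAL_REQUIRED}
    return {
        "vessels": vessels,
        "junctions": [{"parent": j.parent, "daughters": list(j.daughters)}
                      for j in network.junctions],
        "terminals": terminals,
        "root": network.root,
        "aortic_path": list(network.aortic_path),
    }


def read_network(path) -> NetworkTopology:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    return network_from_document(doc)


def write_network(network: NetworkTopology, path) -> None:
    path = Path(path)
    doc = network_to_document(network)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# inflow tables
# ---------------------------------------------------------------------------

def read_inflow(path) -> InflowSource:
    """CSV with header t_s,Q_ml_s spanning exactly one beat."""
    frame = pd.read_csv(path)
    for col in ("t_s", "Q_ml_s"):
        if col not in frame.columns:
            raise ConfigurationError(f"inflow table: missing column {col!r}")
    t = frame["t_s"].to_numpy(dtype=float)
    return InflowSource(RR=float(t[-1]), t=t,
                        Q=frame["Q_ml_s"].to_numpy(dtype=float) * 1e-6)


def write_inflow(inflow: InflowSource, path) -> None:
    pd.DataFrame({"t_s": inflow.t, "Q_ml_s": inflow.Q / 1e-6}).to_csv(
        path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# waveform directories
# ---------------------------------------------------------------------------

def _node_stem(vid: int, cell: int) -> str:
    return f"node_{vid:03d}_{cell:02d}"


def write_waveforms(result: BeatResult, outdir,
                    network: NetworkTopology | None = None) -> None:
    """Write one CSV + JSON sidecar per node, plus beat metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (vid, cell), s in sorted(result.series.items()):
        stem = outdir / _node_stem(vid, cell)
        cols = {"t_s": s.t, "P_mmHg": pa_to_mmhg(s.P), "Q_ml_s": s.Q / 1e-6}
        if s.A is not None:
            cols["A_cm2"] = s.A / CM2_M2
            cols["U_cm_s"] = s.U / CM_M
        pd.DataFrame(cols).to_csv(stem.with_suffix(".csv"), index=False,
                                  float_format=FLOAT_FMT)
        stem.with_suffix(".json").write_text(json.dumps(
            {"vessel_id": vid, "cell_index": cell, "x_m": s.x,
             "elevation_m": s.elevation, "RR_s": s.RR}, sort_keys=True))
    meta = {"RR_s": result.RR, "tilt_deg": result.tilt}
    if result.report is not None:
        meta["converged"] = bool(result.report.converged)
        meta["beats_run"] = int(result.report.beats_run)
        meta["tol"] = float(result.report.tol)
        meta["changes"] = [float(c) for c in result.report.changes]
    (outdir / "beat.json").write_text(json.dumps(meta, sort_keys=True))
    if network is not None:
        write_network(network, outdir / "network.json")


def read_waveforms(wavedir) -> BeatResult:
    """Read a waveform directory back into a BeatResult."""
    wavedir = Path(wavedir)
    meta_path = wavedir / "beat.json"
    if not meta_path.exists():
        raise ConfigurationError(f"{wavedir}: missing beat.json sidecar")
    meta = json.loads(meta_path.read_text())
    series = {}
    for csv_path in sorted(wavedir.glob("node_*.csv")):
        sidecar = csv_path.with_suffix(".json")
        if not sidecar.exists():
            raise ConfigurationError(f"{csv_path.name}: missing JSON sidecar")
        loc = json.loads(sidecar.read_text())
        frame = pd.read_csv(csv_path)
        for col in ("t_s", "P_mmHg", "Q_ml_s"):
            if col not in frame.columns:
                raise ConfigurationError(
                    f"{csv_path.name}: missing column {col!r}")
        t = frame["t_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or np.any(dt <= 0) or not np.allclose(
                dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ConfigurationError(
                f"{csv_path.name}: time grid must be uniform and increasing")
        A = frame["A_cm2"].to_numpy(dtype=float) * CM2_M2 \
            if "A_cm2" in frame.columns else None
        series[(loc["vessel_id"], loc["cell_index"])] = HemoTimeSeries(
            vessel_id=loc["vessel_id"], cell_index=loc["cell_index"],
            x=loc["x_m"], elevation=loc["elevation_m"], t=t,
            P=mmhg_to_pa(frame["P_mmHg"].to_numpy(dtype=float)),
            Q=frame["Q_ml_s"].to_numpy(dtype=float) * 1e-6,
            A=A, RR=loc["RR_s"])
    if not series:
        raise ConfigurationError(f"{wavedir}: no node CSVs found")
    report = None
    if "converged" in meta:
        report = ConvergenceReport(beats_run=meta["beats_run"],
                                   changes=meta["changes"],
                                   converged=meta["converged"],
                                   tol=meta["tol"])
    return BeatResult(series=series, report=report, RR=meta["RR_s"],
                      tilt=meta["tilt_deg"])


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir, inputs: dict, config: dict, seed: int | None = None,
                   ) -> dict:
    """Record input hashes, config snapshot, version, seed and timestamp."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "inputs": {str(p): _sha256(Path(p)) for p in inputs.values()
                   if p is not None and Path(p).exists()},
        "input_names": {k: str(v) for k, v in inputs.items() if v is not None},
        "config": config,
        "version": __version__,
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest


def read_manifest(outdir) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())
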