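"""Serialization: waveform CSV, network JSON, detection reports.

Formats are plain text.  Waveforms are CSV with ``#``-prefixed header lines
carrying metadata; networks are JSON documents in human-scale units (cm, mm,
kPa) that are converted to SI once, at parse time; reports are JSON with
sorted keys so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .geometry import AneurysmProfile, FluidProperties, VesselSegment
from .solver import InletBC, Monitor, Network, TerminalBC
from .waves import Waveform

__all__ = [
    "IOError_",
    "read_waveform",
    "write_waveform",
    "network_to_config",
    "validate_network",
    "load_network",
    "save_network",
    "write_report",
]


class IOError_(ValueError):
    """Raised for malformed waveform or network files."""


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------

_REQUIRED_HEADER = ("quantity", "units", "dt")


def write_waveform(w: Waveform, path) -> None:
    """Write a waveform as CSV with ``# key=value`` metadata headers."""
    path = Path(path)
    lines = [
        f"# site={w.site}",
        f"# quantity={w.quantity}",
        f"# units={w.units}",
        f"# dt={w.dt!r}",
        f"# t0={w.t_start!r}",
    ]
    if w.pulse_start is not None:
        lines.append(f"# pulse_start={w.pulse_start!r}")
    lines.append("t_s,value")
    t = w.times
    # repr gives the shortest digit string that round-trips the float exactly
    lines += [f"{ti:.9g},{float(vi)!r}" for ti, vi in zip(t, w.values)]
    path.write_text("\n".join(lines) + "\n")


def read_waveform(path) -> Waveform:
    """Read a waveform CSV; lossless round trip with :func:`write_waveform`.

    Raises with the offending line number for malformed rows and names the
    missing key for incomplete headers; non-uniform time stamps are rejected.
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.lower().startswith("t_s"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise IOError_(f"{path}:{ln}: expected 't,value', got {line!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise IOError_(f"{path}:{ln}: {exc}")
    for key in _REQUIRED_HEADER:
        if key not in meta:
            raise IOError_(f"{path}: missing required header '# {key}='")
    if len(rows) < 2:
        raise IOError_(f"{path}: needs at least two samples")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    dt = float(meta["dt"])
    steps = np.diff(t)
    if np.any(np.abs(steps - dt) > 1e-6 * dt + 1e-12):
        bad = int(np.argmax(np.abs(steps - dt))) + 2
        raise IOError_(f"{path}: non-uniform sampling near data row {bad}")
    pulse_start = float(meta["pulse_start"]) if "pulse_start" in meta else None
    return Waveform(v, dt, t_start=float(meta.get("t0", t[0])),
                    quantity=meta["quantity"], units=meta["units"],
                    site=meta.get("site", ""), pulse_start=pulse_start)


# ---------------------------------------------------------------------------
# network JSON
# ---------------------------------------------------------------------------

def _segment_to_json(s: VesselSegment) -> dict:
    d = {
        "name": s.name,
        "length_cm": s.length * 100.0,
        "d1_mm": s.radius_in * 2000.0,
        "d2_mm": s.radius_out * 2000.0,
        "E_kPa": s.youngs_modulus / 1e3,
        "poisson": s.poisson,
    }
    if s.wall_thickness == "adan":
        d["h_mm"] = "adan_law"
    elif callable(s.wall_thickness):
        raise IOError_(f"segment {s.name}: callable thickness is not serializable")
    else:
        d["h_mm"] = float(s.wall_thickness) * 1000.0
    if s.external_pressure:
        d["p_ext_kPa"] = s.external_pressure / 1e3
    if s.dx_hint:
        d["dx_hint_cm"] = s.dx_hint * 100.0
    if s.aneurysm is not None:
        a = s.aneurysm
        aj = {"kind": a.kind, "x1_cm": a.x1 * 100.0, "L_A_cm": a.length * 100.0}
        if a.kind == "arc":
            aj["D_mm"] = a.peak_diameter * 1000.0
            aj["R_s_mm"] = a.conjugation_radius * 1000.0
        else:
            aj["k_delta"] = a.k_delta
        d["aneurysm"] = aj
    return d


def network_to_config(net: Network, inlet_series_file: str = "inlet.csv") -> dict:
    """Network object -> JSON-serializable config (human-scale units)."""
    cfg = {
        "fluid": {"rho_kg_m3": net.fluid.density, "mu_Pa_s": net.fluid.viscosity},
        "segments": [_segment_to_json(s) for s in net.segments],
        "junctions": [[f"{n}:{e}" for n, e in j] for j in net.junctions],
        "inlet": {"segment": net.inlet[0], "end": net.inlet[1],
                  "quantity": net.inlet[2].quantity,
                  "series_file": inlet_series_file},
        "terminals": [
            {"segment": n, "end": e, "kind": t.kind,
             **({"R1_Pa_s_m3": t.R1, "R2_Pa_s_m3": t.R2, "C_m3_Pa": t.C,
                 "p_out_Pa": t.p_out} if t.kind == "windkessel" else {})}
            for n, e, t in net.terminals],
        "monitors": [{"segment": m.segment, "s": m.s} for m in net.monitors],
    }
    return cfg


def _parse_segment(d: dict, errors: list) -> Optional[VesselSegment]:
    name = d.get("name", "<unnamed>")
    try:
        for key in ("length_cm", "d1_mm", "d2_mm", "E_kPa"):
            if key not in d:
                errors.append(f"segment {name}: missing field {key!r}")
                return None
        h = d.get("h_mm", "adan_law")
        thickness = "adan" if h == "adan_law" else float(h) * 1e-3
        aneurysm = None
        if "aneurysm" in d and d["aneurysm"] is not None:
            a = d["aneurysm"]
            kind = a.get("kind")
            if kind == "arc":
                aneurysm = AneurysmProfile(
                    "arc", x1=a["x1_cm"] * 1e-2, length=a["L_A_cm"] * 1e-2,
                    peak_diameter=a["D_mm"] * 1e-3,
                    conjugation_radius=a["R_s_mm"] * 1e-3)
            elif kind == "cosine":
                aneurysm = AneurysmProfile(
                    "cosine", x1=a["x1_cm"] * 1e-2, length=a["L_A_cm"] * 1e-2,
                    k_delta=a["k_delta"])
            else:
                errors.append(f"segment {name}: unknown aneurysm kind {kind!r}")
        return VesselSegment(
            name=name,
            length=d["length_cm"] * 1e-2,
            radius_in=d["d1_mm"] * 0.5e-3,
            radius_out=d["d2_mm"] * 0.5e-3,
            wall_thickness=thickness,
            youngs_modulus=d["E_kPa"] * 1e3,
            poisson=d.get("poisson", 0.5),
            external_pressure=d.get("p_ext_kPa", 0.0) * 1e3,
            aneurysm=aneurysm,
            dx_hint=d["dx_hint_cm"] * 1e-2 if "dx_hint_cm" in d else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"segment {name}: {exc}")
        return None


def validate_network(config: dict, inlet_series: Optional[Waveform] = None
                     ) -> tuple[Optional[Network], list]:
    """Build a Network from a JSON config, aggregating all errors.

    Returns ``(network, errors)``; ``network`` is None when errors exist.
    ``inlet_series`` supplies the inlet waveform when the config references an
    external series file that the caller has already loaded.
    """
    errors: list = []
    if not isinstance(config, dict):
        return None, ["config root must be a JSON object"]
    segs = []
    for d in config.get("segments", []):
        s = _parse_segment(d, errors)
        if s is not None:
            segs.append(s)
    if not segs:
        errors.append("no valid segments")
    names = {s.name for s in segs}

    junctions = []
    for j, junc in enumerate(config.get("junctions", [])):
        ends = []
        for ref in junc:
            try:
                n, e = ref.split(":")
            except (ValueError, AttributeError):
                errors.append(f"junction {j}: bad end reference {ref!r}")
                continue
            if n not in names:
                errors.append(f"junction {j}: unknown segment {n!r}")
                continue
            if e not in ("start", "end"):
                errors.append(f"junction {j}: bad end {e!r}")
                continue
            ends.append((n, e))
        junctions.append(ends)

    inlet = None
    icfg = config.get("inlet")
    if not icfg:
        errors.append("missing inlet")
    else:
        if icfg.get("segment") not in names:
            errors.append(f"inlet references unknown segment {icfg.get('segment')!r}")
        if inlet_series is None:
            errors.append("inlet series not supplied")
        else:
            inlet = (icfg.get("segment"), icfg.get("end", "start"),
                     InletBC.from_waveform(inlet_series,
                                           icfg.get("quantity", "velocity")))

    terminals = []
    for tcfg in config.get("terminals", []):
        n = tcfg.get("segment")
        if n not in names:
            errors.append(f"terminal references unknown segment {n!r}")
            continue
        try:
            if tcfg.get("kind", "nonreflecting") == "windkessel":
                term = TerminalBC("windkessel", R1=tcfg["R1_Pa_s_m3"],
                                  R2=tcfg.get("R2_Pa_s_m3", 0.0),
                                  C=tcfg.get("C_m3_Pa", 0.0),
                                  p_out=tcfg.get("p_out_Pa", 0.0))
            else:
                term = TerminalBC("nonreflecting")
            terminals.append((n, tcfg.get("end", "end"), term))
        except (KeyError, ValueError) as exc:
            errors.append(f"terminal {n}: {exc}")

    monitors = []
    for mcfg in config.get("monitors", []):
        if mcfg.get("segment") not in names:
            errors.append(f"monitor references unknown segment {mcfg.get('segment')!r}")
            continue
        try:
            monitors.append(Monitor(mcfg["segment"], mcfg["s"]))
        except (KeyError, ValueError) as exc:
            errors.append(f"monitor: {exc}")

    fcfg = config.get("fluid", {})
    fluid = FluidProperties(fcfg.get("rho_kg_m3", 1000.0),
                            fcfg.get("mu_Pa_s", 1.0e-3))
    if errors:
        return None, errors
    try:
        net = Network(segments=segs, junctions=junctions, inlet=inlet,
                      terminals=terminals, fluid=fluid, monitors=monitors)
    except Exception as exc:
        return None, [str(exc)]
    return net, []


def load_network(path) -> Network:
    """Read a network JSON (resolving the inlet series file) or raise."""
    path = Path(path)
    config = json.loads(path.read_text())
    series = None
    icfg = config.get("inlet") or {}
    if "series_file" in icfg:
        series = read_waveform(path.parent / icfg["series_file"])
    net, errors = validate_network(config, series)
    if errors:
        raise IOError_(f"{path}: " + "; ".join(errors))
    return net


def save_network(net: Network, directory, inlet_series_file: str = "inlet.csv"
                 ) -> Path:
    """Write ``network.json`` + the inlet series CSV into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bc = net.inlet[2]
    w = Waveform(bc.values, float(bc.times[1] - bc.times[0]),
                 t_start=float(bc.times[0]), quantity=bc.quantity,
                 units={"velocity": "m/s", "pressure": "Pa",
                        "flow": "m3/s"}[bc.quantity], site="inlet")
    write_waveform(w, directory / inlet_series_file)
    cfg = network_to_config(net, inlet_series_file)
    out = directory / "network.json"
    out.write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")
    return out


def write_report(report: dict, path) -> None:
    """Deterministic JSON report (sorted keys, version stamped)."""
    report = dict(report)
    report.setdefault("version", __version__)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True,
                                     default=float) + "\n")
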