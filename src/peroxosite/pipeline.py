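"""Orchestration of the analysis stages, with provenance-stamped outputs.

Every output file embeds the fully serialized run configuration and the
package version, so a report is always traceable to the thresholds and
inputs that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    TorsionSpec,
    circular_density_1d,
    cluster_label_array,
    cluster_torsions_2d,
    density_modes,
    per_frame_table,
    residence_trace,
    state_coupling,
    torsion_series,
    water_site_coordinates,
)
from .interactions import active_site_report
from .structure_io import StructureModel, read_ensemble, read_structure

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_structure_analysis",
    "run_ensemble_analysis",
    "deuteration_level",
]


@dataclass
class RunConfig:
    """Everything a run needs; serialized verbatim into every output."""

    input_path: str = ""
    output_dir: str = "peroxosite_out"
    roles: dict = field(default_factory=dict)  # active-site role map
    hbond_criteria: dict = field(default_factory=dict)
    pi_thresholds: dict = field(default_factory=dict)
    residence_threshold: float = 4.0  # Å
    altloc_policy: str = "per-altloc"
    seed: int = 0
    grid_step_1d: float = 1.0
    grid_step_2d: float = 2.0
    concentration_1d: float | None = None
    concentration_2d: float | None = None
    density_floor: float = 0.05
    verbosity: str = "INFO"

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["software"] = f"peroxosite {__version__}"
        return d


def _stamp(payload: dict, config: RunConfig) -> dict:
    return {"config": config.as_dict(), **payload}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_structure_analysis(config: RunConfig,
                           model: StructureModel | None = None) -> dict:
    """Active-site geometry report for a single structure.

    Reads the structure (unless one is passed in), evaluates every role in
    ``config.roles`` (distances, torsions, pi contacts, plane tilts, H-bond
    scope) and writes ``active_site_report.json`` plus a flat
    ``active_site_distances.csv`` into the output directory.
    """
    if model is None:
        model = read_structure(config.input_path)
    site_cfg = dict(config.roles)
    if config.hbond_criteria:
        site_cfg["hbond_criteria"] = config.hbond_criteria
    if config.pi_thresholds:
        site_cfg["pi_thresholds"] = config.pi_thresholds
    report = active_site_report(model, site_cfg)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = _stamp({"report": report.as_dict(),
                      "composition": model.summary()}, config)
    _write_json(outdir / "active_site_report.json", payload)
    rows = []
    for label, per_alt in report.distances.items():
        for tag, val in per_alt.items():
            rows.append(("distance", label, tag, val))
    for label, per_alt in report.torsions.items():
        for tag, val in per_alt.items():
            rows.append(("torsion", label, tag, val))
    for label, val in report.plane_tilts.items():
        rows.append(("plane_tilt", label, "", val))
    for label, c in report.pi_contacts.items():
        rows.append(("pi_d_xm", label, "", c.d_xm))
        rows.append(("pi_omega", label, "", c.omega))
        rows.append(("pi_angle_xhm", label, "", c.angle_xhm))
    pd.DataFrame(rows, columns=["kind", "label", "altloc", "value"]).to_csv(
        outdir / "active_site_distances.csv", index=False
    )
    log.info("structure report: %d distances, %d torsions, %d pi contacts",
             len(report.distances), len(report.torsions),
             len(report.pi_contacts))
    return payload


def run_ensemble_analysis(config: RunConfig,
                          ensemble: StructureModel | None = None) -> dict:
    """Torsion/cluster/residence analysis of an ensemble.

    ``config.roles`` must provide ``torsions`` (list of
    ``[label, role x 4]`` specs); optionally ``cluster_pair`` (two torsion
    labels to cluster on the torus) and ``water`` (roles C4, C5, O, H1, H2).
    Writes the per-frame table, 1D density grids, and a summary JSON;
    deterministic given the config.
    """
    if ensemble is None:
        ensemble = read_ensemble(config.input_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_frames": ensemble.n_frames}
    if ensemble.n_frames < 2:
        log.warning("ensemble has %d frame(s); densities are degenerate",
                    ensemble.n_frames)
        summary["degenerate"] = True

    series = {}
    for label, *roles in config.roles.get("torsions", []):
        spec = TorsionSpec(label, tuple(tuple(r) for r in roles))
        s = torsion_series(ensemble, spec)
        series[label] = s
        dens = circular_density_1d(s, config.concentration_1d,
                                   config.grid_step_1d)
        modes = density_modes(dens)
        pd.DataFrame({"angle_deg": dens.grid[0], "density": dens.values}
                     ).to_csv(outdir / f"density_{label}.csv", index=False)
        summary[f"modes_{label}"] = modes[:5]
        summary[f"kernel_concentration_{label}"] = dens.concentration[0]

    clusters = []
    labels_arr = None
    pair = config.roles.get("cluster_pair")
    if pair and ensemble.n_frames > 1:
        a, b = series[pair[0]], series[pair[1]]
        clusters = cluster_torsions_2d(
            a, b,
            concentration=(
                (config.concentration_2d,) * 2 if config.concentration_2d
                else None),
            grid_step=config.grid_step_2d,
            density_floor=config.density_floor,
        )
        labels_arr = cluster_label_array(clusters, ensemble.n_frames)
        summary["clusters"] = [
            {"id": c.cluster_id, "center_deg": list(c.center),
             "peak_deg": list(c.peak), "population": c.population}
            for c in clusters
        ]
        summary["cluster_axes"] = {"x": pair[0], "y": pair[1]}

    coords = None
    trace = None
    water = config.roles.get("water")
    if water:
        coords = water_site_coordinates(ensemble, *[tuple(r) for r in water])
        trace = residence_trace(coords, config.residence_threshold)
        summary["residence"] = {
            "r_threshold_A": trace.r_threshold,
            "occupancy": trace.occupancy,
            "mean_inside_segment_frames": trace.mean_inside_segment,
            "n_segments": len(trace.segments),
        }
        if labels_arr is not None:
            summary["state_coupling"] = state_coupling(labels_arr, trace)

    table = per_frame_table(series, coords, labels_arr, trace)
    table.to_csv(outdir / "per_frame.csv", index=False)
    payload = _stamp({"summary": summary}, config)
    _write_json(outdir / "ensemble_summary.json", payload)
    return payload


def deuteration_level(observed_mass_difference: float,
                      calculated_mass_difference: float) -> float:
    """Percent deuterium incorporation from ESI-MS mass differences.

    The observed mass shift between the deuterated and protiated protein,
    divided by the shift expected for complete deuteration, as a percent
    rounded to one decimal: ``100 * observed / calculated``.
    """
    if calculated_mass_difference <= 0:
        raise ValueError("calculated mass difference must be positive")
    return round(100.0 * observed_mass_difference / calculated_mass_difference, 1)
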