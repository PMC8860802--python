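"""End-to-end orchestration: load -> sample -> indices -> topology -> stats.

The pipeline consumes either real CFD exports (mesh + field series +
labels + inlet waveform) or a synthetic case specification, and emits the
sampled point table, the detected divergence centers and the bleb vs
non-bleb comparison report. Identical configurations produce identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices, region_stats, sampling, wss_topology
from .exceptions import ConfigError, FormatError
from .mesh_io import (
    BLEB,
    NONBLEB,
    FieldSeries,
    SurfaceMesh,
    define_inlet_plane,
    load_field_series,
    load_mesh,
    load_region_labels,
)
from .region_stats import ComparisonReport, summarize, summarize_counts
from .synthetic_data import (
    SyntheticSpec,
    make_dome_mesh,
    make_fields,
    make_waveform,
    read_counts_csv,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` or ``mesh_path`` must be set. Inlet plane
    parameters are required for real inputs; the synthetic generator
    provides its own.
    """

    synthetic: SyntheticSpec | None = None
    mesh_path: str | None = None
    fields_path: str | None = None
    labels_path: str | None = None
    waveform_path: str | None = None
    inlet_origin: tuple | None = None
    inlet_normal: tuple | None = None
    inlet_thickness: float = 0.2
    spacing_d: float = 0.5
    seed: int = 0
    cycle_index: int = 2
    snapshot_time: float | None = None  # explicit override
    weighted_inlet: bool = True
    min_divergence_percentile: float = wss_topology.MIN_DIVERGENCE_PERCENTILE
    min_separation_mm: float = wss_topology.MIN_SEPARATION_MM
    outflow_fraction_threshold: float = wss_topology.OUTFLOW_FRACTION_THRESHOLD
    detect_centers: bool = True
    contingency_mode: str = "as_printed"
    mwu_mode: str = "auto"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.mesh_path is None):
            raise ConfigError(
                "exactly one of a synthetic spec or real input paths must be set"
            )
        if self.mesh_path is not None and self.inlet_origin is None:
            raise ConfigError("real inputs require an inlet plane definition")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticSpec(**syn)
        try:
            return cls(synthetic=syn, **raw)
        except TypeError as exc:
            raise ConfigError(f"invalid config key: {exc}") from exc


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    mesh: SurfaceMesh
    points: sampling.SamplePointSet
    centers: list[wss_topology.DivergenceCenter]
    report: ComparisonReport
    reference: indices.InletReference
    snapshot_time: float
    truth: object | None = None


def _load_waveform_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if not {"time", "flow"}.issubset(df.columns):
        raise FormatError(f"{path}: waveform CSV needs columns time,flow")
    return df["time"].to_numpy(float), df["flow"].to_numpy(float)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full multipoint analysis and optionally write artifacts."""
    truth = None
    if config.synthetic is not None:
        spec = config.synthetic
        mesh, truth = make_dome_mesh(spec)
        fields, truth = make_fields(mesh, truth, spec, seed=config.seed)
        wave_t, wave_q = make_waveform(spec)
        inlet = define_inlet_plane(
            mesh, truth.inlet_origin, truth.inlet_normal, truth.inlet_thickness
        )
    else:
        mesh = load_mesh(config.mesh_path)
        if config.labels_path is not None:
            mesh = mesh.with_labels(load_region_labels(config.labels_path, mesh))
        fields = load_field_series(config.fields_path, mesh)
        if config.waveform_path is not None:
            wave_t, wave_q = _load_waveform_csv(config.waveform_path)
        elif config.snapshot_time is None:
            raise ConfigError("real inputs need a waveform or an explicit snapshot")
        inlet = define_inlet_plane(
            mesh, config.inlet_origin, config.inlet_normal, config.inlet_thickness
        )

    if config.snapshot_time is not None:
        snapshot = float(config.snapshot_time)
    else:
        snapshot = indices.select_peak_systole(
            wave_t, wave_q, config.cycle_index, fields.period_T
        )
    reference = indices.inlet_reference(
        mesh, inlet, fields, snapshot, weighted=config.weighted_inlet
    )

    points = sampling.distribute_points(
        mesh,
        domain_label={BLEB, NONBLEB},
        spacing_d=config.spacing_d,
        seed=config.seed,
    )
    points = sampling.label_points(points, mesh)
    points = indices.compute_point_records(points, mesh, fields, reference)

    centers: list[wss_topology.DivergenceCenter] = []
    if config.detect_centers:
        k = fields.index_at_time(snapshot)
        tangential = wss_topology.tangential_projection(mesh, fields.wss[k])
        div = wss_topology.surface_divergence(mesh, tangential)
        dome_mask = (
            np.isin(mesh.region_label, [BLEB, NONBLEB])
            if mesh.region_label is not None
            else None
        )
        centers = wss_topology.find_divergence_centers(
            mesh,
            tangential,
            div,
            min_divergence_percentile=config.min_divergence_percentile,
            min_separation_mm=config.min_separation_mm,
            outflow_fraction_threshold=config.outflow_fraction_threshold,
            candidate_mask=dome_mask,
        )
        points = wss_topology.flag_center_points(points, centers)

    report = summarize(
        points,
        contingency_mode=config.contingency_mode,
        mwu_mode=config.mwu_mode,
    )

    if config.output_dir is not None:
        _write_artifacts(config, points, centers, report, reference, snapshot)
    return PipelineResult(mesh, points, centers, report, reference, snapshot, truth)


def _write_artifacts(config, points, centers, report, reference, snapshot) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    points.to_dataframe().to_csv(out / "points.csv", index=False)
    wss_topology.centers_to_dataframe(centers).to_csv(out / "centers.csv", index=False)
    report.to_frame().to_csv(out / "report.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    log = {
        "seed": config.seed,
        "spacing_d": config.spacing_d,
        "snapshot_time": snapshot,
        "pressure_ave_inlet": reference.pressure_ave_inlet,
        "wss_ave_inlet": reference.wss_ave_inlet,
        "n_points": len(points),
        "region_counts": points.region_counts(),
        "n_centers": len(centers),
        "detection": {
            "min_divergence_percentile": config.min_divergence_percentile,
            "min_separation_mm": config.min_separation_mm,
            "outflow_fraction_threshold": config.outflow_fraction_threshold,
        },
        "contingency_mode": config.contingency_mode,
        "mwu_mode": config.mwu_mode,
        "synthetic": asdict(config.synthetic) if config.synthetic else None,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))


def run_stats_only(
    counts_path,
    values_path=None,
    contingency_mode: str = "as_printed",
    mwu_mode: str = "auto",
) -> ComparisonReport:
    """Re-analysis of printed counts (and optional per-point values).

    ``counts_path`` is a CSV of per-case divergence-center counts;
    ``values_path`` optionally adds per-point parameter values (columns
    ``region`` plus any of the four parameters) whose pooled Mann-Whitney
    comparisons are appended to the ``total`` block.
    """
    counts = read_counts_csv(counts_path)
    report = summarize_counts(counts, contingency_mode=contingency_mode)
    if values_path is not None:
        df = pd.read_csv(values_path)
        if len(df):
            if "region" not in df.columns:
                raise FormatError(f"{values_path}: values CSV needs a region column")
            total = report.cases["total"]
            for name in region_stats.PARAMETERS:
                if name not in df.columns:
                    continue
                va = df.loc[df["region"] == BLEB, name].dropna().to_numpy(float)
                vb = df.loc[df["region"] == NONBLEB, name].dropna().to_numpy(float)
                if len(va) == 0 or len(vb) == 0:
                    continue
                u, p = region_stats.mann_whitney_u(va, vb, mode=mwu_mode)
                total.parameters.append(
                    region_stats.ParameterComparison(
                        parameter=name,
                        n_bleb=len(va),
                        n_nonbleb=len(vb),
                        mean_bleb=float(va.mean()),
                        sd_bleb=region_stats._sd(va),
                        mean_nonbleb=float(vb.mean()),
                        sd_nonbleb=region_stats._sd(vb),
                        u_statistic=u,
                        p_value=p,
                    )
                )
    return report
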