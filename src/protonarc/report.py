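"""Cohort summaries: histograms, disease-grouped maxima, trends vs arc
length, and the end-to-end manifest-driven pipeline.

All aggregates are pure functions of the per-patient curve table
(patient id, disease, arc length, energy), so every report can be recomputed
from the curves CSV alone.  The linear regressions are descriptive only —
they characterize the general correlation of the requirement with arc
length; no inference statistics are attached.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arcs import DEFAULT_ARC_LENGTHS, compute_curve, energy_matrix
from .beams import BeamSpec, gantry_angles
from .density import TissueClassification
from .range_energy import build_range_table
from .volumes import read_roi, read_volume

__all__ = [
    "PipelineConfig",
    "CohortSummary",
    "TrendResult",
    "histogram",
    "trend",
    "table_by_disease",
    "run_pipeline",
]

HIST_BIN_MEV = 5.0
HIST_START_MEV = 50.0


def histogram(energies_mev, bin_width_mev: float = HIST_BIN_MEV) -> pd.DataFrame:
    """Bin energies into left-closed bins aligned to multiples of the bin
    width starting at 50 MeV; counts conserve the input size."""
    e = np.asarray(list(energies_mev), float)
    if e.size == 0:
        raise ValueError("cannot histogram an empty energy list")
    top = HIST_START_MEV + bin_width_mev * (
        np.floor((e.max() - HIST_START_MEV) / bin_width_mev) + 1
    )
    edges = np.arange(HIST_START_MEV, top + 0.5 * bin_width_mev, bin_width_mev)
    counts, _ = np.histogram(e, bins=edges)
    return pd.DataFrame(
        {"bin_left_mev": edges[:-1], "bin_right_mev": edges[1:], "count": counts}
    )


@dataclass(frozen=True)
class TrendResult:
    """A cohort statistic per arc length with its descriptive OLS line."""

    statistic: str
    arc_lengths_deg: np.ndarray
    values_mev: np.ndarray
    slope_mev_per_deg: float
    intercept_mev: float


_STATS = {"max": "max", "median": "median", "mean": "mean"}


def trend(curves_df: pd.DataFrame, statistic: str = "max") -> TrendResult:
    """Cohort max/median/mean of En(phi) per arc length, with an OLS fit
    of statistic vs phi.  Needs at least two distinct arc lengths."""
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    grouped = curves_df.groupby("arc_length_deg")["energy_mev"].agg(_STATS[statistic])
    phis = grouped.index.to_numpy(float)
    if len(phis) < 2:
        raise ValueError("trend needs at least two distinct arc lengths")
    vals = grouped.to_numpy(float)
    slope, intercept = np.polyfit(phis, vals, 1)
    return TrendResult(statistic, phis, vals, float(slope), float(intercept))


def table_by_disease(curves_df: pd.DataFrame) -> pd.DataFrame:
    """Per-disease maximum En(phi) for each arc length, plus a Total row.

    Raises ``ValueError`` naming the patient if a disease label is missing.
    """
    missing = curves_df[
        curves_df["disease"].isna() | (curves_df["disease"].astype(str) == "")
    ]
    if len(missing):
        pid = missing["patient_id"].iloc[0]
        raise ValueError(f"patient {pid!r} has no disease label")
    wide = curves_df.pivot_table(
        index="disease", columns="arc_length_deg", values="energy_mev", aggfunc="max"
    )
    n = curves_df.groupby("disease")["patient_id"].nunique()
    wide.insert(0, "patients", n)
    total = wide.max(axis=0)
    total["patients"] = curves_df["patient_id"].nunique()
    wide.loc["Total"] = total
    wide["patients"] = wide["patients"].astype(int)
    return wide


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end run; defaults follow the study conditions."""

    n_angles: int = 51
    sad_cm: float | None = None  # None -> parallel beams
    spot_spacing_cm: float = 0.235
    margin_cm: float = 0.0
    arc_lengths_deg: tuple[float, ...] = DEFAULT_ARC_LENGTHS
    isocenter: tuple[float, float, float] | str = "auto"
    tissue: TissueClassification = field(default_factory=TissueClassification)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        tissue = TissueClassification.from_config(cfg.get("tissue", {}))
        known = {k: cfg[k] for k in (
            "n_angles", "sad_cm", "spot_spacing_cm", "margin_cm"
        ) if k in cfg}
        if "arc_lengths_deg" in cfg:
            known["arc_lengths_deg"] = tuple(cfg["arc_lengths_deg"])
        if "isocenter" in cfg:
            iso = cfg["isocenter"]
            known["isocenter"] = "auto" if iso == "auto" else tuple(iso)
        return cls(tissue=tissue, **known)

    def echo(self) -> dict:
        return {
            "n_angles": self.n_angles,
            "sad_cm": self.sad_cm,
            "spot_spacing_cm": self.spot_spacing_cm,
            "margin_cm": self.margin_cm,
            "arc_lengths_deg": list(self.arc_lengths_deg),
            "isocenter": self.isocenter,
            "tissue_cutoffs": list(self.tissue.cutoffs),
            "tissue_ratios": list(self.tissue.ratios),
        }


@dataclass
class CohortSummary:
    """Long-format per-patient curve table plus any per-patient failures."""

    curves: pd.DataFrame  # patient_id, disease, arc_length_deg, energy_mev, ...
    failures: list[dict] = field(default_factory=list)

    def histogram(self, phi_deg: float) -> pd.DataFrame:
        sel = self.curves[self.curves["arc_length_deg"] == phi_deg]
        return histogram(sel["energy_mev"])

    def trend(self, statistic: str = "max") -> TrendResult:
        return trend(self.curves, statistic)

    def by_disease(self) -> pd.DataFrame:
        return table_by_disease(self.curves)


def _load_manifest(manifest) -> tuple[dict, Path]:
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        return data, path.parent
    return manifest, Path(".")


def run_pipeline(manifest, config: PipelineConfig | None = None, out_dir=None) -> CohortSummary:
    """Run the full cohort pipeline from a manifest.

    The manifest (YAML/JSON path or dict) lists patients with ``id``,
    ``disease``, a ``volume`` NIfTI path and ``rois`` (path + label each);
    relative paths resolve against the manifest location.  Per-patient
    failures are recorded and the run continues.  With ``out_dir`` set,
    writes curves.csv, by_disease.csv, trend.csv, hist_<phi>.csv and
    run_log.json; outputs are deterministic functions of (manifest, config).
    """
    config = config or PipelineConfig()
    data, base = _load_manifest(manifest)
    table = build_range_table()
    beam = BeamSpec(spot_spacing_cm=config.spot_spacing_cm)

    rows: list[dict] = []
    failures: list[dict] = []
    for patient in data["patients"]:
        pid = patient["id"]
        try:
            volume = read_volume(base / patient["volume"])
            targets = [
                read_roi(base / r["path"], volume, label=r.get("label", f"roi-{k}"), index=k)
                for k, r in enumerate(patient["rois"])
            ]
            if config.isocenter == "auto":
                iso = np.mean([t.mask_centroid() for t in targets], axis=0)
            else:
                iso = np.asarray(config.isocenter, float)
            gantry = gantry_angles(config.n_angles, isocenter=iso, sad_cm=config.sad_cm)
            matrix = energy_matrix(
                volume, targets, gantry, beam, table,
                classification=config.tissue, margin_cm=config.margin_cm,
                patient_id=pid,
            )
            curve = compute_curve(matrix, config.arc_lengths_deg)
        except Exception as exc:  # noqa: BLE001 - record and continue
            failures.append({"patient_id": pid, "error": str(exc)})
            print(f"[protonarc] patient {pid} failed: {exc}", file=sys.stderr)
            continue
        for phi, en, k in zip(
            curve.arc_lengths_deg, curve.energies_mev, curve.win_start
        ):
            rows.append(
                {
                    "patient_id": pid,
                    "disease": patient.get("disease", ""),
                    "arc_length_deg": float(phi),
                    "energy_mev": float(en),
                    "arc_start_index": int(k),
                    "clamped": bool(curve.clamped),
                }
            )

    curves = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "disease", "arc_length_deg",
            "energy_mev", "arc_start_index", "clamped",
        ],
    )
    summary = CohortSummary(curves, failures)

    if out_dir is not None:
        write_reports(summary, config, Path(out_dir))
    return summary


def write_reports(summary: CohortSummary, config: PipelineConfig, out: Path) -> None:
    """Write the CSV artifacts and the run log for a cohort summary."""
    out.mkdir(parents=True, exist_ok=True)
    summary.curves.to_csv(out / "curves.csv", index=False)
    if len(summary.curves):
        summary.by_disease().to_csv(out / "by_disease.csv")
        trends = {}
        for stat in ("max", "median", "mean"):
            t = summary.trend(stat)
            trends[stat] = {
                "slope_mev_per_deg": t.slope_mev_per_deg,
                "intercept_mev": t.intercept_mev,
            }
        pd.DataFrame(
            {
                "arc_length_deg": summary.trend("max").arc_lengths_deg,
                "max_mev": summary.trend("max").values_mev,
                "median_mev": summary.trend("median").values_mev,
                "mean_mev": summary.trend("mean").values_mev,
            }
        ).to_csv(out / "trend.csv", index=False)
        for phi in sorted(summary.curves["arc_length_deg"].unique()):
            summary.histogram(phi).to_csv(
                out / f"hist_{phi:g}deg.csv", index=False
            )
    else:
        trends = {}
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "timestamp_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "config": config.echo(),
        "n_patients": int(summary.curves["patient_id"].nunique()) if len(summary.curves) else 0,
        "failures": summary.failures,
        "regressions": trends,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
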