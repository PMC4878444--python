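"""Cohort aggregation, tables and the manifest-driven pipeline."""

import numpy as np
import pandas as pd
import pytest

import protonarc as pa


def _curves(records):
    return pd.DataFrame(
        records, columns=["patient_id", "disease", "arc_length_deg", "energy_mev"]
    )


def test_histogram_hand_binning():
    h = pa.histogram([100.0, 104.0, 106.0])
    assert h.loc[h.bin_left_mev == 100.0, "count"].item() == 2
    assert h.loc[h.bin_left_mev == 105.0, "count"].item() == 1
    assert h["count"].sum() == 3
    assert h.bin_left_mev.iloc[0] == 50.0  # bins aligned to 50 MeV


def test_histogram_degenerate_and_empty():
    h = pa.histogram([117.0] * 5)
    assert (h["count"] > 0).sum() == 1
    assert h["count"].sum() == 5
    with pytest.raises(ValueError):
        pa.histogram([])


def test_trend_recovers_exact_linear_construction():
    phis = [1.0, 90.0, 180.0, 270.0, 360.0]
    rows = []
    for pid, offset in (("a", 0.0), ("b", 10.0)):
        for phi in phis:
            rows.append((pid, "Metastases", phi, 100.0 + 0.1 * phi + offset))
    t = pa.trend(_curves(rows), "max")
    assert t.slope_mev_per_deg == pytest.approx(0.1, abs=1e-9)
    assert t.intercept_mev == pytest.approx(110.0, abs=1e-9)
    t_mean = pa.trend(_curves(rows), "mean")
    assert t_mean.intercept_mev == pytest.approx(105.0, abs=1e-9)


def test_trend_constant_and_errors():
    rows = [("a", "x", phi, 120.0) for phi in (1.0, 90.0, 360.0)]
    assert pa.trend(_curves(rows), "median").slope_mev_per_deg == pytest.approx(0.0)
    with pytest.raises(ValueError):
        pa.trend(_curves([("a", "x", 90.0, 120.0)]), "max")
    with pytest.raises(ValueError):
        pa.trend(_curves(rows), "mode")


def test_trend_mean_equals_median_for_symmetric_cohort():
    phis = (1.0, 180.0, 360.0)
    rows = []
    for pid, delta in (("a", -8.0), ("b", 0.0), ("c", 8.0)):
        for phi in phis:
            rows.append((pid, "x", phi, 120.0 + 0.05 * phi + delta))
    mean = pa.trend(_curves(rows), "mean")
    median = pa.trend(_curves(rows), "median")
    np.testing.assert_allclose(mean.values_mev, median.values_mev)


def test_table_by_disease_group_maxima():
    rows = [
        ("p1", "Metastases", 1.0, 110.0),
        ("p1", "Metastases", 360.0, 150.0),
        ("p2", "Metastases", 1.0, 100.0),
        ("p2", "Metastases", 360.0, 170.0),
        ("p3", "Meningioma", 1.0, 95.0),
        ("p3", "Meningioma", 360.0, 140.0),
    ]
    table = pa.table_by_disease(_curves(rows))
    assert table.loc["Metastases", 1.0] == 110.0
    assert table.loc["Metastases", 360.0] == 170.0
    assert table.loc["Meningioma", 360.0] == 140.0
    assert table.loc["Total", 360.0] == 170.0
    assert table.loc["Total", "patients"] == 3
    # Total dominates every disease row at every arc length
    for phi in (1.0, 360.0):
        assert (table.loc["Total", phi] >= table.drop("Total")[phi]).all()


def test_single_disease_total_equals_group_row():
    rows = [("p1", "Other", 1.0, 100.0), ("p2", "Other", 1.0, 130.0)]
    table = pa.table_by_disease(_curves(rows))
    assert table.loc["Total", 1.0] == table.loc["Other", 1.0]


def test_missing_disease_label_names_patient():
    rows = [("p9", "", 1.0, 100.0)]
    with pytest.raises(ValueError, match="p9"):
        pa.table_by_disease(_curves(rows))


@pytest.fixture(scope="module")
def tiny_cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    pa.make_cohort(
        2, seed=5, out_dir=out, shape=(64, 64, 32), voxel_size=(0.3, 0.3, 0.5)
    )
    return out


def test_pipeline_end_to_end(tiny_cohort_dir, tmp_path):
    cfg = pa.PipelineConfig(n_angles=17)
    summary = pa.run_pipeline(tiny_cohort_dir / "manifest.yaml", cfg, out_dir=tmp_path)
    assert not summary.failures
    # 2 patients x 5 arc lengths
    assert len(summary.curves) == 10
    assert (tmp_path / "curves.csv").exists()
    assert (tmp_path / "by_disease.csv").exists()
    assert (tmp_path / "run_log.json").exists()
    # En is nondecreasing in arc length for every patient
    for _, grp in summary.curves.groupby("patient_id"):
        assert np.all(np.diff(grp.sort_values("arc_length_deg").energy_mev) >= 0)


def test_pipeline_reruns_identically(tiny_cohort_dir, tmp_path):
    cfg = pa.PipelineConfig(n_angles=17)
    s1 = pa.run_pipeline(tiny_cohort_dir / "manifest.yaml", cfg, out_dir=tmp_path / "a")
    s2 = pa.run_pipeline(tiny_cohort_dir / "manifest.yaml", cfg, out_dir=tmp_path / "b")
    pd.testing.assert_frame_equal(s1.curves, s2.curves)
    assert (tmp_path / "a" / "curves.csv").read_bytes() == (
        tmp_path / "b" / "curves.csv"
    ).read_bytes()


def test_pipeline_failure_is_recorded_not_fatal(tiny_cohort_dir, tmp_path):
    import yaml

    with open(tiny_cohort_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    manifest["patients"].append(
        {"id": "ghost", "disease": "Other", "volume": "missing.nii.gz", "rois": []}
    )
    # resolve remaining paths against the cohort dir
    for p in manifest["patients"]:
        p["volume"] = str(tiny_cohort_dir / p["volume"])
        p["rois"] = [
            {"path": str(tiny_cohort_dir / r["path"]), "label": r["label"]}
            for r in p["rois"]
        ]
    summary = pa.run_pipeline(manifest, pa.PipelineConfig(n_angles=9))
    assert [f["patient_id"] for f in summary.failures] == ["ghost"]
    assert summary.curves["patient_id"].nunique() == 2
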