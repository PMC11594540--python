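"""Plate IO, config provenance, pipeline composition, volume utility, CLI."""

import numpy as np
import pandas as pd
import pytest

from exmplate import plateio, synthim
from exmplate.plateio import PlateLayout, RunConfig, WellInfo


class TestPerPostVolume:
    def test_device_worked_example(self):
        # 2806 ug collected over 12 posts at 1 ug/nL -> 234 nL per post
        assert plateio.per_post_volume(2806, 12) == 234

    def test_zero_mass(self):
        assert plateio.per_post_volume(0, 12) == 0

    def test_exact_division(self):
        assert plateio.per_post_volume(1200, 12) == 100

    def test_zero_posts_rejected(self):
        with pytest.raises(ValueError):
            plateio.per_post_volume(100, 0)


class TestConfigAndLayout:
    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = RunConfig(threshold_method="quantile=0.8", dilation_iterations=4, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = RunConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_layout_yaml_roundtrip(self, tmp_path):
        lay = PlateLayout(
            wells={"B02": WellInfo("control", 0, "nM", 1), "B03": WellInfo("10nM", 10, "nM", 1)},
            excluded_wells=["B04"],
        )
        lay.to_yaml(tmp_path / "l.yaml")
        back = PlateLayout.from_yaml(tmp_path / "l.yaml")
        assert back.wells == lay.wells and back.excluded_wells == ["B04"]


class TestStackIO:
    def test_tiff_sidecar_roundtrip(self, tmp_path):
        shape = synthim.make_nucleus_shape(seed=1, base_radius=15, irregularity=0.1)
        st = synthim.render_nucleus_stack(shape, synthim.DEFAULT_PROFILE, n_planes=3)
        plateio.write_stack(tmp_path / "a.tif", st)
        planes, meta = plateio.read_stack(tmp_path / "a.tif")
        assert planes.shape == st.planes.shape
        # 16-bit quantization of the intensity range
        rng_int = st.planes.max() - st.planes.min()
        assert np.abs(planes - st.planes).max() <= rng_int / 60000 + 1e-9
        assert meta["midplane"] == st.midplane
        assert meta["nuclei"][0]["base_radius"] == pytest.approx(15.0)


def write_tiny_plate(root, seed=0):
    doses = ("control", "10nM")
    wells = {}
    rng = np.random.default_rng(seed)
    for rep, row in enumerate("BC"):
        series = synthim.make_dose_series(
            doses=doses, n_nuclei_per_dose=3, seed=int(rng.integers(2**31))
        )
        for i, dose in enumerate(doses):
            well = f"{row}{i + 2:02d}"
            wells[well] = WellInfo(condition=dose, replicate=rep + 1)
            for j, st in enumerate(series[dose]):
                plateio.write_stack(root / f"{well}_f{j}.tif", st)
    return PlateLayout(wells=wells)


@pytest.fixture(scope="module")
def plate(tmp_path_factory):
    root = tmp_path_factory.mktemp("plate")
    layout = write_tiny_plate(root)
    return root, layout


class TestPeripheryPipeline:

    def test_outputs_written_and_composed(self, plate, tmp_path):
        root, layout = plate
        res = plateio.run_periphery_pipeline(root, layout, RunConfig(), tmp_path / "out")
        assert (tmp_path / "out" / "comparisons.csv").exists()
        assert (tmp_path / "out" / "provenance.yaml").exists()
        qc = res["qc"]
        assert len(qc) == 12
        assert set(res["comparisons"]["condition"]) == {"10nM"}
        assert len(res["comparisons"]) == 3  # one row per metric
        # pipeline composition equals the stage functions run directly
        some = sorted(root.glob("B02_f*.tif"))[0]
        planes, _ = plateio.read_stack(some)
        rec = plateio.analyze_nucleus_stack(planes, RunConfig())
        m = res["metrics"]
        row = m[m["field"] == some.stem].iloc[0]
        assert row["outer_slope"] == pytest.approx(rec["metrics"].outer_slope)

    def test_rerun_is_byte_identical(self, plate, tmp_path):
        root, layout = plate
        for d in ("r1", "r2"):
            plateio.run_periphery_pipeline(root, layout, RunConfig(), tmp_path / d)
        for name in ("qc.csv", "metrics.csv", "profiles.csv", "comparisons.csv", "provenance.yaml"):
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()

    def test_excluded_well_absent_from_outputs(self, plate, tmp_path):
        root, layout = plate
        lay2 = PlateLayout(wells=dict(layout.wells), excluded_wells=["C02"])
        res = plateio.run_periphery_pipeline(root, lay2, RunConfig(), tmp_path / "excl")
        assert not (res["qc"]["well"] == "C02").any()
        assert not (res["metrics"]["well"] == "C02").any()

    def test_missing_images_error(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError):
            plateio.run_periphery_pipeline(
                tmp_path / "empty", PlateLayout(wells={}), RunConfig(), tmp_path / "o"
            )


class TestDistortionPipeline:
    def test_identity_pairs_near_zero_error(self, tmp_path, multi_nucleus_field):
        rows = []
        for i, plate_id in enumerate(("p1", "p1")):
            pre, post, _ = synthim.make_expansion_pair(
                multi_nucleus_field, scale=1.0, deform_amplitude=0.0, seed=i
            )
            pre_p = tmp_path / f"pre{i}.tif"
            post_p = tmp_path / f"post{i}.tif"
            plateio.write_stack(pre_p, pre)
            plateio.write_stack(post_p, post)
            rows.append({"pre_path": str(pre_p), "post_path": str(post_p),
                         "plate": plate_id, "field": f"f{i}", "pixel_size": 0.5})
        res = plateio.run_distortion_pipeline(pd.DataFrame(rows), RunConfig(), tmp_path / "o")
        s = res["summary"]
        assert s["registered"].all()
        assert (s["avg_percent_error"].abs() < 0.5).all()
        assert np.allclose(s["expansion_factor"], 1.0, atol=0.02)
        assert (tmp_path / "o" / "error_curves.csv").exists()

    def test_empty_manifest_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            plateio.run_distortion_pipeline(pd.DataFrame(), RunConfig(), tmp_path / "o")


class TestSimulatedPlateAnalysis:
    def test_dose_effect_detected_and_null_conditions_spared(self):
        cfg = RunConfig(min_area=200.0, unit="replicate")
        df = plateio.simulate_plate_metrics(seed=5, n_replicates=4, n_nuclei=8)
        table = plateio.dose_response_from_metrics(df, cfg)
        t10 = table[(table.condition == "10nM") & (table.metric == "outer_slope")]
        assert t10["significant"].item()
        assert t10["t_statistic"].item() > 0


class TestCLI:
    def test_volume_subcommand(self):
        from typer.testing import CliRunner

        from exmplate.cli import app

        result = CliRunner().invoke(app, ["volume", "2806"])
        assert result.exit_code == 0
        assert result.output.strip() == "234"

    def test_profile_subcommand(self, tmp_path):
        from typer.testing import CliRunner

        from exmplate.cli import app

        shape = synthim.make_nucleus_shape(seed=2, base_radius=20, irregularity=0.1)
        st = synthim.render_nucleus_stack(shape, synthim.DEFAULT_PROFILE)
        plateio.write_stack(tmp_path / "n.tif", st)
        out = tmp_path / "prof.csv"
        result = CliRunner().invoke(app, ["profile", str(tmp_path / "n.tif"), "--out", str(out)])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert len(df) == 500
        assert df["relative_intensity"].max() == pytest.approx(1.0)
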