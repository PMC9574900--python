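import numpy as np
import pandas as pd
import pytest

import ctnet
from ctnet.errors import SchemaError, SingularFitError
from ctnet.histology import contrasts_to_frame, validate_records
from ctnet.synthetic import HistologySimConfig


def make_records(rows):
    defaults = dict(age=70.0, sex="F", pmd=400.0)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestValidation:
    def test_missing_column_rejected(self):
        df = make_records([
            dict(subject_id="a", group="NC", marker="exc_synapse", layer="VI",
                 roi_id="a1", density=100.0)
        ]).drop(columns=["pmd"])
        with pytest.raises(SchemaError, match="missing columns"):
            validate_records(df)

    def test_nonpositive_density_rejected(self):
        df = make_records([
            dict(subject_id="a", group="NC", marker="exc_synapse", layer="VI",
                 roi_id="a1", density=0.0)
        ])
        with pytest.raises(SchemaError, match="positive"):
            validate_records(df)

    def test_neuron_record_with_layer_rejected(self):
        df = make_records([
            dict(subject_id="a", group="NC", marker="NeuN", layer="VI",
                 roi_id="a1", density=100.0)
        ])
        with pytest.raises(SchemaError, match="whole-cortex"):
            validate_records(df)

    def test_conflicting_covariates_rejected(self):
        df = make_records([
            dict(subject_id="a", group="NC", marker="exc_synapse", layer="VI",
                 roi_id="a1", density=100.0, age=70.0),
            dict(subject_id="a", group="NC", marker="exc_synapse", layer="VI",
                 roi_id="a2", density=120.0, age=75.0),
        ])
        with pytest.raises(SchemaError, match="covariates"):
            ctnet.aggregate_rois(df)


class TestAggregateRois:
    def test_same_type_rois_averaged(self):
        df = make_records([
            dict(subject_id="a", group="NAGM", marker="exc_synapse",
                 layer="VI", roi_id="a1", density=100.0),
            dict(subject_id="a", group="NAGM", marker="exc_synapse",
                 layer="VI", roi_id="a2", density=140.0),
        ])
        out = ctnet.aggregate_rois(df)
        assert len(out) == 1
        assert out["density"].iloc[0] == pytest.approx(120.0)

    def test_differing_tissue_types_kept_separate(self):
        df = make_records([
            dict(subject_id="a", group="NAGM", marker="exc_synapse",
                 layer="VI", roi_id="a1", density=100.0),
            dict(subject_id="a", group="DEMYEL", marker="exc_synapse",
                 layer="VI", roi_id="a2", density=80.0),
        ])
        out = ctnet.aggregate_rois(df)
        assert len(out) == 2
        assert set(out["group"]) == {"NAGM", "DEMYEL"}

    def test_single_roi_unchanged(self):
        df = make_records([
            dict(subject_id="a", group="NC", marker="exc_synapse", layer="VI",
                 roi_id="a1", density=111.0)
        ])
        out = ctnet.aggregate_rois(df)
        assert out["density"].iloc[0] == pytest.approx(111.0)

    def test_idempotent(self):
        df = ctnet.generate_histology(HistologySimConfig(seed=5))
        once = ctnet.aggregate_rois(df)
        twice = ctnet.aggregate_rois(once)
        pd.testing.assert_frame_equal(
            once.sort_values(["subject_id", "group", "marker", "layer"])
            .reset_index(drop=True)[["subject_id", "group", "marker", "layer",
                                     "density"]],
            twice.sort_values(["subject_id", "group", "marker", "layer"])
            .reset_index(drop=True)[["subject_id", "group", "marker", "layer",
                                     "density"]],
        )


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a,ref,expected",
        [(851.0, 1000.0, -14.9), (5.0, 5.0, 0.0), (707.0, 1000.0, -29.3)],
    )
    def test_reported_percentages_reproduced(self, a, ref, expected):
        assert ctnet.percent_difference(a, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ctnet.percent_difference(100.0, 0.0)


class TestFitDensityModel:
    def test_recovers_injected_layer_vi_effects(self):
        df = ctnet.generate_histology(HistologySimConfig(seed=10))
        results = ctnet.fit_density_model(df, "synapse")
        frame = contrasts_to_frame(results)
        inter = frame[frame["comparison"].str.contains("interaction")]
        assert set(inter["marker"]) == {"exc_synapse", "inh_synapse"}
        vi = frame.query(
            "marker == 'inh_synapse' and layer == 'VI' "
            "and comparison == 'NAGM vs NC'"
        )
        assert len(vi) == 1
        # single replicate: generous band around the injected -14.9%
        assert vi["pct_diff"].iloc[0] == pytest.approx(-14.9, abs=12.0)
        assert vi["ci_low"].iloc[0] <= vi["estimate"].iloc[0] <= vi["ci_high"].iloc[0]

    def test_neuron_class_fits_whole_cortex_contrasts(self):
        df = ctnet.generate_histology(HistologySimConfig(seed=11))
        results = ctnet.fit_density_model(df, "neuron")
        frame = contrasts_to_frame(results)
        assert set(frame["marker"]) == {"NeuN", "PV", "CR"}
        assert frame["layer"].isna().all()
        assert {"NAGM vs NC", "DEMYEL vs NC", "DEMYEL vs NAGM"} <= set(
            frame["comparison"]
        )

    def test_constant_densities_raise_singular_fit_diagnostic(self):
        cfg = HistologySimConfig(
            seed=1, between_subject_sd=0.0, within_subject_sd=0.0,
            effect_multiplier={},
        )
        df = ctnet.generate_histology(cfg)
        with pytest.raises(SingularFitError, match="variance"):
            ctnet.fit_density_model(df, "synapse")

    def test_percent_differences_invariant_to_unit_rescaling(self):
        df = ctnet.generate_histology(HistologySimConfig(seed=12))
        res1 = ctnet.fit_density_model(df, "synapse")
        df2 = df.copy()
        df2["density"] *= 1e-4  # counts/mm^2 -> counts/um^2-ish rescale
        res2 = ctnet.fit_density_model(df2, "synapse")
        f1 = contrasts_to_frame(res1).dropna(subset=["layer"])
        f2 = contrasts_to_frame(res2).dropna(subset=["layer"])
        np.testing.assert_allclose(
            f1["pct_diff"].values, f2["pct_diff"].values, rtol=1e-4
        )
        np.testing.assert_allclose(
            f1["estimate"].values * 1e-4, f2["estimate"].values, rtol=1e-4
        )

    def test_zero_subject_variance_agrees_with_ols(self):
        import statsmodels.formula.api as smf

        cfg = HistologySimConfig(seed=13, between_subject_sd=0.0,
                                 within_subject_sd=0.08)
        df = ctnet.generate_histology(cfg)
        agg = ctnet.aggregate_rois(df)
        sub = agg.query("marker == 'inh_synapse' and layer == 'VI'").copy()
        results = ctnet.fit_density_model(df, "synapse")
        frame = contrasts_to_frame(results)
        got = frame.query(
            "marker == 'inh_synapse' and layer == 'VI' "
            "and comparison == 'NAGM vs NC'"
        )["estimate"].iloc[0]
        sub["is_m"] = (sub["sex"] == "M").astype(float)
        ols = smf.ols(
            "density ~ C(group, Treatment('NC')) + age + is_m + pmd", data=sub
        ).fit()
        expected = ols.params["C(group, Treatment('NC'))[T.NAGM]"]
        assert got == pytest.approx(expected, rel=0.05)

    def test_extra_covariate_changes_adjustment(self):
        df = ctnet.generate_histology(HistologySimConfig(seed=14))
        neun = (
            ctnet.aggregate_rois(df).query("marker == 'NeuN'")
            .groupby("subject_id")["density"].mean().rename("neun")
        )
        df = df.join(neun, on="subject_id")
        res = ctnet.fit_density_model(df, "synapse", extra_covariate="neun")
        for r in res:
            if r.comparison != "tissue type x layer interaction":
                assert "neun" in r.metadata["covariates"]

    def test_table_io_round_trip(self, tmp_path):
        df = ctnet.generate_histology(HistologySimConfig(seed=15))
        path = tmp_path / "densities.csv"
        df.to_csv(path, index=False)
        loaded = ctnet.read_density_table(path)
        assert len(loaded) == len(df)
        np.testing.assert_allclose(loaded["density"], df["density"])
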