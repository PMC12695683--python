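"""Cohort orchestration: per-patient pipeline, paired statistics, age
strata, sensitivity sweeps and report export."""

import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rtimagerisk import (
    AnalysisConfig,
    PatientRecord,
    ProtocolSpec,
    age_stratum,
    compare_protocols,
    export_report,
    load_parameter_registry,
    paired_ttest,
    run_patient,
    sensitivity_sweep,
    stratify_by_age,
    write_rtdose,
    write_rtstruct,
)
from rtimagerisk.cohort import AGE_STRATA_LABELS
from rtimagerisk.errors import ParameterError
from rtimagerisk.synthdata import SITE_TEMPLATES, CohortSpec, generate_patient

from conftest import cylinder_structure, make_grid

# paired t-test oracle values frozen from an independent implementation
# (R 4.3 t.test with paired=TRUE)
R_ORACLE_A = [1.1, 2.3, 2.9, 4.2, 5.0]
R_ORACLE_B = [1.4, 2.2, 3.4, 4.9, 5.4]
R_ORACLE_T = 2.71360210119987
R_ORACLE_P = 0.0533382610456889

R_ORACLE_X = [0.52, 0.61, 0.49, 0.55, 0.58, 0.60, 0.47, 0.53, 0.56, 0.51]
R_ORACLE_Y = [0.58, 0.66, 0.52, 0.61, 0.60, 0.68, 0.50, 0.60, 0.63, 0.55]
R_ORACLE_T2 = 7.96486185631892
R_ORACLE_P2 = 2.29267267981899e-05


class TestPairedTTest:
    def test_matches_independent_oracle_n5(self):
        t, p, degenerate = paired_ttest(R_ORACLE_A, R_ORACLE_B)
        assert abs(t - R_ORACLE_T) < 1e-10
        assert abs(p - R_ORACLE_P) < 1e-10
        assert not degenerate

    def test_matches_independent_oracle_n10(self):
        t, p, degenerate = paired_ttest(R_ORACLE_X, R_ORACLE_Y)
        assert abs(t - R_ORACLE_T2) < 1e-10
        assert abs(p - R_ORACLE_P2) < 1e-10

    def test_identical_vectors_flagged_degenerate(self):
        v = [1.0, 2.0, 3.0]
        t, p, degenerate = paired_ttest(v, v)
        assert p == 1.0 and degenerate

    def test_constant_nonzero_shift_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p, degenerate = paired_ttest(a, a + 0.5)
        assert p == 0.0 and degenerate and t > 0

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            paired_ttest([1.0], [2.0])


class TestAgeStratum:
    @pytest.mark.parametrize("age,expected", [
        (30, "<40"), (39, "<40"), (40, "40-60"), (55, "40-60"),
        (60, "40-60"), (61, ">60"), (85, ">60"),
    ])
    def test_boundary_convention(self, age, expected):
        assert age_stratum(age) == expected

    def test_example_cohort_counts(self):
        strata = [age_stratum(a) for a in (30, 40, 60, 61)]
        assert strata == ["<40", "40-60", "40-60", ">60"]


def _uniform_imaging_patient(tmp_path, imaging_gy=0.03, age=45):
    """A hand-built patient: uniform per-fraction imaging dose over a
    cylindrical lung ROI, zero treatment dose."""
    grid = make_grid(shape=(10, 14, 14), spacing=2.0, value=imaging_gy,
                     frame_ref="1.2.3.4.5.9")
    zero = grid.with_values(np.zeros(grid.shape))
    struct = cylinder_structure(
        name="Lung_IPSI", center=(13.0, 13.0), radius=9.0,
        z_slices=(4.0, 6.0, 8.0, 10.0, 12.0), frame_ref="1.2.3.4.5.9",
    )
    write_rtdose(grid, tmp_path / "img.dcm", uid_entropy=("img", "t"))
    write_rtdose(zero, tmp_path / "tx.dcm", uid_entropy=("tx", "t"))
    write_rtstruct(struct, tmp_path / "rs.dcm", uid_entropy=("rs", "t"))
    return PatientRecord(
        id="P1", age_years=age, sex="F", site="breast", laterality="left",
        n_fractions=25,
        treatment_dose_path=str(tmp_path / "tx.dcm"),
        imaging_dose_path=str(tmp_path / "img.dcm"),
        structure_path=str(tmp_path / "rs.dcm"),
    )


class TestRunPatient:
    def test_uniform_imaging_only_chain_matches_formulas(self, tmp_path):
        """25 fractions x 0.03 Gy uniform imaging -> 0.75 Gy mean; NTCP, OED
        and EAR equal direct formula evaluation on that dose."""
        record = _uniform_imaging_patient(tmp_path)
        config = AnalysisConfig(imaging_only=True)
        protocol = ProtocolSpec("5MU", 5.0, 25)
        df = run_patient(record, protocol, config)
        row = df[df.roi == "Lung_IPSI"].iloc[0]
        assert abs(row.mean_dose_gy - 0.75) < 1e-6

        registry = config.registry
        lung_ntcp = registry.ntcp_for("lung")
        expected_ntcp = 100 * expit(lung_ntcp.gamma * (row.mean_dose_gy - lung_ntcp.d50))
        assert abs(row.ntcp_pct - expected_ntcp) < 1e-9
        # uniform dose: OED = D exp(-alpha' D) up to bin-midpoint error
        lung_ear = registry.ear_for("lung")
        expected_oed = row.mean_dose_gy * math.exp(-lung_ear.alpha_prime * row.mean_dose_gy)
        assert abs(row.oed_gy - expected_oed) < config.bin_width_gy
        mu = math.exp(lung_ear.gamma_e * (45 - lung_ear.e0))
        assert abs(row.ear_per_10k_py - lung_ear.ear0 * row.oed_gy * mu) < 1e-9

    def test_zero_imaging_dose_gives_zero_ear(self, tmp_path):
        record = _uniform_imaging_patient(tmp_path, imaging_gy=0.0)
        config = AnalysisConfig(imaging_only=True)
        df = run_patient(record, ProtocolSpec("5MU", 5.0, 25), config)
        assert (df.ear_per_10k_py == 0.0).all()
        assert (df.mean_dose_gy == 0.0).all()

    def test_unregistered_roi_skipped_others_present(self, tmp_path, default_config):
        from rtimagerisk.grids import ROI, StructureSet
        from conftest import circle_contour

        grid = make_grid(shape=(10, 14, 14), spacing=2.0, value=0.03, frame_ref="1.2.3.4.5.2")
        struct = StructureSet(rois=[
            ROI("Lung_IPSI", [circle_contour((13, 13), 9, z) for z in (4.0, 8.0)]),
            ROI("Unknown_ROI", [circle_contour((13, 13), 5, z) for z in (4.0, 8.0)]),
        ], frame_ref="1.2.3.4.5.2")
        write_rtdose(grid, tmp_path / "img.dcm")
        write_rtdose(grid.with_values(np.zeros(grid.shape)), tmp_path / "tx.dcm")
        write_rtstruct(struct, tmp_path / "rs.dcm")
        record = PatientRecord(
            id="P2", age_years=50, sex="M", site="breast", laterality=None,
            n_fractions=25, treatment_dose_path=str(tmp_path / "tx.dcm"),
            imaging_dose_path=str(tmp_path / "img.dcm"),
            structure_path=str(tmp_path / "rs.dcm"),
        )
        config = AnalysisConfig(imaging_only=True)
        with pytest.warns(UserWarning, match="Unknown_ROI"):
            df = run_patient(record, ProtocolSpec("5MU", 5.0, 25), config)
        assert set(df.roi) == {"Lung_IPSI"}
        assert df.attrs["skipped"] == ["Unknown_ROI"]


class TestCompareProtocols:
    def test_mu_doubling_detected_as_significant(self, breast_cohort,
                                                 imaging_only_config):
        p5 = ProtocolSpec("5MU", 5.0, 25)
        p10 = ProtocolSpec("10MU", 10.0, 25)
        report = compare_protocols(
            breast_cohort["records"], p5, p10, imaging_only_config
        )
        comp = report.comparisons
        dose_rows = comp[comp.metric == "mean_dose_gy"]
        assert (dose_rows.p_value < 0.05).all()
        assert (dose_rows.significant).all()
        # every (patient, roi) present under both protocols
        counts = report.per_patient.groupby(["patient_id", "roi"]).protocol.nunique()
        assert (counts == 2).all()
        # metrics strictly larger under the doubled-MU protocol
        wide = report.per_patient.pivot_table(
            index=["patient_id", "roi"], columns="protocol",
            values=["mean_dose_gy", "ntcp_pct", "ear_per_10k_py"],
        )
        for metric in ("mean_dose_gy", "ntcp_pct", "ear_per_10k_py"):
            assert (wide[metric]["10MU"] > wide[metric]["5MU"]).all()

    def test_identical_protocols_flag_degenerate(self, breast_cohort,
                                                 imaging_only_config):
        p5a = ProtocolSpec("A", 5.0, 25)
        p5b = ProtocolSpec("B", 5.0, 25)
        report = compare_protocols(
            breast_cohort["records"][:3], p5a, p5b, imaging_only_config
        )
        assert report.comparisons.degenerate_variance.all()
        assert (report.comparisons.p_value == 1.0).all()


@pytest.fixture(scope="module")
def identical_dosimetry_report(tmp_path_factory):
    """Three patients sharing one phantom's files, differing only in age."""
    out = tmp_path_factory.mktemp("samedose")
    spec = CohortSpec(site="breast", n_patients=1, seed=5)
    row = generate_patient(SITE_TEMPLATES["breast"], spec, 0, out)
    records = [
        PatientRecord(
            id=f"A{age}", age_years=age, sex="F", site="breast",
            laterality="left", n_fractions=25,
            treatment_dose_path=str(out / row["treatment_dose_path"]),
            imaging_dose_path=str(out / row["imaging_dose_path"]),
            structure_path=str(out / row["structure_path"]),
        )
        for age in (30, 50, 65)
    ]
    config = AnalysisConfig(imaging_only=True)
    report = compare_protocols(
        records, ProtocolSpec("5MU", 5.0, 25), ProtocolSpec("10MU", 10.0, 25),
        config,
    )
    return records, config, report


class TestStratification:
    def test_ear_strictly_decreases_across_age_strata(self, identical_dosimetry_report):
        _, _, report = identical_dosimetry_report
        strata = report.strata
        for (roi, protocol), grp in strata.groupby(["roi", "protocol"]):
            ordered = grp.set_index("age_stratum").loc[list(AGE_STRATA_LABELS)]
            vals = ordered.ear_mean.to_numpy()
            assert vals[0] > vals[1] > vals[2], (roi, protocol)

    def test_null_age_coefficients_collapse_strata(self, identical_dosimetry_report):
        records, _, _ = identical_dosimetry_report
        registry = load_parameter_registry()
        registry.ear = {
            organ: dataclasses.replace(p, gamma_e=0.0, gamma_a=0.0)
            for organ, p in registry.ear.items()
        }
        config = AnalysisConfig(imaging_only=True, registry=registry)
        report = compare_protocols(
            records, ProtocolSpec("5MU", 5.0, 25), ProtocolSpec("10MU", 10.0, 25),
            config,
        )
        for (_, _), grp in report.strata.groupby(["roi", "protocol"]):
            vals = grp.ear_mean.to_numpy()
            np.testing.assert_allclose(vals, vals[0], rtol=1e-12)

    def test_empty_strata_reported_with_zero_count(self, identical_dosimetry_report):
        _, _, report = identical_dosimetry_report
        pp = report.per_patient[report.per_patient.age_years == 30]
        partial = dataclasses.replace(report, per_patient=pp)
        strata = stratify_by_age(partial)
        assert set(strata.age_stratum) == set(AGE_STRATA_LABELS)
        empty = strata[strata.age_stratum == ">60"]
        assert (empty.n == 0).all()
        assert empty.ear_mean.isna().all()


class TestSensitivitySweep:
    def test_alpha_prime_sweep_is_monotone(self, breast_cohort, imaging_only_config):
        record = breast_cohort["records"][0]
        table = sensitivity_sweep(
            record, ProtocolSpec("5MU", 5.0, 25), "alpha_prime",
            [0.0, 0.085, 0.2], imaging_only_config,
        )
        for roi, grp in table.groupby("roi"):
            vals = grp.sort_values("value").oed_gy.to_numpy()
            assert vals[0] >= vals[1] >= vals[2]

    def test_ear0_sweep_is_linear(self, breast_cohort, imaging_only_config):
        record = breast_cohort["records"][0]
        table = sensitivity_sweep(
            record, ProtocolSpec("5MU", 5.0, 25), "ear0", [2.0, 4.0],
            imaging_only_config,
        )
        for roi, grp in table.groupby("roi"):
            lo = grp[grp.value == 2.0].ear_per_10k_py.iloc[0]
            hi = grp[grp.value == 4.0].ear_per_10k_py.iloc[0]
            assert abs(hi - 2 * lo) < 1e-9

    def test_d50_sweep_decreases_ntcp(self, breast_cohort, imaging_only_config):
        record = breast_cohort["records"][0]
        table = sensitivity_sweep(
            record, ProtocolSpec("5MU", 5.0, 25), "d50", [20.0, 40.0, 80.0],
            imaging_only_config,
        )
        for roi, grp in table.groupby("roi"):
            vals = grp.sort_values("value").ntcp_pct.to_numpy()
            assert vals[0] > vals[1] > vals[2]

    def test_unknown_parameter_rejected(self, breast_cohort, imaging_only_config):
        with pytest.raises(ParameterError):
            sensitivity_sweep(
                breast_cohort["records"][0], ProtocolSpec("5MU", 5.0, 25),
                "banana", [1.0], imaging_only_config,
            )


class TestExport:
    def test_all_tables_written_and_consistent(self, breast_cohort,
                                               imaging_only_config, tmp_path):
        records = breast_cohort["records"][:3]
        report = compare_protocols(
            records, ProtocolSpec("5MU", 5.0, 25), ProtocolSpec("10MU", 10.0, 25),
            imaging_only_config,
        )
        paths = export_report(report, tmp_path / "out")
        for key in ("per_patient", "summary", "comparisons", "strata", "manifest"):
            assert key in paths
        pp = pd.read_csv(paths["per_patient"])
        assert len(pp) == len(records) * 4 * 2  # patients x ROIs x protocols
        manifest = json.loads(open(paths["manifest"]).read())
        assert manifest["config_fingerprint"]
        assert manifest["alpha"] == 0.05

    def test_rerun_is_byte_identical(self, breast_cohort, imaging_only_config,
                                     tmp_path):
        records = breast_cohort["records"][:2]
        args = (ProtocolSpec("5MU", 5.0, 25), ProtocolSpec("10MU", 10.0, 25),
                imaging_only_config)
        r1 = compare_protocols(records, *args)
        r2 = compare_protocols(records, *args)
        p1 = export_report(r1, tmp_path / "run1")
        p2 = export_report(r2, tmp_path / "run2")
        for key in ("per_patient", "summary", "comparisons", "strata"):
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_log_plots_drop_zeros_with_note(self, tmp_path):
        record_dir = tmp_path / "zero"
        record_dir.mkdir()
        record = _uniform_imaging_patient(record_dir, imaging_gy=0.0)
        record2 = dataclasses.replace(record, id="P2", age_years=55)
        config = AnalysisConfig(imaging_only=True)
        report = compare_protocols(
            [record, record2], ProtocolSpec("5MU", 5.0, 25),
            ProtocolSpec("10MU", 10.0, 25), config,
        )
        paths = export_report(report, tmp_path / "out", plots=True)
        manifest = json.loads(open(paths["manifest"]).read())
        assert any("dropped from log-scale" in n for n in manifest["plot_notes"])
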