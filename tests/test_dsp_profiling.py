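"""DSP QC gating, normalisation, differential proteins and cell scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatial_ith import dsp_profiling as dsp
from spatial_ith.synthetic_data import DSPConfig, simulate_dsp


def _aoi(**kw):
    base = dict(
        patient_id="P0",
        region="PT_sup",
        roi_id="ROI1",
        compartment="tumour",
        fov_pct=90.0,
        binding_density=1.0,
        nuclei=100,
        area_um2=5000.0,
        counts={},
    )
    base.update(kw)
    return dsp.AOIRecord(**base)


def _panel(targets=("CD8", "CD20"), marker_map=None):
    return dsp.ProbePanel(
        targets=list(targets), marker_map=marker_map or {}
    )


class TestQCFilter:
    @pytest.mark.parametrize(
        "field, value, passes",
        [
            ("fov_pct", 75.0, False),  # <= 75 eliminated
            ("fov_pct", 75.1, True),
            ("binding_density", 2.25, True),  # closed retention range
            ("binding_density", 2.26, False),
            ("binding_density", 0.1, True),
            ("binding_density", 0.09, False),
        ],
    )
    def test_scan_metric_boundaries(self, field, value, passes):
        passed, _ = dsp.qc_filter([_aoi(**{field: value})])
        assert bool(passed) is passes

    @pytest.mark.parametrize(
        "nuclei, area, passes",
        [
            (15, 2000.0, True),  # disjunction: area rescues low nuclei
            (21, 100.0, True),
            (20, 1600.0, False),  # both at their (failing) bounds
            (21, 1601.0, True),
        ],
    )
    def test_nuclei_area_disjunction(self, nuclei, area, passes):
        passed, _ = dsp.qc_filter([_aoi(nuclei=nuclei, area_um2=area)])
        assert bool(passed) is passes

    def test_injected_failures_match_truth_labels(self, dsp_result):
        records = dsp.read_aoi_table_from_frame(dsp_result.aoi_frame)
        passed, report = dsp.qc_filter(records)
        rejected = {a.aoi_id for a in records} - {a.aoi_id for a in passed}
        assert rejected == set(dsp_result.truth["qc_fail"])
        assert report.n_passed == len(records) - len(rejected)


class TestControlNormalize:
    def test_geometric_mean_factor_example(self):
        panel = _panel()
        aois = [
            _aoi(
                roi_id=f"R{i}",
                counts={
                    "CD8": 10.0 * f,
                    "CD20": 20.0 * f,
                    "S6": 4.0 * f,
                    "Histone H3": 8.0 * f,
                    "GAPDH": 16.0 * f,
                    "Ms IgG1": 2.0,
                    "Ms IgG2a": 2.0,
                    "Rb IgG": 2.0,
                },
            )
            for i, f in enumerate([1.0, 2.0])
        ]
        normed = dsp.control_normalize(aois, panel)
        # factors are (8, 16)/gm(8,16): first scaled up, second down
        np.testing.assert_allclose(normed["CD8"].to_numpy(), [10 * np.sqrt(2)] * 2)
        gms = np.exp(np.log(normed[["S6", "Histone H3", "GAPDH"]]).mean(axis=1))
        np.testing.assert_allclose(gms, gms.iloc[0])

    def test_uniform_rescale_of_one_aoi_is_noop(self, dsp_result):
        records = dsp.read_aoi_table_from_frame(dsp_result.aoi_frame)[:10]
        panel = dsp_result.panel
        doubled = [
            _aoi(
                patient_id=a.patient_id,
                region=a.region,
                roi_id=a.roi_id,
                compartment=a.compartment,
                counts={k: (2 * v if i == 0 else v) for k, v in a.counts.items()},
            )
            for i, a in enumerate(records)
        ]
        # fixed reference: the rescaled AOI normalises back exactly
        n1 = dsp.control_normalize(records, panel, reference=100.0)
        n2 = dsp.control_normalize(doubled, panel, reference=100.0)
        np.testing.assert_allclose(n1.to_numpy(), n2.to_numpy(), rtol=1e-10)
        # cohort reference: relative expression across AOIs is preserved
        c1 = dsp.control_normalize(records, panel)
        c2 = dsp.control_normalize(doubled, panel)
        ratio = c2.to_numpy() / c1.to_numpy()
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-10)

    def test_zero_control_rejected(self):
        panel = _panel()
        a = _aoi(counts={"CD8": 1, "CD20": 1, "S6": 0, "Histone H3": 1, "GAPDH": 1,
                         "Ms IgG1": 1, "Ms IgG2a": 1, "Rb IgG": 1})
        with pytest.raises(ValueError, match="S6"):
            dsp.control_normalize([a], panel)


class TestBackgroundNormalize:
    def test_ratio_to_igg_geometric_mean(self):
        panel = _panel(targets=("CD8",))
        a = _aoi(counts={"CD8": 64.0, "Ms IgG1": 2.0, "Ms IgG2a": 4.0, "Rb IgG": 8.0})
        signal = dsp.background_normalize([a], panel)
        assert signal["CD8"].iloc[0] == pytest.approx(16.0)

    def test_target_equal_to_background_gives_one(self):
        panel = _panel(targets=("CD8",))
        a = _aoi(counts={"CD8": 4.0, "Ms IgG1": 4.0, "Ms IgG2a": 4.0, "Rb IgG": 4.0})
        assert dsp.background_normalize([a], panel)["CD8"].iloc[0] == pytest.approx(1.0)

    def test_planted_signal_to_noise_structure(self, dsp_result):
        records = dsp.read_aoi_table_from_frame(dsp_result.aoi_frame)
        passed, _ = dsp.qc_filter(records)
        panel = dsp_result.panel
        signal = dsp.background_normalize(
            dsp.control_normalize(passed, panel), panel
        )
        # real targets sit far above background on the log2 SNR scale
        assert np.log2(signal).mean().mean() > 1.0


class TestSimulatedBulk:
    def test_single_aoi_identity_and_mean(self):
        panel = _panel(targets=("CD8",))
        aois = [
            _aoi(roi_id="R1", counts={"CD8": 2.0, "Ms IgG1": 1, "Ms IgG2a": 1, "Rb IgG": 1}),
            _aoi(roi_id="R2", counts={"CD8": 4.0, "Ms IgG1": 1, "Ms IgG2a": 1, "Rb IgG": 1}),
        ]
        values = dsp.background_normalize(aois, panel)
        bulk = dsp.simulated_bulk(values, aois)
        assert bulk["CD8"].loc[("P0", "PT_sup")] == pytest.approx(3.0)
        single = dsp.simulated_bulk(values.iloc[:1], aois[:1])
        assert single["CD8"].iloc[0] == pytest.approx(2.0)

    def test_matches_independent_mean(self, dsp_result, rng):
        records = dsp.read_aoi_table_from_frame(dsp_result.aoi_frame)
        passed, _ = dsp.qc_filter(records)
        panel = dsp_result.panel
        signal = dsp.background_normalize(passed, panel)
        bulk = dsp.simulated_bulk(signal, passed, compartment="stroma")
        sample = bulk.index[0]
        ids = [
            a.aoi_id
            for a in passed
            if (a.patient_id, a.region) == sample and a.compartment == "stroma"
        ]
        np.testing.assert_allclose(
            bulk.loc[sample].to_numpy(), signal.loc[ids].mean(axis=0).to_numpy()
        )


class TestDifferentialProteins:
    @staticmethod
    def _frames(rng, shift=1.0, n=20):
        a = pd.DataFrame(
            {"CD8": rng.lognormal(1.0 + np.log(shift), 0.2, n),
             "CD20": rng.lognormal(1.0, 0.2, n)}
        )
        b = pd.DataFrame(
            {"CD8": rng.lognormal(1.0, 0.2, n), "CD20": rng.lognormal(1.0, 0.2, n)}
        )
        return a, b

    def test_identical_groups_not_significant(self, rng):
        a, _ = self._frames(rng)
        table = dsp.differential_proteins(a, a.copy())
        assert (table["log2_fc"] == 0).all()
        assert not table["significant"].any()

    def test_planted_two_fold_shift_detected_with_sign(self, rng):
        a, b = self._frames(rng, shift=2.0)
        table = dsp.differential_proteins(a, b)
        assert table.loc["CD8", "significant"]
        assert table.loc["CD8", "log2_fc"] > 0
        assert not table.loc["CD20", "significant"]

    def test_group_swap_negates_fc_and_preserves_p(self, rng):
        a, b = self._frames(rng, shift=2.0)
        t1 = dsp.differential_proteins(a, b)
        t2 = dsp.differential_proteins(b, a)
        np.testing.assert_allclose(t1["log2_fc"], -t2["log2_fc"])
        np.testing.assert_allclose(t1["p"], t2["p"])

    def test_fc_gate_blocks_small_folds(self, rng):
        # strongly significant rank shift but fold change below 1.5
        a = pd.DataFrame({"CD8": rng.lognormal(np.log(1.3), 0.01, 40)})
        b = pd.DataFrame({"CD8": rng.lognormal(0.0, 0.01, 40)})
        table = dsp.differential_proteins(a, b)
        assert table.loc["CD8", "fdr"] <= 0.05
        assert not table.loc["CD8", "significant"]


class TestCellAbundance:
    def test_mean_log2_example(self):
        panel = _panel(targets=("CD8", "CD20"), marker_map={"T": ["CD8", "CD20"]})
        values = pd.DataFrame({"CD8": [4.0], "CD20": [16.0]})
        scores = dsp.cell_abundance(values, panel)
        assert scores["T"].iloc[0] == pytest.approx(3.0)

    def test_translation_equivariance(self, rng):
        panel = _panel(targets=("CD8", "CD20"), marker_map={"T": ["CD8", "CD20"]})
        values = pd.DataFrame(rng.lognormal(0, 1, (5, 2)), columns=["CD8", "CD20"])
        s1 = dsp.cell_abundance(values, panel)
        s2 = dsp.cell_abundance(values * 8.0, panel)
        np.testing.assert_allclose(s2["T"], s1["T"] + 3.0)

    def test_missing_marker_probe_named(self):
        panel = _panel(targets=("CD8",), marker_map={"T": ["CD8"]})
        values = pd.DataFrame({"CD20": [1.0]})
        with pytest.raises(ValueError, match="CD8"):
            dsp.cell_abundance(values, panel)

    def test_planted_b_cell_shift_detected(self, dsp_result):
        from scipy.stats import mannwhitneyu

        records = dsp.read_aoi_table_from_frame(dsp_result.aoi_frame)
        passed, _ = dsp.qc_filter(records)
        panel = dsp_result.panel
        signal = dsp.background_normalize(
            dsp.control_normalize(passed, panel), panel
        )
        scores = dsp.cell_abundance(signal, panel)
        meta = {a.aoi_id: a for a in passed}
        ln = [
            scores.loc[i, "B cells"]
            for i in scores.index
            if meta[i].region == "LN_met" and meta[i].compartment == "stroma"
        ]
        pts = [
            scores.loc[i, "B cells"]
            for i in scores.index
            if meta[i].region == "PT_sup" and meta[i].compartment == "stroma"
        ]
        p = mannwhitneyu(ln, pts, alternative="two-sided").pvalue
        assert p < 0.05
        assert np.mean(ln) > np.mean(pts)
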