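"""Volume statistics: SD tables, mixed models, ANOVA + Tukey, normality."""

import numpy as np
import pandas as pd
import pytest

from gtvkit.grid import Modality, ObserverRole
from gtvkit.stats import (
    VolumeRecord,
    compare_sd_across_modalities,
    cube_root,
    fit_volume_model,
    normality_check,
    role_contrast,
    sd_table,
    sd_table_from_sds,
    simulate_volume_records,
)


def _records(volumes_by_cell):
    """volumes_by_cell: {(patient, modality, observer, role): volume}"""
    return [
        VolumeRecord(p, Modality(m), o, ObserverRole(r), v)
        for (p, m, o, r), v in volumes_by_cell.items()
    ]


class TestCubeRoot:
    @pytest.mark.parametrize("v,expected", [(8, 2), (1, 1), (11.9, 11.9 ** (1 / 3))])
    def test_values(self, v, expected):
        assert cube_root(v) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            cube_root(0.0)

    def test_strictly_monotone(self, rng):
        v = np.sort(rng.uniform(0.1, 50, 20))
        out = [cube_root(x) for x in v]
        assert all(a < b for a, b in zip(out, out[1:]))


class TestSDTable:
    def test_sample_sd_with_n_minus_one(self):
        recs = _records(
            {
                ("P01", "CT", "A", "radiologist"): 10,
                ("P01", "CT", "B", "oncologist"): 12,
                ("P01", "CT", "C", "oncologist"): 14,
            }
        )
        table = sd_table(recs)
        assert table.per_patient.loc["P01", "CT"] == pytest.approx(2.0)

    def test_identical_volumes_give_zero_sd(self):
        recs = _records(
            {
                ("P01", "MR", "A", "radiologist"): 7,
                ("P01", "MR", "B", "oncologist"): 7,
            }
        )
        assert sd_table(recs).per_patient.loc["P01", "MR"] == 0.0

    def test_single_observer_cell_reported_missing(self):
        recs = _records(
            {
                ("P01", "CT", "A", "radiologist"): 10,
                ("P01", "CT", "B", "oncologist"): 12,
                ("P02", "CT", "A", "radiologist"): 9,
            }
        )
        table = sd_table(recs)
        assert np.isnan(table.per_patient.loc["P02", "CT"])
        # column mean over available cells only
        assert table.column_means["CT"] == pytest.approx(np.sqrt(2))

    def test_pet_excluded(self):
        recs = _records(
            {
                ("P01", "CT", "A", "radiologist"): 10,
                ("P01", "CT", "B", "oncologist"): 12,
                ("P01", "PET", "auto", "auto"): 8,
            }
        )
        assert "PET" not in sd_table(recs).per_patient.columns


class TestAnovaTukey:
    def test_identical_columns_give_no_significant_pairs(self):
        per = pd.DataFrame({"CT": [3, 4, 5, 4], "MR": [3, 4, 5, 4], "CTMR": [3, 4, 5, 4]})
        res = compare_sd_across_modalities(sd_table_from_sds(per))
        assert res.significant_pairs == []

    def test_f_statistic_matches_manual_sums_of_squares(self):
        # two groups, n=3 each: hand-computed one-way ANOVA
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 5.0, 9.0]
        per = pd.DataFrame({"A": g1, "B": g2})
        res = compare_sd_across_modalities(sd_table_from_sds(per))
        grand = np.mean(g1 + g2)
        ss_between = 3 * ((np.mean(g1) - grand) ** 2 + (np.mean(g2) - grand) ** 2)
        ss_within = sum((x - np.mean(g1)) ** 2 for x in g1) + sum(
            (x - np.mean(g2)) ** 2 for x in g2
        )
        f_manual = (ss_between / 1) / (ss_within / 4)
        assert res.f_statistic == pytest.approx(f_manual)

    def test_separated_groups_detected(self, rng):
        per = pd.DataFrame(
            {
                "CT": rng.normal(4.5, 1, 11),
                "MR": rng.normal(2.0, 1, 11),
            }
        )
        res = compare_sd_across_modalities(sd_table_from_sds(per))
        assert ("CT", "MR") in [tuple(sorted(p)) for p in res.significant_pairs]

    def test_all_equal_input_reports_undefined_f(self):
        per = pd.DataFrame({"CT": [2.0, 2.0, 2.0], "MR": [2.0, 2.0, 2.0]})
        res = compare_sd_across_modalities(sd_table_from_sds(per))
        assert np.isnan(res.f_statistic)


class TestNormalityCheck:
    def test_exact_normal_quantiles_give_correlation_one(self):
        from scipy import stats as sps

        n = 50
        q = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        r, ok = normality_check(q)
        assert r == pytest.approx(1.0, abs=1e-3)
        assert ok

    def test_skewed_sample_fails(self, rng):
        x = rng.exponential(1.0, 100)
        r, ok = normality_check(x)
        assert r < 0.975
        assert not ok

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="insufficient"):
            normality_check([1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            normality_check([3.0] * 10)


class TestMixedModel:
    def test_single_observer_per_cell_fits_with_pet(self):
        recs = []
        rng = np.random.default_rng(0)
        for p in range(4):
            for m in ("CT", "PET"):
                recs.append(
                    VolumeRecord(
                        f"P{p}", Modality(m), "auto", ObserverRole.AUTO,
                        10 + rng.normal(0, 1) + (2 if m == "CT" else 0),
                    )
                )
        res = fit_volume_model(recs, include_pet=True)
        assert "CT_vs_PET" in res.contrasts
        assert res.include_pet

    def test_effect_sign_recovered(self):
        eff = 2.29 * (1.2 ** (1 / 3) - 1)
        recs = simulate_volume_records(
            modality_effects={Modality.CT: 0.0, Modality.CTMR: eff, Modality.MR: 0.0},
            rng=np.random.default_rng(11),
        )
        res = fit_volume_model(recs)
        assert res.contrast("CTMR", "CT")["estimate"] > 0

    def test_unit_rescaling_shifts_intercept_only(self):
        recs = simulate_volume_records(rng=np.random.default_rng(3))
        res1 = fit_volume_model(recs)
        scaled = [
            VolumeRecord(r.patient_id, r.modality, r.observer_id, r.observer_role,
                         r.volume_cm3 * 1000.0)
            for r in recs
        ]
        res2 = fit_volume_model(scaled)
        # cube-root of a x1000 rescale multiplies the response by 10: all
        # fixed effects scale by 10, so contrast z-scores and p-values match
        for key in res1.contrasts:
            assert res2.contrasts[key]["estimate"] == pytest.approx(
                10 * res1.contrasts[key]["estimate"], rel=1e-4
            )
            assert res2.contrasts[key]["p_value"] == pytest.approx(
                res1.contrasts[key]["p_value"], abs=1e-6
            )

    def test_variance_recovery_at_larger_n(self):
        # the observer component is informed by only 5 observer draws per
        # study, so recovery is assessed on the mean over fixed replicates
        pat, obs, resid = [], [], []
        for i in range(6):
            recs = simulate_volume_records(
                n_patients=50, sd_patient=0.5, sd_observer=0.15, sd_residual=0.2,
                rng=np.random.default_rng([21, i]),
            )
            res = fit_volume_model(recs)
            pat.append(res.random_effect_variances["patient"])
            obs.append(res.random_effect_variances["observer"])
            resid.append(res.residual_variance)
        assert np.mean(pat) == pytest.approx(0.25, rel=0.5)
        assert np.mean(obs) == pytest.approx(0.0225, rel=0.5)
        assert np.mean(resid) == pytest.approx(0.04, rel=0.5)

    def test_permuted_labels_give_uniformish_pvalues(self):
        rng = np.random.default_rng(99)
        pvals = []
        for i in range(40):
            recs = simulate_volume_records(rng=np.random.default_rng([99, i]))
            pvals.append(fit_volume_model(recs).contrast("CT", "MR")["p_value"])
        pvals = np.asarray(pvals)
        # null p-values should not pile up near zero
        assert (pvals < 0.05).mean() <= 0.2
        assert pvals.mean() == pytest.approx(0.5, abs=0.2)

    def test_too_few_modalities_rejected(self):
        recs = _records(
            {
                ("P01", "CT", "A", "radiologist"): 10,
                ("P02", "CT", "A", "radiologist"): 11,
            }
        )
        with pytest.raises(ValueError, match="modalities"):
            fit_volume_model(recs)


class TestRoleContrast:
    def test_null_centred_over_simulations(self):
        ests = []
        for i in range(20):
            recs = simulate_volume_records(role_effect=0.0, rng=np.random.default_rng([5, i]))
            out = role_contrast(recs)
            ests.append(out.loc[out["modality"] == "all", "contrast_cuberoot"].item())
        assert np.mean(ests) == pytest.approx(0.0, abs=0.1)

    def test_positive_effect_recovered_per_modality_and_pooled(self):
        eff = 2.29 * (1.5 ** (1 / 3) - 1)
        recs = simulate_volume_records(role_effect=eff, rng=np.random.default_rng(17))
        out = role_contrast(recs)
        assert (out["contrast_cuberoot"] > 0).all()
        assert set(out["modality"]) == {"CT", "CTMR", "MR", "all"}

    def test_single_role_rejected(self):
        recs = _records(
            {
                ("P01", "CT", "A", "oncologist"): 10,
                ("P01", "CT", "B", "oncologist"): 12,
            }
        )
        with pytest.raises(ValueError, match="role contrast unavailable"):
            role_contrast(recs)
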