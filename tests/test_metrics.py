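"""Concordance metrics: frozen examples, algebraic identities, oracle checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtvkit.grid import EmptyStructureError, GridMismatchError, Modality
from gtvkit.metrics import (
    cgd_mm,
    concordance,
    interobserver_summary,
    intermodality_pairs_table,
    intermodality_summary,
    mdc_mm,
    overlap_metrics,
)

from conftest import brute_force_metrics, cube_mask, make_mask, random_mask_pair


class TestOverlapMetrics:
    def test_identical_masks_are_perfectly_concordant(self):
        m = cube_mask((1, 1, 1), 3)
        assert overlap_metrics(m, m) == pytest.approx((1, 1, 1, 1))
        assert cgd_mm(m, m) == 0.0
        assert mdc_mm(m, m) == 0.0

    def test_disjoint_masks_have_zero_overlap(self):
        a = cube_mask((0, 0, 0), 2)
        b = cube_mask((5, 5, 5), 2)
        assert overlap_metrics(a, b) == pytest.approx((0, 0, 0, 0))

    def test_offset_cubes_frozen_values(self):
        # 2x2x2 cubes offset by one voxel in x: |a|=|b|=8, intersection 4, union 12
        a = cube_mask((0, 0, 0), 2)
        b = cube_mask((1, 0, 0), 2)
        ci, dice, se, incl = overlap_metrics(a, b)
        assert (ci, dice, se, incl) == pytest.approx((1 / 3, 0.5, 0.5, 0.5))
        assert cgd_mm(a, b) == pytest.approx(1.0)
        assert mdc_mm(a, b) == pytest.approx(1.0)

    def test_single_voxel_distances(self):
        a = make_mask([(0, 0, 0)])
        b3 = make_mask([(3, 0, 0)])
        b2 = make_mask([(2, 0, 0)])
        assert cgd_mm(a, b3) == pytest.approx(3.0)
        assert mdc_mm(a, b2) == pytest.approx(2.0)

    def test_anisotropic_spacing_enters_distances(self):
        a = make_mask([(0, 0, 0)], spacing=(1, 1, 3))
        b = make_mask([(0, 0, 1)], spacing=(1, 1, 3))
        assert cgd_mm(a, b) == pytest.approx(3.0)
        assert mdc_mm(a, b) == pytest.approx(3.0)

    def test_empty_and_mismatched_inputs_rejected(self):
        m = cube_mask((0, 0, 0), 2)
        with pytest.raises(EmptyStructureError):
            overlap_metrics(m, make_mask([]))
        other = cube_mask((0, 0, 0), 2, spacing=(2, 2, 2))
        with pytest.raises(GridMismatchError):
            overlap_metrics(m, other)


class TestOracleAndIdentities:
    def test_metrics_match_brute_force_on_random_pairs(self, rng):
        for _ in range(30):
            a, b = random_mask_pair(rng, max_dim=12)
            res = concordance(a, b).as_dict()
            ref = brute_force_metrics(a, b)
            for k in res:
                assert res[k] == pytest.approx(ref[k], abs=1e-9), k

    def test_dice_ci_link_and_direction_symmetry(self, rng):
        for _ in range(20):
            a, b = random_mask_pair(rng)
            ci, dice, se, incl = overlap_metrics(a, b)
            assert dice == pytest.approx(2 * ci / (1 + ci), abs=1e-12)
            assert ci <= dice + 1e-12
            ci2, dice2, se2, incl2 = overlap_metrics(b, a)
            assert se == pytest.approx(incl2, abs=1e-12)
            assert incl == pytest.approx(se2, abs=1e-12)
            assert mdc_mm(a, b) == pytest.approx(mdc_mm(b, a), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        shift=st.tuples(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4)),
        seed=st.integers(0, 10_000),
    )
    def test_translation_equivariance(self, shift, seed):
        """Translating both masks by the same integer offset changes nothing."""
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng, max_dim=8)
        big = (20, 20, 20)

        def embed(mask, offset):
            v = np.zeros(big, dtype=bool)
            sl = tuple(slice(o, o + d) for o, d in zip(offset, mask.grid.dims))
            v[sl] = mask.voxels
            return make_mask([], dims=big).with_voxels(v)

        ref = concordance(embed(a, (0, 0, 0)), embed(b, (0, 0, 0))).as_dict()
        res = concordance(embed(a, shift), embed(b, shift)).as_dict()
        for k in res:
            assert res[k] == pytest.approx(ref[k], abs=1e-9), k

    def test_growing_overlap_increases_ci_and_dice(self):
        # fixed-size 2x2x2 cubes sliding together: offset 2 (disjoint-touching),
        # 1 (half overlap), 0 (identical)
        vals = []
        for off in (2, 1, 0):
            a = cube_mask((0, 0, 0), 2)
            b = cube_mask((off, 0, 0), 2)
            vals.append(overlap_metrics(a, b)[:2])
        assert vals[0][0] < vals[1][0] < vals[2][0]
        assert vals[0][1] < vals[1][1] < vals[2][1]


def _study_masks(n_patients=2, observers=("A", "B", "C"), modalities=("CT",)):
    """Hand-built observer masks: observer k's cube is shifted k voxels in x."""
    masks = {}
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        for mod in modalities:
            for k, obs in enumerate(observers):
                masks[(pid, mod, obs)] = cube_mask(
                    (1 + k, 1 + p, 1), 3, dims=(10, 10, 10),
                    patient_id=pid, modality=Modality(mod), observer_id=obs,
                )
    return masks


class TestAggregation:
    def test_identical_observer_masks_give_perfect_summary(self):
        masks = _study_masks(observers=("A", "B"))
        # make B identical to A
        for p in ("P01", "P02"):
            masks[(p, "CT", "B")] = masks[(p, "CT", "A")].with_voxels(
                masks[(p, "CT", "A")].voxels
            )
        out = interobserver_summary(masks, Modality.CT)
        by_metric = out.set_index("metric")
        assert by_metric.loc["CI", "mean"] == 1.0
        assert by_metric.loc["DICE", "mean"] == 1.0
        assert by_metric.loc["CGD", "mean"] == 0.0
        assert by_metric.loc["MDC", "mean"] == 0.0
        assert (by_metric["sd"] == 0.0).all()

    def test_three_observers_mean_equals_brute_force_over_pairs(self):
        masks = _study_masks(n_patients=1)
        pairs = [("A", "B"), ("A", "C"), ("B", "C")]
        expected_ci = np.mean(
            [
                overlap_metrics(masks[("P01", "CT", x)], masks[("P01", "CT", y)])[0]
                for x, y in pairs
            ]
        )
        out = interobserver_summary(masks, Modality.CT).set_index("metric")
        assert out.loc["CI", "mean"] == pytest.approx(expected_ci)
        assert out.loc["CI", "n_patients"] == 1

    def test_missing_observer_only_drops_their_pairs(self):
        masks = _study_masks()
        del masks[("P02", "CT", "C")]
        out = interobserver_summary(masks, Modality.CT).set_index("metric")
        assert out.loc["CI", "n_patients"] == 2  # both patients still contribute

    def test_insufficient_observers_raises(self):
        masks = _study_masks(observers=("A",))
        with pytest.raises(ValueError, match="insufficient observers"):
            interobserver_summary(masks, Modality.CT)

    def test_intermodality_direction_semantics(self):
        """SeIdx is 'first within second'; InclIdx 'second within first'."""
        masks = {}
        # CT cube 3^3; MR cube 2^3 fully inside it -> MR fully within CT
        masks[("P01", "CT", "A")] = cube_mask(
            (1, 1, 1), 3, patient_id="P01", modality=Modality.CT, observer_id="A"
        )
        masks[("P01", "MR", "A")] = cube_mask(
            (1, 1, 1), 2, patient_id="P01", modality=Modality.MR, observer_id="A"
        )
        table = intermodality_pairs_table(masks, pairs=((Modality.CT, Modality.MR),))
        vals = table.set_index("metric")["value"]
        assert vals["SeIdx"] == pytest.approx(8 / 27)  # CT within MR
        assert vals["InclIdx"] == pytest.approx(1.0)  # MR within CT

    def test_pet_pairs_use_single_auto_mask_per_clinician(self):
        masks = {}
        for obs in ("A", "B"):
            masks[("P01", "CT", obs)] = cube_mask(
                (1, 1, 1), 3, patient_id="P01", modality=Modality.CT, observer_id=obs
            )
        masks[("P01", "PET", "auto")] = cube_mask(
            (1, 1, 1), 3, patient_id="P01", modality=Modality.PET, observer_id="auto"
        )
        table = intermodality_pairs_table(masks, pairs=((Modality.CT, Modality.PET),))
        # both clinicians compared against the one PET mask
        assert len(table) == 2 * 6
        assert set(table["observer_b"]) == {"auto"}

    def test_summary_sd_zero_with_single_patient(self):
        masks = _study_masks(n_patients=1, modalities=("CT", "MR"))
        out = intermodality_summary(masks, pairs=((Modality.CT, Modality.MR),))
        assert (out["n_patients"] == 1).all()
        assert (out["sd"] == 0.0).all()

    def test_no_comparable_pairs_raises(self):
        masks = _study_masks(n_patients=1, modalities=("CT",))
        with pytest.raises(ValueError, match="no comparable pairs"):
            intermodality_summary(masks, pairs=((Modality.CT, Modality.MR),))
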