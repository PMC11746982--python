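"""Generators: geometry, masks, analytic volumes, cohort sampling."""

import numpy as np
import pytest
from scipy import ndimage

import tabfx
from tabfx.grids import GridSpec
from tabfx.synthetic import (
    CardiacStudySpec,
    DefectSpec,
    PhantomSpec,
    TableModel,
    generate_cardiac_study,
    generate_jaszczak,
    sample_cohort,
    table_shell_cross_section_mm2,
)


@pytest.fixture(scope="module")
def grids():
    return (
        GridSpec.centered((64, 64, 64), (9.6, 9.6, 9.6)),
        GridSpec.centered((256, 256, 48), (2.0, 2.0, 5.0)),
    )


class TestJaszczak:
    def test_no_table_leaves_air_below_phantom(self, grids):
        spect, ctg = grids
        ct, _, _ = generate_jaszczak(
            PhantomSpec(), TableModel(enabled=False), ctg, spect
        )
        r_out = 216 / 2 + 9.5
        below = ctg.coords(1) > r_out
        assert np.all(ct.values[:, below, :] <= -700)

    def test_table_voxel_count_matches_analytic_arc_shell(self, grids):
        spect, ctg = grids
        table = TableModel()
        _, _, truth = generate_jaszczak(PhantomSpec(), table, ctg, spect)
        analytic = (
            table_shell_cross_section_mm2(table)
            * ctg.shape[2]
            * ctg.spacing_mm[2]
            / ctg.voxel_volume_mm3
        )
        assert truth.table_mask.values.sum() == pytest.approx(analytic, rel=0.05)

    def test_analytic_agreement_improves_as_spacing_halves(self):
        spect = GridSpec.centered((64, 64, 64), (9.6, 9.6, 9.6))
        table = TableModel()
        errs = []
        for spacing in (4.0, 2.0):
            ctg = GridSpec.centered(
                (int(512 / spacing), int(512 / spacing), 48), (spacing, spacing, 5.0)
            )
            _, _, truth = generate_jaszczak(PhantomSpec(), table, ctg, spect)
            analytic = (
                table_shell_cross_section_mm2(table)
                * ctg.shape[2] * ctg.spacing_mm[2] / ctg.voxel_volume_mm3
            )
            errs.append(abs(truth.table_mask.values.sum() / analytic - 1))
        assert errs[1] < errs[0]

    def test_interior_ct_is_exactly_fill_hu(self, grids):
        spect, ctg = grids
        ct, _, truth = generate_jaszczak(PhantomSpec(fill_hu=0.0), TableModel(), ctg, spect)
        x, y, z = ctg.meshgrid()
        strict_interior = (x * x + y * y <= 90**2) & (np.abs(z) < 80)
        interior = np.broadcast_to(strict_interior, ctg.shape)
        assert np.all(ct.values[interior] == 0.0)

    def test_masks_disjoint_and_connected(self, grids):
        spect, ctg = grids
        _, _, truth = generate_jaszczak(PhantomSpec(), TableModel(), ctg, spect)
        t = truth.table_mask.values
        b = truth.body_mask.values
        assert not (t & b).any()
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for mask in (t, b):
            _, n = ndimage.label(mask, structure=struct)
            assert n == 1

    def test_oversized_phantom_raises_naming_dimension(self, grids):
        spect, ctg = grids
        with pytest.raises(ValueError, match="diameter"):
            generate_jaszczak(
                PhantomSpec(interior_diameter_mm=700), TableModel(), ctg, spect
            )

    def test_activity_uniform_inside_interior(self, grids):
        spect, ctg = grids
        _, act, truth = generate_jaszczak(
            PhantomSpec(activity_concentration=2.5), TableModel(), ctg, spect
        )
        inside = truth.interior_mask.values
        assert np.all(act.values[inside] == 2.5)
        assert np.all(act.values[~inside] == 0.0)


class TestCardiac:
    def test_uniform_shell_without_defect(self, grids):
        spect, ctg = grids
        _, act, truth = generate_cardiac_study(
            CardiacStudySpec(), TableModel(), ctg, spect
        )
        shell = truth.lv_shell_mask.values
        vals = act.values[shell]
        assert np.all(vals == vals[0])

    def test_defect_region_mean_matches_residual_fraction(self, grids):
        spect, ctg = grids
        spec = CardiacStudySpec(defect=DefectSpec("inferior", 0.4))
        _, act, truth = generate_cardiac_study(spec, TableModel(), ctg, spect)
        d = truth.defect_mask.values
        rest = truth.lv_shell_mask.values & ~d
        ratio = act.values[d].mean() / act.values[rest].mean()
        assert ratio == pytest.approx(0.4, rel=0.01)

    def test_same_seed_is_bit_identical(self, grids):
        spect, ctg = grids
        spec = CardiacStudySpec(defect=DefectSpec("lateral", 0.5))
        out1 = generate_cardiac_study(spec, TableModel(), ctg, spect, seed=3)
        out2 = generate_cardiac_study(spec, TableModel(), ctg, spect, seed=3)
        assert np.array_equal(out1[0].values, out2[0].values)
        assert np.array_equal(out1[1].values, out2[1].values)

    def test_invalid_defect_fraction_rejected(self):
        with pytest.raises(ValueError):
            DefectSpec("inferior", 1.5)

    def test_table_mask_disjoint_from_torso(self, grids):
        spect, ctg = grids
        _, _, truth = generate_cardiac_study(
            CardiacStudySpec(), TableModel(), ctg, spect
        )
        assert not (truth.table_mask.values & truth.body_mask.values).any()


class TestCohort:
    def test_reproducible_specs(self):
        a = sample_cohort(19, seed=7)
        b = sample_cohort(19, seed=7)
        assert len(a) == 19
        assert a == b

    def test_body_widths_within_configured_bounds(self):
        ranges = tabfx.CohortRanges()
        specs = sample_cohort(200, seed=1, ranges=ranges)
        ax = np.array([s.body_axes_mm[0] for s in specs])
        ay = np.array([s.body_axes_mm[1] for s in specs])
        assert ax.min() >= ranges.body_ax_range_mm[0]
        assert ax.max() <= ranges.body_ax_range_mm[1]
        assert ay.min() >= ranges.body_ay_range_mm[0]
        assert ay.max() <= ranges.body_ay_range_mm[1]

    def test_stress_fraction_matches_cohort_mix(self):
        specs = sample_cohort(1000, seed=11)
        frac = np.mean([s.protocol_label == "stress" for s in specs])
        assert frac == pytest.approx(13 / 19, abs=0.05)

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            sample_cohort(0, seed=0)


def test_table_below_removal_threshold_rejected():
    with pytest.raises(ValueError, match="-700"):
        TableModel(hu_value=-800.0)
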