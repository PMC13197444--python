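"""Lesion metrics, bracket aggregation, sDmax and spleen reference."""

import numpy as np
import pandas as pd
import pytest

from conftest import as_volume
from dualpet.concordance import label_components
from dualpet.errors import DomainError
from dualpet.features import (
    ClinicalRecord,
    aggregate_patient,
    body_surface_area,
    bracket,
    imaging_feature_columns,
    lesion_metrics,
    sdmax,
    spleen_reference,
)
from dualpet.synthetic import plant_lesion
from dualpet.volume import ScalarVolume


def _uniform_box_lesion(shape, box, suv, spacing):
    mask = np.zeros(shape, np.uint8)
    pet = np.zeros(shape)
    mask[box] = 1
    pet[box] = suv
    les = label_components(as_volume(mask, spacing)).lesions[0]
    return les, as_volume(pet, spacing, units="SUV")


class TestLesionMetrics:
    def test_uniform_box_phantom(self):
        les, pet = _uniform_box_lesion(
            (14, 14, 14), (slice(2, 12),) * 3, 4.0, (2.0, 2.0, 2.0)
        )
        m = lesion_metrics(les, pet)
        assert m.mtv_ml == pytest.approx(8.0)
        assert m.suv_mean == 4.0 and m.suv_max == 4.0
        assert m.tlg == pytest.approx(32.0)

    def test_single_voxel(self):
        les, pet = _uniform_box_lesion(
            (5, 5, 5), (slice(2, 3),) * 3, 7.0, (4.0, 4.0, 4.0)
        )
        m = lesion_metrics(les, pet)
        assert m.mtv_ml == pytest.approx(0.064)
        assert m.tlg == pytest.approx(0.448)

    def test_gaussian_taper_mean_matches_voxel_loop(self):
        base = ScalarVolume(np.zeros((20, 20, 20)), (2, 2, 2), units="SUV")
        pet = plant_lesion(base, (20, 20, 20), 10.0, 5.0, gaussian_taper=True)
        mask = (pet.values > 0).astype(np.uint8)
        les = label_components(as_volume(mask, (2, 2, 2))).lesions[0]
        m = lesion_metrics(les, pet)
        total, peak, n = 0.0, -1.0, 0
        for x, y, z in les.indices:
            total += pet.values[x, y, z]
            peak = max(peak, pet.values[x, y, z])
            n += 1
        assert m.suv_mean == pytest.approx(total / n, abs=1e-12)
        assert m.suv_max == pytest.approx(peak)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["tracer", "site", "category", "n_voxels", "suv_mean", "suv_max", "mtv_ml"],
    )


class TestAggregation:
    def test_volume_weighted_mean_hand_arithmetic(self):
        # 8 ml @ SUVmean 4 and 2 ml @ SUVmean 9 -> pooled (8*4+2*9)/10 = 5.0
        df = _records([
            ("FDG", "medullary", "concordant", 8000, 4.0, 6.0, 8.0),
            ("FDG", "medullary", "concordant", 2000, 9.0, 11.0, 2.0),
        ])
        out = aggregate_patient(df)
        assert out[bracket("MTV", "FDG", "medullary", "concordant")] == pytest.approx(10.0)
        assert out[bracket("SUVmean", "FDG", "medullary", "concordant")] == pytest.approx(5.0)
        assert out[bracket("TLG", "FDG", "medullary", "concordant")] == pytest.approx(50.0)
        assert out[bracket("SUVmax", "FDG", "medullary", "concordant")] == 11.0

    def test_empty_subsets_zero_burden_missing_intensity(self):
        out = aggregate_patient(_records([]))
        assert out[bracket("MTV", "FDG", "extramedullary", "discordant")] == 0.0
        assert np.isnan(out[bracket("SUVmean", "FDG", "extramedullary", "discordant")])
        assert np.isnan(out[bracket("SUVmax", "CXCR4", "medullary", "concordant")])
        assert out[bracket("TLC", "CXCR4", "medullary", "discordant")] == 0.0

    def test_single_lesion_subset_equals_lesion_metrics(self):
        df = _records([("CXCR4", "extramedullary", "CXCR4_only", 500, 6.0, 9.0, 3.0)])
        out = aggregate_patient(df)
        key = ("CXCR4", "extramedullary", "discordant")
        assert out[bracket("SUVmean", *key)] == 6.0
        assert out[bracket("SUVmax", *key)] == 9.0
        assert out[bracket("MTV", *key)] == 3.0
        assert out[bracket("TLC", *key)] == 18.0

    def test_additivity_over_disjoint_subsets(self, rng):
        rows = []
        for _ in range(30):
            tracer = rng.choice(["FDG", "CXCR4"])
            site = rng.choice(["medullary", "extramedullary"])
            cat = rng.choice(["concordant", "FDG_only", "CXCR4_only"])
            if tracer == "FDG" and cat == "CXCR4_only":
                cat = "FDG_only"
            if tracer == "CXCR4" and cat == "FDG_only":
                cat = "CXCR4_only"
            n = int(rng.integers(10, 500))
            rows.append((tracer, site, cat, n, rng.uniform(1, 9),
                         rng.uniform(9, 15), n * 0.008))
        df = _records(rows)
        out = aggregate_patient(df)
        total_mtv = sum(
            out[bracket("MTV", t, s, c)]
            for t in ("FDG", "CXCR4") for s in ("medullary", "extramedullary")
            for c in ("concordant", "discordant")
        )
        assert total_mtv == pytest.approx(df.mtv_ml.sum())

    def test_scale_equivariance(self, rng):
        df = _records([
            ("FDG", "medullary", "concordant", 100, 4.0, 8.0, 0.8),
            ("FDG", "medullary", "FDG_only", 50, 3.0, 5.0, 0.4),
        ])
        out1 = aggregate_patient(df)
        df2 = df.copy()
        df2[["suv_mean", "suv_max"]] *= 3.0
        out2 = aggregate_patient(df2)
        k = bracket("SUVmean", "FDG", "medullary", "concordant")
        assert out2[k] == pytest.approx(3 * out1[k])
        assert out2[bracket("MTV", "FDG", "medullary", "concordant")] == pytest.approx(
            out1[bracket("MTV", "FDG", "medullary", "concordant")]
        )

    def test_canonical_column_count(self):
        cols = imaging_feature_columns()
        assert len(cols) == 2 * 2 * 2 * 4 + 3
        assert len(set(cols)) == len(cols)


class TestSdmax:
    def test_dubois_formula_value(self):
        # independent evaluation of the DuBois-DuBois power law
        want = 0.007184 * 180**0.725 * 75**0.425
        assert body_surface_area(180, 75) == pytest.approx(want, rel=1e-12)
        assert 1.8 < want < 2.1

    def test_definition_with_bsa_forced_to_two(self):
        # Mosteller BSA(160 cm, 90 kg) = sqrt(160*90/3600) = 2.0 exactly
        cents = np.array([[0, 0, 0], [300.0, 0, 0]])  # 30 cm apart
        assert sdmax(cents, 160, 90, formula="mosteller") == pytest.approx(15.0)

    def test_max_pairwise_on_collinear_points(self):
        cents = np.array([[0, 0, 0], [100.0, 0, 0], [250.0, 0, 0]])
        val = sdmax(cents, 160, 90, formula="mosteller")
        assert val == pytest.approx(25.0 / 2.0)

    def test_fewer_than_two_lesions_missing(self):
        assert np.isnan(sdmax(np.zeros((1, 3)), 170, 70))
        assert np.isnan(sdmax(np.zeros((0, 3)), 170, 70))

    def test_rotation_invariance(self, rng):
        cents = rng.normal(scale=80, size=(12, 3))
        theta = 1.1
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        a = sdmax(cents, 175, 80)
        b = sdmax(cents @ rot.T, 175, 80)
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_anthropometrics_rejected(self):
        with pytest.raises(DomainError):
            sdmax(np.zeros((3, 3)), -170, 70)


class TestSpleenReference:
    def test_uniform_spleen_no_lesions(self):
        pet = as_volume(np.full((8, 8, 8), 2.0), units="SUV")
        spleen = np.zeros((8, 8, 8), np.uint8)
        spleen[2:6, 2:6, 2:6] = 1
        assert spleen_reference(pet, as_volume(spleen), []) == pytest.approx(2.0)

    def test_lesion_voxels_excluded(self):
        vals = np.full((8, 8, 8), 2.0)
        spleen = np.zeros((8, 8, 8), np.uint8)
        spleen[2:6, 2:6, 2:6] = 1
        lesion = np.zeros_like(spleen)
        lesion[2:4, 2:6, 2:6] = 1  # half the spleen at SUV 10
        vals[lesion > 0] = 10.0
        got = spleen_reference(as_volume(vals, units="SUV"), as_volume(spleen),
                               [as_volume(lesion)])
        assert got == pytest.approx(2.0)

    def test_fully_covered_spleen_missing(self):
        pet = as_volume(np.full((4, 4, 4), 2.0), units="SUV")
        spleen = np.ones((4, 4, 4), np.uint8)
        assert np.isnan(spleen_reference(pet, as_volume(spleen), [as_volume(spleen)]))

    def test_matches_voxel_loop_oracle(self, rng):
        vals = rng.uniform(0.5, 6.0, (10, 10, 10))
        spleen = (rng.random((10, 10, 10)) > 0.6).astype(np.uint8)
        lesion = (rng.random((10, 10, 10)) > 0.8).astype(np.uint8)
        got = spleen_reference(as_volume(vals, units="SUV"), as_volume(spleen),
                               [as_volume(lesion)])
        acc, n = 0.0, 0
        for x in range(10):
            for y in range(10):
                for z in range(10):
                    if spleen[x, y, z] and not lesion[x, y, z]:
                        acc += vals[x, y, z]
                        n += 1
        assert got == pytest.approx(acc / n, abs=1e-12)


class TestClinicalRecord:
    def test_bmi_consistency_enforced(self):
        with pytest.raises(DomainError):
            ClinicalRecord(60, 1, 170.0, 70.0, 30.0, 0, 2.5, 50.0)
        rec = ClinicalRecord(60, 1, 170.0, 70.0, 24.2, 0, 2.5, 50.0)
        assert rec.as_dict()["bmi"] == 24.2
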