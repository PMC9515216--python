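"""Decimal ages, screening, preprocessing geometry, augmentation, splits."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ardaceph.core import AgedImage
from ardaceph import io_preprocess as pp
from ardaceph.reference import AGE_DISTRIBUTION, IMAGE_SIZE_DISTRIBUTION, cohort_totals


class TestDecimalAge:
    def test_same_date_is_zero(self):
        d = dt.date(2000, 5, 17)
        assert pp.decimal_age(d, d) == 0.00

    def test_exact_twenty_years(self):
        birth = dt.date(1990, 1, 1)
        imaging = birth + dt.timedelta(days=int(365.25 * 20))
        assert pp.decimal_age(birth, imaging) == 20.00

    def test_ten_thousand_days(self):
        birth = dt.date(1990, 1, 1)
        imaging = birth + dt.timedelta(days=10_000)
        assert pp.decimal_age(birth, imaging) == round(10_000 / 365.25, 2)

    def test_negative_interval_raises(self):
        with pytest.raises(ValueError):
            pp.decimal_age(dt.date(2000, 1, 2), dt.date(2000, 1, 1))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=20000), st.integers(min_value=1, max_value=500))
    def test_monotone_in_imaging_date(self, days, extra):
        birth = dt.date(1980, 6, 15)
        a = pp.decimal_age(birth, birth + dt.timedelta(days=days))
        b = pp.decimal_age(birth, birth + dt.timedelta(days=days + extra))
        assert b >= a


class TestScreen:
    def test_young_age_flagged(self):
        im = AgedImage(id="s", pixels=np.zeros((8, 8)), age=3.5)
        assert "age_out_of_range" in pp.screen(im).qc_flags

    def test_in_range_unflagged(self):
        im = AgedImage(id="s", pixels=np.zeros((8, 8)), age=20.0)
        assert pp.screen(im).qc_flags == set()

    def test_annotations_pass_through_and_filter(self):
        images = [
            AgedImage(id=str(i), pixels=np.zeros((4, 4)), age=10.0) for i in range(100)
        ]
        screened = [
            pp.screen(im, annotations={"restoration"} if i < 5 else None)
            for i, im in enumerate(images)
        ]
        assert len(pp.filter_screened(screened)) == 95


class TestPreprocess:
    def test_shape_contract_with_padding(self):
        im = AgedImage(id="s", pixels=np.random.default_rng(0).random((100, 200)), age=10.0)
        out = pp.preprocess(im, (224, 224))
        assert out.pixels.shape == (224, 224)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_constant_image_stays_flat(self):
        im = AgedImage(id="s", pixels=np.full((50, 50), 0.4), age=10.0)
        out = pp.preprocess(im, (64, 64))
        # padding introduces zeros; the interior stays at one flat level
        assert np.ptp(out.pixels[20:44, 20:44]) < 1e-9

    def test_labels_survive_resize(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=(60, 80))
        # blocky labels so every class keeps a sizeable area
        labels = np.kron(labels[:15, :20], np.ones((4, 4), dtype=int))
        im = AgedImage(id="s", pixels=rng.random((60, 80)), age=10.0, label_map=labels)
        out = pp.preprocess(im, (96, 96))
        assert set(np.unique(out.label_map)) == set(np.unique(labels))

    def test_degenerate_image_raises(self):
        im = AgedImage(id="s", pixels=np.zeros((0, 5)), age=10.0)
        with pytest.raises(ValueError):
            pp.preprocess(im, (32, 32))


class TestAugment:
    def _image(self):
        rng = np.random.default_rng(3)
        return AgedImage(id="s", pixels=rng.random((40, 40)), age=12.0,
                         label_map=(rng.random((40, 40)) > 0.5).astype(int))

    def test_zero_amplitude_is_identity(self):
        cfg = pp.AugmentConfig(rotation_deg=0, translate_frac=0, scale_range=(1, 1),
                               flip_prob=0)
        im = self._image()
        out = pp.augment(im, seed=0, config=cfg)
        assert np.array_equal(out.pixels, im.pixels)
        assert out.orientation == im.orientation

    def test_same_seed_same_output(self):
        im = self._image()
        a = pp.augment(im, seed=9)
        b = pp.augment(im, seed=9)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.orientation == b.orientation

    def test_certain_flip_is_involution_and_toggles_orientation(self):
        cfg = pp.AugmentConfig(rotation_deg=0, translate_frac=0, scale_range=(1, 1),
                               flip_prob=1.0)
        im = self._image()
        once = pp.augment(im, seed=1, config=cfg)
        twice = pp.augment(once, seed=2, config=cfg)
        assert once.orientation == "left"
        assert twice.orientation == "right"
        assert np.array_equal(twice.pixels, im.pixels)
        assert np.array_equal(twice.label_map, im.label_map)


class TestStratifiedSplit:
    def _manifest(self, ages):
        return pd.DataFrame({"id": [str(i) for i in range(len(ages))], "age": ages})

    def test_all_train(self):
        man = self._manifest(np.linspace(4.5, 39.5, 50))
        out = pp.stratified_split(man, pp.SplitPlan(fractions=(1.0, 0.0, 0.0)))
        assert (out["split"] == "train").all()

    def test_exact_division_within_group(self):
        man = self._manifest(np.full(100, 12.0))
        out = pp.stratified_split(man, pp.SplitPlan())
        assert out["split"].value_counts().to_dict() == {"train": 70, "val": 15, "test": 15}

    def test_disjoint_exhaustive_and_deterministic(self):
        rng = np.random.default_rng(0)
        man = self._manifest(rng.uniform(4, 40, 300))
        a = pp.stratified_split(man, pp.SplitPlan(seed=4))
        b = pp.stratified_split(man, pp.SplitPlan(seed=4))
        assert a["split"].isin(["train", "val", "test"]).all()
        pd.testing.assert_series_equal(a["split"], b["split"])

    def test_empty_group_warns(self):
        man = self._manifest(np.full(10, 12.0))  # only 11-15 populated
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            pp.stratified_split(man, pp.SplitPlan())
        assert any("empty" in str(w.message) for w in rec)


class TestReaders:
    def test_png_round_trip(self, tmp_path):
        import imageio.v3 as iio

        arr = np.arange(64, dtype=np.uint8).reshape(8, 8)
        path = tmp_path / "img.png"
        iio.imwrite(path, arr)
        im = pp.read_png(path, id="s", age=12.0)
        assert im.pixels.shape == (8, 8)
        assert im.pixels.min() == 0.0 and im.pixels.max() == 1.0

    def test_dicom_16bit_scaled_to_unit(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian

        arr = (np.arange(64, dtype=np.uint16) * 1000).reshape(8, 8)
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        ds = FileDataset(str(tmp_path / "img.dcm"), {}, file_meta=meta,
                         preamble=b"\0" * 128)
        ds.Rows, ds.Columns = 8, 8
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arr.tobytes()
        ds.save_as(tmp_path / "img.dcm", enforce_file_format=True)
        im = pp.read_dicom(tmp_path / "img.dcm", id="s", age=30.0)
        assert im.pixels.shape == (8, 8)
        assert im.pixels.min() == 0.0 and im.pixels.max() == 1.0


class TestReferenceCohort:
    def test_age_table_internally_consistent(self):
        row = AGE_DISTRIBUTION.set_index("age_group").loc["4-10"]
        assert row["train"] + row["val"] + row["test"] == row["total"] == 2599
        per_row = AGE_DISTRIBUTION[["train", "val", "test"]].sum(axis=1)
        assert (per_row == AGE_DISTRIBUTION["total"]).all()

    def test_cohort_totals(self):
        totals = cohort_totals()
        assert totals["train"] == 14142
        assert totals["total"] == 20174
        assert totals["by_size"] == int(IMAGE_SIZE_DISTRIBUTION["count"].sum()) == 20174
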