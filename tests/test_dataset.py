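"""Paired-record containers: BCF, cleaning, splitting, CSV round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cdwheat as cw
from cdwheat.dataset import InvariantError, ParseError

from conftest import make_frame


class TestComputeBcf:
    @pytest.mark.parametrize("wheat,soil,expected", [
        (1.0, 1.0, 1.0),
        # ratio of the dataset's mean grain and soil Cd, by direct division
        (0.298, 1.329, 0.298 / 1.329),
    ])
    def test_values(self, wheat, soil, expected):
        assert cw.compute_bcf(wheat, soil) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("wheat,soil,field", [
        (0.1, 0.0, "cd_soil"), (0.0, 1.0, "cd_wheat"), (0.1, -2.0, "cd_soil"),
    ])
    def test_nonpositive_inputs_name_the_field(self, wheat, soil, field):
        with pytest.raises(InvariantError, match=field):
            cw.compute_bcf(wheat, soil)

    @settings(derandomize=True, max_examples=200)
    @given(wheat=st.floats(1e-6, 1e3), soil=st.floats(1e-6, 1e3))
    def test_roundtrip(self, wheat, soil):
        assert cw.compute_bcf(wheat, soil) * soil == pytest.approx(
            wheat, rel=1e-12)


class TestRecordInvariants:
    def test_soil_record_rejects_bad_values(self):
        ok = dict(ph=6.0, cec=10.0, clay=20.0, som=15.0, fe_dcb=10.0,
                  fe_ox=2.0, cd_total=1.0)
        cw.SoilRecord(**ok)
        for bad in (dict(ph=0.0), dict(ph=14.5), dict(cd_total=0.0),
                    dict(clay=101.0), dict(cec=-1.0), dict(cd_cacl2=0.0)):
            with pytest.raises(InvariantError):
                cw.SoilRecord(**{**ok, **bad})

    def test_paired_record_derives_and_checks_bcf(self):
        soil = cw.SoilRecord(ph=6.0, cec=10.0, clay=20.0, som=15.0,
                             fe_dcb=10.0, fe_ox=2.0, cd_total=2.0)
        rec = cw.PairedRecord(soil=soil, cd_wheat=0.5)
        assert rec.bcf == pytest.approx(0.25, rel=1e-12)
        with pytest.raises(InvariantError):
            cw.PairedRecord(soil=soil, cd_wheat=0.5, bcf=0.9)

    def test_duplicate_record_ids_rejected(self):
        df = make_frame(2)
        df.index = pd.Index(["a", "a"], name="record_id")
        with pytest.raises(InvariantError, match="duplicated"):
            cw.Dataset(df)


class TestCleaning:
    def test_zero_variance_retains_everything(self):
        data = cw.Dataset(make_frame(20))
        out = cw.clean_dataset(data)
        assert len(out) == 20
        assert out.meta["cleaning"]["removed"] == []

    def test_planted_outlier_removed_and_only_it(self):
        rng = np.random.default_rng(3)
        bcf = 0.25 + 0.01 * rng.standard_normal(100)
        df = make_frame(101, cd_total=1.0,
                        cd_wheat=np.concatenate([bcf, [5.0]]))
        # brute-force oracle for the 3-SD screen over all 101 BCFs
        all_bcf = df["cd_wheat"] / df["cd_total"]
        hi = all_bcf.mean() + 3 * all_bcf.std(ddof=1)
        assert 5.0 > hi and (all_bcf[:100] <= hi).all()
        out = cw.clean_dataset(cw.Dataset(df))
        assert len(out) == 100
        removed, = out.meta["cleaning"]["removed"]
        assert removed["record_id"] == "r100"
        assert "outlier" in removed["reason"]

    def test_missing_value_removed_with_reason(self):
        df = make_frame(5)
        df.loc[2, "cd_wheat"] = np.nan
        out = cw.clean_dataset(cw.Dataset(df))
        assert len(out) == 4
        removed, = out.meta["cleaning"]["removed"]
        assert removed["record_id"] == "r2"
        assert "missing value" in removed["reason"]

    def test_idempotent(self, default_dataset):
        once = cw.clean_dataset(default_dataset)
        twice = cw.clean_dataset(once)
        assert twice.equals(once)

    def test_all_removed_raises(self):
        df = make_frame(3)
        df["cd_wheat"] = np.nan
        with pytest.raises(InvariantError, match="empty dataset"):
            cw.clean_dataset(cw.Dataset(df))


class TestSplitting:
    def test_sizes_and_disjointness(self):
        data = cw.Dataset(make_frame(10, cd_wheat=np.linspace(0.1, 1, 10)))
        (train, test), = cw.split_dataset(
            data, cw.SplitSpec(n_repeats=1, seed=5))
        assert len(train) == 8 and len(test) == 2
        assert not set(train.record_ids) & set(test.record_ids)
        assert set(train.record_ids) | set(test.record_ids) == set(
            data.record_ids)

    def test_same_seed_same_partition(self, default_dataset):
        spec = cw.SplitSpec(n_repeats=2, seed=11)
        a = cw.split_dataset(default_dataset, spec)
        b = cw.split_dataset(default_dataset, spec)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert tr1.record_ids == tr2.record_ids
            assert te1.record_ids == te2.record_ids

    def test_repeats_are_distinct_and_conserving(self, default_dataset):
        splits = cw.split_dataset(
            default_dataset, cw.SplitSpec(n_repeats=10, seed=1))
        test_sets = [frozenset(te.record_ids) for _, te in splits]
        # pairwise inequality of the 10 partitions, by brute force
        assert len(set(test_sets)) == 10
        for train, test in splits:
            assert len(train) + len(test) == len(default_dataset)
            assert abs(len(test) - 0.2 * len(default_dataset)) <= 1

    def test_degenerate_fraction_rejected(self):
        data = cw.Dataset(make_frame(6))
        with pytest.raises(ValueError):
            cw.split_dataset(data, cw.SplitSpec(test_fraction=0.01,
                                                n_repeats=1))
        with pytest.raises(ValueError):
            cw.SplitSpec(test_fraction=1.2)


class TestCsvIO:
    def test_roundtrip_preserves_values(self, tmp_path, default_dataset):
        sub = default_dataset.subset(default_dataset.record_ids[:5])
        path = tmp_path / "five.csv"
        cw.write_dataset(sub, path)
        back = cw.load_dataset(path)
        for col in ("ph", "cec", "cd_total", "cd_cacl2", "cd_msm",
                    "cd_wheat"):
            np.testing.assert_allclose(
                back.df[col].to_numpy(), sub.df[col].to_numpy(), rtol=1e-12)

    def test_microgram_unit_declaration(self, tmp_path):
        df = make_frame(1, cd_cacl2=0.032)
        path = tmp_path / "u.csv"
        cw.write_dataset(cw.Dataset(df), path)
        back = cw.load_dataset(path, units={"cd_cacl2": "ug/kg"})
        assert back.df["cd_cacl2"].iloc[0] == pytest.approx(3.2e-5, rel=1e-12)

    def test_negative_cd_total_is_a_parse_error_with_row(self, tmp_path):
        df = make_frame(3)
        path = tmp_path / "bad.csv"
        cw.write_dataset(cw.Dataset(df), path)
        lines = path.read_text().splitlines()
        # corrupt the second data row's cd_total (7th field)
        fields = lines[2].split(",")
        fields[6] = "-1.0"
        lines[2] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="row 3"):
            cw.load_dataset(path)

    def test_non_numeric_cell_and_unknown_column(self, tmp_path):
        path = tmp_path / "nn.csv"
        cw.write_dataset(cw.Dataset(make_frame(2)), path)
        lines = path.read_text().splitlines()
        fields = lines[1].split(",")
        fields[0] = "acidic"
        lines[1] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="row 2"):
            cw.load_dataset(path)
        path2 = tmp_path / "uc.csv"
        path2.write_text("ph,mystery\n6.0,1.0\n")
        with pytest.raises(ParseError, match="mystery"):
            cw.load_dataset(path2)
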