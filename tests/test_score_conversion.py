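"""Converted-score formulas, thresholds and the classification rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_dataset, make_record
from modycalib.score_conversion import (
    Call,
    Conversion,
    ConversionError,
    ConvertedScore,
    MethodSpec,
    classify,
    convert,
    convert_dataset,
    default_registry,
    invert,
    registry_from_config,
    registry_to_config,
)


@pytest.mark.parametrize("method,raw,aux,expected", [
    ("MutationAssessor", -5.545, None, 0.0),     # lower bound maps to 0
    ("MutationAssessor", 5.975, None, 1.0),
    ("FATHMM", -16.13, None, 1.0),               # most-damaging bound maps to 1
    ("FATHMM", 10.64, None, 0.0),
    ("SIFT", 0.05, None, 0.95),                  # S_c = 1 - S_o
    ("SIFT", 1.0, None, 0.0),
    ("RadialSVM", 0.0, "D", 0.5),                # (1 + 0/k) * 0.5
    ("RadialSVM", 0.0, "N", 0.5),
    ("LRT", 0.0, True, 1.0),                     # omega<1 branch limit
    ("LRT", 0.0, False, 0.0),
    ("LRT", 0.5, True, 0.75),
    ("MutationTaster", 0.8, "D", 0.8),
    ("MutationTaster", 0.8, "A", 0.8),
    ("MutationTaster", 0.8, "N", 0.2),
    ("MutationTaster", 0.8, "P", 0.2),
    ("PhyloP", -3.0, None, -3.0),                # identity passthrough
    ("LR", 0.73, None, 0.73),
])
def test_conversion_formulas(registry_by_name, method, raw, aux, expected):
    cs = convert(registry_by_name[method], raw, aux)
    assert cs.present
    assert cs.value == pytest.approx(expected, abs=1e-12)


def test_radialsvm_formulas_use_printed_divisors(registry_by_name):
    spec = registry_by_name["RadialSVM"]
    assert convert(spec, 3.03993691875303, "D").value == pytest.approx(1.0)
    # non-D branch divides by the negative constant as printed, so the
    # benign bound (raw = divisor itself) maps to 0
    assert convert(spec, -2.00575697514507, "N").value == pytest.approx(0.0)
    assert convert(spec, 2.00575697514507, "N").value == pytest.approx(1.0)


def test_absent_raw_score_stays_absent(registry_by_name):
    cs = convert(registry_by_name["SIFT"], None)
    assert not cs.present and cs.value is None


@pytest.mark.parametrize("method,aux", [
    ("LRT", None), ("LRT", "yes"),
    ("MutationTaster", None), ("MutationTaster", "X"),
    ("RadialSVM", None), ("RadialSVM", "Q"),
])
def test_missing_or_invalid_aux_is_conversion_error(registry_by_name, method, aux):
    with pytest.raises(ConversionError, match=method):
        convert(registry_by_name[method], 0.5, aux)


class TestRangePolicy:
    def test_out_of_range_clamps_with_warning(self, registry_by_name):
        spec = registry_by_name["MutationAssessor"]
        with pytest.warns(UserWarning, match="clamped"):
            cs = convert(spec, 7.0)
        assert cs.value == 1.0

    def test_strict_mode_rejects(self, registry_by_name):
        with pytest.raises(ConversionError, match="outside"):
            convert(registry_by_name["MutationAssessor"], 7.0, strict=True)


class TestClassify:
    def test_strictly_above_threshold_is_deleterious(self):
        assert classify(ConvertedScore("SIFT", 0.96, True), 0.95) is Call.DELETERIOUS

    def test_tie_at_threshold_is_benign(self):
        assert classify(ConvertedScore("SIFT", 0.95, True), 0.95) is Call.BENIGN

    def test_absent_score_is_unscored(self):
        assert classify(ConvertedScore("SIFT", None, False), 0.95) is Call.UNSCORED


def test_default_registry_thresholds():
    thresholds = {s.name: s.default_threshold for s in default_registry()}
    assert thresholds == {
        "PhyloP": 1.6, "GERP_RS": 4.4, "SiPhy": 12.17, "SIFT": 0.95,
        "PolyPhen2_HDIV": 0.5, "PolyPhen2_HVAR": 0.5, "LRT": 0.999,
        "MutationTaster": 0.5, "MutationAssessor": 0.65, "FATHMM": 0.453,
        "RadialSVM": 0.5, "LR": 0.5,
    }


def test_registry_config_round_trip():
    reg = default_registry()
    assert registry_from_config(registry_to_config(reg)) == reg


def test_bounded01_threshold_must_be_in_range():
    with pytest.raises(ValueError, match="threshold"):
        MethodSpec("bad", Conversion.SIFT, 1.5, bounded01=True)


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=-5.545, max_value=5.975),
       st.floats(min_value=-16.13, max_value=10.64),
       st.floats(min_value=0.0, max_value=1.0))
def test_bounded_methods_land_in_unit_interval(registry_by_name, ma, fh, s):
    assert 0.0 <= convert(registry_by_name["MutationAssessor"], ma).value <= 1.0
    assert 0.0 <= convert(registry_by_name["FATHMM"], fh).value <= 1.0
    assert 0.0 <= convert(registry_by_name["SIFT"], s).value <= 1.0


def test_monotone_direction_preserves_spearman_up_to_sign(registry_by_name):
    """SIFT/FATHMM conversions are strictly decreasing, MutationAssessor
    strictly increasing, so rank correlations flip or keep sign accordingly."""
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 60)
    y = rng.uniform(0, 1, 60)
    base = stats.spearmanr(x, y).statistic
    sift = [convert(registry_by_name["SIFT"], v).value for v in x]
    assert stats.spearmanr(sift, y).statistic == pytest.approx(-base, abs=1e-12)
    ma_raw = -5.545 + 11.52 * x
    ma = [convert(registry_by_name["MutationAssessor"], v).value for v in ma_raw]
    assert stats.spearmanr(ma, y).statistic == pytest.approx(base, abs=1e-12)


@settings(max_examples=300, deadline=None)
@given(st.sampled_from(["SIFT", "LRT", "MutationTaster", "MutationAssessor",
                        "FATHMM", "RadialSVM", "LR", "PhyloP"]),
       st.floats(min_value=0.0, max_value=1.0))
def test_invert_is_right_inverse_of_convert(registry_by_name, method, c):
    """Converted value -> (raw, aux) -> converted value round-trips."""
    spec = registry_by_name[method]
    raw, aux = invert(spec, c)
    assert convert(spec, raw, aux).value == pytest.approx(c, abs=1e-9)


def test_convert_is_deterministic(registry_by_name):
    spec = registry_by_name["FATHMM"]
    vals = {convert(spec, 1.234).value for _ in range(5)}
    assert len(vals) == 1


class TestConvertDataset:
    def _registry(self):
        return (MethodSpec("A", Conversion.IDENTITY, 0.5, bounded01=False),
                MethodSpec("B", Conversion.SIFT, 0.95, bounded01=True,
                           raw_range=(0.0, 1.0)))

    def test_absent_cells_stay_absent(self):
        ds = make_dataset([
            make_record("GCK", "v1", scores={"A": 1.0, "B": 0.2}),
            make_record("GCK", "v2", scores={"A": 2.0, "B": None}),
        ])
        mat = convert_dataset(ds, self._registry())
        assert mat.shape == (2, 2)
        assert mat.isna().sum().sum() == 1
        assert math.isnan(mat.loc[1, "B"])

    def test_matches_elementwise_convert(self):
        rng = np.random.default_rng(3)
        reg = self._registry()
        recs = [make_record("GCK", f"v{i}",
                            scores={"A": rng.normal(), "B": rng.uniform()})
                for i in range(20)]
        ds = make_dataset(recs)
        mat = convert_dataset(ds, reg)
        for i, r in enumerate(recs):
            for spec in reg:
                expected = convert(spec, r.score(spec.name)).value
                assert mat.loc[i, spec.name] == expected

    def test_unregistered_method_is_error(self):
        ds = make_dataset([make_record("GCK", "v1", scores={"Z": 1.0})])
        with pytest.raises(ConversionError, match="Z"):
            convert_dataset(ds, self._registry())

    def test_error_names_offending_variant(self, registry_by_name):
        ds = make_dataset([make_record("GCK", "vbad",
                                       scores={"LRT": 0.5})])  # aux missing
        with pytest.raises(ConversionError, match="vbad"):
            convert_dataset(ds, (registry_by_name["LRT"],))
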