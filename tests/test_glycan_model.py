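import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glyrep.glycan_model import (
    CompositionError,
    GlycanClass,
    GlycanComposition,
    PhenotypeMatrix,
    TraitConfigError,
    TraitDefinition,
    TraitTerm,
    center_by_batch,
    classify_glycan,
    evaluate_derived_trait,
    load_trait_definitions,
    parse_composition,
    rank_inverse_normal,
    residualize_covariates,
    total_area_normalize,
)


class TestParseComposition:
    def test_full_code(self):
        c = parse_composition("H5N4F1E1L1")
        assert (c.hexose, c.hexnac, c.fucose) == (5, 4, 1)
        assert (c.neu5ac_a26, c.neu5ac_a23, c.hexuronic) == (1, 1, 0)

    def test_oligomannose_code(self):
        c = parse_composition("H9N2")
        assert (c.hexose, c.hexnac) == (9, 2)
        assert c.fucose == c.neu5ac_a26 == c.neu5ac_a23 == c.hexuronic == 0

    def test_hexuronic_code(self):
        c = parse_composition("H5N4E1G1")
        assert (c.hexose, c.hexnac, c.neu5ac_a26, c.hexuronic) == (5, 4, 1, 1)
        assert c.neu5ac_a23 == 0 and c.fucose == 0

    def test_any_letter_order(self):
        assert parse_composition("N4H5F1").code == "H5N4F1"

    @pytest.mark.parametrize("bad", ["H5X2", "H5H4", "H5N", "", "5N4", "H5 N4"])
    def test_malformed_raises(self, bad):
        with pytest.raises(CompositionError):
            parse_composition(bad)

    def test_error_names_token(self):
        with pytest.raises(CompositionError, match="X"):
            parse_composition("H5X2")
        with pytest.raises(CompositionError, match="repeated"):
            parse_composition("H5H4")

    def test_all_zero_invalid(self):
        with pytest.raises(CompositionError):
            parse_composition("F1")

    @given(
        h=st.integers(0, 12), n=st.integers(0, 8), f=st.integers(0, 4),
        e=st.integers(0, 4), l=st.integers(0, 4), g=st.integers(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, h, n, f, e, l, g):
        if h == 0 and n == 0:
            with pytest.raises(CompositionError):
                GlycanComposition(h, n, f, e, l, g)
            return
        comp = GlycanComposition(h, n, f, e, l, g)
        assert parse_composition(comp.code) == comp


class TestClassifyGlycan:
    def test_diantennary_core_fucosylated_sialylated(self):
        # H4N4F1E1: di-antennary core-fucosylated alpha2,6-sialylated
        f = classify_glycan(parse_composition("H4N4F1E1"))
        assert f.glycan_class is GlycanClass.COMPLEX
        assert f.antennae == 2
        assert f.core_fucosylated
        assert f.sialyl_a26 == 1 and f.sialyl_a23 == 0
        assert not f.bisected

    def test_oligomannose(self):
        f = classify_glycan(parse_composition("H9N2"))
        assert f.glycan_class is GlycanClass.OLIGOMANNOSE
        assert f.antennae == 0
        assert f.sialyl_a26 == 0 and f.sialyl_a23 == 0

    @pytest.mark.parametrize("code", ["H3N5F1", "H4N5F1"])
    def test_bisected(self, code):
        f = classify_glycan(parse_composition(code))
        assert f.glycan_class is GlycanClass.COMPLEX
        assert f.bisected
        assert f.antennae == 2

    def test_triantennary(self):
        f = classify_glycan(parse_composition("H6N5F1E1L2"))
        assert f.antennae == 3
        assert f.sialyl_a26 == 1 and f.sialyl_a23 == 2

    def test_tetraantennary_with_antennary_fucose(self):
        f = classify_glycan(parse_composition("H7N6F2E2L2"))
        assert f.antennae == 4
        assert f.core_fucosylated and f.antennary_fucose == 1

    def test_antennae_capped_at_4(self):
        assert classify_glycan(parse_composition("H8N7")).antennae == 4

    def test_override_wins(self):
        comp = parse_composition("H5N5E1")
        default = classify_glycan(comp)
        forced = classify_glycan(
            comp, overrides={"H5N5E1": default.__class__(
                glycan_class=GlycanClass.COMPLEX, antennae=2, bisected=True,
                core_fucosylated=False, antennary_fucose=0,
                sialyl_a26=1, sialyl_a23=0, galactoses_on_antennae=2,
            )},
        )
        assert forced.bisected and forced.antennae == 2
        assert not default.bisected  # heuristic calls H5N5E1 tri-antennary


class TestDerivedTraits:
    @pytest.fixture()
    def diantennary_peaks(self):
        return pd.DataFrame(
            {"H5N4": [10.0], "H5N4E1": [30.0], "H5N4E2": [60.0]},
            index=["s1"],
        )

    def test_sialylation_per_antenna_hand_oracle(self, diantennary_peaks):
        # (1*30 + 2*60) / (2 * (10+30+60)) = 0.75
        defn = TraitDefinition(
            trait_id="A2E", platform="MALDI-MS", kind="derived",
            numerator=(TraitTerm("antennae=2", "E"),),
            denominator=(TraitTerm("antennae=2"),),
            scale=2.0,
        )
        out = evaluate_derived_trait(defn, diantennary_peaks)
        assert out.loc["s1"] == pytest.approx(0.75, abs=1e-12)

    def test_empty_numerator_selector_gives_zero(self, diantennary_peaks):
        defn = TraitDefinition(
            trait_id="A4E", platform="MALDI-MS", kind="derived",
            numerator=(TraitTerm("antennae=4", "E"),),
            denominator=(TraitTerm("*"),),
        )
        out = evaluate_derived_trait(defn, diantennary_peaks)
        assert (out == 0).all()

    def test_total_area_normalization(self):
        peaks = pd.DataFrame({"H5N4": [25.0], "H5N4E1": [75.0]}, index=["s1"])
        rel = total_area_normalize(peaks)
        assert rel.loc["s1", "H5N4"] == 0.25
        assert rel.loc["s1", "H5N4E1"] == 0.75

    def test_direct_trait_is_relative_abundance(self, diantennary_peaks):
        defn = TraitDefinition(
            trait_id="H5N4E2", platform="MALDI-MS", kind="direct",
            numerator=(TraitTerm("H5N4E2"),),
        )
        out = evaluate_derived_trait(defn, diantennary_peaks)
        assert out.loc["s1"] == pytest.approx(0.6)

    def test_missing_referenced_peak_errors(self, diantennary_peaks):
        defn = TraitDefinition(
            trait_id="x", platform="MALDI-MS", kind="derived",
            numerator=(TraitTerm("H9N2"),),
        )
        with pytest.raises(TraitConfigError, match="H9N2"):
            evaluate_derived_trait(defn, diantennary_peaks)

    def test_zero_denominator_gives_missing(self):
        peaks = pd.DataFrame({"H5N4": [0.0, 5.0], "H6N5": [1.0, 5.0]},
                             index=["s1", "s2"])
        defn = TraitDefinition(
            trait_id="r", platform="MALDI-MS", kind="derived",
            numerator=(TraitTerm("antennae=3"),),
            denominator=(TraitTerm("antennae=2"),),
        )
        out = evaluate_derived_trait(defn, peaks)
        assert np.isnan(out.loc["s1"]) and out.loc["s2"] == pytest.approx(1.0)

    @given(
        abundances=st.lists(
            st.floats(0.1, 100.0, allow_nan=False), min_size=2, max_size=6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_normalized_direct_traits_sum_to_one(self, abundances):
        codes = ["H5N2", "H5N4", "H5N4E1", "H6N5", "H7N6", "H3N5F1"][: len(abundances)]
        peaks = pd.DataFrame([abundances], columns=codes, index=["s"])
        rel = total_area_normalize(peaks)
        assert rel.sum(axis=1).loc["s"] == pytest.approx(1.0, abs=1e-12)

    def test_load_trait_definitions_tsv(self, tmp_path):
        path = tmp_path / "traits.tsv"
        path.write_text(
            "trait_id\tplatform\tkind\tnumerator\tdenominator\tscale\n"
            "A2E\tMALDI-MS\tderived\tantennae=2:E\tantennae=2\t2\n"
            "H5N4\tMALDI-MS\tdirect\tH5N4\t*\t1\n"
        )
        defs = load_trait_definitions(str(path))
        assert len(defs) == 2
        assert defs[0].scale == 2.0
        assert defs[0].numerator == (TraitTerm("antennae=2", "E"),)
        assert defs[1].kind == "direct"


class TestResidualize:
    def test_exact_fit_gives_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ np.array([2.0, -1.5])
        assert np.allclose(residualize_covariates(y, X), 0.0, atol=1e-12)

    def test_intercept_only_demeans(self):
        y = np.array([1.0, 4.0, 7.0])
        out = residualize_covariates(y, np.ones((3, 1)))
        assert np.allclose(out, y - y.mean())

    def test_closed_form_example(self):
        # y=[1,2,2] on x=[0,1,2] with intercept -> (-1/6, 1/3, -1/6)
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        out = residualize_covariates(np.array([1.0, 2.0, 2.0]), X)
        assert np.allclose(out, [-1 / 6, 1 / 3, -1 / 6], atol=1e-12)

    def test_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        resid = residualize_covariates(y, X)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficient_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            residualize_covariates(np.arange(10.0), X)


class TestRankInverseNormal:
    def test_n3_blom_values(self):
        # Phi^-1 of (0.625, 1.625, 2.625)/3.25, high-precision oracle
        out = rank_inverse_normal(np.array([5.0, 1.0, 9.0]))
        assert out == pytest.approx([0.0, -0.8694237733, 0.8694237733], abs=1e-4)

    def test_symmetric_input_symmetric_output(self):
        out = rank_inverse_normal(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert np.allclose(out, -out[::-1], atol=1e-12)
        assert abs(out.mean()) < 1e-12

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=101)
        out = rank_inverse_normal(y)
        assert np.array_equal(np.argsort(y), np.argsort(out))

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            rank_inverse_normal(np.full(10, 3.0))

    def test_ties_get_equal_values(self):
        out = rank_inverse_normal(np.array([1.0, 1.0, 2.0, 3.0]))
        assert out[0] == out[1]

    def test_output_approximately_normal(self):
        rng = np.random.default_rng(7)
        out = rank_inverse_normal(rng.uniform(size=10_000))
        assert abs(stats.skew(out)) < 0.05
        assert abs(stats.kurtosis(out)) < 0.1

    @given(
        scale=st.floats(0.1, 50.0, allow_nan=False),
        shift=st.floats(-100.0, 100.0, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance_after_residualization(self, scale, shift):
        rng = np.random.default_rng(11)
        y = rng.normal(size=40)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])

        def transform(v):
            return rank_inverse_normal(residualize_covariates(v, X))

        assert np.allclose(transform(y), transform(scale * y + shift), atol=1e-8)


def test_center_by_batch_zero_means():
    rng = np.random.default_rng(5)
    y = rng.normal(5.0, 2.0, size=60)
    batch = np.repeat([0, 1, 2], 20)
    out = center_by_batch(y, batch)
    for b in (0, 1, 2):
        assert abs(out[batch == b].mean()) < 1e-12


def test_phenotype_matrix_index_mismatch_raises():
    values = pd.DataFrame({"t": [1.0]}, index=["a"])
    covars = pd.DataFrame({"age": [50.0]}, index=["b"])
    with pytest.raises(ValueError):
        PhenotypeMatrix(values=values, covariates=covars)
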