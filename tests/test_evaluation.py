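"""Pearson-R scoring, PTM classing and boxplot summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ionforest import (
    EvaluationRecord,
    Peptide,
    classify_ptms,
    parse_peptide,
    pearson_r,
    records_frame,
    summarize,
)


class TestPearson:
    def test_self_correlation(self):
        r, degen = pearson_r([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r == pytest.approx(1.0)
        assert not degen

    def test_perfect_anticorrelation(self):
        r, _ = pearson_r([1.0, 2.0, 3.0], [2.0, 1.0, 0.0])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # Pearson formula by hand: (1,2,3) vs (1,2,4) -> 0.98198...
        r, _ = pearson_r([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_flagged_degenerate(self):
        r, degen = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert degen and np.isnan(r)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            pearson_r([1, 2, 3], [1, 2])

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_r([1, 2], [1, 2])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30),
        st.floats(0.01, 50),
        st.floats(-100, 100),
    )
    def test_affine_invariance(self, values, scale, shift):
        obs = np.linspace(0, 1, len(values))
        base, degen = pearson_r(values, obs)
        if degen:
            return
        transformed, _ = pearson_r(np.array(values) * scale + shift, obs)
        assert transformed == pytest.approx(base, abs=1e-9)


class TestClassify:
    def test_classes(self, registry):
        assert classify_ptms(parse_peptide("H-SAMPLE-OH", registry), registry) == "no_ptm"
        assert classify_ptms(parse_peptide("H-SAoxMPLE-OH", registry), registry) == "mox"
        assert classify_ptms(parse_peptide("H-SAMPLEcmmC-OH", registry), registry) == "cmm"
        assert classify_ptms(parse_peptide("ace-SAMPLE-OH", registry), registry) == "other"
        both = parse_peptide("H-SAoxMPLEcmmC-OH", registry)
        assert classify_ptms(both, registry) == "other"
        assert classify_ptms(parse_peptide("H-phosSAMPLE-OH", registry), registry) == "other"


def _rec(R, **kw):
    base = dict(
        psm_id="p", R=R, degenerate=np.isnan(R), spectrum_method="CID",
        model_method="CID", precursor_charge=2, ptm_class="no_ptm", n_matched=10,
    )
    base.update(kw)
    return EvaluationRecord(**base)


class TestSummarize:
    def test_small_exact_quantiles(self):
        recs = [_rec(float(v)) for v in (1, 2, 3, 4, 5)]
        out = summarize(recs)
        row = out.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2.0, 3.0, 4.0)
        assert row["n"] == 5

    def test_identical_values_zero_width_box(self):
        recs = [_rec(0.5) for _ in range(4)]
        row = summarize(recs).iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == 0.5
        assert row["whisker_low"] == row["whisker_high"] == 0.5

    def test_tukey_whiskers_clip_outliers(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 5.0]  # 5.0 is beyond 1.5 IQR
        row = summarize([_rec(v) for v in vals]).iloc[0]
        assert row["whisker_high"] == 0.5
        assert row["whisker_low"] == 0.1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-1, 1, 50)
        a = summarize([_rec(v) for v in vals])
        b = summarize([_rec(v) for v in rng.permutation(vals)])
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_excluded_and_counted(self):
        recs = [_rec(v) for v in (0.1, 0.2, 0.3)] + [_rec(float("nan"))]
        row = summarize(recs).iloc[0]
        assert row["n"] == 3
        assert row["n_degenerate"] == 1

    def test_grouped_grid_layout(self):
        recs = []
        for charge in (2, 3):
            for mm in ("CID", "HCD"):
                recs += [
                    _rec(0.5 + 0.01 * i, precursor_charge=charge, model_method=mm)
                    for i in range(5)
                ]
        out = summarize(recs, ["precursor_charge", "model_method"])
        assert len(out) == 4
        assert set(out["precursor_charge"]) == {2, 3}
        assert set(out["model_method"]) == {"CID", "HCD"}

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no records"):
            summarize([])


@pytest.fixture(scope="module")
def setup(registry):
    from ionforest import (
        METHOD_A,
        TrainingConfig,
        as_psm_pairs,
        build_training_set,
        evaluate,
        gen_dataset,
        train,
    )

    psms = gen_dataset(30, 2, METHOD_A, registry, seed=21)
    ts = build_training_set(as_psm_pairs(psms), "CID", registry)[2]
    model = train(ts, TrainingConfig(n_trees=8))
    test = gen_dataset(10, 2, METHOD_A, registry, seed=22)
    return model, test, evaluate


class TestEvaluate:
    def test_one_record_per_psm_with_labels(self, registry, setup):
        from ionforest import as_psm_pairs

        model, test, evaluate = setup
        recs = evaluate(model, as_psm_pairs(test), registry, spectrum_method="CID")
        assert len(recs) == 10
        assert {r.model_method for r in recs} == {"CID"}
        assert {r.spectrum_method for r in recs} == {"CID"}
        assert all(-1 <= r.R <= 1 for r in recs if not r.degenerate)

    def test_cross_application_is_just_labels(self, registry, setup):
        from ionforest import as_psm_pairs

        model, test, evaluate = setup
        recs = evaluate(model, as_psm_pairs(test), registry, spectrum_method="HCD")
        assert {(r.spectrum_method, r.model_method) for r in recs} == {("HCD", "CID")}

    def test_charge_not_covered(self, registry, setup):
        from ionforest import METHOD_A, as_psm_pairs, gen_dataset

        model, _, evaluate = setup
        wrong = gen_dataset(2, 3, METHOD_A, registry, seed=23)
        with pytest.raises(ValueError, match="charge"):
            evaluate(model, as_psm_pairs(wrong), registry, spectrum_method="CID")

    def test_per_series_flag(self, registry, setup):
        from ionforest import as_psm_pairs

        model, test, evaluate = setup
        recs = evaluate(
            model, as_psm_pairs(test)[:3], registry, spectrum_method="CID", per_series=True
        )
        assert len(recs) == 12
        assert {r.psm_id.split(":")[1] for r in recs} == {"b+", "y+", "b++", "y++"}


def test_records_frame_shape():
    recs = [_rec(0.5), _rec(0.7, ptm_class="mox")]
    df = records_frame(recs)
    assert list(df["ptm_class"]) == ["no_ptm", "mox"]
    assert df.shape[0] == 2
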