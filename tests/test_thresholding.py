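"""Detectability thresholds: percentiles, mixture fits, decision rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cite_titration.model import ValidationError
from cite_titration.thresholding import (
    DetectCall,
    MixtureFit,
    ThresholdParams,
    apply_manual_overrides,
    binarize,
    call_detectability,
    calls_to_frame,
    fit_population_model,
    percentile,
)


# ---------------------------------------------------------------------------
# percentile
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("values,q,expected", [
    (list(range(20)), 95, 18.05),
    ([10, 20, 30, 40, 50], 5, 12.0),
    ([3, 1, 2], 100, 3.0),
    ([7], 50, 7.0),
])
def test_percentile_examples(values, q, expected):
    assert percentile(values, q) == pytest.approx(expected)


def _percentile_oracle(values, q):
    s = sorted(values)
    pos = q / 100 * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def test_percentile_matches_sort_interpolate_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        values = rng.normal(size=rng.integers(1, 30))
        q = float(rng.uniform(0, 100))
        assert percentile(values, q) == pytest.approx(
            _percentile_oracle(values, q), abs=1e-10)


def test_percentile_errors():
    with pytest.raises(ValidationError):
        percentile([], 50)
    with pytest.raises(ValidationError):
        percentile([1.0], 101)


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------

def test_known_mixture_recovery():
    rng = np.random.default_rng(1)
    values = np.concatenate([rng.normal(0, 0.3, 500),
                             rng.normal(3, 0.3, 500)])
    fit = fit_population_model(values, seed=0)
    assert fit.means[0] == pytest.approx(0.0, abs=0.1)
    assert fit.means[1] == pytest.approx(3.0, abs=0.1)
    assert 8 <= fit.separation <= 12
    assert fit.positive_fraction == pytest.approx(0.5, abs=0.05)


def test_degenerate_identical_values():
    fit = fit_population_model(np.full(100, 1.5), seed=0)
    assert fit.separation == 0.0
    assert fit.positive_fraction == 0.0


def test_unimodal_sample_is_below_bimodality_cut():
    rng = np.random.default_rng(2)
    fit = fit_population_model(rng.normal(0, 1, 1000), seed=0)
    assert fit.separation < 2


def test_minority_component_is_found():
    """A 2% positive population far from the bulk must be isolated."""
    rng = np.random.default_rng(3)
    values = np.concatenate([rng.normal(-0.8, 0.45, 1960),
                             rng.normal(1.5, 0.4, 40)])
    fit = fit_population_model(values, seed=0)
    assert fit.means[1] == pytest.approx(1.5, abs=0.3)
    assert fit.positive_fraction == pytest.approx(0.02, abs=0.01)
    assert fit.separation > 2


def test_insufficient_cells_raises():
    with pytest.raises(ValidationError, match="insufficient"):
        fit_population_model(np.ones(10), seed=0)


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------

def _fit(values, seed=0):
    return fit_population_model(np.asarray(values, dtype=float), seed=seed)


def test_separated_fit_is_detectable_negative95():
    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(-0.5, 0.3, 700),
                             rng.normal(2.5, 0.3, 300)])
    call = call_detectability(_fit(values), isotype_background=0.2,
                              antibody_id="ab", arm_label="1x")
    assert call.detectable and call.mode == "negative95"
    # threshold sits at the upper edge of the negative population
    assert 0.0 < call.threshold < 1.5


def test_background_only_values_are_not_detectable():
    rng = np.random.default_rng(5)
    values = rng.normal(-0.6, 0.4, 1500)  # hugging the isotype background
    call = call_detectability(_fit(values), isotype_background=0.1,
                              antibody_id="ab", arm_label="1x")
    assert not call.detectable and call.mode == "none"
    assert call.threshold is None


def test_ubiquitous_antigen_uses_positive5():
    rng = np.random.default_rng(6)
    values = rng.normal(2.0, 0.5, 1200)  # all cells well above background
    call = call_detectability(_fit(values), isotype_background=0.0,
                              antibody_id="ab", arm_label="1x")
    assert call.detectable and call.mode == "positive5"
    assert call.threshold == pytest.approx(percentile(values, 5))


def test_discrete_background_split_rejected_by_isotype_guard():
    """EM splits near-discrete low-count background into pseudo-components
    with high separation; the isotype margin must veto the call."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(0.3, 2000)
    values = np.log1p(counts) - np.log1p(counts).mean()
    iso_bg = percentile(values, 95)
    call = call_detectability(_fit(values), isotype_background=iso_bg,
                              antibody_id="ab", arm_label="0.04x")
    assert not call.detectable


# ---------------------------------------------------------------------------
# overrides and binarization
# ---------------------------------------------------------------------------

def _call(ab, arm, detectable, threshold=None, mode=None):
    return DetectCall(ab, arm, detectable,
                      mode or ("negative95" if detectable else "none"),
                      threshold, 3.0 if detectable else 0.5)


def test_manual_overrides():
    calls = [_call("abX", "1x", True, 0.7), _call("abY", "1x", False)]
    assert apply_manual_overrides(calls, pd.DataFrame()) == calls

    table = pd.DataFrame([{"antibody_id": "abX", "arm_label": "1x",
                           "detectable": True, "threshold": 1.2}])
    out = apply_manual_overrides(calls, table)
    assert out[0].threshold == 1.2 and out[0].mode == "manual"
    assert out[1] == calls[1]

    bad = pd.DataFrame([{"antibody_id": "ghost", "arm_label": "1x",
                         "detectable": True, "threshold": 1.0}])
    with pytest.raises(ValidationError, match="ghost"):
        apply_manual_overrides(calls, bad)


def test_detect_call_invariants():
    with pytest.raises(ValidationError):
        DetectCall("ab", "1x", True, "negative95", None, 1.0)
    with pytest.raises(ValidationError):
        DetectCall("ab", "1x", False, "negative95", None, 1.0)


def test_binarize_strict_boundary():
    from cite_titration.model import PanelDefinition, PanelEntry
    panel = PanelDefinition([PanelEntry("abX", "T", False)])
    ann = pd.DataFrame({"barcode": ["b1", "b2", "b3"],
                        "qc_pass": [True] * 3,
                        "qc_fail_reason": ["none"] * 3,
                        "arm_label": ["1x"] * 3,
                        "major_type": ["B"] * 3})
    clr = np.array([[0.99, 1.0, 1.01]])
    calls = [_call("abX", "1x", True, 1.0)]
    out = binarize(clr, calls, ann, panel)
    assert out.tolist() == [[False, False, True]]  # exactly-at-threshold negative

    undetect = [_call("abX", "1x", False)]
    assert not binarize(clr, undetect, ann, panel).any()

    with pytest.raises(ValidationError, match="missing call"):
        binarize(clr, [], ann, panel)


# ---------------------------------------------------------------------------
# end-to-end properties on the default synthetic run
# ---------------------------------------------------------------------------

def test_isotype_controls_never_detectable(default_run):
    iso = set(default_run.dataset.panel.isotype_ids)
    assert not any(c.detectable for c in default_run.calls
                   if c.antibody_id in iso)


def test_detectable_counts_match_truth_within_tolerance(default_run):
    truth = default_run.truth.antibodies
    for arm in ("2x", "1x", "0.2x", "0.04x"):
        called = default_run.detectable_count(arm)
        expected = int(truth[f"detectable_{arm}"].sum())
        assert abs(called - expected) <= 3, (arm, called, expected)


def test_positive_call_agreement_with_truth(default_run):
    """Cells of expressing types are called positive (and others negative)
    for detectable antibodies at the recommended concentration."""
    run = default_run
    binary = binarize(run.clr, run.calls, run.annotations, run.dataset.panel)
    merged = run.annotations.merge(run.truth.droplets, on="barcode")
    at_1x = (merged.qc_pass & (merged.arm_label == "1x")
             & ~merged.is_doublet).to_numpy()
    truth_ab = run.truth.antibodies.set_index("antibody_id")
    agreements = []
    for row, ab_id in enumerate(run.dataset.panel.antibody_ids):
        t = truth_ab.loc[ab_id]
        if not t["detectable_1x"]:
            continue
        expressing = set(t.expressing_types.split(";")) - {""}
        true_pos = merged.true_type.isin(expressing).to_numpy() & at_1x
        true_neg = ~merged.true_type.isin(expressing).to_numpy() & at_1x
        if true_pos.sum() == 0:
            continue
        acc_pos = binary[row][true_pos].mean()
        acc_neg = 1 - binary[row][true_neg].mean() if true_neg.sum() else 1.0
        agreements.append((acc_pos + acc_neg) / 2)
    assert np.mean(agreements) >= 0.95


def test_calls_frame_shape(default_run):
    frame = calls_to_frame(default_run.calls)
    assert len(frame) == 192 * 4
    assert set(frame.arm_label) == {"2x", "1x", "0.2x", "0.04x"}
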