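"""Synthetic cohort generator: counts, determinism, geometry, splits, raters."""

import numpy as np
import pandas as pd
import pytest

from radfuse.cohort import (
    CohortSpec,
    generate_cohort,
    generate_feature_tables,
    generate_image_cohort,
    lesion_max_diameter,
    make_rater_pair,
    split_cohort,
)
from conftest import half_cohort_spec


def test_default_spec_counts_and_feature_mode():
    spec = CohortSpec()
    assert spec.total == 466
    assert spec.n_per_class == {"HR+": 336, "HEBC": 76, "TNBC": 54}
    tables = generate_cohort(spec, mode="features")
    assert len(tables) == 10
    for df in tables.values():
        assert len(df) == 466
        counts = df["class"].value_counts().to_dict()
        assert counts == {"HR+": 336, "HEBC": 76, "TNBC": 54}
        assert df.shape[1] == 110  # class + 109 features


def test_feature_mode_deterministic_for_fixed_seed():
    a = generate_feature_tables(half_cohort_spec(7))
    b = generate_feature_tables(half_cohort_spec(7))
    for ch in a:
        pd.testing.assert_frame_equal(a[ch], b[ch])


def test_invalid_mode_and_bad_spec():
    with pytest.raises(ValueError, match="mode"):
        generate_cohort(CohortSpec(), mode="nonsense")
    with pytest.raises(ValueError):
        CohortSpec(test_size=466)
    with pytest.raises(ValueError):
        CohortSpec(n_per_class={"HR+": -1, "HEBC": 1, "TNBC": 1}, test_size=0)


def test_adc_entropy_direction_over_seeds():
    """TNBC lesions have lower ADC intensity entropy than non-TNBC.

    Checked on >= 100-lesion cohorts over 20 seeds; the direction must hold
    in at least 19 of 20.
    """
    hits = 0
    for seed in range(20):
        tables = generate_feature_tables(half_cohort_spec(seed, channels=("ADC",)))
        adc = tables["ADC"]
        tnbc = adc.loc[adc["class"] == "TNBC", "firstorder_Entropy"].mean()
        rest = adc.loc[adc["class"] != "TNBC", "firstorder_Entropy"].mean()
        hits += tnbc < rest
    assert hits >= 19


def test_adc_mad_direction():
    tables = generate_feature_tables(half_cohort_spec(3, channels=("ADC",)))
    adc = tables["ADC"]
    mad = adc.groupby(adc["class"] == "TNBC")["firstorder_MeanAbsoluteDeviation"].mean()
    assert mad[True] < mad[False]


def test_image_mode_median_tnbc_diameter_near_26mm():
    """Median TNBC max diameter tracks the 26 mm class median."""
    spec = CohortSpec(n_per_class={"HR+": 0, "HEBC": 0, "TNBC": 54},
                      test_size=5, channels=(), seed=0)
    lesions = generate_image_cohort(spec)
    assert len(lesions) == 54
    diam = [lesion_max_diameter(s.mask, s.voxel_spacing) for s in lesions]
    assert np.median(diam) == pytest.approx(26.0, rel=0.20)


def test_image_mode_channels_share_grid():
    spec = CohortSpec(n_per_class={"HR+": 2, "HEBC": 2, "TNBC": 2}, test_size=2,
                      channels=("ADC", "T2WI"), seed=1)
    lesions = generate_image_cohort(spec)
    assert len(lesions) == 6
    for s in lesions:
        assert set(s.channels) == {"ADC", "T2WI"}
        for vol in s.channels.values():
            assert vol.shape == s.mask.shape
        assert s.mask.sum() > 0


# --- rater pairs ----------------------------------------------------------

def _ball(radius=20, shape=(48, 48, 48)):
    c = (np.array(shape) - 1) / 2
    grid = np.indices(shape).transpose(1, 2, 3, 0)
    return ((grid - c) ** 2).sum(axis=-1) <= radius**2


def test_rater_pair_zero_perturbation_identical():
    mask = _ball(8, (24, 24, 24))
    pair = make_rater_pair(mask, 0.0, seed=0, spacing=(1, 1, 1))
    assert np.array_equal(pair.mask_a, pair.mask_b)


def test_rater_pair_small_perturbation_high_dice():
    mask = _ball(20)
    pair = make_rater_pair(mask, 1.0, seed=0, spacing=(1, 1, 1))
    inter = (pair.mask_a & pair.mask_b).sum()
    dice = 2 * inter / (pair.mask_a.sum() + pair.mask_b.sum())
    assert dice > 0.8
    assert not np.array_equal(pair.mask_a, pair.mask_b)


def test_rater_pair_errors():
    with pytest.raises(ValueError, match="empty"):
        make_rater_pair(np.zeros((4, 4, 4), dtype=bool), 1.0, seed=0)
    with pytest.raises(ValueError):
        make_rater_pair(_ball(2, (8, 8, 8)), 50.0, seed=0, spacing=(1, 1, 1))


# --- splits ---------------------------------------------------------------

def test_split_default_cohort_337_129():
    labels = ["HR+"] * 336 + ["HEBC"] * 76 + ["TNBC"] * 54
    train, test = split_cohort(labels, 129, seed=0)
    assert len(train) == 337 and len(test) == 129
    assert len(np.intersect1d(train, test)) == 0
    assert len(np.union1d(train, test)) == 466
    labels = np.asarray(labels)
    frac = 129 / 466
    for cls in ("HR+", "HEBC", "TNBC"):
        n_cls = (labels == cls).sum()
        n_te = (labels[test] == cls).sum()
        assert abs(n_te - frac * n_cls) <= 1.0


def test_split_deterministic_and_errors():
    labels = ["HR+"] * 30 + ["TNBC"] * 10
    t1 = split_cohort(labels, 10, seed=5)
    t2 = split_cohort(labels, 10, seed=5)
    assert np.array_equal(t1[0], t2[0]) and np.array_equal(t1[1], t2[1])
    with pytest.raises(ValueError):
        split_cohort(labels, 0, seed=0)
    with pytest.raises(ValueError):
        split_cohort(["HR+"] * 40, 10, seed=0)  # single class
    with pytest.raises(ValueError):
        split_cohort(["HR+"] * 39 + ["TNBC"], 10, seed=0)  # singleton class
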