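import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methyldrift.qc import (
    apply_annotation_exclusions,
    compute_beta,
    drop_samples,
    flag_conversion_failures,
    flag_low_quality,
    mask_probes,
    run_qc,
)
from methyldrift.types import BetaMatrix


class TestComputeBeta:
    @pytest.mark.parametrize("m,u,expected", [
        (100.0, 100.0, 100.0 / 300.0),
        (0.0, 0.0, 0.0),
        (900.0, 0.0, 0.9),
    ])
    def test_formula(self, m, u, expected):
        assert compute_beta(m, u) == pytest.approx(expected, abs=1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_beta(-1.0, 5.0)

    @settings(max_examples=50, deadline=None)
    @given(u=st.floats(0, 1e5), m1=st.floats(0, 1e5), bump=st.floats(1e-3, 1e4))
    def test_monotone_in_methylated_channel(self, u, m1, bump):
        assert compute_beta(m1 + bump, u) > compute_beta(m1, u)

    @settings(max_examples=50, deadline=None)
    @given(m=st.floats(0, 1e6), u=st.floats(0, 1e6))
    def test_range(self, m, u):
        b = compute_beta(m, u)
        assert 0.0 <= b < 1.0


class TestDetectionFlags:
    def test_strict_inequality_at_threshold(self):
        p = pd.DataFrame({"s1": [0.06, 0.05, 0.0499]},
                         index=["a", "b", "c"])
        flags = flag_low_quality(p)
        assert flags["s1"].tolist() == [True, False, False]

    def test_flag_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        p = pd.DataFrame(rng.uniform(0, 0.2, size=(10, 10)))
        flags = flag_low_quality(p)
        brute = sum(1 for i in range(10) for j in range(10)
                    if p.iat[i, j] > 0.05)
        assert int(flags.to_numpy().sum()) == brute

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            flag_low_quality(pd.DataFrame({"s": [1.5]}))


class TestConversionControls:
    def test_identical_means_flag_nothing(self):
        b = pd.DataFrame([[0.9, 0.9, 0.9]], index=["bs1"],
                         columns=["s1", "s2", "s3"])
        assert not flag_conversion_failures(b).any()

    def test_rule_on_four_sample_fixture(self):
        # per-sample means (0.9, 0.9, 0.9, 0.1): grand mean 0.7, SD 0.4,
        # cutoff 0.7 - 3*0.4 = -0.5, so even the outlier is not below it
        b = pd.DataFrame([[0.9, 0.9, 0.9, 0.1]], index=["bs1"],
                         columns=list("abcd"))
        flags = flag_conversion_failures(b)
        assert not flags.any()

    def test_clear_outlier_among_many_samples_is_flagged(self):
        # 19 well-converted samples plus one failure; with a single outlier
        # the max standardised deviation is (n-1)/sqrt(n), so n must be >= 12
        # before any sample can sit below mean - 3*SD at all
        vals = [0.95, 0.94, 0.96] * 6 + [0.95, 0.5]
        b = pd.DataFrame([vals], index=["bs1"],
                         columns=[f"s{i}" for i in range(20)])
        flags = flag_conversion_failures(b)
        assert flags.tolist() == [False] * 19 + [True]

    def test_huge_k_flags_nothing(self):
        vals = [0.95, 0.9, 0.1, 0.99]
        b = pd.DataFrame([vals], index=["bs1"], columns=list("abcd"))
        assert not flag_conversion_failures(b, k=1e12).any()

    def test_zero_controls_is_explicit_error(self):
        b = pd.DataFrame(np.empty((0, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="skip"):
            flag_conversion_failures(b)


class TestMaskAndDropBoundaries:
    def test_probe_masking_strictly_more_than_fraction(self):
        f10 = pd.DataFrame(False, index=["p"], columns=[f"s{i}" for i in range(10)])
        f10.iloc[0, 0] = True  # 10% > 5%
        assert mask_probes(f10).tolist() == ["p"]

        f20 = pd.DataFrame(False, index=["p"], columns=[f"s{i}" for i in range(20)])
        f20.iloc[0, 0] = True  # exactly 5% -> retained
        assert mask_probes(f20).tolist() == []

        assert mask_probes(f20 & False).tolist() == []

    def test_sample_dropping_strictly_more_than_fraction(self):
        n = 100
        flags = pd.DataFrame(False, index=[f"p{i}" for i in range(n)],
                             columns=["s1", "s2", "s3"])
        flags.iloc[:31, 0] = True   # 31% -> dropped
        flags.iloc[:30, 1] = True   # 30% exactly -> kept
        assert drop_samples(flags).tolist() == ["s1"]

        empty = pd.DataFrame(index=pd.Index([]), columns=["s1"], dtype=bool)
        assert drop_samples(empty).tolist() == []


def test_annotation_exclusions(tiny_manifest):
    excluded = apply_annotation_exclusions(tiny_manifest)
    assert set(excluded) == {"cg06", "cg07"}  # chrX and cross-reactive
    assert "cg00" not in excluded


def test_run_qc_partitions_probe_universe(noisy_cohort):
    c = noisy_cohort
    cleaned, report = run_qc(c["beta"], c["intensities"].detection_p,
                             c["manifest"], c["sheet"])
    masked = set(report.masked_probes)
    retained = set(report.retained_probes)
    assert masked.isdisjoint(retained)
    assert masked | retained == set(c["manifest"].probe_ids)
    assert not set(report.dropped_samples) & set(cleaned.sample_ids)


def test_qc_filter_order_independence(noisy_cohort):
    """Exclusions, masking and dropping computed on the same input commute."""
    c = noisy_cohort
    beta, detp, manifest = c["beta"], c["intensities"].detection_p, c["manifest"]
    flags = flag_low_quality(detp)
    masked = set(mask_probes(flags))
    dropped = set(drop_samples(flags))
    excluded = set(apply_annotation_exclusions(manifest))

    import itertools
    removals = {
        "mask": lambda probes, samples: (probes - masked, samples),
        "drop": lambda probes, samples: (probes, samples - dropped),
        "excl": lambda probes, samples: (probes - excluded, samples),
    }
    outcomes = set()
    for order in itertools.permutations(removals):
        probes = set(beta.probe_ids)
        samples = set(beta.sample_ids)
        for step in order:
            probes, samples = removals[step](probes, samples)
        outcomes.add((frozenset(probes), frozenset(samples)))
    assert len(outcomes) == 1


def test_run_qc_drops_conversion_failure_sample():
    from conftest import make_cohort, NOISE_FREE_CONFIG
    kwargs = dict(NOISE_FREE_CONFIG)
    kwargs["n_subjects_per_group"] = 6
    kwargs["conversion_fail_samples"] = ("subj03_followup",)
    c = make_cohort(kwargs)
    cleaned, report = run_qc(c["beta"], c["intensities"].detection_p,
                             c["manifest"], c["sheet"])
    assert "subj03_followup" in report.dropped_samples
    assert "subj03_followup" not in cleaned.sample_ids
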