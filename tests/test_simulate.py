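import numpy as np
import pandas as pd
import pytest

from methyldrift.context import classify_context
from methyldrift.mdi import compute_mdi
from methyldrift.qc import beta_from_intensities, compute_beta
from methyldrift.simulate import (
    SimulationConfig,
    generate_manifest,
    generate_paired_cohort,
    generate_survival,
)
from methyldrift.survival import km_estimate

from conftest import NOISE_FREE_CONFIG, make_cohort


def test_manifest_generation_is_deterministic():
    m1, i1 = generate_manifest(1000, 10, seed=1)
    m2, i2 = generate_manifest(1000, 10, seed=1)
    pd.testing.assert_frame_equal(m1.table, m2.table)
    assert set(i1) == set(i2)
    for c in i1:
        assert np.array_equal(i1[c], i2[c])


def test_manifest_populates_every_context():
    manifest, islands = generate_manifest(200, 8, seed=4)
    assignment = classify_context(manifest, islands)
    counts = assignment["context"].value_counts()
    assert (counts[["Island", "Shore", "Shelf", "OpenSea"]] >= 1).all()


def test_manifest_without_islands_is_all_open_sea():
    manifest, islands = generate_manifest(50, 0, seed=2)
    assert islands == {}
    assignment = classify_context(manifest, islands)
    assert (assignment["context"] == "OpenSea").all()


def test_cohort_determinism_and_drift_count(noise_free_cohort):
    a = noise_free_cohort
    b = make_cohort(NOISE_FREE_CONFIG)
    pd.testing.assert_frame_equal(a["intensities"].methylated,
                                  b["intensities"].methylated)
    pd.testing.assert_series_equal(a["truth"].true_drift, b["truth"].true_drift)
    cfg = a["config"]
    assert a["truth"].drifted.sum() == round(cfg.drift_fraction * cfg.n_cpgs)


def test_no_drift_no_noise_gives_identical_pairs():
    cfg = SimulationConfig(n_cpgs=300, n_subjects_per_group=2, seed=9,
                           drift_fraction=0.0, noise_sd=0.0,
                           slide_effect_sd=0.02, detection_fail_rate=0.0)
    manifest, islands = generate_manifest(300, 5, seed=9)
    intensities, sheet, design, truth = generate_paired_cohort(manifest, cfg, islands)
    beta = beta_from_intensities(intensities).values
    for pair in design:
        np.testing.assert_array_equal(beta[pair.primary_sample_id],
                                      beta[pair.followup_sample_id])


def test_noise_free_mdi_matches_formula(noise_free_cohort):
    """With drift_fraction f and |effect| d the treated-pair MDI is 100*f*d."""
    c = noise_free_cohort
    cfg = c["config"]
    beta = c["beta"].subset_probes(c["manifest"].analysis_probes()).values
    expected = 100.0 * cfg.drift_fraction * abs(cfg.drift_effect)
    for pair in c["design"]:
        group = c["sheet"].table.at[pair.primary_sample_id, "group"]
        mdi = compute_mdi(beta[pair.primary_sample_id],
                          beta[pair.followup_sample_id])
        want = expected if group == "treated" else 0.0
        assert mdi == pytest.approx(want, abs=1e-9)
        assert c["truth"].expected_mdi[pair.subject_id] == pytest.approx(want)


def test_intensities_recover_target_beta(noise_free_cohort):
    inten = noise_free_cohort["intensities"]
    recovered = compute_beta(inten.methylated, inten.unmethylated)
    target = noise_free_cohort["beta"].values
    assert np.nanmax(np.abs(recovered.to_numpy() - target.to_numpy())) < 1e-9


def test_observed_mdi_under_noise_matches_monte_carlo_oracle():
    """Noisy MDI should match a direct resampling oracle of the same noise law."""
    cfg = SimulationConfig(n_cpgs=4000, n_subjects_per_group=4, seed=31,
                           drift_fraction=0.05, drift_effect=0.3,
                           noise_sd=0.05, slide_effect_sd=0.0,
                           detection_fail_rate=0.0, ffpe_fraction=0.0)
    manifest, islands = generate_manifest(cfg.n_cpgs, 20, seed=31)
    intensities, sheet, design, truth = generate_paired_cohort(manifest, cfg, islands)
    beta = beta_from_intensities(intensities)
    analysis = beta.subset_probes(manifest.analysis_probes()).values
    treated = [p for p in design
               if sheet.table.at[p.primary_sample_id, "group"] == "treated"]
    observed = np.mean([compute_mdi(analysis[p.primary_sample_id],
                                    analysis[p.followup_sample_id])
                        for p in treated])

    # oracle: brute-force Monte-Carlo of E|expit(z1+e1) - expit(z2+e2)| with the
    # generator's own baseline draw and logit noise law, 10,000 draws
    from scipy.special import expit, logit
    rng = np.random.default_rng(123)
    n = 10_000
    base = np.zeros(n)
    ctxs = ["Island", "Shore", "Shelf", "OpenSea"]
    # same context placement weights the manifest generator uses
    which = rng.choice(4, size=n, p=[0.30, 0.25, 0.15, 0.30])
    for i, ctx in enumerate(ctxs):
        a, b = cfg.baseline_beta_params[ctx]
        sel = which == i
        base[sel] = rng.beta(a, b, size=sel.sum())
    base = np.clip(base, 0.001, 0.99)
    drift = np.zeros(n)
    drifted = rng.random(n) < cfg.drift_fraction
    sign = np.where(rng.random(n) < cfg.drift_direction_mix, -1.0, 1.0)
    drift[drifted] = (sign * cfg.drift_effect)[drifted]
    base = np.clip(base, np.maximum(0.001, 0.001 - drift),
                   np.minimum(0.99, 0.99 - drift))
    s = cfg.noise_sd / 0.25
    e1 = rng.normal(0, s, n)
    e2 = rng.normal(0, s, n)
    b1 = np.clip(expit(logit(base) + e1), 0.001, 0.99)
    b2 = np.clip(expit(logit(np.clip(base + drift, 0.001, 0.99)) + e2), 0.001, 0.99)
    oracle = 100.0 * np.mean(np.abs(b2 - b1))
    assert observed == pytest.approx(oracle, rel=0.05)


def test_conversion_failure_samples_get_low_controls():
    cfg = SimulationConfig(n_cpgs=100, n_subjects_per_group=3, seed=8,
                           noise_sd=0.0, slide_effect_sd=0.0,
                           detection_fail_rate=0.0,
                           conversion_fail_samples=("subj02_followup",))
    manifest, islands = generate_manifest(100, 4, seed=8)
    intensities, sheet, design, truth = generate_paired_cohort(manifest, cfg, islands)
    beta = beta_from_intensities(intensities).values
    ctrl = manifest.control_probes()
    means = beta.loc[ctrl].mean()
    assert means["subj02_followup"] < 0.6
    assert (means.drop("subj02_followup") > 0.9).all()
    assert truth.qc_fail_samples == {"subj02_followup": "conversion"}


def test_survival_generator_properties():
    t1 = generate_survival(50, 300.0, 0.2, seed=5)
    t2 = generate_survival(50, 300.0, 0.2, seed=5)
    pd.testing.assert_frame_equal(t1, t2)

    single = generate_survival(1, 100.0, 0.0, seed=1)
    assert len(single) == 1 and single["event"].iloc[0] == 1

    with pytest.raises(ValueError):
        generate_survival(5, 100.0, 1.5, seed=1)


def test_survival_km_median_recovers_generator_median():
    # Monte-Carlo: n=5000 uncensored exponential times, fixed seed
    df = generate_survival(5000, 250.0, 0.0, seed=42)
    est = km_estimate(df["time_days"], df["event"])
    assert est.median == pytest.approx(250.0, rel=0.05)
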