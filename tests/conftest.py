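import numpy as np
import pandas as pd
import pytest

from methyldrift.qc import beta_from_intensities
from methyldrift.simulate import SimulationConfig, generate_manifest, generate_paired_cohort
from methyldrift.types import (
    BetaMatrix,
    PairedDesign,
    ProbeManifest,
    SampleSheet,
    SubjectPair,
)


@pytest.fixture
def tiny_manifest() -> ProbeManifest:
    """Eight CpGs (one per island/shore/shelf/open-sea pair of genes, some
    flagged) plus two bisulfite-control probes."""
    rows = {
        "chromosome": ["chr1"] * 6 + ["chrX", "chr2", "control", "control"],
        "position": [10_500, 12_000, 14_000, 20_000, 10_600, 10_700,
                     5_000, 7_000, 1, 2],
        "genes": [frozenset({"MGMT"}), frozenset({"MGMT", "EBF3"}), frozenset(),
                  frozenset({"TP53"}), frozenset({"MGMT"}), frozenset({"EBF3"}),
                  frozenset({"XG"}), frozenset({"TP53"}),
                  frozenset(), frozenset()],
        "is_bisulfite_control": [False] * 8 + [True, True],
        "exclusion_flags": [frozenset()] * 6
        + [frozenset({"sex_chromosome"}), frozenset({"cross_reactive"}),
           frozenset(), frozenset()],
        "platforms": [frozenset({"450K", "850K"})] * 10,
    }
    idx = pd.Index([f"cg{i:02d}" for i in range(8)] + ["bs00", "bs01"],
                   name="probe_id")
    return ProbeManifest(pd.DataFrame(rows, index=idx))


@pytest.fixture
def one_island() -> dict[str, np.ndarray]:
    # 1-based inclusive [10001, 11000] on chr1
    return {"chr1": np.array([[10_001, 11_000]])}


@pytest.fixture
def paired_sheet() -> SampleSheet:
    rows = []
    for i, (age, sex) in enumerate([(55, "M"), (61, "F"), (47, "M")], start=1):
        for tp in ("primary", "followup"):
            rows.append({
                "sample_id": f"s{i}_{tp}", "subject_id": f"s{i}",
                "timepoint": tp, "group": "treated", "age": float(age),
                "sex": sex, "preparation": "fresh_frozen", "slide_id": "sl1",
            })
    return SampleSheet(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def paired_design(paired_sheet) -> PairedDesign:
    return PairedDesign(tuple(
        SubjectPair(f"s{i}", f"s{i}_primary", f"s{i}_followup")
        for i in (1, 2, 3)))


@pytest.fixture
def small_beta(paired_sheet) -> BetaMatrix:
    probes = [f"cg{i:02d}" for i in range(4)]
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.1, 0.9, size=(4, 6))
    return BetaMatrix(pd.DataFrame(vals, index=pd.Index(probes, name="probe_id"),
                                   columns=paired_sheet.sample_ids))


# --------------------------------------------------------------------------
# synthetic cohorts reused across modules (session-scoped for speed)

NOISE_FREE_CONFIG = dict(
    n_cpgs=2000, n_subjects_per_group=3, seed=11,
    drift_fraction=0.1, drift_effect=0.3, drift_direction_mix=0.4,
    noise_sd=0.0, slide_effect_sd=0.0, detection_fail_rate=0.0,
    ffpe_fraction=0.0,
)

NOISY_CONFIG = dict(
    n_cpgs=2000, n_subjects_per_group=6, seed=23,
    drift_fraction=0.05, drift_effect=0.3, drift_direction_mix=0.4,
    noise_sd=0.05, slide_effect_sd=0.02, detection_fail_rate=0.005,
    ffpe_fraction=0.25,
)


def make_cohort(config_kwargs, manifest_seed=3, n_islands=20):
    cfg = SimulationConfig(**config_kwargs)
    manifest, islands = generate_manifest(cfg.n_cpgs, n_islands, seed=manifest_seed)
    intensities, sheet, design, truth = generate_paired_cohort(manifest, cfg, islands)
    beta = beta_from_intensities(intensities)
    return dict(config=cfg, manifest=manifest, islands=islands,
                intensities=intensities, beta=beta, sheet=sheet,
                design=design, truth=truth)


@pytest.fixture(scope="session")
def noise_free_cohort():
    return make_cohort(NOISE_FREE_CONFIG)


@pytest.fixture(scope="session")
def noisy_cohort():
    return make_cohort(NOISY_CONFIG)


def treated_design(cohort) -> PairedDesign:
    sheet = cohort["sheet"]
    return PairedDesign(tuple(
        p for p in cohort["design"]
        if sheet.table.at[p.primary_sample_id, "group"] == "treated"))
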