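"""Synthetic paired methylome cohorts with known ground truth.

The generator emulates the structure of a paired primary/follow-up tumor
EPIC-like study: per-context baseline beta distributions, a configurable
fraction of CpGs with true methylation drift between timepoints, beta-scale
measurement noise applied on the logit scale, FFPE samples with inflated
noise, slide batch shifts, bisulfite-conversion control probes, detection
p-value failures and designated conversion-failure samples. Intensities are
back-solved from the target beta at a fixed total signal so the beta
formula (M / (M + U + 100)) recovers the intended value to ~1e-9.

Everything is deterministic given the config seed; the ground truth records
exactly which CpGs drifted and the noise-free expected dysregulation index
per pair, so downstream stages can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio
from .context import classify_context
from .types import (
    BetaMatrix,
    IntensityData,
    PairedDesign,
    ProbeManifest,
    SampleSheet,
    SubjectPair,
)

BETA_MIN = 0.001
BETA_MAX = 0.99  # largest beta representable at total intensity 10,000 with offset 100
TOTAL_INTENSITY = 10_000.0  # M + U + offset
INTENSITY_OFFSET = 100.0
CONTROL_BETA_TRUE = 0.95
CONTROL_BETA_FAILED = 0.5
# logit-scale noise with this slope factor has beta-scale SD ~ noise_sd near beta 0.5
LOGIT_SLOPE_AT_HALF = 0.25

DEFAULT_BASELINE_PARAMS = {
    # Beta(a, b) per genomic context: islands mostly unmethylated, open sea high
    "Island": (1.5, 8.0),
    "Shore": (2.0, 4.0),
    "Shelf": (4.0, 3.0),
    "OpenSea": (6.0, 2.5),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic paired cohort."""

    n_cpgs: int = 8000
    n_subjects_per_group: int = 6          # matches a small paired trial cohort
    groups: tuple[str, ...] = ("treated", "control")
    seed: int = 0
    baseline_beta_params: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PARAMS))
    drift_fraction: float = 0.05
    drift_effect: float = 0.3              # |delta beta| of truly drifted CpGs
    drift_direction_mix: float = 0.45      # fraction of drifted CpGs hypomethylated
    context_weights: dict = field(default_factory=lambda: {
        "Island": 1.0, "Shore": 1.0, "Shelf": 1.0, "OpenSea": 1.0})
    noise_sd: float = 0.05                 # approximate beta-scale SD at beta = 0.5
    ffpe_noise_multiplier: float = 1.5
    ffpe_fraction: float = 0.25            # fraction of primary samples that are FFPE
    slide_effect_sd: float = 0.02          # logit-scale additive shift per slide
    subjects_per_slide: int = 4            # both samples of a pair share a slide
    detection_fail_rate: float = 0.005
    conversion_fail_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("drift_fraction", "drift_direction_mix", "ffpe_fraction",
                     "detection_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if not -1.0 < self.drift_effect < 1.0:
            raise ValueError("drift_effect must be in (-1, 1)")
        if self.noise_sd < 0 or self.slide_effect_sd < 0:
            raise ValueError("noise/slide SDs must be nonnegative")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    true_drift: pd.Series            # signed delta beta per analyzable CpG
    drifted: pd.Series               # bool per analyzable CpG
    qc_fail_samples: dict[str, str]  # sample_id -> failure kind
    expected_mdi: dict[str, float]   # subject -> noise-free expected MDI

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"true_drift": self.true_drift,
                             "drifted": self.drifted.astype(int)})


# ---------------------------------------------------------------------------
# manifest generation

def generate_manifest(
    n_cpgs: int,
    n_islands: int,
    genes_per_chromosome: int = 5,
    seed: int = 0,
    *,
    n_chromosomes: int = 4,
    sex_chromosome_fraction: float = 0.0,
    polymorphic_fraction: float = 0.0,
    cross_reactive_fraction: float = 0.0,
    n_control_probes: int | None = None,
) -> tuple[ProbeManifest, dict[str, np.ndarray]]:
    """Generate a probe manifest plus CpG-island intervals.

    Islands are spaced 60 kb apart so shore/shelf/open-sea offsets never
    collide with a neighbouring island. With ``n_islands >= 1`` the first
    four probes are pinned one to each context so every context is
    populated; remaining probes draw a context at random. Deterministic
    given the seed.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    if n_islands < 0 or n_islands > n_cpgs:
        raise ValueError("need n_cpgs >= n_islands >= 0")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]

    islands: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    spacing = 60_000
    island_list = []
    for i in range(n_islands):
        chrom = chroms[i % n_chromosomes]
        base = 10_000 + (i // n_chromosomes) * spacing
        length = int(rng.integers(300, 2001))
        islands[chrom].append((base + 1, base + length))
        island_list.append((chrom, base + 1, base + length))

    contexts = ["Island", "Shore", "Shelf", "OpenSea"]
    weights = np.array([0.30, 0.25, 0.15, 0.30])
    positions = np.empty(n_cpgs, dtype=np.int64)
    probe_chrom = []
    for j in range(n_cpgs):
        if n_islands == 0:
            chrom = chroms[int(rng.integers(n_chromosomes))]
            pos = int(rng.integers(1, 1_000_001))
        else:
            ctx = contexts[j] if j < 4 else contexts[int(rng.choice(4, p=weights))]
            chrom, s1, e1 = island_list[int(rng.integers(len(island_list)))]
            if ctx == "Island":
                pos = int(rng.integers(s1, e1 + 1))
            elif ctx == "Shore":
                pos = e1 + int(rng.integers(1, 2001))
            elif ctx == "Shelf":
                pos = e1 + int(rng.integers(2001, 4001))
            else:
                pos = e1 + int(rng.integers(4001, 25_000))
        probe_chrom.append(chrom)
        positions[j] = pos

    probe_ids = [f"cg{j:08d}" for j in range(n_cpgs)]
    # gene annotation: contiguous 50-kb windows per chromosome map to gene symbols
    genes = []
    for chrom, pos in zip(probe_chrom, positions):
        if genes_per_chromosome > 0 and rng.random() < 0.7:
            gidx = (pos // 50_000) % genes_per_chromosome
            gset = {f"G{chrom[3:]}_{gidx}"}
            if rng.random() < 0.1:
                gset.add(f"G{chrom[3:]}_{(gidx + 1) % genes_per_chromosome}")
            genes.append(frozenset(gset))
        else:
            genes.append(frozenset())

    flags = [set() for _ in range(n_cpgs)]
    def _mark(fraction: float, flag: str) -> None:
        n_mark = int(round(fraction * n_cpgs))
        if n_mark:
            for j in rng.choice(n_cpgs, size=n_mark, replace=False):
                flags[j].add(flag)
    _mark(sex_chromosome_fraction, "sex_chromosome")
    _mark(polymorphic_fraction, "polymorphic")
    _mark(cross_reactive_fraction, "cross_reactive")
    for j, f in enumerate(flags):
        if "sex_chromosome" in f:
            probe_chrom[j] = "chrX"

    if n_control_probes is None:
        n_control_probes = max(8, n_cpgs // 250)
    rows = {
        "chromosome": probe_chrom + ["control"] * n_control_probes,
        "position": np.concatenate([positions,
                                    np.arange(1, n_control_probes + 1)]),
        "genes": genes + [frozenset()] * n_control_probes,
        "is_bisulfite_control": [False] * n_cpgs + [True] * n_control_probes,
        "exclusion_flags": [frozenset(f) for f in flags]
                           + [frozenset()] * n_control_probes,
        "platforms": [frozenset({"450K", "850K"})] * (n_cpgs + n_control_probes),
    }
    index = pd.Index(probe_ids + [f"BS_ctrl_{k:04d}" for k in range(n_control_probes)],
                     name="probe_id")
    manifest = ProbeManifest(pd.DataFrame(rows, index=index))
    island_arrays = {c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
                     for c, iv in islands.items() if iv}
    return manifest, island_arrays


# ---------------------------------------------------------------------------
# cohort generation

def _solve_intensities(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Back-solve (M, U) with M + U + offset = TOTAL_INTENSITY for target beta."""
    m = beta * TOTAL_INTENSITY
    u = (TOTAL_INTENSITY - INTENSITY_OFFSET) - m
    if np.any(u < 0):
        raise ValueError("target beta exceeds the representable maximum")
    return m, u


def generate_paired_cohort(
    manifest: ProbeManifest,
    config: SimulationConfig,
    islands: dict[str, np.ndarray] | None = None,
) -> tuple[IntensityData, SampleSheet, PairedDesign, GroundTruth]:
    """Generate intensities, sample sheet, pairing and ground truth.

    Drift is injected only into treated-group pairs and only at analyzable
    probes (non-control, no exclusion flags), so downstream QC cannot remove
    a truly drifted CpG. The number of drifted CpGs is exactly
    round(drift_fraction * n analyzable CpGs). Baselines for drifted CpGs
    are drawn so the drifted value stays inside the representable beta
    range; the injected drift is therefore never truncated.
    """
    rng = np.random.default_rng(config.seed)
    noncontrol = manifest.table.index[~manifest.table["is_bisulfite_control"]]
    analyzable = manifest.analysis_probes()
    control = manifest.control_probes()

    # per-context baseline beta
    if islands is not None:
        assignment = classify_context(manifest, islands)
        ctx = assignment["context"].reindex(noncontrol).astype(str).fillna("OpenSea")
    else:
        ctx = pd.Series("OpenSea", index=noncontrol)
    baseline = pd.Series(0.0, index=noncontrol)
    for context, (a, b) in config.baseline_beta_params.items():
        sel = (ctx == context).to_numpy()
        if sel.any():
            baseline.iloc[sel] = rng.beta(a, b, size=int(sel.sum()))
    baseline = baseline.clip(BETA_MIN, BETA_MAX)

    # drifted CpG selection among analyzable probes, weighted by context
    n_drift = int(round(config.drift_fraction * len(noncontrol)))
    if n_drift > len(analyzable):
        raise ValueError("drift_fraction asks for more drifted CpGs than "
                         "analyzable probes exist")
    ctx_analyzable = ctx.reindex(analyzable)
    w = ctx_analyzable.map(lambda c: config.context_weights.get(c, 1.0)).to_numpy(float)
    if w.sum() <= 0:
        raise ValueError("context_weights sum to zero")
    pick = rng.choice(len(analyzable), size=n_drift, replace=False, p=w / w.sum())
    drifted_ids = analyzable[np.sort(pick)]

    magnitude = abs(config.drift_effect)
    n_hypo = int(round(config.drift_direction_mix * n_drift))
    signs = np.ones(n_drift)
    signs[:n_hypo] = -1.0
    rng.shuffle(signs)
    true_drift = pd.Series(0.0, index=analyzable)
    true_drift.loc[drifted_ids] = signs * magnitude
    # leave room so primary + drift stays representable
    for pid, d in zip(drifted_ids, true_drift.loc[drifted_ids]):
        lo, hi = (BETA_MIN, BETA_MAX - d) if d > 0 else (BETA_MIN - d, BETA_MAX)
        baseline.loc[pid] = float(np.clip(baseline.loc[pid], lo, hi))

    # subjects, samples, slides
    subjects, rows, pairs = [], [], []
    k = 0
    for group in config.groups:
        for _ in range(config.n_subjects_per_group):
            k += 1
            subjects.append((f"subj{k:02d}", group))
    slide_of = {s: f"slide{(i // config.subjects_per_slide) + 1:02d}"
                for i, (s, _) in enumerate(subjects)}
    slide_ids = sorted(set(slide_of.values()))
    slide_shift = {sl: (rng.normal(0.0, config.slide_effect_sd)
                        if config.slide_effect_sd > 0 else 0.0)
                   for sl in slide_ids}
    for subject, group in subjects:
        age = float(rng.integers(45, 76))
        sex = "F" if rng.random() < 0.5 else "M"
        prep_primary = "FFPE" if rng.random() < config.ffpe_fraction else "fresh_frozen"
        for tp, prep in (("primary", prep_primary), ("followup", "fresh_frozen")):
            rows.append({"sample_id": f"{subject}_{tp}", "subject_id": subject,
                         "timepoint": tp, "group": group, "age": age, "sex": sex,
                         "preparation": prep, "slide_id": slide_of[subject]})
        pairs.append(SubjectPair(subject, f"{subject}_primary", f"{subject}_followup"))
    sheet = SampleSheet(pd.DataFrame(rows).set_index("sample_id"))
    design = PairedDesign(tuple(pairs))

    # beta values per sample
    all_probes = noncontrol.append(control)
    beta_cols: dict[str, np.ndarray] = {}
    s_logit = config.noise_sd / LOGIT_SLOPE_AT_HALF
    for subject, group in subjects:
        for tp in ("primary", "followup"):
            sid = f"{subject}_{tp}"
            target = baseline.copy()
            if tp == "followup" and group == "treated":
                target.loc[analyzable] = (target.loc[analyzable]
                                          + true_drift).clip(BETA_MIN, BETA_MAX)
            ctrl_level = (CONTROL_BETA_FAILED if sid in config.conversion_fail_samples
                          else CONTROL_BETA_TRUE)
            values = np.concatenate([target.to_numpy(),
                                     np.full(len(control), ctrl_level)])
            mult = (config.ffpe_noise_multiplier
                    if sheet.table.at[sid, "preparation"] == "FFPE" else 1.0)
            shift = slide_shift[slide_of[subject]]
            if s_logit > 0 or shift != 0.0:
                z = logit(np.clip(values, BETA_MIN, BETA_MAX)) + shift
                if s_logit > 0:
                    z = z + rng.normal(0.0, s_logit * mult, size=len(values))
                values = np.clip(expit(z), BETA_MIN, BETA_MAX)
            beta_cols[sid] = values
    beta_df = pd.DataFrame(beta_cols, index=all_probes)

    m_df = beta_df * TOTAL_INTENSITY
    u_df = (TOTAL_INTENSITY - INTENSITY_OFFSET) - m_df
    detp = pd.DataFrame(
        rng.uniform(5e-4, 0.01, size=beta_df.shape),
        index=all_probes, columns=beta_df.columns)
    if config.detection_fail_rate > 0:
        fail = rng.random(size=beta_df.shape) < config.detection_fail_rate
        detp = detp.mask(pd.DataFrame(fail, index=detp.index, columns=detp.columns),
                         pd.DataFrame(rng.uniform(0.06, 0.8, size=beta_df.shape),
                                      index=detp.index, columns=detp.columns))
    intensities = IntensityData(methylated=m_df, unmethylated=u_df,
                                detection_p=detp)

    expected = float(100.0 * true_drift.abs().mean())
    expected_mdi = {s: (expected if g == "treated" else 0.0) for s, g in subjects}
    truth = GroundTruth(
        true_drift=true_drift,
        drifted=pd.Series(true_drift.to_numpy() != 0.0, index=analyzable),
        qc_fail_samples={s: "conversion" for s in config.conversion_fail_samples},
        expected_mdi=expected_mdi,
    )
    return intensities, sheet, design, truth


def generate_beta_cohort(manifest: ProbeManifest, config: SimulationConfig,
                         islands: dict[str, np.ndarray] | None = None
                         ) -> tuple[BetaMatrix, SampleSheet, PairedDesign, GroundTruth]:
    """Convenience wrapper returning betas computed back from the intensities."""
    from .qc import beta_from_intensities

    intensities, sheet, design, truth = generate_paired_cohort(manifest, config, islands)
    return beta_from_intensities(intensities), sheet, design, truth


# ---------------------------------------------------------------------------
# survival generation

def generate_survival(n: int, median_days: float, censor_rate: float,
                      seed: int = 0, group: str | None = None) -> pd.DataFrame:
    """Exponential event times with the stated median, independent censoring.

    Censoring times are exponential with rate chosen so the expected
    censored fraction equals ``censor_rate``.
    """
    if median_days <= 0:
        raise ValueError("median_days must be > 0")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    lam = np.log(2.0) / median_days
    t_event = rng.exponential(1.0 / lam, size=n)
    if censor_rate >= 1.0:
        time, event = t_event, np.zeros(n, dtype=int)
    elif censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        lam_c = lam * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame({
        "subject_id": [f"subj{i + 1:04d}" for i in range(n)],
        "time_days": np.round(time, 6),
        "event": event,
    })
    if group is not None:
        df["group"] = group
    return df


# ---------------------------------------------------------------------------
# on-disk cohort

def write_cohort(outdir: str | Path, manifest: ProbeManifest,
                 islands: dict[str, np.ndarray], intensities: IntensityData,
                 sheet: SampleSheet, design: PairedDesign,
                 truth: GroundTruth) -> dict[str, str]:
    """Write every standard pipeline input plus ground_truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.tsv",
        "islands": outdir / "islands.bed",
        "methylated": outdir / "methylated.tsv",
        "unmethylated": outdir / "unmethylated.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "pairs": outdir / "pairs.csv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    mio.write_manifest(manifest, paths["manifest"])
    mio.write_islands(islands, paths["islands"])
    mio.write_intensities(intensities, paths["methylated"],
                          paths["unmethylated"], paths["detection_p"])
    mio.write_sample_sheet(sheet, paths["sample_sheet"])
    mio.write_pairs(design, paths["pairs"])
    truth.to_frame().to_csv(paths["ground_truth"], sep="\t",
                            index_label="probe_id", float_format="%.10g")
    return {k: str(v) for k, v in paths.items()}
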