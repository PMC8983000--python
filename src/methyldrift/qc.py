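"""Beta-value computation and probe/sample quality control.

The QC rules, all with strict inequalities as printed on the source arrays'
standard workflow:

- a measurement is low quality when its detection p-value exceeds 0.05;
- a sample fails bisulfite conversion when its mean over conversion-control
  probes falls below the grand mean of per-sample control means minus
  3 standard deviations of those means;
- a probe is masked for all samples when it is low quality in more than 5%
  of samples;
- a sample is dropped when more than 30% of its probes are low quality;
- probes on sex chromosomes or documented as polymorphic/cross-reactive are
  excluded before analysis.

Detection p-values are an input: computing them from out-of-band intensities
requires raw scanner files and is out of scope here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BetaMatrix, IntensityData, ProbeManifest, QCReport, SampleSheet

DETECTION_P_THRESHOLD = 0.05
PROBE_MASK_FRACTION = 0.05
SAMPLE_DROP_FRACTION = 0.30
CONVERSION_SD_K = 3.0
BETA_OFFSET = 100.0


def compute_beta(methylated, unmethylated, offset: float = BETA_OFFSET):
    """beta = M / (M + U + offset); the offset stabilises low-intensity probes.

    Accepts scalars, arrays or DataFrames; shape is preserved. With the
    default offset, beta lies in [0, 1) and M = U = 0 maps to 0.
    """
    m = np.asarray(methylated, dtype=float) if not isinstance(methylated, pd.DataFrame) else methylated
    u = np.asarray(unmethylated, dtype=float) if not isinstance(unmethylated, pd.DataFrame) else unmethylated
    if np.any(np.asarray(m) < 0) or np.any(np.asarray(u) < 0):
        raise ValueError("negative intensity")
    return m / (m + u + offset)


def beta_from_intensities(data: IntensityData, offset: float = BETA_OFFSET) -> BetaMatrix:
    return BetaMatrix(compute_beta(data.methylated, data.unmethylated, offset))


def flag_low_quality(detection_p: pd.DataFrame,
                     threshold: float = DETECTION_P_THRESHOLD) -> pd.DataFrame:
    """Boolean frame: entry flagged iff detection p strictly exceeds threshold.

    Missing detection p-values are treated as failures (no evidence of signal).
    """
    arr = detection_p.to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("detection p-value outside [0,1]")
    return (detection_p > threshold) | detection_p.isna()


def flag_conversion_failures(control_betas: pd.DataFrame,
                             k: float = CONVERSION_SD_K) -> pd.Series:
    """Per-sample flags from bisulfite conversion-control probe betas.

    A sample is flagged iff its mean over control probes is strictly below
    (grand mean of per-sample control means) - k * (SD of per-sample control
    means). The SD is the sample standard deviation across samples.
    """
    if control_betas.shape[0] < 1:
        raise ValueError(
            "no bisulfite-control probes; skip the conversion filter explicitly")
    if control_betas.shape[1] < 2:
        raise ValueError("need >= 2 samples for a defined conversion SD")
    sample_means = control_betas.mean(axis=0, skipna=True)
    grand = sample_means.mean()
    sd = sample_means.std(ddof=1)
    return sample_means < (grand - k * sd)


def mask_probes(flags: pd.DataFrame,
                max_fraction: float = PROBE_MASK_FRACTION) -> pd.Index:
    """Probe ids flagged low quality in strictly more than max_fraction of samples."""
    if flags.shape[1] == 0:
        return flags.index[:0]
    frac = flags.mean(axis=1)
    return flags.index[frac > max_fraction]


def drop_samples(flags: pd.DataFrame,
                 max_fraction: float = SAMPLE_DROP_FRACTION) -> pd.Index:
    """Sample ids whose low-quality probe fraction strictly exceeds max_fraction."""
    if flags.shape[0] == 0:
        return flags.columns[:0]
    frac = flags.mean(axis=0)
    return flags.columns[frac > max_fraction]


def apply_annotation_exclusions(manifest: ProbeManifest) -> pd.Index:
    """Probes removed before analysis: any exclusion flag set."""
    return manifest.excluded_probes()


def run_qc(
    beta: BetaMatrix,
    detection_p: pd.DataFrame,
    manifest: ProbeManifest,
    sample_sheet: SampleSheet | None = None,
    *,
    detection_threshold: float = DETECTION_P_THRESHOLD,
    probe_mask_fraction: float = PROBE_MASK_FRACTION,
    sample_drop_fraction: float = SAMPLE_DROP_FRACTION,
    conversion_k: float = CONVERSION_SD_K,
    restrict_to_shared_platform: bool = True,
) -> tuple[BetaMatrix, QCReport]:
    """Apply the full QC cascade and return the cleaned matrix plus a report.

    Order (single deterministic pass): platform harmonisation, conversion-
    control sample flags, sample dropping by low-quality fraction, probe
    masking recomputed on surviving samples, then annotation exclusions and
    removal of control probes. Masked/excluded probes are removed from the
    returned matrix and listed with reasons in the report; masked union
    retained exactly partitions the manifest probe universe.
    """
    report = QCReport()
    values = beta.values
    detp = detection_p

    # restrict to probes present in the matrix and on all platforms in play
    universe = manifest.probe_ids
    probes = universe.intersection(values.index)
    if restrict_to_shared_platform:
        shared = manifest.shared_platform_probes()
        off_platform = probes.difference(shared)
        for pid in off_platform:
            report.masked_probes[pid] = "platform"
        probes = probes.intersection(shared)
        if len(off_platform):
            report.notes.append(
                f"{len(off_platform)} probes outside the shared platform set")
    for pid in universe.difference(values.index):
        report.masked_probes[pid] = "absent_from_matrix"
    values = values.loc[probes]
    detp = detp.loc[probes, values.columns]

    # conversion-control sample QC
    ctrl = manifest.control_probes().intersection(values.index)
    conv_fail: set[str] = set()
    if len(ctrl) and values.shape[1] >= 2:
        flags = flag_conversion_failures(values.loc[ctrl], k=conversion_k)
        means = values.loc[ctrl].mean(axis=0, skipna=True)
        report.conversion_control_mean = {s: float(means[s]) for s in values.columns}
        report.conversion_pass = {s: not bool(flags[s]) for s in values.columns}
        conv_fail = set(flags.index[flags])
    else:
        report.notes.append("conversion-control filter skipped "
                            "(no control probes or <2 samples)")

    # sample dropping by low-quality fraction over all measured probes
    lowq = flag_low_quality(detp, threshold=detection_threshold)
    frac = lowq.mean(axis=0)
    report.low_quality_fraction = {s: float(frac[s]) for s in values.columns}
    dropped = set(drop_samples(lowq, max_fraction=sample_drop_fraction)) | conv_fail
    report.dropped_samples = sorted(dropped)
    keep_samples = [s for s in values.columns if s not in dropped]
    values = values[keep_samples]
    lowq = lowq[keep_samples]

    # probe masking recomputed on surviving samples
    masked = mask_probes(lowq, max_fraction=probe_mask_fraction)
    for pid in masked:
        report.masked_probes[pid] = "detection"

    # annotation exclusions + control probes leave the analysis matrix
    excluded = apply_annotation_exclusions(manifest)
    for pid in excluded.intersection(values.index):
        if pid not in report.masked_probes:
            flags_set = manifest.table.at[pid, "exclusion_flags"]
            report.masked_probes[pid] = sorted(flags_set)[0]
    for pid in manifest.control_probes().intersection(values.index):
        if pid not in report.masked_probes:
            report.masked_probes[pid] = "bisulfite_control"

    keep_probes = [p for p in values.index if p not in report.masked_probes]
    cleaned = values.loc[keep_probes]
    # low-quality entries that survive masking stay as missing values
    cleaned = cleaned.mask(lowq.loc[keep_probes])

    report.retained_probes = list(cleaned.index)
    report.retained_samples = list(cleaned.columns)
    return BetaMatrix(cleaned), report
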