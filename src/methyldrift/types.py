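"""Core domain types shared by every pipeline stage.

All containers are thin, validated wrappers around pandas structures so that
downstream stages can rely on their invariants (unique labels, bounded
values, consistent pairing) without re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

EXCLUSION_FLAGS = frozenset({"sex_chromosome", "polymorphic", "cross_reactive"})
PLATFORMS = frozenset({"450K", "850K"})
TIMEPOINTS = ("primary", "followup")


class SubjectPair(NamedTuple):
    """One subject's matched primary and follow-up samples."""

    subject_id: str
    primary_sample_id: str
    followup_sample_id: str


@dataclass(frozen=True)
class ProbeManifest:
    """Per-probe genomic coordinates, gene links and control/mask flags.

    ``table`` is indexed by unique probe_id with columns:

    - ``chromosome``: str
    - ``position``: 1-based bp coordinate (int)
    - ``genes``: frozenset of gene symbols (may be empty)
    - ``is_bisulfite_control``: bool
    - ``exclusion_flags``: frozenset over {sex_chromosome, polymorphic, cross_reactive}
    - ``platforms``: frozenset over {450K, 850K}
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "position", "genes", "is_bisulfite_control",
                    "exclusion_flags", "platforms"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"manifest table missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id in manifest: {dup!r}")
        pos = t["position"].to_numpy()
        if (pos < 1).any():
            bad = t.index[pos < 1][0]
            raise ValueError(f"probe {bad!r} has position < 1")
        for pid, flags in t["exclusion_flags"].items():
            unknown = set(flags) - EXCLUSION_FLAGS
            if unknown:
                raise ValueError(f"probe {pid!r} has unknown exclusion flags {unknown}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def control_probes(self) -> pd.Index:
        return self.table.index[self.table["is_bisulfite_control"]]

    def excluded_probes(self) -> pd.Index:
        """Probes carrying any exclusion flag (sex chromosome / polymorphic / cross-reactive)."""
        has_flag = self.table["exclusion_flags"].map(len) > 0
        return self.table.index[has_flag]

    def analysis_probes(self) -> pd.Index:
        """Probes eligible for analysis: not controls, no exclusion flags."""
        keep = ~self.table["is_bisulfite_control"] & (self.table["exclusion_flags"].map(len) == 0)
        return self.table.index[keep]

    def shared_platform_probes(self) -> pd.Index:
        """Probes present on every platform represented in the manifest."""
        platforms_seen = set().union(*self.table["platforms"]) if len(self.table) else set()
        if len(platforms_seen) <= 1:
            return self.table.index
        keep = self.table["platforms"].map(lambda p: platforms_seen <= set(p))
        return self.table.index[keep]

    def genes_for(self, probe_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for pid in probe_ids:
            out |= set(self.table.at[pid, "genes"])
        return out

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples matrix of methylated fractions in [0, 1].

    Missing entries are NaN. Row (probe) and column (sample) labels are unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {v.index[i]!r}, "
                f"sample {v.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class IntensityData:
    """Methylated/unmethylated channel intensities with detection p-values.

    All three frames share probe index and sample columns.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        m, u, p = self.methylated, self.unmethylated, self.detection_p
        if not (m.shape == u.shape == p.shape):
            raise ValueError("intensity/detection frames have mismatched shapes")
        if not (m.index.equals(u.index) and m.index.equals(p.index)
                and m.columns.equals(u.columns) and m.columns.equals(p.columns)):
            raise ValueError("intensity/detection frames have mismatched labels")
        for name, frame in (("methylated", m), ("unmethylated", u)):
            arr = frame.to_numpy(dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative {name} intensity")
        parr = p.to_numpy(dtype=float)
        if np.any((parr < 0) | (parr > 1)):
            raise ValueError("detection p-value outside [0,1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.methylated.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylated.columns


@dataclass(frozen=True)
class SampleSheet:
    """Sample-level covariates: subject, timepoint, group, age, sex, prep, slide.

    ``table`` is indexed by unique sample_id. Each subject has at most one
    sample per timepoint.
    """

    table: pd.DataFrame

    REQUIRED = ("subject_id", "timepoint", "group", "age", "sex", "preparation", "slide_id")

    def __post_init__(self) -> None:
        t = self.table
        missing = set(self.REQUIRED) - set(t.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad_tp = ~t["timepoint"].isin(TIMEPOINTS)
        if bad_tp.any():
            raise ValueError(f"unknown timepoint {t['timepoint'][bad_tp].iloc[0]!r}")
        bad_sex = ~t["sex"].isin(("M", "F"))
        if bad_sex.any():
            raise ValueError(f"unknown sex {t['sex'][bad_sex].iloc[0]!r}")
        bad_prep = ~t["preparation"].isin(("fresh_frozen", "FFPE"))
        if bad_prep.any():
            raise ValueError(f"unknown preparation {t['preparation'][bad_prep].iloc[0]!r}")
        dup_pair = t.duplicated(subset=["subject_id", "timepoint"])
        if dup_pair.any():
            row = t[dup_pair].iloc[0]
            raise ValueError(
                f"subject {row['subject_id']!r} has more than one "
                f"{row['timepoint']!r} sample"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)])


@dataclass(frozen=True)
class PairedDesign:
    """Matched (subject, primary sample, follow-up sample) triples."""

    pairs: tuple[SubjectPair, ...]

    def __post_init__(self) -> None:
        subjects = [p.subject_id for p in self.pairs]
        if len(set(subjects)) != len(subjects):
            dup = next(s for s in subjects if subjects.count(s) > 1)
            raise ValueError(f"subject {dup!r} appears in more than one pair")

    @classmethod
    def from_sample_sheet(cls, sheet: SampleSheet,
                          subjects: Iterable[str] | None = None) -> "PairedDesign":
        """Build the design from every subject with both timepoints present."""
        t = sheet.table
        wanted = set(subjects) if subjects is not None else None
        pairs = []
        for subject, sub in t.groupby("subject_id", sort=True):
            if wanted is not None and subject not in wanted:
                continue
            by_tp = {tp: sid for sid, tp in sub["timepoint"].items()}
            if "primary" in by_tp and "followup" in by_tp:
                pairs.append(SubjectPair(str(subject), by_tp["primary"], by_tp["followup"]))
        return cls(tuple(pairs))

    def validate_against(self, sheet: SampleSheet) -> None:
        t = sheet.table
        for p in self.pairs:
            for sid, tp in ((p.primary_sample_id, "primary"),
                            (p.followup_sample_id, "followup")):
                if sid not in t.index:
                    raise ValueError(f"pair sample {sid!r} absent from sample sheet")
                if t.at[sid, "subject_id"] != p.subject_id:
                    raise ValueError(
                        f"sample {sid!r} does not belong to subject {p.subject_id!r}")
                if t.at[sid, "timepoint"] != tp:
                    raise ValueError(f"sample {sid!r} is not a {tp} sample")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class QCReport:
    """Outcome of sample/probe quality control.

    Masked + retained probe ids exactly partition the manifest probe universe;
    dropped samples appear in no downstream matrix.
    """

    low_quality_fraction: dict[str, float] = field(default_factory=dict)
    conversion_control_mean: dict[str, float] = field(default_factory=dict)
    conversion_pass: dict[str, bool] = field(default_factory=dict)
    masked_probes: dict[str, str] = field(default_factory=dict)  # probe_id -> reason
    dropped_samples: list[str] = field(default_factory=list)
    retained_probes: list[str] = field(default_factory=list)
    retained_samples: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        reasons: dict[str, list[str]] = {}
        for pid, reason in self.masked_probes.items():
            reasons.setdefault(reason, []).append(pid)
        return {
            "low_quality_fraction": self.low_quality_fraction,
            "conversion_control_mean": self.conversion_control_mean,
            "conversion_pass": self.conversion_pass,
            "n_masked_by_reason": {k: len(v) for k, v in sorted(reasons.items())},
            "masked_probes_by_reason": {k: sorted(v) for k, v in sorted(reasons.items())},
            "dropped_samples": sorted(self.dropped_samples),
            "n_retained_probes": len(self.retained_probes),
            "n_retained_samples": len(self.retained_samples),
            "notes": self.notes,
        }
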