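"""Readers and writers for every file format the pipeline touches.

Conventions, fixed once at the IO seam:

- manifest positions are 1-based;
- island BED intervals are 0-based half-open (standard BED) and are converted
  to 1-based inclusive coordinates exactly once, at read time;
- the missing-beta token is configurable (default "NA") and missingness is
  propagated, never imputed;
- gene annotations may list several symbols per probe; the probe counts
  toward every annotated gene downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EXCLUSION_FLAGS,
    BetaMatrix,
    IntensityData,
    PairedDesign,
    ProbeManifest,
    SampleSheet,
    SubjectPair,
)

MISSING_TOKEN = "NA"
FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# probe manifest

def read_manifest(path: str | Path, gene_separator: str = ";") -> ProbeManifest:
    """Read a probe manifest TSV.

    Required columns: probe_id, chromosome, position. Optional columns:
    genes (separator-joined symbols), is_bisulfite_control (0/1),
    exclusion_flags (separator-joined over {sex_chromosome, polymorphic,
    cross_reactive}), platforms (separator-joined over {450K, 850K}).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "chromosome", "position"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} missing required column {col!r}")
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe_id in {path}: {df['probe_id'][dup].iloc[0]!r}")
    positions = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df["position"]):
        try:
            positions[i] = int(raw)
        except ValueError:
            raise ValueError(
                f"non-integer position {raw!r} in {path} at line {i + 2}") from None

    def split_set(col: str) -> list[frozenset]:
        if col not in df.columns:
            return [frozenset()] * len(df)
        return [frozenset(x for x in raw.split(gene_separator) if x)
                for raw in df[col]]

    genes = split_set("genes")
    flags = split_set("exclusion_flags")
    platforms = split_set("platforms")
    if "platforms" not in df.columns:
        platforms = [frozenset({"450K", "850K"})] * len(df)
    is_ctrl = (df["is_bisulfite_control"].isin(("1", "true", "True"))
               if "is_bisulfite_control" in df.columns
               else pd.Series(False, index=df.index))
    table = pd.DataFrame(
        {
            "chromosome": df["chromosome"].to_numpy(),
            "position": positions,
            "genes": genes,
            "is_bisulfite_control": is_ctrl.to_numpy(),
            "exclusion_flags": flags,
            "platforms": platforms,
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return ProbeManifest(table)


def write_manifest(manifest: ProbeManifest, path: str | Path,
                   gene_separator: str = ";") -> None:
    t = manifest.table
    out = pd.DataFrame(
        {
            "probe_id": t.index,
            "chromosome": t["chromosome"].to_numpy(),
            "position": t["position"].to_numpy(),
            "genes": [gene_separator.join(sorted(g)) for g in t["genes"]],
            "is_bisulfite_control": t["is_bisulfite_control"].astype(int).to_numpy(),
            "exclusion_flags": [gene_separator.join(sorted(f)) for f in t["exclusion_flags"]],
            "platforms": [gene_separator.join(sorted(p)) for p in t["platforms"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# beta / intensity matrices

def _read_matrix(path: str | Path, missing_token: str) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", index_col=0,
                     na_values=[missing_token], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df.astype(float)


def read_beta_matrix(path: str | Path, missing_token: str = MISSING_TOKEN) -> BetaMatrix:
    """Read a probes x samples beta-value TSV; values validated to [0, 1]."""
    return BetaMatrix(_read_matrix(path, missing_token))


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      missing_token: str = MISSING_TOKEN) -> None:
    beta.values.to_csv(path, sep="\t", na_rep=missing_token,
                       float_format=FLOAT_FORMAT)


def read_intensities(methylated_path: str | Path, unmethylated_path: str | Path,
                     detection_p_path: str | Path,
                     missing_token: str = MISSING_TOKEN) -> IntensityData:
    """Read the methylated/unmethylated channel TSVs plus detection p-values."""
    return IntensityData(
        methylated=_read_matrix(methylated_path, missing_token),
        unmethylated=_read_matrix(unmethylated_path, missing_token),
        detection_p=_read_matrix(detection_p_path, missing_token),
    )


def write_intensities(data: IntensityData, methylated_path: str | Path,
                      unmethylated_path: str | Path, detection_p_path: str | Path) -> None:
    data.methylated.to_csv(methylated_path, sep="\t", float_format=FLOAT_FORMAT)
    data.unmethylated.to_csv(unmethylated_path, sep="\t", float_format=FLOAT_FORMAT)
    data.detection_p.to_csv(detection_p_path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# sample sheet & paired design

def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(Path(path), dtype={"sample_id": str, "subject_id": str,
                                        "slide_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"sample sheet {path} missing sample_id column")
    df = df.set_index("sample_id")
    df["age"] = df["age"].astype(float)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index_label="sample_id")


def read_pairs(path: str | Path, sheet: SampleSheet | None = None) -> PairedDesign:
    """Read a CSV of subject_id, primary_sample_id, followup_sample_id."""
    df = pd.read_csv(Path(path), dtype=str)
    needed = {"subject_id", "primary_sample_id", "followup_sample_id"}
    if not needed <= set(df.columns):
        raise ValueError(f"pairs file {path} missing columns {sorted(needed - set(df.columns))}")
    design = PairedDesign(tuple(
        SubjectPair(r.subject_id, r.primary_sample_id, r.followup_sample_id)
        for r in df.itertuples()
    ))
    if sheet is not None:
        design.validate_against(sheet)
    return design


def write_pairs(design: PairedDesign, path: str | Path) -> None:
    pd.DataFrame(list(design), columns=["subject_id", "primary_sample_id",
                                        "followup_sample_id"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CpG islands (BED)

def read_islands(path: str | Path) -> dict[str, np.ndarray]:
    """Read a CpG-island BED file.

    Returns per-chromosome arrays of shape (n, 2) holding 1-based inclusive
    [start, end] coordinates (converted from BED 0-based half-open here, and
    only here). Intervals are sorted; overlap merging is the context
    classifier's job.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno} has fewer than 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"BED line {lineno}: empty interval {start}-{end}")
            out.setdefault(chrom, []).append((start + 1, end))
    return {c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
            for c, iv in out.items()}


def write_islands(islands: dict[str, np.ndarray], path: str | Path) -> None:
    """Write islands back to BED (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(islands):
            for start1, end1 in islands[chrom]:
                fh.write(f"{chrom}\t{start1 - 1}\t{end1}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then member genes, tab-separated.

    Duplicate members within a set are deduplicated; an empty file yields an
    empty mapping.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# survival table

def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival CSV with columns subject_id, time_days, event (0/1).

    Extra columns (e.g. group) are preserved.
    """
    df = pd.read_csv(Path(path), dtype={"subject_id": str})
    needed = {"subject_id", "time_days", "event"}
    if not needed <= set(df.columns):
        raise ValueError(f"survival table {path} missing columns "
                         f"{sorted(needed - set(df.columns))}")
    df["time_days"] = df["time_days"].astype(float)
    df["event"] = df["event"].astype(int)
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event column must be 0/1")
    if (df["time_days"] <= 0).any():
        raise ValueError("time_days must be positive")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
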