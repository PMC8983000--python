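"""CpG island / shore / shelf / open-sea classification.

Context is defined by distance to the nearest provided CpG-island interval:
inside an island -> Island (distance 0); within (0, 2000] bp -> Shore;
(2000, 4000] bp -> Shelf; beyond 4000 bp, or on a chromosome without
islands -> Open Sea. Ties at 2000/4000 bp go to the nearer (smaller-
distance) class. Islands are an annotation input, never called de novo.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .types import ProbeManifest

logger = logging.getLogger(__name__)

CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")
SHORE_MAX_BP = 2000
SHELF_MAX_BP = 4000


def merge_islands(islands: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Sort and merge overlapping/adjacent island intervals per chromosome.

    Intervals are 1-based inclusive [start, end]. Overlaps are merged with a
    logged warning, never an error.
    """
    merged: dict[str, np.ndarray] = {}
    n_merged = 0
    for chrom, iv in islands.items():
        if len(iv) == 0:
            merged[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
        out = [list(iv[0])]
        for start, end in iv[1:]:
            if start <= out[-1][1] + 1:  # overlapping or book-ended
                out[-1][1] = max(out[-1][1], end)
                n_merged += 1
            else:
                out.append([start, end])
        merged[chrom] = np.array(out, dtype=np.int64)
    if n_merged:
        logger.warning("merged %d overlapping/adjacent island intervals", n_merged)
    return merged


def classify_position(position: int, chrom_islands: np.ndarray) -> tuple[str, int]:
    """Classify one 1-based position against merged islands on its chromosome.

    Returns (context, distance to the nearest island edge in bp; 0 inside).
    """
    if len(chrom_islands) == 0:
        return "OpenSea", -1
    starts = chrom_islands[:, 0]
    ends = chrom_islands[:, 1]
    i = int(np.searchsorted(starts, position, side="right")) - 1
    dist = np.inf
    if i >= 0:
        if position <= ends[i]:
            return "Island", 0
        dist = position - ends[i]
    if i + 1 < len(starts):
        dist = min(dist, starts[i + 1] - position)
    dist = int(dist)
    if dist <= SHORE_MAX_BP:
        return "Shore", dist
    if dist <= SHELF_MAX_BP:
        return "Shelf", dist
    return "OpenSea", dist


def classify_context(manifest: ProbeManifest,
                     islands: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Assign a genomic context to every non-control, non-excluded probe.

    Returns a frame indexed by probe_id with columns ``context`` and
    ``distance_bp`` (-1 when no island exists on the chromosome). The four
    contexts partition the assigned probes.
    """
    merged = merge_islands(islands)
    probes = manifest.analysis_probes()
    t = manifest.table.loc[probes]
    contexts = []
    distances = []
    empty = np.empty((0, 2), dtype=np.int64)
    for chrom, pos in zip(t["chromosome"].to_numpy(), t["position"].to_numpy()):
        ctx, d = classify_position(int(pos), merged.get(chrom, empty))
        contexts.append(ctx)
        distances.append(d)
    return pd.DataFrame(
        {"context": pd.Categorical(contexts, categories=list(CONTEXTS)),
         "distance_bp": np.array(distances, dtype=np.int64)},
        index=probes,
    )


def stratify_by_context(values: pd.Series, assignment: pd.DataFrame) -> pd.DataFrame:
    """Summarise a per-CpG quantity within each genomic context.

    Returns one row per context (count of non-missing values, mean, quartiles).
    Contexts with no probes are reported with count 0. Probes in ``values``
    lacking an assignment are an error.
    """
    unassigned = values.index.difference(assignment.index)
    if len(unassigned):
        raise ValueError(f"probe {unassigned[0]!r} has no context assignment")
    ctx = assignment.loc[values.index, "context"]
    rows = []
    for context in CONTEXTS:
        vals = values[(ctx == context).to_numpy()].dropna()
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((context, len(vals), float(vals.mean()),
                         float(q1), float(med), float(q3)))
        else:
            rows.append((context, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["context", "count", "mean",
                                       "q25", "median", "q75"]).set_index("context")
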