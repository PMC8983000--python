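"""Per-CpG paired differential methylation.

For each CpG the change in methylation is summarised two ways:

- ``delta_beta``: the mean within-subject (follow-up minus primary) beta
  difference, the quantity thresholded at |delta beta| > 0.2;
- a random-intercept linear mixed model fit to the beta values with
  timepoint as the effect of interest and optional age, sex, preparation
  and slide fixed-effect covariates, subject as the random intercept.

Estimation is REML with the single variance ratio profiled out and
optimised in one dimension. The Wald test for the timepoint coefficient
uses a t reference with containment-style residual degrees of freedom
(N - rank(X) - (n_subjects - 1)); in a balanced paired design with no
covariates this reproduces the paired t-test exactly. P-values are adjusted
by Benjamini-Hochberg FDR, and CpGs are classified hyper/hypo/unchanged
with strict inequalities at the delta-beta and q-value thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, PairedDesign, ProbeManifest, SampleSheet

logger = logging.getLogger(__name__)

DELTA_BETA_THRESHOLD = 0.2
Q_THRESHOLD = 0.05
CLASSIFICATION_MODES = ("fdr_and_delta", "delta_only")
DEFAULT_COVARIATES = ("age", "sex", "preparation", "slide")


@dataclass
class ModelSpec:
    """Fixed covariates plus the mandatory timepoint effect and subject intercept."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        allowed = {"age", "sex", "preparation", "slide"}
        unknown = set(self.covariates) - allowed
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# delta beta

def compute_delta_beta(beta: BetaMatrix, design: PairedDesign) -> pd.Series:
    """Mean within-subject (follow-up - primary) beta difference per CpG.

    Only subjects with both values non-missing contribute at a CpG; CpGs
    with zero complete pairs are missing.
    """
    if len(design) == 0:
        raise ValueError("empty paired design")
    v = beta.values
    diffs = []
    for pair in design:
        diffs.append(v[pair.followup_sample_id] - v[pair.primary_sample_id])
    return pd.concat(diffs, axis=1).mean(axis=1, skipna=True).rename("delta_beta")


def n_complete_pairs(beta: BetaMatrix, design: PairedDesign) -> pd.Series:
    v = beta.values
    counts = []
    for pair in design:
        counts.append((v[pair.followup_sample_id].notna()
                       & v[pair.primary_sample_id].notna()))
    return pd.concat(counts, axis=1).sum(axis=1).rename("n_pairs")


# ---------------------------------------------------------------------------
# design matrix

def build_design_matrix(sheet: SampleSheet, sample_ids: list[str],
                        spec: ModelSpec) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fixed-effect design matrix for the given samples.

    Columns: intercept, timepoint (followup=1), then requested covariates;
    categorical covariates are dummy-coded dropping the first level in
    sorted order. Returns (X, column names, subject codes).
    """
    t = sheet.table.loc[sample_ids]
    cols: list[np.ndarray] = [np.ones(len(t))]
    names = ["intercept"]
    cols.append((t["timepoint"] == "followup").to_numpy(dtype=float))
    names.append("timepoint")
    if "age" in spec.covariates:
        cols.append(t["age"].to_numpy(dtype=float))
        names.append("age")
    if "sex" in spec.covariates:
        cols.append((t["sex"] == "F").to_numpy(dtype=float))
        names.append("sex_F")
    if "preparation" in spec.covariates:
        cols.append((t["preparation"] == "FFPE").to_numpy(dtype=float))
        names.append("preparation_FFPE")
    if "slide" in spec.covariates:
        levels = sorted(t["slide_id"].unique())
        for lev in levels[1:]:
            cols.append((t["slide_id"] == lev).to_numpy(dtype=float))
            names.append(f"slide_{lev}")
    X = np.column_stack(cols)
    subjects = pd.Categorical(t["subject_id"]).codes
    return X, names, subjects


def drop_aliased_columns(X: np.ndarray, names: list[str],
                         tol: float = 1e-8) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove aliased (rank-deficient) columns deterministically.

    Columns are scanned left to right and a column is dropped when it adds
    no rank over the columns already kept (pivot below tolerance in an
    incrementally grown QR). Because intercept and timepoint come first in
    the design, covariate columns confounded with them (e.g. a slide
    indicator confounded with timepoint or preparation) are the ones that
    leave.
    """
    n, p = X.shape
    norms = np.linalg.norm(X, axis=0)
    scale = max(norms.max(), 1.0)
    keep: list[int] = []
    dropped: list[str] = []
    basis = np.empty((n, 0))
    for j in range(p):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col.copy()
        if np.linalg.norm(resid) > tol * scale:
            keep.append(j)
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
        else:
            dropped.append(names[j])
    return X[:, keep], [names[i] for i in keep], dropped


# ---------------------------------------------------------------------------
# random-intercept REML

@dataclass
class LMMFit:
    coefficients: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    sigma2_resid: float
    sigma2_subject: float
    df_resid: float
    dropped_columns: list[str] = field(default_factory=list)
    converged: bool = True


def _gls_pieces(y: np.ndarray, X: np.ndarray, group_slices: list[np.ndarray],
                lam: float):
    """X'V^-1X, X'V^-1y, y'V^-1y and log|V| for V = I + lam * ZZ' blockwise."""
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    logdet = 0.0
    for idx in group_slices:
        ni = len(idx)
        c = lam / (1.0 + lam * ni)
        xs = X[idx].sum(axis=0)
        ys = float(y[idx].sum())
        xtx = xtx - c * np.outer(xs, xs)
        xty = xty - c * xs * ys
        yty = yty - c * ys * ys
        logdet += np.log1p(lam * ni)
    return xtx, xty, yty, logdet


def _reml_neg2ll(lam: float, y, X, group_slices, n, p) -> float:
    xtx, xty, yty, logdet = _gls_pieces(y, X, group_slices, lam)
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        return np.inf
    rss = yty - float(xty @ beta)
    if rss <= 0:
        rss = np.finfo(float).tiny
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(rss) + logdet + logdet_xtx


def fit_lmm(y: np.ndarray, X: np.ndarray, subjects: np.ndarray,
            names: list[str], *, lambda_override: float | None = None) -> LMMFit:
    """Random-intercept linear mixed model by 1-D profiled REML.

    ``lambda_override`` pins the variance ratio sigma_u^2/sigma_e^2 (0 gives
    ordinary least squares); otherwise it is optimised on the log scale.
    """
    mask = np.isfinite(y)
    y, X, subjects = y[mask], X[mask], subjects[mask]
    n = len(y)
    if n == 0:
        raise ValueError("all responses missing")
    X, names, dropped = drop_aliased_columns(X, list(names))
    p = X.shape[1]
    if p == 0:
        raise ValueError("rank-0 design matrix")
    if n <= p:
        raise ValueError("not enough observations for the fixed effects")
    codes = pd.factorize(subjects)[0]
    group_slices = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    g = len(group_slices)

    if lambda_override is not None:
        lam = float(lambda_override)
        converged = True
    else:
        obj = lambda theta: _reml_neg2ll(np.exp(theta), y, X, group_slices, n, p)
        res = optimize.minimize_scalar(obj, bounds=(-30.0, 30.0),
                                       method="bounded",
                                       options={"xatol": 1e-12})
        lam = float(np.exp(res.x))
        # compare against the boundary lambda = 0 (no subject variance)
        if _reml_neg2ll(0.0, y, X, group_slices, n, p) <= res.fun:
            lam = 0.0
        converged = bool(res.success)

    xtx, xty, yty, _ = _gls_pieces(y, X, group_slices, lam)
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    rss = max(yty - float(xty @ beta), 0.0)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    df = max(n - p - (g - 1), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return LMMFit(
        coefficients=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        p_values=dict(zip(names, map(float, pvals))),
        sigma2_resid=float(sigma2),
        sigma2_subject=float(lam * sigma2),
        df_resid=float(df),
        dropped_columns=dropped,
        converged=converged,
    )


def fit_cpg_lmm(beta_row: pd.Series, sheet: SampleSheet,
                spec: ModelSpec | None = None, *,
                lambda_override: float | None = None) -> LMMFit:
    """Fit the mixed model for one CpG's beta values across samples."""
    spec = spec or ModelSpec()
    sample_ids = [s for s in beta_row.index if s in sheet.table.index]
    X, names, subjects = build_design_matrix(sheet, sample_ids, spec)
    y = beta_row[sample_ids].to_numpy(dtype=float)
    return fit_lmm(y, X, subjects, names, lambda_override=lambda_override)


# ---------------------------------------------------------------------------
# FDR and classification

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-value outside [0,1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify_cpgs(results: pd.DataFrame,
                  delta_threshold: float = DELTA_BETA_THRESHOLD,
                  q_threshold: float = Q_THRESHOLD,
                  mode: str = "fdr_and_delta") -> tuple[pd.Series, dict[str, int]]:
    """Direction per CpG plus (hyper, hypo, unchanged) counts.

    ``fdr_and_delta``: hyper iff q < q_threshold and delta_beta > threshold,
    hypo iff q < q_threshold and delta_beta < -threshold. ``delta_only``
    ignores q (the small-cohort mode where multiplicity-corrected
    significance is not attainable). All inequalities strict.
    """
    if mode not in CLASSIFICATION_MODES:
        raise ValueError(f"unknown classification mode {mode!r}")
    delta = results["delta_beta"]
    hyper = delta > delta_threshold
    hypo = delta < -delta_threshold
    if mode == "fdr_and_delta":
        sig = results["q_value"] < q_threshold
        hyper &= sig
        hypo &= sig
    direction = pd.Series("unchanged", index=results.index, name="direction")
    direction[hyper.fillna(False)] = "hyper"
    direction[hypo.fillna(False)] = "hypo"
    counts = {
        "n_hyper": int((direction == "hyper").sum()),
        "n_hypo": int((direction == "hypo").sum()),
        "n_unchanged": int((direction == "unchanged").sum()),
    }
    return direction, counts


# ---------------------------------------------------------------------------
# per-CpG driver

def run_differential(
    beta: BetaMatrix,
    sheet: SampleSheet,
    design: PairedDesign,
    *,
    spec: ModelSpec | None = None,
    mode: str = "fdr_and_delta",
    delta_threshold: float = DELTA_BETA_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    context_assignment: pd.DataFrame | None = None,
    fit_models: bool = True,
) -> pd.DataFrame:
    """Per-CpG paired differential methylation table.

    Columns: delta_beta, n_pairs, coefficient, se, p_value, q_value,
    direction, sign_inconsistent (model coefficient and delta disagreeing in
    sign) and, when an assignment is supplied, context.
    """
    if mode not in CLASSIFICATION_MODES:
        raise ValueError(f"unknown classification mode {mode!r}")
    spec = spec or ModelSpec()
    design.validate_against(sheet)
    pair_samples = [s for p in design for s in (p.primary_sample_id, p.followup_sample_id)]
    sub = beta.subset_samples(pair_samples)

    delta = compute_delta_beta(sub, design)
    npairs = n_complete_pairs(sub, design)
    out = pd.DataFrame({"delta_beta": delta, "n_pairs": npairs})

    coefs = np.full(len(out), np.nan)
    ses = np.full(len(out), np.nan)
    ps = np.full(len(out), np.nan)
    if fit_models:
        X, names, subjects = build_design_matrix(sheet, pair_samples, spec)
        values = sub.values.to_numpy(dtype=float)
        t_idx = names.index("timepoint")
        for i in range(values.shape[0]):
            y = values[i]
            if np.isfinite(y).sum() <= 2:
                continue
            try:
                fit = fit_lmm(y, X, subjects, names)
            except (ValueError, np.linalg.LinAlgError):
                continue
            coefs[i] = fit.coefficients.get("timepoint", np.nan)
            ses[i] = fit.se.get("timepoint", np.nan)
            ps[i] = fit.p_values.get("timepoint", np.nan)
    out["coefficient"] = coefs
    out["se"] = ses
    out["p_value"] = ps
    out["q_value"] = bh_fdr(out["p_value"])

    direction, _ = classify_cpgs(out, delta_threshold=delta_threshold,
                                 q_threshold=q_threshold, mode=mode)
    out["direction"] = direction
    with np.errstate(invalid="ignore"):
        out["sign_inconsistent"] = (
            np.sign(out["coefficient"]) * np.sign(out["delta_beta"]) < 0)
    if context_assignment is not None:
        out["context"] = context_assignment["context"].reindex(out.index)
    return out


# ---------------------------------------------------------------------------
# gene-locus summary

def gene_locus_summary(beta: BetaMatrix, design: PairedDesign,
                       manifest: ProbeManifest,
                       gene_symbol: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject mean paired delta-beta over one gene's CpGs.

    Returns (per-subject summary with an increased-methylation flag at > 0,
    per-CpG delta-beta table). The flag criterion (any positive mean shift)
    is a documented convention, not a calibrated cutoff.
    """
    gene_probes = [pid for pid in beta.probe_ids
                   if pid in manifest.table.index
                   and gene_symbol in manifest.table.at[pid, "genes"]]
    if not gene_probes:
        all_genes = sorted(set().union(*manifest.table["genes"]))
        near = [g for g in all_genes if g and (g.startswith(gene_symbol[:3])
                                               or gene_symbol.startswith(g[:3]))]
        raise ValueError(
            f"gene {gene_symbol!r} has no surviving CpGs; nearest symbols: {near[:10]}")
    sub = beta.subset_probes(gene_probes)
    v = sub.values
    rows = []
    for pair in design:
        diff = v[pair.followup_sample_id] - v[pair.primary_sample_id]
        mean_delta = float(diff.mean(skipna=True))
        rows.append((pair.subject_id, mean_delta, int(diff.notna().sum()),
                     mean_delta > 0))
    per_subject = pd.DataFrame(
        rows, columns=["subject_id", "mean_delta_beta", "n_cpgs",
                       "increased_methylation"]).set_index("subject_id")
    per_cpg = pd.DataFrame({"delta_beta": compute_delta_beta(sub, design)})
    per_cpg["gene"] = gene_symbol
    return per_subject, per_cpg
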