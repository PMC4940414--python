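"""Normalization, imputation, and mixed-model reduction to line BLUPs.

Raw metabolite intensities are normalized per chromatogram by the
internal-standard (ribitol-style control) channel; raw enzyme activities are
standardized by assay-plate mean and then centred per enzyme. Missing cells
are completed by an EM-style low-rank PCA reconstruction. Each feature is
then reduced with the one-way random-effects model

    y_ij = mu + g_i + e_ij,   g_i ~ N(0, sigma2_g),  e_ij ~ N(0, sigma2_e)

fitted by REML, yielding broad-sense heritability
H2 = sigma2_g / (sigma2_g + sigma2_e) and per-line BLUPs

    BLUP_i = shrink_i * (ybar_i - mu_hat),
    shrink_i = sigma2_g / (sigma2_g + sigma2_e / n_i).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import (
    ENZYME,
    IMPUTED,
    METABOLITE,
    OBSERVED,
    BlupMatrix,
    NormalizedMatrix,
    ReplicateProfileTable,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization


def normalize_metabolites(table: ReplicateProfileTable) -> NormalizedMatrix:
    """Divide each metabolite value by its chromatogram's control intensity.

    Enzyme columns pass through untouched (still raw). Raises ValueError,
    naming the offending samples, if any metabolite record has a missing or
    non-positive control value.
    """
    mets = table.features_of_class(METABOLITE)
    met_rows = table.data[table.data["feature_id"].isin(mets)]
    bad = met_rows[
        met_rows["control_value"].isna() | (met_rows["control_value"] <= 0)
    ]
    if len(bad):
        samples = bad[["line_id", "replicate_id", "feature_id"]].drop_duplicates()
        listing = "; ".join(
            f"(line={r.line_id}, rep={r.replicate_id}, feature={r.feature_id})"
            for r in samples.head(10).itertuples()
        )
        raise ValueError(
            f"{len(samples)} metabolite records with missing/non-positive "
            f"control value: {listing}"
        )
    wide = table.to_wide()
    if mets:
        ctl = table.control_series().reindex(wide.index)
        wide[mets] = wide[mets].div(ctl, axis=0)
    return NormalizedMatrix(wide, annotations=table.annotations)


def standardize_enzymes(
    table: ReplicateProfileTable, plate_method: str = "divide"
) -> NormalizedMatrix:
    """Plate-standardize enzymes, then centre each enzyme at zero.

    Step 1 standardizes every enzyme value by the mean of all enzyme records
    on its plate (``plate_method``: ``"divide"`` default, ``"subtract"``
    as an alternative reading). Step 2 subtracts, per enzyme, the overall
    mean of the standardized values, so each enzyme column has mean zero.
    Metabolite columns pass through untouched.
    """
    if plate_method not in ("divide", "subtract"):
        raise ValueError("plate_method must be 'divide' or 'subtract'")
    enzs = table.features_of_class(ENZYME)
    wide = table.to_wide()
    if not enzs:
        return NormalizedMatrix(wide, annotations=table.annotations)

    enz_rows = table.data[table.data["feature_id"].isin(enzs)]
    if enz_rows["plate_id"].isna().any():
        raise ValueError("enzyme records without a plate id")
    plate_means = enz_rows.groupby("plate_id")["value"].mean()
    if plate_means.isna().any():
        empty = plate_means.index[plate_means.isna()].tolist()
        raise ValueError(f"plates with no observed enzyme values: {empty}")
    if plate_method == "divide" and (plate_means == 0).any():
        zero = plate_means.index[plate_means == 0].tolist()
        raise ValueError(f"plate mean is zero, cannot divide: {zero}")

    # plate of each (line, replicate) sample
    plate_of = enz_rows.groupby(["line_id", "replicate_id"])["plate_id"].first()
    plate_of = plate_of.reindex(wide.index)
    pm = plate_means.reindex(plate_of).to_numpy()
    enz_block = wide[enzs]
    if plate_method == "divide":
        std = enz_block.div(pm, axis=0)
    else:
        std = enz_block.sub(pm, axis=0)
    std = std - std.mean(axis=0)
    wide = wide.copy()
    wide[enzs] = std
    return NormalizedMatrix(wide, annotations=table.annotations)


def normalize_panel(
    table: ReplicateProfileTable, plate_method: str = "divide"
) -> NormalizedMatrix:
    """Apply metabolite normalization and enzyme standardization jointly."""
    table.validate()
    met = normalize_metabolites(table)
    enz = standardize_enzymes(table, plate_method=plate_method)
    values = met.values.copy()
    enzs = table.features_of_class(ENZYME)
    values[enzs] = enz.values[enzs]
    return NormalizedMatrix(values, annotations=table.annotations)


# ---------------------------------------------------------------------------
# imputation


def impute_missing(
    matrix: NormalizedMatrix,
    n_components: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> NormalizedMatrix:
    """Complete missing cells by iterative low-rank PCA reconstruction.

    EM-style alternation: missing cells start at column means; each sweep
    re-centres, takes the rank-``n_components`` truncated SVD, and replaces
    only the missing cells with the reconstruction, until the relative
    change of the imputed cells falls below ``tol``. Observed cells are
    returned bit-identical. The procedure is deterministic; ``seed`` is
    accepted for interface uniformity.

    Raises ValueError for a fully-missing column. Warns (and returns the
    best iterate) on non-convergence.
    """
    X = matrix.values.to_numpy(dtype=float, copy=True)
    miss = np.isnan(X)
    if not miss.any():
        logger.info("imputation skipped: no missing cells")
        return matrix.copy()
    fully = miss.all(axis=0)
    if fully.any():
        names = list(matrix.values.columns[fully])
        raise ValueError(f"features entirely missing, cannot impute: {names}")
    k = int(n_components)
    if not 1 <= k < min(X.shape):
        raise ValueError(
            f"n_components must be in [1, {min(X.shape) - 1}], got {n_components}"
        )

    col_means = np.nanmean(X, axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])
    prev = X[miss].copy()
    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        U, s, Vt = linalg.svd(X - mu, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        X[miss] = recon[miss]
        denom = np.linalg.norm(X[miss]) or 1.0
        delta = np.linalg.norm(X[miss] - prev) / denom
        prev = X[miss].copy()
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM-PCA imputation did not reach tol={tol} in {max_iter} "
            "iterations; returning best iterate",
            RuntimeWarning,
        )
    # observed cells were never written: X is a copy and only X[miss] was
    # assigned, so they are bitwise identical to the input
    values = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    prov = matrix.provenance.to_numpy(copy=True)
    prov[miss] = IMPUTED
    provenance = pd.DataFrame(
        prov, index=matrix.values.index, columns=matrix.values.columns
    )
    return NormalizedMatrix(values, provenance, matrix.annotations)


# ---------------------------------------------------------------------------
# variance components / heritability


@dataclass
class VarianceComponents:
    """Per-feature REML variance components and broad-sense heritability."""

    table: pd.DataFrame  # index feature_id; sigma2_g, sigma2_e, h2, degenerate

    @property
    def h2(self) -> pd.Series:
        return self.table["h2"]

    def degenerate_features(self) -> list[str]:
        return list(self.table.index[self.table["degenerate"]])


def _balanced_oneway_reml(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Closed-form REML (= ANOVA) estimator for the balanced one-way model."""
    labels, inv = np.unique(groups, return_inverse=True)
    a = len(labels)
    n = len(y) // a
    means = np.bincount(inv, weights=y) / np.bincount(inv)
    grand = y.mean()
    msb = n * np.sum((means - grand) ** 2) / (a - 1)
    sse = np.sum((y - means[inv]) ** 2)
    mse = sse / (a * (n - 1)) if n > 1 else 0.0
    s2g = max((msb - mse) / n, 0.0)
    return s2g, mse


def _reml_oneway(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML fit of the one-way random-effects model via statsmodels MixedLM."""
    import statsmodels.api as sm

    exog = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        res = model.fit(reml=True)
    s2g = float(np.asarray(res.cov_re)[0, 0])
    s2e = float(res.scale)
    return max(s2g, 0.0), max(s2e, 0.0)


def fit_variance_components(
    matrix: NormalizedMatrix, design: pd.Series | None = None
) -> VarianceComponents:
    """REML variance components per feature from the replicated matrix.

    ``design`` optionally overrides the line labels (defaults to the
    ``line_id`` index level). Constant features are flagged degenerate with
    H2 reported as missing, not 0. Negative component estimates are clipped
    at zero, keeping H2 in [0, 1].
    """
    lines = (
        design.to_numpy() if design is not None else matrix.line_index().to_numpy()
    )
    if len(np.unique(lines)) < 2:
        raise ValueError("need at least 2 lines to separate variance components")
    counts = pd.Series(lines).value_counts()
    balanced = counts.nunique() == 1

    rows = []
    for f in matrix.values.columns:
        y = matrix.values[f].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        yv, gv = y[ok], lines[ok]
        scale = np.var(yv)
        if scale < 1e-30 or len(yv) < 3:
            rows.append((f, np.nan, np.nan, np.nan, True))
            continue
        # zero-residual limit: replicates identical within every line
        within = pd.Series(yv).groupby(gv).var(ddof=1).fillna(0.0)
        if within.max() <= 1e-12 * scale:
            s2g = float(pd.Series(yv).groupby(gv).mean().var(ddof=1))
            rows.append((f, s2g, 0.0, 1.0, False))
            continue
        if balanced and not np.isnan(y).any():
            s2g, s2e = _balanced_oneway_reml(yv, gv)
        else:
            s2g, s2e = _reml_oneway(yv, gv)
        total = s2g + s2e
        h2 = float(np.clip(s2g / total, 0.0, 1.0)) if total > 0 else np.nan
        rows.append((f, s2g, s2e, h2, False))
    table = pd.DataFrame(
        rows, columns=["feature_id", "sigma2_g", "sigma2_e", "h2", "degenerate"]
    ).set_index("feature_id")
    n_deg = int(table["degenerate"].sum())
    if n_deg:
        logger.warning("%d degenerate (constant) features", n_deg)
    return VarianceComponents(table)


# ---------------------------------------------------------------------------
# BLUPs


def compute_blups(
    matrix: NormalizedMatrix, components: VarianceComponents
) -> BlupMatrix:
    """Per-line BLUPs of the random line effect for every feature.

    The line-mean deviation from the grand mean (unweighted mean of line
    means) is shrunk by sigma2_g / (sigma2_g + sigma2_e / n_i), with n_i the
    line's replicate count. sigma2_g = 0 gives all-zero BLUPs (valid).
    """
    lines = matrix.line_index()
    values = {}
    grand_means = {}
    for f in matrix.values.columns:
        y = matrix.values[f]
        line_means = y.groupby(lines).mean()
        n_i = y.groupby(lines).count()
        mu = float(line_means.mean())
        grand_means[f] = mu
        if f not in components.table.index or components.table.loc[f, "degenerate"]:
            values[f] = pd.Series(0.0, index=line_means.index)
            continue
        s2g = components.table.loc[f, "sigma2_g"]
        s2e = components.table.loc[f, "sigma2_e"]
        if s2g <= 0:
            values[f] = pd.Series(0.0, index=line_means.index)
            continue
        shrink = s2g / (s2g + s2e / n_i)
        values[f] = shrink * (line_means - mu)
    blups = pd.DataFrame(values)
    blups.index.name = "line_id"
    return BlupMatrix(blups, pd.Series(grand_means), matrix.annotations)


# ---------------------------------------------------------------------------
# descriptive statistics


@dataclass
class DescriptiveStats:
    """Per-feature variance / CV on the BLUP scale plus H2 binning."""

    table: pd.DataFrame  # index feature_id; variance, mean, cv, h2, h2_bin
    h2_bin_counts: pd.Series  # 10 bins of width 0.1
    h2_bin_frequencies: pd.Series

    def by_variance(self) -> pd.DataFrame:
        return self.table.sort_values("variance")

    def by_cv(self) -> pd.DataFrame:
        return self.table.sort_values("cv")


H2_BIN_LABELS = [
    "[0.0,0.1)", "[0.1,0.2)", "[0.2,0.3)", "[0.3,0.4)", "[0.4,0.5)",
    "[0.5,0.6)", "[0.6,0.7)", "[0.7,0.8)", "[0.8,0.9)", "[0.9,1.0]",
]


def bin_h2(h2_values: pd.Series) -> pd.Series:
    """Assign H2 values to 10 bins of width 0.1 ([0.9, 1.0] closed above)."""
    idx = np.floor(h2_values * 10).clip(upper=9)
    return idx.where(h2_values.notna()).astype("Int64")


def descriptive_stats(
    blups: BlupMatrix, components: VarianceComponents | None = None
) -> DescriptiveStats:
    """Variance and CV per feature, plus the H2 bin histogram.

    CV = sd / mean is computed on BLUP + grand mean (the measurement scale):
    BLUP deviations are centred at zero, which would make sd/mean
    ill-defined. A zero mean on that basis yields a missing CV with a
    warning.
    """
    if len(blups.values) < 3:
        raise ValueError("need at least 3 lines for descriptive statistics")
    scale = blups.on_measurement_scale()
    var = blups.values.var(axis=0, ddof=1)
    sd = np.sqrt(var)
    mean = scale.mean(axis=0)
    cv = sd / mean.where(mean != 0)
    n_zero = int((mean == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} features have zero mean on the CV basis; CV reported "
            "as missing",
            RuntimeWarning,
        )
    table = pd.DataFrame({"variance": var, "mean": mean, "cv": cv})
    if components is not None:
        table["h2"] = components.h2.reindex(table.index)
    else:
        table["h2"] = np.nan
    table["h2_bin"] = bin_h2(table["h2"])
    counts = (
        table["h2_bin"].value_counts().reindex(range(10), fill_value=0).sort_index()
    )
    counts.index = H2_BIN_LABELS
    n = counts.sum()
    freqs = counts / n if n else counts.astype(float)
    table.index.name = "feature_id"
    return DescriptiveStats(table, counts, freqs)
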