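"""Corrected-FRET feature extraction and correlation-aware hit statistics.

The imaging assay records three channels per cell: donor excitation/donor
emission (I_DD), acceptor excitation/acceptor emission (I_AA), and donor
excitation/acceptor emission (I_DA, the raw FRET channel).  I_DA mixes true
sensitized emission with donor bleedthrough and acceptor cross-excitation,
so the corrected signal is

    cFRET = I_DA - beta * I_DD - alpha * I_AA

with beta and alpha estimated from donor-only and acceptor-only control
cells.  Normalized cFRET divides by total labeled-tRNA signal (I_DD + I_AA)
as a per-cell FRET-efficiency proxy.

Wells are summarized into a fixed 10-feature profile; compound wells are
scored against the vehicle (DMSO) reference population H0 by a robust
Mahalanobis distance in SD units (the screen score), and an aggregated
p-value accounts for inter-feature correlation via a chi-square tail or the
empirical H0 score distribution.  Hits require score > 4 and p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURE_NAMES",
    "BleedthroughCoefficients",
    "WellFeatureVector",
    "ReferencePopulation",
    "ScreenHit",
    "estimate_bleedthrough",
    "corrected_fret",
    "normalized_cfret",
    "aggregate_well",
    "aggregate_plate",
    "median_profiles",
    "fit_reference",
    "screen_score",
    "aggregated_pvalue",
    "call_hits",
    "run_screen",
]

#: Canonical well-profile feature set, in fixed order.
FEATURE_NAMES = (
    "median_norm_cfret",
    "mean_norm_cfret",
    "median_cfret",
    "median_I_DD",
    "median_I_AA",
    "median_total_trna",
    "frac_fret_positive",
    "cell_count",
    "norm_cfret_idr",
    "transfection_pass_frac",
)

MAD_SCALE = 1.4826  # normal-consistency factor for the MAD


@dataclass(frozen=True)
class BleedthroughCoefficients:
    beta_donor: float
    alpha_acceptor: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta_donor) and np.isfinite(self.alpha_acceptor)):
            raise ValueError("bleedthrough coefficients must be finite")
        if self.beta_donor < 0 or self.alpha_acceptor < 0:
            raise ValueError("bleedthrough coefficients must be >= 0")


def estimate_bleedthrough(
    donor_only: pd.DataFrame, acceptor_only: pd.DataFrame
) -> BleedthroughCoefficients:
    """Estimate bleedthrough from single-label control cells.

    beta = median(I_DA / I_DD) over donor-only cells; alpha likewise over
    acceptor-only cells.  The median is robust to segmentation outliers.
    """
    if len(donor_only) == 0 or len(acceptor_only) == 0:
        raise ValueError("both control populations must be non-empty")
    d = donor_only.loc[donor_only["I_DD"] > 0]
    a = acceptor_only.loc[acceptor_only["I_AA"] > 0]
    if len(d) == 0 or len(a) == 0:
        raise ValueError("degenerate controls: all denominator intensities are zero")
    beta = float(np.median(d["I_DA"] / d["I_DD"]))
    alpha = float(np.median(a["I_DA"] / a["I_AA"]))
    return BleedthroughCoefficients(beta_donor=beta, alpha_acceptor=alpha)


def corrected_fret(cells: pd.DataFrame, coeffs: BleedthroughCoefficients) -> np.ndarray:
    """cFRET = I_DA - beta*I_DD - alpha*I_AA.  Negative values are kept."""
    return (
        cells["I_DA"].to_numpy(float)
        - coeffs.beta_donor * cells["I_DD"].to_numpy(float)
        - coeffs.alpha_acceptor * cells["I_AA"].to_numpy(float)
    )


def normalized_cfret(fc, i_dd, i_aa):
    """cFRET normalized to total labeled-tRNA signal.

    Zero denominator yields NaN (the undefined marker); such cells are
    excluded from intensity summaries downstream.
    """
    fc = np.asarray(fc, float)
    total = np.asarray(i_dd, float) + np.asarray(i_aa, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, fc / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class WellFeatureVector:
    well_id: str
    features: np.ndarray  # length len(FEATURE_NAMES), canonical order
    valid: bool
    n_cells: int


def aggregate_well(
    cells: pd.DataFrame,
    coeffs: BleedthroughCoefficients,
    transfection_threshold: float = 0.0,
    min_cells: int = 20,
    fret_positive_threshold: float = 0.0,
) -> WellFeatureVector:
    """Summarize one well's cells into the canonical 10-feature profile.

    Cells with I_DD + I_AA < transfection_threshold are excluded from the
    intensity features but still counted in the transfection-pass fraction.
    Wells with fewer than min_cells passing cells are flagged invalid.
    """
    well_ids = cells["well_id"].unique() if len(cells) else []
    if len(well_ids) > 1:
        raise ValueError(f"cells span multiple wells: {list(well_ids)}")
    well_id = str(well_ids[0]) if len(well_ids) else ""
    n_total = len(cells)
    if n_total == 0:
        return WellFeatureVector(well_id, np.full(len(FEATURE_NAMES), np.nan), False, 0)

    fc = corrected_fret(cells, coeffs)
    total = cells["I_DD"].to_numpy(float) + cells["I_AA"].to_numpy(float)
    passing = total >= transfection_threshold
    n_pass = int(passing.sum())
    if n_pass < min_cells:
        return WellFeatureVector(
            well_id, np.full(len(FEATURE_NAMES), np.nan), False, n_pass
        )

    fc_p = fc[passing]
    total_p = total[passing]
    norm = normalized_cfret(fc_p, cells["I_DD"].to_numpy(float)[passing],
                            cells["I_AA"].to_numpy(float)[passing])
    norm_ok = norm[np.isfinite(norm)]
    q10, q90 = (np.quantile(norm_ok, [0.1, 0.9]) if norm_ok.size else (np.nan, np.nan))
    features = np.array(
        [
            np.median(norm_ok) if norm_ok.size else np.nan,
            np.mean(norm_ok) if norm_ok.size else np.nan,
            np.median(fc_p),
            np.median(cells["I_DD"].to_numpy(float)[passing]),
            np.median(cells["I_AA"].to_numpy(float)[passing]),
            np.median(total_p),
            float(np.mean(norm_ok > fret_positive_threshold)) if norm_ok.size else np.nan,
            float(n_pass),
            q90 - q10,
            n_pass / n_total,
        ]
    )
    return WellFeatureVector(well_id, features, True, n_pass)


def aggregate_plate(
    cells: pd.DataFrame,
    coeffs: BleedthroughCoefficients,
    transfection_threshold: float = 0.0,
    min_cells: int = 20,
    fret_positive_threshold: float = 0.0,
) -> pd.DataFrame:
    """Well-profile table (rows = wells, columns = FEATURE_NAMES + valid)."""
    rows = []
    for well_id, grp in cells.groupby("well_id", sort=True):
        wfv = aggregate_well(
            grp, coeffs, transfection_threshold, min_cells, fret_positive_threshold
        )
        rows.append(
            {"well_id": well_id, "valid": wfv.valid, "n_cells": wfv.n_cells}
            | dict(zip(FEATURE_NAMES, wfv.features))
        )
    return pd.DataFrame(rows).set_index("well_id")


def auto_thresholds(
    cells: pd.DataFrame, coeffs: BleedthroughCoefficients
) -> tuple[float, float]:
    """Plate-derived transfection and FRET-positivity thresholds.

    Transfection pass requires total labeled-tRNA signal above the plate's
    10th percentile; a cell is FRET-positive above the plate-median
    normalized cFRET.  Both fractions then vary between wells instead of
    saturating at 1.
    """
    total = cells["I_DD"].to_numpy(float) + cells["I_AA"].to_numpy(float)
    fc = corrected_fret(cells, coeffs)
    norm = normalized_cfret(fc, cells["I_DD"], cells["I_AA"])
    return float(np.quantile(total, 0.1)), float(np.nanmedian(norm))


def median_profiles(cells: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Per-well median profile for generic (already-derived) cell features."""
    return cells.groupby("well_id", sort=True)[feature_cols].median()


@dataclass
class ReferencePopulation:
    """Robust location/scale/correlation model of the DMSO null wells."""

    location: np.ndarray      # per-feature median over H0 wells
    scale: np.ndarray         # 1.4826 * MAD
    correlation: np.ndarray   # ridge-shrunk correlation of robust z-scores
    n_h0: int
    feature_names: tuple[str, ...]
    dropped: tuple[str, ...] = field(default_factory=tuple)
    _inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.location.size

    def inverse_correlation(self) -> np.ndarray:
        if self._inv is None:
            self._inv = np.linalg.inv(self.correlation)
        return self._inv

    def zscores(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.location) / self.scale


def fit_reference(
    h0: pd.DataFrame | np.ndarray,
    ridge: float = 0.05,
    feature_names: tuple[str, ...] | None = None,
) -> ReferencePopulation:
    """Fit the H0 reference model from vehicle-well profiles.

    Location is the per-feature median, scale the normal-consistent MAD;
    the correlation matrix is computed on robust z-scores and shrunk as
    R <- (1 - ridge) * R + ridge * I so it is always invertible.
    Zero-scale (constant) features are dropped and recorded.
    """
    if isinstance(h0, pd.DataFrame):
        feature_names = tuple(h0.columns) if feature_names is None else feature_names
        x = h0.to_numpy(float)
    else:
        x = np.asarray(h0, float)
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(x.shape[1]))
    x = x[np.all(np.isfinite(x), axis=1)]
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 valid H0 wells, got {n}")
    if n < 2 * x.shape[1]:
        warnings.warn(
            f"only {n} H0 wells for {x.shape[1]} features; reference may be unstable"
        )
    m = np.median(x, axis=0)
    s = MAD_SCALE * np.median(np.abs(x - m), axis=0)
    keep = s > 0
    dropped = tuple(np.asarray(feature_names)[~keep])
    if dropped:
        warnings.warn(f"dropping zero-scale features: {dropped}")
    x, m, s = x[:, keep], m[keep], s[keep]
    kept_names = tuple(np.asarray(feature_names)[keep])
    z = (x - m) / s
    r = np.corrcoef(z, rowvar=False)
    r = np.atleast_2d(r)
    r = (1.0 - ridge) * r + ridge * np.eye(r.shape[0])
    return ReferencePopulation(
        location=m, scale=s, correlation=r, n_h0=n,
        feature_names=kept_names, dropped=dropped,
    )


def screen_score(x: np.ndarray, ref: ReferencePopulation) -> float:
    """Mahalanobis deviation of a well profile from H0, in SD units."""
    x = np.asarray(x, float)
    if x.shape[-1] != ref.k:
        raise ValueError(f"profile has {x.shape[-1]} features, reference has {ref.k}")
    z = ref.zscores(x)
    s2 = float(z @ ref.inverse_correlation() @ z)
    return float(np.sqrt(max(s2, 0.0)))


def screen_scores(profiles: pd.DataFrame | np.ndarray, ref: ReferencePopulation) -> np.ndarray:
    """Vectorized screen_score over rows."""
    x = profiles.to_numpy(float) if isinstance(profiles, pd.DataFrame) else np.asarray(profiles, float)
    z = (x - ref.location) / ref.scale
    s2 = np.einsum("ij,jk,ik->i", z, ref.inverse_correlation(), z)
    return np.sqrt(np.maximum(s2, 0.0))


def aggregated_pvalue(
    s: float,
    ref: ReferencePopulation,
    method: str = "parametric",
    h0_scores: np.ndarray | None = None,
) -> float:
    """Single significance value for a multi-feature deviation.

    parametric: upper chi-square tail with k degrees of freedom at S^2
    (exact if profiles were multivariate normal with correlation R).
    empirical: plug-in tail of the observed H0 score distribution,
    p = (1 + #{H0 >= S}) / (n + 1); requires >= 99 H0 scores.
    """
    if s < 0:
        raise ValueError("screen score must be >= 0")
    if method == "parametric":
        return float(stats.chi2.sf(s * s, df=ref.k))
    if method == "empirical":
        if h0_scores is None or len(h0_scores) < 99:
            raise ValueError("empirical method requires >= 99 H0 scores")
        h0_scores = np.asarray(h0_scores, float)
        return float((1 + np.sum(h0_scores >= s)) / (len(h0_scores) + 1))
    raise ValueError(f"unknown method: {method}")


@dataclass
class ScreenHit:
    well_id: str
    score: float
    p_value: float
    is_hit: bool


def call_hits(
    results: pd.DataFrame,
    score_threshold: float = 4.0,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Flag hits (score > threshold AND p < threshold), sorted by score desc.

    `results` needs columns well_id, score, p_value.
    """
    if score_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    out = results.copy()
    out["is_hit"] = (out["score"] > score_threshold) & (out["p_value"] < p_threshold)
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def run_screen(
    profiles: pd.DataFrame,
    roles: pd.Series,
    method: str = "empirical",
    score_threshold: float = 4.0,
    p_threshold: float = 0.01,
    ridge: float = 0.05,
) -> tuple[pd.DataFrame, ReferencePopulation]:
    """Score every well against the plate's DMSO reference and call hits.

    roles is indexed like profiles with values 'dmso' or 'compound'; the
    reference and (for the empirical method) the null score distribution
    come from the DMSO wells.
    """
    roles = roles.reindex(profiles.index)
    h0 = profiles.loc[roles == "dmso"]
    ref = fit_reference(h0, ridge=ridge)
    cols = list(ref.feature_names)
    scores = screen_scores(profiles[cols], ref)
    h0_scores = scores[(roles == "dmso").to_numpy()] if method == "empirical" else None
    pvals = np.array(
        [aggregated_pvalue(s, ref, method=method, h0_scores=h0_scores) for s in scores]
    )
    res = pd.DataFrame(
        {"well_id": profiles.index, "role": roles.to_numpy(), "score": scores, "p_value": pvals}
    )
    return call_hits(res, score_threshold, p_threshold), ref
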