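"""Downstream hit characterization: CETSA, translational efficiency, dose-response.

Three independent follow-up analyses for compounds coming out of the
imaging screen:

* CETSA isothermal dose-response (compressed format): per-protein soluble
  fraction vs compound concentration, relative to vehicle = 1.  A
  log-logistic shift ``y = 1 + A / (1 + (ec50/c)^h)`` is fit per protein;
  targets satisfy |amplitude| > 0.2 and BH-adjusted p < 0.05.
* Simplified translational-efficiency analysis on paired mRNA / ribosome-
  footprint count matrices: median-of-ratios normalization, per-assay
  log2 fold-changes with a Wald test under a method-of-moments
  negative-binomial dispersion, and delta-TE = lfc_RPF - lfc_mRNA.
  Genes are classified mrna_only / rpf_only / both / none at a 2-fold,
  p < 0.05 cut-off.
* Viability dose-response panel: four-parameter logistic fits (reported
  hill slope negative for inhibition), responsiveness rules, Welch's
  t-test and Tukey-Kramer comparison circles for group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ItdrCurve",
    "ItdrFit",
    "fit_itdr",
    "cetsa_hits",
    "normalize_counts",
    "delta_te",
    "classify_genes",
    "DoseResponseFit",
    "fit_4pl",
    "classify_responsiveness",
    "RESPONSIVENESS_RULES",
    "welch_t",
    "ComparisonCircle",
    "comparison_circles",
]

CETSA_CONCENTRATIONS_UM = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)


# ---------------------------------------------------------------------------
# CETSA isothermal dose-response
# ---------------------------------------------------------------------------

@dataclass
class ItdrCurve:
    """Soluble fraction vs concentration for one protein (vehicle = 1.0)."""

    protein_id: str
    concentrations_um: np.ndarray          # length m
    soluble_fraction: np.ndarray           # replicates x m

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, float)
        self.soluble_fraction = np.atleast_2d(np.asarray(self.soluble_fraction, float))
        if np.unique(self.concentrations_um).size < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if np.any(self.soluble_fraction < 0):
            raise ValueError("soluble fractions must be >= 0")
        if self.soluble_fraction.shape[1] != self.concentrations_um.size:
            raise ValueError("soluble_fraction columns must match concentrations")


@dataclass
class ItdrFit:
    protein_id: str
    amplitude: float
    ec50_um: float
    hill: float
    p: float
    p_adj: float = np.nan
    is_target: bool = False
    converged: bool = True


def _itdr_model(c, amp, ec50, h):
    return 1.0 + amp / (1.0 + (ec50 / c) ** h)


def fit_itdr(curve: ItdrCurve) -> ItdrFit:
    """Fit the stabilization/destabilization shift for one protein.

    Least squares on ``y = 1 + A / (1 + (ec50/c)^h)`` from multiple
    starting points.  Significance against the flat model (a single fitted
    mean) uses an F-statistic with one numerator degree of freedom: under
    the flat null the EC50 and slope are unidentified, so the amplitude is
    the only effective extra parameter; using the nominal two extra
    degrees of freedom makes the test markedly conservative on flat
    curves.  Non-convergent fits fall back to the top-concentration mean
    shift with a one-sample t-test.
    """
    c = np.tile(curve.concentrations_um, curve.soluble_fraction.shape[0])
    y = curve.soluble_fraction.ravel()
    n = y.size
    mu = y.mean()
    rss0 = float(((y - mu) ** 2).sum())

    lo = [-2.0, c.min() / 10.0, 0.3]
    hi = [2.0, c.max() * 10.0, 5.0]
    best = None
    for ec0 in (1.0, 10.0):
        for a0 in (-0.2, 0.2):
            try:
                popt, _ = curve_fit(
                    _itdr_model, c, y, p0=[a0, ec0, 1.0], bounds=(lo, hi), maxfev=5000
                )
            except RuntimeError:
                continue
            rss = float(((y - _itdr_model(c, *popt)) ** 2).sum())
            if best is None or rss < best[1]:
                best = (popt, rss)

    if best is None:
        # fallback: plateau shift at the top concentration
        top = curve.soluble_fraction[:, np.argmax(curve.concentrations_um)]
        amp = float(top.mean() - 1.0)
        if top.size >= 2 and top.std(ddof=1) > 0:
            t = amp / (top.std(ddof=1) / np.sqrt(top.size))
            p = float(2 * stats.t.sf(abs(t), top.size - 1))
        else:
            p = 1.0
        return ItdrFit(curve.protein_id, amp, np.nan, np.nan, p, converged=False)

    (amp, ec50, h), rss1 = best
    df_den = n - 3
    if rss1 <= 0:
        p = 0.0 if rss0 > rss1 else 1.0
    else:
        f = (rss0 - rss1) / (rss1 / df_den)
        p = float(stats.f.sf(f, 1, df_den))
    return ItdrFit(curve.protein_id, float(amp), float(ec50), float(h), p)


def cetsa_hits(
    fits: list[ItdrFit],
    amp_threshold: float = 0.2,
    p_threshold: float = 0.05,
) -> tuple[list[ItdrFit], pd.DataFrame]:
    """BH-correct across proteins and flag targets (|A| > 0.2, p_adj < 0.05).

    Returns the target list and a volcano table (|amplitude| vs
    -log10 p_adj) for all proteins.
    """
    if not fits:
        return [], pd.DataFrame(
            columns=["protein_id", "amplitude", "abs_amplitude", "ec50_um", "hill",
                     "p", "p_adj", "neg_log10_p_adj", "is_target"]
        )
    p_adj = multipletests([f.p for f in fits], method="fdr_bh")[1]
    for f, pa in zip(fits, p_adj):
        f.p_adj = float(pa)
        f.is_target = abs(f.amplitude) > amp_threshold and f.p_adj < p_threshold
    volcano = pd.DataFrame(
        {
            "protein_id": [f.protein_id for f in fits],
            "amplitude": [f.amplitude for f in fits],
            "abs_amplitude": [abs(f.amplitude) for f in fits],
            "ec50_um": [f.ec50_um for f in fits],
            "hill": [f.hill for f in fits],
            "p": [f.p for f in fits],
            "p_adj": [f.p_adj for f in fits],
            "neg_log10_p_adj": [-np.log10(max(f.p_adj, 1e-300)) for f in fits],
            "is_target": [f.is_target for f in fits],
        }
    )
    return [f for f in fits if f.is_target], volcano


def curves_from_table(table: pd.DataFrame) -> list[ItdrCurve]:
    """Build ItdrCurve objects from a long-format CETSA table.

    Columns: protein, concentration_uM, replicate, soluble_fraction.
    """
    curves = []
    for protein, grp in table.groupby("protein", sort=True):
        wide = grp.pivot_table(
            index="replicate", columns="concentration_uM", values="soluble_fraction"
        ).sort_index(axis=1)
        curves.append(
            ItdrCurve(str(protein), wide.columns.to_numpy(float), wide.to_numpy(float))
        )
    return curves


# ---------------------------------------------------------------------------
# Translational efficiency (simplified delta-TE)
# ---------------------------------------------------------------------------

def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization (genes x samples).

    The reference is the per-gene geometric mean over genes positive in
    all samples; each sample's factor is the median ratio to it.  Falls
    back to total-count scaling when no gene is positive everywhere.
    """
    x = counts.to_numpy(float)
    positive = np.all(x > 0, axis=1)
    if positive.sum() == 0:
        import warnings

        totals = x.sum(axis=0)
        if totals.sum() == 0:
            raise ValueError("all-zero count matrix")
        warnings.warn("no gene positive in all samples; using total-count scaling")
        factors = totals / np.exp(np.mean(np.log(np.where(totals > 0, totals, 1))))
    else:
        logx = np.log(x[positive])
        ref = logx.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logx - ref, axis=0))
    factors = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts / factors, factors


def _wald_assay(
    treated: np.ndarray, control: np.ndarray, pseudo: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene log2FC and p for one assay (normalized counts in, t-tail).

    The dispersion alpha in var = mu + alpha*mu^2 is estimated per gene by
    method of moments pooled over both groups (floored); the Wald
    statistic for the log2 ratio of group means (pseudo-count on the
    means) is referred to a t distribution with n1 + n2 - 2 df, which is
    well calibrated at small replicate numbers.
    """
    n_t, n_c = treated.shape[1], control.shape[1]
    mt, mc = treated.mean(1), control.mean(1)
    vt = treated.var(1, ddof=1)
    vc = control.var(1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 0.5 * (
            (vt - mt) / np.maximum(mt, 1e-8) ** 2 + (vc - mc) / np.maximum(mc, 1e-8) ** 2
        )
    alpha = np.clip(np.nan_to_num(a), dispersion_floor, None)
    lfc = np.log2(mt + pseudo) - np.log2(mc + pseudo)
    se2 = (
        (mt + alpha * mt**2) / (n_t * (mt + pseudo) ** 2)
        + (mc + alpha * mc**2) / (n_c * (mc + pseudo) ** 2)
    ) / np.log(2) ** 2
    z = lfc / np.sqrt(np.maximum(se2, 1e-16))
    p = 2 * stats.t.sf(np.abs(z), n_t + n_c - 2)
    return lfc, p


def _perm_assay(
    treated: np.ndarray, control: np.ndarray, pseudo: float = 0.5,
    n_perm: int = 500, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-permutation p-values for the log2 fold-change."""
    rng = np.random.default_rng(seed)
    both = np.concatenate([treated, control], axis=1)
    n_t = treated.shape[1]
    n = both.shape[1]
    lfc = np.log2(treated.mean(1) + pseudo) - np.log2(control.mean(1) + pseudo)
    exceed = np.ones(both.shape[0])
    for _ in range(n_perm):
        idx = rng.permutation(n)
        pt, pc = both[:, idx[:n_t]], both[:, idx[n_t:]]
        plfc = np.log2(pt.mean(1) + pseudo) - np.log2(pc.mean(1) + pseudo)
        exceed += np.abs(plfc) >= np.abs(lfc)
    return lfc, exceed / (n_perm + 1)


def delta_te(
    mrna: pd.DataFrame,
    rpf: pd.DataFrame,
    condition: pd.Series | dict,
    test: str = "wald_mm",
    pseudo: float = 0.5,
    n_perm: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential mRNA / RPF / translational-efficiency statistics.

    mrna and rpf are raw count matrices (genes x samples) over the same
    gene set; `condition` maps sample id -> 'treated' | 'control' for both
    matrices.  TE is the ratio of RPF to mRNA counts, so on the log2
    scale delta_te = lfc_rpf - lfc_mrna exactly.
    """
    if not mrna.index.equals(rpf.index):
        raise ValueError("mRNA and RPF matrices must share an identical gene set")
    cond = pd.Series(condition)
    out: dict[str, np.ndarray] = {}
    for name, mat in (("mrna", mrna), ("rpf", rpf)):
        labels = cond.reindex(mat.columns)
        if labels.isna().any():
            raise ValueError(f"missing condition labels for {name} samples")
        norm, _ = normalize_counts(mat)
        tr = norm.loc[:, (labels == "treated").to_numpy()].to_numpy(float)
        ct = norm.loc[:, (labels == "control").to_numpy()].to_numpy(float)
        if tr.shape[1] < 2 or ct.shape[1] < 2:
            raise ValueError("need >= 2 replicates per condition")
        if test == "wald_mm":
            lfc, p = _wald_assay(tr, ct, pseudo)
        elif test == "permutation":
            lfc, p = _perm_assay(tr, ct, pseudo, n_perm, seed)
        else:
            raise ValueError(f"unknown test: {test}")
        out[f"lfc_{name}"], out[f"p_{name}"] = lfc, p
    res = pd.DataFrame(out, index=mrna.index)
    res["delta_te"] = res["lfc_rpf"] - res["lfc_mrna"]
    return res


def classify_genes(
    results: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Assign mrna_only / rpf_only / both / none per gene.

    A gene "passes" an assay when |log2FC| exceeds the threshold (2-fold
    by default) and the raw p-value is below alpha, mirroring volcano-plot
    cut-offs.
    """
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be > 0")
    m = (results["lfc_mrna"].abs() > lfc_threshold) & (results["p_mrna"] < alpha)
    r = (results["lfc_rpf"].abs() > lfc_threshold) & (results["p_rpf"] < alpha)
    cls = np.where(m & r, "both", np.where(m, "mrna_only", np.where(r, "rpf_only", "none")))
    out = results.copy()
    out["class"] = cls
    return out


# ---------------------------------------------------------------------------
# Viability dose-response panel
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    cell_line: str
    top: float
    bottom: float
    ec50_um: float
    hill: float            # signed; negative for inhibition curves
    rss: float
    converged: bool
    responsive: bool = False
    rule: str = ""

    @property
    def pec50(self) -> float:
        return float(-np.log10(self.ec50_um * 1e-6)) if self.ec50_um > 0 else np.nan


def _four_pl(c, top, bottom, ec50, slope):
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** slope)


def fit_4pl(
    concentrations_um: np.ndarray, response: np.ndarray, cell_line: str = ""
) -> DoseResponseFit:
    """Four-parameter logistic fit of a viability curve.

    Model: ``y = bottom + (top - bottom) / (1 + (c/ec50)^s)`` with s > 0,
    so response falls from top (low c) to bottom (high c); the reported
    hill slope is -s, negative for inhibition, matching the convention of
    plate-based viability software.  EC50 is bounded within
    [min conc / 10, max conc * 10].  Degenerate (flat) curves are returned
    as non-converged fits.
    """
    c = np.asarray(concentrations_um, float)
    y = np.asarray(response, float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.unique(c).size < 5:
        raise ValueError("need >= 5 distinct concentrations")
    span = float(y.max() - y.min())
    if span < 1e-9:
        return DoseResponseFit(cell_line, float(y.mean()), float(y.mean()),
                               np.nan, np.nan, 0.0, converged=False)
    # initialize at data extremes with ec50 at the midpoint crossing
    top0, bot0 = float(y[np.argmin(c)]), float(y[np.argmax(c)])
    if top0 <= bot0:
        top0, bot0 = float(y.max()), float(y.min())
    mid = (top0 + bot0) / 2.0
    order = np.argsort(c)
    cross = c[order][np.argmin(np.abs(y[order] - mid))]
    lo = [y.min() - span, y.min() - span, c.min() / 10.0, 0.2]
    hi = [y.max() + span, y.max() + span, c.max() * 10.0, 10.0]
    best = None
    for s0 in (1.0, 3.0):
        try:
            popt, _ = curve_fit(
                _four_pl, c, y, p0=[top0, bot0, cross, s0], bounds=(lo, hi), maxfev=10000
            )
        except RuntimeError:
            continue
        rss = float(((y - _four_pl(c, *popt)) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return DoseResponseFit(cell_line, np.nan, np.nan, np.nan, np.nan,
                               np.inf, converged=False)
    (top, bottom, ec50, slope), rss = best
    if top < bottom:  # keep the reported orientation canonical
        top, bottom = bottom, top
    return DoseResponseFit(
        cell_line, float(top), float(bottom), float(ec50), float(-slope),
        rss, converged=True,
    )


#: Named responsiveness rules.  "methods": EC50 < 6 uM with hill slope in
#: [-3.5, -1].  "steep": pEC50 > 5.5 with hill slope < -3.5.  The two
#: rules disagree on steep potent curves; both are exposed and the rule
#: used is recorded on the fit.
RESPONSIVENESS_RULES = ("methods", "steep")


def classify_responsiveness(fit: DoseResponseFit, rule: str = "methods") -> bool:
    """Apply a named responsiveness rule; non-converged fits are negative."""
    if rule not in RESPONSIVENESS_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RESPONSIVENESS_RULES}")
    fit.rule = rule
    if not fit.converged or not np.isfinite(fit.ec50_um):
        fit.responsive = False
        return False
    if rule == "methods":
        fit.responsive = bool(fit.ec50_um < 6.0 and -3.5 <= fit.hill <= -1.0)
    else:
        fit.responsive = bool(fit.pec50 > 5.5 and fit.hill < -3.5)
    return fit.responsive


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass
class ComparisonCircle:
    group: str
    center: float
    radius: float
    n: int
    se: float


def comparison_circles(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[list[ComparisonCircle], pd.DataFrame]:
    """Tukey-Kramer comparison circles and pairwise significance decisions.

    Each circle is centered on the group mean with radius
    ``(q / sqrt(2)) * s / sqrt(n_i)`` where q is the alpha-level
    studentized-range quantile for k groups at the pooled error df and s
    the pooled SD.  Groups differ when the center distance exceeds
    ``sqrt(r_i^2 + r_j^2)``, which reproduces the Tukey-Kramer HSD
    decision exactly (circle overlap is the graphical rendering of the
    same inequality).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    ns = np.array([a.size for a in arrays])
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    k = len(names)
    df = int(ns.sum() - k)
    pooled_var = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    s = np.sqrt(pooled_var)
    q = stats.studentized_range.ppf(1 - alpha, k, df)
    circles = [
        ComparisonCircle(
            group=g, center=float(a.mean()),
            radius=float(q / np.sqrt(2) * s / np.sqrt(a.size)),
            n=int(a.size), se=float(s / np.sqrt(a.size)),
        )
        for g, a in zip(names, arrays)
    ]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = circles[i], circles[j]
            diff = abs(ci.center - cj.center)
            crit = np.sqrt(ci.radius**2 + cj.radius**2)
            rows.append(
                dict(group_a=ci.group, group_b=cj.group, mean_diff=diff,
                     critical_diff=float(crit), significant=bool(diff > crit))
            )
    return circles, pd.DataFrame(rows)
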