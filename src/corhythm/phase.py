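"""Cross-species peak-time comparison and peak-time distributions.

Workflow: per-gene acrophases from the cosinor fits are differenced
(human peak minus mouse peak, per gene, sex and human subregion), the
differences are pooled within sex by DerSimonian-Laird random-effects
meta-analysis, and the male/female pooled shifts are contrasted with a
mixed-effects meta-regression (sex as moderator, Wald z test).

Differences are reported **raw** (unwrapped, range (-24, 24)); a wrapped
variant mapping to (-12, 12] exists for callers who prefer circular
differences, but pooled shifts near the half-period would fold under the
wrap, so raw is the default. Effect variances come from delta-method
acrophase standard errors; equal weights are the fallback when variances
are unavailable or degenerate.

The module also summarizes peak-time distributions: two-hour-bin
percentage histograms of rhythmic-transcript peaks and the fraction
peaking in the species' behaviorally active half of the day (dark
[12, 24) for the nocturnal mouse; the first 12 h after sunrise for the
diurnal human).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import CosinorFit, RhythmResults
from .datasets import CLOCK_PANEL
from .errors import AnalysisError, ValidationError

MOUSE_ACTIVE_WINDOW = (12.0, 24.0)  # dark phase under 12:12 LD
HUMAN_ACTIVE_WINDOW = (0.0, 12.0)  # first 12 h after sunrise


def peak_difference(human_peak_h: float, mouse_peak_h: float) -> float:
    """Raw peak-time difference human − mouse, in hours (range (−24, 24))."""
    for v in (human_peak_h, mouse_peak_h):
        if not 0.0 <= v < 24.0:
            raise ValidationError(f"peak time {v} outside [0, 24)")
    return human_peak_h - mouse_peak_h


def wrapped_difference(human_peak_h: float, mouse_peak_h: float) -> float:
    """Circular difference mapped into (−12, 12]."""
    d = peak_difference(human_peak_h, mouse_peak_h)
    w = (d + 12.0) % 24.0 - 12.0
    return 12.0 if w == -12.0 else w


def acrophase_se(fit: CosinorFit) -> float:
    """Delta-method standard error of the acrophase, in hours.

    With phi = (T/2pi) atan2(b_s, b_c), the gradient w.r.t. (b_c, b_s)
    is (T/2pi) * (-b_s, b_c) / A^2, so
    Var(phi) = (T/2pi)^2 [b_s, -b_c] Sigma [b_s, -b_c]^T / A^4
    with Sigma the 2x2 covariance of (b_c, b_s).
    """
    if fit.amplitude <= 1e-10:
        raise AnalysisError(
            f"acrophase undefined for zero amplitude (gene {fit.gene_id!r})"
        )
    g = np.array([fit.beta_sin, -fit.beta_cos])
    sigma = fit.covariance[1:, 1:]
    var = (fit.period / (2.0 * np.pi)) ** 2 * (g @ sigma @ g) / fit.amplitude**4
    return float(np.sqrt(max(var, 0.0)))


def phase_table_from_peaks(
    mouse_peaks: pd.DataFrame, human_peaks: pd.DataFrame
) -> pd.DataFrame:
    """Build a phase-difference table from plain peak-time tables.

    ``mouse_peaks``: genes × sexes (columns M, F); ``human_peaks``:
    genes × (region, sex) MultiIndex columns. One row per
    gene × sex × region with the raw difference.
    """
    rows = []
    for gene in mouse_peaks.index:
        for region, sex in human_peaks.columns:
            hp = float(human_peaks.loc[gene, (region, sex)])
            mp = float(mouse_peaks.loc[gene, sex])
            rows.append(
                {
                    "gene_id": gene,
                    "sex": sex,
                    "human_region": region,
                    "mouse_peak_h": mp,
                    "human_peak_h": hp,
                    "diff_h": peak_difference(hp, mp),
                    "diff_se": np.nan,
                }
            )
    return pd.DataFrame(rows)


def build_phase_table(
    mouse_results: dict[str, RhythmResults],
    human_results: dict[tuple[str, str], RhythmResults],
    genes=None,
    with_se: bool = True,
) -> pd.DataFrame:
    """Per-gene cross-species phase-difference table from fitted results.

    Parameters
    ----------
    mouse_results
        ``{sex: RhythmResults}`` for the mouse region.
    human_results
        ``{(region, sex): RhythmResults}``.
    genes
        Gene panel; defaults to the six-gene conserved clock panel.
    with_se
        Attach ``diff_se = sqrt(se_human^2 + se_mouse^2)`` from
        delta-method acrophase standard errors.
    """
    if genes is None:
        genes = list(CLOCK_PANEL)
    missing = []
    for g in genes:
        for sex, res in mouse_results.items():
            if g not in res.frame.index:
                missing.append((g, res.group))
        for key, res in human_results.items():
            if g not in res.frame.index:
                missing.append((g, res.group))
    if missing:
        raise ValidationError(f"genes missing from fitted groups: {missing}")
    rows = []
    for g in genes:
        for (region, sex), hres in human_results.items():
            if sex not in mouse_results:
                raise ValidationError(f"no mouse results for sex {sex!r}")
            mres = mouse_results[sex]
            mp = float(mres.frame.loc[g, "peak_time_h"])
            hp = float(hres.frame.loc[g, "peak_time_h"])
            se = np.nan
            if with_se:
                se_m = acrophase_se(mres.fit_for(g))
                se_h = acrophase_se(hres.fit_for(g))
                se = float(np.sqrt(se_m**2 + se_h**2))
            rows.append(
                {
                    "gene_id": g,
                    "sex": sex,
                    "human_region": region,
                    "mouse_peak_h": mp,
                    "human_peak_h": hp,
                    "diff_h": peak_difference(hp, mp),
                    "diff_se": se,
                }
            )
    return pd.DataFrame(rows)


# --- random-effects pooling -------------------------------------------------


def _dl_pool(y: np.ndarray, v: np.ndarray) -> dict:
    """DerSimonian-Laird random-effects pooled estimate for one set."""
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    k = len(y)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    wstar = 1.0 / (v + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    se = float(np.sqrt(1.0 / np.sum(wstar)))
    return {"estimate": pooled, "se": se, "tau2": tau2, "q": q, "k": k}


def _dl_meta_regression(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> dict:
    """DL mixed-effects meta-regression: tau2 by method of moments, GLS betas."""
    k, p = X.shape
    W = np.diag(1.0 / v)
    XtWX_inv = np.linalg.inv(X.T @ W @ X)
    H = X @ XtWX_inv @ X.T @ W
    resid = y - H @ y
    qe = float(resid @ W @ resid)
    # moments denominator: tr(P) with P = W - W X (X'WX)^-1 X'W
    P = W - W @ X @ XtWX_inv @ X.T @ W
    tr_p = float(np.trace(P))
    tau2 = max(0.0, (qe - (k - p)) / tr_p) if tr_p > 0 else 0.0
    Ws = np.diag(1.0 / (v + tau2))
    cov = np.linalg.inv(X.T @ Ws @ X)
    beta = cov @ (X.T @ Ws @ y)
    return {"beta": beta, "cov": cov, "tau2": tau2, "qe": qe}


@dataclass
class PooledShift:
    """Per-sex pooled phase shifts and the cross-sex contrast."""

    by_sex: dict  # sex -> {"estimate", "se", "tau2", "q", "k"}
    contrast_h: float  # moderator coefficient: shift of the later sex (sorted order, i.e. M) minus the first (F)
    contrast_se: float
    contrast_z: float
    contrast_p: float
    tau2: float  # residual heterogeneity of the meta-regression
    weights: str = "inverse_variance"


def pool_phase_shift(table: pd.DataFrame, weights: str = "inverse_variance") -> PooledShift:
    """Pool phase differences within sex; Wald test of the sex contrast.

    ``weights='inverse_variance'`` uses ``diff_se**2`` as within-effect
    variances; ``'equal'`` uses unit variances. If inverse-variance
    weighting is requested but every variance is zero while the effects
    disagree, pooling falls back to equal weights with a warning.
    """
    if weights not in ("inverse_variance", "equal"):
        raise ValidationError(f"unknown weighting scheme {weights!r}")
    df = table.copy()
    sexes = sorted(df["sex"].unique())
    for sex in sexes:
        if (df["sex"] == sex).sum() < 2:
            raise ValidationError(f"need at least 2 effects for sex {sex!r}")
    y = df["diff_h"].to_numpy(dtype=float)
    if weights == "equal" or df["diff_se"].isna().any():
        v = np.ones(len(df))
        scheme = "equal"
    else:
        v = df["diff_se"].to_numpy(dtype=float) ** 2
        scheme = "inverse_variance"
        if (v <= 0).all():
            if np.ptp(y) > 0:
                warnings.warn(
                    "all effect variances are zero with heterogeneous effects; "
                    "falling back to equal weights"
                )
                v = np.ones(len(df))
                scheme = "equal"
            else:
                v = np.full(len(df), 1e-12)
        else:
            v = np.clip(v, 1e-12, None)
    by_sex = {}
    for sex in sexes:
        m = (df["sex"] == sex).to_numpy()
        by_sex[sex] = _dl_pool(y[m], v[m])
    if len(sexes) == 2:
        is_second = (df["sex"] == sexes[1]).to_numpy().astype(float)
        X = np.column_stack([np.ones(len(df)), is_second])
        reg = _dl_meta_regression(y, v, X)
        b1 = float(reg["beta"][1])
        se1 = float(np.sqrt(reg["cov"][1, 1]))
        z = b1 / se1 if se1 > 0 else np.inf * np.sign(b1)
        p = float(2.0 * stats.norm.sf(abs(z)))
        tau2 = reg["tau2"]
    else:
        b1, se1, z, p, tau2 = np.nan, np.nan, np.nan, np.nan, np.nan
    return PooledShift(
        by_sex=by_sex, contrast_h=b1, contrast_se=se1, contrast_z=z,
        contrast_p=p, tau2=tau2, weights=scheme,
    )


# --- peak-time distributions ------------------------------------------------


def peak_histogram(
    results: RhythmResults, alpha: float = 0.05, bin_h: float = 2.0
) -> pd.Series:
    """Percentage of rhythmic transcripts peaking in each time bin.

    Bins are left-closed, right-open ([0,2), ..., [22,24) by default);
    percentages sum to 100. Zero rhythmic transcripts yields an empty
    series with a warning.
    """
    mask = results.frame["p_value"] < alpha
    peaks = results.frame.loc[mask, "peak_time_h"].to_numpy()
    edges = np.arange(0.0, 24.0 + bin_h, bin_h)
    labels = pd.IntervalIndex.from_breaks(edges, closed="left")
    if len(peaks) == 0:
        warnings.warn(f"no rhythmic transcripts at alpha={alpha} in {results.group}")
        return pd.Series(dtype=float, index=labels[:0], name="pct")
    counts, _ = np.histogram(peaks, bins=edges)
    return pd.Series(100.0 * counts / counts.sum(), index=labels, name="pct")


def active_phase_fraction(
    results: RhythmResults, species: str, alpha: float = 0.05
) -> float:
    """Fraction of rhythmic transcripts peaking in the active phase.

    Active windows: mouse [12, 24) (dark), human [0, 12) after sunrise.
    """
    if species == "mouse":
        lo, hi = MOUSE_ACTIVE_WINDOW
    elif species == "human":
        lo, hi = HUMAN_ACTIVE_WINDOW
    else:
        raise ValidationError(f"species must be mouse or human, got {species!r}")
    mask = results.frame["p_value"] < alpha
    peaks = results.frame.loc[mask, "peak_time_h"].to_numpy()
    if len(peaks) == 0:
        raise AnalysisError(f"no rhythmic transcripts at alpha={alpha}")
    return float(np.mean((peaks >= lo) & (peaks < hi)))
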