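"""Single-harmonic cosinor regression and rhythmicity statistics.

Each gene's expression y at sample times t is modelled as

    y = M + beta_c * cos(2*pi*t/T) + beta_s * sin(2*pi*t/T) + e

with period T fixed at 24 h. The fit is ordinary least squares; the
derived rhythm parameters are

    amplitude A   = sqrt(beta_c^2 + beta_s^2)          (log2 units)
    peak time phi = (T / 2*pi) * atan2(beta_s, beta_c) mod T

so that the fitted curve equals M + A*cos(2*pi*(t - phi)/T). Rhythmicity
is tested with the F-test of the two harmonic terms against the
intercept-only model, df = (2, n - 3); q-values are Benjamini-Hochberg
over all genes fitted within a group. Rhythmic calls use unadjusted
p < 0.05 by default, reflecting the exploratory convention common in
brain diurnal-transcriptome studies; a q-threshold mode is available
downstream wherever an alpha is taken.

:class:`CosinorRhythmometer` is a scikit-learn estimator fitting all
genes of a samples × genes matrix at once (they share the design
matrix, so the OLS solve is a single linear system); ``fit_cosinor``
and ``fit_group`` are the per-gene / per-group functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ValidationError
from .io import ExpressionMatrix, SampleTable

_P_FLOOR = 1.0e-300  # p-values are clamped into (0, 1]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class CosinorRhythmometer(BaseEstimator):
    """Fixed-period cosinor fit for every column of a samples × genes matrix.

    Parameters
    ----------
    period : float, default 24.0
        Oscillation period in hours.
    alpha : float, default 0.05
        Significance level used by :meth:`rhythmic_mask` (strict
        ``p < alpha``).

    Attributes (after ``fit(X, t)``)
    --------------------------------
    mesor_, amplitude_, peak_time_h_, r2_, f_stat_, p_value_, q_value_ :
        per-gene arrays; ``coef_`` holds (mesor, beta_cos, beta_sin) rows
        and ``covariance_`` the per-gene 3 × 3 coefficient covariance.
    """

    def __init__(self, period: float = 24.0, alpha: float = 0.05):
        self.period = period
        self.alpha = alpha

    def fit(self, X, t):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        t = np.asarray(t, dtype=float)
        n = X.shape[0]
        if t.shape != (n,):
            raise ValidationError("times must match the number of samples (rows)")
        if n < 4:
            # need n - 3 >= 1 residual degrees of freedom for the F-test
            raise ValidationError("cosinor fit needs at least 4 samples")
        if len(np.unique(np.round(t, 9))) < 3:
            raise ValidationError("cosinor fit needs at least 3 distinct time values")
        omega = 2.0 * np.pi / self.period
        D = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
        if np.linalg.matrix_rank(D) < 3:
            raise AnalysisError("cosinor design matrix is rank deficient")
        DtD = D.T @ D
        DtD_inv = np.linalg.inv(DtD)
        beta = DtD_inv @ (D.T @ X)  # 3 x G
        fitted = D @ beta
        resid = X - fitted
        rss = np.einsum("ij,ij->j", resid, resid)
        tss = np.einsum("ij,ij->j", X - X.mean(axis=0), X - X.mean(axis=0))
        dof = n - 3
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((tss - rss) / 2.0) / (rss / dof)
            r2 = 1.0 - rss / tss
        # degenerate geometry: constant input -> no rhythm signal at all
        null_gene = tss <= 1e-12 * n
        perfect = (rss <= 1e-12 * np.maximum(tss, 1.0)) & ~null_gene
        f = np.where(null_gene, 0.0, f)
        r2 = np.clip(np.where(null_gene, 0.0, r2), 0.0, 1.0)
        p = stats.f.sf(f, 2, dof)
        p = np.where(null_gene, 1.0, p)
        p = np.where(perfect, _P_FLOOR, np.clip(p, _P_FLOOR, 1.0))
        sigma2 = rss / dof
        self.n_ = n
        self.coef_ = beta.T  # G x 3
        self.mesor_ = beta[0].copy()
        self.amplitude_ = np.hypot(beta[1], beta[2])
        self.peak_time_h_ = (self.period / (2.0 * np.pi)) * np.arctan2(
            beta[2], beta[1]
        ) % self.period
        self.r2_ = r2
        self.f_stat_ = np.where(np.isfinite(f), f, np.inf)
        self.p_value_ = p
        self.q_value_ = bh_fdr(p)
        self.covariance_ = sigma2[:, None, None] * DtD_inv[None, :, :]
        self.n_features_in_ = X.shape[1]
        return self

    def rhythmic_mask(self) -> np.ndarray:
        """Boolean per-gene mask of p < alpha (strict)."""
        return self.p_value_ < self.alpha

    def results_frame(self, gene_ids=None) -> pd.DataFrame:
        cols = {
            "mesor": self.mesor_,
            "amplitude": self.amplitude_,
            "peak_time_h": self.peak_time_h_,
            "r2": self.r2_,
            "f_stat": self.f_stat_,
            "p_value": self.p_value_,
            "q_value": self.q_value_,
            "beta_cos": self.coef_[:, 1],
            "beta_sin": self.coef_[:, 2],
            "n": self.n_,
        }
        idx = gene_ids if gene_ids is not None else range(len(self.mesor_))
        df = pd.DataFrame(cols, index=pd.Index(idx, name="gene_id"))
        return df


@dataclass
class CosinorFit:
    """Single-gene cosinor fit summary."""

    gene_id: str
    mesor: float
    beta_cos: float
    beta_sin: float
    amplitude: float
    peak_time_h: float
    r2: float
    f_stat: float
    p_value: float
    n: int
    covariance: np.ndarray  # 3x3 for (intercept, beta_cos, beta_sin)
    period: float = 24.0


@dataclass
class RhythmResults:
    """Per-gene cosinor fits for one sample group, with BH q-values."""

    group: str
    frame: pd.DataFrame  # indexed by gene_id; columns as results_frame
    covariances: np.ndarray  # G x 3 x 3, aligned with frame rows
    period: float = 24.0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    def p_values(self) -> pd.Series:
        return self.frame["p_value"]

    def peaks(self) -> pd.Series:
        return self.frame["peak_time_h"]

    def rhythmic_set(self, alpha: float = 0.05) -> set[str]:
        return set(self.frame.index[self.frame["p_value"] < alpha])

    def fit_for(self, gene_id: str) -> CosinorFit:
        if gene_id not in self.frame.index:
            raise ValidationError(f"gene {gene_id!r} not fitted in group {self.group!r}")
        row = self.frame.loc[gene_id]
        pos = self.frame.index.get_loc(gene_id)
        return CosinorFit(
            gene_id=gene_id,
            mesor=float(row["mesor"]),
            beta_cos=float(row["beta_cos"]),
            beta_sin=float(row["beta_sin"]),
            amplitude=float(row["amplitude"]),
            peak_time_h=float(row["peak_time_h"]),
            r2=float(row["r2"]),
            f_stat=float(row["f_stat"]),
            p_value=float(row["p_value"]),
            n=int(row["n"]),
            covariance=self.covariances[pos],
            period=self.period,
        )


def fit_cosinor(values, times, period: float = 24.0, gene_id: str = "") -> CosinorFit:
    """OLS cosinor fit of one expression vector on its sample times."""
    est = CosinorRhythmometer(period=period).fit(np.asarray(values, float)[:, None], times)
    return CosinorFit(
        gene_id=gene_id,
        mesor=float(est.mesor_[0]),
        beta_cos=float(est.coef_[0, 1]),
        beta_sin=float(est.coef_[0, 2]),
        amplitude=float(est.amplitude_[0]),
        peak_time_h=float(est.peak_time_h_[0]),
        r2=float(est.r2_[0]),
        f_stat=float(est.f_stat_[0]),
        p_value=float(est.p_value_[0]),
        n=est.n_,
        covariance=est.covariance_[0],
        period=period,
    )


def fit_group(
    expr: ExpressionMatrix,
    samples: SampleTable,
    group: str,
    period: float = 24.0,
) -> RhythmResults:
    """Fit every gene of one group (species_sex_region label)."""
    meta = samples.frame
    sel = meta[meta["group"] == group]
    if len(sel) < 4:
        raise ValidationError(
            f"group {group!r} selects {len(sel)} samples; need at least 4"
        )
    sample_ids = [s for s in expr.sample_ids if s in set(sel["sample_id"])]
    t = samples.times_for(sample_ids)
    X = expr.values[sample_ids].to_numpy(dtype=float).T  # samples x genes
    try:
        est = CosinorRhythmometer(period=period).fit(X, t)
    except (ValidationError, AnalysisError) as exc:
        raise type(exc)(f"group {group!r}: {exc}") from exc
    frame = est.results_frame(expr.gene_ids)
    return RhythmResults(group=group, frame=frame, covariances=est.covariance_,
                         period=period)
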