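"""Expression filtering and normalization.

The preprocessing chain applied to each species' raw counts:

1. log2CPM transform (pseudocount 1, i.e. ``log2(CPM + 1)``) used only
   for the detection filter;
2. keep genes with log2CPM > 1 in more than half of the samples of at
   least one group (default grouping species × sex × region), and drop
   Y-chromosome-flagged genes;
3. median-of-ratios size factors (the DESeq-style estimator: each
   sample's factor is the median over all-positive "reference" genes of
   count / gene geometric mean);
4. ``log2(count / size_factor + 1)`` as the expression values fed to
   the cosinor fits.

Both pseudocounts are fixed at 1 so the transforms are exactly
reproducible; with that convention the filter's log2CPM > 1 means
CPM > 1.

Scikit-learn-style transformers (samples × genes orientation) are
provided for composition with sklearn pipelines; the module functions
operate on :class:`~corhythm.io.ExpressionMatrix` and are the interface
the pipeline uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ValidationError
from .io import ExpressionMatrix, SampleTable

DEFAULT_GROUP_BY = ("species", "sex", "region")


def _require_counts(counts: ExpressionMatrix) -> None:
    if counts.value_kind != "raw_counts":
        raise ValidationError(
            f"expected raw_counts, got value_kind={counts.value_kind!r}"
        )


def compute_log2cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(counts-per-million + 1) per sample."""
    _require_counts(counts)
    lib = counts.values.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero) > 0:
        raise ValidationError(f"zero library size for sample {zero.index[0]!r}")
    cpm = counts.values * (1.0e6 / lib)
    return ExpressionMatrix(
        np.log2(cpm + 1.0), value_kind="log2cpm",
        gene_annotations=counts.gene_annotations,
    )


def filter_transcripts(
    counts: ExpressionMatrix,
    samples: SampleTable,
    threshold: float = 1.0,
    frac: float = 0.5,
    group_by: tuple[str, ...] = DEFAULT_GROUP_BY,
) -> list[str]:
    """Gene ids passing the detection filter.

    A gene is kept iff (a) in at least one group, the fraction of that
    group's samples with log2CPM strictly above ``threshold`` strictly
    exceeds ``frac``, and (b) it is not Y-chromosome-flagged.
    """
    if counts.value_kind == "raw_counts":
        log2cpm = compute_log2cpm(counts)
    elif counts.value_kind == "log2cpm":
        log2cpm = counts
    else:
        raise ValidationError("filter_transcripts needs raw_counts or log2cpm input")
    meta = samples.frame.set_index("sample_id").loc[log2cpm.sample_ids]
    labels = meta[list(group_by)].astype(str).agg("_".join, axis=1)
    passing = pd.Series(False, index=log2cpm.values.index)
    for label, sample_ids in labels.groupby(labels).groups.items():
        if len(sample_ids) == 0:
            raise ValidationError(f"empty sample group {label!r}")
        sub = log2cpm.values[list(sample_ids)]
        prop = (sub > threshold).mean(axis=1)
        passing |= prop > frac
    y_flagged = counts.y_flagged()
    return [g for g in log2cpm.gene_ids if passing[g] and g not in y_flagged]


def median_of_ratios(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    Reference genes are those with strictly positive counts in every
    sample; each sample's factor is the median over reference genes of
    ``count / geometric_mean_across_samples``.
    """
    _require_counts(counts)
    arr = counts.values.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValidationError(
            "median-of-ratios undefined: no gene has positive counts in all samples"
        )
    logs = np.log(arr[ref])
    geo = np.exp(logs.mean(axis=1))
    ratios = arr[ref] / geo[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_log2(counts: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """``log2(count / size_factor + 1)`` per cell."""
    _require_counts(counts)
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    f = factors.loc[counts.sample_ids].to_numpy(dtype=float)
    norm = counts.values.to_numpy(dtype=float) / f
    values = pd.DataFrame(
        np.log2(norm + 1.0), index=counts.gene_ids, columns=counts.sample_ids
    )
    return ExpressionMatrix(
        values, value_kind="normalized_log2", gene_annotations=counts.gene_annotations
    )


def preprocess_species(
    counts: ExpressionMatrix,
    samples: SampleTable,
    threshold: float = 1.0,
    frac: float = 0.5,
    group_by: tuple[str, ...] = DEFAULT_GROUP_BY,
) -> tuple[ExpressionMatrix, list[str]]:
    """Filter then median-of-ratios-normalize one species' counts.

    Returns the normalized_log2 matrix restricted to kept genes, and
    the kept-gene list.
    """
    kept = filter_transcripts(counts, samples, threshold=threshold, frac=frac,
                              group_by=group_by)
    if not kept:
        raise ValidationError("no genes pass the expression filter")
    sub = counts.subset_genes(kept)
    factors = median_of_ratios(sub)
    return normalize_log2(sub, factors), kept


class Log2CPM(TransformerMixin, BaseEstimator):
    """Stateless samples × genes log2(CPM + 1) transformer."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        lib = X.sum(axis=1, keepdims=True)
        if (lib <= 0).any():
            raise ValidationError("zero library size in input")
        return np.log2(X * (1.0e6 / lib) + 1.0)


class MedianRatioNormalizer(TransformerMixin, BaseEstimator):
    """Samples × genes median-of-ratios normalizer.

    ``fit`` learns per-sample size factors (``size_factors_``) from the
    fitted matrix itself; ``transform`` returns
    ``log2(count / factor + 1)``. Note the factors are per *sample*, so
    transform is only meaningful on the matrix the normalizer was fit
    on — the sklearn surface exists for pipeline composition, not for
    out-of-sample projection.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        em = ExpressionMatrix(
            pd.DataFrame(
                np.round(X).astype(np.int64).T,
                index=[f"g{i}" for i in range(X.shape[1])],
                columns=[f"s{j}" for j in range(X.shape[0])],
            )
        )
        self.size_factors_ = median_of_ratios(em).to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[0] != len(self.size_factors_):
            raise ValidationError(
                "median-of-ratios factors are per sample; transform the fitted matrix"
            )
        return np.log2(X / self.size_factors_[:, None] + 1.0)
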