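"""Rhythmic-set overlap: thresholded intersections and RRHO maps.

Two complementary views of how much two groups' rhythmic transcriptomes
agree:

* :func:`overlap_stats` — fix a significance threshold, intersect the
  two rhythmic sets, and report directional percentages (|A∩B|/|A| and
  |A∩B|/|B| — deliberately asymmetric) plus a hypergeometric
  enrichment p for the intersection within a common universe.
* :func:`rrho_map` — threshold-free rank-rank hypergeometric overlap:
  genes expressed in both groups are ranked by -log10(p) (most rhythmic
  first) on each axis, and for a grid of rank cutoffs (i, j) the overlap
  of the top-i and top-j sets is scored by -log10 of the upper
  hypergeometric tail. Because rhythmicity p-values carry no sign, only
  the single over-enrichment quadrant is computed. Cell-wise
  significance is annotated with Benjamini-Yekutieli q-values (valid
  under the strong dependence between cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cosinor import RhythmResults
from .errors import ValidationError


def rhythmic_set(results: RhythmResults, alpha: float = 0.05) -> set[str]:
    """Genes with p strictly below alpha."""
    if len(results.frame) == 0:
        raise ValidationError("empty results")
    return results.rhythmic_set(alpha)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = universe size, K = size of the first set, n = size of the
    second (the draw), k = observed intersection. Computed in log space
    via the survival function, so tiny tails do not underflow to the
    wrong order of magnitude.
    """
    if not (0 <= k <= min(K, n) <= max(K, n) <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class OverlapResult:
    """Thresholded overlap between two rhythmic sets in a shared universe."""

    set_a_size: int
    set_b_size: int
    intersection_size: int
    universe_size: int
    pct_of_a: float
    pct_of_b: float
    p_value: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_stats(set_a, set_b, universe) -> OverlapResult:
    """Intersection size, directional percentages and enrichment p."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise ValidationError(f"set A not contained in universe: e.g. {sorted(a - u)[:3]}")
    if not b <= u:
        raise ValidationError(f"set B not contained in universe: e.g. {sorted(b - u)[:3]}")
    k = len(a & b)
    p = hypergeom_tail(k, len(a), len(b), len(u)) if a and b else 1.0
    return OverlapResult(
        set_a_size=len(a),
        set_b_size=len(b),
        intersection_size=k,
        universe_size=len(u),
        pct_of_a=100.0 * k / len(a) if a else 0.0,
        pct_of_b=100.0 * k / len(b) if b else 0.0,
        p_value=p,
    )


@dataclass
class RRHOMap:
    """Grid of -log10 overlap p-values over rank cutoffs.

    ``matrix[i, j]`` scores the overlap of the top ``cutoffs_a[i]``
    genes of list A with the top ``cutoffs_b[j]`` genes of list B.
    ``q_matrix`` holds Benjamini-Yekutieli adjusted p-values across
    cells; ``order_a``/``order_b`` are the full rankings (most
    significant first).
    """

    cutoffs_a: np.ndarray
    cutoffs_b: np.ndarray
    matrix: np.ndarray  # -log10 raw p
    q_matrix: np.ndarray  # BY-adjusted p per cell
    common_universe: list[str]
    order_a: list[str]
    order_b: list[str]

    def transpose(self) -> "RRHOMap":
        return RRHOMap(
            cutoffs_a=self.cutoffs_b,
            cutoffs_b=self.cutoffs_a,
            matrix=self.matrix.T.copy(),
            q_matrix=self.q_matrix.T.copy(),
            common_universe=self.common_universe,
            order_a=self.order_b,
            order_b=self.order_a,
        )


def _rank_order(p: pd.Series) -> list[str]:
    """Gene ids sorted most-rhythmic first; ties broken by gene id."""
    df = pd.DataFrame({"p": p.astype(float)})
    df["gene"] = df.index.astype(str)
    df = df.sort_values(["p", "gene"], kind="mergesort")
    return list(df["gene"])


def rrho_map(p_a: pd.Series, p_b: pd.Series, steps: int = 100) -> RRHOMap:
    """Rank-rank hypergeometric overlap map of two per-gene p-value lists.

    Both lists are restricted to their common gene universe; the grid
    uses ``steps`` cutoffs with stride ``ceil(N / steps)`` (the last
    cutoff is the full universe).
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    common = sorted(set(p_a.index.astype(str)) & set(p_b.index.astype(str)))
    if not common:
        raise ValidationError("gene universes do not intersect")
    n_genes = len(common)
    pa = p_a.loc[common]
    pb = p_b.loc[common]
    order_a = _rank_order(pa)
    order_b = _rank_order(pb)
    rank_a = pd.Series(np.arange(1, n_genes + 1), index=order_a)
    rank_b = pd.Series(np.arange(1, n_genes + 1), index=order_b)
    ra = rank_a.loc[common].to_numpy()
    rb = rank_b.loc[common].to_numpy()
    stride = math.ceil(n_genes / steps)
    cutoffs = np.arange(stride, n_genes + 1, stride)
    if cutoffs[-1] != n_genes:
        cutoffs = np.append(cutoffs, n_genes)
    edges = np.concatenate([[0.5], cutoffs + 0.5])
    counts, _, _ = np.histogram2d(ra, rb, bins=[edges, edges])
    k = counts.cumsum(axis=0).cumsum(axis=1)  # overlap of top-i, top-j
    Ki = cutoffs[:, None].astype(int)
    Nj = cutoffs[None, :].astype(int)
    with np.errstate(divide="ignore"):
        p = stats.hypergeom.sf(k - 1, n_genes, Ki, Nj)
    p = np.clip(p, 1e-320, 1.0)
    neg_log10 = -np.log10(p)
    q = multipletests(p.ravel(), method="fdr_by")[1].reshape(p.shape)
    return RRHOMap(
        cutoffs_a=cutoffs.copy(),
        cutoffs_b=cutoffs.copy(),
        matrix=neg_log10,
        q_matrix=q,
        common_universe=common,
        order_a=order_a,
        order_b=order_b,
    )
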