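"""Gene-set over-representation analysis and cross-group comparison.

Rhythmic gene sets are tested against a user-supplied GMT collection by
one-sided hypergeometric over-representation (Fisher right tail) on a
declared background — by convention the list of all transcripts passing
the expression filter for that group. Pathways are first intersected
with the background; those with fewer than ``min_size`` background
members are excluded.

The cross-group rule compares two groups by their top-k (default 10)
enriched pathways: each of group A's top pathways is marked *shared* if
its -log10 p in group B exceeds 1.3 (p < 0.05), *not tested* if it was
not testable in B, and *unique* otherwise — symmetrically in both
directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import bh_fdr
from .errors import ValidationError
from .io import GeneSetCollection
from .overlap import hypergeom_tail


@dataclass
class EnrichmentResult:
    """One pathway's over-representation statistics."""

    pathway: str
    pathway_size: int  # within background
    query_size: int
    overlap: int
    expected: float
    p_value: float
    neg_log10_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def ora(query, pathway, background, name: str = "") -> EnrichmentResult:
    """One-sided hypergeometric over-representation test."""
    q, bg = set(query), set(background)
    if not q <= bg:
        raise ValidationError(
            f"query not contained in background: e.g. {sorted(q - bg)[:3]}"
        )
    pw = set(pathway) & bg
    k = len(q & pw)
    p = hypergeom_tail(k, len(pw), len(q), len(bg))
    return EnrichmentResult(
        pathway=name,
        pathway_size=len(pw),
        query_size=len(q),
        overlap=k,
        expected=len(pw) * len(q) / len(bg) if bg else 0.0,
        p_value=p,
        neg_log10_p=float(-np.log10(max(p, 1e-320))),
    )


def run_collection(
    query,
    collection: GeneSetCollection,
    background,
    min_size: int = 15,
) -> pd.DataFrame:
    """Test every sufficiently large pathway; sorted by (p, name), BH q.

    ``min_size`` applies to the background-restricted pathway. Returns
    an empty frame (with a warning) if nothing is testable.
    """
    bg = set(background)
    rows = []
    for pw_name in sorted(collection.sets):
        members = collection.sets[pw_name] & bg
        if len(members) < min_size:
            continue
        rows.append(ora(query, members, bg, name=pw_name).as_dict())
    if not rows:
        warnings.warn("no pathway meets the minimum-size criterion on this background")
        return pd.DataFrame(
            columns=["pathway", "pathway_size", "query_size", "overlap",
                     "expected", "p_value", "neg_log10_p", "q_value"]
        )
    df = pd.DataFrame(rows).sort_values(["p_value", "pathway"], kind="mergesort")
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df.reset_index(drop=True)


def cross_group_top10(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    k: int = 10,
    threshold_neg_log10: float = 1.3,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Top-k pathway sharing report between two enrichment result frames.

    For each direction, the k most enriched pathways (ties broken by
    name) of the source group are looked up in the opposing group:
    ``shared`` if the opposing -log10 p exceeds the threshold,
    ``not tested`` if absent there, ``unique`` otherwise.
    """
    out = []
    for src, src_label, other, other_label in (
        (results_a, label_a, results_b, label_b),
        (results_b, label_b, results_a, label_a),
    ):
        top = src.sort_values(["p_value", "pathway"], kind="mergesort").head(k)
        lookup = other.set_index("pathway")["neg_log10_p"] if len(other) else pd.Series(dtype=float)
        for _, row in top.iterrows():
            pw = row["pathway"]
            if pw in lookup.index:
                nlp = float(lookup[pw])
                status = "shared" if nlp > threshold_neg_log10 else "unique"
            else:
                nlp = np.nan
                status = "not tested"
            out.append(
                {
                    "direction": f"top_{src_label}_in_{other_label}",
                    "pathway": pw,
                    "source_neg_log10_p": float(row["neg_log10_p"]),
                    "opposing_neg_log10_p": nlp,
                    "status": status,
                }
            )
    return pd.DataFrame(out)
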