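"""Enrichment statistics over residue classes.

Over/under-representation of an annotation (e.g. positions carrying missense
SNPs, or membership in an allosteric-modulator binding site) within a residue
class is assessed with exact hypergeometric tail probabilities; Evolutionary
Trace conservation scores are compared between classes with two-sided
Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "compare_score_groups",
    "site_class_composition",
    "significance_stars",
]


@dataclass(frozen=True)
class AnnotationSet:
    """A named residue set with its statistical background (members must be
    drawn from the background; termini may be excluded upstream)."""

    name: str
    members: frozenset
    background: frozenset

    def __post_init__(self):
        if not self.background:
            raise ValueError(f"annotation set '{self.name}': empty background")
        if not self.members <= self.background:
            extra = sorted(self.members - self.background)[:5]
            raise ValueError(
                f"annotation set '{self.name}': members outside background, "
                f"e.g. {extra}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    draw_size: int
    category_size: int
    background_size: int
    p_over: float
    p_under: float


def hypergeometric_enrichment(
    annotation: AnnotationSet, category: set
) -> EnrichmentResult:
    """Exact hypergeometric over/under-representation of ``category`` residues
    among the annotated residues.

    With X ~ Hypergeom(N=background, K=category, n=draw=|members|):
    p_over = P(X >= observed), p_under = P(X <= observed); exact tail sums.
    """
    category = frozenset(category) & annotation.background
    n_bg = len(annotation.background)
    n_cat = len(category)
    n_draw = len(annotation.members)
    obs = len(annotation.members & category)
    p_over = float(hypergeom.sf(obs - 1, n_bg, n_cat, n_draw))
    p_under = float(hypergeom.cdf(obs, n_bg, n_cat, n_draw))
    return EnrichmentResult(
        observed=obs,
        draw_size=n_draw,
        category_size=n_cat,
        background_size=n_bg,
        p_over=min(p_over, 1.0),
        p_under=min(p_under, 1.0),
    )


def significance_stars(p: float) -> str:
    """Significance bands: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return "ns"


def compare_score_groups(
    scores: dict[str, float],
    classes: dict[str, str],
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparison of conservation scores
    between residue classes.

    Returns one row per class pair with group sizes, medians, the rank-sum
    p-value (tie-corrected) and significance stars; pairs where either group
    has fewer than two scored members are reported as non-testable rather
    than silently dropped.
    """
    groups: dict[str, list[float]] = {}
    for key, cls in classes.items():
        if key in scores and np.isfinite(scores[key]):
            groups.setdefault(cls, []).append(scores[key])
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    rows = []
    for a, b in combinations(names, 2):
        xa, xb = groups[a], groups[b]
        row = {
            "group_a": a,
            "group_b": b,
            "n_a": len(xa),
            "n_b": len(xb),
            "median_a": float(np.median(xa)),
            "median_b": float(np.median(xb)),
        }
        if len(xa) < 2 or len(xb) < 2:
            row.update(p_value=np.nan, stars="non-testable")
        else:
            p = float(mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            row.update(p_value=p, stars=significance_stars(p))
        rows.append(row)
    return pd.DataFrame(rows)


def site_class_composition(
    site: AnnotationSet,
    classes: dict[str, str],
    focal_class: str = "passenger",
) -> tuple[pd.DataFrame, EnrichmentResult | None]:
    """Residue-class composition of a binding site plus the enrichment test
    for the focal class.

    Multiple sites may be pooled upstream by unioning their members.  An
    empty site yields an empty composition and no test.
    """
    in_site = {k for k in site.members if k in classes}
    comp = (
        pd.Series([classes[k] for k in sorted(in_site)], dtype=object)
        .value_counts()
        .rename_axis("residue_class")
        .reset_index(name="count")
    )
    if not site.members:
        return comp, None
    focal = {k for k, c in classes.items() if c == focal_class}
    result = hypergeometric_enrichment(site, focal)
    return comp, result
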