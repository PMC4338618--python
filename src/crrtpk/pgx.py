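"""CYP2C19 genotype-to-phenotype assignment and phenotype-stratified summaries.

CYP2C19 is the principal voriconazole-metabolising enzyme.  Star alleles
carried here: *1 (normal function), *2 and *3 (loss of function), *17 (gain
of function).  Phenotypes follow the conventional mapping with *1/*17 and
*17/*17 assigned ultrarapid (the classification in use before the separate
"rapid" category was introduced):

=====================  ============
genotype               phenotype
=====================  ============
two loss-of-function   poor
one loss-of-function   intermediate
*1/*1                  extensive
any *17, no LoF        ultrarapid
=====================  ============
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ALLELES",
    "LOSS_OF_FUNCTION",
    "PHENOTYPES",
    "assign_phenotype",
    "MetaboliteRatios",
    "metabolite_ratios",
    "PhenotypeSummary",
    "phenotype_comparison",
]

ALLELES = ("*1", "*2", "*3", "*17")
LOSS_OF_FUNCTION = frozenset({"*2", "*3"})
PHENOTYPES = ("ultrarapid", "extensive", "intermediate", "poor")


def assign_phenotype(allele1: str, allele2: str) -> str:
    """Map an unordered CYP2C19 star-allele pair to a metabolizer phenotype."""
    for a in (allele1, allele2):
        if a not in ALLELES:
            raise ValueError(f"unknown CYP2C19 allele {a!r}; expected one of {ALLELES}")
    n_lof = sum(a in LOSS_OF_FUNCTION for a in (allele1, allele2))
    if n_lof == 2:
        return "poor"
    if n_lof == 1:
        return "intermediate"
    if "*17" in (allele1, allele2):
        return "ultrarapid"
    return "extensive"


@dataclass(frozen=True)
class MetaboliteRatios:
    """Parent/metabolite exposure ratios (voriconazole / voriconazole N-oxide)."""

    auc_ratio: float
    cmax_ratio: float


def metabolite_ratios(
    parent_auc: float,
    parent_cmax: float,
    metabolite_auc: float,
    metabolite_cmax: float,
) -> Optional[MetaboliteRatios]:
    """Parent-to-metabolite AUC and Cmax ratios; ``None`` when the metabolite
    exposure is zero (not estimable)."""
    for v in (parent_auc, parent_cmax, metabolite_auc, metabolite_cmax):
        if v < 0:
            raise ValueError("exposures must be non-negative")
    if metabolite_auc == 0 or metabolite_cmax == 0:
        return None
    return MetaboliteRatios(
        auc_ratio=parent_auc / metabolite_auc,
        cmax_ratio=parent_cmax / metabolite_cmax,
    )


@dataclass(frozen=True)
class PhenotypeSummary:
    """Group means of a metric by phenotype with a one-way ANOVA across groups."""

    group_means: Mapping[str, float]
    group_ns: Mapping[str, int]
    f_stat: Optional[float]
    p_value: Optional[float]


def phenotype_comparison(
    values: Sequence[float],
    phenotypes: Sequence[str],
    method: str = "anova",
) -> PhenotypeSummary:
    """Compare a per-subject metric across phenotype groups.

    The default is a one-way ANOVA implemented via explicit sums of squares
    so the degenerate cases are well-defined: zero between-group variance
    reports F=0, P=1 (no group effect); zero residual variance with a real
    group effect reports F=inf, P=0.  Singleton groups are allowed — they
    contribute nothing to the residual but their mean enters the
    between-group term.  With a single group only the means are reported
    (no test).  ``method="kruskal"`` substitutes the rank-based
    Kruskal-Wallis H test (reported in the same stat/P slots).
    """
    if method not in ("anova", "kruskal"):
        raise ValueError(f"method must be 'anova' or 'kruskal', got {method!r}")
    y = np.asarray(values, dtype=float)
    labels = list(phenotypes)
    if y.size != len(labels):
        raise ValueError("values and phenotypes must align")
    if y.size == 0:
        raise ValueError("no observations")
    groups: dict[str, list[float]] = {}
    for v, g in zip(y, labels):
        groups.setdefault(g, []).append(float(v))
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    ns = {g: len(v) for g, v in groups.items()}
    k, n = len(groups), y.size
    if k < 2:
        return PhenotypeSummary(group_means=means, group_ns=ns, f_stat=None, p_value=None)
    if n - k < 1:
        # all groups singletons: no residual degrees of freedom
        return PhenotypeSummary(group_means=means, group_ns=ns, f_stat=None, p_value=None)
    if method == "kruskal":
        if all(v == y[0] for v in y):
            return PhenotypeSummary(group_means=means, group_ns=ns, f_stat=0.0, p_value=1.0)
        h, p = stats.kruskal(*groups.values())
        return PhenotypeSummary(group_means=means, group_ns=ns, f_stat=float(h), p_value=float(p))
    grand = float(y.mean())
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - means[g]) ** 2 for v in vals) for g, vals in groups.items())
    df_b, df_w = k - 1, n - k
    scale = float(np.mean(y**2)) or 1.0
    if ss_between <= 1e-12 * scale * n:
        f, p = 0.0, 1.0
    elif ss_within <= 1e-12 * scale * n:
        f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return PhenotypeSummary(group_means=means, group_ns=ns, f_stat=f, p_value=p)
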