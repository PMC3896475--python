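"""Region assignment and control-vs-treatment statistics.

Scans cover the posterior ileum and the rectum; the rectum is split into
anterior and posterior halves by dividing its measurement sites in two along
the tissue axis (the extra site of an odd count goes anterior).  The unit of
replication is the preparation: each preparation contributes one mean flux
per region, and conditions are compared on those per-preparation means with
a one-way ANOVA followed by Bonferroni-adjusted pairwise tests at p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .pipeline import FluxEstimate

__all__ = [
    "RegionSummary",
    "PercentChange",
    "PairwiseTest",
    "AnovaResult",
    "TreatmentComparison",
    "assign_regions",
    "summarize_region",
    "percent_change",
    "anova_bonferroni",
    "preparation_region_means",
    "compare_conditions",
]


@dataclass(frozen=True)
class RegionSummary:
    region: str
    treatment_label: str
    n: int
    mean_flux: float  # pmol cm⁻² s⁻¹
    sem_flux: Optional[float]  # None when n = 1


@dataclass(frozen=True)
class PercentChange:
    """Percent change of flux magnitude; sign reversals flagged, not signed."""

    value: float  # % (negative = reduction in magnitude)
    sign_reversed: bool


@dataclass(frozen=True)
class PairwiseTest:
    group_a: int
    group_b: int
    t_statistic: float
    p_raw: float
    p_adjusted: float  # Bonferroni: min(1, m·p_raw)
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: tuple[PairwiseTest, ...]


@dataclass(frozen=True)
class TreatmentComparison:
    region: str
    n_control: int
    n_treatment: int
    control_mean: float
    control_sem: Optional[float]
    treatment_mean: float
    treatment_sem: Optional[float]
    percent_change: float
    sign_reversed: bool
    anova_f: float
    anova_p: float
    bonferroni_adjusted_p: float
    significant: bool


def assign_regions(estimates: Sequence[FluxEstimate]) -> list[FluxEstimate]:
    """Label each site ileum / anterior_rectum / posterior_rectum.

    Ileum sites keep their label; rectum sites are ordered by tissue-axis
    ordinal and split into halves, anterior first; an odd count puts the
    extra site in the anterior half.
    """
    rectum = [e for e in estimates if e.region_hint == "rectum"]
    for e in rectum:
        if e.ordinal is None or e.ordinal < 0:
            raise ValueError(f"site {e.site_id}: rectum site lacks a valid ordinal")
    order = {
        id(e): rank for rank, e in enumerate(sorted(rectum, key=lambda e: e.ordinal))
    }
    n_anterior = math.ceil(len(rectum) / 2)
    out = []
    for e in estimates:
        if e.region_hint == "ileum":
            out.append(replace(e, region="ileum"))
        elif e.region_hint == "rectum":
            label = (
                "anterior_rectum" if order[id(e)] < n_anterior else "posterior_rectum"
            )
            out.append(replace(e, region=label))
        else:
            out.append(e)
    return out


def summarize_region(
    fluxes: Sequence[float], region: str = "unknown", treatment_label: str = "control"
) -> RegionSummary:
    """Mean ± SEM of per-preparation fluxes; SEM undefined at n = 1."""
    if len(fluxes) == 0:
        raise ValueError("cannot summarize an empty set of fluxes")
    arr = np.asarray(fluxes, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return RegionSummary(
        region=region,
        treatment_label=treatment_label,
        n=int(arr.size),
        mean_flux=float(arr.mean()),
        sem_flux=sem,
    )


def percent_change(control_mean: float, treatment_mean: float) -> PercentChange:
    """Percent change of flux magnitude: 100·(|T| − |C|)/|C|.

    Computed on magnitudes so that a 75% reduction of secretion (negative
    fluxes) and of absorption (positive fluxes) share one formula.  A
    direction reversal (secretion → absorption or vice versa) is reported as
    a flag, not folded into the sign.
    """
    if control_mean == 0:
        raise ValueError("percent change undefined for zero control mean")
    value = 100.0 * (abs(treatment_mean) - abs(control_mean)) / abs(control_mean)
    reversed_ = treatment_mean != 0 and (control_mean > 0) != (treatment_mean > 0)
    return PercentChange(value=value, sign_reversed=reversed_)


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
    n_comparisons: Optional[int] = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Bonferroni-adjusted pairwise t-tests.

    Pairwise p-values are multiplied by ``n_comparisons`` (default: the
    number of pairs) and capped at 1; significance is declared at adjusted
    p < ``alpha``.  ``welch`` switches the pairwise tests to unequal
    variance; the omnibus ANOVA stays classical (equal variance).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    grand = np.concatenate(arrays)
    if np.allclose(grand, grand[0]):
        # zero between- and within-group variance: no evidence of any effect
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = sps.f_oneway(*arrays)
        if math.isnan(f_stat):
            f_stat, p_val = 0.0, 1.0
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    m = n_comparisons if n_comparisons is not None else len(pairs)
    if m < 1:
        raise ValueError("n_comparisons must be >= 1")
    pairwise = []
    for i, j in pairs:
        t, p = sps.ttest_ind(arrays[i], arrays[j], equal_var=not welch)
        if math.isnan(t):
            t, p = 0.0, 1.0
        p_adj = min(1.0, m * float(p))
        pairwise.append(
            PairwiseTest(
                group_a=i,
                group_b=j,
                t_statistic=float(t),
                p_raw=float(p),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return AnovaResult(
        f_statistic=float(f_stat), p_value=float(p_val), pairwise=tuple(pairwise)
    )


def preparation_region_means(
    estimates_by_preparation: Mapping[str, Sequence[FluxEstimate]],
) -> dict[str, dict[str, float]]:
    """region → {preparation_id → mean flux over that preparation's sites}.

    Estimates must already carry final region labels (see
    :func:`assign_regions`).
    """
    out: dict[str, dict[str, list[float]]] = {}
    for prep_id, estimates in estimates_by_preparation.items():
        for e in estimates:
            out.setdefault(e.region, {}).setdefault(prep_id, []).append(e.flux)
    return {
        region: {prep: float(np.mean(v)) for prep, v in preps.items()}
        for region, preps in out.items()
    }


def compare_conditions(
    control: Mapping[str, Sequence[float]],
    treatment: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    n_comparisons: Optional[int] = None,
    welch: bool = False,
) -> list[TreatmentComparison]:
    """Region-wise control vs treatment comparison on per-preparation means.

    ``control`` and ``treatment`` map region → per-preparation mean fluxes.
    By default the Bonferroni multiplier is the number of regions compared
    (one control-vs-treatment contrast per region).
    """
    regions = [r for r in control if r in treatment]
    if not regions:
        raise ValueError("no region present in both conditions")
    m = n_comparisons if n_comparisons is not None else len(regions)
    results = []
    for region in regions:
        c = summarize_region(control[region], region, "control")
        t = summarize_region(treatment[region], region, "treatment")
        pc = percent_change(c.mean_flux, t.mean_flux)
        anova = anova_bonferroni(
            [list(control[region]), list(treatment[region])],
            n_comparisons=m,
            alpha=alpha,
            welch=welch,
        )
        pair = anova.pairwise[0]
        results.append(
            TreatmentComparison(
                region=region,
                n_control=c.n,
                n_treatment=t.n,
                control_mean=c.mean_flux,
                control_sem=c.sem_flux,
                treatment_mean=t.mean_flux,
                treatment_sem=t.sem_flux,
                percent_change=pc.value,
                sign_reversed=pc.sign_reversed,
                anova_f=anova.f_statistic,
                anova_p=anova.p_value,
                bonferroni_adjusted_p=pair.p_adjusted,
                significant=pair.significant,
            )
        )
    return results
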