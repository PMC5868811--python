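"""Section-level summaries, distribution curves and group comparisons.

Conventions:

- sample standard deviation (n-1 denominator), SEM = SD/sqrt(n),
  CV% = 100 * SD / mean;
- distribution curves are fixed-width histograms over [0, max], expressed as
  absolute fibre count (%) per bin and cumulative fibre count (%) at the
  upper bin edges;
- group mean = unweighted average of section means (a section is one
  biological observation, regardless of how many fibres it holds);
- percent reduction = 100 * (1 - group_mean / reference_mean); fold change =
  group_mean / reference_mean; reported reductions round to the nearest
  integer percent;
- Mann-Whitney U (two-sided) for post hoc pairwise comparison of pooled
  per-fibre values, one-way ANOVA across three or more groups.

Normalising the target intensity to the membrane-marker intensity is *not*
a default output: membrane markers are themselves elevated in dystrophic
muscle, so the ratio underestimates sarcolemmal target levels.  A helper is
provided for explicit, flagged use only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class SectionSummary:
    """Summary of the per-fibre mean intensities of one section."""

    n_fibres: int
    mean: float
    sd: float | None
    sem: float | None
    cv_percent: float | None
    min: float
    max: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DistributionCurve:
    bin_edges: np.ndarray
    absolute_percent: np.ndarray
    cumulative_percent: np.ndarray


@dataclass
class GroupComparison:
    group_mean: float
    reference_mean: float
    fold_change: float
    percent_reduction: float
    percent_reduction_reported: int
    mann_whitney_p: float | None
    anova_p: float | None


def cv_from_sem(mean: float, sem: float, n: int) -> float:
    """CV% recovered from a printed mean +/- SEM and fibre count.

    Uses the identity CV% = 100 * SD / mean with SD = SEM * sqrt(n); lets a
    summary table be checked for internal consistency without the raw data.
    """
    if mean == 0:
        raise ValueError("mean must be non-zero")
    return 100.0 * sem * np.sqrt(n) / mean


def summarize_section(values: Sequence[float]) -> SectionSummary:
    """N, mean, SD, SEM, CV% and dynamic range of per-fibre intensities.

    SD/SEM/CV are undefined (None) for a single fibre; empty input is an
    error.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarise an empty section")
    n = int(arr.size)
    mean = float(arr.mean())
    if n < 2:
        return SectionSummary(n, mean, None, None, None, mean, mean)
    sd = float(arr.std(ddof=1))
    sem = sd / np.sqrt(n)
    cv = 100.0 * sd / mean if mean != 0 else None
    return SectionSummary(
        n_fibres=n,
        mean=mean,
        sd=sd,
        sem=float(sem),
        cv_percent=float(cv) if cv is not None else None,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def distribution_curves(values: Sequence[float], bins: int = 64) -> DistributionCurve:
    """Absolute and cumulative fibre-count (%) curves.

    Fixed-width bins span [0, max(values)]; the absolute percentages sum to
    100 and the cumulative curve (evaluated at upper bin edges) is
    non-decreasing and ends at 100.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot bin an empty section")
    upper = float(arr.max())
    if upper <= 0:
        upper = 1.0
    counts, edges = np.histogram(arr, bins=bins, range=(0.0, upper))
    absolute = 100.0 * counts / arr.size
    return DistributionCurve(
        bin_edges=edges,
        absolute_percent=absolute,
        cumulative_percent=np.cumsum(absolute),
    )


def compare_groups(
    group_section_means: Sequence[float],
    reference_section_means: Sequence[float],
    group_fibre_values: Sequence[float] | None = None,
    reference_fibre_values: Sequence[float] | None = None,
    extra_groups_fibre_values: Sequence[Sequence[float]] | None = None,
) -> GroupComparison:
    """Fold change / percent reduction of a group versus a reference.

    Group means are unweighted averages of section means.  When pooled
    per-fibre values are supplied a two-sided Mann-Whitney test is run; when
    ``extra_groups_fibre_values`` brings the number of groups to three or
    more, a one-way ANOVA across all groups is run as well.
    """
    g = np.asarray(group_section_means, dtype=float)
    r = np.asarray(reference_section_means, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("need at least one section summary per side")
    gm, rm = float(g.mean()), float(r.mean())
    if rm == 0:
        raise ValueError("reference mean is zero; fold change undefined")
    fold = gm / rm
    reduction = 100.0 * (1.0 - fold)

    mw_p = None
    if group_fibre_values is not None and reference_fibre_values is not None:
        mw_p = float(
            sps.mannwhitneyu(
                np.asarray(group_fibre_values, dtype=float),
                np.asarray(reference_fibre_values, dtype=float),
                alternative="two-sided",
            ).pvalue
        )
    anova_p = None
    if extra_groups_fibre_values:
        groups = [
            np.asarray(group_fibre_values, dtype=float),
            np.asarray(reference_fibre_values, dtype=float),
        ] + [np.asarray(v, dtype=float) for v in extra_groups_fibre_values]
        if all(len(x) > 1 for x in groups):
            anova_p = float(sps.f_oneway(*groups).pvalue)
    return GroupComparison(
        group_mean=gm,
        reference_mean=rm,
        fold_change=fold,
        percent_reduction=reduction,
        percent_reduction_reported=int(round(reduction)),
        mann_whitney_p=mw_p,
        anova_p=anova_p,
    )


def experiment_variability(repeat_means: Sequence[float] | Mapping[str, Sequence[float]]):
    """CV% of section means across repeat experiments.

    With a mapping (sample -> repeat means) a per-sample dict is returned.
    Fewer than two repeats leaves the CV undefined (None).
    """
    if isinstance(repeat_means, Mapping):
        return {k: experiment_variability(v) for k, v in repeat_means.items()}
    arr = np.asarray(list(repeat_means), dtype=float)
    if arr.size < 2:
        return None
    mean = arr.mean()
    if mean == 0:
        return None
    return float(100.0 * arr.std(ddof=1) / mean)


def membrane_normalised(
    target_means: Sequence[float], membrane_means: Sequence[float]
) -> np.ndarray:
    """Target/membrane intensity ratio per fibre — use with caution.

    Membrane-marker levels rise in dystrophic muscle, so this ratio
    systematically underestimates sarcolemmal target levels there; it is
    offered only as an explicitly requested output, never a default.
    """
    t = np.asarray(target_means, dtype=float)
    m = np.asarray(membrane_means, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(m > 0, t / m, np.nan)
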