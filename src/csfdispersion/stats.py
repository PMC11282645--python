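"""Repeatability metrics and injection-parameter group comparisons.

Each injection protocol is repeated (three times by default) and the
repetitions are compared pointwise over the spatial-temporal map:

* the sample standard deviation at each (z, t) point, its 95% band
  (1.96 x SD, the limits-of-agreement convention), and the worst-case
  band expressed as a percent of the concentration dynamic range,
  %DR = max 95% CI / C_max x 100, with C_max the maximum of the
  repetition-mean map;
* Bland-Altman agreement: per-point differences of each repetition from
  the repetition mean, with limits of agreement mean +- 1.96 SD.

The eight protocols pair into five single-parameter contrasts (injection
location, bolus volume, bolus rate, flush volume, flush rate); each
contrast is summarized by the change in %ID to eaCSF between the pair's
protocol means and an unpaired two-sample t-test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .quantify import SpatioTemporalMap

__all__ = [
    "RepeatStats",
    "BlandAltman",
    "GroupComparison",
    "GROUP_DEFINITIONS",
    "repetition_stats",
    "bland_altman",
    "group_comparison",
    "delta_table",
]

#: z-multiplier of the 95% band (limits-of-agreement convention)
CI_FACTOR = 1.96

#: The five injection-parameter contrasts: name -> (reference, variant).
#: The delta is variant mean minus reference mean.
GROUP_DEFINITIONS: dict[str, tuple[str, str]] = {
    "location": ("2NHP2", "3G1"),
    "bolus_volume": ("1NHP1", "3G2"),
    "bolus_rate": ("1NHP3", "1NHP2"),
    "flush_volume": ("1NHP2", "2G2"),
    "flush_rate": ("5NHP1", "2G2"),
}


@dataclass(frozen=True)
class RepeatStats:
    """Pointwise repeatability of >= 2 repetitions of one protocol."""

    mean_map: np.ndarray
    sd_map: np.ndarray  # uM, sample SD (ddof=1)
    max_sd: float  # uM
    max_ci: float  # uM, 1.96 x max SD
    c_max: float  # uM, max of the mean map
    percent_dynamic_range: float  # %, max CI / c_max x 100

    @property
    def ci_map(self) -> np.ndarray:
        return CI_FACTOR * self.sd_map


def repetition_stats(maps: list[SpatioTemporalMap]) -> RepeatStats:
    """Pointwise mean/SD across repetitions and the %DR summary."""
    if len(maps) < 2:
        raise ValueError("repeatability needs at least two repetitions")
    ref = maps[0]
    for m in maps[1:]:
        if m.c.shape != ref.c.shape or not np.allclose(m.t_frames, ref.t_frames):
            raise ValueError("repetition maps are not on identical grids")
    stack = np.stack([m.c for m in maps])
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=1)
    max_sd = float(sd_map.max())
    c_max = float(mean_map.max())
    max_ci = CI_FACTOR * max_sd
    pdr = 100.0 * max_ci / c_max if c_max > 0 else 0.0
    return RepeatStats(
        mean_map=mean_map,
        sd_map=sd_map,
        max_sd=max_sd,
        max_ci=max_ci,
        c_max=c_max,
        percent_dynamic_range=pdr,
    )


@dataclass(frozen=True)
class BlandAltman:
    """Agreement of repetitions against their mean.

    ``differences`` has one row per repetition (repetition minus the
    repetition mean, flattened over points); limits of agreement are
    mean difference +- 1.96 SD of the pooled differences.
    """

    differences: np.ndarray  # (n_reps, n_points)
    mean_values: np.ndarray  # (n_points,)
    mean_difference: float
    limits: tuple[float, float]


def bland_altman(values: np.ndarray | list) -> BlandAltman:
    """Bland-Altman analysis of >= 2 repetition series of equal length."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        raise ValueError("at least two repetitions required")
    if arr.ndim > 2:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.shape[0] < 2:
        raise ValueError("at least two repetitions required")
    mean_values = arr.mean(axis=0)
    diffs = arr - mean_values
    pooled = diffs.ravel()
    md = float(pooled.mean())
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return BlandAltman(
        differences=diffs,
        mean_values=mean_values,
        mean_difference=md,
        limits=(md - CI_FACTOR * sd, md + CI_FACTOR * sd),
    )


@dataclass(frozen=True)
class GroupComparison:
    """One injection-parameter contrast between two protocols."""

    parameter: str
    protocol_a: str
    protocol_b: str
    a_values: tuple[float, ...]  # per-repetition %ID, reference protocol
    b_values: tuple[float, ...]
    delta_percent_id: float  # mean(b) - mean(a)
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def group_comparison(
    name: str,
    a_values,
    b_values,
    protocol_a: str = "A",
    protocol_b: str = "B",
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Unpaired two-sample t-test on per-repetition %ID values.

    Student's pooled-variance test by default; Welch's optional.  When
    both groups are degenerate (zero variance) the p-value is reported as
    a finite sentinel: 1 for equal means, 0 otherwise.
    """
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two repetitions")
    delta = float(b.mean() - a.mean())
    # float-epsilon spread in constant inputs is still degenerate
    tol = 1e-12 * max(1.0, float(np.abs(a).max()), float(np.abs(b).max()))
    if a.std(ddof=1) <= tol and b.std(ddof=1) <= tol:
        t_stat = 0.0 if delta == 0 else np.sign(delta) * np.inf
        p = 1.0 if delta == 0 else 0.0
    else:
        res = _sps.ttest_ind(b, a, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        parameter=name,
        protocol_a=protocol_a,
        protocol_b=protocol_b,
        a_values=tuple(a),
        b_values=tuple(b),
        delta_percent_id=delta,
        t_statistic=t_stat,
        p_value=p,
        alpha=alpha,
    )


def delta_table(
    percent_ids: dict[str, list[float]],
    groups: dict[str, tuple[str, str]] | None = None,
    welch: bool = False,
) -> list[GroupComparison]:
    """All parameter-group contrasts from per-protocol repetition %IDs.

    ``percent_ids`` maps protocol name -> per-repetition %ID values.
    """
    groups = groups or GROUP_DEFINITIONS
    out = []
    for parameter, (pa, pb) in groups.items():
        for p in (pa, pb):
            if p not in percent_ids:
                raise ValueError(f"missing protocol {p!r} for group {parameter!r}")
        out.append(
            group_comparison(
                parameter,
                percent_ids[pa],
                percent_ids[pb],
                protocol_a=pa,
                protocol_b=pb,
                welch=welch,
            )
        )
    return out
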