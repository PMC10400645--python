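"""Angular speed from the unwrapped phase, plus summary and group statistics.

The absolute angular speed between consecutive frames is the forward
difference

    Omega(k) = |alpha(k+1) - alpha(k)| / (2*pi) * fps      [revolutions / s]

with alpha in radians — equivalently ``|delta_deg| / 360 * fps``.  Because the
unwrap step bounds each increment by 90 degrees, Omega is bounded by fps/4.
Group comparisons use a two-sided two-sample t-test (Welch by default; the
pooled-variance variant is available via ``equal_var=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .orientation import PhaseTrack


@dataclass
class SpeedSeries:
    """Per-pair rotation speed Omega(k) >= 0, revolutions per second."""

    omega: np.ndarray
    pair_indices: np.ndarray  # (n, 2) frame pairs (k, k+1)
    fps: float


@dataclass
class SpeedSummary:
    mean: float
    median: float
    q25: float
    q75: float
    sd: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "median": self.median, "q25": self.q25,
                "q75": self.q75, "sd": self.sd, "n": self.n}


@dataclass
class GroupComparison:
    """Welch/pooled two-sample two-sided t-test plus both groups' summaries."""

    summary_a: SpeedSummary
    summary_b: SpeedSummary
    t_statistic: float
    p_value: float
    alpha_level: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_level


def angular_speed(track: PhaseTrack) -> SpeedSeries:
    """Forward-difference speed over consecutive valid frame pairs.

    Pairs spanning missing frames are skipped (no rotation is invented across
    a gap).  Raises when the track is not unwrapped or no valid pair exists.
    """
    if track.alpha_unwrapped is None:
        raise ValueError("track must be unwrapped first (see unwrap_phase)")
    if track.fps <= 0:
        raise ValueError("fps must be > 0")
    u = track.alpha_unwrapped
    valid = ~np.isnan(u)
    pair_ok = valid[:-1] & valid[1:]
    ks = np.flatnonzero(pair_ok)
    if ks.size == 0:
        raise ValueError("no consecutive valid frame pairs; cannot compute speed")
    omega = np.abs(u[ks + 1] - u[ks]) / 360.0 * track.fps
    pairs = np.column_stack([ks, ks + 1])
    return SpeedSeries(omega=omega, pair_indices=pairs, fps=track.fps)


def summarize_speed(series: SpeedSeries) -> SpeedSummary:
    """Mean, median, linear-interpolation quartiles, sample SD (ddof=1), n."""
    om = np.asarray(series.omega, dtype=float)
    if om.size == 0:
        raise ValueError("empty speed series")
    q25, med, q75 = np.percentile(om, [25, 50, 75])  # linear interpolation
    sd = float(om.std(ddof=1)) if om.size > 1 else 0.0
    return SpeedSummary(mean=float(om.mean()), median=float(med),
                        q25=float(q25), q75=float(q75), sd=sd, n=int(om.size))


def compare_groups(
    a: SpeedSeries | np.ndarray,
    b: SpeedSeries | np.ndarray,
    alpha_level: float = 0.05,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test on the Omega values of two groups.

    Welch (unequal variances) by default.  Frames are treated as samples
    within a group, following the box-plot/t-test reading of per-frame speeds;
    see the methods note for the pseudo-replication caveat.
    """
    xa = np.asarray(a.omega if isinstance(a, SpeedSeries) else a, dtype=float)
    xb = np.asarray(b.omega if isinstance(b, SpeedSeries) else b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs n >= 2")
    fps_a = a.fps if isinstance(a, SpeedSeries) else 0.0
    fps_b = b.fps if isinstance(b, SpeedSeries) else 0.0
    res = stats.ttest_ind(xa, xb, equal_var=equal_var)
    sa = summarize_speed(SpeedSeries(xa, np.empty((0, 2)), fps_a))
    sb = summarize_speed(SpeedSeries(xb, np.empty((0, 2)), fps_b))
    return GroupComparison(summary_a=sa, summary_b=sb,
                           t_statistic=float(res.statistic),
                           p_value=float(res.pvalue), alpha_level=alpha_level)


def relative_change(summary_a: SpeedSummary, summary_b: SpeedSummary) -> float:
    """Percent change of mean speed from group a to group b,
    ``100 * (mean_b - mean_a) / mean_a``."""
    if summary_a.mean == 0:
        raise ValueError("relative change undefined: reference mean is 0")
    return 100.0 * (summary_b.mean - summary_a.mean) / summary_a.mean
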