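"""Biological-consistency screening of candidate transfer functions.

A kernel meant to represent neurovascular coupling must respect two
facts about the physiology: the vascular response lags neuronal
activity (the cellular cascades impose a strictly positive onset
delay, so a TF cannot start at 0 s), and the underlying processes are
smooth, so the kernel may contain at most one non-derivable (kink)
point — the onset itself. Candidates violating either rule are rejected
regardless of how well they predict the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .signals import TimeSeries

__all__ = [
    "count_nonderivable_points",
    "is_biologically_consistent",
    "ConsistencyVerdict",
    "DEFAULT_KINK_TOL",
    "ONSET_NOISE_FLOOR",
]

#: Threshold on the normalised second difference above which an interior
#: sample counts as a kink.
DEFAULT_KINK_TOL = 10.0

#: Fraction of the peak absolute value below which early samples are
#: treated as numerically zero when locating the onset.
ONSET_NOISE_FLOOR = 0.01


def count_nonderivable_points(tf: TimeSeries, tol: float = DEFAULT_KINK_TOL) -> int:
    """Count kink points via a normalised discrete second difference.

    An interior sample i is flagged when

        |h[i-1] - 2 h[i] + h[i+1]| / (dt * max|Δh|) > tol.

    For a smooth kernel the numerator scales like ``|h''| dt^2`` and the
    denominator like ``max|h'| dt^2``, so the statistic approaches the
    dt-independent curvature-to-slope ratio and stays small; at a slope
    discontinuity the numerator scales like ``dt``, making the statistic
    blow up as ``1/dt`` on fine grids.
    """
    if len(tf) < 5:
        raise ValueError(
            f"kink detection needs at least 5 samples, got {len(tf)}"
        )
    dt = tf.require_dt()
    h = tf.values
    steps = np.abs(np.diff(h))
    max_step = float(steps.max())
    if max_step == 0.0:
        return 0  # constant kernel: no kinks
    second = np.abs(h[:-2] - 2.0 * h[1:-1] + h[2:])
    metric = second / (dt * max_step)
    return int(np.count_nonzero(metric > tol))


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Outcome of the biological-consistency screen."""

    consistent: bool
    reasons: List[str] = field(default_factory=list)
    n_kinks: int = 0
    onset_delay: Optional[float] = None

    def __bool__(self) -> bool:
        return self.consistent


def is_biologically_consistent(
    tf: TimeSeries,
    onset_delay: Optional[float] = None,
    *,
    kink_tol: float = DEFAULT_KINK_TOL,
    noise_floor: float = ONSET_NOISE_FLOOR,
) -> ConsistencyVerdict:
    """Screen a TF: positive onset delay AND at most one kink point.

    Parameters
    ----------
    tf : TimeSeries
        Candidate kernel on a uniform grid starting at 0.
    onset_delay : float, optional
        Known onset delay in seconds (for the one-Γ family, the time
        shift p3). When omitted, the onset is located from the samples
        as the first time the kernel magnitude exceeds ``noise_floor``
        times its peak.

    Returns
    -------
    ConsistencyVerdict
        Truthy iff consistent; ``reasons`` names each violated rule.
    """
    reasons: List[str] = []

    if onset_delay is None:
        peak = float(np.max(np.abs(tf.values)))
        if peak == 0.0:
            onset_delay = 0.0
        else:
            above = np.flatnonzero(np.abs(tf.values) > noise_floor * peak)
            onset_delay = float(tf.times[above[0]]) if above.size else 0.0
    if not onset_delay > 0.0:
        reasons.append("zero onset delay")

    n_kinks = count_nonderivable_points(tf, tol=kink_tol)
    if n_kinks > 1:
        reasons.append("non-derivable points > 1")

    return ConsistencyVerdict(
        consistent=not reasons,
        reasons=reasons,
        n_kinks=n_kinks,
        onset_delay=onset_delay,
    )
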