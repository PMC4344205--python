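"""Right-continuous survival step curves shared by the Cox and forest models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepCurve"]


@dataclass(frozen=True)
class StepCurve:
    """A survival function S(t) represented as a right-continuous step function.

    ``S(0) = 1``; the curve drops to ``values[i]`` at ``times[i]`` and stays
    there until the next step.  ``times`` must be strictly increasing and
    positive.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size and (t[0] <= 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, t: float) -> float:
        """Evaluate S(t)."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.values[i - 1])

    def area(self, horizon: float) -> float:
        """Exact integral of the step function over [0, horizon].

        Raises ``ValueError`` when the curve is not a valid survival curve
        (increasing anywhere, including above the initial value 1).
        """
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        v = self.values
        if v.size and (v[0] > 1.0 + 1e-12 or np.any(np.diff(v) > 1e-12)):
            raise ValueError("survival curve must be non-increasing from S(0)=1")
        keep = self.times < horizon
        knots = np.concatenate(([0.0], self.times[keep], [horizon]))
        heights = np.concatenate(([1.0], v[keep]))
        return float(np.sum(np.diff(knots) * heights))
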