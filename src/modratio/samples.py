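"""Zero-mean sample matrices.

Observable network components are held as a components-by-samples matrix.
The last component plays the role of the reference component ``s_ref``:
it is excluded from every functional module and appears in the
denominators of all moment ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampleMatrix", "center_samples"]


@dataclass
class SampleMatrix:
    """Centered observations, one row per component, one column per sample.

    Attributes
    ----------
    values : ndarray of shape (d, n_samples)
        Zero-mean observations. Component ``d`` (the last row) is the
        reference component.
    labels : list of str
        Component labels, reference last.
    centered : bool
        True once per-component means have been subtracted.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    centered: bool = False

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def component(self, k: int) -> np.ndarray:
        """Return the samples of 1-based component ``k``."""
        if not 1 <= k <= self.d:
            raise IndexError(f"component index {k} outside 1..{self.d}")
        return self.values[k - 1]

    def rescaled(self, factors: np.ndarray) -> "SampleMatrix":
        """Positively rescale each component (used in invariance checks)."""
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (self.d,) or np.any(factors <= 0):
            raise ValueError("need one positive factor per component")
        return SampleMatrix(self.values * factors[:, None], list(self.labels), self.centered)


def center_samples(raw: np.ndarray, labels: list[str] | None = None) -> SampleMatrix:
    """Normalize raw observations to zero mean per component.

    The estimators pair samples, so an odd trailing sample is dropped
    with a warning. Input is components-by-samples.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D components-by-samples matrix")
    d, n = raw.shape
    if n % 2 == 1:
        warnings.warn("odd sample count: dropping the last sample", stacklevel=2)
        raw = raw[:, :-1]
        n -= 1
    if n < 2:
        raise ValueError("insufficient samples: need at least 2 after pairing")
    values = raw - raw.mean(axis=1, keepdims=True)
    if labels is None:
        labels = [f"s{i}" for i in range(1, d + 1)]
    return SampleMatrix(values=values, labels=list(labels), centered=True)
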