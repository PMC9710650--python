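"""Detection thresholding for group comparisons.

In label-free MS data, proteins drop out preferentially at low abundance —
missingness is not at random.  Before comparing a protein between two
groups it must therefore be *detected* (raw intensity > 0) in a sufficient
number of samples per group.  The required fraction of samples follows a
sigmoidal curve: 100% of samples for groups of up to three, relaxing to
50% for groups of twelve or more, with a smooth logistic interpolation in
between.  Small groups must be fully observed; large groups tolerate
half-missing proteins.

Given the threshold, a protein falls into one of four categories for a
pair of groups A and B:

* ``comparable``  — above threshold in both groups;
* ``unique_in_A`` — above threshold in A and never detected in B;
* ``unique_in_B`` — the mirror case;
* ``not_considered`` — everything else (below threshold in both, or above
  in one group but sporadically detected in the other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class Category(str, Enum):
    COMPARABLE = "comparable"
    UNIQUE_IN_A = "unique_in_A"
    UNIQUE_IN_B = "unique_in_B"
    NOT_CONSIDERED = "not_considered"

    def mirrored(self) -> "Category":
        if self is Category.UNIQUE_IN_A:
            return Category.UNIQUE_IN_B
        if self is Category.UNIQUE_IN_B:
            return Category.UNIQUE_IN_A
        return self


@dataclass(frozen=True)
class ThresholdPolicy:
    """Sigmoidal required-detection-fraction policy.

    Parameters
    ----------
    n_full:
        Largest group size that still requires detection in every sample
        (fraction 1.0).
    n_half:
        Smallest group size for which detection in half the samples
        suffices (fraction 0.5).
    steepness:
        Logistic rate (per sample) of the interpolation between the two
        plateaus; the midpoint sits at ``(n_full + n_half) / 2``.
    """

    n_full: int = 3
    n_half: int = 12
    steepness: float = 1.0

    @property
    def midpoint(self) -> float:
        return (self.n_full + self.n_half) / 2.0

    def required_fraction(self, n: int) -> float:
        """Required fraction of detected samples for a group of size ``n``.

        Equals 1.0 for ``n <= n_full``, 0.5 for ``n >= n_half``, and is
        strictly decreasing in between:
        ``0.5 + 0.5 / (1 + exp(steepness * (n - midpoint)))``.
        """
        if n < 1:
            raise ValueError(f"group size must be >= 1, got {n}")
        if n <= self.n_full:
            return 1.0
        if n >= self.n_half:
            return 0.5
        return 0.5 + 0.5 / (1.0 + math.exp(self.steepness * (n - self.midpoint)))

    def required_count(self, n: int) -> int:
        """Minimum number of detections for a group of size ``n``.

        Rounded up, so the threshold is never met with fewer detections
        than the fraction implies.
        """
        return math.ceil(self.required_fraction(n) * n - 1e-12)

    def above_threshold(self, detections: int, n: int) -> bool:
        if not 0 <= detections <= n:
            raise ValueError(
                f"detections must lie in [0, {n}], got {detections}"
            )
        return detections >= self.required_count(n)


def categorize(
    det_a: int, n_a: int, det_b: int, n_b: int, policy: ThresholdPolicy | None = None
) -> Category:
    """Assign the four-scenario comparison category for one protein.

    ``unique`` demands the protein be *entirely* undetected in the other
    group; a protein above threshold in A but sporadically detected in B
    is ``not_considered``.
    """
    policy = policy or ThresholdPolicy()
    above_a = policy.above_threshold(det_a, n_a)
    above_b = policy.above_threshold(det_b, n_b)
    if above_a and above_b:
        return Category.COMPARABLE
    if above_a and det_b == 0:
        return Category.UNIQUE_IN_A
    if above_b and det_a == 0:
        return Category.UNIQUE_IN_B
    return Category.NOT_CONSIDERED
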