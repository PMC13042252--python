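"""Post-classification inference: simulation-null FDR/q-values and the
confusion-matrix-corrected soft-sweep fraction.

The null distribution is the set of combined sweep probabilities assigned
to truly neutral test simulations.  For a candidate threshold t,

    FDR(t) = min(1, n_windows * (#null >= t) / n_null / max(1, #real >= t))

scales the null exceedance rate up to the number of analyzed genomic
windows (implicitly assuming all windows could be neutral — a
conservative pi0 = 1) and compares it with the number of real windows
reaching t.  Per-candidate q-values follow the Storey construction: the
minimum FDR over all observed candidate thresholds at or below the
candidate's own probability.

The corrected soft-sweep fraction conservatively (a) treats every
expected false discovery as a soft call and (b) removes hard sweeps
misclassified as soft — inflating the observed hard count by the hard
recall to estimate the true number of hard sweeps — while ignoring soft
sweeps misclassified as hard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import ConfusionMatrix


@dataclass
class NullDistribution:
    """Combined sweep probabilities of truly neutral test replicates."""

    sweep_probs: np.ndarray

    def __post_init__(self) -> None:
        self.sweep_probs = np.asarray(self.sweep_probs, dtype=float)
        if self.sweep_probs.size == 0:
            raise ValueError("empty null distribution")
        if np.any(self.sweep_probs < 0) or np.any(self.sweep_probs > 1):
            raise ValueError("null probabilities must be in [0, 1]")

    @property
    def n_null(self) -> int:
        return int(self.sweep_probs.size)


def fdr_at_threshold(
    t: float,
    real_sweep_probs: np.ndarray,
    null: NullDistribution,
    n_windows: int,
) -> float:
    """Estimated false discovery rate among real windows reaching t."""
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    real = np.asarray(real_sweep_probs, dtype=float)
    if n_windows < real.size:
        raise ValueError("n_windows must be >= number of real windows")
    null_rate = float(np.mean(null.sweep_probs >= t))
    expected_false = n_windows * null_rate
    n_called = int(np.sum(real >= t))
    return min(1.0, expected_false / max(1, n_called))


def qvalues(
    candidates: np.ndarray,
    all_real_probs: np.ndarray,
    null: NullDistribution,
    n_windows: int,
) -> np.ndarray:
    """Per-candidate q-values: cumulative-minimum FDR over thresholds.

    ``candidates`` are the combined sweep probabilities of the called
    sweeps (a subset of ``all_real_probs``); each candidate's own
    probability defines a threshold, and its q-value is the smallest FDR
    over candidate thresholds at or below it.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        return np.array([])
    # a candidate with probability p is in the rejection set of every
    # threshold t <= p, so its q is the running minimum of FDR over the
    # candidate thresholds from the smallest probability up to p
    order = np.argsort(candidates)  # increasing probability
    fdrs = np.array(
        [
            fdr_at_threshold(candidates[i], all_real_probs, null, n_windows)
            for i in order
        ]
    )
    cummin = np.minimum.accumulate(fdrs)
    out = np.empty_like(candidates)
    out[order] = cummin
    return out


@dataclass
class SoftFractionEstimate:
    """Conservative estimate of the fraction of sweeps that are soft."""

    raw_hard: int
    raw_soft: int
    expected_false_discoveries: float
    hard_as_soft: float
    corrected_soft_fraction: float

    @property
    def raw_soft_fraction(self) -> float:
        total = self.raw_hard + self.raw_soft
        return self.raw_soft / total if total else 0.0


def corrected_soft_fraction(
    raw_hard: int,
    raw_soft: int,
    q_at_threshold: float,
    confusion: ConfusionMatrix,
) -> SoftFractionEstimate:
    """Correct the observed soft fraction for false discoveries and for
    hard sweeps misclassified as soft.

    FD = q * (raw_hard + raw_soft) expected false discoveries, all
    conservatively assumed soft; the true number of hard sweeps is
    estimated as raw_hard / a with a = P(assigned hard | true hard), and
    a * fraction c = P(assigned soft | true hard) of those leak into the
    soft count.  Soft-to-hard misclassification is deliberately ignored.
    """
    if raw_hard < 0 or raw_soft < 0:
        raise ValueError("raw counts must be nonnegative")
    if not 0 <= q_at_threshold <= 1:
        raise ValueError("q must be in [0, 1]")
    total = raw_hard + raw_soft
    fd = min(q_at_threshold * total, float(raw_soft))
    a = confusion.rate("hard", "hard")
    c = confusion.rate("hard", "soft")
    if raw_hard > 0 and a == 0:
        raise ValueError("hard recall is 0; correction undefined")
    true_hard = raw_hard / a if raw_hard > 0 else 0.0
    hard_as_soft = max(0.0, true_hard * c)
    soft = max(0.0, raw_soft - fd - hard_as_soft)
    denom = total - fd
    frac = soft / denom if denom > 0 else 0.0
    return SoftFractionEstimate(
        raw_hard=raw_hard,
        raw_soft=raw_soft,
        expected_false_discoveries=fd,
        hard_as_soft=hard_as_soft,
        corrected_soft_fraction=float(np.clip(frac, 0.0, 1.0)),
    )
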