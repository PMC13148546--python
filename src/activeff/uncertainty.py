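"""Query-by-committee uncertainty and the adaptive moving-average threshold.

The uncertainty of a geometry is the *maximum per-atom force variance*
across the committee,

    δ = max_i (1/(3M)) Σ_j Σ_{k∈x,y,z} (F_ijk − F̄_ik)²,

with M members j, atoms i and Cartesian components k.  The labeling
threshold is a scaled moving average of past uncertainties,

    δ_t = (1 + c) · mean(last N observed δ values),

shared across all sampling trajectories.  Because the average tracks the
(decreasing) uncertainty stream, some configurations always exceed it, so
sampling never stalls; c < 0 tightens the threshold, c > 0 relaxes it, and
the threshold can be frozen once the training set reaches a given size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .committee import CommitteePrediction


class BootstrapSignal(RuntimeError):
    """Threshold requested before any uncertainty has been observed."""


@dataclass
class UncertaintyRecord:
    """One observed uncertainty with its origin."""

    delta: float
    system_tag: str = ""
    trajectory_id: int = 0
    step: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("uncertainty must be non-negative")


def qbc_force_variance(prediction: CommitteePrediction) -> float:
    """Maximum per-atom force variance across committee members.

    Pure function of the prediction; refuses committees with fewer than two
    members (disagreement is undefined).
    """
    forces = prediction.per_member_forces  # (M, N, 3)
    M = forces.shape[0]
    if M < 2:
        raise ValueError("force variance needs at least 2 committee members")
    dev = forces - prediction.mean_forces[None, :, :]
    per_atom = np.sum(dev**2, axis=(0, 2)) / (3 * M)  # (N,)
    return float(per_atom.max())


@dataclass
class ThresholdState:
    """Ring buffer of recent uncertainties defining the adaptive threshold.

    Parameters
    ----------
    window
        N, the number of past uncertainties averaged (default 400).
    c
        Scale factor; the threshold is (1+c)·mean (default 0).
    freeze_at_train_size
        Once the training set reaches this size the history stops updating
        and the threshold stays constant.
    """

    window: int = 400
    c: float = 0.0
    freeze_at_train_size: int | None = None
    frozen: bool = False
    history: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        self.history = deque(self.history, maxlen=self.window)

    def threshold_value(self) -> float:
        """δ_t = (1+c)·mean(history); raises on an empty history."""
        if not self.history:
            raise BootstrapSignal("no uncertainties observed yet")
        return (1.0 + self.c) * float(np.mean(self.history))

    def observe_and_decide(self, delta: float, current_train_size: int = 0) -> bool:
        """Decide whether to label, then record the observation.

        The candidate is compared against the mean of *past* values (strict
        ``>``); it is appended to the history only after the comparison and
        only while the state is not frozen.  With an empty history the
        decision is unconditionally True (bootstrap).  Every observed δ
        enters the history, labeled or not.
        """
        if delta < 0:
            raise ValueError("uncertainty must be non-negative")
        if not self.history:
            label = True
        else:
            label = delta > self.threshold_value()
        if not self.frozen:
            self.history.append(float(delta))
            if (
                self.freeze_at_train_size is not None
                and current_train_size >= self.freeze_at_train_size
            ):
                self.frozen = True
        return label
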