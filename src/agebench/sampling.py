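"""Randomized "history-future" deployment design.

A deployment instance is a pair (t0, dT): the model is trained on the history
window ending at deployment time t0 and evaluated on a fixed-length test
window starting dT days later.  Both t0 and dT are sampled uniformly, with
buffers at each end of the data range so that every admissible pair yields
fully in-range windows — this is what makes the two marginals independently
uniform.  dT is capped at half the dataset span, and small negative dT values
(train and test sets touching or slightly overlapping) anchor the E_rel ≈ 1
calibration point.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .timeline import TimestampedDataset, TimeWindow

__all__ = [
    "SamplingPlan",
    "DeploymentInstance",
    "InfeasiblePlanError",
    "DataDensityError",
    "build_plan",
    "draw_instances",
]

_SEED_MASK = 0x7FFFFFFF  # instance seeds kept below 2**31


class InfeasiblePlanError(ValueError):
    """The dataset span cannot accommodate the requested windows."""


class DataDensityError(ValueError):
    """Too many draws rejected for sparse training windows."""


@dataclasses.dataclass(frozen=True)
class SamplingPlan:
    """Sampling design for a degradation suite.

    ``t0 ~ Uniform(t0_low, t0_high)`` and ``dT ~ Uniform(dt_min, dt_max)``
    independently; bounds are chosen so all derived windows stay inside the
    dataset span.
    """

    n_experiments: int
    train_span_days: float
    test_span_days: float
    dt_min_days: float
    dt_max_days: float
    t0_low: float
    t0_high: float
    seed: int
    min_train_records: int = 50

    def __post_init__(self) -> None:
        if not self.t0_low < self.t0_high:
            raise InfeasiblePlanError(
                f"t0 bounds collapsed: [{self.t0_low}, {self.t0_high}]"
            )
        if not (self.dt_min_days < 0 <= self.dt_max_days):
            raise InfeasiblePlanError(
                f"need dt_min < 0 <= dt_max, got ({self.dt_min_days}, {self.dt_max_days})"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class DeploymentInstance:
    """One simulated deployment: (t0, dT) plus derived windows.

    * ``train_window``  = [t0 - train_span, t0 - test_span) — fitting data.
    * ``mse0_window``   = [t0 - test_span, t0) — chronological holdout scored
      at training time (MSE0).
    * ``test_window``   = [t0 + dT, t0 + dT + test_span) — future data scored
      dT days after deployment (MSE1).
    """

    t0: float
    dT: float
    train_window: TimeWindow
    mse0_window: TimeWindow
    test_window: TimeWindow
    instance_seed: int


def build_plan(
    ds: TimestampedDataset,
    n_experiments: int = 500,
    train_span_days: float = 365.0,
    test_span_days: float = 30.0,
    dt_min_days: float = -14.0,
    dt_max_days: float | None = None,
    seed: int = 0,
    min_train_records: int = 50,
) -> SamplingPlan:
    """Compute uniform-sampling bounds with buffers and the half-range cap.

    ``dt_max_days`` is clipped to half the dataset span.  Raises
    :class:`InfeasiblePlanError` (reporting the shortfall in days) when the
    span cannot hold a train window, both test windows and the requested dT.
    """
    span = ds.span
    start = float(ds.timestamps[0])
    requested = span / 2.0 if dt_max_days is None else float(dt_max_days)
    dt_max = min(requested, span / 2.0)

    required = train_span_days + test_span_days + dt_max + test_span_days
    if required > span:
        raise InfeasiblePlanError(
            f"dataset span {span:.1f} d is {required - span:.1f} d short of the "
            f"{required:.1f} d needed for train {train_span_days} + test {test_span_days} "
            f"+ dt_max {dt_max} + test {test_span_days}"
        )
    t0_low = start + train_span_days
    t0_high = start + span - dt_max - test_span_days
    return SamplingPlan(
        n_experiments=n_experiments,
        train_span_days=float(train_span_days),
        test_span_days=float(test_span_days),
        dt_min_days=float(dt_min_days),
        dt_max_days=float(dt_max),
        t0_low=float(t0_low),
        t0_high=float(t0_high),
        seed=int(seed),
        min_train_records=int(min_train_records),
    )


def _make_instance(plan: SamplingPlan, t0: float, dT: float, index: int) -> DeploymentInstance:
    return DeploymentInstance(
        t0=t0,
        dT=dT,
        train_window=TimeWindow(t0 - plan.train_span_days, t0 - plan.test_span_days),
        mse0_window=TimeWindow(t0 - plan.test_span_days, t0),
        test_window=TimeWindow(t0 + dT, t0 + dT + plan.test_span_days),
        instance_seed=(plan.seed ^ index) & _SEED_MASK,
    )


def draw_instances(
    plan: SamplingPlan,
    ds: TimestampedDataset,
    max_rejection_rate: float = 0.20,
) -> list[DeploymentInstance]:
    """Draw exactly ``plan.n_experiments`` deployment instances.

    (t0, dT) pairs are drawn independently uniform; a draw whose train window
    holds fewer than ``plan.min_train_records`` records is rejected and
    redrawn so the instance count stays exact.  Deterministic given
    ``plan.seed``; per-instance seeds are ``seed XOR index``.
    """
    rng = np.random.default_rng(plan.seed)
    n = plan.n_experiments
    accepted: list[DeploymentInstance] = []
    rejected = 0
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max(100, 50 * n):
            raise DataDensityError(
                f"gave up after {attempts} draws with {rejected} rejections"
            )
        t0 = float(rng.uniform(plan.t0_low, plan.t0_high))
        dT = float(rng.uniform(plan.dt_min_days, plan.dt_max_days))
        inst = _make_instance(plan, t0, dT, len(accepted))
        if ds.window_record_count(inst.train_window) < plan.min_train_records:
            rejected += 1
            continue
        accepted.append(inst)
    if rejected / (rejected + n) > max_rejection_rate:
        raise DataDensityError(
            f"rejection rate {rejected / (rejected + n):.1%} exceeds "
            f"{max_rejection_rate:.0%}: dataset too sparse for the plan"
        )
    return accepted
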