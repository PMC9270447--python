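"""Execute deployment simulations and collect (t0, dT, MSE0, MSE1, E_rel).

For each deployment instance the model is fit on the history window ending
just before t0, scored on a chronological holdout at training time (MSE0) and
on the future window dT days later (MSE1).  The relative error

    E_rel(dT) = MSE(t0 + dT) / MSE(t0)

is ≈ 1 for a model that still matches its environment and grows as the model
ages.  A suite runs many instances sorted by t0, refreshing hyperparameters
once per contiguous t0 batch (default: every 100 experiments) with
chronological grid-search tuning anchored at the batch's median-t0 instance.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .models import HyperparamSet, ModelFamily, TuningError, fit_regressor, score_mse, tune_hyperparameters
from .sampling import DeploymentInstance, SamplingPlan, draw_instances
from .timeline import TimestampedDataset, validate_dataset, slice_window

__all__ = [
    "ExperimentResult",
    "AgingResult",
    "DegenerateBaselineError",
    "run_instance",
    "run_suite",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["t0", "dT", "mse0", "mse1", "e_rel", "hyperparam_batch", "converged"]


class DegenerateBaselineError(RuntimeError):
    """MSE0 = 0 on the training-time holdout; E_rel undefined."""


@dataclasses.dataclass(frozen=True)
class ExperimentResult:
    """Outcome of one deployment simulation."""

    t0: float
    dT: float
    mse0: float
    mse1: float
    e_rel: float
    hyperparam_batch: int = -1
    converged: bool = True

    def __post_init__(self) -> None:
        if self.mse0 <= 0:
            raise DegenerateBaselineError(f"mse0 must be positive, got {self.mse0}")
        if not np.isfinite(self.e_rel):
            raise ValueError("e_rel must be finite")


@dataclasses.dataclass
class AgingResult:
    """All experiment results of one (dataset, family) suite."""

    dataset_name: str
    family: str
    plan: SamplingPlan
    results: list[ExperimentResult]
    provenance: dict = dataclasses.field(default_factory=dict)
    n_degenerate: int = 0

    @property
    def dT(self) -> np.ndarray:
        return np.array([r.dT for r in self.results])

    @property
    def e_rel(self) -> np.ndarray:
        return np.array([r.e_rel for r in self.results])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.results], columns=RESULT_COLUMNS)


def run_instance(
    ds: TimestampedDataset,
    instance: DeploymentInstance,
    family: str | ModelFamily,
    hyperparams: HyperparamSet,
    hyperparam_batch: int = -1,
) -> ExperimentResult:
    """Fit on the train window; score MSE0 (training-time holdout) and MSE1 (future)."""
    code = family.code if isinstance(family, ModelFamily) else family
    train = slice_window(ds, instance.train_window)
    holdout = slice_window(ds, instance.mse0_window)
    future = slice_window(ds, instance.test_window)
    model = fit_regressor(code, hyperparams, train, seed=instance.instance_seed)
    mse0 = score_mse(model, holdout)
    if mse0 == 0.0:
        raise DegenerateBaselineError(
            f"perfect fit on the holdout at t0={instance.t0:.1f}; E_rel undefined"
        )
    mse1 = score_mse(model, future)
    return ExperimentResult(
        t0=instance.t0,
        dT=instance.dT,
        mse0=mse0,
        mse1=mse1,
        e_rel=mse1 / mse0,
        hyperparam_batch=hyperparam_batch,
        converged=model.converged,
    )


def run_suite(
    ds: TimestampedDataset,
    plan: SamplingPlan,
    family: str | ModelFamily,
    batch_size: int = 100,
    tuning_folds: int = 5,
    validate: bool = True,
    min_span_days: float = 730.0,
    provenance: dict | None = None,
) -> AgingResult:
    """Run the full degradation suite with periodic hyperparameter refresh.

    Instances are sorted by t0 and partitioned into ⌈N / batch_size⌉
    contiguous batches; hyperparameters are re-tuned once per batch on the
    training window of the batch's median-t0 instance, then reused within the
    batch.  A batch whose tuning fails falls back to the previous batch's
    hyperparameters with a warning.  Degenerate (MSE0 = 0) instances are
    excluded and counted; if they exceed 1% a suite warning is emitted.
    Deterministic given ``plan.seed``.
    """
    fam = family if isinstance(family, ModelFamily) else ModelFamily(code=family)
    if validate:
        report = validate_dataset(ds, min_span_days=min_span_days)
        if not report.passed:
            raise ValueError(
                f"dataset '{ds.name}' fails validation: span {report.span_days:.0f} d "
                f"(min {min_span_days:.0f}), {report.missing_count} missing values"
            )

    instances = sorted(draw_instances(plan, ds), key=lambda i: i.t0)
    results: list[ExperimentResult] = []
    n_degenerate = 0
    hps: HyperparamSet | None = None
    n_batches = int(np.ceil(len(instances) / batch_size))
    for b in range(n_batches):
        batch = instances[b * batch_size : (b + 1) * batch_size]
        anchor = batch[len(batch) // 2]  # median-t0 instance of the contiguous batch
        tune_seed = (plan.seed ^ (0x5EED + b)) & 0x7FFFFFFF
        try:
            hps = tune_hyperparameters(
                fam, slice_window(ds, anchor.train_window), folds=tuning_folds, seed=tune_seed
            )
        except TuningError as exc:
            if hps is None:
                raise
            warnings.warn(f"tuning failed for batch {b} ({exc}); reusing previous hyperparameters")
        logger.info("batch %d/%d: hyperparams %s", b + 1, n_batches, dict(hps.values))
        for inst in batch:
            try:
                results.append(run_instance(ds, inst, fam, hps, hyperparam_batch=b))
            except DegenerateBaselineError:
                n_degenerate += 1
    if n_degenerate > 0.01 * plan.n_experiments:
        warnings.warn(
            f"{n_degenerate} degenerate-baseline instances excluded "
            f"(> 1% of {plan.n_experiments})"
        )
    prov = {"seed": plan.seed, "family": fam.code, "n_batches": n_batches}
    if provenance:
        prov.update(provenance)
    return AgingResult(
        dataset_name=ds.name,
        family=fam.code,
        plan=plan,
        results=results,
        provenance=prov,
        n_degenerate=n_degenerate,
    )
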