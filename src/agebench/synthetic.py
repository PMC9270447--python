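"""Synthetic timestamped regression scenarios with controlled temporal structure.

Each scenario emulates a multi-year, multi-record-per-day operational series
(the kind produced by hospital operations, weather stations, airport traffic
or market closes) in which the features themselves are stationary — all
temporal structure flows through the coefficients, an unobserved seasonal
driver, or the noise process.  That isolates model aging in the absence of
feature drift, the regime where degradation is hardest to anticipate.

Scenario kinds and the aging behavior they are built to induce:

* ``stationary``        — fixed coefficients, homoscedastic noise → stable E_rel ≈ 1.
* ``coefficient_drift`` — β(t) drifts linearly → gradual (at most linear) E_rel growth.
* ``seasonal_latent``   — an unobserved sinusoidal term in the target → periodic E_rel.
* ``regime_switch``     — β flips at a switch day → explosive degradation and
  feature-importance sign flips.
* ``variance_growth``   — episodic noise-variance bursts whose probability
  grows with time → stable median E_rel with a widening percentile gap
  (increasing unpredictability).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .timeline import TimestampedDataset

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioConfig",
    "ScenarioTruth",
    "generate_scenario",
    "expected_pattern",
    "noise_sd_for_r2",
]

SCENARIO_KINDS = (
    "stationary",
    "coefficient_drift",
    "seasonal_latent",
    "regime_switch",
    "variance_growth",
)

_DEFAULT_BETA = (2.0, 1.0, 0.5, 0.0, 0.0)


def noise_sd_for_r2(coefficients: Sequence[float], r2: float) -> float:
    """Noise SD giving analytic R² = Var(βx) / (Var(βx) + σ²) for i.i.d. N(0,1) features."""
    signal = float(np.sum(np.square(coefficients)))
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return float(np.sqrt(signal * (1.0 - r2) / r2))


@dataclasses.dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults describe a five-year series with five records per day and a
    signal-to-total variance ratio of 0.8 (cross-validated R² ≈ 0.8, the
    middle of the realistic deployment-quality band).  Rate parameters are
    per day; ``switch_day`` defaults to mid-span.
    """

    kind: str = "stationary"
    span_days: int = 1825
    records_per_day: int = 5
    n_features: int = 5
    base_coefficients: tuple[float, ...] | None = None
    noise_sd: float | None = None
    drift_rate: float = 8e-4
    season_period_days: float = 365.0
    season_amplitude: float | None = None
    switch_day: float | None = None
    post_switch_coefficients: tuple[float, ...] | None = None
    variance_growth_rate: float = 6e-4
    variance_onset_day: float | None = None
    episode_days: float = 30.0
    episode_sd_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}")
        if self.span_days < 730:
            raise ValueError(f"span_days must be >= 730, got {self.span_days}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.base_coefficients is None:
            beta = list(_DEFAULT_BETA)[: self.n_features]
            beta += [0.0] * (self.n_features - len(beta))
            self.base_coefficients = tuple(beta)
        else:
            self.base_coefficients = tuple(float(b) for b in self.base_coefficients)
            if len(self.base_coefficients) != self.n_features:
                raise ValueError("base_coefficients length must equal n_features")
        if self.noise_sd is None:
            self.noise_sd = noise_sd_for_r2(self.base_coefficients, 0.8)
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.season_amplitude is None:
            self.season_amplitude = 3.0 * self.noise_sd
        if self.switch_day is None:
            self.switch_day = self.span_days / 2.0
        if not 0 < self.switch_day < self.span_days:
            raise ValueError(f"switch_day must fall inside the span, got {self.switch_day}")
        if self.variance_onset_day is None:
            self.variance_onset_day = self.span_days / 2.0
        if self.post_switch_coefficients is None:
            self.post_switch_coefficients = tuple(-b for b in self.base_coefficients)
        else:
            self.post_switch_coefficients = tuple(float(b) for b in self.post_switch_coefficients)
            if len(self.post_switch_coefficients) != self.n_features:
                raise ValueError("post_switch_coefficients length must equal n_features")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class ScenarioTruth:
    """What the bench should recover from a scenario, by construction."""

    expected_pattern: str
    expected_period_days: float | None
    expected_importance_change: bool


def _episode_mask(t: np.ndarray, cfg: "ScenarioConfig", rng: np.random.Generator) -> np.ndarray:
    """Per-record indicator of high-volatility episodes.

    Time is cut into ``episode_days`` slots; slot s bursts with target rate
    min(0.25, variance_growth_rate × days past the onset), zero before
    ``variance_onset_day``.  Bursts are absent early, then increasingly
    frequent — but capped at a quarter of slots, so the median noise level
    (and hence the median E_rel) stays stable while the spread of
    window-level error ratios widens with model age.  Bursts are placed by
    systematic (cumulative-rate) sampling with a seeded random phase, so the
    realized burst count tracks the intended schedule in every realization
    instead of fluctuating binomially.
    """
    n_slots = int(np.ceil(cfg.span_days / cfg.episode_days)) + 1
    centers = (np.arange(n_slots) + 0.5) * cfg.episode_days
    p = np.clip(cfg.variance_growth_rate * (centers - cfg.variance_onset_day), 0.0, 0.25)
    cum = np.cumsum(p) + rng.uniform(0.0, 1.0)
    burst = np.diff(np.floor(np.concatenate([[cum[0] - p[0]], cum]))) >= 1
    return burst[(t / cfg.episode_days).astype(int)]


def generate_scenario(cfg: ScenarioConfig) -> TimestampedDataset:
    """Generate a :class:`TimestampedDataset` for the configured scenario.

    Features are i.i.d. standard normal per record; timestamps are
    day + uniform intra-day jitter (sorted).  The target is

        y(t) = β(t)·x + s(t) + ε(t)

    with β(t) constant / drifting / stepping per ``kind``, s(t) an
    *unobserved* sinusoid (never added to the feature matrix), and ε(t)
    homoscedastic Gaussian noise except under ``variance_growth``, where the
    noise SD is multiplied by ``episode_sd_multiplier`` during high-volatility
    episodes whose probability grows linearly with time (so the expected noise
    variance grows ≈ linearly).  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.span_days * cfg.records_per_day
    t = np.sort(np.repeat(np.arange(cfg.span_days, dtype=float), cfg.records_per_day) + rng.uniform(0, 1, n))
    X = rng.standard_normal((n, cfg.n_features))

    beta = np.tile(np.asarray(cfg.base_coefficients), (n, 1))
    if cfg.kind == "coefficient_drift":
        beta = beta + cfg.drift_rate * t[:, None]
    elif cfg.kind == "regime_switch":
        beta[t >= cfg.switch_day] = np.asarray(cfg.post_switch_coefficients)

    season = np.zeros(n)
    if cfg.kind == "seasonal_latent":
        season = cfg.season_amplitude * np.sin(2 * np.pi * t / cfg.season_period_days)

    if cfg.kind == "variance_growth":
        burst = _episode_mask(t, cfg, rng)
        sd = cfg.noise_sd * np.where(burst, cfg.episode_sd_multiplier, 1.0)
    else:
        sd = np.full(n, cfg.noise_sd)
    eps = rng.standard_normal(n) * sd

    y = np.sum(beta * X, axis=1) + season + eps
    names = [f"x{i + 1}" for i in range(cfg.n_features)]
    return TimestampedDataset(
        name=f"synthetic_{cfg.kind}", timestamps=t, features=X, feature_names=names, target=y
    )


def expected_pattern(cfg: ScenarioConfig) -> ScenarioTruth:
    """Map a scenario kind to the degradation behavior it was built to show."""
    mapping = {
        "stationary": "stable",
        "coefficient_drift": "gradual",
        "seasonal_latent": "stable",
        "regime_switch": "explosive",
        "variance_growth": "variability_growth",
    }
    return ScenarioTruth(
        expected_pattern=mapping[cfg.kind],
        expected_period_days=cfg.season_period_days if cfg.kind == "seasonal_latent" else None,
        expected_importance_change=cfg.kind in ("coefficient_drift", "regime_switch"),
    )
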