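"""Whole-body retention kinetics from timed exposure-rate readings.

The external dose rate at 1 m is taken as proportional to the retained
whole-body activity, so the ratio of two timed readings gives the effective
clearance directly.  A single exponential R(t) = exp(-λt), normalised to
R(0) = 1 at administration, is assumed over the whole interval; the
residence time is then τ = 1/λ = -t / ln R(t).

Readings are assumed background-corrected upstream; no ambient dose-rate
subtraction is applied here.  The customary measurement times are 2 h and
67 h post-administration (a 65-h window), but any two distinct times are
accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NonPhysicalClearanceError",
    "ExposureReading",
    "RetentionModel",
    "fit_two_point_retention",
    "residence_time_from_fraction",
    "retention_at",
    "predict_exposure_rate",
    "time_to_threshold",
]


class NonPhysicalClearanceError(ValueError):
    """Raised when paired readings imply zero or negative clearance."""


@dataclass(frozen=True)
class ExposureReading:
    """One exposure-rate measurement at 1 m, μSv/h, at ``time_h`` hours
    post-administration."""

    time_h: float
    rate_usv_h: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h!r}")
        if not self.rate_usv_h > 0:
            raise ValueError(f"rate_usv_h must be > 0, got {self.rate_usv_h!r}")


@dataclass(frozen=True)
class RetentionModel:
    """Mono-exponential whole-body retention with an anchor reading.

    ``lambda_eff_per_h`` is the effective decay constant (physical decay plus
    biological clearance); the anchor (``t_ref_h``, ``x_ref_usv_h``) pins the
    exposure-rate scale for prediction.
    """

    lambda_eff_per_h: float
    t_ref_h: float = 0.0
    x_ref_usv_h: float = 1.0

    def __post_init__(self) -> None:
        if not self.lambda_eff_per_h > 0:
            raise ValueError(
                f"lambda_eff_per_h must be > 0, got {self.lambda_eff_per_h!r}"
            )
        if self.t_ref_h < 0 or not self.x_ref_usv_h > 0:
            raise ValueError("anchor reading must have t_ref_h >= 0, x_ref_usv_h > 0")

    @property
    def tau_h(self) -> float:
        """Residence time τ = 1/λ (integral of the retention fraction)."""
        return 1.0 / self.lambda_eff_per_h

    @property
    def half_life_h(self) -> float:
        return math.log(2.0) / self.lambda_eff_per_h


def fit_two_point_retention(
    first: ExposureReading, second: ExposureReading
) -> RetentionModel:
    """Fit λ from two timed readings: λ = ln(X₁/X₂) / (t₂ − t₁).

    The first (earlier) reading becomes the prediction anchor.  Raises
    :class:`NonPhysicalClearanceError` if the later reading is not strictly
    lower, and ``ValueError`` on a degenerate (non-increasing-time) interval.
    """
    dt = second.time_h - first.time_h
    if dt <= 0:
        raise ValueError(
            f"second reading must be later than the first (Δt = {dt!r} h)"
        )
    if second.rate_usv_h >= first.rate_usv_h:
        raise NonPhysicalClearanceError(
            "exposure rate did not decrease between readings "
            f"({first.rate_usv_h!r} -> {second.rate_usv_h!r} μSv/h)"
        )
    lam = math.log(first.rate_usv_h / second.rate_usv_h) / dt
    return RetentionModel(
        lambda_eff_per_h=lam, t_ref_h=first.time_h, x_ref_usv_h=first.rate_usv_h
    )


def residence_time_from_fraction(t_h: float, fraction_retained: float) -> float:
    """Residence time τ = −t / ln R(t) from a single retained fraction."""
    if not t_h > 0:
        raise ValueError(f"t_h must be > 0, got {t_h!r}")
    if not 0.0 < fraction_retained < 1.0:
        raise ValueError(
            f"fraction_retained must lie in (0, 1), got {fraction_retained!r}"
        )
    return -t_h / math.log(fraction_retained)


def retention_at(model: RetentionModel, t_h: float) -> float:
    """Retained fraction R(t) = exp(−λt); R(0) = 1."""
    if t_h < 0:
        raise ValueError(f"t_h must be >= 0, got {t_h!r}")
    return math.exp(-model.lambda_eff_per_h * t_h)


def predict_exposure_rate(model: RetentionModel, t_h: float) -> float:
    """Exposure rate at 1 m at time t: X(t) = X_ref · exp(−λ(t − t_ref))."""
    if t_h < 0:
        raise ValueError(f"t_h must be >= 0, got {t_h!r}")
    return model.x_ref_usv_h * math.exp(-model.lambda_eff_per_h * (t_h - model.t_ref_h))


def time_to_threshold(model: RetentionModel, threshold_usv_h: float) -> float:
    """Earliest time at which the predicted rate falls to ``threshold_usv_h``.

    Used for ward-discharge planning (e.g. the 30 μSv/h-at-1-m criterion).
    If the anchor is already at or below the threshold, the anchor time is
    returned.
    """
    if not threshold_usv_h > 0:
        raise ValueError(f"threshold must be > 0, got {threshold_usv_h!r}")
    if threshold_usv_h >= model.x_ref_usv_h:
        return model.t_ref_h
    return model.t_ref_h + math.log(model.x_ref_usv_h / threshold_usv_h) / (
        model.lambda_eff_per_h
    )
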