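"""Model-vs-experiment curve agreement: correlation and residual spread.

A model-predicted curve f and a reference curve g (the pointwise mean across
experimental trials) on the 100-point normalized gait cycle are compared by
the Pearson correlation coefficient

    r = Σ(f_i − f̄)(g_i − ḡ) / √(Σ(f_i − f̄)² Σ(g_i − ḡ)²)

and the standard deviation of residuals

    σ_e = √( [n Σd_i² − (Σd_i)²] / [n(n−1)] ),   d_i = f_i − g_i,

which equals the sample standard deviation of the residual series and is
therefore insensitive to a constant offset.  σ_e is evaluated in the
numerically stable two-pass form (the one-pass expression above is
algebraically identical but cancellation-prone).  A joint's curve is deemed
valid when r ≥ 0.80 and σ_e ≤ 20% of the peak reference value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_THRESHOLD = 0.80
SIGMA_FRACTION = 0.20


class ValidationError(ValueError):
    pass


@dataclass
class CurvePair:
    """A model series and its reference series on a common cycle grid."""

    model: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.model = np.asarray(self.model, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.model.shape != self.reference.shape or self.model.ndim != 1:
            raise ValidationError("series must be 1-D and of equal length")
        if len(self.model) < 3:
            raise ValidationError("need at least 3 points")
        if not (np.all(np.isfinite(self.model)) and np.all(np.isfinite(self.reference))):
            raise ValidationError("series must be finite")

    @property
    def n(self) -> int:
        return len(self.model)

    @property
    def peak_reference(self) -> float:
        return float(np.max(np.abs(self.reference)))


def correlation_coefficient(pair: CurvePair) -> float:
    """Pearson r between the model and reference series."""
    f = pair.model - pair.model.mean()
    g = pair.reference - pair.reference.mean()
    denom = np.sqrt(np.sum(f**2) * np.sum(g**2))
    if denom < 1e-300:
        raise ValidationError("undefined correlation: a series has zero variance")
    return float(np.sum(f * g) / denom)


def std_residuals(pair: CurvePair) -> float:
    """Sample standard deviation of the pointwise residuals f − g."""
    if pair.n < 2:
        raise ValidationError("need at least 2 points")
    d = pair.model - pair.reference
    return float(np.std(d, ddof=1))


def reference_mean(trials: np.ndarray) -> np.ndarray:
    """Pointwise mean across trials (trials × points) → reference series."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    return trials.mean(axis=0)


@dataclass
class ValidationResult:
    """Agreement metrics and pass/fail against the validity thresholds."""

    name: str
    r: float
    sigma_e: float
    peak_reference: float
    r_threshold: float = R_THRESHOLD
    sigma_fraction: float = SIGMA_FRACTION

    @property
    def sigma_threshold(self) -> float:
        return self.sigma_fraction * self.peak_reference

    @property
    def passes_r(self) -> bool:
        return self.r >= self.r_threshold

    @property
    def passes_sigma(self) -> bool:
        return self.sigma_e <= self.sigma_threshold

    @property
    def passes(self) -> bool:
        return self.passes_r and self.passes_sigma

    def describe(self) -> str:
        return (
            f"{self.name}: r = {self.r:.2f} (threshold {self.r_threshold:.2f}), "
            f"sigma_e = {self.sigma_e:.1f} "
            f"(where {self.sigma_fraction:.0%} of peak reference value = "
            f"{self.sigma_threshold:.1f}) -> {'PASS' if self.passes else 'FAIL'}"
        )


def validity_check(pair: CurvePair, name: str = "curve",
                   peak_reference: float | None = None) -> ValidationResult:
    """Compute r and σ_e for a curve pair and apply the validity rule."""
    return ValidationResult(
        name=name,
        r=correlation_coefficient(pair),
        sigma_e=std_residuals(pair),
        peak_reference=pair.peak_reference if peak_reference is None else peak_reference,
    )


def validation_report(results: list[ValidationResult]) -> str:
    """Human-readable text block listing each joint's metrics and verdict."""
    lines = ["Kinematic validation report", "-" * 27]
    lines += [res.describe() for res in results]
    verdict = "ALL PASS" if all(r.passes for r in results) else "FAILURES PRESENT"
    lines.append(f"Overall: {verdict}")
    return "\n".join(lines)
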