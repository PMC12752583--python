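"""Absolute modulus scale recovery from the applied boundary force.

Phase 1 returns modulus, stress and strain on a *relative* scale: the
equilibrium equations are invariant to jointly rescaling modulus and stress.
Given the total force F applied to the loaded edge, the scale factor is

    c_hat = F / (sum_i sigma_xx(x_b, y_i) * h)

where the sum runs over the stress-grid column adjacent to the loaded edge
(rectangle-rule quadrature; trapezoid available).  The calibrated modulus is
``c_hat * E_hat`` pointwise; Poisson's ratio is untouched.

The boundary column is cell-centered, offset t/2 inward from the physical
edge; all of its (ny - 1) samples enter the quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .field_model import DomainError, ElasticityField
from .phase1_training import Phase1Result

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "boundary_stress_profile",
    "calibrate_scale",
    "apply_calibration",
    "calibrate",
]


class CalibrationError(RuntimeError):
    """Raised when the boundary stress integrates to a non-positive force."""


@dataclass
class CalibrationResult:
    """Scale factor and the absolute-scale elasticity field."""

    c_hat: float
    E_absolute: ElasticityField
    boundary_force_check: float
    Ec: float

    def __post_init__(self) -> None:
        if not self.c_hat > 0:
            raise CalibrationError(f"scale factor must be positive, got {self.c_hat}")


def boundary_stress_profile(result: Phase1Result, side: str = "right") -> np.ndarray:
    """Predicted sigma_xx sampled along the loaded boundary.

    Uses the outermost column of the predicted stress field (from the strain
    and elasticity networks through the constitutive relation), the boundary
    normal being (1, 0) for the right edge.  Requesting a side other than the
    loaded one is an error.
    """
    if side != result.loaded_side:
        raise ValueError(
            f"requested side {side!r} but the load was applied on "
            f"{result.loaded_side!r}"
        )
    return np.asarray(result.stress.sxx[:, -1], dtype=float)


def calibrate_scale(
    profile: np.ndarray, F: float, h: float, rule: str = "rectangle"
) -> float:
    """Scale factor c_hat = F / integral(sigma_xx dh) along the boundary."""
    if not F > 0:
        raise DomainError("applied force F must be positive")
    profile = np.asarray(profile, dtype=float)
    if rule == "rectangle":
        integral = float(profile.sum() * h)
    elif rule == "trapezoid":
        integral = float(np.trapezoid(profile, dx=h))
    else:
        raise ValueError(f"unknown quadrature rule {rule!r}")
    if integral <= 0:
        raise CalibrationError(
            f"boundary stress integrates to {integral} <= 0; the predicted "
            "stress is sign-inconsistent with the applied force"
        )
    return F / integral


def apply_calibration(result: Phase1Result, c_hat: float) -> CalibrationResult:
    """Scale the relative modulus (and stress) to absolute units."""
    if not c_hat > 0:
        raise CalibrationError(f"c_hat must be positive, got {c_hat}")
    E_abs = ElasticityField(E=c_hat * result.elast.E, nu=result.elast.nu.copy())
    profile = boundary_stress_profile(result, result.loaded_side)
    check = float(c_hat * profile.sum() * result.grid.h)
    return CalibrationResult(
        c_hat=float(c_hat), E_absolute=E_abs, boundary_force_check=check,
        Ec=result.Ec,
    )


def calibrate(
    result: Phase1Result, F: float, side: str = "right", rule: str = "rectangle"
) -> CalibrationResult:
    """Convenience: profile extraction, scale estimation and application."""
    profile = boundary_stress_profile(result, side)
    c_hat = calibrate_scale(profile, F, result.grid.h, rule=rule)
    return apply_calibration(result, c_hat)
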