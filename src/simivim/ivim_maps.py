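"""Voxel-wise simplified-IVIM parameter mapping from 3-b-value DWI.

The simplified intravoxel-incoherent-motion (IVIM) approach estimates the
tissue diffusion coefficient D', the perfusion fraction f' and the
conventional apparent diffusion coefficient (ADC) from just three
diffusion weightings (b = 0, 50, 800 s/mm^2) by explicit algebra instead
of a nonlinear biexponential fit:

    D'  = [ln S(b50) - ln S(b800)] / (b800 - b50)
    f'  = 1 - S(b50)/S(b0) * exp(D' * b50)
    ADC = [ln S(b0) - ln S(b800)] / (b800 - b0)

D' is the mono-exponential decay rate between the two higher b values,
where capillary pseudodiffusion is largely suppressed; f' is the relative
signal excess at b = 0 over the diffusion decay extrapolated back from
b = 50. All quantities are kept in SI-like internal units (mm^2/s for
D'/ADC, unitless fraction for f'); the conventional 1e-6 / 1e-3 display
scalings are applied only at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DWIStack",
    "ParameterMap",
    "MissingBValueError",
    "REQUIRED_B_VALUES",
    "DISPLAY_SCALE",
    "compute_dprime",
    "compute_fprime",
    "compute_adc",
    "compute_all",
]

#: b values (s/mm^2) required for simplified-IVIM mapping. Extra b values
#: in a stack (e.g. 250) are carried along but ignored by the estimators.
REQUIRED_B_VALUES = (0.0, 50.0, 800.0)

#: Multiplicative factors applied when reporting values externally:
#: D'/ADC are conventionally printed in 1e-6 mm^2/s, f' in 1e-3.
DISPLAY_SCALE = {"Dprime": 1e6, "ADC": 1e6, "fprime": 1e3}


class MissingBValueError(KeyError):
    """A b value required by an estimator is absent from the stack."""


@dataclass
class DWIStack:
    """Co-registered DWI volumes indexed by b value.

    Parameters
    ----------
    b_values
        Strictly increasing acquisition b values in s/mm^2.
    volumes
        One scalar volume per b value, all sharing a grid.
    spacing
        Voxel spacing (mm) per axis; display metadata only.
    """

    b_values: tuple[float, ...]
    volumes: Mapping[float, np.ndarray]
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b_values = tuple(float(b) for b in self.b_values)
        if list(self.b_values) != sorted(set(self.b_values)):
            raise ValueError("b_values must be strictly increasing")
        self.volumes = {float(b): np.asarray(v, dtype=np.float64) for b, v in self.volumes.items()}
        if set(self.volumes) != set(self.b_values):
            raise ValueError("volumes keys must match b_values")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"volumes must share one grid, got shapes {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape

    def get(self, b: float) -> np.ndarray:
        try:
            return self.volumes[float(b)]
        except KeyError:
            raise MissingBValueError(f"stack has b values {self.b_values}, not b={b}") from None

    def require(self, b_values: Iterable[float]) -> None:
        missing = [b for b in b_values if float(b) not in self.volumes]
        if missing:
            raise MissingBValueError(
                f"mapping requires b values {tuple(missing)}; stack has {self.b_values}"
            )


@dataclass
class ParameterMap:
    """One voxel-wise scalar map (D', f' or ADC) with a validity mask.

    ``values`` holds raw internal-unit estimates; voxels where the estimate
    is undefined (non-positive signal in a log term) carry ``valid=False``
    and an unspecified value. Estimates are deliberately not clamped or
    clipped: flooring a non-positive signal would fabricate a diffusion
    value, and clipping f' to [0, 1] would bias ROI means under noise.
    """

    kind: str  # {"Dprime", "fprime", "ADC"}
    values: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.kind not in DISPLAY_SCALE:
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a grid")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid voxels must hold finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def display_values(self) -> np.ndarray:
        """Values on the conventional reporting scale (1e-6 / 1e-3 units)."""
        return self.values * DISPLAY_SCALE[self.kind]

    def n_invalid(self) -> int:
        return int((~self.valid).sum())


def _log_ratio_rate(s_num: np.ndarray, s_den: np.ndarray, delta_b: float) -> tuple[np.ndarray, np.ndarray]:
    """[ln s_num - ln s_den] / delta_b with validity where both signals > 0."""
    valid = (s_num > 0) & (s_den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (np.log(s_num) - np.log(s_den)) / delta_b
    values = np.where(valid, values, np.nan)
    return values, valid


def compute_dprime(stack: DWIStack, b_low: float = 50.0, b_high: float = 800.0) -> ParameterMap:
    """Estimated diffusion coefficient D' from the b50/b800 signal ratio.

    Voxels with a non-positive signal at either b value are marked invalid
    rather than clamped.
    """
    stack.require((b_low, b_high))
    values, valid = _log_ratio_rate(stack.get(b_low), stack.get(b_high), b_high - b_low)
    return ParameterMap("Dprime", values, valid, stack.spacing)


def compute_fprime(stack: DWIStack, dprime: ParameterMap | None = None,
                   b_low: float = 50.0) -> ParameterMap:
    """Estimated perfusion fraction f' = 1 - S(b50)/S(b0) * exp(D' * b50).

    The raw estimate is retained even when negative (possible under noise);
    validity only reflects log-domain/grid problems, never the sign.
    """
    stack.require((0.0, b_low))
    if dprime is None:
        dprime = compute_dprime(stack, b_low=b_low)
    if dprime.shape != stack.shape:
        raise ValueError("dprime grid does not match the stack")
    s0 = stack.get(0.0)
    s_low = stack.get(b_low)
    valid = (s0 > 0) & dprime.valid
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        values = 1.0 - (s_low / np.where(s0 > 0, s0, np.nan)) * np.exp(dprime.values * b_low)
    values[~valid] = np.nan
    return ParameterMap("fprime", values, valid, stack.spacing)


def compute_adc(stack: DWIStack, b_high: float = 800.0) -> ParameterMap:
    """Conventional ADC from the b0/b800 signal ratio."""
    stack.require((0.0, b_high))
    values, valid = _log_ratio_rate(stack.get(0.0), stack.get(b_high), b_high)
    return ParameterMap("ADC", values, valid, stack.spacing)


def compute_all(stack: DWIStack) -> dict[str, ParameterMap]:
    """D', f' and ADC maps for a stack containing b = 0, 50, 800.

    Note the algebraic identity ADC = D' - ln(1 - f')/b800 that ties the
    three estimators together on every valid voxel.
    """
    stack.require(REQUIRED_B_VALUES)
    dprime = compute_dprime(stack)
    return {
        "Dprime": dprime,
        "fprime": compute_fprime(stack, dprime),
        "ADC": compute_adc(stack),
    }
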