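"""Tortuosity scaling: from measured water ADC to a macromolecule's
purely diffusive ADC.

In tissue, the extracellular matrix hinders diffusion; the apparent
diffusion coefficient relates to the free diffusion coefficient through
the tortuosity lambda:

    lambda^2 = D_free / ADC

Assuming the tracer experiences the same tortuosity as water, the tracer's
tissue ADC follows from its own free diffusivity:

    ADC_tracer = D_free_tracer / lambda^2
               = ADC_water * (D_free_tracer / D_free_water)

The default constants are the free diffusion coefficient of water,
3e-6 mm^2/ms, and of bovine serum albumin (66 kD, a stand-in for the 70 kD
Gd-albumin contrast agent), 8.29e-8 mm^2/ms, giving a fixed scale factor of
about 0.02763.  If the tracer's true tortuosity is larger than water's,
the prediction only drops further, so this scaling is conservative for
bulk-flow detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import DiffusivityEstimate, TracerFlowError

__all__ = ["FreeDiffusionConstants", "tortuosity_squared", "scale_to_tracer"]


@dataclass(frozen=True)
class FreeDiffusionConstants:
    """Free (unhindered) diffusion coefficients in mm^2/ms."""

    d_water: float = 3.0e-6
    d_albumin: float = 8.29e-8

    def __post_init__(self):
        if self.d_water <= 0 or self.d_albumin <= 0:
            raise ValueError("free diffusion coefficients must be positive")
        if self.d_albumin >= self.d_water:
            raise ValueError("the macromolecule must diffuse slower than water")

    @property
    def scale_factor(self) -> float:
        """d_albumin / d_water, the one-step water-to-tracer ADC factor."""
        return self.d_albumin / self.d_water


def tortuosity_squared(d_free: float, adc: float) -> float:
    """lambda^2 = D_free / ADC.

    In tissue lambda^2 >= 1 is expected (hindered diffusion); a value below
    one is physically surprising and triggers a warning, not an error.
    """
    if d_free <= 0:
        raise TracerFlowError("free diffusivity must be positive")
    if adc <= 0:
        raise TracerFlowError("ADC must be positive to compute tortuosity")
    lam2 = d_free / adc
    if lam2 < 1:
        warnings.warn(f"tortuosity^2 = {lam2:.3g} < 1: ADC exceeds the free "
                      "diffusivity, check units", stacklevel=2)
    return lam2


def scale_to_tracer(adc_water: DiffusivityEstimate,
                    constants: FreeDiffusionConstants | None = None
                    ) -> DiffusivityEstimate:
    """Predict the tracer's purely diffusive ADC from measured water ADC.

    Applies lambda^2 = d_water / ADC_water, then ADC_tracer =
    d_albumin / lambda^2 — algebraically a multiplication by
    ``constants.scale_factor``; the standard error scales by the same
    factor (exact for a linear map).
    """
    if constants is None:
        constants = FreeDiffusionConstants()
    if adc_water.value <= 0:
        raise TracerFlowError("water ADC must be positive")
    lam2 = tortuosity_squared(constants.d_water, adc_water.value)
    value = constants.d_albumin / lam2
    return DiffusivityEstimate(
        region=adc_water.region, value=value,
        se=adc_water.se * constants.scale_factor,
        method="dti_scaled", n=adc_water.n,
        extra={"tortuosity_squared": lam2, "adc_water": adc_water.value})
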