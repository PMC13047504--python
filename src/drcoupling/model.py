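"""Two-compartment diffusion-relaxation signal model.

A voxel is modelled as two water pools (in the basal ganglia: neuronal cell
bodies and axonal tracts) with distinct apparent diffusion coefficients (ADC,
mm^2/s) and transverse relaxation rates (R2, 1/s).  The composite magnitude
signal on a (TE, b) acquisition grid is

    S(TE, b) = S0 * [ f1 * exp(-R2_1*TE - ADC_1*b)
                    + f2 * exp(-R2_2*TE - ADC_2*b) ],     f1 + f2 = 1,

with TE in seconds inside the exponent and b in s/mm^2.  When the two pools
differ in both ADC and R2, the mono-exponential ADC fitted at a fixed TE
depends on TE, and the mono-exponential R2 fitted at a fixed b depends on b:
diffusion-relaxation coupling.  The polarity of the coupling is set by the
sign of (ADC_1 - ADC_2) * (R2_1 - R2_2): a negative product gives positive
coupling (ADC rises with TE, R2 rises with b), a positive product gives
negative coupling.

The model is a phenomenological forward model: it generates signals and
provides the analytic coupling-sign oracle.  It is never fitted to data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CompartmentParams", "CouplingClass", "evaluate_signal", "classify_coupling"]

#: tolerance for the f1 + f2 = 1 normalization check
_FRACTION_ATOL = 1e-9


@dataclass(frozen=True)
class CompartmentParams:
    """Parameters of a two-pool tissue voxel.

    Attributes
    ----------
    f1, f2 : float
        Volume fractions of the two pools; non-negative, sum to 1.
    adc1, adc2 : float
        Apparent diffusion coefficients, mm^2/s; strictly positive.
    r2_1, r2_2 : float
        Transverse relaxation rates, 1/s; strictly positive.
    s0 : float
        Signal at TE = 0, b = 0, arbitrary units; strictly positive.
    """

    f1: float
    f2: float
    adc1: float
    adc2: float
    r2_1: float
    r2_2: float
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.f1 < 0 or self.f2 < 0:
            raise ValueError(f"volume fractions must be >= 0, got f1={self.f1}, f2={self.f2}")
        if abs(self.f1 + self.f2 - 1.0) > _FRACTION_ATOL:
            raise ValueError(f"volume fractions must sum to 1, got f1+f2={self.f1 + self.f2!r}")
        for name in ("adc1", "adc2", "r2_1", "r2_2", "s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")

    def swapped(self) -> "CompartmentParams":
        """Return the same tissue with the compartment labels exchanged."""
        return CompartmentParams(self.f2, self.f1, self.adc2, self.adc1,
                                 self.r2_2, self.r2_1, self.s0)

    @property
    def product(self) -> float:
        """(ADC_1 - ADC_2) * (R2_1 - R2_2), the coupling-sign discriminant."""
        return (self.adc1 - self.adc2) * (self.r2_1 - self.r2_2)


@dataclass(frozen=True)
class CouplingClass:
    """Analytic coupling polarity of a two-pool voxel.

    ``label`` is ``"positive"`` when the compartment with the larger ADC has
    the smaller R2 (product < -eps), ``"negative"`` when ADC and R2 order the
    same way (product > +eps), and ``"degenerate"`` when the product is within
    eps of zero (no coupling).
    """

    label: str
    product: float


def evaluate_signal(params: CompartmentParams, te, b):
    """Composite two-compartment magnitude signal at echo time(s) and b-value(s).

    Parameters
    ----------
    params : CompartmentParams
    te : float or array-like
        Echo time(s), **milliseconds** (converted to seconds internally).
    b : float or array-like
        Diffusion weighting(s), s/mm^2.  Broadcast against ``te``.

    Returns
    -------
    float or ndarray, same broadcast shape as (te, b); strictly positive,
    non-increasing in both arguments.
    """
    te = np.asarray(te, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(te < 0):
        raise ValueError("te must be >= 0")
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    te_s = te / 1000.0
    sig = params.s0 * (
        params.f1 * np.exp(-params.r2_1 * te_s - params.adc1 * b)
        + params.f2 * np.exp(-params.r2_2 * te_s - params.adc2 * b)
    )
    return sig if sig.ndim else float(sig)


def classify_coupling(params: CompartmentParams, epsilon: float = 1e-12) -> CouplingClass:
    """Classify the coupling polarity from the compartment parameters.

    The fitted slopes k_ADC/TE and k_R2/b share the *opposite* sign of the
    product (ADC_1 - ADC_2) * (R2_1 - R2_2): e.g. when the high-ADC pool also
    has the low R2 (product < 0), long TEs suppress the other pool and the
    apparent ADC grows with TE (positive coupling).

    ``epsilon`` (>= 0, product units: mm^2/s * 1/s) bounds the degenerate band.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    product = params.product
    if product < -epsilon:
        label = "positive"
    elif product > epsilon:
        label = "negative"
    else:
        label = "degenerate"
    return CouplingClass(label=label, product=product)
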