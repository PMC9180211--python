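"""Biased one-sided difference operators for MacCormack-type schemes.

The forward operator on a 5-node biased stencil (offsets n = -1..3) is

    L^F(U)_i = (1/dx) * sum_n a_n U_{i+n}

and the backward operator is its mirrored negation,

    L^B(U)_i = (1/dx) * sum_n (-a_n) U_{i-n}.

The default coefficient set is the standard 4th-order-exact biased first
derivative on those offsets; any alternative set (e.g. dispersion-optimized
coefficients from the literature) can be supplied as long as it satisfies
the exactness invariants checked at construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["StencilCoefficients", "DEFAULT_COEFFS", "spatial_derivative"]

#: Offsets of the biased stencil relative to the evaluation node.
OFFSETS = np.arange(-1, 4)

#: 4th-order-exact first-derivative weights on offsets -1..3 (Fornberg).
DEFAULT_COEFFS = np.array([-1 / 4, -5 / 6, 3 / 2, -1 / 2, 1 / 12])


@dataclasses.dataclass(frozen=True)
class StencilCoefficients:
    """Coefficients a_n (n = -1..3) of the forward biased operator.

    Invariants: sum a_n = 0 (constants are annihilated) and
    sum n*a_n = 1 (linear functions differentiate exactly).
    """

    a: np.ndarray = dataclasses.field(default_factory=lambda: DEFAULT_COEFFS.copy())
    dx: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (5,):
            raise ValueError("expected 5 coefficients for offsets -1..3")
        if abs(a.sum()) > 1e-12:
            raise ValueError("coefficients must sum to 0 (constant exactness)")
        if abs(float(OFFSETS @ a) - 1.0) > 1e-12:
            raise ValueError("sum of n*a_n must be 1 (linear exactness)")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        object.__setattr__(self, "a", a)

    @property
    def order(self) -> int:
        """Highest polynomial degree differentiated exactly."""
        for p in range(2, 6):
            moment = float((OFFSETS.astype(float) ** p) @ self.a)
            if abs(moment - (p if p == 1 else 0.0)) > 1e-10:
                # exact derivative of x^p at 0 is 0 for p >= 2
                return p - 1
        return 5


def spatial_derivative(
    field: np.ndarray,
    axis: int,
    direction: str,
    coeffs: StencilCoefficients | None = None,
) -> np.ndarray:
    """Apply the forward or backward biased operator along one axis.

    Edge values (within 3 nodes of either end along ``axis``) are computed
    with edge-replicated padding and are only formally valid in the
    interior; the solver handles boundaries through ghost layers instead.
    """
    coeffs = coeffs or StencilCoefficients()
    if direction not in {"forward", "backward"}:
        raise ValueError("direction must be 'forward' or 'backward'")
    field = np.asarray(field, dtype=float)
    if axis < 0 or axis >= field.ndim:
        raise ValueError(f"axis {axis} out of range for {field.ndim}-D field")
    if field.shape[axis] < 5:
        raise ValueError("field extent must be at least the stencil width (5)")
    pad = [(0, 0)] * field.ndim
    pad[axis] = (3, 3)
    padded = np.pad(field, pad, mode="edge")
    out = np.zeros_like(field)
    for n, an in zip(OFFSETS, coeffs.a):
        shift = n if direction == "forward" else -n
        sign = 1.0 if direction == "forward" else -1.0
        sl = [slice(None)] * field.ndim
        sl[axis] = slice(3 + shift, 3 + shift + field.shape[axis])
        out += sign * an * padded[tuple(sl)]
    return out / coeffs.dx
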