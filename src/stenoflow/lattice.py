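"""Discrete velocity sets for the lattice Boltzmann solver.

The flow core uses the two-dimensional nine-velocity (D2Q9) stencil; the
three-dimensional nineteen-velocity (D3Q19) constants are provided for the
optional 3D variant. Both satisfy the standard isotropy conditions

    sum_i w_i           = 1
    sum_i w_i c_ia      = 0
    sum_i w_i c_ia c_ib = c_s^2 delta_ab

with lattice speed of sound c_s^2 = 1/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CS2: float = 1.0 / 3.0


@dataclass(frozen=True)
class LatticeModel:
    """A discrete velocity set: stencil name, velocities, weights.

    Attributes
    ----------
    stencil : str
        ``"D2Q9"`` or ``"D3Q19"``.
    velocities : np.ndarray
        Integer lattice velocity vectors, shape ``(q, d)``.
    weights : np.ndarray
        Quadrature weights, shape ``(q,)``; sum to one.
    opposite : np.ndarray
        Index of the opposite velocity for each direction (bounce-back).
    speed_of_sound_sq : float
        Lattice speed of sound squared (1/3).
    """

    stencil: str
    velocities: np.ndarray
    weights: np.ndarray
    opposite: np.ndarray
    speed_of_sound_sq: float = field(default=CS2)

    @property
    def q(self) -> int:
        return len(self.weights)

    @property
    def ndim(self) -> int:
        return self.velocities.shape[1]


def _opposites(c: np.ndarray) -> np.ndarray:
    opp = np.empty(len(c), dtype=np.intp)
    for i, ci in enumerate(c):
        (j,) = np.nonzero((c == -ci).all(axis=1))[0]
        opp[i] = j
    return opp


def _d2q9() -> LatticeModel:
    c = np.array(
        [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1],
         [1, 1], [-1, 1], [-1, -1], [1, -1]],
        dtype=np.intp,
    )
    w = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)
    return LatticeModel("D2Q9", c, w, _opposites(c))


def _d3q19() -> LatticeModel:
    c = [[0, 0, 0]]
    c += [v for v in
          [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]]
    for a in (1, -1):
        for b in (1, -1):
            c += [[a, b, 0], [a, 0, b], [0, a, b]]
    c = np.array(c, dtype=np.intp)
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    return LatticeModel("D3Q19", c, w, _opposites(c))


D2Q9: LatticeModel = _d2q9()
D3Q19: LatticeModel = _d3q19()

_MODELS = {"D2Q9": D2Q9, "D3Q19": D3Q19}


def get_lattice(stencil: str) -> LatticeModel:
    """Return the lattice model for a stencil name."""
    try:
        return _MODELS[stencil]
    except KeyError:
        raise ValueError(
            f"unknown stencil {stencil!r}; available: {sorted(_MODELS)}"
        ) from None
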