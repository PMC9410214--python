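"""Derivation of the virtual-hexagonal-trellis (VHT) 3x3 kernel.

The kernel is built from a 3x3 square neighbourhood by inserting a virtual
pixel halfway between each diagonal neighbour ``N_k`` and the centre ``C1``
(valued at their arithmetic mean), then averaging the seven hexagonal
samples ``V1, V2, R1, C1, R4, V3, V4``.  Clearing denominators turns that
seven-term average into an integer weight grid over the original nine
pixels; the grid is always ``[[1,0,1],[2,6,2],[1,0,1]]`` and the divisor
(the "constant filter factor", CFF) is a free parameter with unit DC gain
at 14.

The derivation here is performed symbolically with exact rationals so that
each coefficient can be inspected and tested, rather than hard-coding the
final grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import lcm

import numpy as np

#: Grid layout convention: row 1 = (N1, R2, N2), row 2 = (R1, C1, R4),
#: row 3 = (N3, R3, N4).  Corners N_k are diagonal ("unit-plus" distance)
#: neighbours, R_k the edge ("unit" distance) neighbours.
GRID_LAYOUT: tuple[tuple[str, str, str], ...] = (
    ("N1", "R2", "N2"),
    ("R1", "C1", "R4"),
    ("N3", "R3", "N4"),
)

#: CFF range explored in the reference sweep.
CFF_MIN_STANDARD = 7
CFF_MAX_STANDARD = 19
CFF_UNIT_GAIN = 14


def virtual_pixel_intensity(corner: float, centre: float) -> float:
    """Intensity of the virtual pixel between a corner and the centre.

    Exact arithmetic mean ``(corner + centre) / 2``; deliberately not
    rounded so downstream weights stay exact.
    """
    for v in (corner, centre):
        if not 0 <= v <= 255:
            raise ValueError(f"intensity {v!r} outside [0, 255]")
    return (corner + centre) / 2


@dataclass(frozen=True, eq=False)
class Kernel3x3:
    """A 3x3 integer-weight kernel with a positive integer divisor."""

    weights: np.ndarray
    divisor: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.shape != (3, 3):
            raise ValueError(f"kernel weights must be 3x3, got {w.shape}")
        if not (isinstance(self.divisor, (int, np.integer)) and self.divisor >= 1):
            raise ValueError(f"divisor must be an integer >= 1, got {self.divisor!r}")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "divisor", int(self.divisor))

    @property
    def dc_gain(self) -> float:
        """Response of the kernel to a constant unit image, before rounding."""
        return float(self.weights.sum()) / self.divisor

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "divisor": self.divisor}


class VHTKernel(Kernel3x3):
    """The virtual-hexagonal-trellis kernel: weights [[1,0,1],[2,6,2],[1,0,1]]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        expected = np.array([[1, 0, 1], [2, 6, 2], [1, 0, 1]])
        if not np.array_equal(self.weights, expected):
            raise ValueError("VHTKernel weights must be [[1,0,1],[2,6,2],[1,0,1]]")

    @property
    def cff(self) -> int:
        """The constant filter factor (the normalizing divisor)."""
        return self.divisor


#: The plain 3x3 box-average kernel the VHT construction starts from.
MEAN_KERNEL = Kernel3x3(np.ones((3, 3), dtype=np.int64), 9)


def seven_term_coefficients() -> dict[str, Fraction]:
    """Exact rational coefficient of each real pixel in the VHT average.

    Substitutes ``V_k = (N_k + C1) / 2`` into
    ``(V1 + V2 + R1 + C1 + R4 + V3 + V4) / 7`` and collects terms.
    """
    half = Fraction(1, 2)
    terms: list[dict[str, Fraction]] = []
    for k in (1, 2, 3, 4):  # virtual pixels V1..V4
        terms.append({f"N{k}": half, "C1": half})
    terms.append({"R1": Fraction(1)})
    terms.append({"C1": Fraction(1)})
    terms.append({"R4": Fraction(1)})

    coeffs: dict[str, Fraction] = {name: Fraction(0) for row in GRID_LAYOUT for name in row}
    for term in terms:
        for name, c in term.items():
            coeffs[name] += c
    return {name: c / 7 for name, c in coeffs.items()}


def derive_kernel(cff: int = CFF_UNIT_GAIN) -> VHTKernel:
    """Derive the VHT kernel symbolically and attach the given CFF.

    The rational seven-term coefficients are scaled by the least common
    multiple of their denominators so every weight is an integer; the
    scale factor that achieves this is 14, which is why CFF = 14 gives
    unit DC gain.
    """
    if not (isinstance(cff, (int, np.integer)) and cff >= 1):
        raise ValueError(f"cff must be an integer >= 1, got {cff!r}")

    coeffs = seven_term_coefficients()
    scale = lcm(*(c.denominator for c in coeffs.values()))
    weights = np.empty((3, 3), dtype=np.int64)
    for i, row in enumerate(GRID_LAYOUT):
        for j, name in enumerate(row):
            w = coeffs[name] * scale
            if w.denominator != 1:
                raise AssertionError(f"non-integer weight {w} for {name}")
            weights[i, j] = int(w)
    return VHTKernel(weights, int(cff))
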