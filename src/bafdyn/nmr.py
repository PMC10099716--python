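"""NMR-derived flexibility descriptors.

Two small utilities: steady-state heteronuclear 1H->15N nOe ratios (low
values flag picosecond-nanosecond backbone flexibility, high values
rigidity) and a geometric two-state projection that places an amide peak on
the line between "open" and "closed" reference positions in (1H, 15N)
chemical-shift space.  The projection is a descriptor only — it quantifies
where a species' peaks sit between the two reference ensembles, without
fitting exchange kinetics or thermodynamic populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Conventional 15N weighting in combined-shift distances: dN is divided by
#: this factor relative to dH before Euclidean geometry is applied.
N_SCALE = 1.0 / 0.14


class DegenerateAxisError(ValueError):
    pass


@dataclass(frozen=True)
class NoeRecord:
    """Heteronuclear nOe ratio of one backbone amide."""

    residue_number: int
    ratio: float
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")
        if not np.isfinite(self.ratio):
            raise ValueError("nOe ratio must be finite")


@dataclass(frozen=True)
class PeakPosition:
    """One amide cross-peak of one species."""

    residue_number: int
    shift_h: float   # ppm
    shift_n: float   # ppm
    species_label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shift_h) and np.isfinite(self.shift_n)):
            raise ValueError("chemical shifts must be finite")


def het_noe(i_sat: float, i_ref: float) -> float:
    """Steady-state heteronuclear nOe ratio, saturated over reference intensity."""
    if i_ref == 0:
        raise ValueError("reference intensity must be non-zero")
    return i_sat / i_ref


def het_noe_table(pairs: np.ndarray) -> np.ndarray:
    """Vectorized nOe ratios for an (n, 2) array of (i_sat, i_ref) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if np.any(pairs[:, 1] == 0):
        raise ValueError("reference intensities must be non-zero")
    return pairs[:, 0] / pairs[:, 1]


def two_state_projection(
    peak: PeakPosition,
    open_ref: PeakPosition,
    closed_ref: PeakPosition,
    n_scale: float = N_SCALE,
) -> tuple[float, float]:
    """Project a peak onto the open -> closed axis in scaled shift space.

    Nitrogen shifts are divided by ``n_scale`` so both dimensions carry
    comparable weight, then the peak is orthogonally projected onto the
    segment from the open to the closed reference.  Returns
    ``(fraction_closed, collinearity_deviation)``: the projection coordinate
    clipped to [0, 1] and the scaled perpendicular distance (ppm) of the
    peak off the axis.
    """
    def scaled(p: PeakPosition) -> np.ndarray:
        return np.array([p.shift_h, p.shift_n / n_scale])

    a, b, x = scaled(open_ref), scaled(closed_ref), scaled(peak)
    axis = b - a
    norm2 = float(axis @ axis)
    if norm2 == 0.0:
        raise DegenerateAxisError("open and closed references coincide")
    t = float((x - a) @ axis) / norm2
    perp = (x - a) - t * axis
    fraction_closed = float(np.clip(t, 0.0, 1.0))
    return fraction_closed, float(np.linalg.norm(perp))
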