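"""Quasi-harmonic configurational entropy from superposed fluctuations.

The quasi-harmonic approximation diagonalizes the mass-weighted Cartesian
covariance matrix of a trajectory (overall rotation/translation removed by
prior core superposition) and treats each eigenmode as an independent quantum
harmonic oscillator of frequency

    omega_i = sqrt(k_B * T / lambda_i),

where lambda_i is the eigenvalue in amu*Å^2.  The molar entropy is

    S = R * sum_i [ u_i / (exp(u_i) - 1) - ln(1 - exp(-u_i)) ],
    u_i = hbar * omega_i / (k_B * T),

reported in cal mol^-1 K^-1.  Stiff modes (large omega, small lambda)
contribute vanishingly; modes with eigenvalues at or below a floor — the ~6
rigid-body modes nulled by superposition, plus numerical noise — are
discarded and counted, never silently dropped.

Physical constants are CODATA-2018 and echoed by :func:`constants_used` for
auditability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structures import TrajectoryEnsemble

# CODATA-2018
KB_J_PER_K = 1.380649e-23          # Boltzmann constant, J/K
HBAR_J_S = 1.054571817e-34         # reduced Planck constant, J*s
R_CAL_PER_MOL_K = 1.98720425       # molar gas constant, cal mol^-1 K^-1
AMU_KG = 1.66053906660e-27         # atomic mass unit, kg
ANGSTROM_M = 1e-10

DEFAULT_TEMPERATURE = 310.0        # K, the simulation thermostat setting
DEFAULT_EIGENVALUE_FLOOR = 1e-8    # amu*Å^2


class InsufficientDataError(ValueError):
    pass


def constants_used() -> dict[str, float]:
    return {
        "k_B_J_per_K": KB_J_PER_K,
        "hbar_J_s": HBAR_J_S,
        "R_cal_per_mol_K": R_CAL_PER_MOL_K,
        "amu_kg": AMU_KG,
    }


@dataclass
class EntropyResult:
    """Spectrum, mode frequencies and quasi-harmonic entropy of one selection."""

    eigenvalues: np.ndarray            # amu*Å^2, descending
    frequencies: np.ndarray            # rad/s, for retained modes
    temperature: float                 # K
    entropy: float                     # cal mol^-1 K^-1
    n_modes_used: int
    n_modes_discarded: int
    convergence: list[tuple[int, float]]

    @property
    def converged(self) -> bool:
        if len(self.convergence) < 2:
            return False
        (_, s_prev), (_, s_last) = self.convergence[-2], self.convergence[-1]
        if s_last == 0:
            return s_prev == 0
        return abs(s_last - s_prev) / abs(s_last) < 0.01

    def summary(self) -> dict:
        return {
            "entropy_cal_per_mol_K": self.entropy,
            "temperature_K": self.temperature,
            "n_modes_used": self.n_modes_used,
            "n_modes_discarded": self.n_modes_discarded,
            "converged": self.converged,
            "convergence": [[int(k), float(s)] for k, s in self.convergence],
            "constants": constants_used(),
        }


def mass_weighted_covariance(traj: TrajectoryEnsemble, selection: np.ndarray) -> np.ndarray:
    """Mass-weighted covariance of the selected atoms' Cartesian fluctuations.

    Entry (i, j) is sqrt(m_i * m_j) * <dx_i dx_j> with deviations taken from
    the ensemble mean, giving a symmetric positive semi-definite 3N x 3N
    matrix in amu*Å^2.  Frames must already be superposed on the reference
    core so that rigid-body motion does not masquerade as fluctuation.
    """
    selection = np.asarray(selection, dtype=int)
    if traj.n_frames < 2:
        raise InsufficientDataError("covariance needs >= 2 frames")
    if len(selection) < 1:
        raise InsufficientDataError("empty atom selection")
    x = traj.frames[:, selection, :].reshape(traj.n_frames, -1)  # (F, 3N)
    dx = x - x.mean(axis=0)
    cov = dx.T @ dx / traj.n_frames
    masses = traj.topology.masses[selection]
    w = np.sqrt(np.repeat(masses, 3))
    cov *= np.outer(w, w)
    return 0.5 * (cov + cov.T)


def quasi_harmonic_entropy(
    cov: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
) -> EntropyResult:
    """Quasi-harmonic entropy from a mass-weighted covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    eigenvalues = np.linalg.eigvalsh(cov)[::-1]  # descending
    if eigenvalues.size and eigenvalues[-1] < -1e-10 * max(1.0, abs(eigenvalues[0])):
        raise ValueError(f"covariance has a negative eigenvalue: {eigenvalues[-1]:g}")
    retained = eigenvalues[eigenvalues > eigenvalue_floor]
    n_discarded = eigenvalues.size - retained.size
    kbt = KB_J_PER_K * temperature
    lam_si = retained * AMU_KG * ANGSTROM_M**2  # kg*m^2
    omega = np.sqrt(kbt / lam_si) if retained.size else np.array([])
    u = HBAR_J_S * omega / kbt
    per_mode = u / np.expm1(u) - np.log1p(-np.exp(-u)) if retained.size else np.array([])
    entropy = float(R_CAL_PER_MOL_K * per_mode.sum())
    return EntropyResult(
        eigenvalues=eigenvalues,
        frequencies=omega,
        temperature=temperature,
        entropy=entropy,
        n_modes_used=int(retained.size),
        n_modes_discarded=int(n_discarded),
        convergence=[],
    )


def entropy_convergence(
    traj: TrajectoryEnsemble,
    selection: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    checkpoints: Sequence[int] | None = None,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
) -> EntropyResult:
    """Entropy as a function of the number of frames used.

    Recomputes the quasi-harmonic entropy on the first k frames for each
    checkpoint, then on the full trajectory; the result carries the series
    and a ``converged`` flag (last two checkpoints within 1% relative).
    Checking that the entropy has plateaued against sampling length is the
    standard completeness-of-sampling diagnostic.
    """
    if checkpoints is None:
        checkpoints = [
            k for k in range(500, traj.n_frames + 1, 500)
        ] or [traj.n_frames]
    checkpoints = list(checkpoints)
    if any(b <= a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be strictly increasing")
    if checkpoints[-1] > traj.n_frames:
        raise ValueError(
            f"checkpoint {checkpoints[-1]} exceeds trajectory length {traj.n_frames}"
        )
    series: list[tuple[int, float]] = []
    for k in checkpoints:
        sub = TrajectoryEnsemble(traj.topology, traj.frames[:k])
        cov = mass_weighted_covariance(sub, selection)
        series.append((k, quasi_harmonic_entropy(cov, temperature, eigenvalue_floor).entropy))
    cov = mass_weighted_covariance(
        TrajectoryEnsemble(traj.topology, traj.frames[: checkpoints[-1]]), selection
    )
    result = quasi_harmonic_entropy(cov, temperature, eigenvalue_floor)
    result.convergence = series
    return result


def analytic_isotropic_entropy(
    sigma: float, mass: float, temperature: float = DEFAULT_TEMPERATURE, n_atoms: int = 1
) -> float:
    """Closed-form quasi-harmonic entropy of independent isotropic Gaussians.

    For ``n_atoms`` atoms of mass ``mass`` (amu) fluctuating independently
    and isotropically with standard deviation ``sigma`` (Å) per Cartesian
    axis, every eigenvalue equals mass*sigma^2 and the entropy is 3*n_atoms
    identical mode contributions.  Used as the parameter-recovery reference
    for sampled ensembles.
    """
    lam_si = mass * sigma**2 * AMU_KG * ANGSTROM_M**2
    kbt = KB_J_PER_K * temperature
    u = HBAR_J_S * np.sqrt(kbt / lam_si) / kbt
    per_mode = u / np.expm1(u) - np.log1p(-np.exp(-u))
    return float(3 * n_atoms * R_CAL_PER_MOL_K * per_mode)
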