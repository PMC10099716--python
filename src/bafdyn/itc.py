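"""One-set-of-sites ITC titration simulation, fitting and thermodynamics.

The binding model is the standard Wiseman one-set-of-sites isotherm for a
perfusion (overfill) cell: a macromolecule M at total concentration M_t with
n equivalent sites binds titrant X with dissociation constant Kd.  The bound
concentration after each injection follows from the exact quadratic root of

    [MX] = (S + X_t + Kd - sqrt((S + X_t + Kd)^2 - 4 S X_t)) / 2,
    S = n * M_t,

with totals carried through the displacement-dilution bookkeeping of a
constant-volume cell: each dV injection expels cell liquid, multiplying both
totals by (1 - dV/V0) before the fresh titrant is added, and the measured
heat carries the standard half-step correction for material expelled during
the injection itself:

    q_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2 + offset,
    Q_i = V0 * dH * [MX]_i.

The free-energy decomposition uses dG = R T ln(Kd) (molar standard state,
natural log) and the entropic penalty -T dS = dG - dH; all energies are
kcal/mol, heats are ucal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("bafdyn")

R_KCAL_PER_MOL_K = 1.98720425e-3   # molar gas constant, kcal mol^-1 K^-1
DEFAULT_CELL_VOLUME_ML = 1.4       # nominal VP-ITC cell volume
DEFAULT_TEMPERATURE_K = 288.0


class ScheduleError(ValueError):
    pass


class FitError(RuntimeError):
    pass


class UnidentifiableParametersError(FitError):
    pass


@dataclass(frozen=True)
class TitrationSchedule:
    """Injection program and cell contents of one titration."""

    cell_concentration: float                 # M, macromolecule in the cell
    syringe_concentration: float              # M, titrant
    injection_volumes: tuple[float, ...]      # µL each
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    cell_volume: float = DEFAULT_CELL_VOLUME_ML  # mL

    def __post_init__(self) -> None:
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ScheduleError("concentrations must be positive")
        if self.cell_volume <= 0 or self.temperature <= 0:
            raise ScheduleError("cell volume and temperature must be positive")
        if not self.injection_volumes or any(v <= 0 for v in self.injection_volumes):
            raise ScheduleError("injection volumes must be positive")
        v0_ul = self.cell_volume * 1000.0
        if any(v >= v0_ul for v in self.injection_volumes):
            raise ScheduleError("an injection volume reaches the cell volume")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


def standard_schedule(
    cell_concentration: float,
    syringe_concentration: float,
    n_injections: int = 29,
    injection_volume: float = 10.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    cell_volume: float = DEFAULT_CELL_VOLUME_ML,
) -> TitrationSchedule:
    """The study's standard program: 29 x 10 µL injections at 288 K."""
    return TitrationSchedule(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes=(injection_volume,) * n_injections,
        temperature=temperature,
        cell_volume=cell_volume,
    )


@dataclass
class Isotherm:
    """Integrated per-injection heats of one titration."""

    schedule: TitrationSchedule
    heats: np.ndarray                # µcal per injection
    molar_ratio: np.ndarray          # titrant total / cell total after each injection

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if len(self.heats) != self.schedule.n_injections:
            raise ScheduleError("heats length does not match injection count")

    def drop_first(self) -> "Isotherm":
        """Mask the first injection (common practice for the diffusion spike).

        The injection stays in the concentration bookkeeping — its titrant is
        in the cell — but its heat is excluded from fitting (marked NaN).
        """
        heats = self.heats.copy()
        heats[0] = np.nan
        return Isotherm(self.schedule, heats, self.molar_ratio)


@dataclass
class BindingFit:
    """Fitted one-set-of-sites parameters and the derived decomposition."""

    kd: float                  # M
    dh: float                  # kcal/mol of injectant
    n: float                   # sites per cell-species molecule
    dilution_offset: float     # µcal per injection
    temperature: float         # K
    dg: float = field(init=False)               # kcal/mol
    entropic_penalty: float = field(init=False)  # -T dS, kcal/mol
    rss: float = 0.0           # µcal², residual sum of squares
    c_value: float = float("nan")
    n_fixed: bool = False

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        self.dg = gibbs_from_kd(self.kd, self.temperature)
        self.entropic_penalty = decompose(self.dg, self.dh)

    def summary(self) -> dict:
        return {
            "kd_M": self.kd,
            "dh_kcal_per_mol": self.dh,
            "n": self.n,
            "n_fixed": self.n_fixed,
            "dilution_offset_ucal": self.dilution_offset,
            "temperature_K": self.temperature,
            "dg_kcal_per_mol": self.dg,
            "entropic_penalty_kcal_per_mol": self.entropic_penalty,
            "rss_ucal2": self.rss,
            "c_value": self.c_value,
        }


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _bound_concentration(m_tot: np.ndarray, x_tot: np.ndarray, kd: float, n: float) -> np.ndarray:
    """Exact quadratic solution of the 1:n equilibrium, [MX] in M."""
    s = n * m_tot
    b = s + x_tot + kd
    disc = b * b - 4.0 * s * x_tot
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def _titration_totals(schedule: TitrationSchedule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Running cell totals (M) and per-injection dilution ratios after each shot."""
    v0 = schedule.cell_volume * 1000.0  # µL
    m = schedule.cell_concentration
    x = 0.0
    m_tot = np.empty(schedule.n_injections)
    x_tot = np.empty(schedule.n_injections)
    dvr = np.empty(schedule.n_injections)
    for i, dv in enumerate(schedule.injection_volumes):
        f = 1.0 - dv / v0
        m = m * f
        x = x * f + schedule.syringe_concentration * dv / v0
        m_tot[i], x_tot[i], dvr[i] = m, x, dv / v0
    return m_tot, x_tot, dvr


def _model_heats(
    schedule: TitrationSchedule, kd: float, dh: float, n: float, offset: float
) -> np.ndarray:
    """Noise-free per-injection heats (µcal) of the one-set-of-sites model."""
    m_tot, x_tot, dvr = _titration_totals(schedule)
    bound = _bound_concentration(m_tot, x_tot, kd, n)
    v0_l = schedule.cell_volume * 1e-3  # L
    q = v0_l * dh * bound * 1e9  # kcal -> µcal: 1 kcal = 1e9 µcal... see note below
    # Q_i in µcal: V0[L] * [MX][mol/L] * dH[kcal/mol] = kcal; 1 kcal = 1e9 µcal
    q_prev = np.concatenate(([0.0], q[:-1]))
    return q - q_prev + dvr * 0.5 * (q + q_prev) + offset


def simulate_isotherm(
    schedule: TitrationSchedule,
    kd: float,
    dh: float,
    n: float = 1.0,
    dilution_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Isotherm:
    """Simulate integrated injection heats for a one-set-of-sites titration.

    ``kd`` in M, ``dh`` in kcal per mole of injectant, ``noise_sd`` in µcal
    (i.i.d. Gaussian on each integrated heat).
    """
    if kd <= 0 or n <= 0:
        raise ValueError("kd and n must be positive")
    heats = _model_heats(schedule, kd, dh, n, dilution_offset)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, len(heats))
    m_tot, x_tot, _ = _titration_totals(schedule)
    return Isotherm(schedule=schedule, heats=heats, molar_ratio=x_tot / m_tot)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_isotherm(
    iso: Isotherm,
    fix_n: float | None = None,
    fit_offset: bool = True,
) -> BindingFit:
    """Nonlinear least-squares fit of the one-set-of-sites model.

    Free parameters are (Kd, dH, n, dilution offset); ``fix_n`` pins the
    stoichiometry (0.5 for one ligand per dimer counted in monomer units).
    Kd is searched in log space with multi-starts spanning 1 pM - 1 mM and
    the best local optimum is returned.  NaN heats (e.g. a masked first
    injection) stay in the concentration bookkeeping but are excluded from
    the residuals.  A flat isotherm (heat spread indistinguishable from
    zero) raises :class:`UnidentifiableParametersError`.
    """
    valid = np.isfinite(iso.heats)
    heats = iso.heats[valid]
    if len(heats) < 5:
        raise FitError(f"need >= 5 informative injections, got {len(heats)}")
    spread = heats.max() - heats.min()
    scale = max(np.abs(heats).max(), 1.0)
    if spread < 1e-9 * scale or spread == 0.0:
        raise UnidentifiableParametersError(
            "isotherm is flat: binding parameters are unidentifiable"
        )
    sched = iso.schedule

    # convert the first-to-last heat drop to a per-mole enthalpy guess
    moles_first = sched.syringe_concentration * sched.injection_volumes[0] * 1e-6  # mol
    dh_scale = (heats[0] - heats[-1]) * 1e-9 / max(moles_first, 1e-30)  # kcal/mol
    if dh_scale == 0:
        dh_scale = -1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, dh, n, offset = _unpack(theta)
        return _model_heats(sched, 10.0**log_kd, dh, n, offset)[valid] - heats

    def _unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        log_kd, dh = theta[0], theta[1]
        k = 2
        if fix_n is None:
            n = theta[k]
            k += 1
        else:
            n = fix_n
        offset = theta[k] if fit_offset else 0.0
        return log_kd, dh, n, offset

    best = None
    for log_kd0 in np.arange(-12.0, -2.9, 1.0):
        theta0 = [log_kd0, dh_scale]
        lower = [-15.0, -1e4]
        upper = [0.0, 1e4]
        if fix_n is None:
            theta0.append(1.0)
            lower.append(1e-3)
            upper.append(100.0)
        if fit_offset:
            theta0.append(0.0)
            lower.append(-1e6)
            upper.append(1e6)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13,
            )
        except Exception:  # singular Jacobian from a pathological start
            continue
        # keep any finite local optimum: with noisy data the tight tolerances
        # trip the iteration cap before scipy flags formal convergence
        if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("no fit attempt converged from any Kd start")

    log_kd, dh, n, offset = _unpack(best.x)
    kd = 10.0**log_kd
    c_value = n * sched.cell_concentration / kd
    if not 1.0 <= c_value <= 1000.0:
        logger.warning("c-value %.3g outside the reliable 1-1000 window", c_value)
    fit = BindingFit(
        kd=kd,
        dh=dh,
        n=n,
        dilution_offset=offset if fit_offset else 0.0,
        temperature=sched.temperature,
        rss=float(2.0 * best.cost),
        n_fixed=fix_n is not None,
    )
    fit.c_value = c_value
    return fit


# ---------------------------------------------------------------------------
# Thermodynamic decomposition
# ---------------------------------------------------------------------------

def gibbs_from_kd(kd: float, temperature: float) -> float:
    """Binding free energy dG = R T ln(Kd), kcal/mol (1 M standard state)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL_PER_MOL_K * temperature * float(np.log(kd))


def decompose(dg: float, dh: float) -> float:
    """Entropic penalty -T dS = dG - dH (kcal/mol); positive opposes binding."""
    return dg - dh


def affinity_fold_change(kd_ref: float, kd_alt: float) -> tuple[float, int]:
    """Affinity ratio kd_ref / kd_alt and its nearest-integer fold.

    A ratio above 1 means the alternative species binds tighter than the
    reference; below 1, weaker (the nearest fold is then taken on the
    inverse ratio).
    """
    if kd_ref <= 0 or kd_alt <= 0:
        raise ValueError("dissociation constants must be positive")
    ratio = kd_ref / kd_alt
    nearest = round(ratio if ratio >= 1 else 1.0 / ratio)
    return ratio, int(nearest)
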