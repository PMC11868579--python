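"""One-set-of-sites ITC model, ligand efficiency and dose–response fitting.

The calorimetric model is the single-site (Wiseman) isotherm: n identical,
independent sites per macromolecule with association constant Ka = 1/Kd and
molar enthalpy dH. With total macromolecule M_t and total ligand X_t in the
cell, the fraction of sites occupied is

    theta = 1/2 [ 1 + X/(nM) + 1/(n Ka M)
                  - sqrt( (1 + X/(nM) + 1/(n Ka M))^2 - 4 X/(nM) ) ]

and the cumulative heat evolved is Q = n * theta * M_t * dH * V0.

Injections displace well-mixed cell contents (instantaneous-mixing model):
after an injection of volume v into cell volume V0, concentrations are
multiplied by (1 - v/V0) and the ligand gains X_syr * v/V0; the measured
per-injection heat carries the half-volume displacement correction

    q_i = Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1}) / 2.

Derived quantities: dG = R T ln Kd, -T dS = dG - dH, Wiseman
c = n M0 / Kd (fits are reliable for c roughly in [1, 1000]), and ligand
efficiency LE = -dG / N_heavy in (kcal/mol)/heavy atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FragkitError

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3
#: Default experiment temperature (25 degrees C).
T_DEFAULT = 298.15


class UnderDeterminedError(FragkitError):
    """Fewer usable injections than free parameters."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell/syringe concentrations and injection schedule of one titration.

    Units: volumes in litres, concentrations in mol/L, temperature in kelvin.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes", tuple(float(v) for v in self.injection_volumes)
        )
        for label, v in (
            ("cell_volume", self.cell_volume),
            ("cell_conc", self.cell_conc),
            ("syringe_conc", self.syringe_conc),
            ("temperature", self.temperature),
        ):
            if not v > 0:
                raise ValueError(f"{label} must be positive, got {v}")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must all be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Total (macromolecule, ligand) cell concentrations after each injection."""
        M = np.empty(self.n_injections)
        X = np.empty(self.n_injections)
        m, x = self.cell_conc, 0.0
        for i, v in enumerate(self.injection_volumes):
            f = v / self.cell_volume
            m *= 1.0 - f
            x = x * (1.0 - f) + self.syringe_conc * f
            M[i], X[i] = m, x
        return M, X


@dataclass(frozen=True)
class BindingParams:
    """Stoichiometry n, dissociation constant Kd (mol/L), enthalpy dH (kcal/mol)."""

    n: float
    Kd: float
    dH: float

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not self.Kd > 0:
            raise ValueError(f"Kd must be positive, got {self.Kd}")

    @property
    def Ka(self) -> float:
        return 1.0 / self.Kd


@dataclass
class Thermogram:
    """Per-injection heats (kcal) with their titration protocol."""

    heats: np.ndarray
    protocol: TitrationProtocol

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (self.protocol.n_injections,):
            raise ValueError(
                f"{self.heats.size} heats for {self.protocol.n_injections} injections"
            )
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("heats must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_index": np.arange(1, self.heats.size + 1),
                "volume_uL": np.asarray(self.protocol.injection_volumes) * 1e6,
                "heat_ucal": self.heats * 1e9,  # kcal -> ucal
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_thermogram_csv(
    path,
    cell_volume: float,
    cell_conc: float,
    syringe_conc: float,
    temperature: float = T_DEFAULT,
) -> Thermogram:
    """Read injection_index, volume_uL, heat_ucal columns into a Thermogram."""
    df = pd.read_csv(path).sort_values("injection_index")
    protocol = TitrationProtocol(
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=tuple(df["volume_uL"].to_numpy() * 1e-6),
        temperature=temperature,
    )
    return Thermogram(heats=df["heat_ucal"].to_numpy() * 1e-9, protocol=protocol)


# ---------------------------------------------------------------------------
# Forward model


def bound_fraction(M_t, X_t, params: BindingParams):
    """Fraction of sites occupied (theta in [0, 1]) from the binding quadratic."""
    M_t = np.asarray(M_t, dtype=float)
    X_t = np.asarray(X_t, dtype=float)
    nM = params.n * M_t
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(nM > 0, X_t / nM, 0.0)
        inv = np.where(nM > 0, 1.0 / (params.n * params.Ka * M_t), 0.0)
    s = 1.0 + r + inv
    disc = s * s - 4.0 * r
    if np.any(disc < 0):
        warnings.warn("negative discriminant clamped to 0 in binding quadratic")
        disc = np.clip(disc, 0.0, None)
    theta = 0.5 * (s - np.sqrt(disc))
    return np.clip(theta, 0.0, 1.0)


def cumulative_heat(M_t, X_t, params: BindingParams, V0: float):
    """Total heat evolved (kcal) at cell composition (M_t, X_t): n*theta*M_t*dH*V0."""
    if np.any(np.asarray(M_t) < 0) or np.any(np.asarray(X_t) < 0):
        raise ValueError("concentrations must be non-negative")
    theta = bound_fraction(M_t, X_t, params)
    return params.n * theta * np.asarray(M_t, dtype=float) * params.dH * V0


def injection_heats(
    protocol: TitrationProtocol, params: BindingParams, q_dil: float = 0.0
) -> np.ndarray:
    """Noise-free per-injection heats under the displacement bookkeeping."""
    M, X = protocol.concentrations()
    Q = cumulative_heat(M, X, params, protocol.cell_volume)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    f = np.asarray(protocol.injection_volumes) / protocol.cell_volume
    return Q - Qprev + f * (Q + Qprev) / 2.0 + q_dil


def simulate_titration(
    protocol: TitrationProtocol,
    params: BindingParams,
    noise_sd: float = 0.0,
    q_dil: float = 0.0,
    seed: int | None = None,
) -> Thermogram:
    """Forward-simulate a thermogram with Gaussian heat noise (deterministic per seed)."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    q = injection_heats(protocol, params, q_dil)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=q.shape)
    return Thermogram(heats=q, protocol=protocol)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """One-set-of-sites fit with derived thermodynamics.

    dG = R T ln Kd, -T dS = dG - dH (so dG = dH + minus_TdS), and the Wiseman
    parameter c = n M0 / Kd indicates fit reliability (roughly 1 <= c <= 1000).
    """

    params: BindingParams
    q_dil: float
    dG: float
    minus_TdS: float
    stderr: dict[str, float]
    c_value: float
    converged: bool
    rss: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n": self.params.n,
            "Kd_molar": self.params.Kd,
            "Ka_per_molar": self.params.Ka,
            "dH_kcal_per_mol": self.params.dH,
            "q_dil_kcal": self.q_dil,
            "dG_kcal_per_mol": self.dG,
            "minus_TdS_kcal_per_mol": self.minus_TdS,
            "c_value": self.c_value,
            "converged": self.converged,
            "stderr": self.stderr,
        }


def delta_g(Kd: float, T: float = T_DEFAULT) -> float:
    """Binding free energy dG = R T ln Kd in kcal/mol (negative for Kd < 1 M)."""
    if not Kd > 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    return R_KCAL * T * np.log(Kd)


def ligand_efficiency(Kd: float, n_heavy: int, T: float = T_DEFAULT) -> float:
    """Ligand efficiency LE = -dG / N_heavy in (kcal/mol)/heavy atom.

    Presentation convention in tables is 2 decimal places; the full-precision
    value is returned here.
    """
    if n_heavy < 1:
        raise ValueError(f"n_heavy must be >= 1, got {n_heavy}")
    return -delta_g(Kd, T) / n_heavy


def fit_one_set_of_sites(
    thermogram: Thermogram,
    init: BindingParams | None = None,
    discard_first: bool = False,
    fixed_q_dil: float | None = None,
) -> FitResult:
    """Nonlinear least-squares fit of (n, Ka, dH, q_dil) to a thermogram.

    ``fixed_q_dil`` pins the dilution offset (e.g. from a buffer-control
    titration) instead of floating it. ``discard_first`` drops the first
    injection from the residuals, a common practice for syringe-tip dilution.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    protocol = thermogram.protocol
    n_free = 3 if fixed_q_dil is not None else 4
    usable = protocol.n_injections - (1 if discard_first else 0)
    if usable < 4:
        raise UnderDeterminedError(
            f"{usable} usable injections cannot constrain {n_free} parameters"
        )

    q_obs = thermogram.heats
    mask = np.ones(protocol.n_injections, dtype=bool)
    if discard_first:
        mask[0] = False

    # scale floor: heat of full saturation at 1 kcal/mol, guards all-zero data
    floor = protocol.cell_conc * protocol.cell_volume * 1.0
    scale = max(float(np.max(np.abs(q_obs))), floor)

    def residuals(p):
        n, log10_Ka, dH, q_dil = p
        q = injection_heats(protocol, BindingParams(n=n, Kd=10.0 ** -log10_Ka, dH=dH), q_dil)
        return (q - q_obs)[mask] / scale

    if init is not None:
        p0 = [init.n, np.log10(init.Ka), init.dH, 0.0 if fixed_q_dil is None else fixed_q_dil]
    else:
        q_dil0 = float(np.median(q_obs[-3:]))
        dH0 = float(np.sum(q_obs - q_dil0) / (protocol.cell_conc * protocol.cell_volume))
        if abs(dH0) < 1e-6:
            dH0 = -1.0 if np.sum(q_obs) <= 0 else 1.0
        # start at c = 50 (mid Wiseman window)
        p0 = [1.0, np.log10(50.0 / protocol.cell_conc), dH0, q_dil0]

    lower = [1e-2, 0.0, -1e3, -np.inf]
    upper = [1e2, 15.0, 1e3, np.inf]
    if fixed_q_dil is not None:
        eps = max(abs(fixed_q_dil) * 1e-12, 1e-18)
        p0[3] = fixed_q_dil
        lower[3] = fixed_q_dil - eps
        upper[3] = fixed_q_dil + eps

    sol = optimize.least_squares(
        residuals,
        p0,
        bounds=(lower, upper),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=20000,
    )

    n_fit, log10_Ka, dH_fit, q_dil_fit = sol.x
    Kd_fit = 10.0 ** -log10_Ka
    params = BindingParams(n=n_fit, Kd=Kd_fit, dH=dH_fit)
    T = protocol.temperature
    dG = delta_g(Kd_fit, T)
    c_value = n_fit * protocol.cell_conc / Kd_fit
    if not (1.0 <= c_value <= 1000.0):
        warnings.warn(
            f"Wiseman c = {c_value:.3g} outside the reliable window [1, 1000]"
        )

    # covariance from the Jacobian at the solution (residuals were scaled)
    stderr: dict[str, float] = {}
    dof = int(mask.sum()) - n_free
    if dof > 0 and sol.jac is not None:
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(JTJ) * (2.0 * sol.cost / dof)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderr = {
                "n": float(sd[0]),
                "Kd_molar": float(np.log(10.0) * Kd_fit * sd[1]),
                "dH_kcal_per_mol": float(sd[2]),
                "q_dil_kcal": float(sd[3]),
            }
        except np.linalg.LinAlgError:
            stderr = {}

    degenerate = abs(dH_fit) * protocol.cell_conc * protocol.cell_volume < 1e-3 * scale
    return FitResult(
        params=params,
        q_dil=float(q_dil_fit),
        dG=float(dG),
        minus_TdS=float(dG - dH_fit),
        stderr=stderr,
        c_value=float(c_value),
        converged=bool(sol.success and not degenerate),
        rss=float(2.0 * sol.cost * scale * scale),
    )


# ---------------------------------------------------------------------------
# Dose–response (4-parameter logistic)


@dataclass
class FourPLFit:
    """4PL fit y = bottom + (top - bottom) / (1 + (ec50/x)^hill)."""

    bottom: float
    top: float
    ec50: float
    hill: float
    ec50_defined: bool
    ec50_in_range: bool
    warning: str | None = None

    def response(self, x):
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ec50 / x) ** self.hill
        )


def fit_4pl(concentrations: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """Least-squares 4-parameter logistic fit for EC50 extraction.

    Requires >= 5 points spanning >= 2 log units of concentration. Flat data
    return ``ec50_defined=False``; a non-monotone trend beyond noise attaches
    a poor-fit warning rather than failing.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 5:
        raise ValueError(f"need >= 5 points, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.log10(x.max() / x.min()) < 2.0:
        raise ValueError("concentrations must span >= 2 log units")

    span = float(y.max() - y.min())
    noise_scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * noise_scale:
        return FourPLFit(
            bottom=float(y.mean()),
            top=float(y.mean()),
            ec50=np.nan,
            hill=np.nan,
            ec50_defined=False,
            ec50_in_range=False,
            warning="flat responses: EC50 undefined",
        )

    order = np.argsort(x)
    increasing = y[order][-1] >= y[order][0]

    def model(x, bottom, top, log_ec50, hill):
        return bottom + (top - bottom) / (1.0 + (10.0 ** log_ec50 / x) ** hill)

    p0 = [
        float(y[order][0]),
        float(y[order][-1]),
        float(np.log10(np.sqrt(x.min() * x.max()))),
        1.0 if increasing else 1.0,
    ]
    popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    bottom, top, log_ec50, hill = popt
    ec50 = 10.0 ** log_ec50

    resid = y - model(x, *popt)
    warning = None
    if np.sqrt(np.mean(resid**2)) > 0.2 * abs(top - bottom):
        warning = "poor fit: residuals exceed 20% of the response span"
    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(ec50),
        hill=float(hill),
        ec50_defined=True,
        ec50_in_range=bool(x.min() <= ec50 <= x.max()),
        warning=warning,
    )
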