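"""Isothermal titration calorimetry: one-set-of-sites fitting and the
temperature dependence of the binding thermodynamics.

A syringe species X (here the disordered region) is titrated into a cell
species M (the partner GTPase).  Each injection displaces cell volume, so
both species are diluted by (1 - dV/V0) per injection while titrant
accumulates; the bound complex follows the single-site quadratic and the
measured heat of injection i is

    q_i = dH * V0 * ([PM]_i - [PM]_{i-1} (1 - dV_i/V0)) + q_offset .

Several syringe refills into the same cell content are handled by simple
concatenation (the cell composition evolves continuously across segments).

The temperature series gives the heat-capacity change dCp as the slope of
dH vs T, the iso-entropic temperature T_S as the zero crossing of dS vs T,
and Kd at an unmeasured temperature by linear extrapolation of dG.  The
binding entropy is dissected with the Spolar-Record decomposition

    dS(T) = dS_conf + dS_desolv(T) + dS_rt ,
    dS_conf = -1.66 dCp ln(T_S / 386 K) + 110 J/mol/K ,
    dS_desolv(T) = 1.66 dCp ln(T / 386 K),  dS_rt = -110 J/mol/K,

and the number of residues folding upon binding follows from an average
per-residue conformational entropy loss of -24 J/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InvalidInputError

__all__ = [
    "InjectionSeries",
    "OneSiteFit",
    "ThermoTable",
    "EntropyDecomposition",
    "one_site_heats",
    "fit_one_site",
    "gibbs",
    "kd_from_gibbs",
    "extrapolate_kd",
    "heat_capacity",
    "iso_entropic_temp",
    "spolar_record",
    "folded_residue_count",
]

R_GAS = 8.314  # J mol^-1 K^-1

#: Spolar-Record constants (J mol^-1 K^-1 unless noted)
DS_RT = -110.0
T_REF_SPOLAR = 386.0  # K
DS_PER_RESIDUE = -24.0
SPOLAR_SLOPE = 1.66  # dimensionless multiplier of dCp


@dataclass
class InjectionSeries:
    """One (possibly concatenated) titration at a single temperature.

    Volumes in uL, concentrations in uM, heats in uJ.  ``segments`` holds
    the injection indices at which a syringe refill occurred.
    """

    temperature: float  # K
    v0: float  # cell volume, uL
    cell_conc: float  # uM
    syringe_conc: float  # uM
    volumes: np.ndarray  # uL per injection
    heats: np.ndarray  # uJ per injection
    segments: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.v0 <= 0 or np.any(self.volumes <= 0):
            raise InvalidInputError("volumes must be > 0")
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise InvalidInputError("concentrations must be > 0")
        if not np.all(np.isfinite(self.heats)):
            raise InvalidInputError("heats must be finite")
        if self.volumes.shape != self.heats.shape:
            raise InvalidInputError("volumes and heats must have equal length")


@dataclass
class OneSiteFit:
    """Parameters of the one-set-of-sites binding model."""

    n: float  # stoichiometry
    kd: float  # uM
    dh: float  # kJ/mol
    q_offset: float = 0.0  # uJ per injection
    n_sigma: float = 0.0
    kd_sigma: float = 0.0
    dh_sigma: float = 0.0
    flagged: bool = False

    def wiseman_c(self, cell_conc: float) -> float:
        """Dimensionless isotherm shape parameter c = n [cell] / Kd."""
        return self.n * cell_conc / self.kd


def one_site_heats(fit: OneSiteFit, series: InjectionSeries) -> np.ndarray:
    """Predicted per-injection heats (uJ) of the single-site model."""
    if series.syringe_conc <= 0:
        raise InvalidInputError("syringe concentration must be > 0")
    mt = series.cell_conc  # uM, partner in cell
    xt = 0.0  # uM, titrant in cell
    pm_prev = 0.0
    heats = np.empty(series.volumes.size)
    for i, dv in enumerate(series.volumes):
        f = 1.0 - dv / series.v0
        mt *= f
        xt = xt * f + series.syringe_conc * dv / series.v0
        sites = fit.n * mt
        s = sites + xt + fit.kd
        pm = (s - math.sqrt(max(s * s - 4.0 * sites * xt, 0.0))) / 2.0
        # heat in uJ: kJ/mol * uL * uM * 1e-3
        heats[i] = fit.dh * series.v0 * (pm - pm_prev * f) * 1e-3 + fit.q_offset
        pm_prev = pm
    return heats


def fit_one_site(
    series: InjectionSeries,
    init: OneSiteFit | None = None,
    fit_offset: bool = True,
    skip_first: bool = False,
) -> OneSiteFit:
    """Least-squares fit of (n, Kd, dH, q_offset) to a titration.

    ``skip_first`` optionally excludes the first injection of every segment
    from the residuals (classical guard against diffusion across the
    syringe tip); by default every injection is used.
    """
    if series.volumes.size < 10:
        raise InvalidInputError("need >= 10 injections for a one-site fit")
    if init is None:
        dh0 = series.heats[:3].mean() * 3.0 / (
            series.v0 * series.syringe_conc * series.volumes[0] / series.v0
        ) if series.heats[:3].mean() != 0 else 1.0
        init = OneSiteFit(n=1.0, kd=20.0, dh=float(np.clip(dh0, -200, 200)))
    use = np.ones(series.volumes.size, dtype=bool)
    if skip_first:
        use[0] = False
        for b in series.segments:
            if 0 <= b < use.size:
                use[b] = False

    scale_q = max(np.abs(series.heats).max(), 1.0)
    if np.abs(series.heats[use]).max() < 1e-12 * scale_q + 1e-30:
        return OneSiteFit(n=init.n, kd=init.kd, dh=0.0, flagged=True)

    def pack(x):
        return OneSiteFit(n=x[0], kd=10.0 ** x[1], dh=x[2],
                          q_offset=x[3] if fit_offset else 0.0)

    def resid(x):
        return (one_site_heats(pack(x), series) - series.heats)[use]

    x0 = [init.n, math.log10(init.kd), init.dh, init.q_offset]
    lb = [1e-3, -4.0, -1e4, -abs(scale_q)]
    ub = [1e3, 6.0, 1e4, abs(scale_q)]
    if not fit_offset:
        x0, lb, ub = x0[:3] + [0.0], lb[:3] + [-1e-12], ub[:3] + [1e-12]
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", x_scale="jac")
    out = pack(sol.x)
    out.flagged = not sol.success
    # covariance-derived uncertainties (linearization at the optimum)
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(use.sum() - sol.x.size, 1)
        cov = np.linalg.pinv(jtj) * 2.0 * sol.cost / dof
        sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        out.n_sigma = float(sig[0])
        out.kd_sigma = float(out.kd * math.log(10.0) * sig[1])
        out.dh_sigma = float(sig[2])
    except np.linalg.LinAlgError:
        pass
    return out


def gibbs(kd: float, temperature: float) -> float:
    """Binding free energy dG = R T ln(Kd / 1 M) in kJ/mol, Kd in uM."""
    if kd <= 0:
        raise InvalidInputError("Kd must be > 0")
    return R_GAS * temperature * math.log(kd * 1e-6) / 1000.0


def kd_from_gibbs(dg: float, temperature: float) -> float:
    """Inverse of :func:`gibbs`; returns Kd in uM."""
    return math.exp(dg * 1000.0 / (R_GAS * temperature)) * 1e6


@dataclass
class ThermoTable:
    """Per-temperature binding thermodynamics.

    Rows hold (T [K], Kd [uM], dG [kJ/mol], dH [kJ/mol], dS [J/mol/K]);
    dG = dH - T dS and dG = R T ln(Kd) hold identically per row because dS
    is constructed as (dH - dG)/T.
    """

    frame: pd.DataFrame

    @classmethod
    def from_fits(
        cls, fits: dict[float, OneSiteFit] | list[tuple[float, OneSiteFit]]
    ) -> "ThermoTable":
        items = fits.items() if isinstance(fits, dict) else fits
        rows = []
        for t, fit in sorted(items):
            dg = gibbs(fit.kd, t)
            ds = (fit.dh - dg) / t * 1000.0  # J/mol/K
            rows.append(
                {"T_K": t, "Kd_uM": fit.kd, "dG_kJ": dg, "dH_kJ": fit.dh,
                 "dS_J": ds, "minus_TdS_kJ": -t * ds / 1000.0}
            )
        return cls(pd.DataFrame(rows))

    def _require(self, n: int) -> None:
        if len(self.frame) < n:
            raise InvalidInputError(f"need >= {n} temperatures")


def heat_capacity(table: ThermoTable) -> float:
    """dCp (kJ/mol/K): slope of the linear fit of dH vs T."""
    table._require(3)
    return float(np.polyfit(table.frame["T_K"], table.frame["dH_kJ"], 1)[0])


def extrapolate_kd(table: ThermoTable, t_target: float) -> float:
    """Kd (uM) at ``t_target`` from a linear fit of dG vs T."""
    table._require(3)
    coef = np.polyfit(table.frame["T_K"], table.frame["dG_kJ"], 1)
    return kd_from_gibbs(float(np.polyval(coef, t_target)), t_target)


def iso_entropic_temp(table: ThermoTable) -> float:
    """T_S (K): zero crossing of the linear fit of dS vs T."""
    table._require(3)
    slope, intercept = np.polyfit(table.frame["T_K"], table.frame["dS_J"], 1)
    span = abs(table.frame["dS_J"]).max() + 1.0
    t_span = table.frame["T_K"].max() - table.frame["T_K"].min()
    if abs(slope) * t_span < 1e-9 * span:
        raise InvalidInputError("dS(T) has no resolvable slope; T_S undefined")
    return float(-intercept / slope)


@dataclass(frozen=True)
class EntropyDecomposition:
    """Spolar-Record dissection of the binding entropy at temperature T."""

    temperature: float  # K
    ds_total: float  # J/mol/K
    ds_conformational: float
    ds_desolvation: float
    ds_rt: float = DS_RT
    folded_residues: int = 0

    def __post_init__(self) -> None:
        parts = self.ds_conformational + self.ds_desolvation + self.ds_rt
        if abs(self.ds_total - parts) > 1e-6:
            raise InvalidInputError("entropy components do not sum to the total")


def spolar_record(
    dcp: float, t_s: float, temperature: float | None = None
) -> EntropyDecomposition:
    """Entropy decomposition from dCp (kJ/mol/K) and T_S (K).

    Evaluated at ``temperature`` (defaults to T_S, where the total entropy
    vanishes by construction).
    """
    if not math.isfinite(dcp):
        raise InvalidInputError("dCp must be finite")
    if t_s <= 0 or (temperature is not None and temperature <= 0):
        raise InvalidInputError("temperatures must be > 0 K")
    t = t_s if temperature is None else temperature
    dcp_j = dcp * 1000.0
    ds_conf = -SPOLAR_SLOPE * dcp_j * math.log(t_s / T_REF_SPOLAR) - DS_RT
    ds_desolv = SPOLAR_SLOPE * dcp_j * math.log(t / T_REF_SPOLAR)
    ds_total = ds_conf + ds_desolv + DS_RT
    return EntropyDecomposition(
        temperature=t,
        ds_total=ds_total,
        ds_conformational=ds_conf,
        ds_desolvation=ds_desolv,
        folded_residues=folded_residue_count(ds_conf),
    )


def folded_residue_count(
    ds_conf: float, per_residue: float = DS_PER_RESIDUE
) -> int:
    """Residues folding upon binding, from the conformational entropy loss."""
    if per_residue >= 0:
        raise InvalidInputError("per-residue entropy loss must be < 0")
    return round(ds_conf / per_residue)
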