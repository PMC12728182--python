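"""Ground-truth data generator emulating the study conditions.

Generates CEST datasets, R1rho decay curves and ITC titration series with
the statistical structure the analysis stages assume, so every stage can be
verified by parameter recovery against a known truth.

The default scenario reproduces the experimental design: a 4-site linear
exchange chain with the fitted rates as truth, populations constrained by
Kd = 24 uM with 500 uM of the disordered region and 100 uM partner, four
saturation fields (5.2/10.3/20.5 Hz D-CEST with 240/448/800 Hz windows and
8/16/32 Hz steps, 68.6 Hz CW sampled at 100 Hz steps over 103-134 ppm),
Tsat = 0.4 s, and homoscedastic Gaussian intensity noise.  Residue classes
follow the chemical-shift-difference patterns of the folding hierarchy:

* ``crib``   — anchored already in intermediate A: |dw_FA| in [1, 4] ppm,
  dw_FB = dw_FA, dw_FC close to dw_FB;
* ``mre1_helix`` — folds in B: dw_FA = 0, |dw_FB| in [1, 5] ppm,
  dw_FC close to dw_FB;
* ``mre2``   — partially shifted in B, fully in C: dw_FA = 0,
  dw_FB = f * dw_FC with f in (0.2, 0.8), |dw_FC| in [1, 6] ppm;
* ``linker``/``outside`` — no shift changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidInputError
from .exchange import (
    ExchangeScheme,
    MixtureComposition,
    bound_fraction,
    partition_populations,
)
from .forward import CestExperiment, CestProfile, ResidueSpinSystem, _profile_intensities
from .analysis import CestDataset, ResidueMeta
from .relaxation import DEFAULT_DELAYS, DecayCurve
from .itc import InjectionSeries, OneSiteFit, gibbs, kd_from_gibbs, one_site_heats

__all__ = [
    "STUDY_SCHEME",
    "STUDY_COMPOSITION",
    "GroundTruthScenario",
    "make_default_scenario",
    "make_reduced_scenario",
    "generate_cest_dataset",
    "generate_decays",
    "generate_titrations",
    "default_experiments",
]

#: globally fitted 4-site exchange rates of the study (s^-1; kon in M^-1 s^-1)
STUDY_SCHEME = ExchangeScheme(
    kon=7.3e5, koff=56.0, k_ab=72.0, k_ba=64.0, k_bc=89.0, k_cb=94.0
)

#: CEST sample composition: 500 uM IDP, 100 uM partner, Kd = 24 uM at 25 C
STUDY_COMPOSITION = MixtureComposition(p0=500.0, r0=100.0, kd=24.0)

_CLASS_RULES = {
    "crib": {"dwfa": (1.0, 4.0)},
    "mre1_helix": {"dwfb": (1.0, 5.0)},
    "mre2": {"dwfc": (1.0, 6.0), "f": (0.2, 0.8)},
    "linker": {},
    "outside": {},
}


def default_experiments(
    larmor: float = 96.3, carrier: float = 118.5, tsat: float = 0.4
) -> list[CestExperiment]:
    """The four-field experiment grid of the study."""
    expts = []
    for b1, window, step in [(5.2, 240.0, 8.0), (10.3, 448.0, 16.0),
                             (20.5, 800.0, 32.0)]:
        offsets = np.arange(-window / 2.0, window / 2.0, step)
        expts.append(CestExperiment(b1=b1, tsat=tsat, offsets=offsets,
                                    scheme="dante", dante_window=window,
                                    larmor_15n=larmor, carrier=carrier))
    lo, hi = (103.0 - carrier) * larmor, (134.0 - carrier) * larmor
    offsets = np.arange(lo, hi, 100.0)
    expts.append(CestExperiment(b1=68.6, tsat=tsat, offsets=offsets,
                                scheme="cw", larmor_15n=larmor,
                                carrier=carrier))
    return expts


@dataclass
class GroundTruthScenario:
    """Everything needed to generate one synthetic CEST study."""

    scheme: ExchangeScheme
    composition: MixtureComposition
    residues: dict  # rid -> ResidueMeta (class_label set)
    spins: dict  # rid -> ResidueSpinSystem (the truth)
    experiments: list
    sigma: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidInputError("residue roster must be non-empty")
        if self.sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")

    @property
    def crib_truth(self) -> frozenset:
        return frozenset(r for r, m in self.residues.items()
                         if m.class_label == "crib")


def _draw_spin(rid: int, label: str, rng: np.random.Generator,
               carrier: float) -> tuple[ResidueSpinSystem, float]:
    """Residue truth following the class rules; returns (spin, shift_F)."""
    if label not in _CLASS_RULES:
        raise InvalidInputError(f"unknown residue class {label!r}")
    shift_f = rng.uniform(carrier - 3.5, carrier + 3.5)
    sign = rng.choice([-1.0, 1.0])
    dwfa = dwfb = dwfc = 0.0
    if label == "crib":
        dwfa = sign * rng.uniform(*_CLASS_RULES["crib"]["dwfa"])
        dwfb = dwfa
        dwfc = dwfb + rng.uniform(-0.4, 0.4)
    elif label == "mre1_helix":
        dwfb = sign * rng.uniform(*_CLASS_RULES["mre1_helix"]["dwfb"])
        dwfc = dwfb + rng.uniform(-0.4, 0.4)
    elif label == "mre2":
        dwfc = sign * rng.uniform(*_CLASS_RULES["mre2"]["dwfc"])
        dwfb = rng.uniform(*_CLASS_RULES["mre2"]["f"]) * dwfc
    spin = ResidueSpinSystem(
        residue_id=rid, shift_f=shift_f,
        dw_fa=dwfa, dw_fb=dwfb, dw_fc=dwfc,
        r1=rng.uniform(1.0, 2.0),
        r2_f=rng.uniform(3.0, 8.0),
        r2_b=rng.uniform(15.0, 40.0),
        r2_c=rng.uniform(15.0, 40.0),
        r2_a=None,  # resolved per tie rule at simulation time
    )
    return spin, shift_f


#: default roster: the CRIB truth plus representatives of each later class
DEFAULT_ROSTER = {
    325: "crib", 327: "crib", 330: "crib", 331: "crib", 333: "crib",
    336: "mre1_helix", 339: "mre1_helix", 343: "mre1_helix",
    349: "linker",
    357: "mre2", 359: "mre2", 364: "mre2",
}


def make_default_scenario(
    seed: int = 0,
    roster: dict | None = None,
    sigma: float = 0.004,
    scheme: ExchangeScheme = STUDY_SCHEME,
    composition: MixtureComposition = STUDY_COMPOSITION,
    experiments: list | None = None,
) -> GroundTruthScenario:
    """Study-scale scenario: 12 residues across all classes, 4 B1 fields."""
    roster = dict(DEFAULT_ROSTER) if roster is None else dict(roster)
    experiments = experiments or default_experiments()
    carrier = experiments[0].carrier
    rng = np.random.default_rng(seed)
    residues, spins = {}, {}
    for rid in sorted(roster):
        label = roster[rid]
        spin, shift_f = _draw_spin(rid, label, rng, carrier)
        residues[rid] = ResidueMeta(residue_id=rid, shift_f=shift_f,
                                    class_label=label)
        spins[rid] = spin
    return GroundTruthScenario(
        scheme=scheme, composition=composition, residues=residues,
        spins=spins, experiments=experiments, sigma=sigma, seed=seed,
    )


def make_reduced_scenario(seed: int = 0, sigma: float = 0.004,
                          scheme: ExchangeScheme = STUDY_SCHEME) -> GroundTruthScenario:
    """Small calibration scenario for seed sweeps: 3 residues, 2 B1 fields,
    coarse offset grids (one residue per shifted class)."""
    carrier, larmor = 118.5, 96.3
    expts = [
        CestExperiment(b1=10.3, tsat=0.4,
                       offsets=np.arange(-224.0, 224.0, 28.0),
                       scheme="dante", dante_window=448.0,
                       larmor_15n=larmor, carrier=carrier),
        CestExperiment(b1=68.6, tsat=0.4,
                       offsets=np.arange(-1450.0, 1450.0, 150.0),
                       scheme="cw", larmor_15n=larmor, carrier=carrier),
    ]
    roster = {327: "crib", 339: "mre1_helix", 359: "mre2"}
    return make_default_scenario(seed=seed, roster=roster, sigma=sigma,
                                 scheme=scheme, experiments=expts)


def generate_cest_dataset(
    scenario: GroundTruthScenario,
) -> tuple[CestDataset, dict]:
    """Simulate every (residue, B1) profile and add Gaussian noise.

    Returns the dataset plus a ground-truth record (global rates, true
    populations and per-residue parameters) for recovery checks.
    """
    rng = np.random.default_rng(scenario.seed)
    scheme = scenario.scheme
    pops = partition_populations(bound_fraction(scenario.composition), scheme)
    crib = scenario.crib_truth
    profiles = []
    for rid in sorted(scenario.residues):
        base_spin = scenario.spins[rid]
        # tie rule of the truth: R2A = R2B inside the anchored set, R2F outside
        r2_a = base_spin.r2_b if rid in crib else base_spin.r2_f
        spin = replace(base_spin, r2_a=r2_a)
        for expt in scenario.experiments:
            clean = _profile_intensities(spin, scheme, pops, expt)
            noisy = clean + rng.normal(0.0, scenario.sigma, clean.size)
            profiles.append(CestProfile(
                residue_id=rid, experiment=expt,
                offsets=expt.offsets.copy(), intensities=noisy,
                sigmas=np.full(clean.size, scenario.sigma),
            ))
    dataset = CestDataset(
        profiles=profiles,
        composition=scenario.composition,
        residues=dict(scenario.residues),
    )
    truth = {
        "model": scheme.model,
        "koff": scheme.koff,
        "k_ab": scheme.k_ab, "k_ba": scheme.k_ba,
        "k_bc": scheme.k_bc, "k_cb": scheme.k_cb,
        "kon": scheme.kon,
        "kex_ab": scheme.kex_ab if scheme.model == "4site" else None,
        "kex_bc": scheme.kex_bc,
        "keq_ab": scheme.keq_ab if scheme.model == "4site" else None,
        "keq_bc": scheme.keq_bc,
        "populations": {"p_f": pops.p_f, "p_a": pops.p_a,
                        "p_b": pops.p_b, "p_c": pops.p_c},
        "sigma": scenario.sigma,
        "seed": scenario.seed,
        "crib_set": sorted(crib),
        "residues": {
            rid: {"shift_f": s.shift_f, "dw_fa": s.dw_fa, "dw_fb": s.dw_fb,
                  "dw_fc": s.dw_fc, "r1": s.r1, "r2_f": s.r2_f,
                  "r2_b": s.r2_b, "r2_c": s.r2_c,
                  "class": scenario.residues[rid].class_label}
            for rid, s in scenario.spins.items()
        },
    }
    return dataset, truth


def generate_decays(
    rates: dict,
    schedule: np.ndarray = DEFAULT_DELAYS,
    sigma: float = 0.0,
    seed: int | None = None,
    amplitude: float = 100.0,
) -> list[DecayCurve]:
    """Exponential decays at the experiment's delay schedule.

    ``rates`` maps residue_id -> R1rho truth (s^-1); ``sigma`` is the
    absolute intensity noise per plane.
    """
    rng = np.random.default_rng(seed)
    schedule = np.asarray(schedule, dtype=float)
    curves = []
    for rid, rate in sorted(rates.items()):
        if rate <= 0:
            raise InvalidInputError("decay rates must be > 0")
        clean = amplitude * np.exp(-rate * schedule)
        noisy = clean + rng.normal(0.0, sigma, schedule.size) if sigma else clean
        curves.append(DecayCurve(
            residue_id=rid, delays=schedule.copy(), intensities=noisy,
            plane_noise=np.full(schedule.size, sigma) if sigma else
            np.full(schedule.size, 1e-12),
        ))
    return curves


def generate_titrations(
    kd_ref: float = 24.0,  # uM at the reference temperature
    dh_ref: float = 0.0,  # kJ/mol at the reference temperature
    dcp: float = -2.8,  # kJ/mol/K
    t_ref: float = 298.15,  # K
    temperatures: tuple = (278.15, 283.15, 288.15, 308.15),
    sigma_q: float = 0.0,  # uJ heat noise
    seed: int | None = None,
    duplicates: int = 1,
    n_injections: int = 39,  # 3 x 13 syringe fills
    injection_volume: float = 3.0,  # uL
    v0: float = 200.0,  # uL (PEAQ-type cell)
    cell_conc: float = 125.0,  # uM
    syringe_conc: float = 1000.0,  # uM
) -> tuple[list[InjectionSeries], dict]:
    """Single-site titration series across a temperature range.

    The thermodynamic anchor propagates as dH(T) = dH_ref + dCp (T - T_ref)
    and dS(T) = dS_ref + dCp ln(T / T_ref), which fixes Kd(T) through
    dG = dH - T dS.
    """
    rng = np.random.default_rng(seed)
    dg_ref = gibbs(kd_ref, t_ref)
    ds_ref = (dh_ref - dg_ref) / t_ref  # kJ/mol/K
    series, truth_rows = [], []
    segments = tuple(range(13, n_injections, 13))
    for t in temperatures:
        dh = dh_ref + dcp * (t - t_ref)
        ds = ds_ref + dcp * np.log(t / t_ref)
        dg = dh - t * ds
        kd = kd_from_gibbs(dg, t)
        truth_rows.append({"T_K": t, "Kd_uM": kd, "dH_kJ": dh,
                           "dG_kJ": dg, "dS_J": ds * 1000.0})
        fit = OneSiteFit(n=1.0, kd=kd, dh=dh)
        for _ in range(duplicates):
            s = InjectionSeries(
                temperature=t, v0=v0, cell_conc=cell_conc,
                syringe_conc=syringe_conc,
                volumes=np.full(n_injections, injection_volume),
                heats=np.zeros(n_injections), segments=segments,
            )
            heats = one_site_heats(fit, s)
            if sigma_q:
                heats = heats + rng.normal(0.0, sigma_q, heats.size)
            s.heats = heats
            series.append(s)
    truth = {"kd_ref": kd_ref, "dh_ref": dh_ref, "dcp": dcp, "t_ref": t_ref,
             "rows": truth_rows, "seed": seed}
    return series, truth
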