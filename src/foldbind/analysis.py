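"""Staged inference on CEST datasets: noise estimation, dip picking,
residue-specific 3-site fits with minor-state assignment, constrained global
3-site and 4-site fits, nested-model comparison, bootstrap uncertainties,
CRIB-boundary search and grid-search diagnostics.

The population-sum constraint is central: the total bound fraction is fixed
from the mixture composition (concentrations and the calorimetric Kd), so
the fits never optimise absolute populations — only the step equilibrium
constants that partition the bound fraction among the chain states.  The
exchange rates and equilibrium constants are optimised in log10 space for
conditioning; chemical-shift differences and relaxation rates stay linear.

The global fit couples a handful of exchange parameters to several hundred
residue-specific parameters.  Because each residue-specific parameter only
touches that residue's rows, the Jacobian is block sparse; the fits exploit
this with grouped finite differences (``jac_sparsity``) under a bounded
trust-region least-squares minimiser.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .exceptions import InvalidInputError
from .exchange import (
    ExchangeScheme,
    MixtureComposition,
    bound_fraction,
    partition_populations,
)
from .forward import (
    CestExperiment,
    CestProfile,
    ResidueSpinSystem,
    _profile_intensities,
    exclusion_mask,
)

__all__ = [
    "ResidueMeta",
    "CestDataset",
    "FitSpec",
    "GlobalFitResult",
    "BootstrapSummary",
    "AssignmentResult",
    "ModelComparison",
    "CribSearchResult",
    "estimate_noise",
    "robust_noise",
    "pick_dips",
    "fit_residue_3site",
    "assign_minor_states",
    "fit_global",
    "compare_models",
    "bootstrap_global",
    "search_crib_boundary",
    "grid_search",
    "derive_kon",
    "scheme_from_globals",
]

GLOBAL_PARAMS = {
    "3site": ("koff", "k_bc", "k_cb"),
    "4site": ("koff", "kex_ab", "kex_bc", "keq_ab", "keq_bc"),
}

DEFAULT_BOUNDS = {
    "rate": (1e-3, 1e4),  # s^-1
    "keq": (1e-3, 1e3),
    "dw": (-20.0, 20.0),  # ppm
    "r1": (0.01, 50.0),  # s^-1
    "r2": (0.1, 500.0),  # s^-1
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ResidueMeta:
    """Per-residue metadata carried alongside the profiles."""

    residue_id: int
    shift_f: float  # major-state 15N shift, ppm
    class_label: str = "unknown"
    assignable: bool = True


@dataclass
class CestDataset:
    """All CEST profiles of one sample plus the binding constraint."""

    profiles: list[CestProfile]
    composition: MixtureComposition
    residues: dict[int, ResidueMeta]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.profiles:
            key = (p.residue_id, p.experiment.b1)
            if key in seen:
                raise InvalidInputError(
                    f"duplicate profile for residue {p.residue_id} at "
                    f"B1 = {p.experiment.b1} Hz"
                )
            seen.add(key)
            if p.residue_id not in self.residues:
                raise InvalidInputError(
                    f"profile references unknown residue {p.residue_id}"
                )

    @property
    def residue_ids(self) -> list[int]:
        return sorted({p.residue_id for p in self.profiles})

    def profiles_for(self, residue_id: int) -> list[CestProfile]:
        return [p for p in self.profiles if p.residue_id == residue_id]

    def subset(self, residue_ids) -> "CestDataset":
        keep = set(residue_ids)
        return CestDataset(
            profiles=[p for p in self.profiles if p.residue_id in keep],
            composition=self.composition,
            residues={r: m for r, m in self.residues.items() if r in keep},
        )

    def apply_noise_estimates(self, robust: bool = True) -> None:
        """Set per-point sigmas from the profile noise.

        By default the outlier-resistant (median-based) second-difference
        estimate is used for the fit weights: the mean-square form is
        biased high wherever dips curve within a few grid steps, which
        distorts the relative weighting of finely and coarsely sampled
        profiles.  Pass ``robust=False`` for the classical mean-square
        estimator.
        """
        for p in self.profiles:
            sigma = robust_noise(p) if robust else estimate_noise(p)
            p.sigmas = np.full(p.offsets.shape, max(sigma, 1e-6))

    def apply_exclusion_masks(self) -> None:
        """Drop points within +-B1 of each residue's major-state dip."""
        for p in self.profiles:
            shift = self.residues[p.residue_id].shift_f
            p.mask = p.mask & exclusion_mask(p, p.experiment.b1, shift)


@dataclass
class FitSpec:
    """What to fit and how.

    ``crib_set`` lists the residues treated as anchored already in the first
    intermediate A (4-site only): their R2A is tied to R2B and their dw_FA
    is free (initialised at dw_FB); all other residues have R2A = R2F and,
    with ``fix_dwfa_outside_crib`` (default), dw_FA fixed at 0.
    ``r2b_eq_r2c`` lists residues whose minor-state transverse rates are
    tied for convergence.
    """

    model: str = "4site"
    crib_set: frozenset = frozenset()
    r2b_eq_r2c: frozenset = frozenset()
    excluded_residues: frozenset = frozenset()
    fix_dwfa_outside_crib: bool = True
    global_init: dict = field(default_factory=dict)
    residue_init: dict = field(default_factory=dict)  # rid -> {name: value}
    fixed_globals: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 1
    jitter: float = 0.5  # relative multi-start jitter on rate parameters
    max_nfev: int | None = None
    ftol: float = 1e-8

    def __post_init__(self) -> None:
        if self.model not in GLOBAL_PARAMS:
            raise InvalidInputError(f"unknown model {self.model!r}")
        self.crib_set = frozenset(self.crib_set)
        self.r2b_eq_r2c = frozenset(self.r2b_eq_r2c)
        self.excluded_residues = frozenset(self.excluded_residues)

    def default_global_init(self) -> dict:
        if self.model == "3site":
            base = {"koff": 50.0, "k_bc": 100.0, "k_cb": 100.0}
        else:
            base = {"koff": 50.0, "kex_ab": 200.0, "kex_bc": 200.0,
                    "keq_ab": 1.0, "keq_bc": 1.0}
        base.update(self.global_init)
        return base


@dataclass
class GlobalFitResult:
    """Outcome of a (possibly global) constrained least-squares fit."""

    model: str
    global_params: dict
    residue_params: dict  # rid -> {name: value}
    chi2: float
    n_points: int
    n_free: int
    global_sigmas: dict | None = None
    residuals: np.ndarray | None = None
    success: bool = True
    message: str = ""
    spec: FitSpec | None = None

    @property
    def dof(self) -> int:
        return self.n_points - self.n_free

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.dof, 1)


@dataclass
class BootstrapSummary:
    n_replicates: int
    n_dropped: int
    samples: dict  # name -> np.ndarray of replicate values
    ci68: dict  # name -> (lo, hi)
    seed: int | None


@dataclass
class AssignmentResult:
    residue_id: int
    accepted: str  # "original" | "swapped" | "ambiguous"
    original: GlobalFitResult
    swapped: GlobalFitResult | None
    reverted: bool = False


@dataclass
class ModelComparison:
    f_stat: float
    p_value: float
    preferred: str
    delta_k: int
    alpha: float = 0.05


@dataclass
class CribSearchResult:
    best_set: frozenset
    trace: pd.DataFrame
    no_crib: bool
    best_fit: GlobalFitResult


# ---------------------------------------------------------------------------
# noise and dip picking
# ---------------------------------------------------------------------------

def estimate_noise(profile: CestProfile) -> float:
    """Noise sigma of a profile from a second-difference filter.

    The filter annihilates the smooth (locally linear) signal component, so
    sigma^2 = sum (y_{i-1} - 2 y_i + y_{i+1})^2 / (6 (N - 2)) estimates the
    point noise even when the profile has little flat baseline.
    """
    y = profile.intensities[profile.mask]
    n = y.size
    if n < 5:
        raise InvalidInputError("need >= 5 points to estimate noise")
    d2 = y[:-2] - 2.0 * y[1:-1] + y[2:]
    return float(np.sqrt((d2 ** 2).sum() / (6.0 * (n - 2))))


def robust_noise(profile: CestProfile) -> float:
    """Outlier-resistant noise sigma for dip picking.

    The mean-square second-difference estimator is biased high wherever the
    dips themselves curve within a few grid steps; the median absolute
    second difference resists those points and tracks the true noise floor,
    which is what a picking threshold needs.
    """
    y = profile.intensities[profile.mask]
    if y.size < 5:
        raise InvalidInputError("need >= 5 points to estimate noise")
    d2 = y[:-2] - 2.0 * y[1:-1] + y[2:]
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


def pick_dips(
    profile: CestProfile,
    depth_threshold: float = 5.0,
    sigma: float | None = None,
    major_shift: float | None = None,
) -> list[float]:
    """Candidate minor-state positions (ppm), sorted by dip depth.

    Local minima deeper than ``depth_threshold * sigma`` below the local
    baseline (median of the upper half of the intensities) are returned,
    excluding the major-state window of +-B1 Hz when ``major_shift`` is
    given.  ``sigma`` defaults to the outlier-resistant estimate of
    :func:`robust_noise`.
    """
    if sigma is None:
        sigma = robust_noise(profile)
    y = profile.intensities
    baseline = float(np.median(np.sort(y)[y.size // 2:]))
    # prominence (not raw depth) rejects noise wiggles on the flanks of
    # real dips; the baseline test drops shallow ripples in saturated areas
    peaks, props = find_peaks(-y, prominence=depth_threshold * sigma)
    keep = [i for i, p in enumerate(peaks)
            if baseline - y[p] >= depth_threshold * sigma]
    peaks = peaks[keep]
    depths = props["prominences"][keep]
    if major_shift is not None:
        keep_mask = exclusion_mask(profile, profile.experiment.b1, major_shift)
        sel = [i for i, p in enumerate(peaks) if keep_mask[p]]
        peaks, depths = peaks[sel], depths[sel]
    order = np.argsort(depths)[::-1]
    ppm = np.atleast_1d(profile.experiment.hz_to_ppm(profile.offsets[peaks]))
    return [float(ppm[i]) for i in order]


# ---------------------------------------------------------------------------
# model machinery
# ---------------------------------------------------------------------------

def scheme_from_globals(model: str, g: dict) -> ExchangeScheme:
    """Exchange scheme from the fit's global parameters (kon placeholder 1)."""
    if model == "3site":
        return ExchangeScheme(kon=1.0, koff=g["koff"],
                              k_bc=g["k_bc"], k_cb=g["k_cb"])
    kab = g["kex_ab"] * g["keq_ab"] / (1.0 + g["keq_ab"])
    kba = g["kex_ab"] / (1.0 + g["keq_ab"])
    kbc = g["kex_bc"] * g["keq_bc"] / (1.0 + g["keq_bc"])
    kcb = g["kex_bc"] / (1.0 + g["keq_bc"])
    return ExchangeScheme(kon=1.0, koff=g["koff"], k_ab=kab, k_ba=kba,
                          k_bc=kbc, k_cb=kcb)


def derive_kon(scheme: ExchangeScheme, comp: MixtureComposition) -> float:
    """Bimolecular kon (M^-1 s^-1) implied by koff, the constrained
    populations and the free-partner concentration from mass balance."""
    fb = bound_fraction(comp)
    pops = partition_populations(fb, scheme)
    free_r_uM = comp.r0 - fb * comp.p0
    if free_r_uM <= 0:
        raise InvalidInputError("no free partner left; kon undefined")
    p_first = pops.p_a if scheme.model == "4site" else pops.p_b
    return scheme.koff * (p_first / pops.p_f) / (free_r_uM * 1e-6)


class _Param:
    __slots__ = ("name", "rid", "init", "lo", "hi", "log")

    def __init__(self, name, rid, init, lo, hi, log=False):
        self.name, self.rid, self.log = name, rid, log
        self.init, self.lo, self.hi = init, lo, hi


class _CestModel:
    """Parameter bookkeeping + residual evaluation for one dataset/spec."""

    def __init__(self, dataset: CestDataset, spec: FitSpec):
        self.comp = dataset.composition
        self.spec = spec
        self.total_bound = bound_fraction(self.comp)
        self.rids = [r for r in dataset.residue_ids
                     if r not in spec.excluded_residues]
        if not self.rids:
            raise InvalidInputError("no residues left to fit")
        self.profiles = [p for p in dataset.profiles
                         if p.residue_id in set(self.rids)]
        self.meta = dataset.residues
        self._build_params()
        self._build_rows()

    # -- parameters -------------------------------------------------------
    def _build_params(self) -> None:
        spec = self.spec
        b = spec.bounds
        ginit = spec.default_global_init()
        self.params: list[_Param] = []
        for name in GLOBAL_PARAMS[spec.model]:
            if name in spec.fixed_globals:
                continue
            lo, hi = b["keq"] if name.startswith("keq") else b["rate"]
            self.params.append(_Param(name, None, ginit[name], lo, hi, log=True))
        for rid in self.rids:
            rinit = dict(spec.residue_init.get(rid, {}))
            names = ["dw_fb", "dw_fc", "r1", "r2_f", "r2_b"]
            if rid not in spec.r2b_eq_r2c:
                names.append("r2_c")
            if spec.model == "4site" and (
                rid in spec.crib_set or not spec.fix_dwfa_outside_crib
            ):
                names.insert(0, "dw_fa")
            defaults = {"dw_fa": rinit.get("dw_fb", 0.0), "dw_fb": 0.0,
                        "dw_fc": 0.0, "r1": 1.5, "r2_f": 5.0, "r2_b": 30.0,
                        "r2_c": 30.0}
            for name in names:
                init = rinit.get(name, defaults[name])
                if name.startswith("dw"):
                    lo, hi = b["dw"]
                elif name == "r1":
                    lo, hi = b["r1"]
                else:
                    lo, hi = b["r2"]
                init = float(np.clip(init, lo if not name.startswith("dw")
                                     else lo + 1e-9, hi - 1e-9))
                self.params.append(_Param(name, rid, init, lo, hi))
        self.n_free = len(self.params)

    def x0(self) -> np.ndarray:
        return np.array([math.log10(p.init) if p.log else p.init
                         for p in self.params])

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([math.log10(p.lo) if p.log else p.lo for p in self.params])
        hi = np.array([math.log10(p.hi) if p.log else p.hi for p in self.params])
        return lo, hi

    def unpack(self, x: np.ndarray) -> tuple[dict, dict]:
        g = dict(self.spec.fixed_globals)
        per_res: dict[int, dict] = {rid: {} for rid in self.rids}
        for p, v in zip(self.params, x):
            val = 10.0 ** v if p.log else float(v)
            if p.rid is None:
                g[p.name] = val
            else:
                per_res[p.rid][p.name] = val
        for rid, d in per_res.items():
            if "r2_c" not in d:
                d["r2_c"] = d["r2_b"]
            if "dw_fa" not in d:
                d["dw_fa"] = 0.0
        return g, per_res

    # -- data layout ------------------------------------------------------
    def _build_rows(self) -> None:
        self.row_slices: list[slice] = []
        data, sig, offs = [], [], []
        pos = 0
        for p in self.profiles:
            m = p.mask
            if p.sigmas is None:
                raise InvalidInputError(
                    "profiles need sigmas before fitting; run noise estimation"
                )
            n = int(m.sum())
            self.row_slices.append(slice(pos, pos + n))
            pos += n
            data.append(p.intensities[m])
            sig.append(p.sigmas[m])
            offs.append(p.offsets[m])
        self.data = np.concatenate(data)
        self.sigma = np.concatenate(sig)
        self.used_offsets = offs
        self.n_points = pos

    def jac_sparsity(self) -> np.ndarray:
        s = np.zeros((self.n_points, self.n_free), dtype=bool)
        for j, p in enumerate(self.params):
            if p.rid is None:
                s[:, j] = True
            else:
                for prof, sl in zip(self.profiles, self.row_slices):
                    if prof.residue_id == p.rid:
                        s[sl, j] = True
        return s

    # -- evaluation -------------------------------------------------------
    def _spin(self, rid: int, rp: dict) -> ResidueSpinSystem:
        in_crib = rid in self.spec.crib_set
        r2_a = rp["r2_b"] if (self.spec.model == "4site" and in_crib) else rp["r2_f"]
        return ResidueSpinSystem(
            residue_id=rid,
            shift_f=self.meta[rid].shift_f,
            dw_fa=rp["dw_fa"],
            dw_fb=rp["dw_fb"],
            dw_fc=rp["dw_fc"],
            r1=rp["r1"],
            r2_f=rp["r2_f"],
            r2_b=rp["r2_b"],
            r2_c=rp["r2_c"],
            r2_a=r2_a,
        )

    def model_values(self, x: np.ndarray) -> np.ndarray:
        g, per_res = self.unpack(x)
        scheme = scheme_from_globals(self.spec.model, g)
        pops = partition_populations(self.total_bound, scheme)
        out = np.empty(self.n_points)
        for prof, sl, offs in zip(self.profiles, self.row_slices,
                                  self.used_offsets):
            spin = self._spin(prof.residue_id, per_res[prof.residue_id])
            expt = replace(prof.experiment, offsets=offs)
            out[sl] = _profile_intensities(spin, scheme, pops, expt)
        return out

    def residuals(self, x: np.ndarray,
                  weights: np.ndarray | None = None) -> np.ndarray:
        r = (self.model_values(x) - self.data) / self.sigma
        return r if weights is None else r * weights

    def chi2(self, x: np.ndarray) -> float:
        return float((self.residuals(x) ** 2).sum())

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        x0: np.ndarray | None = None,
        weights: np.ndarray | None = None,
        n_starts: int | None = None,
        rng: np.random.Generator | None = None,
        max_nfev: int | None = None,
    ):
        if x0 is None:
            x0 = self.x0()
        lo, hi = self.bounds_arrays()
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        sparsity = self.jac_sparsity() if self.n_free > 12 else None
        n_starts = self.spec.n_starts if n_starts is None else n_starts
        rng = rng or np.random.default_rng(0)
        best = None
        for s in range(max(n_starts, 1)):
            xs = x0.copy()
            if s > 0:  # jitter the (log-scale) rate parameters
                for j, p in enumerate(self.params):
                    if p.log:
                        xs[j] += math.log10(
                            1.0 + self.spec.jitter * rng.uniform(-1, 1)
                        )
                xs = np.clip(xs, lo + 1e-12, hi - 1e-12)
            sol = least_squares(
                self.residuals, xs, bounds=(lo, hi), method="trf",
                x_scale="jac", ftol=self.spec.ftol, xtol=1e-10,
                jac_sparsity=sparsity, kwargs={"weights": weights},
                max_nfev=max_nfev if max_nfev is not None else self.spec.max_nfev,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    def result(self, sol, weights=None) -> GlobalFitResult:
        g, per_res = self.unpack(sol.x)
        chi2 = float((self.residuals(sol.x) ** 2).sum())
        sigmas = None
        try:
            jac = sol.jac.toarray() if hasattr(sol.jac, "toarray") else sol.jac
            cov = np.linalg.pinv(jac.T @ jac) * chi2 / max(
                self.n_points - self.n_free, 1
            )
            diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            sigmas = {}
            for p, s in zip(self.params, diag):
                if p.rid is None:
                    val = g[p.name]
                    sigmas[p.name] = val * math.log(10.0) * s if p.log else s
        except (np.linalg.LinAlgError, ValueError):
            sigmas = None
        return GlobalFitResult(
            model=self.spec.model,
            global_params=g,
            residue_params=per_res,
            chi2=chi2,
            n_points=self.n_points,
            n_free=self.n_free,
            global_sigmas=sigmas,
            residuals=self.residuals(sol.x),
            success=bool(sol.status > 0),
            message=sol.message,
            spec=self.spec,
        )

    def x_from_result(self, res: GlobalFitResult) -> np.ndarray:
        x = np.empty(self.n_free)
        for j, p in enumerate(self.params):
            v = (res.global_params[p.name] if p.rid is None
                 else res.residue_params[p.rid][p.name])
            x[j] = math.log10(v) if p.log else v
        return x


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------

def fit_global(dataset: CestDataset, spec: FitSpec,
               rng: np.random.Generator | None = None) -> GlobalFitResult:
    """Constrained global fit across all residues and B1 fields."""
    model = _CestModel(dataset, spec)
    sol = model.fit(rng=rng)
    res = model.result(sol)
    if not res.success:
        warnings.warn(f"global {spec.model} fit did not converge: "
                      f"{res.message}", stacklevel=2)
    return res


def fit_residue_3site(
    dataset: CestDataset,
    residue_id: int,
    init: dict | None = None,
    residue_init: dict | None = None,
    n_starts: int = 3,
    rng: np.random.Generator | None = None,
) -> GlobalFitResult:
    """Residue-specific 3-site fit across all B1 fields.

    The bound-population sum is fixed from the composition and R2B = R2C is
    tied, leaving k_off, k_BC, k_CB, dw_FB, dw_FC, R1, R2F and R2B free.
    """
    sub = dataset.subset([residue_id])
    spec = FitSpec(
        model="3site",
        r2b_eq_r2c=frozenset([residue_id]),
        global_init=init or {},
        residue_init={residue_id: residue_init or {}},
        n_starts=n_starts,
    )
    model = _CestModel(sub, spec)
    sol = model.fit(rng=rng)
    return model.result(sol)


def assign_minor_states(
    dataset: CestDataset,
    residue_id: int,
    result: GlobalFitResult,
    rng: np.random.Generator | None = None,
    grid_step_ppm: float = 0.2,
) -> AssignmentResult:
    """Swap test for the B/C assignment of a residue's two minor dips.

    The original fit assigns the dip nearest the major state to the
    intermediate B and the farthest to the complex C.  The residue is refit
    with the swapped assignment; the original is accepted when the swap
    increases the residuals or when the swapped fit reverts to the original
    ordering.
    """
    rp = result.residue_params[residue_id]
    if abs(rp["dw_fb"] - rp["dw_fc"]) < grid_step_ppm:
        return AssignmentResult(residue_id, "ambiguous", result, None)
    swapped_init = dict(rp)
    swapped_init["dw_fb"], swapped_init["dw_fc"] = rp["dw_fc"], rp["dw_fb"]
    swapped = fit_residue_3site(
        dataset, residue_id,
        init={k: result.global_params[k] for k in GLOBAL_PARAMS["3site"]},
        residue_init=swapped_init, n_starts=1, rng=rng,
    )
    sp = swapped.residue_params[residue_id]
    reverted = abs(sp["dw_fb"]) < abs(sp["dw_fc"]) - grid_step_ppm
    if swapped.chi2 >= result.chi2 or reverted:
        return AssignmentResult(residue_id, "original", result, swapped,
                                reverted=reverted)
    return AssignmentResult(residue_id, "swapped", result, swapped)


def compare_models(
    res3: GlobalFitResult, res4: GlobalFitResult, alpha: float = 0.05
) -> ModelComparison:
    """F-test between nested least-squares fits on identical data/masks."""
    if res3.n_points != res4.n_points:
        raise InvalidInputError("models were fit on different data")
    delta_k = res4.n_free - res3.n_free
    if delta_k <= 0:
        raise InvalidInputError("the 4-site model must have more parameters")
    if res4.chi2 >= res3.chi2:
        return ModelComparison(0.0, 1.0, res3.model, delta_k, alpha)
    f = ((res3.chi2 - res4.chi2) / delta_k) / (res4.chi2 / res4.dof)
    p = float(stats.f.sf(f, delta_k, res4.dof))
    return ModelComparison(f, p, res4.model if p < alpha else res3.model,
                           delta_k, alpha)


def bootstrap_global(
    dataset: CestDataset,
    spec: FitSpec,
    point_fit: GlobalFitResult,
    n: int = 300,
    seed: int | None = None,
    max_nfev: int | None = 100,
    replicate_ftol: float = 1e-4,
) -> BootstrapSummary:
    """Bootstrap 68% confidence intervals of the global parameters.

    Each replicate resamples every profile's (masked-in) points with
    replacement, preserving the point count per profile, and refits from
    the point estimate at a relaxed tolerance (parameter spread, not the
    last digits of each replicate optimum, sets the interval widths).
    Non-converged replicates are dropped and counted.
    """
    names = [p for p in GLOBAL_PARAMS[spec.model]
             if p not in spec.fixed_globals]
    if n == 0:
        return BootstrapSummary(0, 0, {k: np.array([]) for k in names},
                                {}, seed)
    model = _CestModel(dataset, replace(
        spec, ftol=max(spec.ftol, replicate_ftol)))
    x_start = model.x_from_result(point_fit)
    rng = np.random.default_rng(seed)
    samples = {k: [] for k in names}
    dropped = 0
    for _ in range(n):
        counts = np.empty(model.n_points)
        for sl in model.row_slices:
            m = sl.stop - sl.start
            counts[sl] = np.bincount(rng.integers(0, m, size=m), minlength=m)
        sol = model.fit(x0=x_start, weights=np.sqrt(counts), n_starts=1,
                        max_nfev=max_nfev)
        if sol.status <= 0:
            dropped += 1
            continue
        g, _ = model.unpack(sol.x)
        for k in names:
            samples[k].append(g[k])
    if n and dropped / n > 0.2:
        warnings.warn(f"{dropped}/{n} bootstrap replicates dropped",
                      stacklevel=2)
    samples = {k: np.asarray(v) for k, v in samples.items()}
    ci68 = {k: (float(np.percentile(v, 16)), float(np.percentile(v, 84)))
            for k, v in samples.items() if v.size}
    return BootstrapSummary(n, dropped, samples, ci68, seed)


def search_crib_boundary(
    dataset: CestDataset,
    spec: FitSpec,
    candidate_range: tuple[int, int],
    warm_start: GlobalFitResult | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> CribSearchResult:
    """Find the residues anchored in the first intermediate.

    Enumerates (lower, upper) limit pairs within ``candidate_range``, sets
    the CRIB set to the assignable residues within the limits, runs the
    global 4-site fit for each and keeps the subset with minimal residuals.
    If no subset improves on a CRIB-free fit beyond the F-test threshold,
    an empty set is returned with the ``no_crib`` flag.
    """
    lo, hi = candidate_range
    fitted = set(r for r in dataset.residue_ids
                 if r not in spec.excluded_residues)
    candidates = [r for r in sorted(fitted)
                  if lo <= r <= hi and dataset.residues[r].assignable]
    if not candidates:
        raise InvalidInputError("no candidate residues in range")

    def run(crib):
        s = replace(spec, crib_set=frozenset(crib))
        model = _CestModel(dataset, s)
        x0 = None
        if warm_start is not None:
            x0 = model.x_from_result(warm_start)
            # residues newly granted a dw_FA start at their dw_FB value
            for j, p in enumerate(model.params):
                if p.name == "dw_fa" and x0[j] == 0.0:
                    x0[j] = warm_start.residue_params[p.rid]["dw_fb"]
        return model.result(model.fit(x0=x0, rng=rng))

    base = run(frozenset())
    rows, results = [], {}
    for i in range(lo, hi + 1):
        for j in range(i, hi + 1):
            subset = frozenset(r for r in candidates if i <= r <= j)
            if not subset or subset in results:
                continue
            res = run(subset)
            results[subset] = res
            rows.append({"lower": i, "upper": j,
                         "subset": tuple(sorted(subset)), "chi2": res.chi2})
    trace = pd.DataFrame(rows).sort_values("chi2").reset_index(drop=True)
    best_set = frozenset(trace.loc[0, "subset"])
    best = results[best_set]
    # does the best CRIB set beat the CRIB-free fit beyond chance?
    if best.chi2 >= base.chi2:
        return CribSearchResult(frozenset(), trace, True, base)
    comp = compare_models(base, best, alpha=alpha)
    if comp.p_value >= alpha:
        return CribSearchResult(frozenset(), trace, True, base)
    return CribSearchResult(best_set, trace, False, best)


def grid_search(
    dataset: CestDataset,
    spec: FitSpec,
    kex_ab_grid: np.ndarray,
    kex_bc_grid: np.ndarray,
    warm_start: GlobalFitResult | None = None,
) -> pd.DataFrame:
    """Profile-likelihood chi^2 surface over (kex_AB, kex_BC).

    At each node the two exchange rates are fixed and every remaining
    parameter is re-optimised (warm-started from ``warm_start`` when given).
    """
    if spec.model != "4site":
        raise InvalidInputError("grid search is defined for the 4-site model")
    rows = []
    for ka in np.asarray(kex_ab_grid, dtype=float):
        for kb in np.asarray(kex_bc_grid, dtype=float):
            s = replace(spec, fixed_globals={**spec.fixed_globals,
                                             "kex_ab": ka, "kex_bc": kb})
            model = _CestModel(dataset, s)
            x0 = None
            if warm_start is not None:
                x0 = model.x_from_result(warm_start)
            sol = model.fit(x0=x0, n_starts=1)
            rows.append({"kex_ab": ka, "kex_bc": kb,
                         "chi2": float(2.0 * sol.cost)})
    return pd.DataFrame(rows)
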