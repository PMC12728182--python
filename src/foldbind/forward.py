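"""Forward simulation of 15N CEST profiles under CW or DANTE saturation.

The magnetization of a nitrogen spin exchanging among N chemical states is
propagated with the Bloch-McConnell equations in a basis of three Cartesian
components per state, ordered [x0, y0, z0, x1, y1, z1, ...].  For each state
i the rotating-frame evolution (frame at the irradiation frequency) is

    dMx/dt = -R2_i Mx - Omega_i My
    dMy/dt = +Omega_i Mx - R2_i My - w1 Mz
    dMz/dt = +w1 My - R1 Mz

with Omega_i = 2 pi ((shift_i - carrier) * nu_N - offset) in rad/s and
w1 = 2 pi B1.  First-order exchange couples identical Cartesian components
across states; the exchange sub-matrix conserves summed magnetization per
component by construction.  Longitudinal relaxation drives Mz to zero (no
recovery term); the reference plane is a zero-length saturation period, so
the far-off-resonance baseline of a non-exchanging spin is exp(-R1 * Tsat).

Two irradiation schemes are implemented: continuous-wave saturation (a
single matrix exponential over the saturation time) and the DANTE
multi-frequency scheme (D-CEST), modelled as a train of ideal delta pulses
of flip angle 2 pi B1 / window separated by free-precession periods of
1/window, which makes the simulated profile periodic in the offset with
period equal to the DANTE window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .exceptions import InvalidInputError
from .exchange import (
    ExchangeScheme,
    MixtureComposition,
    StatePopulations,
    bound_fraction,
    partition_populations,
)

__all__ = [
    "CestExperiment",
    "ResidueSpinSystem",
    "CestProfile",
    "bm_generator",
    "propagate_cw",
    "propagate_dante",
    "simulate_profile",
    "exclusion_mask",
]


@dataclass(frozen=True)
class CestExperiment:
    """Saturation-experiment geometry.

    B1 in Hz (nutation frequency), Tsat in s, larmor_15n in MHz (so that
    1 ppm = larmor_15n Hz), carrier in ppm, offsets in Hz relative to the
    carrier.  ``scheme`` is "cw" or "dante"; DANTE requires a spectral
    window larger than twice B1.
    """

    b1: float
    tsat: float
    offsets: np.ndarray
    scheme: str = "cw"
    dante_window: float | None = None
    larmor_15n: float = 96.3  # MHz; 950 MHz 1H field
    carrier: float = 118.5  # ppm

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if self.b1 <= 0:
            raise InvalidInputError("B1 must be > 0")
        if self.tsat < 0:
            raise InvalidInputError("Tsat must be >= 0")
        if self.scheme not in ("cw", "dante"):
            raise InvalidInputError(f"unknown irradiation scheme {self.scheme!r}")
        if self.scheme == "dante":
            if self.dante_window is None or self.dante_window <= 2 * self.b1:
                raise InvalidInputError("DANTE requires dante_window > 2*B1")

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Offset from the carrier in Hz of a position given in ppm."""
        return (np.asarray(ppm) - self.carrier) * self.larmor_15n

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        return np.asarray(hz) / self.larmor_15n + self.carrier


@dataclass(frozen=True)
class ResidueSpinSystem:
    """Chemical shifts and relaxation rates of one residue's 15N spin.

    dw_* are chemical-shift differences (ppm) of the bound states from the
    free state F; r2_a is resolved from the tie rule of the analysis layer
    and stored explicitly here.  A single longitudinal rate r1 is shared by
    all states.
    """

    residue_id: int
    shift_f: float  # ppm
    dw_fb: float
    dw_fc: float
    r1: float
    r2_f: float
    r2_b: float
    r2_c: float
    dw_fa: float = 0.0
    r2_a: float | None = None  # defaults to r2_f (tie R2A <- R2F)

    def __post_init__(self) -> None:
        for name in ("r1", "r2_f", "r2_b", "r2_c"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.r2_a is not None and self.r2_a <= 0:
            raise InvalidInputError("r2_a must be > 0")

    @property
    def dw_ab(self) -> float:
        return self.dw_fb - self.dw_fa

    @property
    def dw_bc(self) -> float:
        return self.dw_fc - self.dw_fb

    def shifts(self, scheme: ExchangeScheme) -> np.ndarray:
        """Absolute shift (ppm) of each state in scheme order."""
        if scheme.model == "4site":
            dw = np.array([0.0, self.dw_fa, self.dw_fb, self.dw_fc])
        else:
            dw = np.array([0.0, self.dw_fb, self.dw_fc])
        return self.shift_f + dw

    def r2s(self, scheme: ExchangeScheme) -> np.ndarray:
        r2a = self.r2_f if self.r2_a is None else self.r2_a
        if scheme.model == "4site":
            return np.array([self.r2_f, r2a, self.r2_b, self.r2_c])
        return np.array([self.r2_f, self.r2_b, self.r2_c])


@dataclass
class CestProfile:
    """One residue's saturation profile at one B1 field."""

    residue_id: int
    experiment: CestExperiment
    offsets: np.ndarray
    intensities: np.ndarray
    sigmas: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets.size and np.any(np.diff(self.offsets) <= 0):
            raise InvalidInputError("profile offsets must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidInputError("profile intensities must be finite")
        if self.mask is None:
            self.mask = np.ones(self.offsets.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.offsets.shape:
            raise InvalidInputError("mask length must equal offsets length")
        if self.sigmas is not None:
            self.sigmas = np.asarray(self.sigmas, dtype=float)


def _exchange_rates(
    scheme: ExchangeScheme, pops: StatePopulations
) -> np.ndarray:
    """N x N first-order rate matrix (row sums zero) with the F->first step
    closed by detailed balance against the constrained populations."""
    if pops.p_f <= 0:
        raise InvalidInputError("p_F must be > 0")
    p_first = pops.p_a if scheme.model == "4site" else pops.p_b
    k_app = scheme.koff * p_first / pops.p_f
    n = scheme.n_states
    q = np.zeros((n, n))
    if scheme.model == "4site":
        pairs = [(k_app, scheme.koff), (scheme.k_ab, scheme.k_ba),
                 (scheme.k_bc, scheme.k_cb)]
    else:
        pairs = [(k_app, scheme.koff), (scheme.k_bc, scheme.k_cb)]
    for i, (kf, kr) in enumerate(pairs):
        q[i, i + 1] = kf
        q[i + 1, i] = kr
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _generator_stack(
    shifts_hz: np.ndarray,
    r1: float,
    r2: np.ndarray,
    q: np.ndarray,
    b1: float,
    offsets: np.ndarray,
) -> np.ndarray:
    """Stack of Bloch-McConnell generators, one 3N x 3N matrix per offset."""
    n = shifts_hz.size
    d = 3 * n
    n_off = offsets.size
    g = np.zeros((n_off, d, d))
    # exchange: identical coupling for each Cartesian component
    g[:] = np.kron(q.T, np.eye(3))
    w1 = 2.0 * np.pi * b1
    omega = 2.0 * np.pi * (shifts_hz[None, :] - offsets[:, None])  # (n_off, n)
    idx = 3 * np.arange(n)
    for i in range(n):
        x, y, z = idx[i], idx[i] + 1, idx[i] + 2
        g[:, x, x] += -r2[i]
        g[:, y, y] += -r2[i]
        g[:, z, z] += -r1
        g[:, x, y] += -omega[:, i]
        g[:, y, x] += +omega[:, i]
        g[:, y, z] += -w1
        g[:, z, y] += +w1
    return g


def _propagate_stack(g: np.ndarray, m0: np.ndarray, t: float) -> np.ndarray:
    """expm(g*t) @ m0 for a stack of generators, via batched diagonalization.

    Falls back to scipy.linalg.expm for any member whose eigenbasis is too
    ill-conditioned to reach machine-precision reconstruction.
    """
    if t == 0:
        return np.broadcast_to(m0, g.shape[:-1]).copy()
    try:
        w, v = np.linalg.eig(g)
        c = np.linalg.solve(v, np.broadcast_to(m0, g.shape[:-1])[..., None])
        m = (v @ (np.exp(w * t)[..., None] * c)).real[..., 0]
        # guard against defective/ill-conditioned eigenbases
        bad = ~np.all(np.isfinite(m), axis=-1)
        recon = np.abs((v @ c).real[..., 0] - m0).max(axis=-1)
        bad |= recon > 1e-9
    except np.linalg.LinAlgError:
        m = np.empty(g.shape[:-1])
        bad = np.ones(g.shape[0], dtype=bool)
    for i in np.nonzero(bad)[0]:
        m[i] = expm(g[i] * t) @ m0
    return m


def _expm_stack(g: np.ndarray, t: float) -> np.ndarray:
    """expm(g*t) for a stack of generators via batched diagonalization,
    with a scipy fallback for ill-conditioned members."""
    try:
        w, v = np.linalg.eig(g)
        vinv = np.linalg.inv(v)
        e = (v * np.exp(w * t)[..., None, :]) @ vinv
        recon = np.abs((v @ vinv).real - np.eye(g.shape[-1])).max(axis=(-2, -1))
        bad = (recon > 1e-9) | ~np.all(np.isfinite(e.real), axis=(-2, -1))
        e = e.real
    except np.linalg.LinAlgError:
        e = np.empty_like(g)
        bad = np.ones(g.shape[0], dtype=bool)
    for i in np.nonzero(bad)[0]:
        e[i] = expm(g[i] * t)
    return e


def bm_generator(
    spin: ResidueSpinSystem,
    scheme: ExchangeScheme,
    pops: StatePopulations,
    expt: CestExperiment,
    offset: float,
) -> np.ndarray:
    """Bloch-McConnell evolution matrix at a single irradiation offset."""
    shifts_hz = np.asarray(expt.ppm_to_hz(spin.shifts(scheme)), dtype=float)
    q = _exchange_rates(scheme, pops)
    g = _generator_stack(
        shifts_hz, spin.r1, spin.r2s(scheme), q, expt.b1, np.array([offset])
    )
    return g[0]


def propagate_cw(generator: np.ndarray, m0: np.ndarray, tsat: float) -> np.ndarray:
    """Propagate magnetization under continuous-wave saturation."""
    if tsat < 0:
        raise InvalidInputError("Tsat must be >= 0")
    m0 = np.asarray(m0, dtype=float)
    if m0.shape[0] != generator.shape[0]:
        raise InvalidInputError("M0 dimension does not match generator")
    if tsat == 0:
        return m0.copy()
    return expm(generator * tsat) @ m0


def _dante_propagator_stack(
    spin: ResidueSpinSystem,
    scheme: ExchangeScheme,
    pops: StatePopulations,
    expt: CestExperiment,
    offsets: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Per-period propagator stack and period count for the DANTE train."""
    window = float(expt.dante_window)
    tau = 1.0 / window
    n_per = int(round(expt.tsat * window))
    theta = 2.0 * np.pi * expt.b1 * tau
    rot = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(theta), -np.sin(theta)],
            [0.0, np.sin(theta), np.cos(theta)],
        ]
    )
    rot_full = np.kron(np.eye(scheme.n_states), rot)
    shifts_hz = np.asarray(expt.ppm_to_hz(spin.shifts(scheme)), dtype=float)
    q = _exchange_rates(scheme, pops)
    g0 = _generator_stack(
        shifts_hz, spin.r1, spin.r2s(scheme), q, 0.0, offsets
    )
    free = _expm_stack(g0, tau)
    return rot_full @ free, n_per


def propagate_dante(
    spin: ResidueSpinSystem,
    scheme: ExchangeScheme,
    pops: StatePopulations,
    expt: CestExperiment,
    offset: float,
    m0: np.ndarray,
) -> np.ndarray:
    """Propagate magnetization under a DANTE pulse train at one offset."""
    if expt.scheme != "dante":
        raise InvalidInputError("experiment is not in DANTE mode")
    if expt.tsat == 0:
        return np.asarray(m0, dtype=float).copy()
    if expt.tsat * expt.dante_window < 1:
        warnings.warn(
            "fewer than one DANTE period fits in Tsat; falling back to CW",
            stacklevel=2,
        )
        g = bm_generator(spin, scheme, pops, expt, offset)
        return propagate_cw(g, m0, expt.tsat)
    u, n_per = _dante_propagator_stack(
        spin, scheme, pops, expt, np.array([float(offset)])
    )
    return np.linalg.matrix_power(u[0], n_per) @ np.asarray(m0, dtype=float)


def _profile_intensities(
    spin: ResidueSpinSystem,
    scheme: ExchangeScheme,
    pops: StatePopulations,
    expt: CestExperiment,
) -> np.ndarray:
    """Normalized I/I0 at every offset of the experiment (no noise)."""
    n = scheme.n_states
    m0 = np.zeros(3 * n)
    m0[2::3] = pops.as_array(scheme)
    i0 = m0[2::3].sum()
    offsets = expt.offsets
    if expt.scheme == "cw" or expt.tsat * (expt.dante_window or 0) < 1:
        shifts_hz = np.asarray(expt.ppm_to_hz(spin.shifts(scheme)), dtype=float)
        q = _exchange_rates(scheme, pops)
        g = _generator_stack(
            shifts_hz, spin.r1, spin.r2s(scheme), q, expt.b1, offsets
        )
        m = _propagate_stack(g, m0, expt.tsat)
    else:
        u, n_per = _dante_propagator_stack(spin, scheme, pops, expt, offsets)
        m = (np.linalg.matrix_power(u, n_per) @ m0[:, None])[..., 0]
    return m[:, 2::3].sum(axis=1) / i0


def simulate_profile(
    spin: ResidueSpinSystem,
    scheme: ExchangeScheme,
    comp: MixtureComposition,
    expt: CestExperiment,
) -> CestProfile:
    """Simulate one residue's CEST profile for a binding mixture.

    The initial magnetization is longitudinal, proportional to the
    equilibrium state populations fixed by the mixture composition; the
    reported intensity is the summed z-magnetization after Tsat, normalized
    to a zero-length saturation reference.
    """
    if expt.offsets.size == 0:
        raise InvalidInputError("experiment has no offsets")
    pops = partition_populations(bound_fraction(comp), scheme)
    intens = _profile_intensities(spin, scheme, pops, expt)
    return CestProfile(
        residue_id=spin.residue_id,
        experiment=expt,
        offsets=expt.offsets.copy(),
        intensities=intens,
    )


def exclusion_mask(
    profile: CestProfile, b1: float, major_shift: float
) -> np.ndarray:
    """Inclusion mask that drops points within +-B1 Hz of the major dip.

    The on-resonance window is dominated by direct saturation and most
    sensitive to B1 inhomogeneity, so it carries no exchange information.
    For DANTE profiles the major resonance is aliased into the sampled
    window before the distance test.
    """
    offsets = profile.offsets
    if offsets.size == 0:
        return np.zeros(0, dtype=bool)
    expt = profile.experiment
    pos = float(expt.ppm_to_hz(major_shift))
    if expt.scheme == "dante" and expt.dante_window:
        lo = offsets.min()
        pos = lo + (pos - lo) % expt.dante_window
    return np.abs(offsets - pos) > b1
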