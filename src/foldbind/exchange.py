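"""Linear N-site exchange kinetics for folding-upon-binding.

An intrinsically disordered region binds its partner through a strictly
linear chain of states,

    F + partner <-> A <-> B <-> C        (4-site scheme)
    F + partner <-> B <-> C              (3-site scheme)

where F is the free, disordered state, A is an anchored encounter-like
intermediate, B an intermediate with the first recognition element folded,
and C the fully folded complex.  The first step is bimolecular (kon, koff);
the folding steps are unimolecular (k_AB/k_BA, k_BC/k_CB).

This module holds the population algebra that ties the microscopic rates to
the macroscopic dissociation constant: the total bound fraction follows from
mass balance of the two total concentrations and Kd, and is partitioned
among the bound states by the step equilibrium constants.  Concentrations
are in uM throughout; conversion to molar happens only inside
:func:`apparent_kd` and :func:`pseudo_first_order_rate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConsistencyError, InvalidInputError

__all__ = [
    "ExchangeScheme",
    "MixtureComposition",
    "StatePopulations",
    "bound_fraction",
    "partition_populations",
    "apparent_kd",
    "pseudo_first_order_rate",
    "rate_matrix",
]


@dataclass(frozen=True)
class ExchangeScheme:
    """Rate constants of the linear exchange chain.

    Parameters
    ----------
    kon : float
        Bimolecular association rate of the first step (M^-1 s^-1).
    koff : float
        Dissociation rate of the first step (s^-1).
    k_bc, k_cb : float
        Forward/reverse rates of the last folding step (s^-1).
    k_ab, k_ba : float, optional
        Forward/reverse rates of the A<->B step (s^-1).  Both present
        selects the 4-site scheme; both absent the 3-site scheme.
    """

    kon: float
    koff: float
    k_bc: float
    k_cb: float
    k_ab: float | None = None
    k_ba: float | None = None

    def __post_init__(self) -> None:
        if (self.k_ab is None) != (self.k_ba is None):
            raise InvalidInputError("k_ab and k_ba must be given together")
        for name in ("kon", "koff", "k_bc", "k_cb", "k_ab", "k_ba"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")

    # -- topology ---------------------------------------------------------
    @property
    def model(self) -> str:
        return "4site" if self.k_ab is not None else "3site"

    @property
    def n_states(self) -> int:
        return 4 if self.model == "4site" else 3

    @property
    def state_labels(self) -> tuple[str, ...]:
        return ("F", "A", "B", "C") if self.model == "4site" else ("F", "B", "C")

    # -- derived rates ----------------------------------------------------
    @property
    def keq_ab(self) -> float:
        """p_B / p_A at equilibrium (4-site only)."""
        if self.model != "4site":
            raise InvalidInputError("keq_ab is defined only for the 4-site scheme")
        if self.k_ba == 0:
            raise InvalidInputError("keq_ab undefined: k_ba is zero")
        return self.k_ab / self.k_ba

    @property
    def keq_bc(self) -> float:
        """p_C / p_B at equilibrium."""
        if self.k_cb == 0:
            raise InvalidInputError("keq_bc undefined: k_cb is zero")
        return self.k_bc / self.k_cb

    @property
    def kex_ab(self) -> float:
        if self.model != "4site":
            raise InvalidInputError("kex_ab is defined only for the 4-site scheme")
        return self.k_ab + self.k_ba

    @property
    def kex_bc(self) -> float:
        return self.k_bc + self.k_cb

    # -- serialization ----------------------------------------------------
    def to_config(self) -> dict:
        """Flat mapping for the ``[exchange]`` config section."""
        cfg = {
            "model": self.model,
            "kon": self.kon,
            "koff": self.koff,
            "kBC": self.k_bc,
            "kCB": self.k_cb,
        }
        if self.model == "4site":
            cfg["kAB"] = self.k_ab
            cfg["kBA"] = self.k_ba
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "ExchangeScheme":
        model = cfg.get("model", "4site" if "kAB" in cfg else "3site")
        kwargs = dict(
            kon=float(cfg["kon"]),
            koff=float(cfg["koff"]),
            k_bc=float(cfg["kBC"]),
            k_cb=float(cfg["kCB"]),
        )
        if model == "4site":
            kwargs["k_ab"] = float(cfg["kAB"])
            kwargs["k_ba"] = float(cfg["kBA"])
        elif model != "3site":
            raise InvalidInputError(f"unknown exchange model {model!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class MixtureComposition:
    """Total concentrations and overall Kd of the binding mixture (uM)."""

    p0: float  # total observed (IDP) concentration, uM
    r0: float  # total partner concentration, uM
    kd: float  # overall complex dissociation constant, uM
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.r0 < 0:
            raise InvalidInputError("concentrations must be >= 0")
        if self.kd <= 0:
            raise InvalidInputError("Kd must be > 0")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0 K")


@dataclass(frozen=True)
class StatePopulations:
    """Fractional populations of the exchange states (p_a = 0 for 3-site)."""

    p_f: float
    p_b: float
    p_c: float
    p_a: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_f", "p_a", "p_b", "p_c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} = {v} outside [0, 1]")
        total = self.p_f + self.p_a + self.p_b + self.p_c
        if abs(total - 1.0) > 1e-10:
            raise InvalidInputError(f"populations sum to {total}, not 1")

    def as_array(self, scheme: ExchangeScheme) -> np.ndarray:
        """Populations in the scheme's state order."""
        if scheme.model == "4site":
            return np.array([self.p_f, self.p_a, self.p_b, self.p_c])
        return np.array([self.p_f, self.p_b, self.p_c])


def bound_fraction(comp: MixtureComposition) -> float:
    """Total bound fraction C/P0 of the observed species from mass balance.

    Solves C^2 - C (P0 + R0 + Kd) + P0 R0 = 0 and keeps the physically
    admissible (smaller) root, 0 <= C <= min(P0, R0).
    """
    if comp.p0 <= 0:
        raise InvalidInputError("P0 must be > 0 to define a bound fraction")
    if comp.r0 == 0:
        return 0.0
    s = comp.p0 + comp.r0 + comp.kd
    disc = s * s - 4.0 * comp.p0 * comp.r0
    if disc < 0:
        raise ConsistencyError("negative discriminant in mass-balance quadratic")
    c = (s - math.sqrt(disc)) / 2.0
    # clip tiny negative round-off
    c = min(max(c, 0.0), min(comp.p0, comp.r0))
    return c / comp.p0


def partition_populations(
    total_bound: float, scheme: ExchangeScheme
) -> StatePopulations:
    """Distribute the fixed total bound fraction over the chain states.

    The step equilibrium constants set the ratios p_B/p_A and p_C/p_B; the
    sum p_A + p_B + p_C (or p_B + p_C for 3-site) is constrained to
    ``total_bound``.
    """
    if not 0.0 <= total_bound < 1.0:
        raise InvalidInputError(f"total_bound = {total_bound} outside [0, 1)")
    kbc = scheme.keq_bc if scheme.k_cb > 0 else math.inf
    if scheme.model == "4site":
        kab = scheme.keq_ab if scheme.k_ba > 0 else math.inf
        p_a = total_bound / (1.0 + kab * (1.0 + kbc))
        p_b = p_a * kab
        p_c = p_b * kbc
        return StatePopulations(p_f=1.0 - total_bound, p_a=p_a, p_b=p_b, p_c=p_c)
    p_b = total_bound / (1.0 + kbc)
    p_c = p_b * kbc
    return StatePopulations(p_f=1.0 - total_bound, p_b=p_b, p_c=p_c)


def apparent_kd(scheme: ExchangeScheme) -> float:
    """Overall dissociation constant (uM) implied by the microscopic rates.

    The first-step Kd1 = koff/kon is reduced by the downstream folding
    equilibria that pull the complex away from the initial bound state:
    Kd = Kd1 / (1 + K_AB (1 + K_BC)) for the 4-site chain.
    """
    if scheme.kon <= 0:
        raise InvalidInputError("apparent_kd requires kon > 0")
    if scheme.k_cb <= 0 or (scheme.model == "4site" and scheme.k_ba <= 0):
        raise InvalidInputError("apparent_kd requires all reverse rates > 0")
    kd1_um = scheme.koff / scheme.kon * 1e6
    if scheme.model == "4site":
        return kd1_um / (1.0 + scheme.keq_ab * (1.0 + scheme.keq_bc))
    return kd1_um / (1.0 + scheme.keq_bc)


def pseudo_first_order_rate(
    scheme: ExchangeScheme, comp: MixtureComposition
) -> float:
    """Effective first-order F -> (first bound state) rate (s^-1).

    Under the population constraint the association step must satisfy
    detailed balance, k_app * p_F = koff * p_first, so the pseudo-first-order
    on-rate is koff * p_first / p_F.  It equals kon * [partner_free] when kon
    and the free-partner concentration are consistent with Kd.
    """
    pops = partition_populations(bound_fraction(comp), scheme)
    if pops.p_f <= 0:
        raise InvalidInputError("p_F must be > 0")
    p_first = pops.p_a if scheme.model == "4site" else pops.p_b
    return scheme.koff * p_first / pops.p_f


def rate_matrix(scheme: ExchangeScheme, comp: MixtureComposition) -> np.ndarray:
    """Continuous-time generator Q of the chain (Q[i, j] = rate i -> j).

    Row sums are zero; the stationary distribution of Q matches
    :func:`partition_populations` by construction of the pseudo-first-order
    closure.
    """
    n = scheme.n_states
    k_app = pseudo_first_order_rate(scheme, comp)
    q = np.zeros((n, n))
    if scheme.model == "4site":
        pairs = [(k_app, scheme.koff), (scheme.k_ab, scheme.k_ba),
                 (scheme.k_bc, scheme.k_cb)]
    else:
        pairs = [(k_app, scheme.koff), (scheme.k_bc, scheme.k_cb)]
    for i, (kf, kr) in enumerate(pairs):
        q[i, i + 1] = kf
        q[i + 1, i] = kr
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q
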