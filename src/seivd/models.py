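"""Compartmental SEIV/SEIVD models of lytic phage-bacteria dynamics.

The pairwise model tracks susceptible cells ``S``, a chain of ``N_E`` exposed
stages ``E_1..E_NE``, lysis-committed infected cells ``I``, free virions
``V`` and (in the SEIVD variant) cumulative lysed-cell debris ``D``::

    dS/dt   = r S - theta(D) phi S V
    dE_1/dt = theta(D) phi S V - k E_1
    dE_m/dt = k (E_{m-1} - E_m)            m = 2..N_E
    dI/dt   = k (E_NE - I)
    dV/dt   = beta k I - theta(D) phi S V
    dD/dt   = k I

with stage rate ``k = (N_E + 1) / tau`` so that the adsorption-to-lysis
transit time is Erlang distributed with mean ``tau`` and coefficient of
variation ``1 / sqrt(N_E + 1)`` (the linear chain trick).  Debris attenuates
the infection flux through a Hill function ``theta(D) = 1 / (1 + (D/D_c)^n)``
with ``n = 2`` by default; ``D_c = inf`` recovers the plain SEIV model.

The community model couples ``H`` hosts and ``P`` phage through a boolean
infection matrix: each interacting pair ``(i, j)`` carries its own exposed
chain and infected stage with pair-specific traits, all pairs feed one shared
debris pool, and attenuation is per-host via ``D_c_i``.  Multiple infection
is excluded: only susceptible cells adsorb virions (an optional flag adds
phage loss to exposed/infected cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "TraitSet",
    "InfectionMatrix",
    "Trajectory",
    "CommunityModel",
    "IntegrationError",
    "hill_attenuation",
    "seiv_rhs",
    "seivd_rhs",
    "integrate",
    "simulate_pairwise",
    "simulate_community",
    "observe",
    "default_community_matrix",
    "OBSERVABLES",
]

OBSERVABLES = ("free_phage", "total_phage", "host_qINT", "phage_qEXT", "total_host")

_EMPTY_I = np.empty((0,), dtype=np.int64)
_EMPTY_F = np.empty((0,), dtype=np.float64)


class IntegrationError(RuntimeError):
    """Raised when the adaptive solver underflows; carries the failure time."""

    def __init__(self, t_fail: float, message: str | None = None):
        self.t_fail = float(t_fail)
        super().__init__(message or f"integration failed at t = {t_fail:.6g} h")


# ---------------------------------------------------------------------------
# traits and infection network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSet:
    """Life-history traits of one phage-host pair.

    Parameters
    ----------
    r
        Host exponential growth rate (1/h).
    phi
        Adsorption rate constant (ml/h).
    tau
        Mean latent period, adsorption to lysis (h).
    n_exposed
        Number of exposed stages ``N_E`` (>= 0).  The latent-period CV is
        ``1/sqrt(N_E + 1)``.
    burst_size
        Mean virions released per lysed cell.
    debris_halfsat
        Critical debris concentration ``D_c`` (cells/ml); ``inf`` disables
        attenuation (SEIV limit).
    hill_coeff
        Hill exponent of the attenuation function (default 2).
    carrying_capacity
        Optional logistic ceiling for host growth (cells/ml, default ``inf``
        i.e. pure exponential growth).
    adsorb_infected
        If True, free phage are additionally lost by attachment to exposed
        and infected cells (off by default: no multiple infection).
    """

    r: float
    phi: float
    tau: float
    n_exposed: int
    burst_size: float
    debris_halfsat: float = math.inf
    hill_coeff: float = 2.0
    carrying_capacity: float = math.inf
    adsorb_infected: bool = False

    def __post_init__(self):
        if not (self.r >= 0 and np.isfinite(self.r)):
            raise ValueError(f"growth rate r must be finite and >= 0, got {self.r}")
        if not (self.phi >= 0 and np.isfinite(self.phi)):
            raise ValueError(f"adsorption rate phi must be finite and >= 0, got {self.phi}")
        if not self.tau > 0:
            raise ValueError(f"latent period tau must be > 0, got {self.tau}")
        if int(self.n_exposed) != self.n_exposed or self.n_exposed < 0:
            raise ValueError(f"n_exposed must be an integer >= 0, got {self.n_exposed}")
        object.__setattr__(self, "n_exposed", int(self.n_exposed))
        if not self.burst_size >= 0:
            raise ValueError(f"burst size must be >= 0, got {self.burst_size}")
        if not self.debris_halfsat > 0:
            raise ValueError(f"debris_halfsat must be > 0 (or inf), got {self.debris_halfsat}")
        if not self.hill_coeff > 0:
            raise ValueError(f"hill_coeff must be > 0, got {self.hill_coeff}")

    @property
    def stage_rate(self) -> float:
        """Per-stage transition rate ``k = (N_E + 1)/tau`` (1/h)."""
        return (self.n_exposed + 1) / self.tau

    @property
    def latent_cv(self) -> float:
        """Coefficient of variation of the Erlang latent period."""
        return 1.0 / math.sqrt(self.n_exposed + 1)

    @property
    def attenuated(self) -> bool:
        return np.isfinite(self.debris_halfsat)

    def with_(self, **kw) -> "TraitSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class InfectionMatrix:
    """Boolean host-range matrix (hosts as rows, phage as columns)."""

    hosts: tuple
    phages: tuple
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (len(self.hosts), len(self.phages)):
            raise ValueError(
                f"mask shape {mask.shape} does not match "
                f"{len(self.hosts)} hosts x {len(self.phages)} phages"
            )
        object.__setattr__(self, "hosts", tuple(self.hosts))
        object.__setattr__(self, "phages", tuple(self.phages))
        object.__setattr__(self, "mask", mask)

    @property
    def n_interactions(self) -> int:
        return int(self.mask.sum())

    @property
    def pairs(self) -> list:
        """Interacting (host, phage) identifier pairs, row-major order."""
        out = []
        for i, h in enumerate(self.hosts):
            for j, p in enumerate(self.phages):
                if self.mask[i, j]:
                    out.append((h, p))
        return out


def default_community_matrix() -> InfectionMatrix:
    """The packaged five-host / five-phage network with nine interactions.

    Three *Cellulophaga baltica* (CBA) and two *Pseudoalteromonas* (PSA)
    strains with their phage; the network is modular (no cross-species
    infection).
    """
    hosts = ("CBA 38", "CBA 4", "CBA 18", "PSA H100", "PSA 13-15")
    phages = ("phi38:1", "phi18:2", "phi18:3", "PSA-HP1", "PSA-HS6")
    links = {
        "phi38:1": ("CBA 38", "CBA 18"),
        "phi18:2": ("CBA 18",),
        "phi18:3": ("CBA 4", "CBA 18"),
        "PSA-HP1": ("PSA H100", "PSA 13-15"),
        "PSA-HS6": ("PSA H100", "PSA 13-15"),
    }
    mask = np.zeros((5, 5), dtype=bool)
    for j, p in enumerate(phages):
        for h in links[p]:
            mask[hosts.index(h), j] = True
    return InfectionMatrix(hosts, phages, mask)


# ---------------------------------------------------------------------------
# right-hand sides (numpy reference implementations)
# ---------------------------------------------------------------------------


def hill_attenuation(d, d_c, n: float = 2.0):
    """Infection-attenuation factor ``1 / (1 + (D/D_c)^n)`` in (0, 1].

    ``d_c = inf`` returns exactly 1 (attenuation disabled).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("debris density D must be >= 0")
    if not n > 0:
        raise ValueError("hill coefficient n must be > 0")
    if np.isinf(d_c):
        return np.ones_like(d)[()] if d.ndim else 1.0
    if not d_c > 0:
        raise ValueError("debris half-saturation D_c must be > 0 or inf")
    out = 1.0 / (1.0 + (d / d_c) ** n)
    return out[()] if d.ndim == 0 else out


def _check_state(y: np.ndarray, traits: TraitSet) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (traits.n_exposed + 4,):
        raise ValueError(
            f"state must have length N_E + 4 = {traits.n_exposed + 4}, got {y.shape}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    return y


def seiv_rhs(y: np.ndarray, traits: TraitSet) -> np.ndarray:
    """SEIV derivative of the flat state ``[S, E_1..E_NE, I, V, D]``.

    Pure function; debris feedback is disabled regardless of
    ``traits.debris_halfsat``.
    """
    return seivd_rhs(y, traits.with_(debris_halfsat=math.inf))


def seivd_rhs(y: np.ndarray, traits: TraitSet) -> np.ndarray:
    """SEIVD derivative: SEIV with the infection flux scaled by the Hill factor."""
    y = _check_state(y, traits)
    ne = traits.n_exposed
    k = traits.stage_rate
    s, i_dens, v, d = y[0], y[1 + ne], y[2 + ne], y[3 + ne]
    theta = hill_attenuation(max(d, 0.0), traits.debris_halfsat, traits.hill_coeff)
    infection = theta * traits.phi * s * v

    dy = np.zeros_like(y)
    if np.isfinite(traits.carrying_capacity):
        total = s + y[1 : 2 + ne].sum()
        dy[0] = traits.r * s * (1.0 - total / traits.carrying_capacity) - infection
    else:
        dy[0] = traits.r * s - infection
    if ne > 0:
        dy[1] = infection - k * y[1]
        dy[2 : 1 + ne] = k * (y[1:ne] - y[2 : 1 + ne])
        dy[1 + ne] = k * (y[ne] - i_dens)
    else:
        dy[1] = infection - k * i_dens
    dy[2 + ne] = traits.burst_size * k * i_dens - infection
    if traits.adsorb_infected:
        dy[2 + ne] -= theta * traits.phi * y[1 : 2 + ne].sum() * v
    dy[3 + ne] = k * i_dens
    return dy


# ---------------------------------------------------------------------------
# community model assembly
# ---------------------------------------------------------------------------


class CommunityModel:
    """State layout and parameter arrays for a multi-host, multi-phage system.

    Built from an :class:`InfectionMatrix` and a trait table mapping each
    interacting ``(host, phage)`` pair to a :class:`TraitSet`.  Host growth
    rate, debris threshold, carrying capacity and the adsorb-infected flag
    must agree across the pairs sharing a host (they are host properties
    carried on the pair records of the CSV trait-table format).
    """

    def __init__(
        self,
        matrix: InfectionMatrix,
        traits: Mapping[tuple, TraitSet],
        attenuation: bool = True,
    ):
        self.matrix = matrix
        self.hosts = matrix.hosts
        self.phages = matrix.phages
        pairs = matrix.pairs
        missing = [pr for pr in pairs if pr not in traits]
        if missing:
            raise KeyError(f"trait table is missing interacting pairs: {missing}")
        self.pairs = pairs
        self.traits = {pr: traits[pr] for pr in pairs}

        host_r = {}
        host_dc = {}
        hill = set()
        cap = {}
        ads = set()
        for (h, p), ts in self.traits.items():
            for store, val in ((host_r, ts.r), (host_dc, ts.debris_halfsat), (cap, ts.carrying_capacity)):
                if h in store and store[h] != val:
                    raise ValueError(f"inconsistent host-level trait for {h!r}")
                store[h] = val
            hill.add(ts.hill_coeff)
            ads.add(ts.adsorb_infected)
        if len(hill) > 1:
            raise ValueError("hill_coeff must be shared across pairs")
        if len(ads) > 1:
            raise ValueError("adsorb_infected must be shared across pairs")

        nh, npg = len(self.hosts), len(self.phages)
        self.n_hosts, self.n_phages = nh, npg
        self.pair_host = np.array([self.hosts.index(h) for h, _ in pairs], dtype=np.int64)
        self.pair_phage = np.array([self.phages.index(p) for _, p in pairs], dtype=np.int64)
        self.pair_ne = np.array([self.traits[pr].n_exposed for pr in pairs], dtype=np.int64)
        self.pair_k = np.array([self.traits[pr].stage_rate for pr in pairs])
        self.pair_phi = np.array([self.traits[pr].phi for pr in pairs])
        self.pair_beta = np.array([self.traits[pr].burst_size for pr in pairs])
        off = nh + npg + 1
        self.pair_off = np.empty(len(pairs), dtype=np.int64)
        for p in range(len(pairs)):
            self.pair_off[p] = off
            off += self.pair_ne[p] + 1
        self.n_state = off
        self.host_r = np.array([host_r.get(h, 0.0) for h in self.hosts])
        dc = np.array([host_dc.get(h, math.inf) for h in self.hosts])
        self.host_dc = dc if attenuation else np.full(nh, math.inf)
        self.hill_n = hill.pop() if hill else 2.0
        caps = set(cap.values())
        self.carrying_capacity = caps.pop() if len(caps) == 1 else math.inf
        self.adsorb_infected = ads.pop() if ads else False
        self.attenuation = attenuation

    # -- state helpers ------------------------------------------------------

    def initial_state(
        self, s0: Mapping[str, float] | Sequence[float], v0: Mapping[str, float] | Sequence[float]
    ) -> np.ndarray:
        """Assemble the flat initial state from per-host and per-phage densities."""
        y0 = np.zeros(self.n_state)
        s_arr = (
            np.array([s0[h] for h in self.hosts], dtype=float)
            if isinstance(s0, Mapping)
            else np.asarray(s0, dtype=float)
        )
        v_arr = (
            np.array([v0[p] for p in self.phages], dtype=float)
            if isinstance(v0, Mapping)
            else np.asarray(v0, dtype=float)
        )
        y0[: self.n_hosts] = s_arr
        y0[self.n_hosts : self.n_hosts + self.n_phages] = v_arr
        return y0

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Numpy reference derivative (the numba kernel is the fast path)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_state,):
            raise ValueError(f"state must have length {self.n_state}")
        nh, npg = self.n_hosts, self.n_phages
        dy = np.zeros_like(y)
        d = max(y[nh + npg], 0.0)
        theta = np.array([hill_attenuation(d, dc, self.hill_n) for dc in self.host_dc])
        if np.isfinite(self.carrying_capacity):
            total = y[:nh].sum() + sum(
                y[self.pair_off[p] : self.pair_off[p] + self.pair_ne[p] + 1].sum()
                for p in range(len(self.pairs))
            )
            dy[:nh] = self.host_r * y[:nh] * (1.0 - total / self.carrying_capacity)
        else:
            dy[:nh] = self.host_r * y[:nh]
        for p in range(len(self.pairs)):
            i, j = self.pair_host[p], self.pair_phage[p]
            off, ne, k = self.pair_off[p], self.pair_ne[p], self.pair_k[p]
            infection = theta[i] * self.pair_phi[p] * y[i] * y[nh + j]
            dy[i] -= infection
            block = y[off : off + ne + 1]
            if ne > 0:
                dy[off] += infection - k * block[0]
                dy[off + 1 : off + ne] += k * (block[:-2] - block[1:-1])
                dy[off + ne] += k * (block[-2] - block[-1])
            else:
                dy[off] += infection - k * block[0]
            dy[nh + j] += self.pair_beta[p] * k * block[-1] - infection
            if self.adsorb_infected:
                dy[nh + j] -= theta[i] * self.pair_phi[p] * block.sum() * y[nh + j]
            dy[nh + npg] += k * block[-1]
        return dy

    def _kernel_args(self):
        ipar = np.array([self.n_hosts, self.n_phages, int(self.adsorb_infected)], dtype=np.int64)
        fpar = np.array([self.hill_n, self.carrying_capacity])
        apar_i = (self.pair_host, self.pair_phage, self.pair_off, self.pair_ne, _EMPTY_I)
        apar_f = (self.pair_k, self.pair_phi, self.pair_beta, self.host_r, self.host_dc)
        return ipar, fpar, apar_i, apar_f


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Dense model solution on a time grid, with observable projections.

    ``y`` holds the raw (clipped-at-zero) state, one row per time point.
    ``kind`` is ``"pairwise"`` or ``"community"``; ``meta`` carries whatever
    is needed to project observables (traits / community layout).
    """

    t: np.ndarray
    y: np.ndarray
    kind: str
    meta: dict

    def observe(self, observable: str, ident: str | None = None) -> np.ndarray:
        return observe(self, observable, ident)

    def state(self, name: str) -> np.ndarray:
        """Column by state label (pairwise: S, E1.., I, V, D; community: S:<id> etc.)."""
        labels = self.meta["labels"]
        return self.y[:, labels.index(name)]


def _pairwise_labels(ne: int) -> list:
    return ["S"] + [f"E{m}" for m in range(1, ne + 1)] + ["I", "V", "D"]


def _community_labels(model: CommunityModel) -> list:
    labels = [f"S:{h}" for h in model.hosts] + [f"V:{p}" for p in model.phages] + ["D"]
    for p, (h, ph) in enumerate(model.pairs):
        ne = model.pair_ne[p]
        labels += [f"E{m}:{h}|{ph}" for m in range(1, ne + 1)] + [f"I:{h}|{ph}"]
    return labels


def _validate_grid(t_eval) -> np.ndarray:
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) < 1:
        raise ValueError("time grid must be a 1-d array")
    if len(t_eval) > 1 and not np.all(np.diff(t_eval) > 0):
        raise ValueError("time grid must be strictly increasing")
    return t_eval


def _finish(out, status, t_fail, neg_tol):
    if status != _kernels.OK:
        raise IntegrationError(t_fail)
    # pre-clip negative excursions must stay at solver-tolerance scale
    tol = max(neg_tol, 1e-6 * float(np.abs(out).max()))
    if out.min() < -tol:
        raise IntegrationError(t_fail, f"negative excursion below -{tol:g} in solution")
    return np.clip(out, 0.0, None)


def simulate_pairwise(
    traits: TraitSet,
    s0: float,
    v0: float,
    t_eval,
    e0: np.ndarray | None = None,
    i0: float = 0.0,
    d0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> Trajectory:
    """Integrate the pairwise SEIV(D) model from (mostly) uninfected conditions."""
    t_eval = _validate_grid(t_eval)
    y0 = np.zeros(traits.n_exposed + 4)
    y0[0] = s0
    if e0 is not None:
        y0[1 : 1 + traits.n_exposed] = e0
    y0[1 + traits.n_exposed] = i0
    y0[2 + traits.n_exposed] = v0
    y0[3 + traits.n_exposed] = d0
    return integrate_pairwise_state(traits, y0, t_eval, rtol=rtol, atol=atol)


def integrate_pairwise_state(
    traits: TraitSet, y0: np.ndarray, t_eval, rtol: float = 1e-8, atol: float = 1e-2
) -> Trajectory:
    """Integrate the pairwise model from an arbitrary full state vector."""
    t_eval = _validate_grid(t_eval)
    y0 = _check_state(y0, traits)
    if y0.min() < 0:
        raise ValueError("initial state must be non-negative")
    ipar = np.array([traits.n_exposed, int(traits.adsorb_infected), 0], dtype=np.int64)
    fpar = np.array(
        [
            traits.r,
            traits.phi,
            traits.stage_rate,
            traits.burst_size,
            traits.debris_halfsat,
            traits.hill_coeff,
            traits.carrying_capacity,
        ]
    )
    apar_i = (_EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_I)
    apar_f = (_EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F)
    out, status, t_fail = _kernels.dp45(0, y0, t_eval, rtol, atol, ipar, fpar, apar_i, apar_f)
    y = _finish(out, status, t_fail, neg_tol=max(atol * 1e3, 1.0))
    return Trajectory(
        t=t_eval,
        y=y,
        kind="pairwise",
        meta={"traits": traits, "labels": _pairwise_labels(traits.n_exposed)},
    )


def simulate_community(
    model: CommunityModel,
    s0,
    v0,
    t_eval,
    y0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> Trajectory:
    """Integrate the community SEIV(D) model on ``t_eval``."""
    t_eval = _validate_grid(t_eval)
    if y0 is None:
        y0 = model.initial_state(s0, v0)
    y0 = np.asarray(y0, dtype=float)
    if y0.min() < 0 or not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite and non-negative")
    ipar, fpar, apar_i, apar_f = model._kernel_args()
    out, status, t_fail = _kernels.dp45(1, y0, t_eval, rtol, atol, ipar, fpar, apar_i, apar_f)
    y = _finish(out, status, t_fail, neg_tol=max(atol * 1e3, 1.0))
    return Trajectory(
        t=t_eval,
        y=y,
        kind="community",
        meta={"model": model, "labels": _community_labels(model)},
    )


def integrate(rhs, y0, t_eval, rtol: float = 1e-8, atol: float = 1e-2, labels=None) -> Trajectory:
    """Adaptive integration of an arbitrary callable RHS ``f(y) -> dy``.

    Generic entry point (scipy RK45) for user-supplied systems; the model
    simulators above use the compiled fast path for the packaged equations.
    """
    from scipy.integrate import solve_ivp

    t_eval = _validate_grid(t_eval)
    y0 = np.asarray(y0, dtype=float)
    if not np.all(np.isfinite(y0)) or y0.min() < 0:
        raise ValueError("initial state must be finite and non-negative")
    sol = solve_ivp(
        lambda t, y: rhs(y),
        (t_eval[0], t_eval[-1]),
        y0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(sol.t[-1] if len(sol.t) else t_eval[0], sol.message)
    y = np.clip(sol.y.T, 0.0, None)
    lab = list(labels) if labels is not None else [f"y{i}" for i in range(len(y0))]
    return Trajectory(t=t_eval, y=y, kind="generic", meta={"labels": lab})


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def observe(traj: Trajectory, observable: str, ident: str | None = None) -> np.ndarray:
    """Project a trajectory onto a measurable quantity.

    ``free_phage``/``phage_qEXT`` count virions only; ``total_phage`` counts
    free virions plus infected centres (each exposed or infected cell counts
    once, as it forms one plaque); ``host_qINT`` counts all cells of a host,
    susceptible or infected; ``total_host`` sums hosts.
    """
    if observable not in OBSERVABLES:
        raise ValueError(f"unknown observable {observable!r}; expected one of {OBSERVABLES}")
    if traj.kind == "pairwise":
        traits: TraitSet = traj.meta["traits"]
        ne = traits.n_exposed
        s = traj.y[:, 0]
        e_i = traj.y[:, 1 : 2 + ne].sum(axis=1)  # all exposed stages + I
        v = traj.y[:, 2 + ne]
        if observable in ("free_phage", "phage_qEXT"):
            return v
        if observable == "total_phage":
            return v + e_i
        if observable in ("host_qINT", "total_host"):
            return s + e_i
    elif traj.kind == "community":
        model: CommunityModel = traj.meta["model"]
        nh, npg = model.n_hosts, model.n_phages
        if observable in ("free_phage", "phage_qEXT"):
            if ident is None:
                raise ValueError("community phage observables need a phage identifier")
            j = model.phages.index(ident)
            return traj.y[:, nh + j]
        if observable == "total_phage":
            if ident is None:
                raise ValueError("community total_phage needs a phage identifier")
            j = model.phages.index(ident)
            tot = traj.y[:, nh + j].copy()
            for p in range(len(model.pairs)):
                if model.pair_phage[p] == j:
                    off, ne = model.pair_off[p], model.pair_ne[p]
                    tot += traj.y[:, off : off + ne + 1].sum(axis=1)
            return tot
        if observable == "host_qINT":
            if ident is None:
                raise ValueError("community host_qINT needs a host identifier")
            i = model.hosts.index(ident)
            tot = traj.y[:, i].copy()
            for p in range(len(model.pairs)):
                if model.pair_host[p] == i:
                    off, ne = model.pair_off[p], model.pair_ne[p]
                    tot += traj.y[:, off : off + ne + 1].sum(axis=1)
            return tot
        if observable == "total_host":
            return sum(observe(traj, "host_qINT", h) for h in model.hosts)
    raise ValueError(f"cannot project {observable!r} from a {traj.kind!r} trajectory")
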