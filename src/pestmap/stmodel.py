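"""Bayesian hierarchical spatiotemporal Poisson model for areal count panels.

The model for observed counts ``y_it`` in area *i* and period *t*, with
expected counts ``E_it`` from indirect standardization as offset, is

    y_it ~ Poisson(E_it * exp(eta_it))
    eta_it = b0 + u_i + v_i + gamma_t + phi_t + delta_it

where ``u`` is a spatially structured ICAR (intrinsic CAR) field on the
contiguity graph, ``v`` an exchangeable (IID) spatial field — together the
Besag-York-Mollie convolution — ``gamma`` a second-order random-walk (RW2)
structured temporal field, ``phi`` an IID temporal field, and ``delta`` a
space-time interaction field whose precision structure follows the
Knorr-Held taxonomy:

    type I   : IID x IID            (fully unstructured)
    type II  : RW2 in time, IID in space (independent temporal trends per area)
    type III : ICAR in space, IID in time (independent spatial surfaces per period)

Each precision carries a Gamma hyperprior.  Inference is by
Metropolis-within-Gibbs: conjugate Gamma updates for the precisions,
adaptive random-walk Metropolis for the latent fields (vectorized over
conditionally independent sites via graph coloring), and post-sweep
re-centering onto the intrinsic fields' constraint spaces with the removed
components absorbed into the confounded model terms so the linear predictor
is left invariant.  Models are compared by DIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln

from .lattice import AreaLattice
from .panel import PanelCounts

INTERACTION_TYPES = ("none", "I", "II", "III")

# Gamma(shape, rate) hyperprior on every precision: a conventional
# weakly-informative disease-mapping default.
DEFAULT_HYPERPRIOR = (1.0, 5e-4)


# --------------------------------------------------------------------------
# structure matrices
# --------------------------------------------------------------------------

def icar_structure(lattice: AreaLattice) -> sp.csr_matrix:
    """ICAR structure matrix Q = D - W (graph Laplacian).

    Symmetric positive semidefinite; its null space is spanned by the
    indicator vectors of the connected components, so rank =
    n_areas - n_components.  Isolated areas form their own component and
    their field value is pinned to zero by the per-component constraint.
    """
    W = lattice.adjacency
    D = sp.diags(lattice.degrees)
    return (D - W).tocsr()


def rw2_structure(T: int) -> sp.csr_matrix:
    """Second-difference penalty matrix for an RW2 field of length T.

    Q = D2' D2 with D2 the (T-2) x T second-difference operator; rank T-2,
    null space spanned by the constant and linear vectors.  Fewer than four
    periods cannot carry a useful RW2 field, so that is refused here; the
    internal penalty helper degrades to an empty penalty instead.
    """
    if T < 4:
        raise ValueError(f"RW2 needs T >= 4, got {T}")
    return _rw2_penalty(T)


def _rw2_penalty(T: int) -> sp.csr_matrix:
    """Second-difference penalty for any T; zero matrix (rank 0) when T < 3."""
    m = max(T - 2, 0)
    if m == 0:
        return sp.csr_matrix((T, T))
    D2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m, T))
    return (D2.T @ D2).tocsr()


def interaction_structure(
    spec: "STModelSpec", lattice: AreaLattice, T: int
) -> tuple[sp.csr_matrix, int]:
    """Kronecker structure matrix for the space-time interaction field.

    The interaction field delta is stored as an (n_areas, T) matrix and
    vectorized row-major (area-major), so a temporal penalty within each
    area is I_n (x) Q_rw2 and a spatial penalty within each period is
    Q_icar (x) I_T.  Returns the matrix and its generalized rank, used as
    the exponent in the conjugate precision update.
    """
    n = lattice.n_areas
    kind = spec.interaction_type
    if kind == "I":
        return sp.identity(n * T, format="csr"), n * T
    if kind == "II":
        Qg = _rw2_penalty(T)
        return sp.kron(sp.identity(n), Qg, format="csr"), n * max(T - 2, 0)
    if kind == "III":
        Qu = icar_structure(lattice)
        rank = T * (n - lattice.n_components)
        return sp.kron(Qu, sp.identity(T), format="csr"), rank
    raise ValueError(
        f"no interaction structure for interaction_type={kind!r}"
    )


def _greedy_coloring(adjacency: sp.csr_matrix) -> list[np.ndarray]:
    """Partition graph nodes into independent sets (largest-degree-first)."""
    adj = adjacency.tocsr()
    n = adj.shape[0]
    colors = np.full(n, -1, dtype=int)
    for i in np.argsort(-np.asarray(adj.sum(axis=1)).ravel(), kind="stable"):
        nb = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
        used = set(colors[nb].tolist())
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]


# --------------------------------------------------------------------------
# model specification and posterior container
# --------------------------------------------------------------------------

def _default_hyperpriors() -> dict[str, tuple[float, float]]:
    return {k: DEFAULT_HYPERPRIOR for k in ("u", "v", "gamma", "phi", "delta")}


@dataclass
class STModelSpec:
    """Specification of the spatiotemporal model and its MCMC settings."""

    interaction_type: str = "none"
    hyperpriors: dict[str, tuple[float, float]] = field(
        default_factory=_default_hyperpriors
    )
    n_iter: int = 4000
    n_burn: int = 1500
    thin: int = 1
    n_chains: int = 1
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"interaction_type must be one of {INTERACTION_TYPES}"
            )
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        full = _default_hyperpriors()
        full.update(self.hyperpriors)
        self.hyperpriors = full
        for name, (a, b) in self.hyperpriors.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Gamma hyperprior for tau_{name} must be positive")

    def label(self) -> str:
        return (
            f"Model {self.interaction_type}"
            if self.interaction_type != "none"
            else "no interaction"
        )


_FIELDS = ("u", "v", "gamma", "phi", "delta")


@dataclass
class STPosterior:
    """Thinned post-burn-in MCMC draws and derived summaries."""

    spec: STModelSpec
    area_ids: list[str]
    periods: list
    b0: np.ndarray                      # (S,)
    u: np.ndarray                       # (S, n)
    v: np.ndarray                       # (S, n)
    gamma: np.ndarray                   # (S, T)
    phi: np.ndarray                     # (S, T)
    delta: np.ndarray | None            # (S, n, T) or None
    tau: dict[str, np.ndarray]          # each (S,)
    deviance: np.ndarray                # (S,)
    acceptance: dict[str, float]
    constraint_residuals: np.ndarray    # (S,) max abs pre-recentering residual
    seed: int
    rhat: dict[str, float] | None = None

    @property
    def n_draws(self) -> int:
        return len(self.b0)

    def eta_draws(self) -> np.ndarray:
        """(S, n, T) linear-predictor draws recomposed from the components."""
        eta = (
            self.b0[:, None, None]
            + self.u[:, :, None]
            + self.v[:, :, None]
            + self.gamma[:, None, :]
            + self.phi[:, None, :]
        )
        if self.delta is not None:
            eta = eta + self.delta
        return eta

    def summary(self) -> pd.DataFrame:
        """Posterior mean and central 95% interval per model component."""
        rows = []

        def add(component, statistic, draws):
            rows.append(
                {
                    "component": component,
                    "statistic": statistic,
                    "mean": float(np.mean(draws)),
                    "q025": float(np.quantile(draws, 0.025)),
                    "q975": float(np.quantile(draws, 0.975)),
                }
            )

        add("intercept", "b0", self.b0)
        add("spatial BYM", "tau_u (structured)", self.tau["u"])
        add("spatial BYM", "tau_v (IID)", self.tau["v"])
        add("temporal RW2", "tau_gamma", self.tau["gamma"])
        add("temporal IID", "tau_phi", self.tau["phi"])
        if self.delta is not None:
            add("interaction", "tau_delta", self.tau["delta"])
        add("deviance", "D", self.deviance)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# log posterior
# --------------------------------------------------------------------------

def _quad(Q: sp.spmatrix, x: np.ndarray) -> float:
    return float(x @ (Q @ x))


def log_posterior(
    state: dict,
    panel: PanelCounts,
    spec: STModelSpec,
    lattice: AreaLattice,
) -> float:
    """Unnormalized log posterior density (up to an additive constant).

    ``state`` maps b0, u, v, gamma, phi, delta (delta may be absent for
    interaction_type 'none') and tau_u, tau_v, tau_gamma, tau_phi,
    tau_delta to values.  The Poisson likelihood enters as
    sum(y*eta - E*exp(eta)); each intrinsic Gaussian field contributes
    (rank/2) log tau - (tau/2) x'Qx, and each precision its Gamma log prior.
    The intercept carries a flat prior.
    """
    if panel.expected is None:
        raise ValueError("panel has no expected counts; run expected_counts first")
    n, T = panel.n_areas, panel.n_periods
    b0 = float(state["b0"])
    u = np.asarray(state["u"], dtype=float)
    v = np.asarray(state["v"], dtype=float)
    gamma = np.asarray(state["gamma"], dtype=float)
    phi = np.asarray(state["phi"], dtype=float)
    eta = b0 + u[:, None] + v[:, None] + gamma[None, :] + phi[None, :]
    if spec.interaction_type != "none":
        delta = np.asarray(state["delta"], dtype=float)
        eta = eta + delta
    lp = float(np.sum(panel.y * eta - panel.expected * np.exp(eta)))

    Qu = icar_structure(lattice)
    Qg = _rw2_penalty(T)
    pieces = [
        ("u", u, Qu, n - lattice.n_components),
        ("v", v, sp.identity(n, format="csr"), n),
        ("gamma", gamma, Qg, max(T - 2, 0)),
        ("phi", phi, sp.identity(T, format="csr"), T),
    ]
    if spec.interaction_type != "none":
        Qd, rank_d = interaction_structure(spec, lattice, T)
        pieces.append(("delta", delta.ravel(), Qd, rank_d))
    for name, x, Q, rank in pieces:
        tau = float(state[f"tau_{name}"])
        if tau <= 0:
            raise ValueError(f"tau_{name} must be positive")
        a, b = spec.hyperpriors[name]
        lp += 0.5 * rank * math.log(tau) - 0.5 * tau * _quad(Q, x)
        lp += (a - 1.0) * math.log(tau) - b * tau
    if not np.isfinite(lp):
        bad = np.argwhere(~np.isfinite(panel.y * eta - panel.expected * np.exp(eta)))
        where = f" (first offending cell {tuple(bad[0])})" if len(bad) else ""
        raise FloatingPointError(f"non-finite log posterior{where}")
    return lp


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------

_DIVERGENCE_BOUND = 50.0


class _Chain:
    """Single-chain Metropolis-within-Gibbs state and sweep logic."""

    def __init__(
        self,
        panel: PanelCounts,
        lattice: AreaLattice,
        spec: STModelSpec,
        seed: int,
    ) -> None:
        if panel.expected is None:
            raise ValueError(
                "panel has no expected counts; run expected_counts first"
            )
        if list(panel.area_ids) != list(lattice.area_ids):
            raise ValueError("panel areas do not match lattice areas")
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.Y = panel.y
        self.E = panel.expected
        self.n, self.T = panel.y.shape
        self.has_delta = spec.interaction_type != "none"

        self.Qu = icar_structure(lattice)
        self.du = lattice.degrees.astype(float)          # diag of Qu
        self.Qg = _rw2_penalty(self.T).toarray()
        self.dg = np.diag(self.Qg).copy()
        self.rank_u = self.n - lattice.n_components
        self.rank_g = max(self.T - 2, 0)
        self.components = [
            np.flatnonzero(lattice.component == c)
            for c in range(lattice.n_components)
        ]
        self.space_colors = _greedy_coloring(lattice.adjacency)
        self.time_colors = [
            np.arange(c, self.T, 3) for c in range(min(3, self.T))
        ]
        if self.has_delta:
            _, self.rank_d = interaction_structure(spec, lattice, self.T)

        self.Ry = self.Y.sum(axis=1)   # per-area count totals
        self.Cy = self.Y.sum(axis=0)   # per-period count totals
        self.Sy = self.Y.sum()

        # warm start from the saturated log-rate surface
        resid = np.log((self.Y + 0.5) / self.E)
        self.b0 = float(resid.mean())
        area = resid.mean(axis=1) - self.b0
        period = resid.mean(axis=0) - self.b0
        self.u = np.zeros(self.n)
        self.v = area.copy()
        self.gamma = np.zeros(self.T)
        self.phi = period.copy()
        self.delta = (
            np.zeros((self.n, self.T)) if self.has_delta else None
        )
        self.tau = {k: 10.0 for k in _FIELDS}
        self._recentre()
        self._refresh_cache()
        if not np.all(np.isfinite(self.mu)):
            raise FloatingPointError("non-finite posterior at initialization")

        self.steps = {
            "b0": 0.05,
            "u": 0.2,
            "v": 0.2,
            "gamma": 0.2,
            "phi": 0.2,
            "delta": 0.2,
        }
        self.window_acc = {k: [0, 0] for k in self.steps}
        self.total_acc = {k: [0, 0] for k in self.steps}

    # -------------------------------------------------------------- caches

    def _refresh_cache(self) -> None:
        eta = (
            self.b0
            + self.u[:, None]
            + self.v[:, None]
            + self.gamma[None, :]
            + self.phi[None, :]
        )
        if self.has_delta:
            eta = eta + self.delta
        self.eta = eta
        self._check_divergence()
        self.mu = self.E * np.exp(eta)

    def _check_divergence(self) -> None:
        amax = np.abs(self.eta).max()
        if amax > _DIVERGENCE_BOUND:
            i, t = np.unravel_index(np.abs(self.eta).argmax(), self.eta.shape)
            raise RuntimeError(
                f"divergent linear predictor |eta|={amax:.1f} at cell "
                f"(area {i}, period {t}); state dump: b0={self.b0:.3f}, "
                f"tau={{{', '.join(f'{k}:{v:.3g}' for k, v in self.tau.items())}}}"
            )

    # ------------------------------------------------------------- updates

    def _accept(self, block: str, n_prop: int, accepted: np.ndarray) -> None:
        self.window_acc[block][0] += int(np.sum(accepted))
        self.window_acc[block][1] += n_prop
        self.total_acc[block][0] += int(np.sum(accepted))
        self.total_acc[block][1] += n_prop

    def _update_b0(self) -> None:
        d = self.steps["b0"] * self.rng.standard_normal()
        dll = self.Sy * d - self.mu.sum() * math.expm1(d)
        if math.log(self.rng.uniform()) < dll:
            self.b0 += d
            self.eta += d
            self.mu *= math.exp(d)
            self._accept("b0", 1, np.ones(1, bool))
        else:
            self._accept("b0", 1, np.zeros(1, bool))

    def _update_area_field(self, name: str) -> None:
        """Row fields u (ICAR prior, colored) and v (IID prior, one shot)."""
        tau = self.tau[name]
        if name == "u":
            groups = self.space_colors
        else:
            groups = [np.arange(self.n)]
        for idx in groups:
            x = getattr(self, name)
            d = self.steps[name] * self.rng.standard_normal(len(idx))
            Mrow = self.mu[idx].sum(axis=1)
            dll = self.Ry[idx] * d - Mrow * np.expm1(d)
            if name == "u":
                Qx = self.Qu @ x
                dlp = -0.5 * tau * (d * d * self.du[idx] + 2.0 * d * Qx[idx])
            else:
                dlp = -0.5 * tau * (d * d + 2.0 * d * x[idx])
            acc = np.log(self.rng.uniform(size=len(idx))) < dll + dlp
            if np.any(acc):
                rows = idx[acc]
                x[rows] += d[acc]
                self.eta[rows] += d[acc][:, None]
                self.mu[rows] *= np.exp(d[acc])[:, None]
            self._accept(name, len(idx), acc)

    def _update_time_field(self, name: str) -> None:
        """Column fields gamma (RW2 prior, mod-3 colors) and phi (IID)."""
        tau = self.tau[name]
        if name == "gamma":
            groups = self.time_colors
        else:
            groups = [np.arange(self.T)]
        for idx in groups:
            x = getattr(self, name)
            d = self.steps[name] * self.rng.standard_normal(len(idx))
            Mcol = self.mu[:, idx].sum(axis=0)
            dll = self.Cy[idx] * d - Mcol * np.expm1(d)
            if name == "gamma":
                Qx = self.Qg @ x
                dlp = -0.5 * tau * (d * d * self.dg[idx] + 2.0 * d * Qx[idx])
            else:
                dlp = -0.5 * tau * (d * d + 2.0 * d * x[idx])
            acc = np.log(self.rng.uniform(size=len(idx))) < dll + dlp
            if np.any(acc):
                cols = idx[acc]
                x[cols] += d[acc]
                self.eta[:, cols] += d[acc][None, :]
                self.mu[:, cols] *= np.exp(d[acc])[None, :]
            self._accept(name, len(idx), acc)

    def _update_delta(self) -> None:
        tau = self.tau["delta"]
        kind = self.spec.interaction_type
        step = self.steps["delta"]
        if kind == "I":
            blocks = [(np.arange(self.n), np.arange(self.T))]
        elif kind == "II":
            blocks = [(np.arange(self.n), idx) for idx in self.time_colors]
        else:  # III
            blocks = [(idx, np.arange(self.T)) for idx in self.space_colors]
        for rows, cols in blocks:
            sub = np.ix_(rows, cols)
            d = step * self.rng.standard_normal((len(rows), len(cols)))
            dll = self.Y[sub] * d - self.mu[sub] * np.expm1(d)
            if kind == "I":
                dlp = -0.5 * tau * (d * d + 2.0 * d * self.delta[sub])
            elif kind == "II":
                M = self.delta @ self.Qg           # per-area RW2 row products
                dlp = -0.5 * tau * (
                    d * d * self.dg[None, cols] + 2.0 * d * M[sub]
                )
            else:
                M = self.Qu @ self.delta           # per-period ICAR products
                dlp = -0.5 * tau * (
                    d * d * self.du[rows][:, None] + 2.0 * d * M[sub]
                )
            acc = (
                np.log(self.rng.uniform(size=d.shape)) < dll + dlp
            )
            if np.any(acc):
                dd = np.where(acc, d, 0.0)
                self.delta[sub] += dd
                self.eta[sub] += dd
                self.mu[sub] *= np.exp(dd)
            self._accept("delta", acc.size, acc)

    def _update_precisions(self) -> None:
        specs = [
            ("u", self.u @ (self.Qu @ self.u), self.rank_u),
            ("v", self.v @ self.v, self.n),
            ("gamma", self.gamma @ (self.Qg @ self.gamma), self.rank_g),
            ("phi", self.phi @ self.phi, self.T),
        ]
        if self.has_delta:
            kind = self.spec.interaction_type
            if kind == "I":
                quad = float(np.sum(self.delta * self.delta))
            elif kind == "II":
                quad = float(np.sum(self.delta * (self.delta @ self.Qg)))
            else:
                quad = float(np.sum(self.delta * (self.Qu @ self.delta)))
            specs.append(("delta", quad, self.rank_d))
        for name, quad, rank in specs:
            a, b = self.spec.hyperpriors[name]
            self.tau[name] = self.rng.gamma(
                a + 0.5 * rank, 1.0 / (b + 0.5 * max(quad, 0.0))
            )

    # --------------------------------------------------------- constraints

    def _recentre(self) -> float:
        """Project intrinsic fields onto their constraint spaces.

        Every removed component is absorbed into the model term it is
        confounded with, so eta is left exactly invariant: ICAR component
        means move into v, the RW2 mean into the intercept and its linear
        part into phi, IID-field means into the intercept, and the
        interaction's confounded null-space directions into v (type II
        per-area means) or phi (type III per-period means).  Returns the
        largest constraint residual found before re-centering.
        """
        resid = 0.0
        if self.has_delta:
            kind = self.spec.interaction_type
            if kind == "II":
                m = self.delta.mean(axis=1)
                resid = max(resid, float(np.abs(m).max()) * self.T)
                self.delta -= m[:, None]
                self.v += m
            elif kind == "III":
                m = self.delta.mean(axis=0)
                resid = max(resid, float(np.abs(m).max()) * self.n)
                self.delta -= m[None, :]
                self.phi += m
        for idx in self.components:
            m = self.u[idx].mean()
            resid = max(resid, abs(m) * len(idx))
            self.u[idx] -= m
            self.v[idx] += m
        t = np.arange(self.T, dtype=float)
        tc = t - t.mean()
        slope = float(self.gamma @ tc) / float(tc @ tc)
        resid = max(resid, abs(float(self.gamma.sum())), abs(float(self.gamma @ t)))
        mg = self.gamma.mean()
        self.gamma -= mg + slope * tc
        self.b0 += mg
        self.phi += slope * tc
        mp = self.phi.mean()
        self.phi -= mp
        self.b0 += mp
        mv = self.v.mean()
        self.v -= mv
        self.b0 += mv
        return resid

    # ------------------------------------------------------------- driving

    def sweep(self) -> float:
        self._update_b0()
        self._update_area_field("u")
        self._update_area_field("v")
        self._update_time_field("gamma")
        self._update_time_field("phi")
        if self.has_delta:
            self._update_delta()
        self._update_precisions()
        resid = self._recentre()
        self._refresh_cache()
        return resid

    def adapt(self) -> None:
        """Tune step sizes toward 30-50% acceptance (burn-in only)."""
        for name, (acc, prop) in self.window_acc.items():
            if prop == 0:
                continue
            rate = acc / prop
            if rate < 0.30:
                self.steps[name] *= 0.8
            elif rate > 0.50:
                self.steps[name] *= 1.25
            self.window_acc[name] = [0, 0]

    def deviance(self) -> float:
        return -2.0 * float(
            np.sum(
                self.Y * np.log(self.mu) - self.mu - gammaln(self.Y + 1.0)
            )
        )


def _prior_only_draws(
    panel: PanelCounts, lattice: AreaLattice, spec: STModelSpec, seed: int
) -> STPosterior:
    """Exact ancestral draws from the joint prior (the likelihood ignored).

    Precisions come straight from their Gamma hyperpriors and each field
    from the corresponding (constrained) Gaussian Markov random field, so
    prior-mode output is exact rather than a Markov chain.
    """
    from .synth import sample_gmrf  # local import; synth depends on stmodel

    rng = np.random.default_rng(seed)
    n, T = panel.n_areas, panel.n_periods
    S = max((spec.n_iter - spec.n_burn) // spec.thin, 1)
    Qu = icar_structure(lattice)
    Qg = _rw2_penalty(T)
    names = list(_FIELDS) if spec.interaction_type != "none" else [
        f for f in _FIELDS if f != "delta"
    ]
    tau = {
        name: rng.gamma(a, 1.0 / b, size=S)
        for name, (a, b) in spec.hyperpriors.items()
        if name in names
    }
    u = np.empty((S, n))
    v = np.empty((S, n))
    gamma = np.empty((S, T))
    phi = np.empty((S, T))
    delta = (
        np.empty((S, n, T)) if spec.interaction_type != "none" else None
    )
    if delta is not None:
        Qd, _ = interaction_structure(spec, lattice, T)
    for s in range(S):
        u[s] = sample_gmrf(Qu, tau["u"][s], rng=rng)
        v[s] = rng.normal(0.0, tau["v"][s] ** -0.5, size=n)
        gamma[s] = sample_gmrf(Qg, tau["gamma"][s], rng=rng)
        phi[s] = rng.normal(0.0, tau["phi"][s] ** -0.5, size=T)
        if delta is not None:
            delta[s] = sample_gmrf(Qd, tau["delta"][s], rng=rng).reshape(n, T)
    b0 = np.zeros(S)
    return STPosterior(
        spec=spec,
        area_ids=list(panel.area_ids),
        periods=list(panel.periods),
        b0=b0,
        u=u,
        v=v,
        gamma=gamma,
        phi=phi,
        delta=delta,
        tau=tau,
        deviance=np.zeros(S),
        acceptance={},
        constraint_residuals=np.zeros(S),
        seed=seed,
    )


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction on stacked (chain, draw) arrays."""
    chains = [h for half in np.array_split(x, 2, axis=-1) for h in half]
    m = len(chains)
    L = min(len(c) for c in chains)
    arr = np.stack([c[:L] for c in chains])
    mean_c = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = L * mean_c.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt(((L - 1) / L * W + B / L) / W))


def fit(
    panel: PanelCounts,
    lattice: AreaLattice,
    spec: STModelSpec,
    prior_only: bool = False,
) -> STPosterior:
    """Fit the spatiotemporal model by Metropolis-within-Gibbs MCMC.

    Runs ``spec.n_chains`` independent chains (seeds derived from
    ``spec.seed``), discards ``n_burn`` sweeps from each, thins by
    ``spec.thin`` and concatenates the retained draws.  With
    ``prior_only`` the data are ignored and exact draws from the joint
    prior are returned instead.
    """
    if prior_only:
        return _prior_only_draws(panel, lattice, spec, spec.seed)
    all_draws: list[dict] = []
    chain_b0 = []
    for chain_idx in range(spec.n_chains):
        seed = spec.seed + 1009 * chain_idx
        chain = _Chain(panel, lattice, spec, seed)
        keep = {
            "b0": [], "u": [], "v": [], "gamma": [], "phi": [],
            "delta": [], "tau": [], "deviance": [], "resid": [],
        }
        for it in range(spec.n_iter):
            resid = chain.sweep()
            burn = it < spec.n_burn
            if burn and (it + 1) % spec.adapt_window == 0:
                chain.adapt()
            if not burn and (it - spec.n_burn) % spec.thin == 0:
                keep["b0"].append(chain.b0)
                keep["u"].append(chain.u.copy())
                keep["v"].append(chain.v.copy())
                keep["gamma"].append(chain.gamma.copy())
                keep["phi"].append(chain.phi.copy())
                if chain.has_delta:
                    keep["delta"].append(chain.delta.copy())
                keep["tau"].append(dict(chain.tau))
                keep["deviance"].append(chain.deviance())
                keep["resid"].append(resid)
        if len(keep["deviance"]) < 1:
            raise ValueError("no draws retained; increase n_iter")
        acc = {
            k: (a / p if p else float("nan"))
            for k, (a, p) in chain.total_acc.items()
        }
        all_draws.append((keep, acc))
        chain_b0.append(np.asarray(keep["b0"]))

    keep0 = all_draws[0][0]
    names = [f for f in _FIELDS if f != "delta" or keep0["delta"]]
    cat = lambda key: np.concatenate(  # noqa: E731
        [np.asarray(k[key]) for k, _ in all_draws]
    )
    tau = {
        name: np.concatenate(
            [np.array([d[name] for d in k["tau"]]) for k, _ in all_draws]
        )
        for name in names
    }
    has_delta = spec.interaction_type != "none"
    acceptance = {
        k: float(np.mean([acc[k] for _, acc in all_draws]))
        for k in all_draws[0][1]
        if not (k == "delta" and not has_delta)
    }
    rhat = None
    if spec.n_chains >= 2:
        rhat = {"b0": _split_rhat(np.stack(chain_b0))}
    return STPosterior(
        spec=spec,
        area_ids=list(panel.area_ids),
        periods=list(panel.periods),
        b0=cat("b0"),
        u=cat("u"),
        v=cat("v"),
        gamma=cat("gamma"),
        phi=cat("phi"),
        delta=cat("delta") if has_delta else None,
        tau=tau,
        deviance=cat("deviance"),
        acceptance=acceptance,
        constraint_residuals=cat("resid"),
        seed=spec.seed,
        rhat=rhat,
    )


# --------------------------------------------------------------------------
# DIC, relative risk, model comparison
# --------------------------------------------------------------------------

def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return -2.0 * float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def dic(posterior: STPosterior, panel: PanelCounts) -> tuple[float, float, float]:
    """Deviance information criterion (dic, p_d, d_bar).

    d_bar is the posterior mean deviance from the stored trace; the plug-in
    deviance D(eta_bar) is evaluated at the posterior mean of the linear
    predictor eta (not at the component-wise parameter means — p_d depends
    on this parameterization choice).  p_d = d_bar - D(eta_bar) and
    dic = d_bar + p_d.  A negative p_d is reported with a warning.
    """
    if posterior.n_draws < 10:
        raise ValueError("need at least 10 retained draws for DIC")
    if panel.expected is None:
        raise ValueError("panel has no expected counts")
    d_bar = float(posterior.deviance.mean())
    eta_bar = posterior.eta_draws().mean(axis=0)
    d_hat = _poisson_deviance(panel.y, panel.expected * np.exp(eta_bar))
    p_d = d_bar - d_hat
    if p_d < 0:
        import warnings

        warnings.warn(
            f"negative effective parameter count p_d={p_d:.3f}; "
            "the posterior mean is a poor plug-in for this fit",
            stacklevel=2,
        )
    return d_bar + p_d, p_d, d_bar


def relative_risk(posterior: STPosterior, mode: str = "interaction") -> pd.DataFrame:
    """Posterior-mean relative-risk surface per (area, period).

    mode 'interaction': posterior mean of exp(delta_it), the smoothed
    space-time departure from the separable model.  mode 'full': posterior
    mean of exp(eta_it - b0), the full area-period risk relative to the
    study-region baseline rate.
    """
    if mode == "interaction":
        if posterior.delta is None:
            raise ValueError(
                "interaction relative risk undefined for interaction_type "
                "'none'; use mode='full'"
            )
        rr = np.exp(posterior.delta).mean(axis=0)
    elif mode == "full":
        eta = posterior.eta_draws()
        rr = np.exp(eta - posterior.b0[:, None, None]).mean(axis=0)
    else:
        raise ValueError("mode must be 'interaction' or 'full'")
    n, T = rr.shape
    return pd.DataFrame(
        {
            "area_id": np.repeat(posterior.area_ids, T),
            "period": np.tile(posterior.periods, n),
            "rr": rr.ravel(),
        }
    )


def compare_models(
    panel: PanelCounts,
    lattice: AreaLattice,
    specs: list[STModelSpec],
) -> tuple[pd.DataFrame, STModelSpec | None]:
    """Fit every spec, rank by DIC ascending, and select the best.

    Near-ties (|dDIC| < 1) are flagged and resolved toward the smaller
    effective parameter count p_d.  A failing fit is recorded and the
    comparison proceeds with the survivors.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    rows = []
    fits: dict[int, STPosterior] = {}
    for k, spec in enumerate(specs):
        try:
            post = fit(panel, lattice, spec)
            d, p_d, d_bar = dic(post, panel)
            fits[k] = post
            rows.append(
                {
                    "model": spec.label(),
                    "interaction_type": spec.interaction_type,
                    "dic": d,
                    "p_d": p_d,
                    "d_bar": d_bar,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - survivors continue
            rows.append(
                {
                    "model": spec.label(),
                    "interaction_type": spec.interaction_type,
                    "dic": np.nan,
                    "p_d": np.nan,
                    "d_bar": np.nan,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    ok = table["dic"].notna()
    order = list(table.loc[ok].sort_values(["dic", "p_d"]).index)
    table["tie"] = False
    if len(order) >= 2:
        top_two = table.loc[order[:2]]
        if abs(top_two["dic"].iloc[0] - top_two["dic"].iloc[1]) < 1.0:
            table.loc[order[:2], "tie"] = True
            # near-tie: prefer the more parsimonious model
            if top_two["p_d"].iloc[1] < top_two["p_d"].iloc[0]:
                order[0], order[1] = order[1], order[0]
    table["rank"] = np.nan
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    best_spec = specs[order[0]] if order else None
    return table, best_spec


def select_min_dic(dics: dict[str, float]) -> tuple[str, float]:
    """Pure min-DIC selection rule over precomputed model DIC values."""
    if not dics:
        raise ValueError("no DIC values supplied")
    best = min(dics, key=dics.get)
    return best, dics[best]
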