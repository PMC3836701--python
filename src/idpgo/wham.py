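"""Binless temperature WHAM and the thermodynamic observables built on it.

Samples from a temperature ladder are pooled; the self-consistent
free-energy offsets f_k give every sample a weight at any query temperature
inside the sampled range.  From the weights: heat capacity C_V(T), melting
temperature (C_V peak refined to the P_bound = 1/2 crossing), reweighted
1D/2D free-energy surfaces, and the dissociation constant from bound and
unbound probabilities with the single-pair-per-box effective concentration

    K_D = C_eff * P_U^2 / (1 - P_U),   C_eff = 1 / (N_A V_box).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants as sc
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import KB

logger = logging.getLogger(__name__)


class WhamConvergenceError(RuntimeError):
    def __init__(self, iterations, max_delta, tol):
        super().__init__(
            f"WHAM did not converge in {iterations} iterations "
            f"(max |df| = {max_delta:.3e}, tol = {tol:.3e})"
        )
        self.iterations = iterations
        self.max_delta = max_delta


@dataclass
class WhamResult:
    temperatures: np.ndarray       # (K,)
    f_k: np.ndarray                # (K,) free-energy offsets, f_0 = 0
    energies: np.ndarray           # (N,) pooled samples, kcal/mol
    sample_counts: np.ndarray      # (K,)
    iterations: int
    max_delta: float

    @property
    def betas(self) -> np.ndarray:
        return 1.0 / (KB * self.temperatures)

    def log_weights(self, temperature: float) -> np.ndarray:
        """Normalized per-sample log-weights at the query temperature."""
        t_lo, t_hi = self.temperatures.min(), self.temperatures.max()
        if not (t_lo <= temperature <= t_hi) and len(self.temperatures) > 1:
            raise ValueError(
                f"query temperature {temperature} K outside sampled range "
                f"[{t_lo}, {t_hi}] K"
            )
        beta = 1.0 / (KB * temperature)
        log_denom = logsumexp(
            np.log(self.sample_counts)[:, None] + self.f_k[:, None]
            - self.betas[:, None] * self.energies[None, :],
            axis=0,
        )
        lw = -beta * self.energies - log_denom
        return lw - logsumexp(lw)

    def weights(self, temperature: float) -> np.ndarray:
        return np.exp(self.log_weights(temperature))

    def expectation(self, observable: np.ndarray, temperature: float) -> float:
        """Reweighted expectation of a per-sample observable."""
        observable = np.asarray(observable, dtype=float)
        if observable.shape != self.energies.shape:
            raise ValueError("observable must be per-sample (pooled order)")
        return float(np.sum(self.weights(temperature) * observable))


def wham(energy_series, temperatures, tol: float = 1e-10,
         max_iter: int = 100000) -> WhamResult:
    """Self-consistent binless WHAM over per-temperature energy samples.

    ``energy_series[k]`` holds potential-energy samples (kcal/mol) collected
    at ``temperatures[k]``.  Iterates the free-energy offsets f_k until
    max |df_k| < tol; raises :class:`WhamConvergenceError` otherwise.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if len(energy_series) != len(temperatures) or len(temperatures) < 1:
        raise ValueError("need one non-empty energy series per temperature")
    for s in energy_series:
        if len(s) == 0:
            raise ValueError("empty energy series")
    n_k = np.array([len(s) for s in energy_series])
    u = np.concatenate([np.asarray(s, dtype=float) for s in energy_series])
    betas = 1.0 / (KB * temperatures)
    k = len(temperatures)

    f = np.zeros(k)
    if k == 1:
        return WhamResult(temperatures, f, u, n_k, 0, 0.0)

    log_nk = np.log(n_k)
    neg_bu = -betas[:, None] * u[None, :]          # (K, N)
    max_delta = np.inf
    for it in range(max_iter):
        log_denom = logsumexp(log_nk[:, None] + f[:, None] + neg_bu, axis=0)
        f_new = -logsumexp(neg_bu - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        max_delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if max_delta < tol:
            return WhamResult(temperatures, f, u, n_k, it + 1, max_delta)
    raise WhamConvergenceError(max_iter, max_delta, tol)


def heat_capacity(result: WhamResult, t_grid) -> np.ndarray:
    """C_V(T) = (<U^2> - <U>^2) / (k_B T^2), kcal/mol/K."""
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        w = result.weights(t)
        mu = np.sum(w * result.energies)
        var = np.sum(w * (result.energies - mu) ** 2)
        out[i] = var / (KB * t * t)
    return out


@dataclass
class MeltingResult:
    t_m: float                 # P_bound = 1/2 crossing, K
    t_cv_peak: float           # heat-capacity peak, K
    p_bound_at_peak: float


def melting_temperature(result: WhamResult, bound_indicator,
                        t_grid) -> MeltingResult:
    """Locate T_m: the C_V peak refined to where the reweighted bound
    probability crosses 1/2."""
    bound = np.asarray(bound_indicator, dtype=float)
    if bound.shape != result.energies.shape:
        raise ValueError("bound indicator must be per-sample")
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 2:
        raise ValueError("temperature grid too small")
    cv = heat_capacity(result, t_grid)
    t_peak = float(t_grid[np.argmax(cv)])

    def p_bound(t):
        return result.expectation(bound, t)

    p = np.array([p_bound(t) for t in t_grid])
    crossings = np.nonzero(np.diff(np.sign(p - 0.5)) != 0)[0]
    if len(crossings) == 0:
        raise ValueError(
            "bound probability does not cross 1/2 in the grid range: "
            f"P_bound({t_grid[0]:.1f} K) = {p[0]:.4f}, "
            f"P_bound({t_grid[-1]:.1f} K) = {p[-1]:.4f}"
        )
    # crossing nearest the heat-capacity peak
    mids = 0.5 * (t_grid[crossings] + t_grid[crossings + 1])
    c = crossings[np.argmin(np.abs(mids - t_peak))]
    t_m = brentq(lambda t: p_bound(t) - 0.5, t_grid[c], t_grid[c + 1],
                 xtol=1e-4)
    return MeltingResult(float(t_m), t_peak, p_bound(t_peak))


def effective_concentration(box_edge: float) -> float:
    """Concentration (mol/L) of one molecule in a cubic box of the given
    edge (A): C_eff = 1/(N_A V)."""
    if box_edge <= 0:
        raise ValueError("box edge must be positive")
    volume_l = (box_edge ** 3) * 1e-27
    return 1.0 / (sc.N_A * volume_l)


def dissociation_constant(
    result: WhamResult,
    n_inter_series,
    box_edge: float,
    t_query: float = 300.0,
    unbound_rule: str = "no_native",
    bound_threshold: int | None = None,
) -> float:
    """K_D (mol/L) from reweighted bound/unbound probabilities.

    ``unbound_rule="no_native"`` takes P_U = P[N_inter = 0] (barrier-
    separated profiles); ``"complement"`` takes P_U = 1 - P[N_inter >=
    bound_threshold], for barrierless profiles where partially bound
    intermediates should not count as unbound.
    """
    n_inter = np.asarray(n_inter_series, dtype=float)
    if unbound_rule == "no_native":
        p_u = result.expectation((n_inter == 0).astype(float), t_query)
    elif unbound_rule == "complement":
        if bound_threshold is None:
            raise ValueError("complement rule requires bound_threshold")
        p_u = 1.0 - result.expectation(
            (n_inter >= bound_threshold).astype(float), t_query)
    else:
        raise ValueError(f"unknown unbound rule {unbound_rule!r}")
    if p_u <= 1e-12 or p_u >= 1.0 - 1e-12:
        raise ValueError(
            f"unbound probability {p_u} is degenerate at {t_query} K; "
            "K_D unresolvable from this sample"
        )
    return effective_concentration(box_edge) * p_u ** 2 / (1.0 - p_u)


@dataclass
class FreeEnergySurface:
    """Free energy per bin in units of k_B T, anchored at 0 over occupied
    bins; empty bins are masked (NaN in ``free_energy``)."""

    edges_x: np.ndarray
    free_energy: np.ndarray        # 1D (nx,) or 2D (nx, ny)
    mask_empty: np.ndarray
    edges_y: np.ndarray | None = None
    observable_x: str = "obs_x"
    observable_y: str | None = None
    temperature: float = 0.0

    @property
    def centers_x(self):
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self):
        return None if self.edges_y is None else \
            0.5 * (self.edges_y[:-1] + self.edges_y[1:])

    def to_table(self) -> str:
        """Tabular text export (bin centers + F/kT; empty bins 'nan')."""
        lines = []
        if self.edges_y is None:
            lines.append(f"# {self.observable_x}  F_per_kT  (T = {self.temperature} K)")
            for x, fe in zip(self.centers_x, self.free_energy):
                lines.append(f"{x:.6g}\t{fe:.6g}")
        else:
            lines.append(
                f"# {self.observable_x}  {self.observable_y}  F_per_kT  "
                f"(T = {self.temperature} K)"
            )
            cy = self.centers_y
            for i, x in enumerate(self.centers_x):
                for j, y in enumerate(cy):
                    lines.append(f"{x:.6g}\t{y:.6g}\t{self.free_energy[i, j]:.6g}")
        return "\n".join(lines) + "\n"


def free_energy_surface(
    result: WhamResult,
    obs_x,
    t_query: float,
    obs_y=None,
    bins: int | tuple = 30,
    range_x: tuple | None = None,
    range_y: tuple | None = None,
    name_x: str = "obs_x",
    name_y: str | None = None,
) -> FreeEnergySurface:
    """Reweighted 1D or 2D free-energy surface F = -ln P in units of k_B T."""
    obs_x = np.asarray(obs_x, dtype=float)
    if obs_x.shape != result.energies.shape or not np.all(np.isfinite(obs_x)):
        raise ValueError("obs_x must be finite and per-sample")
    w = result.weights(t_query)
    if obs_y is None:
        hist, edges = np.histogram(obs_x, bins=bins, range=range_x, weights=w)
        occupied = hist > 0
        if occupied.sum() <= 1:
            warnings.warn("all samples fall in a single bin")
        fe = np.full(hist.shape, np.nan)
        fe[occupied] = -np.log(hist[occupied])
        fe -= np.nanmin(fe)
        return FreeEnergySurface(edges, fe, ~occupied, None, name_x, None, t_query)
    obs_y = np.asarray(obs_y, dtype=float)
    if obs_y.shape != result.energies.shape or not np.all(np.isfinite(obs_y)):
        raise ValueError("obs_y must be finite and per-sample")
    rng = None
    if range_x is not None or range_y is not None:
        rng = (range_x, range_y)
    hist, ex, ey = np.histogram2d(obs_x, obs_y, bins=bins, range=rng, weights=w)
    occupied = hist > 0
    if occupied.sum() <= 1:
        warnings.warn("all samples fall in a single bin")
    fe = np.full(hist.shape, np.nan)
    fe[occupied] = -np.log(hist[occupied])
    fe -= np.nanmin(fe)
    return FreeEnergySurface(ex, fe, ~occupied, ey, name_x, name_y, t_query)
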