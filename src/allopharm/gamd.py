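"""Desk-scale Gaussian-accelerated dynamics on analytic toy potentials.

Gaussian accelerated molecular dynamics (GaMD) enhances sampling by adding a
harmonic boost below a threshold energy E:

    dV(r) = 1/2 k (E - V(r))^2   for V(r) < E,   0 otherwise.

The two parameters are set automatically from potential statistics
(Vmin, Vmax, Vavg, sigma_V) under three principles: the boost preserves the
order of potential values, reduces energy gaps, and keeps the boost SD below
a user limit sigma0 so that second-order cumulant reweighting is accurate.
With k = k0 / (Vmax - Vmin):

    lower bound:  E = Vmax,       k0 = min(1, (sigma0/sigma_V) *
                                             (Vmax - Vmin)/(Vmax - Vavg))
    upper bound:  E = Vmin + 1/k, k0'' = (1 - sigma0/sigma_V) *
                                             (Vmax - Vmin)/(Vavg - Vmin)

the upper-bound k0'' being accepted only when 0 < k0'' <= 1 (fallback to the
lower-bound formula otherwise). The invariant Vmax <= E <= Vmin + 1/k holds
on every valid output.

The dynamics engine is a BAOAB Langevin integrator in reduced units (unit
mass, energies in kcal/mol, configurable time step); only the boost and
reweighting mathematics are claimed faithful to production GaMD codes, not
the molecular force field or thermostat details. Reweighting to a potential
of mean force (PMF) uses per-bin ensemble-averaged Boltzmann factors of the
boost, approximated either exactly (exponential average) or by cumulant
expansion to second order, the latter being the reliable default because
per-bin boost distributions are near-Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import (
    ConfigurationError,
    DomainError,
    EmptyResultError,
    ShapeError,
)

__all__ = [
    "KB_KCAL",
    "PotentialSurface",
    "GamdSettings",
    "BoostParameters",
    "BoostedTrajectory",
    "PmfEstimate",
    "RunningStats",
    "estimate_potential_statistics",
    "compute_boost",
    "delta_v",
    "run_cmd",
    "run_gamd",
    "reweight_pmf",
    "boost_gaussianity",
]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/mol/K


@dataclass
class PotentialSurface:
    """An analytic potential-energy surface (1D or 2D).

    ``energy``/``gradient`` take a coordinate array of shape (dim,). An
    optional two-term additive decomposition ``terms`` (list of
    (energy, gradient) pairs) enables dual-boost: the first term plays the
    role of the fast (dihedral-like) energy term.
    """

    dimensionality: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    terms: list | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2):
            raise ConfigurationError("dimensionality must be 1 or 2")


@dataclass
class GamdSettings:
    """Integrator and boost settings (reduced units; energies kcal/mol)."""

    sigma0: float = 6.0
    bound_mode: str = "lower"
    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 1e-3
    mass: float = 1.0
    n_equil_cmd: int = 20_000
    n_equil_boost: int = 50_000
    n_prod: int = 200_000
    update_interval: int = 10_000
    stride: int = 1
    seed: int = 0
    dual_boost: bool = False
    k0_override: float | None = None
    x0: tuple = (0.0,)

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ConfigurationError("sigma0 must be > 0")
        if not self.n_prod > 0:
            raise ConfigurationError("n_prod must be > 0")
        if not self.dt > 0:
            raise ConfigurationError("dt must be > 0")
        if self.bound_mode not in ("lower", "upper"):
            raise ConfigurationError("bound_mode must be 'lower' or 'upper'")


@dataclass
class BoostParameters:
    """GaMD boost parameters plus the potential statistics they came from."""

    E: float
    k: float
    k0: float
    vmin: float
    vmax: float
    vavg: float
    sigma_v: float
    bound_mode: str = "lower"
    disabled: bool = False

    def __post_init__(self) -> None:
        if self.disabled:
            return
        if not (0.0 < self.k0 <= 1.0):
            raise DomainError(f"k0 must be in (0, 1], got {self.k0}")
        if self.k <= 0:
            raise DomainError("k must be > 0")
        if not (self.vmax <= self.E + 1e-9 and
                self.E <= self.vmin + 1.0 / self.k + 1e-9):
            raise DomainError(
                f"invariant Vmax <= E <= Vmin + 1/k violated: "
                f"{self.vmax} <= {self.E} <= {self.vmin + 1.0 / self.k}")


@dataclass
class BoostedTrajectory:
    """Recorded frames of a (possibly boosted) Langevin run."""

    coords: np.ndarray          # (frames, dim)
    potential: np.ndarray       # V per frame, kcal/mol (unboosted)
    boost: np.ndarray           # total dV per frame, >= 0
    frame_times: np.ndarray
    boost_terms: np.ndarray | None = None   # per boosted term, (frames, n_terms)

    def __post_init__(self) -> None:
        n = self.coords.shape[0]
        if not (self.potential.size == n and self.boost.size == n
                and self.frame_times.size == n):
            raise ShapeError("trajectory arrays must have equal length")
        if np.any(self.boost < -1e-12):
            raise DomainError("boost must be >= 0 everywhere")


@dataclass
class PmfEstimate:
    """Binned, reweighted free-energy profile along a reaction coordinate."""

    bin_edges: np.ndarray
    counts: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    probability: np.ndarray     # reweighted p(A_j) over retained bins
    pmf: np.ndarray             # F(A_j), min = 0 over retained bins
    retained: np.ndarray        # boolean mask of retained bins
    method: str = "cumulant2"
    flags: list = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "count": self.counts,
            "c1": self.c1,
            "c2": self.c2,
            "pmf": self.pmf,
            "retained": self.retained,
        })

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.bin_centers[self.retained]
        ax.plot(c, self.pmf[self.retained], "o-")
        ax.set_xlabel("reaction coordinate")
        ax.set_ylabel("PMF (kcal/mol)")
        return ax


# ---------------------------------------------------------------------------
# potential statistics and boost parameterization


class RunningStats:
    """Streaming min/max/mean/SD (Welford); matches the batch estimator."""

    def __init__(self) -> None:
        self.n = 0
        self.vmin = math.inf
        self.vmax = -math.inf
        self._mean = 0.0
        self._m2 = 0.0

    def push(self, v: float) -> None:
        self.n += 1
        if v < self.vmin:
            self.vmin = v
        if v > self.vmax:
            self.vmax = v
        d = v - self._mean
        self._mean += d / self.n
        self._m2 += d * (v - self._mean)

    def result(self) -> tuple[float, float, float, float]:
        if self.n < 2:
            raise DomainError("need >= 2 potential samples")
        sd = math.sqrt(self._m2 / (self.n - 1))
        return (self.vmin, self.vmax, self._mean, sd)


def estimate_potential_statistics(v_samples) -> tuple[float, float, float, float]:
    """(Vmin, Vmax, Vavg, sigma_V) of a potential-energy series.

    The SD is the sample standard deviation (ddof=1), identical to the
    streaming :class:`RunningStats` estimator.
    """
    arr = np.asarray(list(np.atleast_1d(v_samples)), dtype=float)
    if arr.size < 2:
        raise DomainError("need >= 2 potential samples")
    return (float(arr.min()), float(arr.max()), float(arr.mean()),
            float(arr.std(ddof=1)))


def compute_boost(stats, sigma0: float, bound_mode: str = "lower"
                  ) -> BoostParameters:
    """Boost parameters (E, k, k0) from potential statistics.

    ``stats`` is (vmin, vmax, vavg, sigma_v). In lower-bound mode E = Vmax;
    in upper-bound mode E = Vmin + 1/k with k0'' accepted iff 0 < k0'' <= 1,
    else the lower-bound formula is used. Degenerate statistics
    (vmax == vmin) disable the boost (k0 = 0, flagged); sigma_v = 0 gives
    k0 = 1 in lower mode.
    """
    vmin, vmax, vavg, sigma_v = (float(x) for x in stats)
    if sigma0 <= 0:
        raise DomainError("sigma0 must be > 0")
    if sigma_v < 0:
        raise DomainError("sigma_v must be >= 0")
    if vmax <= vmin:
        return BoostParameters(E=vmax, k=0.0, k0=0.0, vmin=vmin, vmax=vmax,
                               vavg=vavg, sigma_v=sigma_v,
                               bound_mode=bound_mode, disabled=True)
    spread = vmax - vmin
    if bound_mode == "upper" and sigma_v > 0 and vavg > vmin:
        k0pp = (1.0 - sigma0 / sigma_v) * spread / (vavg - vmin)
        if 0.0 < k0pp <= 1.0:
            k = k0pp / spread
            return BoostParameters(E=vmin + 1.0 / k, k=k, k0=k0pp,
                                   vmin=vmin, vmax=vmax, vavg=vavg,
                                   sigma_v=sigma_v, bound_mode="upper")
    # lower bound (also the fallback for an unacceptable k0'')
    if sigma_v == 0 or vmax == vavg:
        k0 = 1.0
    else:
        k0 = min(1.0, (sigma0 / sigma_v) * spread / (vmax - vavg))
    k = k0 / spread
    return BoostParameters(E=vmax, k=k, k0=k0, vmin=vmin, vmax=vmax,
                           vavg=vavg, sigma_v=sigma_v, bound_mode="lower")


def delta_v(v, boost: BoostParameters):
    """Harmonic boost 1/2 k (E - V)^2 for V < E, zero above the threshold."""
    if boost.disabled or boost.k == 0.0:
        out = np.zeros_like(np.asarray(v, dtype=float))
        return out if out.ndim else 0.0
    v_arr = np.asarray(v, dtype=float)
    gap = boost.E - v_arr
    out = np.where(gap > 0, 0.5 * boost.k * gap ** 2, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Langevin engine


def _term_eval(surface: PotentialSurface, dual: bool):
    if dual:
        if not surface.terms or len(surface.terms) != 2:
            raise ConfigurationError(
                "dual_boost requires a surface with a two-term decomposition")
        e1, g1 = surface.terms[0]
        return e1, g1
    return None, None


class _Integrator:
    """BAOAB Langevin integrator with optional GaMD boost forces."""

    def __init__(self, surface: PotentialSurface, settings: GamdSettings):
        self.surface = surface
        self.s = settings
        self.rng = np.random.default_rng(settings.seed)
        dim = surface.dimensionality
        x0 = np.asarray(settings.x0, dtype=float)
        if x0.size != dim:
            x0 = np.resize(x0, dim)
        self.x = x0.copy()
        kbt = KB_KCAL * settings.temperature
        self.v = (math.sqrt(kbt / settings.mass)
                  * self.rng.standard_normal(dim)) if kbt > 0 else np.zeros(dim)
        self.c1 = math.exp(-settings.friction * settings.dt)
        self.c2 = math.sqrt(kbt / settings.mass * (1.0 - self.c1 ** 2))
        self.e1, self.g1 = _term_eval(surface, settings.dual_boost)
        self._f_cache = None  # force at self.x for the active boost params
        self._boost_key = None

    def force(self, boost_total: BoostParameters | None,
              boost_term: BoostParameters | None) -> np.ndarray:
        g = np.asarray(self.surface.gradient(self.x), dtype=float)
        if boost_total is not None and not boost_total.disabled:
            vtot = float(self.surface.energy(self.x))
            gap = boost_total.E - vtot
            if gap > 0:
                g = g * (1.0 - boost_total.k * gap)
        if boost_term is not None and not boost_term.disabled:
            v1 = float(self.e1(self.x))
            gap1 = boost_term.E - v1
            if gap1 > 0:
                g = g - boost_term.k * gap1 * np.asarray(self.g1(self.x),
                                                         dtype=float)
        return -g

    def step(self, boost_total=None, boost_term=None) -> None:
        s = self.s
        key = (id(boost_total), id(boost_term))
        if self._f_cache is None or self._boost_key != key:
            self._f_cache = self.force(boost_total, boost_term)
            self._boost_key = key
        self.v = self.v + 0.5 * s.dt * self._f_cache / s.mass
        self.x = self.x + 0.5 * s.dt * self.v
        self.v = (self.c1 * self.v
                  + self.c2 * self.rng.standard_normal(self.x.size))
        self.x = self.x + 0.5 * s.dt * self.v
        self._f_cache = self.force(boost_total, boost_term)
        self.v = self.v + 0.5 * s.dt * self._f_cache / s.mass

    def potential(self) -> float:
        return float(self.surface.energy(self.x))


def _check_energy(v: float) -> None:
    if not math.isfinite(v) or abs(v) > 1e3:
        raise FloatingPointError(
            f"potential energy diverged to {v}; the time step is too large "
            "for this surface")


def _run(surface: PotentialSurface, settings: GamdSettings, boosted: bool):
    integ = _Integrator(surface, settings)
    s = settings
    dual = s.dual_boost and boosted
    stats_tot = RunningStats()
    stats_term = RunningStats() if dual else None

    # stage 1: conventional MD, collect potential statistics
    for _ in range(s.n_equil_cmd):
        integ.step()
        v = integ.potential()
        _check_energy(v)
        stats_tot.push(v)
        if dual:
            stats_term.push(float(integ.e1(integ.x)))

    def make_boosts():
        if not boosted:
            return None, None
        bt = compute_boost(stats_tot.result(), s.sigma0, s.bound_mode)
        b1 = (compute_boost(stats_term.result(), s.sigma0, s.bound_mode)
              if dual else None)
        if s.k0_override is not None:
            for b in (bt, b1):
                if b is None:
                    continue
                b.k0 = s.k0_override
                b.k = (s.k0_override / (b.vmax - b.vmin)
                       if b.vmax > b.vmin else 0.0)
                b.disabled = b.disabled or s.k0_override == 0.0
        return bt, b1

    # stage 2: boost equilibration with periodic parameter updates
    boost_tot, boost_term = make_boosts()
    for i in range(s.n_equil_boost):
        integ.step(boost_tot, boost_term)
        v = integ.potential()
        _check_energy(v)
        stats_tot.push(v)
        if dual:
            stats_term.push(float(integ.e1(integ.x)))
        if boosted and (i + 1) % s.update_interval == 0:
            boost_tot, boost_term = make_boosts()

    # stage 3: production with frozen boost parameters
    n_frames = s.n_prod // s.stride
    dim = surface.dimensionality
    coords = np.empty((n_frames, dim))
    pot = np.empty(n_frames)
    dv_tot = np.empty(n_frames)
    dv_terms = np.empty((n_frames, 2)) if dual else None
    j = 0
    for i in range(s.n_prod):
        integ.step(boost_tot, boost_term)
        if (i + 1) % s.stride == 0:
            v = integ.potential()
            _check_energy(v)
            coords[j] = integ.x
            pot[j] = v
            d_t = delta_v(v, boost_tot) if boost_tot is not None else 0.0
            d_1 = 0.0
            if dual and boost_term is not None:
                d_1 = delta_v(float(integ.e1(integ.x)), boost_term)
            dv_tot[j] = d_t + d_1
            if dual:
                dv_terms[j] = (d_1, d_t)
            j += 1
    times = s.dt * s.stride * (1 + np.arange(n_frames))
    traj = BoostedTrajectory(coords=coords, potential=pot, boost=dv_tot,
                             frame_times=times, boost_terms=dv_terms)
    return boost_tot, traj


def run_cmd(surface: PotentialSurface, settings: GamdSettings
            ) -> BoostedTrajectory:
    """Conventional (unboosted) Langevin run with the same staging as
    :func:`run_gamd`, recording production frames (boost identically 0)."""
    _, traj = _run(surface, settings, boosted=False)
    return traj


def run_gamd(surface: PotentialSurface, settings: GamdSettings
             ) -> tuple[BoostParameters, BoostedTrajectory]:
    """Three-stage GaMD run: statistics collection, boosted equilibration
    with periodic parameter updates, and production with frozen boost."""
    if settings.n_equil_cmd <= 0:
        raise ConfigurationError("n_equil_cmd must be > 0")
    boost, traj = _run(surface, settings, boosted=True)
    return boost, traj


# ---------------------------------------------------------------------------
# reweighting


def reweight_pmf(cv_series, dv_series, temperature: float, bin_size: float,
                 cutoff_frames: int = 500, method: str = "cumulant2"
                 ) -> PmfEstimate:
    """Reweight a boosted run to a PMF along a 1D reaction coordinate.

    Frames are histogrammed with ``bin_size``; bins with fewer than
    ``cutoff_frames`` frames are discarded. Per retained bin j the
    ensemble-averaged Boltzmann factor of the boost is

        cumulant2:    exp(beta*C1 + beta^2*C2/2),  C1 = mean(dV),
                                                   C2 = var(dV)  (in-bin)
        exponential:  mean(exp(beta*dV))           (log-sum-exp evaluated)
        none:         1

    and p(A_j) is the boosted histogram weight times that factor, normalized
    over retained bins. F(A_j) = -kB*T ln p(A_j), shifted so min F = 0.
    """
    cv = np.asarray(cv_series, dtype=float).ravel()
    dv = np.asarray(dv_series, dtype=float).ravel()
    if cv.size != dv.size:
        raise ShapeError("cv_series and dv_series must have equal length")
    if method not in ("cumulant2", "exponential", "none"):
        raise ConfigurationError(f"unknown reweighting method {method!r}")
    if bin_size <= 0:
        raise DomainError("bin_size must be > 0")
    beta = 1.0 / (KB_KCAL * temperature)

    lo = math.floor(cv.min() / bin_size) * bin_size
    n_bins = max(1, int(math.ceil((cv.max() - lo) / bin_size)))
    edges = lo + bin_size * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(cv, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    retained = counts >= max(1, int(cutoff_frames))
    if not np.any(retained):
        raise EmptyResultError("no bin passes the frame-count cutoff")

    c1 = np.zeros(n_bins)
    c2 = np.zeros(n_bins)
    log_w = np.zeros(n_bins)
    flags: list[str] = []
    for j in np.nonzero(retained)[0]:
        d = dv[idx == j]
        c1[j] = d.mean()
        c2[j] = d.var()  # population variance, as in cumulant reweighting
        if method == "cumulant2":
            log_w[j] = beta * c1[j] + 0.5 * beta ** 2 * c2[j]
        elif method == "exponential":
            m = beta * d
            log_w[j] = float(np.logaddexp.reduce(m) - math.log(d.size))
            if not math.isfinite(log_w[j]):
                flags.append(
                    f"bin {j}: non-finite exponential weight; consider "
                    "method='cumulant2'")
        else:
            log_w[j] = 0.0

    log_p = np.full(n_bins, -math.inf)
    ret = np.nonzero(retained)[0]
    log_p[ret] = np.log(counts[ret]) + log_w[ret]
    log_p[ret] -= np.logaddexp.reduce(log_p[ret])
    prob = np.where(retained, np.exp(log_p), 0.0)
    pmf = np.full(n_bins, math.nan)
    pmf[ret] = -KB_KCAL * temperature * log_p[ret]
    pmf[ret] -= pmf[ret].min()
    return PmfEstimate(bin_edges=edges, counts=counts, c1=c1, c2=c2,
                       probability=prob, pmf=pmf, retained=retained,
                       method=method, flags=flags)


def boost_gaussianity(dv_by_bin: Sequence) -> pd.DataFrame:
    """Per-bin skewness and excess kurtosis of the boost distribution.

    A bin is flagged (|skew| > 0.5) when second-order cumulant reweighting
    is likely unreliable. Constant (zero-variance) boost is handled without
    division errors.
    """
    rows = []
    for j, d in enumerate(dv_by_bin):
        d = np.asarray(d, dtype=float).ravel()
        if d.size == 0:
            continue
        if d.size < 2 or np.allclose(d, d[0]):
            skew = 0.0
            kurt = 0.0
        else:
            skew = float(sp_stats.skew(d))
            kurt = float(sp_stats.kurtosis(d))
        rows.append({"bin": j, "n": int(d.size), "skewness": skew,
                     "excess_kurtosis": kurt, "flagged": abs(skew) > 0.5})
    return pd.DataFrame(rows).set_index("bin")
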