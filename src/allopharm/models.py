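"""Closed-form pharmacological models for orthosteric/allosteric ligand action.

The functions here describe equilibrium radioligand binding and functional
responses at a G protein-coupled receptor that carries both an orthosteric
site (agonist) and an allosteric site (modulator):

* ``saturation_total_binding`` -- hyperbolic radioligand saturation with a
  linear nonspecific component, used to estimate receptor expression (Bmax)
  and radioligand affinity (pK_D).
* ``atcm_fractional_occupancy`` -- the allosteric ternary complex model
  (ATCM): fraction of receptor occupied by a fixed radioligand concentration
  in the presence of a competing agonist and an allosteric modulator with
  binding cooperativity alpha (agonist-modulator) and alpha'
  (radioligand-modulator).
* ``operational_agonism_response`` -- the Black-Leff operational model of
  agonism with transducer slope n and operational efficacy tau.
* ``operational_allosterism_response`` -- the operational model of
  allosterism and agonism (Leach-Sexton-Christopoulos form) combining
  orthosteric efficacy tau_A, allosteric efficacy tau_B, binding
  cooperativity alpha and functional cooperativity alpha*beta.

All affinities and cooperativities are carried in log10 space (pK / log
alpha / log tau), matching how they are reported and keeping optimization
well-scaled. Concentrations are molar and zero is handled exactly: no log
transform is applied to concentrations inside the model functions. All
functions are pure and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ParameterError, ShapeError

__all__ = [
    "BindingModelParams",
    "FunctionalModelParams",
    "ConcentrationGrid",
    "saturation_total_binding",
    "atcm_fractional_occupancy",
    "operational_agonism_response",
    "operational_allosterism_response",
    "bret_ratio_auc",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the equilibrium binding models.

    Attributes
    ----------
    pKd_radioligand : float
        -log10 M equilibrium dissociation constant of the radioligand (K_A*).
    pKi_agonist : float
        -log10 M affinity of the orthosteric agonist for the free receptor.
    pKb_modulator : float
        -log10 M affinity of the allosteric modulator for the free receptor.
    log_alpha : float
        log10 binding cooperativity between agonist and modulator. Positive
        values mean the modulator increases agonist affinity.
    log_alpha_prime : float
        log10 cooperativity between the radioligand and the modulator
        (0 for a modulator that is neutral with respect to the radioligand).
    bmax : float
        Maximal specific binding (sites/cell or counts); > 0.
    ns_slope : float
        Nonspecific binding per unit radioligand concentration; >= 0.
    """

    pKd_radioligand: float
    pKi_agonist: float = 5.0
    pKb_modulator: float = 5.0
    log_alpha: float = 0.0
    log_alpha_prime: float = 0.0
    bmax: float = 1.0
    ns_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pKd_radioligand", "pKi_agonist", "pKb_modulator",
                     "log_alpha", "log_alpha_prime"):
            _require_finite(name, getattr(self, name))
        if not self.bmax > 0:
            raise ParameterError(f"bmax must be > 0, got {self.bmax!r}")
        if self.ns_slope < 0:
            raise ParameterError(f"ns_slope must be >= 0, got {self.ns_slope!r}")


@dataclass(frozen=True)
class FunctionalModelParams:
    """Parameters of the operational models of agonism and allosterism.

    ``log_tau_A`` / ``log_tau_B`` may be ``-inf`` to encode a ligand with no
    intrinsic efficacy (tau = 0); all pK fields must be finite. ``em`` is the
    system maximal response (100 after normalization to the maximal agonist
    response), ``n_slope`` the transducer slope, ``basal`` the response at
    zero ligand.
    """

    pKa_agonist: float
    pKb_modulator: float = 5.0
    log_tau_A: float = 0.0
    log_tau_B: float = -math.inf
    log_alphabeta: float = 0.0
    log_alpha: float = 0.0
    em: float = 100.0
    n_slope: float = 1.0
    basal: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("pKa_agonist", self.pKa_agonist)
        _require_finite("pKb_modulator", self.pKb_modulator)
        for name in ("log_tau_A", "log_tau_B", "log_alphabeta", "log_alpha"):
            v = getattr(self, name)
            if math.isnan(v) or v == math.inf:
                raise ParameterError(f"{name} must be finite or -inf, got {v!r}")
        if not self.em > 0:
            raise ParameterError(f"em must be > 0, got {self.em!r}")
        if not self.n_slope > 0:
            raise ParameterError(f"n_slope must be > 0, got {self.n_slope!r}")
        if self.basal < 0 or self.basal >= self.em:
            raise ParameterError(
                f"basal must satisfy 0 <= basal < em, got {self.basal!r}")


@dataclass(frozen=True)
class ConcentrationGrid:
    """Concentration design of one experiment (molar units; 0 = vehicle)."""

    agonist_concs: tuple = field(default_factory=tuple)
    modulator_concs: tuple = field(default_factory=tuple)
    radioligand_conc: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "agonist_concs", tuple(self.agonist_concs))
        object.__setattr__(self, "modulator_concs", tuple(self.modulator_concs))
        if any(c < 0 for c in self.agonist_concs + self.modulator_concs):
            raise DomainError("concentrations must be >= 0")
        if self.radioligand_conc is not None and self.radioligand_conc < 0:
            raise DomainError("radioligand_conc must be >= 0")
        if not any(c > 0 for c in self.agonist_concs):
            raise DomainError("need at least one nonzero agonist concentration")


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be >= 0")
    return arr


def saturation_total_binding(L, params: BindingModelParams):
    """Total binding (specific + nonspecific) at radioligand concentration L.

    total = bmax * L / (L + K_D) + ns_slope * L, with K_D = 10**-pKd.
    """
    L = _check_nonneg("L", L)
    kd = 10.0 ** (-params.pKd_radioligand)
    out = params.bmax * L / (L + kd) + params.ns_slope * L
    return out if out.ndim else float(out)


def atcm_fractional_occupancy(Lstar, I, B, params: BindingModelParams):
    """Fraction of receptor occupied by the radioligand under the ATCM.

    occ = L* / ( L* + K_A* * (1 + I/K_I + B/K_B + alpha*I*B/(K_I*K_B))
                               / (1 + alpha'*B/K_B) )

    with alpha = 10**log_alpha and alpha' = 10**log_alpha_prime. Monotone
    decreasing in the agonist concentration I; a neutral modulator
    (alpha = alpha' = 1) is invisible.
    """
    Lstar = _check_nonneg("Lstar", Lstar)
    I = _check_nonneg("I", I)
    B = _check_nonneg("B", B)
    ka = 10.0 ** (-params.pKd_radioligand)
    ki = 10.0 ** (-params.pKi_agonist)
    kb = 10.0 ** (-params.pKb_modulator)
    alpha = 10.0 ** params.log_alpha
    alpha_p = 10.0 ** params.log_alpha_prime
    numer = 1.0 + I / ki + B / kb + alpha * I * B / (ki * kb)
    denom = 1.0 + alpha_p * B / kb
    with np.errstate(invalid="ignore"):
        occ = Lstar / (Lstar + ka * numer / denom)
    occ = np.where((Lstar == 0) & ~np.isfinite(occ), 0.0, occ)
    out = np.asarray(occ, dtype=float)
    return out if out.ndim else float(out)


def operational_agonism_response(A, params: FunctionalModelParams):
    """Black-Leff operational model response to agonist concentration A.

    E = basal + (Em - basal) * tau^n A^n / ((A + K_A)^n + tau^n A^n)
    """
    A = _check_nonneg("A", A)
    ka = 10.0 ** (-params.pKa_agonist)
    tau = 10.0 ** params.log_tau_A
    n = params.n_slope
    act = (tau * A) ** n
    out = params.basal + (params.em - params.basal) * act / ((A + ka) ** n + act)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def operational_allosterism_response(A, B, params: FunctionalModelParams):
    """Operational model of allosterism and agonism.

    E = basal + (Em - basal) * N^n / (D^n + N^n) with

        N = tau_A * A * (K_B + alphabeta * B) + tau_B * B * K_A
        D = A*K_B + K_A*K_B + K_A*B + alpha*A*B

    Reduces exactly to ``operational_agonism_response`` at B = 0 and to the
    modulator-alone agonism curve at A = 0.
    """
    A = _check_nonneg("A", A)
    B = _check_nonneg("B", B)
    ka = 10.0 ** (-params.pKa_agonist)
    kb = 10.0 ** (-params.pKb_modulator)
    tau_a = 10.0 ** params.log_tau_A
    tau_b = 10.0 ** params.log_tau_B
    ab = 10.0 ** params.log_alphabeta
    alpha = 10.0 ** params.log_alpha
    n = params.n_slope
    N = tau_a * A * (kb + ab * B) + tau_b * B * ka
    D = A * kb + ka * kb + ka * B + alpha * A * B
    # Scale by D to keep the power terms O(1) for molar concentrations.
    r = N / D
    with np.errstate(over="ignore"):
        act = r ** n
        frac = np.where(np.isinf(act), 1.0, act / (1.0 + act))
    out = params.basal + (params.em - params.basal) * frac
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def bret_ratio_auc(
    times,
    sample,
    vehicle,
    baseline_window: tuple,
    post_window: tuple | None = None,
):
    """Baseline- and vehicle-corrected AUC of a BRET emission-ratio trace.

    The raw readout is a pair of emissions per time point (donor, acceptor);
    the BRET signal is acceptor/donor. Each trace is divided by its own mean
    ratio over ``baseline_window`` (the pre-addition reads), the identically
    processed vehicle trace is subtracted, and the difference is integrated
    by the trapezoid rule over ``post_window`` (default: all times after the
    baseline window ends).

    Parameters
    ----------
    times : array (n,)
        Time points, shared between sample and vehicle.
    sample, vehicle : array (n, 2)
        Columns (donor, acceptor) emission.
    baseline_window : (t0, t1)
        Inclusive time range used for the per-trace baseline ratio.
    post_window : (t0, t1), optional
        Integration range; defaults to times > baseline end.

    Returns
    -------
    float
        Area under the corrected ratio curve (ratio * time units).
    """
    times = np.asarray(times, dtype=float)
    sample = np.asarray(sample, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ShapeError("need at least 2 time points")
    if sample.shape != (times.size, 2) or vehicle.shape != (times.size, 2):
        raise ShapeError(
            "sample and vehicle must be (n_times, 2) arrays of (donor, acceptor)")
    if np.any(sample[:, 0] == 0) or np.any(vehicle[:, 0] == 0):
        raise ArithmeticError("zero donor emission")

    def corrected_ratio(trace: np.ndarray) -> np.ndarray:
        ratio = trace[:, 1] / trace[:, 0]
        in_base = (times >= baseline_window[0]) & (times <= baseline_window[1])
        if not np.any(in_base):
            raise ShapeError("baseline window contains no time points")
        return ratio / ratio[in_base].mean()

    diff = corrected_ratio(sample) - corrected_ratio(vehicle)
    if post_window is None:
        mask = times > baseline_window[1]
    else:
        mask = (times >= post_window[0]) & (times <= post_window[1])
    if mask.sum() < 2:
        raise ShapeError("integration window contains fewer than 2 points")
    return float(np.trapezoid(diff[mask], times[mask]))
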