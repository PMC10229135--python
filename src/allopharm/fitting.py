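"""Global nonlinear least-squares estimation of pharmacological parameters.

The module follows a Model/Results layout: a model object is built from a
list of :class:`AssayDataset` (one per independent experiment and agonist),
``fit()`` performs a bounded, multi-start least-squares optimization (via
lmfit) and returns a :class:`FitResult` carrying point estimates,
uncertainties, the sharing structure, convergence diagnostics and derived
parameters. The default pipeline fits each replicate experiment separately
and summarizes parameters as mean +/- SEM over experiments, mirroring how
interaction-binding and functional data are usually reported; a pooled
global fit (asymptotic SEs from the Jacobian) is also available.

Sharing is expressed through parameter names: dataset-specific parameters
are suffixed with the dataset label (e.g. ``pKi_agonist__ACh``) while shared
parameters (e.g. ``pKb_modulator``) appear once and constrain every dataset
in the fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .exceptions import DomainError, ShapeError
from .models import (
    BindingModelParams,
    FunctionalModelParams,
    atcm_fractional_occupancy,
    operational_allosterism_response,
    saturation_total_binding,
)

__all__ = [
    "ParameterSpec",
    "AssayDataset",
    "FitResult",
    "SaturationBindingModel",
    "TernaryComplexBindingModel",
    "OperationalAllosterismModel",
    "fit_saturation",
    "fit_atcm_global",
    "fit_operational_allosterism_global",
    "correct_efficacy_for_expression",
    "propagate_sem",
    "derived_parameters",
    "summarize_replicates",
    "format_estimate",
    "read_assay_csv",
    "write_assay_csv",
]

_N_STARTS_DEFAULT = 5
_JITTER_LOG_UNITS = 1.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class ParameterSpec:
    """Specification of one fit parameter.

    Parameters with the same ``share_group`` label across datasets collapse
    into a single free variable; ``fixed`` parameters never move.
    """

    name: str
    initial: float
    lower: float = -math.inf
    upper: float = math.inf
    fixed: bool = False
    share_group: str | None = None

    def __post_init__(self) -> None:
        if not (self.lower <= self.initial <= self.upper):
            raise DomainError(
                f"{self.name}: require lower <= initial <= upper, got "
                f"{self.lower} <= {self.initial} <= {self.upper}")


@dataclass
class AssayDataset:
    """One experiment's concentration grid plus measured values.

    Data are stored long-form: one row per observation. ``label`` names the
    agonist (or curve family) and is used to suffix per-agonist parameters
    in global fits.
    """

    agonist_conc: np.ndarray
    modulator_conc: np.ndarray
    value: np.ndarray
    radioligand_conc: float | None = None
    replicate_id: int = 0
    assay_kind: str = "interaction_binding"
    label: str = ""
    normalization: str = ""

    def __post_init__(self) -> None:
        self.agonist_conc = np.asarray(self.agonist_conc, dtype=float)
        self.modulator_conc = np.asarray(self.modulator_conc, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        n = self.value.size
        if self.agonist_conc.size != n or self.modulator_conc.size != n:
            raise ShapeError("agonist_conc, modulator_conc and value must "
                             "have equal length")
        if not np.all(np.isfinite(self.value)):
            raise DomainError("values must be finite")

    @property
    def n_points(self) -> int:
        return int(self.value.size)


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics from one fit.

    ``estimates``/``sems`` map parameter name to value; ``derived`` maps a
    derived-parameter name to ``(value, sem)`` with the SEM propagated by
    root-sum-of-squares. ``per_replicate`` holds the individual-experiment
    fits when the replicate-wise pipeline was used.
    """

    estimates: dict = field(default_factory=dict)
    sems: dict = field(default_factory=dict)
    residual_ss: float = math.nan
    n_points: int = 0
    converged: bool = False
    message: str = ""
    per_replicate: list | None = None
    derived: dict = field(default_factory=dict)
    n_replicates: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable parameter table."""
        lines = [f"{'parameter':<28}{'estimate':>12}  {'formatted':<22}"]
        for name, value in self.estimates.items():
            sem = self.sems.get(name, math.nan)
            n = self.n_replicates.get(name)
            lines.append(f"{name:<28}{value:>12.4g}  "
                         f"{format_estimate(value, sem, n):<22}")
        for name, (value, sem) in self.derived.items():
            lines.append(f"{name:<28}{value:>12.4g}  "
                         f"{format_estimate(value, sem, None):<22} [derived]")
        lines.append(f"residual SS {self.residual_ss:.6g} on {self.n_points} "
                     f"points; converged={self.converged}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "estimates": self.estimates,
            "sems": self.sems,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
            "converged": self.converged,
            "message": self.message,
            "derived": {k: list(v) for k, v in self.derived.items()},
            "n_replicates": self.n_replicates,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "FitResult":
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        payload["derived"] = {k: tuple(v) for k, v in
                              payload.get("derived", {}).items()}
        return cls(**payload)

    def plot_fit(self, datasets=None, predict=None, ax=None):
        """Overlay data and fitted curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if datasets and predict:
            for ds in datasets:
                x = np.where(ds.agonist_conc > 0, ds.agonist_conc, np.nan)
                ax.semilogx(x, ds.value, "o", alpha=0.5, label=f"{ds.label} data")
                ax.semilogx(x, predict(ds, self.estimates), "-", alpha=0.7)
        ax.set_xlabel("agonist concentration (M)")
        ax.set_ylabel("response")
        return ax


# ---------------------------------------------------------------------------
# small calculus helpers


def propagate_sem(sems: Sequence[float]) -> float:
    """Root-sum-of-squares propagation of independent SEMs."""
    arr = np.asarray(list(sems), dtype=float)
    if np.any(arr < 0):
        raise DomainError("SEMs must be >= 0")
    return float(np.sqrt(np.sum(arr ** 2)))


def correct_efficacy_for_expression(log_tau: float, bmax: float,
                                    bmax_reference: float) -> float:
    """Expression-corrected operational efficacy log tau_C.

    tau is proportional to receptor number in the operational model, so
    log tau_C = log tau - log10(Bmax / Bmax_ref).
    """
    if bmax <= 0 or bmax_reference <= 0:
        raise DomainError("bmax and bmax_reference must be > 0")
    return float(log_tau - math.log10(bmax / bmax_reference))


def summarize_replicates(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Per-parameter mean, SEM = sd/sqrt(n), n and formatted cell."""
    names: list[str] = []
    for f in fits:
        for k in f.estimates:
            if k not in names:
                names.append(k)
    rows = []
    for name in names:
        vals = np.array([f.estimates[name] for f in fits if name in f.estimates])
        n = vals.size
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        rows.append({"parameter": name, "mean": mean, "sem": sem, "n": n,
                     "formatted": format_estimate(mean, sem, n)})
    return pd.DataFrame(rows).set_index("parameter")


def _round2(x: float) -> str:
    # round-half-even to 2 decimals, e.g. 0.125 -> "0.12"
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                rounding=ROUND_HALF_EVEN))


def format_estimate(mean: float, sem: float, n: int | None) -> str:
    """Format 'mean +/- SEM (n)'; SEM of a single replicate is undefined."""
    if mean is None or (isinstance(mean, float) and math.isnan(mean)):
        return "N.D."
    if mean == int(mean) and abs(mean) >= 1000:
        mean_s = f"{int(mean):,}"
    else:
        mean_s = _round2(mean)
    sem_s = "undefined" if (sem is None or math.isnan(sem)) else _round2(sem)
    if n is None:
        return f"{mean_s} ± {sem_s}"
    return f"{mean_s} ± {sem_s} ({n})"


def derived_parameters(fit: FitResult,
                       extra: Mapping[str, tuple] | None = None) -> FitResult:
    """Augment a fit with the standard derived quantities.

    For every ``log_alpha<suffix>`` present (paired with ``pKb_modulator`` /
    ``pKi_agonist``), adds the occupied-state modulator affinity
    ``pKb_occupied<suffix> = pKb + log_alpha``, the occupied-state agonist
    affinity ``pKi_occupied<suffix> = pKi + log_alpha``, and the fold
    cooperativity ``alpha_fold<suffix> = 10**log_alpha``. For every
    ``log_alphabeta<suffix>`` with a matching ``log_alpha<suffix>``, adds
    ``log_beta<suffix> = log_alphabeta - log_alpha``. SEMs of sums and
    differences are propagated by root-sum-of-squares; the fold SEM is
    mapped to the linear scale by the delta method.

    ``extra`` supplies (value, sem) pairs from another fit (e.g. binding
    estimates when augmenting a functional fit); missing primaries are
    silently reported as absent.
    """
    values: dict[str, tuple] = {}
    for name, v in fit.estimates.items():
        values[name] = (v, fit.sems.get(name, math.nan))
    if extra:
        for name, pair in extra.items():
            values.setdefault(name, tuple(pair))

    def get(name):
        return values.get(name)

    derived = dict(fit.derived)
    for name in list(values):
        if name.startswith("log_alphabeta"):
            suffix = name[len("log_alphabeta"):]
            la = get("log_alpha" + suffix) or get("log_alpha")
            if la is not None:
                v, s = values[name]
                derived["log_beta" + suffix] = (
                    v - la[0], propagate_sem([_nan0(s), _nan0(la[1])]))
        elif name.startswith("log_alpha") and not name.startswith(
                ("log_alpha_prime", "log_alphabeta")):
            suffix = name[len("log_alpha"):]
            v, s = values[name]
            derived["alpha_fold" + suffix] = (
                10.0 ** v, 10.0 ** v * math.log(10.0) * _nan0(s))
            pkb = get("pKb_modulator") or get("pKb_modulator" + suffix)
            if pkb is not None:
                derived["pKb_occupied" + suffix] = (
                    pkb[0] + v, propagate_sem([_nan0(s), _nan0(pkb[1])]))
            pki = get("pKi_agonist" + suffix) or get("pKi_agonist")
            if pki is not None:
                derived["pKi_occupied" + suffix] = (
                    pki[0] + v, propagate_sem([_nan0(s), _nan0(pki[1])]))
    fit.derived = derived
    return fit


def _nan0(x: float) -> float:
    return 0.0 if (x is None or math.isnan(x)) else float(x)


# ---------------------------------------------------------------------------
# CSV I/O  (columns: replicate, agonist, agonist_conc_M, modulator_conc_M,
#           radioligand_conc_M, value)


def write_assay_csv(datasets: Sequence[AssayDataset], path) -> None:
    frames = []
    for ds in datasets:
        frames.append(pd.DataFrame({
            "replicate": ds.replicate_id,
            "agonist": ds.label,
            "agonist_conc_M": ds.agonist_conc,
            "modulator_conc_M": ds.modulator_conc,
            "radioligand_conc_M": (math.nan if ds.radioligand_conc is None
                                   else ds.radioligand_conc),
            "value": ds.value,
            "assay_kind": ds.assay_kind,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_assay_csv(path) -> list[AssayDataset]:
    df = pd.read_csv(path)
    required = {"replicate", "agonist_conc_M", "modulator_conc_M", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ShapeError(f"assay CSV missing columns: {sorted(missing)}")
    if "agonist" not in df.columns:
        df["agonist"] = ""
    if "assay_kind" not in df.columns:
        df["assay_kind"] = "interaction_binding"
    out = []
    for (rep, label), grp in df.groupby(["replicate", "agonist"], sort=True):
        rl = grp.get("radioligand_conc_M")
        rl_val = None
        if rl is not None and rl.notna().any():
            rl_val = float(rl.dropna().iloc[0])
        out.append(AssayDataset(
            agonist_conc=grp["agonist_conc_M"].to_numpy(),
            modulator_conc=grp["modulator_conc_M"].to_numpy(),
            value=grp["value"].to_numpy(),
            radioligand_conc=rl_val,
            replicate_id=int(rep),
            assay_kind=str(grp["assay_kind"].iloc[0]),
            label=str(label),
        ))
    return out


# ---------------------------------------------------------------------------
# optimizer core


def _multistart_minimize(params: lmfit.Parameters, residual, n_starts: int,
                         seed: int):
    """Bounded least squares from jittered starts; lowest SS wins, ties
    broken by lowest parameter norm."""
    rng = np.random.default_rng(seed)
    free = [p for p in params.values() if p.vary]
    best = None
    for start in range(max(1, n_starts)):
        trial = params.copy()
        if start > 0:
            for p in free:
                jitter = rng.uniform(-_JITTER_LOG_UNITS, _JITTER_LOG_UNITS)
                tp = trial[p.name]
                tp.value = float(np.clip(p.value + jitter, tp.min, tp.max))
        try:
            import warnings

            with warnings.catch_warnings():
                # zero-residual fits make lmfit's correlation matrix 0/0
                warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(residual, trial, method="least_squares",
                                     ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        ss = float(np.sum(np.asarray(res.residual) ** 2))
        norm = float(np.linalg.norm([res.params[p.name].value for p in free]))
        key = (ss, norm)
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return None
    return best[1]


def _result_from_minimizer(res, n_points: int) -> FitResult:
    if res is None:
        return FitResult(converged=False, message="optimization failed",
                         n_points=n_points)
    estimates = {}
    sems = {}
    for name, p in res.params.items():
        if not p.vary and p.expr is None and name.startswith("_"):
            continue
        estimates[name] = float(p.value)
        sems[name] = float(p.stderr) if (p.vary and p.stderr is not None) \
            else math.nan
    ss = float(np.sum(np.asarray(res.residual) ** 2))
    converged = bool(res.success) and all(
        math.isfinite(v) for v in estimates.values())
    return FitResult(estimates=estimates, sems=sems, residual_ss=ss,
                     n_points=n_points, converged=converged,
                     message=str(res.message))


def _group_by_replicate(datasets: Sequence[AssayDataset]) -> dict:
    groups: dict[int, list[AssayDataset]] = {}
    for ds in datasets:
        groups.setdefault(ds.replicate_id, []).append(ds)
    return groups


def _pool_replicate_fits(fits: list[FitResult]) -> FitResult:
    """Mean +/- SEM over replicate fits, packaged as a FitResult."""
    table = summarize_replicates(fits)
    pooled = FitResult(
        estimates={k: float(table.loc[k, "mean"]) for k in table.index},
        sems={k: float(table.loc[k, "sem"]) for k in table.index},
        residual_ss=float(np.nansum([f.residual_ss for f in fits])),
        n_points=int(sum(f.n_points for f in fits)),
        converged=all(f.converged for f in fits),
        per_replicate=list(fits),
        n_replicates={k: int(table.loc[k, "n"]) for k in table.index},
    )
    return pooled


# ---------------------------------------------------------------------------
# model classes


class _BaseModel:
    """Shared multi-start/replicate plumbing for the pharmacology models."""

    def __init__(self, datasets: Sequence[AssayDataset], *,
                 n_starts: int = _N_STARTS_DEFAULT, seed: int = 0):
        if not datasets:
            raise ShapeError("need at least one dataset")
        self.datasets = list(datasets)
        self.n_starts = n_starts
        self.seed = seed

    def _build_params(self, datasets) -> lmfit.Parameters:  # pragma: no cover
        raise NotImplementedError

    def _residual(self, params, datasets) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _fit_group(self, datasets) -> FitResult:
        params = self._build_params(datasets)
        res = _multistart_minimize(
            params, lambda p: self._residual(p, datasets),
            self.n_starts, self.seed)
        n_points = sum(ds.n_points for ds in datasets)
        return _result_from_minimizer(res, n_points)

    def fit(self, per_replicate: bool = True) -> FitResult:
        """Fit the model.

        With ``per_replicate=True`` (default) each replicate experiment is
        fit separately and parameters summarized as mean +/- SEM over
        experiments; otherwise one pooled global fit is performed with
        asymptotic SEs from the Jacobian.
        """
        if per_replicate:
            groups = _group_by_replicate(self.datasets)
            fits = [self._fit_group(dss) for _, dss in sorted(groups.items())]
            if len(fits) == 1:
                out = fits[0]
                out.per_replicate = fits
                out.n_replicates = {k: 1 for k in out.estimates}
                return out
            return _pool_replicate_fits(fits)
        return self._fit_group(self.datasets)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        """Build from a long-form dataframe with the assay CSV columns."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_assay_csv(buf), **kwargs)


class SaturationBindingModel(_BaseModel):
    """Radioligand saturation binding: estimates Bmax, pK_D and the
    nonspecific slope from total-binding curves."""

    def __init__(self, datasets, *, fit_ns: bool = True, **kwargs):
        super().__init__(datasets, **kwargs)
        self.fit_ns = fit_ns

    def _build_params(self, datasets) -> lmfit.Parameters:
        vmax = max(float(np.max(ds.value)) for ds in datasets)
        p = lmfit.Parameters()
        # log-scale Bmax keeps the problem conditioned across 1e3..1e6 counts
        p.add("log10_bmax", value=math.log10(max(vmax * 1.2, 1e-6)),
              min=-6, max=12)
        p.add("pKd_radioligand", value=9.0, min=4.0, max=14.0)
        p.add("ns_slope", value=0.0, min=0.0, max=1e15, vary=self.fit_ns)
        return p

    def _residual(self, params, datasets) -> np.ndarray:
        bp = BindingModelParams(
            pKd_radioligand=params["pKd_radioligand"].value,
            bmax=10.0 ** params["log10_bmax"].value,
            ns_slope=params["ns_slope"].value)
        res = []
        for ds in datasets:
            pred = saturation_total_binding(ds.agonist_conc, bp)
            res.append(np.asarray(pred) - ds.value)
        return np.concatenate(res)

    def _fit_group(self, datasets) -> FitResult:
        out = super()._fit_group(datasets)
        if "log10_bmax" in out.estimates:
            lb = out.estimates.pop("log10_bmax")
            sb = out.sems.pop("log10_bmax", math.nan)
            out.estimates = {"bmax": 10.0 ** lb, **out.estimates}
            out.sems = {"bmax": 10.0 ** lb * math.log(10) * _nan0(sb) or
                        math.nan, **out.sems}
        vmax = max(float(np.max(np.abs(ds.value))) for ds in datasets)
        if vmax < 1e-9 or out.estimates.get("bmax", 0.0) < 1e-3 * vmax:
            out.message += " [degenerate: bmax ~ 0]"
            out.converged = False
        return out


class TernaryComplexBindingModel(_BaseModel):
    """Global ATCM fit of interaction-binding grids.

    Estimates one agonist affinity (``pKi_agonist__<label>``) and one binding
    cooperativity (``log_alpha__<label>``) per agonist dataset, a modulator
    affinity ``pKb_modulator`` shared across agonists (the default, matching
    the shared global analysis used for interaction binding), and optionally
    the radioligand-modulator cooperativity ``log_alpha_prime`` (fixed at 0
    by default: the radioligand is assumed neutral with the modulator).
    The radioligand affinity ``pKd_radioligand`` must be supplied (it comes
    from saturation binding) and is fixed.
    """

    def __init__(self, datasets, pKd_radioligand: float, *,
                 share_pKb: bool = True, fit_alpha_prime: bool = False,
                 log_alpha_prime: float = 0.0,
                 specs: Sequence[ParameterSpec] | None = None, **kwargs):
        super().__init__(datasets, **kwargs)
        self.pKd_radioligand = float(pKd_radioligand)
        self.share_pKb = share_pKb
        self.fit_alpha_prime = fit_alpha_prime
        self.log_alpha_prime = log_alpha_prime
        self.specs = {s.name: s for s in (specs or [])}
        for ds in self.datasets:
            nz = np.unique(ds.modulator_conc[ds.modulator_conc > 0])
            if nz.size < 3:
                import warnings

                warnings.warn(
                    f"dataset {ds.label!r} replicate {ds.replicate_id}: fewer "
                    "than 3 nonzero modulator levels; cooperativity weakly "
                    "identifiable", stacklevel=2)

    def _labels(self, datasets):
        seen = []
        for ds in datasets:
            if ds.label not in seen:
                seen.append(ds.label)
        return seen

    def _add(self, p, name, **defaults):
        spec = self.specs.get(name)
        if spec is None:
            p.add(name, **defaults)
        elif spec.fixed:
            p.add(name, value=spec.initial, vary=False)
        else:
            p.add(name, value=spec.initial, min=spec.lower, max=spec.upper)

    def _build_params(self, datasets) -> lmfit.Parameters:
        p = lmfit.Parameters()
        labels = self._labels(datasets)
        if self.share_pKb:
            self._add(p, "pKb_modulator", value=6.0, min=2.0, max=12.0)
        for lab in labels:
            self._add(p, f"pKi_agonist__{lab}", value=6.0, min=2.0, max=12.0)
            self._add(p, f"log_alpha__{lab}", value=0.5, min=-4.0, max=5.0)
            if not self.share_pKb:
                self._add(p, f"pKb_modulator__{lab}", value=6.0, min=2.0,
                          max=12.0)
        self._add(p, "log_alpha_prime", value=self.log_alpha_prime,
                  min=-4.0, max=3.0, vary=self.fit_alpha_prime)
        return p

    def _residual(self, params, datasets) -> np.ndarray:
        res = []
        for ds in datasets:
            pkb = (params["pKb_modulator"].value if self.share_pKb
                   else params[f"pKb_modulator__{ds.label}"].value)
            bp = BindingModelParams(
                pKd_radioligand=self.pKd_radioligand,
                pKi_agonist=params[f"pKi_agonist__{ds.label}"].value,
                pKb_modulator=pkb,
                log_alpha=params[f"log_alpha__{ds.label}"].value,
                log_alpha_prime=params["log_alpha_prime"].value)
            pred = atcm_fractional_occupancy(
                ds.radioligand_conc, ds.agonist_conc, ds.modulator_conc, bp)
            res.append(np.asarray(pred) - ds.value)
        return np.concatenate(res)


class OperationalAllosterismModel(_BaseModel):
    """Global operational-model fit of functional interaction data.

    Estimates one orthosteric efficacy ``log_tau_A__<label>`` and one
    functional cooperativity ``log_alphabeta__<label>`` per agonist dataset
    and a single allosteric efficacy ``log_tau_B`` shared across agonist
    datasets (configurable). Affinities (``pKa`` per agonist, ``pKb``) and
    binding cooperativities (``log_alpha`` per agonist) are fixed to values
    determined from equilibrium binding. Em is fixed at 100 (data normalized
    to the maximal agonist response) unless ``fit_em``; basal defaults to 0
    and the transducer slope to 1, each fittable via flags.
    """

    def __init__(self, datasets, fixed_affinities: Mapping[str, float], *,
                 share_tau_B: bool = True, em: float = 100.0,
                 fit_em: bool = False, fit_basal: bool = False,
                 fit_slope: bool = False,
                 specs: Sequence[ParameterSpec] | None = None, **kwargs):
        super().__init__(datasets, **kwargs)
        self.fixed = dict(fixed_affinities)
        self.share_tau_B = share_tau_B
        self.em = em
        self.fit_em = fit_em
        self.fit_basal = fit_basal
        self.fit_slope = fit_slope
        self.specs = {s.name: s for s in (specs or [])}

    def _labels(self, datasets):
        seen = []
        for ds in datasets:
            if ds.label not in seen:
                seen.append(ds.label)
        return seen

    def _fixed(self, key: str, label: str) -> float:
        if f"{key}__{label}" in self.fixed:
            return float(self.fixed[f"{key}__{label}"])
        if key in self.fixed:
            return float(self.fixed[key])
        raise DomainError(f"fixed affinity {key!r} (label {label!r}) missing")

    def _add(self, p, name, **defaults):
        spec = self.specs.get(name)
        if spec is None:
            p.add(name, **defaults)
        elif spec.fixed:
            p.add(name, value=spec.initial, vary=False)
        else:
            p.add(name, value=spec.initial, min=spec.lower, max=spec.upper)

    def _build_params(self, datasets) -> lmfit.Parameters:
        p = lmfit.Parameters()
        labels = self._labels(datasets)
        for lab in labels:
            self._add(p, f"log_tau_A__{lab}", value=0.5, min=-3.0, max=6.0)
            self._add(p, f"log_alphabeta__{lab}", value=0.5, min=-4.0, max=5.0)
            if not self.share_tau_B:
                self._add(p, f"log_tau_B__{lab}", value=0.0, min=-5.0, max=5.0)
        if self.share_tau_B:
            self._add(p, "log_tau_B", value=0.0, min=-5.0, max=5.0)
        self._add(p, "em", value=self.em, min=1.0, max=1e4, vary=self.fit_em)
        self._add(p, "basal", value=0.0, min=0.0, max=50.0, vary=self.fit_basal)
        self._add(p, "n_slope", value=1.0, min=0.2, max=5.0, vary=self.fit_slope)
        return p

    def _residual(self, params, datasets) -> np.ndarray:
        res = []
        for ds in datasets:
            tb = (params["log_tau_B"].value if self.share_tau_B
                  else params[f"log_tau_B__{ds.label}"].value)
            fp = FunctionalModelParams(
                pKa_agonist=self._fixed("pKa", ds.label),
                pKb_modulator=self._fixed("pKb", ds.label),
                log_tau_A=params[f"log_tau_A__{ds.label}"].value,
                log_tau_B=tb,
                log_alphabeta=params[f"log_alphabeta__{ds.label}"].value,
                log_alpha=self._fixed("log_alpha", ds.label),
                em=params["em"].value,
                n_slope=params["n_slope"].value,
                basal=params["basal"].value)
            pred = operational_allosterism_response(
                ds.agonist_conc, ds.modulator_conc, fp)
            res.append(np.asarray(pred) - ds.value)
        return np.concatenate(res)

    def _fit_group(self, datasets) -> FitResult:
        out = super()._fit_group(datasets)
        values = np.concatenate([ds.value for ds in datasets])
        if np.ptp(values) < 1e-9 * max(1.0, np.max(np.abs(values))):
            out.message += " [degenerate: all-flat response]"
            out.converged = False
        return out


# ---------------------------------------------------------------------------
# spec-level functional wrappers


def fit_saturation(datasets: Sequence[AssayDataset], **kwargs) -> FitResult:
    """Fit saturation-binding experiments; replicates summarized as
    mean +/- SEM."""
    return SaturationBindingModel(datasets, **kwargs).fit()


def fit_atcm_global(datasets: Sequence[AssayDataset],
                    pKd_radioligand: float,
                    specs: Sequence[ParameterSpec] | None = None,
                    **kwargs) -> FitResult:
    """Global allosteric-ternary-complex fit across agonist datasets."""
    model = TernaryComplexBindingModel(
        datasets, pKd_radioligand, specs=specs, **kwargs)
    return derived_parameters(model.fit())


def fit_operational_allosterism_global(
        datasets: Sequence[AssayDataset],
        fixed_affinities: Mapping[str, float],
        specs: Sequence[ParameterSpec] | None = None,
        **kwargs) -> FitResult:
    """Global operational-allosterism fit across agonist datasets."""
    model = OperationalAllosterismModel(
        datasets, fixed_affinities, specs=specs, **kwargs)
    fit = model.fit()
    extra = {}
    for key, val in model.fixed.items():
        name = {"pKb": "pKb_modulator", "pKa": "pKi_agonist"}.get(
            key.split("__")[0], key.split("__")[0])
        suffix = "__" + key.split("__")[1] if "__" in key else ""
        extra[name + suffix] = (float(val), 0.0)
        if key.startswith("log_alpha"):
            extra[key] = (float(val), 0.0)
    return derived_parameters(fit, extra=extra)
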