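"""Synthetic assay data, toy potentials and reference trajectories.

This module generates every input the analysis pipeline consumes:

* interaction-binding and functional concentration-response grids with the
  replicate structure of equilibrium radioligand assays (radioligand fixed
  near its K_D, half-log agonist/modulator dilution series, three or more
  independent experiments),
* preset generating-truth parameter sets transcribed from the published
  binding and functional parameter tables for the M4 muscarinic receptor
  system (human/mouse wild type and key mutants, agonists acetylcholine
  (ACh) and iperoxo (Ipx), positive allosteric modulators LY2033298 (LY298)
  and VU0467154 (VU154)),
* analytic toy potential-energy surfaces for the accelerated-dynamics
  engine, and
* deterministic reference trajectories with closed-form geometry metrics.

The default noise model is additive Gaussian: SD 0.03 on fractional
specific binding and SD 3 response units on a normalized maximum of 100,
with 3 replicate experiments -- chosen so that recovered standard errors are
of the same order as those reported for the real assays. The real assays'
raw noise structure (counts, plate effects, heteroscedasticity) is not
emulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .fitting import AssayDataset, write_assay_csv
from .gamd import PotentialSurface
from .geometry import Trajectory
from .models import (
    BindingModelParams,
    ConcentrationGrid,
    FunctionalModelParams,
    atcm_fractional_occupancy,
    operational_allosterism_response,
)

__all__ = [
    "TruthPreset",
    "NoiseModel",
    "PRESETS",
    "make_interaction_design",
    "make_functional_design",
    "simulate_interaction_binding",
    "simulate_functional_interaction",
    "toy_potential",
    "make_reference_trajectory",
    "write_simulation",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the simulators."""

    kind: str = "gaussian_additive"
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("noise sd must be >= 0")
        if self.kind not in ("gaussian_additive", "gaussian_multiplicative"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator
              ) -> np.ndarray:
        if self.sd == 0:
            return values
        noise = rng.normal(0.0, self.sd, size=values.shape)
        if self.kind == "gaussian_additive":
            return values + noise
        return values * (1.0 + noise)


@dataclass(frozen=True)
class TruthPreset:
    """A generating-truth parameter set traceable to a published table row."""

    name: str
    binding: BindingModelParams | None = None
    functional: FunctionalModelParams | None = None
    note: str = ""


_HUMAN_WT_BMAX = 598111.0   # sites/cell, human wild-type saturation binding
_HUMAN_WT_PKD = 9.76

PRESETS: dict[str, TruthPreset] = {}


def _preset(p: TruthPreset) -> TruthPreset:
    PRESETS[p.name] = p
    return p


# --- saturation binding truths (sites/cell, pK_D) --------------------------
for _name, _bmax, _pkd in [
    ("SATURATION_HUMAN_WT", 598111.0, 9.76),
    ("SATURATION_MOUSE_WT", 21027.0, 9.76),
    ("SATURATION_HUMAN_D432E", 126377.0, 9.60),
    ("SATURATION_HUMAN_T433R", 157442.0, 9.64),
]:
    _preset(TruthPreset(
        name=_name,
        binding=BindingModelParams(pKd_radioligand=_pkd, bmax=_bmax),
        note="radioligand saturation binding table row"))

# --- interaction-binding truths (ATCM) -------------------------------------
for _name, _pki, _pkb, _la, _lap in [
    ("HUMAN_WT_LY298_ACH", 4.50, 5.65, 2.59, 0.0),
    ("HUMAN_WT_LY298_IPX", 8.30, 5.65, 1.86, 0.0),
    ("HUMAN_WT_VU154_ACH", 4.40, 5.83, 1.61, 0.0),
    ("HUMAN_WT_VU154_IPX", 8.19, 5.83, 1.03, 0.0),
    ("MOUSE_WT_LY298_ACH", 4.52, 5.74, 1.78, 0.0),
    ("MOUSE_WT_VU154_IPX", 8.57, 6.07, 1.75, 0.0),
    ("HUMAN_Q184A_LY298_IPX", 8.74, 6.23, 1.27, -1.10),
]:
    _preset(TruthPreset(
        name=_name,
        binding=BindingModelParams(
            pKd_radioligand=_HUMAN_WT_PKD, pKi_agonist=_pki,
            pKb_modulator=_pkb, log_alpha=_la, log_alpha_prime=_lap,
            bmax=_HUMAN_WT_BMAX),
        note="interaction-binding table row"))

# --- functional truths (operational model) ---------------------------------
_preset(TruthPreset(
    name="TRUPATH_HUMAN_WT_LY298_ACH",
    functional=FunctionalModelParams(
        pKa_agonist=4.50, pKb_modulator=5.65, log_tau_A=2.71,
        log_tau_B=1.02, log_alphabeta=2.01, log_alpha=2.59),
    note="G-protein activation interaction assay, human WT + LY298 + ACh"))
_preset(TruthPreset(
    name="TRUPATH_HUMAN_WT_LY298_IPX",
    functional=FunctionalModelParams(
        pKa_agonist=8.30, pKb_modulator=5.65, log_tau_A=1.49,
        log_tau_B=1.02, log_alphabeta=1.96, log_alpha=1.86),
    note="G-protein activation interaction assay, human WT + LY298 + Ipx"))
_preset(TruthPreset(
    name="TRUPATH_HUMAN_WT_VU154_IPX",
    functional=FunctionalModelParams(
        pKa_agonist=8.19, pKb_modulator=5.83, log_tau_A=1.49,
        log_tau_B=-0.55, log_alphabeta=0.20, log_alpha=1.03),
    note="G-protein activation interaction assay, human WT + VU154 + Ipx"))
_preset(TruthPreset(
    name="PERK_WT_LY298_ACH",
    functional=FunctionalModelParams(
        pKa_agonist=4.51, pKb_modulator=4.89, log_tau_A=2.96,
        log_tau_B=1.10, log_alphabeta=2.43, log_alpha=1.97),
    note="pERK1/2 interaction assay, WT + LY298 + ACh (mutant-panel table)"))


# ---------------------------------------------------------------------------
# assay designs and simulators


def make_interaction_design(n_agonist: int = 13, n_modulator: int = 9,
                            truth: BindingModelParams | None = None
                            ) -> ConcentrationGrid:
    """Interaction-binding design around a generating truth.

    Radioligand fixed at its K_D; agonist as a half-log dilution series
    spanning pKi +/- 3 (top concentration 10**-(pKi-3)); modulator as a
    half-log series from pKb - 1 down over ``n_modulator`` steps, plus the
    vehicle (0) column.
    """
    if n_agonist < 6 or n_modulator < 4:
        raise DomainError("need n_agonist >= 6 and n_modulator >= 4")
    truth = truth or BindingModelParams(pKd_radioligand=_HUMAN_WT_PKD)
    top_a = 10.0 ** (-(truth.pKi_agonist - 3.0))
    agonist = tuple(top_a * 10.0 ** (-0.5 * j) for j in range(n_agonist))
    top_b = 10.0 ** (-(truth.pKb_modulator - 1.0))
    modulator = (0.0,) + tuple(top_b * 10.0 ** (-0.5 * j)
                               for j in range(n_modulator))
    return ConcentrationGrid(
        agonist_concs=(0.0,) + agonist,
        modulator_concs=modulator,
        radioligand_conc=10.0 ** (-truth.pKd_radioligand))


def make_functional_design(n_agonist: int = 13, n_modulator: int = 7,
                           truth: FunctionalModelParams | None = None
                           ) -> ConcentrationGrid:
    """Functional concentration-response design: agonist half-log series
    spanning pKa +/- 3 (plus vehicle), modulator half-log series from
    pKb - 1 plus vehicle; no radioligand."""
    if n_agonist < 6 or n_modulator < 4:
        raise DomainError("need n_agonist >= 6 and n_modulator >= 4")
    truth = truth or FunctionalModelParams(pKa_agonist=6.0)
    top_a = 10.0 ** (-(truth.pKa_agonist - 3.0))
    agonist = tuple(top_a * 10.0 ** (-0.5 * j) for j in range(n_agonist))
    top_b = 10.0 ** (-(truth.pKb_modulator - 1.0))
    modulator = (0.0,) + tuple(top_b * 10.0 ** (-0.5 * j)
                               for j in range(n_modulator))
    return ConcentrationGrid(agonist_concs=(0.0,) + agonist,
                             modulator_concs=modulator)


def _grid_rows(design: ConcentrationGrid):
    a, b = np.meshgrid(design.agonist_concs, design.modulator_concs,
                       indexing="ij")
    return a.ravel(), b.ravel()


def simulate_interaction_binding(
        truth: BindingModelParams,
        design: ConcentrationGrid | None = None,
        noise: NoiseModel = NoiseModel(sd=0.03),
        n_experiments: int = 3,
        seed: int = 0,
        label: str = "") -> list[AssayDataset]:
    """Simulate replicate interaction-binding experiments under the ATCM.

    Values are fractional specific binding (radioligand occupancy with
    nonspecific binding already subtracted) plus the declared noise. With
    sd = 0 the values equal the model predictions exactly; replicates
    differ only through seeded noise.
    """
    design = design or make_interaction_design(truth=truth)
    a, b = _grid_rows(design)
    clean = np.asarray(atcm_fractional_occupancy(
        design.radioligand_conc, a, b, truth))
    streams = np.random.SeedSequence(seed).spawn(n_experiments)
    out = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        out.append(AssayDataset(
            agonist_conc=a, modulator_conc=b,
            value=noise.apply(clean, rng),
            radioligand_conc=design.radioligand_conc,
            replicate_id=rep, assay_kind="interaction_binding", label=label,
            normalization="fractional specific binding"))
    return out


def simulate_functional_interaction(
        truth: FunctionalModelParams,
        design: ConcentrationGrid | None = None,
        noise: NoiseModel = NoiseModel(sd=3.0),
        n_experiments: int = 3,
        seed: int = 0,
        label: str = "") -> list[AssayDataset]:
    """Simulate replicate functional interaction experiments under the
    operational model of allosterism (responses normalized to Em = 100)."""
    design = design or make_functional_design(truth=truth)
    a, b = _grid_rows(design)
    clean = np.asarray(operational_allosterism_response(a, b, truth))
    streams = np.random.SeedSequence(seed).spawn(n_experiments)
    out = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        out.append(AssayDataset(
            agonist_conc=a, modulator_conc=b,
            value=noise.apply(clean, rng),
            replicate_id=rep, assay_kind="functional", label=label,
            normalization="percent of maximal agonist response"))
    return out


def simulate_saturation(
        truth: BindingModelParams,
        concentrations=None,
        noise: NoiseModel = NoiseModel(kind="gaussian_multiplicative",
                                       sd=0.02),
        n_experiments: int = 3,
        seed: int = 0) -> list[AssayDataset]:
    """Simulate replicate saturation-binding curves (total binding)."""
    from .models import saturation_total_binding

    if concentrations is None:
        kd = 10.0 ** (-truth.pKd_radioligand)
        concentrations = kd * 10.0 ** np.linspace(-1.5, 1.5, 10)
    conc = np.asarray(concentrations, dtype=float)
    clean = np.asarray(saturation_total_binding(conc, truth))
    streams = np.random.SeedSequence(seed).spawn(n_experiments)
    out = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        out.append(AssayDataset(
            agonist_conc=conc, modulator_conc=np.zeros_like(conc),
            value=noise.apply(clean, rng), replicate_id=rep,
            assay_kind="saturation", label="radioligand"))
    return out


def write_simulation(datasets, path_csv, path_manifest=None, *,
                     truth=None, noise=None, seed=None) -> None:
    """Write simulated datasets plus a manifest recording truth/noise/seed."""
    write_assay_csv(datasets, path_csv)
    if path_manifest is not None:
        manifest = {
            "truth": asdict(truth) if truth is not None else None,
            "noise": asdict(noise) if noise is not None else None,
            "seed": seed,
            "n_experiments": len(datasets),
            "csv": str(path_csv),
        }
        with open(path_manifest, "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# toy potentials


def toy_potential(name: str, **parameters) -> PotentialSurface:
    """Analytic toy surfaces for the accelerated-dynamics engine.

    * ``harmonic``: 1/2 kappa x**2 (kappa > 0, default 1).
    * ``double_well_1d``: a (x**2 - b**2)**2 with minima at +/- b and an
      analytic barrier a*b**4 at x = 0 (defaults a=7, b=1).
    * ``double_well_2d``: the 1D double well plus a transverse harmonic
      term 1/2 kappa_y y**2; exposes the two-term decomposition used by
      dual-boost.
    """
    if name == "harmonic":
        kappa = float(parameters.pop("kappa", 1.0))
        if parameters:
            raise ConfigurationError(f"unknown parameters {set(parameters)}")
        if kappa <= 0:
            raise DomainError("kappa must be > 0")
        return PotentialSurface(
            dimensionality=1,
            energy=lambda x: 0.5 * kappa * float(x[0]) ** 2,
            gradient=lambda x: np.array([kappa * float(x[0])]),
            name="harmonic")
    if name == "double_well_1d":
        a = float(parameters.pop("a", 7.0))
        b = float(parameters.pop("b", 1.0))
        if parameters:
            raise ConfigurationError(f"unknown parameters {set(parameters)}")
        if a <= 0 or b <= 0:
            raise DomainError("a and b must be > 0")
        return PotentialSurface(
            dimensionality=1,
            energy=lambda x: a * (float(x[0]) ** 2 - b * b) ** 2,
            gradient=lambda x: np.array(
                [4.0 * a * float(x[0]) * (float(x[0]) ** 2 - b * b)]),
            name="double_well_1d")
    if name == "double_well_2d":
        a = float(parameters.pop("a", 7.0))
        b = float(parameters.pop("b", 1.0))
        kappa_y = float(parameters.pop("kappa_y", 2.0))
        if parameters:
            raise ConfigurationError(f"unknown parameters {set(parameters)}")
        if a <= 0 or b <= 0 or kappa_y <= 0:
            raise DomainError("a, b and kappa_y must be > 0")

        def e_dw(x):
            return a * (float(x[0]) ** 2 - b * b) ** 2

        def g_dw(x):
            return np.array(
                [4.0 * a * float(x[0]) * (float(x[0]) ** 2 - b * b), 0.0])

        def e_tr(x):
            return 0.5 * kappa_y * float(x[1]) ** 2

        def g_tr(x):
            return np.array([0.0, kappa_y * float(x[1])])

        return PotentialSurface(
            dimensionality=2,
            energy=lambda x: e_dw(x) + e_tr(x),
            gradient=lambda x: g_dw(x) + g_tr(x),
            terms=[(e_dw, g_dw), (e_tr, g_tr)],
            name="double_well_2d")
    raise ConfigurationError(f"unknown toy potential {name!r}")


# ---------------------------------------------------------------------------
# reference trajectories (geometry-test oracles)


def _base_structure() -> np.ndarray:
    # rigid 5-atom scaffold: a tetrahedron plus its centroid
    return np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [0.0, 0.0, 0.0],
    ])


def make_reference_trajectory(kind: str, n_frames: int = 10, seed: int = 0,
                              amplitude: float = 0.5) -> Trajectory:
    """Deterministic trajectories with known geometry-metric values.

    * ``static``: identical frames (all RMSD/RMSF zero).
    * ``rigid_motion``: random rotations + translations of the scaffold
      (fitted RMSD ~ 0, unfitted > 0).
    * ``single_atom_oscillation``: atom 0 alternates +/- ``amplitude``
      along x against a static scaffold (RMSF of atom 0 is exactly
      ``amplitude`` when aligning on the scaffold).
    * ``torsion_sweep``: 4-atom chain whose dihedral sweeps 0..180 degrees
      in equal steps across the frames.
    """
    if n_frames < 1:
        raise DomainError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "static":
        base = _base_structure()
        return Trajectory(coords=np.repeat(base[None], n_frames, axis=0))
    if kind == "rigid_motion":
        from scipy.spatial.transform import Rotation

        base = _base_structure()
        frames = [base]
        for _ in range(n_frames - 1):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-5, 5, size=3)
            frames.append(base @ R.T + t)
        return Trajectory(coords=np.array(frames))
    if kind == "single_atom_oscillation":
        base = np.vstack([[3.0, 0.0, 0.0], _base_structure()])
        frames = []
        for i in range(n_frames):
            f = base.copy()
            f[0, 0] += amplitude if i % 2 == 0 else -amplitude
            frames.append(f)
        return Trajectory(coords=np.array(frames))
    if kind == "torsion_sweep":
        frames = []
        angles = (np.linspace(0.0, 180.0, n_frames) if n_frames > 1
                  else np.array([0.0]))
        for ang in angles:
            phi = math.radians(ang)
            frames.append(np.array([
                [1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0],
                [math.cos(phi), -math.sin(phi), 1.0],
            ]))
        return Trajectory(coords=np.array(frames))
    raise ConfigurationError(f"unknown reference trajectory kind {kind!r}")
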