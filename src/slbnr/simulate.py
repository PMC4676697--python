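"""Synthetic time-of-flight reflectivity: instrument geometry, noise, presets.

Generates multi-contrast solid–liquid reflectivity datasets from a ground-truth
bilayer parameterization, emulating a time-of-flight reflectometer that covers
Q with a broad wavelength band at two incidence angles. The noise model is
multiplicative Gaussian (relative σ) plus a constant additive background;
counting statistics are not simulated.

Ground-truth presets reproduce three published supported-lipid-bilayer
structures from hydrogenated and per-deuterated E. coli total lipid extracts
(deposited at 50 °C or 25 °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import (
    BilayerModel,
    OneLayerVesicleBilayer,
    ParamSpec,
    ThreeLayerBilayer,
)
from .reflectivity import ReflectivityCurve, smeared_reflectivity
from .scattering import ContrastSpec

__all__ = [
    "InstrumentSpec",
    "FIGARO",
    "D17",
    "make_q_grid",
    "simulate_contrast_series",
    "ground_truth_presets",
    "GroundTruth",
    "FOUR_CONTRASTS",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """Time-of-flight reflectometer geometry and noise model.

    Q coverage is the union over incidence angles of [4π sinθ/λ_max,
    4π sinθ/λ_min]; ``q_min``/``q_max`` optionally trim it. ``dq_over_q`` is
    the FWHM relative resolution; ``noise_rel`` the relative 1σ of the
    multiplicative noise; ``background`` a constant additive floor.
    """

    wavelength_min: float = 2.0
    wavelength_max: float = 30.0
    angles: tuple[float, ...] = (0.624, 3.78)
    dq_over_q: float = 0.08
    points_per_decade: int = 60
    noise_rel: float = 0.03
    background: float = 1e-7
    q_min: float | None = None
    q_max: float | None = None

    def __post_init__(self) -> None:
        if not self.wavelength_min < self.wavelength_max:
            raise ValueError("need wavelength_min < wavelength_max")
        if not self.angles or any(a <= 0 for a in self.angles):
            raise ValueError("angles must be positive")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")

    def q_range(self) -> tuple[float, float]:
        lo = min(
            4 * math.pi * math.sin(math.radians(a)) / self.wavelength_max
            for a in self.angles
        )
        hi = max(
            4 * math.pi * math.sin(math.radians(a)) / self.wavelength_min
            for a in self.angles
        )
        if self.q_min is not None:
            lo = max(lo, self.q_min)
        if self.q_max is not None:
            hi = min(hi, self.q_max)
        if not lo < hi:
            raise ValueError("empty Q range")
        return lo, hi


#: The two reflectometer geometries used for the measurements.
FIGARO = InstrumentSpec(angles=(0.624, 3.78))
D17 = InstrumentSpec(angles=(0.8, 3.2))


def make_q_grid(spec: InstrumentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Logarithmic Q grid over the instrument's coverage, with dQ = dq/q·Q."""
    lo, hi = spec.q_range()
    n = max(2, round(spec.points_per_decade * math.log10(hi / lo)) + 1)
    q = np.logspace(math.log10(lo), math.log10(hi), n)
    return q, spec.dq_over_q * q


#: The four solvent contrasts of the standard measurement series.
FOUR_CONTRASTS = (0.0, 0.4, 0.6, 1.0)


def _contrasts(fractions, dq_over_q: float) -> tuple[ContrastSpec, ...]:
    return tuple(ContrastSpec(f, dq_over_q) for f in fractions)


def simulate_contrast_series(
    model: BilayerModel,
    contrasts: tuple[ContrastSpec, ...],
    spec: InstrumentSpec,
    seed: int | None = None,
) -> list[tuple[ReflectivityCurve, ContrastSpec]]:
    """Simulate one noisy reflectivity curve per contrast from a truth model.

    Pipeline per contrast: exact Abeles curve → dQ/Q smearing → multiplicative
    Gaussian noise R·(1+ε), ε ~ N(0, noise_rel) → additive background. The
    quoted uncertainty is dR = noise_rel·R_smeared + background. Deterministic
    for a given seed (one child stream per contrast).
    """
    q, dq = make_q_grid(spec)
    values = model.init_values()
    rng = np.random.default_rng(seed)
    streams = rng.spawn(len(contrasts))
    out: list[tuple[ReflectivityCurve, ContrastSpec]] = []
    for contrast, stream in zip(contrasts, streams):
        stack = model.build(values, contrast)
        r_smeared = smeared_reflectivity(
            stack, contrast.water_sld, q, contrast.dq_over_q
        )
        if spec.noise_rel > 0:
            eps = stream.normal(0.0, spec.noise_rel, size=q.size)
        else:
            eps = np.zeros(q.size)
        r_obs = r_smeared * (1.0 + eps) + spec.background
        dr = spec.noise_rel * r_smeared + spec.background
        if spec.noise_rel == 0 and spec.background == 0:
            dr = None  # noiseless: leave weighting to the fitter's default
        out.append((ReflectivityCurve(q, r_obs, dr, dq), contrast))
    return out


@dataclass
class GroundTruth:
    """A named truth structure plus the contrasts it was measured in."""

    name: str
    model: BilayerModel
    contrasts: tuple[ContrastSpec, ...]
    description: str = ""

    def truth_values(self) -> dict[str, float]:
        return self.model.init_values()


def _three_layer_hecoli(dq_over_q: float) -> ThreeLayerBilayer:
    params = {
        "d_water": ParamSpec(8.0, 2.0, 20.0),
        "d_head": ParamSpec(7.0, 4.0, 12.0),
        "d_tail": ParamSpec(27.0, 20.0, 35.0),
        "phi_tail": ParamSpec(0.12, 0.0, 0.4),
        "roughness": ParamSpec(4.0, 1.0, 15.0),
        "head_sld_offset": ParamSpec(0.0, -0.5, 0.5),
        "tail_sld_offset": ParamSpec(0.0, -0.5, 0.5),
    }
    return ThreeLayerBilayer(
        params,
        head_sld_h2o=1.55,
        head_sld_d2o=2.16,
        tail_sld=-0.55,
        background=1e-7,
    )


def _one_layer_decoli(
    d_water: float,
    d_bilayer: float,
    phi_bilayer: float,
    roughness: float,
    bilayer_sld: float,
    vesicle_contrasts,
) -> OneLayerVesicleBilayer:
    params = {
        "d_water": ParamSpec(d_water, 2.0, 20.0),
        "d_bilayer": ParamSpec(d_bilayer, 30.0, 50.0),
        "phi_bilayer": ParamSpec(phi_bilayer, 0.0, 0.3),
        "roughness": ParamSpec(roughness, 1.0, 15.0),
        "sld_offset": ParamSpec(0.0, -0.5, 0.5),
        "d_vesicle_gap": ParamSpec(14.0, 5.0, 30.0),
        "coverage": ParamSpec(0.04, 0.0, 0.2),
    }
    return OneLayerVesicleBilayer(
        params,
        bilayer_sld=bilayer_sld,
        vesicle_contrasts=vesicle_contrasts,
        vesicle_roughness=10.0,
        background=1e-7,
    )


def ground_truth_presets(dq_over_q: float = 0.08) -> dict[str, GroundTruth]:
    """The three published bilayer structures as simulation ground truths.

    * ``hEcoli_50C`` — hydrogenated extract deposited at 50 °C: symmetric
      three-layer bilayer (head 7 Å, tail 27 Å at 12% solvent, global
      roughness 4 Å) behind an 8 Å water gap; head SLD 1.55/2.16 (H₂O/D₂O).
    * ``dEcoli_50C`` — per-deuterated extract deposited at 50 °C: one 41 Å
      slab (6% solvent, SLD 6.66, roughness 7 Å) behind a 9 Å gap, with a
      4%-coverage vesicle layer (14 Å water gap) present only in the first
      contrast (H₂O) — rinsed away by the solvent exchanges.
    * ``dEcoli_25C`` — per-deuterated extract deposited at 25 °C: a 42 Å slab
      (3% solvent, SLD 6.60, roughness 7 Å) behind a 6 Å gap, with a
      3%-coverage vesicle layer present in all three contrasts measured.
    """
    four = _contrasts(FOUR_CONTRASTS, dq_over_q)
    three = _contrasts((0.0, 0.6, 1.0), dq_over_q)
    presets = {
        "hEcoli_50C": GroundTruth(
            "hEcoli_50C",
            _three_layer_hecoli(dq_over_q),
            four,
            "hydrogenated extract, deposited 50 °C, three-layer model",
        ),
        "dEcoli_50C": GroundTruth(
            "dEcoli_50C",
            _one_layer_decoli(9.0, 41.0, 0.06, 7.0, 6.66, vesicle_contrasts=(0.0,)),
            four,
            "per-deuterated extract, deposited 50 °C, vesicles in H2O only",
        ),
        "dEcoli_25C": GroundTruth(
            "dEcoli_25C",
            _one_layer_decoli(6.0, 42.0, 0.03, 7.0, 6.60, vesicle_contrasts=None),
            three,
            "per-deuterated extract, deposited 25 °C, vesicles in all contrasts",
        ),
    }
    # 25 °C structure: vesicle coverage 3% (solvent 97%).
    presets["dEcoli_25C"].model.params["coverage"].value = 0.03
    return presets
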