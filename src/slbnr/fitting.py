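"""Simultaneous multi-contrast co-refinement of bilayer slab models.

One structural parameter set is fitted against all solvent-contrast datasets
at once: the structure (thicknesses, solvent fractions, roughness) is shared,
while the solvent SLD and the labile-proton headgroup SLD follow each
contrast. The objective is the error-weighted χ² summed over contrasts;
optimization is bounded least squares (trust-region reflective) restarted from
several jittered initializations, with deterministic seeding and tie-breaking.

Uncertainties come from a residual bootstrap (refit on resampled residuals) or
a one-dimensional χ² profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import BilayerModel
from .reflectivity import ReflectivityCurve, smeared_reflectivity
from .scattering import ContrastSpec

__all__ = [
    "Dataset",
    "FitResult",
    "chi_square",
    "co_refine",
    "estimate_uncertainty",
    "compare_models",
]

#: (curve, contrast) pairing for one measured solvent.
Dataset = tuple[ReflectivityCurve, ContrastSpec]

_CONSTRAINT_PENALTY = 1e3  # residual units per unit of constraint violation
_DEFAULT_REL_WEIGHT = 0.05  # relative weight when a dataset carries no dR


def _model_curve(
    model: BilayerModel,
    values: dict[str, float],
    curve: ReflectivityCurve,
    contrast: ContrastSpec,
) -> np.ndarray:
    stack = model.build(values, contrast)
    r = smeared_reflectivity(stack, contrast.water_sld, curve.q, contrast.dq_over_q)
    return r + model.background


def _residuals_one(
    model: BilayerModel,
    values: dict[str, float],
    curve: ReflectivityCurve,
    contrast: ContrastSpec,
) -> np.ndarray:
    r_model = _model_curve(model, values, curve, contrast)
    dr = curve.dr if curve.dr is not None else _DEFAULT_REL_WEIGHT * np.abs(curve.r)
    return (r_model - curve.r) / dr


def chi_square(
    model: BilayerModel, values: dict[str, float], datasets: Sequence[Dataset]
) -> float:
    """Σ over contrasts and Q of ((R_model − R_obs)/dR)².

    Datasets without dR are weighted by 5% of |R_obs|. A failed model
    evaluation returns +inf.
    """
    total = 0.0
    try:
        for curve, contrast in datasets:
            total += float(np.sum(_residuals_one(model, values, curve, contrast) ** 2))
    except (ValueError, FloatingPointError, ZeroDivisionError):
        return float("inf")
    return total


@dataclass
class FitResult:
    """Best co-refined parameter set and its diagnostics."""

    params: dict[str, float]
    derived: dict[str, float]
    chisq: float
    chisq_per_contrast: list[float]
    n_points: int
    n_varied: int
    model_curves: list[np.ndarray]
    success: bool
    constraint_violated: bool
    n_iterations: int
    start_costs: list[float] = field(default_factory=list)
    start_params: list[dict[str, float]] = field(default_factory=list)
    intervals: dict[str, tuple[float, float]] | None = None

    @property
    def reduced_chisq(self) -> float:
        dof = max(1, self.n_points - self.n_varied)
        return self.chisq / dof


def _finish(
    model: BilayerModel,
    values: dict[str, float],
    datasets: Sequence[Dataset],
    success: bool,
    n_iter: int,
    start_costs: list[float],
    start_params: list[dict[str, float]] | None = None,
) -> FitResult:
    per_contrast = [
        float(np.sum(_residuals_one(model, values, curve, contrast) ** 2))
        for curve, contrast in datasets
    ]
    curves = [
        _model_curve(model, values, curve, contrast) for curve, contrast in datasets
    ]
    return FitResult(
        params=dict(values),
        derived=model.derived(values),
        chisq=float(sum(per_contrast)),
        chisq_per_contrast=per_contrast,
        n_points=int(sum(len(c) for c, _ in datasets)),
        n_varied=len(model.free_names()),
        model_curves=curves,
        success=success,
        constraint_violated=model.constraint_violation(values) > 0,
        n_iterations=n_iter,
        start_costs=start_costs,
        start_params=start_params or [],
    )


def co_refine(
    model: BilayerModel,
    datasets: Sequence[Dataset],
    n_starts: int = 8,
    seed: int | None = None,
    jitter: float = 0.2,
) -> FitResult:
    """Co-refine one parameterization against all contrasts simultaneously.

    ``n_starts`` bounded local optimizations are run from initializations
    jittered uniformly by ±``jitter`` (relative) around the table values and
    clipped to the bounds; the lowest-χ² solution wins, with ties broken by
    lexicographic parameter order so the result is deterministic for a seed.
    """
    if not datasets:
        raise ValueError("co_refine needs at least one dataset")
    free = model.free_names()
    if not free:  # nothing to optimize: report the forward model as-is
        return _finish(model, model.init_values(), datasets, True, 0, [])
    lo, hi = model.bounds()
    x_init = np.array([model.params[n].value for n in free])

    def residuals(x: np.ndarray) -> np.ndarray:
        values = model.values_from_vector(x)
        parts = [
            _residuals_one(model, values, curve, contrast)
            for curve, contrast in datasets
        ]
        violation = model.constraint_violation(values)
        parts.append(np.array([_CONSTRAINT_PENALTY * violation]))
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    starts = []
    for _ in range(n_starts):
        x0 = x_init * (1.0 + rng.uniform(-jitter, jitter, size=x_init.size))
        starts.append(np.clip(x0, lo, hi))

    best: tuple[float, tuple[float, ...]] | None = None
    best_res = None
    costs: list[float] = []
    start_params: list[dict[str, float]] = []
    failures: list[str] = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception as exc:  # keep other starts alive
            failures.append(str(exc))
            continue
        costs.append(2.0 * res.cost)
        start_params.append(model.values_from_vector(res.x))
        key = (2.0 * res.cost, tuple(res.x))
        if best is None or key < best:
            best, best_res = key, res
    if best_res is None:
        raise RuntimeError(
            f"all {n_starts} optimization starts failed: {failures[:3]}"
        )
    values = model.values_from_vector(np.clip(best_res.x, lo, hi))
    return _finish(
        model,
        values,
        datasets,
        bool(best_res.success),
        int(best_res.nfev),
        costs,
        start_params,
    )


def _refit_from(
    model: BilayerModel,
    x0: np.ndarray,
    datasets: Sequence[Dataset],
) -> np.ndarray:
    free = model.free_names()
    lo, hi = model.bounds()

    def residuals(x):
        values = model.values_from_vector(x)
        parts = [
            _residuals_one(model, values, curve, contrast)
            for curve, contrast in datasets
        ]
        parts.append(
            np.array([_CONSTRAINT_PENALTY * model.constraint_violation(values)])
        )
        return np.concatenate(parts)

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac")
    return res.x


def estimate_uncertainty(
    fit: FitResult,
    model: BilayerModel,
    datasets: Sequence[Dataset],
    method: str = "bootstrap",
    n_boot: int = 100,
    seed: int | None = None,
    level: float = 0.68,
) -> dict[str, tuple[float, float]]:
    """Per-parameter uncertainty intervals for a converged co-refinement.

    ``bootstrap`` (default): residual bootstrap — resample the weighted
    residuals with replacement, rebuild synthetic data around the best-fit
    curves, refit from the best-fit start, and take the central ``level``
    percentile interval of each parameter. ``profile``: 1-d χ² profile per
    parameter (others re-optimized), interval at Δχ² = 1.
    """
    if not fit.success:
        raise ValueError("uncertainty estimation needs a converged fit")
    free = model.free_names()
    x_best = np.array([fit.params[n] for n in free])
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_boot):
            boot_sets = []
            for (curve, contrast), r_model in zip(datasets, fit.model_curves):
                dr = (
                    curve.dr
                    if curve.dr is not None
                    else _DEFAULT_REL_WEIGHT * np.abs(curve.r)
                )
                resid = (curve.r - r_model) / dr
                resampled = rng.choice(resid, size=resid.size, replace=True)
                r_boot = r_model + resampled * dr
                boot_sets.append(
                    (
                        ReflectivityCurve(curve.q, r_boot, dr, curve.dq),
                        contrast,
                    )
                )
            samples.append(_refit_from(model, x_best, boot_sets))
        arr = np.array(samples)
        alpha = 100.0 * (1.0 - level) / 2.0
        return {
            name: (
                float(np.percentile(arr[:, i], alpha)),
                float(np.percentile(arr[:, i], 100.0 - alpha)),
            )
            for i, name in enumerate(free)
        }
    if method == "profile":
        return _profile_intervals(fit, model, datasets, x_best)
    raise ValueError(f"unknown uncertainty method {method!r}")


def _profile_intervals(
    fit: FitResult,
    model: BilayerModel,
    datasets: Sequence[Dataset],
    x_best: np.ndarray,
    n_grid: int = 11,
    span: float = 0.15,
) -> dict[str, tuple[float, float]]:
    """Δχ² = 1 crossings of a coarse 1-d profile per free parameter."""
    free = model.free_names()
    lo, hi = model.bounds()
    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(free):
        center = x_best[i]
        width = max(abs(center) * span, 1e-3)
        grid = np.linspace(
            max(lo[i], center - width), min(hi[i], center + width), n_grid
        )
        chis = []
        for g in grid:
            spec = model.params[name]
            was = spec.value, spec.vary
            spec.value, spec.vary = float(g), False
            try:
                x0 = np.array(
                    [x_best[j] for j, n2 in enumerate(free) if n2 != name]
                )
                x_opt = _refit_from(model, x0, datasets)
                values = model.values_from_vector(x_opt)
                chis.append(chi_square(model, values, datasets))
            finally:
                spec.value, spec.vary = was
        chis = np.array(chis)
        target = chis.min() + 1.0
        below = grid[chis <= target]
        out[name] = (float(below.min()), float(below.max()))
    return out


@dataclass
class ModelComparison:
    """Reduced-χ² comparison of two fits of the same datasets."""

    reduced_chisq_a: float
    reduced_chisq_b: float
    preferred: str  # "a", "b" or "tie"
    improvement: float  # ratio worse/better of the reduced χ²
    delta_per_point: float  # (χ²_a − χ²_b) / n_points
    necessary: bool


def compare_models(
    fit_a: FitResult,
    fit_b: FitResult,
    datasets: Sequence[Dataset],
    necessity_factor: float = 1.3,
) -> ModelComparison:
    """Compare two co-refinements of identical datasets by reduced χ².

    By convention ``fit_a`` is the richer model (e.g. with the vesicle
    extension); it is flagged "necessary" when it improves the reduced χ²
    over ``fit_b`` by at least ``necessity_factor``.
    """
    n_points = int(sum(len(c) for c, _ in datasets))
    if fit_a.n_points != n_points or fit_b.n_points != n_points:
        raise ValueError("both fits must cover exactly the given datasets")
    ra, rb = fit_a.reduced_chisq, fit_b.reduced_chisq
    if np.isclose(ra, rb, rtol=1e-12, atol=1e-12):
        preferred, improvement = "tie", 1.0
    elif ra < rb:
        preferred, improvement = "a", rb / ra
    else:
        preferred, improvement = "b", ra / rb
    return ModelComparison(
        reduced_chisq_a=ra,
        reduced_chisq_b=rb,
        preferred=preferred,
        improvement=float(improvement),
        delta_per_point=float((fit_a.chisq - fit_b.chisq) / n_points),
        necessary=preferred == "a" and improvement >= necessity_factor,
    )
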