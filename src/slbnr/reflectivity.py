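"""Specular neutron reflectivity of a slab stack at a solid–liquid interface.

The stack is evaluated with the Abeles optical (characteristic/transfer) matrix
method: each layer contributes a 2×2 matrix built from its phase thickness and
the Fresnel coefficient of its top interface, damped for interfacial roughness
by the Névot–Croce factor. The product over layers gives the reflected
amplitude; |r|² is the reflectivity.

Geometry: the beam travels through the semi-infinite fronting medium (the
silicon block), the slabs are listed from the substrate outward (SiO₂ first),
and the semi-infinite backing is the aqueous solvent. Q is the momentum
transfer in the fronting medium, Å⁻¹; SLDs are in 1e-6 Å⁻²; lengths in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

__all__ = [
    "SI_SLD",
    "SIO2_SLD",
    "Slab",
    "SlabStack",
    "ReflectivityCurve",
    "effective_sld",
    "abeles_reflectivity",
    "smear",
    "smeared_reflectivity",
    "critical_q",
]

#: Standard substrate SLDs, 1e-6 Å⁻².
SI_SLD = 2.07
SIO2_SLD = 3.47


@dataclass(frozen=True)
class Slab:
    """One optical layer.

    ``roughness`` is the Gaussian width (Å) of this layer's interface to the
    *preceding* (substrate-side) layer. ``solvent_fraction`` is the volume
    fraction occupied by the bulk solvent, mixed into the SLD at evaluation
    time.
    """

    thickness: float
    sld: float
    solvent_fraction: float = 0.0
    roughness: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError("solvent_fraction must be in [0, 1]")
        if self.roughness < 0:
            raise ValueError("roughness must be >= 0")


@dataclass(frozen=True)
class SlabStack:
    """Fronting | slabs (substrate-side first) | backing solvent.

    The fronting and backing are semi-infinite; ``backing_roughness`` is the
    width of the outermost interface (last slab against solvent).
    """

    slabs: tuple[Slab, ...]
    fronting_sld: float = SI_SLD
    backing_roughness: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "slabs", tuple(self.slabs))
        for i, s in enumerate(self.slabs):
            prev_d = self.slabs[i - 1].thickness if i else np.inf
            if s.roughness > min(s.thickness if s.thickness > 0 else np.inf, prev_d):
                # value-free message so repeated fit evaluations dedupe
                warnings.warn(
                    f"slab {s.name or i}: roughness exceeds the thinner "
                    "adjoining layer; the Gaussian-interface picture is marginal",
                    stacklevel=2,
                )

    def with_solvent(self, solvent_sld: float) -> "SlabStack":
        """Resolve solvent penetration: return a stack of solvent-mixed SLDs
        with every solvent_fraction set to 0."""
        return replace(
            self,
            slabs=tuple(
                replace(s, sld=effective_sld(s, solvent_sld), solvent_fraction=0.0)
                for s in self.slabs
            ),
        )


def effective_sld(slab: Slab, solvent_sld: float) -> float:
    """SLD of a solvent-penetrated layer: φ·ρ_solvent + (1−φ)·ρ_layer."""
    phi = slab.solvent_fraction
    return phi * solvent_sld + (1.0 - phi) * slab.sld


@dataclass
class ReflectivityCurve:
    """Measured or simulated specular reflectivity for one contrast."""

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    dq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.dr is not None:
            self.dr = np.asarray(self.dr, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.r.shape:
            raise ValueError("q and r must be 1-d arrays of equal length")
        if np.any(self.q <= 0):
            raise ValueError("Q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if self.dr is not None and np.any(self.dr <= 0):
            raise ValueError("dR must be positive where present")

    def __len__(self) -> int:
        return self.q.size


def critical_q(fronting_sld: float, backing_sld: float) -> float:
    """Total-reflection edge Q_c = sqrt(16π Δρ) for Δρ > 0, Å⁻¹."""
    drho = (backing_sld - fronting_sld) * 1e-6
    if drho <= 0:
        return 0.0
    return float(np.sqrt(16.0 * np.pi * drho))


def _kz_layers(stack: SlabStack, solvent_sld: float, q: np.ndarray):
    """Perpendicular wavevectors k_n(Q) in every medium plus layer geometry."""
    resolved = stack.with_solvent(solvent_sld)
    # a zero-thickness layer is no layer: drop it so insertion is exactly inert
    slabs = [s for s in resolved.slabs if s.thickness > 0.0]
    slds = np.array(
        [stack.fronting_sld] + [s.sld for s in slabs] + [solvent_sld]
    )
    d = np.array([0.0] + [s.thickness for s in slabs] + [0.0])
    sigma = np.array([s.roughness for s in slabs] + [stack.backing_roughness])
    k0sq = (np.asarray(q, dtype=float) / 2.0) ** 2
    # k_n^2 = k0^2 - 4π(ρ_n - ρ_fronting); complex branch handles evanescence.
    ksq = k0sq[:, None] - 4.0e-6 * np.pi * (slds - slds[0])[None, :]
    k = np.sqrt(ksq.astype(complex))
    return k, d, sigma


def abeles_reflectivity(
    stack: SlabStack, solvent_sld: float, q: np.ndarray
) -> np.ndarray:
    """Exact (unsmeared) specular reflectivity R(Q) of a stack.

    Interface Fresnel coefficients are damped by the Névot–Croce factor
    exp(−2 k_n k_{n+1} σ²); the result is clipped to [0, 1] at the 1e-12
    level to remove roundoff excursions above total reflection.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("Q must be positive")
    for s in stack.slabs:
        for v in (s.thickness, s.sld, s.solvent_fraction, s.roughness):
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter in slab {s.name!r}")
    if not (np.isfinite(stack.fronting_sld) and np.isfinite(solvent_sld)):
        raise ValueError("non-finite fronting or solvent SLD")

    k, d, sigma = _kz_layers(stack, solvent_sld, q)
    n_media = k.shape[1]

    # Characteristic-matrix product, fronting -> backing.
    m00 = np.ones(q.shape, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for n in range(n_media - 1):
        kn, kn1 = k[:, n], k[:, n + 1]
        rn = (kn - kn1) / (kn + kn1) * np.exp(-2.0 * kn * kn1 * sigma[n] ** 2)
        beta = kn * d[n]  # zero for the fronting medium
        e_pos = np.exp(1j * beta)
        e_neg = np.exp(-1j * beta)
        c00, c01 = e_pos, rn * e_pos
        c10, c11 = rn * e_neg, e_neg
        m00, m01, m10, m11 = (
            m00 * c00 + m01 * c10,
            m00 * c01 + m01 * c11,
            m10 * c00 + m11 * c10,
            m10 * c01 + m11 * c11,
        )
    r_amp = m10 / m00
    refl = np.abs(r_amp) ** 2
    return np.clip(refl, 0.0, 1.0)


_SMEAR_WIDTH = 3.5  # half-range of the resolution kernel, in σ
_SMEAR_POINTS = 21
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355...


def smeared_reflectivity(
    stack: SlabStack,
    solvent_sld: float,
    q: np.ndarray,
    dq_over_q: float,
    n_points: int = _SMEAR_POINTS,
) -> np.ndarray:
    """Resolution-smeared R(Q) by Gaussian quadrature over the dQ/Q kernel.

    dq_over_q is the FWHM relative resolution; the Gaussian σ_Q is
    dq_over_q·Q/2.355. Evaluated by oversampled quadrature (``n_points``
    abscissae spanning ±3.5σ), re-evaluating the exact model at each
    abscissa — no interpolation.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return abeles_reflectivity(stack, solvent_sld, q)
    z = np.linspace(-_SMEAR_WIDTH, _SMEAR_WIDTH, n_points)
    w = np.exp(-0.5 * z**2)
    w /= w.sum()
    sigma_q = dq_over_q * q / _FWHM
    q_samples = q[:, None] + sigma_q[:, None] * z[None, :]
    q_samples = np.clip(q_samples, 1e-8, None)
    r = abeles_reflectivity(stack, solvent_sld, q_samples.ravel())
    return r.reshape(q_samples.shape) @ w


def smear(
    q: np.ndarray, r: np.ndarray, dq_over_q: float, n_points: int = _SMEAR_POINTS
) -> np.ndarray:
    """Smear a tabulated exact curve R(Q) with a Gaussian dQ/Q kernel.

    Quadrature abscissae outside the tabulated range clamp to the end values;
    prefer :func:`smeared_reflectivity` when the model is available.
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0:
        return r.copy()
    z = np.linspace(-_SMEAR_WIDTH, _SMEAR_WIDTH, n_points)
    w = np.exp(-0.5 * z**2)
    w /= w.sum()
    sigma_q = dq_over_q * q / _FWHM
    q_samples = q[:, None] + sigma_q[:, None] * z[None, :]
    r_samples = np.interp(q_samples, q, r)
    return r_samples @ w
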