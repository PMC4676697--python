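"""Constraint-bound slab parameterizations of supported lipid bilayers.

Two model families are provided:

* a symmetric three-layer bilayer (head | tail | head) for hydrogenated
  extracts, with the head-layer hydration *derived* from an equal
  area-per-molecule constraint between the head and tail regions rather than
  fitted, and

* a one-layer bilayer for per-deuterated extracts, optionally extended by a
  sparse co-adsorbed vesicle layer modelled as two extra slabs (a water gap
  plus a dilute bilayer whose thickness and SLD are tied to the supported
  bilayer's).

Every stack sits on Si | SiO₂ with a thin interfacial water gap between the
oxide and the membrane. Structural parameters are shared across solvent
contrasts; only the solvent SLD and the labile-proton headgroup SLD vary
between contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .reflectivity import SIO2_SLD, Slab, SlabStack
from .scattering import ContrastSpec, exchanged_sld

__all__ = [
    "ParamSpec",
    "area_per_molecule",
    "coupled_head_solvent",
    "BilayerModel",
    "ThreeLayerBilayer",
    "OneLayerVesicleBilayer",
    "POPC_HEAD_VOLUME",
    "POPC_TAILS_VOLUME",
]

#: POPC reference partial volumes, Å³ (headgroup; both acyl chains).
POPC_HEAD_VOLUME = 319.0
POPC_TAILS_VOLUME = 937.0


def area_per_molecule(d_tail: float, phi_tail: float, v_tails: float) -> float:
    """Mean interfacial area per lipid from the tail region, Å².

    The tail slab holds the chains of both leaflets, so the lipid volume per
    unit area is 2·V_tails spread over a thickness d_tail·(1−φ_tail):
    A = 2·V_tails / (d_tail·(1−φ_tail)).
    """
    if d_tail <= 0:
        raise ValueError("d_tail must be > 0")
    if not 0.0 <= phi_tail < 1.0:
        raise ValueError("phi_tail must be in [0, 1); phi_tail = 1 leaves no lipid")
    return 2.0 * v_tails / (d_tail * (1.0 - phi_tail))


def coupled_head_solvent(d_head: float, area: float, v_head: float) -> float:
    """Head-layer solvent fraction implied by equal head/tail areas.

    One headgroup of volume V_head per leaflet occupies each area A of the
    head slab: φ_h = 1 − V_head/(d_head·A). Values outside [0, 1] signal
    inconsistent volumes; they are reported unclamped (the caller decides how
    to penalize).
    """
    if d_head <= 0:
        raise ValueError("d_head must be > 0")
    if area <= 0:
        raise ValueError("area must be > 0")
    return 1.0 - v_head / (d_head * area)


@dataclass
class ParamSpec:
    """One model parameter: value, bounds and whether it is optimized."""

    value: float
    lo: float = -math.inf
    hi: float = math.inf
    vary: bool = True

    def __post_init__(self) -> None:
        if self.vary and not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("varied parameters need finite bounds")
        if not self.lo <= self.value <= self.hi:
            raise ValueError(
                f"value {self.value} outside bounds [{self.lo}, {self.hi}]"
            )


class BilayerModel:
    """Common machinery: parameter table, substrate, per-contrast stacks.

    Subclasses define ``PARAM_NAMES`` and ``build(values, contrast)``.
    Structural parameters are shared across contrasts by construction — the
    same value dict feeds every contrast's stack.
    """

    PARAM_NAMES: tuple[str, ...] = ()

    def __init__(
        self,
        params: Mapping[str, ParamSpec],
        *,
        sio2_thickness: float = 12.0,
        sio2_roughness: float = 3.0,
        sio2_solvent: float = 0.0,
        background: float = 0.0,
    ) -> None:
        missing = set(self.PARAM_NAMES) - set(params)
        extra = set(params) - set(self.PARAM_NAMES)
        if missing or extra:
            raise ValueError(
                f"parameter table mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        self.params: dict[str, ParamSpec] = {
            name: params[name] for name in self.PARAM_NAMES
        }
        self.sio2_thickness = sio2_thickness
        self.sio2_roughness = sio2_roughness
        self.sio2_solvent = sio2_solvent
        self.background = background

    # -- parameter-vector plumbing -------------------------------------------
    def free_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.vary]

    def init_values(self) -> dict[str, float]:
        return {n: p.value for n, p in self.params.items()}

    def bounds(self) -> tuple[list[float], list[float]]:
        free = self.free_names()
        return (
            [self.params[n].lo for n in free],
            [self.params[n].hi for n in free],
        )

    def values_from_vector(self, x: Sequence[float]) -> dict[str, float]:
        values = self.init_values()
        for name, v in zip(self.free_names(), x, strict=True):
            values[name] = float(v)
        return values

    def _sio2(self) -> Slab:
        return Slab(
            self.sio2_thickness,
            SIO2_SLD,
            self.sio2_solvent,
            self.sio2_roughness,
            name="SiO2",
        )

    # -- hooks ----------------------------------------------------------------
    def build(self, values: Mapping[str, float], contrast: ContrastSpec) -> SlabStack:
        raise NotImplementedError

    def derived(self, values: Mapping[str, float]) -> dict[str, float]:
        return {}

    def constraint_violation(self, values: Mapping[str, float]) -> float:
        """Magnitude by which derived quantities leave their physical range."""
        return 0.0


class ThreeLayerBilayer(BilayerModel):
    """Symmetric head | tail | head bilayer over an oxide-bound water gap.

    The head solvent fraction is never fitted: it is derived from the equal
    area-per-molecule constraint. The headgroup SLD interpolates between its
    H₂O and D₂O endpoints with the solvent D₂O fraction (labile-proton
    exchange); a global additive offset on each region's SLD (bounded) absorbs
    the uncertainty of the composition calculation.
    """

    PARAM_NAMES = (
        "d_water",
        "d_head",
        "d_tail",
        "phi_tail",
        "roughness",
        "head_sld_offset",
        "tail_sld_offset",
    )

    def __init__(
        self,
        params: Mapping[str, ParamSpec],
        *,
        head_sld_h2o: float,
        head_sld_d2o: float,
        tail_sld: float,
        v_head: float = POPC_HEAD_VOLUME,
        v_tails: float = POPC_TAILS_VOLUME,
        **kw,
    ) -> None:
        super().__init__(params, **kw)
        self.head_sld_h2o = head_sld_h2o
        self.head_sld_d2o = head_sld_d2o
        self.tail_sld = tail_sld
        self.v_head = v_head
        self.v_tails = v_tails

    def derived(self, values: Mapping[str, float]) -> dict[str, float]:
        area = area_per_molecule(values["d_tail"], values["phi_tail"], self.v_tails)
        phi_head = coupled_head_solvent(values["d_head"], area, self.v_head)
        return {
            "area_per_molecule": area,
            "phi_head": phi_head,
            "total_thickness": 2.0 * values["d_head"] + values["d_tail"],
        }

    def constraint_violation(self, values: Mapping[str, float]) -> float:
        phi_head = self.derived(values)["phi_head"]
        return max(0.0, -phi_head) + max(0.0, phi_head - 1.0)

    def build(self, values: Mapping[str, float], contrast: ContrastSpec) -> SlabStack:
        der = self.derived(values)
        phi_head = der["phi_head"]
        if not 0.0 <= phi_head <= 1.0:
            warnings.warn(
                "area coupling puts the head solvent fraction outside [0, 1]; "
                "clamped for stack construction (check fragment volumes)",
                stacklevel=2,
            )
            phi_head = min(1.0, max(0.0, phi_head))
        sigma = values["roughness"]
        head_sld = (
            exchanged_sld(self.head_sld_h2o, self.head_sld_d2o, contrast.d2o_fraction)
            + values["head_sld_offset"]
        )
        tail_sld = self.tail_sld + values["tail_sld_offset"]
        head = Slab(values["d_head"], head_sld, phi_head, sigma, name="head")
        slabs = (
            self._sio2(),
            Slab(values["d_water"], 0.0, 1.0, sigma, name="water"),
            head,
            Slab(values["d_tail"], tail_sld, values["phi_tail"], sigma, name="tail"),
            replace(head),  # symmetric copy
        )
        return SlabStack(slabs, backing_roughness=sigma)


class OneLayerVesicleBilayer(BilayerModel):
    """Single-slab bilayer with an optional sparse co-adsorbed vesicle layer.

    The vesicle layer is two extra slabs — a pure-water gap and a dilute
    bilayer whose thickness and SLD are tied to the supported bilayer's, with
    solvent fraction 1 − coverage. It can be active in a subset of contrasts
    (vesicles may be rinsed away by a solvent exchange).
    """

    PARAM_NAMES = (
        "d_water",
        "d_bilayer",
        "phi_bilayer",
        "roughness",
        "sld_offset",
        "d_vesicle_gap",
        "coverage",
    )

    def __init__(
        self,
        params: Mapping[str, ParamSpec],
        *,
        bilayer_sld: float,
        vesicle_contrasts: Iterable[float] | None = (),
        vesicle_roughness: float = 10.0,
        **kw,
    ) -> None:
        super().__init__(params, **kw)
        self.bilayer_sld = bilayer_sld
        # None = vesicles in every contrast; () = never; else: the D2O
        # fractions of the contrasts where the vesicle layer is present.
        self.vesicle_contrasts = (
            None if vesicle_contrasts is None else tuple(vesicle_contrasts)
        )
        self.vesicle_roughness = vesicle_roughness

    def vesicles_active(self, contrast: ContrastSpec) -> bool:
        if self.vesicle_contrasts is None:
            return True
        return any(
            abs(contrast.d2o_fraction - f) < 1e-6 for f in self.vesicle_contrasts
        )

    def derived(self, values: Mapping[str, float]) -> dict[str, float]:
        return {"coverage_percent": 100.0 * values["coverage"]}

    def build(self, values: Mapping[str, float], contrast: ContrastSpec) -> SlabStack:
        sigma = values["roughness"]
        sld = self.bilayer_sld + values["sld_offset"]
        slabs = [
            self._sio2(),
            Slab(values["d_water"], 0.0, 1.0, sigma, name="water"),
            Slab(
                values["d_bilayer"], sld, values["phi_bilayer"], sigma, name="bilayer"
            ),
        ]
        backing_sigma = sigma
        if self.vesicles_active(contrast) and values["coverage"] > 0.0:
            # the gap's lower interface is the SLB's own top surface, so it
            # keeps the SLB roughness; this also makes R continuous as the
            # vesicle coverage goes to zero
            slabs.append(
                Slab(
                    values["d_vesicle_gap"],
                    0.0,
                    1.0,
                    sigma,
                    name="vesicle_water",
                )
            )
            slabs.append(
                Slab(
                    values["d_bilayer"],
                    sld,
                    1.0 - values["coverage"],
                    self.vesicle_roughness,
                    name="vesicle_bilayer",
                )
            )
            backing_sigma = self.vesicle_roughness
        return SlabStack(tuple(slabs), backing_roughness=backing_sigma)
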