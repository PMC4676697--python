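"""Coherent scattering-length densities of lipid fragments, solvents and mixtures.

Neutron contrast in a slab model is carried entirely by the scattering length
density (SLD), the sum of coherent scattering lengths per molecular volume.
This module computes SLDs for molecular fragments (lipid headgroups, acyl-chain
regions, water isotopologues), handles H/D substitution for per-deuterated
extracts, models the exchange of labile headgroup protons with the solvent,
and forms composition-weighted SLDs for the head and tail regions of a mixed
bilayer (e.g. an E. coli extract of PE, PG and cardiolipin).

Units: scattering lengths in fm, volumes in Å³, SLDs in 1e-6 Å⁻².
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "COHERENT_B",
    "WATER_VOLUME",
    "MolecularFragment",
    "LipidComposition",
    "ContrastSpec",
    "parse_formula",
    "fragment_scattering_length",
    "fragment_sld",
    "water_sld",
    "exchanged_sld",
    "mixture_region_slds",
    "load_fragment_library",
    "H2O_SLD",
    "D2O_SLD",
]

# Bound coherent scattering lengths, fm (standard neutron tabulation).
COHERENT_B: dict[str, float] = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
}

#: Molecular volume of water, Å³; used for both isotopologues.
WATER_VOLUME = 30.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula such as ``'C9H14NO8P'`` into element counts.

    ``D`` is treated as a distinct element symbol (deuterium).
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class MolecularFragment:
    """A molecular moiety with a formula, a partial volume and labile protons.

    ``n_exchangeable`` counts hydrogens that equilibrate with solvent H/D
    (hydroxyl, amine); they follow the solvent isotope ratio rather than the
    synthesis isotope.
    """

    name: str
    formula: Mapping[str, int]
    volume: float
    n_exchangeable: int = 0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"fragment {self.name!r}: volume must be > 0")
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"fragment {self.name!r}: negative element count")
        n_hd = self.formula.get("H", 0) + self.formula.get("D", 0)
        if not 0 <= self.n_exchangeable <= n_hd:
            raise ValueError(
                f"fragment {self.name!r}: n_exchangeable={self.n_exchangeable} "
                f"exceeds H+D count {n_hd}"
            )

    def perdeuterated(self) -> "MolecularFragment":
        """Swap all non-labile H for D (biosynthetic per-deuteration)."""
        f = dict(self.formula)
        n_h = f.get("H", 0)
        keep_h = min(self.n_exchangeable, n_h)
        swapped = n_h - keep_h
        if swapped:
            f["H"] = keep_h
            f["D"] = f.get("D", 0) + swapped
            if f["H"] == 0:
                del f["H"]
        return replace(self, formula=f, name=self.name + "_d")


def fragment_scattering_length(fragment: MolecularFragment) -> float:
    """Total coherent scattering length of a fragment, fm (exact Σ nᵢ·bᵢ)."""
    total = 0.0
    for sym, n in fragment.formula.items():
        try:
            b = COHERENT_B[sym]
        except KeyError:
            raise KeyError(
                f"no coherent scattering length tabulated for element {sym!r}"
            ) from None
        total += n * b
    return total


def fragment_sld(fragment: MolecularFragment) -> float:
    """SLD of a fragment in 1e-6 Å⁻²: Σb / V, with b in fm and V in Å³.

    1 fm/Å³ = 1e-5 Å⁻² = 10 × 1e-6 Å⁻², hence the factor 10.
    """
    return 10.0 * fragment_scattering_length(fragment) / fragment.volume


_H2O = MolecularFragment("H2O", {"H": 2, "O": 1}, WATER_VOLUME, 2)
_D2O = MolecularFragment("D2O", {"D": 2, "O": 1}, WATER_VOLUME, 2)

#: SLDs of the pure water endpoints, 1e-6 Å⁻².
H2O_SLD = fragment_sld(_H2O)
D2O_SLD = fragment_sld(_D2O)


def water_sld(d2o_fraction: float) -> float:
    """SLD of an H2O/D2O mixture, linear in the D2O volume fraction."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    return (1.0 - d2o_fraction) * H2O_SLD + d2o_fraction * D2O_SLD


def exchanged_sld(sld_h2o: float, sld_d2o: float, d2o_fraction: float) -> float:
    """Interpolate a labile-proton-bearing fragment's SLD between its solvent
    endpoints.

    Headgroups exchange protons with the solvent, so their SLD is a linear
    function of the solvent D2O fraction between the pure-H2O and pure-D2O
    values.
    """
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    for v in (sld_h2o, sld_d2o):
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("SLD endpoints must be finite")
    return (1.0 - d2o_fraction) * sld_h2o + d2o_fraction * sld_d2o


@dataclass(frozen=True)
class ContrastSpec:
    """One measurement solvent: D2O volume fraction plus instrument resolution."""

    d2o_fraction: float
    dq_over_q: float = 0.08
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("d2o_fraction must be in [0, 1]")
        if self.dq_over_q <= 0:
            raise ValueError("dq_over_q must be > 0")
        if not self.name:
            object.__setattr__(self, "name", f"{100 * self.d2o_fraction:g}pct_D2O")

    @property
    def water_sld(self) -> float:
        return water_sld(self.d2o_fraction)


@dataclass(frozen=True)
class LipidComposition:
    """Mole fractions of the three main E. coli phospholipid classes.

    ``deuterated`` marks a per-deuterated extract (all non-labile H → D).
    """

    x_pe: float
    x_pg: float
    x_cl: float
    deuterated: bool = False

    def __post_init__(self) -> None:
        for x in (self.x_pe, self.x_pg, self.x_cl):
            if not 0.0 <= x <= 1.0:
                raise ValueError("mole fractions must be in [0, 1]")
        if abs(self.x_pe + self.x_pg + self.x_cl - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"PE": self.x_pe, "PG": self.x_pg, "CL": self.x_cl}


#: Default E. coli extract composition (same for hydrogenated and deuterated).
ECOLI_COMPOSITION = dict(x_pe=0.75, x_pg=0.13, x_cl=0.12)


def _exchanged_b(fragment: MolecularFragment, d2o_fraction: float) -> float:
    """Scattering length with labile H carrying the solvent's D fraction."""
    b = fragment_scattering_length(fragment)
    # Labile positions are H in a hydrogenated fragment (perdeuteration keeps
    # them as H); replace the solvent-equilibrated share by D.
    return b + fragment.n_exchangeable * d2o_fraction * (
        COHERENT_B["D"] - COHERENT_B["H"]
    )


def mixture_region_slds(
    composition: LipidComposition,
    fragments: Mapping[str, tuple[MolecularFragment, MolecularFragment]],
    contrast: ContrastSpec,
) -> tuple[float, float]:
    """Composition-weighted (head, tail) SLDs of a mixed bilayer at a contrast.

    Parameters
    ----------
    composition
        Class mole fractions; cardiolipin counts as one molecule (four chains,
        double headgroup).
    fragments
        Mapping class name -> (head fragment, tail fragment). Tail fragments
        must carry the chains of one molecule of that class (four for CL).
    contrast
        Solvent; labile headgroup hydrogens follow its H/D ratio. Tails do
        not exchange.

    Returns
    -------
    (head_sld, tail_sld) in 1e-6 Å⁻², each Σxᵢbᵢ / ΣxᵢVᵢ.
    """
    b_head = v_head = b_tail = v_tail = 0.0
    for cls, x in composition.as_dict().items():
        if x == 0.0:
            continue
        if cls not in fragments:
            raise KeyError(f"no fragments supplied for lipid class {cls!r}")
        head, tail = fragments[cls]
        if composition.deuterated:
            head, tail = head.perdeuterated(), tail.perdeuterated()
        b_head += x * _exchanged_b(head, contrast.d2o_fraction)
        v_head += x * head.volume
        b_tail += x * fragment_scattering_length(tail)
        v_tail += x * tail.volume
    return 10.0 * b_head / v_head, 10.0 * b_tail / v_tail


def load_fragment_library(
    path: str | None = None,
) -> dict[str, MolecularFragment]:
    """Load the fragment library (name, formula, volume Å³, n_exchangeable).

    The bundled library covers the PE/PG/CL head and tail fragments of an
    E. coli extract with predominantly 16:0/18:1 chains, plus the water
    isotopologues. Plain TSV so users can add lipid classes without touching
    code; '#' starts a comment.
    """
    if path is None:
        text = (
            resources.files("slbnr").joinpath("data/fragments.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    lib: dict[str, MolecularFragment] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"fragment library line {lineno}: expected 4 fields")
        name, formula, vol, nex = parts
        lib[name] = MolecularFragment(
            name, parse_formula(formula), float(vol), int(nex)
        )
    return lib


def ecoli_fragments(
    library: Mapping[str, MolecularFragment] | None = None,
) -> dict[str, tuple[MolecularFragment, MolecularFragment]]:
    """Head/tail fragment pairs for the PE/PG/CL classes from a library."""
    lib = dict(library) if library is not None else load_fragment_library()
    return {
        cls: (lib[f"{cls}_head"], lib[f"{cls}_tails"]) for cls in ("PE", "PG", "CL")
    }
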