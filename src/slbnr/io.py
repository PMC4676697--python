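"""Reflectivity-file and run-configuration I/O.

Data files are plain multi-column text — Q [Å⁻¹], R, optionally dR and dQ —
with '#' comments, so both bare columns and ORSO-style headered files load.
Run configurations are YAML; they are schema-checked before any computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .models import (
    BilayerModel,
    OneLayerVesicleBilayer,
    ParamSpec,
    ThreeLayerBilayer,
)
from .reflectivity import ReflectivityCurve
from .scattering import (
    ContrastSpec,
    LipidComposition,
    ecoli_fragments,
    mixture_region_slds,
)
from .simulate import InstrumentSpec

__all__ = [
    "ParseError",
    "ConfigError",
    "read_reflectivity",
    "write_reflectivity",
    "RunConfig",
    "load_config",
    "model_from_config",
    "write_fit_artifact",
    "read_fit_artifact",
]


class ParseError(ValueError):
    """A reflectivity file could not be parsed; carries the line number."""


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


def read_reflectivity(path: str | Path) -> ReflectivityCurve:
    """Read a 2–4 column text reflectivity file (Q, R[, dR[, dQ]]).

    Whitespace- or comma-delimited; '#' starts a comment (ORSO-style headers
    are comments). Rows are sorted by Q; duplicate or non-positive Q and
    non-numeric rows raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    lines: list[int] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric row: {raw.strip()!r}"
                ) from None
            if len(vals) < 2:
                raise ParseError(f"{path}:{lineno}: need at least 2 columns (Q, R)")
            if ncols is None:
                ncols = min(len(vals), 4)
            if len(vals) < ncols:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(vals)}"
                )
            if vals[0] <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive Q {vals[0]}")
            rows.append(vals[:ncols])
            lines.append(lineno)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows)
    q = arr[:, 0]
    if q.max() > 2.0:
        raise ParseError(
            f"{path}: Q_max = {q.max():g} Å⁻¹ is implausibly large — are the "
            "Q values in nm⁻¹? This reader expects Å⁻¹."
        )
    # duplicate Q check before sorting, so the reported line is meaningful
    seen: dict[float, int] = {}
    for val, lineno in zip(q, lines):
        if val in seen:
            raise ParseError(
                f"{path}:{lineno}: duplicate Q {val:g} (first at line {seen[val]})"
            )
        seen[val] = lineno
    order = np.argsort(q)
    arr = arr[order]
    return ReflectivityCurve(
        arr[:, 0],
        arr[:, 1],
        arr[:, 2] if arr.shape[1] > 2 else None,
        arr[:, 3] if arr.shape[1] > 3 else None,
    )


def write_reflectivity(
    path: str | Path, curve: ReflectivityCurve, header: str = ""
) -> None:
    """Write a curve as multi-column text at 8 significant digits."""
    path = Path(path)
    cols = [curve.q, curve.r]
    names = ["Q [1/A]", "R"]
    if curve.dr is not None:
        cols.append(curve.dr)
        names.append("dR")
        if curve.dq is not None:
            cols.append(curve.dq)
            names.append("dQ [1/A]")
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# " + "  ".join(names) + "\n")
        for row in zip(*cols):
            fh.write("  ".join(f"{v:.8g}" for v in row) + "\n")


# --------------------------------------------------------------------------
# Run configuration


_MODEL_KINDS = ("three_layer", "one_layer_vesicles")

_DEFAULT_BOUNDS = {
    "d_water": (2.0, 20.0),
    "d_head": (4.0, 12.0),
    "d_tail": (20.0, 35.0),
    "phi_tail": (0.0, 0.4),
    "roughness": (1.0, 15.0),
    "head_sld_offset": (-0.5, 0.5),
    "tail_sld_offset": (-0.5, 0.5),
    "d_bilayer": (30.0, 50.0),
    "phi_bilayer": (0.0, 0.3),
    "sld_offset": (-0.5, 0.5),
    "d_vesicle_gap": (5.0, 30.0),
    "coverage": (0.0, 0.2),
}


@dataclass
class RunConfig:
    """Validated run configuration (model, parameters, contrasts, instrument)."""

    model: str
    parameters: dict[str, ParamSpec]
    contrasts: tuple[ContrastSpec, ...]
    instrument: InstrumentSpec
    composition: LipidComposition
    sld_anchors: dict[str, float]
    vesicle_contrasts: tuple[float, ...] | None
    seed: int
    background: float
    n_starts: int
    jitter: float
    raw: dict


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    path = Path(path)
    _require(path.exists(), f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    _require(isinstance(raw, dict), "config must be a YAML mapping")

    model = raw.get("model", "three_layer")
    _require(model in _MODEL_KINDS, f"model must be one of {_MODEL_KINDS}")

    comp_raw = raw.get("composition", {"PE": 0.75, "PG": 0.13, "CL": 0.12})
    deut = bool(comp_raw.pop("deuterated", model == "one_layer_vesicles"))
    try:
        composition = LipidComposition(
            comp_raw.get("PE", 0.0),
            comp_raw.get("PG", 0.0),
            comp_raw.get("CL", 0.0),
            deuterated=deut,
        )
    except ValueError as exc:
        raise ConfigError(f"composition: {exc}") from None

    inst_raw = dict(raw.get("instrument", {}))
    noise_rel = float(inst_raw.pop("noise_rel", 0.03))
    background_inst = float(inst_raw.pop("background", 1e-7))
    try:
        instrument = InstrumentSpec(
            noise_rel=noise_rel, background=background_inst, **inst_raw
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"instrument: {exc}") from None

    fractions = raw.get("contrasts", [0.0, 0.4, 0.6, 1.0])
    _require(
        isinstance(fractions, list) and len(fractions) >= 1,
        "contrasts must be a non-empty list of D2O fractions",
    )
    try:
        contrasts = tuple(
            ContrastSpec(float(f), instrument.dq_over_q) for f in fractions
        )
    except ValueError as exc:
        raise ConfigError(f"contrasts: {exc}") from None

    params: dict[str, ParamSpec] = {}
    for name, entry in (raw.get("parameters") or {}).items():
        _require(isinstance(entry, dict), f"parameter {name}: expected a mapping")
        _require("init" in entry, f"parameter {name}: missing 'init'")
        vary = bool(entry.get("vary", True))
        dlo, dhi = _DEFAULT_BOUNDS.get(name, (-np.inf, np.inf))
        lo = float(entry.get("min", dlo))
        hi = float(entry.get("max", dhi))
        _require(
            not vary or (np.isfinite(lo) and np.isfinite(hi)),
            f"parameter {name}: varied parameters need finite min/max",
        )
        try:
            params[name] = ParamSpec(float(entry["init"]), lo, hi, vary)
        except ValueError as exc:
            raise ConfigError(f"parameter {name}: {exc}") from None

    ves = raw.get("vesicle_contrasts", [])
    if ves in ("all", None):
        vesicle_contrasts = None
    else:
        _require(isinstance(ves, list), "vesicle_contrasts: list, 'all' or omitted")
        vesicle_contrasts = tuple(float(f) for f in ves)

    anchors = {k: float(v) for k, v in (raw.get("sld_anchors") or {}).items()}
    fit_raw = raw.get("fit", {})
    return RunConfig(
        model=model,
        parameters=params,
        contrasts=contrasts,
        instrument=instrument,
        composition=composition,
        sld_anchors=anchors,
        vesicle_contrasts=vesicle_contrasts,
        seed=int(raw.get("seed", 0)),
        background=float(raw.get("background", background_inst)),
        n_starts=int(fit_raw.get("n_starts", 8)),
        jitter=float(fit_raw.get("jitter", 0.2)),
        raw=raw,
    )


def _calculated_anchors(composition: LipidComposition) -> dict[str, float]:
    """Head/tail SLD anchors from the lipid composition (both water endpoints)."""
    frags = ecoli_fragments()
    head_h2o, tail = mixture_region_slds(composition, frags, ContrastSpec(0.0))
    head_d2o, _ = mixture_region_slds(composition, frags, ContrastSpec(1.0))
    return {
        "head_h2o": head_h2o,
        "head_d2o": head_d2o,
        "tail": tail,
        "bilayer": tail,
    }


def model_from_config(cfg: RunConfig) -> BilayerModel:
    """Instantiate the bilayer model a config describes.

    SLD anchors default to the composition-calculated values; any anchor given
    explicitly in the config overrides the calculation.
    """
    anchors = {**_calculated_anchors(cfg.composition), **cfg.sld_anchors}
    defaults = {
        "three_layer": {
            "d_water": 8.0,
            "d_head": 7.0,
            "d_tail": 27.0,
            "phi_tail": 0.12,
            "roughness": 4.0,
            "head_sld_offset": 0.0,
            "tail_sld_offset": 0.0,
        },
        "one_layer_vesicles": {
            "d_water": 9.0,
            "d_bilayer": 41.0,
            "phi_bilayer": 0.06,
            "roughness": 7.0,
            "sld_offset": 0.0,
            "d_vesicle_gap": 14.0,
            "coverage": 0.04,
        },
    }[cfg.model]
    params = {}
    for name, init in defaults.items():
        if name in cfg.parameters:
            params[name] = cfg.parameters[name]
        else:
            lo, hi = _DEFAULT_BOUNDS[name]
            params[name] = ParamSpec(init, lo, hi)
    unknown = set(cfg.parameters) - set(defaults)
    if unknown:
        raise ConfigError(
            f"parameters {sorted(unknown)} do not belong to model {cfg.model!r}"
        )
    if cfg.model == "three_layer":
        return ThreeLayerBilayer(
            params,
            head_sld_h2o=anchors["head_h2o"],
            head_sld_d2o=anchors["head_d2o"],
            tail_sld=anchors["tail"],
            background=cfg.background,
        )
    return OneLayerVesicleBilayer(
        params,
        bilayer_sld=anchors["bilayer"],
        vesicle_contrasts=cfg.vesicle_contrasts,
        background=cfg.background,
    )


# --------------------------------------------------------------------------
# Fit artifacts


def write_fit_artifact(path: str | Path, artifact: Mapping[str, Any]) -> None:
    with open(path, "w") as fh:
        json.dump(artifact, fh, indent=1)
        fh.write("\n")


def read_fit_artifact(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
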