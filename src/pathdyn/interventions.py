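"""Intervention regimes: timed drug doses and model perturbations.

An :class:`Intervention` is a timed discontinuity applied to the simulator
state: a bolus *dose* adds to a drug species' concentration; *set/scale*
kinds overwrite or multiply a species concentration or kinetic constant.
A :class:`Regime` is a named, time-ordered list of interventions — the
convention in differential experiments is an empty "Control" regime versus
an "Experiment" regime carrying doses and mutations (e.g. a 50% reduction of
a phosphatase level standing in for loss-of-function).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import IntegrityError, UnknownTargetError, ValidationError
from .model_io import DrugCatalogue, ReactionNetwork

logger = logging.getLogger(__name__)

SPECIES_KINDS = ("dose", "set_concentration", "scale_concentration")
PARAMETER_KINDS = ("set_parameter", "scale_parameter")
KINDS = SPECIES_KINDS + PARAMETER_KINDS

__all__ = [
    "Intervention",
    "Regime",
    "make_dose",
    "apply_intervention",
    "validate_regime",
    "load_regime",
    "save_regime",
]


@dataclass(frozen=True)
class Intervention:
    """One timed discontinuity.

    ``value`` is nM for dose/set_concentration, a dimensionless factor for
    the scale kinds, and in the parameter's own units for set_parameter.
    ``time`` is in minutes.
    """

    kind: str
    target: str
    value: float
    time: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"unknown intervention kind '{self.kind}'")
        if self.time < 0:
            raise ValidationError(f"intervention time must be >= 0, got {self.time}")
        if self.kind in ("dose", "set_concentration") and self.value < 0:
            raise ValidationError(
                f"{self.kind} value must be >= 0 nM, got {self.value}"
            )
        if self.kind in ("scale_concentration", "scale_parameter") and self.value < 0:
            raise ValidationError(f"scale factor must be >= 0, got {self.value}")


@dataclass
class Regime:
    """A named, time-ordered intervention list ('Control', 'Experiment', ...)."""

    label: str = "Control"
    interventions: list[Intervention] = field(default_factory=list)

    def sorted(self) -> "Regime":
        """Time-sorted copy; ties keep declared order (stable sort)."""
        order = sorted(range(len(self.interventions)), key=lambda i: self.interventions[i].time)
        return Regime(self.label, [self.interventions[i] for i in order])

    @property
    def is_empty(self) -> bool:
        return not self.interventions


def make_dose(
    catalogue: DrugCatalogue,
    drug: str,
    dosage: float | None = None,
    time: float = 0.0,
) -> Intervention:
    """Build a dose intervention from a catalogue entry.

    ``dosage`` (nM) defaults to the catalogue's standard dosage when omitted.
    """
    entry = catalogue.get(drug)  # raises UnknownTargetError
    if dosage is None:
        dosage = entry.default_dosage
    if dosage < 0:
        raise ValidationError(f"dosage must be >= 0 nM, got {dosage}")
    return Intervention(kind="dose", target=entry.target_species, value=dosage, time=time)


def apply_intervention(
    concentrations: np.ndarray,
    parameters: np.ndarray,
    iv: Intervention,
    species_index: dict[str, int],
    parameter_index: dict[str, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one intervention to copies of the state vectors.

    Exactly one entry of exactly one vector changes (locality).  A result
    that would be negative is clipped to 0 with a warning; this cannot occur
    for valid inputs of the defined kinds but guards rounding at 0.
    """
    conc = np.array(concentrations, dtype=float, copy=True)
    pars = np.array(parameters, dtype=float, copy=True)
    if iv.kind in SPECIES_KINDS:
        if iv.target not in species_index:
            raise UnknownTargetError(f"unknown species '{iv.target}'")
        i = species_index[iv.target]
        if iv.kind == "dose":
            conc[i] += iv.value
        elif iv.kind == "set_concentration":
            conc[i] = iv.value
        else:
            conc[i] *= iv.value
        if conc[i] < 0:
            logger.warning(
                "intervention %s on '%s' produced negative concentration %g; clipped to 0",
                iv.kind, iv.target, conc[i],
            )
            conc[i] = 0.0
    else:
        if iv.target not in parameter_index:
            raise UnknownTargetError(f"unknown parameter '{iv.target}'")
        i = parameter_index[iv.target]
        if iv.kind == "set_parameter":
            pars[i] = iv.value
        else:
            pars[i] *= iv.value
    return conc, pars


def validate_regime(regime: Regime, network: ReactionNetwork, t_end: float) -> Regime:
    """Return a time-sorted regime whose targets all exist in ``network``.

    Raises :class:`IntegrityError` for an unknown target and
    :class:`ValidationError` for an intervention scheduled after ``t_end``.
    """
    species = set(network.species_ids)
    params = set(network.parameter_ids)
    for iv in regime.interventions:
        if iv.kind in SPECIES_KINDS and iv.target not in species:
            raise IntegrityError(
                f"regime '{regime.label}': intervention targets unknown species "
                f"'{iv.target}'"
            )
        if iv.kind in PARAMETER_KINDS and iv.target not in params:
            raise IntegrityError(
                f"regime '{regime.label}': intervention targets unknown parameter "
                f"'{iv.target}'"
            )
        if iv.time > t_end:
            raise ValidationError(
                f"regime '{regime.label}': intervention at t={iv.time} min is after "
                f"t_end={t_end} min"
            )
    return regime.sorted()


# ---------------------------------------------------------------------------
# Regime files (YAML; JSON is a YAML subset so both load)
# ---------------------------------------------------------------------------


def load_regime(path: str | os.PathLike, catalogue: DrugCatalogue | None = None) -> Regime:
    """Load a regime file.

    Layout::

        label: Experiment
        interventions:
          - {kind: dose, drug: pertuzumab, value: 30, time: 0}
          - {kind: scale_concentration, target: PTEN, value: 0.5, time: 0}

    A ``drug`` key (instead of ``target``) resolves through ``catalogue``;
    its ``value`` may be omitted to use the catalogue default dosage.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"regime file {path}: expected a mapping at top level")
    regime = Regime(label=str(data.get("label", "Regime")))
    for item in data.get("interventions", []) or []:
        time = float(item.get("time", 0.0))
        if "drug" in item:
            if catalogue is None:
                raise ValidationError(
                    f"regime file {path}: a 'drug' entry requires a drug catalogue"
                )
            value = item.get("value")
            iv = make_dose(catalogue, item["drug"], None if value is None else float(value), time)
            if item.get("kind", "dose") != "dose":
                raise ValidationError("a 'drug' entry must have kind 'dose'")
        else:
            iv = Intervention(
                kind=item["kind"],
                target=item["target"],
                value=float(item["value"]),
                time=time,
            )
        regime.interventions.append(iv)
    return regime


def save_regime(regime: Regime, path: str | os.PathLike) -> str:
    data = {
        "label": regime.label,
        "interventions": [
            {"kind": iv.kind, "target": iv.target, "value": iv.value, "time": iv.time}
            for iv in regime.interventions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return os.fspath(path)
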