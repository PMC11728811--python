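"""Chemical identities, toxicological reference values and unit conversions.

Non-carcinogenic inhalation risk is screened against a reference
concentration (RfC, mg/m³) per chemical and target-organ toxicity.  Where
only an oral reference dose (RfD, mg/kg/day) is published, it is converted
to an equivalent RfC with the conventional occupational defaults of a
70 kg body weight and a 20 m³/day inhalation volume.

Airborne concentrations are handled in ppm (volume) or mg/m³; the two are
related through the molecular weight and the molar volume of an ideal gas,
24.45 L/mol at 25 °C and 1 atm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError, MissingReferenceError

__all__ = [
    "ChemicalSpec",
    "ToxicityGrouping",
    "rfd_to_rfc",
    "convert_concentration",
    "resolve_reference_concentration",
    "default_chemicals",
    "default_groupings",
    "chemicals_from_config",
    "load_chemicals",
    "MOLAR_VOLUME_L_PER_MOL",
    "BODY_WEIGHT_KG",
    "INHALATION_M3_PER_DAY",
    "PPM",
    "MG_M3",
]

#: Molar volume of an ideal gas at 25 °C, 1 atm (L/mol); the standard
#: occupational-hygiene convention for ppm ↔ mg/m³ conversion.
MOLAR_VOLUME_L_PER_MOL = 24.45

#: Default adult body weight (kg) used in the RfD → RfC conversion.
BODY_WEIGHT_KG = 70.0

#: Default daily inhalation volume (m³/day) used in the RfD → RfC conversion.
INHALATION_M3_PER_DAY = 20.0

PPM = "ppm"
MG_M3 = "mg/m3"
_UNIT_ALIASES = {
    "ppm": PPM,
    "mg/m3": MG_M3,
    "mg/m^3": MG_M3,
    "mg/m³": MG_M3,
}


@dataclass(frozen=True)
class ChemicalSpec:
    """Identity and toxicological reference values of one solvent.

    Parameters
    ----------
    name
        Text identifier, e.g. ``"xylene"``.
    molecular_weight
        Molecular weight in g/mol; must be positive.
    rfc_by_toxicity
        Direct reference concentrations (mg/m³) keyed by toxicity label.
    rfd_by_toxicity
        Oral reference doses (mg/kg/day) keyed by toxicity label; used only
        when no direct RfC exists for the label.
    record_count_default
        Number of workplace monitoring records to synthesize by default.
    """

    name: str
    molecular_weight: float
    rfc_by_toxicity: Mapping[str, float] = field(default_factory=dict)
    rfd_by_toxicity: Mapping[str, float] = field(default_factory=dict)
    record_count_default: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("chemical name must be non-empty")
        if not self.molecular_weight > 0:
            raise ConfigurationError(
                f"{self.name}: molecular weight must be positive, got {self.molecular_weight}"
            )
        for label, value in {**self.rfc_by_toxicity, **self.rfd_by_toxicity}.items():
            if not value > 0:
                raise ConfigurationError(
                    f"{self.name}: reference value for {label!r} must be positive, got {value}"
                )
        if self.record_count_default < 0:
            raise ConfigurationError(f"{self.name}: record count must be nonnegative")


@dataclass(frozen=True)
class ToxicityGrouping:
    """A target-organ toxicity group whose member HQs are summed into an HI."""

    group_name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError(f"group {self.group_name!r}: member list is empty")
        if len(set(self.members)) != len(self.members):
            raise ConfigurationError(f"group {self.group_name!r}: duplicate members")


def rfd_to_rfc(
    rfd: float,
    body_weight_kg: float = BODY_WEIGHT_KG,
    inhalation_m3_per_day: float = INHALATION_M3_PER_DAY,
) -> float:
    """Convert an oral reference dose (mg/kg/day) to an inhalation RfC (mg/m³).

    RfC = RfD × body weight / daily inhalation volume, i.e. the airborne
    concentration that delivers the reference dose to a person breathing
    ``inhalation_m3_per_day`` cubic metres per day.
    """
    if rfd < 0:
        raise ConfigurationError(f"RfD must be nonnegative, got {rfd}")
    return rfd * body_weight_kg / inhalation_m3_per_day


def convert_concentration(
    value: float,
    mw: float,
    from_unit: str,
    to_unit: str,
    molar_volume: float = MOLAR_VOLUME_L_PER_MOL,
) -> float:
    """Convert an airborne concentration between ppm and mg/m³.

    mg/m³ = ppm × MW / molar volume (24.45 L/mol at 25 °C, 1 atm).
    Accepts scalars or numpy arrays for ``value``.
    """
    try:
        src = _UNIT_ALIASES[from_unit]
        dst = _UNIT_ALIASES[to_unit]
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown concentration unit {exc.args[0]!r}; expected one of {sorted(set(_UNIT_ALIASES))}"
        ) from None
    if not mw > 0:
        raise ConfigurationError(f"molecular weight must be positive, got {mw}")
    if src == dst:
        return value
    if src == PPM:  # ppm -> mg/m3
        return value * mw / molar_volume
    return value * molar_volume / mw


def resolve_reference_concentration(chem: ChemicalSpec, toxicity: str) -> float:
    """Return the RfC (mg/m³) for a chemical and toxicity label.

    A directly published RfC takes precedence; otherwise the stored RfD is
    converted.  Raises :class:`MissingReferenceError` when neither exists.
    """
    if toxicity in chem.rfc_by_toxicity:
        return chem.rfc_by_toxicity[toxicity]
    if toxicity in chem.rfd_by_toxicity:
        return rfd_to_rfc(chem.rfd_by_toxicity[toxicity])
    raise MissingReferenceError(
        f"no RfC or RfD for chemical {chem.name!r} and toxicity {toxicity!r}"
    )


def default_chemicals() -> tuple[ChemicalSpec, ...]:
    """The packaged six-solvent shipbuilding-paint configuration.

    Molecular weights are textbook constants; reference values follow EPA
    IRIS, with oral RfDs retained for endpoints lacking a direct RfC.
    Record counts are the per-chemical workplace-monitoring sample sizes
    used by the synthetic generator.
    """
    return (
        ChemicalSpec(
            "xylene", 106.17,
            rfc_by_toxicity={"nervous": 0.1},
            rfd_by_toxicity={"other": 0.2},
            record_count_default=952,
        ),
        ChemicalSpec(
            "n-butanol", 74.12,
            rfd_by_toxicity={"nervous": 0.1},
            record_count_default=449,
        ),
        ChemicalSpec(
            "ethylbenzene", 106.17,
            rfc_by_toxicity={"developmental": 1.0},
            rfd_by_toxicity={"hepatic": 0.1, "urinary": 0.1},
            record_count_default=868,
        ),
        ChemicalSpec(
            "isobutyl alcohol", 74.12,
            rfd_by_toxicity={"nervous": 0.3},
            record_count_default=172,
        ),
        ChemicalSpec(
            "toluene", 92.14,
            rfc_by_toxicity={"nervous": 5.0},
            rfd_by_toxicity={"urinary": 0.08},
            record_count_default=427,
        ),
        ChemicalSpec(
            "mibk", 100.16,
            rfc_by_toxicity={"developmental": 3.0},
            record_count_default=290,
        ),
    )


def default_groupings() -> tuple[ToxicityGrouping, ...]:
    """Default target-organ groups: neurotoxic and developmental solvents."""
    return (
        ToxicityGrouping("nervous", ("xylene", "n-butanol", "isobutyl alcohol", "toluene")),
        ToxicityGrouping("developmental", ("mibk", "ethylbenzene")),
    )


def chemicals_from_config(entries: list[dict]) -> tuple[ChemicalSpec, ...]:
    """Build :class:`ChemicalSpec` objects from parsed config entries.

    Each entry is a mapping with keys ``name``, ``mw`` (or
    ``molecular_weight``), optional ``rfc``/``rfd`` maps and ``count``.
    """
    chems = []
    for entry in entries:
        if "name" not in entry:
            raise ConfigurationError(f"chemical entry missing 'name': {entry!r}")
        mw = entry.get("mw", entry.get("molecular_weight"))
        if mw is None:
            raise ConfigurationError(f"chemical {entry['name']!r}: missing molecular weight")
        chems.append(
            ChemicalSpec(
                name=str(entry["name"]),
                molecular_weight=float(mw),
                rfc_by_toxicity={k: float(v) for k, v in (entry.get("rfc") or {}).items()},
                rfd_by_toxicity={k: float(v) for k, v in (entry.get("rfd") or {}).items()},
                record_count_default=int(entry.get("count", 0)),
            )
        )
    return tuple(chems)


def load_chemicals(path) -> tuple[ChemicalSpec, ...]:
    """Load a YAML/JSON chemical list (a list of entries, or under ``chemicals:``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("chemicals", [])
    if not isinstance(doc, list):
        raise ConfigurationError(f"{path}: expected a list of chemical entries")
    return chemicals_from_config(doc)
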