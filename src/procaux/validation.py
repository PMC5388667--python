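"""Structural validation of RInChI + ProcAuxInfo records.

Every rule the ProcAuxInfo standard states is enforced here and reported
as a :class:`Violation` with a stable code, an ``error`` or ``warning``
severity and a field location.  Findings are returned, never thrown, and
always in deterministic order.

Severity policy: rules whose breach makes the record unusable (length
mismatches, unresolvable references, out-of-range fractions) are errors;
rules that real published data are known to break — an unbalanced
reported equation, non-monotone conversion data, immobilised catalyst
masses alongside a flow volume — are warnings, because the layer is a
faithful repository for published data, not a gatekeeper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

from .chem_core import AtomicWeightTable, FormulaError, formula_of_inchi
from .procaux_codec import (
    Group3AmountEntry,
    ProcAuxInfoRecord,
    parse_procauxinfo,
    serialize_procauxinfo,
    split_document,
)
from .rinchi_codec import RInChIError, RInChIRecord, parse_rinchi, serialize_rinchi

__all__ = [
    "Violation",
    "ProcessedReaction",
    "MassBalanceReport",
    "validate",
    "check_mass_balance",
    "VIOLATION_CODES",
]

#: Registry of every violation code the validator can emit.
VIOLATION_CODES: Dict[str, str] = {
    "E_STOICH_LEN": "stoichiometry list length does not match its group size",
    "E_AMOUNT_LEN": "amount list length does not match its group size",
    "E_YIELD_LEN": "yields list length does not match the product-side group size",
    "E_STOICH_POS": "stoichiometric coefficient is not a positive integer",
    "E_RANGE": "yield, conversion, time or amount outside its permitted range",
    "E_DUP_FORWARD": "duplicate marker points forward or at itself in document order",
    "E_DUP_TARGET": "duplicate marker target is absent, missing or itself a marker",
    "E_G3_FLAGS": "group-3 amount lacks its unit or mode flag",
    "E_SM_REF": "starting-material reference cannot be resolved",
    "E_VERSION": "version does not have exactly one decimal point",
    "E_FORMULA": "species formula layer cannot be parsed",
    "W_MODE_CONFLICT": "amount mode flags conflict with the reactor-volume field",
    "W_CONVERSION_ORDER": "conversions are not non-decreasing in time",
    "W_MASS_BALANCE": "stoichiometric equation is not elementally balanced",
}


@dataclass(frozen=True)
class Violation:
    code: str
    severity: str          # "error" | "warning"
    location: str          # e.g. "conditions[0].amounts3[2]"
    message: str

    def __post_init__(self) -> None:
        if self.code not in VIOLATION_CODES:
            raise ValueError(f"unknown violation code {self.code!r}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"unknown severity {self.severity!r}")

    def __str__(self) -> str:
        return f"{self.severity.upper()} {self.code} at {self.location}: {self.message}"


@dataclass(frozen=True)
class ProcessedReaction:
    """One canonical RInChI plus one ProcAuxInfo record per condition set."""

    rinchi: RInChIRecord
    conditions: Tuple[ProcAuxInfoRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @classmethod
    def from_string(cls, text: str) -> "ProcessedReaction":
        rinchi_text, procaux_text = split_document(text.strip())
        if not rinchi_text:
            raise RInChIError("document holds a bare ProcAuxInfo with no RInChI")
        return cls(
            rinchi=parse_rinchi(rinchi_text),
            conditions=tuple(parse_procauxinfo(procaux_text)),
        )

    def to_string(self) -> str:
        if not self.rinchi.is_canonical():
            raise RInChIError(
                "ProcessedReaction must hold a canonical RInChI: ProcAuxInfo "
                "fields are indexed against the sorted group order "
                "(assemble records with procaux.fixtures.assemble)"
            )
        return serialize_rinchi(self.rinchi) + serialize_procauxinfo(self.conditions)


@dataclass(frozen=True)
class MassBalanceReport:
    """Per-element residuals: reactant-side minus product-side atom counts."""

    residuals: Dict[str, int]
    unparseable: Tuple[Tuple[str, str], ...] = ()   # (location, message)

    @property
    def balanced(self) -> bool:
        return not self.unparseable and all(v == 0 for v in self.residuals.values())


def check_mass_balance(
    rinchi: RInChIRecord,
    stoich1: Sequence[Union[int, None]],
    stoich2: Sequence[Union[int, None]],
    table: Union[AtomicWeightTable, None] = None,
) -> MassBalanceReport:
    """Elemental balance of the stoichiometric equation.

    Species with a "?" coefficient are excluded; a species whose formula
    layer cannot be parsed is reported individually and does not poison
    the rest of the ledger.
    """
    residuals: Dict[str, int] = {}
    problems: List[Tuple[str, str]] = []
    reactant_group = rinchi.reactant_group
    for group_no, coeffs in ((1, stoich1), (2, stoich2)):
        bodies = rinchi.group(group_no)
        sign = 1 if group_no == reactant_group else -1
        for idx, (body, nu) in enumerate(zip(bodies, coeffs), start=1):
            if nu is None:
                continue
            try:
                formula = formula_of_inchi(body, table)
            except FormulaError as exc:
                problems.append((f"group{group_no}[{idx}]", str(exc)))
                continue
            for sym, count in formula.counts.items():
                residuals[sym] = residuals.get(sym, 0) + sign * nu * count
    return MassBalanceReport(residuals=residuals, unparseable=tuple(problems))


def _document_position(field_group: int, index: int) -> Tuple[int, int]:
    # Amount fields appear in the order amounts1 | amounts2 | amounts3.
    return (field_group, index)


def _amount_fields(rec: ProcAuxInfoRecord):
    return ((1, rec.amounts1), (2, rec.amounts2), (3, rec.amounts3))


def validate(
    p: ProcessedReaction, table: Union[AtomicWeightTable, None] = None
) -> List[Violation]:
    """All findings for a parsed record; an empty list means valid."""
    out: List[Violation] = []

    def err(code: str, location: str, message: str) -> None:
        out.append(Violation(code, "error", location, message))

    def warn(code: str, location: str, message: str) -> None:
        out.append(Violation(code, "warning", location, message))

    sizes = {g: len(p.rinchi.group(g)) for g in (1, 2, 3)}
    product_group = p.rinchi.product_group

    for ci, rec in enumerate(p.conditions):
        loc = f"conditions[{ci}]"

        if rec.version.count(".") != 1:
            err("E_VERSION", f"{loc}.version", f"version {rec.version!r}")

        if rec.starting_material is not None:
            ref = rec.starting_material
            if ref.index > sizes[ref.group] or sizes[ref.group] == 0:
                err(
                    "E_SM_REF",
                    f"{loc}.starting_material",
                    f"{ref} does not resolve (group {ref.group} has {sizes[ref.group]} species)",
                )

        for gno, coeffs in ((1, rec.stoich1), (2, rec.stoich2)):
            floc = f"{loc}.stoich{gno}"
            if coeffs is None:
                continue
            if len(coeffs) != sizes[gno]:
                err(
                    "E_STOICH_LEN",
                    floc,
                    f"{len(coeffs)} coefficients against {sizes[gno]} species in group {gno}",
                )
            for idx, nu in enumerate(coeffs, start=1):
                if nu is not None and (not isinstance(nu, int) or nu < 1):
                    err("E_STOICH_POS", f"{floc}[{idx}]", f"coefficient {nu!r}")

        if rec.temperature is not None and rec.temperature < 0:
            err("E_RANGE", f"{loc}.temperature", f"{rec.temperature} K below absolute zero")
        if rec.pressure is not None and rec.pressure < 0:
            err("E_RANGE", f"{loc}.pressure", f"negative pressure {rec.pressure}")

        previous = None
        for idx, pair in enumerate(rec.time_conversion, start=1):
            ploc = f"{loc}.time_conversion[{idx}]"
            if not pair.in_range():
                err("E_RANGE", ploc, f"pair {pair.time}:{pair.conversion} out of range")
            previous = pair
        for a, b in zip(rec.time_conversion, rec.time_conversion[1:]):
            if b.time >= a.time and b.conversion < a.conversion:
                warn(
                    "W_CONVERSION_ORDER",
                    f"{loc}.time_conversion",
                    f"conversion falls from {a.conversion} to {b.conversion}",
                )
                break

        if rec.yields is not None:
            floc = f"{loc}.yields"
            if len(rec.yields) != sizes[product_group]:
                err(
                    "E_YIELD_LEN",
                    floc,
                    f"{len(rec.yields)} yields against {sizes[product_group]} "
                    f"species in product group {product_group}",
                )
            for idx, y in enumerate(rec.yields, start=1):
                if y is not None and not 0.0 <= y <= 1.0:
                    err("E_RANGE", f"{floc}[{idx}]", f"yield {y} outside [0, 1]")

        for gno, entries in _amount_fields(rec):
            floc = f"{loc}.amounts{gno}"
            if entries is None:
                continue
            if len(entries) != sizes[gno]:
                err(
                    "E_AMOUNT_LEN",
                    floc,
                    f"{len(entries)} amounts against {sizes[gno]} species in group {gno}",
                )
            for idx, entry in enumerate(entries, start=1):
                eloc = f"{floc}[{idx}]"
                if entry.value is not None and entry.value < 0:
                    err("E_RANGE", eloc, f"negative amount {entry.value}")
                if isinstance(entry, Group3AmountEntry) and entry.value is not None:
                    if entry.unit is None or entry.mode is None:
                        err("E_G3_FLAGS", eloc, "value carries no unit/mode flags")
                if entry.duplicate_of is not None:
                    ref = entry.duplicate_of
                    if _document_position(ref.group, ref.index) >= _document_position(gno, idx):
                        err(
                            "E_DUP_FORWARD",
                            eloc,
                            f"marker x:{ref} does not point strictly backward",
                        )
                    else:
                        target_entries = dict(_amount_fields(rec)).get(ref.group)
                        target = (
                            target_entries[ref.index - 1]
                            if target_entries is not None and ref.index <= len(target_entries)
                            else None
                        )
                        if target is None or target.value is None:
                            err(
                                "E_DUP_TARGET",
                                eloc,
                                f"marker x:{ref} does not land on a value entry",
                            )

        if rec.amounts3 is not None:
            for idx, entry in enumerate(rec.amounts3, start=1):
                if entry.value is None or entry.mode is None:
                    continue
                if rec.is_batch and entry.mode == "f":
                    warn(
                        "W_MODE_CONFLICT",
                        f"{loc}.amounts3[{idx}]",
                        "flowrate entry in a batch record",
                    )
                if isinstance(rec.reactor_volume, float) and entry.mode == "a":
                    warn(
                        "W_MODE_CONFLICT",
                        f"{loc}.amounts3[{idx}]",
                        "absolute amount alongside a flow reactor volume",
                    )

        if (
            rec.stoich1 is not None
            and rec.stoich2 is not None
            and len(rec.stoich1) == sizes[1]
            and len(rec.stoich2) == sizes[2]
            and all(nu is None or (isinstance(nu, int) and nu >= 1) for nu in rec.stoich1 + rec.stoich2)
        ):
            report = check_mass_balance(p.rinchi, rec.stoich1, rec.stoich2, table)
            for floc, message in report.unparseable:
                err("E_FORMULA", f"{loc}.{floc}", message)
            nonzero = {s: r for s, r in report.residuals.items() if r != 0}
            if nonzero and not report.unparseable:
                warn(
                    "W_MASS_BALANCE",
                    f"{loc}.stoichiometry",
                    "element residuals (reactants minus products): "
                    + ", ".join(f"{s}: {r:+d}" for s, r in sorted(nonzero.items())),
                )

    out.sort(key=lambda v: (v.location, v.code))
    return out
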