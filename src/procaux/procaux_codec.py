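"""The ProcAuxInfo wire format: 12 "|"-separated fields behind a "$$" sentinel.

A ProcAuxInfo block appends process data to a RInChI without touching
it — the "$$" sentinel is safe because no RInChI (v0.02/v0.03) contains
a dollar sign.  One block holds one set of operating conditions::

    $$PAI0.01|SM|stoich1|stoich2|T|P|time:conv pairs|yields|
      amounts1|amounts2|amounts3|reactor volume

(wrapped here for readability; the wire form is a single line, and a
reaction studied at several condition sets carries several back-to-back
blocks).  Unknown values are the placeholder "?".  Units are fixed by
the standard: kelvin, pascal, seconds, mole fractions out of one, moles
(or mol/s for flow) for reaction-side feeds, moles-or-grams with
explicit ``:m|g:f|a`` flags for agents, cubic metres (or the literal
``batch``) for the reactor volume.

The emitter writes one canonical dialect — lowercase exponent letter, no
"+" on exponents, shortest mantissa that reproduces the value — while
the parser is liberal (either exponent case, explicit "+", plain
decimals).  ``parse(serialize(records))`` is value-exact, and
``serialize(parse(text))`` is byte-exact on canonical text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

from .rinchi_codec import SpeciesRef

__all__ = [
    "ProcAuxError",
    "BATCH",
    "TimeConversionPair",
    "AmountEntry",
    "Group3AmountEntry",
    "ProcAuxInfoRecord",
    "serialize_procauxinfo",
    "parse_procauxinfo",
    "parse_amount_entry",
    "split_document",
    "format_scientific",
]

SENTINEL = "$$"
N_FIELDS = 12
VERSION_PREFIX = "PAI"
CURRENT_VERSION = "0.01"

#: Reactor-volume marker for batch operation (amounts are then absolute).
BATCH = "batch"


class ProcAuxError(ValueError):
    """Raised for malformed ProcAuxInfo text or unserializable records."""


# ---------------------------------------------------------------------------
# numbers on the wire

def format_scientific(value: float, significant_digits: int) -> str:
    """Scientific notation with an exact number of significant digits.

    Lowercase exponent letter, no "+" and no leading zeros in the
    exponent: ``format_scientific(6.0e6, 1) == "6e6"``.
    """
    if significant_digits < 1:
        raise ProcAuxError(f"significant_digits must be >= 1, got {significant_digits}")
    if not math.isfinite(value) or value < 0:
        raise ProcAuxError(f"ProcAuxInfo quantities are finite and non-negative, got {value!r}")
    mantissa, exp = f"{value:.{significant_digits - 1}e}".split("e")
    return f"{mantissa}e{int(exp)}"


def _shortest_scientific(value: float) -> str:
    """The canonical emission: fewest significant digits that round-trip."""
    for digits in range(1, 18):
        text = format_scientific(value, digits)
        if float(text) == value:
            return text
    return format_scientific(value, 17)  # pragma: no cover


def _plain_decimal(value: float) -> str:
    """Canonical plain-decimal emission for temperatures, yields, conversions."""
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


def _parse_float(text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ProcAuxError(f"malformed number {text!r} in {what}") from None


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class TimeConversionPair:
    """A (residence) time in seconds paired with the conversion reached."""

    time: float
    conversion: float

    def in_range(self) -> bool:
        return self.time >= 0 and 0.0 <= self.conversion <= 1.0


@dataclass(frozen=True)
class AmountEntry:
    """Amount of a reaction-side species: moles fed (mol/s under flow).

    Exactly one of three states: a value, the "?" placeholder, or a
    duplicate marker pointing at the first occurrence of the same
    species elsewhere in the record (so a mass is never counted twice).
    """

    value: Union[float, None] = None
    duplicate_of: Union[SpeciesRef, None] = None

    def __post_init__(self) -> None:
        if self.value is not None and self.duplicate_of is not None:
            raise ProcAuxError("amount entry cannot hold both a value and a duplicate marker")

    @property
    def is_missing(self) -> bool:
        return self.value is None and self.duplicate_of is None

    @property
    def is_duplicate(self) -> bool:
        return self.duplicate_of is not None

    def wire(self) -> str:
        if self.duplicate_of is not None:
            return f"x:{self.duplicate_of}"
        if self.value is None:
            return "?"
        return _shortest_scientific(self.value)


@dataclass(frozen=True)
class Group3AmountEntry:
    """Amount of an agent, with explicit unit (moles|grams) and mode
    (flowrate|absolute) flags — "3:g:a" is three grams immobilised."""

    value: Union[float, None] = None
    unit: Union[str, None] = None   # "m" | "g"
    mode: Union[str, None] = None   # "f" | "a"
    duplicate_of: Union[SpeciesRef, None] = None

    def __post_init__(self) -> None:
        if self.value is not None and self.duplicate_of is not None:
            raise ProcAuxError("amount entry cannot hold both a value and a duplicate marker")
        if self.unit not in (None, "m", "g"):
            raise ProcAuxError(f"unknown unit flag {self.unit!r} (expected 'm' or 'g')")
        if self.mode not in (None, "f", "a"):
            raise ProcAuxError(f"unknown mode flag {self.mode!r} (expected 'f' or 'a')")

    @property
    def is_missing(self) -> bool:
        return self.value is None and self.duplicate_of is None

    @property
    def is_duplicate(self) -> bool:
        return self.duplicate_of is not None

    def wire(self) -> str:
        if self.duplicate_of is not None:
            return f"x:{self.duplicate_of}"
        if self.value is None:
            return "?"
        if self.unit is None or self.mode is None:
            raise ProcAuxError("group-3 amount requires both unit and mode flags")
        return f"{_shortest_scientific(self.value)}:{self.unit}:{self.mode}"


def _as_tuple(seq, missing_when=lambda x: x is None):
    """Tuple-normalize a list field; a list whose every slot is the "?"
    placeholder is indistinguishable on the wire from a wholly-missing
    field, so it is canonicalized to None."""
    if seq is None:
        return None
    t = tuple(seq)
    if not t or all(missing_when(x) for x in t):
        return None
    return t


@dataclass(frozen=True)
class ProcAuxInfoRecord:
    """One condition set: the typed, unit-normalized content of a block.

    Construction is permissive — structurally broken records can be
    represented so the validator has something to report on — but
    :func:`serialize_procauxinfo` refuses to emit a record that fails
    :meth:`check`.
    """

    version: str = CURRENT_VERSION
    starting_material: Union[SpeciesRef, None] = None
    stoich1: Union[Tuple[Union[int, None], ...], None] = None
    stoich2: Union[Tuple[Union[int, None], ...], None] = None
    temperature: Union[float, None] = None          # K
    pressure: Union[float, None] = None             # Pa
    time_conversion: Tuple[TimeConversionPair, ...] = ()
    yields: Union[Tuple[Union[float, None], ...], None] = None
    amounts1: Union[Tuple[AmountEntry, ...], None] = None
    amounts2: Union[Tuple[AmountEntry, ...], None] = None
    amounts3: Union[Tuple[Group3AmountEntry, ...], None] = None
    reactor_volume: Union[float, str, None] = None  # m^3, or BATCH

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoich1", _as_tuple(self.stoich1))
        object.__setattr__(self, "stoich2", _as_tuple(self.stoich2))
        object.__setattr__(self, "time_conversion", tuple(self.time_conversion))
        object.__setattr__(self, "yields", _as_tuple(self.yields))
        for name in ("amounts1", "amounts2", "amounts3"):
            object.__setattr__(
                self, name, _as_tuple(getattr(self, name), lambda e: e.is_missing)
            )
        if isinstance(self.reactor_volume, str) and self.reactor_volume.lower() != BATCH:
            raise ProcAuxError(
                f"reactor volume must be a number, {BATCH!r} or None, got {self.reactor_volume!r}"
            )

    @property
    def is_batch(self) -> bool:
        return isinstance(self.reactor_volume, str)

    def check(self) -> None:
        """Raise :class:`ProcAuxError` on any record-local invariant breach."""
        if self.version.count(".") != 1:
            raise ProcAuxError(f"version {self.version!r} must have exactly one decimal point")
        for pair in self.time_conversion:
            if not pair.in_range():
                raise ProcAuxError(f"time:conversion pair out of range: {pair}")
        if self.yields is not None:
            for y in self.yields:
                if y is not None and not 0.0 <= y <= 1.0:
                    raise ProcAuxError(f"yield {y} outside [0, 1]")
        for coeffs in (self.stoich1, self.stoich2):
            for nu in coeffs or ():
                if nu is not None and (not isinstance(nu, int) or nu < 1):
                    raise ProcAuxError(f"stoichiometric coefficient {nu!r} must be a positive integer")
        for name in ("amounts1", "amounts2", "amounts3"):
            for entry in getattr(self, name) or ():
                if entry.value is not None and entry.value < 0:
                    raise ProcAuxError(f"negative amount in {name}: {entry.value}")
                if isinstance(entry, Group3AmountEntry) and entry.value is not None:
                    if entry.unit is None or entry.mode is None:
                        raise ProcAuxError("group-3 amount requires both unit and mode flags")
        if isinstance(self.reactor_volume, float) and self.reactor_volume < 0:
            raise ProcAuxError(f"negative reactor volume {self.reactor_volume}")


# ---------------------------------------------------------------------------
# serialization

def _emit_list(items, emit_one) -> str:
    if items is None:
        return "?"
    return ";".join(emit_one(x) for x in items)


def serialize_record(rec: ProcAuxInfoRecord) -> str:
    """The 12 "|"-joined fields of one block, without the "$$" sentinel."""
    rec.check()
    fields = [
        VERSION_PREFIX + rec.version,
        str(rec.starting_material) if rec.starting_material is not None else "?",
        _emit_list(rec.stoich1, lambda nu: "?" if nu is None else str(nu)),
        _emit_list(rec.stoich2, lambda nu: "?" if nu is None else str(nu)),
        "?" if rec.temperature is None else _plain_decimal(rec.temperature),
        "?" if rec.pressure is None else _shortest_scientific(rec.pressure),
        _emit_list(
            rec.time_conversion or None,
            lambda p: f"{_shortest_scientific(p.time)}:{_plain_decimal(p.conversion)}",
        ),
        _emit_list(rec.yields, lambda y: "?" if y is None else _plain_decimal(y)),
        _emit_list(rec.amounts1, lambda e: e.wire()),
        _emit_list(rec.amounts2, lambda e: e.wire()),
        _emit_list(rec.amounts3, lambda e: e.wire()),
        _emit_volume(rec.reactor_volume),
    ]
    return "|".join(fields)


def _emit_volume(volume) -> str:
    if volume is None:
        return "?"
    if isinstance(volume, str):
        return BATCH
    return _shortest_scientific(volume)


def serialize_procauxinfo(records: Sequence[ProcAuxInfoRecord]) -> str:
    """Concatenated "$$"-prefixed blocks, one per condition set."""
    return "".join(SENTINEL + serialize_record(r) for r in records)


# ---------------------------------------------------------------------------
# parsing

def split_document(text: str) -> Tuple[str, str]:
    """Split a document line at the first "$$" into (RInChI, ProcAuxInfo).

    Either part may be empty; the sentinel stays with the right part.
    """
    idx = text.find(SENTINEL)
    if idx < 0:
        return text, ""
    return text[:idx], text[idx:]


def parse_amount_entry(text: str, group: int) -> Union[AmountEntry, Group3AmountEntry]:
    """Decode one amount token for the given group (1, 2 or 3).

    Groups 1–2 take bare numbers; group 3 requires ``value:m|g:f|a``;
    "?" is missing and ``x:G:I`` is a duplicate marker in any group.
    """
    t = text.strip()
    cls = Group3AmountEntry if group == 3 else AmountEntry
    if t == "?":
        return cls()
    if t.startswith("x"):
        parts = [p.strip() for p in t.split(":")]
        if len(parts) != 3 or parts[0] != "x" or not parts[1].isdigit() or not parts[2].isdigit():
            raise ProcAuxError(f"malformed duplicate marker {text!r} (expected x:G:I)")
        ref = SpeciesRef(int(parts[1]), int(parts[2]))
        return cls(duplicate_of=ref)
    if group == 3:
        parts = [p.strip() for p in t.split(":")]
        if len(parts) != 3:
            raise ProcAuxError(
                f"group-3 amount {text!r} needs both unit and mode flags (value:m|g:f|a)"
            )
        value = _parse_float(parts[0], "group-3 amount")
        unit, mode = parts[1].lower(), parts[2].lower()
        if unit not in ("m", "g"):
            raise ProcAuxError(f"unknown unit flag {parts[1]!r} in {text!r}")
        if mode not in ("f", "a"):
            raise ProcAuxError(f"unknown mode flag {parts[2]!r} in {text!r}")
        if value < 0:
            raise ProcAuxError(f"negative amount {text!r}")
        return Group3AmountEntry(value=value, unit=unit, mode=mode)
    if ":" in t:
        raise ProcAuxError(f"group-{group} amounts are bare numbers, got {text!r}")
    value = _parse_float(t, f"group-{group} amount")
    if value < 0:
        raise ProcAuxError(f"negative amount {text!r}")
    return AmountEntry(value=value)


def _parse_list(field: str, parse_one):
    if field == "?":
        return None
    return tuple(parse_one(item.strip()) for item in field.split(";"))


def _parse_fraction(text: str, what: str) -> float:
    v = _parse_float(text, what)
    if not 0.0 <= v <= 1.0:
        raise ProcAuxError(f"{what} {text!r} outside [0, 1]")
    return v


def _parse_tc_pair(item: str) -> TimeConversionPair:
    parts = [p.strip() for p in item.split(":")]
    if len(parts) != 2:
        raise ProcAuxError(f"malformed time:conversion pair {item!r}")
    time = _parse_float(parts[0], "time")
    if time < 0:
        raise ProcAuxError(f"negative time {parts[0]!r}")
    return TimeConversionPair(time, _parse_fraction(parts[1], "conversion"))


def parse_record(block: str) -> ProcAuxInfoRecord:
    """Parse one block body (the text between "$$" sentinels)."""
    fields = [f.strip() for f in block.split("|")]
    if len(fields) != N_FIELDS:
        raise ProcAuxError(
            f"ProcAuxInfo block has {len(fields)} fields, expected {N_FIELDS}"
        )
    if not fields[0].startswith(VERSION_PREFIX):
        raise ProcAuxError(f"version field must begin with {VERSION_PREFIX!r}, got {fields[0]!r}")
    version = fields[0][len(VERSION_PREFIX):]
    if version.count(".") != 1:
        raise ProcAuxError(f"version {version!r} must have exactly one decimal point")

    sm = None if fields[1] == "?" else SpeciesRef.from_text(fields[1])

    def parse_coeff(item: str):
        if item == "?":
            return None
        try:
            return int(item)
        except ValueError:
            raise ProcAuxError(f"stoichiometric coefficient {item!r} is not an integer") from None

    stoich1 = _parse_list(fields[2], parse_coeff)
    stoich2 = _parse_list(fields[3], parse_coeff)
    temperature = None if fields[4] == "?" else _parse_float(fields[4], "temperature")
    pressure = None if fields[5] == "?" else _parse_float(fields[5], "pressure")
    tc = _parse_list(fields[6], _parse_tc_pair) or ()
    yields = _parse_list(
        fields[7], lambda y: None if y == "?" else _parse_fraction(y, "yield")
    )
    amounts1 = _parse_list(fields[8], lambda e: parse_amount_entry(e, 1))
    amounts2 = _parse_list(fields[9], lambda e: parse_amount_entry(e, 2))
    amounts3 = _parse_list(fields[10], lambda e: parse_amount_entry(e, 3))
    vol_field = fields[11]
    if vol_field == "?":
        volume: Union[float, str, None] = None
    elif vol_field.lower() == BATCH:
        volume = BATCH
    else:
        volume = _parse_float(vol_field, "reactor volume")

    return ProcAuxInfoRecord(
        version=version,
        starting_material=sm,
        stoich1=stoich1,
        stoich2=stoich2,
        temperature=temperature,
        pressure=pressure,
        time_conversion=tc,
        yields=yields,
        amounts1=amounts1,
        amounts2=amounts2,
        amounts3=amounts3,
        reactor_volume=volume,
    )


def parse_procauxinfo(text: str) -> List[ProcAuxInfoRecord]:
    """Parse zero or more back-to-back "$$"-prefixed blocks."""
    t = text.strip()
    if not t:
        return []
    if not t.startswith(SENTINEL):
        raise ProcAuxError(f"ProcAuxInfo must begin with {SENTINEL!r}")
    return [parse_record(block) for block in t.split(SENTINEL)[1:]]
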