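"""Parsing, canonicalization and serialization of the RInChI container.

A RInChI packs one reaction into a single line::

    RInChI=0.03.1S/group1<>group2<>group3/d+

with the two reaction-side species groups and the agents group
(solvents, catalysts — "above, below or on both sides of the arrow")
holding bare InChI bodies joined by ``//``.  Species within a group are
sorted bytewise, and the two reaction-side groups are themselves ordered
by bytewise comparison of their joined serializations (the Unix-sort
convention); if that swaps the sides, the directionality flag flips so
the chemistry is preserved.  ``d+`` means group1 holds the reactants,
``d-`` means group2 does, ``d=`` marks an equilibrium.

InChI bodies are opaque here: nothing is validated beyond delimiter
safety.  Mass-aware code parses their formula layer via
:mod:`procaux.chem_core` only when it needs to.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import List, Tuple

__all__ = [
    "RInChIError",
    "Direction",
    "SpeciesRef",
    "RInChIRecord",
    "parse_rinchi",
    "serialize_rinchi",
    "canonicalize_rinchi",
    "resolve_species",
]

RINCHI_PREFIX = "RInChI="
GROUP_SEP = "<>"
SPECIES_SEP = "//"
RESERVED = (GROUP_SEP, SPECIES_SEP, "$$")


class RInChIError(ValueError):
    """Raised for malformed RInChI text or invalid records."""


class Direction(str, Enum):
    FORWARD = "forward"      # group1 -> group2, wire token "d+"
    BACKWARD = "backward"    # group2 -> group1, wire token "d-"
    EQUILIBRIUM = "equilibrium"  # wire token "d="
    UNSPECIFIED = "unspecified"  # no directionality layer

    @property
    def token(self) -> str | None:
        return {"forward": "d+", "backward": "d-", "equilibrium": "d="}.get(self.value)

    def flipped(self) -> "Direction":
        if self is Direction.FORWARD:
            return Direction.BACKWARD
        if self is Direction.BACKWARD:
            return Direction.FORWARD
        return self


# "d−" is accepted with a typographic minus as well as the ASCII hyphen.
_DIRECTION_TOKENS = {
    "d+": Direction.FORWARD,
    "d-": Direction.BACKWARD,
    "d−": Direction.BACKWARD,
    "d=": Direction.EQUILIBRIUM,
}

_HEADER = re.compile(r"^RInChI=(\d+\.\d+)\.([^/]+)/(.*)$", re.DOTALL)


@dataclass(frozen=True)
class SpeciesRef:
    """1-based position of a species: group number (1–3) and index within it."""

    group: int
    index: int

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise RInChIError(f"species group must be 1, 2 or 3, got {self.group}")
        if self.index < 1:
            raise RInChIError(f"species index is 1-based, got {self.index}")

    def __str__(self) -> str:
        return f"{self.group}:{self.index}"

    @classmethod
    def from_text(cls, text: str) -> "SpeciesRef":
        parts = text.split(":")
        if len(parts) != 2 or not all(p.strip().isdigit() for p in parts):
            raise RInChIError(f"malformed species reference {text!r} (expected G:I)")
        return cls(int(parts[0]), int(parts[1]))


@dataclass(frozen=True)
class RInChIRecord:
    """Version tags, three ordered groups of bare InChI bodies, directionality."""

    group1: Tuple[str, ...] = ()
    group2: Tuple[str, ...] = ()
    group3: Tuple[str, ...] = ()
    direction: Direction = Direction.UNSPECIFIED
    rinchi_version: str = "0.03"
    inchi_version: str = "1S"

    def __post_init__(self) -> None:
        object.__setattr__(self, "group1", tuple(self.group1))
        object.__setattr__(self, "group2", tuple(self.group2))
        object.__setattr__(self, "group3", tuple(self.group3))
        for body in self.group1 + self.group2 + self.group3:
            for bad in RESERVED:
                if bad in body:
                    raise RInChIError(f"InChI body contains reserved delimiter {bad!r}: {body!r}")
            if not body:
                raise RInChIError("empty InChI body")

    def group(self, number: int) -> Tuple[str, ...]:
        return {1: self.group1, 2: self.group2, 3: self.group3}[number]

    @property
    def reactant_group(self) -> int:
        """Group number holding the reactants (forward assumed if unspecified)."""
        return 2 if self.direction is Direction.BACKWARD else 1

    @property
    def product_group(self) -> int:
        return 1 if self.direction is Direction.BACKWARD else 2

    def is_canonical(self) -> bool:
        return canonicalize_rinchi(self) == self


def parse_rinchi(text: str) -> RInChIRecord:
    """Parse a RInChI line into a record, preserving the given ordering.

    Empty text between delimiters yields an empty group; a trailing
    directionality layer is optional.
    """
    text = text.strip()
    if not text.startswith(RINCHI_PREFIX):
        raise RInChIError(f"missing {RINCHI_PREFIX!r} prefix")
    m = _HEADER.match(text)
    if m is None:
        raise RInChIError("missing or malformed RInChI version header")
    rinchi_version, inchi_version, rest = m.group(1), m.group(2), m.group(3)

    direction = Direction.UNSPECIFIED
    for token, d in _DIRECTION_TOKENS.items():
        if rest.endswith("/" + token):
            direction = d
            rest = rest[: -len(token) - 1]
            break
    else:
        tail = rest.rsplit("/", 1)[-1]
        if re.fullmatch(r"d.?", tail):
            raise RInChIError(f"unknown directionality token {tail!r}")

    raw_groups = [g.strip() for g in rest.split(GROUP_SEP)]
    if len(raw_groups) > 3:
        raise RInChIError(f"RInChI has {len(raw_groups)} groups; at most 3 allowed")
    while len(raw_groups) < 3:
        raw_groups.append("")
    groups: List[Tuple[str, ...]] = []
    for raw in raw_groups:
        if raw == "":
            groups.append(())
        else:
            bodies = tuple(b.strip() for b in raw.split(SPECIES_SEP))
            if any(not b for b in bodies):
                raise RInChIError("empty InChI body between '//' delimiters")
            groups.append(bodies)
    return RInChIRecord(
        group1=groups[0],
        group2=groups[1],
        group3=groups[2],
        direction=direction,
        rinchi_version=rinchi_version,
        inchi_version=inchi_version,
    )


def canonicalize_rinchi(r: RInChIRecord) -> RInChIRecord:
    """Sort species within groups bytewise; order the two reaction-side
    groups bytewise, flipping the direction flag if they swap.  Group 3
    (agents) never participates in the side ordering."""
    g1 = tuple(sorted(r.group1))
    g2 = tuple(sorted(r.group2))
    g3 = tuple(sorted(r.group3))
    direction = r.direction
    if SPECIES_SEP.join(g2) < SPECIES_SEP.join(g1):
        g1, g2 = g2, g1
        direction = direction.flipped()
    return replace(r, group1=g1, group2=g2, group3=g3, direction=direction)


def serialize_rinchi(r: RInChIRecord, canonical: bool = True) -> str:
    """Emit the canonical wire form; round-trips through :func:`parse_rinchi`."""
    rec = canonicalize_rinchi(r) if canonical else r
    body = GROUP_SEP.join(SPECIES_SEP.join(g) for g in (rec.group1, rec.group2, rec.group3))
    out = f"{RINCHI_PREFIX}{rec.rinchi_version}.{rec.inchi_version}/{body}"
    token = rec.direction.token
    if token is not None:
        out += "/" + token
    return out


def resolve_species(r: RInChIRecord, ref: SpeciesRef, prefixed: bool = False) -> str:
    """Return the InChI body at a 1-based (group, index) position.

    With ``prefixed=True`` the body is re-exported as a full
    ``InChI=<version>/<body>`` string.
    """
    group = r.group(ref.group)
    if not 1 <= ref.index <= len(group):
        raise RInChIError(
            f"species index {ref.index} out of range for group {ref.group} "
            f"of size {len(group)}"
        )
    body = group[ref.index - 1]
    if prefixed:
        return f"InChI={r.inchi_version}/{body}"
    return body
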