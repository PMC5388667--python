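"""Molecular formulas and molar masses from InChI formula layers.

The second layer of an InChI is its Hill-notation molecular formula
(e.g. ``C8H13NO2``), possibly dot-separated into components with integer
multipliers for salts and mixtures (``2C2H4O2.Pd``).  Everything in this
package that needs a mass — atom economy, stoichiometric factors,
E-factors — goes through the two primitives here: :func:`parse_formula`
and :func:`molar_mass`.

Only the stoichiometric formula is used.  Isotope, charge and proton
layers of an InChI are deliberately ignored: process-mass bookkeeping on
the scale of an E-factor is insensitive to a proton or an isotope label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "AtomicWeightTable",
    "parse_formula",
    "serialize_formula",
    "formula_of_inchi",
    "molar_mass",
    "load_atomic_weights",
]


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count multiset; the empty map is the identity."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")

    def merge(self, other: "MolecularFormula") -> "MolecularFormula":
        out: Dict[str, int] = dict(self.counts)
        for sym, n in other.counts.items():
            out[sym] = out.get(sym, 0) + n
        return MolecularFormula(out)

    def scaled(self, k: int) -> "MolecularFormula":
        if k < 1:
            raise FormulaError(f"multiplier must be >= 1, got {k}")
        return MolecularFormula({s: n * k for s, n in self.counts.items()})

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))


@dataclass(frozen=True)
class AtomicWeightTable:
    """Element symbol → standard atomic weight in g/mol."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for sym, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"atomic weight for {sym} must be positive, got {w}")

    def __contains__(self, sym: str) -> bool:
        return sym in self.weights

    def __getitem__(self, sym: str) -> float:
        try:
            return self.weights[sym]
        except KeyError:
            raise FormulaError(f"element {sym!r} not in atomic-weight table") from None


def load_atomic_weights(path: str | Path | None = None) -> AtomicWeightTable:
    """Load the bundled weight table, or a user-supplied ``element<TAB>weight`` file."""
    if path is None:
        text = (resources.files("procaux") / "data" / "atomic_weights.tsv").read_text()
    else:
        text = Path(path).read_text()
    weights: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, val = line.split("\t")
        weights[sym] = float(val)
    return AtomicWeightTable(weights)


_DEFAULT_TABLE: AtomicWeightTable | None = None


def default_atomic_weights() -> AtomicWeightTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_atomic_weights()
    return _DEFAULT_TABLE


def _parse_component(text: str, offset: int, table: AtomicWeightTable) -> MolecularFormula:
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise FormulaError(
                f"unexpected character {text[pos]!r} at position {offset + pos} in formula"
            )
        sym, digits = m.group(1), m.group(2)
        # The regex takes the longest (two-letter) symbol reading; correct
        # capitalization makes Hill formulas unambiguous ("Co" vs "CO").
        if sym not in table:
            raise FormulaError(
                f"unknown element symbol {sym!r} at position {offset + pos}"
            )
        pos = m.end()
        if digits:
            n = int(digits)
            if n == 0:
                raise FormulaError(
                    f"zero count for element {sym!r} at position {offset + pos}"
                )
        else:
            n = 1
        counts[sym] = counts.get(sym, 0) + n
    return MolecularFormula(counts)


def parse_formula(text: str, table: AtomicWeightTable | None = None) -> MolecularFormula:
    """Parse a Hill-notation formula, with dot-separated multiplied components.

    >>> parse_formula("C8H13NO2").counts == {"C": 8, "H": 13, "N": 1, "O": 2}
    True
    >>> parse_formula("2C2H4O2.Cu").counts == {"C": 4, "H": 8, "O": 4, "Cu": 1}
    True
    """
    if table is None:
        table = default_atomic_weights()
    if not text:
        raise FormulaError("empty formula")
    total = MolecularFormula({})
    offset = 0
    for component in text.split("."):
        if not component:
            raise FormulaError(f"empty formula component at position {offset}")
        m = re.match(r"(\d+)", component)
        mult = 1
        body = component
        if m:
            mult = int(m.group(1))
            if mult == 0:
                raise FormulaError(f"zero multiplier at position {offset}")
            body = component[m.end():]
            if not body:
                raise FormulaError(f"bare multiplier at position {offset}")
        part = _parse_component(body, offset + (len(component) - len(body)), table)
        total = total.merge(part.scaled(mult))
        offset += len(component) + 1
    return total


def serialize_formula(f: MolecularFormula) -> str:
    """Hill order: C, then H, then the rest alphabetically (all alphabetic if no C)."""
    counts = dict(f.counts)
    symbols = sorted(counts)
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else [])
        ordered += [s for s in symbols if s not in ("C", "H")]
    else:
        ordered = symbols
    return "".join(s + (str(counts[s]) if counts[s] > 1 else "") for s in ordered)


def formula_of_inchi(inchi: str, table: AtomicWeightTable | None = None) -> MolecularFormula:
    """Extract and parse the formula layer of an InChI string or bare body.

    Accepts either a full ``InChI=1S/...`` string or a body whose first
    "/"-delimited segment is the formula layer.
    """
    body = inchi
    if body.startswith("InChI="):
        parts = body.split("/", 1)
        if len(parts) < 2 or not parts[1]:
            raise FormulaError(f"InChI has no formula layer: {inchi!r}")
        body = parts[1]
    layer = body.split("/", 1)[0]
    if not layer:
        raise FormulaError(f"empty formula layer in {inchi!r}")
    return parse_formula(layer, table)


def molar_mass(
    f: MolecularFormula | Mapping[str, int],
    table: AtomicWeightTable | None = None,
) -> float:
    """Σ count × standard atomic weight, in g/mol. Additive over merging."""
    if table is None:
        table = default_atomic_weights()
    counts = f.counts if isinstance(f, MolecularFormula) else f
    return float(sum(n * table[sym] for sym, n in counts.items()))
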