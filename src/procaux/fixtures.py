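"""Worked example reactions, the encode path, and a record generator.

Three published reactions exercise the whole layer end to end:

1. a palladium-catalysed C–H aziridination run in flow (two reactants,
   three products, four agents, acetic acid appearing both as product
   and as auxiliary — the duplicate-marker case),
2. a Ru/Al2O3-catalysed aerobic oxidation of benzyl alcohol in flow
   (the supported catalyst must be stored as two separate species, with
   gram-flagged absolute amounts for the immobilised bed),
3. a Suzuki–Miyaura coupling reported batch-wise with an unbalanced
   equation and several unreported fields (pressure, base amount,
   time:conversion data).

Species InChIs were generated once from their structures and are frozen
as constants; only their formula layers are ever interpreted.  The
:func:`assemble` builder is the single encode path: it canonicalizes
group order, permutes every ProcAuxInfo list to match, places duplicate
markers, and remaps references — hand-building a canonical record is
error-prone enough that nothing else in the package does it.

:func:`random_reaction` draws seeded, structurally valid records (or
records broken in one named way) for property and validator testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .procaux_codec import (
    BATCH,
    AmountEntry,
    Group3AmountEntry,
    ProcAuxInfoRecord,
    TimeConversionPair,
)
from .rinchi_codec import Direction, RInChIRecord, SpeciesRef, canonicalize_rinchi
from .validation import ProcessedReaction

__all__ = [
    "SpeciesRow",
    "ConditionSpec",
    "assemble",
    "species_ref",
    "example1",
    "example2",
    "example3",
    "EXAMPLES",
    "GeneratorConfig",
    "random_reaction",
    "BREAKAGE_CODES",
    "from_table",
    "to_table",
]

# ---------------------------------------------------------------------------
# frozen InChI bodies (without the "InChI=1S/" prefix)

SM_MORPHOLINONE = "C8H15NO2/c1-7(2)5-11-6(10)8(3,4)9-7/h9H,5H2,1-4H3"
DIACETOXYIODOBENZENE = "C10H11IO4/c1-8(12)14-11(15-9(2)13)10-6-4-3-5-7-10/h3-7H,1-2H3"
AZIRIDINE_PRODUCT = "C8H13NO2/c1-7(2)5-11-6(10)8(3)4-9(7)8/h4-5H2,1-3H3"
IODOBENZENE = "C6H5I/c7-6-4-2-1-3-5-6/h1-5H"
ACETIC_ACID = "C2H4O2/c1-2(3)4/h1H3,(H,3,4)"
PD_ACETATE = "2C2H4O2.Pd/c2*1-2(3)4;/h2*1H3,(H,3,4);/q;;+2/p-2"
ACETIC_ANHYDRIDE = "C4H6O3/c1-3(5)7-4(2)6/h1-2H3"
TOLUENE = "C7H8/c1-7-5-3-2-4-6-7/h2-6H,1H3"

BENZYL_ALCOHOL = "C7H8O/c8-6-7-4-2-1-3-5-7/h1-5,8H,6H2"
OXYGEN = "O2/c1-2"
BENZALDEHYDE = "C7H6O/c8-6-7-4-2-1-3-5-7/h1-6H"
WATER = "H2O/h1H2"
RUTHENIUM = "Ru"
ALUMINA = "2Al.3O/q2*+3;3*-2"

PHENYLBORONIC_ACID = "C6H7BO2/c8-7(9)6-4-2-1-3-5-6/h1-5,8-9H"
BROMOTOLUENE = "C7H7Br/c1-6-2-4-7(8)5-3-6/h2-5H,1H3"
PHENYLTOLUENE = "C13H12/c1-11-7-9-13(10-8-11)12-5-3-2-4-6-12/h2-10H,1H3"
#: The source publication never identifies the phosphine ligand
#: structurally (its database lookup prints "unknown"); this body is a
#: synthetic stand-in, tri-tert-butylphosphine.
PHOSPHINE_LIGAND_SYNTHETIC = "C12H27P/c1-10(2,3)13(11(4,5)6)12(7,8)9/h1-9H3"
NMP = "C5H9NO/c1-6-4-2-3-5(6)7/h2-4H2,1H3"
PD_ACAC = "2C5H8O2.Pd/c2*1-4(6)3-5(2)7;/h2*3,6H,1-2H3;/q;;+2/p-2"
SODIUM_CARBONATE = "CH2O3.2Na/c2-1(3)4;;/h(H2,2,3,4);;/q;2*+1/p-2"


# ---------------------------------------------------------------------------
# the encode path

ROLES = ("reactant", "product", "agent")


@dataclass(frozen=True)
class SpeciesRow:
    """One line of the tabular exchange format.

    ``amount`` is moles (mol/s under flow) for reaction-side species and
    carries ``unit``/``mode`` flags for agents; ``None`` means
    unreported.  A species listed under two roles is entered twice; the
    amount goes on whichever occurrence actually carries it and the
    builder places the duplicate marker.
    """

    role: str
    inchi: str
    coeff: Optional[int] = None
    amount: Optional[float] = None
    unit: str = "m"             # agents: "m" (moles) | "g" (grams)
    mode: Optional[str] = None  # agents: "f" | "a"; default follows batch/flow
    yield_: Optional[float] = None
    starting_material: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        body = self.inchi
        if body.startswith("InChI="):
            body = body.split("/", 1)[1]
        object.__setattr__(self, "inchi", body)


@dataclass(frozen=True)
class ConditionSpec:
    """One condition set; amount/yield overrides are keyed by InChI body."""

    temperature: Optional[float] = None   # K
    pressure: Optional[float] = None      # Pa
    time_conversion: Tuple[TimeConversionPair, ...] = ()
    reactor_volume: Union[float, str, None] = None  # m^3 or BATCH
    amounts: Optional[Dict[str, Optional[float]]] = None
    yields: Optional[Dict[str, Optional[float]]] = None


def assemble(
    species: Sequence[SpeciesRow],
    conditions: Sequence[ConditionSpec],
) -> ProcessedReaction:
    """Build a canonical ProcessedReaction from role-tagged species rows.

    The directionality flag is derived, never chosen: after the bytewise
    group ordering, "d+" if the reactant rows ended up as group1 and
    "d-" if they ended up as group2."""
    by_role = {role: [r for r in species if r.role == role] for role in ROLES}
    for role, rows in by_role.items():
        bodies = [r.inchi for r in rows]
        if len(set(bodies)) != len(bodies):
            raise ValueError(f"duplicate species within role {role!r}")

    sorted_reactants = sorted(by_role["reactant"], key=lambda r: r.inchi)
    sorted_products = sorted(by_role["product"], key=lambda r: r.inchi)
    sorted_agents = sorted(by_role["agent"], key=lambda r: r.inchi)

    joined_r = "//".join(r.inchi for r in sorted_reactants)
    joined_p = "//".join(r.inchi for r in sorted_products)
    if joined_r <= joined_p:
        group_rows = {1: sorted_reactants, 2: sorted_products, 3: sorted_agents}
        out_direction = Direction.FORWARD
    else:
        group_rows = {1: sorted_products, 2: sorted_reactants, 3: sorted_agents}
        out_direction = Direction.BACKWARD

    rinchi = canonicalize_rinchi(
        RInChIRecord(
            group1=tuple(r.inchi for r in group_rows[1]),
            group2=tuple(r.inchi for r in group_rows[2]),
            group3=tuple(r.inchi for r in group_rows[3]),
            direction=out_direction,
        )
    )
    product_group = rinchi.product_group

    # document-order walk: first occurrence of each body wins the amount
    positions: List[Tuple[int, int, SpeciesRow]] = []
    for gno in (1, 2, 3):
        for idx, row in enumerate(group_rows[gno], start=1):
            positions.append((gno, idx, row))
    first_seen: Dict[str, Tuple[int, int]] = {}
    for gno, idx, row in positions:
        first_seen.setdefault(row.inchi, (gno, idx))

    def registered_amount(row: SpeciesRow, cond: ConditionSpec) -> Optional[float]:
        if cond.amounts is not None and row.inchi in cond.amounts:
            return cond.amounts[row.inchi]
        return row.amount

    records = []
    for cond in conditions:
        batch = isinstance(cond.reactor_volume, str)

        # one amount per distinct species, registered at its first occurrence
        amount_at: Dict[Tuple[int, int], Optional[float]] = {}
        unit_at: Dict[Tuple[int, int], str] = {}
        for body, pos in first_seen.items():
            rows_for_body = [(g, i, r) for g, i, r in positions if r.inchi == body]
            values = [
                (g, i, r, registered_amount(r, cond))
                for g, i, r in rows_for_body
            ]
            carried = [(g, i, r, v) for g, i, r, v in values if v is not None]
            if len(carried) > 1:
                raise ValueError(f"species {body.split('/', 1)[0]} carries two amounts")
            if carried:
                g, i, r, v = carried[0]
                unit = r.unit if r.role == "agent" else "m"
                if pos[0] != 3 and unit == "g":
                    raise ValueError(
                        "gram amounts can only be registered in the agents group"
                    )
                amount_at[pos] = v
                unit_at[pos] = unit
            else:
                amount_at[pos] = None
                unit_at[pos] = "m"

        def entry_for(gno: int, idx: int, row: SpeciesRow):
            pos = (gno, idx)
            first = first_seen[row.inchi]
            if first != pos:
                ref = SpeciesRef(*first)
                return Group3AmountEntry(duplicate_of=ref) if gno == 3 else AmountEntry(duplicate_of=ref)
            value = amount_at[pos]
            if gno == 3:
                if value is None:
                    return Group3AmountEntry()
                mode = row.mode or ("a" if batch else "f")
                return Group3AmountEntry(value=value, unit=unit_at[pos], mode=mode)
            return AmountEntry() if value is None else AmountEntry(value=value)

        def amounts_for(gno: int):
            rows = group_rows[gno]
            if not rows:
                return None
            return tuple(entry_for(gno, idx, row) for idx, row in enumerate(rows, start=1))

        def stoich_for(gno: int):
            rows = group_rows[gno]
            if not rows:
                return None
            return tuple(row.coeff for row in rows)

        def yield_for(row: SpeciesRow) -> Optional[float]:
            if cond.yields is not None and row.inchi in cond.yields:
                return cond.yields[row.inchi]
            return row.yield_

        yrows = group_rows[product_group]
        yields = tuple(yield_for(r) for r in yrows) if yrows else None
        if yields is not None and all(y is None for y in yields):
            yields = None

        sm_rows = [r for r in species if r.starting_material]
        if len(sm_rows) > 1:
            raise ValueError("at most one species may be flagged as starting material")
        sm_ref = SpeciesRef(*first_seen[sm_rows[0].inchi]) if sm_rows else None

        records.append(
            ProcAuxInfoRecord(
                starting_material=sm_ref,
                stoich1=stoich_for(1),
                stoich2=stoich_for(2),
                temperature=cond.temperature,
                pressure=cond.pressure,
                time_conversion=cond.time_conversion,
                yields=yields,
                amounts1=amounts_for(1),
                amounts2=amounts_for(2),
                amounts3=amounts_for(3),
                reactor_volume=cond.reactor_volume,
            )
        )

    return ProcessedReaction(rinchi=rinchi, conditions=tuple(records))


def species_ref(p: ProcessedReaction, body: str) -> SpeciesRef:
    """Canonical (group, index) of a species given its InChI body."""
    if body.startswith("InChI="):
        body = body.split("/", 1)[1]
    for gno in (1, 2, 3):
        group = p.rinchi.group(gno)
        if body in group:
            return SpeciesRef(gno, group.index(body) + 1)
    raise ValueError(f"species {body.split('/', 1)[0]} not present in record")


# ---------------------------------------------------------------------------
# the three worked examples

def example1() -> ProcessedReaction:
    """Flow C–H aziridination: Pd(OAc)2-catalysed reaction of
    3,3,5,5-tetramethylmorpholin-2-one with (diacetoxyiodo)benzene.

    Acetic acid is both a product and a fed auxiliary: its feed
    (8.3e-6 mol/s) is registered at the product-group occurrence and the
    agents group carries the duplicate marker.
    """
    tc = tuple(
        TimeConversionPair(t, x)
        for t, x in [
            (60, 0.06), (120, 0.14), (180, 0.20), (240, 0.32), (300, 0.40),
            (360, 0.52), (420, 0.70), (480, 0.90), (540, 1.00), (600, 1.00),
        ]
    )
    rows = [
        SpeciesRow("reactant", SM_MORPHOLINONE, coeff=1, amount=8.3e-7, starting_material=True),
        SpeciesRow("reactant", DIACETOXYIODOBENZENE, coeff=1, amount=8.3e-7),
        SpeciesRow("product", AZIRIDINE_PRODUCT, coeff=1, amount=0.0, yield_=0.90),
        SpeciesRow("product", IODOBENZENE, coeff=1, amount=0.0),
        SpeciesRow("product", ACETIC_ACID, coeff=2, amount=8.3e-6),
        SpeciesRow("agent", PD_ACETATE, amount=4.2e-9, unit="m", mode="f"),
        SpeciesRow("agent", ACETIC_ACID),
        SpeciesRow("agent", ACETIC_ANHYDRIDE, amount=1.7e-6, unit="m", mode="f"),
        SpeciesRow("agent", TOLUENE, amount=1.5e-4, unit="m", mode="f"),
    ]
    cond = ConditionSpec(
        temperature=393.0,
        pressure=6e6,
        time_conversion=tc,
        reactor_volume=1e-5,
    )
    return assemble(rows, [cond])


def example2() -> ProcessedReaction:
    """Flow aerobic oxidation of benzyl alcohol over Ru/Al2O3.

    The supported catalyst cannot be expressed as one species, so
    ruthenium and aluminium oxide are stored separately, each with an
    absolute gram amount (the immobilised bed), while the reaction-side
    feeds are flowrates.
    """
    rows = [
        SpeciesRow("reactant", BENZYL_ALCOHOL, coeff=2, amount=3.3e-5, starting_material=True),
        SpeciesRow("reactant", OXYGEN, coeff=1, amount=4.9e-6),
        SpeciesRow("product", BENZALDEHYDE, coeff=2, amount=0.0, yield_=0.25),
        SpeciesRow("product", WATER, coeff=2, amount=0.0),
        SpeciesRow("agent", RUTHENIUM, amount=9e-3, unit="g", mode="a"),
        SpeciesRow("agent", ALUMINA, amount=0.991, unit="g", mode="a"),
        SpeciesRow("agent", TOLUENE, amount=3.1e-4, unit="m", mode="f"),
    ]
    cond = ConditionSpec(
        temperature=388.0,
        pressure=8e6,
        time_conversion=(TimeConversionPair(9, 0.25),),
        reactor_volume=9e-4,
    )
    return assemble(rows, [cond])


def example3() -> ProcessedReaction:
    """Batch Suzuki–Miyaura coupling of phenylboronic acid and
    4-bromotoluene, encoded exactly as published: the equation is
    unbalanced (the byproduct species are not reported), the base amount,
    pressure and time data are missing, and the yield (0.89) refers to
    the limiting reactant, 4-bromotoluene.

    The publication reports no reactor volume; since every amount is
    absolute, the batch marker is used.
    """
    rows = [
        SpeciesRow("reactant", PHENYLBORONIC_ACID, coeff=1, amount=1.1e-3),
        SpeciesRow("reactant", BROMOTOLUENE, coeff=1, amount=1.0e-3, starting_material=True),
        SpeciesRow("product", PHENYLTOLUENE, coeff=1, amount=0.0, yield_=0.89),
        SpeciesRow("agent", PHOSPHINE_LIGAND_SYNTHETIC, amount=2.2e-5, unit="m", mode="a"),
        SpeciesRow("agent", NMP, amount=3.1e-2, unit="m", mode="a"),
        SpeciesRow("agent", PD_ACAC, amount=2.2e-5, unit="m", mode="a"),
        SpeciesRow("agent", SODIUM_CARBONATE),   # amount not reported
    ]
    cond = ConditionSpec(temperature=363.0, reactor_volume=BATCH)
    return assemble(rows, [cond])


#: name -> (builder, desired-product InChI body)
EXAMPLES = {
    "example1": (example1, AZIRIDINE_PRODUCT),
    "example2": (example2, BENZALDEHYDE),
    "example3": (example3, PHENYLTOLUENE),
}


# ---------------------------------------------------------------------------
# random records for property testing

#: Violation codes the generator can inject, one at a time.
BREAKAGE_CODES = (
    "E_STOICH_LEN",
    "E_AMOUNT_LEN",
    "E_YIELD_LEN",
    "E_STOICH_POS",
    "E_RANGE",
    "E_DUP_FORWARD",
    "E_DUP_TARGET",
    "E_G3_FLAGS",
    "E_SM_REF",
    "E_VERSION",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-record generator; the seed fixes everything."""

    seed: int = 0
    max_side_species: int = 3     # species per reaction-side group (>= 1)
    max_agents: int = 3           # agents (>= 0)
    p_missing: float = 0.2        # chance an optional field is "?"
    p_duplicate: float = 0.3      # chance a species also appears as agent
    flow_ratio: float = 0.5       # flow records vs batch records
    max_condition_sets: int = 2
    breakage: Optional[str] = None

    def __post_init__(self) -> None:
        for p in (self.p_missing, self.p_duplicate, self.flow_ratio):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.breakage is not None and self.breakage not in BREAKAGE_CODES:
            raise ValueError(
                f"unknown breakage code {self.breakage!r}; known: {BREAKAGE_CODES}"
            )


def _synthetic_body(rng: random.Random, uid: int) -> str:
    """A well-formed, unique InChI-like body with a parseable formula layer."""
    c = rng.randint(1, 24)
    h = rng.randint(1, 2 * c + 2)
    formula = f"C{c if c > 1 else ''}H{h if h > 1 else ''}"
    for sym in ("N", "O"):
        n = rng.randint(0, 3)
        if n:
            formula += f"{sym}{n if n > 1 else ''}"
    return f"{formula}/c{uid}-{rng.randint(1, 9)}/h{rng.randint(1, 9)}H"


def _non_decreasing_pairs(rng: random.Random) -> Tuple[TimeConversionPair, ...]:
    n = rng.randint(0, 4)
    times = sorted(round(rng.uniform(1, 4000), 1) for _ in range(n))
    convs = sorted(round(rng.uniform(0, 1), 3) for _ in range(n))
    return tuple(TimeConversionPair(t, x) for t, x in zip(times, convs))


def _maybe(rng: random.Random, p_missing: float, value):
    return None if rng.random() < p_missing else value


def random_reaction(cfg: GeneratorConfig) -> ProcessedReaction:
    """Draw one record: structurally valid, or broken in the one named way."""
    rng = random.Random(cfg.seed)
    uid = rng.randint(10, 99) * 1000

    def bodies(n: int) -> List[str]:
        nonlocal uid
        out = []
        for _ in range(n):
            uid += rng.randint(1, 9)
            out.append(_synthetic_body(rng, uid))
        return out

    n_reactants = rng.randint(1, max(1, cfg.max_side_species))
    n_products = rng.randint(1, max(1, cfg.max_side_species))
    n_agents = rng.randint(0, max(0, cfg.max_agents))
    if cfg.breakage in ("E_G3_FLAGS", "E_DUP_TARGET"):
        n_agents = max(1, n_agents)

    batch = rng.random() >= cfg.flow_ratio
    volume = BATCH if batch else 10 ** rng.uniform(-6, -2)

    rows: List[SpeciesRow] = []
    sm_pick = rng.randrange(n_reactants)
    for i, body in enumerate(bodies(n_reactants)):
        rows.append(
            SpeciesRow(
                "reactant", body,
                coeff=rng.randint(1, 3),
                amount=10 ** rng.uniform(-7, -2),
                starting_material=(i == sm_pick),
            )
        )
    desired = rng.randrange(n_products)
    for i, body in enumerate(bodies(n_products)):
        rows.append(
            SpeciesRow(
                "product", body,
                coeff=rng.randint(1, 3),
                amount=0.0,
                yield_=round(rng.uniform(0.05, 0.95), 3) if i == desired else None,
            )
        )
    for body in bodies(n_agents):
        rows.append(
            SpeciesRow(
                "agent", body,
                amount=_maybe(rng, cfg.p_missing, 10 ** rng.uniform(-6, -1)),
                unit=rng.choice("mg"),
                mode="a" if batch else "f",
            )
        )
    # a duplicated species: re-list a reaction-side species as an agent,
    # so the agents group carries the marker and the mass stays put
    if rng.random() < cfg.p_duplicate:
        source = rng.choice([r for r in rows if r.role in ("reactant", "product")])
        rows.append(SpeciesRow("agent", source.inchi))

    conditions = []
    for _ in range(rng.randint(1, max(1, cfg.max_condition_sets))):
        conditions.append(
            ConditionSpec(
                temperature=_maybe(rng, cfg.p_missing, round(rng.uniform(250, 600), 1)),
                pressure=_maybe(rng, cfg.p_missing, round(10 ** rng.uniform(4, 7), 0)),
                time_conversion=_non_decreasing_pairs(rng),
                reactor_volume=volume,
            )
        )
    p = assemble(rows, conditions)
    if cfg.breakage is not None:
        p = _inject_breakage(p, cfg.breakage)
    return p


def _inject_breakage(p: ProcessedReaction, code: str) -> ProcessedReaction:
    """Mutate the first condition record so that validate() reports `code`."""
    rec = p.conditions[0]
    n1 = len(p.rinchi.group1)
    if code == "E_STOICH_LEN":
        rec = replace(rec, stoich1=(1,) * (n1 + 1))
    elif code == "E_AMOUNT_LEN":
        extra = (rec.amounts1 or ()) + (AmountEntry(value=1.0),)
        rec = replace(rec, amounts1=extra)
    elif code == "E_YIELD_LEN":
        # one extra slot; keep a value so the list cannot normalize to "?"
        size = len(p.rinchi.group(p.rinchi.product_group))
        rec = replace(rec, yields=(0.5,) + (None,) * size)
    elif code == "E_STOICH_POS":
        coeffs = list(rec.stoich1 or (1,) * n1)
        coeffs[0] = 0
        rec = replace(rec, stoich1=tuple(coeffs))
    elif code == "E_RANGE":
        size = len(p.rinchi.group(p.rinchi.product_group))
        rec = replace(rec, yields=(1.5,) + (None,) * (size - 1))
    elif code == "E_DUP_FORWARD":
        entries = list(rec.amounts1 or (AmountEntry(),) * n1)
        entries[0] = AmountEntry(duplicate_of=SpeciesRef(3, 1))
        rec = replace(rec, amounts1=tuple(entries))
    elif code == "E_DUP_TARGET":
        a1 = list(rec.amounts1 or (AmountEntry(),) * n1)
        a1[0] = AmountEntry()
        a3 = list(rec.amounts3 or (Group3AmountEntry(),))
        a3[-1] = Group3AmountEntry(duplicate_of=SpeciesRef(1, 1))
        rec = replace(rec, amounts1=tuple(a1), amounts3=tuple(a3))
    elif code == "E_G3_FLAGS":
        a3 = list(rec.amounts3 or (Group3AmountEntry(),))
        a3[0] = Group3AmountEntry(value=1.0)
        rec = replace(rec, amounts3=tuple(a3))
    elif code == "E_SM_REF":
        rec = replace(rec, starting_material=SpeciesRef(1, n1 + 5))
    elif code == "E_VERSION":
        rec = replace(rec, version="0.0.1")
    else:  # pragma: no cover - guarded by GeneratorConfig
        raise ValueError(f"unknown breakage code {code!r}")
    return ProcessedReaction(rinchi=p.rinchi, conditions=(rec,) + p.conditions[1:])


# ---------------------------------------------------------------------------
# tabular exchange format (tab-separated, mirrors the per-species tables)

_TABLE_HEADER = (
    "# procaux table: species\trole\tinchi\tcoeff\tamount\tunit\tmode\tyield\ttags"
)


def to_table(p: ProcessedReaction, condition_index: int = 0) -> str:
    """Render one condition set as the tabular exchange format."""
    rec = p.conditions[condition_index] if p.conditions else ProcAuxInfoRecord()
    role_of_group = {
        p.rinchi.reactant_group: "reactant",
        p.rinchi.product_group: "product",
        3: "agent",
    }
    lines = [_TABLE_HEADER]
    stoich_by_group = {1: rec.stoich1, 2: rec.stoich2, 3: None}
    amounts_by_group = {1: rec.amounts1, 2: rec.amounts2, 3: rec.amounts3}
    for gno in (1, 2, 3):
        for idx, body in enumerate(p.rinchi.group(gno), start=1):
            coeffs = stoich_by_group[gno]
            coeff = coeffs[idx - 1] if coeffs and idx <= len(coeffs) else None
            entries = amounts_by_group[gno]
            entry = entries[idx - 1] if entries and idx <= len(entries) else None
            amount = "?"
            unit, mode = "-", "-"
            if entry is not None:
                if entry.duplicate_of is not None:
                    amount = f"x:{entry.duplicate_of}"
                elif entry.value is not None:
                    amount = repr(entry.value)
                if isinstance(entry, Group3AmountEntry):
                    unit, mode = entry.unit or "-", entry.mode or "-"
            y = "?"
            if gno == p.rinchi.product_group and rec.yields and idx <= len(rec.yields):
                y = "?" if rec.yields[idx - 1] is None else repr(rec.yields[idx - 1])
            tags = []
            if rec.starting_material == SpeciesRef(gno, idx):
                tags.append("sm")
            lines.append(
                "\t".join(
                    [
                        "species", role_of_group[gno], body,
                        "?" if coeff is None else str(coeff),
                        amount, unit, mode, y, ",".join(tags) or "-",
                    ]
                )
            )
    if rec.temperature is not None:
        lines.append(f"temperature\t{rec.temperature!r}")
    if rec.pressure is not None:
        lines.append(f"pressure\t{rec.pressure!r}")
    for pair in rec.time_conversion:
        lines.append(f"tc\t{pair.time!r}\t{pair.conversion!r}")
    if rec.reactor_volume is not None:
        vol = BATCH if rec.is_batch else repr(rec.reactor_volume)
        lines.append(f"volume\t{vol}")
    return "\n".join(lines) + "\n"


def from_table(text: str) -> ProcessedReaction:
    """Parse the tabular exchange format; "%%" lines separate condition sets.

    The first block defines the species; later blocks may restate species
    rows to override amounts and yields for that condition set.
    """
    blocks = [[]]
    for raw in text.splitlines():
        line = raw.strip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() == "%%":
            blocks.append([])
            continue
        blocks[-1].append(line.split("\t"))
    if not blocks[0]:
        raise ValueError("empty table: no species or condition rows")

    def parse_block(rows):
        species: List[SpeciesRow] = []
        cond: Dict[str, object] = {"tc": []}
        for cells in rows:
            kind = cells[0].strip().lower()
            if kind == "species":
                if len(cells) != 9:
                    raise ValueError(f"species row needs 9 columns, got {len(cells)}")
                _, role, inchi, coeff, amount, unit, mode, y, tags = [c.strip() for c in cells]
                species.append(
                    SpeciesRow(
                        role=role,
                        inchi=inchi,
                        coeff=None if coeff in ("?", "-") else int(coeff),
                        # duplicate markers re-derive from the doubled body;
                        # the amount lives at the first occurrence
                        amount=None if amount in ("?", "-") or amount.startswith("x:") else float(amount),
                        unit=unit if unit in ("m", "g") else "m",
                        mode=mode if mode in ("f", "a") else None,
                        yield_=None if y in ("?", "-") else float(y),
                        starting_material="sm" in tags.split(","),
                    )
                )
            elif kind == "temperature":
                cond["temperature"] = float(cells[1])
            elif kind == "pressure":
                cond["pressure"] = float(cells[1])
            elif kind == "tc":
                cond["tc"].append(TimeConversionPair(float(cells[1]), float(cells[2])))
            elif kind == "volume":
                v = cells[1].strip()
                cond["volume"] = BATCH if v.lower() == BATCH else float(v)
            else:
                raise ValueError(f"unknown table row kind {cells[0]!r}")
        spec = ConditionSpec(
            temperature=cond.get("temperature"),
            pressure=cond.get("pressure"),
            time_conversion=tuple(cond["tc"]),
            reactor_volume=cond.get("volume"),
        )
        return species, spec

    base_species, first_cond = parse_block(blocks[0])
    if not base_species:
        raise ValueError("table defines no species")
    conditions = [first_cond]
    for rows in blocks[1:]:
        extra_species, cond = parse_block(rows)
        overrides_amounts = {r.inchi: r.amount for r in extra_species}
        overrides_yields = {r.inchi: r.yield_ for r in extra_species}
        unknown = set(overrides_amounts) - {r.inchi for r in base_species}
        if unknown:
            raise ValueError("later condition blocks may only restate known species")
        conditions.append(
            replace(
                cond,
                amounts=overrides_amounts or None,
                yields=overrides_yields or None,
            )
        )
    return assemble(base_species, conditions)
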