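"""Process metrics from decoded reaction records.

Implements the mass-based green-chemistry calculus on top of the codec:

* yield          Y = (n_i,out − n_i,in) / n_SM,in
* conversion     X = (n_SM,in − n_SM,out) / n_SM,in   (reported as a
  positive fraction of starting material consumed)
* atom economy   AE = ν_p·MR_p / Σ_r ν_r·MR_r
* stoichiometric factor
                 SF = 1 + excess reagent mass / stoichiometric reagent mass
* E-factor, per step and across an n-step route with yield propagation
  (the Andraos ladder generalized to non-1:1 stoichiometry)::

      E_total = (1/MR_pn) Σ_j  (1/Π_{k=j..n} ε_k) ·
                [ (ν_pj/ν_mrj)(MR_pj/AE_j)(SF_j − (ν_mrj/ν_pj) ε_j AE_j)
                  + (c_j + s_j + ω_j)/n_mrj ]

  where ε is the yield with respect to the limiting reactant, c, s, ω
  the catalyst / solvent / work-up masses in grams and n_mr the mole
  scale of the limiting reactant.  The yield product runs from the
  current step j through the final step n inclusive; steps before j do
  not attenuate.
* reaction mass efficiency   RME = product mass out / total mass in.

A brute-force mass ledger (:func:`e_factor_direct`: total mass in minus
product mass out, over product mass out) serves as an independent oracle
for the closed form.  The two agree identically whenever ν_p = ν_mr;
for ν_p ≠ ν_mr the closed form's bracket term deviates from the ledger,
so report both where they differ rather than hiding one.

Flow records are evaluated on a one-second basis; E and RME are mass
ratios, so the basis cancels for any uniformly scaled feed set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

from .chem_core import AtomicWeightTable, FormulaError, formula_of_inchi, molar_mass
from .procaux_codec import AmountEntry, Group3AmountEntry, ProcAuxInfoRecord
from .rinchi_codec import SpeciesRef
from .validation import ProcessedReaction

__all__ = [
    "MetricsError",
    "MissingDataError",
    "StepMassSummary",
    "StepReport",
    "yield_of",
    "conversion_of",
    "atom_economy",
    "stoichiometric_factor",
    "reactant_feeds",
    "step_mass_summary",
    "step_report",
    "route_e_factor",
    "e_factor_direct",
    "reaction_mass_efficiency",
]


class MetricsError(ValueError):
    """Raised when metric inputs are inconsistent or degenerate."""


class MissingDataError(MetricsError):
    """Raised when a record lacks data a metric needs; names every gap."""

    def __init__(self, gaps: Sequence[str]):
        self.gaps = list(gaps)
        super().__init__("missing data: " + "; ".join(self.gaps))


# ---------------------------------------------------------------------------
# the elementary definitions

def yield_of(n_i_out: float, n_i_in: float, n_sm_in: float) -> float:
    """Net moles of species i formed per mole of starting material fed."""
    if n_sm_in <= 0:
        raise MetricsError(f"starting-material feed must be positive, got {n_sm_in}")
    return (n_i_out - n_i_in) / n_sm_in


def conversion_of(n_sm_out: float, n_sm_in: float) -> float:
    """Fraction of starting material consumed, as a positive number."""
    if n_sm_in <= 0:
        raise MetricsError(f"starting-material feed must be positive, got {n_sm_in}")
    if n_sm_out > n_sm_in:
        raise MetricsError(
            f"starting material out ({n_sm_out}) exceeds feed ({n_sm_in}); "
            "negative conversion is not representable"
        )
    return (n_sm_in - n_sm_out) / n_sm_in


def atom_economy(
    reactants: Sequence[Tuple[int, float]], nu_p: int, mr_p: float
) -> float:
    """ν_p·MR_p over the stoichiometric mass of all reactants.

    ``reactants`` is a sequence of (coefficient, molar mass) pairs.
    """
    if not reactants:
        raise MetricsError("atom economy needs at least one reactant")
    denom = 0.0
    for nu, mr in reactants:
        if nu < 1 or mr <= 0:
            raise MetricsError(f"bad reactant term (nu={nu}, MR={mr})")
        denom += nu * mr
    return nu_p * mr_p / denom


def stoichiometric_factor(
    fed_amounts: Sequence[float],
    stoich: Sequence[int],
    molar_masses: Sequence[float],
    limiting_index: int,
) -> float:
    """1 + excess reagent mass over the stoichiometric reagent mass.

    The stoichiometric mass is what the balanced equation requires to
    consume the limiting feed completely; anything fed beyond that is
    excess.  Exactly stoichiometric feeds give SF = 1.
    """
    if not 0 <= limiting_index < len(fed_amounts):
        raise MetricsError(f"limiting index {limiting_index} out of range")
    n_mr = fed_amounts[limiting_index]
    nu_mr = stoich[limiting_index]
    if n_mr <= 0:
        raise MetricsError("limiting reagent fed in zero amount")
    stoich_mass = sum(n_mr * (nu / nu_mr) * mr for nu, mr in zip(stoich, molar_masses))
    fed_mass = sum(n * mr for n, mr in zip(fed_amounts, molar_masses))
    return 1.0 + (fed_mass - stoich_mass) / stoich_mass


# ---------------------------------------------------------------------------
# mapping one decoded record onto the E-factor symbols

@dataclass(frozen=True)
class StepMassSummary:
    """The per-step inputs of the route E-factor.

    Masses are grams (per second of operation for flow records); the
    mole scale n_mr is mol (or mol/s).  ω, the work-up mass, has no
    ProcAuxInfo field and defaults to zero — reports say so loudly.
    """

    n_mr: float       # mole scale of the limiting reactant
    epsilon: float    # yield w.r.t. the limiting reactant
    nu_p: int         # stoichiometric coefficient of the desired product
    nu_mr: int        # stoichiometric coefficient of the limiting reactant
    mr_p: float       # molar mass of the desired product, g/mol
    ae: float         # atom economy
    sf: float         # stoichiometric factor
    c: float = 0.0    # catalyst mass, g
    s: float = 0.0    # solvent / other auxiliary mass, g
    omega: float = 0.0  # work-up mass, g

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise MetricsError(f"yield {self.epsilon} outside [0, 1]")
        if not 0.0 < self.ae <= 1.0:
            raise MetricsError(f"atom economy {self.ae} outside (0, 1]")
        if self.sf < 1.0 - 1e-12:
            raise MetricsError(f"stoichiometric factor {self.sf} below 1")
        if self.nu_p < 1 or self.nu_mr < 1:
            raise MetricsError("stoichiometric coefficients must be positive integers")
        if self.n_mr <= 0 or self.mr_p <= 0:
            raise MetricsError("mole scale and product molar mass must be positive")
        if min(self.c, self.s, self.omega) < 0:
            raise MetricsError("auxiliary masses must be non-negative")

    @property
    def product_mass_out(self) -> float:
        """ε · n_mr · (ν_p/ν_mr) · MR_p, grams of desired product."""
        return self.epsilon * self.n_mr * (self.nu_p / self.nu_mr) * self.mr_p


def _resolve_amount_moles(
    p: ProcessedReaction,
    rec: ProcAuxInfoRecord,
    group: int,
    index: int,
    table: Union[AtomicWeightTable, None],
    gaps: List[str],
    _seen: Union[frozenset, None] = None,
) -> Union[float, None]:
    """Moles behind an amount slot, following duplicate markers; grams
    are converted through the species' formula layer."""
    entries = {1: rec.amounts1, 2: rec.amounts2, 3: rec.amounts3}[group]
    name = f"amounts{group}[{index}]"
    seen = _seen or frozenset()
    if (group, index) in seen:
        gaps.append(f"{name}: duplicate-marker cycle")
        return None
    if entries is None or index > len(entries):
        gaps.append(f"{name}: no amount recorded")
        return None
    entry = entries[index - 1]
    if entry.is_missing:
        gaps.append(f"{name}: amount is '?'")
        return None
    if entry.duplicate_of is not None:
        ref = entry.duplicate_of
        return _resolve_amount_moles(
            p, rec, ref.group, ref.index, table, gaps, seen | {(group, index)}
        )
    if isinstance(entry, Group3AmountEntry) and entry.unit == "g":
        body = p.rinchi.group(group)[index - 1]
        try:
            return entry.value / molar_mass(formula_of_inchi(body, table), table)
        except FormulaError as exc:
            gaps.append(f"{name}: cannot convert grams to moles ({exc})")
            return None
    return entry.value


def _entry_mass_grams(
    p: ProcessedReaction,
    group: int,
    index: int,
    entry: Union[AmountEntry, Group3AmountEntry],
    table: Union[AtomicWeightTable, None],
    gaps: List[str],
) -> float:
    """Grams behind a value entry (duplicates contribute zero here)."""
    if entry.duplicate_of is not None:
        return 0.0
    if entry.value is None:
        body = p.rinchi.group(group)[index - 1]
        gaps.append(f"amounts{group}[{index}] ({body.split('/', 1)[0]}): amount is '?'")
        return 0.0
    if isinstance(entry, Group3AmountEntry) and entry.unit == "g":
        return entry.value
    try:
        mr = molar_mass(formula_of_inchi(p.rinchi.group(group)[index - 1], table), table)
    except FormulaError as exc:
        gaps.append(f"amounts{group}[{index}]: {exc}")
        return 0.0
    return entry.value * mr


def reactant_feeds(
    p: ProcessedReaction,
    condition_index: int = 0,
    table: Union[AtomicWeightTable, None] = None,
) -> List[Tuple[float, float]]:
    """(moles fed, molar mass) for every reactant, duplicate markers resolved."""
    rec = p.conditions[condition_index]
    rg = p.rinchi.reactant_group
    bodies = p.rinchi.group(rg)
    gaps: List[str] = []
    out: List[Tuple[float, float]] = []
    for idx, body in enumerate(bodies, start=1):
        feed = _resolve_amount_moles(p, rec, rg, idx, table, gaps)
        try:
            mr = molar_mass(formula_of_inchi(body, table), table)
        except FormulaError as exc:
            gaps.append(f"group{rg}[{idx}]: {exc}")
            mr = math.nan
        if feed is not None:
            out.append((feed, mr))
    if gaps:
        raise MissingDataError(gaps)
    return out


def step_mass_summary(
    p: ProcessedReaction,
    condition_index: int = 0,
    desired_product: Union[SpeciesRef, None] = None,
    table: Union[AtomicWeightTable, None] = None,
) -> StepMassSummary:
    """Map one condition set onto the E-factor inputs.

    The limiting reactant is the one with the smallest feed/coefficient
    ratio (the starting material wins ties, since yields are referenced
    to it).  When the starting material is not limiting, the recorded
    yield is rescaled onto the limiting-reactant basis through the
    stoichiometric ratio.  Group-3 masses enter c (gram-flagged entries,
    typically catalysts) or s (mole-flagged entries, typically solvents,
    converted via molar mass); product-side feeds other than net product
    formation also land in s, so every input mass is counted exactly
    once.  Flow records are taken on a one-second basis.
    """
    try:
        rec = p.conditions[condition_index]
    except IndexError:
        raise MetricsError(
            f"no condition set {condition_index} (record has {len(p.conditions)})"
        ) from None
    rg, pg = p.rinchi.reactant_group, p.rinchi.product_group
    reactant_bodies = p.rinchi.group(rg)
    product_bodies = p.rinchi.group(pg)
    if not reactant_bodies or not product_bodies:
        raise MetricsError("metrics need both a reactant and a product group")
    if desired_product is None:
        raise MetricsError("desired product reference is required (e.g. SpeciesRef(2, 1))")
    if desired_product.group != pg or desired_product.index > len(product_bodies):
        raise MetricsError(
            f"desired product {desired_product} is not in product group {pg} "
            f"(size {len(product_bodies)})"
        )

    gaps: List[str] = []
    stoich_by_group = {1: rec.stoich1, 2: rec.stoich2}

    def coeff(group: int, index: int) -> Union[int, None]:
        coeffs = stoich_by_group[group]
        if coeffs is None or index > len(coeffs) or coeffs[index - 1] is None:
            gaps.append(f"stoich{group}[{index}]: coefficient unknown")
            return None
        return coeffs[index - 1]

    # reactant ledger: feed, coefficient, molar mass
    feeds: List[float] = []
    nus: List[int] = []
    mrs: List[float] = []
    for idx, body in enumerate(reactant_bodies, start=1):
        feed = _resolve_amount_moles(p, rec, rg, idx, table, gaps)
        nu = coeff(rg, idx)
        try:
            mr = molar_mass(formula_of_inchi(body, table), table)
        except FormulaError as exc:
            gaps.append(f"group{rg}[{idx}]: {exc}")
            mr = math.nan
        if feed is not None and nu is not None:
            feeds.append(feed)
            nus.append(nu)
            mrs.append(mr)
    nu_p = coeff(pg, desired_product.index)
    y = None
    if rec.yields is None or desired_product.index > len(rec.yields):
        gaps.append(f"yields[{desired_product.index}]: no yield recorded")
    else:
        y = rec.yields[desired_product.index - 1]
        if y is None:
            gaps.append(f"yields[{desired_product.index}]: yield is '?'")
    if gaps:
        raise MissingDataError(gaps)
    if any(f <= 0 for f in feeds):
        raise MetricsError("every reactant must be fed in a positive amount")

    # limiting reactant: smallest feed/coefficient; starting material wins ties
    sm_index = None
    if rec.starting_material is not None and rec.starting_material.group == rg:
        sm_index = rec.starting_material.index
    ratios = [f / nu for f, nu in zip(feeds, nus)]
    best = min(ratios)
    limiting = ratios.index(best)
    if sm_index is not None and math.isclose(ratios[sm_index - 1], best, rel_tol=1e-12):
        limiting = sm_index - 1
    n_mr, nu_mr = feeds[limiting], nus[limiting]

    mr_p = molar_mass(formula_of_inchi(product_bodies[desired_product.index - 1], table), table)
    ae = atom_economy(list(zip(nus, mrs)), nu_p, mr_p)
    sf = stoichiometric_factor(feeds, nus, mrs, limiting)

    # yield w.r.t. the limiting reactant: net product formed over the
    # stoichiometric maximum at the limiting feed
    n_sm_in = feeds[sm_index - 1] if sm_index is not None else n_mr
    formed = y * n_sm_in
    epsilon = formed / (n_mr * nu_p / nu_mr)

    # auxiliary masses: c from gram-flagged agents, s from mole-flagged
    # agents and from product-side feeds (duplicate markers add zero)
    c = s = 0.0
    mass_gaps: List[str] = []
    for idx in range(1, len(p.rinchi.group3) + 1):
        entry = (rec.amounts3 or ())[idx - 1] if rec.amounts3 and idx <= len(rec.amounts3) else Group3AmountEntry()
        grams = _entry_mass_grams(p, 3, idx, entry, table, mass_gaps)
        if isinstance(entry, Group3AmountEntry) and entry.unit == "g":
            c += grams
        else:
            s += grams
    for idx in range(1, len(product_bodies) + 1):
        entry = (rec.amounts2 if pg == 2 else rec.amounts1)
        e = entry[idx - 1] if entry and idx <= len(entry) else AmountEntry()
        s += _entry_mass_grams(p, pg, idx, e, table, mass_gaps)
    if mass_gaps:
        raise MissingDataError(mass_gaps)

    return StepMassSummary(
        n_mr=n_mr, epsilon=epsilon, nu_p=nu_p, nu_mr=nu_mr, mr_p=mr_p,
        ae=ae, sf=sf, c=c, s=s, omega=0.0,
    )


# ---------------------------------------------------------------------------
# E-factor: closed form and brute-force ledger

def route_e_factor(route: Sequence[StepMassSummary]) -> float:
    """Route E-factor with yield propagation from each step to the last."""
    steps = list(route)
    if not steps:
        raise MetricsError("route must contain at least one step")
    if any(sm.epsilon == 0 for sm in steps):
        raise MetricsError("a zero-yield step makes the E-factor infinite")
    mr_pn = steps[-1].mr_p
    total = 0.0
    for j, sm in enumerate(steps):
        downstream = math.prod(s.epsilon for s in steps[j:])
        bracket = sm.sf - (sm.nu_mr / sm.nu_p) * sm.epsilon * sm.ae
        term = (sm.nu_p / sm.nu_mr) * (sm.mr_p / sm.ae) * bracket
        term += (sm.c + sm.s + sm.omega) / sm.n_mr
        total += term / downstream
    return total / mr_pn


def e_factor_direct(
    sm: StepMassSummary, reactant_feeds_and_masses: Sequence[Tuple[float, float]]
) -> float:
    """Brute-force single-step ledger: (mass in − product out) / product out."""
    product_out = sm.product_mass_out
    if product_out <= 0:
        raise MetricsError("no product mass: E-factor undefined")
    total_in = sum(n * mr for n, mr in reactant_feeds_and_masses)
    total_in += sm.c + sm.s + sm.omega
    return (total_in - product_out) / product_out


def reaction_mass_efficiency(
    sm: StepMassSummary, reactant_feeds_and_masses: Sequence[Tuple[float, float]]
) -> float:
    """Desired product mass out per total input mass; 1/(1+E) when every
    input counts as potential waste."""
    total_in = sum(n * mr for n, mr in reactant_feeds_and_masses)
    total_in += sm.c + sm.s + sm.omega
    if total_in <= 0:
        raise MetricsError("no input mass: RME undefined")
    return sm.product_mass_out / total_in


# ---------------------------------------------------------------------------
# one-call report for the CLI

@dataclass(frozen=True)
class StepReport:
    """Everything the metrics command prints for one condition set."""

    summary: StepMassSummary
    e_route: float            # closed-form (route equation, single step)
    e_direct: float           # brute-force mass ledger
    rme: float

    @property
    def consistent(self) -> bool:
        return math.isclose(self.e_route, self.e_direct, rel_tol=1e-9)


def step_report(
    p: ProcessedReaction,
    condition_index: int = 0,
    desired_product: Union[SpeciesRef, None] = None,
    table: Union[AtomicWeightTable, None] = None,
) -> StepReport:
    summary = step_mass_summary(p, condition_index, desired_product, table)
    feeds = reactant_feeds(p, condition_index, table)
    return StepReport(
        summary=summary,
        e_route=route_e_factor([summary]),
        e_direct=e_factor_direct(summary, feeds),
        rme=reaction_mass_efficiency(summary, feeds),
    )
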