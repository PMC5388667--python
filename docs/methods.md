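# Methods

## The data model

A reaction document is one line of text: a RInChI (version 0.03 over
InChI 1S) followed by zero or more `$$`-prefixed ProcAuxInfo blocks,
one per set of operating conditions. The RInChI holds three groups of
bare InChI bodies — the two reaction sides plus the agents group
(solvents, catalysts, additives) — and a directionality flag. InChI
bodies are treated as opaque identifiers except for the formula layer
(the first `/`-delimited segment), which is the sole source of molar
masses. No structure perception, tautomer or stereo handling is
attempted, and no InChI is ever generated at runtime.

### Canonical form

Species within a group are sorted bytewise (C-locale), and the two
reaction-side groups are ordered by bytewise comparison of their joined
serializations; when that swaps the sides, the directionality flag flips
(`d+` ⇄ `d-`) so the chemistry is unchanged. The agents group never
participates in the side ordering: it is positionally defined. Every
ProcAuxInfo list is indexed against this canonical order, which is the
only well-defined one; the `assemble` builder is therefore the single
encode path, and `ProcessedReaction.to_string` refuses a non-canonical
container rather than silently permuting lists out from under their
indices.

### Wire dialect

The standard mandates scientific notation for pressures, times, amounts
and volumes but fixes no exact string form, so the emitter defines one
canonical dialect: lowercase `e`, no `+` and no leading zeros in the
exponent, and the shortest mantissa that reproduces the IEEE double
(`9e-3`, `9.91e-1`, `8.3e-7`). Temperatures, yields and conversions are
plain decimals. The parser is liberal — either exponent case, explicit
`+`, plain decimals, stray whitespace around separators — which gives
the two round-trip guarantees the tests enforce: parse∘serialize is
value-exact on records, and serialize∘parse is byte-exact on canonical
text. One representational fold is deliberate: a list whose every slot
is `?` is indistinguishable on the wire from a wholly-`?` field, so the
record constructor normalizes the former to the latter.

The version token is `PAI` immediately followed by the number
(`PAI0.01`, one decimal point always). The batch marker is lowercase
`batch`, parsed case-insensitively. Duplicate markers (`x:G:I`) carry
no amount; the referenced first occurrence holds it.

## Validation policy

All rule checking is pure and returns findings sorted by location and
code; nothing throws. Breaches that make a record unusable are errors:
list lengths differing from their group sizes, non-positive or
non-integer coefficients, fractions outside [0, 1], duplicate markers
pointing forward or at a non-value slot, flagless agent amounts,
unresolvable starting-material references. Rules that published data
are known to break are warnings, because the layer is a repository for
reported data, not a gatekeeper: an elementally unbalanced equation
(the Suzuki example is published that way), non-monotone conversion
series, and mode flags at odds with the volume field (the oxidation
example's immobilised catalyst bed is gram-absolute inside a flow
record). A `?` coefficient inside an otherwise-known stoichiometry list
is permitted and simply excluded from balance checking.

## Metrics

The E-factor machinery is defined with respect to the limiting
reactant: the reactant with the smallest feed/coefficient ratio, with
ties resolved in favour of the starting material. Recorded yields are
referenced to the starting material, which need not be limiting; when
it is not, the yield is rescaled onto the limiting basis through the
stoichiometric ratio (net product formed = Y·n_SM,in, so
ε = Y·n_SM,in·ν_mr/(n_mr·ν_p)).

Mapping a record onto the step symbols: gram-flagged agent entries go
into the catalyst mass c (grams is the catalyst base unit precisely
because "a mole of catalyst" is often ill-defined); mole-flagged agent
entries convert through their formula-layer molar mass into the solvent
mass s; product-side feeds other than net formation also land in s, so
that a species fed as solvent but listed as a product (the duplicate
case) is counted exactly once. Duplicate-marker slots contribute zero
where they stand. The work-up mass ω has no ProcAuxInfo field and is
zero; every report states this rather than hiding it. Flow records are
evaluated on a one-second basis — E and RME are mass ratios, so the
basis cancels, and the tests assert invariance under uniform feed
scaling. A consequence worth knowing: for a flow record with an
absolute (immobilised) catalyst bed, the whole bed mass is charged
against one second of product, which inflates E; that is what the
recorded data say, not an artifact of the implementation.

Two E-factor routes are kept deliberately distinct. The closed-form
route equation propagates yields from each step to the final one
(Π ε runs from the current step j through n inclusive — confirmed by
reproducing the worked example's figure) and handles non-1:1
stoichiometry through the ν_p/ν_mr factors. The direct ledger computes
(total mass in − product mass out)/product mass out from the raw feeds.
They coincide exactly when ν_p = ν_mr; for ν_p ≠ ν_mr the closed form's
bracket term deviates from the ledger (the oxidation example, ν_p = 2
against ν_mr = 1, differs by exactly that factor), the record's sole
worked E-factor cannot disambiguate the intent, and so both values are
reported whenever they differ instead of silently preferring one. The
multi-step form is additionally checked against a chained simulation in
which each step's limiting reactant is the upstream product and every
gram in and out is tracked; the two agree to machine precision.

The conversion definition as printed yields negative values for
consumed material while every tabulated conversion is positive; the
implementation returns the positive magnitude and rejects inputs that
would make it negative.

## Atomic weights

A single table of standard atomic weights (conventional/abridged
values, ≥ 5 significant figures, 85 elements) is bundled as a
plain-text file and can be overridden via `--weights`. Reproducing the
aziridination E-factor with this table gives 127.45 — within one unit
in the last printed digit of the published 127.4, whose source weight
table is unstated. Ignoring InChI charge/proton layers for mass
purposes (e.g. palladium acetate's formula layer sums to the
un-deprotonated components, 2 u high) moves the result by well under
one part in 10⁴ because catalyst feeds are orders of magnitude below
solvent feeds.

## Fixtures and the generator

The three worked examples are constructed programmatically from their
published per-species tables. Their InChIs were generated once from
structures and frozen as constants; a test regenerates each from its
SMILES with an independent InChI implementation and asserts byte
equality. Two interpretive choices are recorded: the Suzuki example's
reactor volume is "not reported" yet its amounts are absolute, so the
fixture uses the `batch` marker; and its phosphine ligand is never
identified structurally, so a representative trialkylphosphine body
stands in, labelled synthetic at its definition.

The random generator draws structurally valid records — 1–3 species per
reaction side, 0–3 agents, batch and flow modes, optional duplicate
listings, missing optional fields at probability 0.2, 1–2 condition
sets — deterministically from a seed, or injects exactly one named
violation for validator testing. It emulates the structural envelope of
the format, not chemistry: synthetic species have well-formed formula
layers but arbitrary connectivity, equations need not balance
(balance is a warning by design), and amounts are log-uniform rather
than realistic. Passing the round-trip and validator suites therefore
demonstrates codec and rule correctness over the format's state space,
not chemical plausibility of the inputs.

Suite sizes (500 round-trip seeds, 200 oracle ledgers, 100-seed
validator sweeps in the unit tests and 500 in the end-to-end suite)
keep the whole test run around a second while covering every
structural feature combination the generator can express.

## Known limitations

* Supported catalysts (e.g. a metal on an oxide carrier) cannot be one
  species; they are stored as separate entries, losing the association.
* No RInChI long-key/web-key hashing, no "no-structure" tokens, no
  RAuxInfo layer, and no kinetic fitting of time:conversion series.
* ω (work-up mass) is structurally absent from the layer, so computed
  E-factors are lower bounds with respect to purification waste.
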