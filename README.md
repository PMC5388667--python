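# procaux

A codec, validator and process-metrics calculator for the **ProcAuxInfo**
auxiliary layer of the RInChI reaction identifier.

Reaction databases are full of entries with no stoichiometry, no amounts,
no temperature and no yield, which makes automated route evaluation —
picking a synthesis by mass efficiency, say — impossible at scale.
ProcAuxInfo addresses this by appending the key process data to a RInChI
as a plain-text block that survives copy-and-paste:

```
RInChI=0.03.1S/group1<>group2<>group3/d+
$$PAIver|SM|stoich1|stoich2|T|P|t:X pairs|yields|amounts1|amounts2|amounts3|volume
```

(the `$$` block follows the RInChI on the same line). Twelve `|`-separated
fields carry the starting-material reference, stoichiometric coefficients,
temperature (K), pressure (Pa), time:conversion pairs (s, fraction),
yields (fractions), moles fed per group (mol, or mol/s in flow), agent
amounts with explicit `:m|g:f|a` unit/mode flags, and the reactor volume
in m³ (or `batch`). Unknowns are `?`; a species listed in two groups
carries a duplicate marker `x:G:I` pointing at its first occurrence so
its mass is never counted twice.

From a decoded record the package computes the mass-based green-chemistry
metrics, with every molar mass taken from the InChI formula layer:

* yield `Y = (n_out − n_in)/n_SM,in` and conversion `X`,
* atom economy `AE = ν_p MR_p / Σ ν_r MR_r`,
* stoichiometric factor `SF = 1 + excess mass / stoichiometric mass`,
* the E-factor across an n-step route with yield propagation,

```
E_total = (1/MR_pn) Σ_j (1/Π_{k=j..n} ε_k) ·
          [ (ν_pj/ν_mrj)(MR_pj/AE_j)(SF_j − (ν_mrj/ν_pj) ε_j AE_j)
            + (c_j + s_j + ω_j)/n_mrj ]
```

* and reaction mass efficiency `RME = product mass out / total mass in`.

A brute-force mass ledger (everything in, product out) is kept alongside
the closed form as an independent oracle; the two agree identically for
`ν_p = ν_mr` and are both reported when they differ.

## Worked example

The package ships three published reactions as first-class fixtures.
The first is a palladium-catalysed C–H aziridination run in flow
(393 K, 6 MPa, yield 0.90 on the bicyclic aziridine, toluene solvent):

```
$ python -c "import procaux as px; print(px.example1().to_string())" > ex1.txt
$ procaux metrics ex1.txt --product 2:3
desired product: 2:3
  n_mr (limiting feed): 8.3e-07 mol
  yield w.r.t. limiting reactant: 0.9
  atom economy: 0.3238
  stoichiometric factor: 1
  catalyst mass c: 0 g; solvent/auxiliary mass s: 0.01449 g
  work-up mass: not recorded in ProcAuxInfo; omega = 0 g assumed
  E-factor (route equation): 127.5
  reaction mass efficiency: 0.007785
```

Reading: both reactants are fed at the exact 1:1 stoichiometric ratio
(SF = 1), about a third of the reactant mass can end up in the product
at best (AE = 0.32), and per gram of aziridine about 127 g of waste
leave the process — dominated by the toluene feed, and in the range
expected of pharmaceutical chemistry. `procaux decode ex1.txt` prints
the full species/condition report, and `procaux validate --strict`
turns warnings (e.g. an unbalanced published equation) into failures.

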