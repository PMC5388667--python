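import pytest

import procaux as px
from procaux import fixtures
from procaux.procaux_codec import BATCH, TimeConversionPair


# ---------------------------------------------------------------------------
# printed table values survive the encode -> decode cycle exactly

def test_example1_table_values(ex1):
    rec = px.ProcessedReaction.from_string(ex1.to_string()).conditions[0]
    assert rec.temperature == 393
    assert rec.pressure == 6e6
    assert rec.reactor_volume == 1e-5
    assert len(rec.time_conversion) == 10
    assert TimeConversionPair(60, 0.06) == rec.time_conversion[0]
    assert dict((p.time, p.conversion) for p in rec.time_conversion)[540] == 1.00
    azir = px.species_ref(ex1, fixtures.AZIRIDINE_PRODUCT)
    assert rec.yields[azir.index - 1] == 0.90
    # all six feeds, wherever their canonical slots landed
    feeds = {e.value for e in rec.amounts1 + rec.amounts2 if e.value}
    assert feeds == {8.3e-7, 8.3e-6}
    g3 = {e.value for e in rec.amounts3 if e.value is not None}
    assert g3 == {4.2e-9, 1.7e-6, 1.5e-4}


def test_example1_starting_material_and_duplicate(ex1):
    rec = ex1.conditions[0]
    sm_body = px.resolve_species(ex1.rinchi, rec.starting_material)
    assert sm_body == fixtures.SM_MORPHOLINONE
    acoh = px.species_ref(ex1, fixtures.ACETIC_ACID)  # first occurrence: product side
    assert acoh.group == ex1.rinchi.product_group
    dup = [e for e in rec.amounts3 if e.is_duplicate]
    assert len(dup) == 1 and dup[0].duplicate_of == acoh


def test_example2_table_values(ex2):
    rec = px.ProcessedReaction.from_string(ex2.to_string()).conditions[0]
    assert rec.temperature == 388
    assert rec.pressure == 8e6
    assert rec.reactor_volume == 9e-4
    assert rec.time_conversion == (TimeConversionPair(9, 0.25),)
    benz = px.species_ref(ex2, fixtures.BENZALDEHYDE)
    assert rec.yields[benz.index - 1] == 0.25
    ru = px.species_ref(ex2, fixtures.RUTHENIUM)
    entry = rec.amounts3[ru.index - 1]
    assert (entry.value, entry.unit, entry.mode) == (9e-3, "g", "a")
    al = px.species_ref(ex2, fixtures.ALUMINA)
    assert rec.amounts3[al.index - 1].value == 0.991
    bnoh = px.species_ref(ex2, fixtures.BENZYL_ALCOHOL)
    amounts_r = rec.amounts2 if bnoh.group == 2 else rec.amounts1
    assert amounts_r[bnoh.index - 1].value == 3.3e-5


def test_example3_table_values(ex3):
    rec = px.ProcessedReaction.from_string(ex3.to_string()).conditions[0]
    assert rec.temperature == 363
    assert rec.pressure is None
    assert rec.time_conversion == ()
    assert rec.reactor_volume == BATCH
    ptol = px.species_ref(ex3, fixtures.PHENYLTOLUENE)
    assert rec.yields[ptol.index - 1] == 0.89
    base = px.species_ref(ex3, fixtures.SODIUM_CARBONATE)
    assert rec.amounts3[base.index - 1].is_missing
    sm_body = px.resolve_species(ex3.rinchi, rec.starting_material)
    assert sm_body == fixtures.BROMOTOLUENE


def test_examples_round_trip_byte_identically(ex1, ex2, ex3):
    for p in (ex1, ex2, ex3):
        text = p.to_string()
        again = px.ProcessedReaction.from_string(text)
        assert again == p
        assert again.to_string() == text


# ---------------------------------------------------------------------------
# the assemble builder

def test_assemble_rejects_conflicting_duplicate_amounts():
    rows = [
        px.SpeciesRow("reactant", "CH4/c1", coeff=1, amount=1.0),
        px.SpeciesRow("product", "CH4O/c1-2", coeff=1, amount=2.0),
        px.SpeciesRow("agent", "CH4O/c1-2", amount=3.0),  # second amount for methanol
    ]
    with pytest.raises(ValueError, match="two amounts"):
        px.assemble(rows, [px.ConditionSpec(reactor_volume=BATCH)])


def test_assemble_rejects_gram_amounts_outside_group3():
    rows = [
        px.SpeciesRow("reactant", "CH4/c1", coeff=1),
        px.SpeciesRow("product", "CH4O/c1-2", coeff=1),
        px.SpeciesRow("agent", "CH4/c1", amount=5.0, unit="g"),
    ]
    with pytest.raises(ValueError, match="gram amounts"):
        px.assemble(rows, [px.ConditionSpec(reactor_volume=BATCH)])


def test_assemble_direction_follows_sort_order():
    """Whichever side sorts first becomes group1 and the flag records
    where the reactants went."""
    p = px.assemble(
        [
            px.SpeciesRow("reactant", "ZZZ9/c1", coeff=1, amount=1.0),
            px.SpeciesRow("product", "C2H4/c1-2", coeff=1),
        ],
        [px.ConditionSpec(reactor_volume=BATCH)],
    )
    assert p.rinchi.direction is px.Direction.BACKWARD
    assert p.rinchi.reactant_group == 2


# ---------------------------------------------------------------------------
# random generator

def test_generator_determinism():
    cfg = px.GeneratorConfig(seed=42)
    assert px.random_reaction(cfg) == px.random_reaction(cfg)
    assert px.random_reaction(cfg) != px.random_reaction(px.GeneratorConfig(seed=43))


def test_generator_unknown_breakage_code():
    with pytest.raises(ValueError, match="unknown breakage"):
        px.GeneratorConfig(breakage="nonsense")


def test_generator_covers_structural_variety():
    """Across seeds the generator must exercise duplicates, empty agent
    groups, batch and flow modes and multi-block condition sets."""
    saw = {"dup": False, "empty_g3": False, "batch": False, "flow": False, "multi": False}
    for seed in range(80):
        p = px.random_reaction(px.GeneratorConfig(seed=seed))
        rec = p.conditions[0]
        if any(e.is_duplicate for e in (rec.amounts3 or ())):
            saw["dup"] = True
        if not p.rinchi.group3:
            saw["empty_g3"] = True
        saw["batch" if rec.is_batch else "flow"] = True
        if len(p.conditions) > 1:
            saw["multi"] = True
    assert all(saw.values()), saw


# ---------------------------------------------------------------------------
# tabular exchange format

def test_table_round_trip(ex1):
    table = px.to_table(ex1)
    p = px.from_table(table)
    assert p.rinchi == ex1.rinchi
    assert p.conditions == ex1.conditions


def test_table_multi_block():
    base = (
        "species\treactant\tCH4/c1\t1\t1e-3\tm\t-\t?\tsm\n"
        "species\tproduct\tCH4O/c1-2\t1\t0\tm\t-\t0.5\t-\n"
        "temperature\t300\nvolume\tbatch\n"
        "%%\n"
        "species\treactant\tCH4/c1\t1\t2e-3\tm\t-\t?\tsm\n"
        "species\tproduct\tCH4O/c1-2\t1\t0\tm\t-\t0.7\t-\n"
        "temperature\t320\nvolume\tbatch\n"
    )
    p = px.from_table(base)
    assert len(p.conditions) == 2
    assert p.conditions[0].temperature == 300
    assert p.conditions[1].temperature == 320
    sm_amounts = p.conditions[1].amounts1 or p.conditions[1].amounts2
    values = {e.value for e in sm_amounts if e.value}
    assert 2e-3 in values


# ---------------------------------------------------------------------------
# frozen InChI constants

def test_frozen_inchis_regenerate_with_rdkit():
    """Cross-check: every fixture InChI written from a structure must be
    exactly what an independent InChI generator produces for it (the
    aziridination product is checked as a self-round-trip because it was
    transcribed, not generated)."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem.inchi import MolFromInchi, MolToInchi

    RDLogger.DisableLog("rdApp.*")
    by_smiles = {
        fixtures.SM_MORPHOLINONE: "O=C1OCC(C)(C)NC1(C)C",
        fixtures.DIACETOXYIODOBENZENE: "CC(=O)OI(OC(C)=O)c1ccccc1",
        fixtures.IODOBENZENE: "Ic1ccccc1",
        fixtures.ACETIC_ACID: "CC(O)=O",
        fixtures.PD_ACETATE: "CC(=O)[O-].CC(=O)[O-].[Pd+2]",
        fixtures.ACETIC_ANHYDRIDE: "CC(=O)OC(C)=O",
        fixtures.TOLUENE: "Cc1ccccc1",
        fixtures.BENZYL_ALCOHOL: "OCc1ccccc1",
        fixtures.OXYGEN: "O=O",
        fixtures.BENZALDEHYDE: "O=Cc1ccccc1",
        fixtures.WATER: "O",
        fixtures.RUTHENIUM: "[Ru]",
        fixtures.ALUMINA: "[Al+3].[Al+3].[O-2].[O-2].[O-2]",
        fixtures.PHENYLBORONIC_ACID: "OB(O)c1ccccc1",
        fixtures.BROMOTOLUENE: "Cc1ccc(Br)cc1",
        fixtures.PHENYLTOLUENE: "Cc1ccc(-c2ccccc2)cc1",
        fixtures.PHOSPHINE_LIGAND_SYNTHETIC: "CC(C)(C)P(C(C)(C)C)C(C)(C)C",
        fixtures.NMP: "CN1CCCC1=O",
        fixtures.PD_ACAC: "CC(=O)C=C(C)[O-].CC(=O)C=C(C)[O-].[Pd+2]",
        fixtures.SODIUM_CARBONATE: "[Na+].[Na+].[O-]C([O-])=O",
    }
    for body, smiles in by_smiles.items():
        mol = Chem.MolFromSmiles(smiles)
        assert MolToInchi(mol) == "InChI=1S/" + body, body
    full = "InChI=1S/" + fixtures.AZIRIDINE_PRODUCT
    assert MolToInchi(MolFromInchi(full)) == full
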