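"""Loading, validation and query semantics of the knowledge universe."""

import pytest

from volatilome import universe as U
from volatilome.universe import UniverseError, load_universe, write_universe


def _write_minimal(tmp_path, **overrides):
    """One-compound universe; individual tables can be overridden."""
    tables = {
        "cogs.tsv": "cog_id\tsource_studies\tlinked_ko_ids\tlinked_protein_ids\n"
                    "COG1\tWeiss\t\t\n",
        "proteins.tsv": "protein_id\tec_numbers\tdomain\n",
        "kos.tsv": "ko_id\tlinked_cog_ids\tec_numbers\n",
        "genomes.tsv": "genome_id\tdomain\tphylum\tko_ids\n",
        "enzymes.tsv": "ec_number\treaction_ids\tpathway_ids\n",
        "reactions.tsv": "reaction_id\tsubstrate_ids\tproduct_ids\treversible\n",
        "compounds.tsv": "compound_id\tname\tsmiles\tformula\tmolar_mass\tinchikey\n"
                         "C1\tethanol\tCCO\tC2H6O\t46.07\t\n",
        "pathways.tsv": "pathway_id\tname\tec_numbers\treaction_ids\n",
        "emissions.tsv": "compound_id\tconfirmed\tsource\n",
        "chem_taxonomy.tsv": "compound_id\tsuperclass\tclass\tsubclass\n",
    }
    tables.update(overrides)
    for name, text in tables.items():
        (tmp_path / name).write_text(text)
    return tmp_path


def test_minimal_universe_loads_single_compound(tmp_path):
    uni = load_universe(_write_minimal(tmp_path))
    assert set(uni.compounds) == {"C1"}
    assert uni.compounds["C1"].molar_mass == pytest.approx(46.07)


def test_missing_table_is_fatal(tmp_path):
    _write_minimal(tmp_path)
    (tmp_path / "emissions.tsv").unlink()
    with pytest.raises(UniverseError, match="emissions"):
        load_universe(tmp_path)


def test_dangling_reaction_compound_names_the_reaction(tmp_path):
    d = _write_minimal(
        tmp_path,
        **{"reactions.tsv": "reaction_id\tsubstrate_ids\tproduct_ids\treversible\n"
                            "R9\tC-unknown\t\tfalse\n"},
    )
    with pytest.raises(UniverseError, match="R9"):
        load_universe(d)


def test_duplicate_primary_id_is_fatal(tmp_path):
    d = _write_minimal(
        tmp_path,
        **{"compounds.tsv": "compound_id\tname\tsmiles\tformula\tmolar_mass\tinchikey\n"
                            "C1\tethanol\tCCO\tC2H6O\t46.07\t\n"
                            "C1\tdup\tCCO\tC2H6O\t46.07\t\n"},
    )
    with pytest.raises(UniverseError, match="duplicate"):
        load_universe(d)


def test_generated_universe_counts_match_manifest(default_universe, tmp_path):
    uni, truth = default_universe
    for table, count in truth.table_counts.items():
        assert len(getattr(uni, table)) == count


def test_roundtrip_stability(default_universe, tmp_path):
    uni, _ = default_universe
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_universe(uni, d1)
    reloaded = load_universe(d1)
    write_universe(reloaded, d2)
    for f1 in sorted(d1.iterdir()):
        assert f1.read_bytes() == (d2 / f1.name).read_bytes()


def test_compounds_for_enzyme_direction_semantics(mini_universe):
    # irreversible: substrates only
    assert mini_universe.compounds_for_enzyme("1.1.1.1") == {"C1"}
    # reversible: products are associated too, unless substrates_only
    assert mini_universe.compounds_for_enzyme("2.2.2.2") == {"C2", "C3"}
    assert mini_universe.compounds_for_enzyme("2.2.2.2", substrates_only=True) == {"C2"}
    # no reactions -> empty set
    assert mini_universe.compounds_for_enzyme("3.3.3.3") == set()


def test_unknown_ids_raise(mini_universe):
    with pytest.raises(KeyError):
        mini_universe.compounds_for_enzyme("9.9.9.9")
    with pytest.raises(KeyError):
        mini_universe.pathways_for_enzyme("9.9.9.9")
    with pytest.raises(KeyError):
        mini_universe.enzymes_for_pathway("nope")


def test_pathway_enzyme_inverse_consistency(default_universe):
    uni, _ = default_universe
    for pid in uni.pathways:
        for ec in uni.enzymes_for_pathway(pid):
            assert pid in uni.pathways_for_enzyme(ec)
    for ec in uni.enzymes:
        for pid in uni.pathways_for_enzyme(ec):
            assert ec in uni.enzymes_for_pathway(pid)


def test_queries_are_pure_and_bounded(default_universe):
    uni, _ = default_universe
    all_compounds = set(uni.compounds)
    for ec in list(uni.enzymes)[:50]:
        first = uni.compounds_for_enzyme(ec)
        assert first == uni.compounds_for_enzyme(ec)
        assert first <= all_compounds


def test_invalid_ec_number_rejected():
    with pytest.raises(UniverseError):
        U.EnzymeEntry("1.2.3", frozenset(), frozenset())
    with pytest.raises(UniverseError):
        U.EnzymeEntry("a.b.c.d", frozenset(), frozenset())
    # dash placeholder in the last field is legal and never expanded
    U.EnzymeEntry("1.2.3.-", frozenset(), frozenset())


def test_study_vocabulary_enforced():
    with pytest.raises(UniverseError):
        U.OrthologGroup("COGX", frozenset({"NotAStudy"}), frozenset(), frozenset())
    with pytest.raises(UniverseError):
        U.OrthologGroup("COGX", frozenset(), frozenset(), frozenset())
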