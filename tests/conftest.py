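import pytest

from volatilome import universe as U
from volatilome.pipeline import run_all
from volatilome.synth import GeneratorConfig, generate_universe


@pytest.fixture(scope="session")
def default_universe():
    """Default synthetic universe with planted truth (seed 0, noiseless)."""
    return generate_universe(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_report(default_universe):
    uni, _ = default_universe
    return run_all(uni)


def build_mini_universe() -> U.Universe:
    """Hand-built universe with enzymes and KOs sitting on each side of the
    two translation distribution criteria.

    * EC 1.1.1.1: proteins span all three domains; KO K00001 spans two
      bacterial and two archaeal phyla -> accepted by both routes.
    * EC 2.2.2.2: proteins in Bacteria+Archaea only; KO K00002 spans three
      bacterial phyla but one archaeal -> rejected by both routes.
    * EC 3.3.3.3: KO K00003 in eukaryotes only -> rejected by the KO route.
    """
    compounds = {
        "C1": U.CompoundRecord("C1", "ethanol", "CCO", "C2H6O", 46.07),
        "C2": U.CompoundRecord("C2", "acetaldehyde", "CC=O", "C2H4O", 44.05),
        "C3": U.CompoundRecord("C3", "acetic acid", "CC(O)=O", "C2H4O2", 60.05),
    }
    reactions = {
        "R1": U.Reaction("R1", frozenset({"C1"}), frozenset({"C2"}), False),
        "R2": U.Reaction("R2", frozenset({"C2"}), frozenset({"C3"}), True),
    }
    enzymes = {
        "1.1.1.1": U.EnzymeEntry("1.1.1.1", frozenset({"R1"}), frozenset({"P1"})),
        "2.2.2.2": U.EnzymeEntry("2.2.2.2", frozenset({"R2"}), frozenset({"P1"})),
        "3.3.3.3": U.EnzymeEntry("3.3.3.3", frozenset(), frozenset()),
    }
    pathways = {
        "P1": U.Pathway("P1", "mini pathway", frozenset({"1.1.1.1", "2.2.2.2"})),
    }
    proteins = {
        "SP1": U.ProteinRecord("SP1", frozenset({"1.1.1.1"}), "Bacteria"),
        "SP2": U.ProteinRecord("SP2", frozenset({"1.1.1.1"}), "Archaea"),
        "SP3": U.ProteinRecord("SP3", frozenset({"1.1.1.1"}), "Eukaryota"),
        "SP4": U.ProteinRecord("SP4", frozenset({"2.2.2.2"}), "Bacteria"),
        "SP5": U.ProteinRecord("SP5", frozenset({"2.2.2.2"}), "Archaea"),
    }
    cogs = {
        "COG1": U.OrthologGroup(
            "COG1", frozenset({"Weiss", "Delaye", "Mirkin", "Wang"}),
            frozenset({"K00001", "K00002", "K00003"}),
            frozenset({"SP1", "SP2", "SP3", "SP4", "SP5"}),
        ),
    }
    kos = {
        "K00001": U.KOEntry("K00001", frozenset({"COG1"}), frozenset({"1.1.1.1"})),
        "K00002": U.KOEntry("K00002", frozenset({"COG1"}), frozenset({"2.2.2.2"})),
        "K00003": U.KOEntry("K00003", frozenset({"COG1"}), frozenset({"3.3.3.3"})),
    }
    genomes = {
        "GB1": U.Genome("GB1", "Bacteria", "b-phy-1", frozenset({"K00001", "K00002"})),
        "GB2": U.Genome("GB2", "Bacteria", "b-phy-2", frozenset({"K00001", "K00002"})),
        "GB3": U.Genome("GB3", "Bacteria", "b-phy-3", frozenset({"K00002"})),
        "GA1": U.Genome("GA1", "Archaea", "a-phy-1", frozenset({"K00001", "K00002"})),
        "GA2": U.Genome("GA2", "Archaea", "a-phy-2", frozenset({"K00001"})),
        "GE1": U.Genome("GE1", "Eukaryota", "e-phy-1", frozenset({"K00003"})),
        "GE2": U.Genome("GE2", "Eukaryota", "e-phy-2", frozenset({"K00003"})),
    }
    return U.Universe(
        cogs=cogs, proteins=proteins, kos=kos, genomes=genomes,
        enzymes=enzymes, reactions=reactions, compounds=compounds,
        pathways=pathways, emissions={}, chem_taxonomy={},
    )


@pytest.fixture()
def mini_universe():
    return build_mini_universe()
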