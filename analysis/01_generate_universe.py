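"""Generate the default synthetic knowledge universe with planted truth.

Writes the TSV universe and its truth manifest to results/universe/.
The planted signal: 40 ancestral enzymes (all passing both translation
criteria), concentrated in 3 designated pathways, linking 12 genuinely
high-volatility, emission-confirmed, broadly supported true VOCs, plus
one decoy compound per conservative-filter criterion.
"""

from pathlib import Path

from volatilome.synth import GeneratorConfig, generate_universe

OUT = Path(__file__).resolve().parent.parent / "results" / "universe"


def main() -> None:
    config = GeneratorConfig(seed=0)
    _, truth = generate_universe(config, out_dir=OUT)
    print(f"wrote universe to {OUT}")
    print(f"table sizes: {truth.table_counts}")
    print(f"planted: {len(truth.luca_ecs)} ancestral enzymes, "
          f"{len(truth.enriched_pathways)} enriched pathways, "
          f"{len(truth.true_vocs)} true VOCs, {len(truth.decoys)} decoys")


if __name__ == "__main__":
    main()
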