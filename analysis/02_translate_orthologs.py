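"""Translate the ancestral ortholog groups to enzymes by both routes.

The curated-protein route requires each enzyme's proteins to span all
three domains of life; the ortholog-database route requires each KO to
appear in at least two phyla of each prokaryotic domain.  The common
list is their intersection.  Writes per-method compound tables to
results/.
"""

from pathlib import Path

from volatilome.translate import (
    common_compound_table,
    common_enzymes,
    compound_study_table,
    translate_ko_style,
    translate_swissprot_style,
)
from volatilome.universe import load_universe

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    uni = load_universe(RESULTS / "universe")
    cogs = set(uni.cogs)
    r1 = translate_swissprot_style(cogs, uni)
    r2 = translate_ko_style(cogs, uni)
    common = common_enzymes(r1, r2, uni)
    for r in (r1, r2):
        table = compound_study_table(r, uni)
        table.to_csv(RESULTS / f"compounds_{r.method}.tsv", sep="\t", index=False)
        print(f"{r.method}: {len(r.accepted_ecs)} enzymes -> "
              f"{len(table)} linked compounds")
    common_compound_table(common, uni).to_csv(
        RESULTS / "compounds_common.tsv", sep="\t", index=False
    )
    print(f"common list: {len(common.ecs)} enzymes shared by both routes, "
          f"{len(common.compounds)} associated compounds")


if __name__ == "__main__":
    main()
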