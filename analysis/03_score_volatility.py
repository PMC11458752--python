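"""Score every compound's volatility with the group-contribution model.

log10 P = b0 + sum_k v_k b_k (atm, 293.15 K), converted to the
saturation mass concentration C* = 1e6*M*P/(RT) in ug m^-3 and binned
into the relative volatility index (nonvolatile < -2 < low < 0 <
intermediate <= 2 < high).  Writes results/volatility.tsv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from volatilome.universe import load_universe
from volatilome.volatility import assess_universe

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    uni = load_universe(RESULTS / "universe")
    results = assess_universe(uni)
    rows = [
        {
            "compound_id": r.compound_id,
            "name": uni.compounds[r.compound_id].name,
            "log10_p_atm": r.log10_p,
            "log10_cstar_ugm3": r.log10_cstar,
            "category": r.category if r.assessable else "unassessable",
            "warnings": "|".join(r.warnings),
        }
        for _, r in sorted(results.items())
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "volatility.tsv", sep="\t", index=False)
    tally = Counter(row["category"] for row in rows)
    print(f"assessed {len(rows)} compounds: {dict(sorted(tally.items()))}")
    ethanol = next(r for r in rows if r["name"] == "ethanol")
    print(f"e.g. ethanol: log10 P = {ethanol['log10_p_atm']:.3f} atm, "
          f"log10 C* = {ethanol['log10_cstar_ugm3']:.2f} -> {ethanol['category']}")


if __name__ == "__main__":
    main()
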