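"""Pathway enrichment and the conservative ancestral-VOC filter.

Hypergeometric enrichment of common-list enzymes per pathway, then the
six-criterion conservative filter with full per-compound traces and the
stage funnel.  Writes results/enrichment.tsv, filter_traces.tsv and
final_vocs.tsv, and checks recovery against the planted truth manifest.
"""

import json
from pathlib import Path

import pandas as pd

from volatilome.pipeline import run_all
from volatilome.universe import load_universe

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    uni = load_universe(RESULTS / "universe")
    report = run_all(uni, out_dir=RESULTS)
    print("funnel:", " -> ".join(f"{k}={v}" for k, v in report.funnel.items()))
    print(f"enriched pathways (p < 0.05): {report.enriched_pathways}")
    print("final conservative VOC list:")
    for voc in report.final_vocs:
        print(f"  {voc['compound_id']} {voc['name']} [{voc['studies']}]")

    truth = json.loads((RESULTS / "universe" / "truth_manifest.json").read_text())
    final = {v["compound_id"] for v in report.final_vocs}
    planted = set(truth["true_vocs"])
    recall = len(final & planted) / len(planted)
    precision = len(final & planted) / len(final) if final else 0.0
    print(f"recovery vs planted truth: precision {precision:.2f}, recall {recall:.2f}")


if __name__ == "__main__":
    main()
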