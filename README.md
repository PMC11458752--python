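# volatilome

Inference of an ancestral volatile metabolome from ortholog-group
reconstructions of early life.

Reconstructions of the last universal common ancestor (LUCA) are usually
published as sets of clusters of orthologous groups (COGs).  This package
asks what those gene sets imply about the *volatile* side of ancestral
metabolism: which volatile organic compounds (VOCs) were plausibly cycled
by early life.  It is written for researchers in molecular evolution and
biogeochemistry who want a tested, reproducible version of that pipeline —
and a synthetic benchmark with planted ground truth to validate every
stage without any external database download.

## The method

1. **Ortholog → enzyme translation** under two independent taxonomic
   distribution criteria: a curated-protein route (an EC number is kept
   only if proteins carrying it span Bacteria, Archaea and Eukaryota) and
   an ortholog-database route (a KO is kept only if present in ≥ 2
   distinct phyla in *each* of Bacteria and Archaea).  The intersection of
   the two enzyme lists is the **common list**; study provenance (8 source
   reconstructions) is propagated throughout.
2. **Enzyme → metabolite linkage**: a compound is associated with an
   enzyme if it is a substrate of a reaction that enzyme catalyses
   (products too, for reactions flagged reversible).
3. **Volatility** by group contribution:

   log₁₀ *P* = *b*₀ + Σₖ *v*ₖ *b*ₖ   (atm, 293.15 K)

   where *v*ₖ counts functional groups of kind *k* (carbon number,
   hydroxyl, carboxylic acid, …) matched from SMILES by precedence-ordered
   SMARTS.  The saturation mass concentration
   *C*\* = 10⁶·*M·P*/(*RT*) (µg m⁻³) bins each compound into a relative
   volatility index: nonvolatile (log₁₀ *C*\* < −2), low (−2–0),
   intermediate (0–2), high (> 2).
4. **Class profiles**: percentage breakdown of each genome's (and each
   source study's) high-volatility compounds by chemical subclass,
   compared with an exact two-sided rank-sum test.
5. **Pathway enrichment**: upper-tail hypergeometric probability that a
   pathway holds its observed number of ancestral enzymes,
   P(X ≥ k), X ~ Hypergeom(N, K, n), computed in log space.
6. **Conservative filter**: a VOC survives only if it is on the common
   list, organic, high-volatility, emission-confirmed in modern
   organisms, a substrate of an ancestral enzyme via a reaction inside an
   enriched pathway, and supported by ≥ 4 of the 8 source studies.  Every
   candidate receives a full trace; the stage funnel is reported.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic universe (300 enzymes, 40 planted ancestral enzymes, 3 enriched
pathways, 12 planted true VOCs, one decoy per filter criterion):

```sh
python analysis/01_generate_universe.py
python analysis/02_translate_orthologs.py
python analysis/03_score_volatility.py
python analysis/04_profile_classes.py
python analysis/05_enrich_and_filter.py
python analysis/06_noise_robustness.py
```

Output of steps 02–05 (seed 0):

```
swissprot_style: 42 enzymes -> 31 linked compounds
ko_style: 41 enzymes -> 30 linked compounds
common list: 40 enzymes shared by both routes, 29 associated compounds
assessed 250 compounds: {'high': 178, 'intermediate': 9, 'low': 2, 'nonvolatile': 61}
e.g. ethanol: log10 P = -1.316 atm, log10 C* = 7.97 -> high
funnel: common=29 -> organic=28 -> high_volatility=22 -> emission_confirmed=14
        -> enriched_supported=13 -> final=12
enriched pathways (p < 0.05): ['P001', 'P002', 'P003']
recovery vs planted truth: precision 1.00, recall 1.00
```

Reading: of the 29 compounds linked to the 40 common-list enzymes, one is
inorganic, six are not high-volatility, eight lack modern emission
evidence, one sits only in a non-enriched pathway, and one has too few
supporting studies — the 12 survivors are exactly the planted true VOCs
(ethanol's log₁₀ *C*\* of 7.97 µg m⁻³ places it far above the high-
volatility threshold of 2).  Step 06 shows mean recall stays ≥ 0.84 even
when 40 % of planted KOs lose a required phylum, with precision 1.0
throughout.

The same stages are exposed as a CLI (`volatilome generate / translate /
volatility / profile / enrich / filter / run-all`); see
`volatilome --help`.

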