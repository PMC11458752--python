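# Methods

## Scope and model

The package infers a conservative ancestral volatile-organic-compound
(VOC) list from ortholog-group reconstructions of early life.  Its
model of the problem is relational: ortholog groups (COGs, each tagged
with the subset of eight source reconstructions that proposed it) link
to proteins and KOs; KOs and proteins carry EC numbers; enzymes
catalyse reactions over compounds; enzymes belong to pathways.  All
downstream claims are derived by querying this universe, never by
consulting external services, so the same code runs identically on a
synthetic benchmark and on tables exported from real knowledge bases.

## Ortholog → enzyme translation

Two deliberately independent routes translate an ancestral COG set to
enzymes, each with a taxonomic distribution criterion that guards
against lineage-specific or horizontally acquired functions:

* **Curated-protein route** — an EC number is accepted if some input
  COG links to protein records carrying it and, across *all* protein
  records carrying that EC, Bacteria, Archaea and Eukaryota are all
  represented.  Evaluating the span over the whole protein table (not
  just the COG-linked records) mirrors checking an enzyme's
  distribution in a curated database; a `per_cog_domains` flag gives
  the narrower alternative.
* **Ortholog-database route** — a KO is accepted if linked to an input
  COG and found in genomes spanning at least two distinct phyla in
  each of Bacteria and Archaea.  The phrase "in both prokaryotic
  domains" is read per-domain (≥ 2 phyla in each); this is the stricter
  of the two possible readings and the one implemented
  (`min_phyla` is configurable).

The **common list** is the intersection of the two accepted-EC sets,
with study provenance merged by union — an enzyme vouched for by both
routes inherits the support of every contributing COG.  Compounds are
associated with an enzyme when they are substrates of one of its
reactions; products of reactions flagged reversible are included too
(`substrates_only` disables this), since a reversible step's "substrate"
is a direction convention rather than chemistry.  EC wildcards (dash in
the fourth field) are opaque identifiers and are never expanded.

## Volatility

Vapor pressure is estimated by group contribution:
log₁₀ P(atm) = b₀ + Σₖ vₖ bₖ at a reference temperature of 293.15 K.
The coefficient table (`data/simpol_coefficients.tsv`) holds the
intercept (1.79), the per-carbon term (−0.438) and terms for aromatic
rings, non-aromatic C=C, hydroxyl, aldehyde, ketone, carboxylic acid,
ester, ether, phenol, nitro, primary/secondary/tertiary amine and
amide.  Functional groups are counted from SMILES with RDKit SMARTS
under a fixed precedence (carboxylic acid > ester > amide > aldehyde >
ketone > phenol > hydroxyl > ether; amines by substitution degree), so
that every oxygen/nitrogen atom is assigned to at most one group —
group-contribution sums require disjoint assignments.  Only the "core"
atoms of a match (the heteroatoms plus the carbonyl carbon) are marked
consumed; flanking carbons are not, so e.g. phenylpyruvate counts one
acid *and* one ketone.

Heteroatom features with no coefficient (S, Se, P, halogens) are
tallied as `unmatched_heteroatom`, contribute zero, and raise a
warning rather than a guessed value; small molecules in this situation
(e.g. methaneselenol) still classify as highly volatile through their
low carbon count.  The estimator ignores hydrogen bonding and other
intermolecular corrections, and therefore tends to overstate the
volatility of strongly associating compounds — the emission-evidence
filter downstream exists precisely to absorb this bias.

Conversion to a saturation mass concentration uses the ideal gas law,
C* = 10⁶·M·P/(R·T) µg m⁻³ with R = 8.20574×10⁻⁵ m³ atm K⁻¹ mol⁻¹, and
the relative volatility index bins log₁₀ C* at −2, 0 and 2:
nonvolatile (< −2), low [−2, 0), intermediate [0, 2], high (> 2).  The
boundaries are half-open exactly as written; 2.0 is intermediate.
Temperature is configurable (default 293.15 K); the coefficients are
fixed-temperature values, and no temperature interpolation of bₖ is
attempted.  Compounds without a structure are flagged unassessable and
carried through, never dropped.

## Class profiles

Compounds are classified by a three-level lookup table
(superclass/class/subclass) shipped with the universe — a stand-in for
a structure-based chemical taxonomy service; unknown compounds get an
explicit `unclassified` sentinel.  A profile is the subclass percentage
breakdown of the unique high-volatility compounds reachable from an
entity (genome → KO → EC → reaction → substrates, or a study's
predicted set); profiles of non-empty entities sum to 100.

The ancestral-vs-modern comparison tests each subclass with a
two-sided rank-sum statistic.  Because "compare against the average of
the modern domains" collapses to n = 3 and is statistically
degenerate, the default compares the 8 study percentages against all
per-genome percentages pooled across domains; `per_domain_means`
restores the collapsed variant.  The null distribution is computed
exactly (a subset-sum dynamic program over doubled midranks, valid
under ties) whenever both sides have ≤ 10 observations, and by the
normal approximation with tie and continuity correction otherwise; the
two branches agree within 0.01 at the crossover.  Raw p-values are
reported by default; Benjamini–Hochberg adjustment is available behind
a flag.

## Enrichment and the conservative filter

Pathway enrichment is the upper-tail hypergeometric probability
P(X ≥ k) for k ancestral enzymes among a pathway's n members, drawn
from N enzymes of which K are ancestral, accumulated from log-pmf
terms to avoid underflow.  The sampling universe is every enzyme in
the enzyme table, including pathway-less ones (`pathway_members_only`
restricts it).  α defaults to 0.05 on raw p-values.

The conservative filter keeps a compound only if all of the following
hold: common-list membership; organic (contains carbon, excluding the
conventional inorganic-carbon species CO₂, CO, carbonate/bicarbonate
and cyanide); high volatility; confirmed emission evidence; linkage to
an ancestral enzyme through a reaction lying *inside* an enriched
pathway's reaction scope (pathway membership of the enzyme alone is
not enough — the same enzyme can act in an unrelated pathway); and
support from ≥ 4 of the 8 source studies, counted over the union of
both routes' provenance.  Every candidate receives a complete
criterion trace, and the funnel of survivors after each stage is part
of the report.

Pathways may declare an explicit reaction scope (`reaction_ids` column);
when absent, the scope defaults to the union of the member enzymes'
reactions.

## Synthetic universe and what it does (not) show

The generator plants: 40 ancestral enzymes whose proteins span all
three domains and whose KOs span ≥ 2 phyla in each prokaryotic domain;
3 designated pathways concentrating those enzymes; and 12 true VOCs
drawn from a template library of small molecules with hand-certified
functional-group counts, each emission-confirmed, organic, highly
volatile and supported by ≥ 4 studies.  Each true VOC is linked
through **two** independently planted enzymes with separate KOs, so a
per-KO distribution-noise probability p removes a VOC only with
probability ≈ p²; this is why recall degrades gracefully (≈ 0.9 at
p = 0.3) — a design choice, not a tuning.  Decoy compounds each
violate exactly one filter criterion (inorganic, non-volatile,
no emission evidence, non-enriched pathway, few studies, or rejection
by exactly one translation route), so each stage of the conjunction is
falsifiable in isolation.  Default sizes — 300 enzymes, 250 compounds,
20 pathways, 60 genomes across 15 phyla — keep a full pipeline run
under 200 ms so the multi-seed robustness sweeps stay cheap.

What passing on this benchmark shows: the set logic, statistics and
unit bookkeeping of every stage are correct, and the filter recovers a
planted signal without false positives.  What it does not show: the
generator's metabolic network is topologically trivial (dedicated
reactions per planted compound, random background links), its taxonomy
is rule-based rather than structure-based, and its study labels are
assigned at random — so benchmark performance says nothing about the
biological fidelity of any particular knowledge base.

The separate funnel fixture encodes prescribed stage memberships
(206 common, 20 inorganic, 27 emission-confirmed, 9 enriched-supported,
7 broadly supported) and verifies the filter reproduces the funnel
206 → 186 → 27 → 9 → 7; it validates filter logic only, since the
fixture itself supplies the memberships.

## Numerical choices and edge cases

* Hypergeometric tails: log-space accumulation; k ≤ 0 returns 1; the
  implementation matches exhaustive subset enumeration to 10⁻¹² on all
  universes up to 12 enzymes.
* Exact rank-sum: doubled midranks keep the dynamic program integral;
  the two-sided tail is P(|W − E[W]| ≥ observed) with a 10⁻⁹ guard on
  the comparison; all-tied data yields p = 1 with a warning.
* Degenerate inputs: empty COG sets, genomes reaching no volatiles,
  pathways with no poolable enzymes, and structureless compounds are
  all flagged-and-continued, never silently dropped; missing files,
  dangling foreign ids and duplicate primary ids abort loading.
* Determinism: all generator randomness flows from one seed;
  serialization sorts every table, so equal universes are
  byte-identical on disk.

## Limitations

The coefficient table is a fixed-temperature snapshot; activity
corrections, hydrogen-bond corrections and temperature interpolation
are out of scope.  The inorganic-carbon exception list is explicit and
short.  Lateral gene transfer is not modelled: an enzyme's broad
taxonomic distribution is treated as evidence of ancestry, as in the
translation criteria themselves.
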