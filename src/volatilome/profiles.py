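"""Chemical-class assignment and volatilome class profiles.

Compounds are classified by a three-level lookup taxonomy
(superclass / class / subclass; a stand-in for a structure-based
chemical-taxonomy service).  A *volatilome profile* for an entity (a
genome, or one of the eight ancestral-reconstruction studies) is the
percentage breakdown of its high-volatility compounds by subclass.

Profiles for the 8 ancestral study sets are compared against modern
per-genome profiles subclass-by-subclass with a two-sided rank-sum
(Wilcoxon/Mann-Whitney) test: exact null enumeration for small samples
(tie-safe, via a dynamic program over midranks), normal approximation
with tie correction otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .universe import Classification, Genome, Universe
from .volatility import VolatilityResult

logger = logging.getLogger(__name__)

#: Largest per-side sample size for which the exact rank-sum null is used.
EXACT_LIMIT = 10


@dataclass(frozen=True)
class VolatilomeProfile:
    entity_id: str
    percentages: dict[str, float]  # subclass (or superclass) -> percent
    n_compounds: int

    @property
    def empty(self) -> bool:
        return self.n_compounds == 0


def classify(
    compound_ids, universe: Universe
) -> dict[str, Classification]:
    """Total classification map; missing compounds get the explicit
    ``unclassified`` sentinel (count of misses is logged)."""
    out: dict[str, Classification] = {}
    missing = 0
    for cid in compound_ids:
        entry = universe.chem_taxonomy.get(cid)
        if entry is None:
            out[cid] = Classification(cid, "unclassified", "unclassified", "unclassified")
            missing += 1
        else:
            out[cid] = entry
    if missing:
        logger.warning("%d compounds without taxonomy entry -> unclassified", missing)
    return out


def _profile_from_compounds(
    entity_id: str,
    compound_ids: set[str],
    universe: Universe,
    volatility_results: dict[str, VolatilityResult],
    level: str = "subclass",
) -> VolatilomeProfile:
    volatile = {
        cid
        for cid in compound_ids
        if (r := volatility_results.get(cid)) is not None
        and r.assessable
        and r.category == "high"
    }
    if not volatile:
        return VolatilomeProfile(entity_id, {}, 0)
    taxonomy = classify(volatile, universe)
    labels = {}
    for cid in volatile:
        cl = taxonomy[cid]
        labels[cid] = cl.subclass if level == "subclass" else cl.superclass
    counts: dict[str, int] = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    total = sum(counts.values())
    percentages = {lab: 100.0 * n / total for lab, n in sorted(counts.items())}
    return VolatilomeProfile(entity_id, percentages, total)


def genome_volatilome(
    genome: Genome,
    universe: Universe,
    volatility_results: dict[str, VolatilityResult],
    level: str = "subclass",
) -> VolatilomeProfile:
    """Profile of the unique high-volatility compounds reachable
    genome -> KO -> EC -> reaction -> substrates."""
    compounds: set[str] = set()
    for ko_id in genome.ko_ids:
        ko = universe.kos[ko_id]
        for ec in ko.ec_numbers:
            if ec in universe.enzymes:
                compounds |= universe.compounds_for_enzyme(ec)
    profile = _profile_from_compounds(
        genome.genome_id, compounds, universe, volatility_results, level
    )
    if profile.empty:
        logger.warning("genome %s reaches no volatile compounds", genome.genome_id)
    return profile


def study_volatilome(
    study_label: str,
    compound_study_table: pd.DataFrame,
    universe: Universe,
    volatility_results: dict[str, VolatilityResult],
    level: str = "subclass",
) -> VolatilomeProfile:
    """Profile over the volatile compounds a study's ortholog groups predict."""
    mask = compound_study_table["studies"].str.split(";").map(
        lambda s: study_label in s
    )
    compounds = set(compound_study_table.loc[mask, "compound_id"])
    return _profile_from_compounds(
        study_label, compounds, universe, volatility_results, level
    )


# ---- rank-sum machinery ------------------------------------------------


def exact_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by full-null enumeration.

    Uses midranks (tie-safe).  The null distribution of the group-1 rank
    sum over all C(n1+n2, n1) assignments is built with a subset-sum
    dynamic program over the doubled midranks; the two-sided p-value is
    the tail probability of |W - E[W]| at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks2 = np.round(2 * stats.rankdata(combined)).astype(int)  # doubled midranks
    w_obs = int(ranks2[:n1].sum())
    n = n1 + n2
    total = ranks2.sum()
    # dp[j] maps doubled-rank-sum -> number of j-subsets achieving it
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for j in range(min(n1, n) - 1, -1, -1):
            if not dp[j]:
                continue
            target = dp[j + 1]
            for s, c in dp[j].items():
                target[s + r] = target.get(s + r, 0) + c
    dist = dp[n1]
    n_subsets = sum(dist.values())
    mu2 = n1 * total / n  # doubled-scale mean of W
    dev = abs(w_obs - mu2)
    tail = sum(c for s, c in dist.items() if abs(s - mu2) >= dev - 1e-9)
    return tail / n_subsets


def approx_ranksum_p(x, y) -> float:
    """Normal-approximation two-sided rank-sum p with tie and continuity
    correction.  Degenerate (all-tied) data returns p = 1 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        logger.warning("all-constant data in rank-sum test; p = 1")
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def ranksum_p(x, y, exact_limit: int = EXACT_LIMIT) -> float:
    """Two-sided rank-sum p-value: exact enumeration when both samples are
    small (default at most 10 per side), normal approximation otherwise."""
    if len(x) <= exact_limit and len(y) <= exact_limit:
        return exact_ranksum_p(x, y)
    return approx_ranksum_p(x, y)


def compare_profiles(
    luca_profiles: list[VolatilomeProfile],
    modern_profiles: list[VolatilomeProfile],
    per_domain_means: bool = False,
    domains: dict[str, str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-subclass two-sided rank-sum comparison of ancestral study
    profiles against modern genome profiles.

    By default each study's subclass percentage (8 values) is compared
    against the percentage in every non-empty modern genome profile
    pooled across domains.  With ``per_domain_means`` the modern side is
    collapsed to per-domain mean percentages (requires ``domains``:
    genome_id -> domain) — a statistically degenerate n=3 comparison kept
    for parity with the pooled default.

    Returns a DataFrame (subclass, luca_mean, modern_mean, p_value[,
    p_adjusted]) sorted by subclass.
    """
    luca_profiles = [p for p in luca_profiles if not p.empty]
    modern_profiles = [p for p in modern_profiles if not p.empty]
    if len(luca_profiles) < 2 or len(modern_profiles) < 2:
        raise ValueError("need at least two non-empty profiles per side")

    if per_domain_means:
        if domains is None:
            raise ValueError("per_domain_means requires a genome -> domain map")
        by_domain: dict[str, list[VolatilomeProfile]] = {}
        for p in modern_profiles:
            by_domain.setdefault(domains[p.entity_id], []).append(p)
        collapsed = []
        for dom, plist in sorted(by_domain.items()):
            keys = sorted({k for p in plist for k in p.percentages})
            mean = {
                k: float(np.mean([p.percentages.get(k, 0.0) for p in plist]))
                for k in keys
            }
            collapsed.append(VolatilomeProfile(dom, mean, len(plist)))
        modern_profiles = collapsed

    subclasses = sorted(
        {k for p in luca_profiles for k in p.percentages}
        | {k for p in modern_profiles for k in p.percentages}
    )
    rows = []
    for sub in subclasses:
        luca = [p.percentages.get(sub, 0.0) for p in luca_profiles]
        modern = [p.percentages.get(sub, 0.0) for p in modern_profiles]
        if len(set(luca) | set(modern)) == 1:
            logger.warning("subclass %s: all-constant percentages; p = 1", sub)
            p_val = 1.0
        else:
            p_val = ranksum_p(luca, modern)
        rows.append(
            {
                "subclass": sub,
                "luca_mean": float(np.mean(luca)),
                "modern_mean": float(np.mean(modern)),
                "p_value": p_val,
            }
        )
    df = pd.DataFrame(rows, columns=["subclass", "luca_mean", "modern_mean", "p_value"])
    if bh_correct and len(df):
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        df["p_adjusted"] = adj
    return df
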