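"""Five-tier evidence integration into a high-confidence interactome,
and hypergeometric overlap statistics between result sets.

Three TurboID baits (the splicing factor ACINUS, its paralog PININ, and
SR45) each yield a protein-level enrichment list; ACINUS additionally
has a peptide-level (biotin-site) list.  Evidence is integrated with a
first-match-wins tier cascade:

1. enriched by all three baits (ACINUS at protein or peptide level);
2. enriched by PININ and ACINUS only;
3. enriched by SR45 and ACINUS only;
4. enriched by ACINUS at both protein and peptide level;
5. exclusively peptide-level, in >= 3 of 4 reciprocally labeled
   experiments at >= 10-fold.

Baits are force-included in tier 1.  The union of the tiers is the
high-confidence network; tiers are mutually exclusive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "EvidenceEntry",
    "OverlapResult",
    "assign_category",
    "build_network",
    "overlap_stats",
    "EVIDENCE_COLUMNS",
]

EVIDENCE_COLUMNS = [
    "protein_id",
    "is_bait",
    "acinus_protein",
    "acinus_peptide",
    "acinus_peptide_n_experiments",
    "acinus_peptide_min_fold_met",
    "pnn_protein",
    "sr45_protein",
]


@dataclass(frozen=True)
class EvidenceEntry:
    """One protein's enrichment evidence across baits and levels."""

    protein_id: str
    is_bait: bool = False
    acinus_protein: bool = False
    acinus_peptide: bool = False
    acinus_peptide_n_experiments: int = 0
    acinus_peptide_min_fold_met: bool = False
    pnn_protein: bool = False
    sr45_protein: bool = False


def assign_category(
    entry: EvidenceEntry | Mapping,
    min_peptide_experiments: int = 3,
) -> int | None:
    """Tier (1-5) of one evidence entry, or None if it is filtered out.

    Tiers are evaluated in order 1 -> 5; the first match wins, which
    makes them mutually exclusive.
    """
    e = entry if isinstance(entry, EvidenceEntry) else EvidenceEntry(**dict(entry))
    acinus_any = e.acinus_protein or e.acinus_peptide
    if e.is_bait:
        return 1
    if acinus_any and e.pnn_protein and e.sr45_protein:
        return 1
    if acinus_any and e.pnn_protein:
        return 2
    if acinus_any and e.sr45_protein:
        return 3
    if e.acinus_protein and e.acinus_peptide:
        return 4
    if (
        e.acinus_peptide
        and not e.acinus_protein
        and e.acinus_peptide_n_experiments >= min_peptide_experiments
        and e.acinus_peptide_min_fold_met
    ):
        return 5
    return None


def build_network(
    evidence: pd.DataFrame | Iterable[EvidenceEntry],
) -> tuple[set, dict[int, int], int]:
    """Integrate an evidence table into the tiered network.

    Returns ``(members, tier_counts, total)`` where ``members`` is the
    union of tiers 1-5, ``tier_counts`` maps tier -> size, and ``total``
    is the network cardinality (= sum of tier sizes: entries are unique
    per protein and each lands in at most one tier).
    """
    if isinstance(evidence, pd.DataFrame):
        entries = [
            EvidenceEntry(**{k: row[k] for k in EVIDENCE_COLUMNS})
            for _, row in evidence.iterrows()
        ]
    else:
        entries = list(evidence)
    seen = set()
    for e in entries:
        if e.protein_id in seen:
            raise ValueError(f"duplicate evidence entry for {e.protein_id}")
        seen.add(e.protein_id)
    tiers: dict[int, set] = {t: set() for t in range(1, 6)}
    for e in entries:
        tier = assign_category(e)
        if tier is not None:
            tiers[tier].add(e.protein_id)
    members = set().union(*tiers.values())
    counts = {t: len(m) for t, m in tiers.items()}
    assert sum(counts.values()) == len(members), "tiers must partition the network"
    return members, counts, len(members)


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    shared: int
    universe: int
    pct_of_a: float
    pct_of_b: float
    p_value: float


def overlap_stats(
    set_a: Iterable | int,
    set_b: Iterable | int,
    universe_size: int,
    shared: int | None = None,
) -> OverlapResult:
    """Overlap of two sets with a hypergeometric enrichment p-value.

    Pass two sets (shared computed as the intersection) or two sizes
    plus ``shared``.  ``p_value`` is the upper tail P(X >= k) for
    X ~ Hypergeometric(universe, nA, nB); percentages are of each set,
    rounded to one decimal.
    """
    if isinstance(set_a, int):
        n_a, n_b = set_a, set_b
        if shared is None:
            raise ValueError("shared count required when passing sizes")
        k = shared
    else:
        sa, sb = set(set_a), set(set_b)
        n_a, n_b = len(sa), len(sb)
        k = len(sa & sb)
    if k > min(n_a, n_b):
        raise ValueError("shared count exceeds a set size")
    if universe_size < n_a + n_b - k:
        raise ValueError("universe smaller than the union of the sets")
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_a, n_b))
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        shared=k,
        universe=universe_size,
        pct_of_a=round(100.0 * k / n_a, 1) if n_a else 0.0,
        pct_of_b=round(100.0 * k / n_b, 1) if n_b else 0.0,
        p_value=p,
    )
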