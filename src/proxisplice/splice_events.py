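"""Junction-based alternative-splicing event classification and testing.

Non-annotated splice junctions are classified against a gene model into
exon skipping (ES), alternative donor (AD), alternative acceptor (AA) or
combined alternative donor and acceptor (ADA).  The donor is the 5'
splice site in transcription order, so on the minus strand it is the
genomically *right* end of the junction.  Per-replicate junction usage
(reads normalised by gene reads, with a pseudocount) is compared between
groups with the same two-tailed t machinery as the intron-retention
module, then gated on gene expression, p-value and fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import DepthExperiment, GeneModel, JunctionTable
from .intron_retention import ri_test

__all__ = [
    "classify_junction",
    "test_event",
    "filter_events",
    "analyze_junctions",
    "EventParams",
]


@dataclass
class EventParams:
    alpha: float = 0.05
    fc_cutoff: float = 1.5
    min_gene_rpkm: float = 1.0
    min_reads: float = 2.0  # max support below this in every replicate -> untested
    pseudocount: float = 0.5
    equal_var: bool = True


def classify_junction(junction: tuple[int, int], gene: GeneModel) -> str:
    """Classify a junction ``(left, right)`` (0-based half-open) on a gene.

    Returns one of ``annotated``, ``ES``, ``AD``, ``AA``, ``ADA`` or
    ``unassignable``.  An end is "annotated" when it coincides with the
    corresponding boundary of some annotated intron.  ES requires both
    ends annotated on *different* introns with at least one whole exon
    strictly inside the junction; a junction with one novel end shifted
    on the donor side is AD, on the acceptor side AA, and with both ends
    novel (and not ES) ADA.
    """
    left, right = junction
    if right <= left:
        raise ValueError("junction must have left < right")
    if left < gene.start or right > gene.end:
        return "unassignable"
    lefts = {i.start for i in gene.introns}
    rights = {i.end for i in gene.introns}
    left_ok = left in lefts
    right_ok = right in rights
    if left_ok and right_ok:
        if any(i.start == left and i.end == right for i in gene.introns):
            return "annotated"
        skipped = any(s > left and e < right for s, e in gene.exons)
        return "ES" if skipped else "ADA"
    if not left_ok and not right_ok:
        return "ADA"
    # exactly one novel end: donor side is left on '+', right on '-'
    novel_left = not left_ok
    donor_is_left = gene.strand == "+"
    if novel_left == donor_is_left:
        return "AD"
    return "AA"


def test_event(
    usage_ref, usage_test, params: EventParams | None = None
) -> tuple[float, float]:
    """Two-tailed t-test on log2 usage; returns ``(p, fold_change)``."""
    params = params or EventParams()
    ref = np.log2(np.asarray(usage_ref, dtype=float))
    test = np.log2(np.asarray(usage_test, dtype=float))
    return ri_test(ref, test, equal_var=params.equal_var)


def filter_events(events: pd.DataFrame, params: EventParams | None = None) -> pd.DataFrame:
    """Keep events on expressed genes passing the p and FC gates.

    Drops events on genes with average RPKM < 1 (strict), then keeps
    p <= alpha and FC >= cutoff or <= 1/cutoff; a ``direction`` column
    records which side the change is on.
    """
    params = params or EventParams()
    ev = events[events["gene_rpkm"] >= params.min_gene_rpkm].copy()
    up = ev["fold_change"] >= params.fc_cutoff
    down = ev["fold_change"] <= 1.0 / params.fc_cutoff
    keep = (ev["p_value"] <= params.alpha) & (up | down)
    ev["direction"] = np.where(up, "increased", np.where(down, "decreased", "none"))
    return ev[keep]


def analyze_junctions(
    junctions: JunctionTable,
    models: list[GeneModel],
    depths: DepthExperiment,
    params: EventParams | None = None,
) -> pd.DataFrame:
    """Classify, test and filter every non-annotated junction.

    Per-replicate usage = (junction reads + pseudocount) / gene reads.
    Junctions supported by fewer than ``min_reads`` in every replicate of
    both groups are not tested.  Returns the called events (one row per
    event) with class, coordinates, usage means, p, FC and direction.
    """
    params = params or EventParams()
    by_id = {g.gene_id: g for g in models}
    ref, test = junctions.groups
    ref_cols = junctions.group_samples(ref)
    test_cols = junctions.group_samples(test)
    rpkm = depths.gene_rpkm()
    gene_reads = {
        grp: depths.gene_reads(grp) for grp in (ref, test)
    }

    rows = []
    for _, j in junctions.table.iterrows():
        gene = by_id.get(j["gene_id"])
        if gene is None:
            continue
        cls = classify_junction((int(j["donor"]), int(j["acceptor"])), gene)
        if cls in ("annotated", "unassignable"):
            continue
        counts = j[ref_cols + test_cols].to_numpy(dtype=float)
        if counts.max() < params.min_reads:
            continue
        gr = gene_reads[ref].loc[gene.gene_id].to_numpy(dtype=float)
        gt = gene_reads[test].loc[gene.gene_id].to_numpy(dtype=float)
        usage_ref = (j[ref_cols].to_numpy(dtype=float) + params.pseudocount) / gr
        usage_test = (j[test_cols].to_numpy(dtype=float) + params.pseudocount) / gt
        p, fc = test_event(usage_ref, usage_test, params)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "event_class": cls,
                "donor": int(j["donor"]),
                "acceptor": int(j["acceptor"]),
                "strand": gene.strand,
                "mean_usage_ref": float(usage_ref.mean()),
                "mean_usage_test": float(usage_test.mean()),
                "p_value": p,
                "fold_change": fc,
                "gene_rpkm": float(rpkm[gene.gene_id]),
            }
        )
    cols = ["gene_id", "event_class", "donor", "acceptor", "strand",
            "mean_usage_ref", "mean_usage_test", "p_value", "fold_change",
            "gene_rpkm"]
    events = pd.DataFrame(rows, columns=cols)
    if events.empty:
        events["direction"] = pd.Series(dtype=str)
        return events
    return filter_events(events, params)
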