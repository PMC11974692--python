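"""Intron-retention calling from read-depth tables via the IDratio.

The IDratio of an intron is its mean read depth divided by the mean depth
of its flanking exons, an estimate of the fraction of a gene's transcripts
that retain the intron (an IDratio of 0.10 means ~10% of transcripts keep
it).  Because terminal exons suffer coverage bias, first introns use only
their 3' flanking exon and last introns only their 5' flanking exon.

The fitting surface follows the statsmodels convention:
``IntronRetentionModel(depths, params).fit()`` returns an
:class:`IntronRetentionResults` with per-intron ratios, imputed log2
values, test statistics, and ``call_events`` applying the six-criterion
filter cascade for increased (or decreased) retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import impute_downshifted_normal, two_sample_t_test
from .gene_models import DepthExperiment, intron_position_class, write_results

__all__ = [
    "RiParams",
    "compute_idratio",
    "impute_log2",
    "ri_test",
    "prefilter",
    "call_ri_events",
    "tally_events",
    "IntronRetentionModel",
    "IntronRetentionResults",
]

#: Human-readable labels for the filter cascade, in evaluation order.
CRITERIA = {
    1: "p-value <= alpha",
    2: "|fold change| >= cutoff",
    3: "gene RPKM > min",
    4: "mean intron depth >= min",
    5: "not a single-intron gene",
    6: "mean IDratio > threshold",
}


@dataclass
class RiParams:
    """Thresholds of the retained-intron filter cascade.

    Boundary semantics follow the filter definitions exactly: ``<=`` for
    p, ``>=`` for fold change and intron depth, strict ``>`` for RPKM and
    the criterion-6 IDratio, and ``>=`` for the 15% prefilter.
    """

    alpha: float = 0.05
    fc_cutoff: float = 1.5
    min_gene_rpkm: float = 1.0
    min_intron_depth: float = 5.0
    min_mean_idratio: float = 0.15
    prefilter_min_idratio: float = 0.15
    impute_downshift: float = 1.8
    impute_width: float = 0.3
    equal_var: bool = True  # Student's pooled t; False -> Welch
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("fc_cutoff", "min_gene_rpkm", "min_intron_depth",
                     "min_mean_idratio", "prefilter_min_idratio",
                     "impute_downshift", "impute_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def compute_idratio(
    intron_depth: float,
    up_exon_depth: float,
    down_exon_depth: float,
    position_class: str = "internal",
) -> float:
    """IDratio of one intron in one replicate; NaN when undefined.

    ``up_exon_depth``/``down_exon_depth`` are the 5' and 3' flanking exon
    depths in transcription order.  Internal (and single-intron) introns
    divide by the mean of both flanks; first introns divide by the 3'
    exon only and last introns by the 5' exon only.
    """
    for name, v in (("intron", intron_depth), ("up exon", up_exon_depth),
                    ("down exon", down_exon_depth)):
        if v < 0:
            raise ValueError(f"negative {name} depth: {v}")
    if position_class == "first":
        denom = down_exon_depth
    elif position_class == "last":
        denom = up_exon_depth
    elif position_class in ("internal", "only"):
        denom = (up_exon_depth + down_exon_depth) / 2.0
    else:
        raise ValueError(f"unknown position_class {position_class!r}")
    if denom == 0:
        return math.nan
    return intron_depth / denom


def impute_log2(
    values,
    downshift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator | None = None,
):
    """Impute non-finite log2 ratios from a per-column downshifted normal.

    Thin seeded wrapper over the shared proteomics-style imputation: each
    imputable entry of a column is drawn from ``Normal(m - downshift*s,
    (width*s)^2)`` with ``m``/``s`` the finite-entry moments of that
    column.  Returns ``(imputed, flags)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return impute_downshifted_normal(values, downshift, width, rng)


def ri_test(ref_log2, test_log2, equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed two-sample t-test on log2 IDratios.

    Returns ``(p_value, fold_change)`` with fold change
    ``2**(mean(test) - mean(ref))`` so FC > 1 means more retention in the
    test group.
    """
    ref = np.asarray(ref_log2, dtype=float)
    test = np.asarray(test_log2, dtype=float)
    if len(ref) != len(test):
        raise ValueError("groups must have equal size")
    p = two_sample_t_test(test, ref, equal_var=equal_var)
    fc = float(2.0 ** (test.mean() - ref.mean()))
    return p, fc


def prefilter(records: pd.DataFrame, params: RiParams) -> pd.DataFrame:
    """Keep introns with mean raw IDratio >= threshold in either group."""
    thr = params.prefilter_min_idratio
    keep = (records["mean_idr_ref"] >= thr) | (records["mean_idr_test"] >= thr)
    return records[keep.fillna(False)]


def _first_failing_criterion(
    row: pd.Series, params: RiParams, direction: str
) -> int | None:
    """Index of the first failing filter criterion, or None if all pass."""
    grp = "test" if direction == "increased" else "ref"
    if not row["p_value"] <= params.alpha:
        return 1
    if direction == "increased":
        if not row["fold_change"] >= params.fc_cutoff:
            return 2
    else:
        if not row["fold_change"] <= 1.0 / params.fc_cutoff:
            return 2
    if not row["gene_rpkm"] > params.min_gene_rpkm:
        return 3
    if not row[f"mean_depth_{grp}"] >= params.min_intron_depth:
        return 4
    if row["position_class"] == "only":
        return 5
    if not row[f"mean_idr_{grp}"] > params.min_mean_idratio:
        return 6
    return None


def ri_verdicts(
    records: pd.DataFrame, params: RiParams, direction: str = "increased"
) -> pd.DataFrame:
    """Annotate tested records with the filter verdict.

    Criteria are evaluated in order, the *first* failure recorded in the
    ``excluded_by`` column (NaN when all pass):

    1. p <= alpha;  2. FC >= cutoff (increased) or <= 1/cutoff
    (decreased);  3. gene RPKM > 1;  4. mean intron depth >= 5 in the
    test group (increased) or reference group (decreased);  5. gene has
    more than one intron;  6. mean IDratio of that same group > 0.15.
    """
    if direction not in ("increased", "decreased"):
        raise ValueError("direction must be 'increased' or 'decreased'")
    needed = {"p_value", "fold_change", "gene_rpkm"}
    if missing := needed - set(records.columns):
        raise ValueError(f"records not tested yet; missing {sorted(missing)}")
    out = records.copy()
    fails = out.apply(_first_failing_criterion, axis=1, args=(params, direction))
    out["excluded_by"] = fails
    out["verdict"] = np.where(fails.isna(), direction, "excluded")
    return out


def call_ri_events(
    records: pd.DataFrame, params: RiParams, direction: str = "increased"
) -> pd.DataFrame:
    """Apply the six-criterion cascade (see :func:`ri_verdicts`) and
    return only the events called in the requested direction."""
    out = ri_verdicts(records, params, direction)
    return out[out["verdict"] == direction].drop(columns=["excluded_by"])


#: Canonical alternative-splicing event-class order for summary tables.
EVENT_CLASSES = ["RI", "ES", "AD", "AA", "ADA"]


def tally_events(per_class: Mapping[str, pd.DataFrame | Iterable]) -> pd.DataFrame:
    """Summarise called events: up/down/total/genes per class + grand total.

    *per_class* maps an event-class label to its called events (any
    iterable of records with ``direction`` and ``gene_id``).  The output
    has one row per class and a ``total`` row whose ``total`` column is
    the grand total over all classes.
    """
    rows = []
    for cls in list(per_class):
        ev = per_class[cls]
        if not isinstance(ev, pd.DataFrame):
            ev = pd.DataFrame(list(ev), columns=["gene_id", "direction"])
        if len(ev) and not {"gene_id", "direction"} <= set(ev.columns):
            raise ValueError(f"event list for {cls} needs gene_id and direction")
        up = int((ev["direction"] == "increased").sum()) if len(ev) else 0
        down = int((ev["direction"] == "decreased").sum()) if len(ev) else 0
        genes = int(ev["gene_id"].nunique()) if len(ev) else 0
        rows.append({"event_class": cls, "up": up, "down": down,
                     "total": up + down, "genes": genes})
    out = pd.DataFrame(rows, columns=["event_class", "up", "down", "total", "genes"])
    grand = {
        "event_class": "total",
        "up": int(out["up"].sum()),
        "down": int(out["down"].sum()),
        "total": int(out["total"].sum()),
        "genes": int(out["genes"].sum()),
    }
    return pd.concat([out, pd.DataFrame([grand])], ignore_index=True)


# ---------------------------------------------------------------------------
# model / results


class IntronRetentionModel:
    """Retained-intron differential model over a two-group depth table.

    Parameters
    ----------
    depths : DepthExperiment
        Per-feature depths; the first group is the reference (wild type),
        the second the test group (mutant).
    params : RiParams, optional
    """

    def __init__(self, depths: DepthExperiment, params: RiParams | None = None):
        self.depths = depths
        self.params = params or RiParams()

    # -- assembly ----------------------------------------------------------

    def _assemble(self) -> pd.DataFrame:
        exp = self.depths
        ref, test = exp.groups
        samples = exp.samples
        exons = exp.features("exon")
        introns = exp.features("intron")
        if introns.empty:
            raise ValueError("depth table contains no intron features")
        exon_depth = {
            s: exons.set_index(["gene_id", "ordinal"])[s] for s in samples
        }
        n_introns = introns.groupby("gene_id")["ordinal"].max()
        rpkm = exp.gene_rpkm()

        recs = introns[["feature_id", "gene_id", "ordinal"]].copy()
        recs["position_class"] = [
            intron_position_class(o, n_introns[g])
            for g, o in zip(recs["gene_id"], recs["ordinal"])
        ]
        idx_up = pd.MultiIndex.from_arrays([recs["gene_id"], recs["ordinal"]])
        idx_dn = pd.MultiIndex.from_arrays([recs["gene_id"], recs["ordinal"] + 1])
        for s in samples:
            up = exon_depth[s].reindex(idx_up).to_numpy(dtype=float)
            dn = exon_depth[s].reindex(idx_dn).to_numpy(dtype=float)
            it = introns[s].to_numpy(dtype=float)
            pc = recs["position_class"].to_numpy()
            denom = np.where(
                pc == "first", dn, np.where(pc == "last", up, (up + dn) / 2.0)
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(denom > 0, it / denom, np.nan)
            recs[f"idr_{s}"] = ratio
        ref_cols = [f"idr_{s}" for s in exp.group_samples(ref)]
        test_cols = [f"idr_{s}" for s in exp.group_samples(test)]
        recs["mean_idr_ref"] = recs[ref_cols].mean(axis=1)
        recs["mean_idr_test"] = recs[test_cols].mean(axis=1)
        recs["mean_depth_ref"] = introns[exp.group_samples(ref)].mean(axis=1).to_numpy()
        recs["mean_depth_test"] = introns[exp.group_samples(test)].mean(axis=1).to_numpy()
        recs["gene_rpkm"] = rpkm.reindex(recs["gene_id"]).to_numpy()
        return recs.reset_index(drop=True)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "IntronRetentionResults":
        p = self.params
        exp = self.depths
        ref, test = exp.groups
        recs = self._assemble()
        tested = prefilter(recs, p).copy()

        ref_cols = [f"idr_{s}" for s in exp.group_samples(ref)]
        test_cols = [f"idr_{s}" for s in exp.group_samples(test)]
        all_cols = ref_cols + test_cols
        with np.errstate(divide="ignore", invalid="ignore"):
            log2 = np.log2(tested[all_cols].to_numpy(dtype=float))
        rng = np.random.default_rng(p.seed)
        imputed, flags = impute_log2(log2, p.impute_downshift, p.impute_width, rng)
        for j, c in enumerate(all_cols):
            tested[f"log2_{c}"] = imputed[:, j]
            tested[f"imputed_{c}"] = flags[:, j]

        g_ref = imputed[:, : len(ref_cols)]
        g_test = imputed[:, len(ref_cols):]
        pvals, fcs = _vectorized_t(g_test, g_ref, equal_var=p.equal_var)
        tested["p_value"] = pvals
        tested["fold_change"] = fcs
        return IntronRetentionResults(self, recs, tested)


def _vectorized_t(
    g1: np.ndarray, g2: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-tailed two-sample t over matrices (groups in columns).

    Mirrors :func:`ri_test` exactly, including the degenerate-variance
    conventions (both variances zero: p = 1 on equal means, else 0).
    """
    n1, n2 = g1.shape[1], g2.shape[1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    if equal_var:
        df = np.full(len(m1), n1 + n2 - 2, dtype=float)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = (v1 == 0) & (v2 == 0)
    p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    fc = 2.0 ** (m1 - m2)
    return p, fc


class IntronRetentionResults:
    """Fitted per-intron retention statistics.

    Attributes
    ----------
    records : pd.DataFrame
        Every intron of the experiment with raw-scale summaries.
    tested : pd.DataFrame
        The prefiltered subset with imputed log2 ratios, p-values and
        fold changes.
    """

    def __init__(self, model: IntronRetentionModel, records: pd.DataFrame,
                 tested: pd.DataFrame):
        self.model = model
        self.records = records
        self.tested = tested

    @property
    def params(self) -> RiParams:
        return self.model.params

    def call_events(self, direction: str = "increased") -> pd.DataFrame:
        return call_ri_events(self.tested, self.params, direction)

    def summary(self) -> str:
        p = self.params
        inc = len(self.call_events("increased"))
        dec = len(self.call_events("decreased"))
        lines = [
            "Intron retention (IDratio) differential analysis",
            "=" * 48,
            f"introns (total / prefiltered for testing): "
            f"{len(self.records)} / {len(self.tested)}",
            f"groups: {self.model.depths.groups[0]} (ref) vs "
            f"{self.model.depths.groups[1]} (test)",
            f"alpha={p.alpha}  FC cutoff={p.fc_cutoff}  "
            f"min RPKM={p.min_gene_rpkm}  min depth={p.min_intron_depth}",
            f"increased retention events: {inc}",
            f"decreased retention events: {dec}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str, extra_meta: Mapping | None = None) -> None:
        meta = {f"ri.{k}": v for k, v in asdict(self.params).items()}
        meta.update(extra_meta or {})
        write_results(self.tested, path, meta)
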