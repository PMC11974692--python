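"""Proximity-labeling LFQ enrichment: S0-moderated testing with
permutation FDR, and interaction-change classification between runs.

The enrichment statistic is the SAM-style moderated t,
``d = (mean_bait - mean_control) / (se_pooled + s0)``, whose fudge
factor ``s0`` damps proteins with small absolute log2 differences.
Significance is controlled by a permutation FDR: group labels are
rearranged over all distinct balanced relabelings (10 partitions for a
3-vs-3 design, so the null is exhaustive and deterministic) and the |d|
threshold is the loosest one whose estimated false-discovery proportion
stays at or below the target.

``ProximityEnrichmentModel(matrix, groups).fit()`` returns an
:class:`EnrichmentResults` carrying per-protein differences, d
statistics and the significant set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import impute_downshifted_normal, pooled_t
from .gene_models import write_results

__all__ = [
    "LfqParams",
    "preprocess_lfq",
    "s0_statistic",
    "permutation_fdr",
    "classify_interaction_change",
    "ProximityEnrichmentModel",
    "EnrichmentResults",
]


@dataclass
class LfqParams:
    s0: float = 2.0
    fdr: float = 0.05
    n_permutations: int = 250  # cap when the balanced relabelings exceed this
    min_valid_per_group: int = 3
    impute_downshift: float = 1.8
    impute_width: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


def preprocess_lfq(
    matrix: pd.DataFrame, min_valid_per_group: int = 3, groups: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """log2-transform intensities and drop sparsely quantified proteins.

    A protein is kept when it has at least ``min_valid_per_group`` finite
    values in *at least one* group (a bait-exclusive protein that is
    absent from every control run is real signal, not noise).  Zeros are
    treated as missing, the MaxQuant convention.
    """
    mat = matrix.replace(0, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(mat.astype(float))
    if groups is None:
        return log2.dropna(how="all")
    keep = pd.Series(False, index=log2.index)
    for grp in set(groups.values()):
        cols = [c for c in log2.columns if groups[c] == grp]
        keep |= log2[cols].notna().sum(axis=1) >= min_valid_per_group
    return log2[keep]


def s0_statistic(g1: Sequence[float], g2: Sequence[float], s0: float = 2.0) -> float:
    """SAM-moderated two-sample statistic ``(m1 - m2)/(se_pooled + s0)``.

    With ``s0 = 0`` this is exactly the pooled-variance t statistic.
    """
    diff, se, _ = pooled_t(np.asarray(g1, float), np.asarray(g2, float))
    if se + s0 == 0:
        raise ValueError("degenerate variance with s0=0: statistic undefined")
    return float(diff / (se + s0))


def _d_stats(mat: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float) -> np.ndarray:
    """Row-wise moderated d for one labeling (columns idx1 vs idx2)."""
    g1, g2 = mat[:, idx1], mat[:, idx2]
    n1, n2 = g1.shape[1], g2.shape[1]
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return (g1.mean(axis=1) - g2.mean(axis=1)) / (se + s0)


def _balanced_relabelings(
    n1: int, n2: int, cap: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Distinct non-identity balanced label partitions (complement-deduped)."""
    cols = np.arange(n1 + n2)
    partitions = []
    seen = set()
    for combo in itertools.combinations(range(n1 + n2), n1):
        comp = tuple(sorted(set(range(n1 + n2)) - set(combo)))
        key = min(combo, comp) if n1 == n2 else combo
        if key in seen:
            continue
        seen.add(key)
        partitions.append(combo)
    identity = tuple(range(n1))
    partitions = [p for p in partitions if p != identity]
    if len(partitions) > cap:
        pick = rng.choice(len(partitions), size=cap, replace=False)
        partitions = [partitions[i] for i in sorted(pick)]
    out = []
    for p in partitions:
        i1 = np.array(p)
        i2 = np.array([c for c in cols if c not in p])
        out.append((i1, i2))
    return out


def permutation_fdr(
    log2_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    bait_group: str,
    params: LfqParams | None = None,
) -> pd.DataFrame:
    """Moderated-t significance with a permutation-based FDR threshold.

    Missing values are imputed column-wise from a downshifted normal,
    observed ``d`` is computed per protein, and the null is built from
    the distinct balanced relabelings of the sample columns.  For each
    candidate cutoff ``c`` (the observed |d| values) the false-discovery
    proportion is estimated as the mean permuted count of |d| >= c over
    the observed count; a monotone (step-up) envelope is applied and the
    loosest cutoff with estimate <= ``fdr`` is selected.

    Returns a DataFrame indexed like the input with columns
    ``difference``, ``d_stat``, ``significant``, ``n_valid_bait``,
    ``n_valid_control``.
    """
    params = params or LfqParams()
    samples = list(log2_matrix.columns)
    bait_cols = [s for s in samples if groups[s] == bait_group]
    ctrl_cols = [s for s in samples if groups[s] != bait_group]
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    ordered = log2_matrix[bait_cols + ctrl_cols]
    rng = np.random.default_rng(params.seed)
    mat, _ = impute_downshifted_normal(
        ordered.to_numpy(dtype=float),
        params.impute_downshift,
        params.impute_width,
        rng,
        min_finite=2,
    )
    n1, n2 = len(bait_cols), len(ctrl_cols)
    i1, i2 = np.arange(n1), np.arange(n1, n1 + n2)
    d_obs = _d_stats(mat, i1, i2, params.s0)

    perms = _balanced_relabelings(n1, n2, params.n_permutations, rng)
    d_perm = np.array([_d_stats(mat, a, b, params.s0) for a, b in perms])

    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(d_perm).ravel()
    # candidate cutoffs: observed |d| sorted descending (strictest first)
    cuts = np.sort(np.unique(abs_obs))[::-1]
    obs_counts = np.searchsorted(np.sort(abs_obs), cuts, side="left")
    obs_counts = len(abs_obs) - obs_counts
    perm_counts = (len(abs_perm) - np.searchsorted(np.sort(abs_perm), cuts, side="left")) / len(perms)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_est = np.minimum(perm_counts / obs_counts, 1.0)
    # loosest cutoff whose estimated FDR passes (step-up); the passing set
    # is nested in the target FDR, so the significant set shrinks
    # monotonically as the target tightens
    passing = np.nonzero(fdr_est <= params.fdr)[0]
    if len(passing):
        cut = cuts[passing[-1]]
        significant = abs_obs >= cut
    else:
        significant = np.zeros(len(abs_obs), dtype=bool)

    valid = ordered.notna()
    return pd.DataFrame(
        {
            "difference": mat[:, i1].mean(axis=1) - mat[:, i2].mean(axis=1),
            "d_stat": d_obs,
            "significant": significant,
            "n_valid_bait": valid[bait_cols].sum(axis=1).to_numpy(),
            "n_valid_control": valid[ctrl_cols].sum(axis=1).to_numpy(),
        },
        index=log2_matrix.index,
    )


def classify_interaction_change(
    full: "EnrichmentResults | pd.DataFrame",
    variant: "EnrichmentResults | pd.DataFrame",
    loss_log2: float = 1.0,
) -> pd.Series:
    """Classify each full-bait interactor as retained / reduced / lost.

    Considers proteins significantly enriched (positive difference) by
    the full-length bait.  ``lost``: no longer significant with the
    variant bait; ``reduced``: still significant but the variant log2
    difference is at least ``loss_log2`` below the full one; otherwise
    ``retained``.
    """
    ft = full.table if isinstance(full, EnrichmentResults) else full
    vt = variant.table if isinstance(variant, EnrichmentResults) else variant
    interactors = ft[(ft["significant"]) & (ft["difference"] > 0)]
    out = {}
    for pid, row in interactors.iterrows():
        if pid not in vt.index or not vt.loc[pid, "significant"]:
            out[pid] = "lost"
        elif vt.loc[pid, "difference"] <= row["difference"] - loss_log2:
            out[pid] = "reduced"
        else:
            out[pid] = "retained"
    return pd.Series(out, name="interaction_change", dtype=str)


class ProximityEnrichmentModel:
    """Two-group LFQ enrichment model for one bait vs its control.

    Parameters
    ----------
    matrix : pd.DataFrame
        Raw protein intensities, proteins in rows, samples in columns
        (NaN or 0 = not quantified).
    groups : mapping sample -> group label
    bait_group : str
        The label whose enrichment is reported with positive sign.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        groups: Mapping[str, str],
        bait_group: str,
        params: LfqParams | None = None,
    ):
        self.matrix = matrix
        self.groups = dict(groups)
        self.bait_group = bait_group
        self.params = params or LfqParams()
        labels = set(self.groups.values())
        if bait_group not in labels or len(labels) != 2:
            raise ValueError("groups must define exactly two labels incl. bait_group")

    def fit(self) -> "EnrichmentResults":
        log2 = preprocess_lfq(
            self.matrix, self.params.min_valid_per_group, self.groups
        )
        table = permutation_fdr(log2, self.groups, self.bait_group, self.params)
        return EnrichmentResults(self, table)


class EnrichmentResults:
    """Per-protein enrichment differences, d statistics and calls."""

    def __init__(self, model: ProximityEnrichmentModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def params(self) -> LfqParams:
        return self.model.params

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def enriched_proteins(self) -> set:
        sig = self.table[(self.table["significant"]) & (self.table["difference"] > 0)]
        return set(sig.index)

    def summary(self) -> str:
        p = self.params
        n_enr = len(self.enriched_proteins)
        n_ctrl = int((self.table["significant"] & (self.table["difference"] < 0)).sum())
        return "\n".join(
            [
                "Proximity-labeling LFQ enrichment",
                "=" * 40,
                f"proteins tested: {len(self.table)}",
                f"S0={p.s0}  permutation FDR={p.fdr}",
                f"enriched by bait ({self.model.bait_group}): {n_enr}",
                f"enriched in control: {n_ctrl}",
            ]
        )

    def volcano(self, ax=None):
        """Volcano-style plot: log2 difference vs |d| statistic."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.scatter(t["difference"], np.abs(t["d_stat"]), s=8, c="grey", label="ns")
        sig = t[t["significant"]]
        ax.scatter(sig["difference"], np.abs(sig["d_stat"]), s=10, c="crimson",
                   label="significant")
        ax.set_xlabel("log2 enrichment difference (bait - control)")
        ax.set_ylabel("|d| (S0-moderated)")
        ax.legend(frameon=False)
        return ax

    def to_tsv(self, path: str, extra_meta: Mapping | None = None) -> None:
        meta = {f"lfq.{k}": v for k, v in asdict(self.params).items()}
        meta.update(extra_meta or {})
        write_results(self.table.reset_index(names="protein_id"), path, meta)
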