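"""Synthetic data with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
returns the data object alongside a truth table that records what was
spiked in, so detection stages can be scored exactly.  Defaults mirror
the study designs the pipeline targets: four-replicate two-group RNA-seq
depth tables with negative-binomial noise, three-replicate two-group LFQ
matrices with intensity-dependent missingness, reciprocally labeled
14N/15N peptide pairs, and evidence tables realising the five-tier
integration structure.

The generators model read depths as negative-binomial (mean mu, variance
mu + mu^2/size) around a log-normal gene-expression baseline and protein
intensities as log-normal — standard noise models for count and
intensity data.  A single master seed fans out to per-generator child
seeds via ``numpy.random.SeedSequence`` spawn keys, so the generators
stay independent of each other and of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .gene_models import DepthExperiment, GeneModel, JunctionTable
from .silia import (
    SIGNATURE_MZ_14N,
    SIGNATURE_MZ_15N,
    SpectrumRecord,
    n15_mass_shift,
)
from .splice_events import classify_junction

__all__ = [
    "SimTruth",
    "gen_gene_models",
    "gen_depth_experiment",
    "gen_junction_experiment",
    "gen_lfq_experiment",
    "gen_spectra",
    "gen_evidence_fixture",
]

# stable child-seed identifiers, one per generator
_GENERATOR_KEYS = {
    "gene_models": 1,
    "depths": 2,
    "junctions": 3,
    "lfq": 4,
    "spectra": 5,
    "evidence": 6,
}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_GENERATOR_KEYS[generator],))
    )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, serialisable next to it."""

    seed: int
    kind: str
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def save(self, path_prefix: str) -> None:
        import json

        self.table.to_csv(f"{path_prefix}.truth.tsv", sep="\t", index=False)
        with open(f"{path_prefix}.truth.json", "w") as fh:
            json.dump(
                {"seed": self.seed, "kind": self.kind, "params": self.params},
                fh,
                indent=2,
                default=str,
            )


# ---------------------------------------------------------------------------
# gene models


def gen_gene_models(
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 8),
    exon_length_range: tuple[int, int] = (80, 300),
    intron_length_range: tuple[int, int] = (60, 400),
    chrom: str = "Chr1",
    seed: int = 0,
) -> list[GeneModel]:
    """Random non-overlapping gene models on both strands.

    When the exon-count range allows it, the first gene is forced to be
    a single-intron (two-exon) gene so the single-intron filter rule is
    always exercised by downstream fixtures.
    """
    lo, hi = exon_count_range
    if n_genes <= 0 or lo < 1 or hi < lo:
        raise ValueError("impossible gene-count or exon-count range")
    if exon_length_range[0] < 1 or intron_length_range[0] < 1:
        raise ValueError("length ranges must be positive")
    rng = _rng(seed, "gene_models")
    models = []
    cursor = 1000
    for i in range(n_genes):
        n_exons = int(rng.integers(lo, hi + 1))
        if i == 0 and hi >= 2:
            n_exons = 2  # guaranteed single-intron gene
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for j in range(n_exons):
            elen = int(rng.integers(exon_length_range[0], exon_length_range[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if j < n_exons - 1:
                pos += int(
                    rng.integers(intron_length_range[0], intron_length_range[1] + 1)
                )
        cursor = pos + 500
        models.append(GeneModel(f"GENE{i + 1:05d}", chrom, strand, tuple(exons)))
    return models


# ---------------------------------------------------------------------------
# depth experiment


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; mean >= 0 elementwise."""
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    lam = rng.gamma(shape=size, scale=np.where(mean > 0, mean / size, 0.0))
    return rng.poisson(lam).astype(float)


def gen_depth_experiment(
    models: Sequence[GeneModel],
    n_reps: int = 4,
    groups: tuple[str, str] = ("wt", "mut"),
    baseline_log_mean: float = 4.5,
    baseline_log_sd: float = 0.8,
    dispersion: float = 20.0,
    retention_range: tuple[float, float] = (0.2, 0.5),
    ri_spike_fraction: float = 0.0,
    ri_spike_count: int | None = None,
    ri_spike_fold_changes: Sequence[float] = (1.5, 2.0, 3.0),
    zero_exon_fraction: float = 0.0,
    read_length: int = 150,
    seed: int = 0,
) -> tuple[DepthExperiment, SimTruth]:
    """Two-group depth table with NB noise and spiked retention changes.

    Exon depths share a log-normal per-gene expression level with NB
    replicate noise; intron depth is that level times the intron's true
    retention fraction.  A ``ri_spike_fraction`` of introns gets its
    test-group retention multiplied by a fold change drawn from
    ``ri_spike_fold_changes`` (capped at 0.95 retention);
    ``ri_spike_count`` instead plants an exact number of spikes.  A
    ``zero_exon_fraction`` of introns has both flanking exons zeroed in
    one reference replicate, creating undefined IDratios for the
    imputation path.
    """
    if not 0 <= ri_spike_fraction <= 1:
        raise ValueError("ri_spike_fraction must be in [0, 1]")
    if min(ri_spike_fold_changes, default=1.5) < 1.0:
        raise ValueError("spike fold changes must be >= 1")
    rng = _rng(seed, "depths")
    ref, test = groups
    samples = [f"{g}_{r + 1}" for g in groups for r in range(n_reps)]
    ref_cols = samples[:n_reps]

    # spike decisions drawn up front so an exact count can be requested
    total_introns = sum(g.n_introns for g in models)
    if ri_spike_count is not None:
        if not 0 <= ri_spike_count <= total_introns:
            raise ValueError("ri_spike_count out of range")
        spike_flags = np.zeros(total_introns, dtype=bool)
        spike_flags[rng.choice(total_introns, ri_spike_count, replace=False)] = True
    else:
        spike_flags = rng.random(total_introns) < ri_spike_fraction
    spike_fcs = rng.choice(list(ri_spike_fold_changes), size=total_introns)
    intron_counter = 0

    rows, truth_rows = [], []
    for g in models:
        mu = float(rng.lognormal(baseline_log_mean, baseline_log_sd))
        n_ex = len(g.exons)
        exon_depths = {}
        # exons carry transcription-order ordinals 1..n_ex
        for idx, (s, e) in enumerate(g.exons):
            ordinal = g.exon_ordinal(idx)
            depths = _nb_draw(rng, np.full(len(samples), mu), dispersion)
            exon_depths[ordinal] = depths
            rows.append(
                {
                    "feature_id": f"{g.gene_id}:exon:{ordinal}",
                    "gene_id": g.gene_id,
                    "feature_type": "exon",
                    "ordinal": ordinal,
                    "length": e - s,
                    **dict(zip(samples, depths)),
                }
            )
        for intr in g.introns:
            r_ref = float(rng.uniform(*retention_range))
            spiked = bool(spike_flags[intron_counter])
            fc = float(spike_fcs[intron_counter]) if spiked else 1.0
            intron_counter += 1
            r_test = min(r_ref * fc, 0.95)
            mean_vec = np.array(
                [mu * (r_ref if s in ref_cols else r_test) for s in samples]
            )
            depths = _nb_draw(rng, mean_vec, dispersion)
            rows.append(
                {
                    "feature_id": f"{g.gene_id}:intron:{intr.ordinal}",
                    "gene_id": g.gene_id,
                    "feature_type": "intron",
                    "ordinal": intr.ordinal,
                    "length": intr.length,
                    **dict(zip(samples, depths)),
                }
            )
            truth_rows.append(
                {
                    "feature_id": f"{g.gene_id}:intron:{intr.ordinal}",
                    "gene_id": g.gene_id,
                    "ordinal": intr.ordinal,
                    "retention_ref": r_ref,
                    "retention_test": r_test,
                    "spiked": spiked,
                    "fold_change": fc if spiked else 1.0,
                }
            )
            if zero_exon_fraction and rng.random() < zero_exon_fraction:
                rep = ref_cols[int(rng.integers(n_reps))]
                for flank in (intr.ordinal, intr.ordinal + 1):
                    exon_depths[flank][samples.index(rep)] = 0.0
        # re-sync possibly zeroed exon rows
        for row in rows[-(n_ex + g.n_introns):]:
            if row["feature_type"] == "exon":
                row.update(dict(zip(samples, exon_depths[row["ordinal"]])))
        reads = _nb_draw(
            rng, np.full(len(samples), mu * g.exonic_length / read_length), dispersion
        )
        rows.append(
            {
                "feature_id": f"{g.gene_id}:gene",
                "gene_id": g.gene_id,
                "feature_type": "gene",
                "ordinal": 0,
                "length": g.exonic_length,
                **dict(zip(samples, reads)),
            }
        )

    table = pd.DataFrame(rows)
    gene_rows = table[table["feature_type"] == "gene"]
    library_size = {s: max(float(gene_rows[s].sum()), 1.0) for s in samples}
    exp = DepthExperiment(
        table=table, groups=groups, library_size=library_size, meta={"seed": seed}
    )
    truth = SimTruth(
        seed=seed,
        kind="depth_experiment",
        table=pd.DataFrame(truth_rows),
        params={
            "n_reps": n_reps,
            "ri_spike_fraction": ri_spike_fraction,
            "ri_spike_fold_changes": list(ri_spike_fold_changes),
            "dispersion": dispersion,
        },
    )
    return exp, truth


# ---------------------------------------------------------------------------
# junction experiment


def _spike_coordinates(
    gene: GeneModel, event_class: str, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Genomic (left, right) of a novel junction of the requested class."""
    introns = sorted(gene.introns, key=lambda i: i.start)
    if not introns:
        return None
    if event_class == "ES":
        if len(introns) < 2:
            return None
        i = int(rng.integers(len(introns) - 1))
        return introns[i].start, introns[i + 1].end

    intr = introns[int(rng.integers(len(introns)))]
    idx = next(j for j in range(len(gene.exons) - 1) if gene.exons[j][1] == intr.start)
    left_exon, right_exon = gene.exons[idx], gene.exons[idx + 1]
    donor_is_left = gene.strand == "+"

    def shift_left():
        room = left_exon[1] - left_exon[0] - 1
        off = int(rng.integers(5, max(6, min(25, room))))
        return intr.start - off

    def shift_right():
        room = right_exon[1] - right_exon[0] - 1
        off = int(rng.integers(5, max(6, min(25, room))))
        return intr.end + off

    if event_class == "AD":
        return (shift_left(), intr.end) if donor_is_left else (intr.start, shift_right())
    if event_class == "AA":
        return (intr.start, shift_right()) if donor_is_left else (shift_left(), intr.end)
    if event_class == "ADA":
        return shift_left(), shift_right()
    raise ValueError(f"unknown event class {event_class!r}")


def gen_junction_experiment(
    models: Sequence[GeneModel],
    depths: DepthExperiment,
    event_spikes: Mapping[str, tuple[int, float]] | None = None,
    annotated_usage: float = 0.10,
    novel_usage: float = 0.03,
    seed: int = 0,
) -> tuple[JunctionTable, SimTruth]:
    """Junction counts with spiked non-annotated events per class.

    ``event_spikes`` maps event class (ES/AD/AA/ADA) to ``(count,
    effect)``: *count* novel junctions of that class are planted with
    test-group usage = ``novel_usage * effect``.  Every annotated intron
    junction is emitted with equal usage in both groups.  Junction reads
    are Poisson around usage x per-replicate gene reads.  Each spiked
    junction is verified against :func:`classify_junction` at
    construction, so the truth labels are exact by the classifier's own
    definition.
    """
    event_spikes = dict(event_spikes or {})
    rng = _rng(seed, "junctions")
    ref, test = depths.groups
    samples = depths.samples
    test_cols = set(depths.group_samples(test))
    gene_reads = {
        grp: depths.gene_reads(grp) for grp in depths.groups
    }

    def reads_for(gene_id: str, usage_ref: float, usage_test: float) -> dict:
        out = {}
        for s in samples:
            grp = test if s in test_cols else ref
            gr = float(gene_reads[grp].loc[gene_id, s])
            rate = usage_test if s in test_cols else usage_ref
            out[s] = int(rng.poisson(rate * gr))
        return out

    rows, truth_rows = [], []
    for g in models:
        for intr in g.introns:
            rows.append(
                {
                    "chrom": g.chrom,
                    "donor": intr.start,
                    "acceptor": intr.end,
                    "strand": g.strand,
                    "gene_id": g.gene_id,
                    "annotated": True,
                    **reads_for(g.gene_id, annotated_usage, annotated_usage),
                }
            )

    eligible = [g for g in models if g.n_introns >= 1]
    for cls, (count, effect) in event_spikes.items():
        planted = 0
        attempts = 0
        while planted < count and attempts < 50 * max(count, 1):
            attempts += 1
            g = eligible[int(rng.integers(len(eligible)))]
            coords = _spike_coordinates(g, cls, rng)
            if coords is None:
                continue
            if classify_junction(coords, g) != cls:
                continue
            if any(
                t["gene_id"] == g.gene_id and (t["donor"], t["acceptor"]) == coords
                for t in truth_rows
            ):
                continue
            rows.append(
                {
                    "chrom": g.chrom,
                    "donor": coords[0],
                    "acceptor": coords[1],
                    "strand": g.strand,
                    "gene_id": g.gene_id,
                    "annotated": False,
                    **reads_for(g.gene_id, novel_usage, novel_usage * effect),
                }
            )
            truth_rows.append(
                {
                    "gene_id": g.gene_id,
                    "donor": coords[0],
                    "acceptor": coords[1],
                    "event_class": cls,
                    "effect": effect,
                }
            )
            planted += 1
        if planted < count:
            raise RuntimeError(f"could not place {count} {cls} spikes")

    jt = JunctionTable(
        table=pd.DataFrame(rows), groups=depths.groups, meta={"seed": seed}
    )
    truth = SimTruth(
        seed=seed,
        kind="junction_experiment",
        table=pd.DataFrame(
            truth_rows, columns=["gene_id", "donor", "acceptor", "event_class", "effect"]
        ),
        params={"event_spikes": {k: list(v) for k, v in event_spikes.items()}},
    )
    return jt, truth


# ---------------------------------------------------------------------------
# LFQ experiment


def gen_lfq_experiment(
    n_proteins: int = 500,
    n_reps: int = 3,
    groups: tuple[str, str] = ("control", "bait"),
    frac_enriched: float = 0.1,
    n_enriched: int | None = None,
    effect_log2_mean: float = 3.0,
    effect_log2_sd: float = 0.5,
    base_log2_mean: float = 25.0,
    base_log2_sd: float = 2.0,
    noise_log2_sd: float = 0.3,
    missing_intercept: float = -2.0,
    missing_slope: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-group log-normal LFQ matrix with intensity-dependent missingness.

    Latent log2 intensities are normal around a per-protein baseline;
    enriched proteins get their bait-group mean raised by a drawn log2
    effect.  The probability that a measurement is missing is
    ``expit(missing_intercept - missing_slope * (x - grand_mean))`` so
    low-intensity values go missing more often (left censoring); with
    ``missing_slope = 0`` missingness is completely at random at rate
    ``expit(missing_intercept)``.  Returns the raw-scale intensity
    matrix (NaN = missing) and the truth table.
    """
    if not 0 <= frac_enriched <= 1:
        raise ValueError("frac_enriched must be in [0, 1]")
    rng = _rng(seed, "lfq")
    ctrl, bait = groups
    samples = [f"{g}_{r + 1}" for g in groups for r in range(n_reps)]
    bait_cols = np.array([s.startswith(f"{bait}_") for s in samples])

    base = rng.normal(base_log2_mean, base_log2_sd, size=n_proteins)
    if n_enriched is not None:
        if not 0 <= n_enriched <= n_proteins:
            raise ValueError("n_enriched out of range")
        enriched = np.zeros(n_proteins, dtype=bool)
        enriched[rng.choice(n_proteins, n_enriched, replace=False)] = True
    else:
        enriched = rng.random(n_proteins) < frac_enriched
    effects = np.where(
        enriched, rng.normal(effect_log2_mean, effect_log2_sd, size=n_proteins), 0.0
    )
    latent = (
        base[:, None]
        + effects[:, None] * bait_cols[None, :]
        + rng.normal(0.0, noise_log2_sd, size=(n_proteins, len(samples)))
    )
    p_missing = expit(missing_intercept - missing_slope * (latent - base_log2_mean))
    missing = rng.random(latent.shape) < p_missing
    intensities = np.where(missing, np.nan, 2.0**latent)

    index = [f"PROT{i + 1:05d}" for i in range(n_proteins)]
    matrix = pd.DataFrame(intensities, index=index, columns=samples)
    matrix.index.name = "protein_id"
    truth = SimTruth(
        seed=seed,
        kind="lfq_experiment",
        table=pd.DataFrame(
            {"protein_id": index, "enriched": enriched, "log2_effect": effects}
        ),
        params={
            "n_reps": n_reps,
            "frac_enriched": frac_enriched,
            "effect_log2_mean": effect_log2_mean,
            "effect_log2_sd": effect_log2_sd,
            "missing_intercept": missing_intercept,
            "missing_slope": missing_slope,
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# spectra

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def gen_spectra(
    peptides: Sequence[tuple[str, bool]],
    label: str = "14N",
    n_decoy_peaks: int = 25,
    seed: int = 0,
) -> tuple[list[SpectrumRecord], SimTruth]:
    """MS2 peaklists with or without the biotin signature ion.

    ``peptides`` is a sequence of ``(sequence, biotinylated)`` pairs.  A
    biotinylated peptide's spectrum carries the exact ImKBio-NH3
    signature peak for the requested label (310.1589 for 14N, 311.1559
    for 15N) among random decoy peaks; a non-biotinylated spectrum is
    guaranteed to carry no peak within 0.05 Da of either signature m/z.
    """
    if label not in ("14N", "15N"):
        raise ValueError("label must be '14N' or '15N'")
    rng = _rng(seed, "spectra")
    signature = SIGNATURE_MZ_14N if label == "14N" else SIGNATURE_MZ_15N
    exclusion = np.array([SIGNATURE_MZ_14N, SIGNATURE_MZ_15N])

    from pyteomics import mass as pmass

    spectra, truth_rows = [], []
    for i, (seq, biotinylated) in enumerate(peptides):
        if any(r not in _RESIDUES for r in seq):
            raise ValueError(f"invalid residue in peptide {seq!r}")
        mz_peaks = []
        while len(mz_peaks) < n_decoy_peaks:
            cand = rng.uniform(150.0, 1500.0, size=n_decoy_peaks)
            ok = np.abs(cand[:, None] - exclusion[None, :]).min(axis=1) > 0.05
            mz_peaks.extend(cand[ok].tolist())
        mz_peaks = mz_peaks[:n_decoy_peaks]
        if biotinylated:
            mz_peaks.append(signature)
        mz = np.array(mz_peaks)
        inten = rng.uniform(1e3, 1e6, size=len(mz))
        pep_mass = pmass.calculate_mass(sequence=seq)
        if label == "15N":
            pep_mass += n15_mass_shift(seq)
        charge = 2
        spectra.append(
            SpectrumRecord(
                spectrum_id=f"synthetic_scan_{i + 1}",
                precursor_mz=(pep_mass + charge * _PROTON) / charge,
                charge=charge,
                mz=mz,
                intensity=inten,
                source="synthetic",
            )
        )
        truth_rows.append(
            {
                "spectrum_id": f"synthetic_scan_{i + 1}",
                "peptide": seq,
                "biotinylated": biotinylated,
                "label": label,
            }
        )
    truth = SimTruth(
        seed=seed,
        kind="spectra",
        table=pd.DataFrame(truth_rows),
        params={"label": label, "n_decoy_peaks": n_decoy_peaks},
    )
    return spectra, truth


_PROTON = 1.00727646688  # monoisotopic proton mass, Da


# ---------------------------------------------------------------------------
# evidence fixture


def gen_evidence_fixture(
    tier_counts: Sequence[int] = (171, 42, 49, 15, 21),
    n_baits: int = 3,
    n_decoys: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Evidence table whose tier assignment reproduces ``tier_counts``.

    Builds, per tier, exactly the flag combination that lands a protein
    in that tier (and no earlier one), the first ``n_baits`` tier-1 rows
    being the baits, plus ``n_decoys`` rows engineered to fall outside
    the network.  Rows are shuffled so integration cannot rely on input
    order.
    """
    if len(tier_counts) != 5:
        raise ValueError("tier_counts must have exactly 5 entries")
    if any(c < 0 for c in tier_counts):
        raise ValueError("tier counts must be >= 0")
    if tier_counts[0] < n_baits:
        raise ValueError("tier 1 must be large enough to hold the baits")
    rng = _rng(seed, "evidence")

    rows, truth_rows = [], []
    counter = 0

    def add(tier: int | None, **flags):
        nonlocal counter
        counter += 1
        pid = f"AT{counter:05d}"
        base = {
            "protein_id": pid,
            "is_bait": False,
            "acinus_protein": False,
            "acinus_peptide": False,
            "acinus_peptide_n_experiments": 0,
            "acinus_peptide_min_fold_met": False,
            "pnn_protein": False,
            "sr45_protein": False,
        }
        base.update(flags)
        rows.append(base)
        truth_rows.append({"protein_id": pid, "tier": tier})

    for i in range(tier_counts[0]):
        # alternate protein-only / peptide-supported evidence inside tier 1
        add(
            1,
            is_bait=(i < n_baits),
            acinus_protein=True,
            acinus_peptide=(i % 3 == 0),
            acinus_peptide_n_experiments=4 if i % 3 == 0 else 0,
            acinus_peptide_min_fold_met=(i % 3 == 0),
            pnn_protein=True,
            sr45_protein=True,
        )
    for _ in range(tier_counts[1]):
        add(2, acinus_protein=True, pnn_protein=True)
    for _ in range(tier_counts[2]):
        add(3, acinus_protein=True, sr45_protein=True)
    for _ in range(tier_counts[3]):
        add(
            4,
            acinus_protein=True,
            acinus_peptide=True,
            acinus_peptide_n_experiments=4,
            acinus_peptide_min_fold_met=True,
        )
    for _ in range(tier_counts[4]):
        add(
            5,
            acinus_peptide=True,
            acinus_peptide_n_experiments=int(rng.integers(3, 5)),
            acinus_peptide_min_fold_met=True,
        )
    decoy_makers = [
        dict(pnn_protein=True),
        dict(sr45_protein=True),
        dict(pnn_protein=True, sr45_protein=True),
        dict(
            acinus_peptide=True,
            acinus_peptide_n_experiments=2,
            acinus_peptide_min_fold_met=True,
        ),
        dict(
            acinus_peptide=True,
            acinus_peptide_n_experiments=4,
            acinus_peptide_min_fold_met=False,
        ),
    ]
    for _ in range(n_decoys):
        add(None, **decoy_makers[int(rng.integers(len(decoy_makers)))])

    order = rng.permutation(len(rows))
    evidence = pd.DataFrame([rows[i] for i in order])
    truth = SimTruth(
        seed=seed,
        kind="evidence_fixture",
        table=pd.DataFrame([truth_rows[i] for i in order]),
        params={"tier_counts": list(tier_counts), "n_baits": n_baits,
                "n_decoys": n_decoys},
    )
    return evidence, truth
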