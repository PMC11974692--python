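"""Biotin signature-ion spectrum filtering and 14N/15N SILIA ratios.

Biotinylated-lysine peptides betray themselves in MS2 by a diagnostic
low-mass fragment: the immonium ion of biotinyl-lysine after ammonia
loss (ImKBio - NH3), at m/z 310.1589 for natural-abundance (14N)
peptides and 311.1559 for metabolically 15N-labeled ones (the lysine
retains one labelable nitrogen after the NH3 leaves; the biotin moiety
is added post-labeling and stays light).  Peaklists are screened for a
peak within tolerance of either value before search, which removes the
vast majority of non-biotinylated spectra.

Quantification follows the reciprocal-labeling SILIA design: in a
forward (Fw) mix the bait is 14N (light) and the control 15N (heavy); a
reverse (Rv) mix swaps the labels, cancelling label bias.  Peptide
bait/control ratios are aggregated to protein ratios by the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pmass

__all__ = [
    "SpectrumRecord",
    "immonium_mz",
    "filter_peaklist",
    "n15_mass_shift",
    "peptide_ratio",
    "protein_ratio",
    "call_peptide_level_hits",
    "quantify_proteins",
    "read_mgf",
    "write_mgf",
    "BIOTIN_MOD_MASS",
    "N15_MASS_DIFF",
    "SIGNATURE_MZ_14N",
    "SIGNATURE_MZ_15N",
]

#: Monoisotopic mass added by biotinylation of a lysine (C10H14N2O2S).
BIOTIN_MOD_MASS = pmass.calculate_mass(formula="C10H14N2O2S")
#: 15N - 14N monoisotopic mass difference per nitrogen atom.
N15_MASS_DIFF = 0.9970349
#: Reported ratio for a bait-only peptide (zero control intensity).
RATIO_CEILING = 1000.0

_CO = pmass.calculate_mass(formula="CO")
_H = pmass.calculate_mass(formula="H")
_NH3 = pmass.calculate_mass(formula="NH3")

_LOSS_MASSES = {"NH3": _NH3, "H2O": pmass.calculate_mass(formula="H2O")}


def immonium_mz(
    residue: str,
    mod_mass: float = 0.0,
    neutral_losses: Sequence[str | float] = (),
    n15_heavy_count: int = 0,
) -> float:
    """m/z of a (modified) residue immonium ion, singly charged.

    ``immonium = residue_monoisotopic - CO + H``, plus any modification
    mass, minus the listed neutral losses (names like ``"NH3"`` or Da
    values), plus ``n15_heavy_count`` times the 15N-14N mass difference
    for heavy nitrogens *retained* in the fragment.
    """
    if residue not in pmass.std_aa_mass:
        raise ValueError(f"unknown residue {residue!r}")
    mz = pmass.std_aa_mass[residue] - _CO + _H + mod_mass
    for loss in neutral_losses:
        mz -= _LOSS_MASSES[loss] if isinstance(loss, str) else float(loss)
    mz += n15_heavy_count * N15_MASS_DIFF
    return mz


#: Diagnostic ImKBio-NH3 m/z for 14N and (one heavy nitrogen) 15N peptides.
SIGNATURE_MZ_14N = immonium_mz("K", BIOTIN_MOD_MASS, ("NH3",), 0)
SIGNATURE_MZ_15N = immonium_mz("K", BIOTIN_MOD_MASS, ("NH3",), 1)


@dataclass
class SpectrumRecord:
    """One MS2 peaklist with precursor info and the signature-ion flag."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    source: str = ""
    passes_signature: bool | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity arrays differ in length")
        if len(self.mz) and np.min(self.intensity) < 0:
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def has_peak_near(self, target_mz: float, tolerance_ppm: float) -> bool:
        if len(self.mz) == 0:
            return False
        tol = target_mz * tolerance_ppm * 1e-6
        return bool(np.any(np.abs(self.mz - target_mz) <= tol))


def filter_peaklist(
    spectra: Iterable[SpectrumRecord],
    signature_mzs: Sequence[float] = (SIGNATURE_MZ_14N, SIGNATURE_MZ_15N),
    tolerance_ppm: float = 20.0,
) -> list[SpectrumRecord]:
    """Return spectra carrying a peak within tolerance of a signature ion.

    Each spectrum's ``passes_signature`` flag is set in place, so both
    the filtered and the full peaklist remain writable afterwards.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be > 0")
    passing = []
    for spec in spectra:
        spec.passes_signature = any(
            spec.has_peak_near(mz, tolerance_ppm) for mz in signature_mzs
        )
        if spec.passes_signature:
            passing.append(spec)
    return passing


def n15_mass_shift(peptide_sequence: str) -> float:
    """Full-15N metabolic-labeling mass shift of a peptide, in Da.

    Every nitrogen — backbone amides and side chains alike — is heavy,
    so the shift is (number of N atoms) x 0.9970349 Da.
    """
    comp = pmass.Composition(sequence=peptide_sequence)
    return comp["N"] * N15_MASS_DIFF


def peptide_ratio(light: float, heavy: float, orientation: str) -> float:
    """Bait/control intensity ratio honouring the labeling orientation.

    ``Fw``: bait is light (14N) -> light/heavy; ``Rv``: bait is heavy
    (15N) -> heavy/light.  A zero control intensity with nonzero bait
    intensity reports the documented ceiling; 0/0 is NaN.
    """
    if orientation not in ("Fw", "Rv"):
        raise ValueError("orientation must be 'Fw' or 'Rv'")
    if light < 0 or heavy < 0:
        raise ValueError("intensities must be >= 0")
    num, den = (light, heavy) if orientation == "Fw" else (heavy, light)
    if den == 0:
        return RATIO_CEILING if num > 0 else float("nan")
    return num / den


def protein_ratio(peptide_ratios: Sequence[float]) -> float:
    """Protein-level bait/control ratio: median of its peptide ratios."""
    ratios = [r for r in peptide_ratios if np.isfinite(r)]
    if not ratios:
        return float("nan")
    return float(np.median(ratios))


def quantify_proteins(peptide_table: pd.DataFrame) -> pd.DataFrame:
    """Protein ratios per experiment from a peptide intensity table.

    Expects columns ``peptide``, ``protein_id``, ``experiment``,
    ``orientation`` (Fw/Rv), ``light``, ``heavy``.  Returns a wide table
    (protein x experiment) of median bait/control ratios plus an
    ``n_experiments`` column counting experiments with a finite ratio.
    """
    required = {"peptide", "protein_id", "experiment", "orientation", "light", "heavy"}
    if missing := required - set(peptide_table.columns):
        raise ValueError(f"peptide table missing column(s): {sorted(missing)}")
    tbl = peptide_table.copy()
    tbl["ratio"] = [
        peptide_ratio(l, h, o)
        for l, h, o in zip(tbl["light"], tbl["heavy"], tbl["orientation"])
    ]
    wide = (
        tbl.groupby(["protein_id", "experiment"])["ratio"]
        .apply(lambda r: protein_ratio(list(r)))
        .unstack("experiment")
    )
    wide["n_experiments"] = wide.notna().sum(axis=1)
    return wide


def call_peptide_level_hits(
    protein_ratios: pd.DataFrame,
    min_experiments: int = 3,
    min_fold: float = 10.0,
) -> set:
    """High-confidence peptide-level set: ratio >= min_fold in enough runs.

    ``protein_ratios`` is the wide table from :func:`quantify_proteins`
    (the ``n_experiments`` helper column, if present, is ignored).  A
    protein passes when its bait/control ratio reaches ``min_fold`` in at
    least ``min_experiments`` experiments.
    """
    cols = [c for c in protein_ratios.columns if c != "n_experiments"]
    hits = (protein_ratios[cols] >= min_fold).sum(axis=1) >= min_experiments
    return set(protein_ratios.index[hits])


# ---------------------------------------------------------------------------
# MGF I/O (via pyteomics)


def read_mgf(path: str) -> list[SpectrumRecord]:
    from pyteomics import mgf

    out = []
    with mgf.MGF(path) as reader:
        for spec in reader:
            params = spec["params"]
            charge = int(params.get("charge", [1])[0])
            out.append(
                SpectrumRecord(
                    spectrum_id=str(params.get("title", f"spectrum_{len(out)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    source=path,
                )
            )
    return out


def write_mgf(spectra: Iterable[SpectrumRecord], path: str) -> None:
    from pyteomics import mgf

    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
            },
        }
        for s in spectra
    ]
    mgf.write(entries, output=path, file_mode="w")
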