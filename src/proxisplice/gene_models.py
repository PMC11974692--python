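"""Gene models, depth/junction tables and annotation I/O.

Coordinates are 0-based half-open internally; GFF3/GTF input (1-based
inclusive) is converted on read and back on write.  A :class:`GeneModel`
is a single representative transcript per gene: its sorted exon chain and
the introns derived as the gaps between consecutive exons.  Intron and
exon *ordinals* count in transcription order, i.e. ordinal 1 is the
5'-most feature, which is the genomically last one on the minus strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "Intron",
    "DepthExperiment",
    "JunctionTable",
    "read_gene_models",
    "compute_rpkm",
    "read_depth_table",
    "write_depth_table",
    "read_junction_table",
    "write_junction_table",
    "write_results",
]


class FormatError(ValueError):
    """A record in an external file violates its format contract."""


class SchemaError(ValueError):
    """A table is missing a required column or holds an invalid value."""


@dataclass(frozen=True)
class Intron:
    start: int
    end: int
    ordinal: int  # 1-based, transcription order

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene's representative exon chain and derived introns.

    Parameters
    ----------
    gene_id : str
    chrom : str
    strand : str
        ``'+'`` or ``'-'``; unstranded annotations are rejected because
        the first/last-intron convention and donor/acceptor sides are
        defined in transcription order.
    exons : tuple of (start, end)
        Non-overlapping, sorted by genomic position, 0-based half-open.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: zero exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def introns(self) -> tuple[Intron, ...]:
        """Gaps between consecutive exons, ordinal 1 = 5'-most intron."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]
        n = len(gaps)
        if self.strand == "+":
            return tuple(Intron(s, e, i + 1) for i, (s, e) in enumerate(gaps))
        return tuple(Intron(s, e, n - i) for i, (s, e) in enumerate(gaps))

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_ordinal(self, index_genomic: int) -> int:
        """Transcription-order ordinal of the exon at genomic index."""
        n = len(self.exons)
        return index_genomic + 1 if self.strand == "+" else n - index_genomic

    def intron_position_class(self, ordinal: int) -> str:
        """``first``/``internal``/``last``/``only`` for a 1-based ordinal."""
        n = self.n_introns
        if not 1 <= ordinal <= n:
            raise ValueError(f"gene {self.gene_id}: no intron with ordinal {ordinal}")
        if n == 1:
            return "only"
        if ordinal == 1:
            return "first"
        if ordinal == n:
            return "last"
        return "internal"

    def flanking_exons(self, ordinal: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """(5' exon, 3' exon) flanking the intron with this ordinal."""
        intron = next(i for i in self.introns if i.ordinal == ordinal)
        idx = next(
            j for j in range(len(self.exons) - 1) if self.exons[j][1] == intron.start
        )
        left, right = self.exons[idx], self.exons[idx + 1]
        return (left, right) if self.strand == "+" else (right, left)


def intron_position_class(ordinal: int, n_introns: int) -> str:
    """Position class from ordinal and total intron count alone."""
    if n_introns == 1:
        return "only"
    if ordinal == 1:
        return "first"
    if ordinal == n_introns:
        return "last"
    return "internal"


# ---------------------------------------------------------------------------
# annotation I/O


def read_gene_models(path: str, dialect: str = "GFF3") -> list[GeneModel]:
    """Parse an annotation file into one :class:`GeneModel` per gene.

    Multi-transcript genes are collapsed to a single representative
    transcript: the one with the largest exonic length, ties broken by
    lexicographically smallest transcript ID.  Genes whose exons carry
    no strand, or transcripts with zero exons, are rejected.
    """
    import gffutils

    dialect = dialect.upper()
    if dialect not in ("GFF3", "GTF"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=(dialect == "GFF3"),
            disable_infer_transcripts=(dialect == "GFF3"),
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc

    # transcript_id -> (gene_id, chrom, strand, [exons])
    transcripts: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        if dialect == "GTF":
            tid = exon.attributes.get("transcript_id", [None])[0]
            gid = exon.attributes.get("gene_id", [None])[0]
        else:
            tid = exon.attributes.get("Parent", [None])[0]
            gid = None
        if tid is None:
            raise FormatError(
                f"{path}: exon without transcript attribution near "
                f"{exon.seqid}:{exon.start}"
            )
        rec = transcripts.setdefault(
            tid, {"gene_id": gid, "chrom": exon.seqid, "strand": exon.strand,
                  "exons": []}
        )
        # GFF3/GTF are 1-based inclusive -> 0-based half-open
        rec["exons"].append((exon.start - 1, exon.end))

    if dialect == "GFF3":
        # resolve gene ids through the transcript features' Parent
        for feat in db.all_features():
            if feat.id in transcripts and transcripts[feat.id]["gene_id"] is None:
                parent = feat.attributes.get("Parent", [feat.id])[0]
                transcripts[feat.id]["gene_id"] = parent
        for tid, rec in transcripts.items():
            if rec["gene_id"] is None:
                rec["gene_id"] = tid

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for tid, rec in transcripts.items():
        by_gene.setdefault(rec["gene_id"], []).append((tid, rec))

    models = []
    for gid, cands in sorted(by_gene.items()):
        def _key(item):
            tid, rec = item
            return (-sum(e - s for s, e in rec["exons"]), tid)

        tid, rec = min(cands, key=_key)
        if not rec["exons"]:
            raise FormatError(f"{path}: transcript {tid} of gene {gid} has no exons")
        if rec["strand"] not in ("+", "-"):
            raise FormatError(f"{path}: gene {gid} is unstranded; strand is required")
        exons = tuple(sorted(rec["exons"]))
        models.append(GeneModel(gid, rec["chrom"], rec["strand"], exons))
    return models


def write_gene_models_gff3(models: Iterable[GeneModel], path: str) -> None:
    """Write gene/mRNA/exon features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chrom}\tproxisplice\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tproxisplice\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tproxisplice\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent={tid}\n"
                )


# ---------------------------------------------------------------------------
# expression


def compute_rpkm(gene_reads: float, gene_length: float, library_size: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return gene_reads / ((gene_length / 1e3) * (library_size / 1e6))


# ---------------------------------------------------------------------------
# depth tables

#: Fixed leading columns of the depth-table TSV.
DEPTH_META_COLUMNS = ["feature_id", "gene_id", "feature_type", "ordinal", "length"]


@dataclass
class DepthExperiment:
    """Per-feature mean read depths plus gene read counts for two groups.

    ``table`` holds one row per feature (``feature_type`` in
    {gene, exon, intron}) with the metadata columns of
    :data:`DEPTH_META_COLUMNS` followed by one column per sample named
    ``<group>_<rep>``.  For exon/intron rows the sample columns are mean
    per-base read depths; for gene rows they are mapped read counts.
    """

    table: pd.DataFrame
    groups: tuple[str, str]  # (reference, test)
    library_size: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in DEPTH_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"depth table missing column(s): {', '.join(missing)}")
        samples = self.samples
        if not samples:
            raise SchemaError("depth table has no sample columns")
        for s in samples:
            if s not in self.library_size:
                raise SchemaError(f"no library size recorded for sample {s}")
            if self.library_size[s] <= 0:
                raise SchemaError(f"library_size must be > 0 for sample {s}")
        vals = self.table[samples].to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise SchemaError("negative depth/count values in depth table")

    @property
    def samples(self) -> list[str]:
        pref = tuple(f"{g}_" for g in self.groups)
        return [c for c in self.table.columns if c.startswith(pref)]

    def group_samples(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [c for c in self.samples if c.startswith(f"{group}_")]

    def features(self, feature_type: str) -> pd.DataFrame:
        return self.table[self.table["feature_type"] == feature_type]

    def gene_rpkm(self, gene_id: str | None = None) -> pd.Series | float:
        """Mean RPKM across all replicates of both groups, per gene."""
        genes = self.features("gene").set_index("gene_id")
        rpkm = pd.DataFrame(
            {
                s: [
                    compute_rpkm(r, l, self.library_size[s])
                    for r, l in zip(genes[s], genes["length"])
                ]
                for s in self.samples
            },
            index=genes.index,
        ).mean(axis=1)
        return rpkm if gene_id is None else float(rpkm[gene_id])

    def gene_reads(self, group: str) -> pd.DataFrame:
        return self.features("gene").set_index("gene_id")[self.group_samples(group)]


def _write_commented_header(fh, meta: Mapping) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_commented_header(path: str) -> tuple[dict, io.StringIO]:
    meta, lines = {}, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    return meta, io.StringIO("".join(lines))


def write_depth_table(exp: DepthExperiment, path: str, extra_meta: Mapping | None = None) -> None:
    meta = dict(exp.meta)
    meta.update(extra_meta or {})
    meta["groups"] = ",".join(exp.groups)
    meta["library_size"] = ",".join(
        f"{s}={exp.library_size[s]:g}" for s in exp.samples
    )
    with open(path, "w") as fh:
        _write_commented_header(fh, meta)
        exp.table.to_csv(fh, sep="\t", index=False)


def read_depth_table(path: str) -> DepthExperiment:
    meta, buf = _read_commented_header(path)
    table = pd.read_csv(buf, sep="\t")
    for col in DEPTH_META_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"{path}: depth table missing column {col!r}")
    if "groups" not in meta or "library_size" not in meta:
        raise SchemaError(f"{path}: header must record 'groups' and 'library_size'")
    groups = tuple(meta["groups"].split(","))
    if len(groups) != 2:
        raise SchemaError(f"{path}: exactly two groups required, got {groups}")
    libsize = {}
    for item in meta["library_size"].split(","):
        s, v = item.split("=")
        libsize[s] = float(v)
    keep = {"groups", "library_size"}
    exp_meta = {k: v for k, v in meta.items() if k not in keep}
    return DepthExperiment(table=table, groups=groups, library_size=libsize, meta=exp_meta)


# ---------------------------------------------------------------------------
# junction tables

JUNCTION_META_COLUMNS = ["chrom", "donor", "acceptor", "strand", "gene_id", "annotated"]


@dataclass
class JunctionTable:
    """Splice-junction read support per replicate.

    ``donor``/``acceptor`` are the genomic left/right ends of the excised
    region (0-based half-open), so ``donor < acceptor`` always holds; on
    the minus strand the biological donor is the *right* coordinate and
    classification handles that strand-awarely.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in JUNCTION_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"junction table missing column(s): {', '.join(missing)}")
        if not (self.table["donor"] < self.table["acceptor"]).all():
            raise SchemaError("junction donor coordinate must be < acceptor")
        vals = self.table[self.samples].to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise SchemaError("negative junction counts")

    @property
    def samples(self) -> list[str]:
        pref = tuple(f"{g}_" for g in self.groups)
        return [c for c in self.table.columns if c.startswith(pref)]

    def group_samples(self, group: str) -> list[str]:
        return [c for c in self.samples if c.startswith(f"{group}_")]


def write_junction_table(jt: JunctionTable, path: str, extra_meta: Mapping | None = None) -> None:
    meta = dict(jt.meta)
    meta.update(extra_meta or {})
    meta["groups"] = ",".join(jt.groups)
    with open(path, "w") as fh:
        _write_commented_header(fh, meta)
        jt.table.to_csv(fh, sep="\t", index=False)


def read_junction_table(path: str) -> JunctionTable:
    meta, buf = _read_commented_header(path)
    table = pd.read_csv(buf, sep="\t")
    if "groups" not in meta:
        raise SchemaError(f"{path}: header must record 'groups'")
    groups = tuple(meta["groups"].split(","))
    exp_meta = {k: v for k, v in meta.items() if k != "groups"}
    return JunctionTable(table=table, groups=groups, meta=exp_meta)


def write_results(df: pd.DataFrame, path: str, meta: Mapping | None = None) -> None:
    """Write an analysis result table as TSV with a commented header."""
    with open(path, "w") as fh:
        _write_commented_header(fh, meta or {})
        df.to_csv(fh, sep="\t", index=False)
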