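"""Gene annotation and expression-matrix I/O.

This module defines the in-memory containers used throughout the package:

* an annotation table (one row per gene: chromosome, coordinates, length)
  read from GFF3 or a simple TSV dialect;
* an :class:`ExpressionMatrix` — genes x samples values (fragment counts or
  FPKM) together with the sample design (population I-IV, replicate);
* per-population expression profiles (mean FPKM across replicates).

Chromosome names are normalised to the five-way scheme ``2 / 3 / X / Y /
other``; chromosome arms (``2L``, ``2R``, ``3L``, ``3R``) collapse onto
their chromosome, and any sequence named like a Y contig maps to ``Y``.
Coordinates are 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Germline populations, ordered from premeiotic (I) to postmeiotic (IV).
POPULATIONS: tuple[str, ...] = ("I", "II", "III", "IV")

#: Normalised chromosome labels.
CHROMOSOMES: tuple[str, ...] = ("2", "3", "X", "Y", "other")

#: Chromosomes counted as autosomes in X:A ratios.
AUTOSOMES: tuple[str, ...] = ("2", "3")

ANNOTATION_COLUMNS = ("chromosome", "start", "end", "length", "strand")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression input."""


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene or transcript.

    ``length`` is the base-pair length used for FPKM normalisation: the
    union of exonic bases when exons are annotated, otherwise the genomic
    span ``end - start + 1``.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    length: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise AnnotationError("gene_id must be non-empty")
        if self.chromosome not in CHROMOSOMES:
            raise AnnotationError(
                f"{self.gene_id}: chromosome {self.chromosome!r} not in {CHROMOSOMES}"
            )
        if self.start < 1:
            raise AnnotationError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise AnnotationError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.length < 1:
            raise AnnotationError(f"{self.gene_id}: length {self.length} < 1")
        if self.strand not in ("+", "-", "unknown"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")


def normalize_chromosome(name: str, y_contigs: Sequence[str] = ()) -> str:
    """Map a raw sequence name onto ``2 / 3 / X / Y / other``.

    Arms (2L/2R/3L/3R) collapse to the chromosome; a leading ``chr`` is
    ignored; names listed in *y_contigs* or starting with ``Y`` map to Y.
    """
    raw = name.strip()
    if raw in y_contigs:
        return "Y"
    s = raw.lower()
    if s.startswith("chr"):
        s = s[3:]
    if s in ("2", "2l", "2r"):
        return "2"
    if s in ("3", "3l", "3r"):
        return "3"
    if s == "x":
        return "X"
    if s.startswith("y"):
        return "Y"
    return "other"


def records_to_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Build the canonical annotation DataFrame (indexed by gene_id)."""
    rows = list(records)
    ids = [r.gene_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise AnnotationError(f"duplicate gene ids: {', '.join(dupes)}")
    frame = pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in rows],
            "start": [r.start for r in rows],
            "end": [r.end for r in rows],
            "length": [r.length for r in rows],
            "strand": [r.strand for r in rows],
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return frame


def frame_to_records(annotation: pd.DataFrame) -> list[GeneRecord]:
    """Inverse of :func:`records_to_frame` (validates every row)."""
    return [
        GeneRecord(
            gene_id=str(gid),
            chromosome=row["chromosome"],
            start=int(row["start"]),
            end=int(row["end"]),
            length=int(row["length"]),
            strand=row["strand"],
        )
        for gid, row in annotation.iterrows()
    ]


def _read_annotation_tsv(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, comment="#")
    required = {"gene_id", "chromosome", "start", "end", "length"}
    missing = required - set(table.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    if "strand" not in table.columns:
        table["strand"] = "unknown"
    records = [
        GeneRecord(
            gene_id=row.gene_id,
            chromosome=normalize_chromosome(str(row.chromosome)),
            start=int(row.start),
            end=int(row.end),
            length=int(row.length),
            strand=str(row.strand),
        )
        for row in table.itertuples(index=False)
    ]
    return records_to_frame(records)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total base pairs covered by the union of 1-based inclusive intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def _read_annotation_gff3(path: Path, y_contigs: Sequence[str]) -> pd.DataFrame:
    import gffutils

    # Light pre-scan so malformed lines are reported with their number.
    n_feature_lines = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno} (expected 9 tab-separated fields)"
                )
            n_feature_lines += 1
    if n_feature_lines == 0:
        return records_to_frame([])
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several exception types
        raise AnnotationError(f"{path}: failed to parse GFF3 ({exc})") from exc

    feature_types = set(db.featuretypes())
    if "gene" in feature_types:
        top_type = "gene"
    elif "mRNA" in feature_types:
        top_type = "mRNA"
    elif "transcript" in feature_types:
        top_type = "transcript"
    else:
        return records_to_frame([])

    records: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type(top_type, order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise AnnotationError(f"{path}: duplicate feature ID {gene_id!r}")
        seen.add(gene_id)
        exons = [(e.start, e.end) for e in db.children(feat, featuretype="exon")]
        length = _union_length(exons) if exons else feat.end - feat.start + 1
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chromosome=normalize_chromosome(feat.seqid, y_contigs),
                start=feat.start,
                end=feat.end,
                length=length,
                strand=strand,
            )
        )
    return records_to_frame(records)


def read_annotation(
    path: str | Path,
    dialect: str = "tsv",
    y_contigs: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a gene annotation as a DataFrame indexed by gene_id.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"tsv"`` (columns gene_id, chromosome, start, end, length[, strand])
        or ``"gff3"`` (gene/mRNA/exon features; gene length is the union of
        exon spans when exons are present).
    y_contigs:
        Extra sequence names to treat as Y contigs (the assembled Y of
        *A. gambiae* is a set of contigs rather than a single scaffold).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_annotation_tsv(path)
    if dialect == "gff3":
        return _read_annotation_gff3(path, y_contigs)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write the TSV annotation dialect (lossless round trip)."""
    annotation.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus the sample design.

    ``values`` is a DataFrame indexed by gene_id with one column per
    sample_id; ``design`` is indexed by sample_id with ``population`` and
    ``replicate`` columns; ``unit`` is ``"counts"`` or ``"FPKM"``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "FPKM"):
            raise ExpressionError(f"unit must be 'counts' or 'FPKM', got {self.unit!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(f"duplicate gene ids: {list(dupes[:5])}")
        if not set(("population", "replicate")) <= set(self.design.columns):
            raise ExpressionError("design needs 'population' and 'replicate' columns")
        if list(self.values.columns) != list(self.design.index):
            raise ExpressionError("values columns and design sample_ids disagree")
        bad_pop = set(self.design["population"]) - set(POPULATIONS)
        if bad_pop:
            raise ExpressionError(f"unknown populations {sorted(bad_pop)}")
        missing = set(POPULATIONS) - set(self.design["population"])
        if missing:
            raise ExpressionError(f"populations absent from design: {sorted(missing)}")
        if self.design.duplicated(subset=["population", "replicate"]).any():
            raise ExpressionError("(population, replicate) pairs must be unique")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ExpressionError("expression values must be finite")
        if (arr < 0).any():
            raise ExpressionError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.design.index

    def samples_of(self, population: str) -> list[str]:
        return list(self.design.index[self.design["population"] == population])


def read_expression(
    values_path: str | Path, design_path: str | Path, unit: str
) -> ExpressionMatrix:
    """Read a values TSV (gene_id + sample columns) and its design TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id", comment="#")
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id", comment="#")
    return ExpressionMatrix(values=values, design=design, unit=unit)


def write_expression(m: ExpressionMatrix, values_path: str | Path, design_path: str | Path) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="gene_id")
    m.design.to_csv(design_path, sep="\t", index_label="sample_id")


def counts_to_fpkm(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Convert fragment counts to FPKM.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total_counts[s]).
    """
    if m.unit != "counts":
        raise ExpressionError(f"expected a counts matrix, got unit={m.unit!r}")
    missing = m.genes.difference(annotation.index)
    if len(missing):
        raise ExpressionError(
            f"no gene length for {len(missing)} genes: {list(missing[:10])}"
        )
    lengths = annotation.loc[m.genes, "length"].to_numpy(dtype=float)
    totals = m.values.sum(axis=0).to_numpy(dtype=float)
    zero = m.values.columns[totals == 0]
    if len(zero):
        raise ExpressionError(f"samples with zero total counts: {list(zero)}")
    fpkm = m.values.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=m.genes, columns=m.values.columns),
        design=m.design.copy(),
        unit="FPKM",
    )


def population_profiles(m: ExpressionMatrix) -> pd.DataFrame:
    """Collapse replicates to one FPKM value per gene per population.

    Uses the arithmetic mean of replicate FPKM. Returns a DataFrame indexed
    by gene_id with columns I, II, III, IV.
    """
    if m.unit != "FPKM":
        raise ExpressionError("population profiles require an FPKM matrix")
    cols = {}
    for pop in POPULATIONS:
        samples = m.samples_of(pop)
        if not samples:
            raise ExpressionError(f"population {pop} absent from design")
        cols[pop] = m.values[samples].mean(axis=1)
    profiles = pd.DataFrame(cols, index=m.genes)
    profiles.index.name = "gene_id"
    return profiles


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read a per-population profile TSV (gene_id, I, II, III, IV)."""
    profiles = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
    missing = set(POPULATIONS) - set(profiles.columns)
    if missing:
        raise ExpressionError(f"profile table missing populations {sorted(missing)}")
    return profiles[list(POPULATIONS)]
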