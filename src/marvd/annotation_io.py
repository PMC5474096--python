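"""Read gene-level taxonomic annotation evidence into a common table.

Two evidence paths feed the classifier:

* a gene-per-contig annotation table (tab-delimited, with one row per
  predicted gene, annotated or not, carrying the free-text taxonomy of the
  best reference hit and its bit-score), and
* raw protein-similarity hits in BLAST tabular ``outfmt 6``, reduced to the
  best hit per gene and joined against a subject-to-lineage map.

Both produce an :class:`AnnotationTable`: one :class:`GeneAnnotation` per
gene, grouped by contig, with per-contig total gene counts (annotated and
unannotated alike) derived from the row counts.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, TextIO

import pandas as pd

from .lexicon import TaxonGroup, TaxonLexicon, default_lexicon

#: Documented header of the annotation TSV dialect.
ANNOTATION_COLUMNS = ("contig_id", "gene_id", "gene_index", "lineage", "bit_score", "e_value")
_REQUIRED_COLUMNS = ("contig_id", "gene_id", "lineage", "bit_score")

#: Column names of BLAST tabular ``-outfmt 6`` (12 columns).
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class AnnotationFormatError(ValueError):
    """Malformed annotation input (missing column, bad value, bad row)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's best reference hit, affiliated to a coarse taxon group.

    ``bit_score`` is 0 and ``taxon_group`` is ``unclassified`` for genes
    without an annotation (empty lineage) or whose lineage matches no
    lexicon keyword.
    """

    contig_id: str
    gene_id: str
    gene_index: int
    lineage: str
    taxon_group: TaxonGroup
    bit_score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError(f"negative bit-score for gene {self.gene_id!r}")


class AnnotationTable:
    """Gene annotations grouped by contig, with per-contig gene totals.

    Internally a :class:`pandas.DataFrame` (one row per gene) so that whole
    viromes (10^5+ genes) profile quickly; the row-level API yields
    :class:`GeneAnnotation` objects.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ("contig_id", "gene_id", "gene_index", "lineage",
                               "taxon_group", "bit_score", "e_value") if c not in frame.columns]
        if missing:
            raise AnnotationFormatError(f"annotation frame missing columns: {missing}")
        dup = frame.duplicated(subset=["contig_id", "gene_id"])
        if dup.any():
            offenders = frame.loc[dup, ["contig_id", "gene_id"]].drop_duplicates()
            pairs = [f"{c}/{g}" for c, g in offenders.itertuples(index=False)]
            raise AnnotationFormatError(f"duplicate gene ids within a contig: {', '.join(pairs)}")
        self._frame = frame.reset_index(drop=True)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_annotations(cls, annotations: Iterable[GeneAnnotation]) -> "AnnotationTable":
        rows = [
            (a.contig_id, a.gene_id, a.gene_index, a.lineage, a.taxon_group.value,
             a.bit_score, math.nan if a.e_value is None else a.e_value)
            for a in annotations
        ]
        frame = pd.DataFrame(
            rows,
            columns=["contig_id", "gene_id", "gene_index", "lineage",
                     "taxon_group", "bit_score", "e_value"],
        )
        if frame.empty:
            frame = frame.astype({"gene_index": "int64", "bit_score": "float64",
                                  "e_value": "float64"})
        return cls(frame)

    # -- queries ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def contig_ids(self) -> list[str]:
        return list(dict.fromkeys(self._frame["contig_id"]))

    def total_genes(self) -> dict[str, int]:
        """Per-contig total gene count, unannotated genes included."""
        return self._frame.groupby("contig_id", sort=False).size().to_dict()

    def annotated_genes(self) -> dict[str, int]:
        mask = self._frame["taxon_group"] != TaxonGroup.UNCLASSIFIED.value
        counts = self._frame[mask].groupby("contig_id", sort=False).size()
        return {c: int(counts.get(c, 0)) for c in self.contig_ids()}

    def by_contig(self) -> Iterator[tuple[str, list[GeneAnnotation]]]:
        for contig_id, sub in self._frame.groupby("contig_id", sort=False):
            yield contig_id, [self._row_to_annotation(r) for r in sub.itertuples(index=False)]

    @staticmethod
    def _row_to_annotation(row) -> GeneAnnotation:
        ev = row.e_value
        return GeneAnnotation(
            contig_id=row.contig_id,
            gene_id=row.gene_id,
            gene_index=int(row.gene_index),
            lineage=row.lineage,
            taxon_group=TaxonGroup(row.taxon_group),
            bit_score=float(row.bit_score),
            e_value=None if (ev is None or (isinstance(ev, float) and math.isnan(ev))) else float(ev),
        )

    # -- serialization ---------------------------------------------------

    def to_tsv(self, stream: TextIO) -> None:
        """Write the documented annotation TSV dialect (round-trippable)."""
        stream.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for row in self._frame.itertuples(index=False):
            ev = "" if (row.e_value is None or (isinstance(row.e_value, float) and math.isnan(row.e_value))) else repr(float(row.e_value))
            bit = "" if row.taxon_group == TaxonGroup.UNCLASSIFIED.value and row.bit_score == 0 else repr(float(row.bit_score))
            stream.write(
                f"{row.contig_id}\t{row.gene_id}\t{int(row.gene_index)}\t{row.lineage}\t{bit}\t{ev}\n"
            )

    def to_tsv_text(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


def _affiliate_frame(frame: pd.DataFrame, lexicon: TaxonLexicon) -> pd.Series:
    """Vectorised lineage -> taxon-group affiliation (memoised per table)."""
    unique = frame["lineage"].unique()
    mapping = {lin: lexicon.affiliate(lin).value for lin in unique}
    return frame["lineage"].map(mapping)


def parse_annotation_table(
    stream: TextIO | str,
    lexicon: TaxonLexicon | None = None,
) -> AnnotationTable:
    """Parse the gene-per-contig annotation TSV dialect.

    Required columns: ``contig_id``, ``gene_id``, ``lineage``, ``bit_score``
    (``gene_index`` and ``e_value`` optional).  Genes with an empty lineage
    are kept as unannotated rows so per-contig totals count every predicted
    gene.  An empty stream yields an empty table.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lexicon = lexicon or default_lexicon()

    header_line = stream.readline()
    if not header_line.strip():
        return AnnotationTable.from_annotations([])
    header = header_line.rstrip("\n").split("\t")
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise AnnotationFormatError(f"missing required column(s): {', '.join(missing)}")
    col = {name: i for i, name in enumerate(header)}

    records: list[tuple] = []
    per_contig_index: dict[str, int] = {}
    for lineno, raw in enumerate(stream, start=2):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < len(header):
            fields += [""] * (len(header) - len(fields))
        contig_id = fields[col["contig_id"]]
        gene_id = fields[col["gene_id"]]
        lineage = fields[col["lineage"]].strip()
        bit_raw = fields[col["bit_score"]].strip()
        if lineage and bit_raw:
            try:
                bit = float(bit_raw)
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"line {lineno}: non-numeric bit-score {bit_raw!r}"
                ) from exc
        elif not lineage:
            bit = 0.0
        else:
            raise AnnotationFormatError(
                f"line {lineno}: annotated gene {gene_id!r} has no bit-score"
            )
        if "gene_index" in col and fields[col["gene_index"]].strip():
            try:
                gidx = int(fields[col["gene_index"]])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"line {lineno}: non-integer gene_index {fields[col['gene_index']]!r}"
                ) from exc
        else:
            gidx = per_contig_index.get(contig_id, 0)
        per_contig_index[contig_id] = gidx + 1
        ev = math.nan
        if "e_value" in col and fields[col["e_value"]].strip():
            try:
                ev = float(fields[col["e_value"]])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"line {lineno}: non-numeric e-value"
                ) from exc
        records.append((contig_id, gene_id, gidx, lineage, bit, ev))

    frame = pd.DataFrame(
        records,
        columns=["contig_id", "gene_id", "gene_index", "lineage", "bit_score", "e_value"],
    )
    if frame.empty:
        return AnnotationTable.from_annotations([])
    frame["taxon_group"] = _affiliate_frame(frame, lexicon)
    return AnnotationTable(frame[["contig_id", "gene_id", "gene_index", "lineage",
                                  "taxon_group", "bit_score", "e_value"]])


def split_query_id(qseqid: str, separator: str = "_") -> tuple[str, str, int]:
    """Split an outfmt-6 query id into (contig_id, gene_id, gene_index).

    Convention: the gene index is the final separator-delimited token,
    the contig id is everything before it; the full query id is the gene id.
    """
    head, sep, tail = qseqid.rpartition(separator)
    if not sep or not tail.isdigit():
        raise AnnotationFormatError(
            f"query id {qseqid!r} does not end in {separator!r}<gene index>"
        )
    return head, qseqid, int(tail)


def parse_blast_hits(
    stream: TextIO | str,
    taxmap: Mapping[str, str],
    lexicon: TaxonLexicon | None = None,
    separator: str = "_",
) -> AnnotationTable:
    """Reduce BLAST tabular (``-outfmt 6``) hits to one best hit per gene.

    Per gene the hit with the highest bit-score is kept; ties break to the
    lowest e-value, remaining ties to file order.  Subjects absent from
    ``taxmap`` yield an unclassified annotation whose bit-score is kept.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lexicon = lexicon or default_lexicon()

    # best[gene_id] = (bit, -evalue ordering handled explicitly)
    best: dict[str, tuple[float, float, int, str, str, int]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != len(BLAST6_COLUMNS):
            raise AnnotationFormatError(
                f"line {lineno}: expected {len(BLAST6_COLUMNS)} tab-separated "
                f"columns, got {len(fields)}"
            )
        qseqid, sseqid = fields[0], fields[1]
        try:
            evalue = float(fields[10])
            bit = float(fields[11])
        except ValueError as exc:
            raise AnnotationFormatError(f"line {lineno}: non-numeric e-value/bit-score") from exc
        contig_id, gene_id, gene_index = split_query_id(qseqid, separator)
        incumbent = best.get(gene_id)
        if incumbent is None:
            order.append(gene_id)
            best[gene_id] = (bit, evalue, lineno, contig_id, sseqid, gene_index)
        else:
            ibit, iev, _iline, *_ = incumbent
            if bit > ibit or (bit == ibit and evalue < iev):
                best[gene_id] = (bit, evalue, lineno, contig_id, sseqid, gene_index)

    annotations = []
    for gene_id in order:
        bit, evalue, _, contig_id, sseqid, gene_index = best[gene_id]
        lineage = taxmap.get(sseqid, "")
        annotations.append(
            GeneAnnotation(
                contig_id=contig_id,
                gene_id=gene_id,
                gene_index=gene_index,
                lineage=lineage,
                taxon_group=lexicon.affiliate(lineage),
                bit_score=bit,
                e_value=evalue,
            )
        )
    return AnnotationTable.from_annotations(annotations)
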