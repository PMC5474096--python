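"""Majority-rules category assignment for putative archaeal virus contigs.

A contig is profiled from its gene annotations — how many genes are
annotated at all, what fraction of the (non-eukaryotic-virus) annotated
genes affiliate with reference archaeal viruses, and the best bit-score per
taxon group — and then assigned to one of three categories:

* **Category 1** — three or more annotated genes, a strict majority
  (> 2/3) affiliating with archaeal viruses, at least one such annotation
  above the quality floor (bit-score 75) and better than every phage
  annotation.  Contigs with only one or two annotations, *all* of them
  archaeal-virus, also land here: archaeal viruses are so under-represented
  in reference databases that most genes on a genuine archaeal virus contig
  are expected to be unclassifiable.
* **Category 2** — the same majority and quality conditions, but at least
  one phage annotation outscores the archaeal-virus ones (mosaic genomes,
  horizontal transfer, or phage-biased databases).
* **Category 3** — a minority-to-half share (1/3 to 2/3 inclusive) of
  archaeal-virus annotations whose quality nevertheless exceeds the phage
  annotations; evidence is weighted by annotation quality rather than count.

Eukaryotic-virus annotations are counted but excluded from the
archaeal-virus fraction.  The printed thresholds 66.6% and 33.3% are
treated as the exact rationals 2/3 and 1/3, with category 3 inclusive on
both ends and categories 1/2 strictly above 2/3; "higher than 75" and
"exceeds" are strict comparisons, which makes categories 1 and 2 mutually
exclusive.  All thresholds are user-configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .annotation_io import AnnotationTable, GeneAnnotation
from .lexicon import TaxonGroup

_EVIDENCE_GROUPS = (
    TaxonGroup.ARCHAEAL_VIRUS,
    TaxonGroup.PHAGE,
    TaxonGroup.EUKARYOTIC_VIRUS,
    TaxonGroup.CELLULAR,
)


class Category(enum.Enum):
    """Assignment outcome; CAT1 is the most confident archaeal-virus call."""

    CAT1 = 1
    CAT2 = 2
    CAT3 = 3
    NONE = "none"

    def __str__(self) -> str:
        return str(self.value)

    @property
    def is_positive(self) -> bool:
        return self is not Category.NONE


@dataclass(frozen=True)
class Thresholds:
    """Tunable decision thresholds (defaults are the published rules)."""

    majority_fraction: Fraction = Fraction(2, 3)
    minor_fraction: Fraction = Fraction(1, 3)
    min_bit: float = 75.0
    min_annotations_main: int = 3
    few_annotation_clause_max: int = 2
    require_min_bit_in_clause: bool = True
    exclude_cellular_from_fraction: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.minor_fraction <= self.majority_fraction < 1):
            raise ValueError("need 0 < minor_fraction <= majority_fraction < 1")
        if self.min_bit <= 0:
            raise ValueError("min_bit must be positive")


@dataclass(frozen=True)
class ContigProfile:
    """Per-contig annotation summary the category rules operate on.

    ``arch_fraction`` is the share of archaeal-virus genes among annotated
    genes, excluding eukaryotic-virus genes from both numerator and
    denominator (and optionally cellular genes too); it is ``None`` when the
    denominator is empty.  Kept as an exact :class:`fractions.Fraction` so
    the 1/3 and 2/3 boundaries compare exactly.
    """

    contig_id: str
    n_genes_total: int
    counts: dict[TaxonGroup, int] = field(default_factory=dict)
    max_bit: dict[TaxonGroup, float] = field(default_factory=dict)
    exclude_cellular_from_fraction: bool = False

    @property
    def n_annotated(self) -> int:
        return sum(self.counts.get(g, 0) for g in _EVIDENCE_GROUPS)

    @property
    def arch_fraction(self) -> Fraction | None:
        n_arch = self.counts.get(TaxonGroup.ARCHAEAL_VIRUS, 0)
        denom = n_arch + self.counts.get(TaxonGroup.PHAGE, 0)
        if not self.exclude_cellular_from_fraction:
            denom += self.counts.get(TaxonGroup.CELLULAR, 0)
        if denom == 0:
            return None
        return Fraction(n_arch, denom)

    def bit(self, group: TaxonGroup) -> float:
        """Best bit-score in a group; 0 when the group has no genes."""
        return self.max_bit.get(group, 0.0)


@dataclass(frozen=True)
class CategoryAssignment:
    """A contig's category together with the evaluated rule trace."""

    contig_id: str
    category: Category
    rule_trace: tuple[str, ...] = ()


def profile_contig(
    annotations: Sequence[GeneAnnotation],
    n_genes_total: int,
    exclude_cellular_from_fraction: bool = False,
) -> ContigProfile:
    """Summarise one contig's annotations into a :class:`ContigProfile`."""
    contig_ids = {a.contig_id for a in annotations}
    if len(contig_ids) > 1:
        raise ValueError(f"annotations span multiple contigs: {sorted(contig_ids)}")
    if n_genes_total < len(annotations):
        raise ValueError("n_genes_total smaller than the number of annotation rows")
    contig_id = next(iter(contig_ids)) if contig_ids else ""
    counts: dict[TaxonGroup, int] = {}
    max_bit: dict[TaxonGroup, float] = {}
    for a in annotations:
        if a.taxon_group is TaxonGroup.UNCLASSIFIED:
            continue
        counts[a.taxon_group] = counts.get(a.taxon_group, 0) + 1
        if a.bit_score > max_bit.get(a.taxon_group, 0.0):
            max_bit[a.taxon_group] = a.bit_score
    return ContigProfile(
        contig_id=contig_id,
        n_genes_total=n_genes_total,
        counts=counts,
        max_bit=max_bit,
        exclude_cellular_from_fraction=exclude_cellular_from_fraction,
    )


def assign_category(profile: ContigProfile, t: Thresholds | None = None) -> CategoryAssignment:
    """Evaluate the category rules (precedence 1, 2, 3) on one profile."""
    t = t or Thresholds()
    trace: list[str] = []
    n_ann = profile.n_annotated
    frac = profile.arch_fraction
    arch_bit = profile.bit(TaxonGroup.ARCHAEAL_VIRUS)
    phage_bit = profile.bit(TaxonGroup.PHAGE)
    n_arch = profile.counts.get(TaxonGroup.ARCHAEAL_VIRUS, 0)

    def check(label: str, ok: bool) -> bool:
        trace.append(f"{label}: {'pass' if ok else 'fail'}")
        return ok

    # Category 1, main rule
    if (
        check("cat1 n_annotated>=min", n_ann >= t.min_annotations_main)
        and check("cat1 arch_fraction>majority", frac is not None and frac > t.majority_fraction)
        and check("cat1 max_bit(arch)>min_bit", arch_bit > t.min_bit)
        and check("cat1 max_bit(arch)>max_bit(phage)", arch_bit > phage_bit)
    ):
        return CategoryAssignment(profile.contig_id, Category.CAT1, tuple(trace))

    # Category 1, few-annotation clause: 1-2 annotations, all archaeal-virus
    if check(
        "cat1-clause 1<=n_annotated<=clause_max",
        1 <= n_ann <= t.few_annotation_clause_max,
    ):
        all_arch = n_arch == n_ann
        ok = check("cat1-clause all annotations archaeal", all_arch)
        if ok and t.require_min_bit_in_clause:
            ok = check("cat1-clause max_bit(arch)>min_bit", arch_bit > t.min_bit)
        if ok:
            return CategoryAssignment(profile.contig_id, Category.CAT1, tuple(trace))

    # Category 2: majority rule but a phage annotation outscores the archaeal ones
    if (
        check("cat2 n_annotated>=min", n_ann >= t.min_annotations_main)
        and check("cat2 arch_fraction>majority", frac is not None and frac > t.majority_fraction)
        and check("cat2 max_bit(arch)>min_bit", arch_bit > t.min_bit)
        and check("cat2 max_bit(phage)>=max_bit(arch)", phage_bit >= arch_bit)
    ):
        return CategoryAssignment(profile.contig_id, Category.CAT2, tuple(trace))

    # Category 3: minority share with superior annotation quality
    if (
        check("cat3 n_annotated>=min", n_ann >= t.min_annotations_main)
        and check(
            "cat3 minor<=arch_fraction<=majority",
            frac is not None and t.minor_fraction <= frac <= t.majority_fraction,
        )
        and check("cat3 max_bit(arch)>min_bit", arch_bit > t.min_bit)
        and check("cat3 max_bit(arch)>max_bit(phage)", arch_bit > phage_bit)
    ):
        return CategoryAssignment(profile.contig_id, Category.CAT3, tuple(trace))

    return CategoryAssignment(profile.contig_id, Category.NONE, tuple(trace))


@dataclass
class ClassificationResult:
    """All assignments for a table plus the induced contig-id partition."""

    assignments: list[CategoryAssignment]
    profiles: dict[str, ContigProfile]

    def partition(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {"cat1": set(), "cat2": set(), "cat3": set(), "rejected": set()}
        for a in self.assignments:
            key = {Category.CAT1: "cat1", Category.CAT2: "cat2",
                   Category.CAT3: "cat3", Category.NONE: "rejected"}[a.category]
            sets[key].add(a.contig_id)
        return sets

    def summary(self) -> dict[str, int]:
        part = self.partition()
        return {k: len(v) for k, v in part.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            p = self.profiles[a.contig_id]
            frac = p.arch_fraction
            rows.append(
                {
                    "contig_id": a.contig_id,
                    "category": str(a.category),
                    "n_genes": p.n_genes_total,
                    "n_annotated": p.n_annotated,
                    "arch_fraction": float(frac) if frac is not None else float("nan"),
                    "max_bit_archaeal_virus": p.bit(TaxonGroup.ARCHAEAL_VIRUS),
                    "max_bit_phage": p.bit(TaxonGroup.PHAGE),
                    "max_bit_eukaryotic_virus": p.bit(TaxonGroup.EUKARYOTIC_VIRUS),
                    "max_bit_cellular": p.bit(TaxonGroup.CELLULAR),
                    "rule_trace": "; ".join(a.rule_trace),
                }
            )
        return pd.DataFrame(rows)


def _profiles_from_table(
    table: AnnotationTable, exclude_cellular: bool
) -> dict[str, ContigProfile]:
    """Vectorised profiling of a whole table (fast path for large viromes)."""
    frame = table.frame
    totals = table.total_genes()
    profiles: dict[str, ContigProfile] = {}
    annotated = frame[frame["taxon_group"] != TaxonGroup.UNCLASSIFIED.value]
    if len(annotated):
        grouped = annotated.groupby(["contig_id", "taxon_group"], sort=False)["bit_score"]
        counts = grouped.size()
        maxima = grouped.max()
    else:
        counts = pd.Series(dtype="int64")
        maxima = pd.Series(dtype="float64")
    per_contig: dict[str, tuple[dict, dict]] = {}
    for (contig_id, group), n in counts.items():
        cdict, bdict = per_contig.setdefault(contig_id, ({}, {}))
        g = TaxonGroup(group)
        cdict[g] = int(n)
        bdict[g] = float(maxima.loc[(contig_id, group)])
    for contig_id, total in totals.items():
        cdict, bdict = per_contig.get(contig_id, ({}, {}))
        profiles[contig_id] = ContigProfile(
            contig_id=contig_id,
            n_genes_total=int(total),
            counts=cdict,
            max_bit=bdict,
            exclude_cellular_from_fraction=exclude_cellular,
        )
    return profiles


def classify_table(
    table: AnnotationTable, t: Thresholds | None = None
) -> ClassificationResult:
    """Profile and categorise every contig in an annotation table.

    Every contig receives exactly one assignment; the induced
    {cat1, cat2, cat3, rejected} sets partition the input contigs.
    """
    t = t or Thresholds()
    profiles = _profiles_from_table(table, t.exclude_cellular_from_fraction)
    assignments = [assign_category(profiles[c], t) for c in table.contig_ids()]
    return ClassificationResult(assignments=assignments, profiles=profiles)
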