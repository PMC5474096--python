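"""Contig filtering and ANI-based collapse into viral populations.

Candidate contigs are first filtered (by length, ORF count and presence of
an archaeal-virus hit), then contigs ≥ 10 kb are dereplicated into
"populations": clusters sharing ≥ 95% average nucleotide identity across
≥ 80% of the shorter sequence, the operational species-like unit in
viromics.  Clustering is greedy and longest-first with a fixed
representative, mirroring cd-hit semantics: contigs are sorted by length
(descending, contig-id tie-break), and each contig joins the first earlier
representative it matches, else founds a new population.

ANI is computed from the best local pairwise alignment (affine gaps,
blastn-like scoring).  Identities are counted over alignment columns
including internal gap columns; columns involving N never count as
identities.  The aligned fraction is measured on the shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner


@dataclass(frozen=True)
class ContigRecord:
    """A candidate contig with the metadata the filters need."""

    contig_id: str
    sequence: str
    n_orfs: int = 0
    has_archaeal_hit: bool = False

    def __post_init__(self) -> None:
        if self.n_orfs < 0:
            raise ValueError("n_orfs must be non-negative")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AniResult:
    """Pairwise identity summary: ANI (%) and aligned fraction of the shorter."""

    ani: float
    aligned_fraction_shorter: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ani <= 100.0):
            raise ValueError("ani out of [0, 100]")
        if not (0.0 <= self.aligned_fraction_shorter <= 1.0 + 1e-12):
            raise ValueError("aligned fraction out of [0, 1]")


@dataclass
class Population:
    """A dereplicated cluster; the representative is its longest member."""

    representative_id: str
    member_ids: set[str] = field(default_factory=set)


def read_contigs(path, orf_counts: dict[str, int] | None = None,
                 archaeal_hits: set[str] | None = None) -> list[ContigRecord]:
    """Load contigs from FASTA, optionally joining ORF counts and hit flags."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ContigRecord(
                contig_id=rec.id,
                sequence=str(rec.seq),
                n_orfs=(orf_counts or {}).get(rec.id, 0),
                has_archaeal_hit=rec.id in (archaeal_hits or set()),
            )
        )
    return records


#: Candidate preset: the entry filter applied to assembled viral contigs
#: before classification (strictly > 1,000 bp, ≥ 3 ORFs, ≥ 1 archaeal hit).
CANDIDATE_PRESET = dict(min_len=1000, min_orfs=3, require_archaeal_hit=True)
#: Population preset: only contigs above 10 kb are long enough to treat as
#: population-level genomes/fragments.
POPULATION_PRESET = dict(min_len=10000, min_orfs=0, require_archaeal_hit=False)


def prefilter(
    contigs: Iterable[ContigRecord],
    min_len: int = 1000,
    min_orfs: int = 3,
    require_archaeal_hit: bool = True,
) -> list[ContigRecord]:
    """Order-preserving filter; length thresholds are strict (``> min_len``)."""
    if min_len < 0 or min_orfs < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        c
        for c in contigs
        if c.length > min_len
        and c.n_orfs >= min_orfs
        and (c.has_archaeal_hit or not require_archaeal_hit)
    ]


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.wildcard = "N"  # N scores 0 against anything
    return aligner


def ani(a: ContigRecord | str, b: ContigRecord | str) -> AniResult:
    """ANI and aligned fraction from the best local alignment of two contigs.

    ANI = identities / alignment columns (gap columns included); the
    aligned fraction is the span of the alignment on the shorter sequence
    divided by the shorter sequence's length.  Symmetric in its arguments.
    """
    seq_a = a.sequence if isinstance(a, ContigRecord) else a.upper()
    seq_b = b.sequence if isinstance(b, ContigRecord) else b.upper()
    if not seq_a or not seq_b:
        raise ValueError("cannot compute ANI of an empty sequence")

    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return AniResult(ani=0.0, aligned_fraction_shorter=0.0)

    identities = 0
    aligned_pairs = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_pairs += a1 - a0
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if x == y and x != "N":
                identities += 1
    # internal gap columns: unaligned stretches between consecutive blocks
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    gap_columns = (span_a - aligned_pairs) + (span_b - aligned_pairs)
    columns = aligned_pairs + gap_columns

    shorter_len = min(len(seq_a), len(seq_b))
    shorter_span = span_a if len(seq_a) <= len(seq_b) else span_b
    return AniResult(
        ani=100.0 * identities / columns,
        aligned_fraction_shorter=min(1.0, shorter_span / shorter_len),
    )


def greedy_cluster(
    contigs: Sequence[ContigRecord],
    min_ani: float = 95.0,
    min_fraction: float = 0.8,
) -> list[Population]:
    """Greedy longest-first clustering into populations (cd-hit semantics).

    Contigs are processed in length-descending order (ties broken by
    contig id); each joins the first existing population whose
    representative it matches at ``ani >= min_ani`` and aligned fraction
    ``>= min_fraction``, else founds a new population.  The output is a
    partition of the input, listed in founding order, and is independent
    of the input ordering.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    populations: list[Population] = []
    representatives: list[ContigRecord] = []
    for contig in ordered:
        placed = False
        for pop, rep in zip(populations, representatives):
            result = ani(contig, rep)
            if result.ani >= min_ani and result.aligned_fraction_shorter >= min_fraction:
                pop.member_ids.add(contig.contig_id)
                placed = True
                break
        if not placed:
            populations.append(
                Population(representative_id=contig.contig_id,
                           member_ids={contig.contig_id})
            )
            representatives.append(contig)
    return populations
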