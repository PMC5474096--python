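"""Keyword lexicon mapping free-text taxonomy strings to coarse taxon groups.

Gene annotations in viromic pipelines carry a free-text lineage or organism
name for the best reference hit ("Sulfolobus spindle-shaped virus 1",
"Prochlorococcus phage P-SSM2", ...).  Affiliation to a coarse host-taxonomy
group is done by case-insensitive substring search against an ordered,
user-tailorable keyword list, one keyword set per group.  Groups are
evaluated in a fixed priority order so that specific tokens (archaeal virus
family names) win over generic ones ("virus", "phage").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, TextIO


class TaxonGroup(str, enum.Enum):
    """Coarse taxon group of a gene's best reference hit."""

    ARCHAEAL_VIRUS = "archaeal_virus"
    PHAGE = "phage"
    EUKARYOTIC_VIRUS = "eukaryotic_virus"
    CELLULAR = "cellular"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: Priority order in which groups are tested: archaeal-virus keywords are
#: checked before eukaryotic-virus, then phage, then cellular, so that e.g.
#: "Halovirus" is not shadowed by the generic "virus" token of the phage set.
DEFAULT_PRIORITY = (
    TaxonGroup.ARCHAEAL_VIRUS,
    TaxonGroup.EUKARYOTIC_VIRUS,
    TaxonGroup.PHAGE,
    TaxonGroup.CELLULAR,
)


@dataclass(frozen=True)
class TaxonLexicon:
    """Ordered (group, keywords) table with case-insensitive substring match.

    ``groups`` preserves priority order; a lineage maps to the first group
    with any matching keyword, else to :attr:`TaxonGroup.UNCLASSIFIED`.
    """

    groups: tuple[tuple[TaxonGroup, tuple[str, ...]], ...]
    _lowered: tuple[tuple[TaxonGroup, tuple[str, ...]], ...] = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for group, keywords in self.groups:
            for kw in keywords:
                if not kw or not kw.strip():
                    raise ValueError(f"empty keyword in group {group.value!r}")
        object.__setattr__(
            self,
            "_lowered",
            tuple((g, tuple(k.lower() for k in kws)) for g, kws in self.groups),
        )

    def affiliate(self, lineage: str) -> TaxonGroup:
        """Map a free-text lineage to a taxon group (total, deterministic)."""
        if not lineage:
            return TaxonGroup.UNCLASSIFIED
        text = lineage.lower()
        for group, keywords in self._lowered:
            if any(kw in text for kw in keywords):
                return group
        return TaxonGroup.UNCLASSIFIED

    def keywords_for(self, group: TaxonGroup) -> tuple[str, ...]:
        for g, kws in self.groups:
            if g is group:
                return kws
        return ()

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[TaxonGroup | str, Iterable[str]]]
    ) -> "TaxonLexicon":
        return cls(
            tuple((TaxonGroup(g), tuple(kws)) for g, kws in pairs)
        )

    @classmethod
    def from_stream(cls, stream: TextIO) -> "TaxonLexicon":
        """Parse the plain-text lexicon format: ``group: keyword`` per line.

        Lines are grouped preserving first-appearance order of each group;
        blank lines and ``#`` comments are ignored.
        """
        order: list[TaxonGroup] = []
        table: dict[TaxonGroup, list[str]] = {}
        for n, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"lexicon line {n}: expected 'group: keyword', got {line!r}")
            gname, keyword = line.split(":", 1)
            try:
                group = TaxonGroup(gname.strip())
            except ValueError as exc:
                raise ValueError(f"lexicon line {n}: unknown group {gname.strip()!r}") from exc
            keyword = keyword.strip()
            if not keyword:
                raise ValueError(f"lexicon line {n}: empty keyword")
            if group not in table:
                order.append(group)
                table[group] = []
            table[group].append(keyword)
        return cls.from_pairs((g, table[g]) for g in order)

    @classmethod
    def from_file(cls, path) -> "TaxonLexicon":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_stream(fh)

    def to_text(self) -> str:
        lines = []
        for group, keywords in self.groups:
            for kw in keywords:
                lines.append(f"{group.value}: {kw}")
        return "\n".join(lines) + "\n"


# Default keyword sets.  Archaeal-virus keywords cover the named isolate
# viruses and virus families of Archaea in RefSeq; host-genus tokens paired
# with "virus"/"phage" catch names such as "Methanobacterium phage psiM2"
# that would otherwise fall to the generic phage tokens.  The list is a
# starting point -- the lexicon is deliberately user-tailorable.
_DEFAULT_KEYWORDS: dict[TaxonGroup, tuple[str, ...]] = {
    TaxonGroup.ARCHAEAL_VIRUS: (
        "archaeal virus",
        "archaeal tailed virus",
        "fusellovir",
        "lipothrixvir",
        "rudivir",
        "bicaudavir",
        "ampullavir",
        "globulovir",
        "guttavir",
        "turrivir",
        "pleolipovir",
        "sphaerolipovir",
        "salterprovir",
        "spiravir",
        "halovirus",
        "sulfolobus spindle-shaped virus",
        "sulfolobus virus",
        "sulfolobus turreted",
        "sulfolobus monocaudavirus",
        "acidianus virus",
        "acidianus filamentous virus",
        "acidianus bottle-shaped virus",
        "acidianus two-tailed virus",
        "aeropyrum pernix virus",
        "aeropyrum pernix bacilliform virus",
        "thermoproteus virus",
        "thermoproteus tenax virus",
        "pyrobaculum virus",
        "pyrobaculum spherical virus",
        "pyrococcus abyssi virus",
        "thermococcus virus",
        "methanococcus virus",
        "methanococcus voltae virus",
        "methanobacterium virus",
        "methanobacterium phage",
        "methanothermobacter phage",
        "haloarcula virus",
        "haloarcula hispanica virus",
        "halorubrum virus",
        "halorubrum pleomorphic virus",
        "haloferax virus",
        "halobacterium virus",
        "halobacterium phage",
        "halogeometricum pleomorphic virus",
        "natrialba virus",
        "natrialba phage",
        "his1 virus",
        "his2 virus",
        "ssv1",
        "ssv2",
        "sirv1",
        "sirv2",
    ),
    TaxonGroup.EUKARYOTIC_VIRUS: (
        "mimivirus",
        "megavirus",
        "pandoravirus",
        "phycodnavir",
        "chlorella virus",
        "ostreococcus",
        "micromonas",
        "bathycoccus",
        "emiliania huxleyi virus",
        "coccolithovirus",
        "prymnesiovirus",
        "herpesvir",
        "baculovir",
        "nucleopolyhedrovirus",
        "granulovirus",
        "iridovir",
        "ascovir",
        "poxvir",
        "adenovir",
        "polyomavir",
        "papillomavir",
        "circovir",
        "parvovir",
        "retrovir",
        "reovir",
        "picornavir",
        "nudivir",
        "marseillevir",
    ),
    TaxonGroup.PHAGE: (
        "phage",
        "myovir",
        "siphovir",
        "podovir",
        "caudovirales",
        "inovir",
        "microvir",
        "tectivir",
        "corticovir",
        "leviviridae",
        "cystoviridae",
        "prophage",
        "virus",  # generic fallback: unadorned "...virus" names in RefSeq
    ),
    TaxonGroup.CELLULAR: (
        "archaeon",
        "archaea",
        "thaumarchaeota",
        "euryarchaeota",
        "crenarchaeota",
        "thermoplasmata",
        "nitrosopumilus",
        "bacterium",
        "bacteria",
        "proteobacteri",
        "firmicutes",
        "actinobacteri",
        "bacteroidetes",
        "cyanobacteri",
        "planctomyce",
        "chloroflexi",
        "verrucomicrobi",
        "candidatus",
        "uncultured",
        "eukaryota",
        "chromosome",
    ),
}


def default_lexicon() -> TaxonLexicon:
    """The built-in lexicon, in the default group priority order."""
    return TaxonLexicon.from_pairs(
        (g, _DEFAULT_KEYWORDS[g]) for g in DEFAULT_PRIORITY
    )


def affiliate(lineage: str, lexicon: TaxonLexicon | None = None) -> TaxonGroup:
    """Affiliate one lineage string; uses the default lexicon when none given."""
    return (lexicon or default_lexicon()).affiliate(lineage)
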