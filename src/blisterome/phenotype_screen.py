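"""Phenotype gene lists: representation, merging, and screen summary statistics.

An RNAi wing screen yields one phenotype call per transgenic line; a gene
may be targeted by several lines with differing outcomes.  Downstream
analyses operate on *genes*, so lists collapse lines onto gene identifiers
while keeping line multiplicity as metadata.  Lists from the screen are
combined with literature-curated hit lists, and the overlap between the two
gives an empirical recovery (sensitivity) estimate for the screen.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._util import round_half_up

PHENOTYPES = ("none", "lethal", "blister", "burned", "other_visible")

SOURCE_SCREEN = "screen"
SOURCE_LITERATURE = "literature"


@dataclass(frozen=True)
class ScreenRecord:
    """One RNAi line and the single phenotype scored for it."""

    line_id: str
    gene_id: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )


@dataclass
class GeneEntry:
    """Per-gene metadata inside a :class:`GeneList`."""

    labels: set[str] = field(default_factory=set)
    n_lines: int = 0
    sources: set[str] = field(default_factory=set)

    def copy(self) -> "GeneEntry":
        return GeneEntry(set(self.labels), self.n_lines, set(self.sources))


@dataclass
class GeneList:
    """A named gene set with phenotype labels, line counts and provenance.

    ``members`` maps a gene identifier to its :class:`GeneEntry`.  Gene
    identifiers are canonical case-sensitive strings; alias resolution is a
    reader concern, not handled here.
    """

    name: str
    members: dict[str, GeneEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def gene_ids(self) -> set[str]:
        return set(self.members)

    @classmethod
    def from_genes(
        cls,
        name: str,
        genes: Iterable[str],
        label: str | None = None,
        source: str = SOURCE_SCREEN,
        n_lines: int = 1,
    ) -> "GeneList":
        members = {}
        for g in genes:
            entry = members.setdefault(g, GeneEntry(sources={source}))
            if label is not None:
                entry.labels.add(label)
            entry.n_lines += n_lines
        return cls(name, members)

    @classmethod
    def from_records(cls, name: str, records: Iterable[ScreenRecord],
                     keep: Iterable[str] = ("blister", "burned")) -> "GeneList":
        """Collapse line-level records onto genes, keeping hit phenotypes only."""
        keep = set(keep)
        members: dict[str, GeneEntry] = {}
        for rec in records:
            if rec.phenotype not in keep:
                continue
            entry = members.setdefault(rec.gene_id, GeneEntry(sources={SOURCE_SCREEN}))
            entry.labels.add(rec.phenotype)
            entry.n_lines += 1
        return cls(name, members)


@dataclass(frozen=True)
class OverlapStats:
    """Overlap between two gene lists restricted to a screened universe."""

    n_a: int
    n_b: int
    n_shared: int
    union_size: int
    recovery_percent: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_shared <= min(self.n_a, self.n_b)):
            raise ValueError("n_shared must lie in [0, min(n_a, n_b)]")
        if self.union_size != self.n_a + self.n_b - self.n_shared:
            raise ValueError("union_size inconsistent with counts")


def merge_lists(a: GeneList, b: GeneList, name: str | None = None) -> GeneList:
    """Union of two gene lists in the same identifier namespace.

    Shared genes carry the union of phenotype labels and sources, with
    line counts summed.  Commutative up to the output ``name``.
    """
    members: dict[str, GeneEntry] = {g: e.copy() for g, e in a.members.items()}
    for g, e in b.members.items():
        if g in members:
            tgt = members[g]
            tgt.labels |= e.labels
            tgt.n_lines += e.n_lines
            tgt.sources |= e.sources
        else:
            members[g] = e.copy()
    return GeneList(name or f"{a.name}+{b.name}", members)


def combine_with_literature(screen: GeneList, literature: GeneList,
                            name: str = "combined") -> GeneList:
    """Union a screen hit list with a literature-curated list.

    Genes present in both end up with ``sources == {'screen', 'literature'}``,
    which readers may render as source "both".
    """
    lit = GeneList(literature.name, {
        g: GeneEntry(set(e.labels), e.n_lines, {SOURCE_LITERATURE})
        for g, e in literature.members.items()
    })
    return merge_lists(screen, lit, name=name)


def literature_recovery(screen: GeneList, literature: GeneList,
                        screened_universe: set[str]) -> OverlapStats:
    """Recovery of known (literature) genes by the screen.

    Only literature genes that were actually screened (present in
    ``screened_universe``) enter the denominator; the recovery percentage is
    integer-rounded half-up.
    """
    if not screen.gene_ids() <= screened_universe:
        raise ValueError("screen members must be a subset of the screened universe")
    lit_screened = literature.gene_ids() & screened_universe
    detected = literature.gene_ids() & screen.gene_ids()
    if not lit_screened:
        raise ZeroDivisionError(
            "no literature gene falls inside the screened universe; "
            "recovery rate undefined"
        )
    n_a = len(lit_screened)
    n_b = len(screen)
    n_shared = len(detected)
    return OverlapStats(
        n_a=n_a,
        n_b=n_b,
        n_shared=n_shared,
        union_size=n_a + n_b - n_shared,
        recovery_percent=int(round_half_up(100.0 * n_shared / n_a)),
    )


def phenotype_fractions(records: Iterable[ScreenRecord]) -> dict[str, float]:
    """Per-phenotype percentage of lines, rounded to one decimal.

    The denominator is the total number of lines (not genes).
    """
    counts = Counter(rec.phenotype for rec in records)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no screen records supplied")
    return {ph: round_half_up(100.0 * n / total, 1) for ph, n in sorted(counts.items())}
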