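"""Core domain types for annotated prokaryotic genomes and their operons.

The unit of analysis is the *gene cassette*: an ordered run of co-transcribed,
same-strand adjacent genes (an operon, in DOOR-style precomputed tables).
Coordinates are 1-based inclusive throughout, following the GenBank/GFF3
convention, and gene order within a cassette is defined by ascending start
coordinate regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DataError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class GeneRecord:
    """One annotated gene.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates;
    ``strand`` is ``+`` or ``-``.  ``gene_name`` may be empty (annotation
    dropout); such records can still be resolved through COG ids or product
    keywords.
    """

    genome_id: str
    locus_tag: str
    gene_name: str
    synonyms: list[str]
    product: str
    cog_ids: list[str]
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"{self.genome_id}/{self.locus_tag}: invalid coordinates "
                f"start={self.start} end={self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise DataError(
                f"{self.genome_id}/{self.locus_tag}: unknown strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Cassette:
    """An ordered run of genes forming one operon/cassette in one genome.

    Genes are sorted by ascending start and share genome and strand.
    """

    genome_id: str
    cassette_id: str
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"cassette {self.cassette_id}: empty gene list")
        if any(g.genome_id != self.genome_id for g in self.genes):
            raise DataError(f"cassette {self.cassette_id}: mixed genome_ids")
        strands = {g.strand for g in self.genes}
        if len(strands) > 1:
            raise DataError(f"cassette {self.cassette_id}: mixed strands")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            self.genes = sorted(self.genes, key=lambda g: g.start)

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    @property
    def locus_tags(self) -> list[str]:
        return [g.locus_tag for g in self.genes]


@dataclass
class Taxon:
    genus: str = "unclassified"
    phylum: str = "unclassified"
    labels: set[str] = field(default_factory=set)


@dataclass
class GenomeAnnotation:
    """All annotated genes of one genome (replicons concatenated under one id)."""

    genome_id: str
    genes: list[GeneRecord]
    taxon: Taxon = field(default_factory=Taxon)
    sequence: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise DataError(
                    f"{self.genome_id}: duplicate locus_tag {g.locus_tag}"
                )
            seen.add(g.locus_tag)
        self.genes.sort(key=lambda g: (g.start, g.end))
        if self.sequence is not None:
            for g in self.genes:
                if g.end > len(self.sequence):
                    raise DataError(
                        f"{self.genome_id}/{g.locus_tag}: end {g.end} beyond "
                        f"sequence length {len(self.sequence)}"
                    )

    def gene_by_tag(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)


@dataclass
class Corpus:
    """A collection of annotated genomes with their cassette (operon) lists.

    Genomes lacking any cassette are retained (``genomes_without_cassettes``)
    so corpus-level denominators stay explicit.
    """

    genomes: dict[str, GenomeAnnotation]
    cassettes: dict[str, list[Cassette]]

    def __post_init__(self) -> None:
        for gid, cas_list in self.cassettes.items():
            if gid not in self.genomes:
                raise DataError(f"cassettes reference unknown genome {gid!r}")
            tags = {g.locus_tag for g in self.genomes[gid].genes}
            for cas in cas_list:
                missing = [t for t in cas.locus_tags if t not in tags]
                if missing:
                    raise DataError(
                        f"genome {gid} cassette {cas.cassette_id}: "
                        f"unresolvable locus_tags {missing}"
                    )

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genomes)

    @property
    def genomes_without_cassettes(self) -> set[str]:
        return {gid for gid in self.genomes if not self.cassettes.get(gid)}

    @property
    def n_cassettes(self) -> int:
        return sum(len(v) for v in self.cassettes.values())

    def iter_cassettes(self):
        for gid in self.genome_ids:
            yield from self.cassettes.get(gid, [])
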