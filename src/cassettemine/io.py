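"""Readers and writers for annotation tables, operon tables and FASTA.

Two plain-text dialects are defined, both UTF-8, tab-separated, with a header
row and ``#``-comment lines ignored:

* annotation TSV — columns ``genome_id, locus_tag, gene_name, synonyms,
  product, cog_ids, start, end, strand`` (synonyms and cog_ids are
  semicolon-joined; coordinates 1-based inclusive);
* operon TSV — columns ``genome_id, cassette_id, locus_tag, rank`` with ranks
  per cassette contiguous from 1.

GFF3 is read through :mod:`gffutils` with coordinates taken as 1-based
inclusive; gene names come from the ``gene`` attribute, synonyms from
``gene_synonym`` and COG ids from ``Dbxref`` entries prefixed ``COG:``.
Writers are byte-stable given identical input.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, TextIO

import gffutils
from Bio import SeqIO

from .model import Cassette, Corpus, DataError, GeneRecord, GenomeAnnotation, Taxon

ANNOTATION_COLUMNS = [
    "genome_id",
    "locus_tag",
    "gene_name",
    "synonyms",
    "product",
    "cog_ids",
    "start",
    "end",
    "strand",
]
OPERON_COLUMNS = ["genome_id", "cassette_id", "locus_tag", "rank"]


def _split_multi(value: str) -> list[str]:
    return [v for v in value.split(";") if v]


def _iter_rows(source: TextIO, expected: list[str], what: str):
    header: list[str] | None = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header != expected:
                raise DataError(
                    f"{what}: expected header {expected}, got {header} (line {lineno})"
                )
            continue
        if len(fields) != len(expected):
            raise DataError(
                f"{what}: line {lineno} has {len(fields)} fields, expected "
                f"{len(expected)}"
            )
        yield lineno, dict(zip(expected, fields))


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise DataError(f"{what}: non-integer value {value!r} at line {lineno}") from None


def read_annotation(source: TextIO, format: str = "tsv") -> GenomeAnnotation:
    """Read one genome's annotation from a TSV or GFF3 stream."""
    if format == "tsv":
        return _read_annotation_tsv(source)
    if format == "gff3":
        return _read_annotation_gff3(source)
    raise DataError(f"unknown annotation format {format!r}")


def _read_annotation_tsv(source: TextIO) -> GenomeAnnotation:
    genes: list[GeneRecord] = []
    genome_id = ""
    for lineno, row in _iter_rows(source, ANNOTATION_COLUMNS, "annotation TSV"):
        start = _parse_int(row["start"], "annotation TSV", lineno)
        end = _parse_int(row["end"], "annotation TSV", lineno)
        if start > end or start < 1:
            raise DataError(
                f"annotation TSV: malformed coordinates start={start} end={end} "
                f"at line {lineno}"
            )
        if row["strand"] not in ("+", "-"):
            raise DataError(
                f"annotation TSV: unknown strand {row['strand']!r} at line {lineno}"
            )
        genome_id = genome_id or row["genome_id"]
        genes.append(
            GeneRecord(
                genome_id=row["genome_id"],
                locus_tag=row["locus_tag"],
                gene_name=row["gene_name"],
                synonyms=_split_multi(row["synonyms"]),
                product=row["product"],
                cog_ids=_split_multi(row["cog_ids"]),
                start=start,
                end=end,
                strand=row["strand"],
            )
        )
    return GenomeAnnotation(genome_id=genome_id or "unknown", genes=genes)


def _read_annotation_gff3(source: TextIO) -> GenomeAnnotation:
    data = source.read()
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneRecord] = []
    genome_id = ""
    for feat in db.features_of_type("gene", order_by="start"):
        genome_id = genome_id or feat.seqid
        attrs = feat.attributes
        locus_tag = attrs.get("locus_tag", [feat.id])[0]
        cogs = [
            x.split("COG:", 1)[1]
            for x in attrs.get("Dbxref", [])
            if x.startswith("COG:")
        ]
        if feat.strand not in ("+", "-"):
            raise DataError(f"GFF3: unknown strand {feat.strand!r} for {locus_tag}")
        genes.append(
            GeneRecord(
                genome_id=feat.seqid,
                locus_tag=locus_tag,
                gene_name=attrs.get("gene", [""])[0],
                synonyms=list(attrs.get("gene_synonym", [])),
                product=attrs.get("product", [""])[0],
                cog_ids=cogs,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return GenomeAnnotation(genome_id=genome_id or "unknown", genes=genes)


def read_annotation_table(source: TextIO) -> dict[str, GenomeAnnotation]:
    """Read a multi-genome annotation TSV, split by ``genome_id``."""
    merged = _read_annotation_tsv(source)
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in merged.genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    return {
        gid: GenomeAnnotation(genome_id=gid, genes=genes)
        for gid, genes in by_genome.items()
    }


def write_annotation_table(
    genomes: dict[str, GenomeAnnotation], dest: TextIO
) -> None:
    dest.write("# coordinates are 1-based inclusive\n")
    dest.write("\t".join(ANNOTATION_COLUMNS) + "\n")
    for gid in sorted(genomes):
        for g in genomes[gid].genes:
            dest.write(
                "\t".join(
                    [
                        g.genome_id,
                        g.locus_tag,
                        g.gene_name,
                        ";".join(g.synonyms),
                        g.product,
                        ";".join(g.cog_ids),
                        str(g.start),
                        str(g.end),
                        g.strand,
                    ]
                )
                + "\n"
            )


def write_annotation(genome: GenomeAnnotation, dest: TextIO) -> None:
    dest.write("# coordinates are 1-based inclusive\n")
    dest.write("\t".join(ANNOTATION_COLUMNS) + "\n")
    for g in genome.genes:
        dest.write(
            "\t".join(
                [
                    g.genome_id,
                    g.locus_tag,
                    g.gene_name,
                    ";".join(g.synonyms),
                    g.product,
                    ";".join(g.cog_ids),
                    str(g.start),
                    str(g.end),
                    g.strand,
                ]
            )
            + "\n"
        )


def write_annotation_gff3(genome: GenomeAnnotation, dest: TextIO) -> None:
    """Write the same content as GFF3 (used by the format-equivalence tests)."""
    dest.write("##gff-version 3\n")
    for g in genome.genes:
        attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
        if g.gene_name:
            attrs.append(f"gene={g.gene_name}")
        for s in g.synonyms:
            attrs.append(f"gene_synonym={s}")
        if g.product:
            attrs.append(f"product={g.product}")
        if g.cog_ids:
            attrs.append("Dbxref=" + ",".join(f"COG:{c}" for c in g.cog_ids))
        dest.write(
            "\t".join(
                [
                    g.genome_id,
                    "cassettemine",
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
            + "\n"
        )


def read_operon_table(
    source: TextIO, annotations: dict[str, GenomeAnnotation] | None = None
) -> dict[str, list[tuple[str, list[str]]]]:
    """Read an operon TSV into ``genome_id -> [(cassette_id, [locus_tag, ...])]``.

    Locus tags are kept symbolic here; resolution against annotations happens
    in :func:`assemble_corpus` (dangling tags are a deferred error).  Ranks
    must be contiguous ``1..k`` per cassette.
    """
    by_cassette: dict[tuple[str, str], list[tuple[int, str]]] = {}
    order: list[tuple[str, str]] = []
    for lineno, row in _iter_rows(source, OPERON_COLUMNS, "operon TSV"):
        rank = _parse_int(row["rank"], "operon TSV", lineno)
        key = (row["genome_id"], row["cassette_id"])
        if key not in by_cassette:
            by_cassette[key] = []
            order.append(key)
        by_cassette[key].append((rank, row["locus_tag"]))
    result: dict[str, list[tuple[str, list[str]]]] = {}
    for gid, cid in order:
        members = sorted(by_cassette[(gid, cid)])
        ranks = [r for r, _ in members]
        if ranks != list(range(1, len(ranks) + 1)):
            raise DataError(
                f"operon TSV: cassette {cid} in {gid} has non-contiguous ranks {ranks}"
            )
        result.setdefault(gid, []).append((cid, [t for _, t in members]))
    return result


def write_operon_table(corpus_cassettes: dict[str, list[Cassette]], dest: TextIO) -> None:
    dest.write("\t".join(OPERON_COLUMNS) + "\n")
    for gid in sorted(corpus_cassettes):
        for cas in corpus_cassettes[gid]:
            for rank, tag in enumerate(cas.locus_tags, start=1):
                dest.write(f"{gid}\t{cas.cassette_id}\t{tag}\t{rank}\n")


def assemble_corpus(
    annotations: dict[str, GenomeAnnotation],
    operon_tables: dict[str, list[tuple[str, list[str]]]],
) -> Corpus:
    """Join annotations with operon membership into a validated :class:`Corpus`.

    Every operon locus tag must resolve to an annotated gene; genomes without
    any cassette are retained (flagged through
    :attr:`Corpus.genomes_without_cassettes`).  No cassette is ever silently
    dropped.
    """
    cassettes: dict[str, list[Cassette]] = {}
    for gid, cas_list in operon_tables.items():
        if gid not in annotations:
            raise DataError(f"operon table references unknown genome {gid!r}")
        genome = annotations[gid]
        by_tag = {g.locus_tag: g for g in genome.genes}
        out: list[Cassette] = []
        for cid, tags in cas_list:
            missing = [t for t in tags if t not in by_tag]
            if missing:
                raise DataError(
                    f"genome {gid} cassette {cid}: unresolvable locus_tags {missing}"
                )
            out.append(
                Cassette(genome_id=gid, cassette_id=cid, genes=[by_tag[t] for t in tags])
            )
        cassettes[gid] = out
    for gid in annotations:
        cassettes.setdefault(gid, [])
    return Corpus(genomes=annotations, cassettes=cassettes)


def read_fasta(source: TextIO) -> dict[str, str]:
    """Read genome sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(source, "fasta")}


def write_fasta(sequences: dict[str, str], dest: TextIO, width: int = 70) -> None:
    for name in sorted(sequences):
        dest.write(f">{name}\n")
        seq = sequences[name]
        for i in range(0, len(seq), width):
            dest.write(seq[i : i + width] + "\n")


TAXONOMY_COLUMNS = ["genome_id", "genus", "phylum", "labels"]


def read_taxonomy(source: TextIO) -> dict[str, Taxon]:
    out: dict[str, Taxon] = {}
    for _, row in _iter_rows(source, TAXONOMY_COLUMNS, "taxonomy TSV"):
        out[row["genome_id"]] = Taxon(
            genus=row["genus"],
            phylum=row["phylum"],
            labels=set(_split_multi(row["labels"])),
        )
    return out


def write_taxonomy(taxa: dict[str, Taxon], dest: TextIO) -> None:
    dest.write("\t".join(TAXONOMY_COLUMNS) + "\n")
    for gid in sorted(taxa):
        t = taxa[gid]
        dest.write(f"{gid}\t{t.genus}\t{t.phylum}\t{';'.join(sorted(t.labels))}\n")


def loads_annotation(text: str, format: str = "tsv") -> GenomeAnnotation:
    return read_annotation(_io.StringIO(text), format=format)
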