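"""Ground-truth corpus simulator.

Emits a corpus of annotated genomes with operon tables in the exact dialects
the readers consume, together with a *manifest* recording every planted
truth: cassette placements (exact / reordered / subset), operon boundaries,
taxonomy labels.  The simulator emulates the statistical structure the
analysis assumes — operon-internal intergenic distances drawn from a tight
distribution inside the [-50, 250] nt band, operon-boundary distances from a
wide distribution truncated above it, synonym usage in gene names,
annotation dropout, decoy genes and (optionally) genome sequence with
planted upstream motifs.  It makes no attempt to mimic real genome
composition, GC content or real taxonomies beyond labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .catalog import CuratedCatalog, load_default_catalog
from .counting import CassetteQuery, matches
from .model import Cassette, Corpus, DataError, GeneRecord, GenomeAnnotation, Taxon

# fixed genus -> (phylum, labels) background used for taxonomy labels
GENUS_INFO: dict[str, tuple[str, frozenset[str]]] = {
    "Escherichia": ("Proteobacteria", frozenset({"pathogenic"})),
    "Salmonella": ("Proteobacteria", frozenset({"pathogenic"})),
    "Neisseria": ("Proteobacteria", frozenset({"pathogenic"})),
    "Treponema": ("Spirochaetes", frozenset({"pathogenic"})),
    "Prevotella": ("Bacteroidetes", frozenset({"pathogenic"})),
    "Helicobacter": ("Proteobacteria", frozenset({"pathogenic"})),
    "Bacillus": ("Firmicutes", frozenset({"soil"})),
    "Pseudomonas": ("Proteobacteria", frozenset({"soil"})),
    "Chlorobium": ("Chlorobi", frozenset({"soil"})),
    "Thermococcus": ("Euryarchaeota", frozenset({"archaea"})),
    "Pyrococcus": ("Euryarchaeota", frozenset({"archaea"})),
}


@dataclass
class PlantedQuery:
    """One query cassette to plant, with per-rule genome counts."""

    query: CassetteQuery
    n_exact: int = 0
    n_reordered: int = 0
    n_subset: int = 0

    @property
    def total(self) -> int:
        return self.n_exact + self.n_reordered + self.n_subset


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    Defaults reflect a modest desk-scale corpus: 200 genomes of 60-100 genes
    organized in 1-5 gene operons, operon-internal gaps ~ N(20, 15) nt inside
    the [-50, 250] band and boundary gaps ~ N(300, 80) nt truncated above it,
    a 200-gene decoy pool, 10% synonym usage and no annotation dropout.
    """

    n_genomes: int = 200
    seed: int = 0
    planted: list[PlantedQuery] = field(default_factory=list)
    decoy_gene_pool: int = 200
    genes_per_genome: tuple[int, int] = (60, 100)
    operon_size: tuple[int, int] = (1, 5)
    d_i_operon: tuple[float, float] = (20.0, 15.0)
    d_i_boundary: tuple[float, float] = (300.0, 80.0)
    d_i_min: int = -50
    d_i_max: int = 250
    synonym_use_rate: float = 0.1
    annotation_dropout: float = 0.0
    taxonomy: dict[str, float] = field(
        default_factory=lambda: {
            "Escherichia": 0.3,
            "Bacillus": 0.3,
            "Neisseria": 0.2,
            "Treponema": 0.2,
        }
    )
    partner_pool: list[str] = field(
        default_factory=lambda: ["rplA", "secE", "rbfA", "truB"]
    )
    motif_spec: tuple[str, float] | None = None
    emit_sequence: bool = False

    def __post_init__(self) -> None:
        for p in self.planted:
            if p.total > self.n_genomes:
                raise DataError(
                    f"cannot plant {p.query} in {p.total} of {self.n_genomes} genomes"
                )
        if abs(sum(self.taxonomy.values()) - 1.0) > 1e-9:
            raise DataError("taxonomy proportions must sum to 1")


@dataclass
class Placement:
    query: str
    genome_id: str
    cassette_id: str
    rule: str


@dataclass
class Manifest:
    """Everything the simulator planted, for use as a downstream oracle."""

    placements: list[Placement]
    taxonomy: dict[str, Taxon]
    operons: dict[str, list[tuple[str, list[str]]]]  # genome -> [(cid, tags)]

    def count(self, query: str) -> dict[str, int]:
        out = {"exact": 0, "reordered": 0, "subset": 0}
        for p in self.placements:
            if p.query == query:
                out[p.rule] += 1
        return out

    def genomes_with(self, query: str) -> set[str]:
        return {p.genome_id for p in self.placements if p.query == query}


def _exact_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so planted fractions are exact."""
    keys = sorted(proportions)
    raw = {k: proportions[k] * n for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    rest = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:rest]:
        counts[k] += 1
    return counts


def _planted_record(
    canonical: str,
    catalog: CuratedCatalog,
    rng: np.random.Generator,
    synonym_use_rate: float,
    annotation_dropout: float,
) -> dict:
    entry = catalog.entries.get(canonical)
    if entry is None:
        raise DataError(f"planted gene {canonical!r} not in catalog")
    name = canonical
    synonyms = sorted(entry.synonyms)
    if synonyms and rng.random() < synonym_use_rate:
        name = synonyms[int(rng.integers(len(synonyms)))]
    if rng.random() < annotation_dropout:
        name = ""
    product = sorted(entry.function_keywords)[0] if entry.function_keywords else ""
    return {
        "gene_name": name,
        "synonyms": [],
        "product": product,
        "cog_ids": sorted(entry.cog_ids),
    }


def _plan_operon_contents(
    gid: str,
    plants: list[tuple[PlantedQuery, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[list[str], str | None, str | None]]:
    """Operon plan for one genome: list of (gene names, query or None, rule)."""
    target = int(rng.integers(config.genes_per_genome[0], config.genes_per_genome[1] + 1))
    operons: list[tuple[list[str], str | None, str | None]] = []
    n_genes = 0
    for planted, rule in plants:
        genes = list(planted.query.genes)
        if rule == "reordered":
            while True:
                perm = list(rng.permutation(genes))
                if perm != genes:
                    genes = perm
                    break
        elif rule == "subset":
            extras = [g for g in config.partner_pool if g not in planted.query.gene_set]
            n_extra = int(rng.integers(1, min(3, len(extras)) + 1))
            picked = list(rng.choice(extras, size=n_extra, replace=False))
            for ex in picked:
                genes.insert(int(rng.integers(len(genes) + 1)), ex)
        operons.append((genes, str(planted.query), rule))
        n_genes += len(genes)
    decoys = rng.permutation(config.decoy_gene_pool)
    di = 0
    while n_genes < target and di < len(decoys):
        size = int(rng.integers(config.operon_size[0], config.operon_size[1] + 1))
        size = min(size, len(decoys) - di)
        if size == 0:
            break
        names = [f"dcy{decoys[di + j]:04d}" for j in range(size)]
        di += size
        operons.append((names, None, None))
        n_genes += size
    # planted operons sit at seeded random positions among the decoys
    order = rng.permutation(len(operons))
    return [operons[i] for i in order]


def simulate_corpus(
    config: SimulationConfig, catalog: CuratedCatalog | None = None
) -> tuple[Corpus, Manifest]:
    """Simulate a corpus; deterministic given the config seed."""
    catalog = catalog or load_default_catalog()
    rng = np.random.default_rng(config.seed)
    genome_ids = [f"G{i:04d}" for i in range(1, config.n_genomes + 1)]

    # taxonomy with exact planted proportions
    taxonomy: dict[str, Taxon] = {}
    if genome_ids:
        counts = _exact_counts(config.taxonomy, config.n_genomes)
        genera: list[str] = []
        for genus in sorted(counts):
            genera += [genus] * counts[genus]
        genera = [genera[i] for i in rng.permutation(len(genera))]
        for gid, genus in zip(genome_ids, genera):
            phylum, labels = GENUS_INFO.get(genus, ("unclassified", frozenset()))
            taxonomy[gid] = Taxon(genus=genus, phylum=phylum, labels=set(labels))

    # assign plant slots (without replacement per query)
    plant_by_genome: dict[str, list[tuple[PlantedQuery, str]]] = {g: [] for g in genome_ids}
    for planted in config.planted:
        slots = rng.choice(genome_ids, size=planted.total, replace=False)
        rules = (
            ["exact"] * planted.n_exact
            + ["reordered"] * planted.n_reordered
            + ["subset"] * planted.n_subset
        )
        for gid, rule in zip(slots, rules):
            plant_by_genome[gid].append((planted, rule))

    genomes: dict[str, GenomeAnnotation] = {}
    cassettes: dict[str, list[Cassette]] = {}
    placements: list[Placement] = []
    operon_truth: dict[str, list[tuple[str, list[str]]]] = {}
    sequences: dict[str, str] = {}

    for gid in genome_ids:
        plan = _plan_operon_contents(gid, plant_by_genome[gid], config, rng)
        genes: list[GeneRecord] = []
        cas_list: list[Cassette] = []
        truth: list[tuple[str, list[str]]] = []
        motif_sites: list[tuple[int, str]] = []  # (0-based pos, motif on + strand)
        pos = 101
        tag_i = 0
        for op_i, (names, query, rule) in enumerate(plan, start=1):
            cid = f"{gid}_op{op_i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            members: list[GeneRecord] = []
            for j, name in enumerate(names):
                if j > 0:
                    gap = int(round(rng.normal(*config.d_i_operon)))
                    gap = min(max(gap, config.d_i_min), config.d_i_max)
                    pos = members[-1].end + 1 + gap
                length = int(np.clip(round(rng.normal(900, 300)), 150, 3000))
                tag_i += 1
                if name.startswith("dcy"):
                    meta = {
                        "gene_name": name,
                        "synonyms": [],
                        "product": f"hypothetical protein {name}",
                        "cog_ids": [],
                    }
                else:
                    meta = _planted_record(
                        name, catalog, rng,
                        config.synonym_use_rate, config.annotation_dropout,
                    )
                members.append(
                    GeneRecord(
                        genome_id=gid,
                        locus_tag=f"{gid}_t{tag_i:05d}",
                        start=pos,
                        end=pos + length - 1,
                        strand=strand,
                        **meta,
                    )
                )
            # optional planted motif upstream of operon-internal downstream genes
            if config.motif_spec is not None and config.emit_sequence:
                motif, rate = config.motif_spec
                for down in members[1:]:
                    if rng.random() < rate:
                        if strand == "+":
                            lo = max(0, down.start - 1 - 100)
                            site = int(rng.integers(lo, max(lo + 1, down.start - 1 - len(motif) + 1)))
                            motif_sites.append((site, motif))
                        else:
                            site = int(rng.integers(down.end, down.end + 100 - len(motif)))
                            motif_sites.append((site, _revcomp(motif)))
            cas = Cassette(genome_id=gid, cassette_id=cid, genes=members)
            cas_list.append(cas)
            truth.append((cid, [m.locus_tag for m in members]))
            if query is not None:
                placements.append(
                    Placement(query=query, genome_id=gid, cassette_id=cid, rule=rule)
                )
            # boundary gap to the next operon, truncated above the cutoff band
            gap = int(round(rng.normal(*config.d_i_boundary)))
            gap = max(gap, config.d_i_max + 1)
            pos = members[-1].end + 1 + gap
        genome = GenomeAnnotation(genome_id=gid, genes=genes + [g for c in cas_list for g in c.genes])
        genome.taxon = taxonomy.get(gid, Taxon())
        if config.emit_sequence:
            total = (genome.genes[-1].end if genome.genes else 0) + 200
            seq = rng.choice(list("ACGT"), size=total)
            for site, motif in motif_sites:
                seq[site : site + len(motif)] = list(motif)
            genome.sequence = "".join(seq)
            sequences[gid] = genome.sequence
        genomes[gid] = genome
        cassettes[gid] = cas_list
        operon_truth[gid] = truth

    corpus = Corpus(genomes=genomes, cassettes=cassettes)
    manifest = Manifest(placements=placements, taxonomy=taxonomy, operons=operon_truth)
    return corpus, manifest


def _revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


def verify_manifest(
    corpus: Corpus, manifest: Manifest, catalog: CuratedCatalog
) -> tuple[bool, list[str]]:
    """Check that every manifest claim is realized in the corpus."""
    problems: list[str] = []
    for gid, truth in manifest.operons.items():
        if gid not in corpus.genomes:
            problems.append(f"missing genome {gid}")
            continue
        observed = [
            (c.cassette_id, c.locus_tags) for c in corpus.cassettes.get(gid, [])
        ]
        if observed != truth:
            problems.append(f"{gid}: operon table differs from manifest")
    by_id = {
        (gid, c.cassette_id): c
        for gid, cl in corpus.cassettes.items()
        for c in cl
    }
    for p in manifest.placements:
        cas = by_id.get((p.genome_id, p.cassette_id))
        if cas is None:
            problems.append(f"{p.genome_id}/{p.cassette_id}: planted cassette missing")
            continue
        rule = matches(CassetteQuery.parse(p.query), cas, catalog)
        if rule != p.rule:
            problems.append(
                f"{p.genome_id}/{p.cassette_id}: planted rule {p.rule}, observed {rule}"
            )
    for gid, taxon in manifest.taxonomy.items():
        if gid in corpus.genomes and corpus.genomes[gid].taxon != taxon:
            problems.append(f"{gid}: taxonomy differs from manifest")
    return (not problems), problems


def write_corpus(
    corpus: Corpus, manifest: Manifest, outdir: str | Path
) -> None:
    """Emit the corpus and manifest as the package's TSV/FASTA dialects.

    Layout: ``annotations.tsv``, ``operons.tsv``, ``taxonomy.tsv``, optional
    ``genomes.fasta`` and the truth tables under ``truth/``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "annotations.tsv", "w", encoding="utf-8") as fh:
        cio.write_annotation_table(corpus.genomes, fh)
    with open(outdir / "operons.tsv", "w", encoding="utf-8") as fh:
        cio.write_operon_table(corpus.cassettes, fh)
    with open(outdir / "taxonomy.tsv", "w", encoding="utf-8") as fh:
        cio.write_taxonomy(manifest.taxonomy, fh)
    seqs = {
        gid: g.sequence for gid, g in corpus.genomes.items() if g.sequence is not None
    }
    if seqs:
        with open(outdir / "genomes.fasta", "w", encoding="utf-8") as fh:
            cio.write_fasta(seqs, fh)
    truth = outdir / "truth"
    truth.mkdir(exist_ok=True)
    with open(truth / "placements.tsv", "w", encoding="utf-8") as fh:
        fh.write("query\tgenome_id\tcassette_id\trule\n")
        for p in manifest.placements:
            fh.write(f"{p.query}\t{p.genome_id}\t{p.cassette_id}\t{p.rule}\n")
    with open(truth / "operons.tsv", "w", encoding="utf-8") as fh:
        fh.write("genome_id\tcassette_id\tlocus_tag\trank\n")
        for gid in sorted(manifest.operons):
            for cid, tags in manifest.operons[gid]:
                for rank, tag in enumerate(tags, start=1):
                    fh.write(f"{gid}\t{cid}\t{tag}\t{rank}\n")


def read_corpus(indir: str | Path) -> tuple[Corpus, dict[str, Taxon]]:
    """Read a corpus directory written by :func:`write_corpus`."""
    indir = Path(indir)
    with open(indir / "annotations.tsv", encoding="utf-8") as fh:
        annotations = cio.read_annotation_table(fh)
    with open(indir / "operons.tsv", encoding="utf-8") as fh:
        operons = cio.read_operon_table(fh)
    taxa: dict[str, Taxon] = {}
    tax_path = indir / "taxonomy.tsv"
    if tax_path.exists():
        with open(tax_path, encoding="utf-8") as fh:
            taxa = cio.read_taxonomy(fh)
    fasta = indir / "genomes.fasta"
    if fasta.exists():
        with open(fasta, encoding="utf-8") as fh:
            for gid, seq in cio.read_fasta(fh).items():
                if gid in annotations:
                    annotations[gid].sequence = seq
    corpus = cio.assemble_corpus(annotations, operons)
    for gid, taxon in taxa.items():
        if gid in corpus.genomes:
            corpus.genomes[gid].taxon = taxon
    return corpus, taxa
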