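"""End-to-end pipeline: simulate/ingest -> classify -> rank -> link -> count
-> enrich -> summarize.

Every stage writes a plain TSV artifact stamped with the hash of the
configuration that produced it; identical config + seed gives byte-identical
outputs.  The configuration is a flat YAML mapping (every key overridable
from the command line).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as cio
from .catalog import (
    CuratedCatalog,
    classify_corpus,
    load_catalog,
    load_default_catalog,
)
from .counting import (
    CassetteQuery,
    cooccurring_partners,
    count_genomes,
    independence_fraction,
)
from .enrichment import read_term_map, run_ora
from .linkage import CHANNELS, bipartition, build_linkage_graph, extract_candidates
from .model import Corpus, DataError
from .ranking import (
    RankingConfig,
    build_frequency_table,
    consensus_genes,
    summarize_taxa,
    top_ranked,
)
from .simulate import PlantedQuery, SimulationConfig, simulate_corpus, write_corpus

logger = logging.getLogger("cassettemine.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "artifacts"
    corpus_dir: str | None = None
    catalog_path: str | None = None
    term_map_path: str | None = None
    seed: int = 0
    top_n: int = 20
    min_genomes: int = 300
    min_rankings: int = 2
    linkage_threshold: float = 0.7
    min_partner_fraction: float = 0.5
    alpha: float = 0.05
    queries: list[str] = field(default_factory=list)
    # simulation block (used when corpus_dir is absent)
    simulate: bool = False
    n_genomes: int = 200
    planted: list[str] = field(default_factory=list)  # "rplK-nusG:60:30:20"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_params(self) -> dict:
        """Parameters that determine output content (the output location
        itself is excluded so identical analyses hash identically)."""
        params = asdict(self)
        params.pop("out_dir")
        return params

    def config_hash(self) -> str:
        blob = json.dumps(self.content_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _parse_planted(spec: str) -> PlantedQuery:
    parts = spec.split(":")
    if len(parts) != 4:
        raise DataError(f"planted spec {spec!r}; expected QUERY:exact:reordered:subset")
    return PlantedQuery(
        query=CassetteQuery.parse(parts[0]),
        n_exact=int(parts[1]),
        n_reordered=int(parts[2]),
        n_subset=int(parts[3]),
    )


class _TableWriter:
    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.config_hash = config_hash
        self.row_counts: dict[str, int] = {}

    def write(self, name: str, header: list[str], rows: list[list]) -> None:
        path = self.out_dir / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash={self.config_hash}\n")
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(c) for c in row) + "\n")
        self.row_counts[name] = len(rows)


def load_pipeline_catalog(config: PipelineConfig) -> CuratedCatalog:
    if config.catalog_path:
        with open(config.catalog_path, encoding="utf-8") as fh:
            return load_catalog(fh)
    return load_default_catalog()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory."""
    logging.basicConfig(
        level=config.log_level,
        format="%(name)s: %(message)s",
        force=False,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = load_pipeline_catalog(config)
    writer = _TableWriter(out_dir, config.config_hash())

    # --- simulate or ingest -------------------------------------------------
    if config.corpus_dir is not None and not config.simulate:
        logger.info("[ingest] reading corpus from %s", config.corpus_dir)
        from .simulate import read_corpus

        corpus, taxa = read_corpus(config.corpus_dir)
    else:
        sim = SimulationConfig(
            n_genomes=config.n_genomes,
            seed=config.seed,
            planted=[_parse_planted(s) for s in config.planted],
        )
        logger.info("[simulate] %d genomes, seed %d", sim.n_genomes, sim.seed)
        corpus, manifest = simulate_corpus(sim, catalog)
        write_corpus(corpus, manifest, out_dir / "corpus")
        taxa = manifest.taxonomy

    # --- classify -----------------------------------------------------------
    logger.info("[classify] %d cassettes", corpus.n_cassettes)
    cls = classify_corpus(corpus, catalog)
    writer.write(
        "categories.tsv",
        ["genome_id", "cassette_id", "category"],
        [[g, c, cat] for (g, c), cat in sorted(cls.categories.items())],
    )
    writer.write(
        "category_tallies.tsv",
        ["genome_id", "transcription_only", "translation_only", "both", "none"],
        [
            [
                gid,
                cls.tallies[gid]["transcription_only"],
                cls.tallies[gid]["translation_only"],
                cls.tallies[gid]["both"],
                cls.tallies[gid]["none"],
            ]
            for gid in sorted(cls.tallies)
        ],
    )

    # --- rank ---------------------------------------------------------------
    rank_cfg = RankingConfig(top_n=config.top_n, min_genomes=config.min_genomes)
    tops: dict[str, list[tuple[str, int]]] = {}
    for axis in ("gene", "function", "cog"):
        table = build_frequency_table(corpus, axis, catalog, rank_cfg, cls)
        tops[axis] = top_ranked(table, rank_cfg)
        writer.write(
            f"ranked_{axis}.tsv",
            ["key", "count", "denominator", "axis"],
            [[k, c, table.denominator, axis] for k, c in tops[axis]],
        )
    consensus = consensus_genes(
        [k for k, _ in tops["gene"]],
        [k for k, _ in tops["function"]],
        [k for k, _ in tops["cog"]],
        catalog,
        min_rankings=config.min_rankings,
    )
    writer.write(
        "consensus.tsv",
        ["canonical_gene", "category"],
        [[g, catalog.category_of(g)] for g in sorted(consensus)],
    )
    logger.info("[rank] consensus of %d genes", len(consensus))

    # --- link ---------------------------------------------------------------
    candidates = []
    partition_rows: list[list] = []
    edge_rows: list[list] = []
    if len(consensus) >= 2:
        graph = build_linkage_graph(
            consensus, corpus, catalog, threshold=config.linkage_threshold
        )
        for a, b, data in sorted(graph.edges(data=True)):
            edge_rows.append(
                [a, b]
                + [f"{data[c]:.6f}" for c in CHANNELS]
                + [f"{data['combined']:.6f}", ";".join(data["confident_channels"])]
            )
        candidates = extract_candidates(
            graph, corpus, catalog, denominator=len(cls.both_genomes)
        )
        left, right = bipartition(graph, seed=config.seed)
        partition_rows = [["cluster1", ";".join(left)], ["cluster2", ";".join(right)]]
    writer.write(
        "linkage_edges.tsv",
        ["geneA", "geneB", *CHANNELS, "combined", "confident_channels"],
        edge_rows,
    )
    writer.write(
        "candidates.tsv",
        ["method", "motif", "genome_count", "frequency", "role"],
        [
            [
                c.channel,
                "-".join(sorted(c.genes)),
                c.genome_count,
                f"{c.frequency:.6f}",
                _role(c.genes, catalog),
            ]
            for c in candidates
        ],
    )
    writer.write("bipartition.tsv", ["cluster", "genes"], partition_rows)
    logger.info("[link] %d candidate cassettes", len(candidates))

    # --- count --------------------------------------------------------------
    queries = [CassetteQuery.parse(q) for q in config.queries]
    if not queries:
        seen = set()
        for c in candidates:
            key = tuple(sorted(c.genes))
            if key not in seen:
                seen.add(key)
                queries.append(CassetteQuery(key))
    count_rows = []
    taxa_rows = []
    for q in queries:
        report = count_genomes(q, corpus, catalog)
        tallies = report.rule_tallies
        indep = independence_fraction(q, corpus, catalog, report=report)
        partners = cooccurring_partners(
            q, corpus, catalog, min_fraction=config.min_partner_fraction, report=report
        )
        count_rows.append(
            [
                str(q),
                report.genome_count,
                tallies["exact"],
                tallies["reordered"],
                tallies["subset"],
                "" if indep is None else f"{indep:.6f}",
                ";".join(f"{g}={f:.4f}" for g, f in partners),
            ]
        )
        for group, (count, frac) in summarize_taxa(
            sorted(report.matched), taxa, group_by="genus"
        ).items():
            taxa_rows.append([str(q), group, f"{count:g}", f"{frac:.6f}"])
    writer.write(
        "cassette_counts.tsv",
        ["query", "genome_count", "exact", "reordered", "subset",
         "independence_fraction", "partners"],
        count_rows,
    )
    writer.write(
        "taxa_summary.tsv", ["query", "genus", "count", "fraction"], taxa_rows
    )
    logger.info("[count] %d queries counted", len(queries))

    # --- enrich -------------------------------------------------------------
    enrich_rows = []
    if config.term_map_path:
        with open(config.term_map_path, encoding="utf-8") as fh:
            term_map = read_term_map(fh)
        universe = _corpus_universe(corpus, catalog)
        query_genes = consensus & universe
        if query_genes:
            for r in run_ora(query_genes, term_map, universe, alpha=config.alpha):
                enrich_rows.append(
                    [r.term_id, r.term_name, r.k, r.K, r.n, r.N,
                     f"{r.gene_ratio:.6f}", f"{r.p:.6g}", f"{r.p_adj:.6g}",
                     int(r.significant)]
                )
    writer.write(
        "enrichment.tsv",
        ["term_id", "term_name", "k", "K", "n", "N", "gene_ratio", "p", "p_adj",
         "significant"],
        enrich_rows,
    )

    # --- run manifest -------------------------------------------------------
    manifest_obj = {
        "config": config.content_params(),
        "config_hash": config.config_hash(),
        "row_counts": dict(sorted(writer.row_counts.items())),
        "n_genomes": len(corpus.genomes),
        "n_cassettes": corpus.n_cassettes,
        "n_both_genomes": len(cls.both_genomes),
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest_obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def _role(genes: frozenset[str], catalog: CuratedCatalog) -> str:
    cats = {catalog.category_of(g) for g in genes if g in catalog}
    if cats == {"transcription", "translation"}:
        return "Transcription/Translation"
    if cats == {"transcription"}:
        return "Transcription"
    if cats == {"translation"}:
        return "Translation"
    return "Unknown"


def _corpus_universe(corpus: Corpus, catalog: CuratedCatalog) -> set[str]:
    """Background set for enrichment: catalog genes observed in the corpus."""
    from .catalog import resolve_gene

    universe: set[str] = set()
    for gid in corpus.genome_ids:
        for g in corpus.genomes[gid].genes:
            res = resolve_gene(g, catalog)
            if res is not None:
                universe.add(res[0])
    return universe
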