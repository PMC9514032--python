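"""Shared fixtures: the default catalog, handmade corpora and a seeded
simulated corpus with its ground-truth manifest."""

from __future__ import annotations

import pytest

from cassettemine.catalog import load_default_catalog
from cassettemine.counting import CassetteQuery
from cassettemine.model import Cassette, Corpus, GeneRecord, GenomeAnnotation
from cassettemine.simulate import PlantedQuery, SimulationConfig, simulate_corpus


def build_corpus(
    spec: dict[str, list[list[str]]],
    intra_gap: int = 50,
    gaps: dict[str, int] | None = None,
    strand: str = "+",
    gene_length: int = 300,
) -> Corpus:
    """Handmade corpus: ``genome -> list of cassettes (gene-name lists)``.

    Coordinates are assigned left to right with ``intra_gap`` nt between
    cassette members (overridable per genome via ``gaps``) and 400 nt between
    cassettes.  Gene names double as the annotation's gene_name field, so
    catalog genes resolve by name and anything else is a decoy.
    """
    genomes: dict[str, GenomeAnnotation] = {}
    cassettes: dict[str, list[Cassette]] = {}
    for gid, cas_specs in spec.items():
        gap = gaps.get(gid, intra_gap) if gaps else intra_gap
        genes: list[GeneRecord] = []
        cas_list: list[Cassette] = []
        pos = 101
        tag = 0
        for ci, names in enumerate(cas_specs, start=1):
            members = []
            for j, name in enumerate(names):
                if j > 0:
                    pos = members[-1].end + 1 + gap
                tag += 1
                members.append(
                    GeneRecord(
                        genome_id=gid,
                        locus_tag=f"{gid}_t{tag:04d}",
                        gene_name=name,
                        synonyms=[],
                        product="",
                        cog_ids=[],
                        start=pos,
                        end=pos + gene_length - 1,
                        strand=strand,
                    )
                )
            genes.extend(members)
            cas_list.append(
                Cassette(genome_id=gid, cassette_id=f"{gid}_op{ci:03d}", genes=members)
            )
            pos = members[-1].end + 1 + 400
        genomes[gid] = GenomeAnnotation(genome_id=gid, genes=genes)
        cassettes[gid] = cas_list
    return Corpus(genomes=genomes, cassettes=cassettes)


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def planted_corpus(catalog):
    """50-genome corpus planting rplK-nusG (12 exact / 6 reordered / 4 subset)
    and the alpha-operon (10 exact), with its manifest."""
    config = SimulationConfig(
        n_genomes=50,
        seed=11,
        planted=[
            PlantedQuery(CassetteQuery(("rplK", "nusG")), 12, 6, 4),
            PlantedQuery(
                CassetteQuery(("rpoA", "rplQ", "rpsD", "rpsK", "rpsM")), 10, 0, 0
            ),
        ],
        genes_per_genome=(30, 50),
    )
    return simulate_corpus(config, catalog)
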