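"""Synthetic rice-panel generator with known ground truth.

Emulates the structure of a multi-population inbred rice panel at desk
scale: per gene, haplotypes arise on a random mutation tree over CDS SNPs
(root = all-reference; every new haplotype adds one previously unmutated
site, so tree-path lengths equal Hamming distances); each population gets
its own Dirichlet-drawn haplotype frequency spectrum; modern varieties
(MVs) are a drifted re-weighting of the landrace (LAN) spectrum that
concentrates frequency on the dominant haplotype, mimicking the diversity
loss of modern breeding; traits are additive per-haplotype effects plus
Gaussian noise.

Default panel composition mirrors the landrace/modern-variety strata of
the 3K Rice Genomes panel: 732 LAN-Xian, 358 MV-Xian, 328 LAN-Geng,
139 MV-Geng.

The generator writes ordinary VCF/GFF3/TSV inputs plus a JSON manifest of
the full ground truth, so every pipeline stage can be checked against what
was planted.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    HET,
    MISSING,
    TRAITS,
    AccessionPanel,
    GeneModel,
    VariantSite,
    write_gff3,
    write_panel,
    write_traits,
    write_vcf,
)
import pandas as pd


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    seed: int = 1
    n_genes: int = 11
    sites_per_gene: int = 24
    n_haps_per_gene: int = 16
    #: (population, variety_class, size) strata.
    populations: tuple[tuple[str, str, int], ...] = (
        ("Xian", "LAN", 732),
        ("Xian", "MV", 358),
        ("Geng", "LAN", 328),
        ("Geng", "MV", 139),
    )
    #: Dirichlet concentration for per-population haplotype frequencies;
    #: 0.5 gives realistically skewed spectra with a dominant Hap1.
    dirichlet_alpha: float = 0.5
    #: Fraction of MV frequency mass moved onto the LAN-dominant haplotype.
    drift_strength: float = 0.5
    #: Traits simulated (default: the 15-trait rice vocabulary).
    traits: tuple[str, ...] = tuple(TRAITS)
    #: Optional planted effects: trait -> (gene_index, per-hap effect list).
    #: When None, each trait is tied to gene (trait_index mod n_genes) with
    #: per-haplotype effects drawn N(0, effect_scale^2).
    trait_effects: dict | None = None
    effect_scale: float = 1.0
    trait_sd: float = 1.0
    het_rate: float = 0.001
    missing_rate: float = 0.002
    n_decoy_snps: int = 2   # intronic SNPs per gene that calling must ignore
    chromosome: str = "chr1"

    def __post_init__(self) -> None:
        if any(size < 0 for _, _, size in self.populations):
            raise ValueError("stratum sizes must be >= 0")
        for rate in (self.het_rate, self.missing_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be > 0")
        if self.n_haps_per_gene > self.sites_per_gene + 1:
            raise ValueError(
                f"infeasible config: {self.n_haps_per_gene} haplotypes need at "
                f"least {self.n_haps_per_gene - 1} sites, have {self.sites_per_gene}"
            )


@dataclass
class GeneTruth:
    """Planted ground truth for one gene."""

    gene_id: str
    model: GeneModel
    site_positions: tuple[int, ...]
    hap_vectors: list[tuple[int, ...]]            # index 0 = all-reference root
    tree_edges: list[tuple[int, int, int]]        # (parent, child, mutated site idx)
    stratum_freqs: dict[tuple[str, str], np.ndarray]
    assignment: dict[str, int]                    # accession -> hap index


@dataclass
class SimResult:
    config: SimConfig
    panel: AccessionPanel
    genes: list[GeneTruth] = field(default_factory=list)
    paths: dict[str, str] = field(default_factory=dict)


def _gene_rng(seed: int, gene_index: int, stage: int = 0) -> np.random.Generator:
    # one stream per (stage, gene): per-gene output is stable when n_genes
    # changes, and tree construction and panel sampling never share a stream
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stage, gene_index))
    )


def _trait_rng(seed: int, trait_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, trait_index))
    )


def _gene_layout(config: SimConfig, gene_index: int
                 ) -> tuple[GeneModel, tuple[int, ...], tuple[int, ...]]:
    """Gene model with two CDS exons and an intron, plus SNP positions.

    Returns (model, cds_site_positions, decoy_intron_positions).
    """
    base = 1 + gene_index * 100_000
    exon1 = (base, base + 599)
    intron = (base + 600, base + 899)
    exon2 = (base + 900, base + 1299)
    gene_id = f"Gene{gene_index + 1:02d}"
    model = GeneModel(
        gene_id=gene_id,
        chromosome=config.chromosome,
        strand="+" if gene_index % 2 == 0 else "-",
        cds_intervals=(exon1, exon2),
    )
    cds_positions = list(range(exon1[0], exon1[1] + 1)) + list(
        range(exon2[0], exon2[1] + 1)
    )
    idx = np.linspace(0, len(cds_positions) - 1, config.sites_per_gene).astype(int)
    sites = tuple(cds_positions[i] for i in idx)
    decoys = tuple(
        intron[0] + 50 + 37 * k for k in range(config.n_decoy_snps)
    )
    return model, sites, decoys


def simulate_haplotypes(config: SimConfig) -> list[GeneTruth]:
    """Per-gene haplotype vectors on a random mutation tree.

    The root haplotype is all-reference; each subsequent haplotype copies a
    random existing parent and mutates one site never mutated before, so
    vectors are unique and the pairwise Hamming distance equals the path
    length on the tree.
    """
    genes = []
    for g in range(config.n_genes):
        rng = _gene_rng(config.seed, g)
        model, site_positions, _ = _gene_layout(config, g)
        n_sites, n_haps = config.sites_per_gene, config.n_haps_per_gene
        mutation_sites = rng.permutation(n_sites)[: n_haps - 1]
        vectors = [tuple([0] * n_sites)]
        edges = []
        for k in range(1, n_haps):
            parent = int(rng.integers(0, k))
            site = int(mutation_sites[k - 1])
            vec = list(vectors[parent])
            vec[site] = 1
            vectors.append(tuple(vec))
            edges.append((parent, k, site))
        genes.append(
            GeneTruth(
                gene_id=model.gene_id,
                model=model,
                site_positions=site_positions,
                hap_vectors=vectors,
                tree_edges=edges,
                stratum_freqs={},
                assignment={},
            )
        )
    return genes


def _stratum_frequencies(config: SimConfig, rng: np.random.Generator
                         ) -> dict[tuple[str, str], np.ndarray]:
    """Per-stratum haplotype frequencies.

    One Dirichlet draw per population defines the LAN spectrum; the MV
    spectrum re-weights it toward the LAN-dominant haplotype by
    ``drift_strength``; any other class reuses the LAN spectrum.
    """
    n_haps = config.n_haps_per_gene
    pops = list(dict.fromkeys(pop for pop, _, _ in config.populations))
    base = {
        pop: rng.dirichlet(np.full(n_haps, config.dirichlet_alpha)) for pop in pops
    }
    freqs = {}
    for pop, cls, _size in config.populations:
        lan = base[pop]
        if cls == "MV" and config.drift_strength > 0:
            target = np.zeros(n_haps)
            target[int(np.argmax(lan))] = 1.0
            freqs[(pop, cls)] = (1 - config.drift_strength) * lan \
                + config.drift_strength * target
        else:
            freqs[(pop, cls)] = lan.copy()
    return freqs


def build_panel(config: SimConfig) -> AccessionPanel:
    accession_ids, population, variety_class = [], {}, {}
    i = 0
    for pop, cls, size in config.populations:
        for _ in range(size):
            acc = f"ACC{i:04d}"
            accession_ids.append(acc)
            population[acc] = pop
            variety_class[acc] = cls
            i += 1
    return AccessionPanel(accession_ids=accession_ids, population=population,
                          variety_class=variety_class)


def simulate_panel(config: SimConfig, out_dir: str) -> SimResult:
    """Generate the full dataset and write VCF/GFF3/panel/trait files.

    Returns the ground truth (per-gene haplotype trees, stratum spectra and
    accession assignments) alongside the written paths; the same truth is
    stored as ``manifest.json`` next to the outputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    panel = build_panel(config)
    genes = simulate_haplotypes(config)
    n_acc = len(panel)
    strata = [(pop, cls) for pop, cls, size in config.populations
              for _ in range(size)]

    all_sites: list[VariantSite] = []
    for g, truth in enumerate(genes):
        rng = _gene_rng(config.seed, g, stage=2)
        truth.stratum_freqs = _stratum_frequencies(config, rng)
        hap_idx = np.empty(n_acc, dtype=np.int64)
        for i, acc in enumerate(panel.accession_ids):
            freqs = truth.stratum_freqs[strata[i]]
            hap_idx[i] = rng.choice(config.n_haps_per_gene, p=freqs)
            truth.assignment[acc] = int(hap_idx[i])
        geno = np.array(truth.hap_vectors, dtype=np.int8)[hap_idx]  # acc x site
        noise = rng.random(geno.shape)
        geno = np.where(noise < config.missing_rate, MISSING, geno)
        geno = np.where(
            (noise >= config.missing_rate)
            & (noise < config.missing_rate + config.het_rate),
            HET, geno,
        )
        for s, pos in enumerate(truth.site_positions):
            all_sites.append(VariantSite(
                chromosome=config.chromosome, position=pos, ref="A",
                alts=("G",), genotypes=geno[:, s].astype(np.int8),
            ))
        _, _, decoys = _gene_layout(config, g)
        for pos in decoys:
            codes = (rng.random(n_acc) < 0.3).astype(np.int8)
            all_sites.append(VariantSite(
                chromosome=config.chromosome, position=pos, ref="C",
                alts=("T",), genotypes=codes,
            ))
    all_sites.sort(key=lambda s: s.position)

    trait_frame = {}
    effects_record = {}
    for t, trait in enumerate(config.traits):
        rng = _trait_rng(config.seed, t)
        if config.trait_effects is not None and trait in config.trait_effects:
            gene_index, effects = config.trait_effects[trait]
            effects = np.asarray(effects, dtype=float)
        else:
            gene_index = t % config.n_genes
            effects = config.effect_scale * rng.standard_normal(
                config.n_haps_per_gene
            )
        truth = genes[gene_index]
        hap_of = np.array([truth.assignment[a] for a in panel.accession_ids])
        values = effects[hap_of] + config.trait_sd * rng.standard_normal(n_acc)
        trait_frame[trait] = values
        effects_record[trait] = {"gene": truth.gene_id,
                                 "effects": [float(e) for e in effects]}
    panel.traits = pd.DataFrame(trait_frame, index=panel.accession_ids)
    panel.traits.index.name = "accession"

    paths = {
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "panel": os.path.join(out_dir, "panel.tsv"),
        "traits": os.path.join(out_dir, "traits.tsv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_vcf(paths["vcf"], all_sites, panel.accession_ids)
    write_gff3(paths["gff3"], [t.model for t in genes])
    write_panel(paths["panel"], panel)
    write_traits(paths["traits"], panel)

    manifest = {
        "config": _config_dict(config),
        "trait_effects": effects_record,
        "genes": [
            {
                "gene_id": t.gene_id,
                "site_positions": list(t.site_positions),
                "hap_vectors": [list(v) for v in t.hap_vectors],
                "tree_edges": [list(e) for e in t.tree_edges],
                "stratum_freqs": {
                    f"{pop}/{cls}": [float(x) for x in f]
                    for (pop, cls), f in t.stratum_freqs.items()
                },
                "assignment": t.assignment,
            }
            for t in genes
        ],
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
    return SimResult(config=config, panel=panel, genes=genes, paths=paths)


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["populations"] = [list(s) for s in config.populations]
    d["traits"] = list(config.traits)
    if d.get("trait_effects"):
        d["trait_effects"] = {
            k: [int(g), [float(x) for x in e]]
            for k, (g, e) in config.trait_effects.items()
        }
    return d
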