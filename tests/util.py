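"""Shared builders for hand-constructed fixtures."""

from __future__ import annotations

import numpy as np

from gchap import AccessionPanel, GeneModel, VariantSite
from gchap.gchap_core import GcHap, GcHapTable

_ALLELES = ("A", "G", "T", "C")


def sites_from_matrix(mat, positions=None, chrom="chr1") -> list[VariantSite]:
    """Build VariantSite objects from an accession x site genotype matrix."""
    mat = np.asarray(mat, dtype=np.int8)
    n_acc, n_site = mat.shape
    if positions is None:
        positions = [100 + 10 * j for j in range(n_site)]
    sites = []
    for j in range(n_site):
        n_alt = max(1, int(mat[:, j].max()))
        sites.append(VariantSite(
            chromosome=chrom, position=int(positions[j]), ref=_ALLELES[0],
            alts=tuple(_ALLELES[1:1 + n_alt]), genotypes=mat[:, j].copy(),
        ))
    return sites


def simple_gene(intervals=((1, 10_000),), chrom="chr1", gene_id="GeneA",
                strand="+") -> GeneModel:
    return GeneModel(gene_id=gene_id, chromosome=chrom, strand=strand,
                     cds_intervals=tuple(intervals))


def simple_panel(n, population="Xian", variety_class="LAN",
                 prefix="A") -> AccessionPanel:
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    return AccessionPanel(
        accession_ids=ids,
        population={a: population for a in ids},
        variety_class={a: variety_class for a in ids},
    )


def two_class_panel(n_lan, n_mv, group="Xian") -> AccessionPanel:
    ids = [f"L{i:04d}" for i in range(n_lan)] + [f"M{i:04d}" for i in range(n_mv)]
    return AccessionPanel(
        accession_ids=ids,
        population={a: group for a in ids},
        variety_class={a: ("LAN" if a.startswith("L") else "MV") for a in ids},
    )


def table_from_hap_indices(lan_haps, mv_haps, group="Xian",
                           gene_id="GeneA") -> tuple[GcHapTable, AccessionPanel]:
    """GcHapTable + panel built directly from per-class haplotype indices.

    Haplotype k gets the one-site-per-index allele vector (0,..,1,..,0) so
    vectors are distinct; ranking follows pooled counts.
    """
    lan_haps = np.asarray(lan_haps, dtype=int)
    mv_haps = np.asarray(mv_haps, dtype=int)
    panel = two_class_panel(lan_haps.size, mv_haps.size, group)
    pooled = np.concatenate([lan_haps, mv_haps])
    n_types = int(pooled.max()) + 1 if pooled.size else 0
    counts = np.bincount(pooled, minlength=n_types)
    order = sorted(range(n_types), key=lambda k: (-counts[k], k))
    rank_of = {k: r for r, k in enumerate(order)}
    haps = []
    for r, k in enumerate(order):
        if counts[k] == 0:
            continue
        vec = tuple(1 if j == k else 0 for j in range(n_types))
        haps.append(GcHap(hap_id=f"Hap{r + 1}", allele_vector=vec,
                          global_count=int(counts[k])))
    assignment = {}
    per_pop: dict[str, dict[str, int]] = {}
    per_cls: dict[str, dict[tuple[str, str], int]] = {}
    for acc, k in zip(panel.accession_ids, pooled):
        hap_id = f"Hap{rank_of[int(k)] + 1}"
        assignment[acc] = hap_id
        pop, cls = panel.population[acc], panel.variety_class[acc]
        per_pop.setdefault(hap_id, {}).setdefault(pop, 0)
        per_pop[hap_id][pop] += 1
        per_cls.setdefault(hap_id, {}).setdefault((pop, cls), 0)
        per_cls[hap_id][(pop, cls)] += 1
    for h in haps:
        h.per_population_count = per_pop.get(h.hap_id, {})
        h.per_class_count = per_cls.get(h.hap_id, {})
    table = GcHapTable(gene_id=gene_id, site_positions=tuple(range(n_types)),
                       haplotypes=haps, assignment=assignment, excluded_count=0)
    return table, panel
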