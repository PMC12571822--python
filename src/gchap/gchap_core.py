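"""Gene-CDS-haplotype (gcHap) construction.

A gcHap is a distinct combination of SNP alleles within a gene's coding
sequence.  Accessions carrying exactly the same allele vector over the
gene's CDS SNPs share a gcHap.  Haplotypes are ranked by descending count
over the whole panel and named Hap1, Hap2, ... so that the same name means
the same CDS sequence in every population table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HET, MISSING, AccessionPanel, GeneModel, VariantSite


class NotAnalyzableError(ValueError):
    """A gene does not support the requested analysis (e.g. <2 major gcHaps)."""


@dataclass
class GcHap:
    hap_id: str
    allele_vector: tuple[int, ...]
    global_count: int
    per_population_count: dict[str, int] = field(default_factory=dict)
    per_class_count: dict[tuple[str, str], int] = field(default_factory=dict)


@dataclass
class GcHapTable:
    """Per-gene haplotype table: frequency-ranked gcHaps and the accession
    assignment.  ``excluded_count`` counts accessions dropped by the
    het/missing policy; counts + excluded always sum to the panel size."""

    gene_id: str
    site_positions: tuple[int, ...]
    haplotypes: list[GcHap]
    assignment: dict[str, str]   # accession -> hap_id (excluded accessions absent)
    excluded_count: int

    @property
    def n_assigned(self) -> int:
        return sum(h.global_count for h in self.haplotypes)

    def hap(self, hap_id: str) -> GcHap:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def frequencies(self) -> dict[str, float]:
        """Global hap frequencies among non-excluded accessions."""
        n = self.n_assigned
        if n == 0:
            return {}
        return {h.hap_id: h.global_count / n for h in self.haplotypes}


def select_cds_sites(gene: GeneModel, variants: list[VariantSite]) -> list[VariantSite]:
    """SNPs whose position lies inside any CDS interval of the gene.

    Sites are returned in genomic order regardless of strand; interval
    bounds are inclusive on both ends.
    """
    return [
        v
        for v in variants
        if v.chromosome == gene.chromosome and gene.contains(v.position)
    ]


def call_gchaps(
    gene: GeneModel,
    variants: list[VariantSite],
    panel: AccessionPanel,
    policy: str = "exclude",
) -> GcHapTable:
    """Group accessions into gcHaps by exact allele-vector identity.

    policy
        ``"exclude"`` (default): an accession with any missing or
        heterozygous genotype at a selected site is excluded from the gene.
        ``"ref-fill"``: missing and heterozygous calls are replaced by the
        reference allele.

    Groups are sorted by descending global count, ties broken by the first
    occurrence in accession order, then named Hap1, Hap2, ...  A gene with
    zero CDS SNPs yields a single haplotype holding every accession.
    """
    if policy not in ("exclude", "ref-fill"):
        raise ValueError(f"unknown policy {policy!r}")
    sites = select_cds_sites(gene, variants)
    mismatched = [v for v in variants if v.chromosome != gene.chromosome]
    if mismatched and len(mismatched) == len(variants) and variants:
        raise ValueError(
            f"gene {gene.gene_id} is on {gene.chromosome} but no variant matches "
            "that chromosome"
        )
    n_acc = len(panel.accession_ids)
    if sites:
        mat = np.stack([s.genotypes for s in sites], axis=1).astype(np.int16)
    else:
        mat = np.zeros((n_acc, 0), dtype=np.int16)
    bad = (mat == MISSING) | (mat == HET)
    if policy == "ref-fill":
        mat = np.where(bad, 0, mat)
        keep = np.ones(n_acc, dtype=bool)
    else:
        keep = ~bad.any(axis=1)

    groups: dict[tuple[int, ...], list[str]] = {}
    order: list[tuple[int, ...]] = []
    for i, acc in enumerate(panel.accession_ids):
        if not keep[i]:
            continue
        vec = tuple(int(x) for x in mat[i])
        if vec not in groups:
            groups[vec] = []
            order.append(vec)
        groups[vec].append(acc)

    first_seen = {vec: k for k, vec in enumerate(order)}
    ranked = sorted(order, key=lambda v: (-len(groups[v]), first_seen[v]))

    haplotypes: list[GcHap] = []
    assignment: dict[str, str] = {}
    for rank, vec in enumerate(ranked, start=1):
        members = groups[vec]
        hap_id = f"Hap{rank}"
        per_pop: dict[str, int] = {}
        per_class: dict[tuple[str, str], int] = {}
        for acc in members:
            pop = panel.population[acc]
            cls = panel.variety_class[acc]
            per_pop[pop] = per_pop.get(pop, 0) + 1
            per_class[(pop, cls)] = per_class.get((pop, cls), 0) + 1
            assignment[acc] = hap_id
        haplotypes.append(
            GcHap(
                hap_id=hap_id,
                allele_vector=vec,
                global_count=len(members),
                per_population_count=per_pop,
                per_class_count=per_class,
            )
        )
    return GcHapTable(
        gene_id=gene.gene_id,
        site_positions=tuple(s.position for s in sites),
        haplotypes=haplotypes,
        assignment=assignment,
        excluded_count=int(n_acc - keep.sum()),
    )


def major_gchaps(table: GcHapTable, threshold: float = 0.01) -> list[str]:
    """Haplotypes with global frequency >= ``threshold`` among non-excluded
    accessions, in Hap rank order.  The default 1% cut-off defines the
    'major gcHap' set."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = table.n_assigned
    if n == 0:
        return []
    return [h.hap_id for h in table.haplotypes if h.global_count / n >= threshold]


def favorable_unfavorable(
    table: GcHapTable, threshold: float = 0.01
) -> tuple[str, str]:
    """The (highest-frequency, lowest-frequency) major gcHap pair.

    The most frequent major haplotype is interpreted as selection-favored,
    the least frequent major one as unfavorable.  Ties resolve to the lower
    Hap rank.  Raises :class:`NotAnalyzableError` with fewer than two major
    haplotypes.
    """
    majors = major_gchaps(table, threshold)
    if len(majors) < 2:
        raise NotAnalyzableError(
            f"gene {table.gene_id}: {len(majors)} major gcHap(s); "
            "favorable/unfavorable comparison needs at least 2"
        )
    counts = {h.hap_id: h.global_count for h in table.haplotypes}
    # majors is in Hap rank order: on ties the favorable haplotype takes the
    # lowest rank and the unfavorable one the highest, so the pair is always
    # distinct
    fav = max(majors, key=lambda h: counts[h])
    unfav = min(reversed(majors), key=lambda h: counts[h])
    return fav, unfav


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def assignments_frame(tables: list[GcHapTable]) -> pd.DataFrame:
    rows = [
        {"accession": acc, "gene": t.gene_id, "hap_id": hap}
        for t in tables
        for acc, hap in t.assignment.items()
    ]
    return pd.DataFrame(rows, columns=["accession", "gene", "hap_id"])


def summary_frame(tables: list[GcHapTable]) -> pd.DataFrame:
    """One row per (gene, haplotype) with counts per population and class."""
    rows = []
    for t in tables:
        for h in t.haplotypes:
            row = {
                "gene": t.gene_id,
                "hap_id": h.hap_id,
                "allele_vector": "".join(str(a) for a in h.allele_vector),
                "global_count": h.global_count,
            }
            for pop, c in sorted(h.per_population_count.items()):
                row[f"n_{pop}"] = c
            for (pop, cls), c in sorted(h.per_class_count.items()):
                row[f"n_{pop}_{cls}"] = c
            rows.append(row)
    return pd.DataFrame(rows).fillna(0)
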