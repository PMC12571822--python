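"""Readers and writers for the pipeline's standard formats.

Inputs are a VCF of SNP genotypes (inbred, effectively haploid rice
accessions), a GFF3 of gene models with CDS features, and TSV tables of
accession metadata (population, variety class) and phenotypes.  All result
tables are written as plain TSV so that every output can be inspected and
round-tripped.

Coordinates are kept 1-based inclusive end to end, matching both VCF and
GFF3, so no conversion ever happens at a module boundary.
"""

from __future__ import annotations

import difflib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gchap")

# Genotype codes used throughout the package.  Non-negative values are
# allele indices (0 = REF, 1.. = ALT order in the VCF record).
MISSING = -1
HET = -2

#: The five rice population groups of the 3K Rice Genomes panel.
POPULATIONS = ("Xian", "Geng", "Aus", "Bas", "Admix")
#: Variety classes: landrace, modern variety, everything else.
VARIETY_CLASSES = ("LAN", "MV", "other")

#: Agronomic trait vocabulary with units.
TRAITS = {
    "DTH": "day",      # days to heading
    "PH": "cm",        # plant height
    "FLL": "cm",       # flag leaf length
    "FLW": "cm",       # flag leaf width
    "PN": "count",     # panicle number
    "PL": "cm",        # panicle length
    "CN": "count",     # culm number
    "CL": "cm",        # culm length
    "GL": "mm",        # grain length
    "GW": "mm",        # grain width
    "GLWR": "ratio",   # grain length-to-width ratio
    "TGW": "g",        # 1000-grain weight
    "LRI": "%",        # leaf rolling index
    "SH": "cm",        # seedling height
    "LL": "mm",        # lemma length
}

# Common mislabels seen in rice metadata, mapped to the canonical token.
_POPULATION_SYNONYMS = {
    "indica": "Xian",
    "xi": "Xian",
    "japonica": "Geng",
    "gj": "Geng",
    "basmati": "Bas",
    "admixed": "Admix",
    "mixed": "Admix",
    "intermediate": "Admix",
}
_CLASS_SYNONYMS = {
    "landrace": "LAN",
    "lans": "LAN",
    "modern": "MV",
    "mvs": "MV",
    "improved": "MV",
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding intervals on a chromosome.

    ``cds_intervals`` are 1-based inclusive ``(start, end)`` pairs, sorted
    by start, non-overlapping, with book-ended neighbours merged.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id}: at least one CDS interval required")
        prev_end = 0
        for start, end in self.cds_intervals:
            if end < start:
                raise ValueError(f"gene {self.gene_id}: interval ({start}, {end}) has end < start")
            if start <= prev_end:
                raise ValueError(f"gene {self.gene_id}: intervals overlap or are unsorted")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def contains(self, position: int) -> bool:
        """True if a 1-based genomic position falls in any CDS interval."""
        return any(s <= position <= e for s, e in self.cds_intervals)


@dataclass(frozen=True)
class VariantSite:
    """One SNP site with per-accession genotype codes.

    ``genotypes`` holds allele indices (0 = ref, 1.. = alt) with ``MISSING``
    (-1) for uncalled and ``HET`` (-2) for heterozygous calls.
    """

    chromosome: str
    position: int
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("allele strings must be non-empty")


@dataclass
class AccessionPanel:
    """Accession metadata: population, variety class, and phenotypes.

    ``traits`` is a DataFrame indexed by accession id with one column per
    trait; missing phenotypes are NaN and are never imputed.
    """

    accession_ids: list[str]
    population: dict[str, str]
    variety_class: dict[str, str]
    traits: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for acc in self.accession_ids:
            if acc not in self.population:
                raise ValueError(f"accession {acc} has no population label")
            if acc not in self.variety_class:
                raise ValueError(f"accession {acc} has no variety class")

    def __len__(self) -> int:
        return len(self.accession_ids)

    def accessions_in(self, population: str | None = None,
                      variety_class: str | None = None) -> list[str]:
        """Accessions matching the given population and/or class filters."""
        out = []
        for acc in self.accession_ids:
            if population is not None and self.population[acc] != population:
                continue
            if variety_class is not None and self.variety_class[acc] != variety_class:
                continue
            out.append(acc)
        return out

    def trait_values(self, accessions: list[str], trait: str) -> pd.Series:
        """Non-missing phenotype values for the given accessions."""
        if trait not in self.traits.columns:
            raise KeyError(f"trait {trait!r} not in panel")
        sub = self.traits.loc[[a for a in accessions if a in self.traits.index], trait]
        return sub.dropna()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _prevalidate_vcf(path: str) -> int:
    """Cheap structural pass over a plain-text VCF.

    Returns the number of sample columns, raising :class:`ParseError` with a
    line number on a malformed header or a genotype column count mismatch.
    """
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 9 or cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise ParseError(f"{path}:{lineno}: malformed #CHROM header line")
                n_samples = len(cols) - 9
                continue
            if n_samples is None:
                raise ParseError(f"{path}:{lineno}: data line before #CHROM header")
            ncol = line.count("\t") + 1
            if ncol != 9 + n_samples:
                raise ParseError(
                    f"{path}:{lineno}: expected {9 + n_samples} columns, found {ncol}"
                )
    if n_samples is None:
        raise ParseError(f"{path}: no #CHROM header line found")
    return n_samples


def read_vcf(path: str) -> tuple[list[VariantSite], list[str]]:
    """Read SNP records from a VCF 4.x file.

    Only sites where REF and every ALT are single bases are kept; indel and
    MNP records are skipped (their count is logged).  Genotypes are decoded
    phase-agnostically: ``0/0`` and ``0|0`` give allele 0, ``./.`` gives
    ``MISSING``, and any unequal pair such as ``0/1`` or ``1|0`` gives
    ``HET``.

    Returns ``(sites, accession_ids)`` with sites in file order.
    """
    from cyvcf2 import VCF

    _prevalidate_vcf(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare Exception subclasses
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    skipped = 0
    for rec in vcf:
        alts = tuple(rec.ALT)
        if len(rec.REF) != 1 or not alts or any(len(a) != 1 for a in alts):
            skipped += 1
            continue
        gts = np.asarray(rec.genotype.array(), dtype=np.int32)
        a0, a1 = gts[:, 0], gts[:, 1]
        codes = np.where(
            (a0 < 0) | (a1 < 0), MISSING, np.where(a0 != a1, HET, a0)
        ).astype(np.int8)
        sites.append(
            VariantSite(
                chromosome=rec.CHROM,
                position=rec.POS,
                ref=rec.REF,
                alts=alts,
                genotypes=codes,
            )
        )
    if skipped:
        logger.info("read_vcf: skipped %d non-SNP record(s) in %s", skipped, path)
    read_vcf.last_skipped = skipped  # type: ignore[attr-defined]
    return sites, samples


def write_vcf(path: str, sites: list[VariantSite], accession_ids: list[str]) -> None:
    """Write sites as a minimal plain-text VCF 4.2 with GT-only genotypes."""
    gt_of = {MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chromosome for s in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accession_ids) + "\n")
        for s in sites:
            cols = [s.chromosome, str(s.position), ".", s.ref, ",".join(s.alts),
                    ".", "PASS", ".", "GT"]
            for g in s.genotypes:
                g = int(g)
                if g == HET:
                    cols.append("0/1")
                else:
                    cols.append(gt_of.get(g, f"{g}/{g}"))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping or book-ended 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def read_gff3(path: str, feature: str = "CDS") -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Each CDS feature is attributed to a gene by climbing its Parent chain
    (CDS -> mRNA -> gene); a Parent reference pointing outside the file is
    accepted as the gene id itself.  Per gene, intervals from all isoforms
    are unioned and book-ended pieces merged.
    """
    import gffutils

    if os.path.getsize(path) == 0 or not any(
        not ln.startswith("#") and ln.strip() for ln in open(path)
    ):
        logger.warning("read_gff3: %s contains no features", path)
        return []
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_gene: dict[str, dict] = {}
    for cds in db.features_of_type(feature):
        gene_id = None
        for anc in db.parents(cds):
            gene_id = anc.id  # last parent reached = topmost ancestor
        if gene_id is None:
            parents = cds.attributes.get("Parent", [])
            if parents:
                gene_id = parents[0]
            else:
                raise ParseError(
                    f"{path}: {feature} feature at {cds.seqid}:{cds.start}-{cds.end} "
                    f"(line: {cds})"
                    " has no resolvable gene identifier (no Parent/ID chain)"
                )
        entry = by_gene.setdefault(
            gene_id, {"chrom": cds.seqid, "strand": cds.strand, "ivs": []}
        )
        entry["ivs"].append((cds.start, cds.end))
    models = []
    for gene_id, entry in by_gene.items():
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=entry["chrom"],
                strand=entry["strand"] if entry["strand"] in ("+", "-") else "+",
                cds_intervals=_merge_intervals(entry["ivs"]),
            )
        )
    return models


def write_gff3(path: str, models: list[GeneModel]) -> None:
    """Write gene models as gene/mRNA/CDS GFF3 lines (one isoform per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start = min(s for s, _ in m.cds_intervals)
            end = max(e for _, e in m.cds_intervals)
            base = f"{m.chromosome}\tgchap\t"
            tail = f"\t.\t{m.strand}\t.\t"
            fh.write(base + f"gene\t{start}\t{end}" + tail + f"ID={m.gene_id}\n")
            fh.write(base + f"mRNA\t{start}\t{end}" + tail
                     + f"ID={m.gene_id}.1;Parent={m.gene_id}\n")
            for s, e in m.cds_intervals:
                fh.write(base + f"CDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                         + f"ID=cds-{m.gene_id};Parent={m.gene_id}.1\n")


# ---------------------------------------------------------------------------
# Panel / traits TSV
# ---------------------------------------------------------------------------

def _canonical_token(value: str, vocabulary: tuple[str, ...],
                     synonyms: dict[str, str], kind: str) -> str:
    if value in vocabulary:
        return value
    hint = synonyms.get(value.lower())
    if hint is None:
        close = difflib.get_close_matches(value, vocabulary, n=1)
        hint = close[0] if close else None
    suggestion = f" (did you mean {hint!r}?)" if hint else ""
    raise ParseError(
        f"unknown {kind} token {value!r}; expected one of {list(vocabulary)}{suggestion}"
    )


def read_panel(path: str) -> AccessionPanel:
    """Read an accession metadata TSV (accession, population, variety_class).

    Unknown population or class tokens are rejected with a suggestion;
    duplicate accession ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "population", "variety_class"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: panel TSV must have columns {sorted(required)}")
    dups = df["accession"][df["accession"].duplicated()]
    if not dups.empty:
        raise ParseError(f"{path}: duplicate accession id(s): {sorted(set(dups))}")
    population, variety_class = {}, {}
    for _, row in df.iterrows():
        acc = row["accession"]
        population[acc] = _canonical_token(
            row["population"], POPULATIONS, _POPULATION_SYNONYMS, "population")
        variety_class[acc] = _canonical_token(
            row["variety_class"], VARIETY_CLASSES, _CLASS_SYNONYMS, "variety class")
    return AccessionPanel(
        accession_ids=list(df["accession"]),
        population=population,
        variety_class=variety_class,
    )


def read_traits(path: str, panel: AccessionPanel,
                vocabulary: dict[str, str] | None = None) -> AccessionPanel:
    """Attach a phenotype TSV (accession + one column per trait) to a panel.

    Trait names must come from ``vocabulary`` (default: the 15-trait rice
    set in :data:`TRAITS`).  Blank cells stay missing (NaN).
    """
    vocabulary = TRAITS if vocabulary is None else vocabulary
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "accession" not in df.columns:
        raise ParseError(f"{path}: traits TSV must have an 'accession' column")
    unknown = [c for c in df.columns if c != "accession" and c not in vocabulary]
    if unknown:
        raise ParseError(
            f"{path}: unknown trait column(s) {unknown}; declared traits: "
            f"{sorted(vocabulary)}"
        )
    dups = df["accession"][df["accession"].duplicated()]
    if not dups.empty:
        raise ParseError(f"{path}: duplicate accession id(s): {sorted(set(dups))}")
    traits = df.set_index("accession").astype(float)
    panel.traits = traits
    return panel


def write_panel(path: str, panel: AccessionPanel) -> None:
    rows = [
        {
            "accession": acc,
            "population": panel.population[acc],
            "variety_class": panel.variety_class[acc],
        }
        for acc in panel.accession_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_traits(path: str, panel: AccessionPanel) -> None:
    panel.traits.reset_index().rename(columns={"index": "accession"}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_table(path: str, df: pd.DataFrame) -> None:
    """Write any result table as TSV with full float precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
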