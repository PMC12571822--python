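"""Haplotype diversity statistics.

Three frequency-based statistics quantify gcHap diversity:

* Shannon equitability ``E_H = (-sum p_i ln p_i) / ln S`` — entropy of the
  haplotype frequency spectrum normalised by its maximum, so 1 means a
  perfectly even spectrum and 0 a monomorphic gene.
* Nei's normalised genetic identity
  ``I = sum x_i y_i / sqrt(sum x_i^2 * sum y_i^2)`` between two
  populations' spectra; 1 means identical composition, low values mean
  strong differentiation.
* Haplotype Fst as Nei's G_ST with sample-size weights:
  ``(H_T - H_S) / H_T`` where ``H_S`` is the weighted mean within-population
  heterozygosity and ``H_T`` the heterozygosity of the pooled spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gchap_core import GcHapTable, major_gchaps
from .io_formats import AccessionPanel


@dataclass
class FrequencySpectrum:
    """Haplotype frequencies within one population (or subset) at one gene."""

    gene_id: str
    population: str
    freqs: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n == 0 and self.freqs:
            raise ValueError("non-empty spectrum with n = 0")
        if self.freqs:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")
            if any(f < 0 or f > 1 for f in self.freqs.values()):
                raise ValueError("frequencies must lie in [0, 1]")


def spectrum_from_counts(gene_id: str, population: str,
                         counts: dict[str, int]) -> FrequencySpectrum:
    counts = {h: c for h, c in counts.items() if c > 0}
    n = sum(counts.values())
    freqs = {h: c / n for h, c in counts.items()} if n else {}
    return FrequencySpectrum(gene_id=gene_id, population=population, freqs=freqs, n=n)


def population_spectrum(table: GcHapTable, population: str | None = None,
                        panel: AccessionPanel | None = None,
                        variety_class: str | None = None) -> FrequencySpectrum:
    """Spectrum over non-excluded accessions, optionally restricted to a
    population and/or variety class (requires the panel for restriction)."""
    if population is None and variety_class is None:
        counts = {h.hap_id: h.global_count for h in table.haplotypes}
        label = "all"
    else:
        if panel is None:
            raise ValueError("panel required to restrict by population/class")
        wanted = set(panel.accessions_in(population=population,
                                         variety_class=variety_class))
        counts: dict[str, int] = {}
        for acc, hap in table.assignment.items():
            if acc in wanted:
                counts[hap] = counts.get(hap, 0) + 1
        label = "/".join(x for x in (population, variety_class) if x)
    return spectrum_from_counts(table.gene_id, label, counts)


def shannon_equitability(spectrum: FrequencySpectrum) -> float:
    """E_H of a spectrum; 0 by convention when only one haplotype is present.

    Natural log is used in both entropy and its normaliser, so the base
    cancels and the result lies in [0, 1].
    """
    if spectrum.n == 0:
        raise ValueError(f"E_H undefined for empty spectrum ({spectrum.gene_id})")
    p = np.array([f for f in spectrum.freqs.values() if f > 0.0])
    s = p.size
    if s <= 1:
        return 0.0
    h = float(-(p * np.log(p)).sum())
    return h / float(np.log(s))


def nei_identity(spec_x: FrequencySpectrum, spec_y: FrequencySpectrum) -> float:
    """Nei's normalised identity between two spectra of the same gene.

    Haplotype universes are unioned with zero fill, so disjoint spectra give
    0 and proportional (hence equal) spectra give 1.
    """
    if spec_x.n == 0 or spec_y.n == 0:
        raise ValueError("I_Nei undefined when either population is empty")
    haps = sorted(set(spec_x.freqs) | set(spec_y.freqs))
    x = np.array([spec_x.freqs.get(h, 0.0) for h in haps])
    y = np.array([spec_y.freqs.get(h, 0.0) for h in haps])
    return float(x @ y / np.sqrt((x @ x) * (y @ y)))


def fst_haplotype(spectra: list[FrequencySpectrum]) -> float:
    """G_ST-style Fst over K >= 2 populations from haplotype frequencies.

    ``H_S = sum_k w_k (1 - sum_i p_ki^2)`` with weights ``w_k = n_k / n``,
    ``H_T = 1 - sum_i pbar_i^2`` with ``pbar_i = sum_k w_k p_ki``;
    Fst = (H_T - H_S) / H_T, defined as 0 when H_T = 0 (no variation).
    """
    if len(spectra) < 2:
        raise ValueError("Fst requires at least two populations")
    if any(s.n == 0 for s in spectra):
        raise ValueError("Fst undefined with an empty population")
    haps = sorted(set().union(*(s.freqs for s in spectra)))
    p = np.array([[s.freqs.get(h, 0.0) for h in haps] for s in spectra])
    w = np.array([s.n for s in spectra], dtype=float)
    w /= w.sum()
    h_s = float(w @ (1.0 - (p**2).sum(axis=1)))
    pbar = w @ p
    h_t = 1.0 - float(pbar @ pbar)
    if h_t == 0.0:
        return 0.0
    return (h_t - h_s) / h_t


def diversity_table(tables: list[GcHapTable], panel: AccessionPanel,
                    populations: list[str],
                    major_threshold: float = 0.01) -> pd.DataFrame:
    """Per gene x population E_H / gcHapN / major gcHapN, plus mean rows.

    ``major_gcHapN`` counts haplotypes that pass the global >= 1% rule and
    are present in the population.  The ``Mean`` row per population is the
    arithmetic mean of the per-gene values.
    """
    present = set()
    for acc in panel.accession_ids:
        present.add(panel.population[acc])
    missing = [p for p in populations if p not in present]
    if missing:
        raise ValueError(f"population(s) absent from panel: {missing}")
    rows = []
    for table in tables:
        global_major = set(major_gchaps(table, major_threshold))
        for pop in populations:
            spec = population_spectrum(table, population=pop, panel=panel)
            if spec.n == 0:
                eh, n_hap, n_major = float("nan"), 0, 0
            else:
                eh = shannon_equitability(spec)
                n_hap = len(spec.freqs)
                n_major = len(set(spec.freqs) & global_major)
            rows.append({
                "gene": table.gene_id, "population": pop, "EH": eh,
                "gcHapN": n_hap, "major_gcHapN": n_major, "n": spec.n,
            })
    df = pd.DataFrame(rows)
    means = (
        df.groupby("population", sort=False)[["EH", "gcHapN", "major_gcHapN"]]
        .mean()
        .reset_index()
    )
    means.insert(0, "gene", "Mean")
    means["n"] = np.nan
    return pd.concat([df, means], ignore_index=True)


def nei_identity_table(tables: list[GcHapTable], panel: AccessionPanel,
                       populations: list[str]) -> pd.DataFrame:
    """All pairwise I_Nei values per gene (the Fig.-5-style matrix as a long
    table)."""
    rows = []
    for table in tables:
        specs = {
            pop: population_spectrum(table, population=pop, panel=panel)
            for pop in populations
        }
        for i, pa in enumerate(populations):
            for pb in populations[i + 1:]:
                if specs[pa].n == 0 or specs[pb].n == 0:
                    val = float("nan")
                else:
                    val = nei_identity(specs[pa], specs[pb])
                rows.append({"gene": table.gene_id, "pop_a": pa, "pop_b": pb,
                             "INei": val})
    return pd.DataFrame(rows)


def fst_table(tables: list[GcHapTable], panel: AccessionPanel,
              populations: list[str]) -> pd.DataFrame:
    rows = []
    for table in tables:
        specs = [
            population_spectrum(table, population=pop, panel=panel)
            for pop in populations
        ]
        specs = [s for s in specs if s.n > 0]
        rows.append({
            "gene": table.gene_id,
            "Fst": fst_haplotype(specs) if len(specs) >= 2 else float("nan"),
            "K": len(specs),
            "estimator": "Nei_GST_weighted",
        })
    return pd.DataFrame(rows)
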