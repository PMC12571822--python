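"""Breeding-driven diversity shift between landraces and modern varieties.

For each gene within a population group (Xian or Geng), the Shannon
equitability E_H and the haplotype count gcHapN are computed separately on
the landrace (LAN) and modern-variety (MV) subsets.  Significance of the
E_H difference comes from a label-permutation test: under the null of no
LAN/MV structuring, variety-class labels are exchangeable, so |dE_H| is
recomputed under random reshuffles of the labels with subset sizes fixed.

Haplotype frequency drift between the two classes is tested per major
haplotype with a 2x2 chi-square (hap vs not-hap x LAN vs MV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gchap_core import GcHapTable, major_gchaps
from .diversity import population_spectrum, shannon_equitability
from .io_formats import AccessionPanel

#: Significance bands used in the shift tables.
P_STRONG = 0.0001   # '**'
P_WEAK = 0.05       # '*'


@dataclass
class ShiftResult:
    """One per-gene row of the LAN-vs-MV comparison table."""

    gene_id: str
    group: str
    eh_lan: float
    eh_mv: float
    gchapn_lan: int | float
    gchapn_mv: int | float
    p_value: float = float("nan")

    @property
    def delta_eh(self) -> float:
        return self.eh_mv - self.eh_lan

    @property
    def delta_gchapn(self) -> float:
        return self.gchapn_mv - self.gchapn_lan

    @property
    def significance(self) -> str:
        if np.isnan(self.p_value):
            return "na"
        if self.p_value < P_STRONG:
            return "**"
        if self.p_value < P_WEAK:
            return "*"
        return "ns"

    @property
    def selection_label(self) -> str:
        # 'up' marks a significant artificial-selection effect on the locus,
        # irrespective of the sign of delta_eh.
        return "up" if self.significance in ("*", "**") else "down"


@dataclass
class DriftRecord:
    """Major-haplotype frequency drift between LAN and MV, with chi-square."""

    gene_id: str
    hap_id: str
    freq_lan: float
    freq_mv: float
    chi2: float
    p: float
    low_count: bool = False


def _class_hap_indices(table: GcHapTable, panel: AccessionPanel, group: str
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """(LAN hap indices, MV hap indices, number of haplotypes) for a group.

    Haplotypes are indexed by rank so that count vectors are cheap to build
    with bincount during permutation.
    """
    rank = {h.hap_id: i for i, h in enumerate(table.haplotypes)}
    lan, mv = [], []
    for acc, hap in table.assignment.items():
        if panel.population[acc] != group:
            continue
        cls = panel.variety_class[acc]
        if cls == "LAN":
            lan.append(rank[hap])
        elif cls == "MV":
            mv.append(rank[hap])
    return (np.array(sorted(lan), dtype=np.int64),
            np.array(sorted(mv), dtype=np.int64),
            len(table.haplotypes))


def _eh_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    pos = counts[counts > 0]
    if n == 0 or pos.size <= 1:
        return 0.0
    p = pos / n
    return float(-(p * np.log(p)).sum() / np.log(pos.size))


def eh_permutation_test(table: GcHapTable, panel: AccessionPanel, group: str,
                        reps: int = 10_000, seed: int = 1) -> float:
    """Two-sided permutation p-value for |E_H(MV) - E_H(LAN)| in a group.

    LAN/MV labels are reshuffled among the group's non-excluded accessions
    with subset sizes held fixed; ``p = (1 + #{perm >= observed}) / (1 +
    reps)``.  The result depends only on (seed, reps, data) — accession
    input order is canonicalised away.
    """
    lan, mv, n_hap = _class_hap_indices(table, panel, group)
    if lan.size == 0 or mv.size == 0:
        raise ValueError(
            f"gene {table.gene_id}: empty LAN or MV subset in group {group}"
        )
    observed = abs(
        _eh_from_counts(np.bincount(mv, minlength=n_hap))
        - _eh_from_counts(np.bincount(lan, minlength=n_hap))
    )
    pooled = np.sort(np.concatenate([lan, mv]))
    n_lan = lan.size
    rng = np.random.default_rng(seed)
    hits = 0
    work = pooled.copy()
    for _ in range(reps):
        rng.shuffle(work)
        stat = abs(
            _eh_from_counts(np.bincount(work[n_lan:], minlength=n_hap))
            - _eh_from_counts(np.bincount(work[:n_lan], minlength=n_hap))
        )
        if stat >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + reps)


def shift_table(tables: list[GcHapTable], panel: AccessionPanel, group: str,
                reps: int = 10_000, seed: int = 1) -> list[ShiftResult]:
    """Per-gene LAN-vs-MV shift rows for one population group."""
    if not panel.accessions_in(population=group, variety_class="LAN"):
        raise ValueError(f"no LAN accessions in group {group}")
    if not panel.accessions_in(population=group, variety_class="MV"):
        raise ValueError(f"no MV accessions in group {group}")
    results = []
    for table in tables:
        spec_lan = population_spectrum(table, population=group, panel=panel,
                                       variety_class="LAN")
        spec_mv = population_spectrum(table, population=group, panel=panel,
                                      variety_class="MV")
        if spec_lan.n == 0 or spec_mv.n == 0:
            raise ValueError(
                f"gene {table.gene_id}: empty {'LAN' if spec_lan.n == 0 else 'MV'} "
                f"subset in group {group} after exclusion"
            )
        results.append(
            ShiftResult(
                gene_id=table.gene_id,
                group=group,
                eh_lan=shannon_equitability(spec_lan),
                eh_mv=shannon_equitability(spec_mv),
                gchapn_lan=len(spec_lan.freqs),
                gchapn_mv=len(spec_mv.freqs),
                p_value=eh_permutation_test(table, panel, group,
                                            reps=reps, seed=seed),
            )
        )
    return results


def summarize_shift(rows: list[ShiftResult]) -> dict[str, float]:
    """Arithmetic means of the per-gene columns (the tables' 'Mean' row).

    Deltas are averaged as exact differences of the per-gene values, so
    e.g. a gcHapN delta mean keeps full precision (-36.81818182...) while
    the E_H columns stay on their own scale.
    """
    n = len(rows)
    if n == 0:
        raise ValueError("no rows to summarize")
    return {
        "eh_lan": sum(r.eh_lan for r in rows) / n,
        "eh_mv": sum(r.eh_mv for r in rows) / n,
        "gchapn_lan": sum(r.gchapn_lan for r in rows) / n,
        "gchapn_mv": sum(r.gchapn_mv for r in rows) / n,
        "delta_eh": sum(r.delta_eh for r in rows) / n,
        "delta_gchapn": sum(r.delta_gchapn for r in rows) / n,
    }


def shift_frame(rows: list[ShiftResult]) -> pd.DataFrame:
    """Shift rows plus a Mean row, in the published tables' column order."""
    recs = [
        {
            "gene": r.gene_id, "group": r.group,
            "EH_LAN": r.eh_lan, "gcHapN_LAN": r.gchapn_lan,
            "EH_MV": r.eh_mv, "gcHapN_MV": r.gchapn_mv,
            "delta_EH": r.delta_eh, "delta_gcHapN": r.delta_gchapn,
            "p_value": r.p_value, "significance": r.significance,
            "selection": r.selection_label,
        }
        for r in rows
    ]
    mean = summarize_shift(rows)
    recs.append({
        "gene": "Mean", "group": rows[0].group,
        "EH_LAN": mean["eh_lan"], "gcHapN_LAN": mean["gchapn_lan"],
        "EH_MV": mean["eh_mv"], "gcHapN_MV": mean["gchapn_mv"],
        "delta_EH": mean["delta_eh"], "delta_gcHapN": mean["delta_gchapn"],
        "p_value": float("nan"), "significance": "", "selection": "",
    })
    return pd.DataFrame(recs)


def drift_chi2(table: GcHapTable, panel: AccessionPanel, group: str,
               hap_id: str, major_threshold: float = 0.01) -> DriftRecord:
    """2x2 chi-square for one major haplotype's LAN-vs-MV proportion shift.

    No continuity correction, matching the plain chi-square on gcHap
    proportions.  Results with an expected cell below 1 are flagged
    ``low_count``; a degenerate margin (all-zero row/column) gives
    chi2 = 0 with undefined p, also flagged.
    """
    if hap_id not in major_gchaps(table, major_threshold):
        raise ValueError(f"{hap_id} is not a major gcHap of {table.gene_id}")
    counts = np.zeros((2, 2), dtype=np.int64)  # rows: LAN, MV; cols: hap, other
    for acc, hap in table.assignment.items():
        if panel.population[acc] != group:
            continue
        cls = panel.variety_class[acc]
        if cls not in ("LAN", "MV"):
            continue
        counts[0 if cls == "LAN" else 1, 0 if hap == hap_id else 1] += 1
    n_lan, n_mv = counts.sum(axis=1)
    if n_lan == 0 or n_mv == 0:
        raise ValueError(f"empty LAN or MV subset in group {group}")
    freq_lan = counts[0, 0] / n_lan
    freq_mv = counts[1, 0] / n_mv
    if (counts.sum(axis=0) == 0).any():
        return DriftRecord(table.gene_id, hap_id, freq_lan, freq_mv,
                           chi2=0.0, p=float("nan"), low_count=True)
    chi2, p, _, expected = stats.chi2_contingency(counts, correction=False)
    return DriftRecord(
        table.gene_id, hap_id, freq_lan, freq_mv,
        chi2=float(chi2), p=float(p), low_count=bool((expected < 1).any()),
    )


def drift_frame(tables: list[GcHapTable], panel: AccessionPanel, group: str,
                major_threshold: float = 0.01) -> pd.DataFrame:
    rows = []
    for table in tables:
        for hap_id in major_gchaps(table, major_threshold):
            r = drift_chi2(table, panel, group, hap_id, major_threshold)
            rows.append({
                "gene": r.gene_id, "hap_id": r.hap_id, "group": group,
                "freq_LAN": r.freq_lan, "freq_MV": r.freq_mv,
                "chi2": r.chi2, "p": r.p, "low_count": r.low_count,
            })
    return pd.DataFrame(rows)
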