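"""Association of major gcHaps with quantitative agronomic traits.

Per gene x trait, accessions are grouped by their major haplotype and a
classical one-way ANOVA is run, followed by Tukey HSD over all pairs and a
compact-letter display (groups sharing a letter are not significantly
different at the Tukey-adjusted 0.05 level).  Associations with ANOVA
p < 1e-7 are flagged 'strong'.

The favorable-vs-unfavorable scan compares the highest- and
lowest-frequency major haplotype per gene across all traits with a Welch
(unequal-variance) two-sample test — group sizes are wildly unbalanced by
construction, so pooled variance is inappropriate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import string

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gchap_core import (
    GcHapTable,
    NotAnalyzableError,
    favorable_unfavorable,
    major_gchaps,
)
from .io_formats import AccessionPanel

P_STRONG = 1e-7
ALPHA = 0.05
MIN_N = 10


@dataclass
class AssocResult:
    gene_id: str
    trait: str
    groups: dict[str, dict]          # hap_id -> {n, mean, sd}
    f_stat: float
    p: float
    letters: dict[str, str]          # hap_id -> compact letter string
    strong: bool
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class FavUnfavComparison:
    gene_id: str
    trait: str
    fav: str
    unfav: str
    mean_fav: float
    mean_unfav: float
    p: float
    different: bool
    skipped_reason: str | None = None


def compact_letter_display(groups: list[str],
                           significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds unordered pairs that differ; the result maps each
    group to a letter string such that two groups share a letter iff their
    pair is not significant.  Letter identity depends on group order but the
    sharing structure does not.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(tuple(sorted(p)) for p in significant):
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.extend([col - {a}, col - {b}])
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = []
        for col in new_columns:
            if any(col < other or (col == other and other in columns)
                   for other in new_columns if other is not col):
                continue
            columns.append(col)
    alphabet = string.ascii_lowercase
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for k, col in enumerate(columns):
        symbol = alphabet[k % 26] * (k // 26 + 1)
        for g in groups:
            if g in col:
                letters[g].append(symbol)
    return {g: "".join(v) for g, v in letters.items()}


def _one_way_anova(samples: list[np.ndarray]) -> tuple[float, float]:
    """F and p from sums of squares; degenerate between-group SS gives F=0."""
    all_values = np.concatenate(samples)
    grand = all_values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = len(all_values) - len(samples)
    if ssb <= 1e-300:
        return 0.0, 1.0
    if ssw <= 1e-300:
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


def anova_by_hap(table: GcHapTable, panel: AccessionPanel, trait: str,
                 min_n: int = MIN_N,
                 major_threshold: float = 0.01) -> AssocResult:
    """One-way ANOVA of a trait across a gene's major haplotype groups.

    Groups are major haplotypes with at least ``min_n`` phenotyped
    accessions; accessions with a missing trait value are dropped.  Raises
    :class:`NotAnalyzableError` with fewer than two eligible groups.
    """
    majors = major_gchaps(table, major_threshold)
    samples: dict[str, np.ndarray] = {}
    for hap_id in majors:
        members = [a for a, h in table.assignment.items() if h == hap_id]
        values = panel.trait_values(members, trait).to_numpy(dtype=float)
        if values.size >= min_n:
            samples[hap_id] = values
    if len(samples) < 2:
        raise NotAnalyzableError(
            f"gene {table.gene_id}, trait {trait}: "
            f"{len(samples)} group(s) with >= {min_n} phenotyped accessions"
        )
    hap_ids = list(samples)
    f_stat, p = _one_way_anova(list(samples.values()))

    endog = np.concatenate([samples[h] for h in hap_ids])
    labels = np.concatenate([[h] * samples[h].size for h in hap_ids])
    if np.ptp(endog) == 0:
        # all observations identical: nothing differs
        tukey_p = {tuple(sorted((a, b))): 1.0
                   for i, a in enumerate(hap_ids) for b in hap_ids[i + 1:]}
    else:
        res = pairwise_tukeyhsd(endog, labels, alpha=ALPHA)
        uniq = list(res.groupsunique)
        tukey_p = {}
        k = 0
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                tukey_p[tuple(sorted((uniq[i], uniq[j])))] = float(res.pvalues[k])
                k += 1
    significant = {pair for pair, pv in tukey_p.items() if pv < ALPHA}
    order = sorted(hap_ids, key=lambda h: -samples[h].mean())
    letters = compact_letter_display(order, significant)
    return AssocResult(
        gene_id=table.gene_id,
        trait=trait,
        groups={
            h: {"n": int(samples[h].size), "mean": float(samples[h].mean()),
                "sd": float(samples[h].std(ddof=1)) if samples[h].size > 1 else 0.0}
            for h in hap_ids
        },
        f_stat=f_stat,
        p=p,
        letters={h: letters[h] for h in hap_ids},
        strong=bool(p < P_STRONG),
        tukey_p=tukey_p,
    )


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def fav_unfav_scan(tables: list[GcHapTable], panel: AccessionPanel,
                   traits: list[str], alpha: float = ALPHA,
                   major_threshold: float = 0.01
                   ) -> tuple[list[FavUnfavComparison], dict[str, int]]:
    """Welch test between favorable and unfavorable gcHap per gene x trait.

    Genes with fewer than two major haplotypes are left out (the pair is not
    resolvable).  A comparison where either group has < 2 phenotyped
    accessions is counted as attempted but skipped with a reason.  Returns
    the comparisons and summary counts {attempted, tested, different,
    skipped}.
    """
    comparisons = []
    counts = {"attempted": 0, "tested": 0, "different": 0, "skipped": 0}
    for table in tables:
        try:
            fav, unfav = favorable_unfavorable(table, major_threshold)
        except NotAnalyzableError:
            continue
        fav_members = [a for a, h in table.assignment.items() if h == fav]
        unfav_members = [a for a, h in table.assignment.items() if h == unfav]
        for trait in traits:
            counts["attempted"] += 1
            va = panel.trait_values(fav_members, trait).to_numpy(dtype=float)
            vb = panel.trait_values(unfav_members, trait).to_numpy(dtype=float)
            if va.size < 2 or vb.size < 2:
                which = "favorable" if va.size < 2 else "unfavorable"
                comparisons.append(FavUnfavComparison(
                    table.gene_id, trait, fav, unfav,
                    float(va.mean()) if va.size else float("nan"),
                    float(vb.mean()) if vb.size else float("nan"),
                    p=float("nan"), different=False,
                    skipped_reason=f"{which} group has < 2 phenotyped accessions",
                ))
                counts["skipped"] += 1
                continue
            p = _welch(va, vb)
            different = bool(p < alpha)
            comparisons.append(FavUnfavComparison(
                table.gene_id, trait, fav, unfav,
                float(va.mean()), float(vb.mean()), p=p, different=different,
            ))
            counts["tested"] += 1
            counts["different"] += int(different)
    return comparisons, counts


def assoc_frame(results: list[AssocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for hap_id, g in r.groups.items():
            rows.append({
                "gene": r.gene_id, "trait": r.trait, "hap_id": hap_id,
                "n": g["n"], "mean": g["mean"], "sd": g["sd"],
                "F": r.f_stat, "p": r.p, "letter": r.letters[hap_id],
                "strong": r.strong,
            })
    return pd.DataFrame(rows)


def fav_unfav_frame(comparisons: list[FavUnfavComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": c.gene_id, "trait": c.trait, "fav": c.fav, "unfav": c.unfav,
            "mean_fav": c.mean_fav, "mean_unfav": c.mean_unfav, "p": c.p,
            "different": c.different, "skipped_reason": c.skipped_reason or "",
        }
        for c in comparisons
    ])
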