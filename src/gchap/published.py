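"""Published per-gene diversity values for the 11 OsDLH loci.

These are the per-gene Shannon equitability (E_H) and gcHap count (gcHapN)
values reported for the landrace (LAN) and modern-variety (MV) subsets of
the Xian and Geng populations of the 3K Rice Genomes panel — the worked
example shipped with this package.  Feeding them through
:func:`gchap.selection_shift.summarize_shift` reproduces the published
aggregate rows (e.g. the exact Xian gcHapN shift of -36.81818182).
"""

from __future__ import annotations

from .selection_shift import ShiftResult

# gene, EH_LAN, gcHapN_LAN, EH_MV, gcHapN_MV
_XIAN = [
    ("OsDLH1", 0.596, 173, 0.711, 129),
    ("OsDLH2", 0.070, 19, 0.110, 16),
    ("OsDLH3", 0.642, 248, 0.658, 121),
    ("OsDLH4", 0.530, 156, 0.595, 99),
    ("OsDLH5", 0.224, 9, 0.274, 10),
    ("OsDLH6", 0.444, 117, 0.581, 82),
    ("OsDLH7", 0.399, 53, 0.525, 45),
    ("OsDLH8", 0.347, 77, 0.488, 71),
    ("OsDLH9", 0.384, 91, 0.597, 91),
    ("OsDLH10", 0.622, 236, 0.768, 155),
    ("OsDLH11", 0.589, 177, 0.730, 132),
]

_GENG = [
    ("OsDLH1", 0.250, 46, 0.268, 28),
    ("OsDLH2", 0.154, 18, 0.186, 11),
    ("OsDLH3", 0.538, 98, 0.464, 38),
    ("OsDLH4", 0.501, 87, 0.464, 34),
    ("OsDLH5", 0.041, 5, 0.062, 6),
    ("OsDLH6", 0.424, 73, 0.364, 25),
    ("OsDLH7", 0.318, 19, 0.343, 15),
    ("OsDLH8", 0.203, 32, 0.155, 15),
    ("OsDLH9", 0.316, 28, 0.438, 24),
    ("OsDLH10", 0.433, 59, 0.456, 38),
    ("OsDLH11", 0.244, 40, 0.283, 25),
]


def published_shift_rows(group: str) -> list[ShiftResult]:
    """Published per-gene LAN/MV rows for ``group`` in {'Xian', 'Geng'}."""
    data = {"Xian": _XIAN, "Geng": _GENG}[group]
    return [
        ShiftResult(gene_id=g, group=group, eh_lan=ehl, eh_mv=ehm,
                    gchapn_lan=nl, gchapn_mv=nm)
        for g, ehl, nl, ehm, nm in data
    ]
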