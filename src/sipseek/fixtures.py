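"""Worked-example fixture: heavy-fraction pmoA genotype percentages.

The table holds the ten most abundant pmoA genotypes and their relative
abundance (percent of the methanotroph community) in heavy DNA fractions
4-6 of the SIP incubations of a gas-well soil (P1) and a dry-well soil
(J3).  It anchors the worked examples for active-set calling, indicator
selection, biotic-index sums and diversity indices.
"""

from __future__ import annotations

import pandas as pd

_GENOTYPE_ROWS = [
    # genotype,        P1 f4, P1 f5, P1 f6,   J3 f4, J3 f5, J3 f6
    ("Methylocystis",  89.49, 45.01, 26.93,   91.69, 97.44, 88.72),
    ("RPC-2",           2.34, 41.15, 50.40,    1.40,  0.00,  5.93),
    ("USC-gamma",       0.89,  0.67,  0.61,    1.94,  0.00,  1.48),
    ("Methylosarcina",  0.84,  5.21, 19.43,    0.85,  2.56,  0.00),
    ("RPCs",            1.76,  1.95,  0.47,    0.65,  0.00,  2.08),
    ("pmoA-2",          1.97,  3.64,  1.51,    0.27,  0.00,  0.59),
    ("USC-alpha",       0.04,  0.15,  0.04,    0.58,  0.00,  0.00),
    ("Methylobacter",   0.59,  0.06,  0.01,    0.00,  0.00,  0.30),
    ("Methylocaldum",   0.01,  0.01,  0.00,    0.10,  0.00,  0.00),
    ("Methylosinus",    0.05,  0.02,  0.01,    0.78,  0.00,  0.30),
]


def heavy_fraction_table() -> dict[str, pd.DataFrame]:
    """Heavy-fraction genotype percentages per soil.

    Returns ``{"P1": df, "J3": df}`` with genotypes as the index and heavy
    fraction numbers (4, 5, 6) as columns; values are percent of the
    methanotroph community.
    """
    idx = [r[0] for r in _GENOTYPE_ROWS]
    p1 = pd.DataFrame([r[1:4] for r in _GENOTYPE_ROWS], index=idx, columns=[4, 5, 6])
    j3 = pd.DataFrame([r[4:7] for r in _GENOTYPE_ROWS], index=idx, columns=[4, 5, 6])
    return {"P1": p1.astype(float), "J3": j3.astype(float)}


def fraction_profiles(soil: str) -> dict[int, dict[str, float]]:
    """Per-fraction genotype->percent mappings for one soil (P1 or J3)."""
    df = heavy_fraction_table()[soil]
    return {int(c): df[c].to_dict() for c in df.columns}
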