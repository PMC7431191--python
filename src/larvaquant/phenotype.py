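"""Per-segment muscle phenotype tallies with Wilson confidence intervals.

A phenotype table has one row per scored A1–A7 hemisegment with a
categorical call (normal DA3, branched DA3, DA3-to-DA2 transformation, or
absent DA3) and a genotype label.  ``tally`` reports, per genotype, the
relative category proportions with n and 95% Wilson score intervals, both
at segment level (every segment an independent trial) and averaged per
embryo (guarding against pseudo-replication across segments of one embryo).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .synthetic import PHENOTYPE_CATEGORIES

_SEGMENT_IDS = tuple(f"A{i}" for i in range(1, 8))
_REQUIRED = ("embryo_id", "segment_id", "genotype", "category")


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s) {missing}")
    if table.empty:
        raise ValueError("phenotype table is empty")
    bad = set(table["category"]) - set(PHENOTYPE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown phenotype categor{'y' if len(bad)==1 else 'ies'}: "
                         f"{sorted(bad)}; allowed: {PHENOTYPE_CATEGORIES}")
    bad_seg = set(table["segment_id"]) - set(_SEGMENT_IDS)
    if bad_seg:
        raise ValueError(f"invalid segment id(s) {sorted(bad_seg)}; "
                         f"allowed: A1..A7")


def tally(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-genotype category proportions with n and Wilson CIs.

    Returns one row per (genotype, category) with columns: count, n,
    proportion, ci_low, ci_high (Wilson score, segment level) and
    proportion_embryo_mean (mean of per-embryo proportions).  Proportions
    sum to 1 per genotype; rows are emitted for all four categories even
    when a count is zero.
    """
    validate_table(table)
    rows = []
    for genotype, g in table.groupby("genotype", sort=True):
        n = len(g)
        counts = g["category"].value_counts()
        per_embryo = (
            g.groupby("embryo_id")["category"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        for cat in PHENOTYPE_CATEGORIES:
            k = int(counts.get(cat, 0))
            lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
            rows.append({
                "genotype": genotype,
                "category": cat,
                "count": k,
                "n": n,
                "proportion": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "proportion_embryo_mean": float(per_embryo[cat].mean())
                if cat in per_embryo.columns else 0.0,
                "n_embryos": int(per_embryo.shape[0]),
            })
    return pd.DataFrame(rows)
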