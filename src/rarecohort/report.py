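"""Cohort summaries and diagnostic-yield arithmetic.

Everything here is recomputed from the input tables at call time; display
values are rounded half-up to two decimals while full precision is retained
on the returned objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .burden import ttest_two_tailed

logger = logging.getLogger(__name__)

__all__ = ["DiagnosticYield", "CohortSummary", "diagnostic_yield", "summarize_cohort",
           "round_half_up"]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding for display (3.375 -> 3.38 at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DiagnosticYield:
    total_pct: float
    excl_screen_pct: float

    @property
    def total_pct_display(self) -> float:
        return round_half_up(self.total_pct)

    @property
    def excl_screen_pct_display(self) -> float:
        return round_half_up(self.excl_screen_pct)


def diagnostic_yield(n_diagnosed: int, n_screen_detected: int, n_total: int) -> DiagnosticYield:
    """Diagnostic yield of the panel, total and excluding screen-detected cases.

    ``total = 100 * n_diagnosed / n_total``; the second figure removes cases
    found by a dedicated screening assay (e.g. repeat-expansion PCR) rather
    than by panel sequencing.
    """
    if n_total <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= n_screen_detected <= n_diagnosed <= n_total:
        raise ValueError(
            "need 0 <= n_screen_detected <= n_diagnosed <= n_total, got "
            f"({n_screen_detected}, {n_diagnosed}, {n_total})"
        )
    return DiagnosticYield(
        total_pct=100.0 * n_diagnosed / n_total,
        excl_screen_pct=100.0 * (n_diagnosed - n_screen_detected) / n_total,
    )


@dataclass
class CohortSummary:
    n_total: int
    n_male: int
    n_female: int
    sex_ratio: float | None
    median_age: float | None
    age_iqr: float | None
    n_sibpairs: int
    yield_total_pct: float | None
    yield_excl_screen_pct: float | None
    malformation_histogram: dict[int, int]
    mean_malformations_syndromic: float | None
    mean_malformations_nonsyndromic: float | None
    malformation_ttest_p: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(phenotypes: pd.DataFrame, labels: np.ndarray | None = None) -> CohortSummary:
    """Clinical-demographic summary recomputed from the phenotype table.

    Expects columns sex (M/F), family_id, age, malformations, syndromic and
    optionally screen_detected. Missing sex codes are excluded from the sex
    ratio; the malformation histogram bins individuals by their
    minor-malformation count.
    """
    df = phenotypes
    n_total = len(df)
    if n_total == 0:
        raise ValueError("empty phenotype table")
    sex = df["sex"].astype(str)
    n_male = int((sex == "M").sum())
    n_female = int((sex == "F").sum())
    n_missing_sex = n_total - n_male - n_female
    if n_missing_sex:
        logger.warning("%d individuals with missing sex codes excluded from ratio", n_missing_sex)
    sex_ratio = n_male / n_female if n_female else None

    median_age = age_iqr = None
    if "age" in df.columns:
        age = df["age"].dropna().astype(float)
        if len(age):
            median_age = float(age.median())
            age_iqr = float(age.quantile(0.75) - age.quantile(0.25))

    fam_sizes = df["family_id"].value_counts() if "family_id" in df.columns else pd.Series(dtype=int)
    n_sibpairs = int((fam_sizes == 2).sum())

    yield_total = yield_excl = None
    if "syndromic" in df.columns:
        n_diag = int(df["syndromic"].astype(bool).sum())
        n_screen = (
            int((df["syndromic"].astype(bool) & df["screen_detected"].astype(bool)).sum())
            if "screen_detected" in df.columns
            else 0
        )
        y = diagnostic_yield(n_diag, n_screen, n_total) if n_diag or n_total else None
        yield_total, yield_excl = y.total_pct, y.excl_screen_pct

    hist: dict[int, int] = {}
    mean_syn = mean_nonsyn = ttest_p = None
    if "malformations" in df.columns:
        counts = df["malformations"].dropna().astype(int)
        hist = {int(k): int(v) for k, v in counts.value_counts().sort_index().items()}
        if "syndromic" in df.columns:
            syn = df.loc[df["syndromic"].astype(bool), "malformations"].dropna()
            nonsyn = df.loc[~df["syndromic"].astype(bool), "malformations"].dropna()
            mean_syn = float(syn.mean()) if len(syn) else None
            mean_nonsyn = float(nonsyn.mean()) if len(nonsyn) else None
            if len(syn) >= 2 and len(nonsyn) >= 2:
                ttest_p = ttest_two_tailed(syn, nonsyn)

    return CohortSummary(
        n_total=n_total,
        n_male=n_male,
        n_female=n_female,
        sex_ratio=sex_ratio,
        median_age=median_age,
        age_iqr=age_iqr,
        n_sibpairs=n_sibpairs,
        yield_total_pct=yield_total,
        yield_excl_screen_pct=yield_excl,
        malformation_histogram=hist,
        mean_malformations_syndromic=mean_syn,
        mean_malformations_nonsyndromic=mean_nonsyn,
        malformation_ttest_p=ttest_p,
    )
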