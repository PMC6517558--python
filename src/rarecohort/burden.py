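"""Cohort-level rare-variant statistics.

Three pieces:

* a per-gene carrier-excess test: among ``n`` unrelated cases, the number of
  carriers of >= 1 qualifying rare variant in a gene is compared with a
  reference background carrier probability ``p_g`` by an exact binomial upper
  tail ``P(X >= k | n, p_g)`` (sib-pair shared events are reported
  descriptively alongside, never folded into the p-value);
* an RVIS-weighted per-individual burden ``B_i = sum_g v_ig * w_g`` with
  ``w_g = 1 - RVIS_percentile_g / 100``, so variants in intolerant genes
  count for more;
* burden-phenotype association: OLS regression of a severity measure on
  burden, and two-tailed t-tests for group comparisons (Welch by default).

A calibrated-severity lookup (raw ADOS total -> 1..10 score by age band and
module) is provided as a deterministic table lookup; the table itself is
user-supplied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import CarrierMatrix
from .panel import GenePanelEntry, rvis_weight

logger = logging.getLogger(__name__)

__all__ = [
    "SorvaResult",
    "BurdenVector",
    "RegressionResult",
    "sorva_test",
    "sorva_scan",
    "burden_score",
    "regress",
    "ttest_two_tailed",
    "calibrated_severity",
    "rvis_weight",
]


@dataclass
class SorvaResult:
    """Per-gene carrier-excess result: k/n unrelated carriers, s/n_sib shared sib events."""

    gene: str
    k: int
    n: int
    s: int
    n_sib: int
    n_variants: int  # total qualifying variant count in the gene (Table-style accounting)
    p_value: float
    flagged: bool


@dataclass
class BurdenVector:
    """Per-individual RVIS-weighted burden scores."""

    values: pd.Series
    mode: str = "rare_all"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def sorva_test(k: int, n: int, p_g: float) -> float:
    """Exact binomial upper tail ``P(X >= k)`` for ``X ~ Binomial(n, p_g)``.

    ``k = 0`` returns 1 exactly. ``p_g = 0`` with ``k > 0`` is a model
    violation (carriers observed under a zero background rate); 0 is returned
    with a warning.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p_g <= 1.0:
        raise ValueError(f"background probability must be in [0, 1], got {p_g}")
    if k == 0:
        return 1.0
    if p_g == 0.0:
        logger.warning("carriers observed (k=%d) under background probability 0", k)
        return 0.0
    return float(stats.binom.sf(k - 1, n, p_g))


def sorva_scan(
    carriers: CarrierMatrix,
    panel: Sequence[GenePanelEntry],
    alpha: float = 0.05,
    sib_pairs: Sequence[tuple[str, str]] | None = None,
    bonferroni: bool = False,
) -> list[SorvaResult]:
    """Carrier-excess test for every panel gene.

    The p-value uses only the unrelated component (carriers among individuals
    that are not part of a sib-pair); for each sib-pair a "shared" event is
    counted when both sibs carry >= 1 qualifying variant in the gene. With
    ``bonferroni=True`` the flagging threshold is ``alpha / n_genes``.
    """
    sib_pairs = list(sib_pairs or [])
    idx = {s: i for i, s in enumerate(carriers.individuals)}
    sib_members = set()
    pair_rows: list[tuple[int, int]] = []
    for a, b in sib_pairs:
        if a not in idx or b not in idx:
            logger.warning("sib pair (%s, %s) not fully in cohort; members treated as unrelated", a, b)
            continue
        pair_rows.append((idx[a], idx[b]))
        sib_members.update((a, b))
    unrelated_rows = np.array(
        [i for s, i in idx.items() if s not in sib_members], dtype=int
    )
    flags = carriers.carrier_flags()
    n_unrelated = len(unrelated_rows)
    threshold = alpha / len(panel) if bonferroni else alpha

    results = []
    by_gene = {g: j for j, g in enumerate(carriers.genes)}
    for entry in panel:
        j = by_gene.get(entry.gene)
        if j is None:
            raise KeyError(f"panel gene {entry.gene!r} missing from carrier matrix")
        k = int(flags[unrelated_rows, j].sum()) if n_unrelated else 0
        s = sum(int(flags[a, j] and flags[b, j]) for a, b in pair_rows)
        p = sorva_test(k, n_unrelated, entry.background_carrier_prob)
        results.append(
            SorvaResult(
                gene=entry.gene,
                k=k,
                n=n_unrelated,
                s=s,
                n_sib=len(pair_rows),
                n_variants=int(carriers.values[:, j].sum()),
                p_value=p,
                flagged=bool(k > 0 and p < threshold),
            )
        )
    return results


def burden_score(carriers: CarrierMatrix, panel: Sequence[GenePanelEntry],
                 mode: str = "rare_all") -> BurdenVector:
    """RVIS-weighted burden ``B_i = sum_g v_ig * (1 - percentile_g/100)``.

    Siblings are scored separately like everyone else (each sib keeps their
    own variant counts). Raises if a carrier-matrix gene is absent from the
    panel, naming the gene.
    """
    weight_by_gene = {e.gene: e.weight for e in panel}
    try:
        w = np.array([weight_by_gene[g] for g in carriers.genes])
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} is not in the panel") from None
    values = pd.Series(carriers.values @ w, index=pd.Index(carriers.individuals, name="individual"))
    return BurdenVector(values=values, mode=mode)


def regress(x, y) -> RegressionResult:
    """OLS of ``y`` on ``x``: slope, intercept, R^2 and the two-sided slope p
    from the t distribution with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("regression needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is not identifiable")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def ttest_two_tailed(a, b, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def calibrated_severity(raw_total: float, age: float, module: int,
                        table: pd.DataFrame) -> int:
    """Deterministic calibrated-severity lookup (1..10).

    ``table`` must have columns module, age_min, age_max, raw_min, raw_max,
    score; bands are inclusive. A raw total outside every band for the
    matching (module, age) clamps to the nearest band's score with a warning;
    a missing (module, age) cell raises.
    """
    rows = table[
        (table["module"] == module)
        & (table["age_min"] <= age)
        & (age <= table["age_max"])
    ]
    if rows.empty:
        raise LookupError(
            f"calibrated-severity table has no cell for module={module}, age={age}"
        )
    hit = rows[(rows["raw_min"] <= raw_total) & (raw_total <= rows["raw_max"])]
    if not hit.empty:
        return int(hit.iloc[0]["score"])
    rows = rows.sort_values("raw_min")
    if raw_total < rows.iloc[0]["raw_min"]:
        warnings.warn(
            f"raw total {raw_total} below the lowest band; clamping", stacklevel=2
        )
        return int(rows.iloc[0]["score"])
    warnings.warn(f"raw total {raw_total} above the highest band; clamping", stacklevel=2)
    return int(rows.iloc[-1]["score"])


def sorva_results_frame(results: Sequence[SorvaResult]) -> pd.DataFrame:
    """Tabular form mirroring a published results table: gene, carriers k/n,
    shared sib events s/n_sib, total variant count, p-value."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "carriers_unrelated": f"{r.k}/{r.n}",
                "shared_sib_pairs": f"{r.s}/{r.n_sib}",
                "k": r.k,
                "n": r.n,
                "s": r.s,
                "n_sib": r.n_sib,
                "n_variants": r.n_variants,
                "p_value": r.p_value,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )
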