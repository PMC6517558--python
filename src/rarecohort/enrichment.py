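"""Cluster-gene enrichment and the syndromic-by-cluster distribution test.

For each panel gene the per-individual qualifying-variant counts (or,
optionally, binary carrier flags) are compared across the phenotype clusters
by one-way ANOVA, with all pairwise two-sample t-tests alongside. Bonferroni
correction is applied over explicit families: the ANOVA p-values over the
number of testable genes, the pairwise p-values over genes x cluster-pairs.

The syndromic-case distribution over clusters is tested against the
proportional-to-cluster-size null by a chi-square goodness-of-fit test, or by
an exact multinomial test when any expected count falls below 5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import CarrierMatrix

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrichment_scan", "syndromic_distribution",
           "bonferroni", "exact_multinomial_gof"]


def bonferroni(p: float, n_tests: int) -> float:
    """min(1, p * n_tests); monotone in p and capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if n_tests < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p * n_tests)


@dataclass
class EnrichmentResult:
    gene: str
    f_statistic: float
    p_raw: float
    p_bonferroni: float
    testable: bool
    flagged: bool
    pairwise: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    # pairwise maps (cluster_a, cluster_b) -> (p_raw, p_corrected)


def enrichment_scan(
    carriers: CarrierMatrix,
    labels: np.ndarray,
    alpha: float = 0.05,
    use_carrier_flag: bool = False,
    pairwise: bool = True,
    equal_var: bool = False,
) -> list[EnrichmentResult]:
    """Per-gene ANOVA of variant counts across clusters, with pairwise t-tests.

    Genes with zero variance everywhere are untestable and reported as such
    (never flagged). Flagging uses the Bonferroni-corrected ANOVA p at
    ``alpha``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(carriers.individuals):
        raise ValueError("labels must cover every individual in the carrier matrix")
    clusters = sorted(np.unique(labels))
    if sum(np.count_nonzero(labels == c) > 0 for c in clusters) < 2:
        raise ValueError("need at least 2 non-empty clusters")
    X = carriers.carrier_flags().astype(float) if use_carrier_flag else carriers.values.astype(float)
    groups = [X[labels == c] for c in clusters]

    testable = X.var(axis=0) > 0
    n_testable = int(testable.sum())
    n_genes = X.shape[1]
    F = np.full(n_genes, np.nan)
    p_raw = np.full(n_genes, np.nan)
    if n_testable:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-input warnings handled via mask
            res = stats.f_oneway(*[g[:, testable] for g in groups], axis=0)
        F[testable] = res.statistic
        p_raw[testable] = res.pvalue

    pair_results: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    pairs = list(combinations(range(len(clusters)), 2))
    n_pair_tests = max(n_testable * len(pairs), 1)
    if pairwise:
        for ia, ib in pairs:
            ga, gb = groups[ia], groups[ib]
            p_pair = np.full(n_genes, np.nan)
            if len(ga) >= 2 and len(gb) >= 2 and n_testable:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    t = stats.ttest_ind(ga[:, testable], gb[:, testable], axis=0,
                                        equal_var=equal_var)
                p_pair[testable] = t.pvalue
            corrected = np.minimum(p_pair * n_pair_tests, 1.0)
            pair_results[(clusters[ia], clusters[ib])] = (p_pair, corrected)

    results = []
    for j, gene in enumerate(carriers.genes):
        ok = bool(testable[j]) and np.isfinite(p_raw[j])
        p_b = bonferroni(float(p_raw[j]), n_testable) if ok else np.nan
        results.append(
            EnrichmentResult(
                gene=gene,
                f_statistic=float(F[j]) if ok else np.nan,
                p_raw=float(p_raw[j]) if ok else np.nan,
                p_bonferroni=p_b,
                testable=ok,
                flagged=bool(ok and p_b < alpha),
                pairwise={
                    pair: (float(praw[j]), float(pcorr[j]))
                    for pair, (praw, pcorr) in pair_results.items()
                },
            )
        )
    n_untestable = n_genes - n_testable
    if n_untestable:
        logger.info("%d genes had zero variance everywhere and were untestable", n_untestable)
    return results


def exact_multinomial_gof(observed: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p-value.

    Enumerates every composition of ``N = sum(observed)`` over the cells and
    sums the probabilities of all outcomes no more probable than the observed
    one. Feasible for the small tables this package meets (N <= ~30, k <= 6).
    """
    observed = np.asarray(observed, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if observed.ndim != 1 or observed.shape != probs.shape:
        raise ValueError("observed and probs must be 1-D and aligned")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("cell probabilities must sum to 1")
    n = int(observed.sum())
    k = len(observed)
    dist = stats.multinomial(n, probs)
    p_obs = dist.pmf(observed)

    def compositions(total: int, cells: int):
        if cells == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, cells - 1):
                yield (first, *rest)

    table = np.array(list(compositions(n, k)))
    pmf = dist.pmf(table)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def syndromic_distribution(
    labels: np.ndarray, syndromic_flags: np.ndarray
) -> tuple[pd.Series, float | None]:
    """Contingency of syndromic cases per cluster, tested against cluster sizes.

    Returns the per-cluster syndromic counts and a p-value (chi-square
    goodness-of-fit, or exact multinomial when any expected count is < 5).
    With zero syndromic cases the table is returned and the test skipped
    (p is None).
    """
    labels = np.asarray(labels)
    flags = np.asarray(syndromic_flags).astype(bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and syndromic flags must be aligned")
    clusters = sorted(np.unique(labels))
    sizes = np.array([np.count_nonzero(labels == c) for c in clusters], dtype=float)
    counts = np.array([np.count_nonzero(flags & (labels == c)) for c in clusters])
    table = pd.Series(counts, index=pd.Index(clusters, name="cluster"), name="syndromic")
    n_syn = int(counts.sum())
    if n_syn == 0:
        logger.info("no syndromic cases; distribution test skipped")
        return table, None
    probs = sizes / sizes.sum()
    expected = n_syn * probs
    if (expected < 5).any():
        p = exact_multinomial_gof(counts, probs)
    else:
        p = float(stats.chisquare(counts, f_exp=expected).pvalue)
    return table, p


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "gene": r.gene,
            "f_statistic": r.f_statistic,
            "p_raw": r.p_raw,
            "p_bonferroni": r.p_bonferroni,
            "testable": r.testable,
            "flagged": r.flagged,
        }
        for (a, b), (praw, pcorr) in r.pairwise.items():
            row[f"p_pair_{a}_{b}"] = praw
            row[f"p_pair_{a}_{b}_corrected"] = pcorr
        rows.append(row)
    return pd.DataFrame(rows)
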