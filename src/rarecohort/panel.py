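"""Gene panel handling and RVIS-based genic-intolerance weighting.

A panel entry carries, per gene, its RVIS percentile (rank of tolerance to
functional variation; low percentile = intolerant), the derived burden weight
``w = 1 - percentile/100``, the background carrier probability (fraction of
reference-population individuals carrying at least one qualifying rare variant
in the gene), and the chromosome the gene sits on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenePanelEntry",
    "rvis_weight",
    "read_panel",
    "write_panel",
    "synthetic_panel",
]

_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def rvis_weight(rvis_percentile: float) -> float:
    """Inverse-RVIS-percentile weight ``1 - percentile/100``.

    A gene at the 2nd percentile (highly intolerant) gets weight 0.98; the
    most tolerant gene (percentile 100) gets weight 0.

    Parameters
    ----------
    rvis_percentile : float
        RVIS percentile in the half-open interval (0, 100].

    Returns
    -------
    float
        Weight in [0, 1).
    """
    if not 0 < rvis_percentile <= 100:
        raise ValueError(
            f"RVIS percentile must be in (0, 100], got {rvis_percentile!r}"
        )
    return 1.0 - rvis_percentile / 100.0


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene of the panel."""

    gene: str
    rvis_percentile: float
    background_carrier_prob: float
    chromosome: str

    def __post_init__(self) -> None:
        rvis_weight(self.rvis_percentile)  # validates the range
        if not 0.0 <= self.background_carrier_prob <= 1.0:
            raise ValueError(
                f"background carrier probability must be in [0, 1], got "
                f"{self.background_carrier_prob!r} for {self.gene}"
            )

    @property
    def weight(self) -> float:
        return rvis_weight(self.rvis_percentile)


def read_panel(path: str | Path) -> list[GenePanelEntry]:
    """Read a panel TSV with columns gene, rvis_percentile, background_carrier_prob, chromosome."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "rvis_percentile", "background_carrier_prob", "chromosome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} is missing columns: {sorted(missing)}")
    return [
        GenePanelEntry(
            gene=str(r.gene),
            rvis_percentile=float(r.rvis_percentile),
            background_carrier_prob=float(r.background_carrier_prob),
            chromosome=str(r.chromosome),
        )
        for r in df.itertuples()
    ]


def write_panel(panel: Iterable[GenePanelEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": e.gene,
                "rvis_percentile": e.rvis_percentile,
                "background_carrier_prob": e.background_carrier_prob,
                "chromosome": e.chromosome,
            }
            for e in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def synthetic_panel(
    n_genes: int = 101,
    seed: int = 0,
    carrier_prob_range: tuple[float, float] = (0.01, 0.12),
) -> list[GenePanelEntry]:
    """Generate a synthetic gene panel.

    Gene symbols are GENE001..GENEnnn; RVIS percentiles are uniform on
    (0.5, 100]; background carrier probabilities uniform over
    ``carrier_prob_range`` (a few percent, the typical per-gene fraction of
    reference individuals carrying a rare functional variant); chromosomes
    cycle through chr1..chr22, chrX so X-linked handling is exercised.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = carrier_prob_range
    return [
        GenePanelEntry(
            gene=f"GENE{i + 1:03d}",
            rvis_percentile=float(np.round(rng.uniform(0.5, 100.0), 2)),
            background_carrier_prob=float(np.round(rng.uniform(lo, hi), 4)),
            chromosome=_CHROMOSOMES[i % len(_CHROMOSOMES)],
        )
        for i in range(n_genes)
    ]


def panel_genes(panel: Sequence[GenePanelEntry]) -> list[str]:
    return [e.gene for e in panel]
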