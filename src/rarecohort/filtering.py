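"""Variant loading and the quality / rarity / effect filter cascade.

The cascade mirrors a panel-sequencing analysis of a case-only cohort:

* quality: a call must have read depth > 10, mapping quality > 40 and
  quality-by-depth > 2 (strict inequalities);
* rarity: within the cohort the variant may appear in at most one homozygous
  (or hemizygous) and at most two heterozygous individuals, and every
  reference-population MAF that is present (1000G-EUR, ExAC, in-house) must be
  below 5%; a missing MAF counts as rare, since absence from the databases is
  the strongest rarity evidence;
* effect: frameshift, stop-gained and canonical-splice variants are
  loss-of-function; a missense variant is predicted damaging when CADD phred
  >= 20 or the meta-SVM label is "damaging".

Three cascade modes are exposed: ``rare_all`` (quality-passing, rare,
non-synonymous coding), ``rare_predicted_damaging`` (additionally LoF or
damaging missense) and ``known_pathogenic`` (ClinVar/HGMD-flagged,
quality-passing, regardless of prediction or rarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "HEMI",
    "MISSING",
    "AnnotatedVariant",
    "CarrierMatrix",
    "Cohort",
    "load_cohort",
    "read_annotations",
    "quality_pass",
    "is_rare",
    "effect_class",
    "filter_cascade",
    "FILTER_MODES",
]

# genotype codes
HOM_REF, HET, HOM_ALT, HEMI, MISSING = 0, 1, 2, 3, -1

#: coding consequences kept by the rare_all mode (everything non-synonymous)
NONSYNONYMOUS = frozenset(
    {"missense", "stop_gained", "frameshift", "canonical_splice", "inframe_indel"}
)
LOF_CONSEQUENCES = frozenset({"frameshift", "stop_gained", "canonical_splice"})

FILTER_MODES = ("rare_all", "rare_predicted_damaging", "known_pathogenic")

CADD_DAMAGING_THRESHOLD = 20.0
MAF_CUTOFF = 0.05
RD_MIN, MQ_MIN, QD_MIN = 10.0, 40.0, 2.0
MAX_HOM_CARRIERS, MAX_HET_CARRIERS = 1, 2


@dataclass
class AnnotatedVariant:
    """A bi-allelic variant site with annotations and per-sample genotypes.

    ``genotypes`` holds one integer code per cohort member (HOM_REF, HET,
    HOM_ALT, HEMI or MISSING), in the sample order of the source VCF.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: str
    maf_1000g_eur: float | None
    maf_exac: float | None
    maf_inhouse: float | None
    cadd_phred: float | None
    svm_label: str  # "damaging", "tolerated" or "missing"
    clinvar_flag: bool
    rd: float | None
    mq: float | None
    qd: float | None
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("maf_1000g_eur", "maf_exac", "maf_inhouse"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carrier_mask(self) -> np.ndarray:
        return np.isin(self.genotypes, (HET, HOM_ALT, HEMI))


@dataclass
class CarrierMatrix:
    """Individuals x genes matrix of qualifying rare-variant counts.

    A homozygous (or hemizygous) call counts as one variant carried, matching
    variant-level (not allele-level) accounting. Column order follows the
    panel order it was built against.
    """

    values: np.ndarray
    individuals: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.individuals), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.genes)} genes"
            )
        if (self.values < 0).any():
            raise ValueError("carrier matrix entries must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.genes)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="individual")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CarrierMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.int64), list(df.index.astype(str)), list(df.columns))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CarrierMatrix":
        return cls(df.to_numpy(dtype=np.int64), list(df.index.astype(str)), list(df.columns))

    def carrier_flags(self) -> np.ndarray:
        """Binary matrix: 1 iff the individual carries >= 1 qualifying variant."""
        return (self.values > 0).astype(np.int64)


@dataclass
class Cohort:
    """Parsed multi-sample VCF joined with its annotation table."""

    variants: list[AnnotatedVariant]
    samples: list[str]


# ---------------------------------------------------------------------------
# loading


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV (one row per variant-transcript)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {
        "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
        "maf_1000g_eur", "maf_exac", "maf_inhouse", "cadd_phred", "svm_label",
        "clinvar_flag",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} is missing columns: {sorted(missing)}")
    return df


def _canonical_rows(group: pd.DataFrame) -> pd.Series:
    """Pick one transcript row per variant: the canonical-tagged one when a
    ``canonical`` column exists, else the lexicographically first transcript."""
    if "canonical" in group.columns:
        tagged = group[group["canonical"].astype(bool)]
        if len(tagged):
            group = tagged
    if len(group) > 1:
        logger.info(
            "variant %s:%s has %d transcript rows; keeping first by transcript id",
            group.iloc[0]["chrom"], group.iloc[0]["pos"], len(group),
        )
    return group.sort_values("transcript").iloc[0]


def _genotype_code(gt: tuple, alt_index: int) -> int:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    hits = sum(a == alt_index for a in alleles)
    if len(alleles) == 1:
        return HEMI if hits else HOM_REF
    if hits == 0:
        return HOM_REF
    if hits == len(alleles):
        return HOM_ALT
    return HET


def _opt_float(v) -> float | None:
    if v is None:
        return None
    try:
        if pd.isna(v):
            return None
    except (TypeError, ValueError):
        pass
    return float(v)


def load_cohort(vcf_path: str | Path, annotation_path: str | Path) -> Cohort:
    """Parse a multi-sample VCF and join the annotation table.

    Multi-allelic records are decomposed into bi-allelic entries (the filter
    rules are per-allele). Records with no matching annotation row are dropped
    with a logged count.
    """
    ann = read_annotations(annotation_path)
    ann_by_key: dict[tuple, pd.Series] = {}
    for key, group in ann.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        ann_by_key[key] = _canonical_rows(group)

    variants: list[AnnotatedVariant] = []
    n_unannotated = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            rd = _opt_float(info.get("RD"))
            mq = _opt_float(info.get("MQ"))
            qd = _opt_float(info.get("QD"))
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                key = (rec.chrom, rec.pos, rec.ref, alt)
                row = ann_by_key.get(key)
                if row is None:
                    n_unannotated += 1
                    continue
                genotypes = np.array(
                    [
                        _genotype_code(rec.samples[s].get("GT", (None,)), alt_index)
                        for s in samples
                    ],
                    dtype=np.int8,
                )
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(row["gene"]),
                        transcript=str(row["transcript"]),
                        consequence=str(row["consequence"]),
                        maf_1000g_eur=_opt_float(row["maf_1000g_eur"]),
                        maf_exac=_opt_float(row["maf_exac"]),
                        maf_inhouse=_opt_float(row["maf_inhouse"]),
                        cadd_phred=_opt_float(row["cadd_phred"]),
                        svm_label=(
                            "missing" if pd.isna(row["svm_label"]) else str(row["svm_label"])
                        ),
                        clinvar_flag=bool(int(row["clinvar_flag"])),
                        rd=rd,
                        mq=mq,
                        qd=qd,
                        genotypes=genotypes,
                    )
                )
    if n_unannotated:
        logger.warning("%d VCF alleles had no annotation row and were dropped", n_unannotated)
    return Cohort(variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# filter predicates


def quality_pass(v: AnnotatedVariant) -> bool:
    """True iff RD > 10 and MQ > 40 and QD > 2 (strict).

    A missing quality field rejects the variant with a logged warning.
    """
    if v.rd is None or v.mq is None or v.qd is None:
        logger.warning(
            "variant %s:%d %s>%s rejected: missing quality field", v.chrom, v.pos, v.ref, v.alt
        )
        return False
    return v.rd > RD_MIN and v.mq > MQ_MIN and v.qd > QD_MIN


def is_rare(v: AnnotatedVariant) -> bool:
    """True iff the variant is rare both in the cohort and in the references.

    Cohort rule: at most one homozygous-or-hemizygous carrier AND at most two
    heterozygous carriers (hemizygous calls count in the homozygous cap).
    Reference rule: each MAF that is present must be < 0.05; missing MAFs pass.
    """
    g = v.genotypes
    n_hom = int(np.count_nonzero((g == HOM_ALT) | (g == HEMI)))
    n_het = int(np.count_nonzero(g == HET))
    if n_hom > MAX_HOM_CARRIERS or n_het > MAX_HET_CARRIERS:
        return False
    for maf in (v.maf_1000g_eur, v.maf_exac, v.maf_inhouse):
        if maf is not None and not maf < MAF_CUTOFF:
            return False
    return True


def effect_class(v: AnnotatedVariant) -> str:
    """Classify into ``lof``, ``damaging_missense`` or ``other``."""
    if v.consequence in LOF_CONSEQUENCES:
        return "lof"
    if v.consequence == "missense":
        cadd_hit = v.cadd_phred is not None and v.cadd_phred >= CADD_DAMAGING_THRESHOLD
        if cadd_hit or v.svm_label == "damaging":
            return "damaging_missense"
    return "other"


# ---------------------------------------------------------------------------
# cascade


def _mode_keep(v: AnnotatedVariant, mode: str) -> bool:
    if mode == "known_pathogenic":
        return v.clinvar_flag
    if v.consequence not in NONSYNONYMOUS:
        return False
    if not is_rare(v):
        return False
    if mode == "rare_predicted_damaging":
        return effect_class(v) in ("lof", "damaging_missense")
    return True  # rare_all


def filter_cascade(
    variants: Iterable[AnnotatedVariant],
    samples: Sequence[str],
    panel_genes: Sequence[str],
    mode: str = "rare_all",
) -> tuple[list[AnnotatedVariant], CarrierMatrix]:
    """Apply the filter cascade and count qualifying variants per individual per gene.

    Returns the qualifying variants and the CarrierMatrix (columns in panel
    order). Variants annotated to genes outside the panel are excluded with a
    logged count; stage-by-stage drop counts are logged as the audit trail.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; expected one of {FILTER_MODES}")
    gene_index = {g: j for j, g in enumerate(panel_genes)}
    counts = np.zeros((len(samples), len(panel_genes)), dtype=np.int64)
    qualifying: list[AnnotatedVariant] = []
    n_total = n_quality = n_off_panel = n_filtered = 0
    for v in variants:
        n_total += 1
        if not quality_pass(v):
            n_quality += 1
            continue
        j = gene_index.get(v.gene)
        if j is None:
            n_off_panel += 1
            continue
        if not _mode_keep(v, mode):
            n_filtered += 1
            continue
        qualifying.append(v)
        counts[v.carrier_mask(), j] += 1
    logger.info(
        "filter cascade (%s): %d variants in, %d failed quality, %d off-panel, "
        "%d failed %s rules, %d qualifying",
        mode, n_total, n_quality, n_off_panel, n_filtered, mode, len(qualifying),
    )
    return qualifying, CarrierMatrix(counts, list(samples), list(panel_genes))
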