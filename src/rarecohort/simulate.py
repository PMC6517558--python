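"""Synthetic cohort generation.

Emulates the study design the downstream statistics assume: a case-only
cohort (by default 164 unrelated individuals plus 5 sib-pairs, i.e. 174
cases) sequenced over a 101-gene panel, where each individual carries a
qualifying rare variant in gene *g* with a per-gene background probability
``p_g`` (optionally inflated for a few planted enriched genes); a binarized
clinical questionnaire of ~149 items drawn from a Bernoulli mixture with
planted phenotype clusters; and a phenotype table (ADOS severity linked
linearly to variant burden, minor-malformation counts, sex, syndromic flags).

The generator writes a VCF v4.2 plus annotation TSV that round-trip through
:mod:`rarecohort.filtering` to reproduce its own carrier matrix exactly; all
simulated variants are heterozygous SNVs at distinct positions (one variant
per carrier event), annotated as damaging missense so the same matrix is
recovered under both rare-variant cascade modes. Quality fields pass the
filter by default; failing, synonymous or common records can be injected to
exercise the cascade, and those never enter the carrier matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .filtering import CarrierMatrix
from .panel import GenePanelEntry

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSpec",
    "PhenotypeLink",
    "SimulationConfig",
    "SimulatedGenotypes",
    "simulate_genotypes",
    "simulate_questionnaire",
    "simulate_phenotypes",
    "default_cluster_spec",
]

_CONTIG_LENGTH = 250_000_000


@dataclass
class ClusterSpec:
    """Bernoulli-mixture specification of the questionnaire clusters.

    ``feature_probs[c, j]`` is the probability that a member of cluster ``c``
    answers item ``j`` positively.
    """

    k: int
    sizes: list[int]
    feature_probs: np.ndarray
    item_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("cluster count k must be >= 1")
        if len(self.sizes) != self.k:
            raise ValueError(f"expected {self.k} cluster sizes, got {len(self.sizes)}")
        if any(s < 0 for s in self.sizes):
            raise ValueError("cluster sizes must be non-negative")
        self.feature_probs = np.asarray(self.feature_probs, dtype=float)
        if self.feature_probs.shape[0] != self.k:
            raise ValueError("feature_probs must have one row per cluster")
        if ((self.feature_probs < 0) | (self.feature_probs > 1)).any():
            raise ValueError("feature probabilities must be in [0, 1]")
        if self.item_labels is None:
            self.item_labels = [f"item_{j + 1:03d}" for j in range(self.feature_probs.shape[1])]

    @property
    def n_items(self) -> int:
        return self.feature_probs.shape[1]

    @property
    def n_individuals(self) -> int:
        return int(sum(self.sizes))


def default_cluster_spec(
    n_individuals: int = 174,
    k: int = 4,
    n_items: int = 149,
    n_discriminative: int = 30,
    p_high: float = 0.9,
    p_low: float = 0.1,
    p_background: float = 0.3,
    pattern_seed: int = 0,
) -> ClusterSpec:
    """Cluster spec with per-cluster 0.1/0.9 profiles over the discriminative items.

    Each cluster gets its own pattern over the first ``n_discriminative``
    items: every such item is answered positively with either ``p_high`` or
    ``p_low`` depending on the cluster (an independent fair coin per cluster
    and item, fixed by ``pattern_seed``). Remaining items are
    undiscriminative background at ``p_background``. This is the
    strong-separation regime: any two clusters disagree on about half of the
    discriminative items.
    """
    base = n_individuals // k
    sizes = [base + (1 if c < n_individuals % k else 0) for c in range(k)]
    probs = np.full((k, n_items), p_background)
    rng = np.random.default_rng(pattern_seed)
    pattern = rng.random((k, n_discriminative)) < 0.5
    probs[:, :n_discriminative] = np.where(pattern, p_high, p_low)
    return ClusterSpec(k=k, sizes=sizes, feature_probs=probs)


@dataclass
class PhenotypeLink:
    """Linear link of ADOS raw total on rare-variant burden."""

    slope: float = 0.0
    intercept: float = 20.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise SD must be >= 0, got {self.noise_sd}")


@dataclass
class SimulationConfig:
    """Everything the genotype simulator needs; fixed seed => bit-identical output."""

    panel: list[GenePanelEntry]
    n_unrelated: int = 164
    n_sibpairs: int = 5
    enrichment_multipliers: dict[str, float] = field(default_factory=dict)
    cluster_spec: ClusterSpec | None = None
    phenotype_link: PhenotypeLink | None = None
    seed: int = 0
    n_quality_fail: int = 0
    n_synonymous: int = 0
    n_common: int = 0

    def __post_init__(self) -> None:
        if self.n_unrelated < 0 or self.n_sibpairs < 0:
            raise ValueError("cohort sizes must be non-negative")
        genes = {e.gene for e in self.panel}
        for gene, mult in self.enrichment_multipliers.items():
            if gene not in genes:
                raise ValueError(f"enrichment multiplier for unknown gene {gene!r}")
            if mult < 1:
                raise ValueError(f"enrichment multiplier must be >= 1, got {mult} for {gene}")
        for e in self.panel:
            p = self.effective_prob(e)
            if p > 1:
                raise ValueError(
                    f"carrier probability x multiplier = {p} > 1 for gene {e.gene}"
                )

    def effective_prob(self, entry: GenePanelEntry) -> float:
        return entry.background_carrier_prob * self.enrichment_multipliers.get(entry.gene, 1.0)

    @property
    def sample_ids(self) -> list[str]:
        ids = [f"U{i + 1:04d}" for i in range(self.n_unrelated)]
        for f in range(self.n_sibpairs):
            ids += [f"SP{f + 1:02d}A", f"SP{f + 1:02d}B"]
        return ids

    @property
    def sib_pairs(self) -> list[tuple[str, str]]:
        return [(f"SP{f + 1:02d}A", f"SP{f + 1:02d}B") for f in range(self.n_sibpairs)]


@dataclass
class SimulatedGenotypes:
    vcf_path: Path
    annotation_path: Path
    carriers: CarrierMatrix
    samples: list[str]
    sib_pairs: list[tuple[str, str]]


def _vcf_header(samples: list[str], contigs: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig, length=_CONTIG_LENGTH)
    header.info.add("RD", 1, "Integer", "Read depth at the site")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("QD", 1, "Float", "Quality by depth")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    return header


def simulate_genotypes(config: SimulationConfig, out_dir: str | Path) -> SimulatedGenotypes:
    """Draw carrier events, write VCF + annotation TSV, return the true carrier matrix.

    Unrelated individual *i* carries one qualifying rare variant in gene *g*
    with probability ``p_g x multiplier_g`` (independent across genes and
    individuals). Each sib-pair has, with the same probability, one
    heterozygous carrier parent whose variant each sib inherits independently
    with probability 1/2; a record is emitted for every inheriting sib, so a
    "shared" event (both inherit) shows the same site heterozygous in both.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    samples = config.sample_ids
    sample_index = {s: i for i, s in enumerate(samples)}
    genes = [e.gene for e in config.panel]
    counts = np.zeros((len(samples), len(genes)), dtype=np.int64)

    # records: (contig_order, pos, contig, ref, alt, rd, mq, qd, het_sample_idx, ann_row)
    records: list[tuple] = []
    contigs = sorted({e.chromosome for e in config.panel}, key=_contig_sort_key)
    contig_order = {c: i for i, c in enumerate(contigs)}

    def passing_quality() -> tuple[int, float, float]:
        return (
            int(rng.integers(60, 200)),
            float(np.round(rng.uniform(50.0, 60.0), 2)),
            float(np.round(rng.uniform(5.0, 30.0), 2)),
        )

    def annotation(gene: str, consequence: str = "missense", *, cadd: float | None = None,
                   maf: float = 0.0, clinvar: int = 0) -> dict:
        if cadd is None:
            cadd = float(np.round(rng.uniform(21.0, 40.0), 1))
        return {
            "gene": gene,
            "transcript": f"{gene}-T1",
            "consequence": consequence,
            "maf_1000g_eur": maf,
            "maf_exac": maf,
            "maf_inhouse": maf,
            "cadd_phred": cadd,
            "svm_label": "damaging" if consequence == "missense" else "missing",
            "clinvar_flag": clinvar,
        }

    event_counter = {g: 0 for g in genes}

    def new_site(gene_idx: int) -> tuple[str, int]:
        gene = genes[gene_idx]
        event_counter[gene] += 1
        pos = (gene_idx + 1) * 1_000_000 + event_counter[gene] * 10
        return config.panel[gene_idx].chromosome, pos

    for j, entry in enumerate(config.panel):
        p = config.effective_prob(entry)
        # unrelated carriers
        carrier_draws = rng.random(config.n_unrelated) < p
        for i in np.flatnonzero(carrier_draws):
            chrom, pos = new_site(j)
            rd, mq, qd = passing_quality()
            records.append((contig_order[chrom], pos, chrom, rd, mq, qd, [int(i)],
                            annotation(entry.gene)))
            counts[i, j] += 1
        # sib-pairs: carrier parent, each sib inherits w.p. 0.5
        for a, b in config.sib_pairs:
            if rng.random() >= p:
                continue
            inherit = rng.random(2) < 0.5
            carriers_idx = [sample_index[s] for s, inh in zip((a, b), inherit) if inh]
            if not carriers_idx:
                continue
            chrom, pos = new_site(j)
            rd, mq, qd = passing_quality()
            records.append((contig_order[chrom], pos, chrom, rd, mq, qd, carriers_idx,
                            annotation(entry.gene)))
            for i in carriers_idx:
                counts[i, j] += 1

    # injected records never enter the carrier matrix
    n_inject = config.n_quality_fail + config.n_synonymous + config.n_common
    for inject_i in range(n_inject):
        j = int(rng.integers(len(genes)))
        chrom, pos = new_site(j)
        rd, mq, qd = passing_quality()
        carrier = [int(rng.integers(len(samples)))]
        ann = annotation(genes[j])
        if inject_i < config.n_quality_fail:
            which = inject_i % 3  # cycle through failing RD / MQ / QD
            if which == 0:
                rd = int(rng.integers(0, 11))
            elif which == 1:
                mq = float(np.round(rng.uniform(0.0, 40.0), 2))
            else:
                qd = float(np.round(rng.uniform(0.0, 2.0), 2))
        elif inject_i < config.n_quality_fail + config.n_synonymous:
            ann = annotation(genes[j], consequence="synonymous")
        else:
            # common: three heterozygous cohort carriers (or a high MAF)
            if len(samples) >= 3:
                carrier = sorted(rng.choice(len(samples), size=3, replace=False).tolist())
            else:
                ann = annotation(genes[j], maf=0.2)
        records.append((contig_order[chrom], pos, chrom, rd, mq, qd, carrier, ann))

    records.sort(key=lambda r: (r[0], r[1]))

    vcf_path = out_dir / "cohort.vcf"
    ann_rows = []
    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for _, pos, chrom, rd, mq, qd, het_idx, ann in records:
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=("A", "G"))
            rec.info["RD"] = rd
            rec.info["MQ"] = mq
            rec.info["QD"] = qd
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (0, 1) if i in het_idx else (0, 0)
            vcf.write(rec)
            ann_rows.append({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G", **ann})

    annotation_path = out_dir / "annotations.tsv"
    pd.DataFrame(
        ann_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
                 "maf_1000g_eur", "maf_exac", "maf_inhouse", "cadd_phred", "svm_label",
                 "clinvar_flag"],
    ).to_csv(annotation_path, sep="\t", index=False)

    logger.info("simulated %d variant records for %d samples", len(records), len(samples))
    return SimulatedGenotypes(
        vcf_path=vcf_path,
        annotation_path=annotation_path,
        carriers=CarrierMatrix(counts, samples, genes),
        samples=samples,
        sib_pairs=config.sib_pairs,
    )


def _contig_sort_key(c: str):
    body = c.removeprefix("chr")
    return (0, int(body)) if body.isdigit() else (1, body)


def simulate_questionnaire(
    spec: ClusterSpec, seed: int, ids: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the binary questionnaire matrix from the Bernoulli mixture.

    Returns the individuals x items 0/1 DataFrame and the true cluster labels
    (0-based), for recovery testing.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(spec.k), spec.sizes)
    X = (rng.random((len(labels), spec.n_items)) < spec.feature_probs[labels]).astype(np.int64)
    if ids is None:
        ids = [f"I{i + 1:04d}" for i in range(len(labels))]
    if len(ids) != len(labels):
        raise ValueError(
            f"got {len(ids)} ids for a cluster spec of {len(labels)} individuals"
        )
    return pd.DataFrame(X, index=ids, columns=spec.item_labels), labels


def simulate_phenotypes(
    burden: pd.Series,
    link: PhenotypeLink,
    seed: int,
    male_fraction: float = 129 / 174,
    malformation_mean: float = 5.0,
    syndromic_rate: float = 13 / 174,
    screen_detected_rate: float = 4 / 13,
) -> pd.DataFrame:
    """Phenotype table aligned with a burden vector.

    ADOS raw total is ``intercept + slope * burden + N(0, noise_sd)``;
    minor-malformation counts are Poisson; sex is Bernoulli at the cohort's
    male fraction; ages are ``2 + Poisson(4)`` years (child cohort, median ~6);
    a random subset is flagged syndromic, of which a fraction was detected by
    a screening assay rather than panel sequencing. Family ids are derived
    from the sib-pair naming scheme (``SPnnA``/``SPnnB``).
    """
    if link.noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(burden)
    ados = link.intercept + link.slope * burden.to_numpy(dtype=float)
    if link.noise_sd > 0:
        ados = ados + rng.normal(0.0, link.noise_sd, size=n)
    syndromic = rng.random(n) < syndromic_rate
    screen = syndromic & (rng.random(n) < screen_detected_rate)
    ids = list(burden.index.astype(str))
    family = [i[:-1] if i.startswith("SP") and i[-1] in "AB" else i for i in ids]
    return pd.DataFrame(
        {
            "individual": ids,
            "sex": np.where(rng.random(n) < male_fraction, "M", "F"),
            "family_id": family,
            "age": 2 + rng.poisson(4.0, size=n),
            "ados_raw": ados,
            "malformations": rng.poisson(malformation_mean, size=n),
            "syndromic": syndromic.astype(int),
            "screen_detected": screen.astype(int),
        }
    ).set_index("individual")
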