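"""Recessive-disease variant filtering and prioritization.

The cascade reduces a few thousand called variants per sample down to
candidate pathogenic alleles in successive stages — allele-fraction
detection threshold, panel genes, protein-affecting classes ("NS/SS"),
population-frequency exclusion (dbSNP / in-house above 2%), disease genes,
and finally a "pathogenic clue": truncating classes are pathogenic outright,
missense needs a quorum of damaging in-silico predictor verdicts.

Survivors are then combined with read-depth deletion calls under a
recessive mode of inheritance: two hits in one disease gene (homozygous
point variant, compound heterozygous pair, het point variant over a het
deletion, or a homozygous deletion) make a biallelic finding; a single hit
escalates the gene's intronic/UTR variants for manual inspection — the
route by which deep-intronic second alleles are found.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .coverage_cnv import DeletionCall
from .variant_annotation import AnnotatedVariant, CODING_EFFECTS

__all__ = [
    "CascadeConfig",
    "FilterReport",
    "GeneFinding",
    "FA_GENES",
    "STAGES",
    "af_filter",
    "clue_score",
    "run_cascade",
    "recessive_prioritize",
    "report",
    "write_funnel_tsv",
    "write_report_json",
]

#: the 15 Fanconi anemia genes (complementation groups A–P)
FA_GENES = (
    "FANCA", "FANCB", "FANCC", "BRCA2", "FANCD2", "FANCE", "FANCF", "FANCG",
    "FANCI", "BRIP1", "FANCL", "FANCM", "PALB2", "RAD51C", "SLX4",
)

#: funnel stages, in order
STAGES = ("total", "on_target_genes", "ns_ss", "not_in_dbsnp", "disease_genes", "pathogenic_clue")


@dataclass
class CascadeConfig:
    """Thresholds of the filtering cascade.

    Defaults: variants are detected at >= 31% of covering reads (12% when
    screening for mosaicism), and known variants above 2% population or
    in-house frequency are excluded. A missense needs ``predictor_quorum``
    damaging verdicts to count as a pathogenic clue.
    """

    min_allele_fraction: float = 0.31
    mosaic_min_allele_fraction: float = 0.12
    max_population_frequency: float = 0.02
    panel_genes: tuple[str, ...] = FA_GENES
    disease_genes: tuple[str, ...] = FA_GENES
    predictor_quorum: int = 2
    hom_allele_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.mosaic_min_allele_fraction <= self.min_allele_fraction <= 1:
            raise ValueError("require 0 < mosaic_min_allele_fraction <= min_allele_fraction <= 1")
        if not 0 <= self.max_population_frequency <= 1:
            raise ValueError("max_population_frequency must be in [0,1]")
        unknown = set(self.disease_genes) - set(self.panel_genes)
        if unknown:
            raise ValueError(f"disease genes not on panel: {sorted(unknown)}")


@dataclass
class FilterReport:
    """Per-stage survivor counts and variants, in funnel order."""

    counts: dict[str, int]
    survivors: dict[str, list[AnnotatedVariant]]

    def __post_init__(self) -> None:
        ordered = [self.counts[s] for s in STAGES]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("stage counts must be non-increasing")

    @property
    def final(self) -> list[AnnotatedVariant]:
        return self.survivors[STAGES[-1]]


@dataclass
class GeneFinding:
    """Recessive-model conclusion for one disease gene in one sample."""

    gene: str
    status: str  # biallelic | one_allele | none
    allele1: AnnotatedVariant | DeletionCall | None = None
    allele2: AnnotatedVariant | DeletionCall | None = None
    phase: str = ""  # "hom", "compound (phase unknown)", "point+deletion", "hom deletion"
    escalation: bool = False
    escalation_candidates: list[AnnotatedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("biallelic", "one_allele", "none"):
            raise ValueError(f"unknown status {self.status!r}")
        n_alleles = sum(x is not None for x in (self.allele1, self.allele2))
        if self.status == "biallelic" and n_alleles != 2:
            raise ValueError("biallelic finding requires two alleles")
        if self.escalation != (self.status == "one_allele"):
            raise ValueError("escalation is set iff status is one_allele")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def af_filter(
    variants: Sequence[AnnotatedVariant],
    config: CascadeConfig = CascadeConfig(),
    mosaic_mode: bool = False,
) -> list[AnnotatedVariant]:
    """Detection threshold on allele fraction: keep variants at or above 31%
    of covering reads (12% in mosaic mode); pseudogene-flagged variants
    bypass the threshold because their AF is expected to be diluted."""
    threshold = config.mosaic_min_allele_fraction if mosaic_mode else config.min_allele_fraction
    return [v for v in variants if v.pseudogene_flag or v.allele_fraction >= threshold]


def clue_score(variant: AnnotatedVariant, quorum: int = 2) -> tuple[bool, str]:
    """Is this variant a pathogenic clue?

    Truncating classes (frameshift, stopgain, canonical splice) are clues by
    themselves; a nonsynonymous variant is a clue when at least ``quorum``
    predictors call it damaging; everything else is not a clue.
    """
    if variant.effect_class in ("frameshift", "stopgain", "canonical_splice"):
        return True, "truncating"
    if variant.effect_class == "nonsynonymous":
        n = variant.n_damaging
        if n >= quorum:
            return True, f"predicted damaging ({n}/{len(variant.predictor_verdicts)})"
        return False, f"insufficient predictor support ({n}/{len(variant.predictor_verdicts)})"
    return False, f"effect class {variant.effect_class}"


def _passes_frequency(v: AnnotatedVariant, cutoff: float) -> bool:
    """Absent from a database counts as novel and passes."""
    for f in (v.dbsnp_frequency, v.inhouse_frequency):
        if f is not None and f > cutoff:
            return False
    return True


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    config: CascadeConfig = CascadeConfig(),
) -> FilterReport:
    """Apply the filtering funnel to one sample's annotated variants.

    Stages, in order: (1) all variants; (2) in panel genes; (3) protein-
    affecting classes (nonsynonymous, stopgain, frameshift, in-frame indel,
    canonical splice); (4) population frequency absent or <= cutoff in both
    dbSNP and the in-house database; (5) disease genes; (6) pathogenic clue.
    """
    panel = set(config.panel_genes)
    disease = set(config.disease_genes)
    stage_sets: dict[str, list[AnnotatedVariant]] = {}
    current = list(variants)
    stage_sets["total"] = current
    current = [v for v in current if v.gene in panel and v.effect_class != "intergenic"]
    stage_sets["on_target_genes"] = current
    current = [v for v in current if v.effect_class in CODING_EFFECTS]
    stage_sets["ns_ss"] = current
    current = [v for v in current if _passes_frequency(v, config.max_population_frequency)]
    stage_sets["not_in_dbsnp"] = current
    current = [v for v in current if v.gene in disease]
    stage_sets["disease_genes"] = current
    current = [v for v in current if clue_score(v, config.predictor_quorum)[0]]
    stage_sets["pathogenic_clue"] = current
    return FilterReport({s: len(stage_sets[s]) for s in STAGES}, stage_sets)


# ---------------------------------------------------------------------------
# recessive prioritization
# ---------------------------------------------------------------------------


def _deletion_in_gene(calls: Sequence[DeletionCall], gene: str) -> list[DeletionCall]:
    return [c for c in calls if c.gene == gene]


def recessive_prioritize(
    survivors: Sequence[AnnotatedVariant],
    deletion_calls: Sequence[DeletionCall],
    all_annotated: Sequence[AnnotatedVariant],
    config: CascadeConfig = CascadeConfig(),
) -> list[GeneFinding]:
    """Combine clue variants and deletion calls per disease gene.

    Biallelic: homozygous clue variant (AF >= ``hom_allele_fraction``); two
    heterozygous clue variants (compound, phase unknown); one heterozygous
    clue variant plus an overlapping deletion call; or a homozygous deletion
    alone. One hit alone (het clue variant, or a het/mosaic deletion) yields
    one_allele with an escalation list of the gene's intronic/UTR variants
    that are absent from the frequency databases.
    """
    findings: list[GeneFinding] = []
    for gene in config.disease_genes:
        gene_vars = sorted(
            (v for v in survivors if v.gene == gene), key=lambda v: v.pos
        )
        dels = _deletion_in_gene(deletion_calls, gene)
        hom_dels = [d for d in dels if d.zygosity_class == "hom"]
        het_dels = [d for d in dels if d.zygosity_class in ("het", "mosaic")]
        homs = [v for v in gene_vars if v.allele_fraction >= config.hom_allele_fraction]
        hets = [v for v in gene_vars if v not in homs]

        if homs:
            findings.append(GeneFinding(gene, "biallelic", homs[0], homs[0], phase="hom"))
        elif len(hets) >= 2:
            findings.append(
                GeneFinding(gene, "biallelic", hets[0], hets[1], phase="compound (phase unknown)")
            )
        elif len(hets) == 1 and het_dels:
            findings.append(
                GeneFinding(gene, "biallelic", hets[0], het_dels[0], phase="point+deletion")
            )
        elif hom_dels:
            findings.append(
                GeneFinding(gene, "biallelic", hom_dels[0], hom_dels[0], phase="hom deletion")
            )
        elif len(hets) == 1 or het_dels:
            allele = hets[0] if hets else het_dels[0]
            candidates = sorted(
                (
                    v
                    for v in all_annotated
                    if v.gene == gene
                    and v.effect_class in ("intronic", "utr5", "utr3")
                    and v.dbsnp_frequency is None
                    and v.inhouse_frequency is None
                ),
                key=lambda v: v.pos,
            )
            findings.append(
                GeneFinding(
                    gene,
                    "one_allele",
                    allele,
                    None,
                    escalation=True,
                    escalation_candidates=candidates,
                )
            )
        else:
            findings.append(GeneFinding(gene, "none"))
    return findings


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_FUNNEL_HEADER = [
    "sample", "variants_total", "variants_target_genes", "ns_ss", "not_in_dbsnp",
    "disease_genes", "pathogenic_clue",
]


def _allele_dict(allele) -> dict | None:
    if allele is None:
        return None
    if isinstance(allele, DeletionCall):
        return {
            "type": "deletion",
            "gene": allele.gene,
            "first_exon": allele.first_exon,
            "last_exon": allele.last_exon,
            "class": allele.zygosity_class,
            "mean_M": round(allele.mean_M, 4),
            "mosaic_fraction": None if allele.mosaic_fraction is None else round(allele.mosaic_fraction, 4),
        }
    v = allele.variant
    return {
        "type": "variant",
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "gene": allele.gene,
        "effect": allele.effect_class,
        "hgvs_c": allele.hgvs_c,
        "protein_change": allele.protein_change,
        "allele_fraction": round(v.allele_fraction, 4),
    }


def report(
    findings: Sequence[GeneFinding],
    filter_report: FilterReport,
    deletion_calls: Sequence[DeletionCall],
    sample_id: str = "",
) -> dict:
    """Machine-readable per-sample summary with deterministic ordering."""
    return {
        "sample": sample_id,
        "funnel": {s: filter_report.counts[s] for s in STAGES},
        "deletion_calls": [
            _allele_dict(c) for c in sorted(deletion_calls, key=lambda c: (c.gene, c.first_exon))
        ],
        "findings": [
            {
                "gene": f.gene,
                "status": f.status,
                "phase": f.phase,
                "allele1": _allele_dict(f.allele1),
                "allele2": _allele_dict(f.allele2),
                "escalation": f.escalation,
                "escalation_candidates": [_allele_dict(v) for v in f.escalation_candidates],
            }
            for f in sorted(findings, key=lambda f: f.gene)
        ],
    }


def write_report_json(path: str | Path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


def write_funnel_tsv(path: str | Path, reports: Mapping[str, FilterReport]) -> None:
    """Funnel counts for a cohort, one row per sample."""
    with open(path, "w") as fh:
        fh.write("\t".join(_FUNNEL_HEADER) + "\n")
        for sample in sorted(reports):
            counts = reports[sample].counts
            fh.write(sample + "\t" + "\t".join(str(counts[s]) for s in STAGES) + "\n")
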