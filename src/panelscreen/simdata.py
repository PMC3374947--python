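"""Seeded synthetic capture-cohort generator with ground truth.

Emulates a multiplexed capture-panel sequencing run over the Fanconi anemia
genes: gene models with realistic exon counts (including a 43-exon FANCA-like
and a 38-exon FANCI-like gene), capture targets (exons ± flanks), per-base
Poisson depth with per-target capture-efficiency variation shared across
samples (capture bias is bait-driven, which is what lets a pooled reference
cancel it), spiked heterozygous/homozygous/mosaic deletions, equimolar sample
mixtures, and per-sample variant tables with effect classes, population
frequencies and predictor verdicts.

Everything is deterministic given the spec and seed: identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .formats_io import (
    DepthTrack,
    FrequencyTable,
    GeneModel,
    TargetRegion,
    VariantRecord,
    write_bed,
    write_depth_table,
    write_fasta,
    write_frequency_table,
    write_predictor_table,
    write_refflat,
    write_vcf,
)
from .prioritization import FA_GENES, CascadeConfig
from .variant_annotation import grantham_surrogate_verdict

__all__ = [
    "PlantedDeletion",
    "PlantedVariant",
    "CohortSpec",
    "Panel",
    "Sample",
    "TruthSet",
    "Cohort",
    "make_panel",
    "planted_records",
    "build_mosaic_mixture_tracks",
    "simulate_depth",
    "simulate_variants",
    "mix_samples",
    "simulate_cohort",
    "write_cohort",
]

#: exon counts for the FA gene roster (panel disease genes, realistic shapes:
#: FANCA has 43 exons, FANCI 38) plus two non-disease panel genes.
FA_EXON_COUNTS: dict[str, int] = {
    "FANCA": 43,
    "FANCB": 10,
    "FANCC": 15,
    "BRCA2": 27,
    "FANCD2": 44,
    "FANCE": 10,
    "FANCF": 1,
    "FANCG": 14,
    "FANCI": 38,
    "BRIP1": 20,
    "FANCL": 14,
    "FANCM": 23,
    "PALB2": 13,
    "RAD51C": 9,
    "SLX4": 15,
}
EXTRA_PANEL_GENES: dict[str, int] = {"BRCA1": 23, "ATM": 26}

_PREDICTORS = ("Align-GVGD", "PolyPhen-2", "SIFT")
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PlantedDeletion:
    sample: str
    gene: str
    first_exon: int
    last_exon: int
    genotype: str  # het_del | hom_del
    mosaic_fraction: float | None = None  # fraction of genomes carrying a het deletion

    def __post_init__(self) -> None:
        if self.genotype not in ("het_del", "hom_del"):
            raise ValueError(f"unknown genotype {self.genotype}")
        if self.first_exon > self.last_exon:
            raise ValueError("first_exon must be <= last_exon")

    @property
    def copy_number(self) -> float:
        if self.genotype == "hom_del":
            return 0.0
        if self.mosaic_fraction is not None:
            return 2.0 - self.mosaic_fraction
        return 1.0


@dataclass(frozen=True)
class PlantedVariant:
    sample: str
    gene: str
    vclass: str  # missense_damaging | missense_benign | stopgain | frameshift | splice | deep_intronic
    zygosity: str = "het"  # het | hom
    population_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.vclass not in (
            "missense_damaging", "missense_benign", "stopgain", "frameshift", "splice", "deep_intronic",
        ):
            raise ValueError(f"unknown variant class {self.vclass}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity}")

    @property
    def is_clue(self) -> bool:
        return self.vclass in ("missense_damaging", "stopgain", "frameshift", "splice")


@dataclass
class CohortSpec:
    """Study conditions of a simulated capture run.

    Defaults mirror a multiplexed diagnostic run: 11 pooled libraries at
    ~100× per-base depth over the 15 FA genes, lognormal per-target capture
    efficiency (sigma 0.3) shared across samples, and ~2500 background
    variants per sample.
    """

    seed: int = 0
    n_samples: int = 11
    mean_depth: float = 100.0
    n_genes: int = 15
    efficiency_sigma: float = 0.3
    target_flank: int = 50
    exon_length_range: tuple[int, int] = (80, 250)
    intron_length_range: tuple[int, int] = (500, 2000)
    n_background_variants: int = 2500
    planted_deletions: list[PlantedDeletion] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    #: the capture design is fixed per lab; set this to reuse one panel
    #: across noise replicates that vary only ``seed``
    panel_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 1 <= self.n_genes <= len(FA_EXON_COUNTS):
            raise ValueError(f"n_genes must be in 1..{len(FA_EXON_COUNTS)}")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class Panel:
    models: list[GeneModel]
    targets: list[TargetRegion]
    genome: dict[str, str]
    cds_sequences: dict[str, str]  # keyed by transcript id
    efficiencies: np.ndarray  # per target, shared across samples
    disease_genes: tuple[str, ...]
    panel_genes: tuple[str, ...]

    def model(self, gene: str) -> GeneModel:
        for m in self.models:
            if m.gene == gene:
                return m
        raise KeyError(gene)

    def config(self) -> CascadeConfig:
        return CascadeConfig(panel_genes=self.panel_genes, disease_genes=self.disease_genes)


@dataclass
class Sample:
    sample_id: str
    depth: DepthTrack
    variants: list[VariantRecord]


@dataclass
class TruthSet:
    """Expected pipeline output implied by the planted events."""

    deletions: dict[str, list[dict]] = field(default_factory=dict)  # sample -> calls
    findings: dict[str, dict[str, str]] = field(default_factory=dict)  # sample -> gene -> status


@dataclass
class Cohort:
    spec: CohortSpec
    panel: Panel
    samples: dict[str, Sample]
    frequencies: FrequencyTable
    predictors: dict[tuple[str, int, str, str], dict[str, str]]
    truth: TruthSet


def _rng(seed: int, *streams: int | str) -> np.random.Generator:
    parts = [seed & 0x7FFFFFFF]
    for s in streams:
        parts.append(zlib.crc32(str(s).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(parts)


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + one stop codon."""
    n_internal = n_codons - 2
    internal: list[str] = []
    while len(internal) < n_internal:
        draw = rng.integers(0, 4, size=3 * (n_internal - len(internal) + 8))
        text = "".join("ACGT"[i] for i in draw)
        internal.extend(
            c for c in (text[i : i + 3] for i in range(0, len(text) - 2, 3)) if c not in _STOPS
        )
    return "ATG" + "".join(internal[:n_internal]) + str(rng.choice(sorted(_STOPS)))


def _coding_positions(model: GeneModel) -> list[int]:
    """Genomic 0-based positions of coding bases, in transcript order."""
    out: list[int] = []
    if model.strand == "+":
        for s, e in zip(model.exon_starts, model.exon_ends):
            out.extend(range(max(s, model.cds_start), min(e, model.cds_end)))
    else:
        for s, e in zip(reversed(model.exon_starts), reversed(model.exon_ends)):
            out.extend(range(min(e, model.cds_end) - 1, max(s, model.cds_start) - 1, -1))
    return out


def make_panel(spec: CohortSpec) -> Panel:
    """Build gene models, capture targets and a consistent synthetic genome.

    Targets are exons ± ``target_flank`` bp (exon-intron boundaries and UTRs
    are captured along with the coding sequence). CDS sequences are random
    with an ATG start and a terminal stop, written back into the genome so
    variant alleles and transcript sequences agree.
    """
    rng = _rng(spec.seed if spec.panel_seed is None else spec.panel_seed, "panel")
    disease = tuple(g for g in FA_GENES if g in list(FA_EXON_COUNTS)[: spec.n_genes])
    roster = {g: FA_EXON_COUNTS[g] for g in list(FA_EXON_COUNTS)[: spec.n_genes]}
    roster.update(EXTRA_PANEL_GENES)

    chrom = "chr1"
    cursor = 5000
    models: list[GeneModel] = []
    targets: list[TargetRegion] = []
    for i, (gene, n_exons) in enumerate(roster.items()):
        strand = "+" if i % 2 == 0 else "-"
        exon_lens = rng.integers(spec.exon_length_range[0], spec.exon_length_range[1] + 1, n_exons)
        intron_lens = (
            rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1, n_exons - 1)
            if n_exons > 1
            else np.array([], dtype=int)
        )
        starts, ends = [], []
        pos = cursor
        for j, el in enumerate(exon_lens):
            starts.append(pos)
            ends.append(pos + int(el))
            pos = ends[-1] + (int(intron_lens[j]) if j < n_exons - 1 else 0)
        total_exonic = int(exon_lens.sum())
        first_len = int(exon_lens[0] if strand == "+" else exon_lens[-1])
        last_len = int(exon_lens[-1] if strand == "+" else exon_lens[0])
        # UTRs stay inside the terminal exons and leave a workable CDS
        utr5 = max(0, min(60, first_len - 10, (total_exonic - 30) // 2))
        utr3 = max(0, min(60, last_len - 10, (total_exonic - 30) // 2))
        utr3 += (total_exonic - utr5 - utr3) % 3  # keep the CDS a codon multiple
        if strand == "+":
            cds_start, cds_end = starts[0] + utr5, ends[-1] - utr3
        else:
            cds_start, cds_end = starts[0] + utr3, ends[-1] - utr5
        models.append(
            GeneModel(
                gene=gene,
                transcript=f"TX_{gene}",
                chrom=chrom,
                strand=strand,
                exon_starts=tuple(starts),
                exon_ends=tuple(ends),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        for number in range(1, n_exons + 1):
            es, ee = models[-1].exon_interval(number)
            targets.append(
                TargetRegion(chrom, es - spec.target_flank, ee + spec.target_flank, f"{gene}_ex{number}")
            )
        cursor = ends[-1] + 5000

    targets.sort(key=lambda t: t.start)
    genome_len = cursor + 5000
    seq = _BASES[rng.integers(0, 4, size=genome_len)].copy()
    cds_sequences: dict[str, str] = {}
    for m in models:
        positions = np.array(_coding_positions(m))
        cds = _random_cds(rng, len(positions) // 3)
        cds_sequences[m.transcript] = cds
        written = cds if m.strand == "+" else str(Seq(cds).complement())
        seq[positions] = np.frombuffer(written.encode(), dtype="S1")
    genome = {chrom: seq.tobytes().decode()}
    efficiencies = rng.lognormal(mean=0.0, sigma=spec.efficiency_sigma, size=len(targets))
    return Panel(models, targets, genome, cds_sequences, efficiencies, disease, tuple(roster))


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------


def _deletion_intervals(spec: CohortSpec, panel: Panel, sample_id: str) -> list[tuple[int, int, float]]:
    """(start0, end0, copy_number) genomic intervals of this sample's deletions."""
    out = []
    for ev in spec.planted_deletions:
        if ev.sample != sample_id:
            continue
        model = panel.model(ev.gene)
        bounds = [model.exon_interval(n) for n in (ev.first_exon, ev.last_exon)]
        lo = min(b[0] for b in bounds) - spec.target_flank
        hi = max(b[1] for b in bounds) + spec.target_flank
        out.append((lo, hi, ev.copy_number))
    return out


def simulate_depth(spec: CohortSpec, panel: Panel, sample_id: str) -> DepthTrack:
    """Per-base Poisson depth over the capture targets for one sample.

    Depth at each base is Poisson(mean_depth × e_t × cn/2), where e_t is the
    target's capture efficiency (shared across samples) and cn the planted
    copy number (2, 1, 0, or 2 − f for a mosaic het deletion).
    """
    rng = _rng(spec.seed, "depth", sample_id)
    deletions = _deletion_intervals(spec, panel, sample_id)
    all_pos: list[np.ndarray] = []
    all_depth: list[np.ndarray] = []
    for t, e_t in zip(panel.targets, panel.efficiencies):
        pos0 = np.arange(t.start, t.end)
        lam = np.full(t.width, spec.mean_depth * e_t)
        for lo, hi, cn in deletions:
            mask = (pos0 >= lo) & (pos0 < hi)
            lam[mask] *= cn / 2.0
        all_pos.append(pos0 + 1)  # 1-based
        all_depth.append(rng.poisson(lam))
    return DepthTrack(
        sample_id,
        {panel.targets[0].chrom: (np.concatenate(all_pos), np.concatenate(all_depth))},
    )


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------


def _target_efficiency_at(panel: Panel, pos1: int) -> float:
    for t, e in zip(panel.targets, panel.efficiencies):
        if t.start < pos1 <= t.end:
            return float(e)
    return 1.0


def _pick_missense_site(model, cds: str, rng, want_damaging: bool) -> tuple[int, str, str] | None:
    """(coding index 0-based, tx_ref, tx_alt) for a missense of the wanted severity."""
    n_codons = len(cds) // 3
    order = rng.permutation(np.arange(1, n_codons - 1))
    for aa_idx in order:
        codon = cds[3 * aa_idx : 3 * aa_idx + 3]
        aa_ref = str(Seq(codon).translate())
        for within in rng.permutation(3):
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                mutated = codon[:within] + alt + codon[within + 1 :]
                aa_alt = str(Seq(mutated).translate())
                if aa_alt in ("*", aa_ref):
                    continue
                damaging = grantham_surrogate_verdict(aa_ref, aa_alt) == "damaging"
                if damaging == want_damaging:
                    return 3 * aa_idx + int(within), codon[within], alt
    return None


def _pick_stopgain_site(cds: str, rng) -> tuple[int, str, str]:
    n_codons = len(cds) // 3
    order = rng.permutation(np.arange(1, n_codons - 1))
    for aa_idx in order:
        codon = cds[3 * aa_idx : 3 * aa_idx + 3]
        for within in range(3):
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                if codon[:within] + alt + codon[within + 1 :] in _STOPS:
                    return 3 * aa_idx + int(within), codon[within], alt
    raise RuntimeError("no stopgain site found (CDS too short)")


def _genomic_of_coding_index(model: GeneModel, c_idx: int) -> int:
    """1-based genomic position of the 0-based coding index."""
    return _coding_positions(model)[c_idx] + 1


_COMP = str.maketrans("ACGT", "TGCA")


def _plant_variant(
    pv: PlantedVariant, panel: Panel, spec: CohortSpec, rng: np.random.Generator
) -> tuple[VariantRecord, dict[str, str]]:
    """Realize one planted variant as a VCF-style record plus predictor verdicts."""
    model = panel.model(pv.gene)
    cds = panel.cds_sequences[model.transcript]
    chrom = model.chrom
    genome = panel.genome[chrom]
    verdicts: dict[str, str] = {}

    if pv.vclass in ("missense_damaging", "missense_benign", "stopgain"):
        if pv.vclass == "stopgain":
            c_idx, tx_ref, tx_alt = _pick_stopgain_site(cds, rng)
        else:
            site = _pick_missense_site(model, cds, rng, pv.vclass == "missense_damaging")
            if site is None:
                raise ValueError(f"no {pv.vclass} site available in {pv.gene}")
            c_idx, tx_ref, tx_alt = site
        pos = _genomic_of_coding_index(model, c_idx)
        if model.strand == "+":
            ref, alt = tx_ref, tx_alt
        else:
            ref, alt = tx_ref.translate(_COMP), tx_alt.translate(_COMP)
        if pv.vclass != "stopgain":
            codon = cds[3 * (c_idx // 3) : 3 * (c_idx // 3) + 3]
            aa_ref = str(Seq(codon).translate())
            mutated = codon[: c_idx % 3] + tx_alt + codon[c_idx % 3 + 1 :]
            aa_alt = str(Seq(mutated).translate())
            verdict = grantham_surrogate_verdict(aa_ref, aa_alt)
            verdicts = {p: verdict for p in _PREDICTORS}
    elif pv.vclass == "frameshift":
        # dinucleotide insertion after a mid-CDS base whose ref is not part of
        # the insert, mirroring the c.755_756insAT mutation pattern
        coding = _coding_positions(model)
        for c_idx in rng.permutation(np.arange(3, len(coding) - 6)):
            pos = coding[int(c_idx)] + 1
            nxt = coding[int(c_idx) + 1]
            if genome[pos - 1] not in "AT" and nxt == pos:  # next coding base contiguous
                break
        ref = genome[pos - 1]
        alt = ref + "AT"
    elif pv.vclass == "splice":
        internal = rng.integers(1, model.n_exons - 1) if model.n_exons > 2 else 1
        # first intronic base 3' of the exon on the genomic strand
        g0 = model.exon_ends[int(internal) - 1]
        pos = g0 + 1
        ref = genome[g0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    elif pv.vclass == "deep_intronic":
        model_introns = [
            (model.exon_ends[i], model.exon_starts[i + 1]) for i in range(model.n_exons - 1)
        ]
        wide = [iv for iv in model_introns if iv[1] - iv[0] > 1000] or model_introns
        lo, hi = wide[int(rng.integers(len(wide)))]
        g0 = int(min(lo + 900, hi - 10))
        pos = g0 + 1
        ref = genome[g0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    else:  # pragma: no cover
        raise AssertionError(pv.vclass)

    af = 1.0 if pv.zygosity == "hom" else 0.5
    dp = max(int(rng.poisson(spec.mean_depth * _target_efficiency_at(panel, pos))), 10)
    ad = int(rng.binomial(dp, af))
    rec = VariantRecord(chrom, pos, ref, alt, dp, ad, pv.sample)
    return rec, verdicts


def planted_records(
    spec: CohortSpec, panel: Panel, sample_id: str
) -> list[tuple[PlantedVariant, VariantRecord, dict[str, str]]]:
    """Realize the sample's planted variants (own deterministic rng stream)."""
    rng = _rng(spec.seed, "plant", sample_id)
    out = []
    for pv in spec.planted_variants:
        if pv.sample == sample_id:
            rec, verdicts = _plant_variant(pv, panel, spec, rng)
            out.append((pv, rec, verdicts))
    return out


def simulate_variants(
    spec: CohortSpec,
    panel: Panel,
    sample_id: str,
    frequencies: FrequencyTable | None = None,
    predictors: dict | None = None,
    reserved_keys: set[tuple[str, int, str, str]] | None = None,
) -> tuple[list[VariantRecord], FrequencyTable, dict]:
    """One sample's called variants plus frequency/predictor table entries.

    Background variants are drawn panel-wide (mostly intronic, a minority
    coding) with population frequencies; novel (database-absent) coding
    variants are kept out of the disease genes so that planted events remain
    the only pathogenic signal, and ``reserved_keys`` (the cohort's planted
    variants, which are novel by construction) are never drawn as background.
    Planted variants get class-appropriate alleles and allele depths
    Binomial(depth, AF) with AF 0.5/1.0.
    """
    rng = _rng(spec.seed, "variants", sample_id)
    freq = frequencies if frequencies is not None else FrequencyTable()
    preds = predictors if predictors is not None else {}
    planted = planted_records(spec, panel, sample_id)
    reserved = set(reserved_keys or ()) | {rec.key for _, rec, _ in planted}
    genome = panel.genome
    chrom = panel.targets[0].chrom
    seq = genome[chrom]
    disease = set(panel.disease_genes)

    gene_spans = [(m.gene, m.tx_start, m.tx_end) for m in panel.models]
    span_lens = np.array([e - s for _, s, e in gene_spans], dtype=float)
    span_p = span_lens / span_lens.sum()

    records: list[VariantRecord] = []
    seen: set[tuple[str, int, str, str]] = set()

    n_bg = spec.n_background_variants
    n_on_gene = int(round(n_bg * 0.62))
    for i in range(n_bg):
        if i < n_on_gene:
            gi = int(rng.choice(len(gene_spans), p=span_p))
            gene, s, e = gene_spans[gi]
            g0 = int(rng.integers(s, e))
            in_disease = gene in disease
        else:
            g0 = int(rng.integers(0, len(seq)))  # mostly intergenic / off panel genes
            in_disease = any(m.tx_start <= g0 < m.tx_end and m.gene in disease for m in panel.models)
        ref = seq[g0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = (chrom, g0 + 1, ref, alt)
        if key in seen or key in reserved:
            continue
        seen.add(key)
        # frequency status: common / rare-known / novel; novel variants never
        # fall in a disease-gene exon so the planted signal stays unambiguous
        u = rng.random()
        coding_in_disease = in_disease and _near_exon(panel, g0 + 1)
        if u < 0.88 or coding_in_disease:
            freq.add(*key, "dbsnp", float(rng.uniform(0.03, 0.6)))
            if rng.random() < 0.3:
                freq.add(*key, "inhouse", float(rng.uniform(0.03, 0.6)))
        elif u < 0.95:
            freq.add(*key, "dbsnp", float(rng.uniform(0.001, 0.02)))
        # else: novel, absent from both databases
        af = 1.0 if rng.random() < 0.2 else 0.5
        dp = max(int(rng.poisson(spec.mean_depth)), 1)
        ad = int(rng.binomial(dp, af))
        if ad == 0:
            ad = 1
        records.append(VariantRecord(chrom, g0 + 1, ref, alt, dp, ad, sample_id))

    for pv, rec, verdicts in planted:
        records.append(rec)
        if verdicts:
            preds[rec.key] = verdicts
        if pv.population_frequency is not None:
            freq.add(*rec.key, "dbsnp", pv.population_frequency)

    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records, freq, preds


def _near_exon(panel: Panel, pos1: int, margin: int = 2) -> bool:
    """Exonic, or within the canonical splice region of an exon boundary."""
    g0 = pos1 - 1
    for m in panel.models:
        if m.tx_start <= g0 < m.tx_end:
            return any(
                s - margin <= g0 < e + margin for s, e in zip(m.exon_starts, m.exon_ends)
            )
    return False


# ---------------------------------------------------------------------------
# mixtures
# ---------------------------------------------------------------------------


def mix_samples(a: Sample, b: Sample, proportion: float, sample_id: str | None = None) -> Sample:
    """Equimolar-style pool of two samples: depth(pos) = round(p·a + (1−p)·b),
    variant allele fractions re-derived from the proportionally summed depths.

    Mimics pre-library DNA pooling: with p = 0.5 and a het deletion private
    to one sample, deleted exons sit at 3/4 of normal depth — one allele lost
    in a four-copy background.
    """
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    rows_a = list(a.depth.iter_rows())
    rows_b = list(b.depth.iter_rows())
    if [(c, p) for c, p, _ in rows_a] != [(c, p) for c, p, _ in rows_b]:
        raise ValueError("mismatched panels: depth tracks cover different positions")
    mixed_rows = [
        (c, p, int(np.rint(proportion * da + (1 - proportion) * db)))
        for (c, p, da), (_, _, db) in zip(rows_a, rows_b)
    ]
    sid = sample_id or f"{a.sample_id}+{b.sample_id}"
    depth = DepthTrack.from_pairs(sid, mixed_rows)

    by_key_a = {v.key: v for v in a.variants}
    by_key_b = {v.key: v for v in b.variants}
    variants: list[VariantRecord] = []
    for key in sorted(set(by_key_a) | set(by_key_b)):
        va, vb = by_key_a.get(key), by_key_b.get(key)
        dp_a = va.total_depth if va else a.depth.depth_at(key[0], key[1])
        dp_b = vb.total_depth if vb else b.depth.depth_at(key[0], key[1])
        ad_a = va.alt_depth if va else 0
        ad_b = vb.alt_depth if vb else 0
        dp = int(np.rint(proportion * dp_a + (1 - proportion) * dp_b))
        ad = min(int(np.rint(proportion * ad_a + (1 - proportion) * ad_b)), dp)
        if ad > 0:
            variants.append(VariantRecord(key[0], key[1], key[2], key[3], dp, ad, sid))
    return Sample(sid, depth, variants)


def build_mosaic_mixture_tracks(
    seed: int,
    panel: Panel | None = None,
    gene: str = "FANCA",
    first_exon: int = 15,
    last_exon: int = 23,
    n_diploid: int = 10,
    proportion: float = 0.5,
    mean_depth: float = 100.0,
) -> tuple[Panel, list[DepthTrack], str]:
    """Depth tracks for the pooled-DNA mosaic validation design.

    ``n_diploid`` diploid samples plus one pooled sample built by mixing a
    diploid sample with a heterozygous-deletion carrier at ``proportion``
    (equimolar by default: the deletion then sits in a four-copy background,
    expected log2 ratio log2(3/4)). Returns the panel, the cohort's depth
    tracks (pooled sample last) and the pooled sample's id.
    """
    if panel is None:
        panel = make_panel(CohortSpec(seed=seed, mean_depth=mean_depth))
    base = CohortSpec(seed=seed, n_samples=n_diploid, mean_depth=mean_depth, n_background_variants=0)
    tracks = [simulate_depth(base, panel, sid) for sid in base.sample_ids()]
    carrier_spec = CohortSpec(
        seed=seed, mean_depth=mean_depth, n_background_variants=0,
        planted_deletions=[PlantedDeletion("CARRIER", gene, first_exon, last_exon, "het_del")],
    )
    normal = Sample("NORMAL", simulate_depth(base, panel, "NORMAL"), [])
    carrier = Sample("CARRIER", simulate_depth(carrier_spec, panel, "CARRIER"), [])
    pooled = mix_samples(normal, carrier, proportion, "POOLED")
    tracks.append(pooled.depth)
    return panel, tracks, "POOLED"


# ---------------------------------------------------------------------------
# cohort assembly and ground truth
# ---------------------------------------------------------------------------


def _expected_findings(spec: CohortSpec, sample_id: str) -> dict[str, str]:
    alleles: dict[str, int] = {}
    for pv in spec.planted_variants:
        if pv.sample == sample_id and pv.is_clue:
            alleles[pv.gene] = alleles.get(pv.gene, 0) + (2 if pv.zygosity == "hom" else 1)
    for ev in spec.planted_deletions:
        if ev.sample == sample_id and ev.mosaic_fraction is None:
            alleles[ev.gene] = alleles.get(ev.gene, 0) + (2 if ev.genotype == "hom_del" else 1)
    return {
        gene: ("biallelic" if n >= 2 else "one_allele") for gene, n in alleles.items() if n >= 1
    }


def simulate_cohort(spec: CohortSpec, panel: Panel | None = None) -> Cohort:
    """Generate the full cohort: panel, depth tracks, variants, truth."""
    if panel is None:
        panel = make_panel(spec)
    freq = FrequencyTable()
    preds: dict[tuple[str, int, str, str], dict[str, str]] = {}
    samples: dict[str, Sample] = {}
    truth = TruthSet()
    # planted variants are novel by construction: reserve their keys so no
    # sample's background draw can place them in the population databases
    reserved = {
        rec.key
        for sid in spec.sample_ids()
        for _, rec, _ in planted_records(spec, panel, sid)
    }
    for sid in spec.sample_ids():
        depth = simulate_depth(spec, panel, sid)
        variants, freq, preds = simulate_variants(spec, panel, sid, freq, preds, reserved)
        samples[sid] = Sample(sid, depth, variants)
        truth.findings[sid] = _expected_findings(spec, sid)
        truth.deletions[sid] = [
            {
                "gene": ev.gene,
                "first_exon": ev.first_exon,
                "last_exon": ev.last_exon,
                "class": (
                    "hom"
                    if ev.genotype == "hom_del"
                    else ("mosaic" if ev.mosaic_fraction is not None else "het")
                ),
                "mosaic_fraction": 1.0 if ev.mosaic_fraction is None and ev.genotype == "het_del" else ev.mosaic_fraction,
            }
            for ev in spec.planted_deletions
            if ev.sample == sid
        ]
    return Cohort(spec, panel, samples, freq, preds, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as plain-text fixtures: BED, refFlat, CDS FASTA,
    per-sample depth TSV and VCF, frequency TSV, predictor TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(outdir / "targets.bed", cohort.panel.targets)
    write_refflat(outdir / "genes.refflat", cohort.panel.models)
    write_fasta(outdir / "cds.fasta", cohort.panel.cds_sequences)
    write_frequency_table(outdir / "frequencies.tsv", cohort.frequencies)
    write_predictor_table(outdir / "predictors.tsv", cohort.predictors)
    for sid, sample in cohort.samples.items():
        write_depth_table(outdir / f"{sid}.depth.tsv", sample.depth)
        write_vcf(outdir / f"{sid}.vcf", sample.variants, sid)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {"deletions": cohort.truth.deletions, "findings": cohort.truth.findings},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    with open(outdir / "panel.json", "w") as fh:
        json.dump(
            {
                "panel_genes": list(cohort.panel.panel_genes),
                "disease_genes": list(cohort.panel.disease_genes),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
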