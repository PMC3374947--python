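"""Transcript-aware consequence annotation with HGVS c. positions.

Covers the annotation context the downstream filtering cascade needs: effect
class (nonsynonymous / synonymous / stopgain / frameshift / inframe indel /
canonical splice / intronic / UTR / intergenic), HGVS coding-DNA positions
including intronic offsets (c.893+920 style), population-frequency lookup,
external predictor verdict attachment, and allele-fraction flagging of
variants inside pseudogene-homologous regions.

Predictor verdicts (SIFT / PolyPhen-2 / Align-GVGD style) are consumed as
input, never computed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .formats_io import FrequencyTable, GeneModel, VariantRecord

__all__ = [
    "AnnotatedVariant",
    "PseudogeneRegion",
    "EFFECT_CLASSES",
    "CODING_EFFECTS",
    "genomic_to_cdna",
    "cdna_to_genomic",
    "classify_consequence",
    "annotate",
    "flag_pseudogene",
    "trim_alleles",
    "write_annotated_tsv",
    "write_annotated_vcf",
    "grantham_surrogate_verdict",
]

EFFECT_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "frameshift",
    "inframe_indel",
    "canonical_splice",
    "intronic",
    "utr5",
    "utr3",
    "intergenic",
)

#: effect classes that survive the "NS/SS" stage of the filtering cascade
CODING_EFFECTS = frozenset(
    {"nonsynonymous", "stopgain", "frameshift", "inframe_indel", "canonical_splice"}
)

SPLICE_REGION = 2  # intronic bases each side of a junction (GT donor / AG acceptor)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PseudogeneRegion:
    """Genomic region with highly similar copies elsewhere in the genome.

    Reads from the copies co-map over the functional locus and dilute the
    apparent allele fraction of true variants; ``copy_factor`` counts the
    similar copies including the functional locus, so a true heterozygote is
    expected near AF = 0.5 / copy_factor.
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    copy_factor: int = 2

    def __post_init__(self) -> None:
        if self.copy_factor < 2:
            raise ValueError("copy_factor must be >= 2")
        if self.end <= self.start:
            raise ValueError("region must have positive width")

    def contains_pos1(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass
class AnnotatedVariant:
    """A variant joined to its transcript context and external evidence."""

    variant: VariantRecord
    gene: str = ""
    transcript: str = ""
    effect_class: str = "intergenic"
    hgvs_c: str = ""
    protein_change: str = ""
    dbsnp_frequency: float | None = None
    inhouse_frequency: float | None = None
    predictor_verdicts: dict[str, str] = field(default_factory=dict)
    pseudogene_flag: bool = False
    expected_af: float | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")

    # convenience delegates
    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def allele_fraction(self) -> float:
        return self.variant.allele_fraction

    @property
    def key(self):
        return self.variant.key

    @property
    def n_damaging(self) -> int:
        return sum(1 for v in self.predictor_verdicts.values() if v == "damaging")


# ---------------------------------------------------------------------------
# transcript coordinate machinery
# ---------------------------------------------------------------------------


def _exons_transcript_order(model: GeneModel) -> list[tuple[int, int]]:
    exons = list(zip(model.exon_starts, model.exon_ends))
    return exons if model.strand == "+" else exons[::-1]


def _spliced_index(g0: int, model: GeneModel) -> int | None:
    """0-based index of genomic base g0 within the spliced transcript, or None."""
    offset = 0
    if model.strand == "+":
        for s, e in _exons_transcript_order(model):
            if s <= g0 < e:
                return offset + (g0 - s)
            offset += e - s
    else:
        for s, e in _exons_transcript_order(model):
            if s <= g0 < e:
                return offset + (e - 1 - g0)
            offset += e - s
    return None


def _cds_span_spliced(model: GeneModel) -> tuple[int, int]:
    """CDS bounds [cs, ce) in spliced-transcript coordinates."""
    if not model.has_cds:
        raise ValueError(f"{model.transcript}: model has no CDS")
    first_coding = model.cds_start if model.strand == "+" else model.cds_end - 1
    cs = _spliced_index(first_coding, model)
    if cs is None:
        raise ValueError(f"{model.transcript}: CDS start not inside an exon")
    coding_len = sum(
        max(0, min(e, model.cds_end) - max(s, model.cds_start))
        for s, e in zip(model.exon_starts, model.exon_ends)
    )
    return cs, cs + coding_len


def _exonic_label(t: int, cs: int, ce: int) -> str:
    if t < cs:
        return f"-{cs - t}"
    if t < ce:
        return f"{t - cs + 1}"
    return f"*{t - ce + 1}"


def genomic_to_cdna(pos: int, model: GeneModel) -> str:
    """HGVS c. position for a 1-based genomic position within the transcript.

    Coding bases are numbered from the A of the start codon (c.1); 5'/3' UTR
    bases as c.-k / c.*k; intronic bases as offsets from the nearest exon
    edge, choosing the smaller offset ("+" from the preceding exon on ties),
    e.g. ``c.893+920``.
    """
    g0 = pos - 1
    if not (model.tx_start <= g0 < model.tx_end):
        raise ValueError(f"position {pos} outside transcript {model.transcript}")
    cs, ce = _cds_span_spliced(model)
    t = _spliced_index(g0, model)
    if t is not None:
        return "c." + _exonic_label(t, cs, ce)
    # intronic: locate the flanking exons in genomic order
    for i in range(model.n_exons - 1):
        if model.exon_ends[i] <= g0 < model.exon_starts[i + 1]:
            d_left = g0 - model.exon_ends[i] + 1
            d_right = model.exon_starts[i + 1] - g0
            t_left = _spliced_index(model.exon_ends[i] - 1, model)
            t_right = _spliced_index(model.exon_starts[i + 1], model)
            if model.strand == "+":
                d_prev, anchor_prev = d_left, _exonic_label(t_left, cs, ce)
                d_next, anchor_next = d_right, _exonic_label(t_right, cs, ce)
            else:
                d_prev, anchor_prev = d_right, _exonic_label(t_right, cs, ce)
                d_next, anchor_next = d_left, _exonic_label(t_left, cs, ce)
            if d_prev <= d_next:
                return f"c.{anchor_prev}+{d_prev}"
            return f"c.{anchor_next}-{d_next}"
    raise ValueError(f"position {pos} not locatable in {model.transcript}")


_CDNA_RE = re.compile(r"^(?:c\.)?(\*?-?\d+)(?:([+-])(\d+))?$")


def cdna_to_genomic(label: str, model: GeneModel) -> int:
    """Inverse of :func:`genomic_to_cdna`: 1-based genomic position of a c. label."""
    m = _CDNA_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse HGVS c. position {label!r}")
    anchor, sign, off = m.group(1), m.group(2), m.group(3)
    cs, ce = _cds_span_spliced(model)
    if anchor.startswith("*"):
        t = ce + int(anchor[1:]) - 1
    elif anchor.startswith("-"):
        t = cs - int(anchor[1:])
    else:
        t = cs + int(anchor) - 1
    # map spliced index back to genomic
    offset = 0
    g0 = None
    for s, e in _exons_transcript_order(model):
        width = e - s
        if offset <= t < offset + width:
            g0 = s + (t - offset) if model.strand == "+" else e - 1 - (t - offset)
            break
        offset += width
    if g0 is None:
        raise ValueError(f"c. position {label!r} outside transcript {model.transcript}")
    if sign:
        delta = int(off)
        step = delta if sign == "+" else -delta
        g0 = g0 + step if model.strand == "+" else g0 - step
    return g0 + 1


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize a VCF-style allele pair to its minimal representation.

    Shared suffix then shared prefix are trimmed (prefix trimming advances
    the position); a pure insertion/deletion ends with one empty allele.
    """
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:  # shared base remained on both sides of a pure indel
        raise ValueError("alleles identical after trimming")
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    # strip the residual shared anchor base of pure indels
    if ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _position_class(pos: int, model: GeneModel) -> str:
    """Positional class of a 1-based genomic position w.r.t. one transcript."""
    g0 = pos - 1
    if not (model.tx_start <= g0 < model.tx_end):
        return "intergenic"
    t = _spliced_index(g0, model)
    if t is not None:
        cs, ce = _cds_span_spliced(model)
        if t < cs:
            return "utr5"
        if t < ce:
            return "coding"
        return "utr3"
    # intronic: canonical splice = first SPLICE_REGION bases each intron end
    for i in range(model.n_exons - 1):
        if model.exon_ends[i] <= g0 < model.exon_starts[i + 1]:
            if g0 - model.exon_ends[i] < SPLICE_REGION or model.exon_starts[i + 1] - g0 <= SPLICE_REGION:
                return "canonical_splice"
            return "intronic"
    return "intronic"


def classify_consequence(
    variant: VariantRecord,
    model: GeneModel,
    reference_sequence: str | None = None,
) -> tuple[str, str]:
    """Effect class (and protein change for coding variants) of one variant.

    ``reference_sequence`` is the transcript's CDS in coding orientation; it
    is required to classify coding SNVs and must agree with the variant's
    ref allele (disagreement raises, flagging inconsistent inputs).

    Rules, in priority order: CDS indel with length difference not divisible
    by 3 → frameshift, divisible → inframe_indel; CDS SNV creating a stop →
    stopgain, changing the amino acid → nonsynonymous, preserving it →
    synonymous; position within 2 intronic bases of a junction →
    canonical_splice; otherwise intronic / utr5 / utr3 / intergenic.
    """
    pos, ref, alt = trim_alleles(variant.pos, variant.ref, variant.alt)
    is_indel = len(ref) != len(alt)
    region = _position_class(pos, model)

    if is_indel:
        if region == "coding":
            diff = abs(len(ref) - len(alt))
            cls = "frameshift" if diff % 3 else "inframe_indel"
            prot = ""
            if reference_sequence and cls == "frameshift":
                t = _spliced_index(pos - 1, model)
                cs, _ = _cds_span_spliced(model)
                if t is not None and t >= cs:
                    aa_idx = (t - cs) // 3
                    codon = reference_sequence[3 * aa_idx : 3 * aa_idx + 3]
                    if len(codon) == 3:
                        prot = f"p.{Seq(codon).translate()}{aa_idx + 1}fs"
            return cls, prot
        return region, ""

    # SNV
    if region != "coding":
        return region, ""
    if reference_sequence is None:
        raise ValueError("reference_sequence required to classify coding SNVs")
    t = _spliced_index(pos - 1, model)
    cs, ce = _cds_span_spliced(model)
    c_idx = t - cs  # 0-based coding index
    tx_ref = ref if model.strand == "+" else ref.translate(_COMPLEMENT)
    tx_alt = alt if model.strand == "+" else alt.translate(_COMPLEMENT)
    if c_idx >= len(reference_sequence) or reference_sequence[c_idx].upper() != tx_ref.upper():
        raise ValueError(
            f"ref allele {ref} at {variant.chrom}:{pos} disagrees with CDS of {model.transcript}"
        )
    aa_idx = c_idx // 3
    codon = reference_sequence[3 * aa_idx : 3 * aa_idx + 3].upper()
    mutated = codon[: c_idx % 3] + tx_alt.upper() + codon[c_idx % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == aa_ref:
        return "synonymous", ""
    prot = f"p.{aa_ref}{aa_idx + 1}{aa_alt if aa_alt != '*' else 'X'}"
    if aa_alt == "*":
        return "stopgain", prot
    return "nonsynonymous", prot


# ---------------------------------------------------------------------------
# annotation join
# ---------------------------------------------------------------------------


def annotate(
    variants: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    freq: FrequencyTable | None = None,
    predictors: Mapping[tuple[str, int, str, str], Mapping[str, str]] | None = None,
    cds_sequences: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Join variants to transcripts, consequences, frequencies and verdicts.

    Each variant is annotated against the first transcript overlapping its
    position (models in genomic order); variants in no transcript get the
    closest gene on the chromosome and class intergenic. Absent frequency
    entries stay ``None`` (treated as novel downstream).
    """
    cds_sequences = cds_sequences or {}
    predictors = predictors or {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for lst in by_chrom.values():
        lst.sort(key=lambda m: m.tx_start)

    out: list[AnnotatedVariant] = []
    for v in variants:
        candidates = by_chrom.get(v.chrom, [])
        model = next(
            (m for m in candidates if m.tx_start < v.pos <= m.tx_end), None
        )
        gene = transcript = ""
        effect, hgvs, prot = "intergenic", "", ""
        if model is not None:
            gene, transcript = model.gene, model.transcript
            seq = cds_sequences.get(model.transcript) or cds_sequences.get(model.gene)
            effect, prot = classify_consequence(v, model, seq)
            try:
                hgvs = genomic_to_cdna(v.pos, model)
            except ValueError:
                hgvs = ""
        elif candidates:
            nearest = min(
                candidates,
                key=lambda m: min(abs(v.pos - m.tx_start), abs(v.pos - m.tx_end)),
            )
            gene = nearest.gene
        freqs = freq.lookup(v.key) if freq is not None else {}
        out.append(
            AnnotatedVariant(
                variant=v,
                gene=gene,
                transcript=transcript,
                effect_class=effect,
                hgvs_c=hgvs,
                protein_change=prot,
                dbsnp_frequency=freqs.get("dbsnp"),
                inhouse_frequency=freqs.get("inhouse"),
                predictor_verdicts=dict(predictors.get(v.key, {})),
            )
        )
    return out


def flag_pseudogene(
    variants: Sequence[AnnotatedVariant],
    regions: Sequence[PseudogeneRegion],
    flag_af_below: float = 0.35,
    af_floor: float = 0.05,
) -> list[AnnotatedVariant]:
    """Flag variants whose allele fraction looks diluted by pseudogene copies.

    A variant is flagged iff it lies inside a declared region and its allele
    fraction is in [af_floor, flag_af_below). Flagged variants carry the
    expected heterozygous AF 0.5/copy_factor and bypass the allele-fraction
    filter downstream.
    """
    out: list[AnnotatedVariant] = []
    for v in variants:
        region = next((r for r in regions if r.contains_pos1(v.chrom, v.pos)), None)
        flagged = region is not None and af_floor <= v.allele_fraction < flag_af_below
        out.append(
            AnnotatedVariant(
                variant=v.variant,
                gene=v.gene,
                transcript=v.transcript,
                effect_class=v.effect_class,
                hgvs_c=v.hgvs_c,
                protein_change=v.protein_change,
                dbsnp_frequency=v.dbsnp_frequency,
                inhouse_frequency=v.inhouse_frequency,
                predictor_verdicts=dict(v.predictor_verdicts),
                pseudogene_flag=flagged,
                expected_af=(0.5 / region.copy_factor) if flagged else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# optional surrogate verdicts for simulated cohorts
# ---------------------------------------------------------------------------

# Grantham (1974) distances for the substitutions the simulator produces;
# used only to decorate synthetic cohorts, never as a real predictor.
_GRANTHAM: dict[frozenset[str], int] = {}
_GRANTHAM_ROWS = """
A,C,195 A,D,126 A,E,107 A,F,113 A,G,60 A,H,86 A,I,94 A,K,106 A,L,96 A,M,84 A,N,111 A,P,27 A,Q,91 A,R,112 A,S,99 A,T,58 A,V,64 A,W,148 A,Y,112
C,D,154 C,E,170 C,F,205 C,G,159 C,H,174 C,I,198 C,K,202 C,L,198 C,M,196 C,N,139 C,P,169 C,Q,154 C,R,180 C,S,112 C,T,149 C,V,192 C,W,215 C,Y,194
D,E,45 D,F,177 D,G,94 D,H,81 D,I,168 D,K,101 D,L,172 D,M,160 D,N,23 D,P,108 D,Q,61 D,R,96 D,S,65 D,T,85 D,V,152 D,W,181 D,Y,160
E,F,140 E,G,98 E,H,40 E,I,134 E,K,56 E,L,138 E,M,126 E,N,42 E,P,93 E,Q,29 E,R,54 E,S,80 E,T,65 E,V,121 E,W,152 E,Y,122
F,G,153 F,H,100 F,I,21 F,K,102 F,L,22 F,M,28 F,N,158 F,P,114 F,Q,116 F,R,97 F,S,155 F,T,103 F,V,50 F,W,40 F,Y,22
G,H,98 G,I,135 G,K,127 G,L,138 G,M,127 G,N,80 G,P,42 G,Q,87 G,R,125 G,S,56 G,T,59 G,V,109 G,W,184 G,Y,147
H,I,94 H,K,32 H,L,99 H,M,87 H,N,68 H,P,77 H,Q,24 H,R,29 H,S,89 H,T,47 H,V,84 H,W,115 H,Y,83
I,K,102 I,L,5 I,M,10 I,N,149 I,P,95 I,Q,109 I,R,97 I,S,142 I,T,89 I,V,29 I,W,61 I,Y,33
K,L,107 K,M,95 K,N,94 K,P,103 K,Q,53 K,R,26 K,S,121 K,T,78 K,V,97 K,W,110 K,Y,85
L,M,15 L,N,153 L,P,98 L,Q,113 L,R,102 L,S,145 L,T,92 L,V,32 L,W,61 L,Y,36
M,N,142 M,P,87 M,Q,101 M,R,91 M,S,135 M,T,81 M,V,21 M,W,67 M,Y,36
N,P,91 N,Q,46 N,R,86 N,S,46 N,T,65 N,V,133 N,W,174 N,Y,143
P,Q,76 P,R,103 P,S,74 P,T,38 P,V,68 P,W,147 P,Y,110
Q,R,43 Q,S,68 Q,T,42 Q,V,96 Q,W,130 Q,Y,99
R,S,110 R,T,71 R,V,96 R,W,101 R,Y,77
S,T,58 S,V,124 S,W,177 S,Y,144
T,V,69 T,W,128 T,Y,92
V,W,88 V,Y,55
W,Y,37
"""
for _tok in _GRANTHAM_ROWS.split():
    _a, _b, _d = _tok.split(",")
    _GRANTHAM[frozenset((_a, _b))] = int(_d)


def grantham_surrogate_verdict(aa_ref: str, aa_alt: str, cutoff: int = 100) -> str:
    """Damaging iff the Grantham distance exceeds ``cutoff``; for synthetic data."""
    d = _GRANTHAM.get(frozenset((aa_ref.upper(), aa_alt.upper())), 215)
    return "damaging" if d > cutoff else "benign"


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample", "total_depth", "alt_depth", "allele_fraction",
    "gene", "transcript", "effect", "hgvs_c", "protein_change",
    "dbsnp_frequency", "inhouse_frequency", "predictors", "pseudogene_flag", "expected_af",
]


def write_annotated_tsv(path: str | Path, variants: Sequence[AnnotatedVariant]) -> None:
    def fmt(x):
        return "NA" if x is None or x == "" else str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for av in sorted(variants, key=lambda a: a.key):
            v = av.variant
            preds = ";".join(f"{k}={val}" for k, val in sorted(av.predictor_verdicts.items()))
            fh.write(
                "\t".join(
                    [
                        v.chrom, str(v.pos), v.ref, v.alt, fmt(v.sample_id),
                        str(v.total_depth), str(v.alt_depth), f"{v.allele_fraction:.4f}",
                        fmt(av.gene), fmt(av.transcript), av.effect_class, fmt(av.hgvs_c),
                        fmt(av.protein_change),
                        fmt(av.dbsnp_frequency), fmt(av.inhouse_frequency), fmt(preds),
                        "1" if av.pseudogene_flag else "0", fmt(av.expected_af),
                    ]
                )
                + "\n"
            )


def write_annotated_vcf(path: str | Path, variants: Sequence[AnnotatedVariant], sample_id: str = "SAMPLE") -> None:
    """Annotated VCF twin with INFO keys EFFECT, HGVSC, DBSNP_AF, INHOUSE_AF, PGFLAG."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, desc in [
            ("EFFECT", "Consequence class"),
            ("HGVSC", "HGVS c. position"),
            ("DBSNP_AF", "dbSNP population frequency"),
            ("INHOUSE_AF", "In-house cohort frequency"),
            ("PGFLAG", "Pseudogene-region low-AF flag"),
        ]:
            num_type = "0,Type=Flag" if key == "PGFLAG" else "1,Type=String"
            fh.write(f"##INFO=<ID={key},Number={num_type},Description=\"{desc}\">\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for av in sorted(variants, key=lambda a: a.key):
            v = av.variant
            info = [f"EFFECT={av.effect_class}"]
            if av.hgvs_c:
                info.append(f"HGVSC={av.hgvs_c}")
            if av.dbsnp_frequency is not None:
                info.append(f"DBSNP_AF={av.dbsnp_frequency:.6g}")
            if av.inhouse_frequency is not None:
                info.append(f"INHOUSE_AF={av.inhouse_frequency:.6g}")
            if av.pseudogene_flag:
                info.append("PGFLAG")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\t"
                f"AD\t{v.total_depth - v.alt_depth},{v.alt_depth}\n"
            )
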