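"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are strict and converted only at the file boundary:

* BED and refFlat intervals are 0-based half-open.
* VCF positions and per-base depth tables are 1-based.

A 1-based position ``p`` therefore lies inside a half-open interval
``(start, end)`` iff ``start < p <= end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger("panelscreen")

__all__ = [
    "TargetRegion",
    "GeneModel",
    "DepthTrack",
    "VariantRecord",
    "FrequencyTable",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_refflat",
    "write_refflat",
    "read_vcf",
    "write_vcf",
    "read_depth_table",
    "write_depth_table",
    "read_frequency_table",
    "write_frequency_table",
    "read_predictor_table",
    "write_predictor_table",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetRegion:
    """A captured interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains_pos1(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position lies inside this region."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: exon structure plus CDS bounds, 0-based half-open.

    ``exon_starts``/``exon_ends`` are parallel, sorted, non-overlapping and in
    genomic order regardless of strand; exon *numbering* (1-based, transcript
    order) runs 5'→3' and is therefore reversed on the minus strand.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError("exon_starts and exon_ends differ in length")
        if not self.exon_starts:
            raise ValueError("model must have at least one exon")
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if e <= s:
                raise ValueError(f"exon ({s},{e}) is empty or inverted")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError("CDS bounds must lie within the transcript span")

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    @property
    def tx_start(self) -> int:
        return self.exon_starts[0]

    @property
    def tx_end(self) -> int:
        return self.exon_ends[-1]

    @property
    def has_cds(self) -> bool:
        return self.cds_end > self.cds_start

    def exon_interval(self, number: int) -> tuple[int, int]:
        """Genomic (start, end) of 1-based exon ``number`` in transcript order."""
        if not 1 <= number <= self.n_exons:
            raise ValueError(f"exon {number} out of range 1..{self.n_exons}")
        i = number - 1 if self.strand == "+" else self.n_exons - number
        return self.exon_starts[i], self.exon_ends[i]


class DepthTrack:
    """Per-base read depth for one sample.

    Positions are 1-based; positions absent from the table mean depth zero.
    Internally stored as sorted position/depth arrays per chromosome with a
    cumulative sum so that interval sums are O(log n).
    """

    def __init__(self, sample_id: str, data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self.sample_id = sample_id
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (pos, depth) in data.items():
                self._set(chrom, np.asarray(pos, dtype=np.int64), np.asarray(depth, dtype=np.int64))

    def _set(self, chrom: str, pos: np.ndarray, depth: np.ndarray) -> None:
        if np.any(depth < 0):
            raise ValueError(f"negative depth on {chrom}")
        order = np.argsort(pos, kind="stable")
        pos, depth = pos[order], depth[order]
        if pos.size and np.any(np.diff(pos) == 0):
            dup = int(pos[np.where(np.diff(pos) == 0)[0][0]])
            raise ValueError(f"duplicate position {chrom}:{dup}")
        cum = np.concatenate([[0], np.cumsum(depth)])
        self._data[chrom] = (pos, depth, cum)

    @classmethod
    def from_pairs(cls, sample_id: str, rows: Iterable[tuple[str, int, int]]) -> "DepthTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos, depth in rows:
            by_chrom.setdefault(chrom, []).append((pos, depth))
        track = cls(sample_id)
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs, dtype=np.int64).reshape(-1, 2)
            track._set(chrom, arr[:, 0], arr[:, 1])
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def total_depth(self) -> int:
        return int(sum(cum[-1] for _, _, cum in self._data.values()))

    def depth_at(self, chrom: str, pos: int) -> int:
        if chrom not in self._data:
            return 0
        positions, depth, _ = self._data[chrom]
        i = np.searchsorted(positions, pos)
        if i < positions.size and positions[i] == pos:
            return int(depth[i])
        return 0

    def window_sum(self, chrom: str, start: int, end: int) -> int:
        """Sum of depth over 0-based half-open [start, end)."""
        if chrom not in self._data:
            return 0
        positions, _, cum = self._data[chrom]
        lo = np.searchsorted(positions, start + 1)  # first 1-based pos > start
        hi = np.searchsorted(positions, end, side="right")
        return int(cum[hi] - cum[lo])

    def window_sums(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized interval sums for same-chromosome windows."""
        if chrom not in self._data:
            return np.zeros(len(starts), dtype=np.int64)
        positions, _, cum = self._data[chrom]
        lo = np.searchsorted(positions, np.asarray(starts) + 1)
        hi = np.searchsorted(positions, np.asarray(ends), side="right")
        return cum[hi] - cum[lo]

    def iter_rows(self) -> Iterable[tuple[str, int, int]]:
        for chrom in sorted(self._data):
            positions, depth, _ = self._data[chrom]
            for p, d in zip(positions.tolist(), depth.tolist()):
                yield chrom, p, d


@dataclass(frozen=True)
class VariantRecord:
    """One called small variant for one sample (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError("require 0 <= alt_depth <= total_depth")

    @property
    def allele_fraction(self) -> float:
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class FrequencyTable:
    """Population / in-house allele frequencies keyed by (chrom, pos, ref, alt)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, int, str, str], dict[str, float]] = {}

    def add(self, chrom: str, pos: int, ref: str, alt: str, source: str, frequency: float) -> None:
        if not 0.0 <= frequency <= 1.0:
            raise ValueError(f"frequency {frequency} outside [0,1]")
        if source not in ("dbsnp", "inhouse"):
            raise ValueError(f"unknown frequency source {source!r}")
        self._entries.setdefault((chrom, pos, ref, alt), {})[source] = frequency

    def lookup(self, key: tuple[str, int, str, str]) -> dict[str, float]:
        return dict(self._entries.get(key, {}))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._entries

    def items(self):
        return self._entries.items()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[TargetRegion]:
    """Read a 3+ column BED file into 0-based half-open target regions.

    Track/browser/comment lines are skipped; input order is preserved.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            label = fields[3] if len(fields) > 3 else ""
            regions.append(TargetRegion(fields[0], start, end, label))
    return regions


def write_bed(path: str | Path, regions: Iterable[TargetRegion], extra_columns=None) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fields = [r.chrom, str(r.start), str(r.end), r.label]
            if extra_columns is not None:
                fields.extend(str(c) for c in extra_columns[i])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# refFlat
# ---------------------------------------------------------------------------

_REFFLAT_NCOL = 11


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Read UCSC refFlat gene models.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds (exon lists comma-separated, possibly with
    a trailing comma). exonCount must match the list lengths.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _REFFLAT_NCOL:
                raise FormatError(f"{path}:{lineno}: expected {_REFFLAT_NCOL} columns")
            try:
                exon_count = int(fields[8])
                starts = tuple(int(x) for x in fields[9].rstrip(",").split(","))
                ends = tuple(int(x) for x in fields[10].rstrip(",").split(","))
                cds_start, cds_end = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if len(starts) != exon_count or len(ends) != exon_count:
                raise FormatError(
                    f"{path}:{lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends listed"
                )
            try:
                models.append(
                    GeneModel(
                        gene=fields[0],
                        transcript=fields[1],
                        chrom=fields[2],
                        strand=fields[3],
                        exon_starts=starts,
                        exon_ends=ends,
                        cds_start=cds_start,
                        cds_end=cds_end,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_refflat(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.gene,
                        m.transcript,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.cds_start),
                        str(m.cds_end),
                        str(m.n_exons),
                        ",".join(str(s) for s in m.exon_starts) + ",",
                        ",".join(str(e) for e in m.exon_ends) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantRecord]:
    """Read a VCF 4.x file into per-alt variant records with allele fractions.

    Allele depths come from the per-sample AD field (ref, alt1, alt2, ...);
    multi-allelic records are split into one record per alt. Records without
    usable depth fields are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    if sample_id is None:
        sample_id = samples[0] if samples else ""
    sample_idx = samples.index(sample_id) if samples else None

    records: list[VariantRecord] = []
    for rec in vcf:
        ad = None
        if sample_idx is not None:
            try:
                ad_arr = rec.format("AD")
                if ad_arr is not None:
                    ad = [int(x) for x in np.atleast_2d(ad_arr)[sample_idx]]
            except (KeyError, TypeError):
                ad = None
        if ad is None or len(ad) < 1 + len(rec.ALT):
            log.warning("skipping %s:%s: no usable AD field", rec.CHROM, rec.POS)
            continue
        total = sum(max(x, 0) for x in ad[: 1 + len(rec.ALT)])
        for i, alt in enumerate(rec.ALT):
            alt_depth = max(ad[1 + i], 0)
            records.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    total_depth=total,
                    alt_depth=alt_depth,
                    sample_id=sample_id,
                )
            )
    vcf.close()
    return records


def write_vcf(path: str | Path, records: Iterable[VariantRecord], sample_id: str = "SAMPLE") -> None:
    """Write variant records as a minimal single-sample VCF 4.2 with AD/DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            ref_depth = r.total_depth - r.alt_depth
            gt = "1/1" if r.allele_fraction >= 0.9 else "0/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ref_depth},{r.alt_depth}:{r.total_depth}\n"
            )


# ---------------------------------------------------------------------------
# depth tables (samtools depth dialect: chrom, 1-based pos, depth)
# ---------------------------------------------------------------------------


def read_depth_table(path: str | Path, sample_id: str | None = None) -> DepthTrack:
    """Read a samtools-depth-style TSV. Absent positions mean depth zero."""
    if sample_id is None:
        sample_id = Path(path).stem
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                pos, depth = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position/depth") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            rows.append((fields[0], pos, depth))
    try:
        return DepthTrack.from_pairs(sample_id, rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_depth_table(path: str | Path, track: DepthTrack) -> None:
    with open(path, "w") as fh:
        for chrom, pos, depth in track.iter_rows():
            fh.write(f"{chrom}\t{pos}\t{depth}\n")


# ---------------------------------------------------------------------------
# frequency and predictor tables
# ---------------------------------------------------------------------------


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a frequency TSV: chrom, pos (1-based), ref, alt, source, frequency."""
    table = FrequencyTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                table.add(fields[0], int(fields[1]), fields[2], fields[3], fields[4], float(fields[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_frequency_table(path: str | Path, table: FrequencyTable) -> None:
    with open(path, "w") as fh:
        for (chrom, pos, ref, alt), sources in sorted(table.items()):
            for source, freq in sorted(sources.items()):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{source}\t{freq:.6g}\n")


def read_predictor_table(path: str | Path) -> dict[tuple[str, int, str, str], dict[str, str]]:
    """Read predictor verdicts: chrom, pos, ref, alt, predictor, verdict."""
    verdicts: dict[tuple[str, int, str, str], dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            verdict = fields[5].lower()
            if verdict not in ("damaging", "benign"):
                raise FormatError(f"{path}:{lineno}: verdict must be damaging/benign")
            key = (fields[0], int(fields[1]), fields[2], fields[3])
            verdicts.setdefault(key, {})[fields[4]] = verdict
    return verdicts


def write_predictor_table(path: str | Path, verdicts: Mapping[tuple[str, int, str, str], Mapping[str, str]]) -> None:
    with open(path, "w") as fh:
        for (chrom, pos, ref, alt), preds in sorted(verdicts.items()):
            for predictor, verdict in sorted(preds.items()):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{predictor}\t{verdict}\n")


# ---------------------------------------------------------------------------
# FASTA (plain text, used for synthetic CDS sequences)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is None:
                raise FormatError(f"{path}: sequence data before first header")
            else:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
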