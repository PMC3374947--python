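"""Large-deletion detection from capture read depth.

The detector works on per-base depth from a multi-sample capture run:

1. tile each capture target with fixed-size windows and bin per-base depth
   into per-window means;
2. scale every sample to the cohort median library size;
3. build a pooled per-window reference (median across samples);
4. compute per-window log2 ratios M = log2(sample / reference) with a
   pseudocount, clamped to ±5;
5. mean-shift normalize M to zero;
6. aggregate M per exon (mean plus 25th/75th percentile);
7. call maximal runs of depressed exons as deletions, classifying them as
   homozygous, heterozygous or mosaic and inverting the depth model to an
   estimated mosaic fraction f (depth ratio = 1 − f/2 for a heterozygous
   deletion carried by a fraction f of genomes; an equimolar mixture of a
   carrier and a normal sample gives f = 0.5 and M ≈ log2(3/4) ≈ −0.42,
   i.e. one allele lost in a four-copy background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import DepthTrack, GeneModel, TargetRegion

__all__ = [
    "Window",
    "WindowCountMatrix",
    "WindowRatioTrack",
    "ExonSummary",
    "DeletionCall",
    "CnvThresholds",
    "make_windows",
    "bin_depth",
    "library_size_normalize",
    "build_reference",
    "log2_ratio_track",
    "mean_shift_normalize",
    "aggregate_exons",
    "call_deletions",
    "estimate_mosaic_fraction",
    "project_orf",
    "run_cnv_pipeline",
    "write_ratio_tsv",
    "write_exon_summary_tsv",
    "write_calls_tsv",
    "plot_gene",
]

M_CLAMP = 5.0
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_WINDOW = 100
DEFAULT_STEP = 100


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window must have positive width")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and self.start < end and start < self.end


@dataclass
class WindowCountMatrix:
    """Per-(sample, window) mean per-base depth with library scaling factors."""

    windows: list[Window]
    samples: list[str]
    counts: np.ndarray  # shape (n_samples, n_windows)
    library_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.samples), len(self.windows)):
            raise ValueError("counts shape must be (n_samples, n_windows)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.samples.index(sample_id)]


@dataclass
class WindowRatioTrack:
    """Per-window normalized log2 depth ratio for one sample."""

    sample_id: str
    windows: list[Window]
    M: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if len(self.M) != len(self.windows):
            raise ValueError("M length must match window count")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M must be finite")


@dataclass(frozen=True)
class ExonSummary:
    gene: str
    exon_number: int  # 1-based, transcript order
    mean_M: float | None
    q25_M: float | None
    q75_M: float | None
    n_windows: int

    def __post_init__(self) -> None:
        if self.n_windows > 0 and self.q25_M is not None and self.q75_M is not None:
            if self.q25_M > self.q75_M + 1e-12:
                raise ValueError("q25 must not exceed q75")


@dataclass(frozen=True)
class DeletionCall:
    gene: str
    first_exon: int
    last_exon: int
    mean_M: float
    zygosity_class: str  # hom | het | mosaic | gain
    mosaic_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.first_exon > self.last_exon:
            raise ValueError("first_exon must be <= last_exon")
        if self.zygosity_class not in ("hom", "het", "mosaic", "gain"):
            raise ValueError(f"unknown class {self.zygosity_class}")


@dataclass(frozen=True)
class CnvThresholds:
    """Calling thresholds on the normalized log2 ratio scale.

    ``het_M`` flags exons in the constitutional regime (midpoint between the
    diploid 0 and the heterozygous −1, biased toward specificity); in mosaic
    mode the flag threshold drops to ``mosaic_M`` to keep sensitivity for
    diluted deletions. ``q75_guard`` requires the bulk of an exon's windows
    to be depressed, not just its mean. Runs at or below ``hom_M`` are
    homozygous losses; gains (``gain_M``) are off by default.
    """

    het_M: float = -0.65
    hom_M: float = -3.0
    mosaic_M: float = -0.2
    q75_guard: float = -0.2
    gain_M: float = 0.4
    call_gains: bool = False


# ---------------------------------------------------------------------------
# windowing and binning
# ---------------------------------------------------------------------------


def make_windows(targets: Sequence[TargetRegion], size: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> list[Window]:
    """Tile each capture target with windows of ``size`` bp every ``step`` bp.

    Windows start at the target start, never span two targets, and the final
    window of each target is truncated at the target end. ``step > size``
    would leave uncovered gaps and is rejected.
    """
    if size < 20:
        raise ValueError("window size must be >= 20 bp")
    if not 1 <= step <= size:
        raise ValueError("require 1 <= step <= size (gaps would drop signal)")
    windows: list[Window] = []
    by_chrom: dict[str, list[TargetRegion]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    idx = 0
    for chrom in sorted(by_chrom):
        for t in sorted(by_chrom[chrom], key=lambda r: r.start):
            for start in range(t.start, t.end, step):
                windows.append(Window(chrom, start, min(start + size, t.end), idx))
                idx += 1
    return windows


def bin_depth(track: DepthTrack, windows: Sequence[Window], stat: str = "mean") -> np.ndarray:
    """Bin per-base depth into per-window values.

    ``stat="mean"`` returns (sum of per-base depth)/(window width) — absent
    positions count as zero; ``stat="sum"`` returns the integer window sums,
    which conserve total depth exactly when windows partition the targets.
    """
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    sums = np.zeros(len(windows), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        starts = np.array([windows[i].start for i in idxs])
        ends = np.array([windows[i].end for i in idxs])
        sums[idxs] = track.window_sums(chrom, starts, ends)
    if stat == "sum":
        return sums
    widths = np.array([w.width for w in windows], dtype=float)
    return sums / widths


def build_count_matrix(tracks: Sequence[DepthTrack], windows: Sequence[Window]) -> WindowCountMatrix:
    counts = np.vstack([bin_depth(t, windows) for t in tracks]) if tracks else np.zeros((0, len(windows)))
    return WindowCountMatrix(list(windows), [t.sample_id for t in tracks], counts)


# ---------------------------------------------------------------------------
# normalization, reference, ratios
# ---------------------------------------------------------------------------


def library_size_normalize(matrix: WindowCountMatrix) -> WindowCountMatrix:
    """Scale each sample so its total count equals the cohort median total."""
    if not matrix.samples:
        raise ValueError("need at least one sample")
    totals = matrix.counts.sum(axis=1)
    for sample, total in zip(matrix.samples, totals):
        if total <= 0:
            raise ValueError(f"sample {sample} has all-zero counts")
    target = float(np.median(totals))
    factors = target / totals
    return WindowCountMatrix(
        matrix.windows,
        list(matrix.samples),
        matrix.counts * factors[:, None],
        {s: float(f) for s, f in zip(matrix.samples, factors)},
    )


def build_reference(
    matrix: WindowCountMatrix,
    exclude_self: bool = False,
    test_sample: str | None = None,
) -> np.ndarray:
    """Per-window pooled reference: the median across samples' normalized counts.

    By default all samples (including the test sample) are pooled; with
    ``exclude_self`` the test sample's own row is dropped.
    """
    rows = matrix.counts
    if exclude_self:
        if test_sample is None:
            raise ValueError("exclude_self requires test_sample")
        if len(matrix.samples) < 2:
            raise ValueError("exclude_self requires >= 2 samples")
        keep = [i for i, s in enumerate(matrix.samples) if s != test_sample]
        rows = matrix.counts[keep]
    return np.median(rows, axis=0)


def log2_ratio_track(
    sample_counts: np.ndarray,
    reference: np.ndarray,
    windows: Sequence[Window],
    sample_id: str = "",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> WindowRatioTrack:
    """Unnormalized per-window M = log2((count + pc)/(reference + pc)), clamped to ±5."""
    sample_counts = np.asarray(sample_counts, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample_counts.shape != reference.shape:
        raise ValueError("sample and reference vectors differ in length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    M = np.log2((sample_counts + pseudocount) / (reference + pseudocount))
    M = np.clip(M, -M_CLAMP, M_CLAMP)
    return WindowRatioTrack(sample_id, list(windows), M, normalized=False)


def mean_shift_normalize(track: WindowRatioTrack) -> WindowRatioTrack:
    """Shift M so its mean is zero (within 1e-9)."""
    if len(track.M) == 0:
        raise ValueError("cannot normalize an empty track")
    return WindowRatioTrack(track.sample_id, track.windows, track.M - track.M.mean(), normalized=True)


# ---------------------------------------------------------------------------
# exon aggregation and calling
# ---------------------------------------------------------------------------


def aggregate_exons(track: WindowRatioTrack, model: GeneModel) -> list[ExonSummary]:
    """Per-exon mean and 25th/75th percentile of assigned window M values.

    A window is assigned to an exon iff it overlaps it by at least 1 bp.
    Quantiles use linear interpolation between order statistics. Exons with
    no overlapping window are reported with n_windows=0 and absent summaries.
    """
    if not track.normalized:
        raise ValueError("track must be mean-shift normalized first")
    on_chrom = np.array([w.chrom == model.chrom for w in track.windows])
    starts = np.array([w.start for w in track.windows], dtype=np.int64)
    ends = np.array([w.end for w in track.windows], dtype=np.int64)
    summaries: list[ExonSummary] = []
    for number in range(1, model.n_exons + 1):
        es, ee = model.exon_interval(number)
        vals = track.M[on_chrom & (starts < ee) & (ends > es)]
        if vals.size == 0:
            summaries.append(ExonSummary(model.gene, number, None, None, None, 0))
        else:
            summaries.append(
                ExonSummary(
                    model.gene,
                    number,
                    float(vals.mean()),
                    float(np.percentile(vals, 25)),
                    float(np.percentile(vals, 75)),
                    int(vals.size),
                )
            )
    return summaries


def estimate_mosaic_fraction(M: float) -> float:
    """Invert the heterozygous-deletion dilution model.

    A het deletion in a fraction f of genomes gives depth ratio 1 − f/2,
    so f = 2·(1 − 2^M), clamped to [0, 1]. M = −1 is a constitutional het
    deletion (f = 1); M = log2(3/4) is one allele lost in a four-copy
    background (f = 0.5).
    """
    if M > 0:
        raise ValueError("M > 0 is a gain, not a deletion")
    return float(np.clip(2.0 * (1.0 - 2.0 ** M), 0.0, 1.0))


def call_deletions(
    summaries: Sequence[ExonSummary],
    thresholds: CnvThresholds = CnvThresholds(),
    mosaic_mode: bool = False,
) -> list[DeletionCall]:
    """Merge maximal runs of depressed exons into deletion calls.

    An exon is flagged when its mean M is at or below the active threshold
    (``mosaic_M`` in mosaic mode, else ``het_M``) and its 75th percentile is
    at or below ``q75_guard``. Consecutive flagged exons merge into one call;
    single-exon calls are permitted. Run class: hom when the run mean is at
    or below ``hom_M``; mosaic when mosaic mode is on and the run mean is
    above −0.8; otherwise het.
    """
    genes = {s.gene for s in summaries}
    if len(genes) > 1:
        raise ValueError(f"summaries mix genes: {sorted(genes)}")
    flag_M = thresholds.mosaic_M if mosaic_mode else thresholds.het_M

    def flagged(s: ExonSummary) -> bool:
        return (
            s.n_windows > 0
            and s.mean_M is not None
            and s.mean_M <= flag_M
            and s.q75_M <= thresholds.q75_guard
        )

    calls: list[DeletionCall] = []
    ordered = sorted(summaries, key=lambda s: s.exon_number)
    run: list[ExonSummary] = []

    def close_run() -> None:
        if not run:
            return
        vals = [s.mean_M for s in run]
        run_mean = float(np.mean(vals))
        if run_mean <= thresholds.hom_M:
            cls, f = "hom", None
        elif mosaic_mode and run_mean > -0.8:
            cls = "mosaic"
            f = estimate_mosaic_fraction(min(run_mean, 0.0))
        else:
            cls = "het"
            f = estimate_mosaic_fraction(min(run_mean, 0.0))
        calls.append(
            DeletionCall(run[0].gene, run[0].exon_number, run[-1].exon_number, run_mean, cls, f)
        )
        run.clear()

    for s in ordered:
        if flagged(s):
            if run and s.exon_number != run[-1].exon_number + 1:
                close_run()
            run.append(s)
        else:
            close_run()
    close_run()

    if thresholds.call_gains:
        gain_run: list[ExonSummary] = []

        def close_gain() -> None:
            if not gain_run:
                return
            run_mean = float(np.mean([s.mean_M for s in gain_run]))
            calls.append(
                DeletionCall(gain_run[0].gene, gain_run[0].exon_number, gain_run[-1].exon_number, run_mean, "gain", None)
            )
            gain_run.clear()

        for s in ordered:
            if s.n_windows > 0 and s.mean_M is not None and s.mean_M >= thresholds.gain_M:
                if gain_run and s.exon_number != gain_run[-1].exon_number + 1:
                    close_gain()
                gain_run.append(s)
            else:
                close_gain()
        close_gain()

    return sorted(calls, key=lambda c: (c.first_exon, c.last_exon))


# ---------------------------------------------------------------------------
# projections and output
# ---------------------------------------------------------------------------


def project_orf(track: WindowRatioTrack, summaries: Sequence[ExonSummary], model: GeneModel):
    """Plot-ready series on the ORF and exon scales.

    ORF scale: one row per window overlapping the transcript span, with an
    exonic flag (>=1 bp overlap with any exon). Exon scale: one row per exon
    with the mean and quartile bars.
    """
    import pandas as pd

    if not track.normalized:
        raise ValueError("track must be normalized")
    orf_rows = []
    for w, m in zip(track.windows, track.M):
        if not w.overlaps(model.chrom, model.tx_start, model.tx_end):
            continue
        exonic = any(
            w.overlaps(model.chrom, es, ee)
            for es, ee in zip(model.exon_starts, model.exon_ends)
        )
        orf_rows.append({"chrom": w.chrom, "start": w.start, "end": w.end, "M": m, "exonic": exonic})
    orf = pd.DataFrame(orf_rows, columns=["chrom", "start", "end", "M", "exonic"])
    exon = pd.DataFrame(
        [
            {
                "gene": s.gene,
                "exon": s.exon_number,
                "mean_M": s.mean_M,
                "q25_M": s.q25_M,
                "q75_M": s.q75_M,
                "n_windows": s.n_windows,
            }
            for s in sorted(summaries, key=lambda s: s.exon_number)
        ],
        columns=["gene", "exon", "mean_M", "q25_M", "q75_M", "n_windows"],
    )
    return orf, exon


def plot_gene(track: WindowRatioTrack, summaries: Sequence[ExonSummary], model: GeneModel, path: str | Path) -> None:
    """Two-panel figure: per-window M along the ORF (exonic windows highlighted)
    and per-exon mean M with quartile error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    orf, exon = project_orf(track, summaries, model)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6))
    if not orf.empty:
        mid = (orf["start"] + orf["end"]) / 2
        colors = np.where(orf["exonic"], "red", "black")
        ax1.scatter(mid, orf["M"], c=colors, s=8)
    ax1.axhline(0, color="grey", lw=0.5)
    ax1.set_ylabel("M (log2 ratio)")
    ax1.set_title(f"{model.gene} — {track.sample_id}")
    covered = exon.dropna(subset=["mean_M"])
    if not covered.empty:
        yerr = np.vstack(
            [covered["mean_M"] - covered["q25_M"], covered["q75_M"] - covered["mean_M"]]
        )
        ax2.errorbar(covered["exon"], covered["mean_M"], yerr=np.abs(yerr), fmt="o", ms=4, capsize=2)
    ax2.axhline(0, color="grey", lw=0.5)
    ax2.set_xlabel("exon")
    ax2.set_ylabel("mean M per exon")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_ratio_tsv(path: str | Path, track: WindowRatioTrack) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tM\n")
        for w, m in zip(track.windows, track.M):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{m:.6f}\n")


def write_exon_summary_tsv(path: str | Path, summaries: Sequence[ExonSummary]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\texon\tmean_M\tq25_M\tq75_M\tn_windows\n")
        for s in summaries:
            fmt = lambda v: "NA" if v is None else f"{v:.6f}"
            fh.write(f"{s.gene}\t{s.exon_number}\t{fmt(s.mean_M)}\t{fmt(s.q25_M)}\t{fmt(s.q75_M)}\t{s.n_windows}\n")


def write_calls_tsv(path: str | Path, calls: Sequence[DeletionCall]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tfirst_exon\tlast_exon\tclass\tmean_M\tmosaic_fraction\n")
        for c in calls:
            f = "NA" if c.mosaic_fraction is None else f"{c.mosaic_fraction:.4f}"
            fh.write(f"{c.gene}\t{c.first_exon}\t{c.last_exon}\t{c.zygosity_class}\t{c.mean_M:.4f}\t{f}\n")


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------


@dataclass
class CnvResult:
    """Per-sample output of the cohort pipeline."""

    track: WindowRatioTrack
    summaries: dict[str, list[ExonSummary]]  # gene -> exon summaries
    calls: list[DeletionCall]


def run_cnv_pipeline(
    targets: Sequence[TargetRegion],
    models: Sequence[GeneModel],
    tracks: Sequence[DepthTrack],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    thresholds: CnvThresholds = CnvThresholds(),
    mosaic_mode: bool = False,
    exclude_self: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, CnvResult]:
    """End-to-end deletion screen over a cohort of depth tracks.

    Returns one :class:`CnvResult` per sample, keyed by sample id.
    """
    if len(tracks) < 2:
        raise ValueError("pooled reference requires >= 2 samples")
    windows = make_windows(targets, window, step)
    matrix = library_size_normalize(build_count_matrix(tracks, windows))
    results: dict[str, CnvResult] = {}
    for sample in matrix.samples:
        reference = build_reference(matrix, exclude_self=exclude_self, test_sample=sample)
        raw = log2_ratio_track(matrix.row(sample), reference, windows, sample, pseudocount)
        norm = mean_shift_normalize(raw)
        summaries: dict[str, list[ExonSummary]] = {}
        calls: list[DeletionCall] = []
        for model in models:
            s = aggregate_exons(norm, model)
            summaries[model.gene] = s
            calls.extend(call_deletions(s, thresholds, mosaic_mode))
        results[sample] = CnvResult(norm, summaries, calls)
    return results
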