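"""Coverage tracks, replicate QC, narrow-peak calling, and peak filtering.

The peak caller is a self-contained Poisson model: each bin of the IP track
is tested against the larger of a local control mean and the genome-wide
control mean (control scaled to the IP library size), p-values are corrected
genome-wide by Benjamini-Hochberg, significant bins are merged into peaks,
and peaks below a minimum width are dropped.  Replicate reconciliation and
hyper-ChIPable-region (HCR) masking implement the study-design filters:
a region must be detected in every replicate with >2-fold enrichment in at
least one, and any peak touching an HCR is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CoverageTrack",
    "Peak",
    "PeakSet",
    "cpm_normalize",
    "rebin",
    "replicate_correlation",
    "call_narrow_peaks",
    "reconcile_replicates",
    "mask_hcr",
    "read_bedgraph",
    "write_bedgraph",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed_intervals",
    "write_bed_intervals",
]


@dataclass
class CoverageTrack:
    """Fixed-bin read-density track over a genome.

    ``values`` maps chromosome name to a float vector of length
    ``ceil(chrom_length / bin_size)``.  ``library_size`` is the total mapped
    read count used for counts-per-million (CPM) scaling.
    """

    sample_id: str
    bin_size: int
    values: dict[str, np.ndarray]
    library_size: float
    condition: str = ""
    units: str = "counts"

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for c, v in self.values.items():
            if np.any(v < 0):
                raise ValueError(f"negative coverage on {c}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def concat(self) -> np.ndarray:
        """All bins as one vector (chromosome order of ``values``)."""
        return np.concatenate([self.values[c] for c in self.values])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean bin value over genomic interval [start, end)."""
        v = self.values[chrom]
        i0 = max(0, start // self.bin_size)
        i1 = min(len(v), -(-end // self.bin_size))
        if i1 <= i0:
            return float("nan")
        return float(v[i0:i1].mean())


@dataclass
class Peak:
    """One called enrichment interval with its summit."""

    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    q_value: float
    replicate_support: int = 1
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie within [start, end)")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        if not (0 <= self.q_value <= 1):
            raise ValueError("q_value must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class PeakSet:
    """Sorted collection of peaks with provenance metadata."""

    peaks: list[Peak] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


# ---------------------------------------------------------------------------
# Track operations
# ---------------------------------------------------------------------------


def cpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale every bin by 1e6 / library_size (counts per million)."""
    if track.library_size <= 0:
        raise ValueError("library_size must be positive for CPM scaling")
    scale = 1e6 / track.library_size
    return replace(
        track,
        values={c: v * scale for c, v in track.values.items()},
        units="cpm",
    )


def rebin(track: CoverageTrack, new_bin: int) -> CoverageTrack:
    """Sum-pool a track onto a coarser bin grid (new_bin a multiple is not
    required; trailing partial windows are kept)."""
    if new_bin < track.bin_size or new_bin % track.bin_size:
        raise ValueError("new_bin must be a multiple of the current bin size")
    k = new_bin // track.bin_size
    out = {}
    for c, v in track.values.items():
        n = -(-len(v) // k)
        padded = np.zeros(n * k)
        padded[: len(v)] = v
        out[c] = padded.reshape(n, k).sum(axis=1)
    return replace(track, bin_size=new_bin, values=out)


def replicate_correlation(
    a: CoverageTrack, b: CoverageTrack, corr_bin: int = 1000
) -> float:
    """Genome-wide Pearson correlation between two tracks at ``corr_bin``."""
    if set(a.values) != set(b.values):
        raise ValueError("tracks cover different chromosomes")
    x = rebin(a, corr_bin).concat()
    y = rebin(b, corr_bin).concat()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant track")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


def poisson_bin_pvalues(
    ip: CoverageTrack,
    control: CoverageTrack,
    local_window: int = 1000,
) -> dict[str, np.ndarray]:
    """Per-bin Poisson upper-tail p-values of IP counts vs control rate.

    The expected rate per bin is max(local control mean, genome-wide control
    mean), with the control scaled to the IP library size.  Returned per
    chromosome, aligned with the track bins.
    """
    if control.total() == 0:
        raise ValueError("all-zero control: cannot form a background model")
    scale = ip.library_size / control.library_size
    genome_mean = control.total() / sum(len(v) for v in control.values.values())
    k = max(1, local_window // control.bin_size)
    out: dict[str, np.ndarray] = {}
    for chrom, x in ip.values.items():
        c = control.values[chrom]
        kernel = np.ones(k) / k
        local = np.convolve(c, kernel, mode="same")
        lam = np.maximum(local, genome_mean) * scale
        out[chrom] = stats.poisson.sf(np.round(x) - 1, lam)
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def call_narrow_peaks(
    ip: CoverageTrack,
    control: CoverageTrack,
    fdr: float = 0.05,
    merge_gap: int = 300,
    min_width: int = 50,
    local_window: int = 1000,
) -> PeakSet:
    """Call narrow peaks on one IP/control track pair.

    Significant bins (BH q <= fdr) are merged when separated by at most
    ``merge_gap`` bp; merged intervals narrower than ``min_width`` are
    dropped.  The summit is the leftmost maximal IP bin within the peak;
    fold enrichment is the ratio of mean IP CPM to mean control CPM over
    the peak interval.
    """
    pvals = poisson_bin_pvalues(ip, control, local_window=local_window)
    chroms = list(pvals)
    lengths = [len(pvals[c]) for c in chroms]
    flat_q = bh_qvalues(np.concatenate([pvals[c] for c in chroms]))
    qvals: dict[str, np.ndarray] = {}
    off = 0
    for c, n in zip(chroms, lengths):
        qvals[c] = flat_q[off : off + n]
        off += n

    ip_cpm = cpm_normalize(ip)
    ctl_cpm = cpm_normalize(control)
    bs = ip.bin_size
    gap_bins = merge_gap // bs

    peaks: list[Peak] = []
    for chrom in chroms:
        sig = np.flatnonzero(qvals[chrom] <= fdr)
        if sig.size == 0:
            continue
        # merge significant bins separated by <= gap_bins
        breaks = np.flatnonzero(np.diff(sig) > gap_bins + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sig.size - 1]])
        for s, e in zip(starts, ends):
            b0, b1 = sig[s], sig[e] + 1
            start, end = b0 * bs, b1 * bs
            if end - start < min_width:
                continue
            x = ip.values[chrom][b0:b1]
            summit_bin = b0 + int(np.argmax(x))  # leftmost maximum
            num = ip_cpm.values[chrom][b0:b1].mean()
            den = ctl_cpm.values[chrom][b0:b1].mean()
            fold = float(num / den) if den > 0 else float("inf")
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit_bin * bs,
                    fold_enrichment=fold,
                    q_value=float(qvals[chrom][b0:b1].min()),
                )
            )
    return PeakSet(
        peaks=peaks,
        sample_ids=[ip.sample_id],
        params={
            "fdr": fdr,
            "merge_gap": merge_gap,
            "min_width": min_width,
            "local_window": local_window,
        },
    )


# ---------------------------------------------------------------------------
# Replicate reconciliation and HCR masking
# ---------------------------------------------------------------------------


def _overlap_clusters(peaks: Sequence[tuple[Peak, int]]) -> list[list[tuple[Peak, int]]]:
    """Group (peak, replicate-index) pairs into >=1 bp overlap chains."""
    by_chrom: dict[str, list[tuple[Peak, int]]] = {}
    for p, i in peaks:
        by_chrom.setdefault(p.chrom, []).append((p, i))
    clusters: list[list[tuple[Peak, int]]] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        current: list[tuple[Peak, int]] = []
        current_end = -1
        for p, i in items:
            if current and p.start < current_end:
                current.append((p, i))
                current_end = max(current_end, p.end)
            else:
                if current:
                    clusters.append(current)
                current = [(p, i)]
                current_end = p.end
        if current:
            clusters.append(current)
    return clusters


def reconcile_replicates(
    peaksets: Sequence[PeakSet], fold_threshold: float = 2.0
) -> PeakSet:
    """Keep regions detected in every replicate with strong enrichment.

    A region (a >=1 bp overlap chain across the pooled peaks) is retained
    iff every replicate contributes at least one peak to the chain AND the
    maximum fold enrichment across its peaks is strictly greater than
    ``fold_threshold``.  The output interval is the union extent of the
    supporting peaks; the summit is taken from the highest-fold peak.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two replicate peak sets")
    pooled = [(p, i) for i, ps in enumerate(peaksets) for p in ps]
    retained: list[Peak] = []
    n_reps = len(peaksets)
    for cluster in _overlap_clusters(pooled):
        reps = {i for _, i in cluster}
        if len(reps) < n_reps:
            continue
        best = max(cluster, key=lambda t: t[0].fold_enrichment)[0]
        if best.fold_enrichment <= fold_threshold:
            continue
        start = min(p.start for p, _ in cluster)
        end = max(p.end for p, _ in cluster)
        retained.append(
            Peak(
                chrom=best.chrom,
                start=start,
                end=end,
                summit=best.summit,
                fold_enrichment=best.fold_enrichment,
                q_value=min(p.q_value for p, _ in cluster),
                replicate_support=n_reps,
            )
        )
    return PeakSet(
        peaks=retained,
        sample_ids=sorted({s for ps in peaksets for s in ps.sample_ids}),
        params={"fold_threshold": fold_threshold, "n_replicates": n_reps},
    )


def mask_hcr(
    peaks: PeakSet, hcr: Iterable[tuple[str, int, int]]
) -> tuple[PeakSet, PeakSet]:
    """Split peaks into (retained, removed) by >=1 bp overlap with HCRs."""
    hcr_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in hcr:
        hcr_by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    kept, removed = [], []
    for p in peaks:
        hit = any(
            p.start < e and s < p.end for s, e in hcr_by_chrom.get(p.chrom, [])
        )
        (removed if hit else kept).append(p)
    meta = dict(sample_ids=peaks.sample_ids, params=peaks.params)
    return PeakSet(peaks=kept, **meta), PeakSet(peaks=removed, **meta)


# ---------------------------------------------------------------------------
# I/O: bedGraph, narrowPeak, BED
# ---------------------------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a fixed-bin track as bedGraph (runs of equal value merged)."""
    bs = track.bin_size
    with Path(path).open("w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.sample_id}" '
            f"medlsm_bin={bs} medlsm_library={track.library_size:g} "
            f'medlsm_condition="{track.condition}"\n'
        )
        for chrom, v in track.values.items():
            i = 0
            n = len(v)
            while i < n:
                j = i
                while j + 1 < n and v[j + 1] == v[i]:
                    j += 1
                fh.write(f"{chrom}\t{i * bs}\t{(j + 1) * bs}\t{v[i]:g}\n")
                i = j + 1


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> CoverageTrack:
    """Read a bedGraph written by :func:`write_bedgraph` back into a track."""
    path = Path(path)
    bin_size = None
    library = None
    sample_id = path.stem
    condition = ""
    rows: list[tuple[str, int, int, float]] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("track"):
                for tok in line.split():
                    if tok.startswith("medlsm_bin="):
                        bin_size = int(tok.split("=")[1])
                    elif tok.startswith("medlsm_library="):
                        library = float(tok.split("=")[1])
                    elif tok.startswith("name="):
                        sample_id = tok.split("=")[1].strip('"')
                    elif tok.startswith("medlsm_condition="):
                        condition = tok.split("=")[1].strip('"')
                continue
            chrom, start, end, value = line.split()
            rows.append((chrom, int(start), int(end), float(value)))
    if bin_size is None:
        # infer from the smallest interval
        bin_size = min(e - s for _, s, e, _ in rows)
    ends: dict[str, int] = {}
    for chrom, _, end, _ in rows:
        ends[chrom] = max(ends.get(chrom, 0), end)
    if chrom_sizes:
        ends.update(chrom_sizes)
    values = {
        c: np.zeros(-(-size // bin_size)) for c, size in ends.items()
    }
    for chrom, start, end, value in rows:
        values[chrom][start // bin_size : end // bin_size] = value
    if library is None:
        library = sum(v.sum() for v in values.values())
    return CoverageTrack(
        sample_id=sample_id,
        bin_size=bin_size,
        values=values,
        library_size=library,
        condition=condition,
    )


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    """Write peaks in ENCODE narrowPeak (BED6+4) format.

    Column 10 is the summit offset from the peak start; p-value column is
    unused (-1); q-value is stored as -log10.
    """
    with Path(path).open("w") as fh:
        for i, p in enumerate(peaks):
            q = -np.log10(max(p.q_value, 1e-300))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t"
                f"{min(1000, int(round(10 * p.fold_enrichment)))}\t.\t"
                f"{p.fold_enrichment:.4f}\t-1\t{q:.4f}\t{p.summit - p.start}\n"
            )


def read_narrowpeak(path: str | Path) -> PeakSet:
    peaks = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            fold = float(f[6])
            q = 10 ** (-float(f[8])) if float(f[8]) >= 0 else 1.0
            summit = start + int(f[9])
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    fold_enrichment=fold,
                    q_value=min(q, 1.0),
                    name=name,
                )
            )
    return PeakSet(peaks=peaks)


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED3+ file."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed_intervals(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
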