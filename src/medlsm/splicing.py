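"""Splice-ratio estimation and grouped expression comparisons from paired
whole-gene / exon-only count matrices.

Intron-mapped reads for an intron-containing (IC) gene are the difference
between its whole-gene and exon-only counts.  The splice ratio compares the
length-normalized intron read density with the exon read density::

    I = max(G - E, 0)
    s = clamp(1 - (I / Li) / (E / Le), 0, 1)

so a fully spliced transcript pool (no intron reads) gives s = 1 and equal
intron/exon densities (no splicing) give s = 0.  Multi-intron genes pool
their introns: Li is the total intron length and I the pooled intron count,
since exon/gene counting cannot resolve individual introns.  The statistic
is undefined when E = 0 (a 0/0 density ratio carries no information) and
such gene-samples are excluded from averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "filter_ic_genes",
    "normalize_libraries",
    "splice_ratio",
    "splice_table",
    "splice_ratio_by_timepoint",
    "expression_summary",
    "compare_groups",
    "PairedTestResult",
]

COUNT_MODES = ("whole_gene", "exon_only")


@dataclass
class CountMatrix:
    """Gene x sample counts in one counting mode, with sample metadata.

    ``samples`` is indexed by sample name with columns ``time_point``
    (integer), ``time_label``, ``batch`` and ``library_size``.  Batch labels
    are carried through but never used for correction; inputs are assumed
    already batch-adjusted.
    """

    mode: str
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mode not in COUNT_MODES:
            raise ValueError(f"unknown counting mode {self.mode!r}")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample metadata disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def library_sizes(self) -> pd.Series:
        return self.samples["library_size"]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Two metadata header lines (mode + per-sample fields), then counts."""
        with Path(path).open("w") as fh:
            fh.write(f"#mode={self.mode}\n")
            meta = ";".join(
                f"{s}:{int(r.time_point)}:{r.time_label}:{r.batch}:{r.library_size:g}"
                for s, r in self.samples.iterrows()
            )
            fh.write(f"#samples={meta}\n")
            self.counts.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        with path.open() as fh:
            mode_line = fh.readline().strip()
            meta_line = fh.readline().strip()
        mode = mode_line.split("=", 1)[1]
        rows = []
        for entry in meta_line.split("=", 1)[1].split(";"):
            name, tp, label, batch, lib = entry.split(":")
            rows.append((name, int(tp), label, batch, float(lib)))
        samples = pd.DataFrame(
            [(r[1], r[2], r[3], r[4]) for r in rows],
            columns=["time_point", "time_label", "batch", "library_size"],
            index=pd.Index([r[0] for r in rows], name="sample"),
        )
        counts = pd.read_csv(path, sep="\t", skiprows=2, index_col="gene_id")
        return cls(mode=mode, counts=counts, samples=samples)


def validate_paired(
    whole: CountMatrix, exon: CountMatrix, clamp: bool = True
) -> tuple[CountMatrix, CountMatrix]:
    """Check a whole-gene / exon-only pair; clamp G < E artifacts upward.

    Real exon/gene counters only approximately guarantee G >= E; offending
    entries are clamped (G := E) with a logged count.
    """
    if whole.mode != "whole_gene" or exon.mode != "exon_only":
        raise ValueError("expected (whole_gene, exon_only) matrices")
    if not whole.counts.index.equals(exon.counts.index):
        raise ValueError("gene indices differ")
    deficit = (whole.counts < exon.counts).to_numpy().sum()
    if deficit:
        logger.warning("clamping %d gene-samples with G < E", int(deficit))
        if clamp:
            whole = replace(
                whole, counts=whole.counts.where(whole.counts >= exon.counts,
                                                 exon.counts)
            )
    return whole, exon


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def filter_ic_genes(
    annot: GenomeAnnotation,
    whole_gene: CountMatrix,
    hcr_genes: Iterable[str] = (),
    min_intron: int = 25,
    min_reads: int = 75,
    per_sample: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """The IC-gene filtering cascade.

    Retains genes that (1) have at least one intron of length >=
    ``min_intron`` bp, (2) reach ``min_reads`` whole-gene counts in every
    sample (or in the sample mean if ``per_sample`` is False), and (3) are
    not associated with hyper-ChIPable regions.  Zero intron-mapped reads
    never disqualify a gene.  Returns the retained ids plus an audit table
    with exactly one exclusion reason per removed gene.
    """
    hcr_set = set(hcr_genes)
    rows = []
    retained = []
    for gid in whole_gene.gene_ids:
        gene = annot.genes_by_id.get(gid)
        reason = None
        if gene is None or not gene.is_ic:
            reason = "no_intron"
        elif max(b - a for a, b in gene.introns) < min_intron:
            reason = "intron_too_short"
        else:
            c = whole_gene.counts.loc[gid]
            enough = (c >= min_reads).all() if per_sample else c.mean() >= min_reads
            if not enough:
                reason = "low_counts"
            elif gid in hcr_set:
                reason = "hcr_associated"
        if reason is None:
            retained.append(gid)
        rows.append({"gene_id": gid, "retained": reason is None,
                     "reason": reason})
    return retained, pd.DataFrame(rows).set_index("gene_id")


def normalize_libraries(counts: CountMatrix) -> CountMatrix:
    """Scale every sample to the average library size."""
    libs = counts.library_sizes()
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    target = libs.mean()
    scaled = counts.counts * (target / libs)
    samples = counts.samples.copy()
    samples["library_size"] = target
    return replace(counts, counts=scaled, samples=samples)


# ---------------------------------------------------------------------------
# Splice ratio
# ---------------------------------------------------------------------------


def splice_ratio(E: float, G: float, Le: float, Li: float) -> float:
    """Length-normalized splice ratio in [0, 1]; NaN when E = 0."""
    if Le <= 0 or Li <= 0:
        raise ValueError("exon and intron lengths must be positive")
    if E == 0:
        return float("nan")
    I = max(G - E, 0.0)
    return float(np.clip(1.0 - (I / Li) / (E / Le), 0.0, 1.0))


def splice_table(
    annot: GenomeAnnotation,
    whole: CountMatrix,
    exon: CountMatrix,
    gene_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene, per-sample splice ratios (tidy table).

    Columns: gene_id, sample, time_point, exon_count, gene_count,
    intron_count, splice_ratio (NaN where undefined).
    """
    whole, exon = validate_paired(whole, exon)
    ids = list(gene_ids) if gene_ids is not None else whole.gene_ids
    le = {g.id: g.total_exon_length for g in annot.genes}
    li = {g.id: g.total_intron_length for g in annot.genes}
    rows = []
    for gid in ids:
        if li.get(gid, 0) <= 0:
            continue
        ge = exon.counts.loc[gid]
        gw = whole.counts.loc[gid]
        for sample in whole.counts.columns:
            E, G = float(ge[sample]), float(gw[sample])
            rows.append(
                {
                    "gene_id": gid,
                    "sample": sample,
                    "time_point": int(whole.samples.loc[sample, "time_point"]),
                    "exon_count": E,
                    "gene_count": G,
                    "intron_count": max(G - E, 0.0),
                    "splice_ratio": splice_ratio(E, G, le[gid], li[gid]),
                }
            )
    return pd.DataFrame(rows)


def splice_ratio_by_timepoint(table: pd.DataFrame) -> pd.DataFrame:
    """Average splice ratios over replicates: genes x time points.

    Undefined (NaN) gene-samples are excluded from the averages.
    """
    return table.pivot_table(
        index="gene_id", columns="time_point", values="splice_ratio",
        aggfunc="mean",
    )


def expression_summary(
    counts: CountMatrix, gene_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Mean normalized counts per gene per time point (replicate averages)."""
    sub = counts.counts if gene_ids is None else counts.counts.loc[list(gene_ids)]
    tps = counts.samples["time_point"]
    return sub.T.groupby(tps).mean().T


# ---------------------------------------------------------------------------
# Grouped paired comparisons
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    group: str
    n: int
    t_statistic: float
    p_value: float
    mean_t0: float
    mean_t1: float
    median_t0: float
    median_t1: float
    degenerate: bool = False
    warning: Optional[str] = None


def compare_groups(
    values: pd.DataFrame,
    groups: Mapping[str, str],
    t0: int,
    t1: int,
) -> dict[str, PairedTestResult]:
    """Two-sided paired t-tests of per-gene values between two time points.

    ``values`` is a genes x time-points table (e.g. replicate-averaged
    splice ratios or normalized counts); ``groups`` maps gene id -> group
    label.  Pairing is by gene.  Groups smaller than 3, or with zero
    difference variance, are reported with a flag instead of a p-value of
    convenience.
    """
    out: dict[str, PairedTestResult] = {}
    labels = sorted(set(groups.values()))
    for label in labels:
        ids = [g for g in values.index if groups.get(g) == label]
        sub = values.loc[ids, [t0, t1]].dropna()
        a, b = sub[t0].to_numpy(), sub[t1].to_numpy()
        n = len(sub)
        if n < 3:
            out[label] = PairedTestResult(
                group=label, n=n, t_statistic=float("nan"),
                p_value=float("nan"),
                mean_t0=float(np.mean(a)) if n else float("nan"),
                mean_t1=float(np.mean(b)) if n else float("nan"),
                median_t0=float(np.median(a)) if n else float("nan"),
                median_t1=float(np.median(b)) if n else float("nan"),
                warning="group smaller than 3",
            )
            continue
        diff = b - a
        if np.allclose(diff.std(ddof=1), 0.0):
            zero = np.allclose(diff.mean(), 0.0)
            out[label] = PairedTestResult(
                group=label, n=n,
                t_statistic=0.0 if zero else float(np.sign(diff.mean())) * float("inf"),
                p_value=1.0 if zero else 0.0,
                mean_t0=float(a.mean()), mean_t1=float(b.mean()),
                median_t0=float(np.median(a)), median_t1=float(np.median(b)),
                degenerate=True, warning="zero difference variance",
            )
            continue
        t, p = stats.ttest_rel(b, a)
        out[label] = PairedTestResult(
            group=label, n=n, t_statistic=float(t), p_value=float(p),
            mean_t0=float(a.mean()), mean_t1=float(b.mean()),
            median_t0=float(np.median(a)), median_t1=float(np.median(b)),
        )
    return out
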