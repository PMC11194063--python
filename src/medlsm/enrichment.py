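"""Gene-set intersections and hypergeometric class enrichment.

Over-representation of a gene category (e.g. ribosomal-protein genes) in an
occupied gene set is tested with the one-sided hypergeometric upper tail
(Fisher exact, enrichment direction), computed in log space so that tails
far below float underflow are still meaningful.  The genome background
(population size N and category size K) is always supplied explicitly
because it depends on the annotation version.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GENE_CLASSES

__all__ = [
    "EnrichmentResult",
    "intersect_gene_sets",
    "hypergeom_enrichment",
    "class_overlap_report",
    "round_half_away",
]


@dataclass
class EnrichmentResult:
    """One-sided hypergeometric enrichment of a category in a sample.

    ``k`` of ``n`` sampled genes fall in a category of size ``K`` within a
    population of ``N``.  ``p_value`` is P(X >= k); ``log10_p`` stays finite
    when ``p_value`` underflows; ``fold`` is (k/n) / (K/N).
    """

    k: int
    n: int
    K: int
    N: int
    p_value: float
    log10_p: float
    fold: float


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Upper-tail hypergeometric test: P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(n, K)):
        raise ValueError("require 0 <= k <= min(n, K)")
    # sf(k-1) = P(X >= k); logsf keeps extreme tails representable
    logp = float(stats.hypergeom.logsf(k - 1, N, K, n))
    p = float(np.exp(logp))
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return EnrichmentResult(
        k=k, n=n, K=K, N=N,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        log10_p=logp / np.log(10),
        fold=fold,
    )


def intersect_gene_sets(
    a: Iterable[str], b: Iterable[str]
) -> dict[str, object]:
    """Partition two gene-id sets into common / a-only / b-only.

    Percentages are reported relative to each input set.
    """
    sa, sb = set(a), set(b)
    common = sa & sb
    return {
        "common": sorted(common),
        "a_only": sorted(sa - sb),
        "b_only": sorted(sb - sa),
        "n_a": len(sa),
        "n_b": len(sb),
        "n_common": len(common),
        "pct_of_a": 100.0 * len(common) / len(sa) if sa else float("nan"),
        "pct_of_b": 100.0 * len(common) / len(sb) if sb else float("nan"),
    }


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-value style)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def class_overlap_report(
    gene_sets: Mapping[str, Iterable[str]],
    classes: Mapping[str, str],
    background: Mapping[str, tuple[int, int]] | None = None,
    population_size: int | None = None,
) -> pd.DataFrame:
    """Four-way class composition of named gene sets.

    ``classes`` maps gene id -> one of the four IC/RP classes; ids missing
    from it are tallied in an ``unclassified`` column rather than dropped.
    ``background`` optionally maps a class (or the ``IC``/``RP`` margins) to
    ``(K, N)`` category/population sizes; when given together with
    ``population_size`` fallback N, an enrichment p-value column is added
    per class.  Percentages use half-away-from-zero rounding only in the
    ``*_pct_rounded`` columns; exact values are kept alongside.
    """
    rows = []
    for name, ids in gene_sets.items():
        ids = list(ids)
        counts = {c: 0 for c in GENE_CLASSES}
        unclassified = 0
        for gid in ids:
            cls = classes.get(gid)
            if cls is None:
                unclassified += 1
            else:
                counts[cls] += 1
        row: dict[str, object] = {"set": name, "n": len(ids)}
        classified = len(ids) - unclassified
        for c in GENE_CLASSES:
            row[c] = counts[c]
            pct = 100.0 * counts[c] / classified if classified else float("nan")
            row[f"{c}_pct"] = pct
            row[f"{c}_pct_rounded"] = (
                round_half_away(pct) if classified else None
            )
        row["unclassified"] = unclassified
        if background:
            for c, (K, N_c) in background.items():
                k = counts.get(c)
                if k is None:
                    # margin categories: IC = IC-RP + IC-nonRP, RP likewise
                    if c == "IC":
                        k = counts["IC-RP"] + counts["IC-nonRP"]
                    elif c == "RP":
                        k = counts["IC-RP"] + counts["nonIC-RP"]
                    else:
                        continue
                N = N_c or (population_size or 0)
                res = hypergeom_enrichment(k, classified, K, N)
                row[f"{c}_p"] = res.p_value
                row[f"{c}_log10_p"] = res.log10_p
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
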