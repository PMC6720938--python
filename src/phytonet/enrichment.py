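"""Hypergeometric over-representation analysis of target genes on pathway sets.

Given a query gene list (the surviving targets), a collection of pathway
gene sets and a gene universe, each pathway with at least one overlapping
gene is tested with the two-sided hypergeometric test: the smaller of the
upper tail P(X ≥ k) and the lower tail P(X ≤ k) is doubled and capped at 1.
Tails are accumulated in log space (log-binomials via gammaln + logsumexp)
so extreme enrichments do not underflow.  Pathways are ranked by ascending
p-value, ties by name; the reporting mirrors the usual over-representation
table: overlap genes, Nr (= k), % associated genes (100·k/K, half-up to two
decimals) and the p-value, flagged at the significance level (study default
raw p < 0.01, no multiple-testing correction; Benjamini–Hochberg optional).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import TextIO

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "PathwayAnnotation",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "two_sided_p",
    "enrich",
    "read_gmt",
    "write_gmt",
    "write_results_table",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayAnnotation:
    """Pathway gene sets plus the gene universe they are tested against."""

    pathways: list[tuple[str, str, frozenset]]  # (pathway_id, name, genes)
    universe: frozenset

    def __post_init__(self) -> None:
        names = [name for _, name, _ in self.pathways]
        if len(names) != len(set(names)):
            raise ValueError("pathway names must be unique")
        for pid, name, genes in self.pathways:
            if not genes:
                raise ValueError(f"pathway {name!r} has no genes")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"pathway {name!r} has genes outside the universe: {sorted(stray)[:5]}"
                )


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    common_genes: list[str]
    nr: int
    pct_associated: float
    p_value: float
    passes: bool
    q_value: float | None = None


def _check_params(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")


def _log_pmf(N: int, K: int, n: int, ks: np.ndarray) -> np.ndarray:
    # log C(K,k) + log C(N-K, n-k) - log C(N,n)
    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(K, ks) + logC(N - K, n - ks) - logC(N, n)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), accumulated in log space."""
    _check_params(N, K, n, k)
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 1.0
    ks = np.arange(k, hi + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf(N, K, n, ks)))))


def hypergeom_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X <= k), accumulated in log space."""
    _check_params(N, K, n, k)
    lo = max(0, n + K - N)
    if k >= min(K, n):
        return 1.0
    ks = np.arange(lo, k + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf(N, K, n, ks)))))


def two_sided_p(N: int, K: int, n: int, k: int) -> float:
    """Two-sided hypergeometric p by tail doubling, capped at 1."""
    upper = hypergeom_upper_tail(N, K, n, k)
    lower = hypergeom_lower_tail(N, K, n, k)
    return min(1.0, 2.0 * min(upper, lower))


def _pct(k: int, K: int) -> float:
    """100·k/K rounded half-up to two decimals (table formatting convention)."""
    return float(
        (Decimal(100 * k) / Decimal(K)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def enrich(
    query_genes: list[str] | set[str],
    annotation: PathwayAnnotation,
    alpha: float = 0.01,
    sided: str = "two",
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Rank pathways by hypergeometric over-representation of the query genes.

    Query genes outside the universe are logged and dropped.  Only pathways
    with overlap k >= 1 are reported, ascending by p-value then name.
    """
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    query = set(query_genes)
    stray = query - annotation.universe
    if stray:
        logger.warning("%d query genes outside the universe dropped: %s",
                       len(stray), sorted(stray)[:5])
        query -= stray
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N, n = len(annotation.universe), len(query)
    results = []
    for pid, name, genes in annotation.pathways:
        common = sorted(query & genes)
        k = len(common)
        if k < 1:
            continue
        K = len(genes)
        p = two_sided_p(N, K, n, k) if sided == "two" else hypergeom_upper_tail(N, K, n, k)
        results.append(EnrichmentResult(
            pathway_id=pid,
            pathway_name=name,
            common_genes=common,
            nr=k,
            pct_associated=_pct(k, K),
            p_value=p,
            passes=p < alpha,
        ))
    results.sort(key=lambda r: (r.p_value, r.pathway_name))
    if bh_correct and results:
        m = len(results)
        qs = [r.p_value * m / (i + 1) for i, r in enumerate(results)]
        # enforce monotonicity from the largest p downwards
        for i in range(m - 2, -1, -1):
            qs[i] = min(qs[i], qs[i + 1])
        for r, q in zip(results, qs):
            r.q_value = min(1.0, q)
    return results


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(stream: TextIO | str, universe: set[str] | None = None) -> PathwayAnnotation:
    """Parse GMT lines (name, description, genes...) into a PathwayAnnotation.

    The universe defaults to the union of all pathway genes.  Duplicate
    genes within one line are deduplicated with a warning.
    """
    text = stream if isinstance(stream, str) else stream.read()
    pathways = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name = fields[0]  # GMT: first field is the canonical set name
        genes = [g for g in fields[2:] if g]
        if len(genes) != len(set(genes)):
            logger.warning("GMT line %d (%s): duplicate genes deduplicated", lineno, name)
        pathways.append((name, name, frozenset(genes)))
    union = frozenset().union(*(g for _, _, g in pathways)) if pathways else frozenset()
    full_universe = frozenset(universe) if universe is not None else union
    return PathwayAnnotation(pathways=pathways, universe=full_universe)


def write_gmt(annotation: PathwayAnnotation) -> str:
    lines = []
    for pid, name, genes in annotation.pathways:
        lines.append("\t".join([pid, name, *sorted(genes)]))
    return "\n".join(lines) + ("\n" if lines else "")


def write_results_table(results: list[EnrichmentResult], path=None) -> str | None:
    import pandas as pd

    rows = [
        {
            "pathway": r.pathway_name,
            "common_genes": ", ".join(r.common_genes),
            "Nr": r.nr,
            "pct_associated": f"{r.pct_associated:.2f}",
            "p_value": f"{r.p_value:.3g}",
            "passes": r.passes,
            **({"q_value": f"{r.q_value:.3g}"} if r.q_value is not None else {}),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if path is None:
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    df.to_csv(path, sep="\t", index=False)
    return None
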