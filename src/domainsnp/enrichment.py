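"""Hypergeometric enrichment statistics.

Everything downstream of the classifier asks variations of one question:
is an annotated subset over-represented in a sample drawn from a
population?  The answer is the exact one-tailed (upper) hypergeometric
probability ``P(X >= k)`` for ``k`` annotated items in a sample of ``n``
from a population of ``N`` containing ``K`` annotated items, evaluated in
log space so that very small tail probabilities do not underflow.

Three front-ends are provided:

* :func:`enrich_class` — one SNP/protein class against one annotation set;
* :func:`dd_sweep` — disease enrichment of DA-SNPs across a ladder of
  domain-distortion cutoffs (population = all D-SNPs);
* :func:`term_enrichment` — generic term (GO/KEGG-style) enrichment with
  Benjamini-Hochberg adjusted q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .variant_impact import da_snp_ids, snp_table

__all__ = [
    "ContingencyResult",
    "SweepRow",
    "TermResult",
    "hypergeom_upper",
    "enrich_class",
    "dd_sweep",
    "term_enrichment",
    "write_sweep",
    "write_terms",
]

#: Smallest positive double; used only to keep p strictly positive when the
#: tail is too small to represent.
_TINY = 5e-324


@dataclass(frozen=True)
class ContingencyResult:
    population_n: int
    population_k: int
    sample_n: int
    sample_k: int
    p_value: float


@dataclass(frozen=True)
class SweepRow:
    dd_cutoff: float
    n_da_snp: int
    n_da_snp_diseased: int
    p_value: float
    q_value: Optional[float] = None


@dataclass(frozen=True)
class TermResult:
    term: str
    result: ContingencyResult
    q_value: float


def _validate_contingency(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid contingency: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"invalid contingency: k={k} not in [0, min(n={n}, K={K})]")
    if k < n - (N - K):
        raise ValueError(f"invalid contingency: k={k} below forced minimum")


def _log_pmf(N: int, K: int, n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability ``P(X >= k)``.

    Computed as a log-space sum of the point masses from ``k`` to
    ``min(n, K)``; the result is clamped into ``(0, 1]``.
    """
    _validate_contingency(N, K, n, k)
    if k <= max(0, n - (N - K)):
        return 1.0
    hi = min(n, K)
    ks = np.arange(k, hi + 1)
    logp = logsumexp(_log_pmf(N, K, n, ks))
    p = float(np.exp(logp))
    return min(1.0, max(p, _TINY))


def enrich_class(sample_ids, annotated_ids, population_ids) -> ContingencyResult:
    """Enrichment of an annotation inside a sample drawn from a population.

    ``sample_ids`` must be a subset of ``population_ids``; the annotated
    set is intersected with the population before counting.
    """
    population = set(population_ids)
    sample = set(sample_ids)
    if not sample <= population:
        extra = sorted(sample - population)[:3]
        raise ValueError(f"sample is not a subset of the population (e.g. {extra})")
    annotated = set(annotated_ids) & population
    N, K, n = len(population), len(annotated), len(sample)
    k = len(sample & annotated)
    return ContingencyResult(N, K, n, k, hypergeom_upper(N, K, n, k))


def dd_sweep(
    calls,
    annotation,
    cutoffs,
    level: str = "snp",
    snp_proteins: Optional[dict] = None,
    adjust: bool = False,
) -> list:
    """Disease enrichment of DA-SNPs across DD cutoffs.

    The population is the set of all D-SNPs; at each cutoff the sample is
    the DA-SNP set (pattern-loss and profile-erasure SNPs belong to every
    cutoff's sample).  ``level`` selects whether an SNP counts as diseased
    through its own id (``"snp"``) or through its host protein
    (``"protein"``).  ``adjust=True`` adds BH q-values across the rows.
    """
    if not cutoffs:
        raise ValueError("empty cutoff list")
    table = snp_table(calls)
    pop_mask = table["in_domain"]
    population = set(table.loc[pop_mask, "snp_id"])
    if level == "snp":
        annotated = annotation.snp_ids & population
    elif level == "protein":
        prot_map = snp_proteins or dict(
            zip(table["snp_id"], table["protein_id"])
        )
        annotated = {
            s for s in population if prot_map.get(s) in annotation.protein_ids
        }
    else:
        raise ValueError(f"unknown disease id level {level!r}")

    rows = []
    for c in sorted(cutoffs):
        sample = da_snp_ids(table, c) & population
        k = len(sample & annotated)
        p = hypergeom_upper(len(population), len(annotated), len(sample), k)
        rows.append(SweepRow(c, len(sample), k, p))
    if adjust:
        q = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        rows = [
            SweepRow(r.dd_cutoff, r.n_da_snp, r.n_da_snp_diseased, r.p_value, float(qv))
            for r, qv in zip(rows, q)
        ]
    return rows


def term_enrichment(
    gene_set,
    term_to_genes: dict,
    universe,
    p_cutoff: Optional[float] = 0.01,
) -> list:
    """Generic term enrichment with BH-adjusted q-values.

    One :class:`TermResult` per term having at least one gene in the
    universe, sorted by ascending p.  q-values are computed across all
    eligible terms *before* the report is filtered at ``p_cutoff``
    (``None`` disables filtering).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not term_to_genes:
        raise ValueError("empty term mapping")
    genes = set(gene_set) & universe
    results = []
    for term in sorted(term_to_genes):
        members = set(term_to_genes[term]) & universe
        if not members:
            continue
        N, K, n = len(universe), len(members), len(genes)
        k = len(genes & members)
        results.append((term, ContingencyResult(N, K, n, k, hypergeom_upper(N, K, n, k))))
    if not results:
        return []
    q = multipletests([r.p_value for _, r in results], method="fdr_bh")[1]
    out = [TermResult(t, r, float(qv)) for (t, r), qv in zip(results, q)]
    out.sort(key=lambda tr: (tr.result.p_value, tr.term))
    if p_cutoff is not None:
        out = [tr for tr in out if tr.result.p_value <= p_cutoff]
    return out


def write_sweep(rows, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (r.dd_cutoff, r.n_da_snp, r.n_da_snp_diseased, f"{r.p_value:.6g}")
            for r in rows
        ],
        columns=["dd_cutoff", "n_da_snp", "n_da_snp_diseased", "p_value"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_terms(terms, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (
                t.term,
                t.result.population_n,
                t.result.population_k,
                t.result.sample_n,
                t.result.sample_k,
                f"{t.result.p_value:.6g}",
                f"{t.q_value:.6g}",
            )
            for t in terms
        ],
        columns=["term", "N", "K", "n", "k", "p", "q"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
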