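"""Edgetic impact of domain-altering SNPs on a PPI network.

The model: when a SNP distorts domain *d* on protein *K*, any interaction
edge (K, L) whose formation depends on *d* pairing with a signature *s*
(domain or linear motif) on the partner *L* is at risk.  Candidate
signature pairs (d, s) are found by counting, over all edges, how often a
DA-capable domain on one endpoint co-occurs with signature *s* on the
other, and testing that count against a random-partner background with
the upper-tail hypergeometric.  Enriched pairs are tiered by external
evidence: present in a reference domain-domain list (DOMINE-like role),
present in a reference domain-motif list, or supported by the enrichment
alone.  An edge is then called **broken** if the partner of a DA-SNP
protein carries at least one admitted enriched signature for the altered
domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .domain_scan import parse_pattern, scan_pattern
from .enrichment import ContingencyResult, hypergeom_upper
from .io_formats import PpiEdge

__all__ = [
    "TIER_ORDER",
    "SignatureAnnotation",
    "SignaturePairScore",
    "BrokenEdgeCall",
    "ConnectivityRow",
    "annotate_signatures",
    "build_score_matrix",
    "score_pairs",
    "call_broken_edges",
    "connectivity_report",
    "connectivity_histogram",
]

#: Evidence tiers, strongest first.  ``min_tier`` filters admit every tier
#: whose rank is >= the configured one.
TIER_ORDER = {"ddi_reference": 2, "domain_motif_reference": 1, "enrichment_only": 0}


@dataclass
class SignatureAnnotation:
    """Per-protein signature sets plus a signature-kind lookup."""

    sig_sets: dict = field(default_factory=dict)  # protein_id -> set of sig ids
    kinds: dict = field(default_factory=dict)  # sig id -> "domain" | "motif"

    def proteins(self) -> list:
        return sorted(self.sig_sets)

    def carriers(self, sig: str) -> set:
        return {p for p, sigs in self.sig_sets.items() if sig in sigs}


@dataclass(frozen=True)
class SignaturePairScore:
    altered_domain: str
    partner_signature: str
    observed: int
    contingency: ContingencyResult
    enriched: bool
    tier: str


@dataclass(frozen=True)
class BrokenEdgeCall:
    edge: PpiEdge
    da_protein: str
    altered_domain: str
    matched_signatures: tuple
    status: str  # broken | intact
    best_tier: Optional[str] = None


@dataclass(frozen=True)
class ConnectivityRow:
    protein_id: str
    gene_symbol: str
    n_broken: int
    n_intact: int


def annotate_signatures(proteome, domain_matches, motifs) -> SignatureAnnotation:
    """Signature sets per protein: domain signatures from reference-sequence
    domain matches, motif signatures from scanning the motif patterns with
    the pattern engine."""
    ann = SignatureAnnotation()
    for p in proteome:
        ann.sig_sets[p.protein_id] = set()
    for m in domain_matches:
        ann.sig_sets.setdefault(m.protein_id, set()).add(m.domain_id)
        ann.kinds[m.domain_id] = "domain"
    parsed = [(mid, parse_pattern(pat, mid)) for mid, pat in motifs]
    for p in proteome:
        for mid, pat in parsed:
            ann.kinds.setdefault(mid, "motif")
            if scan_pattern(pat, p.sequence):
                ann.sig_sets[p.protein_id].add(mid)
    return ann


def build_score_matrix(da_domains, annotations: SignatureAnnotation, edges):
    """Co-occurrence counts across edges.

    For every edge (K, L) and every DA-capable domain ``d`` carried by K,
    each signature ``s`` on L increments ``count[(d, s)]``; both edge
    orientations are evaluated.  Endpoints without annotation coverage are
    skipped and counted.  Returns ``(counts, n_skipped_edges)``.
    """
    da_domains = set(da_domains)
    counts: dict = {}
    n_skipped = 0
    for e in edges:
        if e.protein_a not in annotations.sig_sets or e.protein_b not in annotations.sig_sets:
            n_skipped += 1
            continue
        for host, partner in ((e.protein_a, e.protein_b), (e.protein_b, e.protein_a)):
            host_da = annotations.sig_sets[host] & da_domains
            if not host_da:
                continue
            for d in host_da:
                for s in annotations.sig_sets[partner]:
                    counts[(d, s)] = counts.get((d, s), 0) + 1
    return counts, n_skipped


def _normalized_pair(d: str, s: str, s_kind: str):
    """domain-domain pairs are unordered; domain-motif pairs are ordered."""
    if s_kind == "domain":
        return tuple(sorted((d, s)))
    return (d, s)


def _assign_tier(d, s, s_kind, pairlists) -> str:
    if pairlists:
        if s_kind == "domain" and "domain_domain" in pairlists:
            if _normalized_pair(d, s, "domain") in pairlists["domain_domain"].pairs:
                return "ddi_reference"
        if s_kind == "motif" and "domain_motif" in pairlists:
            if (d, s) in pairlists["domain_motif"].pairs:
                return "domain_motif_reference"
    return "enrichment_only"


def score_pairs(
    counts: dict,
    annotations: SignatureAnnotation,
    edges,
    da_domains,
    alpha: float = 0.05,
    pairlists: Optional[dict] = None,
    mode: str = "analytic",
    n_background: int = 1000,
    seed: Optional[int] = None,
) -> list:
    """Test each observed (domain, signature) pair against a random-partner
    background.

    Analytic mode (default) uses the closed-form hypergeometric with
    population = all annotated proteins, K = carriers of the signature,
    n = distinct partners of the domain's carrier proteins, and k = those
    partners carrying the signature.  Empirical mode resamples
    ``n_background`` partner sets uniformly from the proteome (seeded) and
    reports ``p = (1 + #{null >= observed k}) / (1 + n_background)``.
    Pairs whose signature occurs on no protein are skipped.
    """
    if mode not in ("analytic", "empirical"):
        raise ValueError(f"unknown background mode {mode!r}")
    if mode == "empirical" and n_background < 1:
        raise ValueError("n_background must be >= 1")
    proteins = annotations.proteins()
    index = {p: i for i, p in enumerate(proteins)}
    N = len(proteins)
    carriers = {}  # sig -> bool vector over proteins
    for p, sigs in annotations.sig_sets.items():
        for s in sigs:
            vec = carriers.get(s)
            if vec is None:
                vec = carriers[s] = np.zeros(N, dtype=bool)
            vec[index[p]] = True

    # distinct partners of each DA domain's carrier proteins
    partners: dict = {d: set() for d in set(da_domains)}
    for e in edges:
        for host, partner in ((e.protein_a, e.protein_b), (e.protein_b, e.protein_a)):
            host_sigs = annotations.sig_sets.get(host, ())
            for d in partners:
                if d in host_sigs and partner in index:
                    partners[d].add(partner)

    rng = np.random.default_rng(seed)
    out = []
    for (d, s) in sorted(counts):
        if s not in carriers or not carriers[s].any():
            continue
        part = sorted(partners.get(d, ()))
        n = len(part)
        K = int(carriers[s].sum())
        k = int(sum(carriers[s][index[p]] for p in part))
        if mode == "analytic":
            p_val = hypergeom_upper(N, K, n, k)
        else:
            draws = np.empty(n_background, dtype=np.int64)
            for b in range(n_background):
                sample = rng.choice(N, size=n, replace=False)
                draws[b] = int(carriers[s][sample].sum())
            p_val = (1 + int((draws >= k).sum())) / (1 + n_background)
        s_kind = annotations.kinds.get(s, "domain")
        tier = _assign_tier(d, s, s_kind, pairlists)
        out.append(
            SignaturePairScore(
                d, s, counts[(d, s)], ContingencyResult(N, K, n, k, p_val),
                p_val <= alpha, tier,
            )
        )
    return out


def call_broken_edges(
    calls,
    scores,
    annotations: SignatureAnnotation,
    edges,
    min_tier: str = "enrichment_only",
) -> list:
    """Per-edge broken/intact verdicts.

    For each protein P carrying a DA-SNP in domain d and each edge incident
    to P, the edge is broken iff the partner carries at least one signature
    s such that (d, s) is enriched and its evidence tier is admitted by
    ``min_tier``.  One call per (edge, DA-protein, altered domain).
    """
    if min_tier not in TIER_ORDER:
        raise ValueError(f"unknown tier {min_tier!r}")
    min_rank = TIER_ORDER[min_tier]
    admitted: dict = {}  # (d, s) -> tier
    for sc in scores:
        if sc.enriched and TIER_ORDER[sc.tier] >= min_rank:
            admitted[(sc.altered_domain, sc.partner_signature)] = sc.tier

    da_map: dict = {}  # protein -> sorted set of altered domains
    for c in calls:
        if c.status == "da_snp" and c.domain_id is not None:
            da_map.setdefault(c.protein_id, set()).add(c.domain_id)

    out = []
    for e in sorted(edges):
        for host, partner in ((e.protein_a, e.protein_b), (e.protein_b, e.protein_a)):
            if host not in da_map:
                continue
            partner_sigs = annotations.sig_sets.get(partner, set())
            for d in sorted(da_map[host]):
                matched = sorted(
                    s for s in partner_sigs if (d, s) in admitted
                )
                if matched:
                    best = max(matched, key=lambda s: TIER_ORDER[admitted[(d, s)]])
                    out.append(
                        BrokenEdgeCall(
                            e, host, d, tuple(matched), "broken",
                            admitted[(d, best)],
                        )
                    )
                else:
                    out.append(BrokenEdgeCall(e, host, d, (), "intact"))
    return out


def connectivity_report(broken_calls, edges, gene_symbols: Optional[dict] = None):
    """Per-DA-protein connectivity totals (most-broken first).

    An edge counts as broken for a protein if *any* of its altered domains
    breaks it; each edge contributes exactly once per DA-protein, so
    ``n_broken + n_intact`` equals the protein's evaluated degree.
    """
    gene_symbols = gene_symbols or {}
    broken: dict = {}  # protein -> set of broken edges
    evaluated: dict = {}  # protein -> set of evaluated edges
    for c in broken_calls:
        evaluated.setdefault(c.da_protein, set()).add(c.edge)
        if c.status == "broken":
            broken.setdefault(c.da_protein, set()).add(c.edge)
    rows = [
        ConnectivityRow(
            p,
            gene_symbols.get(p, ""),
            len(broken.get(p, ())),
            len(evaluated[p]) - len(broken.get(p, ())),
        )
        for p in evaluated
    ]
    rows.sort(key=lambda r: (-r.n_broken, r.protein_id))
    return rows


def connectivity_histogram(broken_calls, edges) -> list:
    """(protein, degree, n_broken) rows for every DA-protein, where degree
    counts all edges incident to the protein in the full edge list."""
    degree: dict = {}
    for e in edges:
        degree[e.protein_a] = degree.get(e.protein_a, 0) + 1
        degree[e.protein_b] = degree.get(e.protein_b, 0) + 1
    rows = connectivity_report(broken_calls, edges)
    return [
        (r.protein_id, degree.get(r.protein_id, 0), r.n_broken) for r in rows
    ]


def write_pair_scores(scores, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (
                s.altered_domain, s.partner_signature, s.observed,
                s.contingency.population_n, s.contingency.population_k,
                s.contingency.sample_n, s.contingency.sample_k,
                f"{s.contingency.p_value:.6g}", int(s.enriched), s.tier,
            )
            for s in scores
        ],
        columns=["domain", "signature", "observed", "N", "K", "n", "k", "p", "enriched", "tier"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_broken(calls, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (
                c.edge.protein_a, c.edge.protein_b, c.da_protein, c.altered_domain,
                c.status, c.best_tier or "NA", ";".join(c.matched_signatures) or "NA",
            )
            for c in calls
        ],
        columns=[
            "protein_a", "protein_b", "da_protein", "domain", "status",
            "best_tier", "matched_signatures",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_connectivity(rows, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(r.protein_id, r.gene_symbol, r.n_broken, r.n_intact) for r in rows],
        columns=["protein_id", "gene_symbol", "n_broken", "n_intact"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_histogram(rows, path) -> None:
    import pandas as pd

    pd.DataFrame(rows, columns=["protein_id", "degree", "n_broken"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
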