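"""Classify missense SNPs by their impact on annotated domains.

A SNP whose position falls inside a matched domain span is a **D-SNP**.
A D-SNP is promoted to **DA-SNP** (domain-altering) when

* the domain is a pattern and the mutated sequence no longer has any match
  of that pattern overlapping the SNP position (``pattern_loss``), or
* the domain is a profile and the domain distortion

      DD = (MS_ref - MS_alt) / MS_ref

  reaches the configured cutoff (inclusive), or the mutated score drops
  below the profile's presence cutoff entirely — the profile analogue of
  losing the presence bit (``profile_distortion`` either way).

DD is clamped below at zero: a score-improving substitution does not
distort the domain.  SNPs inside no match receive a single ``outside``
call.  A SNP inside several matched domains receives one call per domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .domain_scan import (
    PatternDefinition,
    profile_score,
    scan_pattern,
    scan_proteome,
)
from .io_formats import ProteinRecord, SnpRecord

__all__ = [
    "DdConfig",
    "DomainSnpCall",
    "UndefinedDistortionError",
    "apply_snp",
    "domain_distortion",
    "classify_snp",
    "classify_all",
    "ClassifyResult",
    "snp_table",
    "n_da_at",
    "write_calls",
    "write_summary",
]

STATUS_OUTSIDE = "outside"
STATUS_D = "d_snp"
STATUS_DA = "da_snp"


class UndefinedDistortionError(ValueError):
    """Raised when DD is requested for a non-positive reference score."""


@dataclass(frozen=True)
class DdConfig:
    """Domain-distortion cutoff configuration.

    The default of 0.10 sits inside the empirically observed distortion
    range (0 to 0.3) and is the working cutoff used throughout.
    The comparison is inclusive (``dd >= dd_cutoff`` is altering).
    """

    dd_cutoff: float = 0.10

    def __post_init__(self):
        if not 0 < self.dd_cutoff <= 1:
            raise ValueError("dd_cutoff must lie in (0, 1]")


@dataclass(frozen=True)
class DomainSnpCall:
    snp_id: str
    protein_id: str
    status: str  # outside | d_snp | da_snp
    domain_id: Optional[str] = None
    mechanism: str = "none"  # none | pattern_loss | profile_distortion
    dd: Optional[float] = None
    ms_ref: Optional[float] = None
    ms_alt: Optional[float] = None
    #: profile presence bit lost (MS_alt < presence cutoff <= MS_ref); such a
    #: SNP is domain-altering regardless of the DD cutoff
    erased: bool = False


def apply_snp(sequence: str, snp: SnpRecord) -> str:
    """Return the sequence with the SNP's substitution applied."""
    if not 1 <= snp.position <= len(sequence):
        raise ValueError(f"{snp.snp_id}: position {snp.position} out of range")
    if sequence[snp.position - 1] != snp.ref_aa:
        raise ValueError(f"{snp.snp_id}: reference mismatch at {snp.position}")
    i = snp.position - 1
    return sequence[:i] + snp.alt_aa + sequence[i + 1 :]


def domain_distortion(ms_ref: float, ms_alt: float) -> float:
    """DD = (MS_ref - MS_alt) / MS_ref, clamped below at 0."""
    if ms_ref <= 0:
        raise UndefinedDistortionError(
            f"reference matching score {ms_ref} is not positive"
        )
    return max(0.0, (ms_ref - ms_alt) / ms_ref)


def classify_snp(
    snp: SnpRecord,
    protein: ProteinRecord,
    ref_matches,
    domains_by_id: dict,
    cfg: DdConfig = DdConfig(),
) -> list:
    """Classify one SNP against the reference-sequence matches of its protein.

    ``ref_matches`` must be the reference matches for ``snp.protein_id``;
    ``domains_by_id`` maps domain ids to their definitions.  Returns one
    call per containing domain match, or a single ``outside`` call.
    """
    containing = [
        m
        for m in ref_matches
        if m.protein_id == snp.protein_id and m.contains(snp.position)
    ]
    if not containing:
        return [DomainSnpCall(snp.snp_id, snp.protein_id, STATUS_OUTSIDE)]

    mutated = apply_snp(protein.sequence, snp)
    calls = []
    # at most one rescan/rescore per distinct domain
    for domain_id in sorted({m.domain_id for m in containing}):
        d = domains_by_id[domain_id]
        if isinstance(d, PatternDefinition):
            survived = any(
                s <= snp.position <= e for s, e in scan_pattern(d, mutated)
            )
            status = STATUS_D if survived else STATUS_DA
            mech = "none" if survived else "pattern_loss"
            calls.append(
                DomainSnpCall(snp.snp_id, snp.protein_id, status, domain_id, mech)
            )
        else:
            ms_ref = max(
                m.matching_score for m in containing if m.domain_id == domain_id
            )
            ms_alt, _ = profile_score(d, mutated)
            if ms_ref <= 0:  # unevaluable; presence cutoff > 0 normally prevents this
                calls.append(
                    DomainSnpCall(
                        snp.snp_id, snp.protein_id, STATUS_D, domain_id,
                        "none", None, ms_ref, ms_alt,
                    )
                )
                continue
            dd = domain_distortion(ms_ref, ms_alt)
            erased = ms_alt < d.cutoff <= ms_ref
            altered = dd >= cfg.dd_cutoff or erased
            calls.append(
                DomainSnpCall(
                    snp.snp_id,
                    snp.protein_id,
                    STATUS_DA if altered else STATUS_D,
                    domain_id,
                    "profile_distortion" if altered else "none",
                    dd,
                    float(ms_ref),
                    float(ms_alt),
                    erased,
                )
            )
    return calls


@dataclass
class ClassifyResult:
    calls: list
    n_snps: int
    n_outside: int
    n_d_snp: int  # SNPs falling inside >= 1 matched domain span
    n_da_snp: int  # at the working cutoff
    dd_cutoff: float
    per_cutoff: dict = field(default_factory=dict)  # cutoff -> n_da_snp


def classify_all(
    snps,
    proteome,
    domains,
    cfg: DdConfig = DdConfig(),
    ref_matches=None,
    cutoffs=None,
) -> ClassifyResult:
    """Classify every SNP; returns calls ordered by (snp_id, domain_id) plus
    summary counts.  ``ref_matches`` may be precomputed to skip the scan;
    ``cutoffs`` adds DA counts at additional cutoffs to the summary."""
    proteins = {p.protein_id: p for p in proteome}
    domains_by_id = {d.domain_id: d for d in domains}
    if ref_matches is None:
        ref_matches = scan_proteome(domains, proteome)
    by_protein: dict = {}
    for m in ref_matches:
        by_protein.setdefault(m.protein_id, []).append(m)

    calls = []
    for snp in snps:
        calls.extend(
            classify_snp(
                snp, proteins[snp.protein_id], by_protein.get(snp.protein_id, []),
                domains_by_id, cfg,
            )
        )
    calls.sort(key=lambda c: (c.snp_id, c.domain_id or ""))

    table = snp_table(calls)
    in_domain = int(table["in_domain"].sum()) if len(table) else 0
    result = ClassifyResult(
        calls=calls,
        n_snps=len(snps),
        n_outside=len(snps) - in_domain,
        n_d_snp=in_domain,
        n_da_snp=n_da_at(table, cfg.dd_cutoff),
        dd_cutoff=cfg.dd_cutoff,
    )
    for c in cutoffs or []:
        result.per_cutoff[c] = n_da_at(table, c)
    return result


def snp_table(calls) -> pd.DataFrame:
    """Aggregate per-domain calls to one row per SNP.

    Columns: snp_id, protein_id, in_domain, pattern_loss, erased, max_dd
    (NaN when no profile call had a defined DD).  ``erased`` marks SNPs
    whose substitution dropped a profile below its presence cutoff; those
    SNPs, like pattern-loss SNPs, are domain-altering at every DD cutoff.
    """
    rows: dict = {}
    for c in calls:
        row = rows.setdefault(
            c.snp_id,
            {
                "snp_id": c.snp_id,
                "protein_id": c.protein_id,
                "in_domain": False,
                "pattern_loss": False,
                "erased": False,
                "max_dd": np.nan,
            },
        )
        if c.status == STATUS_OUTSIDE:
            continue
        row["in_domain"] = True
        if c.mechanism == "pattern_loss":
            row["pattern_loss"] = True
        if c.erased:
            row["erased"] = True
        if c.dd is not None:
            if not np.isnan(row["max_dd"]):
                row["max_dd"] = max(row["max_dd"], c.dd)
            else:
                row["max_dd"] = c.dd
    df = pd.DataFrame(
        rows.values(),
        columns=["snp_id", "protein_id", "in_domain", "pattern_loss", "erased", "max_dd"],
    )
    return df.sort_values("snp_id", ignore_index=True)


def n_da_at(table: pd.DataFrame, cutoff: float) -> int:
    """Number of DA-SNPs at a DD cutoff, from a :func:`snp_table` frame."""
    if len(table) == 0:
        return 0
    dd_hit = table["max_dd"].fillna(-1.0) >= cutoff
    return int((table["pattern_loss"] | table["erased"] | dd_hit).sum())


def da_snp_ids(table: pd.DataFrame, cutoff: float) -> set:
    if len(table) == 0:
        return set()
    dd_hit = table["max_dd"].fillna(-1.0) >= cutoff
    mask = table["pattern_loss"] | table["erased"] | dd_hit
    return set(table.loc[mask, "snp_id"])


def write_calls(calls, path) -> None:
    rows = [
        (
            c.snp_id,
            c.protein_id,
            c.domain_id or "NA",
            c.status,
            c.mechanism,
            "NA" if c.dd is None else f"{c.dd:.6f}",
            "NA" if c.ms_ref is None else f"{c.ms_ref:.6f}",
            "NA" if c.ms_alt is None else f"{c.ms_alt:.6f}",
        )
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "snp_id", "protein_id", "domain_id", "status", "mechanism",
            "dd", "ms_ref", "ms_alt",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_summary(result: ClassifyResult, path) -> None:
    rows = [(result.dd_cutoff, result.n_snps, result.n_d_snp, result.n_da_snp)]
    for c in sorted(result.per_cutoff):
        rows.append((c, result.n_snps, result.n_d_snp, result.per_cutoff[c]))
    pd.DataFrame(
        rows, columns=["cutoff", "n_snps", "n_d_snp", "n_da_snp"]
    ).drop_duplicates(subset="cutoff").to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
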