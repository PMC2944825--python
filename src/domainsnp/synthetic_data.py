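"""Seeded generator for a complete toy universe with planted ground truth.

The generator emulates the study conditions of the analysis: a proteome
with planted pattern/profile domain instances and linear-motif instances,
missense SNPs stratified outside/inside domains with a tunable
domain-altering fraction, disease labels enriched among the intended
DA-SNPs with a controllable odds ratio, a PPI network wired by planted
(domain, signature) binding rules plus uniform noise edges, and reference
pair lists containing the planted rules plus decoys.

Constructive guarantees (checked, and re-drawn on rare failure):

* every intended DA-SNP is classified ``da_snp`` by the classifier at the
  generator's DD cutoff — pattern-breaking substitutions are verified
  against the scanner, and damaging profile substitutions replace the
  consensus residue at the profile's single high-differential position so
  that DD >= cutoff holds analytically;
* intended benign in-domain SNPs sit at wildcard/alternative-class pattern
  positions or low-differential profile positions, so their DD margin
  stays well below the smallest sweep cutoff;
* the same seed reproduces the universe byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import domain_scan, io_formats
from .domain_scan import (
    PatternDefinition,
    PatternElement,
    ProfileDefinition,
    scan_pattern,
    scan_proteome,
)
from .io_formats import (
    AMINO_ACIDS,
    DiseaseAnnotation,
    PpiEdge,
    ProteinRecord,
    ReferencePairList,
    SnpRecord,
)
from .variant_impact import DdConfig, classify_all

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "Universe",
    "generate_universe",
    "expected_counts",
    "write_universe",
    "classify_universe",
    "sweep_universe",
    "recover_rules",
]

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic universe.

    The fraction defaults mirror the gross proportions of the real scan
    this package emulates: roughly a fifth of missense SNPs fall inside
    domains, about 5% of in-domain SNPs are domain-altering, and about 6%
    of in-domain SNPs carry a disease annotation.
    """

    seed: int = 0
    n_proteins: int = 300
    protein_length: tuple = (80, 400)
    n_pattern_domains: int = 6
    n_profile_domains: int = 6
    n_motifs: int = 4
    snps_per_protein: float = 2.0
    frac_snp_in_domain: float = 0.2
    frac_da_given_domain: float = 0.05
    disease_base_rate: float = 0.06
    disease_odds_ratio_da: float = 2.0
    n_binding_rules: int = 5
    edge_density: float = 2.0  # mean PPI degree
    rule_fidelity: float = 0.9
    domain_prevalence: float = 0.08  # fraction of proteome carrying each signature
    motif_prevalence: float = 0.12
    n_decoy_pairs: int = 8
    dd_cutoff: float = 0.10  # margin target for damaging/benign construction

    def validate(self) -> None:
        for name in (
            "frac_snp_in_domain",
            "frac_da_given_domain",
            "disease_base_rate",
            "rule_fidelity",
            "domain_prevalence",
            "motif_prevalence",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.5 < self.rule_fidelity <= 1:
            raise ValueError("rule_fidelity must lie in (0.5, 1]")
        if self.disease_odds_ratio_da < 1:
            raise ValueError("disease_odds_ratio_da must be >= 1")
        lo, hi = self.protein_length
        if not 1 <= lo <= hi:
            raise ValueError("invalid protein_length range")
        if lo < 40:
            raise ValueError("proteins shorter than 40 residues cannot host domains")
        if self.n_proteins < 10:
            raise ValueError("need at least 10 proteins")
        if self.n_binding_rules > self.n_pattern_domains + self.n_profile_domains:
            raise ValueError("more binding rules than domains")
        if not 0 < self.dd_cutoff <= 1:
            raise ValueError("dd_cutoff must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Planted structure sufficient to recompute every expected count."""

    instances: list = field(default_factory=list)  # (protein, sig, start, end)
    snp_intent: dict = field(default_factory=dict)  # snp_id -> intent dict
    rules: list = field(default_factory=list)  # (domain, signature, sig_kind)
    edge_rules: dict = field(default_factory=dict)  # "A|B" -> rule idx or -1
    diseased_snps: list = field(default_factory=list)
    da_domains: list = field(default_factory=list)
    consensus: dict = field(default_factory=dict)  # sig -> consensus string

    def to_json(self) -> str:
        payload = asdict(self)
        payload["rules"] = [list(r) for r in self.rules]
        payload["instances"] = [list(i) for i in self.instances]
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            instances=[tuple(i) for i in d["instances"]],
            snp_intent=d["snp_intent"],
            rules=[tuple(r) for r in d["rules"]],
            edge_rules=d["edge_rules"],
            diseased_snps=d["diseased_snps"],
            da_domains=d["da_domains"],
            consensus=d["consensus"],
        )


@dataclass
class Universe:
    config: GeneratorConfig
    proteome: list
    domains: list
    motifs: list  # (motif_id, pattern_text)
    snps: list
    edges: list
    disease: DiseaseAnnotation
    pairlists: dict
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Signature construction
# ---------------------------------------------------------------------------

def _random_pattern(rng, domain_id):
    """A pattern with >= 4 exact elements (specific enough that chance
    matches are rare), 1-2 fixed-width wildcard runs, and optionally one
    two-letter alternative class.  Fixed repeat widths keep the planted
    instance length deterministic.

    Returns (definition, consensus string, benign offsets, damaging
    offsets) where offsets are 0-based positions inside the instance.
    """
    n_exact = int(rng.integers(4, 7))
    n_wild = int(rng.integers(1, 3))
    specs = [("exact",)] * n_exact + [("wild", int(rng.integers(1, 4))) for _ in range(n_wild)]
    if rng.random() < 0.7:
        specs.append(("any2",))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    elements = []
    consensus = []
    benign, damaging = [], []
    pos = 0
    for spec in specs:
        if spec[0] == "exact":
            aa = AMINO_ACIDS[int(rng.integers(20))]
            elements.append(PatternElement("exact", frozenset(aa)))
            damaging.append(pos)
            consensus.append(aa)
            pos += 1
        elif spec[0] == "wild":
            width = spec[1]
            elements.append(PatternElement("wildcard", frozenset(), width, width))
            for _ in range(width):
                benign.append(pos)
                consensus.append(AMINO_ACIDS[int(rng.integers(20))])
                pos += 1
        else:  # two-letter alternative class
            pair = rng.choice(20, size=2, replace=False)
            letters = frozenset(AMINO_ACIDS[int(i)] for i in pair)
            elements.append(PatternElement("any_of", letters))
            benign.append(pos)
            consensus.append(sorted(letters)[0])
            pos += 1
    return (
        PatternDefinition(domain_id, tuple(elements)),
        "".join(consensus),
        benign,
        damaging,
    )


def _random_profile(rng, domain_id, dd_cutoff):
    """A profile favouring a planted consensus.

    One 'hot' position carries a large consensus score whose loss pushes DD
    past 1.5x the cutoff; 'cold' positions carry a small score and a
    designated benign alternative letter scoring 0.25 below consensus, so a
    benign substitution distorts by well under half the smallest sweep
    cutoff.  The presence cutoff is 70% of the consensus score.

    Returns (definition, consensus, hot offset, benign (offset, letter)
    pairs).
    """
    L = int(rng.integers(8, 15))
    cons_idx = rng.integers(0, 20, size=L)
    scores = np.full((L, 20), -1.0)
    hot = int(rng.integers(L))
    hot_high = float(rng.choice([3.5, 4.5, 5.5]))
    benign_sites = []
    for i in range(L):
        if i == hot:
            scores[i, cons_idx[i]] = hot_high
        else:
            scores[i, cons_idx[i]] = 2.0
            alt = int(rng.integers(20))
            while alt == cons_idx[i]:
                alt = int(rng.integers(20))
            scores[i, alt] = 2.0 - 0.25
            benign_sites.append((i, AMINO_ACIDS[alt]))
    total = 2.0 * (L - 1) + hot_high
    # guarantee the damaging substitution clears the cutoff with margin
    while (hot_high + 1.0) / total < 1.5 * dd_cutoff:
        hot_high += 1.0
        scores[hot, cons_idx[hot]] = hot_high
        total = 2.0 * (L - 1) + hot_high
    consensus = "".join(AMINO_ACIDS[int(i)] for i in cons_idx)
    definition = ProfileDefinition(
        domain_id, scores, gap_open=-5.0, gap_extend=-1.0, cutoff=0.7 * total
    )
    return definition, consensus, hot, benign_sites


def _random_motif(rng, motif_id):
    """A short specific motif: 4 exact letters with one internal wildcard run."""
    letters = [AMINO_ACIDS[int(rng.integers(20))] for _ in range(4)]
    width = int(rng.integers(1, 3))
    elements = [
        PatternElement("exact", frozenset(letters[0])),
        PatternElement("exact", frozenset(letters[1])),
        PatternElement("wildcard", frozenset(), width, width),
        PatternElement("exact", frozenset(letters[2])),
        PatternElement("exact", frozenset(letters[3])),
    ]
    consensus = (
        letters[0]
        + letters[1]
        + "".join(AMINO_ACIDS[int(rng.integers(20))] for _ in range(width))
        + letters[2]
        + letters[3]
    )
    return PatternDefinition(motif_id, tuple(elements)), consensus


# ---------------------------------------------------------------------------
# Universe generation
# ---------------------------------------------------------------------------

def generate_universe(cfg: GeneratorConfig) -> Universe:
    """Generate the full synthetic universe for a configuration."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    # --- signatures
    patterns, profiles, motifs = [], [], []
    pattern_info = {}  # id -> (definition, consensus, benign, damaging)
    profile_info = {}  # id -> (definition, consensus, hot, benign_sites)
    for k in range(cfg.n_pattern_domains):
        did = f"PAT{k + 1:02d}"
        p, cons, benign, damaging = _random_pattern(rng, did)
        patterns.append(p)
        pattern_info[did] = (p, cons, benign, damaging)
        truth.consensus[did] = cons
    for k in range(cfg.n_profile_domains):
        did = f"PRO{k + 1:02d}"
        pr, cons, hot, benign_sites = _random_profile(rng, did, cfg.dd_cutoff)
        profiles.append(pr)
        profile_info[did] = (pr, cons, hot, benign_sites)
        truth.consensus[did] = cons
    motif_defs = {}
    for k in range(cfg.n_motifs):
        mid = f"MOT{k + 1:02d}"
        m, cons = _random_motif(rng, mid)
        motif_defs[mid] = m
        motifs.append((mid, domain_scan.format_pattern(m)))
        truth.consensus[mid] = cons
    domains = patterns + profiles
    domain_ids = [d.domain_id for d in domains]

    # --- proteome with planted instances
    lo, hi = cfg.protein_length
    lengths = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    seq_arrays = [
        _AA[rng.integers(0, 20, size=int(L))].copy() for L in lengths
    ]
    sig_ids = domain_ids + [m for m, _ in motifs]
    consensi = [truth.consensus[s] for s in sig_ids]
    prevalences = [cfg.domain_prevalence] * len(domain_ids) + [
        cfg.motif_prevalence
    ] * len(motifs)
    instances = []
    occupied = {i: [] for i in range(cfg.n_proteins)}

    def fits(i, s, e):
        return all(e <= a or s >= b for a, b in occupied[i])

    for sig, cons, prev in zip(sig_ids, consensi, prevalences):
        want = max(6, round(prev * cfg.n_proteins))
        carriers = sorted(
            int(c) for c in rng.choice(cfg.n_proteins, size=min(want, cfg.n_proteins), replace=False)
        )
        for ci in carriers:
            L = len(cons)
            limit = len(seq_arrays[ci]) - L
            if limit < 0:
                continue
            for _ in range(20):
                s = int(rng.integers(0, limit + 1))
                if fits(ci, s, s + L):
                    seq_arrays[ci][s : s + L] = np.frombuffer(cons.encode(), dtype=np.uint8)
                    occupied[ci].append((s, s + L))
                    instances.append((ci, sig, s + 1, s + L))
                    break

    pids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    proteome = [
        ProteinRecord(pids[i], seq_arrays[i].tobytes().decode(), f"G{i + 1:04d}")
        for i in range(cfg.n_proteins)
    ]
    truth.instances = [(pids[i], sig, s, e) for i, sig, s, e in instances]

    inst_by_protein: dict = {}
    for i, sig, s, e in instances:
        inst_by_protein.setdefault(i, []).append((sig, s, e))
    domain_instances = [
        (i, sig, s, e) for i, sig, s, e in instances if sig in set(domain_ids)
    ]

    # --- reference spans for SNP placement: engine pattern spans plus
    # planted profile spans (random background cannot reach a profile cutoff)
    pattern_by_id = {p.domain_id: p for p in patterns}
    spans_by_protein = {i: [] for i in range(cfg.n_proteins)}
    for i in range(cfg.n_proteins):
        seq = proteome[i].sequence
        for p in patterns:
            for s, e in scan_pattern(p, seq):
                spans_by_protein[i].append((p.domain_id, s, e))
        for sig, s, e in inst_by_protein.get(i, []):
            if sig in profile_info:
                spans_by_protein[i].append((sig, s, e))

    # --- binding rules (before SNPs: every rule row needs a damaging SNP)
    rule_rows = [
        domain_ids[int(i)]
        for i in rng.choice(len(domain_ids), size=cfg.n_binding_rules, replace=False)
    ]
    motif_ids = [m for m, _ in motifs]
    rules = []
    used_pairs = set()
    for ridx, d in enumerate(rule_rows):
        for _ in range(100):
            if ridx % 2 == 1 and motif_ids:
                s = motif_ids[int(rng.integers(len(motif_ids)))]
                kind = "motif"
            else:
                s = domain_ids[int(rng.integers(len(domain_ids)))]
                kind = "domain"
            if s == d:
                continue
            key = (d, s, kind)
            if key not in used_pairs:
                used_pairs.add(key)
                rules.append(key)
                break
    truth.rules = rules

    # --- SNPs
    n_total = round(cfg.snps_per_protein * cfg.n_proteins)
    n_in = round(cfg.frac_snp_in_domain * n_total)
    n_da = round(cfg.frac_da_given_domain * n_in)
    n_benign = n_in - n_da
    n_out = n_total - n_in

    used_positions = {i: set() for i in range(cfg.n_proteins)}
    placed = []  # (protein_idx, pos1, ref, alt, intent dict)

    def other_span_free(i, pos1, sig):
        return not any(
            s <= pos1 <= e and d != sig for d, s, e in spans_by_protein[i]
        )

    def place_damaging(target_domain):
        """Plant one damaging SNP inside an instance of target_domain."""
        cands = [t for t in domain_instances if t[1] == target_domain]
        rng.shuffle(cands)
        for i, sig, s, e in cands:
            seq = proteome[i].sequence
            if sig in pattern_info:
                _, cons, _, damaging = pattern_info[sig]
                offs = list(damaging)
                rng.shuffle(offs)
                for off in offs:
                    pos1 = s + off
                    if pos1 in used_positions[i]:
                        continue
                    ref = seq[pos1 - 1]
                    alts = [a for a in AMINO_ACIDS if a != ref]
                    rng.shuffle(alts)
                    for alt in alts[:5]:
                        mutated = seq[: pos1 - 1] + alt + seq[pos1:]
                        if not any(
                            a <= pos1 <= b
                            for a, b in scan_pattern(pattern_by_id[sig], mutated)
                        ):
                            return i, pos1, ref, alt, sig, "pattern_loss"
            else:
                pr, cons, hot, _ = profile_info[sig]
                pos1 = s + hot
                if pos1 in used_positions[i]:
                    continue
                ref = seq[pos1 - 1]
                alts = [a for a in AMINO_ACIDS if a != ref]
                alt = alts[int(rng.integers(len(alts)))]
                # analytic guarantee, verified numerically at test time
                return i, pos1, ref, alt, sig, "profile_distortion"
        return None

    # damaging SNPs: cover every rule row first, then spread randomly
    da_targets = [d for d in rule_rows]
    pool = [t[1] for t in domain_instances]
    while len(da_targets) < n_da and pool:
        da_targets.append(pool[int(rng.integers(len(pool)))])
    da_targets = da_targets[:max(n_da, 0)]
    if n_da < len(rule_rows):
        # tiny universes: still cover as many rule rows as the DA budget allows
        da_targets = rule_rows[:n_da]
    for target in da_targets:
        hit = place_damaging(target)
        if hit is None:
            continue
        i, pos1, ref, alt, sig, mech = hit
        used_positions[i].add(pos1)
        placed.append(
            (i, pos1, ref, alt, {"status": "da_snp", "mechanism": mech, "domain": sig})
        )
        truth.da_domains = sorted(set(truth.da_domains) | {sig})

    # benign in-domain SNPs
    attempts = 0
    n_placed_benign = 0
    while n_placed_benign < n_benign and attempts < 50 * max(n_benign, 1):
        attempts += 1
        i, sig, s, e = domain_instances[int(rng.integers(len(domain_instances)))]
        seq = proteome[i].sequence
        if sig in pattern_info:
            _, cons, benign, _ = pattern_info[sig]
            if not benign:
                continue
            off = benign[int(rng.integers(len(benign)))]
            pos1 = s + off
            if pos1 in used_positions[i] or not other_span_free(i, pos1, sig):
                continue
            ref = seq[pos1 - 1]
            alts = [a for a in AMINO_ACIDS if a != ref]
            alt = alts[int(rng.integers(len(alts)))]
            mutated = seq[: pos1 - 1] + alt + seq[pos1:]
            if not any(
                a <= pos1 <= b for a, b in scan_pattern(pattern_by_id[sig], mutated)
            ):
                continue  # landed on a constrained spot after all; redraw
        else:
            pr, cons, hot, benign_sites = profile_info[sig]
            if not benign_sites:
                continue
            off, alt = benign_sites[int(rng.integers(len(benign_sites)))]
            pos1 = s + off
            if pos1 in used_positions[i] or not other_span_free(i, pos1, sig):
                continue
            ref = seq[pos1 - 1]
            if ref == alt:
                continue
        used_positions[i].add(pos1)
        placed.append(
            (i, pos1, ref, alt, {"status": "d_snp", "mechanism": "none", "domain": sig})
        )
        n_placed_benign += 1

    # outside SNPs
    attempts = 0
    n_placed_out = 0
    while n_placed_out < n_out and attempts < 50 * max(n_out, 1):
        attempts += 1
        i = int(rng.integers(cfg.n_proteins))
        pos1 = int(rng.integers(1, len(proteome[i].sequence) + 1))
        if pos1 in used_positions[i]:
            continue
        if any(s <= pos1 <= e for _, s, e in spans_by_protein[i]):
            continue
        ref = proteome[i].sequence[pos1 - 1]
        alts = [a for a in AMINO_ACIDS if a != ref]
        alt = alts[int(rng.integers(len(alts)))]
        used_positions[i].add(pos1)
        placed.append(
            (i, pos1, ref, alt, {"status": "outside", "mechanism": "none", "domain": None})
        )
        n_placed_out += 1

    placed.sort(key=lambda t: (t[0], t[1]))
    snps = []
    for j, (i, pos1, ref, alt, intent) in enumerate(placed, 1):
        sid = f"rs{j:05d}"
        snps.append(SnpRecord(sid, pids[i], pos1, ref, alt))
        truth.snp_intent[sid] = intent

    # --- disease labels
    base = cfg.disease_base_rate
    odds = base / (1.0 - base) if base < 1 else math.inf
    p_da = (cfg.disease_odds_ratio_da * odds) / (1.0 + cfg.disease_odds_ratio_da * odds)
    disease = DiseaseAnnotation()
    for snp in snps:
        intent = truth.snp_intent[snp.snp_id]
        p = p_da if intent["status"] == "da_snp" else base
        if rng.random() < p:
            disease.snp_ids.add(snp.snp_id)
            disease.protein_ids.add(snp.protein_id)
            disease.labels[snp.snp_id] = f"disorder{int(rng.integers(7)) + 1}"
            disease.labels.setdefault(snp.protein_id, disease.labels[snp.snp_id])
    truth.diseased_snps = sorted(disease.snp_ids)

    # --- PPI edges
    carriers_of = {}
    for i, sig, s, e in instances:
        carriers_of.setdefault(sig, set()).add(i)
    n_edges = round(cfg.edge_density * cfg.n_proteins / 2)
    n_rule_edges = round(cfg.rule_fidelity * n_edges)
    edge_set = {}
    per_rule = [n_rule_edges // len(rules)] * len(rules) if rules else []
    for r in range(n_rule_edges - sum(per_rule)):
        per_rule[r % len(per_rule)] += 1
    for ridx, (d, s, kind) in enumerate(rules):
        eligible = sorted(
            tuple(sorted((a, b)))
            for a in carriers_of.get(d, ())
            for b in carriers_of.get(s, ())
            if a != b
        )
        eligible = sorted(set(eligible) - set(edge_set))
        take = min(per_rule[ridx], len(eligible))
        idx = rng.choice(len(eligible), size=take, replace=False) if take else []
        for t in sorted(int(x) for x in idx):
            edge_set[eligible[t]] = ridx
    attempts = 0
    while len(edge_set) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        a, b = rng.choice(cfg.n_proteins, size=2, replace=False)
        key = tuple(sorted((int(a), int(b))))
        if key not in edge_set:
            edge_set[key] = -1
    edges = sorted(PpiEdge(pids[a], pids[b]) for a, b in edge_set)
    truth.edge_rules = {
        f"{pids[a]}|{pids[b]}": ridx for (a, b), ridx in sorted(edge_set.items())
    }

    # --- reference pair lists: planted rules + decoys
    ddi = ReferencePairList("domain_domain")
    dmi = ReferencePairList("domain_motif")
    for d, s, kind in rules:
        (ddi if kind == "domain" else dmi).add(d, s)
    planted = {(d, s) for d, s, _ in rules} | {(s, d) for d, s, _ in rules}
    n_decoys = cfg.n_decoy_pairs
    guard = 0
    while n_decoys > 0 and guard < 1000:
        guard += 1
        if rng.random() < 0.5:
            a, b = (
                domain_ids[int(rng.integers(len(domain_ids)))],
                domain_ids[int(rng.integers(len(domain_ids)))],
            )
            if a == b or (a, b) in planted or (a, b) in ddi:
                continue
            ddi.add(a, b)
        else:
            a = domain_ids[int(rng.integers(len(domain_ids)))]
            b = motif_ids[int(rng.integers(len(motif_ids)))] if motif_ids else None
            if b is None or (a, b) in planted or (a, b) in dmi:
                continue
            dmi.add(a, b)
        n_decoys -= 1

    return Universe(
        cfg,
        proteome,
        domains,
        motifs,
        snps,
        edges,
        disease,
        {"domain_domain": ddi, "domain_motif": dmi},
        truth,
    )


# ---------------------------------------------------------------------------
# Expected counts and evaluation helpers
# ---------------------------------------------------------------------------

def expected_counts(truth: GroundTruth, cfg: GeneratorConfig) -> dict:
    """Manifest of intended downstream counts.

    Deterministic quantities (the intended class of every SNP) are exact;
    stochastic ones (disease overlaps) come with +-3 sd binomial bands.
    """
    statuses = [v["status"] for v in truth.snp_intent.values()]
    n_da = statuses.count("da_snp")
    n_d = n_da + statuses.count("d_snp")
    n_out = statuses.count("outside")

    def band(n, p):
        sd = math.sqrt(max(n * p * (1 - p), 0.0))
        return (n * p, max(0.0, n * p - 3 * sd), min(n, n * p + 3 * sd))

    base = cfg.disease_base_rate
    odds = base / (1 - base)
    p_da = cfg.disease_odds_ratio_da * odds / (1 + cfg.disease_odds_ratio_da * odds)
    return {
        "n_snps": len(truth.snp_intent),
        "n_d_snp": n_d,
        "n_da_snp": n_da,
        "n_outside": n_out,
        "diseased_d_snp_band": band(n_d - n_da, base),
        "diseased_da_snp_band": band(n_da, p_da),
        "planted_rules": [(d, s) for d, s, _ in truth.rules],
        "n_edges": len(truth.edge_rules),
        "n_noise_edges": sum(1 for r in truth.edge_rules.values() if r == -1),
    }


def classify_universe(universe: Universe, cfg: DdConfig = DdConfig(), cutoffs=None):
    """Scan + classify a universe in memory; returns (matches, result)."""
    matches = scan_proteome(universe.domains, universe.proteome)
    result = classify_all(
        universe.snps,
        universe.proteome,
        universe.domains,
        cfg,
        ref_matches=matches,
        cutoffs=cutoffs,
    )
    return matches, result


def sweep_universe(universe: Universe, cutoffs, dd_cfg: DdConfig = DdConfig(), level="snp"):
    """Classify then run the DD sweep against the universe's disease set."""
    from .enrichment import dd_sweep

    _, result = classify_universe(universe, dd_cfg)
    return dd_sweep(result.calls, universe.disease, cutoffs, level=level)


def recover_rules(
    universe: Universe,
    alpha: float = 0.05,
    mode: str = "analytic",
    seed=None,
    require_reference: bool = True,
    dd_cfg: DdConfig = DdConfig(),
):
    """Run the network stage and compare enriched pairs to planted rules.

    Following the pipeline's own false-positive filter, ``require_reference``
    keeps only enriched pairs backed by a reference pair list; the truth set
    is then the planted rules (all of which the generator writes into the
    reference lists).  Returns ``(predicted, truth_pairs, precision, recall,
    scores)``; precision and recall are 1.0 by convention on empty
    denominators.
    """
    from .network_impact import annotate_signatures, build_score_matrix, score_pairs

    matches, result = classify_universe(universe, dd_cfg)
    ann = annotate_signatures(universe.proteome, matches, universe.motifs)
    da_domains = {
        c.domain_id for c in result.calls if c.status == "da_snp" and c.domain_id
    }
    counts, _ = build_score_matrix(da_domains, ann, universe.edges)
    scores = score_pairs(
        counts,
        ann,
        universe.edges,
        da_domains,
        alpha=alpha,
        pairlists=universe.pairlists,
        mode=mode,
        seed=seed,
    )
    def norm(d, s):
        # domain-domain pairs are unordered; domain-motif pairs ordered
        if ann.kinds.get(s, "domain") == "domain":
            return tuple(sorted((d, s)))
        return (d, s)

    predicted = {
        norm(s.altered_domain, s.partner_signature)
        for s in scores
        if s.enriched and (not require_reference or s.tier != "enrichment_only")
    }
    truth_pairs = {norm(d, s) for d, s, _ in universe.truth.rules}
    tp = len(predicted & truth_pairs)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth_pairs) if truth_pairs else 1.0
    return predicted, truth_pairs, precision, recall, scores


# ---------------------------------------------------------------------------
# On-disk materialisation
# ---------------------------------------------------------------------------

def write_universe(universe: Universe, outdir) -> dict:
    """Write every pipeline input plus the ground-truth manifest; returns
    the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "domains": outdir / "domains.txt",
        "motifs": outdir / "motifs.tsv",
        "snps": outdir / "snps.tsv",
        "edges": outdir / "edges.tsv",
        "disease": outdir / "disease.tsv",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.json",
    }
    io_formats.write_fasta(universe.proteome, paths["proteome"])
    domain_scan.write_domains(universe.domains, paths["domains"])
    io_formats.write_motifs(universe.motifs, paths["motifs"])
    io_formats.write_snps(universe.snps, paths["snps"])
    io_formats.write_edges(universe.edges, paths["edges"])
    io_formats.write_annotations(universe.disease, paths["disease"])
    io_formats.write_pairlists(universe.pairlists, paths["pairs"])
    paths["truth"].write_text(universe.truth.to_json(), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
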