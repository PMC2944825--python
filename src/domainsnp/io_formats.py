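"""Readers and writers for every on-disk format the pipeline consumes.

All protein coordinates are 1-based with spans inclusive on both ends,
matching standard protein mutation nomenclature.  Tables are tab-separated
UTF-8 text with a header row; lines starting with ``#`` are comments.

The module validates aggressively on read: sequences must use the 20
standard amino-acid letters in uppercase, SNP records must agree with the
reference residue of the protein they point at, and edges are normalized
to undirected, deduplicated, self-loop-free form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, in the fixed column order used by profile
#: score matrices throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class LoadError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional gene symbol."""

    protein_id: str
    sequence: str
    gene_symbol: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise LoadError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise LoadError(
                f"protein {self.protein_id!r}: illegal residue {sorted(bad)[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpRecord:
    """A missense variant in protein coordinates (1-based)."""

    snp_id: str
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.position < 1:
            raise LoadError(f"{self.snp_id}: position must be >= 1")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA_SET:
                raise LoadError(f"{self.snp_id}: illegal residue {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise LoadError(f"{self.snp_id}: synonymous substitution (ref == alt)")


@dataclass(frozen=True, order=True)
class PpiEdge:
    """An undirected protein-protein interaction edge (endpoints sorted)."""

    protein_a: str
    protein_b: str

    @classmethod
    def normalized(cls, a: str, b: str) -> "PpiEdge":
        if a == b:
            raise LoadError(f"self-loop edge ({a}, {b})")
        lo, hi = sorted((a, b))
        return cls(lo, hi)

    def other(self, protein_id: str) -> str:
        return self.protein_b if protein_id == self.protein_a else self.protein_a


@dataclass
class DiseaseAnnotation:
    """Disease/disorder labels for SNPs and/or proteins (OMIM-like role)."""

    snp_ids: set = field(default_factory=set)
    protein_ids: set = field(default_factory=set)
    labels: dict = field(default_factory=dict)
    n_orphans: int = 0


@dataclass
class ReferencePairList:
    """A reference list of interacting signature pairs (DOMINE-like role).

    ``domain_domain`` pairs are unordered and stored sorted; ``domain_motif``
    pairs are ordered (domain first, motif second).
    """

    kind: str
    pairs: set = field(default_factory=set)

    def __post_init__(self):
        if self.kind not in ("domain_domain", "domain_motif"):
            raise LoadError(f"unknown pair-list kind {self.kind!r}")

    def normalize(self, a: str, b: str) -> tuple:
        if self.kind == "domain_domain":
            return tuple(sorted((a, b)))
        return (a, b)

    def add(self, a: str, b: str) -> None:
        self.pairs.add(self.normalize(a, b))

    def __contains__(self, pair) -> bool:
        return self.normalize(*pair) in self.pairs


@dataclass
class LoadReport:
    """Deterministic summary of what a reader accepted and dropped."""

    n_rows: int = 0
    n_accepted: int = 0
    n_dropped_unknown: int = 0
    n_rejected: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    messages: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_fasta_lines(path) -> None:
    """Line-numbered validation so load errors can name the offending line."""
    with open(path, encoding="utf-8") as fh:
        saw_header = False
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line.split()) == 0 or line[1:].split() == []:
                    raise LoadError(f"{path}: line {ln}: malformed FASTA header")
                saw_header = True
            else:
                if not saw_header:
                    raise LoadError(f"{path}: line {ln}: sequence before header")
                bad = set(line) - AA_SET
                if bad:
                    raise LoadError(
                        f"{path}: line {ln}: illegal residue {sorted(bad)[0]!r}"
                    )


def read_fasta(path) -> list:
    """Read a proteome FASTA file into a list of :class:`ProteinRecord`.

    The record id is the first whitespace-delimited token of the header; a
    gene symbol is parsed from a ``GN=`` tag in the description if present.
    Illegal residues or malformed headers raise :class:`LoadError` naming
    the line number.
    """
    _validate_fasta_lines(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = ""
        for token in rec.description.split():
            if token.startswith("GN="):
                gene = token[3:]
                break
        if rec.id in seen:
            raise LoadError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq), gene))
    return records


def write_fasta(proteome, path, width: int = 60) -> None:
    recs = []
    for p in proteome:
        desc = f"GN={p.gene_symbol}" if p.gene_symbol else ""
        recs.append(SeqRecord(Seq(p.sequence), id=p.protein_id, description=desc))
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required_columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path}: empty table") from None
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

SNP_COLUMNS = ["snp_id", "protein_id", "position", "ref_aa", "alt_aa"]


def read_snps(path, proteome) -> tuple:
    """Read and validate SNP records against a loaded proteome.

    Returns ``(records, report)``.  Records referencing unknown proteins are
    dropped and counted; records whose ``ref_aa`` disagrees with the protein
    sequence are rejected with reason ``"reference mismatch"``.
    """
    df = _read_tsv(path, SNP_COLUMNS)
    seqs = {p.protein_id: p.sequence for p in proteome}
    report = LoadReport(n_rows=len(df))
    out = []
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid not in seqs:
            report.n_dropped_unknown += 1
            report.messages.append(f"{row.snp_id}: unknown protein {pid}")
            continue
        try:
            pos = int(row.position)
        except ValueError:
            report.n_rejected += 1
            report.messages.append(f"{row.snp_id}: non-integer position")
            continue
        seq = seqs[pid]
        if not 1 <= pos <= len(seq):
            report.n_rejected += 1
            report.messages.append(f"{row.snp_id}: position out of range")
            continue
        if seq[pos - 1] != row.ref_aa:
            report.n_rejected += 1
            report.messages.append(f"{row.snp_id}: reference mismatch")
            continue
        try:
            rec = SnpRecord(row.snp_id, pid, pos, row.ref_aa, row.alt_aa)
        except LoadError as exc:
            report.n_rejected += 1
            report.messages.append(str(exc))
            continue
        out.append(rec)
        report.n_accepted += 1
    return out, report


def write_snps(snps, path) -> None:
    df = pd.DataFrame(
        [(s.snp_id, s.protein_id, s.position, s.ref_aa, s.alt_aa) for s in snps],
        columns=SNP_COLUMNS,
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def read_edges(path) -> tuple:
    """Read an undirected PPI edge list; self-loops are dropped with a
    warning count and duplicates are silently merged."""
    df = _read_tsv(path, ["protein_a", "protein_b"])
    report = LoadReport(n_rows=len(df))
    seen = set()
    for row in df.itertuples(index=False):
        if row.protein_a == row.protein_b:
            report.n_self_loops += 1
            report.messages.append(f"self-loop dropped: {row.protein_a}")
            continue
        key = tuple(sorted((row.protein_a, row.protein_b)))
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
    edges = sorted(PpiEdge(a, b) for a, b in seen)
    report.n_accepted = len(edges)
    return edges, report


def write_edges(edges, path) -> None:
    df = pd.DataFrame(
        [(e.protein_a, e.protein_b) for e in sorted(edges)],
        columns=["protein_a", "protein_b"],
    )
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# Disease annotations
# ---------------------------------------------------------------------------

def read_annotations(path, snp_ids=None, protein_ids=None) -> DiseaseAnnotation:
    """Read disease labels.  Rows carry ``id_type`` (snp|protein), ``id`` and
    ``disorder``.  Ids absent from the supplied universes are kept but
    counted as orphans, with a single summary warning."""
    df = _read_tsv(path, ["id_type", "id", "disorder"])
    ann = DiseaseAnnotation()
    for row in df.itertuples(index=False):
        if row.id_type == "snp":
            ann.snp_ids.add(row.id)
            if snp_ids is not None and row.id not in snp_ids:
                ann.n_orphans += 1
        elif row.id_type == "protein":
            ann.protein_ids.add(row.id)
            if protein_ids is not None and row.id not in protein_ids:
                ann.n_orphans += 1
        else:
            raise LoadError(f"{path}: unknown id_type {row.id_type!r}")
        ann.labels[row.id] = row.disorder
    if ann.n_orphans:
        warnings.warn(
            f"{path}: {ann.n_orphans} annotation id(s) not in the loaded universe",
            stacklevel=2,
        )
    return ann


def write_annotations(ann: DiseaseAnnotation, path) -> None:
    rows = [("snp", i, ann.labels.get(i, "")) for i in sorted(ann.snp_ids)]
    rows += [("protein", i, ann.labels.get(i, "")) for i in sorted(ann.protein_ids)]
    _write_tsv(pd.DataFrame(rows, columns=["id_type", "id", "disorder"]), path)


# ---------------------------------------------------------------------------
# Reference signature-pair lists
# ---------------------------------------------------------------------------

def read_pairlists(path) -> dict:
    """Read reference signature pairs into ``{kind: ReferencePairList}``.

    Both kinds are always present in the result (possibly empty), so callers
    can index without guards.
    """
    df = _read_tsv(path, ["kind", "sig_a", "sig_b"])
    lists = {
        "domain_domain": ReferencePairList("domain_domain"),
        "domain_motif": ReferencePairList("domain_motif"),
    }
    for row in df.itertuples(index=False):
        if row.kind not in lists:
            raise LoadError(f"{path}: unknown pair kind {row.kind!r}")
        lists[row.kind].add(row.sig_a, row.sig_b)
    return lists


def write_pairlists(lists: dict, path) -> None:
    rows = []
    for kind in sorted(lists):
        for a, b in sorted(lists[kind].pairs):
            rows.append((kind, a, b))
    _write_tsv(pd.DataFrame(rows, columns=["kind", "sig_a", "sig_b"]), path)


# ---------------------------------------------------------------------------
# Linear motifs
# ---------------------------------------------------------------------------

def read_motifs(path) -> list:
    """Read named linear-motif patterns (ELM-like role) as
    ``[(motif_id, pattern_text), ...]``.  Patterns use the same mini-language
    as domain patterns and are parsed by the pattern engine downstream."""
    df = _read_tsv(path, ["motif_id", "pattern"])
    out = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.motif_id in seen:
            raise LoadError(f"{path}: duplicate motif id {row.motif_id!r}")
        seen.add(row.motif_id)
        out.append((row.motif_id, row.pattern))
    return out


def write_motifs(motifs, path) -> None:
    _write_tsv(pd.DataFrame(motifs, columns=["motif_id", "pattern"]), path)
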