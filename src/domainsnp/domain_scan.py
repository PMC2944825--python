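"""PROSITE-style domain annotation.

Two signature flavours are supported:

* **Patterns** — restricted regular expressions over the 20 amino-acid
  letters, written in a PROSITE-like mini-language: elements joined by
  ``-``; ``A`` exact residue; ``[ACD]`` any-of class; ``{P}`` none-of
  class; ``x`` wildcard; an optional ``(n)`` or ``(n,m)`` repetition on any
  element; a leading ``<`` anchors the match to position 1 and a trailing
  ``>`` anchors it to the last residue; a terminal ``.`` is optional.
  Domain presence is the binary fact the downstream classifier consumes.

* **Profiles** — a position score matrix (L rows x 20 columns) with affine
  gap penalties and a presence cutoff.  The *matching score* (MS) is the
  best local alignment score of the profile against the sequence; a domain
  is called present iff MS >= cutoff.  MS is the quantity the domain
  distortion statistic is built from.

At each start position a pattern's variable repetitions are resolved
greedily longest-first (standard backtracking-regex semantics) and only
that one span per start is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import AA_INDEX, AA_SET, AMINO_ACIDS

__all__ = [
    "PatternElement",
    "PatternDefinition",
    "ProfileDefinition",
    "DomainMatch",
    "PatternSyntaxError",
    "parse_pattern",
    "pattern_to_regex",
    "scan_pattern",
    "profile_score",
    "scan_proteome",
    "read_domains",
    "write_domains",
    "read_matches",
    "write_matches",
]


class PatternSyntaxError(ValueError):
    """Pattern mini-language syntax error, carrying the column offset."""

    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class PatternElement:
    kind: str  # exact | any_of | none_of | wildcard
    residues: frozenset
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self):
        if self.kind not in ("exact", "any_of", "none_of", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not (0 <= self.min_repeat <= self.max_repeat):
            raise ValueError("require 0 <= min_repeat <= max_repeat")
        if self.max_repeat == 0:
            raise ValueError("min_repeat and max_repeat cannot both be 0")
        if self.kind == "wildcard" and self.residues:
            raise ValueError("wildcard carries no residues")
        if self.kind == "any_of" and not self.residues:
            raise ValueError("empty any_of class")
        if self.kind == "none_of" and not 0 < len(self.residues) < len(AA_SET):
            raise ValueError("none_of must exclude a proper non-empty subset")

    def admits(self, aa: str) -> bool:
        """Whether a single residue satisfies one repetition of the element."""
        if self.kind == "wildcard":
            return True
        if self.kind == "exact" or self.kind == "any_of":
            return aa in self.residues
        return aa not in self.residues


@dataclass(frozen=True)
class PatternDefinition:
    domain_id: str
    elements: tuple
    n_anchor: bool = False
    c_anchor: bool = False

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern needs at least one element")


@dataclass
class ProfileDefinition:
    """Position score matrix with affine gaps and a presence cutoff.

    ``scores`` has shape (L, 20) with columns ordered as
    :data:`~domainsnp.io_formats.AMINO_ACIDS`.
    """

    domain_id: str
    scores: np.ndarray
    gap_open: float
    gap_extend: float
    cutoff: float

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AMINO_ACIDS):
            raise ValueError("profile scores must be an L x 20 matrix")
        if self.scores.shape[0] < 1:
            raise ValueError("profile length must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("profile cutoff must be > 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.gap_extend < self.gap_open:
            raise ValueError("require gap_extend >= gap_open")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DomainMatch:
    protein_id: str
    domain_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    kind: str  # pattern | profile
    matching_score: Optional[float] = None

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


# ---------------------------------------------------------------------------
# Pattern parsing
# ---------------------------------------------------------------------------

def parse_pattern(text: str, domain_id: str = "") -> PatternDefinition:
    """Parse the pattern mini-language into a :class:`PatternDefinition`.

    Raises :class:`PatternSyntaxError` with a 1-based column offset on
    unbalanced brackets, empty classes, inverted repeat bounds or illegal
    letters.
    """
    s = text.strip()
    if s.endswith("."):
        s = s[:-1]
    n_anchor = s.startswith("<")
    if n_anchor:
        s = s[1:]
    c_anchor = s.endswith(">")
    if c_anchor:
        s = s[:-1]
    if not s:
        raise PatternSyntaxError("empty pattern", 1)

    offset = (1 if n_anchor else 0)  # for column reporting against `text`
    elements = []
    i = 0
    n = len(s)
    while i < n:
        col = i + offset + 1
        ch = s[i]
        kind = None
        residues = frozenset()
        if ch == "[" or ch == "{":
            close = "]" if ch == "[" else "}"
            j = s.find(close, i + 1)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced {ch!r}", col)
            letters = s[i + 1 : j]
            if not letters:
                raise PatternSyntaxError("empty residue class", col)
            bad = set(letters) - AA_SET
            if bad:
                raise PatternSyntaxError(f"illegal letter {sorted(bad)[0]!r}", col)
            kind = "any_of" if ch == "[" else "none_of"
            residues = frozenset(letters)
            i = j + 1
        elif ch == "]" or ch == "}":
            raise PatternSyntaxError(f"unbalanced {ch!r}", col)
        elif ch == "x":
            kind = "wildcard"
            i += 1
        elif ch in AA_SET:
            kind = "exact"
            residues = frozenset(ch)
            i += 1
        else:
            raise PatternSyntaxError(f"illegal letter {ch!r}", col)

        min_rep = max_rep = 1
        if i < n and s[i] == "(":
            j = s.find(")", i + 1)
            if j < 0:
                raise PatternSyntaxError("unbalanced '('", i + offset + 1)
            body = s[i + 1 : j]
            parts = body.split(",")
            try:
                if len(parts) == 1:
                    min_rep = max_rep = int(parts[0])
                elif len(parts) == 2:
                    min_rep, max_rep = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise PatternSyntaxError(
                    f"malformed repetition ({body})", i + offset + 1
                ) from None
            if min_rep < 0 or max_rep < min_rep:
                raise PatternSyntaxError(
                    f"bad repeat bounds ({body})", i + offset + 1
                )
            if max_rep == 0:
                raise PatternSyntaxError("repeat (0,0) is empty", i + offset + 1)
            i = j + 1

        try:
            elements.append(PatternElement(kind, residues, min_rep, max_rep))
        except ValueError as exc:
            raise PatternSyntaxError(str(exc), col) from None

        if i < n:
            if s[i] != "-":
                raise PatternSyntaxError(f"expected '-', got {s[i]!r}", i + offset + 1)
            i += 1
            if i == n:
                raise PatternSyntaxError("trailing '-'", i + offset)

    return PatternDefinition(domain_id, tuple(elements), n_anchor, c_anchor)


def _element_regex(el: PatternElement) -> str:
    if el.kind == "wildcard":
        body = f"[{AMINO_ACIDS}]"
    elif el.kind == "exact":
        body = next(iter(el.residues))
    elif el.kind == "any_of":
        body = "[" + "".join(sorted(el.residues)) + "]"
    else:  # none_of
        body = "[" + "".join(sorted(AA_SET - el.residues)) + "]"
    if el.min_repeat == el.max_repeat == 1:
        return body
    if el.min_repeat == el.max_repeat:
        return f"{body}{{{el.min_repeat}}}"
    return f"{body}{{{el.min_repeat},{el.max_repeat}}}"


def pattern_to_regex(p: PatternDefinition) -> str:
    """Compile a pattern to a Python regular expression (greedy repeats,
    which is exactly the longest-first backtracking resolution the scanner
    documents)."""
    body = "".join(_element_regex(el) for el in p.elements)
    if p.c_anchor:
        body += r"\Z"
    return body


def scan_pattern(p: PatternDefinition, sequence: str) -> list:
    """All match spans of a pattern on a sequence, 1-based inclusive.

    One (greedy) span per matching start position; overlapping starts are
    allowed; zero-length matches are discarded.  Anchored patterns are
    checked only at the forced positions.
    """
    rx = re.compile(pattern_to_regex(p))
    spans = []
    if p.n_anchor:
        m = rx.match(sequence, 0)
        if m is not None and m.end() > 0:
            spans.append((1, m.end()))
        return spans
    # Lookahead trick reports the greedy match at every start, including
    # starts inside earlier matches.
    look = re.compile("(?=(" + pattern_to_regex(p) + "))")
    for m in look.finditer(sequence):
        s, e = m.start(1), m.end(1)
        if e > s:
            spans.append((s + 1, e))
    return spans


# ---------------------------------------------------------------------------
# Profile scoring
# ---------------------------------------------------------------------------

def _profile_dp_impl(S, gap_open, gap_extend):  # pragma: no cover - numba path
    # Local alignment of a profile (rows) against a sequence (columns).
    # Three states per cell: M ends in a match; X ends in a sequence
    # insertion; Y ends in a profile-position deletion.  Alignments start
    # and end in M; leading/trailing gaps are therefore free (local).
    # Ties are broken toward the smallest start, then the smallest end.
    L, n = S.shape
    NEG = -1.0e18
    Mp = np.full(n + 1, NEG)
    Xp = np.full(n + 1, NEG)
    Yp = np.full(n + 1, NEG)
    SMp = np.zeros(n + 1, np.int64)
    SXp = np.zeros(n + 1, np.int64)
    SYp = np.zeros(n + 1, np.int64)
    best = NEG
    b_start = 0
    b_end = 0
    for i in range(1, L + 1):
        Mc = np.full(n + 1, NEG)
        Xc = np.full(n + 1, NEG)
        Yc = np.full(n + 1, NEG)
        SMc = np.zeros(n + 1, np.int64)
        SXc = np.zeros(n + 1, np.int64)
        SYc = np.zeros(n + 1, np.int64)
        for j in range(1, n + 1):
            # --- M: match profile row i to residue j (or start fresh here)
            v = 0.0
            st = j
            if Mp[j - 1] > v or (Mp[j - 1] == v and SMp[j - 1] < st):
                v = Mp[j - 1]
                st = SMp[j - 1]
            if Xp[j - 1] > v or (Xp[j - 1] == v and SXp[j - 1] < st):
                v = Xp[j - 1]
                st = SXp[j - 1]
            if Yp[j - 1] > v or (Yp[j - 1] == v and SYp[j - 1] < st):
                v = Yp[j - 1]
                st = SYp[j - 1]
            Mc[j] = S[i - 1, j - 1] + v
            SMc[j] = st
            # --- Y: delete (skip) profile row i at sequence position j
            v = Mp[j] + gap_open
            st = SMp[j]
            c = Yp[j] + gap_extend
            if c > v or (c == v and SYp[j] < st):
                v = c
                st = SYp[j]
            c = Xp[j] + gap_open
            if c > v or (c == v and SXp[j] < st):
                v = c
                st = SXp[j]
            Yc[j] = v
            SYc[j] = st
            # --- X: insert residue j between profile rows i and i+1
            v = Mc[j - 1] + gap_open
            st = SMc[j - 1]
            c = Xc[j - 1] + gap_extend
            if c > v or (c == v and SXc[j - 1] < st):
                v = c
                st = SXc[j - 1]
            c = Yc[j - 1] + gap_open
            if c > v or (c == v and SYc[j - 1] < st):
                v = c
                st = SYc[j - 1]
            Xc[j] = v
            SXc[j] = st
            # --- track the best alignment ending in a match
            sc = Mc[j]
            if (
                sc > best
                or (sc == best and SMc[j] < b_start)
                or (sc == best and SMc[j] == b_start and j < b_end)
            ):
                best = sc
                b_start = SMc[j]
                b_end = j
        Mp, Xp, Yp = Mc, Xc, Yc
        SMp, SXp, SYp = SMc, SXc, SYc
    return best, b_start, b_end


try:  # numba acceleration; the fallback is the same function, uncompiled
    from numba import njit

    _profile_dp = njit(cache=False)(_profile_dp_impl)
except Exception:  # pragma: no cover
    _profile_dp = _profile_dp_impl


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter(
        (AA_INDEX[aa] for aa in sequence), dtype=np.int64, count=len(sequence)
    )


def profile_score(pr: ProfileDefinition, sequence: str) -> tuple:
    """Best local matching score of a profile on a sequence.

    Returns ``(best_score, (start, end))`` with a 1-based inclusive span.
    The alignment uses position-specific match scores, affine insertions in
    the sequence and affine deletions of profile positions; it must consume
    at least one profile position, and no score floor is applied (the best
    score can be negative).  Ties are broken toward the smallest start,
    then the smallest end.
    """
    if not sequence:
        raise ValueError("empty sequence")
    S = pr.scores[:, _encode(sequence)]
    best, start, end = _profile_dp(np.ascontiguousarray(S), pr.gap_open, pr.gap_extend)
    return float(best), (int(start), int(end))


# ---------------------------------------------------------------------------
# Proteome scanning
# ---------------------------------------------------------------------------

def scan_proteome(domains, proteome) -> list:
    """Annotate a proteome with all domain definitions.

    Patterns contribute every match span; each profile contributes at most
    one match per protein — its best-scoring span — and only when the best
    score reaches the profile's cutoff (inclusive).  Output is ordered by
    protein_id, then domain_id, then start.
    """
    matches = []
    for prot in proteome:
        for d in domains:
            if isinstance(d, PatternDefinition):
                for s, e in scan_pattern(d, prot.sequence):
                    matches.append(
                        DomainMatch(prot.protein_id, d.domain_id, s, e, "pattern")
                    )
            else:
                score, (s, e) = profile_score(d, prot.sequence)
                if score >= d.cutoff:
                    matches.append(
                        DomainMatch(
                            prot.protein_id, d.domain_id, s, e, "profile", score
                        )
                    )
    matches.sort(key=lambda m: (m.protein_id, m.domain_id, m.start))
    return matches


# ---------------------------------------------------------------------------
# Domain-definition file dialect
# ---------------------------------------------------------------------------
#
#   ID=<domain id>
#   TYPE=PATTERN            |  TYPE=PROFILE
#   PA=<pattern text>       |  GAP_OPEN=<float>
#                           |  GAP_EXT=<float>
#                           |  CUTOFF=<float>
#                           |  MA=            (followed by L rows of 20
#                           |                  tab-separated scores)
#   //
#
# '#' comment lines are allowed anywhere.

def read_domains(path) -> list:
    """Parse a domain-definition file into pattern/profile definitions."""
    defs = []
    block: dict = {}
    rows: list = []
    in_matrix = False

    def flush(lineno):
        nonlocal block, rows, in_matrix
        if not block:
            return
        if "ID" not in block or "TYPE" not in block:
            raise ValueError(f"{path}: line {lineno}: block missing ID/TYPE")
        if block["TYPE"] == "PATTERN":
            if "PA" not in block:
                raise ValueError(f"{path}: line {lineno}: pattern block missing PA=")
            defs.append(parse_pattern(block["PA"], block["ID"]))
        elif block["TYPE"] == "PROFILE":
            for key in ("GAP_OPEN", "GAP_EXT", "CUTOFF"):
                if key not in block:
                    raise ValueError(f"{path}: line {lineno}: missing {key}=")
            if not rows:
                raise ValueError(f"{path}: line {lineno}: profile block missing MA rows")
            defs.append(
                ProfileDefinition(
                    block["ID"],
                    np.array(rows, dtype=np.float64),
                    float(block["GAP_OPEN"]),
                    float(block["GAP_EXT"]),
                    float(block["CUTOFF"]),
                )
            )
        else:
            raise ValueError(f"{path}: line {lineno}: unknown TYPE {block['TYPE']!r}")
        block = {}
        rows = []
        in_matrix = False

    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.strip() == "//":
                flush(ln)
                continue
            if in_matrix and "=" not in line:
                vals = line.split("\t")
                if len(vals) != 20:
                    raise ValueError(
                        f"{path}: line {ln}: expected 20 scores, got {len(vals)}"
                    )
                rows.append([float(v) for v in vals])
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key == "MA":
                in_matrix = True
                continue
            block[key] = value.strip()
    flush("EOF")
    return defs


def write_domains(domains, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in domains:
            fh.write(f"ID={d.domain_id}\n")
            if isinstance(d, PatternDefinition):
                fh.write("TYPE=PATTERN\n")
                fh.write(f"PA={format_pattern(d)}\n")
            else:
                fh.write("TYPE=PROFILE\n")
                fh.write(f"GAP_OPEN={d.gap_open!r}\n")
                fh.write(f"GAP_EXT={d.gap_extend!r}\n")
                fh.write(f"CUTOFF={d.cutoff!r}\n")
                fh.write("MA=\n")
                for row in d.scores:
                    fh.write("\t".join(repr(float(v)) for v in row) + "\n")
            fh.write("//\n")


def format_pattern(p: PatternDefinition) -> str:
    """Render a parsed pattern back into the mini-language (round-trips
    through :func:`parse_pattern`)."""
    parts = []
    for el in p.elements:
        if el.kind == "wildcard":
            body = "x"
        elif el.kind == "exact":
            body = next(iter(el.residues))
        elif el.kind == "any_of":
            body = "[" + "".join(sorted(el.residues)) + "]"
        else:
            body = "{" + "".join(sorted(el.residues)) + "}"
        if (el.min_repeat, el.max_repeat) == (1, 1):
            pass
        elif el.min_repeat == el.max_repeat:
            body += f"({el.min_repeat})"
        else:
            body += f"({el.min_repeat},{el.max_repeat})"
        parts.append(body)
    text = "-".join(parts)
    if p.n_anchor:
        text = "<" + text
    if p.c_anchor:
        text += ">"
    return text + "."


# ---------------------------------------------------------------------------
# Match table IO (matches.tsv)
# ---------------------------------------------------------------------------

def write_matches(matches, path) -> None:
    import pandas as pd

    rows = [
        (
            m.protein_id,
            m.domain_id,
            m.kind,
            m.start,
            m.end,
            "NA" if m.matching_score is None else repr(float(m.matching_score)),
        )
        for m in matches
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "domain_id", "kind", "start", "end", "matching_score"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_matches(path) -> list:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        score = None if row.matching_score == "NA" else float(row.matching_score)
        out.append(
            DomainMatch(
                row.protein_id, row.domain_id, int(row.start), int(row.end), row.kind, score
            )
        )
    return out
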