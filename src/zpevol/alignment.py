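"""Alignment reading, conservation profiles, domain intervals, gap profiles.

All alignment columns are 1-based and intervals are closed, following the
usual convention for describing positions in a trimmed protein alignment
(e.g. "ZP-N spans positions 1–80").  Gap characters ('-', with '.'
normalized on input) and ambiguous residues ('X', '?') both count as
missing data throughout; B/Z/U are treated as ordinary residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO


MISSING_CHARS = frozenset("-X?")


class FormatError(ValueError):
    """Malformed alignment input."""


class LookupError_(KeyError):
    """Unknown sequence or domain name."""


@dataclass
class Alignment:
    """An aligned set of equal-length protein sequences.

    ``replicate_id`` identifies which replicate alignment run produced it
    when the same sequence set is aligned repeatedly.
    """

    rows: List[Tuple[str, str]]
    replicate_id: Optional[str] = None

    def __post_init__(self):
        if not self.rows:
            raise FormatError("empty alignment")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        names = [n for n, _ in self.rows]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate sequence names: {dup}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def names(self) -> List[str]:
        return [n for n, _ in self.rows]

    def sequence(self, name: str) -> str:
        for n, s in self.rows:
            if n == name:
                return s
        raise LookupError_(f"no sequence named {name!r}")

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, one per row."""
        if not 1 <= col <= self.n_cols:
            raise ValueError(f"column {col} outside 1..{self.n_cols}")
        return "".join(s[col - 1] for _, s in self.rows)


def read_alignment(path, replicate_id: Optional[str] = None) -> Alignment:
    """Read an aligned FASTA file.

    Residues are upper-cased and '.' gaps normalized to '-'.  Ragged rows,
    duplicate names, and empty files are format errors.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no sequences in {path}")
    rows = [(r.id, str(r.seq).upper().replace(".", "-")) for r in records]
    return Alignment(rows, replicate_id=replicate_id)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.rows:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Column statistics
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    col: int
    residue_freqs: Dict[str, float]
    missing_frac: float


def column_profile(aln: Alignment, col: int) -> ColumnProfile:
    """Residue frequencies (among non-missing rows) and missing fraction."""
    chars = aln.column(col)
    n = len(chars)
    present = [c for c in chars if c not in MISSING_CHARS]
    missing_frac = (n - len(present)) / n
    freqs: Dict[str, float] = {}
    if present:
        for c in present:
            freqs[c] = freqs.get(c, 0) + 1
        freqs = {c: k / len(present) for c, k in sorted(freqs.items())}
    return ColumnProfile(col, freqs, missing_frac)


def consensus_sequence(aln: Alignment, threshold: float = 0.5) -> Tuple[str, int]:
    """Majority-rule consensus and its cysteine count.

    A column's consensus residue must exceed ``threshold`` strictly among
    non-missing rows (ties at the threshold give '-'), so the result does
    not depend on row order.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out = []
    for col in range(1, aln.n_cols + 1):
        prof = column_profile(aln, col)
        best = "-"
        if prof.residue_freqs:
            res, frac = max(prof.residue_freqs.items(), key=lambda kv: (kv[1], kv[0]))
            if frac > threshold:
                best = res
        out.append(best)
    consensus = "".join(out)
    return consensus, consensus.count("C")


def logo_matrix(aln: Alignment) -> List[ColumnProfile]:
    """Per-column residue-frequency table (position frequency matrix)."""
    return [column_profile(aln, c) for c in range(1, aln.n_cols + 1)]


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

@dataclass
class DomainMap:
    """Ordered, non-overlapping closed 1-based column intervals."""

    domains: List[Tuple[str, int, int]]

    def __post_init__(self):
        prev_end = 0
        for name, start, end in self.domains:
            if start > end:
                raise ValueError(f"domain {name}: start {start} > end {end}")
            if start <= prev_end:
                raise ValueError(f"domain {name} overlaps the previous domain")
            prev_end = end

    def interval(self, domain_id: str) -> Tuple[int, int]:
        for name, s, e in self.domains:
            if name == domain_id:
                return s, e
        raise LookupError_(f"no domain named {domain_id!r}")

    def domain_ids(self) -> List[str]:
        return [name for name, _, _ in self.domains]


DEFAULT_ANCHORS = (1, 80, 105, 218)


def demarcate_domains(
    anchor_cols: Tuple[int, int, int, int] = DEFAULT_ANCHORS,
    n_cols: Optional[int] = None,
) -> DomainMap:
    """ZP-N / ZP-C domain intervals from four cysteine anchor columns.

    ZP-N runs from the first to the second anchor (Cys1..Cys4) and ZP-C
    from the third to the fourth (the conserved betaA-strand cysteine to
    Cys8).
    """
    a1, a2, a3, a4 = anchor_cols
    if not (a1 < a2 < a3 < a4):
        raise ValueError(f"anchors must be strictly increasing, got {anchor_cols}")
    if a1 < 1:
        raise ValueError("anchors must be positive")
    if n_cols is not None and a4 > n_cols:
        raise ValueError(f"anchor {a4} beyond alignment length {n_cols}")
    return DomainMap([("ZP-N", a1, a2), ("ZP-C", a3, a4)])


def locate_anchor(
    aln: Alignment, nominal: int, window: int = 3, min_c_frac: float = 0.5
) -> int:
    """Find the conserved-cysteine column nearest ``nominal`` within a window.

    Replicate alignments jitter columns by a few positions, so anchors are
    re-located per replicate as the column (within +/- ``window`` of the
    nominal position) whose cysteine fraction among non-missing rows is at
    least ``min_c_frac``; the nearest qualifying column wins, with the
    leftmost preferred on distance ties.  Falls back to the nominal column
    if none qualifies.
    """
    best = None
    for col in range(max(1, nominal - window), min(aln.n_cols, nominal + window) + 1):
        prof = column_profile(aln, col)
        if prof.residue_freqs.get("C", 0.0) >= min_c_frac:
            key = (abs(col - nominal), col)
            if best is None or key < best:
                best = key
    return best[1] if best else nominal


def locate_domain_map(
    aln: Alignment,
    nominal_anchors: Tuple[int, int, int, int] = DEFAULT_ANCHORS,
    window: int = 3,
) -> DomainMap:
    """Per-replicate DomainMap with anchors re-located by conserved cysteines."""
    anchors = tuple(locate_anchor(aln, a, window=window) for a in nominal_anchors)
    return demarcate_domains(anchors, n_cols=aln.n_cols)


# ---------------------------------------------------------------------------
# Gap profiles
# ---------------------------------------------------------------------------

@dataclass
class GapProfile:
    seq_name: str
    per_domain: Dict[str, float]
    replicate_id: str = "mean"


def gap_proportion(aln: Alignment, seq_name: str, interval: Tuple[int, int]) -> float:
    """Fraction of gap/ambiguous characters of a row in a closed interval."""
    seq = aln.sequence(seq_name)
    start, end = interval
    if not (1 <= start <= end <= aln.n_cols):
        raise ValueError(f"interval {interval} outside 1..{aln.n_cols}")
    chunk = seq[start - 1 : end]
    return sum(1 for c in chunk if c in MISSING_CHARS) / len(chunk)


def gap_profile(aln: Alignment, seq_name: str, domain_map: DomainMap) -> GapProfile:
    per_domain = {
        d: gap_proportion(aln, seq_name, domain_map.interval(d))
        for d in domain_map.domain_ids()
    }
    return GapProfile(seq_name, per_domain, replicate_id=aln.replicate_id or "0")


def replicate_mean_gap(
    replicates: Sequence[Alignment],
    domain_maps: Sequence[DomainMap],
    seq_name: str,
    domain_id: str,
) -> GapProfile:
    """Across-replicate arithmetic mean of a sequence's domain gap fraction.

    ``domain_maps`` supplies one (possibly re-located) DomainMap per
    replicate, matched by position.
    """
    if len(replicates) != len(domain_maps):
        raise ValueError("one DomainMap per replicate required")
    vals = []
    for aln, dm in zip(replicates, domain_maps):
        if seq_name not in aln.names():
            raise LookupError_(
                f"sequence {seq_name!r} missing from replicate {aln.replicate_id!r}"
            )
        vals.append(gap_proportion(aln, seq_name, dm.interval(domain_id)))
    return GapProfile(seq_name, {domain_id: float(np.mean(vals))}, "mean")


def mean_gap_profiles(
    replicates: Sequence[Alignment],
    domain_maps: Sequence[DomainMap],
) -> Dict[str, GapProfile]:
    """Replicate-averaged per-domain gap profile for every sequence."""
    names = replicates[0].names()
    domain_ids = domain_maps[0].domain_ids()
    out: Dict[str, GapProfile] = {}
    for nm in names:
        per_domain = {
            d: replicate_mean_gap(replicates, domain_maps, nm, d).per_domain[d]
            for d in domain_ids
        }
        out[nm] = GapProfile(nm, per_domain, "mean")
    return out


def gap_profile_table(profiles: Iterable[GapProfile]) -> List[dict]:
    rows = []
    for p in profiles:
        for d, frac in sorted(p.per_domain.items()):
            rows.append(
                {
                    "name": p.seq_name,
                    "replicate": p.replicate_id,
                    "domain": d,
                    "gap_fraction": frac,
                }
            )
    return rows
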