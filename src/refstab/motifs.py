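"""Cysteine-spacing classification of OBP and CSP protein sequences.

Small soluble olfactory proteins are classed by the number and spacing
of their conserved cysteines:

* **minus-C OBP** — 4 cysteines, Cys1-X(28–32)-Cys2-X(37–39)-Cys3-X(16–23)-Cys4
* **classic OBP** — 6 cysteines, Cys1-X27-Cys2-X3-Cys3-X29-Cys4-X9-Cys5-X8-Cys6
* **plus-C OBP** — 8 cysteines,
  Cys1-X35-Cys2-X3-Cys3-X43-Cys4-X13-Cys4a-X9-Cys5-X8-Cys6-X10-Cys6a
* **CSP** — 4 cysteines, Cys1-X(6–8)-Cys2-X18-Cys3-X2-Cys4

A gap of ``X_n`` means *n* residues strictly between two consecutive
matched cysteines.  Single-width spacings above are observations from
individual sequences rather than family-wide windows, so the shipped
patterns widen every gap longer than 10 residues by a configurable
tolerance (default ±2) while keeping short gaps exact.

Matching enumerates increasing subsequences of cysteine positions by
depth-first search; by default non-matched cysteines may occur inside a
gap (the patterns describe *conserved* cysteines), and a strict mode
forbids them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CysPattern",
    "MotifMatch",
    "default_patterns",
    "DEFAULT_PATTERNS",
    "find_matches",
    "verify_match",
    "classify",
    "read_fasta",
    "write_fasta",
]

#: The 20 standard residues; X is tolerated in input but never matches Cys.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AMINO_ACIDS) | {"X"}


class MotifError(ValueError):
    """Invalid sequence or pattern."""


@dataclass(frozen=True)
class CysPattern:
    """Ordered gap windows between consecutive conserved cysteines.

    ``gaps`` holds ``(min_gap, max_gap)`` residue counts strictly between
    cysteine i and cysteine i+1; a pattern with g gaps has ``g + 1``
    conserved cysteines.
    """

    name: str
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        gaps = tuple((int(lo), int(hi)) for lo, hi in self.gaps)
        for lo, hi in gaps:
            if lo < 0 or lo > hi:
                raise MotifError(f"invalid gap window ({lo}, {hi})")
        object.__setattr__(self, "gaps", gaps)

    @property
    def cys_count(self) -> int:
        return len(self.gaps) + 1


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a pattern's conserved cysteines on a sequence.

    ``positions`` are 1-based within the analyzed region; ``offset`` is
    the 0-based start of that region in the full sequence (nonzero when a
    mature-peptide start was supplied).
    """

    pattern: str
    positions: tuple[int, ...]
    offset: int = 0

    @property
    def absolute_positions(self) -> tuple[int, ...]:
        """1-based positions on the full input sequence."""
        return tuple(p + self.offset for p in self.positions)


def _widen(gap: int, tolerance: int, wide_gap_min: int) -> tuple[int, int]:
    if gap >= wide_gap_min:
        return (max(0, gap - tolerance), gap + tolerance)
    return (gap, gap)


def default_patterns(
    *, tolerance: int = 2, wide_gap_min: int = 11
) -> dict[str, CysPattern]:
    """The four shipped patterns with tolerance applied to long gaps.

    ``tolerance`` widens every single-width spacing of at least
    ``wide_gap_min`` residues by ± that many residues; spacings already
    given as ranges (minus-C, CSP's first gap) are kept as published.
    """
    return {
        "minus_c_obp": CysPattern(
            "minus_c_obp", ((28, 32), (37, 39), (16, 23))
        ),
        "classic_obp": CysPattern(
            "classic_obp",
            tuple(_widen(g, tolerance, wide_gap_min) for g in (27, 3, 29, 9, 8)),
        ),
        "plus_c_obp": CysPattern(
            "plus_c_obp",
            tuple(
                _widen(g, tolerance, wide_gap_min)
                for g in (35, 3, 43, 13, 9, 8, 10)
            ),
        ),
        "csp": CysPattern(
            "csp",
            ((6, 8),) + tuple(_widen(g, tolerance, wide_gap_min) for g in (18, 2)),
        ),
    }


DEFAULT_PATTERNS: dict[str, CysPattern] = default_patterns()


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise MotifError(f"invalid residue character {sorted(bad)[0]!r}")
    return seq


def find_matches(
    seq: str,
    pattern: CysPattern,
    mature_start: int | None = None,
    *,
    strict: bool = False,
) -> list[MotifMatch]:
    """All placements of ``pattern`` on ``seq`` (DFS over Cys positions).

    ``mature_start`` (1-based) restricts the search to the mature
    peptide, e.g. after a signal peptide.  ``strict`` forbids non-matched
    cysteines inside gaps, reading the X-notation literally.
    """
    seq = _check_sequence(seq)
    offset = 0
    if mature_start is not None:
        if not 1 <= mature_start <= len(seq):
            raise MotifError(f"mature_start {mature_start} outside sequence")
        offset = mature_start - 1
        seq = seq[offset:]

    cys = [i for i, aa in enumerate(seq) if aa == "C"]  # 0-based
    matches: list[MotifMatch] = []

    def extend(path: list[int], next_from: int) -> None:
        depth = len(path) - 1  # gaps placed so far
        if depth == len(pattern.gaps):
            matches.append(
                MotifMatch(
                    pattern.name,
                    tuple(p + 1 for p in path),
                    offset,
                )
            )
            return
        lo, hi = pattern.gaps[depth]
        last = path[-1]
        for idx in range(next_from, len(cys)):
            gap = cys[idx] - last - 1
            if gap > hi:
                break  # cys positions increase, so later gaps only grow
            if gap < lo:
                continue
            if strict and seq.count("C", last + 1, cys[idx]) > 0:
                continue
            path.append(cys[idx])
            extend(path, idx + 1)
            path.pop()

    for start_idx in range(len(cys)):
        extend([cys[start_idx]], start_idx + 1)
    return matches


def verify_match(seq: str, match: MotifMatch, pattern: CysPattern) -> bool:
    """Independent re-check: positions are Cys and gaps fall in windows."""
    seq = _check_sequence(seq)
    pos = [p - 1 + match.offset for p in match.positions]
    if len(pos) != pattern.cys_count:
        return False
    if any(p2 <= p1 for p1, p2 in zip(pos, pos[1:])):
        return False
    if any(not 0 <= p < len(seq) or seq[p] != "C" for p in pos):
        return False
    for (lo, hi), p1, p2 in zip(pattern.gaps, pos, pos[1:]):
        if not lo <= p2 - p1 - 1 <= hi:
            return False
    return True


def classify(
    seq: str,
    patterns: Mapping[str, CysPattern] | None = None,
    mature_start: int | None = None,
    *,
    strict: bool = False,
) -> str | list[str]:
    """Class label for a sequence, ``"unclassified"`` when nothing matches.

    Among matching patterns the one with the most conserved cysteines
    wins (plus-C over classic over the 4-cysteine groups); a tie between
    equal-cysteine-count patterns is reported as a list of labels.
    """
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    best: list[str] = []
    best_count = 0
    for name, pattern in patterns.items():
        if find_matches(seq, pattern, mature_start, strict=strict):
            if pattern.cys_count > best_count:
                best, best_count = [name], pattern.cys_count
            elif pattern.cys_count == best_count:
                best.append(name)
    if not best:
        return "unclassified"
    return best[0] if len(best) == 1 else best


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs, order preserved.

    Ids are the first whitespace token of the header line.
    """
    path = Path(path)
    if not path.exists():
        raise MotifError(f"no such file: {path}")
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise MotifError(
                        f"sequence data before first header in {path}"
                    )
                break
        else:
            raise MotifError(f"no FASTA records in {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise MotifError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA (60-column wrapped)."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, Path(path), "fasta")
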