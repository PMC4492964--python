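"""Perfect tandem-repeat detection and candidate-locus selection.

Detection reports maximal perfect runs of 3- and 4-base motifs; selection
keeps runs long enough to be promising markers (3-base motifs at >= 10
units, 4-base motifs at >= 8 units by default).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class RepeatHit:
    """One maximal perfect tandem run; coordinates are 0-based half-open."""

    seq_id: str
    start: int
    end: int
    motif: str
    unit_length: int
    n_units: int

    def __post_init__(self):
        if self.end - self.start != self.unit_length * self.n_units:
            raise ValueError("span does not equal unit_length * n_units")

    @property
    def canonical_motif(self) -> str:
        """Lexicographic minimum over motif rotations (grouping key)."""
        return min(
            self.motif[i:] + self.motif[:i] for i in range(len(self.motif))
        )


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_tandem_repeats(
    sequence: str,
    seq_id: str = "seq",
    unit_lengths: Iterable[int] = (3, 4),
    min_units: int = 4,
) -> list[RepeatHit]:
    """Find all maximal perfect tandem runs of the given unit lengths.

    ``N`` (or any non-ACGT character) breaks runs. Runs whose motif is a
    repetition of a shorter motif (homopolymers inside a 3-mer scan,
    dinucleotide doublets inside a 4-mer scan) are suppressed: they belong
    to the shorter unit length, which is outside the scanned set.

    A maximal periodic stretch whose length is not a whole number of
    units admits several phase alignments (rotated motifs), and stretches
    of adjacent arrays can overlap by up to ``unit_length - 1`` flanking
    characters. Per unit length, the reported hits are the non-overlapping
    set of whole-unit arrays maximizing the total number of units (ties
    broken toward later starts), so adjacent arrays tile flush against
    each other and a stray flank character cannot rotate a reported
    motif. Every hit's slice is exactly ``motif * n_units``.
    """
    seq = sequence.upper()
    n = len(seq)
    valid = [c in VALID_BASES for c in seq]
    hits: list[RepeatHit] = []
    for u in sorted(set(unit_lengths)):
        if u < 1:
            raise ValueError("unit length must be positive")
        if n < u * min_units:
            continue
        # b[x] = True when position x matches the one a unit ahead
        b = [valid[x] and valid[x + u] and seq[x] == seq[x + u] for x in range(n - u)]
        candidates: list[tuple[int, int, int]] = []  # (start, end, n_units)
        x = 0
        while x < len(b):
            if not b[x]:
                x += 1
                continue
            j = x
            while j < len(b) and b[j]:
                j += 1
            stretch_len = (j - x) + u  # periodic stretch seq[x : j + u]
            # one candidate per phase; off >= u would repeat a phase with a
            # full same-motif unit in front of it
            for off in range(min(u, stretch_len - u * min_units + 1)):
                k = (stretch_len - off) // u
                if k < min_units:
                    continue
                start = x + off
                if _is_primitive(seq[start : start + u]):
                    candidates.append((start, start + u * k, k))
            x = j + 1
        hits.extend(
            RepeatHit(
                seq_id=seq_id,
                start=s,
                end=e,
                motif=seq[s : s + u],
                unit_length=u,
                n_units=k,
            )
            for s, e, k in _best_tiling(candidates)
        )
    hits.sort(key=lambda h: (h.start, h.unit_length))
    return hits


def _best_tiling(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Non-overlapping subset maximizing (total units, total start).

    Weighted interval scheduling; the start-sum tie-break prefers
    right-aligned phases when a stretch's slack characters are unclaimed.
    """
    if not candidates:
        return []
    cands = sorted(candidates, key=lambda c: c[1])
    ends = [c[1] for c in cands]
    # best[i]: (value, chosen) over the first i candidates
    best: list[tuple[tuple[int, int], tuple]] = [((0, 0), ())]
    for i, (s, e, k) in enumerate(cands):
        skip_val, skip_sel = best[i]
        p = bisect.bisect_right(ends, s, hi=i)
        prev_val, prev_sel = best[p]
        take_val = (prev_val[0] + k, prev_val[1] + s)
        if take_val > skip_val:
            best.append((take_val, prev_sel + ((s, e, k),)))
        else:
            best.append((skip_val, skip_sel))
    return sorted(best[-1][1])


def select_candidates(
    hits: Iterable[RepeatHit],
    min_units_3: int = 10,
    min_units_4: int = 8,
) -> list[RepeatHit]:
    """Keep hits long enough to be candidate marker loci.

    Thresholds: 3-base motifs need >= ``min_units_3`` units, 4-base motifs
    >= ``min_units_4``. Idempotent by construction.
    """
    out = []
    for h in hits:
        if h.unit_length == 3 and h.n_units >= min_units_3:
            out.append(h)
        elif h.unit_length == 4 and h.n_units >= min_units_4:
            out.append(h)
    return out


def scan_fasta(
    path,
    unit_lengths: Iterable[int] = (3, 4),
    min_units: int = 4,
    min_units_3: int = 10,
    min_units_4: int = 8,
) -> list[tuple[RepeatHit, bool]]:
    """Scan a FASTA file; return (hit, selected) pairs in file order."""
    results: list[tuple[RepeatHit, bool]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        hits = find_tandem_repeats(
            str(rec.seq), seq_id=rec.id, unit_lengths=unit_lengths, min_units=min_units
        )
        selected = set(
            id(h) for h in select_candidates(hits, min_units_3, min_units_4)
        )
        results.extend((h, id(h) in selected) for h in hits)
    return results


def write_hits_tsv(results: Sequence[tuple[RepeatHit, bool]], path) -> None:
    lines = ["seq_id\tstart\tend\tmotif\tunit_length\tn_units\tselected"]
    for h, sel in results:
        lines.append(
            f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif}\t{h.unit_length}\t"
            f"{h.n_units}\t{int(sel)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
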