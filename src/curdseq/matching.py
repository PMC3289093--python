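"""Full-length, substitution-only matching of short queries against references.

This is the alignment primitive behind both the rRNA contamination screen
and read-to-unigene alignment: a query matches a reference iff its *entire*
length can be placed on either strand of the reference with at most
``max_mismatch`` substitutions (N counts as a mismatch, never a match).

Candidate placements are found by k-mer pigeonhole seeding: the query is
split into ``max_mismatch + 1`` non-overlapping seeds, so any placement
within the mismatch budget leaves at least one seed exact.  Each exact seed
hit proposes an offset, which is then verified by direct Hamming counting.
Queries too short to carry informative seeds fall back to a brute scan.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .records import revcomp

class SubstringMatcher:
    """Index of reference sequences supporting ≤k-mismatch full-length lookup."""

    def __init__(self, references: Sequence, seed_len: int = 12):
        self.seed_len = seed_len
        self.refs: dict[str, str] = {}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref in references:
            ref_id = getattr(ref, "seq_id", None) or getattr(ref, "unigene_id", None)
            seq = ref.sequence.upper()
            self.refs[ref_id] = seq
            for pos in range(0, len(seq) - seed_len + 1):
                self._index[seq[pos : pos + seed_len]].append((ref_id, pos))

    @staticmethod
    def _hamming(a: str, b: str, limit: int) -> int:
        """Mismatch count between equal-length strings, short-circuited at limit+1."""
        mm = 0
        for ca, cb in zip(a, b):
            if ca != cb or ca == "N":
                mm += 1
                if mm > limit:
                    return mm
        return mm

    def _candidate_starts(self, query: str, max_mismatch: int) -> set[tuple[str, int]]:
        n_seeds = max_mismatch + 1
        qlen = len(query)
        starts: set[tuple[str, int]] = set()
        if qlen < n_seeds * self.seed_len:
            # too short for pigeonhole chunks: brute scan every feasible window
            for ref_id, seq in self.refs.items():
                for pos in range(0, len(seq) - qlen + 1):
                    starts.add((ref_id, pos))
            return starts
        # n_seeds equal chunks, each at least seed_len long, so a placement
        # with ≤ max_mismatch substitutions leaves at least one seed exact
        bounds = [i * qlen // n_seeds for i in range(n_seeds)]
        for off in bounds:
            seed = query[off : off + self.seed_len]
            for ref_id, pos in self._index.get(seed, ()):
                start = pos - off
                if 0 <= start <= len(self.refs[ref_id]) - qlen:
                    starts.add((ref_id, start))
        return starts

    def best_placements(
        self, query: str, max_mismatch: int
    ) -> tuple[list[tuple[str, int, str]], int]:
        """All equally-best full-length placements of ``query``.

        Returns ``(placements, mismatches)`` where each placement is
        ``(ref_id, start, strand)`` with ``start`` on the forward reference
        coordinate; the list is empty when no placement is within budget.
        Placements are ordered deterministically.
        """
        query = query.upper()
        best_mm = max_mismatch + 1
        hits: list[tuple[str, int, str, int]] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for ref_id, start in self._candidate_starts(q, max_mismatch):
                window = self.refs[ref_id][start : start + len(q)]
                mm = self._hamming(q, window, max_mismatch)
                if mm <= max_mismatch:
                    hits.append((ref_id, start, strand, mm))
        if not hits:
            return [], best_mm
        best_mm = min(h[3] for h in hits)
        best = sorted(
            {(h[0], h[1], h[2]) for h in hits if h[3] == best_mm}
        )
        return best, best_mm

    def matches(self, query: str, max_mismatch: int) -> bool:
        placements, _ = self.best_placements(query, max_mismatch)
        return bool(placements)


def hamming_distance(a: str, b: str) -> int:
    """Plain mismatch count between equal-length strings (N mismatches everything)."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal lengths")
    return sum(1 for ca, cb in zip(a, b) if ca != cb or ca == "N")
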