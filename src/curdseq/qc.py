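"""Read quality control: adaptor/quality trimming and rRNA screening.

Trimming runs before contamination screening, mirroring the processing
order of the pipeline: 3' adaptor read-through is clipped first (exact
seed match extended allowing 10% mismatch), then low-quality 3' bases are
trimmed by a simple scan, and reads shorter than the minimum length are
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .matching import SubstringMatcher
from .records import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class TrimStats:
    n_input: int = 0
    n_adaptor_trimmed: int = 0
    n_quality_trimmed: int = 0
    n_discarded: int = 0
    n_kept: int = 0


def _find_adaptor(seq: str, adaptor: str, seed_len: int, max_mismatch_frac: float) -> int:
    """Leftmost position where the adaptor starts at the 3' end, or -1.

    An occurrence is an exact match of the first ``seed_len`` adaptor bases
    followed by extension to the end of the read allowing a 10% mismatch
    rate over the extended region; the adaptor prefix must run to the end
    of the read (read-through geometry).
    """
    seed = adaptor[:seed_len]
    pos = seq.find(seed)
    while pos != -1:
        tail = seq[pos:]
        ref = adaptor[: len(tail)]
        if len(ref) == len(tail):
            mm = sum(1 for a, b in zip(tail, ref) if a != b)
            if mm <= max_mismatch_frac * len(tail):
                return pos
        pos = seq.find(seed, pos + 1)
    return -1


def trim_reads(
    reads: Sequence[ReadRecord],
    quality_min: int = 20,
    adaptor: str | None = None,
    min_len: int = 30,
    adaptor_seed_len: int = 10,
) -> tuple[list[ReadRecord], TrimStats]:
    """Trim adaptor read-through and low-quality 3' tails; drop short reads."""
    if quality_min < 0:
        raise ValueError("quality_min must be >= 0")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    stats = TrimStats(n_input=len(reads))
    out: list[ReadRecord] = []
    adaptor = adaptor.upper() if adaptor else None
    for read in reads:
        seq, qual = read.sequence, read.quality
        if len(seq) != len(qual):
            raise ValueError(f"malformed record {read.read_id!r}: length mismatch")
        if adaptor:
            pos = _find_adaptor(seq, adaptor, adaptor_seed_len, 0.10)
            if pos != -1:
                seq, qual = seq[:pos], qual[:pos]
                stats.n_adaptor_trimmed += 1
        end = len(seq)
        while end > 0 and ord(qual[end - 1]) - 33 < quality_min:
            end -= 1
        if end < len(seq):
            stats.n_quality_trimmed += 1
            seq, qual = seq[:end], qual[:end]
        if len(seq) < min_len:
            stats.n_discarded += 1
            continue
        out.append(ReadRecord(read.read_id, seq, qual))
    stats.n_kept = len(out)
    logger.info(
        "trim_reads: %d in, %d adaptor-trimmed, %d quality-trimmed, %d discarded",
        stats.n_input, stats.n_adaptor_trimmed, stats.n_quality_trimmed, stats.n_discarded,
    )
    return out, stats


def screen_rrna(
    reads: Sequence[ReadRecord],
    rrna: Sequence,
    max_mismatch: int = 2,
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """Partition reads into (kept, removed) by full-length rRNA matching.

    A read is removed iff its entire length matches some position on either
    strand of an rRNA record with at most ``max_mismatch`` substitutions.
    Also returns a report table (read_id, contaminant_id, mismatches) for
    the removed reads.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not rrna:
        logger.warning("screen_rrna: empty rRNA reference, keeping all reads")
        return list(reads), [], pd.DataFrame(
            columns=["read_id", "contaminant_id", "mismatches"]
        )
    matcher = SubstringMatcher(rrna)
    kept: list[ReadRecord] = []
    removed: list[ReadRecord] = []
    rows = []
    for read in reads:
        placements, mm = matcher.best_placements(read.sequence, max_mismatch)
        if placements:
            removed.append(read)
            rows.append((read.read_id, placements[0][0], mm))
        else:
            kept.append(read)
    report = pd.DataFrame(rows, columns=["read_id", "contaminant_id", "mismatches"])
    logger.info("screen_rrna: %d kept, %d removed", len(kept), len(removed))
    return kept, removed, report
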