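"""Per-unigene read counting and RPKM normalization.

RPKM (reads per kilobase of transcript model per million mapped reads):

    rpkm = count * 1e9 / (library_size * length)

where ``library_size`` is the number of reads assigned to the unigene set
in that library (mapped-read denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import AlignmentHit, Unigene


@dataclass
class CountTable:
    """Per-(unigene, library) integer counts with library totals."""

    counts: pd.DataFrame  # index unigene_id, one column per library
    library_sizes: pd.Series  # total assigned reads per library

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class RPKMTable:
    """Per-(unigene, library) RPKM values plus unigene lengths."""

    rpkm: pd.DataFrame
    lengths: pd.Series


def count_reads(
    hits_by_library: Mapping[str, Sequence[AlignmentHit]],
    unigenes: Sequence[Unigene],
    policy: str = "discard-ties",
    seed: int = 0,
) -> CountTable:
    """Assign aligned reads to unigenes and tally counts per library.

    Each read contributes at most 1 to exactly one unigene.  Under
    ``discard-ties`` (default) a read with two or more equally-best
    placements contributes to none; under ``best-unique`` one of the tied
    placements is chosen uniformly at random (seeded).
    """
    if policy not in ("discard-ties", "best-unique"):
        raise ValueError(f"unknown counting policy {policy!r}")
    known = {u.unigene_id for u in unigenes}
    index = pd.Index([u.unigene_id for u in unigenes], name="unigene_id")
    rng = np.random.default_rng(seed)
    data = {}
    sizes = {}
    for lib, hits in hits_by_library.items():
        tally = dict.fromkeys(index, 0)
        assigned = 0
        for hit in hits:
            if not hit.placements:
                continue
            bad = [p[0] for p in hit.placements if p[0] not in known]
            if bad:
                raise ValueError(f"hit on unknown unigene {bad[0]!r}")
            if hit.n_best > 1:
                if policy == "discard-ties":
                    continue
                choice = hit.placements[int(rng.integers(hit.n_best))]
            else:
                choice = hit.placements[0]
            tally[choice[0]] += 1
            assigned += 1
        data[lib] = [tally[u] for u in index]
        sizes[lib] = assigned
    counts = pd.DataFrame(data, index=index, dtype=int)
    return CountTable(counts=counts, library_sizes=pd.Series(sizes, dtype=int))


def compute_rpkm(table: CountTable, lengths: Mapping[str, int] | pd.Series) -> RPKMTable:
    """RPKM = count * 1e9 / (library_size * length)."""
    lengths = pd.Series(lengths, dtype=float).reindex(table.counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every unigene needs a positive length")
    rpkm = table.counts.astype(float).copy()
    for lib in table.libraries:
        n = table.library_sizes[lib]
        if n == 0:
            if table.counts[lib].sum() > 0:
                raise ValueError(f"library {lib!r} has counts but zero library size")
            rpkm[lib] = 0.0
        else:
            rpkm[lib] = table.counts[lib] * 1e9 / (n * lengths)
    return RPKMTable(rpkm=rpkm, lengths=lengths)


def write_expression_table(
    table: CountTable, rpkm: RPKMTable, path: str | Path
) -> pd.DataFrame:
    """Write the combined count/RPKM table as TSV and return it."""
    out = pd.DataFrame({"length": rpkm.lengths.astype(int)})
    for lib in table.libraries:
        out[f"count_{lib}"] = table.counts[lib]
    for lib in table.libraries:
        out[f"rpkm_{lib}"] = rpkm.rpkm[lib]
    out.index.name = "unigene_id"
    out.to_csv(path, sep="\t")
    return out
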