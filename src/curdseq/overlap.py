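"""Regulator target-set overlap and functional-category accounting.

Unigenes are mapped to a reference organism's genes by best-hit local
alignment (k-mer seeded, desk scale); differentially expressed unigene
sets are then intersected, through that homolog map, with a regulator's
target catalogue (e.g. the genome-wide HY5 binding target set, whose
entries carry light/dark condition labels), and tallied into functional
categories from an annotation map.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .records import Unigene, revcomp

logger = logging.getLogger(__name__)

VALID_CONDITIONS = {"light", "dark", "both", "unlabeled"}


@dataclass
class TargetSet:
    """Reference-gene targets of a regulator, labeled by condition."""

    entries: dict[str, str]  # reference_gene_id -> condition label
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values()} - VALID_CONDITIONS
        if bad:
            raise ValueError(f"invalid condition labels: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetSet":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["gene_id"], df["condition"])), provenance=str(path))


@dataclass
class HomologHit:
    reference_gene_id: str
    score: float
    evalue_like: float


# Karlin–Altschul-style score scaling for the e-value-like quantity; the
# parameters are generic for the match/mismatch scheme below and the value
# is approximate — only the thresholds matter here.
_KA_LAMBDA = 0.5
_KA_K = 0.1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def map_homologs(
    unigenes: Sequence[Unigene],
    reference: Sequence,
    min_score: float = 50.0,
    max_eval: float = 1e-6,
    seed_k: int = 11,
) -> dict[str, HomologHit]:
    """Best-hit homolog assignment of unigenes to reference genes.

    Candidate reference genes must share an exact ``seed_k``-mer with the
    unigene (either strand); candidates are scored by local alignment and
    the best hit per unigene is kept when it passes both thresholds.  Ties
    break to the lexicographically smallest reference id.
    """
    if min_score <= 0 or max_eval <= 0:
        raise ValueError("thresholds must be positive")
    if not reference:
        logger.warning("map_homologs: empty reference, empty map")
        return {}
    aligner = _make_aligner()
    ref_kmers: dict[str, set[int]] = defaultdict(set)
    ref_list = [(r.seq_id, r.sequence) for r in reference]
    total_ref_len = sum(len(s) for _, s in ref_list)
    for ri, (_, seq) in enumerate(ref_list):
        for i in range(len(seq) - seed_k + 1):
            ref_kmers[seq[i : i + seed_k]].add(ri)
    out: dict[str, HomologHit] = {}
    for uni in unigenes:
        candidates: set[int] = set()
        for query in (uni.sequence, revcomp(uni.sequence)):
            for i in range(len(query) - seed_k + 1):
                candidates |= ref_kmers.get(query[i : i + seed_k], set())
        best: tuple[float, str] | None = None
        for ri in sorted(candidates):
            ref_id, ref_seq = ref_list[ri]
            score = max(
                aligner.score(ref_seq, uni.sequence),
                aligner.score(ref_seq, revcomp(uni.sequence)),
            )
            cand = (score, ref_id)
            if best is None or score > best[0] or (score == best[0] and ref_id < best[1]):
                best = cand
        if best is None:
            continue
        score, ref_id = best
        evalue = _KA_K * len(uni.sequence) * total_ref_len * math.exp(-_KA_LAMBDA * score)
        if score >= min_score and evalue <= max_eval:
            out[uni.unigene_id] = HomologHit(ref_id, float(score), float(evalue))
    logger.info("map_homologs: %d/%d unigenes mapped", len(out), len(unigenes))
    return out


@dataclass
class OverlapSummary:
    """Counts of DE unigenes whose homologs fall in the regulator target set."""

    n_up: int
    n_down: int
    up_in_targets: int
    down_in_targets: int
    total_overlap: int
    up_light: int
    up_dark: int
    down_light: int
    down_dark: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def venn_counts(
    de_up: set[str],
    de_down: set[str],
    homologs: Mapping[str, HomologHit],
    targets: TargetSet,
    known_unigenes: set[str] | None = None,
) -> OverlapSummary:
    """Intersect DE unigene sets with the regulator target catalogue.

    Membership is via the homolog map; a condition label of ``both``
    counts toward both the light and dark decompositions.  All four
    up/down × light/dark intersections are reported explicitly.
    """
    if de_up & de_down:
        raise ValueError("de_up and de_down must be disjoint")
    if known_unigenes is not None:
        missing = (de_up | de_down) - known_unigenes
        if missing:
            raise ValueError(f"DE unigenes absent from assembly: {sorted(missing)[:5]}")

    def label(uid: str) -> str | None:
        hit = homologs.get(uid)
        if hit is None:
            return None
        return targets.entries.get(hit.reference_gene_id)

    def tally(uids: set[str]) -> tuple[int, int, int]:
        in_targets = light = dark = 0
        for uid in uids:
            lab = label(uid)
            if lab is None:
                continue
            in_targets += 1
            if lab in ("light", "both"):
                light += 1
            if lab in ("dark", "both"):
                dark += 1
        return in_targets, light, dark

    up_in, up_light, up_dark = tally(de_up)
    down_in, down_light, down_dark = tally(de_down)
    return OverlapSummary(
        n_up=len(de_up),
        n_down=len(de_down),
        up_in_targets=up_in,
        down_in_targets=down_in,
        total_overlap=up_in + down_in,
        up_light=up_light,
        up_dark=up_dark,
        down_light=down_light,
        down_dark=down_dark,
    )


def categorize(
    genes: Sequence[str],
    annotation: Mapping[str, Sequence[str]],
) -> Counter:
    """Tally functional categories over a gene set.

    A gene may belong to several categories (each counted once per gene);
    genes with no annotation count toward ``unclassified``.  Duplicate
    input ids are deduplicated first.
    """
    tally: Counter = Counter()
    for gene in sorted(set(genes)):
        cats = annotation.get(gene)
        if not cats:
            tally["unclassified"] += 1
        else:
            for cat in set(cats):
                tally[cat] += 1
    return tally


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Annotation TSV (unigene_id, category), possibly multiple rows per id."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = defaultdict(list)
    for uid, cat in zip(df["unigene_id"], df["category"]):
        out[uid].append(cat)
    return dict(out)
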