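"""Hybrid unigene assembly.

The reference transcript set (the "unigenes") is built without a genome by
a hybrid strategy: clean and assemble Sanger ESTs into EST-unigenes by
greedy overlap-layout-consensus; align the short reads to those; assemble
the unaligned reads de novo on a de Bruijn graph; then meta-assemble the
two unigene sets with the same overlap assembler and renumber the result.

The overlap assembler and the de Bruijn assembler here are deliberately
minimal desk-scale implementations with explicit contracts (overlap and
identity thresholds, k-mer size, coverage cutoff, deterministic
tie-breaking); they are not scaffolding, paired-end or quality aware.
"""

from __future__ import annotations

import heapq
import logging
from collections import Counter, defaultdict
from typing import Sequence

from .matching import SubstringMatcher
from .records import (
    AlignmentHit,
    ESTRecord,
    ReadRecord,
    Unigene,
    format_unigene_id,
    revcomp,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# EST cleaning


def _kmer_set(seqs: Sequence[str], k: int) -> set[str]:
    out: set[str] = set()
    for s in seqs:
        for seq in (s, revcomp(s)):
            for i in range(len(seq) - k + 1):
                out.add(seq[i : i + k])
    return out


def _kmer_index(seqs: Sequence[str], k: int) -> dict[str, list[tuple[int, int]]]:
    idx: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for si, s in enumerate(seqs):
        for i in range(len(s) - k + 1):
            idx[s[i : i + k]].append((si, i))
    return idx


def _terminal_vector_match(seq: str, vec_seqs: list[str], k: int, end: str) -> int:
    """Length of the longest terminal segment exactly matching some vector.

    ``end`` is '5p' (prefix) or '3p' (suffix); matching is exact substring
    extension seeded at the EST terminus, on either vector strand.
    """
    if len(seq) < k:
        return 0
    best = 0
    seed = seq[:k] if end == "5p" else seq[-k:]
    for vec in vec_seqs:
        for v in (vec, revcomp(vec)):
            pos = v.find(seed)
            while pos != -1:
                n = k
                if end == "5p":
                    while n < len(seq) and pos + n < len(v) and seq[n] == v[pos + n]:
                        n += 1
                else:
                    while n < len(seq) and pos - (n - k + 1) >= 0 and (
                        seq[-n - 1] == v[pos - (n - k + 1)]
                    ):
                        n += 1
                best = max(best, n)
                pos = v.find(seed, pos + 1)
    return best


def screen_ests(
    ests: Sequence[ESTRecord],
    vector: Sequence = (),
    bacterial: Sequence = (),
    rrna: Sequence = (),
    min_clean_len: int = 100,
    k: int = 16,
    discard_fraction: float = 0.8,
) -> list[ESTRecord]:
    """Clip vector-matching termini and discard contaminant-dominated ESTs.

    Terminal segments exactly matching a vector record (either strand) are
    clipped; ESTs whose k-mer coverage by the bacterial/rRNA references
    spans at least ``discard_fraction`` of their length are discarded; the
    survivors must be at least ``min_clean_len`` long.
    """
    if min_clean_len < 1:
        raise ValueError("min_clean_len must be >= 1")
    vec_seqs = [r.sequence for r in vector]
    contam_kmers = _kmer_set(
        [r.sequence for r in list(bacterial) + list(rrna)], k
    )
    out: list[ESTRecord] = []
    for est in ests:
        seq = est.sequence
        clip5 = _terminal_vector_match(seq, vec_seqs, k, "5p") if vec_seqs else 0
        clip3 = _terminal_vector_match(seq, vec_seqs, k, "3p") if vec_seqs else 0
        if clip5 + clip3 >= len(seq):
            continue
        seq = seq[clip5 : len(seq) - clip3]
        if len(seq) < min_clean_len:
            continue
        if contam_kmers and len(seq) >= k:
            covered = [False] * len(seq)
            for i in range(len(seq) - k + 1):
                if seq[i : i + k] in contam_kmers:
                    for j in range(i, i + k):
                        covered[j] = True
            if sum(covered) >= discard_fraction * len(seq):
                continue
        out.append(ESTRecord(est.est_id, seq))
    logger.info("screen_ests: %d in, %d kept", len(ests), len(out))
    return out


# ---------------------------------------------------------------------------
# greedy overlap-layout-consensus assembly


class _Contig:
    __slots__ = ("cid", "profile", "members", "consensus", "key")

    def __init__(self, cid: int, profile: list[dict], members: set[str]):
        self.cid = cid
        self.profile = profile
        self.members = members
        self.consensus = "".join(
            min(sorted(col, key=lambda b: (-col[b], b))[:1]) for col in profile
        )
        self.key = min(members)


def _profile_from_seq(seq: str) -> list[dict]:
    return [{b: 1} for b in seq]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc_profile(profile: list[dict]) -> list[dict]:
    return [{_COMP[b]: n for b, n in col.items()} for col in reversed(profile)]


def _best_pair_overlap(
    a: str, b: str, k: int, min_overlap: int, min_identity: float
):
    """Best dovetail/containment overlap of b (either strand) against a.

    Returns ``(score, orient, offset)`` or None; score is the number of
    matching bases in the overlap window.  Candidate offsets come from
    shared k-mers.  Deterministic preference: higher score, then forward
    orientation, then smaller offset.
    """
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        idx[a[i : i + k]].append(i)
    best = None
    for orient, bseq in (("+", b), ("-", revcomp(b))):
        offsets = set()
        for j in range(len(bseq) - k + 1):
            for i in idx.get(bseq[j : j + k], ()):
                offsets.add(i - j)
        for d in sorted(offsets):
            s, e = max(0, d), min(len(a), d + len(bseq))
            ovl = e - s
            if ovl < min_overlap:
                continue
            limit = int((1 - min_identity) * ovl)
            mm = 0
            for p in range(s, e):
                if a[p] != bseq[p - d]:
                    mm += 1
                    if mm > limit:
                        break
            if mm > limit:
                continue
            cand = (ovl - mm, orient, d)
            if best is None or (cand[0], cand[1] == "+", -cand[2]) > (
                best[0], best[1] == "+", -best[2]
            ):
                best = cand
    return best


def _merge_profiles(pa: list[dict], pb: list[dict], d: int) -> list[dict]:
    start = min(0, d)
    length = max(len(pa), d + len(pb)) - start
    out: list[dict] = [dict() for _ in range(length)]
    for i, col in enumerate(pa):
        out[i - start] = dict(col)
    for j, col in enumerate(pb):
        tgt = out[j + d - start]
        for base, n in col.items():
            tgt[base] = tgt.get(base, 0) + n
    return out


def greedy_assemble(
    named_seqs: Sequence[tuple[str, str]],
    min_overlap: int = 40,
    min_identity: float = 0.97,
) -> list[tuple[str, set[str]]]:
    """Greedy overlap-layout-consensus assembly of named sequences.

    Iteratively merges the pair with the highest-scoring suffix-prefix (or
    containment) overlap of at least ``min_overlap`` bases and
    ``min_identity`` identity, either strand, until none remains.  The
    consensus is per-column majority vote (ties to the lexicographically
    smallest base).  Ties in overlap score break lexicographically on the
    smallest member id of each contig.

    Returns ``(consensus, member_ids)`` pairs.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    if not 0.9 <= min_identity <= 1:
        raise ValueError("min_identity must be in [0.9, 1]")
    k = max(5, min(16, min_overlap // 2))

    contigs: dict[int, _Contig] = {}
    for cid, (name, seq) in enumerate(sorted(named_seqs)):
        contigs[cid] = _Contig(cid, _profile_from_seq(seq.upper()), {name})
    next_cid = len(contigs)

    kmer_map: dict[str, set[int]] = defaultdict(set)

    def index_contig(c: _Contig) -> None:
        seen = set()
        for seq in (c.consensus, revcomp(c.consensus)):
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if km not in seen:
                    kmer_map[km].add(c.cid)
                    seen.add(km)

    def candidates(c: _Contig) -> set[int]:
        out: set[int] = set()
        for i in range(len(c.consensus) - k + 1):
            out |= kmer_map.get(c.consensus[i : i + k], set())
        out.discard(c.cid)
        return out

    heap: list[tuple] = []

    def push_pair(c1: _Contig, c2: _Contig) -> None:
        if c1.key > c2.key:
            c1, c2 = c2, c1
        res = _best_pair_overlap(
            c1.consensus, c2.consensus, k, min_overlap, min_identity
        )
        if res is not None:
            score, orient, d = res
            heapq.heappush(heap, (-score, c1.key, c2.key, c1.cid, c2.cid, orient, d))

    for c in contigs.values():
        index_contig(c)
    done_pairs = set()
    for c in list(contigs.values()):
        for other_id in candidates(c):
            pair = (min(c.cid, other_id), max(c.cid, other_id))
            if pair not in done_pairs:
                done_pairs.add(pair)
                push_pair(contigs[c.cid], contigs[other_id])

    while heap:
        _, _, _, ca, cb, orient, d = heapq.heappop(heap)
        if ca not in contigs or cb not in contigs:
            continue
        a, b = contigs.pop(ca), contigs.pop(cb)
        pb = b.profile if orient == "+" else _rc_profile(b.profile)
        merged = _Contig(next_cid, _merge_profiles(a.profile, pb, d), a.members | b.members)
        next_cid += 1
        contigs[merged.cid] = merged
        index_contig(merged)
        for other_id in candidates(merged):
            if other_id in contigs:
                push_pair(merged, contigs[other_id])

    return [
        (c.consensus, set(c.members))
        for c in sorted(contigs.values(), key=lambda c: c.key)
    ]


def _number_unigenes(
    assembled: list[tuple[str, set[str]]], provenance_of=None
) -> tuple[list[Unigene], dict[str, str]]:
    """Assign PP-ids in decreasing length order; return unigenes and member map."""
    ordered = sorted(assembled, key=lambda t: (-len(t[0]), t[0]))
    unigenes: list[Unigene] = []
    id_map: dict[str, str] = {}
    for i, (seq, members) in enumerate(ordered):
        uid = format_unigene_id(i + 1)
        prov = provenance_of(members) if provenance_of else "est"
        unigenes.append(Unigene(uid, seq, prov))
        for m in members:
            id_map[m] = uid
    return unigenes, id_map


def assemble_ests(
    ests: Sequence[ESTRecord],
    min_overlap: int = 40,
    min_identity: float = 0.97,
) -> list[Unigene]:
    """Assemble cleaned ESTs into EST-unigenes (singletons included)."""
    assembled = greedy_assemble(
        [(e.est_id, e.sequence) for e in ests], min_overlap, min_identity
    )
    unigenes, _ = _number_unigenes(assembled, provenance_of=lambda m: "est")
    logger.info("assemble_ests: %d ESTs -> %d unigenes", len(ests), len(unigenes))
    return unigenes


# ---------------------------------------------------------------------------
# read alignment


def align_reads(
    reads: Sequence[ReadRecord],
    unigenes: Sequence[Unigene],
    max_mismatch: int = 2,
) -> tuple[list[AlignmentHit], list[ReadRecord]]:
    """Place each read at its best (fewest-mismatch) full-length position.

    Every equally-best placement across all unigenes and both strands is
    retained on the hit (for the downstream multimapping policy); reads
    with no placement within the mismatch budget are returned unaligned.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not unigenes:
        logger.warning("align_reads: empty unigene set, all reads unaligned")
        return [], list(reads)
    matcher = SubstringMatcher(unigenes)
    hits: list[AlignmentHit] = []
    unaligned: list[ReadRecord] = []
    for read in reads:
        placements, mm = matcher.best_placements(read.sequence, max_mismatch)
        if placements:
            hits.append(AlignmentHit(read.read_id, placements, mm))
        else:
            unaligned.append(read)
    return hits, unaligned


# ---------------------------------------------------------------------------
# de Bruijn assembly of unaligned reads


def _canonical(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def denovo_assemble(
    unaligned: Sequence[ReadRecord],
    k: int = 31,
    min_contig_len: int = 100,
    coverage_cutoff: str | int = "auto",
) -> list[Unigene]:
    """Assemble unaligned reads on a de Bruijn graph of k-mers.

    Canonical k-mers are counted; when mean k-mer coverage is at least 10
    (or a fixed ``coverage_cutoff`` is given) singleton k-mers are dropped
    as likely sequencing errors.  Unbranched paths are emitted as contigs;
    dead-end tips shorter than 2k are pruned first.  Contigs are reported
    once (canonical orientation) with provisional de-novo ids.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    if unaligned and k >= max(len(r) for r in unaligned):
        raise ValueError("k must be smaller than the read length")
    counts: Counter[str] = Counter()
    for read in unaligned:
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            counts[_canonical(km)] += 1
    if not counts:
        return []
    if coverage_cutoff == "auto":
        mean_cov = sum(counts.values()) / len(counts)
        cutoff = 1 if mean_cov >= 10 else 0
    else:
        cutoff = int(coverage_cutoff)
    kmers = {km for km, n in counts.items() if n > cutoff}

    def build(kmers: set[str]):
        out_edges: dict[str, set[str]] = defaultdict(set)
        in_edges: dict[str, set[str]] = defaultdict(set)
        for km in kmers:
            for orient in (km, revcomp(km)):
                out_edges[orient[:-1]].add(orient[-1])
                in_edges[orient[1:]].add(orient[0])
        return out_edges, in_edges

    def walk_paths(kmers: set[str]):
        """Maximal unbranched paths as sequences (each path appears fw and rc)."""
        out_edges, in_edges = build(kmers)
        nodes = set(out_edges) | set(in_edges)

        def simple(node: str) -> bool:
            return len(out_edges.get(node, ())) == 1 and len(in_edges.get(node, ())) == 1

        paths = []
        visited_edges: set[tuple[str, str]] = set()
        for node in sorted(nodes):
            if simple(node):
                continue
            for base in sorted(out_edges.get(node, ())):
                if (node, base) in visited_edges:
                    continue
                seq = node + base
                visited_edges.add((node, base))
                cur = seq[-(k - 1):]
                while simple(cur):
                    nxt = next(iter(out_edges[cur]))
                    if (cur, nxt) in visited_edges:
                        break
                    visited_edges.add((cur, nxt))
                    seq += nxt
                    cur = seq[-(k - 1):]
                paths.append(seq)
        return paths, out_edges, in_edges

    # tip pruning: drop short dead-end paths, then rebuild
    for _ in range(3):
        paths, out_edges, in_edges = walk_paths(kmers)
        tips = []
        for seq in paths:
            start, end = seq[: k - 1], seq[-(k - 1):]
            dead_start = not in_edges.get(start)
            dead_end = not out_edges.get(end)
            if (dead_start or dead_end) and not (dead_start and dead_end):
                if len(seq) < 2 * k:
                    tips.append(seq)
        if not tips:
            break
        for seq in tips:
            for i in range(len(seq) - k + 1):
                kmers.discard(_canonical(seq[i : i + k]))

    paths, _, _ = walk_paths(kmers)
    contigs = sorted(
        {min(p, revcomp(p)) for p in paths if len(p) >= min_contig_len}
    )
    unigenes = [
        Unigene(f"DN{idx + 1:06d}", seq, "denovo")
        for idx, seq in enumerate(sorted(contigs, key=lambda s: (-len(s), s)))
    ]
    logger.info(
        "denovo_assemble: %d reads -> %d contigs >= %d bp",
        len(unaligned), len(unigenes), min_contig_len,
    )
    return unigenes


# ---------------------------------------------------------------------------
# meta-assembly


def merge_assemblies(
    est_unigenes: Sequence[Unigene],
    denovo_unigenes: Sequence[Unigene],
    min_overlap: int = 40,
    min_identity: float = 0.97,
) -> tuple[list[Unigene], dict[str, str]]:
    """Meta-assemble EST and de-novo unigenes; renumber PP-ids by length.

    Returns the final unigene set and a total id_map from every input
    unigene id to the final id of the contig it merged into.
    """
    inputs = list(est_unigenes) + list(denovo_unigenes)
    prov_by_id = {u.unigene_id: u.provenance for u in inputs}
    assembled = greedy_assemble(
        [(u.unigene_id, u.sequence) for u in inputs], min_overlap, min_identity
    )

    def provenance_of(members: set[str]) -> str:
        provs = {prov_by_id[m] for m in members}
        if len(provs) > 1:
            return "merged"
        return provs.pop()

    final, id_map = _number_unigenes(assembled, provenance_of)
    logger.info(
        "merge_assemblies: %d + %d inputs -> %d final unigenes",
        len(est_unigenes), len(denovo_unigenes), len(final),
    )
    return final, id_map
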