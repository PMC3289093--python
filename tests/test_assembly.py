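"""Hybrid assembly: EST cleaning, overlap assembly, alignment, de Bruijn."""

import re

import numpy as np
import pytest

from curdseq import synthetic
from curdseq.assembly import (
    align_reads,
    assemble_ests,
    denovo_assemble,
    greedy_assemble,
    merge_assemblies,
    screen_ests,
)
from curdseq.matching import hamming_distance
from curdseq.records import ESTRecord, FastaRecord, ReadRecord, Unigene, revcomp


def _rng_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _canon(seq):
    rc = revcomp(seq)
    return seq if seq <= rc else rc


# ---------------------------------------------------------------- screening


def test_screen_ests_clean_unchanged(contaminants):
    rng = np.random.default_rng(31)
    est = ESTRecord("e1", _rng_seq(rng, 400))
    out = screen_ests([est], contaminants.vector, contaminants.bacterial,
                      contaminants.rrna)
    assert out == [est]


def test_screen_ests_pure_vector_discarded(contaminants):
    vec = contaminants.vector[0].sequence
    est = ESTRecord("e1", vec[100:500])
    out = screen_ests([est], contaminants.vector, (), ())
    assert out == []


def test_screen_ests_mostly_rrna_discarded(contaminants):
    rrna = contaminants.rrna[0].sequence
    rng = np.random.default_rng(32)
    est = ESTRecord("e1", rrna[0:350] + _rng_seq(rng, 40))
    assert screen_ests([est], (), (), contaminants.rrna) == []


def test_screen_ests_planted_vector_prefixes_clipped(transcripts, contaminants):
    # ESTs with a planted 60 bp exact vector prefix: exactly the prefix is
    # clipped (the transcript base after the junction differs from the
    # vector continuation, so extension stops at the planted length)
    vec = contaminants.vector[0].sequence
    prefix = vec[200:260]
    after = vec[260]
    ests = []
    for i, t in enumerate(transcripts.records[:10]):
        frag = t.sequence[:300]
        if frag[0] == after:  # force a junction mismatch
            frag = ("A" if after != "A" else "C") + frag[1:]
        ests.append(ESTRecord(f"e{i}", prefix + frag))
    out = screen_ests(ests, contaminants.vector, (), (), min_clean_len=100)
    assert len(out) == len(ests)
    for before, cleaned in zip(ests, out):
        assert cleaned.sequence == before.sequence[60:]


# ---------------------------------------------------------------- OLC assembly


def test_two_tiling_ests_reconstruct_transcript():
    rng = np.random.default_rng(33)
    transcript = _rng_seq(rng, 500)
    ests = [ESTRecord("a", transcript[:300]), ESTRecord("b", transcript[200:])]
    unigenes = assemble_ests(ests, min_overlap=40, min_identity=0.97)
    assert len(unigenes) == 1
    assert _canon(unigenes[0].sequence) == _canon(transcript)


def test_disjoint_ests_stay_separate():
    rng = np.random.default_rng(34)
    ests = [ESTRecord("a", _rng_seq(rng, 300)), ESTRecord("b", _rng_seq(rng, 300))]
    unigenes = assemble_ests(ests)
    assert len(unigenes) == 2


def test_reverse_complement_overlap_merges():
    rng = np.random.default_rng(35)
    transcript = _rng_seq(rng, 500)
    ests = [ESTRecord("a", transcript[:300]), ESTRecord("b", revcomp(transcript[200:]))]
    unigenes = assemble_ests(ests)
    assert len(unigenes) == 1
    assert _canon(unigenes[0].sequence) == _canon(transcript)


def test_fifty_tiling_ests_reconstruct_exactly():
    rng = np.random.default_rng(36)
    transcript = _rng_seq(rng, 2000)
    starts = np.linspace(0, 2000 - 500, 50).astype(int)
    ests = [
        ESTRecord(f"e{i:02d}", transcript[s : s + 500]) for i, s in enumerate(starts)
    ]
    unigenes = assemble_ests(ests, min_overlap=30, min_identity=0.97)
    assert len(unigenes) == 1
    assert _canon(unigenes[0].sequence) == _canon(transcript)


def test_consensus_majority_vote_fixes_lone_error():
    rng = np.random.default_rng(37)
    transcript = _rng_seq(rng, 400)
    # three ESTs covering the same region; one carries a substitution
    err = list(transcript[:300])
    err[150] = "A" if err[150] != "A" else "C"
    ests = [
        ESTRecord("a", transcript[:300]),
        ESTRecord("b", "".join(err)),
        ESTRecord("c", transcript[100:]),
    ]
    unigenes = assemble_ests(ests, min_overlap=40, min_identity=0.95)
    assert len(unigenes) == 1
    assert _canon(unigenes[0].sequence) == _canon(transcript)


def test_every_input_aligns_to_an_output_unigene():
    rng = np.random.default_rng(38)
    transcript = _rng_seq(rng, 1000)
    named = [(f"e{i}", transcript[s : s + 400]) for i, s in enumerate(range(0, 601, 100))]
    assembled = greedy_assemble(named, min_overlap=40, min_identity=0.97)
    members = set().union(*(m for _, m in assembled))
    assert members == {name for name, _ in named}
    for seq, _ in assembled:
        for _, est_seq in named:
            assert est_seq in seq or revcomp(est_seq) in seq


# ---------------------------------------------------------------- alignment


def _unigenes_from(transcripts):
    return [
        Unigene(f"PP{i + 1:06d}", t.sequence, "est")
        for i, t in enumerate(transcripts.records)
    ]


def test_align_read_exact_substring(transcripts):
    unis = _unigenes_from(transcripts)
    read = ReadRecord("r1", unis[3].sequence[17 : 17 + 86], "I" * 86)
    hits, unaligned = align_reads([read], unis, max_mismatch=2)
    assert unaligned == []
    assert hits[0].placements == [(unis[3].unigene_id, 17, "+")]
    assert hits[0].mismatches == 0


def test_align_unrepresented_read_unaligned(transcripts):
    unis = _unigenes_from(transcripts)
    rng = np.random.default_rng(39)
    read = ReadRecord("r1", _rng_seq(rng, 86), "I" * 86)
    hits, unaligned = align_reads([read], unis, max_mismatch=2)
    assert hits == [] and len(unaligned) == 1


def test_align_empty_unigene_set(transcripts, clean_libraries):
    lib1, _, _ = clean_libraries
    hits, unaligned = align_reads(lib1[:5], [], max_mismatch=2)
    assert hits == [] and len(unaligned) == 5


def test_alignment_matches_truth_ledger(transcripts, clean_libraries):
    # error-free reads vs the complete transcript set: every best placement
    # is the recorded origin, and every hit verifies by Hamming recount
    lib1, lib2, truth = clean_libraries
    unis = _unigenes_from(transcripts)
    gene_to_uid = {
        t.seq_id: u.unigene_id for t, u in zip(transcripts.records, unis)
    }
    seqs = {u.unigene_id: u.sequence for u in unis}
    origin = truth.reads.set_index("read_id")
    reads = (lib1 + lib2)[:500]
    hits, unaligned = align_reads(reads, unis, max_mismatch=2)
    assert unaligned == []
    by_read = {r.read_id: r for r in reads}
    for hit in hits:
        row = origin.loc[hit.read_id]
        expected = (gene_to_uid[row["origin"]], int(row["start"]), row["strand"])
        assert expected in hit.placements
        uid, start, strand = hit.placements[0]
        window = seqs[uid][start : start + len(by_read[hit.read_id].sequence)]
        query = by_read[hit.read_id].sequence
        if strand == "-":
            query = revcomp(query)
        assert hamming_distance(query, window) == hit.mismatches <= 2


# ---------------------------------------------------------------- de Bruijn


def test_denovo_unique_path_reconstructs_transcript():
    rng = np.random.default_rng(40)
    transcript = _rng_seq(rng, 400)
    starts = sorted(set(range(0, 400 - 86 + 1, 5)) | {400 - 86})
    reads = [
        ReadRecord(f"r{i}", transcript[s : s + 86], "I" * 86)
        for i, s in enumerate(starts)
    ]
    contigs = denovo_assemble(reads, k=31, min_contig_len=100)
    assert len(contigs) == 1
    assert contigs[0].sequence == _canon(transcript)
    assert contigs[0].provenance == "denovo"


def test_denovo_empty_input():
    assert denovo_assemble([], k=31) == []


def test_denovo_k_validation():
    read = ReadRecord("r1", "ACGT" * 20, "I" * 80)
    with pytest.raises(ValueError):
        denovo_assemble([read], k=80)
    with pytest.raises(ValueError):
        denovo_assemble([read], k=10)


def test_denovo_30x_coverage_recovers_95_percent():
    rng = np.random.default_rng(41)
    transcript = _rng_seq(rng, 1000)
    n_reads = int(1000 * 30 / 86)
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, 1000 - 86 + 1))
        frag = transcript[start : start + 86]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(ReadRecord(f"r{i}", frag, "I" * 86))
    contigs = denovo_assemble(reads, k=31, min_contig_len=100)
    best = max(
        (len(c.sequence) for c in contigs
         if c.sequence in transcript or revcomp(c.sequence) in transcript),
        default=0,
    )
    assert best >= 0.95 * 1000


# ---------------------------------------------------------------- merging


def test_merge_disjoint_sets_concatenates_and_renumbers():
    rng = np.random.default_rng(42)
    est = [Unigene("PP000001", _rng_seq(rng, 600), "est")]
    dn = [Unigene("DN000001", _rng_seq(rng, 300), "denovo")]
    final, id_map = merge_assemblies(est, dn)
    assert [u.unigene_id for u in final] == ["PP000001", "PP000002"]
    assert [u.length for u in final] == [600, 300]
    assert set(id_map) == {"PP000001", "DN000001"}
    assert all(re.fullmatch(r"PP\d{6}", u.unigene_id) for u in final)


def test_merge_overlapping_est_and_denovo_unigenes():
    rng = np.random.default_rng(43)
    transcript = _rng_seq(rng, 800)
    est = [Unigene("PP000001", transcript[:500], "est")]
    dn = [Unigene("DN000001", transcript[300:], "denovo")]
    final, id_map = merge_assemblies(est, dn, min_overlap=40)
    assert len(final) == 1
    assert final[0].provenance == "merged"
    assert _canon(final[0].sequence) == _canon(transcript)
    assert id_map == {"PP000001": "PP000001", "DN000001": "PP000001"}


def test_merge_id_map_is_total_and_deterministic(transcripts):
    ests, _ = synthetic.simulate_ests(
        transcripts, 60, len_mean=400, error_rate=0.0, seed=44
    )
    est_unis = assemble_ests(ests)
    runs = [merge_assemblies(est_unis, []) for _ in range(2)]
    (final1, map1), (final2, map2) = runs
    assert map1 == map2
    assert [u.sequence for u in final1] == [u.sequence for u in final2]
    assert set(map1) == {u.unigene_id for u in est_unis}
    ids = [u.unigene_id for u in final1]
    assert len(ids) == len(set(ids))
    lengths = [u.length for u in final1]
    assert lengths == sorted(lengths, reverse=True)
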