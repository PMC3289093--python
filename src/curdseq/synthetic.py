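"""Synthetic transcriptomes, contaminants, ESTs and two-condition read libraries.

Every downstream stage of the pipeline is exercised against data generated
here, with the ground truth recorded in a :class:`TruthLedger` so that
recovery can be checked exactly.

The emulated study design is a two-condition, one-library-per-condition
comparison of short unstranded reads (86 bp by default) against a
transcript population that has partial Sanger-EST coverage.  Per-gene read
counts are Poisson with mean proportional to the gene's true expression
level times the library depth; a configurable fraction of reads derives
from rRNA contamination, and a fraction carries 3' adaptor read-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ESTRecord, FastaRecord, ReadRecord, revcomp, IUPAC_DNA

BASES = np.array(list("ACGT"))

DEFAULT_ADAPTOR = "AGATCGGAAGAGCGGTTCAG"

# condition labels: library 1 = white curd (reference), library 2 = green curd (test)
LIB_REFERENCE = "white"
LIB_TEST = "green"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TranscriptSet:
    """A synthetic transcript population standing in for the curd transcriptome."""

    records: list[FastaRecord]
    gc_target: float

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]


@dataclass
class ContaminantSet:
    """rRNA, cloning-vector and bacterial contaminant references."""

    rrna: list[FastaRecord] = field(default_factory=list)
    vector: list[FastaRecord] = field(default_factory=list)
    bacterial: list[FastaRecord] = field(default_factory=list)

    def all_ids(self) -> list[str]:
        return [r.seq_id for r in self.rrna + self.vector + self.bacterial]


@dataclass
class DEDesign:
    """Differential-expression design for a simulated two-library comparison.

    ``fraction_up``/``fraction_down`` genes are planted with true fold
    change drawn from ``fold_values`` (test/reference orientation, i.e.
    green over white); the rest are null.  ``depth`` is the expected number
    of reads emitted per library.
    """

    fraction_up: float = 0.05
    fraction_down: float = 0.05
    fold_values: tuple[float, ...] = (3.0, 5.0, 10.0)
    depth: int = 20_000


@dataclass
class TruthLedger:
    """Ground truth for a simulation run.

    ``genes`` is indexed by gene_id with columns ``mean_expr_cond1``,
    ``mean_expr_cond2`` (expected read counts per library), ``true_fold``
    (test/reference; the string flag ``ref_zero`` when the reference mean
    is zero) and ``de_flag`` in {up, down, null}.  ``reads`` records one
    row per emitted read: read_id, library, origin (gene or contaminant
    id), start, strand, n_errors, adaptor.
    """

    genes: pd.DataFrame
    reads: pd.DataFrame

    def rrna_read_ids(self, contaminants: ContaminantSet) -> set[str]:
        rrna_ids = {r.seq_id for r in contaminants.rrna}
        mask = self.reads["origin"].isin(rrna_ids)
        return set(self.reads.loc[mask, "read_id"])


# ---------------------------------------------------------------------------
# helpers


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    """Apply iid substitution errors; returns (sequence, n_errors)."""
    if error_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode(), len(hits)


# ---------------------------------------------------------------------------
# operations


def generate_transcriptome(
    n_genes: int,
    len_min: int = 300,
    len_max: int = 2000,
    gc: float = 0.4,
    seed: int = 0,
) -> TranscriptSet:
    """Generate ``n_genes`` random transcripts with lengths uniform in bounds."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not (0 < len_min <= len_max):
        raise ValueError(f"invalid length bounds ({len_min}, {len_max})")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genes):
        length = int(rng.integers(len_min, len_max + 1))
        records.append(FastaRecord(f"gene{i + 1:05d}", _random_dna(rng, length, gc)))
    return TranscriptSet(records=records, gc_target=gc)


def generate_contaminants(
    n_rrna: int = 2,
    n_vector: int = 1,
    n_bacterial: int = 2,
    length: int = 1500,
    seed: int = 0,
) -> ContaminantSet:
    """Generate labeled rRNA / vector / bacterial contaminant references."""
    for name, n in (("n_rrna", n_rrna), ("n_vector", n_vector), ("n_bacterial", n_bacterial)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    make = lambda prefix, n: [
        FastaRecord(f"{prefix}{i + 1:03d}", _random_dna(rng, length, 0.5))
        for i in range(n)
    ]
    return ContaminantSet(
        rrna=make("rrna", n_rrna),
        vector=make("vector", n_vector),
        bacterial=make("bacterial", n_bacterial),
    )


def simulate_ests(
    transcripts: TranscriptSet,
    n_ests: int,
    len_mean: int = 500,
    error_rate: float = 0.005,
    seed: int = 0,
    len_sd: int = 80,
    len_min: int = 100,
) -> tuple[list[ESTRecord], pd.DataFrame]:
    """Simulate Sanger ESTs as mutated (sub)sequences of random transcripts.

    Returns the EST records and an origin table (est_id, origin, start,
    end, strand, n_errors) suitable for folding into a TruthLedger.
    """
    if n_ests > 0 and len(transcripts) == 0:
        raise ValueError("cannot simulate ESTs from an empty transcript set")
    rng = np.random.default_rng(seed)
    ests: list[ESTRecord] = []
    origins = []
    for i in range(n_ests):
        t = transcripts.records[int(rng.integers(len(transcripts)))]
        length = int(np.clip(round(rng.normal(len_mean, len_sd)), len_min, len(t)))
        start = int(rng.integers(0, len(t) - length + 1))
        frag = t.sequence[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag, n_err = _mutate(rng, frag, error_rate)
        est_id = f"est{i + 1:06d}"
        ests.append(ESTRecord(est_id, frag))
        origins.append((est_id, t.seq_id, start, start + length, strand, n_err))
    table = pd.DataFrame(
        origins, columns=["est_id", "origin", "start", "end", "strand", "n_errors"]
    )
    return ests, table


def _gene_means(
    rng: np.random.Generator, gene_ids: list[str], design: DEDesign
) -> pd.DataFrame:
    """Assign per-gene expected read counts for both conditions.

    Base abundances are log-normal (a long-tailed expression distribution);
    they are scaled so the reference library's expected total equals the
    design depth, then fold changes are applied to the planted genes.
    """
    n = len(gene_ids)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    n_up = int(round(design.fraction_up * n))
    n_down = int(round(design.fraction_down * n))
    flags = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    up_idx, down_idx = perm[:n_up], perm[n_up : n_up + n_down]
    flags[up_idx] = "up"
    flags[down_idx] = "down"
    folds = np.ones(n)
    fold_pool = np.asarray(design.fold_values, dtype=float)
    folds[up_idx] = rng.choice(fold_pool, size=n_up)
    folds[down_idx] = 1.0 / rng.choice(fold_pool, size=n_down)
    mean1 = base / base.sum() * design.depth
    mean2 = mean1 * folds
    return pd.DataFrame(
        {
            "mean_expr_cond1": mean1,
            "mean_expr_cond2": mean2,
            "true_fold": folds,
            "de_flag": flags,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_counts(
    n_genes: int,
    design: DEDesign,
    seed: int = 0,
    planted_min_mean: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-gene Poisson counts for two libraries, skipping read emission.

    A fast path for testing the count-based stages (quantification and
    differential expression) at realistic depth without simulating reads.
    When ``planted_min_mean`` is given, every planted DE gene's reference
    mean is raised to at least that many expected counts so power against
    the design is well-defined.

    Returns ``(counts, genes)`` where counts has columns white/green.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    genes = _gene_means(rng, gene_ids, design)
    if planted_min_mean is not None:
        low = (genes["de_flag"] != "null") & (genes["mean_expr_cond1"] < planted_min_mean)
        n_low = int(low.sum())
        if n_low:
            boosted = rng.uniform(planted_min_mean, 3 * planted_min_mean, size=n_low)
            genes.loc[low, "mean_expr_cond1"] = boosted
            genes.loc[low, "mean_expr_cond2"] = boosted * genes.loc[low, "true_fold"]
    counts = pd.DataFrame(
        {
            LIB_REFERENCE: rng.poisson(genes["mean_expr_cond1"].to_numpy()),
            LIB_TEST: rng.poisson(genes["mean_expr_cond2"].to_numpy()),
        },
        index=genes.index,
    )
    return counts, genes


def _emit_reads(
    rng: np.random.Generator,
    library: str,
    genes: pd.DataFrame,
    mean_col: str,
    transcripts_by_id: dict[str, str],
    rrna: list[FastaRecord],
    read_len: int,
    error_rate: float,
    rrna_fraction: float,
    adaptor: str,
    adaptor_rate: float,
    depth: int,
    quality_char: str,
    tail_len: int,
    tail_char: str,
    counter_start: int,
) -> tuple[list[ReadRecord], list[tuple], int]:
    reads: list[ReadRecord] = []
    rows: list[tuple] = []
    counter = counter_start

    def emit(origin_seq: str, origin_id: str) -> None:
        nonlocal counter
        counter += 1
        read_id = f"read{counter:08d}"
        has_adaptor = adaptor_rate > 0 and rng.random() < adaptor_rate
        if has_adaptor:
            insert_len = int(rng.integers(max(read_len // 2, 1), read_len))
        else:
            insert_len = read_len
        insert_len = min(insert_len, len(origin_seq))
        start = int(rng.integers(0, len(origin_seq) - insert_len + 1))
        frag = origin_seq[start : start + insert_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag, n_err = _mutate(rng, frag, error_rate)
        if has_adaptor and len(frag) < read_len:
            frag = (frag + adaptor)[:read_len]
        qual = quality_char * len(frag)
        if tail_len > 0 and len(frag) > tail_len and rng.random() < 0.25:
            qual = qual[:-tail_len] + tail_char * tail_len
        reads.append(ReadRecord(read_id, frag, qual))
        rows.append((read_id, library, origin_id, start, strand, n_err, has_adaptor, insert_len))

    # contaminant reads
    rrna_total = 0
    if rrna and rrna_fraction > 0:
        rrna_total = rng.poisson(depth * rrna_fraction)
        for _ in range(rrna_total):
            rec = rrna[int(rng.integers(len(rrna)))]
            emit(rec.sequence, rec.seq_id)
    # transcript reads: per-gene Poisson, mean proportional to expression
    means = genes[mean_col].to_numpy() * (1 - rrna_fraction)
    gene_counts = rng.poisson(means)
    for gene_id, k in zip(genes.index, gene_counts):
        seq = transcripts_by_id[gene_id]
        if len(seq) < read_len:
            continue
        for _ in range(k):
            emit(seq, gene_id)
    return reads, rows, counter


def simulate_libraries(
    transcripts: TranscriptSet,
    design: DEDesign,
    read_len: int = 86,
    error_rate: float = 0.005,
    rrna_fraction: float = 0.05,
    contaminants: ContaminantSet | None = None,
    adaptor: str = DEFAULT_ADAPTOR,
    adaptor_rate: float = 0.05,
    seed: int = 0,
    quality_char: str = "I",
    tail_len: int = 0,
    tail_char: str = "#",
) -> tuple[list[ReadRecord], list[ReadRecord], TruthLedger]:
    """Simulate the two curd libraries (white reference, green test).

    Per-gene read counts are Poisson with mean proportional to the gene's
    true expression times library depth; ``rrna_fraction`` of the expected
    depth derives from the rRNA contaminant records; ``adaptor_rate`` of
    reads carry 3' adaptor read-through.  Qualities are constant high
    (``quality_char``) with an optional low-quality 3' tail on a quarter
    of reads so that quality trimming is exercised.
    """
    if not 0 <= rrna_fraction <= 1 or not 0 <= adaptor_rate <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if not 0 <= design.fraction_up + design.fraction_down <= 1:
        raise ValueError("DE fractions must sum to at most 1")
    if design.depth < 0:
        raise ValueError("depth must be >= 0")
    if any(b not in IUPAC_DNA for b in adaptor.upper()):
        raise ValueError("adaptor contains non-IUPAC characters")
    rng_design, rng_lib1, rng_lib2 = _child_rngs(seed, 3)
    genes = _gene_means(rng_design, transcripts.ids(), design)
    transcripts_by_id = {r.seq_id: r.sequence for r in transcripts.records}
    rrna = contaminants.rrna if contaminants else []

    common = dict(
        transcripts_by_id=transcripts_by_id,
        rrna=rrna,
        read_len=read_len,
        error_rate=error_rate,
        rrna_fraction=rrna_fraction,
        adaptor=adaptor.upper(),
        adaptor_rate=adaptor_rate,
        depth=design.depth,
        quality_char=quality_char,
        tail_len=tail_len,
        tail_char=tail_char,
    )
    lib1, rows1, counter = _emit_reads(
        rng_lib1, LIB_REFERENCE, genes, "mean_expr_cond1", counter_start=0, **common
    )
    lib2, rows2, _ = _emit_reads(
        rng_lib2, LIB_TEST, genes, "mean_expr_cond2", counter_start=counter, **common
    )
    reads_table = pd.DataFrame(
        rows1 + rows2,
        columns=["read_id", "library", "origin", "start", "strand", "n_errors",
                 "adaptor", "insert_len"],
    )
    genes_out = genes.copy()
    zero_ref = genes_out["mean_expr_cond1"] == 0
    genes_out["true_fold"] = genes_out["true_fold"].astype(object)
    genes_out.loc[zero_ref, "true_fold"] = "ref_zero"
    return lib1, lib2, TruthLedger(genes=genes_out, reads=reads_table)


def invert_mackinney(chl_a: float, chl_b: float) -> tuple[float, float]:
    """Solve the chlorophyll equations in reverse: concentrations to ODs.

    Given chlorophyll a and b concentrations in the acetone extract
    (μg/mL), return the (OD645, OD663) pair that produces them under the
    MacKinney coefficient system.  Raises ValueError when the requested
    concentrations are infeasible (negative input or negative implied OD).
    """
    from .pigments import MACKINNEY  # local import to avoid a cycle

    if chl_a < 0 or chl_b < 0:
        raise ValueError("chlorophyll concentrations must be >= 0")
    od645, od663 = np.linalg.solve(MACKINNEY, [chl_a, chl_b])
    if od645 < -1e-12 or od663 < -1e-12:
        raise ValueError(
            f"infeasible concentrations (a={chl_a}, b={chl_b}): implied OD negative"
        )
    return float(max(od645, 0.0)), float(max(od663, 0.0))


def write_truth_ledger(ledger: TruthLedger, genes_path, reads_path) -> None:
    """Write the ledger as two TSVs (per-gene truth, per-read origins)."""
    ledger.genes.to_csv(genes_path, sep="\t")
    ledger.reads.to_csv(reads_path, sep="\t", index=False)
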