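r"""Simulation benchmark: planted-CNV genomes, shotgun reads, and depth tracks.

Two levels are provided. The *sequence* level builds a reference/test FASTA
pair (tandem-duplicated gains, deleted losses, SNPs and short indels) and
extracts 36 bp paired-end reads with per-base errors, emulating a shotgun
sequencing run. The *coverage* level skips alignment entirely and draws the
per-base depth track the caller consumes directly: read start positions
form a Poisson process whose rate is modulated by the planted copy ratio,
and each read contributes a 36 bp span of depth. The marginal depth at a
base is then exactly Poisson with mean ``C * rho(E) * r(x)`` — coverage
times the aligner retention rate times the local copy ratio — while
retaining the read-span autocorrelation of real depth tracks (which is what
lets a 151-sample median filter operate below 1x coverage, exactly as with
aligned reads).

``rho(E) = P[Binomial(read_length, E) <= e]`` models mappability attrition:
a read with more than ``e`` sequencing errors (default 2, the usual short-
read aligner mismatch tolerance for 36 bp reads) fails to align and is lost,
so raising the error rate thins the usable coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .coverage import ReadCoverage

__all__ = [
    "CNV_LENGTH_POOL",
    "SimulationConfig",
    "GroundTruth",
    "alignment_retention_rate",
    "sample_cnv_layout",
    "make_sequences",
    "simulate_reads",
    "simulate_coverage",
    "write_truth",
    "read_truth",
]

# Synthetic pool of 17 candidate CNV lengths. Only the summary statistics of
# the real candidate set are published (min 1024, max 70613, total 318750,
# mean 18750 bp); this geometric ladder reproduces all four exactly.
CNV_LENGTH_POOL: tuple[int, ...] = (
    1024, 1442, 1878, 2448, 3189, 4155, 5412, 7052, 9187, 11970,
    15596, 20319, 26474, 34493, 44942, 58556, 70613,
)


@dataclass
class SimulationConfig:
    """Stochastic model of one simulated dataset.

    ``coverage`` is fold coverage C (mean sequenced bases per genome base),
    ``error_rate`` the per-base sequencing error E, ``mismatch_tolerance``
    the aligner's per-read mismatch cap e. ``cnv_count`` regions are drawn
    without replacement from ``cnv_length_pool``; gains multiply local depth
    by ``gain_ratio``, losses by ``loss_ratio``. The defaults (2.0 / 0.0)
    mirror the haploid substitution semantics of the sequence-level
    generator: a tandem-duplicated gain doubles the dosage mapped onto the
    reference locus and a deleted region receives no reads at all; set
    1.5 / 0.5 for a diploid single-copy-change model instead.
    """

    genome_length: int = 1_000_000
    coverage: float = 1.0
    error_rate: float = 0.02
    read_length: int = 36
    paired: bool = True
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    cnv_count: int = 10
    cnv_length_pool: tuple[int, ...] = CNV_LENGTH_POOL
    gain_ratio: float = 2.0
    loss_ratio: float = 0.0
    snp_rate: float = 1e-3      # 1 SNP per kb
    indel_rate: float = 1e-4    # 1 indel per 10 kb
    indel_max_length: int = 10
    mismatch_tolerance: int = 2
    contig_id: str = "sim"

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class GroundTruth:
    """Planted CNVs in reference coordinates (0-based half-open), sorted."""

    regions: list[tuple[int, int, str]] = field(default_factory=list)
    snps: list[int] = field(default_factory=list)
    indels: list[tuple[int, int]] = field(default_factory=list)  # (pos, signed length)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions)
        prev_end = -1
        for start, end, kind in self.regions:
            if end <= start or start < prev_end:
                raise ValueError("truth regions must be disjoint, non-empty, sorted")
            if kind not in ("gain", "loss"):
                raise ValueError(f"unknown CNV type {kind!r}")
            prev_end = end

    @property
    def total_bases(self) -> int:
        return sum(e - s for s, e, _ in self.regions)


def alignment_retention_rate(error_rate: float, read_length: int = 36,
                             mismatch_tolerance: int = 2) -> float:
    """Probability a read survives the aligner's mismatch cap.

    ``P[Binomial(read_length, error_rate) <= mismatch_tolerance]`` — strictly
    decreasing in the error rate, ~0.965 at E=2% and ~0.288 at E=10% for
    36 bp reads with e=2.
    """
    return float(binom.cdf(mismatch_tolerance, read_length, error_rate))


def sample_cnv_layout(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Place ``cnv_count`` disjoint CNV regions uniformly at random.

    Lengths are drawn from the pool without replacement; each region is a
    gain or a loss with equal probability. Placement uses the gap method
    (distribute the free space between regions uniformly), which is exact
    and cannot fail while the regions fit.
    """
    pool = np.asarray(config.cnv_length_pool)
    if config.cnv_count > pool.size:
        raise ValueError("cnv_count exceeds the length pool")
    lengths = rng.choice(pool, size=config.cnv_count, replace=False)
    total = int(lengths.sum())
    if total >= config.genome_length // 2:
        raise ValueError("planted CNVs must occupy less than half the genome")
    order = rng.permutation(config.cnv_count)
    lengths = lengths[order]
    free = config.genome_length - total
    cuts = np.sort(rng.integers(0, free + 1, size=config.cnv_count))
    starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
    kinds = rng.choice(["gain", "loss"], size=config.cnv_count)
    regions = [(int(s), int(s + l), str(k)) for s, l, k in zip(starts, lengths, kinds)]
    return GroundTruth(regions=regions)


# ---------------------------------------------------------------------------
# Sequence level
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def make_sequences(config: SimulationConfig, truth: GroundTruth,
                   rng: np.random.Generator):
    """Build the (reference, test) sequence pair carrying the planted variants.

    The reference is a uniform-random ATCG sequence. The test sequence
    duplicates gain regions in tandem, deletes loss regions, substitutes
    SNPs (always to a different nucleotide) and applies short indels outside
    CNV regions. Returns ``(reference, test, block_map)`` where the
    sequences are byte strings and ``block_map`` lists
    ``(test_start, ref_start, length)`` collinear blocks.

    The returned ``truth`` (mutated in place) gains SNP/indel bookkeeping.
    """
    n = config.genome_length
    ref = _random_sequence(n, rng)

    # choose indels in reference coordinates outside CNV regions
    n_indels = rng.poisson(config.indel_rate * n)
    cnv_mask = np.zeros(n, dtype=bool)
    for s, e, _ in truth.regions:
        cnv_mask[s:e] = True
    free_pos = np.flatnonzero(~cnv_mask)
    indels: list[tuple[int, int]] = []
    if n_indels and free_pos.size:
        for p in np.sort(rng.choice(free_pos, size=min(n_indels, free_pos.size),
                                    replace=False)):
            length = int(rng.integers(1, config.indel_max_length + 1))
            sign = 1 if rng.random() < 0.5 else -1
            indels.append((int(p), sign * length))
    truth.indels = indels

    # stitch the test sequence from reference blocks (edits sorted by position)
    edits = [(s, e, kind) for s, e, kind in truth.regions]
    edits += [(p, p, f"indel{l:+d}") for p, l in indels]
    edits.sort()
    pieces: list[np.ndarray] = []
    block_map: list[tuple[int, int, int]] = []
    cursor = 0
    test_len = 0

    def emit(ref_start: int, ref_end: int) -> None:
        nonlocal test_len
        if ref_end > ref_start:
            pieces.append(ref[ref_start:ref_end])
            block_map.append((test_len, ref_start, ref_end - ref_start))
            test_len += ref_end - ref_start

    for s, e, kind in edits:
        emit(cursor, s)
        if kind == "gain":
            emit(s, e)
            emit(s, e)  # tandem duplication
            cursor = e
        elif kind == "loss":
            cursor = e  # deletion
        else:  # indel
            length = int(kind[5:])
            if length > 0:
                pieces.append(_random_sequence(length, rng))
                test_len += length
            else:
                cursor = min(n, s - length)
            cursor = max(cursor, s)
    emit(cursor, n)
    test = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)

    # SNPs: substitute to a different nucleotide at random test positions
    n_snps = rng.poisson(config.snp_rate * n)
    if n_snps and test.size:
        snp_pos = np.sort(rng.choice(test.size, size=min(n_snps, test.size),
                                     replace=False))
        shift = rng.integers(1, 4, size=snp_pos.size)
        base_idx = np.argmax(test[snp_pos, None] == _BASES[None, :], axis=1)
        test[snp_pos] = _BASES[(base_idx + shift) % 4]
        truth.snps = [int(p) for p in snp_pos]
    return ref.tobytes(), test.tobytes(), block_map


def _revcomp(read: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    comp[ord("A")], comp[ord("C")] = ord("T"), ord("G")
    comp[ord("G")], comp[ord("T")] = ord("C"), ord("A")
    return comp[read[::-1]]


def simulate_reads(test_sequence: bytes, config: SimulationConfig,
                   rng: np.random.Generator):
    """Extract paired 36 bp reads at coverage C with per-base errors.

    The number of pairs is ``round(C * len / (2 * read_length))``; fragment
    starts are uniform; each base is flipped to a different random base with
    probability E. Yields ``(name, seq1, seq2)`` tuples (read 2 is the
    reverse complement of the fragment end).
    """
    seq = np.frombuffer(test_sequence, dtype=np.uint8)
    L = seq.size
    rlen = config.read_length
    if L <= config.insert_mean:
        raise ValueError("test sequence shorter than the insert size")
    n_pairs = int(round(config.coverage * L / (2 * rlen)))
    inserts = np.maximum(2 * rlen, rng.normal(config.insert_mean, config.insert_sd,
                                              size=n_pairs)).astype(int)
    inserts = np.minimum(inserts, L)
    starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
    out = []
    for i, (s, ins) in enumerate(zip(starts, inserts)):
        r1 = seq[s : s + rlen].copy()
        r2 = _revcomp(seq[s + ins - rlen : s + ins])
        for r in (r1, r2):
            errs = np.flatnonzero(rng.random(rlen) < config.error_rate)
            if errs.size:
                base_idx = np.argmax(r[errs, None] == _BASES[None, :], axis=1)
                r[errs] = _BASES[(base_idx + rng.integers(1, 4, size=errs.size)) % 4]
        out.append((f"sim_pair_{i}", r1.tobytes().decode(), r2.tobytes().decode()))
    return out


def write_fastq_pairs(pairs, path1, path2) -> None:
    """Write paired reads as two FASTQ files with /1 and /2 suffixes."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in pairs:
            q = "I" * len(s1)
            f1.write(f"@{name}/1\n{s1}\n+\n{q}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")


def write_fasta(records: dict[str, bytes], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq.decode()), id=name, description="")
            for name, seq in records.items()]
    seq_write(recs, path, "fasta")


# ---------------------------------------------------------------------------
# Coverage level
# ---------------------------------------------------------------------------

def simulate_coverage(config: SimulationConfig, truth: GroundTruth,
                      rng: np.random.Generator) -> ReadCoverage:
    """Draw the per-base depth track directly (no alignment step).

    Read starts form a Poisson process with rate
    ``C * rho(E) * r(x) / read_length`` per bp, where ``r`` is the local copy
    ratio (``gain_ratio`` inside gains, ``loss_ratio`` inside losses, 1
    elsewhere); each read adds one unit of depth over its 36 bp span. Depth
    at any base is marginally Poisson with mean ``C * rho(E) * r``, and CNV
    edges taper over one read length because reads straddle them.
    """
    n = config.genome_length
    rlen = config.read_length
    rho = alignment_retention_rate(config.error_rate, rlen, config.mismatch_tolerance)
    base_rate = config.coverage * rho / rlen

    # piecewise-constant start-rate segments
    bounds = [0]
    ratios = []
    cursor = 0
    for s, e, kind in truth.regions:
        if s > cursor:
            ratios.append(1.0)
            bounds.append(s)
        ratios.append(config.gain_ratio if kind == "gain" else config.loss_ratio)
        bounds.append(e)
        cursor = e
    if cursor < n:
        ratios.append(1.0)
        bounds.append(n)
    bounds = np.asarray(bounds)
    seg_len = np.diff(bounds)
    seg_rate = base_rate * np.asarray(ratios)
    seg_lambda = seg_rate * seg_len

    n_reads = rng.poisson(seg_lambda.sum())
    seg_of_read = rng.choice(seg_lambda.size, size=n_reads,
                             p=seg_lambda / seg_lambda.sum())
    offsets = rng.random(n_reads)
    starts = (bounds[seg_of_read] + offsets * seg_len[seg_of_read]).astype(np.int64)

    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    ends = np.minimum(starts + rlen, n)
    np.add.at(diff, ends, -1)
    values = np.cumsum(diff[:-1])
    return ReadCoverage(config.contig_id, values, origin=0)


# ---------------------------------------------------------------------------
# Truth I/O (BED with gain|loss in the name column)
# ---------------------------------------------------------------------------

def write_truth(truth: GroundTruth, path, contig_id: str = "sim") -> None:
    with open(path, "w") as fh:
        for s, e, kind in sorted(truth.regions):
            fh.write(f"{contig_id}\t{s}\t{e}\t{kind}\n")


def read_truth(path) -> GroundTruth:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4 or parts[3] not in ("gain", "loss"):
                raise ValueError(f"malformed truth BED line: {line!r}")
            regions.append((int(parts[1]), int(parts[2]), parts[3]))
    return GroundTruth(regions=regions)
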