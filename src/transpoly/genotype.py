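"""Replicate-validated amplicon genotyping.

Turns demultiplexed, replicated amplicon reads into per-individual allele
sets using the classical conservative rules for multi-locus MHC amplicon
data: length/indel/stop-codon read filters, a minimum identical-read count
that must be met independently in two PCR replicates (which makes repeated
validation of a PCR chimera vanishingly unlikely), and a minimum nucleotide
divergence from more-supported variants (guards single-base 454 errors).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import AlleleAlignment

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class Read:
    seq: str
    count: int = 1
    pretrim_len: int | None = None  # read length before tag/primer trimming

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if not self.seq or set(self.seq) - VALID_BASES:
            raise ValueError(f"invalid read sequence {self.seq[:20]!r}...")


@dataclass
class ReadBatch:
    individual_id: str
    replicate_id: str  # 'A' or 'B'
    reads: list[Read] = field(default_factory=list)

    def total_reads(self) -> int:
        return sum(r.count for r in self.reads)

    def counts(self) -> Counter:
        c: Counter = Counter()
        for r in self.reads:
            c[r.seq] += r.count
        return c


@dataclass
class Rejection:
    seq: str
    count: int
    reason: str  # short | indel | stop_codon | ambiguous_base |
    #              insufficient_replication | low_divergence


@dataclass
class ValidatedGenotype:
    individual_id: str
    alleles: list[str]
    support: dict[str, dict[str, int]]  # allele -> {'A': n, 'B': n}
    rejected: list[Rejection] = field(default_factory=list)


# ---------------------------------------------------------------------------
# demultiplexing


def read_mid_table(path: str | Path) -> dict[tuple[str, str], tuple[str, str]]:
    """TSV columns: fwd_tag, rev_tag, individual, replicate."""
    table: dict[tuple[str, str], tuple[str, str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("fwd"):
            continue
        fwd, rev, indiv, rep = line.split("\t")[:4]
        key = (fwd.upper(), rev.upper())
        if key in table:
            raise ValueError(f"duplicate MID pair {key} in table")
        table[key] = (indiv, rep)
    return table


def demultiplex(
    raw_reads: list[str],
    mid_table: dict[tuple[str, str], tuple[str, str]],
    fwd_primer_len: int = 0,
    rev_primer_len: int = 0,
) -> tuple[list[ReadBatch], int]:
    """Sort reads into (individual, replicate) batches by exact MID pairs.

    Reads whose forward/reverse tag pair is not in the table (including
    swapped pairs from tag switching) are discarded and counted.  Tags and
    primers are stripped from the output sequences; the pre-trim read length
    is kept for the downstream minimum-length filter.
    """
    if len(set(mid_table.values())) != len(mid_table):
        raise ValueError("MID table maps two tag pairs to the same sample")
    tag_lens = {len(f) for f, _ in mid_table} | {len(r) for _, r in mid_table}
    if len(tag_lens) != 1:
        raise ValueError("all MID tags must have equal length")
    tl = tag_lens.pop()

    grouped: dict[tuple[str, str], Counter] = defaultdict(Counter)
    pretrims: dict[tuple[str, str], dict[str, int]] = defaultdict(dict)
    discarded = 0
    for seq in raw_reads:
        seq = seq.upper()
        key = (seq[:tl], seq[-tl:])
        if key not in mid_table or len(seq) < 2 * tl + fwd_primer_len + rev_primer_len + 1:
            discarded += 1
            continue
        trimmed = seq[tl + fwd_primer_len : len(seq) - tl - rev_primer_len]
        grouped[mid_table[key]][trimmed] += 1
        # pre-trim length: reads of identical trimmed sequence share it
        pretrims[mid_table[key]].setdefault(trimmed, len(seq))

    batches = []
    for (indiv, rep), counts in sorted(grouped.items()):
        reads = [
            Read(seq=s, count=c, pretrim_len=pretrims[(indiv, rep)][s])
            for s, c in sorted(counts.items())
        ]
        batches.append(ReadBatch(individual_id=indiv, replicate_id=rep, reads=reads))
    return batches, discarded


# ---------------------------------------------------------------------------
# read filtering


def filter_reads(
    batch: ReadBatch,
    min_len: int = 270,
    ref_len: int = 248,
    frame_offset: int = 0,
) -> tuple[ReadBatch, list[Rejection]]:
    """Apply the length / indel / stop-codon / ambiguity filters.

    ``min_len`` applies to the pre-trim read length; a trimmed fragment whose
    length differs from ``ref_len`` is treated as indel-bearing; translation
    in the configured frame must be free of internal stops; reads containing
    N are rejected (conservative).
    """
    from .codon import has_internal_stop

    kept: list[Read] = []
    rejected: list[Rejection] = []
    for r in batch.reads:
        pre = r.pretrim_len if r.pretrim_len is not None else len(r.seq)
        if pre < min_len:
            rejected.append(Rejection(r.seq, r.count, "short"))
        elif len(r.seq) != ref_len:
            rejected.append(Rejection(r.seq, r.count, "indel"))
        elif "N" in r.seq:
            rejected.append(Rejection(r.seq, r.count, "ambiguous_base"))
        elif has_internal_stop(r.seq, frame_offset):
            rejected.append(Rejection(r.seq, r.count, "stop_codon"))
        else:
            kept.append(r)
    return ReadBatch(batch.individual_id, batch.replicate_id, kept), rejected


def choose_frame_offset(seqs: list[str]) -> int:
    """Pick the frame (0-2) minimising internal stop codons across reads."""
    from .codon import translate

    best, best_stops = 0, None
    for off in range(3):
        stops = sum(translate(s, off).count("*") for s in seqs)
        if best_stops is None or stops < best_stops:
            best, best_stops = off, stops
    return best


# ---------------------------------------------------------------------------
# replicate validation and divergence collapsing


def validate_variants(
    batch_a: ReadBatch, batch_b: ReadBatch, min_copies: int = 3
) -> tuple[list[tuple[str, int, int]], list[Rejection]]:
    """Candidate variants: sequences with >= min_copies identical reads in
    BOTH independent PCR replicates of the same individual."""
    if batch_a.individual_id != batch_b.individual_id:
        raise ValueError("replicates belong to different individuals")
    if batch_a.replicate_id == batch_b.replicate_id:
        raise ValueError("need two distinct replicates")
    ca, cb = batch_a.counts(), batch_b.counts()
    candidates, rejected = [], []
    for seq in sorted(set(ca) | set(cb)):
        na, nb = ca.get(seq, 0), cb.get(seq, 0)
        if na >= min_copies and nb >= min_copies:
            candidates.append((seq, na, nb))
        else:
            rejected.append(Rejection(seq, na + nb, "insufficient_replication"))
    return candidates, rejected


def hamming(s1: str, s2: str) -> int:
    if len(s1) != len(s2):
        raise ValueError("hamming distance needs equal lengths")
    return sum(a != b for a, b in zip(s1, s2))


def collapse_low_divergence(
    candidates: list[tuple[str, int, int]],
    min_nt_diff: int = 3,
    individual_id: str = "",
    prior_rejections: list[Rejection] | None = None,
) -> ValidatedGenotype:
    """Keep candidates in decreasing total read support (ties broken
    lexicographically by sequence); a candidate survives only if it differs
    by >= min_nt_diff substitutions from every already-kept variant."""
    order = sorted(candidates, key=lambda c: (-(c[1] + c[2]), c[0]))
    alleles: list[str] = []
    support: dict[str, dict[str, int]] = {}
    rejected = list(prior_rejections or [])
    for seq, na, nb in order:
        if all(hamming(seq, kept) >= min_nt_diff for kept in alleles):
            alleles.append(seq)
            support[seq] = {"A": na, "B": nb}
        else:
            rejected.append(Rejection(seq, na + nb, "low_divergence"))
    return ValidatedGenotype(individual_id, alleles, support, rejected)


def genotype_individual(
    batch_a: ReadBatch,
    batch_b: ReadBatch,
    min_len: int = 270,
    ref_len: int = 248,
    frame_offset: int = 0,
    min_copies: int = 3,
    min_nt_diff: int = 3,
) -> ValidatedGenotype:
    """filter -> replicate-validate -> divergence-collapse for one bird."""
    fa, rej_a = filter_reads(batch_a, min_len, ref_len, frame_offset)
    fb, rej_b = filter_reads(batch_b, min_len, ref_len, frame_offset)
    candidates, rej_v = validate_variants(fa, fb, min_copies)
    return collapse_low_divergence(
        candidates, min_nt_diff, batch_a.individual_id, rej_a + rej_b + rej_v
    )


# ---------------------------------------------------------------------------
# species pooling


@dataclass
class SpeciesPool:
    alignments: dict[str, AlleleAlignment]
    # species -> allele sequence -> list of individuals carrying it
    occurrence: dict[str, dict[str, list[str]]]
    individual_counts: dict[str, list[int]]  # species -> per-bird allele counts


def pool_species_variants(
    genotypes: list[ValidatedGenotype],
    species_map: dict[str, tuple[str, str]],
    frame_offset: int = 0,
) -> SpeciesPool:
    """Pool unique validated variants per species.

    ``species_map``: individual -> (species, genus).  Allele labels are
    ``<species>-NN`` numbered by decreasing carrier count then sequence.
    """
    per_species: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    counts: dict[str, list[int]] = defaultdict(list)
    genera: dict[str, str] = {}
    length: int | None = None
    for g in genotypes:
        sp, ge = species_map[g.individual_id]
        genera[sp] = ge
        counts[sp].append(len(g.alleles))
        for seq in g.alleles:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError("pooled alleles differ in length")
            per_species[sp][seq].append(g.individual_id)

    alignments = {}
    for sp in sorted(per_species):
        seqs = sorted(per_species[sp], key=lambda s: (-len(per_species[sp][s]), s))
        labels = [f"{sp}-{i + 1:02d}" for i in range(len(seqs))]
        alignments[sp] = AlleleAlignment(
            labels=labels,
            seqs=seqs,
            species=[sp] * len(seqs),
            genus=[genera[sp]] * len(seqs),
            frame_offset=frame_offset,
        )
    return SpeciesPool(
        alignments=alignments,
        occurrence={sp: dict(d) for sp, d in per_species.items()},
        individual_counts=dict(counts),
    )


__all__ = [
    "Read",
    "ReadBatch",
    "Rejection",
    "ValidatedGenotype",
    "SpeciesPool",
    "read_mid_table",
    "demultiplex",
    "filter_reads",
    "choose_frame_offset",
    "validate_variants",
    "collapse_low_divergence",
    "genotype_individual",
    "pool_species_variants",
    "hamming",
]
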