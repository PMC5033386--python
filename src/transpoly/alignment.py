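"""AlleleAlignment: equal-length, gap-free allele sets with taxon metadata.

The container used by every downstream stage.  Sequences are MHC IIB exon 2
fragments (default 248 nt); each allele carries a species and genus label, a
reading-frame offset shared by the alignment, and a set of codon indices
flagged as peptide-binding-region (PBR) codons.

The PBR codon list is an *input*: human class II beta-1 contact residues
mapped onto the fragment are supplied via config; the packaged default
(`DEFAULT_PBR_CODONS`) is a conventional choice for a 248 nt exon 2 fragment
and should be overridden when the primer frame of a real dataset differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Default PBR codon indices (0-based, within the 82 complete codons of a
# 248 nt fragment read at frame offset 0).  Derived from the classical human
# class II beta-chain peptide-contact positions; shipped as a configurable
# input, not a fact derived from any dataset.
DEFAULT_PBR_CODONS: frozenset[int] = frozenset(
    {7, 10, 12, 25, 27, 29, 31, 36, 37, 46, 55, 56, 59, 60, 64, 66, 67, 69, 70, 73, 77, 80}
)


@dataclass
class AlleleAlignment:
    labels: list[str]
    seqs: list[str]
    species: list[str]
    genus: list[str]
    frame_offset: int = 0
    pbr_codons: frozenset[int] = field(default_factory=lambda: DEFAULT_PBR_CODONS)

    def __post_init__(self) -> None:
        if len({len(self.labels), len(self.seqs), len(self.species), len(self.genus)}) != 1:
            raise ValueError("labels/seqs/species/genus must have equal length")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not equal length: {sorted(lengths)}")
        if any("-" in s for s in self.seqs):
            raise ValueError("alignment must be gap-free")
        # the default PBR mask targets the 248 nt fragment; clamp to the
        # complete codons actually present
        self.pbr_codons = frozenset(c for c in self.pbr_codons if c < self.n_codons)

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def subset(self, indices: list[int]) -> "AlleleAlignment":
        return AlleleAlignment(
            labels=[self.labels[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
            species=[self.species[i] for i in indices],
            genus=[self.genus[i] for i in indices],
            frame_offset=self.frame_offset,
            pbr_codons=self.pbr_codons,
        )

    def by_species(self) -> dict[str, "AlleleAlignment"]:
        out: dict[str, AlleleAlignment] = {}
        for sp in sorted(set(self.species)):
            idx = [i for i, s in enumerate(self.species) if s == sp]
            out[sp] = self.subset(idx)
        return out

    # ---- I/O -------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=lab, description=f"species={sp} genus={ge}")
            for lab, s, sp, ge in zip(self.labels, self.seqs, self.species, self.genus)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        species_map: dict[str, tuple[str, str]] | None = None,
        frame_offset: int = 0,
        pbr_codons: frozenset[int] | None = None,
    ) -> "AlleleAlignment":
        """Read a FASTA alignment; taxon metadata from ``species_map``
        (label -> (species, genus)) or from ``species=.. genus=..`` tokens in
        the FASTA description lines."""
        labels, seqs, species, genus = [], [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq).upper())
            if species_map is not None:
                sp, ge = species_map[rec.id]
            else:
                tokens = dict(
                    t.split("=", 1) for t in rec.description.split() if "=" in t
                )
                sp = tokens.get("species", "unknown")
                ge = tokens.get("genus", "unknown")
            species.append(sp)
            genus.append(ge)
        kwargs = {} if pbr_codons is None else {"pbr_codons": pbr_codons}
        return cls(labels, seqs, species, genus, frame_offset=frame_offset, **kwargs)


def read_species_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns: label, species, genus (header optional)."""
    out: dict[str, tuple[str, str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("label", "allele", "id"):
            continue
        if len(parts) < 3:
            raise ValueError(f"species map line needs 3 columns: {line!r}")
        out[parts[0]] = (parts[1], parts[2])
    return out
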