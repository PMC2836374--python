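"""DNA alignments (strict ACGT) and FASTA/PHYLIP round-trip I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substmodel import NUCLEOTIDES

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NUCLEOTIDES):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string into int codes 0..3; rejects other symbols."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(arr < 0):
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[c] for c in codes)


@dataclass
class Alignment:
    """Taxa-by-sites DNA matrix over {A,C,G,T}, codes 0..3."""

    taxa: list[str]
    sites: np.ndarray  # (n_taxa, n_sites) int8
    site_multipliers: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int8)
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise ValueError("sites must be (n_taxa, n_sites) matching taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def sequence(self, taxon: str) -> str:
        return decode(self.sites[self.taxa.index(taxon)])

    @classmethod
    def from_sequences(cls, taxa, sequences) -> "Alignment":
        rows = [encode(s) for s in sequences]
        if len({len(r) for r in rows}) > 1:
            raise ValueError("sequences have unequal lengths")
        return cls(list(taxa), np.vstack(rows))

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their counts: ((n_taxa, n_patterns), (n_patterns,))."""
        pats, counts = np.unique(self.sites, axis=1, return_counts=True)
        return pats, counts.astype(float)

    def p_distance(self, a: str, b: str) -> float:
        """Proportion of differing sites between two taxa."""
        ia, ib = self.taxa.index(a), self.taxa.index(b)
        return float(np.mean(self.sites[ia] != self.sites[ib]))

    def base_frequencies(self) -> np.ndarray:
        counts = np.bincount(self.sites.ravel(), minlength=4)
        return counts / counts.sum()


def _to_biopython(aln: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(decode(aln.sites[i])), id=t, description="")
        for i, t in enumerate(aln.taxa)
    )


def write_fasta(aln: Alignment, path: str) -> None:
    SeqIO.write(_to_biopython(aln), path, "fasta")


def read_fasta(path: str) -> Alignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_sequences([r.id for r in records], [str(r.seq) for r in records])


def write_phylip(aln: Alignment, path: str, strict: bool = False) -> None:
    fmt = "phylip" if strict else "phylip-relaxed"
    AlignIO.write(_to_biopython(aln), path, fmt)


def read_phylip(path: str, strict: bool = False) -> Alignment:
    fmt = "phylip" if strict else "phylip-relaxed"
    msa = AlignIO.read(path, fmt)
    return Alignment.from_sequences([r.id for r in msa], [str(r.seq) for r in msa])
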