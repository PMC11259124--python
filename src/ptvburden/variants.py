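"""Genomic variant records, allele normalization, and genotype evidence.

Variants follow the VCF convention: 1-based genomic positions with an
anchor (context) base shared between REF and ALT for insertions and
deletions.  Normalization trims shared context down to the minimal edit,
which downstream code then shifts 3'-most on the transcript strand for
HGVS naming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_TOKEN_RE = re.compile(r"^([\w.]+)-(\d+)-([ACGTNacgtn]+)-([ACGTNacgtn]+)$")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantRecord:
    """One genomic small variant in VCF-style representation.

    ``pos`` is 1-based; ``ref`` and ``alt`` are non-empty, differ, and may
    share a leading anchor base (the VCF indel convention).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ (identity edit rejected)")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not re.fullmatch(r"[ACGTNacgtn]+", allele):
                raise ValueError(f"{name} contains non-nucleotide characters: {allele!r}")

    @classmethod
    def from_token(cls, token: str) -> "VariantRecord":
        """Parse a ``chrom-pos-ref-alt`` token such as ``15-85401543-T-TC``."""
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise ValueError(f"cannot parse variant token {token!r}")
        contig, pos, ref, alt = m.groups()
        return cls(contig=contig, pos=int(pos), ref=ref.upper(), alt=alt.upper(), id=token.strip())

    @property
    def token(self) -> str:
        return f"{self.contig}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def end(self) -> int:
        """Last genomic position covered by the (untrimmed) ref allele."""
        return self.pos + len(self.ref) - 1


class EditKind(str, Enum):
    substitution = "substitution"
    deletion = "deletion"
    insertion = "insertion"
    delins = "delins"


@dataclass(frozen=True)
class NormalizedEdit:
    """A variant with shared REF/ALT context trimmed away.

    ``start``..``end`` is the affected reference interval (1-based,
    inclusive).  For a pure insertion the inserted bases sit between
    ``start - 1`` and ``start`` and ``end == start - 1``.
    """

    kind: EditKind
    start: int
    end: int
    ref: str
    alt: str

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


def normalize(v: VariantRecord) -> NormalizedEdit:
    """Trim shared suffix, then shared prefix, yielding the minimal edit."""
    ref, alt, pos = v.ref.upper(), v.alt.upper(), v.pos
    # suffix first so the anchor base convention (shared prefix) survives
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref and alt:
        kind = EditKind.substitution if len(ref) == len(alt) == 1 else EditKind.delins
        return NormalizedEdit(kind, pos, pos + len(ref) - 1, ref, alt)
    if ref:
        return NormalizedEdit(EditKind.deletion, pos, pos + len(ref) - 1, ref, "")
    return NormalizedEdit(EditKind.insertion, pos, pos - 1, "", alt)


class Zygosity(str, Enum):
    het = "het"
    hom = "hom"
    hemi = "hemi"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's sequencing evidence for one variant.

    ``allele_depth`` counts reads supporting the alternate allele;
    ``vaf`` is the variant allele fraction ``allele_depth / total_depth``.
    """

    sample_id: str
    variant: VariantRecord
    zygosity: Zygosity
    allele_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if not (0 <= self.allele_depth <= self.total_depth):
            raise ValueError(
                f"require 0 <= allele_depth <= total_depth, got "
                f"AD={self.allele_depth}, DP={self.total_depth}"
            )

    @property
    def vaf(self) -> float:
        if self.total_depth == 0:
            return 0.0
        return self.allele_depth / self.total_depth


def decompose_multiallelic(contig: str, pos: int, ref: str, alts: list[str],
                           id: Optional[str] = None) -> list[VariantRecord]:
    """Split a multi-allelic VCF site into biallelic records, one per ALT."""
    return [
        VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                      id=None if id in (None, ".") else f"{id}:{i}" if len(alts) > 1 else id)
        for i, alt in enumerate(alts, start=1)
        if alt not in (".", "*", "<NON_REF>")
    ]
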