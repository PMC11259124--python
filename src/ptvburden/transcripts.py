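"""Transcript models, consequence classification, and HGVS naming.

The consequence engine applies an SNV/indel to a spliced transcript,
re-translates the coding sequence, and classifies the molecular effect.
A variant is a premature terminating variant (PTV) when it is a stop
gain, a frameshift, or disrupts a canonical (+/-1, +/-2) splice
dinucleotide of an intron inside the coding span.  HGVS coding names are
3'-normalized on the transcript strand, with insertions that repeat the
immediately preceding bases written as duplications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .variants import (
    EditKind,
    NormalizedEdit,
    VariantRecord,
    normalize,
    revcomp,
)


class Consequence(str, Enum):
    stop_gain = "stop_gain"
    frameshift = "frameshift"
    canonical_splice = "canonical_splice"
    inframe_indel = "inframe_indel"
    missense = "missense"
    synonymous = "synonymous"
    start_loss = "start_loss"
    stop_loss = "stop_loss"
    intronic = "intronic"
    utr = "utr"


#: consequence classes counted as premature terminating variants
PTV_CLASSES = frozenset(
    {Consequence.stop_gain, Consequence.frameshift, Consequence.canonical_splice}
)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genomic contig.

    ``exons`` are 1-based inclusive genomic intervals sorted by genomic
    position and non-overlapping.  ``cds_start``/``cds_end`` are the
    genomic bounds of the translated region (``cds_start < cds_end``
    regardless of strand; on the minus strand translation begins at
    ``cds_end``).  ``sequence`` is the spliced transcript 5'->3' on the
    transcript strand.  ``contig_sequence``, when present, is the full
    contig (used by the simulator and for REF checks).
    """

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str
    contig_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon {s}..{e} has start > end")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise ValueError("cds_start does not fall inside an exon")
        if not any(s <= self.cds_end <= e for s, e in self.exons):
            raise ValueError("cds_end does not fall inside an exon")
        if len(self.sequence) != sum(e - s + 1 for s, e in self.exons):
            raise ValueError("spliced sequence length does not match exon lengths")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("spliced CDS length is not a multiple of 3")

    # -- coordinate plumbing ------------------------------------------------

    @cached_property
    def _tx_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @cached_property
    def length(self) -> int:
        return len(self.sequence)

    def g2t(self, gpos: int) -> Optional[int]:
        """Genomic position -> 1-based transcript position, or None if intronic/outside."""
        offset = 0
        for s, e in self._tx_exons:
            if s <= gpos <= e:
                if self.strand == "+":
                    return offset + (gpos - s) + 1
                return offset + (e - gpos) + 1
            offset += e - s + 1
        return None

    def t2g(self, tpos: int) -> int:
        """1-based transcript position -> genomic position."""
        if not 1 <= tpos <= self.length:
            raise ValueError(f"transcript position {tpos} outside 1..{self.length}")
        offset = 0
        for s, e in self._tx_exons:
            n = e - s + 1
            if tpos <= offset + n:
                within = tpos - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += n
        raise AssertionError("unreachable")

    @cached_property
    def tx_cds_start(self) -> int:
        """Transcript position of the first CDS base (the A of ATG)."""
        g = self.cds_start if self.strand == "+" else self.cds_end
        t = self.g2t(g)
        assert t is not None
        return t

    @cached_property
    def tx_cds_end(self) -> int:
        """Transcript position of the last CDS base (third base of the stop codon)."""
        g = self.cds_end if self.strand == "+" else self.cds_start
        t = self.g2t(g)
        assert t is not None
        return t

    @cached_property
    def cds_sequence(self) -> str:
        return self.sequence[self.tx_cds_start - 1 : self.tx_cds_end]

    @cached_property
    def protein(self) -> str:
        """Reference peptide including the terminal ``*``."""
        return translate_to_stop(self.cds_sequence)

    def validate_cds(self) -> None:
        """Check start/stop codon invariants (fixtures and simulated models)."""
        cds = self.cds_sequence.upper()
        if not cds.startswith("ATG"):
            raise ValueError("CDS does not begin with ATG")
        if cds[-3:] not in ("TAA", "TAG", "TGA"):
            raise ValueError("CDS does not end with a stop codon")

    @cached_property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals (1-based inclusive), genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @cached_property
    def canonical_splice_positions(self) -> frozenset[int]:
        """Genomic positions of the +/-1,+/-2 dinucleotides of CDS-span introns.

        Only introns lying inside the genomic CDS span count: disrupting
        splicing of a purely untranslated intron does not truncate the
        protein, so it is not a PTV here.
        """
        lo, hi = self.cds_start, self.cds_end
        pos: set[int] = set()
        for s, e in self.introns:
            if s >= lo and e <= hi and e - s + 1 >= 4:
                pos.update((s, s + 1, e - 1, e))
        return frozenset(pos)


# -- coding-position descriptors -------------------------------------------


@dataclass(frozen=True)
class CodingPosition:
    """HGVS-style c. coordinate of a single genomic position.

    ``kind`` is one of cds / utr5 / utr3 / intronic / outside.  ``base``
    is the anchor c. coordinate string ("4", "-12", "*33"); ``offset``
    is the intronic +/- offset (0 for exonic positions).
    """

    kind: str
    base: str = ""
    offset: int = 0

    def __str__(self) -> str:
        if self.kind == "outside":
            return "outside"
        if self.offset == 0:
            return self.base
        return f"{self.base}{self.offset:+d}"


def _c_label(t: TranscriptModel, tpos: int) -> str:
    """c. coordinate string for a transcript position."""
    if tpos < t.tx_cds_start:
        return str(tpos - t.tx_cds_start)  # negative: 5' UTR
    if tpos > t.tx_cds_end:
        return f"*{tpos - t.tx_cds_end}"
    return str(tpos - t.tx_cds_start + 1)


def _c_kind(t: TranscriptModel, tpos: int) -> str:
    if tpos < t.tx_cds_start:
        return "utr5"
    if tpos > t.tx_cds_end:
        return "utr3"
    return "cds"


def project_position(t: TranscriptModel, gpos: int) -> CodingPosition:
    """Project one genomic position into the transcript's c. frame."""
    tpos = t.g2t(gpos)
    if tpos is not None:
        return CodingPosition(kind=_c_kind(t, tpos), base=_c_label(t, tpos))
    # intronic or outside: find the flanking exons in transcript order
    tx = t._tx_exons
    span_lo = min(s for s, _ in t.exons)
    span_hi = max(e for _, e in t.exons)
    if not span_lo <= gpos <= span_hi:
        return CodingPosition(kind="outside")
    for i in range(len(tx) - 1):
        up, down = tx[i], tx[i + 1]
        if t.strand == "+":
            in_intron = up[1] < gpos < down[0]
            d_up, d_down = gpos - up[1], down[0] - gpos
            up_edge, down_edge = up[1], down[0]
        else:
            in_intron = down[1] < gpos < up[0]
            d_up, d_down = up[0] - gpos, gpos - down[1]
            up_edge, down_edge = up[0], down[1]
        if in_intron:
            if d_up <= d_down:
                anchor = t.g2t(up_edge)
                assert anchor is not None
                return CodingPosition(kind="intronic", base=_c_label(t, anchor), offset=d_up)
            anchor = t.g2t(down_edge)
            assert anchor is not None
            return CodingPosition(kind="intronic", base=_c_label(t, anchor), offset=-d_down)
    return CodingPosition(kind="outside")


# -- mapping edits onto the transcript --------------------------------------


@dataclass(frozen=True)
class TranscriptEdit:
    """A normalized edit expressed in transcript coordinates.

    ``start``..``end`` is the affected 1-based transcript interval; for a
    pure insertion ``end == start - 1`` and the bases go between
    ``start - 1`` and ``start``.  Alleles are on the transcript strand.
    """

    kind: EditKind
    start: int
    end: int
    ref: str
    alt: str

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


def _edit_to_transcript(t: TranscriptModel, e: NormalizedEdit) -> Optional[TranscriptEdit]:
    """Map a genomic edit to transcript space.  None if not representable
    as a contiguous transcript edit (e.g. intronic, or spanning a junction)."""
    if e.kind == EditKind.insertion:
        # inserted between genomic e.end (= start-1) and e.start
        left, right = e.end, e.start
        tl, tr = t.g2t(left), t.g2t(right)
        if tl is None or tr is None or abs(tl - tr) != 1:
            return None
        tpoint = max(tl, tr)  # transcript position before which bases go
        seq = e.alt if t.strand == "+" else revcomp(e.alt)
        return TranscriptEdit(EditKind.insertion, tpoint, tpoint - 1, "", seq)
    ts, te = t.g2t(e.start), t.g2t(e.end)
    if ts is None or te is None:
        return None
    lo, hi = min(ts, te), max(ts, te)
    if hi - lo != e.end - e.start:  # spans an intron
        return None
    ref = e.ref if t.strand == "+" else revcomp(e.ref)
    alt = e.alt if t.strand == "+" else revcomp(e.alt)
    return TranscriptEdit(e.kind, lo, hi, ref, alt)


def _shift3(seq: str, edit: TranscriptEdit) -> TranscriptEdit:
    """Shift a pure deletion/insertion 3'-most along the transcript (HGVS rule)."""
    if edit.kind == EditKind.deletion:
        s, seg = edit.start, edit.ref
        L = len(seg)
        while s + L <= len(seq) and seq[s + L - 1] == seg[0]:
            seg = seg[1:] + seq[s + L - 1]
            s += 1
        return TranscriptEdit(EditKind.deletion, s, s + L - 1, seg, "")
    if edit.kind == EditKind.insertion:
        p, seg = edit.start, edit.alt
        while p <= len(seq) and seq[p - 1] == seg[0]:
            seg = seg[1:] + seq[p - 1]
            p += 1
        return TranscriptEdit(EditKind.insertion, p, p - 1, "", seg)
    return edit


# -- translation ------------------------------------------------------------


def translate_to_stop(cds: str) -> str:
    """Translate from the first base through the first stop (inclusive, as ``*``).

    Uses the standard nuclear code; a trailing partial codon is ignored.
    Returns the peptide without a stop if no stop codon is reached.
    """
    usable = len(cds) - len(cds) % 3
    pep = str(Seq(cds[:usable]).translate())
    idx = pep.find("*")
    return pep if idx == -1 else pep[: idx + 1]


@dataclass(frozen=True)
class EditedTranslation:
    """Result of applying an edit to the CDS and re-translating."""

    edited_cds: str       #: CDS with the edit applied (read-through into 3' UTR not included)
    peptide: str          #: translation up to and including the first stop ('*')
    start_lost: bool      #: the edit destroyed the initiation codon
    no_downstream_stop: bool  #: no stop before the transcript end (frameshift read-through)


def apply_and_translate(t: TranscriptModel, v: VariantRecord) -> EditedTranslation:
    """Apply a variant to the spliced CDS and translate the result.

    The variant must touch the CDS.  Deletions spanning an exon/intron
    junction delete only their exonic bases.  Frameshifted reading
    continues into the 3' UTR when hunting for the new stop codon.
    """
    if v.contig != t.contig:
        raise ValueError(f"variant contig {v.contig!r} != transcript contig {t.contig!r}")
    e = normalize(v)
    tedit = _edit_to_transcript(t, e)
    if tedit is None:
        tedit = _clip_to_exons(t, e)
        if tedit is None:
            raise ValueError("variant does not overlap the spliced transcript")
    edited = _apply(t.sequence, tedit)
    # the CDS start shifts only if the edit removes/adds bases 5' of it
    delta_before = 0
    if tedit.end < t.tx_cds_start:
        delta_before = tedit.length_change
    cds_from = t.tx_cds_start + delta_before
    edited_cds_through_utr = edited[cds_from - 1 :]
    # locate natural CDS extent in the edited string for reporting
    nat_len = t.tx_cds_end - t.tx_cds_start + 1
    edited_cds = edited_cds_through_utr[: nat_len + max(0, tedit.length_change)]
    start_lost = not edited_cds_through_utr.upper().startswith("ATG")
    pep = translate_to_stop(edited_cds_through_utr)
    no_stop = not pep.endswith("*")
    return EditedTranslation(
        edited_cds=edited_cds,
        peptide=pep,
        start_lost=start_lost,
        no_downstream_stop=no_stop,
    )


def _apply(seq: str, e: TranscriptEdit) -> str:
    if e.kind == EditKind.insertion:
        return seq[: e.start - 1] + e.alt + seq[e.start - 1 :]
    return seq[: e.start - 1] + e.alt + seq[e.end :]


def _clip_to_exons(t: TranscriptModel, e: NormalizedEdit) -> Optional[TranscriptEdit]:
    """Junction-spanning deletion: keep only the exonic (spliced) portion."""
    if e.kind not in (EditKind.deletion, EditKind.delins):
        return None
    tpos = sorted(
        tp for g in range(e.start, e.end + 1) if (tp := t.g2t(g)) is not None
    )
    if not tpos:
        return None
    lo, hi = tpos[0], tpos[-1]
    ref = t.sequence[lo - 1 : hi]
    alt = "" if e.kind == EditKind.deletion else (e.alt if t.strand == "+" else revcomp(e.alt))
    kind = EditKind.deletion if not alt else EditKind.delins
    return TranscriptEdit(kind, lo, hi, ref, alt)


# -- consequence calls ------------------------------------------------------


@dataclass(frozen=True)
class ConsequenceCall:
    """Classified consequence of one variant against one transcript."""

    variant: VariantRecord
    transcript_id: str
    consequence: Consequence
    is_ptv: bool
    hgvs_c: str
    hgvs_p: str
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        assert self.is_ptv == (self.consequence in PTV_CLASSES)


def classify_consequence(t: TranscriptModel, v: VariantRecord) -> ConsequenceCall:
    """Classify a variant's molecular consequence against a transcript.

    Canonical-splice disruption takes precedence (conservative PTV
    calling for junction-spanning edits); otherwise CDS-overlapping
    indels with length change not divisible by 3 are frameshifts, and
    in-frame edits are classified by re-translation.
    """
    if v.contig != t.contig:
        raise ValueError(f"variant contig {v.contig!r} != transcript contig {t.contig!r}")
    e = normalize(v)
    affected = _affected_interval(e)
    note = None

    if any(p in t.canonical_splice_positions for p in range(affected[0], affected[1] + 1)):
        hgvs_c = _hgvs_c_intronic(t, e)
        return ConsequenceCall(v, t.id, Consequence.canonical_splice, True, hgvs_c, "p.?", note)

    overlaps_cds = _overlaps_cds(t, e)
    if overlaps_cds:
        cds_len_change = _cds_length_change(t, e)
        trans = apply_and_translate(t, v)
        if cds_len_change % 3 != 0:
            cons = Consequence.frameshift
        else:
            cons = _inframe_class(t, trans, cds_len_change)
        hgvs_c, hgvs_p = hgvs_name(t, v, cons, trans)
        if cons is Consequence.frameshift and trans.no_downstream_stop:
            note = "no downstream stop codon before transcript end"
            warnings.warn(f"{v.token}: {note}", stacklevel=2)
        return ConsequenceCall(v, t.id, cons, cons in PTV_CLASSES, hgvs_c, hgvs_p, note)

    # non-coding territory
    in_exon = all(t.g2t(p) is not None for p in range(affected[0], affected[1] + 1))
    if in_exon and affected[1] >= affected[0]:
        hgvs_c = _hgvs_c_exonic_name(t, e)
        return ConsequenceCall(v, t.id, Consequence.utr, False, hgvs_c, "p.?", note)
    pos_desc = project_position(t, e.start)
    if pos_desc.kind == "outside":
        note = "outside transcript span"
    hgvs_c = _hgvs_c_intronic(t, e) if pos_desc.kind == "intronic" else f"c.{pos_desc}"
    return ConsequenceCall(v, t.id, Consequence.intronic, False, hgvs_c, "p.?", note)


def _affected_interval(e: NormalizedEdit) -> tuple[int, int]:
    """Genomic interval an edit touches; insertions touch both flanks."""
    if e.kind == EditKind.insertion:
        return (e.end, e.start)  # (start-1, start)
    return (e.start, e.end)


def _overlaps_cds(t: TranscriptModel, e: NormalizedEdit) -> bool:
    lo, hi = _affected_interval(e)
    if e.kind == EditKind.insertion:
        # insertion changes the CDS only if strictly inside it
        tl, tr = t.g2t(lo), t.g2t(hi)
        if tl is None or tr is None:
            return False
        inner = max(tl, tr)
        return t.tx_cds_start < inner <= t.tx_cds_end
    for g in range(lo, hi + 1):
        tp = t.g2t(g)
        if tp is not None and t.tx_cds_start <= tp <= t.tx_cds_end:
            return True
    return False


def _cds_length_change(t: TranscriptModel, e: NormalizedEdit) -> int:
    """Net change in CDS length: inserted bases minus deleted CDS bases."""
    if e.kind == EditKind.insertion:
        return len(e.alt)
    deleted_cds = sum(
        1
        for g in range(e.start, e.end + 1)
        if (tp := t.g2t(g)) is not None and t.tx_cds_start <= tp <= t.tx_cds_end
    )
    return len(e.alt) - deleted_cds


def _inframe_class(
    t: TranscriptModel, trans: EditedTranslation, cds_len_change: int
) -> Consequence:
    ref_pep = t.protein
    new_pep = trans.peptide
    if trans.start_lost:
        return Consequence.start_loss
    # peptide length expected if translation still ends at the natural stop
    expected = len(ref_pep) + cds_len_change // 3
    if new_pep.endswith("*") and len(new_pep) < expected:
        return Consequence.stop_gain
    if not new_pep.endswith("*") or len(new_pep) > expected:
        return Consequence.stop_loss
    if new_pep == ref_pep:
        return Consequence.synonymous
    if cds_len_change != 0:
        return Consequence.inframe_indel
    return Consequence.missense


# -- HGVS naming ------------------------------------------------------------


def hgvs_name(
    t: TranscriptModel,
    v: VariantRecord,
    consequence: Consequence,
    trans: Optional[EditedTranslation] = None,
) -> tuple[str, str]:
    """Emit the (hgvs_c, hgvs_p) pair for a classified variant.

    The c. name is 3'-shifted on the transcript strand; insertions equal
    to the immediately preceding bases become ``dup``.  Protein names:
    stop gains ``p.<Ref><pos>Ter``; frameshifts
    ``p.<Ref><pos><New>fsTer<k>`` with k counting codons from the first
    changed residue (inclusive) to the new stop; splice calls ``p.?``.
    """
    e = normalize(v)
    if consequence is Consequence.canonical_splice:
        return _hgvs_c_intronic(t, e), "p.?"
    hgvs_c = _hgvs_c_exonic_name(t, e)
    if trans is None:
        trans = apply_and_translate(t, v)
    hgvs_p = _hgvs_p(t, consequence, trans)
    return hgvs_c, hgvs_p


def _hgvs_c_exonic_name(t: TranscriptModel, e: NormalizedEdit) -> str:
    tedit = _edit_to_transcript(t, e)
    if tedit is None:
        tedit = _clip_to_exons(t, e)
    if tedit is None:
        return f"c.{project_position(t, e.start)}"
    tedit = _shift3(t.sequence, tedit)
    lab = lambda tp: _c_label(t, tp)  # noqa: E731
    if tedit.kind == EditKind.substitution:
        return f"c.{lab(tedit.start)}{tedit.ref}>{tedit.alt}"
    if tedit.kind == EditKind.deletion:
        if tedit.start == tedit.end:
            return f"c.{lab(tedit.start)}del"
        return f"c.{lab(tedit.start)}_{lab(tedit.end)}del"
    if tedit.kind == EditKind.insertion:
        L = len(tedit.alt)
        p = tedit.start
        if p - 1 - L >= 0 and t.sequence[p - 1 - L : p - 1] == tedit.alt:
            if L == 1:
                return f"c.{lab(p - 1)}dup"
            return f"c.{lab(p - L)}_{lab(p - 1)}dup"
        return f"c.{lab(p - 1)}_{lab(p)}ins{tedit.alt}"
    # delins
    if tedit.start == tedit.end:
        return f"c.{lab(tedit.start)}delins{tedit.alt}"
    return f"c.{lab(tedit.start)}_{lab(tedit.end)}delins{tedit.alt}"


def _hgvs_c_intronic(t: TranscriptModel, e: NormalizedEdit) -> str:
    lo, hi = _affected_interval(e)
    # anchor on an intronic position of the edit (splice naming)
    desc = None
    for g in (lo, hi):
        d = project_position(t, g)
        if d.kind == "intronic":
            desc = d
            anchor_g = g
            break
    if desc is None:
        desc = project_position(t, lo)
        anchor_g = lo
    if e.kind == EditKind.substitution:
        ref = e.ref if t.strand == "+" else revcomp(e.ref)
        alt = e.alt if t.strand == "+" else revcomp(e.alt)
        return f"c.{desc}{ref}>{alt}"
    suffix = {EditKind.deletion: "del", EditKind.insertion: "ins", EditKind.delins: "delins"}[e.kind]
    return f"c.{desc}{suffix}"


def _hgvs_p(t: TranscriptModel, consequence: Consequence, trans: EditedTranslation) -> str:
    ref_pep, new_pep = t.protein, trans.peptide
    if consequence in (
        Consequence.start_loss,
        Consequence.inframe_indel,
        Consequence.stop_loss,
    ):
        return "p.?"
    if consequence is Consequence.synonymous:
        return "p.(=)"
    i = _first_diff(ref_pep, new_pep)
    if i is None:
        return "p.(=)"
    ref_aa = seq3(ref_pep[i]) if i < len(ref_pep) else "Ter"
    if consequence is Consequence.stop_gain:
        return f"p.{ref_aa}{i + 1}Ter"
    if consequence is Consequence.missense:
        return f"p.{ref_aa}{i + 1}{seq3(new_pep[i])}"
    if consequence is Consequence.frameshift:
        if i >= len(new_pep):
            return f"p.{ref_aa}{i + 1}fsTer?"
        new_aa = new_pep[i]
        if new_aa == "*":
            # the first changed residue is itself the new stop
            return f"p.{ref_aa}{i + 1}fsTer1"
        stop = new_pep.find("*", i)
        if stop == -1:
            return f"p.{ref_aa}{i + 1}{seq3(new_aa)}fsTer?"
        return f"p.{ref_aa}{i + 1}{seq3(new_aa)}fsTer{stop - i + 1}"
    return "p.?"


def _first_diff(a: str, b: str) -> Optional[int]:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    if len(a) != len(b):
        return min(len(a), len(b))
    return None


# -- public projection API ---------------------------------------------------


def project_to_cds(t: TranscriptModel, v: VariantRecord) -> CodingPosition:
    """c. frame descriptor of a variant's (3'-shifted) start position.

    The edit is first trimmed to its minimal representation and, when it
    lies inside an exon, shifted 3'-most on the transcript strand before
    projecting, so the descriptor matches the HGVS name's anchor.
    """
    if v.contig != t.contig:
        raise ValueError(f"variant contig {v.contig!r} != transcript contig {t.contig!r}")
    e = normalize(v)
    tedit = _edit_to_transcript(t, e)
    if tedit is not None:
        tedit = _shift3(t.sequence, tedit)
        tp = tedit.start if tedit.kind != EditKind.insertion else tedit.start - 1
        tp = min(max(tp, 1), t.length)
        return CodingPosition(kind=_c_kind(t, tp), base=_c_label(t, tp))
    return project_position(t, e.start)


# -- c. name parsing (round-trip support) ------------------------------------

import re as _re

_C_POS = r"(\*?-?\d+)"
_SUB_RE = _re.compile(rf"^c\.{_C_POS}([ACGT])>([ACGT])$")
_DEL_RE = _re.compile(rf"^c\.{_C_POS}(?:_{_C_POS})?del$")
_DUP_RE = _re.compile(rf"^c\.{_C_POS}(?:_{_C_POS})?dup$")
_INS_RE = _re.compile(rf"^c\.{_C_POS}_{_C_POS}ins([ACGT]+)$")
_DELINS_RE = _re.compile(rf"^c\.{_C_POS}(?:_{_C_POS})?delins([ACGT]+)$")


def _c_to_t(t: TranscriptModel, label: str) -> int:
    if label.startswith("*"):
        return t.tx_cds_end + int(label[1:])
    n = int(label)
    if n < 0:
        return t.tx_cds_start + n
    return t.tx_cds_start + n - 1


def parse_hgvs_c(t: TranscriptModel, name: str) -> TranscriptEdit:
    """Parse an exonic c. name emitted by this module back to a transcript edit.

    Supports substitution, del, dup, ins and delins with exonic
    coordinates; intended for round-trip verification.
    """
    if m := _SUB_RE.match(name):
        p = _c_to_t(t, m.group(1))
        return TranscriptEdit(EditKind.substitution, p, p, m.group(2), m.group(3))
    if m := _DEL_RE.match(name):
        s = _c_to_t(t, m.group(1))
        e = _c_to_t(t, m.group(2)) if m.group(2) else s
        return TranscriptEdit(EditKind.deletion, s, e, t.sequence[s - 1 : e], "")
    if m := _DUP_RE.match(name):
        s = _c_to_t(t, m.group(1))
        e = _c_to_t(t, m.group(2)) if m.group(2) else s
        seg = t.sequence[s - 1 : e]
        return TranscriptEdit(EditKind.insertion, e + 1, e, "", seg)
    if m := _INS_RE.match(name):
        p = _c_to_t(t, m.group(2))
        return TranscriptEdit(EditKind.insertion, p, p - 1, "", m.group(3))
    if m := _DELINS_RE.match(name):
        s = _c_to_t(t, m.group(1))
        e = _c_to_t(t, m.group(2)) if m.group(2) else s
        return TranscriptEdit(EditKind.delins, s, e, t.sequence[s - 1 : e], m.group(3))
    raise ValueError(f"cannot parse c. name {name!r}")
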