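"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own code paths: translation uses
a hand-written codon dictionary, coordinate mapping walks exon intervals
directly, and consecutive-exon overlap is a literal run scan.
"""

from __future__ import annotations

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon_by_codon(seq: str) -> str:
    """Character-by-character re-translation up to and including first stop."""
    pep = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i : i + 3].upper()]
        pep.append(aa)
        if aa == "*":
            break
    return "".join(pep)


def genomic_to_spliced_map(exons, strand) -> dict[int, int]:
    """Brute-force genomic -> 1-based spliced-position map."""
    ordered = list(exons) if strand == "+" else list(reversed(exons))
    mapping: dict[int, int] = {}
    t = 1
    for s, e in ordered:
        rng = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        for g in rng:
            mapping[g] = t
            t += 1
    return mapping


def edited_spliced_sequence(spliced: str, tx_map: dict[int, int], strand: str,
                            gstart: int, ref: str, alt: str, revcomp) -> str:
    """Apply a fully-exonic genomic edit to the spliced sequence by brute force."""
    positions = [tx_map[g] for g in range(gstart, gstart + len(ref))]
    if positions:
        lo, hi = min(positions), max(positions)
        ref_t = ref if strand == "+" else revcomp(ref)
        alt_t = alt if strand == "+" else revcomp(alt)
        assert spliced[lo - 1 : hi] == ref_t
        return spliced[: lo - 1] + alt_t + spliced[hi:]
    raise ValueError("empty edit")


def max_consecutive_overlap(exons, start: int, end: int) -> int:
    """Longest run of consecutive exons intersecting [start, end]."""
    best = run = 0
    for s, e in exons:
        if not (end < s or start > e):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def oracle_exonic_ptv(ref_read: str, edited_read: str, cds_delta: int) -> tuple[bool, str]:
    """Oracle PTV predicate and class for a fully-CDS-internal edit.

    ``ref_read``/``edited_read`` are the CDS continued through the 3'
    UTR (so frameshifted stops in the UTR are found); ``cds_delta`` is
    the net base change inside the CDS.  Returns (is_ptv, class) where
    class is "frameshift", "stop_gain", or "other".
    """
    if cds_delta % 3 != 0:
        return True, "frameshift"
    p0 = translate_codon_by_codon(ref_read)
    p1 = translate_codon_by_codon(edited_read)
    expected = len(p0) + cds_delta // 3
    if p1.endswith("*") and len(p1) < expected:
        return True, "stop_gain"
    return False, "other"


def random_cds_edits(t, rng: np.random.Generator, n: int):
    """Random SNVs/indels fully inside one exon, clear of start/stop codons.

    ``t`` is a transcript model with a contig sequence; ``rng`` a numpy
    Generator.  Returns ``n`` VCF-style variant records.
    """
    from ptvburden.variants import VariantRecord
    seq = t.contig_sequence
    margin = 9
    eligible = []
    for s, e in t.exons:
        for g in range(s, e + 1 - 8):
            tps = [t.g2t(x) for x in range(g, g + 9)]
            if all(
                tp is not None and t.tx_cds_start + margin <= tp <= t.tx_cds_end - margin
                for tp in tps
            ):
                eligible.append(g)
    out = []
    while len(out) < n:
        g = int(rng.choice(eligible))
        mode = rng.random()
        if mode < 0.4:  # SNV
            ref = seq[g - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            out.append(VariantRecord(contig=t.contig, pos=g, ref=ref, alt=alt))
        elif mode < 0.7:  # deletion of 1..6 bases with anchor
            k = int(rng.integers(1, 7))
            out.append(
                VariantRecord(contig=t.contig, pos=g, ref=seq[g - 1 : g + k], alt=seq[g - 1])
            )
        else:  # insertion of 1..6 bases with anchor
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
            out.append(VariantRecord(contig=t.contig, pos=g, ref=seq[g - 1], alt=seq[g - 1] + ins))
    return out
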