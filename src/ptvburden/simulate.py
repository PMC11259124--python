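"""Synthetic transcripts, cohorts, and variant call sets.

The generator emulates the statistical structure the burden analysis
assumes: a case panel with a PTV carrier frequency near 1.5% and
control panels near 0.07-0.15%, heterozygous carriers harbouring one
qualifying PTV each, non-PTV decoy variants, genotypes corrupted to
fail QC at a configurable rate, and ages drawn from a truncated normal
(mean 53, SD 17, minimum 17 years by default).  Everything is
deterministic under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .transcripts import TranscriptModel
from .variants import GenotypeCall, VariantRecord, Zygosity, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n > 0 else ""


def simulate_transcript(
    seed,
    n_exons: int = 5,
    exon_length: tuple[int, int] = (30, 120),
    intron_length: tuple[int, int] = (20, 80),
    utr_length: tuple[int, int] = (6, 30),
    pad: int = 50,
    contig: str = "chrS",
    transcript_id: str = "SYN1.1",
    strand: str = "+",
) -> TranscriptModel:
    """Generate a valid protein-coding transcript model with contig sequence.

    The CDS begins with ATG, contains no in-frame internal stop, and
    ends with a stop codon; introns carry GT..AG ends so canonical
    splice-site variants have correct reference bases.
    """
    rng = _rng(seed)
    if n_exons < 1:
        raise ValueError("need at least one exon")
    if intron_length[0] < 4:
        raise ValueError("introns must be at least 4 bp for GT..AG ends")
    exon_lens = rng.integers(exon_length[0], exon_length[1] + 1, size=n_exons)
    total = int(exon_lens.sum())
    u5 = int(rng.integers(utr_length[0], utr_length[1] + 1))
    u3 = int(rng.integers(utr_length[0], utr_length[1] + 1))
    cds_len = total - u5 - u3
    cds_len -= cds_len % 3
    if cds_len < 9:
        raise ValueError("exon lengths leave no room for a CDS; increase exon_length")
    u3 = total - u5 - cds_len
    n_codons = cds_len // 3
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    cds = "ATG" + "".join(body) + str(rng.choice(_STOPS))
    spliced = _random_seq(rng, u5) + cds + _random_seq(rng, u3)

    # lay exons onto the contig
    exons: list[tuple[int, int]] = []
    contig_parts: list[str] = [_random_seq(rng, pad)]
    gpos = pad
    offset = 0
    for i, L in enumerate(exon_lens):
        start = gpos + 1
        end = gpos + int(L)
        exons.append((start, end))
        contig_parts.append(spliced[offset : offset + int(L)])
        offset += int(L)
        gpos = end
        if i < n_exons - 1:
            ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
            contig_parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            gpos += ilen
    contig_parts.append(_random_seq(rng, pad))
    contig_seq = "".join(contig_parts)

    # spliced index -> genomic position (plus strand layout)
    def g_of(t_index: int) -> int:
        off = 0
        for s, e in exons:
            n = e - s + 1
            if t_index <= off + n:
                return s + (t_index - off - 1)
            off += n
        raise AssertionError

    model = TranscriptModel(
        id=transcript_id,
        contig=contig,
        strand="+",
        exons=tuple(exons),
        cds_start=g_of(u5 + 1),
        cds_end=g_of(u5 + cds_len),
        sequence=spliced,
        contig_sequence=contig_seq,
    )
    model.validate_cds()
    if strand == "-":
        model = mirror_transcript(model)
        model.validate_cds()
    return model


def mirror_transcript(t: TranscriptModel) -> TranscriptModel:
    """Reverse-complement mirror of a transcript on the opposite strand.

    Genomic coordinates flip around the contig; the spliced transcript
    sequence is unchanged.  Requires ``contig_sequence``.
    """
    if t.contig_sequence is None:
        raise ValueError("mirroring requires the contig sequence")
    L = len(t.contig_sequence)
    flip = lambda p: L - p + 1  # noqa: E731
    exons = tuple(sorted((flip(e), flip(s)) for s, e in t.exons))
    lo, hi = flip(t.cds_end), flip(t.cds_start)
    return TranscriptModel(
        id=t.id,
        contig=t.contig,
        strand="-" if t.strand == "+" else "+",
        exons=exons,
        cds_start=lo,
        cds_end=hi,
        sequence=t.sequence,
        contig_sequence=revcomp(t.contig_sequence),
    )


def mirror_variant(t: TranscriptModel, v: VariantRecord) -> VariantRecord:
    """The variant's image under ``mirror_transcript`` of ``t``'s contig."""
    if t.contig_sequence is None:
        raise ValueError("mirroring requires the contig sequence")
    L = len(t.contig_sequence)
    new_pos = L - (v.pos + len(v.ref) - 1) + 1
    return VariantRecord(
        contig=v.contig, pos=new_pos, ref=revcomp(v.ref), alt=revcomp(v.alt), id=v.id
    )


# -- cohort simulation -------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Generating conditions for a synthetic case-control cohort.

    Defaults mirror the study conditions of the analysis this package
    targets: 2,366 cases at a carrier frequency of ~1.5% against large
    control panels at ~0.07%, carriers heterozygous for a single PTV,
    ages truncated-normal with mean 53 and SD 17, minimum 17 years.
    """

    seed: int
    n_cases: int = 2366
    n_controls: int = 22448
    carrier_freq_case: float = 0.0152
    carrier_freq_control: float = 0.00071
    qc_fail_rate: float = 0.0
    common_variant_rate: float = 0.0
    decoy_rate: float = 0.05
    multi_variant_rate: float = 0.0
    age_mean: float = 53.0
    age_sd: float = 17.0
    age_min: float = 17.0
    age_max: float = 99.0
    male_fraction: float = 0.66

    def __post_init__(self) -> None:
        for name in (
            "carrier_freq_case",
            "carrier_freq_control",
            "qc_fail_rate",
            "common_variant_rate",
            "decoy_rate",
            "multi_variant_rate",
            "male_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")

    @property
    def true_odds_ratio(self) -> float:
        p, q = self.carrier_freq_case, self.carrier_freq_control
        return (p / (1 - p)) / (q / (1 - q))


@dataclass
class SyntheticCohort:
    """A simulated cohort with its generating truth.

    ``genotypes`` is a long-format table (sample_id, contig, pos, ref,
    alt, zygosity, allele_depth, total_depth); ``truth`` records each
    sample's generated carrier status before QC corruption.
    """

    config: SimulationConfig
    transcript: TranscriptModel
    manifest: pd.DataFrame
    genotypes: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame

    def genotype_calls(self) -> list[GenotypeCall]:
        return [
            GenotypeCall(
                sample_id=r.sample_id,
                variant=VariantRecord(contig=r.contig, pos=int(r.pos), ref=r.ref, alt=r.alt),
                zygosity=Zygosity(r.zygosity),
                allele_depth=int(r.allele_depth),
                total_depth=int(r.total_depth),
            )
            for r in self.genotypes.itertuples(index=False)
        ]


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        out[need] = draw
        need = (out < lo) | (out > hi)
    return np.round(out).astype(int)


def _passing_depths(rng: np.random.Generator) -> tuple[int, int]:
    """AD/DP for a QC-passing het: DP around 60, AD binomial(DP, 0.5)."""
    dp = int(rng.integers(45, 81))
    for _ in range(100):
        ad = int(rng.binomial(dp, 0.5))
        if ad >= 20 and ad / dp >= 0.25:
            return ad, dp
    return 30, 60


def _failing_depths(rng: np.random.Generator) -> tuple[int, int]:
    """AD/DP guaranteed to fail QC: low depth, or adequate depth at low VAF."""
    if rng.random() < 0.5:
        ad = int(rng.integers(1, 20))
        dp = int(rng.integers(max(ad, 30), 81))
        return ad, dp
    ad = int(rng.integers(20, 30))
    dp = int(rng.integers(5 * ad, 8 * ad))  # VAF <= 0.20
    return ad, dp


def simulate_cohort(
    cfg: SimulationConfig,
    t: TranscriptModel,
    variant_pool: Sequence[VariantRecord],
    decoy_pool: Sequence[VariantRecord] = (),
) -> SyntheticCohort:
    """Draw a case-control cohort under the configured generating process.

    Each sample is independently a carrier at its panel's frequency;
    carriers receive one pool PTV as a heterozygous genotype with
    QC-passing depths (unless selected for corruption).  Decoy variants
    are sprinkled at ``decoy_rate`` per sample, and a
    ``common_variant_rate`` fraction of pool variants is annotated with
    MAF >= 0.1% so it fails the rarity filter downstream.
    """
    if not variant_pool:
        raise ValueError("variant pool must be non-empty")
    rng = _rng(cfg.seed)
    panels = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    n = len(panels)
    sample_ids = [
        f"{'CASE' if p == 'case' else 'CTRL'}{i:06d}" for i, p in enumerate(panels, 1)
    ]
    p_vec = np.where(
        np.array(panels) == "case", cfg.carrier_freq_case, cfg.carrier_freq_control
    )
    is_carrier = rng.random(n) < p_vec
    ages = _truncated_normal(rng, n, cfg.age_mean, cfg.age_sd, cfg.age_min, cfg.age_max)
    sexes = np.where(rng.random(n) < cfg.male_fraction, "male", "female")

    manifest = pd.DataFrame(
        {"sample_id": sample_ids, "panel": panels, "age": ages, "sex": sexes}
    ).set_index("sample_id")

    pool = list(variant_pool)
    decoys = list(decoy_pool)
    # vectorized assignment draws; per-genotype depth sampling only for
    # the (sparse) samples that actually receive a genotype
    carrier_idx = np.flatnonzero(is_carrier)
    first_variant = rng.integers(len(pool), size=carrier_idx.size)
    second_mask = rng.random(carrier_idx.size) < cfg.multi_variant_rate
    second_variant = rng.integers(len(pool), size=carrier_idx.size)
    decoy_mask = (rng.random(n) < cfg.decoy_rate) if decoys else np.zeros(n, dtype=bool)
    decoy_variant = rng.integers(len(decoys) if decoys else 1, size=n)

    rows: list[dict] = []

    def _add(sample_i: int, v: VariantRecord, may_fail: bool) -> None:
        corrupted = may_fail and rng.random() < cfg.qc_fail_rate
        ad, dp = _failing_depths(rng) if corrupted else _passing_depths(rng)
        rows.append(
            {
                "sample_id": sample_ids[sample_i],
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "zygosity": "het",
                "allele_depth": ad,
                "total_depth": dp,
            }
        )

    for j, i in enumerate(carrier_idx):
        _add(int(i), pool[int(first_variant[j])], may_fail=True)
        if second_mask[j]:
            _add(int(i), pool[int(second_variant[j])], may_fail=True)
    for i in np.flatnonzero(decoy_mask):
        _add(int(i), decoys[int(decoy_variant[i])], may_fail=False)

    genotypes = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "contig", "pos", "ref", "alt",
            "zygosity", "allele_depth", "total_depth",
        ],
    )
    truth = pd.DataFrame(
        {"sample_id": sample_ids, "true_carrier": is_carrier}
    ).set_index("sample_id")
    truth.attrs["true_odds_ratio"] = cfg.true_odds_ratio

    all_variants = pool + decoys
    is_common = rng.random(len(pool)) < cfg.common_variant_rate
    ann_rows = []
    for i, v in enumerate(all_variants):
        common = bool(is_common[i]) if i < len(pool) else False
        ann_rows.append(
            {
                "variant": v.token,
                "population_maf": 0.005 if common else 0.0,
                "clinvar_id": "",
                "previously_reported": False,
            }
        )
    annotations = pd.DataFrame(ann_rows).set_index("variant")
    return SyntheticCohort(
        config=cfg,
        transcript=t,
        manifest=manifest,
        genotypes=genotypes,
        annotations=annotations,
        truth=truth,
    )


def default_variant_pools(
    t: TranscriptModel, seed: int = 0, n_ptv: int = 8, n_decoy: int = 8
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Draw a PTV pool (verified by the consequence engine) and a non-PTV
    decoy pool (synonymous/missense/intronic) from a transcript."""
    from .transcripts import Consequence, classify_consequence

    if t.contig_sequence is None:
        raise ValueError("pool drawing requires the contig sequence")
    rng = _rng(seed)
    seq = t.contig_sequence
    cds_positions = [
        g
        for s, e in t.exons
        for g in range(s, e + 1)
        if (tp := t.g2t(g)) is not None and t.tx_cds_start + 3 <= tp <= t.tx_cds_end - 3
    ]
    ptvs: dict[str, VariantRecord] = {}
    decoys: dict[str, VariantRecord] = {}
    for _ in range(20000):
        if len(ptvs) >= n_ptv and len(decoys) >= n_decoy:
            break
        g = int(rng.choice(cds_positions))
        ref = seq[g - 1]
        if rng.random() < 0.5:
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v = VariantRecord(contig=t.contig, pos=g, ref=ref, alt=alt)
        else:  # 1-2 bp deletion with anchor base
            k = int(rng.integers(1, 3))
            v = VariantRecord(contig=t.contig, pos=g, ref=seq[g - 1 : g + k], alt=ref)
        call = classify_consequence(t, v)
        if call.is_ptv and len(ptvs) < n_ptv:
            ptvs.setdefault(v.token, v)
        elif call.consequence in (
            Consequence.missense,
            Consequence.synonymous,
            Consequence.inframe_indel,
        ) and len(decoys) < n_decoy:
            decoys.setdefault(v.token, v)
    if len(ptvs) < n_ptv or len(decoys) < n_decoy:
        raise RuntimeError("could not assemble variant pools; use a longer transcript")
    return list(ptvs.values()), list(decoys.values())
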