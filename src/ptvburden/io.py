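"""Reading and writing the pipeline's file formats.

Genotypes travel either as a multi-sample VCF 4.2 with GT:AD:DP fields
(read back through pysam, multi-allelic sites decomposed to biallelic
records) or as a long-format TSV.  Annotations and manifests are TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd
import pysam

from .filtering import VariantAnnotation
from .variants import VariantRecord

PathLike = Union[str, Path]

GENOTYPE_COLUMNS = [
    "sample_id", "contig", "pos", "ref", "alt",
    "zygosity", "allele_depth", "total_depth",
]


def write_vcf(
    genotypes: pd.DataFrame,
    path: PathLike,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a long-format genotype table as a multi-sample VCF 4.2.

    Samples without a genotype at a site get ``./.``; AD is emitted as
    ``ref_depth,alt_depth`` with ref depth derived as DP - alt depth.
    """
    samples = sorted(genotypes["sample_id"].unique())
    sites = (
        genotypes[["contig", "pos", "ref", "alt"]]
        .drop_duplicates()
        .sort_values(["contig", "pos", "ref", "alt"])
        .reset_index(drop=True)
    )
    by_site: dict[tuple, dict[str, tuple]] = {}
    for r in genotypes.itertuples(index=False):
        key = (r.contig, int(r.pos), r.ref, r.alt)
        gt = "1/1" if r.zygosity == "hom" else ("1" if r.zygosity == "hemi" else "0/1")
        by_site.setdefault(key, {})[r.sample_id] = (
            gt, int(r.total_depth) - int(r.allele_depth), int(r.allele_depth), int(r.total_depth)
        )
    lines = ["##fileformat=VCFv4.2", "##source=ptvburden"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in sites["contig"].unique():
            lines.append(f"##contig=<ID={name}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for r in sites.itertuples(index=False):
        key = (r.contig, int(r.pos), r.ref, r.alt)
        cells = []
        for s in samples:
            if s in by_site.get(key, {}):
                gt, rd, ad, dp = by_site[key][s]
                cells.append(f"{gt}:{rd},{ad}:{dp}")
            else:
                cells.append("./.")
        lines.append(
            f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT:AD:DP\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_genotypes(path: PathLike) -> pd.DataFrame:
    """Read a multi-sample VCF into the long-format genotype table.

    Multi-allelic sites are decomposed into biallelic records; samples
    with missing genotypes are skipped.  AD per record is the depth of
    that record's alternate allele.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt in ("*", "<NON_REF>"):
                    continue
                for sample, sdata in rec.samples.items():
                    gt = sdata.get("GT")
                    if gt is None or all(g is None for g in gt):
                        continue
                    n_alt = sum(1 for g in gt if g == ai)
                    if n_alt == 0:
                        continue
                    if len(gt) == 1:
                        zyg = "hemi"
                    else:
                        zyg = "hom" if n_alt == len(gt) else "het"
                    ad_field = sdata.get("AD")
                    ad = int(ad_field[ai]) if ad_field is not None and ad_field[ai] is not None else 0
                    dp = sdata.get("DP")
                    if dp is None and ad_field is not None:
                        dp = sum(int(x) for x in ad_field if x is not None)
                    rows.append(
                        {
                            "sample_id": sample,
                            "contig": rec.chrom,
                            "pos": rec.pos,
                            "ref": rec.ref,
                            "alt": alt,
                            "zygosity": zyg,
                            "allele_depth": ad,
                            "total_depth": int(dp or 0),
                        }
                    )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def read_genotypes_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "contig": str})
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype TSV missing columns: {sorted(missing)}")
    return df[GENOTYPE_COLUMNS]


def write_genotypes_tsv(genotypes: pd.DataFrame, path: PathLike) -> None:
    genotypes[GENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: PathLike) -> dict[str, VariantAnnotation]:
    """Annotation TSV keyed by ``chrom-pos-ref-alt`` token."""
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "clinvar_id": str})
    out: dict[str, VariantAnnotation] = {}
    for r in df.itertuples(index=False):
        v = VariantRecord.from_token(r.variant)
        maf = getattr(r, "population_maf", None)
        clinvar = getattr(r, "clinvar_id", None)
        if isinstance(clinvar, float) or clinvar in ("", "nan", None):
            clinvar = None
        out[v.token] = VariantAnnotation(
            variant=v,
            population_maf=None if maf is None or pd.isna(maf) else float(maf),
            clinvar_id=clinvar,
            previously_reported=bool(getattr(r, "previously_reported", False)),
        )
    return out


def read_manifest_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("manifest TSV requires a sample_id column")
    return df.set_index("sample_id")


def write_manifest_tsv(manifest: pd.DataFrame, path: PathLike) -> None:
    manifest.to_csv(path, sep="\t")


# -- transcript model input --------------------------------------------------


def read_transcript_tsv(path: PathLike) -> "TranscriptModel":
    """Compact transcript fixture format: ``##key=value`` metadata lines
    (id, contig, strand, cds_start, cds_end, sequence, optionally
    contig_sequence) followed by a header and one exon interval per row.
    """
    from .transcripts import TranscriptModel

    meta: dict[str, str] = {}
    exons: list[tuple[int, int]] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            meta[key.strip()] = val.strip()
        elif not header_seen:
            header_seen = True  # "start\tend" header row
        else:
            s, e = line.split("\t")[:2]
            exons.append((int(s), int(e)))
    required = {"id", "contig", "strand", "cds_start", "cds_end", "sequence"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"transcript TSV missing metadata: {sorted(missing)}")
    return TranscriptModel(
        id=meta["id"],
        contig=meta["contig"],
        strand=meta["strand"],
        exons=tuple(sorted(exons)),
        cds_start=int(meta["cds_start"]),
        cds_end=int(meta["cds_end"]),
        sequence=meta["sequence"].upper(),
        contig_sequence=meta.get("contig_sequence", "").upper() or None,
    )


def write_transcript_tsv(t: "TranscriptModel", path: PathLike) -> None:
    lines = [
        f"##id={t.id}",
        f"##contig={t.contig}",
        f"##strand={t.strand}",
        f"##cds_start={t.cds_start}",
        f"##cds_end={t.cds_end}",
        f"##sequence={t.sequence}",
    ]
    if t.contig_sequence:
        lines.append(f"##contig_sequence={t.contig_sequence}")
    lines.append("start\tend")
    lines += [f"{s}\t{e}" for s, e in t.exons]
    Path(path).write_text("\n".join(lines) + "\n")


def read_transcript_gff3(
    gff_path: PathLike, fasta_path: PathLike, transcript_id: Optional[str] = None
) -> "TranscriptModel":
    """Build a transcript model from a GFF3 subset (exon + CDS features)
    and a contig FASTA.  One transcript per file unless ``transcript_id``
    narrows the Parent attribute."""
    from pyfaidx import Fasta

    from .transcripts import TranscriptModel
    from .variants import revcomp

    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(gff_path, sep="\t", comment="#", names=cols, dtype={"seqid": str})
    if transcript_id is not None:
        df = df[df["attributes"].str.contains(transcript_id, regex=False)]
    exon_rows = df[df["type"] == "exon"]
    cds_rows = df[df["type"] == "CDS"]
    if exon_rows.empty or cds_rows.empty:
        raise ValueError("GFF3 must contain exon and CDS features")
    contig = exon_rows["seqid"].iloc[0]
    strand = exon_rows["strand"].iloc[0]
    exons = tuple(sorted((int(r.start), int(r.end)) for r in exon_rows.itertuples()))
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    contig_seq = str(fa[contig][:])
    spliced = "".join(contig_seq[s - 1 : e] for s, e in exons)
    if strand == "-":
        spliced = revcomp(spliced)
    tid = transcript_id
    if tid is None:
        import re as _re

        m = _re.search(r"Parent=([^;]+)", exon_rows["attributes"].iloc[0])
        tid = m.group(1) if m else "transcript"
    return TranscriptModel(
        id=tid,
        contig=contig,
        strand=strand,
        exons=exons,
        cds_start=int(cds_rows["start"].min()),
        cds_end=int(cds_rows["end"].max()),
        sequence=spliced,
        contig_sequence=contig_seq,
    )
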