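"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ go through Biopython. The locus table is JSON (canonical) or a
compact TSV; the variant table is TSV (a small VCF reader is available when
cyvcf2/pyfaidx are installed). Logos are plain TSV matrices and predictions
are JSON. TSV dialect: UTF-8, tab-separated, '#'-prefixed header line.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._sequences import normalize_dna
from .model import (
    CasGene,
    CasLocus,
    CrisprArray,
    GenomeRecord,
    PamLogo,
    PamPrediction,
    ProtospacerMatch,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_RETAINED_SIGNIFICANCE = {"pathogenic", "likely-pathogenic", "likely pathogenic"}
MAX_INDEL_LEN = 10


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path, source: str = "") -> list[GenomeRecord]:
    """Read a multi-FASTA into GenomeRecords; lowercase and ambiguity codes
    are normalized (non-ACGT -> N). Duplicate ids and empty sequences error."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_dna(str(rec.seq))
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        records.append(GenomeRecord(id=rec.id, sequence=seq, source=source))
    return records


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_protein_fasta(path) -> dict[str, str]:
    """Protein FASTA as an id -> uppercase amino-acid string mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty protein sequence for {rec.id!r}")
        out[rec.id] = seq
    return out


def write_protein_fasta(proteins: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")


def read_fastq_sequences(path) -> list[str]:
    """Sequences (only) of a FASTQ file, normalized to uppercase ACGTN."""
    seqs = [normalize_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
    if not seqs:
        raise ValueError(f"no reads in FASTQ {path}")
    return seqs


# ---------------------------------------------------------------------------
# Locus table
# ---------------------------------------------------------------------------

def _locus_to_dict(locus: CasLocus) -> dict:
    return {
        "locus_id": locus.locus_id,
        "contig_id": locus.contig_id,
        "contig_length": locus.contig_length,
        "subtype": locus.subtype,
        "cas9_protein": locus.cas9_protein,
        "cas_genes": [
            {"name": g.name, "start": g.start, "end": g.end, "strand": g.strand}
            for g in locus.cas_genes
        ],
        "arrays": [
            {
                "array_id": a.array_id,
                "start": a.start,
                "end": a.end,
                "orientation": a.orientation,
                "units": [{"repeat": r, "spacer": s} for r, s in a.units],
            }
            for a in locus.arrays
        ],
    }


def _locus_from_dict(d: dict) -> CasLocus:
    for col in ("locus_id", "contig_id", "cas9_protein", "cas_genes", "arrays"):
        if col not in d:
            raise KeyError(f"locus table record missing mandatory field {col!r}")
    genes = [
        CasGene(name=g["name"], start=int(g["start"]), end=int(g["end"]), strand=g["strand"])
        for g in d["cas_genes"]
    ]
    arrays = [
        CrisprArray(
            array_id=a["array_id"],
            units=[
                (normalize_dna(u["repeat"]), normalize_dna(u["spacer"]) if u.get("spacer") else None)
                for u in a["units"]
            ],
            start=int(a.get("start", 0)),
            end=int(a.get("end", 0)),
            orientation=a.get("orientation", "as-annotated"),
        )
        for a in d["arrays"]
    ]
    return CasLocus(
        locus_id=d["locus_id"],
        contig_id=d["contig_id"],
        cas_genes=genes,
        arrays=arrays,
        cas9_protein=d["cas9_protein"].upper(),
        subtype=d.get("subtype", "unknown"),
        contig_length=d.get("contig_length"),
    )


def read_locus_table(path) -> list[CasLocus]:
    """Read a locus annotation table (JSON canonical, TSV accepted).

    Malformed records are skipped with a warning naming the record number;
    a missing mandatory column raises immediately.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        raw = _read_locus_tsv_rows(path)
    else:
        with open(path) as fh:
            doc = json.load(fh)
        raw = doc["loci"] if isinstance(doc, dict) else doc
    loci: list[CasLocus] = []
    for i, rec in enumerate(raw, start=1):
        try:
            loci.append(_locus_from_dict(rec))
        except KeyError:
            raise
        except (ValueError, TypeError) as exc:
            logger.warning("locus table %s: record %d skipped: %s", path, i, exc)
    return loci


def write_locus_table(loci: Iterable[CasLocus], path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        _write_locus_tsv(loci, path)
        return
    with open(path, "w") as fh:
        json.dump({"loci": [_locus_to_dict(l) for l in loci]}, fh, indent=1)
        fh.write("\n")


_LOCUS_TSV_COLS = [
    "locus_id", "contig_id", "contig_length", "subtype", "cas9_protein", "cas_genes", "arrays",
]


def _write_locus_tsv(loci: Iterable[CasLocus], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_LOCUS_TSV_COLS) + "\n")
        for l in loci:
            genes = ";".join(f"{g.name}:{g.start}-{g.end}:{g.strand}" for g in l.cas_genes)
            arrays = ";".join(
                f"{a.array_id}:{a.start}-{a.end}:{a.orientation}:"
                + ",".join(f"{r}|{s or ''}" for r, s in a.units)
                for a in l.arrays
            )
            fh.write(
                "\t".join(
                    [
                        l.locus_id,
                        l.contig_id,
                        "" if l.contig_length is None else str(l.contig_length),
                        l.subtype,
                        l.cas9_protein,
                        genes,
                        arrays,
                    ]
                )
                + "\n"
            )


def _read_locus_tsv_rows(path: Path) -> list[dict]:
    rows: list[dict] = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line[1:].split("\t")
                continue
            if header is None:
                raise ValueError(f"{path}:{lineno}: missing '#' header line")
            fields = dict(zip(header, line.split("\t")))
            for col in _LOCUS_TSV_COLS[:2] + _LOCUS_TSV_COLS[4:]:
                if col not in fields:
                    raise KeyError(f"{path}:{lineno}: missing mandatory column {col!r}")
            genes = []
            for chunk in fields["cas_genes"].split(";"):
                name, span, strand = chunk.split(":")
                start, end = span.split("-")
                genes.append({"name": name, "start": start, "end": end, "strand": strand})
            arrays = []
            for chunk in fields["arrays"].split(";"):
                aid, span, orientation, units_s = chunk.split(":")
                start, end = span.split("-")
                units = []
                for u in units_s.split(","):
                    rep, _, sp = u.partition("|")
                    units.append({"repeat": rep, "spacer": sp or None})
                arrays.append(
                    {
                        "array_id": aid,
                        "start": start,
                        "end": end,
                        "orientation": orientation,
                        "units": units,
                    }
                )
            rows.append(
                {
                    "locus_id": fields["locus_id"],
                    "contig_id": fields["contig_id"],
                    "contig_length": int(fields["contig_length"]) if fields.get("contig_length") else None,
                    "subtype": fields.get("subtype", "unknown"),
                    "cas9_protein": fields["cas9_protein"],
                    "cas_genes": genes,
                    "arrays": arrays,
                }
            )
    return rows


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------

def _normalize_significance(s: str) -> str:
    s = s.strip().lower().replace("_", " ")
    if s == "pathogenic":
        return "pathogenic"
    if s in {"likely pathogenic", "likely-pathogenic"}:
        return "likely-pathogenic"
    return "other"


def variant_passes_filters(significance: str, ref: str, alt: str, inheritance: str) -> Optional[str]:
    """Return the exclusion reason, or None if the record is retained.

    Retained records are pathogenic or likely-pathogenic SNVs and short
    indels (length change of 10 nt or less) with a known mode of inheritance.
    """
    if _normalize_significance(significance) == "other":
        return "significance"
    if abs(len(alt) - len(ref)) > MAX_INDEL_LEN:
        return "indel-length"
    if not inheritance.strip():
        return "inheritance"
    return None


def read_variant_table(path) -> list[VariantRecord]:
    """Read the variant TSV, applying the significance/indel/inheritance
    filters; exclusion counts are logged by reason."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, keep_default_na=False)
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    required = {"variant_id", "ref", "alt", "significance", "inheritance", "window_seq", "window_offset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path} missing columns: {sorted(missing)}")
    kept: list[VariantRecord] = []
    excluded: dict[str, int] = {}
    for row in df.itertuples(index=False):
        ref = normalize_dna(row.ref)
        alt = normalize_dna(row.alt)
        reason = variant_passes_filters(row.significance, ref, alt, row.inheritance)
        if reason is not None:
            excluded[reason] = excluded.get(reason, 0) + 1
            continue
        try:
            kept.append(
                VariantRecord(
                    variant_id=row.variant_id,
                    ref=ref,
                    alt=alt,
                    significance=_normalize_significance(row.significance),
                    inheritance=row.inheritance.strip(),
                    window_seq=normalize_dna(row.window_seq),
                    window_offset=int(row.window_offset),
                )
            )
        except ValueError as exc:
            logger.warning("variant table %s: %s", path, exc)
            excluded["window-mismatch"] = excluded.get("window-mismatch", 0) + 1
    for reason, n in sorted(excluded.items()):
        logger.info("variant table %s: %d records excluded (%s)", path, n, reason)
    return kept


def write_variant_table(variants: Iterable[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#variant_id\tref\talt\tsignificance\tinheritance\twindow_seq\twindow_offset\n")
        for v in variants:
            fh.write(
                f"{v.variant_id}\t{v.ref}\t{v.alt}\t{v.significance}\t{v.inheritance}\t"
                f"{v.window_seq}\t{v.window_offset}\n"
            )


def read_variant_vcf(vcf_path, fasta_path, flank: int = 30) -> list[VariantRecord]:
    """Optional VCF reader: SNVs and short indels with CLNSIG/INHERITANCE
    INFO fields, context windows extracted from the reference FASTA."""
    from cyvcf2 import VCF
    from pyfaidx import Fasta

    ref_fa = Fasta(str(fasta_path))
    kept: list[VariantRecord] = []
    for var in VCF(str(vcf_path)):
        if var.ALT is None or len(var.ALT) != 1:
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        significance = str(var.INFO.get("CLNSIG", "") or "")
        inheritance = str(var.INFO.get("INHERITANCE", "") or "")
        if variant_passes_filters(significance, ref, alt, inheritance) is not None:
            continue
        pos0 = var.POS - 1
        w_start = max(0, pos0 - flank)
        w_end = pos0 + len(ref) + flank
        window = normalize_dna(str(ref_fa[var.CHROM][w_start:w_end]))
        kept.append(
            VariantRecord(
                variant_id=var.ID or f"{var.CHROM}:{var.POS}:{ref}>{alt}",
                ref=normalize_dna(ref),
                alt=normalize_dna(alt),
                significance=_normalize_significance(significance),
                inheritance=inheritance,
                window_seq=window,
                window_offset=pos0 - w_start,
            )
        )
    return kept


# ---------------------------------------------------------------------------
# Matches, logos, predictions
# ---------------------------------------------------------------------------

_MATCH_COLS = [
    "spacer_id", "genome_id", "strand", "start", "end", "mismatches", "gaps", "up_flank", "down_flank",
]


def write_matches(matches: Iterable[ProtospacerMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_MATCH_COLS) + "\n")
        for m in matches:
            fh.write(
                f"{m.spacer_id}\t{m.genome_id}\t{m.strand}\t{m.start}\t{m.end}\t"
                f"{m.mismatches}\t{m.gaps}\t{m.up_flank}\t{m.down_flank}\n"
            )


def read_matches(path) -> list[ProtospacerMatch]:
    out: list[ProtospacerMatch] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                ProtospacerMatch(
                    spacer_id=f[0], genome_id=f[1], strand=f[2],
                    start=int(f[3]), end=int(f[4]),
                    mismatches=int(f[5]), gaps=int(f[6]),
                    up_flank=f[7] if len(f) > 7 else "",
                    down_flank=f[8] if len(f) > 8 else "",
                )
            )
    return out


def write_logo(logo: PamLogo, path) -> None:
    """Logo as a TSV matrix: anchored position, A/C/G/T frequency, coverage,
    information in bits."""
    info = logo.information
    with open(path, "w") as fh:
        fh.write(f"#side={logo.side}\n")
        fh.write("#position\tA\tC\tG\tT\tcoverage\tinfo_bits\n")
        for i, pos in enumerate(logo.positions):
            a, c, g, t = logo.freqs[i]
            fh.write(
                f"{pos}\t{a:.10g}\t{c:.10g}\t{g:.10g}\t{t:.10g}\t"
                f"{logo.coverage[i]}\t{info[i]:.10g}\n"
            )


def read_logo(path) -> PamLogo:
    side = None
    positions: list[int] = []
    freqs: list[list[float]] = []
    coverage: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#side="):
                side = line.split("=", 1)[1]
                continue
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            positions.append(int(f[0]))
            freqs.append([float(x) for x in f[1:5]])
            coverage.append(int(f[5]))
    if side is None:
        raise ValueError(f"logo file {path} missing '#side=' line")
    return PamLogo(side=side, positions=positions, freqs=np.array(freqs).reshape(len(positions), 4),
                   coverage=np.array(coverage, dtype=int))


def prediction_to_dict(pred: PamPrediction) -> dict:
    return {
        "cluster_id": pred.cluster_id,
        "status": pred.status,
        "side": pred.side,
        "conserved_positions": sorted([s, int(p)] for s, p in pred.conserved_positions),
        "threshold": pred.threshold,
        "floor_bits": pred.floor_bits,
        "q3": pred.q3,
        "iqr": pred.iqr,
        "consensus": pred.consensus,
        "n_spacers": pred.n_spacers,
        "reason": pred.reason,
    }


def write_predictions(preds: Iterable[PamPrediction], path) -> None:
    with open(path, "w") as fh:
        json.dump([prediction_to_dict(p) for p in preds], fh, indent=1)
        fh.write("\n")
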