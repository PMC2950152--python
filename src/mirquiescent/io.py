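"""Readers and writers for the flat-file formats the pipeline touches.

Every writer emits a leading ``#`` comment recording the package version and,
when supplied, a configuration hash, so stage outputs are self-describing.
Readers skip ``#`` comment lines.  CT tables may be TSV or CSV (by
extension); everything else is TSV.  Genomic annotations come in as GFF3 or
as 6-column BED plus a band column; BED starts are shifted to the internal
1-based inclusive convention on load.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

from . import __version__
from .containers import (
    CtMatrix,
    DysregulationCall,
    LocusSet,
    MirGeneAnnotation,
    SampleTable,
    TargetCatalog,
)
from .errors import FormatError, ParseError

#: Cell tokens interpreted as "no amplification" in CT tables.
DEFAULT_SENTINELS = ("Undetermined", "NA", "NaN", "")


def _header_comment(config_hash: str | None = None) -> str:
    tag = f"# mirquiescent v{__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag + "\n"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# CT matrix
# ---------------------------------------------------------------------------

def read_ct_table(
    path: str | Path,
    sentinel_tokens: Sequence[str] = DEFAULT_SENTINELS,
    reference_id: str = "U6",
) -> CtMatrix:
    """Read a miRNAs × samples CT table.

    The first column holds miRNA ids, the header row sample ids.  Cells are
    numeric CT values or one of ``sentinel_tokens``, which map to the
    no-amplification sentinel (NaN) and are later treated as CT ≥ the
    detection cut-off.
    """
    sep = _sep_for(path)
    sentinels = set(sentinel_tokens)
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            rows.append(next(csv.reader([line], delimiter=sep)))
    if not rows:
        raise FormatError(f"{path}: empty CT table")
    header = rows[0]
    sample_ids = header[1:]
    mirna_ids = []
    data = np.full((len(rows) - 1, len(sample_ids)), np.nan)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {row[0]!r} has {len(row)} fields, expected {len(header)}"
            )
        mirna_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in sentinels:
                continue
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at "
                    f"(miRNA {row[0]!r}, sample {sample_ids[j]!r})"
                ) from None
    frame = pd.DataFrame(data, index=mirna_ids, columns=sample_ids)
    return CtMatrix(frame, reference_id=reference_id)


def write_ct_table(
    path: str | Path,
    ct: CtMatrix,
    sentinel_token: str = "Undetermined",
    config_hash: str | None = None,
) -> None:
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write(sep.join(["mirna_id", *ct.sample_ids]) + "\n")
        for mid, row in ct.values.iterrows():
            cells = [
                sentinel_token if math.isnan(v) else format(v, ".6g")
                for v in row.to_numpy()
            ]
            fh.write(sep.join([str(mid), *cells]) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read the TSV of sample_id / subject_id / group / state / grade."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "subject_id", "group", "state"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df.set_index("sample_id")
    return SampleTable(df)


def write_sample_metadata(
    path: str | Path, samples: SampleTable, config_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        out = samples.frame.reset_index(names="sample_id")
        out.to_csv(fh, sep="\t", index=False, float_format="%g")


# ---------------------------------------------------------------------------
# miRNA gene annotation (GFF3 or BED+band)
# ---------------------------------------------------------------------------

def read_mirna_annotation(path: str | Path) -> list[MirGeneAnnotation]:
    """Read miRNA gene records from GFF3 (``.gff``/``.gff3``) or BED+band.

    GFF3 coordinates are already 1-based inclusive and are taken as-is; BED
    lines (chrom, start, end, name, score, strand, band) are half-open
    0-based and are shifted by +1 on start.  GFF3 attributes must carry
    ``gene_id`` (falls back to ``ID``), ``band``, and optionally ``mirna_id``.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_annotation_gff3(path)
    return _read_annotation_bed(path)


def _read_annotation_gff3(path: Path) -> list[MirGeneAnnotation]:
    out = []
    for feat in DataIterator(str(path)):
        attrs = feat.attributes
        gene_id = (attrs.get("gene_id") or attrs.get("ID") or [None])[0]
        if gene_id is None:
            raise FormatError(f"{path}: GFF3 record without gene_id/ID")
        band = (attrs.get("band") or [None])[0]
        if not band:
            raise FormatError(f"{path}: record {gene_id!r} lacks a band attribute")
        mirna_id = (attrs.get("mirna_id") or [gene_id])[0]
        out.append(
            MirGeneAnnotation(
                gene_id=gene_id,
                mirna_id=mirna_id,
                chromosome=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand or ".",
                band=band,
            )
        )
    return out


def _read_annotation_bed(path: Path) -> list[MirGeneAnnotation]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(
                    f"{path}:{ln}: expected 7 fields (BED6 + band), got {len(fields)}"
                )
            chrom, start, end, name, _score, strand, band = fields[:7]
            out.append(
                MirGeneAnnotation(
                    gene_id=name,
                    mirna_id=name,
                    chromosome=chrom,
                    start=int(start) + 1,  # BED half-open 0-based → 1-based closed
                    end=int(end),
                    strand=strand,
                    band=band,
                )
            )
    return out


def write_annotation_gff3(
    path: str | Path,
    annotation: Iterable[MirGeneAnnotation],
    config_hash: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_comment(config_hash))
        for rec in annotation:
            attrs = (
                f"ID={rec.gene_id};gene_id={rec.gene_id};"
                f"mirna_id={rec.mirna_id};band={rec.band}"
            )
            fh.write(
                "\t".join(
                    [
                        rec.chromosome,
                        "mirquiescent",
                        "miRNA_gene",
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_annotation_bed(
    path: str | Path, annotation: Iterable[MirGeneAnnotation]
) -> None:
    """Write BED6+band (half-open 0-based), the inverse of the BED reader."""
    with open(path, "w") as fh:
        for rec in annotation:
            fh.write(
                "\t".join(
                    [
                        rec.chromosome,
                        str(rec.start - 1),
                        str(rec.end),
                        rec.gene_id,
                        "0",
                        rec.strand,
                        rec.band,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Susceptibility loci
# ---------------------------------------------------------------------------

def read_locus_bed(path: str | Path) -> LocusSet:
    """Read a BED-like locus file: chrom, start, end, locus_id[, source]."""
    recs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: need chrom/start/end/name")
            source = fields[4] if len(fields) > 4 else "linkage"
            recs.append(
                {
                    "locus_id": fields[3],
                    "chromosome": fields[0],
                    "start": int(fields[1]) + 1,
                    "end": int(fields[2]),
                    "source": source,
                }
            )
    frame = pd.DataFrame(
        recs, columns=["locus_id", "chromosome", "start", "end", "source"]
    ).set_index("locus_id")
    return LocusSet(frame)


def write_locus_bed(path: str | Path, loci: LocusSet) -> None:
    with open(path, "w") as fh:
        for lid, row in loci.frame.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(row["chromosome"]),
                        str(int(row["start"]) - 1),
                        str(int(row["end"])),
                        str(lid),
                        str(row["source"]),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Target catalog and gene → process table
# ---------------------------------------------------------------------------

def read_target_catalog(path: str | Path) -> TargetCatalog:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] == 2:
        df.columns = ["mirna_id", "gene_id"]
    else:
        df = df.iloc[:, :3]
        df.columns = ["mirna_id", "gene_id", "score"]
    return TargetCatalog(df)


def write_target_catalog(
    path: str | Path, catalog: TargetCatalog, config_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        catalog.pairs.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_process_table(path: str | Path) -> pd.DataFrame:
    """Read the two-column gene_id / process TSV (one row per membership)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = ["gene_id", "process"]
    return df


def write_process_table(path: str | Path, table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dysregulation calls
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "condition",
    "mirna_id",
    "mean_log_fold",
    "sd_log_fold",
    "direction",
    "p_value",
    "passes_cutoff",
    "significant",
    "n",
]


def write_calls(
    path: str | Path,
    calls: Sequence[DysregulationCall],
    config_hash: str | None = None,
) -> None:
    """Write calls as TSV in deterministic order (condition, then miRNA id)."""
    rows = sorted(calls, key=lambda c: (c.condition, c.mirna_id))
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                "\t".join(
                    [
                        c.condition,
                        c.mirna_id,
                        format(c.mean_log_fold, ".10g"),
                        format(c.sd_log_fold, ".10g"),
                        c.direction,
                        format(c.p_value, ".10g"),
                        str(c.passes_cutoff),
                        str(c.significant),
                        str(c.n),
                    ]
                )
                + "\n"
            )


def read_calls(path: str | Path) -> list[DysregulationCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            DysregulationCall(
                mirna_id=str(row["mirna_id"]),
                condition=str(row["condition"]),
                mean_log_fold=float(row["mean_log_fold"]),
                sd_log_fold=float(row["sd_log_fold"]),
                direction=str(row["direction"]),
                p_value=float(row["p_value"]),
                passes_cutoff=bool(row["passes_cutoff"]),
                significant=bool(row["significant"]),
                n=int(row["n"]),
            )
        )
    return out
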