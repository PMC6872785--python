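"""Readers and writers for the formats the analysis stages exchange.

Coordinates are 1-based inclusive in every file (IMGT and CDS conventions)
and 0-based internally; the conversion lives here.  Split symbols are
written in ASCII (``S1``/``S2`` etc.); Unicode prime spellings are accepted
on read.  Real-valued matrices round-trip at 6 decimal places, integer
matrices exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .genetic_code import SplitConfig, normalize_symbol
from .phospho import PhosphoSite, SNVRecord
from .repertoire import ReceptorRecord
from .split_blosum import AlignmentBlock


class ParseError(ValueError):
    """Malformed input file; the message names the offending record."""


def read_alignment(path, codon_mode: bool = True) -> AlignmentBlock:
    """Aligned FASTA -> AlignmentBlock; validates length and alphabet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty FASTA")
    sequences, ids = [], []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGT-")
        if bad:
            raise ParseError(f"{path}: record {rec.id} has invalid characters {sorted(bad)}")
        if codon_mode and len(seq) % 3 != 0:
            raise ParseError(f"{path}: record {rec.id} length {len(seq)} breaks codon frame")
        sequences.append(seq)
        ids.append(rec.id)
    if len({len(s) for s in sequences}) != 1:
        raise ParseError(f"{path}: records have unequal lengths")
    return AlignmentBlock(sequences, ids)


def write_alignment(block: AlignmentBlock, path) -> None:
    with open(path, "w") as fh:
        ids = block.ids or [f"seq{i}" for i in range(len(block.sequences))]
        for name, seq in zip(ids, block.sequences):
            fh.write(f">{name}\n{seq}\n")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Matrix TSV: symbol header row/column; 6-decimal reals, exact ints."""
    if matrix.shape[0] == 0:
        raise ValueError("refusing to write a matrix with an empty alphabet")
    out = matrix.copy()
    if not all(np.issubdtype(d, np.integer) for d in out.dtypes):
        out = out.round(6)
    out.to_csv(path, sep="\t", index_label="symbol")


def read_matrix(path, alphabet=None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = [normalize_symbol(str(s)) for s in frame.index]
    frame.columns = [normalize_symbol(str(s)) for s in frame.columns]
    if alphabet is not None and set(frame.index) != set(alphabet):
        raise ParseError(f"{path}: alphabet mismatch on read-back")
    return frame


def read_snv_table(path, dialect: str = "tsv") -> list[SNVRecord]:
    """SNV records from a flat TSV or a VCF whose CHROM is the CDS id.

    TSV columns: ``cds_id  position  ref  alt  quality`` (quality ``PASS``
    for high quality).  VCF: CHROM/POS/REF/ALT/FILTER, with POS interpreted
    as the 1-based CDS coordinate; FILTER other than PASS/. marks the record
    low quality.  The two dialects yield identical records for the same
    content.
    """
    if dialect == "vcf":
        from cyvcf2 import VCF
        out = []
        for var in VCF(str(path)):
            if var.ALT is None or len(var.ALT) == 0:
                continue
            for alt in var.ALT:
                if len(var.REF) != 1 or len(alt) != 1:
                    continue  # indels/MNVs out of scope
                out.append(SNVRecord(var.CHROM, var.POS, var.REF, alt,
                                     high_quality=var.FILTER is None))
        return out
    if dialect != "tsv":
        raise ValueError(f"unknown SNV dialect: {dialect}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("cds_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            quality = fields[4] if len(fields) > 4 else "PASS"
            try:
                out.append(SNVRecord(fields[0], int(fields[1]), fields[2].upper(),
                                     fields[3].upper(), high_quality=quality == "PASS"))
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from err
    return out


def write_snv_table(snvs: list[SNVRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("cds_id\tposition\tref\talt\tquality\n")
        for s in snvs:
            fh.write(f"{s.cds_id}\t{s.position}\t{s.ref}\t{s.alt}\t"
                     f"{'PASS' if s.high_quality else 'lowq'}\n")


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_cds_fasta(cds_set: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in cds_set.items():
            fh.write(f">{name}\n{seq}\n")


def read_phosphosites(path) -> list[PhosphoSite]:
    """Phosphosite TSV: ``cds_id  position  residue  [codon]``."""
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        out.append(PhosphoSite(str(row.cds_id), int(row.position),
                               str(row.residue),
                               str(getattr(row, "codon", "") or "")))
    return out


def write_phosphosites(sites: list[PhosphoSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("cds_id\tposition\tresidue\tcodon\n")
        for s in sites:
            fh.write(f"{s.cds_id}\t{s.position}\t{s.residue}\t{s.codon}\n")


def read_repertoire_table(path) -> list[ReceptorRecord]:
    """AIRR-rearrangement-like TSV -> receptor records."""
    frame = pd.read_csv(path, sep="\t")
    required = {"individual", "sequence", "germline", "v_call", "j_call", "cdr3_length"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(ReceptorRecord(
            str(row.individual), str(row.sequence), str(row.germline),
            str(row.v_call), str(row.j_call), int(row.cdr3_length),
            int(getattr(row, "imgt_start", 1))))
    return out


def read_region_mask(path) -> dict[int, str]:
    """BED-like TSV of 1-based inclusive intervals: ``start  end  label``.

    Returns 0-based position -> label.
    """
    labels: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("start"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected start, end, label")
            start, end, label = int(fields[0]), int(fields[1]), fields[2]
            for pos in range(start - 1, end):
                labels[pos] = label
    return labels


def profiles_to_frame(profiles, groups=None) -> pd.DataFrame:
    """Per-position TSV payload: depth, diversity, meaningful set, fractions."""
    from .enrichment import GS2N, S1PA, fraction_from_profile
    groups = groups or (GS2N, S1PA)
    rows = []
    for pr in profiles:
        row = {
            "position": pr.position + 1,
            "depth": pr.depth,
            "diversity": round(pr.diversity, 6),
            "n_meaningful": pr.n_meaningful,
            "meaningful_set": "".join(sorted(pr.meaningful_set())),
            "serine_meaningful": pr.serine_meaningful,
        }
        for g in groups:
            row[f"{g.name}_fraction"] = round(fraction_from_profile(pr, g), 6)
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    """YAML run configuration; round-trips through save_config."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return config


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def split_config_from(config: dict) -> SplitConfig:
    return SplitConfig(
        split_serine=bool(config.get("split_serine", True)),
        split_leucine=bool(config.get("split_leucine", False)),
        split_arginine=bool(config.get("split_arginine", False)),
    )
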