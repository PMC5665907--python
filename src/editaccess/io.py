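"""File-format dialects for the pipeline.

Conventions: BED intervals are 0-based half-open; the VCF-like site table is
1-based.  All tables are plain TSV.  Text inputs with CRLF line endings are
accepted and normalised; malformed lines are rejected with their line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sitecall import EditingSite, FilterResult, MismatchObservation

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_pileup",
    "write_pileup",
    "write_site_table",
    "read_site_table",
    "read_expression",
    "write_expression",
    "read_dotbracket",
    "write_dotbracket",
    "load_config_yaml",
    "dump_config_yaml",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
PILEUP_COLUMNS = [
    "gene", "pos0", "strand", "ref", "alt", "depth", "alt_count", "quals", "read_pos",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                header_note: str = "") -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=header_note)
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-style track (3-6 columns, 0-based half-open)."""
    rows = []
    with open(path, newline=None) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from err
            if start < 0 or end < start:
                raise ValueError(f"{path}: line {lineno}: invalid interval")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else ".",
                    "score": parts[4] if len(parts) > 4 else ".",
                    "strand": parts[5] if len(parts) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    df = intervals.copy()
    for col in BED_COLUMNS:
        if col not in df.columns:
            df[col] = "."
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _parse_int_list(field: str) -> tuple[int, ...]:
    field = field.strip()
    if not field or field == ".":
        return ()
    return tuple(int(x) for x in field.split(","))


def read_pileup(path: str | Path) -> list[MismatchObservation]:
    """Read a TSV pileup table into mismatch observations."""
    obs = []
    with open(path, newline=None) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        has_individual = "individual" in header
        expected = PILEUP_COLUMNS + (["individual"] if has_individual else [])
        if header != expected:
            raise ValueError(f"{path}: line 1: expected columns {expected}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(expected):
                raise ValueError(f"{path}: line {lineno}: wrong number of fields")
            try:
                obs.append(
                    MismatchObservation(
                        contig=parts[0],
                        pos0=int(parts[1]),
                        strand=parts[2],
                        ref=parts[3],
                        alt=parts[4],
                        depth=int(parts[5]),
                        alt_count=int(parts[6]),
                        quals=_parse_int_list(parts[7]),
                        read_pos=_parse_int_list(parts[8]),
                        individual=parts[9] if has_individual else "",
                    )
                )
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from err
    return obs


def write_pileup(observations: Iterable[MismatchObservation], path: str | Path,
                 with_individual: bool = True) -> None:
    cols = PILEUP_COLUMNS + (["individual"] if with_individual else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for o in observations:
            row = [
                o.contig, str(o.pos0), o.strand, o.ref, o.alt,
                str(o.depth), str(o.alt_count),
                ",".join(map(str, o.quals)) or ".",
                ",".join(map(str, o.read_pos)) or ".",
            ]
            if with_individual:
                row.append(o.individual or ".")
            fh.write("\t".join(row) + "\n")


def write_site_table(results: Sequence[FilterResult], path: str | Path,
                     contexts: Mapping[str, str] | None = None) -> None:
    """VCF-like site table: 1-based POS, REF/ALT, INFO-style columns."""
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\tSTRAND\tDEPTH\tALT_COUNT\tLEVEL\tLLR"
                 "\tCONTEXT\tPASS\tREJECT_REASONS\n")
        for res in results:
            o = res.observation
            key = f"{o.contig}:{o.pos0}"
            ctx = (contexts or {}).get(key, ".")
            fh.write(
                "\t".join(
                    [
                        o.contig,
                        str(o.pos0 + 1),
                        o.ref,
                        o.alt,
                        o.strand,
                        str(o.depth),
                        str(o.alt_count),
                        f"{o.level:.4f}" if o.depth else ".",
                        f"{res.llr:.3f}",
                        ctx,
                        "PASS" if res.passed else "FAIL",
                        ",".join(res.failures) or ".",
                    ]
                )
                + "\n"
            )


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"#CHROM": "CHROM"})
    df["pos0"] = df["POS"] - 1
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes (rows) x individuals (columns) expression matrix."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_dotbracket(path: str | Path) -> list[tuple[str, str, str]]:
    """Vienna-format records: (name, sequence, structure)."""
    records = []
    with open(path, newline=None) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: record {len(records) + 1}: missing '>' header")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record {lines[i]!r}")
        name = lines[i][1:].split()[0]
        seq, struct = lines[i + 1], lines[i + 2].split()[0]
        if len(seq) != len(struct):
            raise ValueError(f"{path}: record {name}: sequence/structure length mismatch")
        records.append((name, seq, struct))
        i += 3
    return records


def write_dotbracket(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, struct in records:
            fh.write(f">{name}\n{seq}\n{struct}\n")


def load_config_yaml(path: str | Path) -> dict:
    with open(path, newline=None) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return data


def dump_config_yaml(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
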