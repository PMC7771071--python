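"""Readers and writers for on-disk formats.

No science logic lives here.  Coordinate conventions are enforced at this
boundary: VCF positions are 1-based on disk and converted to 0-based on the
way in; BED and PAF are 0-based half-open and pass through unchanged.  All
in-memory intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

log = logging.getLogger(__name__)

MARKER_COLUMNS = [
    "marker_id", "contig", "kind", "start", "end",
    "ref", "alt", "alt_depth", "total_depth",
]

OBSERVATION_COLUMNS = ["gamete", "marker_id", "ref_count", "alt_count"]
DELETION_OBS_COLUMNS = ["gamete", "marker_id", "read_count", "rpkm"]


class VcfParseError(ValueError):
    """Raised for a structurally invalid VCF line; carries the line number."""


@dataclass(frozen=True)
class SnpCandidate:
    """A biallelic SNP candidate read from VCF (position already 0-based)."""

    contig: str
    pos: int
    ref: str
    alt: str
    alt_depth: int
    total_depth: int


@dataclass
class PafAlignment:
    """One long-read alignment with substitutions decoded from the cs tag.

    ``substitutions`` maps 0-based target position -> read base, in target
    coordinates regardless of strand.  ``has_cs`` is False when the aligner
    emitted no cs tag; such records are usable only for overlap tests.
    """

    read_id: str
    read_length: int
    strand: str
    contig: str
    contig_length: int
    target_start: int
    target_end: int
    mapq: int = 60
    score: int = 0
    has_cs: bool = True
    substitutions: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_NUC = set("ACGT")


def read_vcf_candidates(path: str | Path) -> list[SnpCandidate]:
    """Read biallelic SNP candidates from a VCF 4.x file.

    Multiallelic and indel records are skipped (counted and logged), as are
    records without recoverable depth information (INFO DP plus INFO AD, or a
    sample AD field).  Malformed lines raise :class:`VcfParseError` naming the
    line number.
    """
    records: list[SnpCandidate] = []
    n_skipped_type = 0
    n_skipped_depth = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"line {lineno}: expected >= 8 tab-separated fields, got {len(fields)}"
                )
            contig, pos_s, _id, ref, alt = fields[:5]
            info = fields[7]
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise VcfParseError(f"line {lineno}: non-integer POS {pos_s!r}") from exc
            if pos1 < 1:
                raise VcfParseError(f"line {lineno}: POS must be >= 1 (VCF is 1-based), got {pos1}")
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == "." or ref == ".":
                n_skipped_type += 1
                continue
            if ref.upper() not in _NUC or alt.upper() not in _NUC:
                n_skipped_type += 1
                continue
            depths = _extract_depths(info, fields)
            if depths is None:
                n_skipped_depth += 1
                continue
            alt_depth, total_depth = depths
            records.append(
                SnpCandidate(contig, pos1 - 1, ref.upper(), alt.upper(), alt_depth, total_depth)
            )
    if n_skipped_type:
        log.info("skipped %d non-biallelic-SNP VCF records", n_skipped_type)
    if n_skipped_depth:
        log.info("skipped %d VCF records without depth information", n_skipped_depth)
    return records


def _extract_depths(info: str, fields: list[str]) -> tuple[int, int] | None:
    kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
    ad = kv.get("AD")
    dp = kv.get("DP")
    if ad is None and len(fields) >= 10:
        fmt = fields[8].split(":")
        sample = fields[9].split(":")
        fmtmap = dict(zip(fmt, sample))
        ad = fmtmap.get("AD")
        dp = dp or fmtmap.get("DP")
    if ad is not None:
        parts = ad.split(",")
        if len(parts) >= 2:
            try:
                ref_d, alt_d = int(parts[0]), int(parts[1])
            except ValueError:
                return None
            total = int(dp) if dp is not None else ref_d + alt_d
            return alt_d, total
    return None


def write_vcf_candidates(records: list[SnpCandidate], path: str | Path) -> None:
    """Write candidates as a minimal VCF 4.2 body (positions back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            ref_d = r.total_depth - r.alt_depth
            fh.write(
                f"{r.contig}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"DP={r.total_depth};AD={ref_d},{r.alt_depth}\n"
            )


# ---------------------------------------------------------------------------
# PAF with cs tag
# ---------------------------------------------------------------------------

_CS_TOKEN = re.compile(r"(:\d+|\*[a-z]{2}|\+[a-z]+|-[a-z]+|=[A-Za-z]+)")


def decode_cs(cs: str, target_start: int) -> dict[int, str]:
    """Decode a short-form cs difference string into target-position -> read base.

    Only substitutions contribute entries; matches advance the cursor,
    insertions consume read only, deletions consume target only.
    """
    subs: dict[int, str] = {}
    pos = target_start
    consumed = 0
    for m in _CS_TOKEN.finditer(cs):
        tok = m.group(0)
        consumed += len(tok)
        op = tok[0]
        if op == ":":
            pos += int(tok[1:])
        elif op == "=":
            pos += len(tok) - 1
        elif op == "*":
            subs[pos] = tok[2].upper()
            pos += 1
        elif op == "-":
            pos += len(tok) - 1
        # '+' consumes read bases only
    if consumed != len(cs):
        raise ValueError(f"unparseable cs string at offset {consumed}: {cs!r}")
    return subs


def encode_cs(ref_segment: str, substitutions: dict[int, str], target_start: int) -> str:
    """Inverse of :func:`decode_cs` for a pure match/substitution alignment."""
    out: list[str] = []
    run = 0
    for i, base in enumerate(ref_segment):
        pos = target_start + i
        if pos in substitutions:
            if run:
                out.append(f":{run}")
                run = 0
            out.append(f"*{base.lower()}{substitutions[pos].lower()}")
        else:
            run += 1
    if run:
        out.append(f":{run}")
    return "".join(out)


def read_paf_alignments(path: str | Path) -> list[PafAlignment]:
    """Read PAF records, decoding the cs tag where present."""
    records: list[PafAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: truncated PAF line ({len(fields)} fields)")
            cs = None
            score = 0
            for tag in fields[12:]:
                if tag.startswith("cs:Z:"):
                    cs = tag[5:]
                elif tag.startswith("AS:i:"):
                    score = int(tag[5:])
            tstart = int(fields[7])
            rec = PafAlignment(
                read_id=fields[0],
                read_length=int(fields[1]),
                strand=fields[4],
                contig=fields[5],
                contig_length=int(fields[6]),
                target_start=tstart,
                target_end=int(fields[8]),
                mapq=int(fields[11]),
                score=score,
                has_cs=cs is not None,
                substitutions=decode_cs(cs, tstart) if cs is not None else {},
            )
            records.append(rec)
    return records


def write_paf_alignments(records: list[PafAlignment], path: str | Path,
                         ref_bases: dict[int, str] | None = None) -> None:
    """Write PAF records.  Substitutions are re-encoded into a cs tag.

    ``ref_bases`` optionally maps target position -> reference base for
    substitution sites; when absent 'a' placeholders are used for the
    reference side of each substitution (the decoder ignores them).
    """
    with open(path, "w") as fh:
        for r in records:
            span = r.target_end - r.target_start
            cs_parts: list[str] = []
            prev = r.target_start
            for pos in sorted(r.substitutions):
                if pos > prev:
                    cs_parts.append(f":{pos - prev}")
                refb = (ref_bases or {}).get(pos, "a")
                cs_parts.append(f"*{refb.lower()}{r.substitutions[pos].lower()}")
                prev = pos + 1
            if r.target_end > prev:
                cs_parts.append(f":{r.target_end - prev}")
            n_sub = len(r.substitutions)
            fields = [
                r.read_id, str(r.read_length), "0", str(r.read_length), r.strand,
                r.contig, str(r.contig_length), str(r.target_start), str(r.target_end),
                str(span - n_sub), str(span), str(r.mapq),
                f"AS:i:{r.score}",
            ]
            if r.has_cs:
                fields.append("cs:Z:" + "".join(cs_parts))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Tabular formats (TSV)
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_marker_table(markers: pd.DataFrame, path: str | Path) -> None:
    write_tsv(markers[MARKER_COLUMNS], path)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df[MARKER_COLUMNS]


MAP_COLUMNS = ["linkage_group", "order_index", "contig", "end", "cM", "phase"]


def write_genetic_map(gmap, path: str | Path) -> None:
    """Serialize a GeneticMap to TSV (one row per placed map entry)."""
    rows = []
    for gi, group in enumerate(gmap.groups, start=1):
        for oi, entry in enumerate(group.entries):
            rows.append(
                {
                    "linkage_group": gi,
                    "order_index": oi,
                    "contig": entry.contig,
                    "end": entry.end,
                    "cM": entry.cm,
                    "phase": entry.phase,
                }
            )
    write_tsv(pd.DataFrame(rows, columns=MAP_COLUMNS), path)


def read_genetic_map(path: str | Path):
    """Inverse of :func:`write_genetic_map` (bit-exact round trip)."""
    from .genetic_map import GeneticMap, LinkageGroup, MapEntry

    df = read_tsv(path)
    groups = []
    if len(df):
        for _, sub in df.groupby("linkage_group", sort=True):
            sub = sub.sort_values("order_index")
            entries = [
                MapEntry(contig=r.contig, end=r.end, cm=float(r.cM), phase=int(r.phase))
                for r in sub.itertuples()
            ]
            groups.append(LinkageGroup(entries=entries))
    return GeneticMap(groups=groups)


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    yield from read_fasta(path).items()


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write (contig, start, end[, name]) intervals as BED (already 0-based)."""
    cols = [c for c in ("contig", "start", "end", "name") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["contig", "start", "end", "name"][: df.shape[1]]
    return df


def read_config_file(path: str | Path) -> dict[str, str]:
    """Read a simple key=value configuration file (''#'' comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
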