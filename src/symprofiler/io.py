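"""Readers and writers for the external formats the pipeline touches.

All text I/O is UTF-8 with "." as the decimal point. Sequences are
uppercased on read and RNA ``U`` is mapped to ``T`` so that downstream
restriction digestion and identity calculations operate on a DNA alphabet.
Fragment sizes are carried as floats rounded to 0.01 bp, the practical
resolution of capillary sizing.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("symprofiler")

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

SIZE_DECIMALS = 2


class ParseError(ValueError):
    """Raised when an input file violates a format or type invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """A 5'->3' sense-strand nucleotide sequence with a unique id."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: source group and optional location."""

    sample_id: str
    source: str
    location: str | None = None
    n_clones: int | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ParseError("sample with empty sample_id")
        if not self.source:
            raise ParseError(f"sample {self.sample_id!r}: empty source")


@dataclass
class PeakProfile:
    """One electropherogram: ordered (size bp, fluorescence) peaks."""

    sample_id: str
    enzyme: str
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.peaks = sorted(
            (round(float(s), SIZE_DECIMALS), float(f)) for s, f in self.peaks
        )
        sizes = [s for s, _ in self.peaks]
        if len(set(sizes)) != len(sizes):
            raise ParseError(
                f"profile ({self.sample_id}, {self.enzyme}): duplicate peak sizes"
            )
        for s, f in self.peaks:
            if s < 0 or f < 0:
                raise ParseError(
                    f"profile ({self.sample_id}, {self.enzyme}): "
                    f"negative size or fluorescence at {s} bp"
                )

    @property
    def total_fluorescence(self) -> float:
        return sum(f for _, f in self.peaks)


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_seq(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_MANDATORY_META = ("sample_id", "source")


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a tab-separated sample table; unknown columns kept in ``extra``."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        for col in _MANDATORY_META:
            if col not in cols:
                raise ParseError(f"{path}: missing mandatory column {col!r}")
        out: list[SampleMetadata] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            sid = row["sample_id"]
            if sid in seen:
                raise ParseError(f"{path}:{i}: duplicate sample_id {sid!r}")
            seen.add(sid)
            extra = {
                k: v
                for k, v in row.items()
                if k not in ("sample_id", "source", "location", "n_clones")
                and v not in (None, "")
            }
            out.append(
                SampleMetadata(
                    sample_id=sid,
                    source=row["source"],
                    location=row.get("location") or None,
                    n_clones=int(row["n_clones"]) if row.get("n_clones") else None,
                    extra=extra,
                )
            )
    return out


def write_sample_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    extra_cols = sorted({k for s in samples for k in s.extra})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "source", "location", "n_clones", *extra_cols])
        for s in samples:
            w.writerow(
                [
                    s.sample_id,
                    s.source,
                    s.location or "",
                    "" if s.n_clones is None else s.n_clones,
                    *[s.extra.get(k, "") for k in extra_cols],
                ]
            )


_PEAK_COLS = ("sample_id", "enzyme", "size_bp", "fluorescence")


def read_peak_table(path: str | Path) -> list[PeakProfile]:
    """Read a GeneScan-style peak table (CSV or TSV, auto-detected)."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        header = fh.readline()
        delim = "\t" if header.count("\t") >= header.count(",") else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = reader.fieldnames or []
        for col in _PEAK_COLS:
            if col not in cols:
                raise ParseError(f"{path}: missing mandatory column {col!r}")
        grouped: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for i, row in enumerate(reader, start=2):
            try:
                size = float(row["size_bp"])
                fluor = float(row["fluorescence"])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-numeric peak field") from exc
            if size < 0 or fluor < 0:
                raise ParseError(
                    f"{path}:{i}: negative size or fluorescence "
                    f"({row['sample_id']}, {row['enzyme']})"
                )
            grouped.setdefault((row["sample_id"], row["enzyme"]), []).append(
                (size, fluor)
            )
    return [
        PeakProfile(sample_id=sid, enzyme=enz, peaks=peaks)
        for (sid, enz), peaks in grouped.items()
    ]


def write_peak_table(profiles: Iterable[PeakProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_PEAK_COLS)
        for p in profiles:
            for size, fluor in p.peaks:
                w.writerow([p.sample_id, p.enzyme, f"{size:.2f}", repr(fluor)])


def read_newick(path: str | Path, id_universe: set[str] | None = None) -> dendropy.Tree:
    """Read a newick tree with branch lengths; tips outside ``id_universe`` warn."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: malformed newick ({exc})") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError(f"{path}: negative branch length {edge.length}")
    if id_universe is not None:
        unknown = {t.label for t in tree.taxon_namespace} - id_universe
        if unknown:
            logger.warning("tree tips absent from id universe: %s", sorted(unknown))
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_otu_table(path: str | Path):
    """Read an OTU count table (TSV; rows = OTUs, columns = samples)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{i}: expected 'key = value'")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
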