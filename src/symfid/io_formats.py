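"""Readers and writers for the plain-text formats the pipeline touches.

Everything downstream consumes the domain types defined here: decoded
pileup columns (one reference position of one sample), validated sample
tables (host id, mitochondrial lineage, location), reference genomes, and
square PHYLIP distance matrices.  Coordinates are 1-based inclusive
everywhere at the I/O boundary (the samtools-mpileup convention); internal
arrays are 0-based.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Phred floor applied while decoding pileups; reads below this quality are
#: dropped together with their base call.
DEFAULT_MIN_BASE_QUALITY = 2


class PileupParseError(ValueError):
    """Raised when an mpileup line cannot be decoded; names the line number."""


@dataclass(frozen=True)
class PileupColumn:
    """Observed bases and Phred qualities at one reference position.

    The pipeline's atomic input: strand is already collapsed (everything
    uppercased), indel blocks and read start/end markers are stripped, and
    only the four unambiguous bases remain.
    """

    sample_id: str
    ref_name: str
    pos: int  # 1-based
    bases: tuple[str, ...]
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")
        for b in self.bases:
            if b not in BASE_INDEX:
                raise ValueError(f"base {b!r} outside alphabet {ALPHABET}")

    @property
    def depth(self) -> int:
        return len(self.bases)

    def base_counts(self) -> np.ndarray:
        """Counts of A, C, G, T at this column."""
        out = np.zeros(4, dtype=np.int64)
        for b in self.bases:
            out[BASE_INDEX[b]] += 1
        return out


@dataclass(frozen=True)
class ReferenceGenome:
    """A named reference sequence (symbiont MAG or host mitochondrion role)."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError("reference sequence must be non-empty")
        if not set(self.seq) <= set("ACGTN"):
            raise ValueError("reference sequence restricted to A,C,G,T,N")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SampleTable:
    """Host sample metadata: id, mitochondrial lineage (A/B) and location.

    ``group`` is derived deterministically as ``"<lineage>|<location>"``.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "lineage", "location")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dup))}")
        bad = set(self.frame["lineage"]) - {"A", "B"}
        if bad:
            raise ValueError(f"lineage must be 'A' or 'B', got {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True).copy()
        self.frame["group"] = (
            self.frame["lineage"].astype(str) + "|" + self.frame["location"].astype(str)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def lineage_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["lineage"].iloc[0])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleTable(keep[list(self.REQUIRED)])

    def groups(self) -> dict[str, list[str]]:
        """Sample ids per ``lineage|location`` group."""
        return {
            g: list(sub["sample_id"])
            for g, sub in self.frame.groupby("group", sort=True)
        }


# ---------------------------------------------------------------------------
# mpileup
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def _decode_base_string(
    bases: str, quals: str, ref_base: str, line_no: int
) -> tuple[list[str], list[int]]:
    """Decode one mpileup base string against its quality string.

    Supported dialect: ``.``/``,`` (reference base), ``ACGTacgt``, ``^X``
    read-start markers, ``$`` read-end markers, ``+N<seq>``/``-N<seq>``
    indel blocks (the inserted/deleted sequence is skipped -- the analysis
    is substitution-only), and ``*``/``N`` placeholders which are dropped
    together with their quality.
    """
    out_bases: list[str] = []
    out_quals: list[int] = []
    ref = ref_base.upper()
    i = 0  # index into bases
    j = 0  # index into quals
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if m is None:
                raise PileupParseError(f"line {line_no}: malformed indel block")
            length = int(m.group(1))
            i = m.end() + length
            continue
        # every remaining code consumes one quality character
        if j >= len(quals):
            raise PileupParseError(
                f"line {line_no}: base/quality length mismatch after decoding"
            )
        q = ord(quals[j]) - 33
        j += 1
        i += 1
        if c in ".,":
            if ref in BASE_INDEX:
                out_bases.append(ref)
                out_quals.append(q)
            # reference-matching read against an N reference: drop
            continue
        cu = c.upper()
        if cu in BASE_INDEX:
            out_bases.append(cu)
            out_quals.append(q)
        elif cu in "*N":
            continue
        else:
            raise PileupParseError(f"line {line_no}: unsupported base code {c!r}")
    if j != len(quals):
        raise PileupParseError(
            f"line {line_no}: base/quality length mismatch after decoding"
        )
    return out_bases, out_quals


def read_pileup(
    stream: TextIO | str,
    sample_id: str,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list[PileupColumn]:
    """Parse samtools-mpileup text into decoded :class:`PileupColumn` s.

    Bases with Phred quality below ``min_base_quality`` are dropped, and
    positions left with zero surviving bases are omitted entirely.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    columns: list[PileupColumn] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            raise PileupParseError(
                f"line {line_no}: expected 6 columns, got {len(fields)}"
            )
        ref_name, pos_s, ref_base, depth_s, base_str, qual_str = fields[:6]
        try:
            pos = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise PileupParseError(f"line {line_no}: bad integer field") from exc
        if depth == 0:
            continue
        bases, quals = _decode_base_string(base_str, qual_str, ref_base, line_no)
        keep = [(b, q) for b, q in zip(bases, quals) if q >= min_base_quality]
        if not keep:
            continue
        columns.append(
            PileupColumn(
                sample_id=sample_id,
                ref_name=ref_name,
                pos=pos,
                bases=tuple(b for b, _ in keep),
                quals=tuple(q for _, q in keep),
            )
        )
    return columns


def write_pileup(columns: Iterable[PileupColumn], ref: ReferenceGenome) -> str:
    """Encode decoded columns back to mpileup text (explicit base letters).

    Decoding the output with :func:`read_pileup` at ``min_base_quality=0``
    reproduces the input columns exactly (involution property).
    """
    lines = []
    for col in columns:
        base_str = "".join(col.bases)
        qual_str = "".join(chr(min(q, 93) + 33) for q in col.quals)
        ref_base = ref.seq[col.pos - 1]
        lines.append(
            f"{col.ref_name}\t{col.pos}\t{ref_base}\t{col.depth}\t{base_str}\t{qual_str}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------


def read_sample_table(stream: TextIO | str) -> SampleTable:
    """Read a delimited (TSV/CSV) sample table with header
    ``sample_id, lineage, location``."""
    if isinstance(stream, str) and "\n" not in stream:
        frame = pd.read_csv(stream, sep=None, engine="python", dtype=str)
    else:
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        frame = pd.read_csv(stream, sep=None, engine="python", dtype=str)
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path_or_buf) -> None:
    table.frame[list(SampleTable.REQUIRED) + ["group"]].to_csv(
        path_or_buf, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------


def write_phylip_distances(labels: Sequence[str], D: np.ndarray) -> str:
    """Serialize a square distance matrix in full (square) PHYLIP format.

    Round-trips with :func:`read_phylip_distances` at 10 significant digits.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"matrix must be square, got shape {D.shape}")
    if len(labels) != D.shape[0]:
        raise ValueError("label count must match matrix dimension")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    lines = [str(len(labels))]
    for label, row in zip(labels, D):
        vals = " ".join(format(v, ".10g") for v in row)
        lines.append(f"{label} {vals}")
    return "\n".join(lines) + "\n"


def read_phylip_distances(stream: TextIO | str) -> tuple[list[str], np.ndarray]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    tokens_lines = [ln.split() for ln in stream if ln.strip()]
    n = int(tokens_lines[0][0])
    labels: list[str] = []
    rows: list[list[float]] = []
    for tok in tokens_lines[1 : n + 1]:
        labels.append(tok[0])
        rows.append([float(v) for v in tok[1 : n + 1]])
    D = np.array(rows, dtype=float)
    if D.shape != (n, n):
        raise ValueError("malformed PHYLIP distance matrix")
    return labels, D


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path_or_buf) -> list[ReferenceGenome]:
    return [
        ReferenceGenome(name=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(path_or_buf, "fasta")
    ]


def write_fasta(genomes: Iterable[ReferenceGenome], path_or_buf) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.name, description="") for g in genomes
    ]
    SeqIO.write(records, path_or_buf, "fasta")
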