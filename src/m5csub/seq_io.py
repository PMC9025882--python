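"""Reading standard genomic formats and extracting C-centered sequence windows.

All internal coordinates are 0-based half-open.  BED is consumed natively;
GTF exon records (1-based inclusive) are converted on read.  DNA input is
normalized to RNA (T -> U, uppercase) at ingestion so that every downstream
encoder works over the alphabet {A, C, G, U, N}.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO

RNA_ALPHABET = "ACGUN"
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (input may be DNA or RNA)."""
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSite:
    """A single cytosine position on a chromosome or transcript.

    ``chrom`` holds either a chromosome name (genomic coordinates) or a
    transcript id (transcript coordinates); ``kind`` records provenance:
    methylated site, regulator-bound site, in-vitro-transcription artifact,
    or prediction candidate.
    """

    chrom: str
    position: int
    strand: str = "+"
    kind: str = "m5c"
    name: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"site position must be >= 0, got {self.position}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass(frozen=True)
class PeakInterval:
    """A regulator-binding (CLIP) interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."


@dataclass
class TranscriptModel:
    """A transcript: ordered exons on a chromosome plus (optional) sequence.

    ``exons`` are 0-based half-open genomic intervals, sorted by genomic
    start, non-overlapping.  ``spliced_seq`` is the mature (exon-joined)
    RNA in transcript orientation; ``premrna_seq`` is the unspliced span,
    also transcript-oriented.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    spliced_seq: str | None = None
    premrna_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"transcript {self.transcript_id}: empty exon [{s},{e})")
        if self.spliced_seq is not None and len(self.spliced_seq) != self.spliced_length:
            raise ValueError(
                f"transcript {self.transcript_id}: spliced sequence length "
                f"{len(self.spliced_seq)} != exon total {self.spliced_length}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def sequence(self, model_kind: str) -> str:
        """Transcript-oriented sequence: spliced for ``mature_mrna``,
        unspliced for ``full_transcript``."""
        if model_kind == "mature_mrna":
            if self.spliced_seq is None:
                raise ValueError(f"{self.transcript_id}: no spliced sequence attached")
            return self.spliced_seq
        if model_kind == "full_transcript":
            if self.premrna_seq is None:
                raise ValueError(f"{self.transcript_id}: no pre-mRNA sequence attached")
            return self.premrna_seq
        raise ValueError(f"unknown model kind {model_kind!r}")

    def contains(self, position: int) -> bool:
        lo, hi = self.span
        return lo <= position < hi

    def in_exon(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)

    def genomic_to_spliced(self, position: int) -> int | None:
        """Map a genomic coordinate to a 0-based spliced (mature) coordinate,
        in transcript orientation; None if the position is intronic."""
        offset = 0
        for s, e in self.exons:
            if s <= position < e:
                plus_coord = offset + (position - s)
                if self.strand == "+":
                    return plus_coord
                return self.spliced_length - 1 - plus_coord
            offset += e - s
        return None

    def genomic_to_premrna(self, position: int) -> int | None:
        """Map a genomic coordinate to a 0-based pre-mRNA coordinate in
        transcript orientation; None if outside the transcript span."""
        lo, hi = self.span
        if not (lo <= position < hi):
            return None
        if self.strand == "+":
            return position - lo
        return (hi - 1) - position

    def genomic_to_model(self, position: int, model_kind: str) -> int | None:
        if model_kind == "mature_mrna":
            return self.genomic_to_spliced(position)
        return self.genomic_to_premrna(position)


@dataclass
class LabeledWindow:
    """A fixed-length RNA window centered on a candidate cytosine."""

    sequence: str
    label: int
    transcript_id: str = "."
    regulator: str = "."
    window_id: str = "."
    position: int = -1  # center coordinate in its source (transcript space)

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 == 0:
            raise ValueError("window length must be odd")

    @property
    def center_index(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center_base(self) -> str:
        return self.sequence[self.center_index]


def _as_text_handle(source: str | IO) -> IO:
    """Open a path (plain or gzip) or pass through a text handle."""
    if hasattr(source, "read"):
        first = source
        # binary handle: sniff gzip magic
        if isinstance(first.read(0), bytes):  # type: ignore[union-attr]
            data = first.read()
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            return io.StringIO(data.decode())
        return first
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_bed_line(line: str, lineno: int) -> tuple[str, int, int, str, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"BED line {lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise ValueError(f"BED line {lineno}: non-integer coordinate") from exc
    name = fields[3] if len(fields) > 3 else "."
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
    return chrom, start, end, name, strand


def _bed_records(stream: str | IO) -> Iterator[tuple[int, tuple[str, int, int, str, str]]]:
    handle = _as_text_handle(stream)
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, _parse_bed_line(line, lineno)


def read_sites(stream: str | IO, kind: str = "m5c") -> list[GenomicSite]:
    """Read single-base sites from BED3+; the interval start is the site
    position.  Strand defaults to '+' when column 6 is absent."""
    sites = []
    for _, (chrom, start, _end, name, strand) in _bed_records(stream):
        sites.append(GenomicSite(chrom, start, strand, kind=kind, name=name))
    return sites


def read_intervals(stream: str | IO) -> list[PeakInterval]:
    """Read full intervals (e.g. CLIP peaks) from BED3+."""
    return [
        PeakInterval(chrom, start, end, strand, name)
        for _, (chrom, start, end, name, strand) in _bed_records(stream)
    ]


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_fasta(stream: str | IO) -> dict[str, str]:
    """Read FASTA into {id: RNA-normalized sequence}."""
    handle = _as_text_handle(stream)
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")}


def read_transcripts(gtf_stream: str | IO, fasta_stream: str | IO) -> list[TranscriptModel]:
    """Assemble transcript models from GTF exon features plus a genome FASTA.

    The spliced sequence is built in transcript orientation: exon slices are
    concatenated 5'->3' genomically and reverse-complemented for '-' strand
    transcripts.  GTF coordinates (1-based inclusive) are converted to
    0-based half-open.
    """
    genome = read_fasta(fasta_stream)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    handle = _as_text_handle(gtf_stream)
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"GTF line {lineno}: expected 9 fields")
        chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
        if feature != "exon":
            continue
        attrs = _parse_gtf_attributes(attr)
        tid = attrs.get("transcript_id")
        if tid is None:
            raise ValueError(f"GTF line {lineno}: exon without transcript_id")
        try:
            iv = (int(start) - 1, int(end))
        except ValueError as exc:
            raise ValueError(f"GTF line {lineno}: non-integer coordinate") from exc
        exons.setdefault(tid, []).append(iv)
        meta[tid] = (chrom, strand)

    transcripts = []
    for tid, ivs in exons.items():
        chrom, strand = meta[tid]
        if chrom not in genome:
            raise ValueError(f"transcript {tid}: chromosome {chrom!r} missing from FASTA")
        chrom_seq = genome[chrom]
        ivs = sorted(ivs)
        plus_spliced = "".join(chrom_seq[s:e] for s, e in ivs)
        lo, hi = ivs[0][0], ivs[-1][1]
        plus_pre = chrom_seq[lo:hi]
        if strand == "-":
            spliced = reverse_complement(plus_spliced)
            pre = reverse_complement(plus_pre)
        else:
            spliced = plus_spliced
            pre = plus_pre
        transcripts.append(
            TranscriptModel(tid, chrom, strand, ivs, spliced_seq=spliced, premrna_seq=pre)
        )
    return transcripts


def extract_window(sequence: str, center: int, flank: int) -> str:
    """Extract a (2*flank + 1)-nt window centered at ``center``.

    Positions beyond the sequence ends are padded with 'N', so the result
    always has the declared length.  Output is RNA-normalized.
    """
    if not 0 <= center < len(sequence):
        raise IndexError(
            f"center {center} out of range for sequence of length {len(sequence)}"
        )
    seq = normalize_rna(sequence)
    lo = center - flank
    hi = center + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    return "N" * left_pad + seq[max(0, lo) : min(len(seq), hi)] + "N" * right_pad


def write_labeled_fasta(windows: Iterable[LabeledWindow], handle_or_path: str | IO) -> None:
    """Write labeled windows as FASTA with self-contained headers
    ``id|label|transcript|regulator``."""
    own = not hasattr(handle_or_path, "write")
    handle = open(handle_or_path, "w") if own else handle_or_path
    try:
        for w in windows:
            handle.write(f">{w.window_id}|{w.label}|{w.transcript_id}|{w.regulator}\n")
            handle.write(w.sequence + "\n")
    finally:
        if own:
            handle.close()


def read_labeled_fasta(stream: str | IO) -> list[LabeledWindow]:
    """Inverse of :func:`write_labeled_fasta`."""
    handle = _as_text_handle(stream)
    windows = []
    for rec in SeqIO.parse(handle, "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"labeled FASTA header {rec.description!r}: expected id|label|transcript|regulator"
            )
        wid, label, tid, regulator = parts
        windows.append(
            LabeledWindow(
                sequence=normalize_rna(str(rec.seq)),
                label=int(label),
                transcript_id=tid,
                regulator=regulator,
                window_id=wid,
            )
        )
    return windows
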