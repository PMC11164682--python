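"""Demultiplexing and trimming of splinkerette-PCR junction reads.

Splinkerette libraries amplify transposon-genome junctions: each read is
expected to start with a sample barcode, followed by the transposon-end tag
(the stretch of inverted terminal repeat carried into the amplicon), then
the genomic fragment, optionally running into the splinkerette adaptor at
the 3' end.  Processing recovers the genomic fragment: assign the read to a
sample by its barcode prefix, strip the transposon tag, cut at the adaptor,
and discard fragments that are still transposon sequence (internal
re-amplification products).

Barcode and tag matching is prefix-anchored Hamming distance — splinkerette
primers put these elements at fixed offsets, so indel-tolerant matching
would only add ambiguity.  Reads matching zero or several barcodes within
the mismatch budget are left unassigned rather than force-assigned, which
avoids sample bleed-through at the cost of a few lost reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class SequenceRead:
    id: str
    bases: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("read has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError("quality string length differs from sequence length")


@dataclass(frozen=True)
class AdaptorConfig:
    """Library structure: barcodes, transposon tag, adaptor, enzyme site.

    ``restriction_site`` (default GATC, Sau3AI) records how fragment ends
    were generated; it is metadata only — sequencing often stops before the
    adaptor, so fragments are not required to end in it.
    """

    barcode_table: Mapping[str, str]
    transposon_tag: str
    adaptor_tail: str = ""
    restriction_site: str = "GATC"
    max_mismatches: int = 1
    transposon_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        barcodes = list(self.barcode_table.values())
        if any(not b for b in barcodes):
            raise ValueError("empty barcode")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes for different samples")
        object.__setattr__(self, "barcode_table", dict(self.barcode_table))


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    sample_id: str
    fragment: str
    transposon_end: str = "PB3"
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.fragment:
            raise ValueError("trimmed read has empty fragment")


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # no_transposon_tag | empty_fragment | transposon_only


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[SequenceRead], config: AdaptorConfig
) -> tuple[dict[str, list[SequenceRead]], list[SequenceRead]]:
    """Assign reads to samples by barcode prefix; strip the barcode.

    A read goes to the unique sample whose barcode matches the read prefix
    within ``max_mismatches``; zero or multiple matches leave it unassigned
    (returned untrimmed).  Assignment is per-read, hence order-invariant.
    """
    assigned: dict[str, list[SequenceRead]] = {s: [] for s in config.barcode_table}
    unassigned: list[SequenceRead] = []
    items = list(config.barcode_table.items())
    for read in reads:
        hits = []
        for sample, barcode in items:
            if len(read.bases) >= len(barcode) and (
                hamming(read.bases[: len(barcode)], barcode) <= config.max_mismatches
            ):
                hits.append((sample, len(barcode)))
        if len(hits) != 1:
            unassigned.append(read)
            continue
        sample, blen = hits[0]
        rest = read.bases[blen:]
        if not rest:
            unassigned.append(read)
            continue
        quals = read.qualities[blen:] if read.qualities is not None else None
        assigned[sample].append(SequenceRead(read.id, rest, quals))
    return assigned, unassigned


def trim_read(
    read: SequenceRead, config: AdaptorConfig, sample_id: str = ""
) -> TrimmedRead | Rejection:
    """Strip the transposon tag and adaptor tail, keep the genomic fragment.

    The transposon tag must sit at the read start within ``max_mismatches``;
    otherwise the read is rejected (``no_transposon_tag``).  If the adaptor
    tail occurs downstream, it and everything 3' of it are removed.  An
    empty remainder rejects as ``empty_fragment``; a remainder that is still
    a transposon substring (when ``transposon_sequence`` is configured)
    rejects as ``transposon_only``.
    """
    tag = config.transposon_tag
    if len(read.bases) < len(tag) or hamming(read.bases[: len(tag)], tag) > config.max_mismatches:
        return Rejection(read.id, "no_transposon_tag")
    frag = read.bases[len(tag):]
    quals = read.qualities[len(tag):] if read.qualities is not None else None
    if config.adaptor_tail:
        cut = frag.find(config.adaptor_tail)
        if cut >= 0:
            frag = frag[:cut]
            quals = quals[:cut] if quals is not None else None
    if not frag:
        return Rejection(read.id, "empty_fragment")
    if config.transposon_sequence and frag in config.transposon_sequence:
        return Rejection(read.id, "transposon_only")
    return TrimmedRead(read.id, sample_id, frag, qualities=quals)


def filter_transposon_only(
    trimmed: Iterable[TrimmedRead], config: AdaptorConfig
) -> tuple[list[TrimmedRead], list[Rejection]]:
    """Discard fragments that are (near-)exact substrings of the transposon.

    These arise from amplification internal to the transposon rather than a
    genuine genome junction.  Requires ``transposon_sequence`` in the
    config.
    """
    if not config.transposon_sequence:
        raise ValueError("transposon_sequence required to filter transposon-only reads")
    ref = config.transposon_sequence
    kept: list[TrimmedRead] = []
    discarded: list[Rejection] = []
    for t in trimmed:
        if t.fragment in ref or _near_substring(t.fragment, ref, config.max_mismatches):
            discarded.append(Rejection(t.read_id, "transposon_only"))
        else:
            kept.append(t)
    return kept, discarded


def _near_substring(frag: str, ref: str, max_mm: int) -> bool:
    if max_mm == 0 or len(frag) > len(ref):
        return False
    return any(
        hamming(frag, ref[i : i + len(frag)]) <= max_mm
        for i in range(len(ref) - len(frag) + 1)
    )


def process_reads(
    reads: Iterable[SequenceRead], config: AdaptorConfig
) -> tuple[dict[str, list[TrimmedRead]], list[Rejection], list[SequenceRead]]:
    """demultiplex + trim (+ transposon filter if a reference is configured)."""
    assigned, unassigned = demultiplex(reads, config)
    out: dict[str, list[TrimmedRead]] = {}
    rejections: list[Rejection] = []
    for sample, sample_reads in assigned.items():
        kept: list[TrimmedRead] = []
        for r in sample_reads:
            res = trim_read(r, config, sample_id=sample)
            if isinstance(res, Rejection):
                rejections.append(res)
            else:
                kept.append(res)
        out[sample] = kept
    return out, rejections, unassigned


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """FASTQ reader, gzip-transparent."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield SequenceRead(rec.id, str(rec.seq), quals)


def write_fastq(reads: Iterable[SequenceRead | TrimmedRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            seq = r.bases if isinstance(r, SequenceRead) else r.fragment
            quals = r.qualities if r.qualities is not None else "I" * len(seq)
            rec = SeqRecord(Seq(seq), id=r.id if isinstance(r, SequenceRead) else r.read_id,
                            description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_barcode_table(path: str | Path) -> dict[str, str]:
    """TSV (sample_id, barcode); a header line is tolerated."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or parts[0].lower() in ("sample_id", "sample"):
                continue
            table[parts[0]] = parts[1].upper()
    return table


def write_discard_log(rejections: Sequence[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for r in rejections:
            fh.write(f"{r.read_id}\t{r.reason}\n")
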