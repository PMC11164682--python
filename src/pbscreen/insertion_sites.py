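"""From junction alignments to filtered per-lesion integration sites.

An integration site is the genomic coordinate of a transposon-genome
junction in one lesion, supported by one or more sequencing reads.  The
pipeline here is: drop poorly mapped alignments, take the junction-proximal
coordinate of each read, collapse identical calls into sites with read
counts, merge sites a few base pairs apart (PCR-duplicate positional
jitter), and apply the screen's site filters (donor-chromosome exclusion,
optional read-depth cut).

Coordinates are 1-based inclusive internally; BED I/O converts to/from
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["lesion_id", "chrom", "pos", "orientation", "read_count"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned junction fragment.

    ``start``/``end`` are the 1-based inclusive span of the alignment on the
    reference; ``strand`` is the alignment strand of the fragment.
    """

    read_id: str
    lesion_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 255

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad alignment span {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class IntegrationSite:
    """One (possibly merged) transposon integration in one lesion."""

    lesion_id: str
    chrom: str
    pos: int
    orientation: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be +/-, got {self.orientation!r}")


@dataclass(frozen=True)
class SiteFilterConfig:
    """Site-level filters.

    min_reads
        keep sites with read_count strictly greater than this (the screen's
        ">10 reads" rule); applied only when ``apply_read_filter`` is true.
    exclude_chromosomes
        chromosomes dropped outright, by default the transposon donor
        chromosome (local hopping inflates its site density).
    merge_window
        maximum distance in bp at which two sites of one lesion are treated
        as PCR-duplicate jitter and merged.
    """

    min_reads: int = 10
    exclude_chromosomes: frozenset[str] = frozenset()
    merge_window: int = 5
    mapq_min: int = 10
    apply_read_filter: bool = False

    def __post_init__(self) -> None:
        if self.merge_window < 0:
            raise ValueError("merge_window must be >= 0")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        object.__setattr__(self, "exclude_chromosomes", frozenset(self.exclude_chromosomes))


def sites_from_alignments(
    alignments: Iterable[AlignmentRecord],
    config: SiteFilterConfig = SiteFilterConfig(),
) -> tuple[list[IntegrationSite], list[tuple[AlignmentRecord, str]]]:
    """Convert alignments to raw single-read site calls.

    The integration position is the junction-proximal end of the fragment:
    the leftmost aligned base for ``+`` strand alignments and the rightmost
    for ``-`` strand (the transposon end abuts the 5' end of the sequenced
    fragment).  Alignments below ``mapq_min`` are rejected, never fatal.

    Returns (raw calls each with read_count 1, rejected records with reason).
    """
    calls: list[IntegrationSite] = []
    rejected: list[tuple[AlignmentRecord, str]] = []
    for aln in alignments:
        if aln.mapq < config.mapq_min:
            rejected.append((aln, "low_mapq"))
            continue
        pos = aln.start if aln.strand == "+" else aln.end
        calls.append(IntegrationSite(aln.lesion_id, aln.chrom, pos, aln.strand, 1))
    return calls, rejected


def collapse_duplicates(raw_calls: Iterable[IntegrationSite]) -> list[IntegrationSite]:
    """Group calls by (lesion, chrom, pos, orientation); read_count = group size.

    Input read counts are summed so the function also accepts pre-counted
    calls; conservation of total read count is an invariant either way.
    """
    counts: dict[tuple[str, str, int, str], int] = {}
    for c in raw_calls:
        key = (c.lesion_id, c.chrom, c.pos, c.orientation)
        counts[key] = counts.get(key, 0) + c.read_count
    return [
        IntegrationSite(lesion, chrom, pos, orient, n)
        for (lesion, chrom, pos, orient), n in sorted(counts.items())
    ]


def merge_nearby(
    sites: Sequence[IntegrationSite], merge_window: int = 5
) -> list[IntegrationSite]:
    """Merge sites of one lesion lying within ``merge_window`` bp of each other.

    Merging is transitive (single linkage): sites whose pairwise gaps along a
    chain are each <= merge_window collapse into one site, negating PCR
    duplicates recovered at slightly shifted coordinates.  The merged site
    takes the position and orientation of the member with the highest read
    count (leftmost on ties) and the summed read count.  Sites of different
    lesions or chromosomes never merge; opposite orientations do merge (a
    duplicate may be recovered from either primer), which is logged.
    """
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")
    by_group: dict[tuple[str, str], list[IntegrationSite]] = {}
    for s in sites:
        by_group.setdefault((s.lesion_id, s.chrom), []).append(s)

    merged: list[IntegrationSite] = []
    for group in by_group.values():
        group.sort(key=lambda s: (s.pos, s.orientation))
        chain: list[IntegrationSite] = []
        for s in group:
            if chain and s.pos - chain[-1].pos <= merge_window:
                chain.append(s)
            else:
                if chain:
                    merged.append(_merge_chain(chain))
                chain = [s]
        if chain:
            merged.append(_merge_chain(chain))
    merged.sort(key=lambda s: (s.lesion_id, s.chrom, s.pos, s.orientation))
    return merged


def _merge_chain(chain: list[IntegrationSite]) -> IntegrationSite:
    if len(chain) == 1:
        return chain[0]
    rep = max(chain, key=lambda s: (s.read_count, -s.pos))
    if len({s.orientation for s in chain}) > 1:
        logger.info(
            "merging %d sites of mixed orientation at %s:%d (lesion %s)",
            len(chain), rep.chrom, rep.pos, rep.lesion_id,
        )
    total = sum(s.read_count for s in chain)
    return replace(rep, read_count=total)


def apply_site_filters(
    sites: Sequence[IntegrationSite], config: SiteFilterConfig
) -> tuple[list[IntegrationSite], dict[str, int]]:
    """Apply chromosome exclusion, then (optionally) the read-depth cut.

    The read rule keeps sites with read_count strictly greater than
    ``min_reads``; removal counts are reported per filter in application
    order.
    """
    removed = {"excluded_chromosome": 0, "low_read_count": 0}
    kept: list[IntegrationSite] = []
    for s in sites:
        if s.chrom in config.exclude_chromosomes:
            removed["excluded_chromosome"] += 1
        elif config.apply_read_filter and s.read_count <= config.min_reads:
            removed["low_read_count"] += 1
        else:
            kept.append(s)
    return kept, removed


def call_sites(
    alignments: Iterable[AlignmentRecord], config: SiteFilterConfig = SiteFilterConfig()
) -> tuple[list[IntegrationSite], dict[str, int]]:
    """Full alignment -> filtered site pipeline (convenience wrapper)."""
    raw, rejected = sites_from_alignments(alignments, config)
    sites = merge_nearby(collapse_duplicates(raw), config.merge_window)
    kept, removed = apply_site_filters(sites, config)
    removed["low_mapq"] = len(rejected)
    return kept, removed


# ---------------------------------------------------------------------------
# I/O


def sites_to_frame(sites: Sequence[IntegrationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.lesion_id, s.chrom, s.pos, s.orientation, s.read_count) for s in sites],
        columns=SITE_COLUMNS,
    )


def sites_from_frame(df: pd.DataFrame) -> list[IntegrationSite]:
    return [
        IntegrationSite(str(r.lesion_id), str(r.chrom), int(r.pos), str(r.orientation), int(r.read_count))
        for r in df.itertuples(index=False)
    ]


def write_sites_tsv(sites: Sequence[IntegrationSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[IntegrationSite]:
    return sites_from_frame(pd.read_csv(path, sep="\t"))


def write_sites_bed(sites: Sequence[IntegrationSite], path: str | Path) -> None:
    """BED6: 0-based half-open single-base intervals, score = read count."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.lesion_id}\t{s.read_count}\t{s.orientation}\n"
            )


def read_alignments_bed(path: str | Path, lesion_id: str | None = None) -> list[AlignmentRecord]:
    """Read BED6 alignments; lesion id from the name column unless given."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                logger.warning("skipping malformed BED line %d in %s", i + 1, path)
                continue
            chrom, start, end, name, score, strand = parts[:6]
            records.append(
                AlignmentRecord(
                    read_id=name,
                    lesion_id=lesion_id or name.split("/")[0],
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    strand=strand,
                    mapq=int(score) if score.isdigit() else 255,
                )
            )
    return records


def read_alignments_sam(path: str | Path, lesion_id: str | None = None) -> list[AlignmentRecord]:
    """Read SAM/BAM alignments via pysam.

    The lesion id comes from, in order: the explicit argument, the read
    group sample (RG -> SM), or the file stem.  Unmapped and secondary /
    supplementary records are skipped.
    """
    path = Path(path)
    rg_sample: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rg in fh.header.to_dict().get("RG", []):
            rg_sample[rg["ID"]] = rg.get("SM", rg["ID"])
        records = []
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if lesion_id is not None:
                lesion = lesion_id
            elif aln.has_tag("RG"):
                lesion = rg_sample.get(str(aln.get_tag("RG")), str(aln.get_tag("RG")))
            else:
                lesion = path.stem
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name or "",
                    lesion_id=lesion,
                    chrom=aln.reference_name or "",
                    start=aln.reference_start + 1,
                    end=aln.reference_end if aln.reference_end else aln.reference_start + 1,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                )
            )
    return records
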