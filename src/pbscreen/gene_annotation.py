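"""Gene-body assignment of integration sites and CIS windows.

An integration is assigned to a gene when its coordinate lies anywhere in
the gene body — the full transcriptional span including introns — which is
the convention insertional-mutagenesis screens use, since a transposon
anywhere in the transcription unit can disrupt or redirect it.  Relative
orientation (transposon vs gene strand) is reported because promoter-
carrying transposons activate genes preferentially when inserted in the
sense orientation upstream of coding exons.

Gene models load from GFF3 (gene features) or BED6; coordinates are
normalized to 1-based inclusive.  Interval lookup is by sorted starts with
bisection, sublinear in gene count.
"""

from __future__ import annotations

import bisect
import logging
import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from pbscreen.cis_gkc import CISCall
from pbscreen.insertion_sites import IntegrationSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class GeneAssignment:
    site: IntegrationSite
    gene_id: str
    symbol: str
    relative_orientation: str | None  # same | opposite | None when a strand is unknown


@dataclass(frozen=True)
class CISGene:
    gene_id: str
    symbol: str
    relation: str       # overlap | nearest
    distance: int       # 0 for overlap; bp from peak otherwise


@dataclass(frozen=True)
class AnnotatedCIS:
    call: CISCall
    genes: tuple[CISGene, ...]
    multi_gene: bool


class GeneIndex:
    """Per-chromosome interval index over gene bodies.

    Genes are kept sorted by start; a query walks candidates whose start is
    <= the query point and prunes with the running maximum end, giving
    O(log n + k) typical lookups without an external interval-tree
    dependency.
    """

    def __init__(self, genes: Iterable[GeneRecord]):
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._max_end_prefix: dict[str, list[int]] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[chrom] = [g.start for g in gs]
            running = []
            m = 0
            for g in gs:
                m = max(m, g.end)
                running.append(m)
            self._max_end_prefix[chrom] = running

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def overlapping_point(self, chrom: str, pos: int) -> list[GeneRecord]:
        return self.overlapping_interval(chrom, pos, pos)

    def overlapping_interval(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return []
        hi = bisect.bisect_right(self._starts[chrom], end)
        hits = []
        prefix = self._max_end_prefix[chrom]
        for i in range(hi - 1, -1, -1):
            if prefix[i] < start:
                break  # nothing earlier can reach the query
            if gs[i].end >= start:
                hits.append(gs[i])
        hits.reverse()
        return hits

    def nearest(self, chrom: str, pos: int) -> tuple[GeneRecord, int] | None:
        """Closest gene on the chromosome by distance to the gene body."""
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return None
        best, best_d = None, None
        for g in gs:
            d = 0 if g.start <= pos <= g.end else min(abs(pos - g.start), abs(pos - g.end))
            if best_d is None or d < best_d:
                best, best_d = g, d
        return best, int(best_d)  # type: ignore[arg-type]


def load_gene_model(path: str | Path) -> list[GeneRecord]:
    """Load genes from GFF3 (``gene`` features) or BED6 by extension."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _load_gff3(path)
    else:
        genes = _load_bed6(path)
    if not genes:
        raise ValueError(f"no gene records parsed from {path}")
    return genes


def _load_bed6(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                logger.warning("skipping malformed BED line %d in %s", i + 1, path)
                continue
            chrom, start, end, name, _score, strand = parts[:6]
            genes.append(GeneRecord(name, name, chrom, int(start) + 1, int(end), strand))
    return genes


def _load_gff3(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                logger.warning("skipping malformed GFF3 line %d in %s", i + 1, path)
                continue
            if parts[2].lower() != "gene":
                continue
            attrs = {}
            for kv in parts[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = urllib.parse.unquote(v.strip())
            gene_id = attrs.get("ID", f"gene_{i}")
            symbol = attrs.get("Name", gene_id)
            genes.append(GeneRecord(gene_id, symbol, parts[0], int(parts[3]),
                                    int(parts[4]), parts[6]))
    return genes


def assign_sites_to_genes(
    sites: Sequence[IntegrationSite], genes: Sequence[GeneRecord] | GeneIndex
) -> tuple[list[GeneAssignment], list[IntegrationSite]]:
    """Assign each site to every gene whose body contains its position.

    Containment is start <= pos <= end.  Sites landing in overlapping genes
    are assigned to all of them; sites in no gene come back unassigned.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    assignments: list[GeneAssignment] = []
    unassigned: list[IntegrationSite] = []
    for s in sites:
        hits = index.overlapping_point(s.chrom, s.pos)
        if not hits:
            unassigned.append(s)
            continue
        for g in hits:
            rel = None
            if g.strand in ("+", "-") and s.orientation in ("+", "-"):
                rel = "same" if g.strand == s.orientation else "opposite"
            assignments.append(GeneAssignment(s, g.gene_id, g.symbol, rel))
    return assignments, unassigned


def annotate_cis(
    calls: Sequence[CISCall], genes: Sequence[GeneRecord] | GeneIndex
) -> list[AnnotatedCIS]:
    """List each CIS window's overlapping genes; fall back to the nearest gene.

    A window overlapping no gene body gets the single closest gene on the
    chromosome (distance measured from the CIS peak), labelled "nearest".
    Windows overlapping more than one gene carry the multi_gene flag — such
    loci are ambiguous candidates.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    annotated = []
    for c in calls:
        hits = index.overlapping_interval(c.chrom, int(round(c.start)), int(round(c.end)))
        if hits:
            cg = tuple(CISGene(g.gene_id, g.symbol, "overlap", 0) for g in hits)
        else:
            near = index.nearest(c.chrom, int(round(c.peak)))
            cg = (CISGene(near[0].gene_id, near[0].symbol, "nearest", near[1]),) if near else ()
        annotated.append(AnnotatedCIS(call=c, genes=cg, multi_gene=len(hits) > 1))
    return annotated


def assignments_to_frame(assignments: Sequence[GeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.site.lesion_id, a.site.chrom, a.site.pos, a.site.orientation,
             a.site.read_count, a.gene_id, a.symbol, a.relative_orientation)
            for a in assignments
        ],
        columns=["lesion_id", "chrom", "pos", "orientation", "read_count",
                 "gene_id", "symbol", "relative_orientation"],
    )


def annotated_cis_to_frame(annotated: Sequence[AnnotatedCIS]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        c = a.call
        rows.append((
            c.chrom, c.peak, c.start, c.end, c.scale, c.height, c.n_sites,
            c.n_lesions, c.p_adjusted,
            ",".join(g.symbol for g in a.genes),
            ",".join(g.relation for g in a.genes),
            a.multi_gene,
        ))
    return pd.DataFrame(rows, columns=[
        "chrom", "peak", "start", "end", "scale", "height", "n_sites",
        "n_lesions", "p_adjusted", "genes", "gene_relations", "multi_gene",
    ])
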