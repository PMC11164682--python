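"""Candidate triage of annotated CIS calls.

A statistically significant CIS is not automatically a good validation
candidate.  Screens weigh: read-depth support (a locus whose every
supporting site has few reads may be PCR noise), physical window span
(integrations scattered over hundreds of kb suggest a fragile cluster or a
huge gene), gene ambiguity (several genes under one window), recurrent
false positives from prior screens (hotspot genes hit more often than
chance across unrelated studies), and whether more than one independent
lesion contributes.  Each becomes a flag; a call with no flags is a strong
candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from pbscreen.gene_annotation import AnnotatedCIS
from pbscreen.insertion_sites import IntegrationSite

FLAGS = ("low_read_depth", "large_span", "multi_gene", "blacklisted", "single_lesion")


@dataclass(frozen=True)
class TriageRules:
    """Thresholds of the candidate-strength rules.

    min_supporting_reads
        a CIS escapes the low-depth flag if ANY supporting site has
        read_count strictly greater than this — one well-supported
        integration is enough evidence the locus is real.
    max_span
        window length above which the large-span flag is raised; the
        default sits between the tight clusters screens validate (tens of
        kb) and the diffuse ones they discard (>100 kb).
    blacklist
        gene symbols recurrently called in unrelated transposon screens;
        ships with Nav2, extensible.
    lenient_multi_gene
        when set, the multi_gene flag alone does not demote a call to weak.
    """

    min_supporting_reads: int = 10
    max_span: int = 100_000
    blacklist: frozenset[str] = frozenset({"Nav2"})
    require_multiple_lesions: bool = False
    lenient_multi_gene: bool = False

    def __post_init__(self) -> None:
        if self.max_span <= 0:
            raise ValueError("max_span must be > 0")
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))


@dataclass(frozen=True)
class TriageReport:
    cis: AnnotatedCIS
    flags: frozenset[str]
    span: int
    verdict: str  # strong | weak


def triage(
    annotated: Sequence[AnnotatedCIS],
    sites: Sequence[IntegrationSite],
    rules: TriageRules = TriageRules(),
) -> list[TriageReport]:
    """Flag each annotated CIS and derive a strong/weak verdict.

    Supporting sites are those inside the CIS window on its chromosome; a
    CIS whose window contains no site from the table is an inconsistency
    and raises.  Verdict is strong iff no flags (multi_gene alone tolerated
    when ``lenient_multi_gene``).
    """
    reports = []
    for a in annotated:
        c = a.call
        support = [s for s in sites if s.chrom == c.chrom and c.start <= s.pos <= c.end]
        if not support:
            raise ValueError(
                f"CIS {c.chrom}:{c.start:.0f}-{c.end:.0f} has no supporting sites in the table"
            )
        flags = set()
        if all(s.read_count <= rules.min_supporting_reads for s in support):
            flags.add("low_read_depth")
        span = int(round(c.end - c.start))
        if span > rules.max_span:
            flags.add("large_span")
        if a.multi_gene:
            flags.add("multi_gene")
        if any(g.symbol in rules.blacklist for g in a.genes):
            flags.add("blacklisted")
        if rules.require_multiple_lesions and len({s.lesion_id for s in support}) == 1:
            flags.add("single_lesion")
        effective = flags - {"multi_gene"} if rules.lenient_multi_gene else flags
        reports.append(TriageReport(
            cis=a, flags=frozenset(flags), span=span,
            verdict="strong" if not effective else "weak",
        ))
    return reports


def reports_to_frame(reports: Sequence[TriageReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        c = r.cis.call
        rows.append((
            c.chrom, c.peak, c.start, c.end, r.span,
            ",".join(g.symbol for g in r.cis.genes),
            ",".join(sorted(r.flags)),
            r.verdict,
        ))
    return pd.DataFrame(rows, columns=[
        "chrom", "peak", "start", "end", "span", "genes", "flags", "verdict",
    ])


def write_reports(reports: Sequence[TriageReport], tsv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    df = reports_to_frame(reports)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(df.to_json(orient="records", indent=2))


def load_rules(path: str | Path) -> TriageRules:
    """Rules from a YAML/JSON mapping file."""
    import yaml

    data: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    return TriageRules(
        min_supporting_reads=int(data.get("min_supporting_reads", 10)),
        max_span=int(data.get("max_span", 100_000)),
        blacklist=frozenset(data.get("blacklist", ["Nav2"])),
        require_multiple_lesions=bool(data.get("require_multiple_lesions", False)),
        lenient_multi_gene=bool(data.get("lenient_multi_gene", False)),
    )
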