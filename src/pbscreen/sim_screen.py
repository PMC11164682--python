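"""Synthetic transposon screens and expression cohorts with ground truth.

The generator states a small world that mirrors what a real sensitised
piggyBac screen produces, so every downstream stage can be tested offline:

* per-lesion integration sites: uniform background insertions at a stated
  rate per megabase, planted clusters (the CISs a caller should recover),
  a local-hopping hotspot on the donor chromosome, PCR-duplicate records
  jittered by a few base pairs, and negative-binomial read counts with a
  low-depth contaminant so read-depth filters bite;
* splinkerette-style reads for those sites (barcode + transposon tag +
  genomic fragment + adaptor tail) with a truth BED of fragment origins;
* expression matrices in which a target gene and a signature gene set share
  one latent factor of configurable strength, with the implied population
  Spearman correlation recorded as truth.

Positions live on an abstract coordinate line — the screen statistics never
read bases — and random chromosome sequence is materialized only when reads
are simulated.  Identical seed and config give identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from pbscreen.insertion_sites import IntegrationSite
from pbscreen.splinkerette import AdaptorConfig, SequenceRead


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the transposon donor chromosome."""

    chromosomes: tuple[tuple[str, int], ...]
    donor_chromosome: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        if self.donor_chromosome is not None and self.donor_chromosome not in names:
            raise ValueError(f"donor chromosome {self.donor_chromosome!r} not in layout")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class PlantedCIS:
    """One planted cluster: where, how wide, how many sites, over how many lesions."""

    chrom: str
    center: int
    width: int
    n_insertions: int
    n_lesions: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("cluster width must be > 0")
        if self.n_lesions > self.n_insertions:
            raise ValueError("cannot spread insertions over more lesions than insertions")

    @property
    def window(self) -> tuple[int, int]:
        half = self.width // 2
        return (self.center - half, self.center - half + self.width)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Generative parameters of a synthetic screen.

    Defaults emulate the screen scale the pipeline targets: ~100 lesions,
    a handful of well-supported integrations each, read counts dispersed
    around ~50 with a contaminating low-depth (<10 reads) fraction, <=5 bp
    duplicate jitter, and donor-chromosome local hopping.
    """

    n_lesions: int = 110
    background_rate: float = 0.05        # insertions / Mb / lesion
    planted_cis: tuple[PlantedCIS, ...] = ()
    duplicate_jitter_max: int = 5
    duplicate_rate: float = 0.1
    read_count_mean: float = 50.0
    read_count_dispersion: float = 2.0   # NB size parameter; smaller = noisier
    low_depth_fraction: float = 0.2      # P(site draws reads ~ Uniform{1..9})
    hopping_enabled: bool = True
    hopping_halfwidth: int = 2_000_000
    hopping_per_lesion: float = 2.0
    hotspot_center: int | None = None    # donor midpoint when None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_rate, self.duplicate_rate, self.low_depth_fraction,
               self.hopping_per_lesion) < 0:
            raise ValueError("rates must be >= 0")
        if self.duplicate_jitter_max < 0:
            raise ValueError("duplicate_jitter_max must be >= 0")
        object.__setattr__(self, "planted_cis", tuple(self.planted_cis))

    def validate_against(self, layout: GenomeLayout) -> None:
        names = set(layout.lengths)
        for p in self.planted_cis:
            if p.chrom not in names:
                raise ValueError(f"planted cluster on unknown chromosome {p.chrom!r}")
        if self.hopping_enabled and self.hopping_per_lesion > 0 and layout.donor_chromosome is None:
            raise ValueError("local hopping requires a donor chromosome in the layout")


@dataclass(frozen=True)
class SimulatedSite:
    """Raw emitted integration call with its generative origin label."""

    site_id: int
    lesion_id: str
    chrom: str
    pos: int
    orientation: str
    read_count: int
    origin: str  # background | planted | hopping | duplicate-of:<site_id>

    def as_integration_site(self) -> IntegrationSite:
        return IntegrationSite(self.lesion_id, self.chrom, self.pos,
                               self.orientation, self.read_count)


@dataclass(frozen=True)
class TruthRecord:
    planted_cis_windows: tuple[tuple[str, int, int], ...]
    origins: dict[int, str]              # site_id -> origin label
    n_background: int = 0
    n_planted: int = 0
    n_hopping: int = 0
    n_duplicates: int = 0


# ---------------------------------------------------------------------------
# insertion simulation


def simulate_insertions(
    layout: GenomeLayout, config: ScreenSimConfig
) -> tuple[list[SimulatedSite], TruthRecord]:
    """Draw one synthetic screen's raw integration calls plus ground truth.

    Background counts per (lesion, chromosome) are Poisson with mean
    rate x length/1e6; planted cluster insertions are spread over a random
    lesion subset (uniform multinomial) within the stated window; hopping
    insertions fall uniformly in the donor hotspot.  Every site then spawns
    a jittered duplicate with probability ``duplicate_rate`` (offset +/-1..
    jitter_max bp, never 0, so position merging is exercised).
    """
    config.validate_against(layout)
    rng = np.random.default_rng(config.seed)
    lesions = [f"L{i + 1:03d}" for i in range(config.n_lesions)]
    sites: list[SimulatedSite] = []
    next_id = 0

    def emit(lesion: str, chrom: str, pos: int, origin: str) -> None:
        nonlocal next_id
        length = layout.lengths[chrom]
        pos = min(max(int(pos), 1), length)
        orientation = "+" if rng.random() < 0.5 else "-"
        if rng.random() < config.low_depth_fraction:
            reads = int(rng.integers(1, 10))
        else:
            # NB(mean m, size k): p = k/(k+m)
            k = config.read_count_dispersion
            p = k / (k + config.read_count_mean)
            reads = max(1, int(rng.negative_binomial(k, p)))
        sites.append(SimulatedSite(next_id, lesion, chrom, pos, orientation, reads, origin))
        next_id += 1

    # background, uniform per chromosome per lesion
    for lesion in lesions:
        for chrom, length in layout.chromosomes:
            n = rng.poisson(config.background_rate * length / 1e6)
            for pos in rng.integers(1, length + 1, size=n):
                emit(lesion, chrom, int(pos), "background")

    # planted clusters
    for cluster in config.planted_cis:
        start, end = cluster.window
        carriers = rng.choice(config.n_lesions, size=cluster.n_lesions, replace=False)
        alloc = rng.multinomial(
            cluster.n_insertions - cluster.n_lesions,
            np.full(cluster.n_lesions, 1.0 / cluster.n_lesions),
        ) + 1  # every carrier lesion gets >= 1 insertion
        for carrier, n in zip(carriers, alloc):
            for pos in rng.integers(start, end + 1, size=int(n)):
                emit(lesions[int(carrier)], cluster.chrom, int(pos), "planted")

    # donor-chromosome local hopping
    if config.hopping_enabled and config.hopping_per_lesion > 0 and layout.donor_chromosome:
        donor = layout.donor_chromosome
        length = layout.lengths[donor]
        center = config.hotspot_center if config.hotspot_center is not None else length // 2
        lo = max(1, center - config.hopping_halfwidth)
        hi = min(length, center + config.hopping_halfwidth)
        for lesion in lesions:
            n = rng.poisson(config.hopping_per_lesion)
            for pos in rng.integers(lo, hi + 1, size=n):
                emit(lesion, donor, int(pos), "hopping")

    # PCR-duplicate positional jitter
    n_primary = len(sites)
    for parent in list(sites):
        if rng.random() < config.duplicate_rate and config.duplicate_jitter_max > 0:
            mag = int(rng.integers(1, config.duplicate_jitter_max + 1))
            sign = 1 if rng.random() < 0.5 else -1
            emit(parent.lesion_id, parent.chrom, parent.pos + sign * mag,
                 f"duplicate-of:{parent.site_id}")

    origins = {s.site_id: s.origin for s in sites}
    truth = TruthRecord(
        planted_cis_windows=tuple((p.chrom, p.window[0], p.window[1]) for p in config.planted_cis),
        origins=origins,
        n_background=sum(o == "background" for o in origins.values()),
        n_planted=sum(o == "planted" for o in origins.values()),
        n_hopping=sum(o == "hopping" for o in origins.values()),
        n_duplicates=len(sites) - n_primary,
    )
    return sites, truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadSimConfig:
    fragment_len_mean: float = 80.0
    fragment_len_sd: float = 15.0
    fragment_len_min: int = 25
    error_rate: float = 0.0           # per-base substitution probability
    reads_per_site: int | None = None  # None -> one read per supporting read count
    seed: int = 0


@dataclass(frozen=True)
class TruthAlignment:
    """True origin of one simulated read's genomic fragment (1-based inclusive)."""

    read_id: str
    lesion_id: str
    chrom: str
    start: int
    end: int
    strand: str
    fragment: str


_BASES = np.array(list("ACGT"))


def random_genome(layout: GenomeLayout, seed: int = 0) -> dict[str, str]:
    """I.i.d. random sequence per chromosome (deterministic in the seed)."""
    rng = np.random.default_rng(seed)
    return {
        name: "".join(_BASES[rng.integers(0, 4, size=length)])
        for name, length in layout.chromosomes
    }


def simulate_reads(
    sites: Sequence[SimulatedSite],
    layout: GenomeLayout,
    adaptor: AdaptorConfig,
    read_config: ReadSimConfig = ReadSimConfig(),
) -> tuple[list[SequenceRead], list[TruthAlignment], dict[str, str]]:
    """Emit splinkerette-style reads for each site with truth alignments.

    Each read is barcode + transposon tag + genomic fragment + adaptor tail.
    The fragment starts at the integration position and runs 3'-ward on the
    site's strand (reverse-complemented for '-' sites); its true genomic
    interval is recorded one-per-read in the truth list.  Every lesion must
    have a barcode in ``adaptor.barcode_table``.
    """
    missing = {s.lesion_id for s in sites} - set(adaptor.barcode_table)
    if missing:
        raise ValueError(f"lesions without barcodes: {sorted(missing)}")
    rng = np.random.default_rng(read_config.seed)
    genome = random_genome(layout, seed=read_config.seed)

    reads: list[SequenceRead] = []
    truth: list[TruthAlignment] = []
    for s in sites:
        barcode = adaptor.barcode_table[s.lesion_id]
        n_reads = read_config.reads_per_site if read_config.reads_per_site else s.read_count
        chrom_seq = genome[s.chrom]
        length = layout.lengths[s.chrom]
        for j in range(n_reads):
            flen = max(read_config.fragment_len_min,
                       int(round(rng.normal(read_config.fragment_len_mean,
                                            read_config.fragment_len_sd))))
            if s.orientation == "+":
                start = s.pos
                end = min(length, s.pos + flen - 1)
                frag = chrom_seq[start - 1 : end]
            else:
                end = s.pos
                start = max(1, s.pos - flen + 1)
                frag = _revcomp(chrom_seq[start - 1 : end])
            read_id = f"site{s.site_id}_r{j}"
            seq = barcode + adaptor.transposon_tag + frag + adaptor.adaptor_tail
            seq = _with_errors(seq, read_config.error_rate, rng)
            reads.append(SequenceRead(read_id, seq, "I" * len(seq)))
            truth.append(TruthAlignment(read_id, s.lesion_id, s.chrom, start, end,
                                        s.orientation, frag))
    return reads, truth, genome


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# expression simulation


@dataclass(frozen=True)
class ExprSimConfig:
    """One latent factor shared by a target gene and a signature gene set.

    Gene g in the signature (and the target) is latent_loading * F +
    noise_sd * eps; all other genes are pure noise.  With everything
    jointly Gaussian the implied population Spearman correlation between
    the target's expression and the sum-of-z-scores signature score has a
    closed form, reported in the truth.
    """

    n_genes: int = 200
    n_samples: int = 108      # cohort scale the signature analysis targets
    signature_size: int = 20
    target_gene_label: str = "TARGET"
    latent_loading: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature_size >= self.n_genes:
            raise ValueError("signature_size must be < n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ExprTruth:
    latent_loading: float
    population_pearson: float
    population_spearman: float
    signature_genes: tuple[str, ...]


def _population_pearson(loading: float, noise_sd: float, m: int) -> float:
    """Pearson corr between target expression and the m-gene z-score sum."""
    v = loading**2 + noise_sd**2
    if v == 0 or loading == 0:
        return 0.0 if loading == 0 else 1.0
    num = m * loading**2
    den = math.sqrt(v * (m**2 * loading**2 + m * noise_sd**2))
    return num / den


def population_spearman(loading: float, noise_sd: float, signature_size: int) -> float:
    """Bivariate-normal identity rho_S = (6/pi) asin(rho_P / 2)."""
    rp = _population_pearson(loading, noise_sd, signature_size)
    return (6.0 / math.pi) * math.asin(rp / 2.0)


def loading_for_spearman(rho_s: float, signature_size: int, noise_sd: float = 1.0) -> float:
    """Invert the loading -> population Spearman map numerically."""
    if not 0 <= rho_s < population_spearman(1e9, noise_sd, signature_size):
        raise ValueError("requested Spearman rho outside the attainable range")
    if rho_s == 0:
        return 0.0
    return float(brentq(
        lambda a: population_spearman(a, noise_sd, signature_size) - rho_s, 1e-9, 1e9,
    ))


def simulate_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, ExprTruth]:
    """Genes x samples expression matrix with a planted pathway factor.

    Returns the matrix (rows = genes: the target, SIG_*, then background
    NOISE_* genes) and the truth with the implied population correlations.
    """
    rng = np.random.default_rng(config.seed)
    m = config.signature_size
    sig_genes = tuple(f"SIG{i + 1:03d}" for i in range(m))
    noise_genes = [f"NOISE{i + 1:04d}" for i in range(config.n_genes - m - 1)]
    genes = [config.target_gene_label, *sig_genes, *noise_genes]

    factor = rng.standard_normal(config.n_samples)
    values = np.empty((config.n_genes, config.n_samples))
    n_loaded = m + 1
    values[:n_loaded] = (
        config.latent_loading * factor
        + config.noise_sd * rng.standard_normal((n_loaded, config.n_samples))
    )
    values[n_loaded:] = rng.standard_normal((config.n_genes - n_loaded, config.n_samples))

    matrix = pd.DataFrame(values, index=genes,
                          columns=[f"S{i + 1:04d}" for i in range(config.n_samples)])
    truth = ExprTruth(
        latent_loading=config.latent_loading,
        population_pearson=_population_pearson(config.latent_loading, config.noise_sd, m),
        population_spearman=population_spearman(config.latent_loading, config.noise_sd, m),
        signature_genes=sig_genes,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# I/O


SIM_SITE_COLUMNS = ["site_id", "lesion_id", "chrom", "pos", "orientation", "read_count", "origin"]


def sim_sites_to_frame(sites: Sequence[SimulatedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.site_id, s.lesion_id, s.chrom, s.pos, s.orientation, s.read_count, s.origin)
         for s in sites],
        columns=SIM_SITE_COLUMNS,
    )


def write_sim_sites_tsv(sites: Sequence[SimulatedSite], path: str | Path) -> None:
    sim_sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def write_truth_json(truth: TruthRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "planted_cis_windows": [list(w) for w in truth.planted_cis_windows],
        "origins": {str(k): v for k, v in truth.origins.items()},
        "n_background": truth.n_background,
        "n_planted": truth.n_planted,
        "n_hopping": truth.n_hopping,
        "n_duplicates": truth.n_duplicates,
    }, indent=2))


def write_truth_bed(truth: Sequence[TruthAlignment], path: str | Path) -> None:
    """Truth alignments as BED6 (0-based half-open, name = read id)."""
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.read_id}\t0\t{t.strand}\n")
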