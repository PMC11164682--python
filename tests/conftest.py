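"""Shared fixtures: a small genome layout and a splinkerette library config."""

import pytest

from pbscreen.sim_screen import GenomeLayout
from pbscreen.splinkerette import AdaptorConfig


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout(
        chromosomes=(("chr1", 10_000_000), ("chr2", 5_000_000), ("chr10", 8_000_000)),
        donor_chromosome="chr10",
    )


@pytest.fixture
def adaptor() -> AdaptorConfig:
    # synthetic barcodes/tag/adaptor: real screens keep these in a config file
    return AdaptorConfig(
        barcode_table={"L001": "ACGTAC", "L002": "TGCATG", "L003": "GGATCC"},
        transposon_tag="TTAACCCTAGAAAGATA",
        adaptor_tail="GATCCCACTAGTGTCGAC",
        max_mismatches=1,
        transposon_sequence=(
            "TTAACCCTAGAAAGATAATCATATTGTGACGTACGTTAAAGATAATCATGCGTAAAATTGACGCATG"
        ),
    )
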