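"""Bundled reference amplicon coordinates (GRCh36/hg18).

The classical validation set for TUF-region analysis: single-copy Southern
probes on chromosome 2q plus six paralogue-ratio-test designs, each pairing
a 'test' amplicon inside a weak-signal (TUF) region with a 'reference'
amplicon from a normal-signal region. Coordinates are 1-based fully closed;
``printed_length`` is the published amplicon length in bp, which must equal
``end - start + 1``.
"""
from __future__ import annotations

from .intervals import GenomicInterval
from .prt import PrtAssay

__all__ = ["AMPLICONS", "amplicon_intervals", "prt_assays"]

#: (name, region, printed length bp, kind); kind is 'TUF' or 'Non-TUF'.
AMPLICONS = (
    ("HDLBP", "chr2:241,855,412-241,860,011", 4600, "TUF"),
    ("HDAC4", "chr2:239,860,758-239,863,570", 2813, "TUF"),
    ("CAPN10", "chr2:241,173,030-241,175,779", 2750, "TUF"),
    ("PSCDBP", "chr2:158,003,567-158,006,035", 2469, "Non-TUF"),
    ("MARCH7", "chr2:160,329,568-160,332,075", 2508, "Non-TUF"),
    ("RBMS1", "chr2:160,889,938-160,892,713", 2776, "Non-TUF"),
    ("2n13_test", "chr2:241,151,005-241,151,733", 729, "TUF"),
    ("2n13_ref", "chr13:31,949,825-31,950,179", 355, "Non-TUF"),
    ("8n6_test", "chr8:142,286,472-142,286,937", 466, "TUF"),
    ("8n6_ref", "chr6:89,689,978-89,690,367", 390, "Non-TUF"),
    ("8n3_test", "chr8:145,234,022-145,234,464", 443, "TUF"),
    ("8n3_ref", "chr3:134,693,119-134,693,550", 432, "Non-TUF"),
    ("2n1_test", "chr2:241,707,017-241,707,258", 242, "TUF"),
    ("2n1_ref", "chr1:37,721,785-37,722,026", 242, "Non-TUF"),
    ("5nX_test", "chr5:179,593,910-179,594,270", 361, "TUF"),
    ("5nX_ref", "chrX:63,694,585-63,694,959", 375, "Non-TUF"),
    ("9n14_test", "chr9:139,562,111-139,562,372", 262, "TUF"),
    ("9n14_ref", "chr14:94,217,995-94,218,256", 262, "Non-TUF"),
)


def amplicon_intervals() -> list[GenomicInterval]:
    """All bundled amplicons as labelled intervals."""
    return [GenomicInterval.from_string(region, label=name) for name, region, _, _ in AMPLICONS]


def prt_assays() -> list[PrtAssay]:
    """The six paired test/reference PRT designs."""
    by_name = {name: GenomicInterval.from_string(region, label=name)
               for name, region, _, _ in AMPLICONS}
    assays = []
    for aid in ("2n13", "8n6", "8n3", "2n1", "5nX", "9n14"):
        assays.append(PrtAssay(aid, by_name[f"{aid}_test"], by_name[f"{aid}_ref"]))
    return assays
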