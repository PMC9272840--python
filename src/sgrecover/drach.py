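"""DRACH motif scanning.

m6A is installed almost exclusively within the degenerate 5-mer consensus
DRACH (D = A/G/T, R = A/G, central A, C, H = T/A/C in the DNA alphabet; U in
RNA). Peak calls are only accepted when anchored on such a motif, so the
scanner below is the gatekeeper of the methylation classification. Scanning
is exhaustive over every 5-mer on the given (sense) strand — transcripts are
single-stranded, so no reverse-complement scan is performed — and
overlapping matches are all reported. ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import Transcript

#: Allowed bases per motif offset, DNA alphabet.
DRACH = (b"AGT", b"AG", b"A", b"C", b"TAC")

MOTIF_LEN = 5
#: Offset of the modified adenine within the motif.
A_OFFSET = 2


@dataclass(frozen=True)
class DrachSite:
    """One DRACH occurrence; ``a_position`` indexes the central (modified) A."""

    transcript_id: str
    a_position: int
    motif_seq: str = ""

    @property
    def motif_start(self) -> int:
        return self.a_position - A_OFFSET

    @property
    def motif_end(self) -> int:
        return self.a_position - A_OFFSET + MOTIF_LEN


def scan_drach(transcript: Transcript) -> list[DrachSite]:
    """All DRACH sites of a transcript, in ascending ``a_position``."""
    seq = transcript.sequence
    if len(seq) < MOTIF_LEN:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = np.ones(len(seq) - MOTIF_LEN + 1, dtype=bool)
    for offset, allowed in enumerate(DRACH):
        pos_ok = np.isin(arr[offset : offset + ok.size], np.frombuffer(allowed, dtype=np.uint8))
        ok &= pos_ok
    starts = np.nonzero(ok)[0]
    return [
        DrachSite(transcript.transcript_id, int(s) + A_OFFSET, seq[s : s + MOTIF_LEN])
        for s in starts
    ]


def sites_in_window(sites: list[DrachSite], start: int, end: int) -> list[DrachSite]:
    """Sites whose full 5-mer lies inside the half-open interval [start, end).

    Full motif containment is required: a partially overlapping motif does
    not count as "within" the window.
    """
    return [s for s in sites if s.motif_start >= start and s.motif_end <= end]


def write_sites(sites: list[DrachSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript_id\ta_position\tmotif_seq\n")
        for s in sites:
            fh.write(f"{s.transcript_id}\t{s.a_position}\t{s.motif_seq}\n")


def read_sites(path: str) -> list[DrachSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            sites.append(DrachSite(f[0], int(f[1]), f[2] if len(f) > 2 else ""))
    return sites
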