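"""Readers and writers for the package's external representations.

Everything downstream works on transcript coordinates: sequences come from a
transcriptome FASTA, coverage is per-nucleotide over a single transcript, and
counts are per-transcript. Coordinates are 0-based, half-open throughout; the
internal sequence alphabet is DNA (``U`` is canonicalized to ``T`` on input).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA records; carries the offending line number."""


@dataclass(frozen=True)
class Transcript:
    """One transcript of the transcriptome: the unit over which windows,
    motifs and scores are defined."""

    transcript_id: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: illegal characters {sorted(bad)}"
            )


@dataclass
class CoverageTrack:
    """Per-nucleotide read coverage for one sample over one transcript."""

    transcript_id: str
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"{self.transcript_id}: coverage must be a nonempty 1-D array")
        if np.any(self.values < 0):
            raise ValueError(f"{self.transcript_id}: negative coverage")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CountTable:
    """Per-transcript raw counts per sample, with per-sample library sizes.

    ``counts`` is a DataFrame indexed by transcript_id with one integer
    column per sample. Library sizes are total mapped reads and need not
    equal the column sums (counts may be a mapped subset).
    """

    counts: pd.DataFrame
    library_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for s, n in self.library_sizes.items():
            if n <= 0:
                raise ValueError(f"library size for {s!r} must be positive, got {n}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def _canonicalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _locate_bad_char(path: str, record_id: str, bad: str) -> int:
    """Best-effort line number of the first illegal character in a record."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and bad in _canonicalize(line.strip()):
                return lineno
    return -1


def read_fasta(path: str) -> list[Transcript]:
    """Read a transcriptome FASTA into :class:`Transcript` records.

    Headers of the form ``>transcript_id gene=GENE`` (or ``>tx|gene``) carry
    the gene id; otherwise gene_id defaults to the transcript_id. ``U`` and
    lowercase bases are canonicalized; characters outside ``ACGTN`` raise
    :class:`FastaParseError` naming the line.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        tx_id = rec.id
        gene_id = tx_id
        if "|" in rec.id:
            tx_id, gene_id = rec.id.split("|", 1)
        for tok in rec.description.split()[1:]:
            if tok.startswith("gene="):
                gene_id = tok[5:]
        seq = _canonicalize(str(rec.seq))
        bad = set(seq) - VALID_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            lineno = _locate_bad_char(path, rec.id, ch)
            raise FastaParseError(
                f"{path}: illegal character {ch!r} in record {rec.id!r}"
                + (f" (line {lineno})" if lineno > 0 else "")
            )
        if not seq:
            raise FastaParseError(f"{path}: empty sequence for record {rec.id!r}")
        if tx_id in seen:
            raise FastaParseError(f"{path}: duplicate transcript id {tx_id!r}")
        seen.add(tx_id)
        transcripts.append(Transcript(tx_id, gene_id, seq))
    return transcripts


def write_fasta(transcripts: list[Transcript], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.transcript_id} gene={tx.gene_id}\n")
            for i in range(0, tx.length, width):
                fh.write(tx.sequence[i : i + width] + "\n")


def select_longest_isoform(transcripts: list[Transcript]) -> list[Transcript]:
    """Keep one transcript per gene: the longest isoform.

    Length ties break to the lexicographically smallest transcript_id so the
    choice is deterministic. Output order follows first appearance of each
    gene in the input.
    """
    best: dict[str, Transcript] = {}
    order: list[str] = []
    for tx in transcripts:
        cur = best.get(tx.gene_id)
        if cur is None:
            best[tx.gene_id] = tx
            order.append(tx.gene_id)
        elif (-tx.length, tx.transcript_id) < (-cur.length, cur.transcript_id):
            best[tx.gene_id] = tx
    return [best[g] for g in order]


def read_coverage(
    path: str,
    transcriptome: dict[str, Transcript],
    sample_id: str = "",
    dialect: str = "tsv",
) -> dict[str, CoverageTrack]:
    """Read per-transcript nucleotide coverage into dense tracks.

    ``dialect='tsv'``: rows ``transcript_id <TAB> position <TAB> coverage``
    with 0-based positions. ``dialect='bedgraph'``: rows
    ``transcript_id <TAB> start <TAB> end <TAB> coverage`` (half-open).
    Positions absent from the file are coverage 0. Unknown transcript ids are
    skipped with a warning; out-of-bounds positions are an error.
    """
    if dialect not in ("tsv", "bedgraph"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    tracks = {
        tx_id: np.zeros(tx.length) for tx_id, tx in transcriptome.items()
    }
    skipped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tx_id = fields[0]
            if tx_id not in tracks:
                if tx_id not in skipped:
                    logger.warning("%s:%d: unknown transcript %r, skipping", path, lineno, tx_id)
                    skipped.add(tx_id)
                continue
            n = len(tracks[tx_id])
            if dialect == "tsv":
                pos, value = int(fields[1]), float(fields[2])
                if not 0 <= pos < n:
                    raise ValueError(
                        f"{path}:{lineno}: position {pos} out of bounds for "
                        f"{tx_id!r} (length {n})"
                    )
                tracks[tx_id][pos] = value
            else:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                if not (0 <= start < end <= n):
                    raise ValueError(
                        f"{path}:{lineno}: interval [{start},{end}) out of bounds "
                        f"for {tx_id!r} (length {n})"
                    )
                tracks[tx_id][start:end] = value
    return {
        tx_id: CoverageTrack(tx_id, values, sample_id)
        for tx_id, values in tracks.items()
    }


def write_coverage(tracks: dict[str, CoverageTrack], path: str) -> None:
    """Write dense tracks as sparse per-position TSV (zeros omitted)."""
    frames = []
    for tx_id in sorted(tracks):
        values = tracks[tx_id].values
        pos = np.nonzero(values)[0]
        frames.append(
            pd.DataFrame({"transcript_id": tx_id, "position": pos, "coverage": values[pos]})
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["transcript_id", "position", "coverage"])
    )
    cov = out["coverage"].to_numpy()
    if cov.size and np.all(cov == np.floor(cov)):  # integer formatting is much faster
        out["coverage"] = cov.astype(np.int64)
    with open(path, "w") as fh:
        fh.write("#")
        out.to_csv(fh, sep="\t", index=False, float_format="%g")


PEAK_COLUMNS = [
    "transcript_id", "window_start", "window_end", "drach_a_positions",
    "mean_cov_ip", "pom_ip", "pom_input", "poi", "flagged",
]


def write_peaks(calls: list, path: str) -> None:
    """Write peak calls as a BED-like header + TSV table.

    One row per call; multiple DRACH anchors in one window are comma-joined
    in ``drach_a_positions``. Round-trips losslessly through
    :func:`read_peaks` given the transcriptome.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PEAK_COLUMNS) + "\n")
        for call in calls:
            w = call.window
            a_pos = ",".join(str(s.a_position) for s in call.drach_sites)
            fh.write(
                f"{w.transcript_id}\t{w.start}\t{w.end}\t{a_pos}\t"
                f"{w.mean_cov!r}\t{w.pom!r}\t{call.pom_input!r}\t{call.poi!r}\t"
                f"{int(call.flagged)}\n"
            )


def read_peaks(path: str, transcriptome: dict[str, Transcript] | None = None) -> list:
    """Read peak calls written by :func:`write_peaks`.

    With a transcriptome, DRACH motif sequences are reconstructed from the
    transcript sequences; without one they are left empty.
    """
    from .drach import DrachSite
    from .peaks import PeakCall, Window

    calls: list[PeakCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            tx_id = f[0]
            start, end = int(f[1]), int(f[2])
            mean_cov, pom, pom_input, poi = (float(x) for x in f[4:8])
            sites = []
            for a in f[3].split(","):
                a_pos = int(a)
                motif = ""
                if transcriptome is not None and tx_id in transcriptome:
                    seq = transcriptome[tx_id].sequence
                    motif = seq[a_pos - 2 : a_pos + 3]
                sites.append(DrachSite(tx_id, a_pos, motif))
            window = Window(tx_id, start, end, mean_cov, pom)
            calls.append(PeakCall(window, pom_input, poi, sites, flagged=bool(int(f[8]))))
    return calls


def read_counts(path: str) -> CountTable:
    """Read a count table TSV with ``# library_size <sample> <N>`` comment lines."""
    library_sizes: dict[str, int] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("# library_size"):
                _, sample, n = line[1:].split()
                library_sizes[sample] = int(n)
            elif not line.startswith("#"):
                body.write(line)
    body.seek(0)
    counts = pd.read_csv(body, sep="\t", index_col="transcript_id")
    return CountTable(counts.astype(int), library_sizes)


def write_counts(table: CountTable, path: str) -> None:
    with open(path, "w") as fh:
        for sample in table.samples:
            if sample in table.library_sizes:
                fh.write(f"# library_size {sample} {table.library_sizes[sample]}\n")
        table.counts.to_csv(fh, sep="\t", index_label="transcript_id")


def read_group_list(path: str) -> dict[str, str]:
    """Read a ``transcript_id <TAB> status`` table into a mapping."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tx_id, status = line.split("\t")[:2]
            if tx_id == "transcript_id":  # unhashed header row
                continue
            groups[tx_id] = status
    return groups


def write_group_list(groups: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript_id\tstatus\n")
        for tx_id in sorted(groups):
            fh.write(f"{tx_id}\t{groups[tx_id]}\n")
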