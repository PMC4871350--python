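"""Part 1: demultiplexed FASTQ -> peptide frequency table with read accounting.

Every read is classified into exactly one of five bins: accepted, no usable
flank pair, ambiguous base (non-ACGT) inside the insert, codon-constraint
violation, or stop codon. The bins partition the total read count, so screen
statistics can be audited exactly. Quality scores are ignored throughout:
frequency-based ranking across screens is robust to the occasional
miscalled base, and no quality filtering is applied anywhere in the pipeline.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .scheme import LibraryScheme, SelPepError, allowed_codons, _codon_to_aa, UNCONSTRAINED

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")
_REVCOMP = str.maketrans("ACGTN", "TGCAN")

#: Rejection reasons, in the order they are decided for each read.
REASON_NO_FLANK = "no_flank"
REASON_AMBIGUOUS = "ambiguous_base"
REASON_CODON = "codon_constraint"
REASON_STOP = "stop"


class InputFormatError(SelPepError, ValueError):
    """An input file does not conform to its declared format."""


@dataclass
class ScreenStats:
    """Read accounting for one screen; the five bins partition ``total_reads``."""

    total_reads: int = 0
    accepted_reads: int = 0
    rejected_no_flank: int = 0
    rejected_ambiguous_base: int = 0
    rejected_codon_constraint: int = 0
    rejected_stop: int = 0
    unique_peptides: int = 0

    def check_partition(self) -> None:
        parts = (
            self.accepted_reads
            + self.rejected_no_flank
            + self.rejected_ambiguous_base
            + self.rejected_codon_constraint
            + self.rejected_stop
        )
        if parts != self.total_reads:
            raise AssertionError(
                f"stats partition broken: {parts} classified != {self.total_reads} total"
            )


@dataclass
class ScreenTable:
    """Per-screen peptide -> raw read count, plus accounting statistics."""

    screen_id: str
    scheme_name: str
    counts: dict[str, int] = field(default_factory=dict)
    stats: ScreenStats = field(default_factory=ScreenStats)


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def extract_insert(read_sequence: str, scheme: LibraryScheme) -> tuple[str | None, str | None]:
    """Locate the insert in one read; returns ``(insert, None)`` or ``(None, reason)``.

    The search anchors on the longer, more specific 3' flank: the leftmost
    occurrence of ``flank3`` far enough into the read to leave room for the
    insert and the 5' flank is tested; the candidate insert is the
    ``insert_length`` nucleotides immediately preceding it, accepted iff the
    bases immediately before the insert equal ``flank5``. Occurrences whose 5'
    flank does not verify are skipped and the search continues rightward. A
    located insert containing any non-ACGT character is an
    ``ambiguous_base`` rejection; no qualifying flank pair is ``no_flank``.
    """
    s = read_sequence.upper()
    f3 = scheme.flank3
    f5 = scheme.flank5
    n5 = len(f5)
    ins_len = scheme.insert_length
    p = s.find(f3, ins_len + n5)
    while p != -1:
        start = p - ins_len
        if s[start - n5 : start] == f5:
            insert = s[start:p]
            if set(insert) <= _DNA:
                return insert, None
            return None, REASON_AMBIGUOUS
        p = s.find(f3, p + 1)
    return None, REASON_NO_FLANK


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def process_screen(
    fastq_path: str | Path,
    scheme: LibraryScheme,
    screen_id: str,
    *,
    try_revcomp: bool = False,
) -> ScreenTable:
    """Count accepted peptides in one demultiplexed FASTQ file.

    Applies :func:`extract_insert`, the scheme's codon-constraint filter and
    translation to every read; the result is deterministic and independent of
    read order. With ``try_revcomp``, a read whose forward-strand search finds
    no flank pair is retried on its reverse complement.
    """
    counts: dict[str, int] = {}
    stats = ScreenStats()
    f3 = scheme.flank3
    f5 = scheme.flank5
    n5 = len(f5)
    ins_len = scheme.insert_length
    min_pos = ins_len + n5
    filt = scheme.codon_filter and scheme.codon_constraint != UNCONSTRAINED
    allowed = allowed_codons(scheme.codon_constraint) if filt else None
    table = _codon_to_aa(scheme.amber_as_gln)

    with _open_maybe_gzip(fastq_path) as handle:
        records = FastqGeneralIterator(handle)
        while True:
            try:
                rec = next(records, None)
            except ValueError as exc:  # malformed 4-line record
                raise InputFormatError(
                    f"{fastq_path}: malformed FASTQ at record {stats.total_reads + 1}: {exc}"
                ) from exc
            if rec is None:
                break
            stats.total_reads += 1
            s = rec[1].upper()
            insert, reason = _extract(s, f3, f5, n5, ins_len, min_pos)
            if reason == REASON_NO_FLANK and try_revcomp:
                insert, reason = _extract(
                    reverse_complement(s), f3, f5, n5, ins_len, min_pos
                )
            if reason == REASON_NO_FLANK:
                stats.rejected_no_flank += 1
                continue
            if reason == REASON_AMBIGUOUS:
                stats.rejected_ambiguous_base += 1
                continue
            codons = [insert[i : i + 3] for i in range(0, ins_len, 3)]
            if filt and not all(c in allowed for c in codons):
                stats.rejected_codon_constraint += 1
                continue
            residues = []
            stopped = False
            for c in codons:
                aa = table[c]
                if aa is None:
                    stopped = True
                    break
                residues.append(aa)
            if stopped:
                stats.rejected_stop += 1
                continue
            peptide = "".join(residues)
            stats.accepted_reads += 1
            counts[peptide] = counts.get(peptide, 0) + 1

    stats.unique_peptides = len(counts)
    stats.check_partition()
    if stats.total_reads == 0:
        logger.warning("screen %s: FASTQ %s contains no reads", screen_id, fastq_path)
    return ScreenTable(screen_id=screen_id, scheme_name=scheme.name, counts=counts, stats=stats)


def _extract(s, f3, f5, n5, ins_len, min_pos):
    # Hot path; mirrors extract_insert but with precomputed lengths.
    p = s.find(f3, min_pos)
    while p != -1:
        start = p - ins_len
        if s[start - n5 : start] == f5:
            insert = s[start:p]
            if set(insert) <= _DNA:
                return insert, None
            return None, REASON_AMBIGUOUS
        p = s.find(f3, p + 1)
    return None, REASON_NO_FLANK


def stats_path_for(counts_path: str | Path) -> Path:
    """Sidecar stats path: ``x.counts.csv`` -> ``x.stats.json``."""
    counts_path = Path(counts_path)
    name = counts_path.name
    if name.endswith(".counts.csv"):
        return counts_path.with_name(name[: -len(".counts.csv")] + ".stats.json")
    return counts_path.with_name(name + ".stats.json")


def write_screen_table(
    table: ScreenTable, path: str | Path, stats_path: str | Path | None = None
) -> None:
    """Write ``peptide,count`` CSV plus a JSON stats sidecar.

    Rows are ordered by descending count then peptide, so output is
    byte-reproducible for a given table.
    """
    path = Path(path)
    if stats_path is None:
        stats_path = stats_path_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["peptide", "count"])
        for pep, c in sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            w.writerow([pep, c])
    payload = {
        "screen_id": table.screen_id,
        "scheme_name": table.scheme_name,
        "stats": asdict(table.stats),
    }
    with open(stats_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_screen_table(
    path: str | Path,
    stats_path: str | Path | None = None,
    *,
    screen_id: str | None = None,
) -> ScreenTable:
    """Read a counts CSV (+ stats sidecar) back into a :class:`ScreenTable`.

    Negative, non-integer or duplicate peptide rows are format errors; there is
    no silent merging. When the stats sidecar is missing, minimal statistics
    are reconstructed from the counts (total = accepted = sum) with a warning —
    adequate for re-sorting workflows, but the true sequencing depth is lost.
    """
    path = Path(path)
    if stats_path is None:
        stats_path = stats_path_for(path)
    counts: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["peptide", "count"]:
            raise InputFormatError(f"{path}: expected header 'peptide,count', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise InputFormatError(f"{path}:{lineno}: missing count column")
            pep, raw = row[0].strip(), row[1].strip()
            try:
                c = int(raw)
            except ValueError as exc:
                raise InputFormatError(f"{path}:{lineno}: non-integer count {raw!r}") from exc
            if c < 0:
                raise InputFormatError(f"{path}:{lineno}: negative count {c}")
            if pep in counts:
                raise InputFormatError(f"{path}:{lineno}: duplicate peptide {pep!r}")
            counts[pep] = c

    stats_path = Path(stats_path)
    if stats_path.exists():
        with open(stats_path) as fh:
            payload = json.load(fh)
        try:
            stats = ScreenStats(**payload["stats"])
            sid = payload["screen_id"]
            scheme_name = payload["scheme_name"]
        except (KeyError, TypeError) as exc:
            raise InputFormatError(f"{stats_path}: malformed stats sidecar: {exc}") from exc
        stats.check_partition()
        if stats.unique_peptides != len(counts):
            raise InputFormatError(
                f"{stats_path}: unique_peptides {stats.unique_peptides} != {len(counts)} rows"
            )
        if sum(counts.values()) != stats.accepted_reads:
            raise InputFormatError(
                f"{path}: counts sum {sum(counts.values())} != accepted_reads {stats.accepted_reads}"
            )
    else:
        total = sum(counts.values())
        logger.warning(
            "%s: no stats sidecar found; reconstructing total_reads=%d from counts", path, total
        )
        stats = ScreenStats(
            total_reads=total, accepted_reads=total, unique_peptides=len(counts)
        )
        sid = screen_id or path.stem.removesuffix(".counts")
        scheme_name = "unknown"
    if screen_id is not None:
        sid = screen_id
    return ScreenTable(screen_id=sid, scheme_name=scheme_name, counts=counts, stats=stats)
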