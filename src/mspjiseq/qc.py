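"""FASTQ quality filtering and adapter trimming.

A read is dropped when more than 30% of its bases are N, or when more than
10% of its bases have Phred quality below 20 (both strict inequalities,
fractions of the read length).  Adapter trimming removes the longest exact
prefix of the adapter found anchored at the read's 3' end, with a minimum
overlap of 5 bases.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

#: Illumina TruSeq single-end read-1 adapter.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

PHRED_OFFSET = 33  # Phred+33 encoding assumed; configurable at the IO layer


@dataclass(frozen=True)
class SequencedRead:
    id: str
    bases: str
    quals: tuple[int, ...]  # per-base Phred scores

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QcPolicy:
    max_n_frac: float = 0.30
    max_lowq_frac: float = 0.10
    lowq_threshold: int = 20
    adapter: str = DEFAULT_ADAPTER
    min_adapter_overlap: int = 5

    def __post_init__(self) -> None:
        for name in ("max_n_frac", "max_lowq_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def filter_read(read: SequencedRead, policy: QcPolicy = QcPolicy()) -> tuple[bool, str]:
    """(keep, reason).  Reason is "" for kept reads."""
    n = len(read)
    if n == 0:
        return False, "empty"
    n_frac = read.bases.upper().count("N") / n
    if n_frac > policy.max_n_frac:
        return False, f"n_frac={n_frac:.3f}"
    lowq_frac = sum(q < policy.lowq_threshold for q in read.quals) / n
    if lowq_frac > policy.max_lowq_frac:
        return False, f"lowq_frac={lowq_frac:.3f}"
    return True, ""


def trim_adapter(
    read: SequencedRead, policy: QcPolicy = QcPolicy()
) -> tuple[SequencedRead, bool]:
    """Remove the adapter from the 3' end; returns (read, found_adapter).

    The longest suffix of the read equal to a prefix of the adapter (length
    >= min_adapter_overlap) is removed.  No match leaves the read unchanged
    with found_adapter=False.
    """
    if not policy.adapter:
        raise ValueError("no adapter configured")
    adapter = policy.adapter.upper()
    bases = read.bases.upper()
    n = len(bases)
    for i in range(n):  # smallest i = longest suffix
        k = n - i
        if k < policy.min_adapter_overlap:
            break
        if k <= len(adapter) and bases[i:] == adapter[:k]:
            return SequencedRead(read.id, read.bases[:i], read.quals[:i]), True
    return read, False


# ---------------------------------------------------------------------------
# FASTQ IO (4-line records, gzip-transparent)

def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            bases = fh.readline().strip()
            plus = fh.readline()
            quals = fh.readline().strip()
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r} in {path}")
            yield SequencedRead(
                header[1:].split()[0],
                bases,
                tuple(ord(c) - PHRED_OFFSET for c in quals),
            )


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


@dataclass
class QcSummary:
    n_in: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_trimmed: int = 0
    drop_log: list[tuple[str, str]] = None  # (read id, reason)

    def __post_init__(self) -> None:
        if self.drop_log is None:
            self.drop_log = []


def run_qc(
    reads: Iterable[SequencedRead], policy: QcPolicy = QcPolicy()
) -> tuple[list[SequencedRead], QcSummary]:
    """Filter then trim a read stream; returns (clean inserts, summary)."""
    summary = QcSummary()
    kept: list[SequencedRead] = []
    for read in reads:
        summary.n_in += 1
        ok, reason = filter_read(read, policy)
        if not ok:
            summary.n_dropped += 1
            summary.drop_log.append((read.id, reason))
            continue
        trimmed, found = trim_adapter(read, policy)
        summary.n_kept += 1
        summary.n_trimmed += found
        kept.append(trimmed)
    return kept, summary
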