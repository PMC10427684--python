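"""DNA tag-set design, read-layout encoding, and barcode decoding.

Each synthesis cycle ligates a short DNA tag recording which skeleton or
building block was used; a sequencing read therefore contains the three
cycle tags at fixed offsets within a constant scaffold. The decoder
recovers (cy1, cy2, cy3) tuples by nearest-tag matching under a Hamming
budget, and aggregates reads into per-sample count tables.

The default behavior is exact matching (``max_mismatch=0``): tolerant
matching can rescue reads but makes unobserved-sequence analyses less
conservative, so it is opt-in.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

_ALPHABET = "ACGT"

#: decode failure reasons
NO_MATCH = "no_match"
AMBIGUOUS = "ambiguous"
TRUNCATED = "truncated"


class CapacityError(ValueError):
    """Raised when a requested tag set is infeasible at the given length/distance."""


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagLibrary:
    """Per-cycle tag_id -> sequence maps with a minimum pairwise distance."""

    cycles: dict[str, dict[str, str]]
    min_hamming: int = 1

    def __post_init__(self) -> None:
        for cycle, tags in self.cycles.items():
            lengths = {len(s) for s in tags.values()}
            if len(lengths) > 1:
                raise ValueError(f"cycle {cycle}: tag lengths differ")
            for s in tags.values():
                if set(s) - set(_ALPHABET):
                    raise ValueError(f"cycle {cycle}: non-ACGT tag {s!r}")
            seqs = list(tags.values())
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    if hamming(seqs[i], seqs[j]) < self.min_hamming:
                        raise ValueError(
                            f"cycle {cycle}: tags {seqs[i]}/{seqs[j]} closer than "
                            f"min_hamming={self.min_hamming}"
                        )

    def tag_length(self, cycle: str) -> int:
        return len(next(iter(self.cycles[cycle].values())))


@dataclass
class ReadLayout:
    """Ordered read regions; constant regions carry their sequence.

    ``regions`` is a list of (name, length, constant_sequence_or_None);
    cycle regions are named "cy1"/"cy2"/"cy3" and have no constant
    sequence.
    """

    regions: list[tuple[str, int, str | None]]

    def __post_init__(self) -> None:
        for name, length, const in self.regions:
            if const is not None and len(const) != length:
                raise ValueError(f"region {name}: constant length mismatch")

    @property
    def total_length(self) -> int:
        return sum(length for _, length, _ in self.regions)

    def region_offsets(self) -> dict[str, tuple[int, int]]:
        offsets = {}
        pos = 0
        for name, length, _ in self.regions:
            offsets[name] = (pos, pos + length)
            pos += length
        return offsets

    @classmethod
    def default_for(cls, tags: TagLibrary, prefix: str = "ACGTAC",
                    spacer: str = "TT", closing: str = "GCATGC") -> "ReadLayout":
        """A synthetic default layout: prefix, cy1, spacer, cy2, spacer, cy3, closing."""
        return cls(
            regions=[
                ("prefix", len(prefix), prefix),
                ("cy1", tags.tag_length("cy1"), None),
                ("spacer1", len(spacer), spacer),
                ("cy2", tags.tag_length("cy2"), None),
                ("spacer2", len(spacer), spacer),
                ("cy3", tags.tag_length("cy3"), None),
                ("closing", len(closing), closing),
            ]
        )


def design_tags(
    n: int, length: int, min_hamming: int, seed: int = 0, max_attempts: int = 200_000
) -> dict[str, str]:
    """Greedy random construction of n tags with pairwise Hamming >= min_hamming.

    GC content is kept within 25-75%. Deterministic given seed. Raises
    :class:`CapacityError` if the request cannot be met within a bounded
    number of attempts (e.g. more tags than the code space holds).
    """
    if n > 4**length:
        raise CapacityError(f"only {4**length} length-{length} tags exist")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    lo, hi = 0.25 * length, 0.75 * length
    for _ in range(max_attempts):
        if len(chosen) == n:
            break
        cand = "".join(_ALPHABET[i] for i in rng.integers(0, 4, size=length))
        gc = cand.count("G") + cand.count("C")
        if length >= 4 and not (lo <= gc <= hi):
            continue
        if all(hamming(cand, t) >= min_hamming for t in chosen):
            chosen.append(cand)
    if len(chosen) < n:
        raise CapacityError(
            f"could not place {n} tags of length {length} at distance "
            f">= {min_hamming} within {max_attempts} attempts"
        )
    return {f"t{i:03d}": s for i, s in enumerate(chosen)}


def design_tag_library(
    n_per_cycle: dict[str, int], length: int, min_hamming: int, seed: int = 0
) -> TagLibrary:
    cycles = {
        cycle: design_tags(n, length, min_hamming, seed=seed + k)
        for k, (cycle, n) in enumerate(sorted(n_per_cycle.items()))
    }
    return TagLibrary(cycles=cycles, min_hamming=min_hamming)


def encode_read(
    barcode: tuple[str, str, str], layout: ReadLayout, tags: TagLibrary
) -> str:
    """Concatenate layout regions; cycle regions take the barcode's tag sequences."""
    by_cycle = dict(zip(("cy1", "cy2", "cy3"), barcode))
    parts = []
    for name, length, const in layout.regions:
        if const is not None:
            parts.append(const)
        else:
            parts.append(tags.cycles[name][by_cycle[name]])
    return "".join(parts)


def _match_cycle(
    observed: str, tags: dict[str, str], max_mismatch: int
) -> tuple[str | None, str | None]:
    """Nearest tag by Hamming distance; must be unique and within budget."""
    best_d = len(observed) + 1
    best_id: str | None = None
    tied = False
    for tag_id, seq in tags.items():
        d = hamming(observed, seq)
        if d < best_d:
            best_d, best_id, tied = d, tag_id, False
        elif d == best_d:
            tied = True
    if best_d > max_mismatch:
        return None, NO_MATCH
    if tied:
        return None, AMBIGUOUS
    return best_id, None


def decode_read(
    seq: str, layout: ReadLayout, tags: TagLibrary, max_mismatch: int = 0
) -> tuple[tuple[str, str, str] | None, str | None]:
    """Decode one read into a barcode tuple, or (None, failure_reason)."""
    if len(seq) < layout.total_length:
        return None, TRUNCATED
    offsets = layout.region_offsets()
    decoded: dict[str, str] = {}
    for name, _, const in layout.regions:
        lo, hi = offsets[name]
        if const is not None:
            continue  # constant regions verified only via prefix policy below
        tag_id, reason = _match_cycle(seq[lo:hi], tags.cycles[name], max_mismatch)
        if tag_id is None:
            return None, reason
        decoded[name] = tag_id
    return (decoded["cy1"], decoded["cy2"], decoded["cy3"]), None


def _iter_fastq(path: str | Path) -> Iterator[str]:
    """Stream sequences from a (plain or gzipped) FASTQ file."""
    from Bio import SeqIO
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def count_reads(
    fastq: str | Path | Iterable[str],
    layout: ReadLayout,
    tags: TagLibrary,
    max_mismatch: int = 0,
) -> tuple[Counter, dict[str, int]]:
    """Decode a FASTQ (path) or an iterable of sequences into barcode counts.

    Streaming: memory is constant in the number of reads. Returns the
    per-tuple counts and decode statistics; decoded + failed always equals
    the total read count.
    """
    seqs = _iter_fastq(fastq) if isinstance(fastq, (str, Path)) else fastq
    counts: Counter = Counter()
    stats = {"total": 0, "decoded": 0, NO_MATCH: 0, AMBIGUOUS: 0, TRUNCATED: 0}
    for seq in seqs:
        stats["total"] += 1
        barcode, reason = decode_read(seq, layout, tags, max_mismatch)
        if barcode is None:
            stats[reason] += 1
        else:
            stats["decoded"] += 1
            counts[barcode] += 1
    return counts, stats


def counts_to_table(
    columns: dict[str, Counter], design_barcodes: Iterable[tuple[str, str, str]] | None = None
) -> pd.DataFrame:
    """Assemble sample columns into a count table.

    With a design attached, every design barcode appears as a row (zeros
    filled in); otherwise rows are the union of observed barcodes.
    """
    if design_barcodes is not None:
        index = pd.MultiIndex.from_tuples(
            list(design_barcodes), names=["cy1", "cy2", "cy3"]
        )
    else:
        keys = sorted({k for c in columns.values() for k in c})
        index = pd.MultiIndex.from_tuples(keys, names=["cy1", "cy2", "cy3"])
    table = pd.DataFrame(index=index)
    for name, counter in columns.items():
        table[name] = [counter.get(k, 0) for k in index]
    return table


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=[0, 1, 2])


def load_tag_library_tsv(path: str | Path, min_hamming: int = 1) -> TagLibrary:
    """Read a tag library from TSV with columns cycle, tag_id, sequence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cycles: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        cycles.setdefault(row["cycle"], {})[row["tag_id"]] = row["sequence"]
    return TagLibrary(cycles=cycles, min_hamming=min_hamming)


def write_tag_library_tsv(tags: TagLibrary, path: str | Path) -> None:
    rows = [
        {"cycle": cycle, "tag_id": tag_id, "sequence": seq}
        for cycle, m in tags.cycles.items()
        for tag_id, seq in m.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
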