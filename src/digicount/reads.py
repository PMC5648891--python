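"""FASTQ ingestion, demultiplexing and per-read filtering.

The filter chain mirrors the published analysis order: length filter, target
mapping, N removal, fixed-base mismatch filter.  Quality scores are read and
carried but never used for filtering; no stage trims reads — a read either
survives a stage intact or is flagged and excluded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import BarcodeDesign, ReadObservation


@dataclass
class FilterStats:
    """Per-stage read accounting: input and surviving counts per sample index.

    Counts are monotone non-increasing along the stage order, and at every
    stage ``n_in == n_out + removed``.
    """

    rows: list[dict] = field(default_factory=list)

    def record(self, stage: str, sample_index: str, n_in: int, n_out: int) -> None:
        self.rows.append(
            {"stage": stage, "sample_index": sample_index, "n_in": n_in, "n_out": n_out}
        )

    def extend(self, other: "FilterStats") -> "FilterStats":
        self.rows.extend(other.rows)
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "sample_index", "n_in", "n_out"])

    def total(self, stage: str) -> tuple[int, int]:
        n_in = sum(r["n_in"] for r in self.rows if r["stage"] == stage)
        n_out = sum(r["n_out"] for r in self.rows if r["stage"] == stage)
        return n_in, n_out


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` from a FASTQ or FASTQ.gz file."""
    with _open_maybe_gzip(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write ``(title, sequence, quality)`` records as 4-line FASTQ."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def index_from_title(title: str) -> str:
    """Extract the index sequence from an Illumina-style FASTQ title.

    The index read is the final colon-separated field of the description,
    e.g. ``"M00001:...:0:CGCTCATT"`` -> ``"CGCTCATT"``.
    """
    return title.rsplit(":", 1)[-1].strip()


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    records: Iterable[tuple[str, str, str]],
    index_map: dict[str, str],
    max_index_mismatch: int = 0,
) -> dict[str, list[tuple[str, str, str]]]:
    """Sort FASTQ records by sample index.

    Each record is assigned to the unique index within ``max_index_mismatch``
    of the index read in its title; records matching no index, or tied
    between two, go to the ``"undetermined"`` stream.
    """
    if max_index_mismatch < 0:
        raise ValueError("max_index_mismatch must be >= 0")
    seqs = list(index_map.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate index sequences in index_map")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("index sequences must have equal length")
    out: dict[str, list] = {label: [] for label in index_map}
    out["undetermined"] = []
    for record in records:
        idx_read = index_from_title(record[0])
        dists = {label: _mismatches(idx_read, seq) for label, seq in index_map.items()}
        best = min(dists.values())
        winners = [label for label, d in dists.items() if d == best]
        if best <= max_index_mismatch and len(winners) == 1:
            out[winners[0]].append(record)
        else:
            out["undetermined"].append(record)
    return out


def make_observations(
    reads_by_index: dict[str, Iterable],
) -> list[ReadObservation]:
    """Build :class:`ReadObservation` objects from per-index read streams.

    Accepts FASTQ ``(title, seq, qual)`` tuples, ``(read_id, seq)`` pairs, or
    simulator reads exposing ``read_id`` and ``sequence`` attributes.
    """
    observations = []
    for index, records in reads_by_index.items():
        for rec in records:
            if hasattr(rec, "sequence"):
                rid, seq = rec.read_id, rec.sequence
            elif len(rec) == 3:
                rid, seq, _ = rec
                rid = rid.split()[0]
            else:
                rid, seq = rec
            observations.append(ReadObservation(read_id=rid, sample_index=index, sequence=seq))
    return observations


def _split(observations, predicate, flag_name, stage, stats) -> list[ReadObservation]:
    kept_by_index: dict[str, int] = {}
    in_by_index: dict[str, int] = {}
    kept = []
    for obs in observations:
        in_by_index[obs.sample_index] = in_by_index.get(obs.sample_index, 0) + 1
        if predicate(obs):
            kept.append(obs)
            kept_by_index[obs.sample_index] = kept_by_index.get(obs.sample_index, 0) + 1
        else:
            obs.flag(flag_name)
    for index, n_in in in_by_index.items():
        stats.record(stage, index, n_in, kept_by_index.get(index, 0))
    return kept


def length_filter(
    observations: Sequence[ReadObservation], design: BarcodeDesign
) -> tuple[list[ReadObservation], FilterStats]:
    """Keep reads whose length lies inside the design's accepted window."""
    lo, hi = design.length_window
    stats = FilterStats()

    def ok(obs):
        n = len(obs.sequence)
        return n >= lo and (hi is None or n <= hi)

    kept = _split(observations, ok, "length", "length", stats)
    for obs in kept:
        obs.design = design
    return kept, stats


def extract_barcodes(
    observations: Sequence[ReadObservation], design: BarcodeDesign
) -> tuple[list[ReadObservation], FilterStats]:
    """Extract the first ``barcode_length`` bases of each read as its barcode.

    Reads too short to cover the barcode region are flagged ``short_read``
    and excluded.
    """
    stats = FilterStats()
    L = design.barcode_length

    def ok(obs):
        if len(obs.sequence) < L:
            return False
        obs.barcode = obs.sequence[:L]
        obs.design = design
        return True

    kept = _split(observations, ok, "short_read", "barcode_extracted", stats)
    return kept, stats


def n_filter(
    observations: Sequence[ReadObservation],
) -> tuple[list[ReadObservation], FilterStats]:
    """Remove reads whose barcode contains an ``N`` call."""
    stats = FilterStats()
    kept = _split(
        observations,
        lambda obs: obs.barcode is not None and "N" not in obs.barcode,
        "N_in_barcode",
        "N_pass",
        stats,
    )
    return kept, stats


def fixed_base_filter(
    observations: Sequence[ReadObservation],
    design: BarcodeDesign,
    selected_fixed="all",
) -> tuple[list[ReadObservation], FilterStats]:
    """Remove reads mismatching any selected fixed base of the barcode.

    ``selected_fixed`` is ``"all"``, ``"furthest:k"`` (the k fixed bases
    furthest from the sequencing primer site), or an explicit list of fixed
    positions.  A mismatch at a fixed position indicates an upstream indel
    shifted the barcode out of frame; k selected bases downstream of an indel
    catch it with probability ``1 - (1/4)**k``.
    """
    positions = design.select_fixed(selected_fixed)
    expected = design.fixed_map
    checks = [(p - 1, expected[p]) for p in positions]
    stats = FilterStats()

    def ok(obs):
        barcode = obs.barcode
        return barcode is not None and all(barcode[i] == b for i, b in checks)

    kept = _split(observations, ok, "fixed_base_mismatch", "fixed_base_pass", stats)
    return kept, stats
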