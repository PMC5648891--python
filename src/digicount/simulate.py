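"""Synthetic barcoded-amplicon read generator with full ground truth.

Emulates the measurement system end to end: a pool of template molecules,
each carrying a unique random-base barcode with fixed-base anchors, is
"amplified and sequenced" into reads.  Per molecule a read count is drawn
from a negative binomial (overdispersed Poisson) distribution; each read is
the molecule's barcode+target sequence with i.i.d. per-base substitutions,
insertions, deletions and N calls applied, and its sample index may be
swapped to the other index at a configurable low rate (index hopping /
primer contamination).  Indels shift the remainder of the read without
re-padding, so downstream fixed-base filtering can detect them as designed.

Every random draw flows from one seed, the full output is byte-for-byte
reproducible, and all injected events are logged so that simulations serve
as parameter-recovery oracles for the counting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    PANEL_COPIES,
    TemplateReference,
    default_panel_references,
    template_read,
)

#: Sample index sequences of the two-sample layout.
DEFAULT_INDEX_SEQUENCES = {"A": "CGCTCATT", "B": "GAGATTCC"}

_BASES = np.array(list("ACGT"))
_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass(slots=True)
class SimRead:
    """One emitted read: id, (possibly swapped) sample index, sequence."""

    read_id: str
    sample_index: str
    sequence: str


@dataclass
class GroundTruth:
    """Injected-event log of one simulation.

    ``molecules`` has one row per molecule (id, template, true index, barcode,
    emitted read count); ``errors`` one row per injected event (read id, kind
    in sub/ins/del/N/index_swap, 1-based position in the error-free sequence,
    introduced base).
    """

    molecules: pd.DataFrame
    errors: pd.DataFrame

    def swapped_reads(self) -> pd.DataFrame:
        return self.errors[self.errors["kind"] == "index_swap"]


@dataclass
class SimulationConfig:
    """Study conditions of a simulation run.

    Defaults follow the measured system: per-base substitution rate 0.25%
    (midpoint of the 0.23–0.29% window), total indel rate 0.1% split evenly
    between insertions and deletions, mean per-molecule coverage 15 with
    negative-binomial dispersion, and a low index-swap rate.  ``input_copies``
    of each reference gives the molecule count per sample index (the study
    used two identically composed samples).
    """

    references: list[TemplateReference] = field(default_factory=default_panel_references)
    indices: tuple[str, ...] = ("A", "B")
    index_sequences: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_SEQUENCES)
    )
    composition: dict[str, Sequence[float]] | Sequence[float] | None = None
    mean_coverage: float = 15.0
    dispersion: float | None = 8.0
    min_reads: int = 0
    substitution_rate: float = 0.0025
    insertion_rate: float = 0.0005
    deletion_rate: float = 0.0005
    n_rate: float = 0.0002
    index_swap_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "insertion_rate",
            "deletion_rate",
            "n_rate",
            "index_swap_rate",
        ):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_coverage < 0 or self.min_reads < 0:
            raise ValueError("coverage parameters must be nonnegative")
        for ref in self.references:
            if ref.input_copies is None or ref.input_copies < 0:
                raise ValueError(f"{ref.template_id}: input_copies must be set and >= 0")

    def composition_for(self, template_id: str) -> np.ndarray:
        comp = self.composition
        if isinstance(comp, dict):
            comp = comp.get(template_id)
        if comp is None:
            return np.full(4, 0.25)
        comp = np.asarray(comp, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("composition must be 4 A/C/G/T probabilities summing to 1")
        return comp


def preset_paper_panel(
    seed: int = 0, copies_scale: float = 1.0, **overrides
) -> SimulationConfig:
    """The full study panel: eleven templates, two indices, default error rates.

    Per sample index: 40,000/40,000/4,000/300/100/20 copies of LT1–LT6 and
    20,000/20,000/4,000/4,000/4,000 copies of ST1–ST5.  ``copies_scale``
    shrinks every copy number proportionally (minimum 1) for reduced-scale
    runs.
    """
    if copies_scale != 1.0:
        overrides.setdefault(
            "references",
            [
                replace(ref, input_copies=max(1, round(ref.input_copies * copies_scale)))
                for ref in default_panel_references()
            ],
        )
    return SimulationConfig(seed=seed, **overrides)


def panel_total_copies(kind: str = "LT") -> int:
    """Total panel input per sample for one template class ('LT' or 'ST')."""
    return sum(v for k, v in PANEL_COPIES.items() if k.startswith(kind))


def draw_molecules(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``input_copies`` barcoded molecules per (template, sample index).

    Random positions are drawn independently from the configured base
    composition; fixed positions carry their expected bases.  Barcode
    collisions between molecules are possible and preserved (true collisions).
    """
    frames = []
    for ref in config.references:
        design = ref.design
        comp = config.composition_for(ref.template_id)
        rand_idx = np.array([p - 1 for p in sorted(design.random_positions)])
        proto = np.array(list("?" * design.barcode_length))
        for pos, base in design.fixed_positions:
            proto[pos - 1] = base
        for index in config.indices:
            n = ref.input_copies
            if n == 0:
                continue
            mat = np.tile(proto, (n, 1))
            mat[:, rand_idx] = _BASES[rng.choice(4, size=(n, len(rand_idx)), p=comp)]
            barcodes = ["".join(row) for row in mat]
            frames.append(
                pd.DataFrame(
                    {
                        "molecule_id": [
                            f"{ref.template_id}.{index}.m{i}" for i in range(n)
                        ],
                        "template_id": ref.template_id,
                        "sample_index": index,
                        "barcode": barcodes,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["molecule_id", "template_id", "sample_index", "barcode"]
        )
    return pd.concat(frames, ignore_index=True)


def _draw_read_counts(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    m = config.mean_coverage
    if config.dispersion is None:
        counts = rng.poisson(m, size=n)
    else:
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + m), size=n)
    return np.maximum(counts, config.min_reads)


def _mutate(
    seq: str,
    n_sub: int,
    n_ins: int,
    n_del: int,
    n_n: int,
    rng: np.random.Generator,
    read_id: str,
    error_rows: list,
) -> str:
    """Apply the drawn error events to one read and log them.

    Substitutions and N calls land on original coordinates first; insertions
    and deletions are then applied right-to-left so earlier coordinates stay
    valid.  Positions logged are 1-based in the error-free sequence.
    """
    L = len(seq)
    chars = list(seq)
    if n_sub:
        for p in rng.choice(L, size=min(n_sub, L), replace=False):
            new = _OTHER[chars[p]][rng.integers(3)] if chars[p] in _OTHER else "A"
            chars[p] = new
            error_rows.append((read_id, "sub", int(p) + 1, new))
    if n_n:
        for p in rng.choice(L, size=min(n_n, L), replace=False):
            chars[p] = "N"
            error_rows.append((read_id, "N", int(p) + 1, "N"))
    indels = []
    if n_del:
        for p in rng.choice(L, size=min(n_del, L), replace=False):
            indels.append(("del", int(p), ""))
    if n_ins:
        for p in rng.choice(L + 1, size=min(n_ins, L + 1), replace=False):
            indels.append(("ins", int(p), str(_BASES[rng.integers(4)])))
    for kind, p, base in sorted(indels, key=lambda t: t[1], reverse=True):
        if kind == "del":
            del chars[p]
            error_rows.append((read_id, "del", p + 1, ""))
        else:
            chars.insert(p, base)
            error_rows.append((read_id, "ins", p + 1, base))
    return "".join(chars)


def reconstruct_read(true_sequence: str, error_records: Iterable[tuple]) -> str:
    """Re-apply logged errors to the error-free sequence (truth reconciliation).

    ``error_records`` are ``(kind, position, base)`` rows for one read in log
    order; the result must equal the emitted read byte-for-byte.
    """
    chars = list(true_sequence)
    offset_events = []
    for kind, pos, base in error_records:
        if kind == "sub" or kind == "N":
            chars[pos - 1] = base
        elif kind in ("del", "ins"):
            offset_events.append((kind, pos, base))
    for kind, pos, base in offset_events:  # already logged right-to-left
        if kind == "del":
            del chars[pos - 1]
        else:
            chars.insert(pos - 1, base)
    return "".join(chars)


def amplify_and_sequence(
    molecules: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, list[SimRead]], GroundTruth]:
    """Emit reads per molecule with injected errors and index swaps."""
    refs = {ref.template_id: ref for ref in config.references}
    reads_by_index: dict[str, list[SimRead]] = {idx: [] for idx in config.indices}
    error_rows: list[tuple] = []
    mol_read_counts = np.zeros(len(molecules), dtype=int)

    order = np.arange(len(molecules))
    n_reads_all = _draw_read_counts(len(molecules), config, rng)
    mol_read_counts[:] = n_reads_all
    total_reads = int(n_reads_all.sum())

    # Per-read event counts, drawn in molecule order.
    templates = molecules["template_id"].to_numpy()
    lengths = np.array(
        [
            refs[t].design.barcode_length + refs[t].design.target_width
            for t in templates
        ]
    )
    read_lengths = np.repeat(lengths, n_reads_all)
    n_sub = rng.binomial(read_lengths, config.substitution_rate)
    n_ins = rng.binomial(read_lengths, config.insertion_rate)
    n_del = rng.binomial(read_lengths, config.deletion_rate)
    n_n = rng.binomial(read_lengths, config.n_rate)
    swap = (
        rng.random(total_reads) < config.index_swap_rate
        if config.index_swap_rate > 0 and len(config.indices) > 1
        else np.zeros(total_reads, dtype=bool)
    )

    other_index = {}
    if len(config.indices) == 2:
        a, b = config.indices
        other_index = {a: b, b: a}

    cursor = 0
    barcodes = molecules["barcode"].to_numpy()
    sample_indices = molecules["sample_index"].to_numpy()
    mol_ids = molecules["molecule_id"].to_numpy()
    for i in order:
        ref = refs[templates[i]]
        true_seq = template_read(ref, barcodes[i])
        true_index = sample_indices[i]
        for j in range(n_reads_all[i]):
            k = cursor
            cursor += 1
            read_id = f"{mol_ids[i]}.r{j}"
            if n_sub[k] or n_ins[k] or n_del[k] or n_n[k]:
                seq = _mutate(
                    true_seq, n_sub[k], n_ins[k], n_del[k], n_n[k], rng, read_id, error_rows
                )
            else:
                seq = true_seq
            emitted = true_index
            if swap[k] and other_index:
                emitted = other_index[true_index]
                error_rows.append((read_id, "index_swap", 0, emitted))
            reads_by_index[emitted].append(SimRead(read_id, emitted, seq))

    truth_molecules = molecules.copy()
    truth_molecules["n_reads"] = mol_read_counts
    errors = pd.DataFrame(error_rows, columns=["read_id", "kind", "position", "base"])
    return reads_by_index, GroundTruth(truth_molecules, errors)


def simulate(config: SimulationConfig) -> tuple[dict[str, list[SimRead]], GroundTruth]:
    """Run a full simulation: draw molecules, then amplify and sequence."""
    rng = np.random.default_rng(config.seed)
    molecules = draw_molecules(config, rng)
    return amplify_and_sequence(molecules, config, rng)


def write_fastq_by_index(
    reads_by_index: dict[str, list[SimRead]],
    out_dir,
    index_sequences: dict[str, str] | None = None,
    gzip_output: bool = True,
) -> dict[str, str]:
    """Write one FASTQ(.gz) per sample index; titles carry the index read.

    Quality strings are constant high quality (qualities are carried but never
    used downstream).  Returns the written paths per index.
    """
    import os

    from .reads import write_fastq

    index_sequences = index_sequences or DEFAULT_INDEX_SEQUENCES
    os.makedirs(str(out_dir), exist_ok=True)
    paths = {}
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    for index, reads in reads_by_index.items():
        idx_seq = index_sequences.get(index, index)
        path = os.path.join(str(out_dir), f"index_{index}{suffix}")
        write_fastq(
            (
                (f"{r.read_id} 1:N:0:{idx_seq}", r.sequence, "I" * len(r.sequence))
                for r in reads
            ),
            path,
        )
        paths[index] = path
    return paths
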