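"""Domain types for digital molecule counting with random-base barcodes.

A molecular barcode (UMI) is a stretch of random bases attached to each target
molecule before amplification, so that the number of distinct barcodes — not
the number of sequenced reads — measures the absolute pre-amplification copy
number.  The barcode designs modelled here are "hybrid": invariant *fixed*
bases are interleaved within the random region.  A mismatch at a fixed base
reveals that an upstream insertion or deletion shifted the read out of the
designed reading frame, which makes indel-carrying reads removable without
alignment.

Positions in all public interfaces are 1-based and counted from the 5' end of
the read, i.e. from the sequencing primer site.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import yaml

DNA_BASES = ("A", "C", "G", "T")


def barcode_capacity(n_random_bases: int) -> int:
    """Number of distinct barcode sequences for a given random-base count.

    With four possible bases per random position the capacity is
    ``4 ** n_random_bases``; e.g. 24 random bases give 2.8e14 sequences.
    """
    if n_random_bases < 0:
        raise ValueError("n_random_bases must be nonnegative")
    return 4**n_random_bases


class DesignError(ValueError):
    """Raised for an invalid barcode design configuration."""


@dataclass(frozen=True)
class BarcodeDesign:
    """Declarative layout of the barcode region of a template.

    Parameters
    ----------
    name:
        Label of the design (e.g. ``"short_template"``).
    barcode_length:
        Number of bases in the barcode region, which starts at read
        position 1.
    random_positions:
        1-based positions (within the barcode) holding random bases.
    fixed_positions:
        ``(position, expected_base)`` pairs for the invariant bases.
        Together with ``random_positions`` they must cover every barcode
        position exactly once.
    target_region:
        1-based inclusive ``(start, end)`` coordinates of the target
        sequence within the read, downstream of the barcode.
    length_window:
        ``(min_len, max_len)`` accepted read lengths; ``max_len`` may be
        ``None`` for an unbounded window.
    """

    name: str
    barcode_length: int
    random_positions: tuple[int, ...]
    fixed_positions: tuple[tuple[int, str], ...]
    target_region: tuple[int, int]
    length_window: tuple[int, int | None]

    def __post_init__(self) -> None:
        rand = set(self.random_positions)
        fixed = {p for p, _ in self.fixed_positions}
        if len(rand) != len(self.random_positions):
            raise DesignError("duplicate random positions")
        if len(fixed) != len(self.fixed_positions):
            raise DesignError("duplicate fixed positions")
        overlap = rand & fixed
        if overlap:
            raise DesignError(
                f"position(s) {sorted(overlap)} listed as both random and fixed"
            )
        covered = rand | fixed
        expected = set(range(1, self.barcode_length + 1))
        if covered != expected:
            missing = sorted(expected - covered)
            extra = sorted(covered - expected)
            raise DesignError(
                f"random+fixed positions must cover 1..{self.barcode_length} "
                f"exactly (missing {missing}, out of range {extra})"
            )
        for pos, base in self.fixed_positions:
            if base not in DNA_BASES:
                raise DesignError(f"fixed base at {pos} must be one of ACGT, got {base!r}")
        start, end = self.target_region
        if not (start > self.barcode_length and end >= start):
            raise DesignError("target_region must lie downstream of the barcode")
        lo, hi = self.length_window
        if hi is not None and hi < lo:
            raise DesignError("length_window max below min")

    @property
    def fixed_map(self) -> dict[int, str]:
        """Mapping of fixed barcode position -> expected base."""
        return dict(self.fixed_positions)

    @property
    def target_width(self) -> int:
        start, end = self.target_region
        return end - start + 1

    def furthest_fixed(self, k: int) -> tuple[int, ...]:
        """The ``k`` fixed positions furthest from the sequencing primer site.

        The primer sits upstream of position 1, so distance from the primer is
        the position index itself and the furthest bases are the ones with the
        largest positions.
        """
        if not 1 <= k <= len(self.fixed_positions):
            raise DesignError(f"k must be in 1..{len(self.fixed_positions)}")
        positions = sorted(p for p, _ in self.fixed_positions)
        return tuple(positions[-k:])

    def select_fixed(self, selection) -> tuple[int, ...]:
        """Resolve a fixed-base selection to concrete barcode positions.

        ``selection`` may be ``"all"``, ``"furthest:k"``, or an explicit
        iterable of fixed positions.
        """
        if selection == "all":
            return tuple(sorted(p for p, _ in self.fixed_positions))
        if isinstance(selection, str) and selection.startswith("furthest:"):
            return self.furthest_fixed(int(selection.split(":", 1)[1]))
        positions = tuple(int(p) for p in selection)
        known = {p for p, _ in self.fixed_positions}
        bad = [p for p in positions if p not in known]
        if bad:
            raise DesignError(f"position(s) {bad} are not fixed positions of {self.name}")
        return tuple(sorted(positions))


@dataclass(frozen=True)
class TemplateReference:
    """One reference template: a target sequence under a barcode design."""

    template_id: str
    target_sequence: str
    design: BarcodeDesign
    input_copies: int | None = None

    def __post_init__(self) -> None:
        if len(self.target_sequence) != self.design.target_width:
            raise DesignError(
                f"{self.template_id}: target length {len(self.target_sequence)} "
                f"does not match design target region width {self.design.target_width}"
            )


@dataclass(slots=True)
class ReadObservation:
    """One sequenced read after extraction and filtering annotations.

    ``templates`` holds every reference the read maps to (more than one in
    misidentification mode); ``flags`` records which filters failed.  A read
    with any flag is excluded from clustering.
    """

    read_id: str
    sample_index: str
    sequence: str
    design: BarcodeDesign | None = None
    barcode: str | None = None
    templates: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.flags

    def flag(self, name: str) -> None:
        if name not in self.flags:
            self.flags = self.flags + (name,)


@dataclass
class Cluster:
    """A set of reads whose barcode keys are chained within the Distance bound.

    ``reads_by_index`` tallies member reads per sample index and
    ``reads_by_category`` per ``(template_id, sample_index)`` with fractional
    weights (1/k for a read mapped to k templates).
    """

    cluster_id: str
    members: list[ReadObservation] = field(default_factory=list)
    reads_by_index: dict[str, int] = field(default_factory=dict)
    reads_by_category: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Design I/O
# ---------------------------------------------------------------------------

def _design_to_dict(design: BarcodeDesign) -> dict:
    return {
        "name": design.name,
        "barcode_length": design.barcode_length,
        "random_positions": list(design.random_positions),
        "fixed_positions": {int(p): b for p, b in design.fixed_positions},
        "target_region": list(design.target_region),
        "length_window": [design.length_window[0], design.length_window[1]],
    }


def dump_design(design: BarcodeDesign) -> str:
    """Serialize a design to YAML (parseable by :func:`load_design`)."""
    return yaml.safe_dump(_design_to_dict(design), sort_keys=False)


def load_design(source) -> BarcodeDesign:
    """Load and validate a barcode design from YAML/JSON text, path or dict.

    Raises
    ------
    DesignError
        If positions overlap, fall outside the barcode, or fail to cover it.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    elif isinstance(source, io.IOBase):
        data = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
            with open(text) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise DesignError("design config must be a mapping")
    try:
        fixed = data["fixed_positions"]
        if isinstance(fixed, Mapping):
            fixed_positions = tuple(sorted((int(p), str(b)) for p, b in fixed.items()))
        else:
            fixed_positions = tuple(sorted((int(p), str(b)) for p, b in fixed))
        window = data.get("length_window", [0, None])
        return BarcodeDesign(
            name=str(data["name"]),
            barcode_length=int(data["barcode_length"]),
            random_positions=tuple(int(p) for p in data["random_positions"]),
            fixed_positions=fixed_positions,
            target_region=tuple(int(x) for x in data["target_region"]),
            length_window=(int(window[0]), None if window[1] is None else int(window[1])),
        )
    except KeyError as exc:
        raise DesignError(f"design config missing key {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Built-in designs and a synthetic reference panel
# ---------------------------------------------------------------------------

def _make_design(name, length, fixed, target_region, window) -> BarcodeDesign:
    fixed_pos = {p for p, _ in fixed}
    random_positions = tuple(p for p in range(1, length + 1) if p not in fixed_pos)
    return BarcodeDesign(
        name=name,
        barcode_length=length,
        random_positions=random_positions,
        fixed_positions=tuple(fixed),
        target_region=target_region,
        length_window=window,
    )


#: Short-template design: 30-base barcode = 24 random + 6 fixed, followed by an
#: 8-base target; accepted read lengths 34–39.  The four largest fixed
#: positions (16, 21, 24, 28) are the default filtering set.
SHORT_DESIGN = _make_design(
    "short_template",
    30,
    [(6, "T"), (11, "A"), (16, "C"), (21, "A"), (24, "T"), (28, "G")],
    (31, 38),
    (34, 39),
)

#: Long-template design: 50-base barcode = 38 random + 12 fixed, followed by a
#: 50-base target; accepted read length >= 90.  Shares fixed positions
#: 16/21/24/28 with the short design so one filtering set serves all templates.
LONG_DESIGN = _make_design(
    "long_template",
    50,
    [
        (4, "A"), (8, "C"), (12, "G"), (16, "C"), (21, "A"), (24, "T"),
        (28, "G"), (33, "T"), (38, "A"), (43, "C"), (47, "G"), (50, "T"),
    ],
    (51, 100),
    (90, None),
)

#: Default fixed positions used for filtering in the final pipeline: the 16th,
#: 21st, 24th and 28th bases of the barcode, present as fixed bases in both
#: built-in designs.
DEFAULT_FIXED_SELECTION = (16, 21, 24, 28)

BUILTIN_DESIGNS = {d.name: d for d in (SHORT_DESIGN, LONG_DESIGN)}


def builtin_design(name: str) -> BarcodeDesign:
    try:
        return BUILTIN_DESIGNS[name]
    except KeyError:
        raise DesignError(
            f"unknown design {name!r}; built-ins: {sorted(BUILTIN_DESIGNS)}"
        ) from None


# Synthetic stand-in target sequences (the study's own target sequences are
# not bundled): deterministic literals, pairwise well separated so unique
# mapping is unambiguous.
_ST_TARGETS = ["TTTTGATC", "CCGCGTGA", "AGGCCGTA", "GAATCTAG", "TCGCTCCT"]
_LT_TARGETS = [
    "CTCGCTTGCGCACTCAAGAAAATTCTCCGGGATTGTCGTCAGGCCATGTA",
    "ATTTGTAGGTATGACGCGCTGACCGGCCTATCCATGGCAGGCTGTAGAAC",
    "TACAGTTCTGGGGTGAGTCTCCTTCATAGACAATACCAGAACTTTGGGTA",
    "AGACGCGCATACGTTACAGCAGTCGACCGGTAGACACAGAAAGCGCATAA",
    "TTACTAAGGAGGCATGGACCCTCCCAATGACCCGATAGCACACGATCAGG",
    "CGAGTTATTTAACCCTCCGGGGTTAGCTCTGCAGTGACGCCGACTTGATA",
]

#: Copy numbers of the study panel: two identically composed samples, each
#: with these per-template input molecule counts.
PANEL_COPIES = {
    "LT1": 40_000, "LT2": 40_000, "LT3": 4_000, "LT4": 300, "LT5": 100, "LT6": 20,
    "ST1": 20_000, "ST2": 20_000, "ST3": 4_000, "ST4": 4_000, "ST5": 4_000,
}


def default_panel_references() -> list[TemplateReference]:
    """Synthetic eleven-template reference panel (LT1–LT6, ST1–ST5).

    Target sequences are synthetic stand-ins with the designed lengths;
    ``input_copies`` carry the study panel's per-sample copy numbers.
    """
    refs = [
        TemplateReference(f"LT{i + 1}", seq, LONG_DESIGN, PANEL_COPIES[f"LT{i + 1}"])
        for i, seq in enumerate(_LT_TARGETS)
    ]
    refs += [
        TemplateReference(f"ST{i + 1}", seq, SHORT_DESIGN, PANEL_COPIES[f"ST{i + 1}"])
        for i, seq in enumerate(_ST_TARGETS)
    ]
    return refs


def template_read(reference: TemplateReference, barcode: str) -> str:
    """Error-free read sequence for one molecule: barcode then target."""
    design = reference.design
    if len(barcode) != design.barcode_length:
        raise ValueError("barcode length does not match design")
    return barcode + reference.target_sequence
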