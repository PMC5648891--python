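"""Assign reads to reference templates.

Two routes are provided.  The native mapper compares the designed target
region of each read against every reference target with an ungapped,
fixed-position mismatch count — sufficient for a panel of a few short
reference sequences at known coordinates.  Alternatively, alignments from an
external gapped mapper can be imported from SAM.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .model import BarcodeDesign, ReadObservation, TemplateReference
from .reads import FilterStats


def default_max_mismatch(design: BarcodeDesign) -> int:
    """Default mismatch allowance: 1 for short (<=10 nt) targets, else 5."""
    return 1 if design.target_width <= 10 else 5


def _target_mismatches(sequence: str, target: str, start0: int) -> int:
    """Ungapped mismatch count of ``target`` vs the read slice at ``start0``.

    Read positions missing (read shorter than the target region) count as
    mismatches, so frame-shifted or truncated reads fail cleanly.
    """
    window = sequence[start0 : start0 + len(target)]
    missing = len(target) - len(window)
    return missing + sum(a != b for a, b in zip(window, target))


def map_targets(
    observations: Sequence[ReadObservation],
    references: Sequence[TemplateReference],
    max_mismatch: int | None = None,
) -> tuple[list[ReadObservation], FilterStats]:
    """Assign each read the set of templates matching its target region.

    Every reference template must share one design.  Reads matching no
    template within ``max_mismatch`` substitutions are flagged ``unmapped``
    and excluded; reads matching several keep the full set (used only in
    misidentification-resolution mode, where multi-mapped reads are retained).
    """
    if not references:
        raise ValueError("references must be non-empty")
    designs = {ref.design.name for ref in references}
    if len(designs) > 1:
        raise ValueError("map_targets requires references sharing one design")
    design = references[0].design
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(design)
    targets = [(ref.template_id, ref.target_sequence) for ref in references]
    if len({t for _, t in targets}) != len(targets):
        warnings.warn("duplicate target sequences in reference; assignments ambiguous")
    start0 = design.target_region[0] - 1

    stats = FilterStats()
    in_by_index: dict[str, int] = {}
    out_by_index: dict[str, int] = {}
    kept = []
    for obs in observations:
        in_by_index[obs.sample_index] = in_by_index.get(obs.sample_index, 0) + 1
        hits = tuple(
            tid
            for tid, target in targets
            if _target_mismatches(obs.sequence, target, start0) <= max_mismatch
        )
        if hits:
            obs.templates = hits
            obs.design = design
            kept.append(obs)
            out_by_index[obs.sample_index] = out_by_index.get(obs.sample_index, 0) + 1
        else:
            obs.flag("unmapped")
    for index, n_in in in_by_index.items():
        stats.record("mapped", index, n_in, out_by_index.get(index, 0))
    return kept, stats


def import_sam(
    path,
    references: Sequence[TemplateReference],
    observations: Sequence[ReadObservation] | None = None,
    sample_index: str = "unknown",
) -> list[ReadObservation]:
    """Import template assignments from a headered single-end SAM file.

    Primary and secondary alignments of one read are combined into its
    template set; unmapped records are dropped.  If ``observations`` is given,
    assignments are attached to the matching read ids and the annotated subset
    is returned; otherwise bare observations are built from the SAM records
    (SAM carries no sample index, so ``sample_index`` labels them all).

    Raises
    ------
    ValueError
        If an alignment references a template id absent from ``references``.
    """
    known = {ref.template_id: ref for ref in references}
    hits: dict[str, set[str]] = {}
    seqs: dict[str, str] = {}
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for record in sam:
            if record.is_unmapped:
                continue
            name = record.reference_name
            if name not in known:
                unknown.add(name)
                continue
            hits.setdefault(record.query_name, set()).add(name)
            if record.query_sequence and record.query_name not in seqs:
                seqs[record.query_name] = record.query_sequence
    if unknown:
        raise ValueError(f"SAM references unknown template id(s): {sorted(unknown)}")
    if observations is not None:
        annotated = []
        for obs in observations:
            templates = hits.get(obs.read_id)
            if templates:
                obs.templates = tuple(sorted(templates))
                annotated.append(obs)
            else:
                obs.flag("unmapped")
        return annotated
    design = references[0].design
    return [
        ReadObservation(
            read_id=rid,
            sample_index=sample_index,
            sequence=seqs.get(rid, ""),
            design=design,
            templates=tuple(sorted(templates)),
        )
        for rid, templates in hits.items()
    ]


def load_references(
    fasta_path,
    design_for: dict[str, BarcodeDesign] | None = None,
    designs: Iterable[BarcodeDesign] | None = None,
    copies: dict[str, int] | None = None,
) -> list[TemplateReference]:
    """Read reference templates from FASTA.

    Designs are resolved per record either from an explicit ``design_for``
    mapping (template id -> design) or by matching each sequence length to the
    target width of one of ``designs``.
    """
    from .model import BUILTIN_DESIGNS

    if designs is None:
        designs = BUILTIN_DESIGNS.values()
    by_width = {}
    for d in designs:
        by_width.setdefault(d.target_width, d)
    refs = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if design_for and record.id in design_for:
            design = design_for[record.id]
        elif len(seq) in by_width:
            design = by_width[len(seq)]
        else:
            raise ValueError(
                f"cannot infer design for {record.id} (target length {len(seq)})"
            )
        refs.append(
            TemplateReference(
                record.id, seq, design, None if copies is None else copies.get(record.id)
            )
        )
    if len({r.template_id for r in refs}) != len(refs):
        raise ValueError("duplicate template ids in reference FASTA")
    return refs


def write_references_fasta(references: Sequence[TemplateReference], path) -> None:
    with open(path, "w") as fh:
        for ref in references:
            fh.write(f">{ref.template_id}\n{ref.target_sequence}\n")
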