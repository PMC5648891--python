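"""End-to-end pipeline: filter -> map -> cluster -> count.

Composes the stages in their published order (length filter, target mapping,
N removal, fixed-base filter, clustering, resolution) for reads of one or
several barcode designs.  All outputs are pure functions of the inputs and
parameters; reports carry their parameters in ``attrs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import counting, reads as rp
from .cluster import ClusteringParams
from .mapping import map_targets
from .model import (
    DEFAULT_FIXED_SELECTION,
    BarcodeDesign,
    ReadObservation,
    TemplateReference,
)
from .reads import FilterStats

#: Random bases used when templates of different designs are clustered
#: together (the largest count at which the final all-template analysis
#: still plateaus for the study panel).
MIXED_DESIGN_RANDOM_BASES = 20


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    report: pd.DataFrame
    stats: FilterStats
    observations: list[ReadObservation] = field(default_factory=list)


def split_by_design(
    observations: Sequence[ReadObservation], designs: Sequence[BarcodeDesign]
) -> dict[str, list[ReadObservation]]:
    """Assign reads to the unique design whose length window accepts them.

    Reads fitting no window are flagged ``length``; reads fitting several are
    flagged ``ambiguous_design`` (the built-in windows are disjoint).
    """
    out: dict[str, list[ReadObservation]] = {d.name: [] for d in designs}
    for obs in observations:
        n = len(obs.sequence)
        hits = [
            d
            for d in designs
            if n >= d.length_window[0]
            and (d.length_window[1] is None or n <= d.length_window[1])
        ]
        if len(hits) == 1:
            out[hits[0].name].append(obs)
        elif not hits:
            obs.flag("length")
        else:
            obs.flag("ambiguous_design")
    return out


def run_pipeline(
    reads_by_index: dict[str, Sequence],
    references: Sequence[TemplateReference],
    params: ClusteringParams | None = None,
    mode: str = "full_resolved",
    fixed_selection=DEFAULT_FIXED_SELECTION,
    max_mismatch: int | None = None,
) -> PipelineResult:
    """Run filtering, mapping and counting over per-index read streams.

    ``reads_by_index`` maps sample index labels to reads (FASTQ record tuples
    or simulator reads).  When the references span several barcode designs and
    ``params`` does not already select a common number of random bases, the
    first ``MIXED_DESIGN_RANDOM_BASES`` random bases are used so that barcode
    keys remain comparable across designs.
    """
    if params is None:
        params = ClusteringParams()
    if not references:
        raise ValueError("references must be non-empty")
    designs: dict[str, BarcodeDesign] = {}
    refs_by_design: dict[str, list[TemplateReference]] = {}
    for ref in references:
        designs[ref.design.name] = ref.design
        refs_by_design.setdefault(ref.design.name, []).append(ref)

    if len(designs) > 1 and params.n_random_bases is None and params.positions is None:
        k = min(
            MIXED_DESIGN_RANDOM_BASES,
            *(len(d.random_positions) for d in designs.values()),
        )
        params = ClusteringParams(distance=params.distance, n_random_bases=k)

    observations = rp.make_observations(reads_by_index)
    stats = FilterStats()
    n_by_index: dict[str, int] = {}
    for obs in observations:
        n_by_index[obs.sample_index] = n_by_index.get(obs.sample_index, 0) + 1
    for index, n in n_by_index.items():
        stats.record("input", index, n, n)

    branches = split_by_design(observations, list(designs.values()))
    assigned_by_index: dict[str, int] = {}
    for branch in branches.values():
        for obs in branch:
            assigned_by_index[obs.sample_index] = (
                assigned_by_index.get(obs.sample_index, 0) + 1
            )
    for index, n in n_by_index.items():
        stats.record("design_assigned", index, n, assigned_by_index.get(index, 0))
    surviving: list[ReadObservation] = []
    for design_name, branch in branches.items():
        design = designs[design_name]
        branch_stats = FilterStats()
        kept, st = rp.length_filter(branch, design)
        branch_stats.extend(st)
        kept, st = map_targets(kept, refs_by_design[design_name], max_mismatch)
        branch_stats.extend(st)
        kept, st = rp.extract_barcodes(kept, design)
        branch_stats.extend(st)
        kept, st = rp.n_filter(kept)
        branch_stats.extend(st)
        kept, st = rp.fixed_base_filter(kept, design, fixed_selection)
        branch_stats.extend(st)
        for row in branch_stats.rows:
            row["design"] = design_name
        stats.extend(branch_stats)
        surviving.extend(kept)

    if mode == "full_resolved":
        report = counting.count_report(surviving, params, mode)
    else:
        # per-design reports concatenated (clustering never mixes designs here)
        parts = []
        n_clusters = 0.0
        for design_name in branches:
            subset = [obs for obs in surviving if obs.design.name == design_name]
            if not subset:
                continue
            part = counting.count_report(subset, params, mode)
            n_clusters += part.attrs["n_clusters"]
            parts.append(part)
        if parts:
            attrs = parts[0].attrs | {"n_clusters": n_clusters}
            report = pd.concat(parts, ignore_index=True)
            report.attrs.update(attrs)
        else:
            report = counting.count_report([], params, mode)
    report.attrs["fixed_selection"] = tuple(fixed_selection) if not isinstance(
        fixed_selection, str
    ) else fixed_selection
    return PipelineResult(report=report, stats=stats, observations=surviving)
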