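"""From barcode clusters to molecule counts.

The number of clusters is taken as the number of molecules before
amplification.  Three modes are provided:

``per_category``
    Clustering performed independently per (template, sample index) with
    uniquely mapped reads only — the unresolved baseline.
``index_resolved``
    Reads of all sample indices are merged per template before clustering.
    A cluster spanning several indices marks cross-sample contamination
    (primer carry-over, index errors, or index switching); it is counted for
    the index holding the majority of its reads, and an exact tie splits the
    cluster as 1/m per tied index.
``full_resolved``
    Reads of all templates and indices (multi-mapped reads included at weight
    1/k per template) are merged before clustering.  A cluster spanning
    several (template, index) categories additionally marks target
    misidentification; it is counted for the category with the largest
    weighted read tally, ties split 1/m.

Every mode conserves the total: summed counts equal the number of clusters.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Sequence

import pandas as pd

from .cluster import ClusteringParams, cluster_observations
from .model import Cluster, ReadObservation

REPORT_COLUMNS = ["template_id", "sample_index", "molecules", "reads", "coverage", "mode"]


def _finalize(rows: list[dict], mode: str, params: ClusteringParams, n_clusters: float) -> pd.DataFrame:
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS[:-1])
    if len(report):
        report = report.sort_values(["template_id", "sample_index"], ignore_index=True)
    report["mode"] = mode
    report.attrs["mode"] = mode
    report.attrs["distance"] = params.distance
    report.attrs["n_random_bases"] = params.n_random_bases
    report.attrs["n_clusters"] = n_clusters
    return report


def _row(template_id, sample_index, molecules, reads):
    coverage = reads / molecules if molecules else math.nan
    return {
        "template_id": template_id,
        "sample_index": sample_index,
        "molecules": molecules,
        "reads": reads,
        "coverage": coverage,
    }


def _unique_only(observations: Sequence[ReadObservation]) -> list[ReadObservation]:
    return [obs for obs in observations if len(obs.templates) == 1]


def count_per_category(
    observations: Sequence[ReadObservation], params: ClusteringParams
) -> pd.DataFrame:
    """Cluster counts per (template, index) without any resolution step."""
    groups: dict[tuple[str, str], list[ReadObservation]] = defaultdict(list)
    for obs in _unique_only(observations):
        groups[(obs.templates[0], obs.sample_index)].append(obs)
    rows = []
    total_clusters = 0
    for (tid, index), group in groups.items():
        clusters = cluster_observations(group, params)
        total_clusters += len(clusters)
        rows.append(_row(tid, index, float(len(clusters)), len(group)))
    return _finalize(rows, "per_category", params, float(total_clusters))


def _majority_split(tallies: dict, rows: defaultdict, reads: float) -> None:
    """Add one cluster to the majority key of ``tallies``; split ties 1/m."""
    best = max(tallies.values())
    winners = [key for key, t in tallies.items() if t == best]
    share = 1.0 / len(winners)
    for key in winners:
        rows[key][0] += share
        rows[key][1] += reads * share


def resolve_index_contamination(
    observations: Sequence[ReadObservation], params: ClusteringParams
) -> pd.DataFrame:
    """Merge indices per template, cluster, and assign clusters by majority index.

    Uses uniquely mapped reads.  A cluster containing reads of both indices is
    counted for the index with the most reads; when the per-index read counts
    are identical each tied index receives a coefficient of 1/m (0.5 for two).
    """
    groups: dict[str, list[ReadObservation]] = defaultdict(list)
    for obs in _unique_only(observations):
        groups[obs.templates[0]].append(obs)
    rows: list[dict] = []
    total_clusters = 0
    for tid, group in groups.items():
        clusters = cluster_observations(group, params)
        total_clusters += len(clusters)
        acc: defaultdict[str, list[float]] = defaultdict(lambda: [0.0, 0.0])
        for cl in clusters:
            _majority_split(cl.reads_by_index, acc, float(cl.n_reads))
        for index, (molecules, reads) in acc.items():
            rows.append(_row(tid, index, molecules, reads))
    return _finalize(rows, "index_resolved", params, float(total_clusters))


def resolve_misidentification(
    observations: Sequence[ReadObservation], params: ClusteringParams
) -> pd.DataFrame:
    """Merge all templates and indices, cluster, and assign by majority category.

    Multi-mapped reads are retained, contributing 1/k weight to each of their
    k templates' tallies.  Each cluster is counted for the (template, index)
    category with the largest weighted read tally; exact ties split 1/m.
    When reads of several designs are mixed, ``params`` must select a common
    number of random bases so the barcode keys are comparable.
    """
    mapped = [obs for obs in observations if obs.templates]
    rows: defaultdict[tuple[str, str], list[float]] = defaultdict(lambda: [0.0, 0.0])
    clusters = cluster_observations(mapped, params)
    for cl in clusters:
        _majority_split(cl.reads_by_category, rows, float(cl.n_reads))
    out = [_row(tid, index, molecules, reads) for (tid, index), (molecules, reads) in rows.items()]
    return _finalize(out, "full_resolved", params, float(len(clusters)))


_MODES = {
    "per_category": count_per_category,
    "index_resolved": resolve_index_contamination,
    "full_resolved": resolve_misidentification,
}


def count_report(
    observations: Sequence[ReadObservation],
    params: ClusteringParams,
    mode: str = "full_resolved",
) -> pd.DataFrame:
    """Dispatch to one of the three counting modes."""
    try:
        fn = _MODES[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(_MODES)}") from None
    return fn(observations, params)


def total_molecules(report: pd.DataFrame) -> float:
    return float(report["molecules"].sum())
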