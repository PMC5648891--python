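"""Saturation analyses and error-rate estimators.

Digital counting is accurate only when (i) the barcode variety is large
enough that every molecule is labelled distinctly and (ii) sequencing depth
is high enough that every barcode is read at least once.  Both requirements
are certified empirically by sweeping a parameter computationally and looking
for a plateau in the cluster count: the number of retained random bases is
swept by truncating barcodes, and the coverage is swept by randomly
subsampling reads.  Means and standard deviations are reported over seeded
resampling repeats (default n = 8).

The module also reconstructs the per-base error estimators: substitution
rates from mismatches against per-cluster consensus barcodes, fixed-base
mismatch rates from pre-filter reads, and the random-region base composition
from cluster consensuses (one vote per molecule).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ClusteringParams
from .counting import count_report, total_molecules
from .model import BarcodeDesign, Cluster, ReadObservation

#: Read fractions swept in the coverage analysis (100% down to 0.1%).
DEFAULT_FRACTIONS = (1.0, 0.32, 0.10, 0.032, 0.01, 0.0032, 0.001)


def subsample_reads(
    observations: Sequence[ReadObservation], fraction: float, seed
) -> list[ReadObservation]:
    """Draw exactly ``round(fraction * N)`` reads uniformly without replacement.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.  Input
    order is preserved in the returned subset, and equal seeds give equal
    subsets.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(observations)
    k = round(fraction * n)
    if k >= n:
        return list(observations)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return [observations[i] for i in np.sort(idx)]


def truncate_random_bases(
    params: ClusteringParams, design: BarcodeDesign, k: int
) -> ClusteringParams:
    """Clustering parameters restricted to the first ``k`` random bases (5' end)."""
    if not 1 <= k <= len(design.random_positions):
        raise ValueError(
            f"k must be in 1..{len(design.random_positions)} for design {design.name}"
        )
    return replace(params, n_random_bases=k, positions=None)


def _curve_frame(rows, swept_variable: str) -> pd.DataFrame:
    curve = pd.DataFrame(rows, columns=["swept", "mean", "sd", "n", "reads", "coverage"])
    reference = float(curve["mean"].iloc[-1])
    curve["relative"] = curve["mean"] / reference if reference else np.nan
    curve.attrs["swept_variable"] = swept_variable
    curve.attrs["reference"] = reference
    return curve


def coverage_curve(
    observations: Sequence[ReadObservation],
    params: ClusteringParams,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_repeats: int = 8,
    seed: int = 0,
    mode: str = "per_category",
) -> pd.DataFrame:
    """Cluster count versus subsampled read fraction (sequencing coverage).

    For each fraction the count is the total molecule count of the chosen
    counting mode, averaged over ``n_repeats`` independent subsamples seeded
    as ``seed + repeat_index``.  At fraction 1 no resampling happens and the
    SD is 0.  Coverage is reported as reads used / mean count.  Rows are
    ordered by increasing fraction so the last row is the full-depth
    reference, and ``relative`` is normalized to it.
    """
    rows = []
    for f_idx, fraction in enumerate(sorted(fractions)):
        if fraction >= 1.0:
            value = total_molecules(count_report(list(observations), params, mode))
            counts = [value] * max(n_repeats, 1)
            reads = len(observations)
        else:
            counts = []
            for rep in range(n_repeats):
                subset = subsample_reads(
                    observations, fraction, seed + 1009 * f_idx + rep
                )
                counts.append(total_molecules(count_report(subset, params, mode)))
            reads = round(fraction * len(observations))
        mean = float(np.mean(counts))
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        coverage = reads / mean if mean else np.nan
        rows.append((fraction, mean, sd, len(counts), reads, coverage))
    return _curve_frame(rows, "coverage_fraction")


def random_base_curve(
    observations: Sequence[ReadObservation],
    params: ClusteringParams,
    ks: Sequence[int],
    fraction: float = 0.10,
    n_repeats: int = 8,
    seed: int = 0,
    mode: str = "per_category",
) -> pd.DataFrame:
    """Cluster count versus number of retained random bases.

    Barcodes are computationally truncated to their first k random bases for
    each k in ``ks``; reads are subsampled to ``fraction`` (repeated
    ``n_repeats`` times unless fraction is 1).  ``relative`` is normalized to
    the mean count at the largest k.
    """
    designs = {obs.design.name: obs.design for obs in observations}
    if len(designs) != 1 and params.n_random_bases is None:
        raise ValueError("random_base_curve over mixed designs needs explicit k range")
    design = next(iter(designs.values()))
    rows = []
    for k in sorted(ks):
        k_params = truncate_random_bases(params, design, k)
        if fraction >= 1.0:
            counts = [total_molecules(count_report(list(observations), k_params, mode))]
            reads = len(observations)
        else:
            counts = []
            for rep in range(n_repeats):
                subset = subsample_reads(observations, fraction, seed + rep)
                counts.append(total_molecules(count_report(subset, k_params, mode)))
            reads = round(fraction * len(observations))
        mean = float(np.mean(counts))
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        coverage = reads / mean if mean else np.nan
        rows.append((k, mean, sd, len(counts), reads, coverage))
    return _curve_frame(rows, "random_bases")


def required_random_bases(curve: pd.DataFrame, threshold: float = 0.95):
    """Smallest swept k whose relative mean count reaches ``threshold``.

    Returns ``None`` ("not reached") when no grid point qualifies.  Applied to
    a family of matched curves this yields the required number of random bases
    as a function of input molecule count.
    """
    if curve.attrs.get("swept_variable") != "random_bases":
        raise ValueError("required_random_bases needs a random-base curve")
    hit = curve.loc[curve["relative"] >= threshold, "swept"]
    return None if hit.empty else int(hit.iloc[0])


# ---------------------------------------------------------------------------
# Error-rate and composition estimators
# ---------------------------------------------------------------------------

def consensus_barcode(barcodes: Sequence[str]) -> str:
    """Per-position majority barcode; ties break to the lexicographically
    smallest base.  The consensus estimates the original pre-error barcode."""
    if not barcodes:
        raise ValueError("empty cluster")
    length = len(barcodes[0])
    out = []
    for i in range(length):
        counts = Counter(b[i] for b in barcodes)
        best = max(counts.values())
        out.append(min(base for base, c in counts.items() if c == best))
    return "".join(out)


def estimate_substitution_rate(
    clusters: Sequence[Cluster], design: BarcodeDesign
) -> float:
    """Per-base substitution rate from mismatches against cluster consensuses.

    Counted over random-base positions only; singleton clusters carry no
    mismatch evidence and are excluded from the denominator.
    """
    positions = [p - 1 for p in design.random_positions]
    mismatches = 0
    compared = 0
    for cl in clusters:
        if cl.n_reads < 2:
            continue
        cons = consensus_barcode([obs.barcode for obs in cl.members])
        for obs in cl.members:
            barcode = obs.barcode
            mismatches += sum(barcode[i] != cons[i] for i in positions)
        compared += cl.n_reads * len(positions)
    return mismatches / compared if compared else 0.0


def estimate_fixed_base_mismatch_rates(
    observations: Sequence[ReadObservation], design: BarcodeDesign
) -> pd.Series:
    """Fraction of reads mismatching each fixed base, before fixed-base filtering.

    Indels upstream of a fixed base shift it out of frame, so mismatch rates
    grow with distance from the sequencing primer site; pure substitution
    noise at rate e contributes e at every fixed position.
    """
    totals = {p: 0 for p, _ in design.fixed_positions}
    mism = {p: 0 for p, _ in design.fixed_positions}
    expected = design.fixed_map
    for obs in observations:
        barcode = obs.barcode
        if barcode is None:
            continue
        for p in totals:
            totals[p] += 1
            if barcode[p - 1] != expected[p]:
                mism[p] += 1
    rates = {p: (mism[p] / totals[p] if totals[p] else np.nan) for p in totals}
    return pd.Series(rates, name="mismatch_rate").sort_index()


def estimate_base_composition(
    clusters: Sequence[Cluster], design: BarcodeDesign
) -> pd.DataFrame:
    """Per-random-position A/C/G/T fractions among cluster consensus barcodes.

    Each cluster (molecule) votes once via its consensus, so PCR duplicates do
    not bias the composition estimate.  Rows sum to 1.
    """
    if not clusters:
        return pd.DataFrame(columns=list("ACGT"))
    consensuses = [consensus_barcode([obs.barcode for obs in cl.members]) for cl in clusters]
    rows = {}
    for p in sorted(design.random_positions):
        counts = Counter(c[p - 1] for c in consensuses)
        total = sum(counts.values())
        rows[p] = {base: counts.get(base, 0) / total for base in "ACGT"}
    return pd.DataFrame.from_dict(rows, orient="index")[list("ACGT")]


def plot_curve(curve: pd.DataFrame, ax=None, **kwargs):
    """Render a saturation curve (mean ± SD error bars) with matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(curve["swept"], curve["mean"], yerr=curve["sd"], marker="o", **kwargs)
    label = curve.attrs.get("swept_variable", "swept")
    ax.set_xlabel("number of random bases" if label == "random_bases" else "read fraction")
    ax.set_ylabel("number of clusters")
    if label == "coverage_fraction":
        ax.set_xscale("log")
    return ax
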