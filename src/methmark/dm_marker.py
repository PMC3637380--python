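"""Delta-beta differential methylation calling and marker selection.

The effect statistic is the difference of group-mean beta values,
``delta_beta = mean(beta, tumor) - mean(beta, reference)``.  A probe is
called *hyper*methylated when ``delta_beta > +threshold`` and
*hypo*methylated when ``delta_beta < -threshold`` (default threshold 0.3,
both inequalities strict, so a difference of exactly 0.30 is ``none``).
No significance test is attached: the threshold on the mean difference is
the whole rule.

A gene is a *group-specific* marker when at least one of its probes clears
the threshold in the same direction against **every** other tumor group
and the reference simultaneously — the probe-wise rule is evaluated
against all contrasts, then lifted to gene level via "one or more
qualifying probes".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ValidationError

__all__ = [
    "DMCallSet",
    "SpecificMarkerSet",
    "call_dm",
    "tabulate_dm",
    "select_specific_markers",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.3


@dataclass
class DMCallSet:
    """Per-probe delta-beta values and calls for one tumor-vs-reference contrast."""

    tumor: str
    reference: str
    threshold: float
    table: pd.DataFrame  # index probe_id; columns delta_beta, call, cpg_island

    @property
    def contrast(self) -> str:
        return f"{self.tumor}_vs_{self.reference}"

    def probes(self, call: str) -> set[str]:
        return set(self.table.index[self.table["call"] == call])

    @property
    def called(self) -> set[str]:
        return set(self.table.index[self.table["call"] != "none"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out.insert(1, "contrast", self.contrast)
        return out


@dataclass
class SpecificMarkerSet:
    """Genes exclusively hyper- or hypomethylated in one tumor group."""

    reference: str
    threshold: float
    table: pd.DataFrame  # columns gene_symbol, group, direction, probe_ids

    def genes(self, group: str, direction: str) -> set[str]:
        t = self.table
        m = (t["group"] == group) & (t["direction"] == direction)
        return set(t.loc[m, "gene_symbol"])

    def counts(self) -> pd.DataFrame:
        """Gene counts per group x direction, plus genes found in both directions."""
        rows = []
        for group in sorted(self.table["group"].unique()):
            hyper = self.genes(group, "hyper")
            hypo = self.genes(group, "hypo")
            rows.append(
                {
                    "group": group,
                    "n_hyper_genes": len(hyper),
                    "n_hypo_genes": len(hypo),
                    "n_both_directions": len(hyper & hypo),
                }
            )
        return pd.DataFrame(rows)


def _group_means(matrix: BetaMatrix, groups: list[str]) -> pd.DataFrame:
    """Arithmetic mean beta per probe per group over non-missing samples."""
    cols = {}
    for g in groups:
        samples = matrix.samples_of(g)
        if not samples:
            raise ValidationError(f"group {g!r} has no samples")
        cols[g] = matrix.beta[samples].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def call_dm(
    matrix: BetaMatrix,
    annotation: pd.DataFrame | None,
    tumor: str,
    reference: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> DMCallSet:
    """Call hyper/hypomethylated probes for one tumor against the reference.

    Missing beta values are excluded from the group means; a probe with no
    non-missing value in either group is excluded from the contrast and
    logged.
    """
    reference = reference if reference is not None else matrix.reference
    if tumor == reference:
        raise ValidationError("tumor and reference groups must differ")
    means = _group_means(matrix, [tumor, reference])
    delta = means[tumor] - means[reference]

    dropped = delta.index[delta.isna()]
    if len(dropped):
        log.warning(
            "%d probes missing in an entire group dropped from contrast %s vs %s",
            len(dropped), tumor, reference,
        )
    delta = delta.dropna()

    # Strict inequalities on the decimal value: deltas are rounded to 10
    # decimals before comparison so a difference that is exactly 0.30 in
    # decimal arithmetic (e.g. means 0.40 vs 0.10) is not pushed over the
    # threshold by float representation error.
    delta_cmp = np.round(delta.to_numpy(), 10)
    call = np.where(
        delta_cmp > threshold,
        "hyper",
        np.where(delta_cmp < -threshold, "hypo", "none"),
    )
    table = pd.DataFrame({"delta_beta": delta, "call": call}, index=delta.index)
    if annotation is not None:
        table["cpg_island"] = annotation.reindex(table.index)["cpg_island"]
    else:
        table["cpg_island"] = pd.NA
    table.index.name = "probe_id"
    return DMCallSet(tumor=tumor, reference=reference, threshold=threshold, table=table)


def tabulate_dm(callset: DMCallSet, annotation: pd.DataFrame) -> pd.DataFrame:
    """Probe and unique-gene counts per direction x CpG-island stratum.

    Genes are counted once per stratum regardless of how many of their
    probes are called.
    """
    ann = annotation.reindex(callset.table.index)
    rows = []
    for stratum, island_flag in (("island", True), ("non_island", False)):
        in_stratum = ann["cpg_island"] == island_flag
        for direction in ("hyper", "hypo"):
            mask = in_stratum & (callset.table["call"] == direction)
            probes = callset.table.index[mask]
            genes = ann.loc[probes, "gene_symbol"].dropna().unique()
            rows.append(
                {
                    "contrast": callset.contrast,
                    "stratum": stratum,
                    "direction": direction,
                    "n_probes": int(mask.sum()),
                    "n_genes": len(genes),
                }
            )
    return pd.DataFrame(rows)


def select_specific_markers(
    matrix: BetaMatrix,
    annotation: pd.DataFrame,
    groups: list[str] | None = None,
    reference: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SpecificMarkerSet:
    """Select genes specifically hyper/hypomethylated in exactly one group.

    A probe qualifies as group-G hyper-specific iff
    ``mean_beta(G) - mean_beta(X) > threshold`` for every X among the
    other tumor groups and the reference (hypo symmetric, ``< -threshold``).
    Island strata are combined.  Gene sets for a fixed direction are
    disjoint across groups by construction (the strict pairwise rule
    cannot hold for two groups at once).
    """
    reference = reference if reference is not None else matrix.reference
    groups = groups if groups is not None else matrix.tumor_entities
    if len(groups) < 2:
        raise ValidationError("specific-marker selection needs >=2 tumor groups")
    all_groups = list(groups) + [reference]
    means = _group_means(matrix, all_groups)

    rows = []
    for g in groups:
        others = [x for x in all_groups if x != g]
        diffs = means[others].rsub(means[g], axis=0).round(10)  # means[g] - means[other]
        hyper_mask = (diffs > threshold).all(axis=1) & diffs.notna().all(axis=1)
        hypo_mask = (diffs < -threshold).all(axis=1) & diffs.notna().all(axis=1)
        for direction, mask in (("hyper", hyper_mask), ("hypo", hypo_mask)):
            probes = means.index[mask]
            genes = annotation.reindex(probes)["gene_symbol"]
            for gene, probe_ids in genes.groupby(genes).groups.items():
                rows.append(
                    {
                        "gene_symbol": gene,
                        "group": g,
                        "direction": direction,
                        "probe_ids": ",".join(sorted(probe_ids)),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["gene_symbol", "group", "direction", "probe_ids"]
    )
    return SpecificMarkerSet(reference=reference, threshold=threshold, table=table)
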