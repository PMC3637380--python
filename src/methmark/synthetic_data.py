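"""Synthetic methylation cohorts with known planted structure.

The generator emits a group-structured beta matrix together with a probe
annotation and a truth registry, so every downstream stage (QC, delta-beta
calling, marker selection, clustering, single-locus classification) can be
tested against a known answer.

Noise model
-----------
Each cell is drawn from a Beta distribution parameterised by mean and
concentration, ``beta ~ Beta(mu * nu, (1 - mu) * nu)``, which is the
simplest bounded-support model consistent with methylation fractions in
[0, 1].  ``mu`` is the probe's group mean: a stratum baseline (CpG-island
probes sit near 0.08, open-sea probes near 0.65, emulating the bimodal
beta distribution of promoter arrays), shifted by +/- ``effect_size`` at
planted differential sites and clipped to [0.02, 0.98].  At the default
concentration nu = 50 the within-group SD is about 0.04-0.07, well below
the 0.2 SD exclusion used by probe QC, so planted structure survives QC.

Planted structure
-----------------
Per non-reference group, ``n_planted_hyper`` island probes are shifted up
and ``n_planted_hypo`` open-sea probes shifted down, each on its own gene,
with probe sets disjoint across groups (group-exclusive markers).  On top
of this a small panel of named marker genes (default ADRA1D, MGMT, VHL,
THBS1, several probes each) carries a tumor-type-specific pattern whose
offsets scale with ``effect_size``; at effect_size = 0 the whole matrix is
a pure null.  Detection p-values are Uniform(0, 0.04) except for dropout
cells, which draw Uniform(0.06, 0.5) to emulate occasional failed
detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_beta_matrix",
    "simulate_methyl_template",
    "DEFAULT_PANEL_PATTERN",
]

MU_CLIP = (0.02, 0.98)

# Per-gene, per-group offsets in units of effect_size, added to the gene's
# stratum baseline.  The pattern mirrors a four-marker diagnostic panel:
# THBS1 hypermethylated only in CCSK, MGMT in all tumors, VHL
# hypomethylated in CCSK and RTK, ADRA1D graded across groups.
DEFAULT_PANEL_PATTERN: dict[str, tuple[bool, dict[str, float]]] = {
    # gene: (cpg_island, {group: offset multiplier})
    "THBS1": (True, {"CCSK": 1.5}),
    "MGMT": (True, {"CCSK": 1.1, "RTK": 1.1, "ESFT": 1.1}),
    "VHL": (False, {"CCSK": -1.2, "RTK": -1.2}),
    "ADRA1D": (True, {"CCSK": 1.4, "RTK": 0.9}),
}


@dataclass
class SimulationConfig:
    """Conditions for a simulated cohort.

    Defaults mirror a small pediatric renal tumor study: three sarcoma
    entities (CCSK, RTK, ESFT) plus non-neoplastic kidney (NK) as the
    reference, six samples each, with a few dozen planted
    differentially-methylated probes per tumor at a mean beta difference
    of 0.45.
    """

    n_probes: int = 2000
    island_fraction: float = 0.7
    groups: tuple[tuple[str, int], ...] = (
        ("CCSK", 6),
        ("RTK", 6),
        ("ESFT", 6),
        ("NK", 6),
    )
    reference: str = "NK"
    n_planted_hyper: int = 50
    n_planted_hypo: int = 20
    effect_size: float = 0.45
    baseline_island_mean: float = 0.08
    baseline_open_mean: float = 0.65
    noise_concentration: float = 50.0
    dropout_rate: float = 0.005
    panel_pattern: Mapping[str, tuple[bool, Mapping[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_PATTERN)
    )
    probes_per_panel_gene: int = 3
    dm_threshold: float = 0.3  # used only to derive the truth marker registry
    seed: int = 0

    def validate(self) -> None:
        group_names = [g for g, _ in self.groups]
        if len(set(group_names)) != len(group_names):
            raise ValidationError("duplicate group labels in config")
        if self.reference not in group_names:
            raise ValidationError(f"reference {self.reference!r} not among groups")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValidationError("effect_size must be in [0, 1]")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValidationError("island_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must be in [0, 1]")
        n_tumors = len(group_names) - 1
        n_panel = len(self.panel_pattern) * self.probes_per_panel_gene
        n_island_needed = self.n_planted_hyper * n_tumors
        n_open_needed = self.n_planted_hypo * n_tumors
        n_island = int(round(self.n_probes * self.island_fraction))
        if n_island_needed + n_panel > n_island or n_open_needed + n_panel > (
            self.n_probes - n_island
        ):
            raise ValidationError(
                "infeasible config: planted sites exceed available probes"
            )

    @property
    def tumor_groups(self) -> list[str]:
        return [g for g, _ in self.groups if g != self.reference]


@dataclass
class SyntheticTruth:
    """Registry of planted structure; the recovery-test oracle.

    ``planted_sites`` has one row per planted probe x group with its
    direction and configured mean beta difference against the reference.
    ``specific_markers`` lists genes whose configured group means make
    them group-specific at the configured delta-beta threshold (the same
    rule the marker-selection stage applies, evaluated on the noise-free
    means).
    """

    planted_sites: pd.DataFrame  # probe_id, group, direction, true_delta
    specific_markers: pd.DataFrame  # gene_symbol, group, direction
    group_means: pd.DataFrame  # probes x groups configured mu

    def planted_probes(self, group: str | None = None, direction: str | None = None) -> set[str]:
        t = self.planted_sites
        if group is not None:
            t = t[t["group"] == group]
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t["probe_id"])


def _derive_specific_markers(
    mu: pd.DataFrame, gene_of: pd.Series, groups: Sequence[str], reference: str, threshold: float
) -> pd.DataFrame:
    """Apply the marker-selection rule to the configured (noise-free) means."""
    tumors = [g for g in groups if g != reference]
    rows = []
    for probe in mu.index:
        gene = gene_of[probe]
        for g in tumors:
            others = [x for x in groups if x != g]
            deltas = mu.loc[probe, g] - mu.loc[probe, others]
            if (deltas > threshold).all():
                rows.append((gene, g, "hyper", probe))
            elif (deltas < -threshold).all():
                rows.append((gene, g, "hypo", probe))
    frame = pd.DataFrame(rows, columns=["gene_symbol", "group", "direction", "probe_id"])
    return (
        frame.drop_duplicates(subset=["gene_symbol", "group", "direction"])
        .reset_index(drop=True)
    )


def simulate_beta_matrix(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort; returns (matrix, annotation, truth).

    The same seed always yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_probes
    probe_ids = [f"cg{i:06d}" for i in range(n)]
    n_island = int(round(n * config.island_fraction))
    island = np.zeros(n, dtype=bool)
    island_idx = rng.choice(n, size=n_island, replace=False)
    island[island_idx] = True

    group_names = [g for g, _ in config.groups]
    baselines = np.where(island, config.baseline_island_mean, config.baseline_open_mean)

    # per-gene symbols; each probe its own gene unless overridden by panel
    gene_of = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)

    mu = pd.DataFrame(
        np.tile(baselines[:, None], (1, len(group_names))),
        index=probe_ids,
        columns=group_names,
    )

    island_pool = [i for i in range(n) if island[i]]
    open_pool = [i for i in range(n) if not island[i]]
    # deterministic draw order: panel probes first, then planted per group
    pool_iters = {"island": iter(island_pool), "open": iter(open_pool)}

    def take(stratum: str, k: int) -> list[int]:
        it = pool_iters[stratum]
        return [next(it) for _ in range(k)]

    # panel genes: several probes each with a group-specific mean pattern
    for gene, (is_island, offsets) in config.panel_pattern.items():
        idx = take("island" if is_island else "open", config.probes_per_panel_gene)
        for i in idx:
            island[i] = is_island
            gene_of[i] = gene
            for grp, mult in offsets.items():
                if grp in group_names:
                    mu.iloc[i, mu.columns.get_loc(grp)] = np.clip(
                        baselines[i] + mult * config.effect_size, *MU_CLIP
                    )

    planted_rows = []
    for grp in config.tumor_groups:
        hyper_idx = take("island", config.n_planted_hyper)
        hypo_idx = take("open", config.n_planted_hypo)
        for i in hyper_idx:
            shifted = float(np.clip(baselines[i] + config.effect_size, *MU_CLIP))
            mu.iloc[i, mu.columns.get_loc(grp)] = shifted
            planted_rows.append((probe_ids[i], grp, "hyper", shifted - baselines[i]))
        for i in hypo_idx:
            shifted = float(np.clip(baselines[i] - config.effect_size, *MU_CLIP))
            mu.iloc[i, mu.columns.get_loc(grp)] = shifted
            planted_rows.append((probe_ids[i], grp, "hypo", shifted - baselines[i]))

    planted = pd.DataFrame(
        planted_rows, columns=["probe_id", "group", "direction", "true_delta"]
    )

    # sample the beta and detection-p matrices
    sample_ids: list[str] = []
    entity: list[str] = []
    cols = []
    nu = config.noise_concentration
    for grp, n_samples in config.groups:
        mu_g = np.clip(mu[grp].to_numpy(), *MU_CLIP)
        for j in range(n_samples):
            sample_ids.append(f"{grp}{j + 1}")
            entity.append(grp)
            cols.append(rng.beta(mu_g * nu, (1.0 - mu_g) * nu))
    beta = pd.DataFrame(np.column_stack(cols), index=probe_ids, columns=sample_ids)

    shape = beta.shape
    detection = rng.uniform(0.0, 0.04, size=shape)
    dropout = rng.random(size=shape) < config.dropout_rate
    detection[dropout] = rng.uniform(0.06, 0.5, size=int(dropout.sum()))
    detection_p = pd.DataFrame(detection, index=probe_ids, columns=sample_ids)

    annotation = pd.DataFrame(
        {
            "gene_symbol": gene_of,
            "cpg_island": island,
            "chrom": "chrS",
            "pos": np.arange(1, n + 1) * 1000,
            "strand": "+",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    matrix = BetaMatrix(
        beta=beta,
        detection_p=detection_p,
        entity_of=pd.Series(entity, index=sample_ids, name="entity"),
        reference=config.reference,
    )
    gene_series = pd.Series(gene_of, index=probe_ids)
    specific = _derive_specific_markers(
        mu, gene_series, group_names, config.reference, config.dm_threshold
    )
    truth = SyntheticTruth(planted_sites=planted, specific_markers=specific, group_means=mu)
    return matrix, annotation, truth


# -- bisulfite templates ------------------------------------------------------


def random_template_sequence(
    length: int, cpg_positions: Sequence[int], rng: np.random.Generator
) -> str:
    """Random DNA of ``length`` bp whose only CpG dinucleotides sit at the
    given 1-based positions (position = the C of the CpG)."""
    for p in cpg_positions:
        if not 1 <= p < length:
            raise ValidationError(f"CpG position {p} outside sequence of length {length}")
    seq = rng.choice(list("ACGT"), size=length).astype(object)
    for p in cpg_positions:
        seq[p - 1] = "C"
        seq[p] = "G"
    wanted = set(cpg_positions)
    # destroy accidental CpGs without touching the planted ones
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and (i + 1) not in wanted:
            if i + 2 in wanted:  # next base is a planted C; change this C
                seq[i] = "A"
            else:
                seq[i + 1] = "A"
    return "".join(seq)


def simulate_methyl_template(
    length: int,
    cpg_positions: Sequence[int],
    methylation: Mapping[int, float],
    n_molecules: int = 1000,
    seed: int = 0,
    sequence: str | None = None,
):
    """Generate a population of template molecules with per-CpG methylation.

    Each CpG of each molecule is methylated independently with its site's
    configured fraction (a Bernoulli draw), emulating the 0/50/100 %
    methylated control DNAs of a restriction-digest assay at intermediate
    fractions.  Returns a :class:`~methmark.bisulfite_cobra.MethylTemplate`.
    """
    from .bisulfite_cobra import MethylTemplate

    rng = np.random.default_rng(seed)
    positions = sorted(cpg_positions)
    if sequence is None:
        sequence = random_template_sequence(length, positions, rng)
    for p in positions:
        if p not in methylation:
            raise ValidationError(f"no methylation fraction supplied for CpG at {p}")
        if not 0.0 <= methylation[p] <= 1.0:
            raise ValidationError(f"methylation fraction at {p} outside [0, 1]")
    fractions = np.array([methylation[p] for p in positions])
    states = rng.random(size=(n_molecules, len(positions))) < fractions
    return MethylTemplate(
        sequence=sequence, cpg_positions=tuple(positions), methyl_states=states
    )
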