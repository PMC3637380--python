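import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methmark.bisulfite_cobra import TaggedPrimer, reverse_complement
from methmark.io_formats import BetaMatrix
from methmark.synthetic_data import SimulationConfig, simulate_beta_matrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# Tagged primer pair used throughout the bisulfite/COBRA tests; the genomic
# parts contain no cytosine (they are written against the converted top
# strand), so a template embedding them amplifies irrespective of
# methylation state.
THBS1_F = TaggedPrimer("THBS1_F", "aggaagagagGGAGAGAGGAGTTTAGATTGGTTTT")
THBS1_R = TaggedPrimer(
    "THBS1_R", "cagtaatacgactcactatagggagaaggctACCTTACCCTAAAAAATCCTCCAAC"
)


def make_matrix(beta_rows, entities, probe_ids=None, detection=None, reference="NK"):
    """Small BetaMatrix from a dict/array of rows and a sample->entity list."""
    beta = pd.DataFrame(beta_rows, dtype=float)
    if probe_ids is not None:
        beta.index = probe_ids
    else:
        beta.index = [f"p{i}" for i in range(len(beta))]
    n_per = {}
    sample_ids = []
    for e in entities:
        n_per[e] = n_per.get(e, 0) + 1
        sample_ids.append(f"{e}_{n_per[e]}")
    beta.columns = sample_ids
    if detection is None:
        det = pd.DataFrame(0.01, index=beta.index, columns=beta.columns)
    else:
        det = pd.DataFrame(np.asarray(detection, dtype=float), index=beta.index, columns=beta.columns)
    return BetaMatrix(
        beta=beta,
        detection_p=det,
        entity_of=pd.Series(entities, index=sample_ids),
        reference=reference,
    )


def make_annotation(probe_ids, genes=None, island=None):
    n = len(probe_ids)
    return pd.DataFrame(
        {
            "gene_symbol": genes if genes is not None else [f"G{i}" for i in range(n)],
            "cpg_island": island if island is not None else [True] * n,
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 100,
            "strand": "+",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def embed_template(middle: str) -> tuple[str, int]:
    """Template = forward site + middle + reverse-complemented reverse site.

    Returns (sequence, offset) where positions in `middle` map to template
    position offset + i (1-based).
    """
    fsite = THBS1_F.genomic
    rsite = reverse_complement(THBS1_R.genomic)
    return fsite + middle + rsite, len(fsite)


def complete_linkage_oracle(points: np.ndarray) -> list[tuple[float, frozenset, frozenset]]:
    """Naive agglomerative complete-linkage clustering.

    Base pairwise distances are Euclidean (taken from scipy's pdist so the
    floating-point primitive matches); the agglomeration itself is an
    independent O(n^3) re-implementation.  Returns the merge history as
    (height, members_a, members_b), heights non-decreasing.
    """
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        merges.append((dist, frozenset(clusters[i]), frozenset(clusters[j])))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged synthetic study: 4 groups x 6 samples, 2000 probes,
    50 hyper + 20 hypo planted per tumor group at effect 0.45, seed 1."""
    config = SimulationConfig(seed=1)
    matrix, annotation, truth = simulate_beta_matrix(config)
    return config, matrix, annotation, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Same conditions with effect_size=0: nothing planted anywhere."""
    config = SimulationConfig(seed=1, effect_size=0.0)
    matrix, annotation, truth = simulate_beta_matrix(config)
    return config, matrix, annotation, truth
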