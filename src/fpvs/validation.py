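"""Statistical validation studies: type-I-error calibration and recovery.

These run the full analysis chain on synthetic data with known ground truth:

* :func:`null_rejection_rate` simulates cohorts with a zero oddball effect
  and measures how often the cluster permutation test reports any significant
  cluster — the family-wise false-positive rate, which should sit near the
  nominal alpha.
* :func:`patch_recovery` seeds a contiguous sensor patch with an elevated
  oddball response at the response level and measures how often the test
  finds a significant cluster that overlaps the seeded patch (Jaccard index).

Problem sizes default to scaled-down study dimensions (fewer subjects and
shorter trials than the full design) so a few hundred replicates run on one
CPU in minutes; the observable per-sensor SNR levels are kept in the range
of the full-scale design.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .cluster import AdjacencyGraph, ClusterTestConfig, build_adjacency, cluster_permutation_test
from .pipeline import RunConfig, run_pipeline
from .simulate import SimulationConfig, make_layout
from .utils import derive_seed

__all__ = ["null_rejection_rate", "patch_recovery", "contiguous_patch"]


def null_rejection_rate(
    n_cohorts: int = 200,
    n_subjects: int = 17,
    n_sensors: int = 160,
    trial_duration: float = 30.0,
    n_trials: int = 1,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate under a zero seeded oddball effect.

    Each cohort is simulated, reduced to oddball responses, and cluster-tested
    against the SNR noise level of 1; returns the fraction of cohorts with at
    least one significant cluster.

    The defaults keep the two features the test's operating characteristics
    depend on at study scale: the subject count (df of the t threshold) and a
    frequency grid fine enough that the 21-bin SNR baseline window stays in
    the locally flat part of the 1/f spectrum (single 30-s trials; much
    shorter epochs widen the window into the curved region and bias the null
    SNR below 1).
    """
    rejections = 0
    for i in range(n_cohorts):
        cfg = RunConfig(
            n_subjects=n_subjects,
            conditions=[0],
            condition_effects={0: 0.0},
            simulation=SimulationConfig(
                n_sensors=n_sensors,
                trial_duration=trial_duration,
                n_trials=n_trials,
            ),
            n_permutations=n_permutations,
            alpha=alpha,
            seed=derive_seed(seed, "null-cohort", i),
        )
        report = run_pipeline(cfg)
        if report.cluster_results[0].significant_clusters:
            rejections += 1
    return rejections / n_cohorts


def contiguous_patch(adjacency: AdjacencyGraph, center: int, size: int) -> np.ndarray:
    """Breadth-first set of ``size`` mutually connected sensors around a center."""
    seen = [center]
    queue = deque([center])
    while queue and len(seen) < size:
        for j in sorted(adjacency.neighbors[queue.popleft()]):
            if j not in seen:
                seen.append(j)
                queue.append(j)
                if len(seen) == size:
                    break
    if len(seen) < size:
        raise ValueError("graph too small for the requested patch")
    return np.asarray(seen[:size])


def patch_recovery(
    n_runs: int = 20,
    n_subjects: int = 20,
    n_sensors: int = 160,
    patch_size: int = 10,
    effect: float = 2.0,
    subject_noise_sd: float = 0.7,
    jaccard_threshold: float = 0.7,
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict:
    """Recovery of a seeded contiguous response patch at the response level.

    Responses are drawn per subject and sensor around the noise level 1
    (between-subject sd ``subject_noise_sd``); patch sensors get ``effect``
    added, i.e. a per-sensor mean SNR of 1 + effect (~3 with the default).
    A run counts as a success when some significant cluster has Jaccard
    overlap >= ``jaccard_threshold`` with the seeded patch.
    """
    layout = make_layout(n_sensors)
    adjacency = build_adjacency(layout)
    # posterior-most sensor as patch anchor
    center = int(np.argmin(layout.positions[:, 1]))
    patch = contiguous_patch(adjacency, center, patch_size)
    patch_set = set(patch.tolist())
    successes = 0
    jaccards = []
    for i in range(n_runs):
        rng = np.random.default_rng(derive_seed(seed, "recovery", i))
        X = rng.normal(1.0, subject_noise_sd, size=(n_subjects, n_sensors))
        X[:, patch] += effect
        res = cluster_permutation_test(
            X,
            adjacency,
            ClusterTestConfig(
                n_permutations=n_permutations, seed=derive_seed(seed, "perm", i)
            ),
        )
        best = 0.0
        for c in res.significant_clusters:
            members = set(c.members)
            best = max(
                best, len(members & patch_set) / len(members | patch_set)
            )
        jaccards.append(best)
        if best >= jaccard_threshold:
            successes += 1
    return {
        "n_runs": n_runs,
        "successes": successes,
        "jaccards": jaccards,
        "patch": patch.tolist(),
    }
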