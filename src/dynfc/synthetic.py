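"""Synthetic two-group ROI time-series cohorts with planted connectivity states.

Real resting-state cohorts of this kind are rarely shareable, so every
downstream stage is exercised against simulated data with known ground
truth.  Each subject's brain alternates between a small number of latent
connectivity *states* following a first-order Markov chain with geometric
dwell times; while a state is active the ROI signal at each time point is
an independent draw from a zero-mean multivariate normal with that state's
covariance, plus white observation noise.  State covariances are modular
(block-structured correlation matrices) with the ROI-to-block assignment
permuted per state, so each state has a distinct connectivity-strength
profile.  One state's stationary occupancy can differ between the two
groups, planting a detectable "group-specific pattern" signal.

The generator mirrors a two-site acquisition: the two groups default to
different sampling intervals (TR 3.0 s vs 2.0 s) and run lengths (150 vs
215 retained volumes).

All randomness flows from a single cohort seed; per-subject streams are
spawned deterministically, so a cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RoiTimeSeries

__all__ = [
    "StateSpec",
    "CohortConfig",
    "SyntheticCohort",
    "make_state_covariances",
    "sample_state_sequence",
    "generate_subject_timeseries",
    "generate_cohort",
    "make_cohort_config",
    "window_state_labels",
    "segment_state_labels",
]

GROUP_A = "patient"
GROUP_B = "control"


@dataclass
class StateSpec:
    """One latent connectivity state.

    ``covariance`` is a symmetric positive-definite n_roi x n_roi matrix;
    ``occupancy_by_group`` gives the stationary probability of the state per
    group (summing to 1 across a config's states within each group);
    ``mean_dwell`` is the expected consecutive time points spent in the
    state per visit.
    """

    state_id: int
    covariance: np.ndarray
    occupancy_by_group: dict[str, float]
    mean_dwell: float = 40.0

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError(f"state {self.state_id}: covariance not symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError(f"state {self.state_id}: covariance not positive definite")
        if self.mean_dwell < 2:
            raise ValueError(f"state {self.state_id}: mean_dwell must be >= 2")


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort."""

    n_subjects_per_group: int
    states: list[StateSpec]
    n_roi: int = 246
    tr_by_group: dict[str, float] = field(
        default_factory=lambda: {GROUP_A: 3.0, GROUP_B: 2.0}
    )
    n_timepoints_by_group: dict[str, int] = field(
        default_factory=lambda: {GROUP_A: 150, GROUP_B: 215}
    )
    observation_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < 3:
            raise ValueError("n_roi must be >= 3")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        for g, occ_sum in self._occupancy_sums().items():
            if abs(occ_sum - 1.0) > 1e-9:
                raise ValueError(f"group {g!r}: state occupancies sum to {occ_sum}")
        for s in self.states:
            if s.covariance.shape != (self.n_roi, self.n_roi):
                raise ValueError(
                    f"state {s.state_id}: covariance shape {s.covariance.shape} "
                    f"!= ({self.n_roi}, {self.n_roi})"
                )

    def _occupancy_sums(self) -> dict[str, float]:
        groups = set()
        for s in self.states:
            groups.update(s.occupancy_by_group)
        return {
            g: sum(s.occupancy_by_group.get(g, 0.0) for s in self.states)
            for g in groups
        }

    @property
    def groups(self) -> list[str]:
        return list(self.tr_by_group)


@dataclass
class SyntheticCohort:
    """Generated cohort: manifest, per-subject series, and ground truth."""

    config: CohortConfig
    subjects: list[RoiTimeSeries]
    manifest: pd.DataFrame
    state_sequences: dict[str, np.ndarray]

    def occupancy_table(self) -> pd.DataFrame:
        """Empirical per-subject state occupancies (ground truth)."""
        n_states = len(self.config.states)
        rows = []
        for ts in self.subjects:
            seq = self.state_sequences[ts.subject_id]
            occ = np.bincount(seq, minlength=n_states) / seq.size
            rows.append([ts.subject_id, ts.group, *occ])
        return pd.DataFrame(
            rows,
            columns=["subject_id", "group"]
            + [f"state_{s.state_id}" for s in self.config.states],
        )


# ---------------------------------------------------------------------------
# State covariances


def _block_sizes(n_roi: int, n_blocks: int) -> np.ndarray:
    """Unequal block sizes in geometric proportion 1:2:4:... (distinct on
    purpose: permuting ROIs between different-sized blocks changes each
    ROI's expected connectivity strength, and the dominant block gives each
    state a strong hub module, keeping states well separated in strength
    space)."""
    w = 2.0 ** np.arange(n_blocks)
    sizes = np.floor(n_roi * w / w.sum()).astype(int)
    sizes[sizes < 1] = 1
    # distribute the remainder over the largest blocks
    i = n_blocks - 1
    while sizes.sum() < n_roi:
        sizes[i] += 1
        i = (i - 1) % n_blocks
    while sizes.sum() > n_roi:
        j = int(np.argmax(sizes))
        sizes[j] -= 1
    return sizes


def _nearest_pd_correlation(mat: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at a floor and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() > eig_floor:
        return mat
    vals = np.clip(vals, eig_floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    if np.linalg.eigvalsh(repaired).min() <= 0:
        raise ValueError("covariance repair failed to produce a PD matrix")
    return repaired


def make_state_covariances(
    n_roi: int,
    n_states: int,
    n_blocks: int = 4,
    within_r: float = 0.9,
    between_r: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Block-structured correlation matrices, one per state.

    Each matrix has unit diagonal, correlation ``within_r`` inside a block
    and ``between_r`` across blocks; the assignment of ROIs to the
    (unequal-sized) blocks is permuted independently per state.  Matrices
    are repaired to positive definiteness if needed.
    """
    if not (0 <= between_r <= within_r < 1):
        raise ValueError("need 0 <= between_r <= within_r < 1")
    if between_r == within_r and within_r > 0:
        raise ValueError("between_r must be strictly below a nonzero within_r")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    rng = np.random.default_rng(seed)
    sizes = _block_sizes(n_roi, n_blocks)
    block_of_base = np.repeat(np.arange(n_blocks), sizes)
    covs = []
    for _ in range(n_states):
        block_of = block_of_base[rng.permutation(n_roi)]
        same = block_of[:, None] == block_of[None, :]
        mat = np.where(same, within_r, between_r)
        np.fill_diagonal(mat, 1.0)
        covs.append(_nearest_pd_correlation(mat))
    return covs


# ---------------------------------------------------------------------------
# State dynamics and signals


def sample_state_sequence(
    n_timepoints: int,
    state_specs: list[StateSpec],
    group: str,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Markov state sequence with geometric dwells and target occupancy.

    Per time point the chain stays in state i with probability
    1 - 1/mean_dwell_i; on a jump event the next state (which may be i
    itself) is drawn with probability proportional to
    occupancy_j / mean_dwell_j.  This makes the stationary occupancy
    exactly the configured one; the realised mean dwell is
    mean_dwell_i / (1 - q_i) where q_i is state i's jump probability
    (exact occupancy and exact nominal dwell cannot hold simultaneously
    in a Markov chain).  Returns 0-based state indices into
    ``state_specs``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.array([s.occupancy_by_group.get(group, 0.0) for s in state_specs])
    if pi.sum() <= 0:
        raise ValueError(f"no occupancy defined for group {group!r}")
    pi = pi / pi.sum()
    dwell = np.array([s.mean_dwell for s in state_specs], dtype=float)
    q = np.where(pi > 0, pi / dwell, 0.0)
    q = q / q.sum()
    n_states = len(state_specs)
    seq = np.empty(n_timepoints, dtype=int)
    current = int(rng.choice(n_states, p=pi))
    for t in range(n_timepoints):
        seq[t] = current
        if rng.random() < 1.0 / dwell[current]:
            current = int(rng.choice(n_states, p=q))
    return seq


def generate_subject_timeseries(
    config: CohortConfig, group: str, subject_seed: int | np.random.SeedSequence
) -> tuple[RoiTimeSeries, np.ndarray]:
    """One subject's ROI x time matrix plus its ground-truth state sequence.

    At each time point the signal is an independent draw from the active
    state's zero-mean multivariate normal, plus isotropic observation noise.
    """
    rng = np.random.default_rng(subject_seed)
    n_t = config.n_timepoints_by_group[group]
    seq = sample_state_sequence(n_t, config.states, group, rng)
    chols = []
    for s in config.states:
        try:
            chols.append(np.linalg.cholesky(s.covariance))
        except np.linalg.LinAlgError:
            raise ValueError(
                f"state {s.state_id}: covariance is not positive definite "
                "(Cholesky failed)"
            ) from None
    z = rng.standard_normal((config.n_roi, n_t))
    series = np.empty_like(z)
    for s_idx, chol in enumerate(chols):
        cols = seq == s_idx
        if cols.any():
            series[:, cols] = chol @ z[:, cols]
    if config.observation_noise_sd > 0:
        series += config.observation_noise_sd * rng.standard_normal(series.shape)
    ts = RoiTimeSeries(
        subject_id="",
        group=group,
        tr=config.tr_by_group[group],
        series=series,
    )
    return ts, seq


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate every subject of a two-group cohort, deterministically.

    Per-subject random streams are spawned from the cohort seed, so
    generation order (or parallelism) cannot change the output.
    """
    subjects: list[RoiTimeSeries] = []
    sequences: dict[str, np.ndarray] = {}
    rows = []
    for g_idx, group in enumerate(config.groups):
        for s_idx in range(config.n_subjects_per_group):
            seed = np.random.SeedSequence(
                config.seed, spawn_key=(g_idx, s_idx)
            )
            ts, seq = generate_subject_timeseries(config, group, seed)
            ts.subject_id = f"{group}_{s_idx + 1:03d}"
            subjects.append(ts)
            sequences[ts.subject_id] = seq
            rows.append(
                [ts.subject_id, group, config.tr_by_group[group], f"{ts.subject_id}.tsv"]
            )
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "tr", "path"])
    return SyntheticCohort(
        config=config, subjects=subjects, manifest=manifest, state_sequences=sequences
    )


# ---------------------------------------------------------------------------
# Study-design presets and truth utilities


def make_cohort_config(
    n_subjects_per_group: int = 34,
    n_roi: int = 246,
    n_states: int = 5,
    differential_occupancy: tuple[float, float] = (0.45, 0.05),
    n_blocks: int = 4,
    within_r: float = 0.9,
    between_r: float = 0.0,
    observation_noise_sd: float = 0.2,
    mean_dwell: float = 40.0,
    seed: int = 0,
) -> CohortConfig:
    """Standard planted-difference design: state 1's occupancy differs
    between groups (defaults 0.45 vs 0.05); the remaining probability mass
    is split evenly over the other states.  Pass equal values in
    ``differential_occupancy`` for a null (no group difference) cohort.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    covs = make_state_covariances(
        n_roi, n_states, n_blocks=n_blocks, within_r=within_r,
        between_r=between_r, seed=seed,
    )
    occ_a, occ_b = differential_occupancy
    states = []
    for i, cov in enumerate(covs):
        if n_states == 1:
            occ = {GROUP_A: 1.0, GROUP_B: 1.0}
        elif i == 0:
            occ = {GROUP_A: occ_a, GROUP_B: occ_b}
        else:
            occ = {
                GROUP_A: (1 - occ_a) / (n_states - 1),
                GROUP_B: (1 - occ_b) / (n_states - 1),
            }
        states.append(
            StateSpec(state_id=i, covariance=cov, occupancy_by_group=occ,
                      mean_dwell=mean_dwell)
        )
    return CohortConfig(
        n_subjects_per_group=n_subjects_per_group,
        states=states,
        n_roi=n_roi,
        observation_noise_sd=observation_noise_sd,
        seed=seed,
    )


def window_state_labels(seq: np.ndarray, w: int, step: int = 1) -> np.ndarray:
    """Dominant ground-truth state per sliding window (majority vote;
    ties break toward the smaller state id)."""
    n_windows = (seq.size - w) // step + 1
    n_states = int(seq.max()) + 1
    out = np.empty(n_windows, dtype=int)
    for b in range(n_windows):
        counts = np.bincount(seq[b * step : b * step + w], minlength=n_states)
        out[b] = int(np.argmax(counts))
    return out


def segment_state_labels(
    seq: np.ndarray, segments: list[tuple[int, int]], w: int, step: int = 1
) -> np.ndarray:
    """Dominant ground-truth state per segment of the window axis."""
    win_labels = window_state_labels(seq, w, step)
    n_states = win_labels.max() + 1
    return np.array(
        [
            int(np.argmax(np.bincount(win_labels[s:e], minlength=n_states)))
            for s, e in segments
        ]
    )


# ---------------------------------------------------------------------------
# Ground-truth evaluation helpers for simulated cohorts


def empirical_state_centers(cohort: SyntheticCohort, results) -> np.ndarray:
    """Per-state mean dFC-strength vector, using the ground-truth sequences.

    Each window is attributed to its dominant true state; the state's center
    is the mean of the attributed dFCS columns pooled over subjects.  Rows
    are ordered by state id.  ``results`` is a fitted
    :class:`~dynfc.model.ConnectomeDynamicsResults` on the same cohort.
    """
    n_states = len(cohort.config.states)
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for ts in cohort.subjects:
        w = results.tensors[ts.subject_id].window_length
        labels = window_state_labels(cohort.state_sequences[ts.subject_id], w)
        values = results.dfcs[ts.subject_id].values
        for s in range(n_states):
            m = labels == s
            if m.any():
                sums[s] = sums.get(s, 0) + values[:, m].sum(axis=1)
                counts[s] = counts.get(s, 0) + int(m.sum())
    return np.vstack([sums[s] / counts[s] for s in sorted(sums)])


def match_patterns_to_states(results, cohort: SyntheticCohort):
    """Match fitted patterns to planted states by center correlation.

    Returns a dict with the greedy ``matching`` (0-based cluster -> state),
    the correlation matrix, ``perfect`` (K equals the number of visited
    states, the matching is a bijection, and each cluster's matched state is
    its argmax correlation), and ``state0_cluster`` — the 1-based cluster id
    matched to the differential state 0, or None.
    """
    from .inference import match_clusters_by_correlation

    centers_true = empirical_state_centers(cohort, results)
    pairs, corr = match_clusters_by_correlation(
        results.clustering.final_centers, centers_true
    )
    n_states = centers_true.shape[0]
    bijection = len({j for _, j in pairs}) == n_states
    argmax_ok = all(int(np.nanargmax(corr[i])) == j for i, j in pairs)
    state_of_cluster = dict(pairs)
    cluster_of_state = {j: i for i, j in pairs}
    return {
        "matching": state_of_cluster,
        "correlation": corr,
        "perfect": results.k == n_states and bijection and argmax_ok,
        "state0_cluster": (
            cluster_of_state[0] + 1 if 0 in cluster_of_state else None
        ),
    }
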