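"""Synthetic resting-state cohorts with planted modular correlation structure.

Each subject's node time series are drawn from a Gaussian factor model: every
node loads on one latent module factor (shared by all nodes of its module), on
one global factor shared by all nodes, and carries independent observation
noise.  The two mixing weights are solved analytically so that the population
correlation between two nodes equals ``within_r`` when they share a module and
``between_r`` otherwise:

    x_i(t) = a * f_{m(i)}(t) + b * g(t) + e_i(t),   e_i ~ N(0, noise_sd^2)

    total variance v = noise_sd^2 / (1 - within_r)
    a^2 = (within_r - between_r) * v
    b^2 = between_r * v

Cohorts are collections of such subjects organized into named groups; a group
may reassign selected nodes to a different module, which is the planted
group-difference that the downstream modular-architecture tests are meant to
recover.  Per-subject seeds are derived from the design's master seed and the
(group index, subject index) pair, so adding a group never changes the series
of existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .parcellation import aal116_labels

DEFAULT_N_VOLUMES = 200
DEFAULT_TR_SECONDS = 2.5


@dataclass
class TimeSeriesMatrix:
    """Per-subject node x volume signal matrix with its sampling interval."""

    values: np.ndarray
    tr_seconds: float = DEFAULT_TR_SECONDS
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_nodes x n_volumes) matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 volumes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.node_ids is None:
            self.node_ids = [f"node{i}" for i in range(self.values.shape[0])]
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length must equal the number of rows")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupSpec:
    """One group of a cohort design.

    ``partition`` maps node id -> module label; ``noi_reassignments`` moves the
    named nodes to a different (existing) module for this group only.
    """

    name: str
    n_subjects: int
    within_r: float = 0.6
    between_r: float = 0.1
    noise_sd: float = 1.0
    noi_reassignments: dict[str, int] = field(default_factory=dict)
    partition: dict[str, int] | None = None


@dataclass
class CohortDesign:
    groups: list[GroupSpec]
    partition: dict[str, int] | None = None  # shared default generative partition
    n_volumes: int = DEFAULT_N_VOLUMES
    tr_seconds: float = DEFAULT_TR_SECONDS
    master_seed: int = 0


@dataclass
class Cohort:
    subjects: dict[str, list[TimeSeriesMatrix]]  # group name -> subjects
    design: CohortDesign
    seeds: dict[str, list[int]]

    @property
    def node_ids(self) -> list[str]:
        first = next(iter(self.subjects.values()))
        return list(first[0].node_ids)


def default_partition(node_ids: list[str] | None = None) -> dict[str, int]:
    """A stylized five-module partition of the 116-region node set.

    Modules loosely follow the canonical resting-state decomposition: visual,
    sensorimotor/auditory, default-mode + frontal control + dorsal parietal,
    orbitofrontal/limbic/temporal, and subcortical-cerebellar.  It is a
    generative fixture, not an empirical map.
    """
    if node_ids is None:
        node_ids = aal116_labels()
    groups = {
        1: {"CAL", "CUN", "LING", "SOG", "MOG", "IOG", "FFG"},
        2: {"PreC", "PostC", "PCL", "SPG", "SMA", "ROL", "HES", "STG"},
        3: {"SFGdor", "SFGmed", "MFG", "ACG", "DCG", "PCG", "PCUN", "ANG",
            "IPL", "SMG", "CAU", "THA"},
        4: {"ORBsup", "ORBmid", "ORBinf", "ORBsupmed", "REC", "OLF", "AMYG",
            "HIP", "PHG", "INS", "IFGoper", "IFGtriang", "TPOsup", "TPOmid",
            "MTG", "ITG"},
    }
    partition: dict[str, int] = {}
    for nid in node_ids:
        abbr = nid.split(".")[0]
        module = 5  # subcortical-cerebellar catch-all
        for label, members in groups.items():
            if abbr in members:
                module = label
                break
        partition[nid] = module
    return partition


def _mixing_weights(within_r: float, between_r: float, noise_sd: float):
    if not (0.0 <= between_r <= within_r < 1.0):
        raise ValueError(
            "need 0 <= between_r <= within_r < 1; got "
            f"within_r={within_r}, between_r={between_r} "
            "(the implied covariance would not be positive definite)"
        )
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    v = noise_sd**2 / (1.0 - within_r)
    a = np.sqrt((within_r - between_r) * v)
    b = np.sqrt(between_r * v)
    return a, b


def generate_subject_timeseries(
    partition: dict[str, int],
    n_volumes: int = DEFAULT_N_VOLUMES,
    within_r: float = 0.6,
    between_r: float = 0.1,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> TimeSeriesMatrix:
    """Draw one subject's node time series from the block factor model.

    The expected sample correlation between two nodes is ``within_r`` if they
    share a module under ``partition`` and ``between_r`` otherwise.  Output is
    deterministic for a fixed seed.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    node_ids = list(partition.keys())
    labels = np.asarray([partition[nid] for nid in node_ids])
    modules = np.unique(labels)
    a, b = _mixing_weights(within_r, between_r, noise_sd)
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((len(modules), n_volumes))
    global_factor = rng.standard_normal(n_volumes)
    noise = rng.standard_normal((len(node_ids), n_volumes)) * noise_sd
    module_index = np.searchsorted(modules, labels)
    values = a * factors[module_index] + b * global_factor + noise
    return TimeSeriesMatrix(values, tr_seconds=tr_seconds, node_ids=node_ids)


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic per-subject seed fan-out, stable under added groups."""
    ss = np.random.SeedSequence([int(master_seed), int(group_index), int(subject_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate every group of a cohort design.

    Each group's subjects are drawn with the group partition after applying its
    node reassignments.  Identical designs yield bit-identical cohorts.
    """
    names = [g.name for g in design.groups]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names in design: {names}")
    base = design.partition or default_partition()
    subjects: dict[str, list[TimeSeriesMatrix]] = {}
    seeds: dict[str, list[int]] = {}
    for gi, group in enumerate(design.groups):
        partition = dict(group.partition or base)
        for node, module in group.noi_reassignments.items():
            if node not in partition:
                raise ValueError(f"reassigned node {node!r} is not in the partition")
            if module not in set(partition.values()):
                raise ValueError(
                    f"reassignment of {node!r} names unknown module {module}"
                )
            partition[node] = module
        group_subjects = []
        group_seeds = []
        for si in range(group.n_subjects):
            seed = subject_seed(design.master_seed, gi, si)
            group_seeds.append(seed)
            group_subjects.append(
                generate_subject_timeseries(
                    partition,
                    n_volumes=design.n_volumes,
                    within_r=group.within_r,
                    between_r=group.between_r,
                    noise_sd=group.noise_sd,
                    seed=seed,
                    tr_seconds=design.tr_seconds,
                )
            )
        subjects[group.name] = group_subjects
        seeds[group.name] = group_seeds
    return Cohort(subjects=subjects, design=design, seeds=seeds)


def regress_nuisance(ts: TimeSeriesMatrix, covariates: np.ndarray) -> TimeSeriesMatrix:
    """Replace each node series by its OLS residual against [intercept | covariates].

    With an empty covariate set this mean-centers every row.  Residuals are
    orthogonal to every covariate column.
    """
    covariates = np.asarray(covariates, dtype=float)
    if covariates.size == 0:
        covariates = covariates.reshape(ts.n_volumes, 0)
    if covariates.ndim != 2 or covariates.shape[0] != ts.n_volumes:
        raise ValueError(
            f"covariates must have {ts.n_volumes} rows (one per volume), "
            f"got shape {covariates.shape}"
        )
    design = np.column_stack([np.ones(ts.n_volumes), covariates])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            trial = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                bad.append(j - 1)  # covariate index (0-based, excl. intercept)
        raise ValueError(f"rank-deficient nuisance design; collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    residuals = ts.values - (design @ beta).T
    return TimeSeriesMatrix(residuals, tr_seconds=ts.tr_seconds, node_ids=list(ts.node_ids))


def bandpass(
    ts: TimeSeriesMatrix, low_hz: float = 0.01, high_hz: float = 0.1
) -> TimeSeriesMatrix:
    """Zero-phase band-pass filter of every node series.

    Second-order Butterworth applied forward and backward (``sosfiltfilt``), so
    the passband is preserved without phase shift and the effective attenuation
    is the squared single-pass response.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4g} Hz"
        )
    sos = scipy.signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, ts.values, axis=1)
    return TimeSeriesMatrix(filtered, tr_seconds=ts.tr_seconds, node_ids=list(ts.node_ids))
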