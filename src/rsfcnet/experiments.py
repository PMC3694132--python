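"""Replicate-level simulation experiments on planted synthetic cohorts.

Two canned study designs drive the statistical validation of the pipeline:

* a *null* design — two groups drawn from the identical generative partition,
  used to check that the NMI group test rejects at its nominal rate and that
  the Bonferroni-corrected node scan controls familywise error; and
* a *reassignment* design — group B moves a handful of nodes to a different
  module, the planted analogue of a focal group difference in modular
  architecture, used to measure the power of both tests.

Each replicate generates a cohort, builds per-subject networks at the
group-level cost, detects modules, and runs the NMI permutation test and the
per-node co-module scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import GROUP_LEVEL_COST, mst_threshold, weight_matrix_from_timeseries
from .modules import Partition, detect_partition, similarity_permutation_test
from .noi import NoiScanResult, noi_scan
from .synthetic import CohortDesign, GroupSpec, default_partition, generate_cohort

# six cerebellar nodes moved from the subcortical-cerebellar module to the
# default-mode/frontal module in the reassignment design
DEFAULT_REASSIGNED_NODES = ["CL8.L", "CL8.R", "CL9.L", "CL9.R", "Vr8", "Vr9"]


def null_design(
    n_subjects: int = 20,
    master_seed: int = 0,
    within_r: float = 0.6,
    between_r: float = 0.1,
) -> CohortDesign:
    """Two groups with the identical generative partition (exchangeable null)."""
    return CohortDesign(
        groups=[
            GroupSpec(name="A", n_subjects=n_subjects, within_r=within_r, between_r=between_r),
            GroupSpec(name="B", n_subjects=n_subjects, within_r=within_r, between_r=between_r),
        ],
        master_seed=master_seed,
    )


def reassignment_design(
    n_subjects: int = 20,
    master_seed: int = 0,
    nodes: list[str] | None = None,
    target_module: int = 3,
    within_r: float = 0.6,
    between_r: float = 0.1,
) -> CohortDesign:
    """Group B reassigns the given nodes to ``target_module``."""
    nodes = DEFAULT_REASSIGNED_NODES if nodes is None else nodes
    return CohortDesign(
        groups=[
            GroupSpec(name="A", n_subjects=n_subjects, within_r=within_r, between_r=between_r),
            GroupSpec(
                name="B",
                n_subjects=n_subjects,
                within_r=within_r,
                between_r=between_r,
                noi_reassignments={n: target_module for n in nodes},
            ),
        ],
        master_seed=master_seed,
    )


def detect_cohort_partitions(
    design: CohortDesign,
    cost: float = GROUP_LEVEL_COST,
    n_restarts: int = 2,
    mode: str = "binary",
) -> dict[str, list[Partition]]:
    """Generate the cohort and detect one partition per subject at one cost."""
    cohort = generate_cohort(design)
    partitions: dict[str, list[Partition]] = {}
    for gi, (group, subjects) in enumerate(cohort.subjects.items()):
        parts = []
        for si, ts in enumerate(subjects):
            wm = weight_matrix_from_timeseries(ts)
            g = mst_threshold(wm, cost, mode=mode)
            parts.append(
                detect_partition(
                    g,
                    seed=design.master_seed + 1000 * gi + si,
                    n_restarts=n_restarts,
                )
            )
        partitions[group] = parts
    return partitions


@dataclass
class ReplicateResult:
    nmi_p: float
    scan: NoiScanResult
    partitions: dict[str, list[Partition]]


def run_replicate(
    design: CohortDesign,
    n_permutations_nmi: int = 1000,
    n_permutations_noi: int = 5000,
    cost: float = GROUP_LEVEL_COST,
    n_restarts: int = 2,
    mode: str = "binary",
    test_seed: int | None = None,
) -> ReplicateResult:
    """One replicate: cohort -> partitions -> NMI test + node scan.

    Permutation seeds default to the design's master seed so a replicate is
    fully determined by its design.
    """
    if test_seed is None:
        test_seed = design.master_seed
    partitions = detect_cohort_partitions(design, cost=cost, n_restarts=n_restarts, mode=mode)
    a, b = (partitions[g.name] for g in design.groups)
    nmi_test = similarity_permutation_test(
        a, b, n_permutations=n_permutations_nmi, seed=test_seed
    )
    scan = noi_scan(a, b, n_permutations=n_permutations_noi, seed=test_seed)
    return ReplicateResult(nmi_p=nmi_test.p, scan=scan, partitions=partitions)


def collateral_nodes(
    nodes: list[str] | None = None, target_module: int = 3
) -> set[str]:
    """Nodes whose functional community changes as a side effect of reassignment.

    Moving a node alters the co-module vector of every member of its donor and
    recipient modules, so those co-members are genuine (not false) positives
    for the scan.  The remaining nodes are the truly null set.
    """
    nodes = DEFAULT_REASSIGNED_NODES if nodes is None else nodes
    partition = default_partition()
    donor_modules = {partition[n] for n in nodes}
    affected = {
        nid
        for nid, module in partition.items()
        if module in donor_modules or module == target_module
    }
    return affected - set(nodes)


def type_one_error_experiment(
    n_replicates: int = 200,
    n_subjects: int = 20,
    master_seed: int = 0,
    n_permutations_nmi: int = 1000,
    n_permutations_noi: int = 5000,
    alpha: float = 0.05,
    n_restarts: int = 2,
) -> dict:
    """Null-cohort calibration: NMI-test rejection rate and scan FWE."""
    rejections = 0
    fwe_hits = 0
    nmi_pvalues = []
    scan_pvalues = []
    for rep in range(n_replicates):
        design = null_design(n_subjects=n_subjects, master_seed=master_seed + rep)
        result = run_replicate(
            design,
            n_permutations_nmi=n_permutations_nmi,
            n_permutations_noi=n_permutations_noi,
            n_restarts=n_restarts,
        )
        nmi_pvalues.append(result.nmi_p)
        scan_pvalues.extend(result.scan.table["p"].tolist())
        rejections += result.nmi_p < alpha
        fwe_hits += bool(result.scan.table["significant_corrected"].any())
    return {
        "n_replicates": n_replicates,
        "nmi_rejection_rate": rejections / n_replicates,
        "noi_familywise_error_rate": fwe_hits / n_replicates,
        "nmi_pvalues": np.array(nmi_pvalues),
        "scan_pvalues": np.array(scan_pvalues),
    }


def power_experiment(
    n_replicates: int = 50,
    n_subjects: int = 20,
    master_seed: int = 0,
    n_permutations_nmi: int = 1000,
    n_permutations_noi: int = 10000,
    alpha: float = 0.05,
    n_restarts: int = 2,
) -> dict:
    """Reassignment-cohort power: NMI-test rejections and nodes recovered."""
    moved = DEFAULT_REASSIGNED_NODES
    null_set = (
        set(default_partition().keys()) - set(moved) - collateral_nodes(moved)
    )
    nmi_rejections = 0
    full_recovery = 0
    n_flagged_moved = []
    n_flagged_null = []
    for rep in range(n_replicates):
        design = reassignment_design(n_subjects=n_subjects, master_seed=master_seed + rep)
        result = run_replicate(
            design,
            n_permutations_nmi=n_permutations_nmi,
            n_permutations_noi=n_permutations_noi,
            n_restarts=n_restarts,
        )
        nmi_rejections += result.nmi_p < alpha
        flagged = set(result.scan.significant_nodes(corrected=True))
        n_flagged_moved.append(len(flagged & set(moved)))
        n_flagged_null.append(len(flagged & null_set))
        full_recovery += len(flagged & set(moved)) >= 5
    return {
        "n_replicates": n_replicates,
        "nmi_power": nmi_rejections / n_replicates,
        "noi_recovery_rate": full_recovery / n_replicates,
        "mean_flagged_reassigned": float(np.mean(n_flagged_moved)),
        "mean_flagged_null": float(np.mean(n_flagged_null)),
    }
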