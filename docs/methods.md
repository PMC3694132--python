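# Methods

## Scope and model of the data

The package analyzes resting-state functional-connectivity (rsFC) networks:
per subject, a node × volume matrix of regional BOLD time series (by default
116 AAL regions, 200 volumes at TR = 2.5 s), grouped into cohorts. It begins
*after* image preprocessing — motion correction, normalization, nuisance
regression on voxel data and atlas parcellation are upstream concerns; only
light node-level preprocessing (OLS nuisance regression, band-pass filtering)
is provided for completeness.

## Synthetic cohorts

Because participant-level rsFC data are rarely distributable, the generator
is a first-class module. Node series follow a Gaussian factor model

    x_i(t) = a · f_{m(i)}(t) + b · g(t) + e_i(t)

with one latent factor f_m per module, a global factor g shared by all nodes,
and independent noise e_i ~ N(0, noise_sd²). Given target correlations
r_within and r_between, the mixing weights are solved exactly:
v = noise_sd²/(1 − r_within), a² = (r_within − r_between)·v, b² = r_between·v,
so the population correlation of two nodes is r_within within a module and
r_between across modules. This makes correlation recovery testable to
Monte-Carlo precision and keeps the planted partition the unique
block-structure of the data. Defaults — 116 nodes, 200 volumes, TR 2.5 s,
r_within = 0.6, r_between = 0.1, noise_sd = 1, 20 subjects per group in the
experiment designs — mirror a realistic single-site study of this size; the
five-module default partition is a stylized resting-state decomposition
(visual; sensorimotor/auditory; default-mode + frontal; orbitofrontal/limbic;
subcortical-cerebellar), not an empirical map.

What the generator does **not** emulate: hemodynamic autocorrelation, scanner
drift and physiological noise spectra, head motion, inter-subject anatomical
variability, and hub/centrality structure. Passing tests therefore show that
the statistical machinery recovers planted modular structure under Gaussian
stationary noise — not that any particular empirical finding would replicate.

Per-subject seeds are spawned as `SeedSequence([master_seed, group_index,
subject_index])`, so extending a design never changes existing subjects, and
identical designs are bit-identical.

Group designs may *reassign* selected nodes to another module. Note that
reassignment also perturbs the co-module vectors of every member of the donor
and recipient modules; those co-members are genuine secondary positives for
the node scan, and the experiment helpers report them separately from the
untouched ("truly null") nodes.

## Preprocessing choices

Nuisance regression is ordinary least squares against `[intercept |
covariates]`, returning residuals (mean-centering when the covariate set is
empty). The band-pass filter is a second-order Butterworth applied
forward-backward (zero phase); the default 0.01–0.1 Hz band at TR 2.5 s
retains ≥ 99 % amplitude at band center and passes < 0.1 % at 0.18 Hz after
the two passes. Regression runs before filtering when both are used.

## Network construction

Edge weights are |atanh(r)| (rectified Fisher z). Thresholding at cost κ
keeps round(κ·n(n−1)/2) edges (round-half-up; the rounding convention is a
package choice): first the maximum-weight spanning tree (Kruskal on
descending weights) as a backbone — this realizes "every node keeps its
strongest link and no island remains" with a standard deterministic
construction — then remaining edges in descending weight order. Ties break
lexicographically on (smaller index, larger index) for cross-platform
reproducibility. Because a sweep ranks edges once (tree edges first, each
block in descending weight), the graph at any cost is a prefix of that
ranking: connectedness, exact edge counts and nestedness hold by
construction and are re-verified in tests. Costs below (n−1)/(n(n−1)/2) are
rejected as infeasible. Negative correlations contribute through their
magnitude only; no signed-network variant is provided.

## Topological metrics

C_p, L_p, E_global, E_local use the standard binary definitions (L_p only on
connected graphs, which thresholding guarantees; efficiencies treat
unreachable pairs as zero contribution; nodes with < 2 neighbors contribute 0
to C_p and E_local). The implementation computes distances with a sparse BFS
and triangles with matrix products for speed; correctness is pinned to naive
Floyd–Warshall/pair-enumeration oracles at 1e-12 in the tests. Small-worldness
σ normalizes by degree-preserving, connectedness-preserving rewired graphs
(10·|E| double-edge swaps each, default 20 references); the matched ring
lattice (edges assigned ring by ring of increasing circular distance) is
provided as the regular reference for context, as is conventional in cost
sweeps. Group metric curves are compared by pooled two-tailed t tests per
cost, uncorrected across costs; the report flags this ambiguity explicitly.

## Modular architecture

Community detection is Louvain modularity maximization — the algorithm choice
is the package's own, made for determinism under seeding, weighted-graph
support and ubiquity — run `n_restarts` times (default 20) keeping the
highest-Q labeling. For the cohort-scale simulation experiments the helpers
default to 2 restarts: on 116-node, 200-edge graphs the Q gain from further
restarts is marginal while the runtime scales linearly, and the permutation
tests are valid for any fixed detection rule.

Partition similarity is NMI with arithmetic-mean normalization,
2·I(A;B)/(H(A)+H(B)), natural logs. Degenerate cases follow the continuity
convention: two single-module partitions → 1, single-module vs anything else
→ 0. The group test statistic pools within-A and within-B pairs into one
within mean and subtracts the between mean; per-group within means are also
reported. The null permutes pooled group memberships preserving group sizes;
p-values use the add-one rule (1 + #{null ≥ observed})/(1 + N), so p is never
zero and the test is exactly valid under exchangeability.

Consensus maps: the representative subject maximizes mean NMI to the rest
(ties → lowest index); other subjects' labels are matched to it by maximizing
contingency-table overlap via the Hungarian algorithm, with unmatched modules
given fresh ids above the reference's maximum; per-node modal labels (ties →
smaller id) and their frequencies form the consensus. "Major modules" are
modules with ≥ 6 nodes.

## Node-of-interest scan

For node v and subject s, the indicator vector marks which other nodes share
v's module in s's partition. Pair similarity is the phi coefficient; if an
indicator has zero variance (v in a singleton module, or one module overall)
the pair is undefined — identical vectors count as phi = 1, otherwise the
pair is excluded from the within/between means and the exclusion count is
reported. One shuffle sequence is shared across all 116 node tests per seed,
making the scan deterministic and its null consistent across nodes; the
per-node statistics for all shuffles are computed with two matrix products,
so the full scan at 10⁴ permutations runs in about a second. Bonferroni
control uses α/n_nodes (0.05/116 by default); both corrected and uncorrected
flags are reported.

A permutation count note: with N permutations the smallest attainable p is
1/(N+1). The Bonferroni threshold 0.05/116 ≈ 4.3·10⁻⁴ therefore requires
N ≥ 2320; the power experiments use the full 10⁴ and the null-calibration
experiments use 5·10³ so the familywise-error check is non-vacuous, while the
NMI group test (threshold 0.05) uses 10³ in the simulation experiments.

## Simulation experiment sizes

The calibration experiment runs 200 null replicate cohorts (20 subjects per
group each) and checks the NMI-test rejection rate at α = 0.05 and the scan's
familywise error; the power experiment runs 50 replicates with six
cerebellar nodes reassigned in group B and checks the NMI-test rejection
rate and recovery of ≥ 5/6 reassigned nodes under Bonferroni correction.
These sizes put the binomial standard error of an 0.05 rate at ~0.015 and of
a 0.9 power at ~0.04, adequate for the bands being asserted; the acceptance
script uses 100/30 replicates for the same quantities.

## Summary-statistic inference

Demographic-table tests are recomputed from printed means/SDs/sizes: pooled
(not Welch) two-sample t — matching the integer degrees of freedom such
tables report — one-way ANOVA from group summaries, Tukey HSD with the
studentized range and harmonic-mean pair sizes, and a Pearson chi-square for
count tables. Recomputation from rounded summaries reproduces printed t and F
values to within ~1 % (e.g. t = 6.90 vs a printed 6.94 computed from
unrounded data).

## Known limitations

- The generator's exchangeable Gaussian model understates the heterogeneity
  of real cohorts; power estimates are optimistic relative to real data.
- Louvain is a heuristic; different restart budgets can change individual
  partitions (never the validity, only the power, of the permutation tests).
- Weighted-mode modularity uses the |z| weights directly; no alternative
  null models (e.g. signed or correlation-adjusted) are implemented.
- Hub/centrality analysis (participation coefficient etc.) is out of scope.
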