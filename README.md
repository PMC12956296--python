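# connalign

Multimodal, anatomically constrained alignment of brain connectomes
across subjects.

## The problem

Fine-grained cortical parcellations (hundreds to a thousand regions)
assume that a region label means the same thing in every brain. It does
not: at small region sizes, anatomical and functional variability means
that the region called *k* in one subject may play the role of its
neighbor *l* in another. Group studies built on a fixed labeling then
compare mismatched regions. Because a region's connectivity profile is a
fingerprint of its role, one can correct the labeling by *permuting*
regions so that each subject's brain networks best match those of a
reference subject.

`connalign` estimates such permutations jointly from two network
modalities — a structural connectome **S** (streamline counts, symmetric,
non-negative) and a functional connectome **F** (Pearson correlations of
region-averaged BOLD signals) — while forbidding anatomically implausible
moves.

## The method

For a subject with connectomes C₁…C_I and a reference subject with
C₁,ref…C_I,ref, the aligner seeks the permutation matrix P minimizing

    L(P) = Σᵢ βᵢ ‖P Cᵢ Pᵀ − Cᵢ,ref‖²_F ,   Σᵢ βᵢ = 1 ,

which for symmetric matrices is equivalent to minimizing
−Σᵢ βᵢ Tr(P Cᵢ Pᵀ Cᵢ,ref). With two modalities the weights are written
β = (α, 1−α): α = 1 aligns on structure only, α = 0 on function only.

This quadratic assignment problem is NP-hard; the solver uses the
fast-approximate-QAP (FAQ) scheme: relax P to the Birkhoff polytope of
doubly stochastic matrices and run Frank–Wolfe descent — at each
iteration linearize the objective, solve a linear sum assignment problem
for the extreme-point search direction, take an exact line-search step —
then project the final iterate back onto the permutation group.

Anatomical constraints enter as a binary mask R of forbidden assignments
whose entries carry infinite cost inside the assignment subproblem, i.e.
a hard constraint that needs no penalty weight. Three strategies:

| strategy | constraint | mechanics |
|---|---|---|
| `ha`    | within hemisphere | two independent unconstrained runs on the hemispheric blocks |
| `wba`   | within hemisphere | one whole-brain run with the hemisphere mask (keeps inter-hemispheric edges in the objective) |
| `wbanc` | spatially adjacent regions only | one whole-brain run with the neighborhood mask |

Alignment quality is measured by the gain
η(P, a, b) = ‖C_a − C_b‖_F − ‖P C_a Pᵀ − C_b‖_F (positive = improved
similarity), tested across subject pairs with a one-sided Wilcoxon
signed-rank test under Bonferroni control, and characterized spatially by
classifying each moved label as self / local / remote by its
shortest-path distance on the region adjacency graph.

## Worked example

Simulate a 20-region two-hemisphere cohort and align subject 0 to
subject 1 under the neighborhood constraint, for α ∈ {0, 0.5, 1}:

```sh
connalign simulate --n-subjects 2 --grid-rows 2 --grid-cols 5 \
    --sc-noise 0.1 --fc-noise 0.1 --n-swaps 3 --seed 7 --out demo/cohort
connalign align --strategy wbanc --alpha 0:1:0.5 \
    --sc demo/cohort/sub-000_sc.csv --fc demo/cohort/sub-000_fc.csv \
    --ref-sc demo/cohort/sub-001_sc.csv --ref-fc demo/cohort/sub-001_fc.csv \
    --adjacency demo/cohort/adjacency.tsv --out demo/aligned
```

prints

```
alpha=0.00: 2 iterations, objective -182.038
alpha=0.50: 3 iterations, objective -182.556
alpha=1.00: 3 iterations, objective -183.632
wrote 3 permutations to demo/aligned
```

Each α yields one permutation TSV (`source_label → target_label`; here
e.g. `r0 → r5` swaps two vertically adjacent grid regions), an objective
trace, and `eta_records.csv` with the per-modality gains:

```
moving,reference,modality,alpha,strategy,in_training,eta
moving,reference,SC,0.5,wbanc,True,3.6610897463018146
moving,reference,FC,0.5,wbanc,True,0.012490408226982108
```

Both gains are positive: the α = 0.5 permutation brings the moving
subject's structural *and* functional networks closer to the reference.
The planted-permutation experiment is run end to end by

```sh
connalign validate --n-subjects 5 --grid-rows 5 --grid-cols 5 \
    --n-swaps 3 --n-permutations 10 --strategy wbanc \
    --sc-noise 0.1 --fc-noise 0.1 --seed 1
# wbanc alpha=0.5: mean mismatched labels 0.000 over N=50,
# exact recovery 100% of 50 trials
```

The library surface mirrors scikit-learn: `ConnectomeAligner(strategy,
alpha, adjacency).fit(moving, reference)` exposes `permutation_`,
`objective_trace_`, `n_iter_`, and `transform` applies the learned
permutation to any connectome of the moving subject — including
modalities not used in the fit, which is how generalization is assessed.

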