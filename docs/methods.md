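# Methods

## The score

Given `N` samples with true class labels `T` and hypothetical cluster
assignments `K` (hard, disjoint, no missing labels), every class/cluster
pair receives the Jaccard index `I(t,k) = |V_t ∩ V_k| / |V_t ∪ V_k|`.
Matching is performed in both directions: per class `I_t = max_k I(t,k)` and
per cluster `I_k = max_t I(t,k)`. The score aggregates these with size
weights, `R = Σ_t (|V_t|/N) I_t` and `P = Σ_k (|V_k|/N) I_k`, and reports
their harmonic mean `J = 2RP/(R+P)`.

Guarantees (all enforced by tests): `0 < J ≤ 1`; `J = 1` iff the two label
columns induce the same partition; swapping the columns swaps `R` and `P`
and leaves `J` unchanged; any bijective relabelling leaves all scores
unchanged; `min(R,P) ≤ J ≤ max(R,P)`. Because the cluster-side sum `P`
includes clusters that no class selected ("stray" clusters), splitting a
stray cluster that sits inside one class strictly lowers `P` and `J` while
leaving `R` — and the unidirectional H- and F-scores — untouched. J is not a
metric (no triangle inequality) and no significance test is attached to it.

**Tie rule.** Equal Jaccard maxima are resolved in favour of the first label
in lexicographic order of the labels' string form. Weighted sums are
unaffected by ties (the maximal *value* is unique); only the reported
correspondences depend on this rule, and the choice makes them
platform-independent and reproducible.

**Degenerate inputs.** `N = 1` is legal and gives `J = 1`. A single cluster
against many classes is legal — it is exactly the regime in which the chance
baseline maximises. Missing labels are rejected rather than dropped, since
dropping would silently change `N` and every weight.

## Chance baseline

Under independent class and cluster labels the expected intersection count
is `E|V_t ∩ V_k| = |V_t||V_k|/N`. Substituting this expectation into the
Jaccard ratio makes it strictly increasing in the partner's size, so the
largest partner always wins the argmax, giving the closed forms

```
I0t = |V_t||V_k_max| / ((N−|V_t|)|V_k_max| + N|V_t|)
I0k = |V_k||V_t_max| / ((N−|V_k|)|V_t_max| + N|V_k|)
```

and `J₀ = 2R₀P₀/(R₀+P₀)` with the usual size weights. With equal-size
classes and clusters this collapses to `J₀ = 1/(|T|+|K|−1)`, which is
strictly decreasing in both block counts: the baseline is *not* constant —
it is high when everything lands in one big cluster and vanishes as either
partition refines.

**J₀ is a plug-in approximation, not the exact expectation of J.** The
substitution happens inside a max and a ratio, both of which are convex in
the cell counts, so the Monte-Carlo mean of J over random shuffles sits at
or above J₀. How far above depends on how contested the argmax is:

* two blocks per side with a unique dominant size — the gap decays roughly
  as 1/N and falls within 3 standard errors of a 10⁴-shuffle mean by
  N ≈ 2000 (the configuration the acceptance test uses);
* tied sizes (e.g. two clusters of 50) — the expected maximum of two
  fluctuating cells strictly exceeds the plug-in value and the gap does not
  vanish with more shuffles (about +1.6% relative for classes 10/90 vs
  clusters 50/50 at N = 100);
* many blocks (the uniform many-cluster regime) — the gap grows with the
  number of competing cells, reaching tens of percent at K ≈ 20.

Tests therefore assert tight agreement only in the regimes where the
plug-in is sharp, and the one-sided bound (empirical mean ≥ J₀) elsewhere.
For interpretation this means J₀ should be read as a lower reference line,
excellent for few/skewed blocks, conservative for many equal blocks.

## Comparison measures

All seven comparison measures are computed from the same class-by-cluster
contingency table, using their standard formulas: H-score (fraction of
points outside each class's largest-overlap cluster; a distance, reported
alongside 1−H), F-score (class-size-weighted best per-class F1 with
precision `n/|V_k|` and recall `n/|V_t|`), Rand index and its chance-
adjusted form from the pair-counting identities, and the entropy family
(NMI with geometric-mean normalisation, V-measure with β = 1, NVI) with
natural logarithms — the normalised quantities are base-invariant. NVI is
normalised by the joint entropy `H(T,K)` (`NVI = 1 − I/H(T,K)`), a common
convention; other normalisations would shift its curves monotonically
without moving peak locations. Zero-entropy conventions: identical trivial
partitions score NMI = 1, V = 1, NVI = 0; if exactly one side is a single
block and the partitions differ, NMI = V = 0. Per-pair, F1 and Jaccard are
monotonically related (`F1 = 2I/(1+I)`), which is why the F-score baseline
sits below the 1−H baseline in the random-partition sweeps: small overlaps
are roughly halved twice.

## Simulators

The ground-truth generator draws one value per sample from a Gaussian
`G(μ, 0.05)` per class — the narrow, fixed standard deviation makes class
membership unambiguous, and only the labels feed the measures. Hypothetical
partitions come from three generators:

* **predetermined** — explicit point-to-cluster maps; includes the four
  canonical worked examples on 100 points in classes 10/30/60 ("stray",
  "stray-split", "merged", "merged-split"). In "merged-split" the 30-point
  stray cluster is dealt alternately into two halves of 15 so each half
  keeps the cluster's class mix; a contiguous cut would hand one half a
  class majority, letting it steal best matches and *raise* J, which
  defeats the configuration's purpose (demonstrating that H and F cannot
  see the split while J drops, here from 0.39 to 0.38 at 2 d.p.).
* **random** — cluster sizes drawn uniformly over the positive compositions
  of N into K parts (stars and bars, so no empty cluster), then the ordered
  label list is permuted. Compositions produce strongly skewed sizes (an
  approximately geometric profile), which is what keeps the J baseline near
  0.07–0.08 at large K instead of the equal-size value 1/(2K−1).
* **split/merge** — starting from the true classes, a uniformly chosen
  cluster of size ≥ 2 is split at a uniform ratio (recursively, so any K up
  to N is reachable) or a uniformly chosen pair is merged, until K clusters
  remain. At K = |T| this returns the truth intact, so every similarity
  measure attains its maximum there by construction; the design isolates
  class-number inference from assignment noise.

The experiments use these at the study scale: class-number inference with
1,000 points in 10 (or 5) equal classes, K = 1..50, 50 replicates per K;
baseline sweeps scoring two independent random partitions of 1,000 points
per replicate, 50 replicates per K. Fifty replicates keep the whole suite
and the acceptance script in the seconds-to-minutes range while leaving the
Monte-Carlo error on per-K means far smaller than the effects being read
off (the J peak at the true K is attained in every run across seeds).

What the simulations do *not* emulate: feature noise feeding a real
clustering algorithm (the partitions are simulated directly, so there is no
model-misfit pathway), overlapping classes, or missing labels. Passing
these tests shows the measures behave as designed on clean partition
structures; behaviour on real data is exercised separately by the
benchmarks.

## Benchmarks

The two classical labelled datasets (Iris, 150×4, three classes of 50;
Wine, 178×13, classes 59/71/48) are loaded from scikit-learn's bundled
copies of the UCI originals, standardised column-wise to mean 0 and sample
standard deviation 1, and clustered with

* K-means (Lloyd's algorithm, random initialisation, 10 restarts, at most
  10 iterations, best inertia kept; the restart cap mirrors the common R
  protocol, and the algorithm name is recorded in every output), and
* agglomerative hierarchical clustering with Ward's criterion on Euclidean
  distances (the "ward.D2" convention), cutting one dendrogram at each K.

Scores against the true classes are computed for K = 2..10; the peak K per
measure uses the smallest K on ties. Subsample stability repeats the whole
curve on uniform 90% subsamples drawn without replacement or
stratification, so class proportions vary across replicates. J peaks at
K = 3 on the Iris K-means curve and the Wine Ward curve, and does so in
every subsample replicate at the tested seeds; H-score peaks at K = 2
throughout (under-estimation is intrinsic to its one-sided matching, which
rewards lumping).

## Numerical choices

Scores are computed and stored at full float precision; comparisons against
conventionally rounded reference values use round-half-away-from-zero to
2 decimals (`round_score`, 0.7652 → 0.77). Label order everywhere is the
lexicographic sort of the labels' string form. The contingency table is
exact integer arithmetic; Jaccard denominators are always positive because
every label indexes a non-empty set. Pair-counting formulas are evaluated
in closed form and cross-checked against O(N²) enumeration in tests;
entropy sums skip empty cells. ARI returns 1 when its chance-correction
denominator vanishes (both partitions trivial). Experiment randomness flows
through a single `numpy` Generator per run, so identical (parameters, seed)
give bit-identical outputs.

## Known limitations

* J₀'s plug-in bias under tied or highly fragmented size vectors (above).
* The split/merge design cannot exhibit the over-estimation bias of the
  information-theoretic measures (their score at K = |T| is exactly 1 by
  construction); that bias does appear in the baseline sweeps, where their
  chance level rises steadily with K.
* K-means results depend on the restart seed; only the hierarchical
  protocol is bit-deterministic.
* Inputs must be hard partitions; fuzzy or overlapping assignments are out
  of scope.
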