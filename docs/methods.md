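# Methods

## Problem setting

A DNA-binding domain (DBD) family — here modelled after single C2H2 zinc
fingers — binds DNA through a conserved structural scaffold in which a small
set of aligned domain positions contacts the bases of a k-position binding
site. Instances identical at those base-contacting positions are aggregated
under one *core sequence* and treated as a single entity with one PWM
(4 × k, columns on the probability simplex, base order A, C, G, T, no
reverse-complement matching). Given a dataset of per-core PWMs `S_a` and
family-level structural knowledge, the package infers revised PWMs `Ŝ_a`
for all cores jointly.

## Structural similarity prior

The contact-frequency matrix `M[i, j]` is the uniqueness-weighted fraction
of co-complex instances in which domain position `i` contacts a base at
binding-site position `j`. Uniqueness weighting assigns each instance the
reciprocal of the number of instances with an identical aligned domain
sequence, so duplicating a structure never changes `M` (a tested
invariant). Contact calling from atomic coordinates (non-hydrogen atom of
the base within 3.6 Å) happens upstream; the package consumes boolean
contact maps or a ready-made `M`. A domain position is *base-contacting*
when its contact frequency reaches 10% (inclusive) at some binding-site
position; the *key position* of `j` is the base-contacting position with
maximal `M[i, j]`, ties broken toward the lowest index (ties are
measure-zero on real contact data; the break only pins down determinism).

Pair weights between cores `a ≠ a′`, per position `j`:

* differing in more than `max_mismatch` contacting positions → 0 at all
  `j` (no prior expectation of similarity). `max_mismatch = 1` is the
  single-finger C2H2 setting; homeodomain-style analyses use up to 4.
* differing at the key position of `j` → 0 at `j`.
* otherwise `∏_{i ∈ D} (1 − M[i, j])` over the differing positions `D`;
  with one mismatch this is exactly `1 − M[i, j]`. The product form is the
  package's chosen multi-mismatch generalization: it reduces to the
  single-mismatch rule and penalizes each additional mismatch
  monotonically.

Weights are normalized per node and per position (each node's outgoing
weights sum to 1), making the graphs directed; zero-weight pairs are not
stored. Cores with no partner anywhere can be dropped by
`filter_isolated`, mirroring the preprocessing applied to real datasets —
both solvers leave them unchanged in any case.

## Solvers

Both solvers operate on one binding-site position at a time (no
cross-position coupling; the four bases couple only through the shared
simplex constraint).

**Quadratic program.** Minimize
`α Σ_a ‖S_a − Ŝ_a‖² + (1 − α) Σ_{a,a′} w_j(a,a′) ‖Ŝ_a − Ŝ_{a′}‖²` subject
to each column lying on the simplex. With
`L = D_out + D_in − W − Wᵀ` (the Laplacian of the symmetrized weights) the
per-base stationarity system is `(αI + (1 − α)L) x_b = α s_b`. Two facts
make the constrained problem collapse to this unconstrained solve:
`L · 1 = 0`, so the per-base solutions sum to one automatically; and
`αI + (1 − α)L` is a strictly diagonally dominant M-matrix, so its inverse
is entrywise nonnegative and the box constraints are never active. The
implementation is therefore one sparse SPD factorization per position with
four right-hand sides. The test suite verifies agreement with an
independent general-purpose constrained optimizer (SLSQP over the full
4n-dimensional problem) to 1e-4 per entry on random instances. Roundoff
negatives within `qp_feasibility_tol = 1e-9` are clipped and the column
renormalized; larger violations raise.

**Label propagation (adsorption).** The default *anchored* update
`Ŝ⁽ᵗ⁾ = αS + (1 − α)WŜ⁽ᵗ⁻¹⁾`, started at `Ŝ⁽⁰⁾ = S`, is a contraction for
α > 0 (spectral radius of `(1 − α)W` ≤ 1 − α), converging to
`Ŝ = α(I − (1 − α)W)⁻¹S` — the absorbing-random-walk semantics in which α
is the probability of stopping at the start node. Iteration stops when the
maximum entry change drops below `lpa_tol = 1e-8` (then the fixed-point
residual of the returned iterate is below the same bound) or after
`lpa_max_iter = 1000` iterations, in which case a warning diagnostic is
attached and the last iterate returned. A *literal* variant
`Ŝ⁽ᵗ⁾ = αŜ⁽ᵗ⁻¹⁾ + (1 − α)WŜ⁽ᵗ⁻¹⁾` is provided for finite-iteration
experiments; it has no anchor and drifts toward per-component consensus,
which is why it is not the default. Nodes without outgoing edges keep
`Ŝ = S` under both variants. With `max_iter = 1` both variants equal the
weighted nearest-neighbour blend. α = 1 short-circuits to an exact
identity in both solvers.

## Agreement statistics

Two columns agree when their Pearson correlation (over the 4 base
frequencies) is ≥ 0.5; the threshold is a parameter and a sweep utility
covers robustness checks. PCC is invariant to affine rescaling, hence
insensitive to information-content differences between datasets. A uniform
column has undefined PCC: such pairs are excluded from agreement fractions
and counted separately, except that entrywise-equal columns (within 1e-9)
always agree. Median PCC is computed over defined pairs only.

Gain/loss analysis partitions corresponding column pairs by initial
agreement status; gain is the fraction of initially disagreeing pairs that
agree after revision, loss the converse. Empty partitions yield `None`
rather than a coerced number, since the ratio is unstable on small cells.
The random-pairing control draws a seeded bijection between the shared
cores so that pair counts match the corresponding pairing. The
node-permutation null relabels each similarity graph's nodes with an
independent seeded bijection — independently for each dataset, which is
what actually severs the coordinated movement of the two replicates.

## Synthetic worlds

The generator produces the structure the method assumes, so every claim the
tests make is about the method, not about fixture quirks:

* **Contact model** — each binding-site position `j` has one dominant key
  position (`M ≈ 0.85–0.95`) and one weaker secondary contact
  (`M ≈ 0.2–0.4`); remaining contacting positions receive a weak 0.15
  contact so they clear the 10% call. Defaults: k = 3, four contacting
  positions (the single-C2H2-finger geometry).
* **Cores** — sampled as a variant cloud: `n_cores // 10` uniform seed
  cores, then single-residue mutants of existing cores until `n_cores`
  distinct cores exist. Real core-sequence collections are exactly such
  Hamming-dense variant libraries. Alphabets offer 15 residues per
  contacting position; key positions of real zinc-finger libraries use
  most of the 20 amino acids, and this diversity matters — with few
  residues per key position, each position's dataset-wide mean column is
  itself truth-correlated, and even randomized smoothing would shrink
  failed estimates toward an informative mean, contaminating the
  permutation null.
* **Truth** — one Dirichlet(0.3) column per (key residue, position);
  cores sharing the key residue share the column exactly. Concentration
  0.3 gives realistically peaked specificity columns. An optional
  `secondary_jitter` perturbs truth by the residue at the secondary
  contact position (scaled by its contact frequency); it defaults to 0 so
  truth sharing within key-residue groups is exact.
* **Observation** — per dataset, each non-failed column is a multinomial
  resample of truth at `noise_effective_counts = 50` pseudo-sites
  (moderate experimental depth); independently per dataset, a
  `failure_rate = 0.2` fraction of cores is replaced wholesale by flat
  Dirichlet noise. This failure mixture is the minimal model of assays
  being far less accurate for some proteins than others.

What the generator does **not** emulate: raw selection/probe readouts,
position-dependent sequencing depth, inter-position dependencies within
binding sites, systematic laboratory batch effects, or imperfect
column-frame registration between datasets. Passing tests therefore show
that the solvers exploit interface-derived similarity correctly under the
assumed noise model — not that any particular real dataset will improve by
a given amount.

## Study sizes and defaults

The synthetic study (tests and `scripts/acceptance.py`) uses 200 cores,
two replicates, 20% failures, the α grid 1.0/0.8/0.6/0.4/0.2 for QP and a
0.1-step grid for LPA, and pools the permutation null over 3 independent
draws — sizes at which every reported quantity is stable across seeds
while the whole study runs in seconds. Enrichment ratios in the acceptance
report apply a half-count continuity floor to the loss fraction so a zero
observed loss yields a finite, conservative ratio. All randomness flows
from explicit seeds; the two solvers themselves are deterministic.

## Known limitations

* The multi-mismatch product rule and the unweighted-mean aggregation of
  PWMs sharing a core are the package's own choices among reasonable
  variants; both are documented invariants rather than fitted quantities.
* The QP's linear-solve shortcut relies on per-column inputs being valid
  probability vectors (enforced on entry); it does not apply to objectives
  with non-Laplacian coupling.
* Graph construction is O(n²) in the number of cores per position —
  adequate for tens of thousands of cores, but no spatial indexing is
  attempted.
* α is not auto-tuned. On overlapping replicate datasets, the gain/loss
  enrichment curve as a function of α (exposed by the evaluation module)
  is the intended selection diagnostic; without overlap, moderate-to-high
  α (0.5–0.9) with a check that confident estimates move little is the
  recommended practice.
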