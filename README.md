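# jointpwm

Joint inference of DNA-binding specificities for structurally similar
DNA-binding domains.

High-throughput protein–DNA assays yield a position weight matrix (PWM) per
protein, but estimate each protein's specificity in isolation — even when
the dataset contains hundreds of proteins binding DNA through the same
structural domain, whose interfaces make their specificities mutually
informative. `jointpwm` revises all PWMs in such a dataset *jointly*: each
protein's estimate is smoothed toward the estimates of proteins with a
near-identical DNA-contacting interface, with the amount of sharing
controlled by a single parameter α. It is aimed at researchers working with
large single-domain PWM collections (C2H2 zinc fingers, homeodomains, …)
who want to denoise them using family-level structural knowledge.

## The model

Each domain instance is identified by its **core sequence** *a* — the
concatenation of its base-contacting residues (four for a single C2H2 zinc
finger). A family-level **contact-frequency matrix** *M*[*i*, *j*] gives the
fraction of co-complex structures in which domain position *i* contacts the
base at binding-site position *j* (contacts called at 3.6 Å, positions kept
when contacting in ≥ 10% of instances, instances uniqueness-weighted).

From *M*, a per-position similarity prior *w<sub>j</sub>*(*a*, *a*′) is
built: zero for pairs differing in more than `max_mismatch` contacting
positions (1 for C2H2-ZF, up to 4 for homeodomains), zero at positions
whose *key* (most frequently contacting) residue differs, and otherwise
∏(1 − *M*[*i*, *j*]) over the differing positions *i*; weights are
normalized per node, Σ<sub>a′</sub> *w<sub>j</sub>*(*a*, *a*′) = 1.

Revised specificities Ŝ minimize, independently per binding-site position
*j* (QP formulation):

```
min   α Σ_a ‖S_a − Ŝ_a‖²  +  (1 − α) Σ_{a,a′} w_j(a,a′) ‖Ŝ_a − Ŝ_{a′}‖²
s.t.  each Ŝ_a[·, j] on the probability simplex
```

or iterate the **label-propagation / adsorption** update
Ŝ⁽ᵗ⁾ = αS + (1 − α)WŜ⁽ᵗ⁻¹⁾ to its fixed point
Ŝ = α(I − (1 − α)W)⁻¹S. α = 1 returns the input unchanged; one iteration
equals a weighted nearest-neighbour blend. Agreement between two PWM
columns is defined as Pearson correlation ≥ 0.5.

## Worked example

```python
import jointpwm as jp

# two replicate datasets of 200 noisy PWMs over shared cores, 20% failures
world = jp.generate_world(jp.SyntheticConfig(n_cores=200, failure_rate=0.2, seed=1))
graphs = jp.build_graphs(world.cores, world.contact_model, max_mismatch=1)

before = jp.across_dataset_agreement(world.dataset_1, world.dataset_2)
print(f"initial agreement: {before.fraction_agreeing:.3f} (median PCC {before.median_pcc:.3f})")

config = jp.InferenceConfig(alpha=0.4, method="qp")
r1 = jp.joint_infer(world.dataset_1, graphs, config).revised
r2 = jp.joint_infer(world.dataset_2, graphs, config).revised

after = jp.across_dataset_agreement(r1, r2)
print(f"revised agreement: {after.fraction_agreeing:.3f} (median PCC {after.median_pcc:.3f})")

gl = jp.gain_loss(world.dataset_1, world.dataset_2, r1, r2)
print(f"agreement gain {gl.gain:.2f}, loss {gl.loss:.3f} "
      f"({gl.n_gained}/{gl.n_initially_disagreeing} gained, {gl.n_lost}/{gl.n_initially_agreeing} lost)")
```

Output:

```
initial agreement: 0.703 (median PCC 0.972)
revised agreement: 0.907 (median PCC 0.980)
agreement gain 0.70, loss 0.005 (124/178 gained, 2/422 lost)
```

The two replicates observe the same underlying specificities, yet only 70%
of their corresponding PWM columns initially agree — the disagreement is
dominated by the planted failed experiments. Joint revision at α = 0.4
brings 70% of the initially disagreeing column pairs into agreement while
disturbing only 2 of 422 initially agreeing pairs: information sharing
repairs unreliable estimates without touching reproducible ones.

The same pipeline is scriptable from the shell:

```
jointpwm simulate --n-cores 200 --seed 1 --outdir world/
jointpwm infer --pwms world/pwms_1.txt --graphs world/edges.tsv \
               --method qp --alpha 0.4 --out revised_1.txt
jointpwm evaluate --pwms-a revised_1.txt --pwms-b revised_2.txt \
                  --initial-a world/pwms_1.txt --initial-b world/pwms_2.txt \
                  --report report.json
```

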