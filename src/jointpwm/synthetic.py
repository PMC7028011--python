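"""Synthetic worlds with the statistical structure the method assumes.

The generator emulates the C2H2 zinc-finger setting: each binding-site
position ``j`` is specified chiefly by one *key* base-contacting residue
position (contact frequency ~0.9) with at most one weaker secondary contact
(~0.2-0.4).  Cores sharing the residue at ``j``'s key position share the
ground-truth column at ``j`` exactly, which is precisely the structure the
similarity prior is built to exploit.

Two independent replicate datasets are observed from the same truth:

* each non-failed core's column is a multinomial resample of its truth
  column at a finite effective sampling depth (per-column pseudo-sites),
  emulating finite experimental data;
* independently per dataset, a fraction of cores *fail*: their entire PWM
  is replaced by flat-Dirichlet noise, emulating experiments that are far
  less accurate for some proteins than for others.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import across_dataset_agreement, column_pcc
from .interface_model import ContactModel
from .pwm_io import PWM, PWMDataset

# residues offered at each contacting position; broad (15 per position)
# because key positions of real zinc-finger libraries use most amino acids
DEFAULT_ALPHABETS = (
    "DERKHNQSTGAVLIM",
    "NQSTGAVLIMDERKH",
    "AVLIMDERKHNQSTG",
    "FYWSRNQDEKHGTAL",
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for :func:`generate_world`.

    Defaults describe a C2H2-like benchmark: 200 cores over a 3-base site
    with 4 contacting residue positions, moderate sampling depth (50
    pseudo-sites per column) and a 20% per-dataset failure rate.
    ``truth_concentration`` is the symmetric Dirichlet concentration of
    ground-truth columns (0.3 gives realistically peaked specificities).
    ``secondary_jitter`` optionally perturbs truth columns according to the
    residue at the secondary contacting position, scaled by its contact
    frequency; the default 0 keeps truth sharing within key-residue groups
    exact.

    Cores are sampled as a variant cloud: ``n_seed_cores`` cores drawn
    uniformly, then single-residue mutants of existing cores until
    ``n_cores`` distinct cores exist.  This emulates the Hamming-dense
    variant libraries real datasets come from; set
    ``n_seed_cores = n_cores`` for uniform sampling.  ``None`` means
    ``max(1, n_cores // 10)``.
    """

    n_cores: int = 200
    k: int = 3
    n_contacting: int = 4
    alphabet_per_position: tuple[str, ...] = DEFAULT_ALPHABETS
    truth_concentration: float = 0.3
    noise_effective_counts: float = 50.0
    failure_rate: float = 0.2
    secondary_jitter: float = 0.0
    n_seed_cores: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.failure_rate < 1:
            raise SyntheticError("failure_rate must lie in [0, 1)")
        if self.noise_effective_counts <= 0:
            raise SyntheticError("noise_effective_counts must be positive")
        if self.n_contacting < self.k:
            raise SyntheticError(
                "need at least one distinct key position per binding-site position"
            )
        if len(self.alphabet_per_position) != self.n_contacting:
            raise SyntheticError(
                f"alphabet_per_position must have {self.n_contacting} entries"
            )


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    contact_model: ContactModel
    cores: tuple[str, ...]
    truth: PWMDataset
    dataset_1: PWMDataset
    dataset_2: PWMDataset
    failed_cores_1: frozenset[str] = field(default_factory=frozenset)
    failed_cores_2: frozenset[str] = field(default_factory=frozenset)


def _build_contact_model(config: SyntheticConfig, rng: np.random.Generator) -> ContactModel:
    """One dominant key per binding-site position plus one secondary contact.

    Key of position j is contacting position j (distinct keys); the
    secondary contact of j is position j+1 (mod n_contacting), which also
    guarantees every contacting position clears the 10% contact threshold.
    """
    n, k = config.n_contacting, config.k
    M = np.zeros((n, k))
    for j in range(k):
        M[j, j] = rng.uniform(0.85, 0.95)
        M[(j + 1) % n, j] = max(M[(j + 1) % n, j], rng.uniform(0.2, 0.4))
    # contacting positions not reached above get a weak contact somewhere
    for i in range(n):
        if M[i].max() < 0.10:
            M[i, i % k] = 0.15
    return ContactModel(M, contact_threshold=0.10)


def _sample_cores(config: SyntheticConfig, rng: np.random.Generator) -> tuple[str, ...]:
    """Variant-cloud sampling: uniform seed cores plus single-residue mutants."""
    alphabets = config.alphabet_per_position
    n_possible = int(np.prod([len(a) for a in alphabets]))
    if config.n_cores > n_possible:
        raise SyntheticError(
            f"cannot draw {config.n_cores} distinct cores from an alphabet "
            f"admitting only {n_possible}"
        )
    n_seeds = config.n_seed_cores
    if n_seeds is None:
        n_seeds = max(1, config.n_cores // 10)
    n_seeds = min(n_seeds, config.n_cores)
    cores: set[str] = set()
    while len(cores) < n_seeds:
        cores.add("".join(rng.choice(list(a)) for a in alphabets))
    pool = list(cores)
    while len(cores) < config.n_cores:
        base = pool[rng.integers(len(pool))]
        p = int(rng.integers(len(alphabets)))
        mutant = base[:p] + rng.choice(list(alphabets[p])) + base[p + 1 :]
        if mutant not in cores:
            cores.add(mutant)
            pool.append(mutant)
    return tuple(sorted(cores))


def _generate_truth(
    config: SyntheticConfig,
    model: ContactModel,
    cores: Sequence[str],
    rng: np.random.Generator,
) -> PWMDataset:
    k = config.k
    conc = config.truth_concentration
    # one truth column per (key residue, position); shared exactly by every
    # core carrying that residue at the key position
    tables: list[dict[str, np.ndarray]] = []
    for j in range(k):
        key = model.key_position(j)
        tables.append(
            {r: rng.dirichlet(np.full(4, conc)) for r in config.alphabet_per_position[key]}
        )
    jitter_tables: list[dict[str, np.ndarray]] = []
    if config.secondary_jitter > 0:
        for j in range(k):
            sec = (j + 1) % config.n_contacting
            jitter_tables.append(
                {r: rng.dirichlet(np.ones(4)) for r in config.alphabet_per_position[sec]}
            )
    entries = {}
    for core in cores:
        mat = np.empty((4, k))
        for j in range(k):
            key = model.key_position(j)
            col = tables[j][core[key]]
            if config.secondary_jitter > 0:
                sec = (j + 1) % config.n_contacting
                eps = config.secondary_jitter * model.M[sec, j]
                col = (1 - eps) * col + eps * jitter_tables[j][core[sec]]
            mat[:, j] = col / col.sum()
        entries[core] = PWM(mat)
    return PWMDataset(entries, k=k, label="truth")


def _observe(
    config: SyntheticConfig,
    truth: PWMDataset,
    cores: Sequence[str],
    rng: np.random.Generator,
    label: str,
) -> tuple[PWMDataset, frozenset[str]]:
    depth = int(round(config.noise_effective_counts))
    n_failed = int(round(config.failure_rate * len(cores)))
    failed = frozenset(
        cores[i] for i in rng.choice(len(cores), size=n_failed, replace=False)
    )
    entries = {}
    for core in cores:
        if core in failed:
            mat = np.column_stack([rng.dirichlet(np.ones(4)) for _ in range(config.k)])
        else:
            mat = np.empty((4, config.k))
            for j in range(config.k):
                counts = rng.multinomial(depth, truth[core].values[:, j])
                mat[:, j] = counts / depth
        entries[core] = PWM(mat)
    return PWMDataset(entries, k=config.k, label=label), failed


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Build contact model, cores, ground truth and two replicate datasets."""
    rng = np.random.default_rng(config.seed)
    model = _build_contact_model(config, rng)
    cores = _sample_cores(config, rng)
    truth = _generate_truth(config, model, cores, rng)
    ds1, failed1 = _observe(config, truth, cores, rng, "replicate_1")
    ds2, failed2 = _observe(config, truth, cores, rng, "replicate_2")
    return SyntheticWorld(
        config=config,
        contact_model=model,
        cores=cores,
        truth=truth,
        dataset_1=ds1,
        dataset_2=ds2,
        failed_cores_1=failed1,
        failed_cores_2=failed2,
    )


def _distance_to_truth(
    dataset: PWMDataset, truth: PWMDataset, cores: Sequence[str]
) -> dict[str, float]:
    """Mean per-column 1 - PCC and L1 distance to truth over *cores*."""
    pcc_d, l1 = [], []
    for core in cores:
        for j in range(truth.k):
            u = dataset[core].values[:, j]
            v = truth[core].values[:, j]
            pcc = column_pcc(u, v)
            if not np.isnan(pcc):
                pcc_d.append(1.0 - pcc)
            l1.append(float(np.abs(u - v).sum()))
    return {
        "mean_one_minus_pcc": float(np.mean(pcc_d)) if pcc_d else float("nan"),
        "mean_l1": float(np.mean(l1)) if l1 else float("nan"),
    }


def recovery_metrics(
    world: SyntheticWorld,
    revised_1: PWMDataset,
    revised_2: PWMDataset,
    threshold: float = 0.5,
) -> dict:
    """Distance-to-truth (failed vs non-failed cores, before/after revision)
    and across-dataset agreement at both stages."""
    report: dict = {}
    stages = {
        "initial": (world.dataset_1, world.dataset_2),
        "revised": (revised_1, revised_2),
    }
    for stage, (d1, d2) in stages.items():
        per_ds = {}
        for name, ds, failed in (
            ("dataset_1", d1, world.failed_cores_1),
            ("dataset_2", d2, world.failed_cores_2),
        ):
            ok = [c for c in world.cores if c not in failed]
            per_ds[name] = {
                "failed": _distance_to_truth(ds, world.truth, sorted(failed)),
                "non_failed": _distance_to_truth(ds, world.truth, ok),
            }
        agreement = across_dataset_agreement(d1, d2, threshold=threshold)
        report[stage] = {
            "distance_to_truth": per_ds,
            "agreement_fraction": agreement.fraction_agreeing,
            "median_pcc": agreement.median_pcc,
        }
    return report
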