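"""Agreement statistics and randomization controls.

Two PWM columns *agree* when their Pearson correlation coefficient (PCC)
over the four base frequencies is at least a threshold (default 0.5).  PCC
is insensitive to affine rescaling, hence to differences in information
content between datasets.  A uniform column has zero variance and an
undefined PCC; such pairs are excluded from agreement fractions and counted
separately, except that two columns equal entrywise (within 1e-9) always
count as agreeing.

Built on that primitive:

* across-dataset agreement for corresponding cores, with a seeded
  random-pairing control;
* agreement gain / loss / enrichment between initial and revised datasets;
* Jaccard overlap of agreement sets (for comparing solvers);
* comparison against an external reference dataset with a random-column
  control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pwm_io import PWMDataset

#: entrywise-equality tolerance under which two zero-variance columns agree
EQUAL_TOL = 1e-9


@dataclass
class ColumnPair:
    core: str
    j: int
    col1: np.ndarray
    col2: np.ndarray


@dataclass
class ColumnPairing:
    pairs: list[ColumnPair]
    kind: str  # "corresponding" | "random"


@dataclass
class AgreementReport:
    fraction_agreeing: float
    median_pcc: float
    pccs: list[float] = field(repr=False)
    n_pairs: int = 0
    n_undefined_pcc: int = 0


@dataclass
class GainLossReport:
    gain: float | None
    loss: float | None
    enrichment: float | None
    n_initially_agreeing: int = 0
    n_initially_disagreeing: int = 0
    n_gained: int = 0
    n_lost: int = 0


def column_pcc(u: Sequence[float], v: Sequence[float]) -> float:
    """Pearson correlation of two 4-vectors; NaN when either is constant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u - u.mean()
    dv = v - v.mean()
    su = float(du @ du)
    sv = float(dv @ dv)
    if su <= 0 or sv <= 0:
        return float("nan")
    return float(du @ dv / np.sqrt(su * sv))


def columns_agree(u: Sequence[float], v: Sequence[float], threshold: float = 0.5) -> bool:
    """True iff PCC is defined and >= *threshold* (inclusive).

    Two entrywise-equal columns agree even when both are uniform (PCC
    undefined but agreement unambiguous).
    """
    pcc = column_pcc(u, v)
    if np.isnan(pcc):
        return bool(np.allclose(u, v, rtol=0, atol=EQUAL_TOL))
    return pcc >= threshold


def _pair_status(pair: ColumnPair, threshold: float) -> str:
    """Classify a pair: 'agree', 'disagree' or 'undefined'."""
    pcc = column_pcc(pair.col1, pair.col2)
    if np.isnan(pcc):
        if np.allclose(pair.col1, pair.col2, rtol=0, atol=EQUAL_TOL):
            return "agree"
        return "undefined"
    return "agree" if pcc >= threshold else "disagree"


def _resolve_positions(k: int, positions: Iterable[int] | None) -> tuple[int, ...]:
    pos = tuple(range(k)) if positions is None else tuple(positions)
    if any(j < 0 or j >= k for j in pos):
        raise ValueError(f"positions must lie in 0..{k - 1}")
    return pos


def build_pairing(
    d1: PWMDataset,
    d2: PWMDataset,
    kind: str = "corresponding",
    seed: int | None = None,
    positions: Iterable[int] | None = None,
) -> ColumnPairing:
    """Pair columns of the cores shared between two datasets.

    ``corresponding`` pairs each shared core with itself; ``random`` draws a
    seeded bijection (a permutation of the shared cores, sampled without
    replacement) so the number of pairs matches the corresponding pairing.
    """
    if d1.k != d2.k:
        raise ValueError("datasets must share the binding-site length k")
    shared = sorted(set(d1.cores) & set(d2.cores))
    if not shared:
        raise ValueError("datasets share no core sequences")
    pos = _resolve_positions(d1.k, positions)
    if kind == "corresponding":
        partner = dict(zip(shared, shared))
    elif kind == "random":
        if seed is None:
            raise ValueError("random pairing requires a seed")
        rng = np.random.default_rng(seed)
        partner = dict(zip(shared, [shared[i] for i in rng.permutation(len(shared))]))
    else:
        raise ValueError(f"unknown pairing kind {kind!r}")
    pairs = [
        ColumnPair(core=a, j=j, col1=d1[a].values[:, j], col2=d2[partner[a]].values[:, j])
        for a in shared
        for j in pos
    ]
    return ColumnPairing(pairs=pairs, kind=kind)


def agreement_report(pairing: ColumnPairing, threshold: float = 0.5) -> AgreementReport:
    pccs = []
    n_agree = 0
    n_undef = 0
    n_defined = 0
    for pair in pairing.pairs:
        status = _pair_status(pair, threshold)
        if status == "undefined":
            n_undef += 1
            continue
        n_defined += 1
        pcc = column_pcc(pair.col1, pair.col2)
        if not np.isnan(pcc):
            pccs.append(pcc)
        if status == "agree":
            n_agree += 1
    return AgreementReport(
        fraction_agreeing=n_agree / n_defined if n_defined else float("nan"),
        median_pcc=float(np.median(pccs)) if pccs else float("nan"),
        pccs=pccs,
        n_pairs=n_defined,
        n_undefined_pcc=n_undef,
    )


def across_dataset_agreement(
    d1: PWMDataset,
    d2: PWMDataset,
    pairing_kind: str = "corresponding",
    seed: int | None = None,
    positions: Iterable[int] | None = None,
    threshold: float = 0.5,
) -> AgreementReport:
    """Fraction of agreeing column pairs and median PCC for shared cores."""
    pairing = build_pairing(d1, d2, kind=pairing_kind, seed=seed, positions=positions)
    return agreement_report(pairing, threshold=threshold)


def agreement_set(
    d1: PWMDataset,
    d2: PWMDataset,
    positions: Iterable[int] | None = None,
    threshold: float = 0.5,
) -> set[tuple[str, int]]:
    """The (core, position) pairs whose corresponding columns agree."""
    pairing = build_pairing(d1, d2, kind="corresponding", positions=positions)
    return {
        (p.core, p.j) for p in pairing.pairs if _pair_status(p, threshold) == "agree"
    }


def gain_loss(
    initial_1: PWMDataset,
    initial_2: PWMDataset,
    revised_1: PWMDataset,
    revised_2: PWMDataset,
    positions: Iterable[int] | None = None,
    threshold: float = 0.5,
) -> GainLossReport:
    """Agreement gain and loss of revised datasets over their initials.

    Corresponding column pairs are partitioned by their *initial* agreement
    status; gain is the fraction of initially disagreeing pairs that agree
    after revision, loss the fraction of initially agreeing pairs that no
    longer do.  Pairs with an undefined initial status are excluded from
    both partitions.  Fractions over an empty partition are None (small
    partitions make the enrichment ratio unstable, so emptiness is reported
    rather than coerced).
    """
    init = build_pairing(initial_1, initial_2, kind="corresponding", positions=positions)
    rev = build_pairing(revised_1, revised_2, kind="corresponding", positions=positions)
    rev_status = {(p.core, p.j): _pair_status(p, threshold) for p in rev.pairs}
    n_agree = n_disagree = n_gain = n_loss = 0
    for p in init.pairs:
        status0 = _pair_status(p, threshold)
        if status0 == "undefined":
            continue
        status1 = rev_status.get((p.core, p.j))
        if status0 == "agree":
            n_agree += 1
            if status1 != "agree":
                n_loss += 1
        else:
            n_disagree += 1
            if status1 == "agree":
                n_gain += 1
    gain = n_gain / n_disagree if n_disagree else None
    loss = n_loss / n_agree if n_agree else None
    if gain is None or loss is None or loss == 0:
        enrichment = None
    else:
        enrichment = gain / loss
    return GainLossReport(
        gain=gain,
        loss=loss,
        enrichment=enrichment,
        n_initially_agreeing=n_agree,
        n_initially_disagreeing=n_disagree,
        n_gained=n_gain,
        n_lost=n_loss,
    )


def jaccard_agreement_overlap(
    agree_set_a: set[tuple[str, int]], agree_set_b: set[tuple[str, int]]
) -> float:
    """Jaccard coefficient |A ∩ B| / |A ∪ B|; 1.0 when both sets are empty."""
    union = agree_set_a | agree_set_b
    if not union:
        return 1.0
    return len(agree_set_a & agree_set_b) / len(union)


@dataclass
class ExternalComparison:
    fraction_revised: float
    fraction_initial: float
    delta: float
    fraction_revised_random_control: float
    fraction_initial_random_control: float
    n_shared_cores: int = 0


def external_comparison(
    revised: PWMDataset,
    external: PWMDataset,
    initial: PWMDataset,
    positions: Iterable[int] | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> ExternalComparison:
    """Agreement with an independent external reference, before vs after.

    Reports the agreement fraction of revised-vs-external minus
    initial-vs-external over the shared cores, plus a seeded random-pairing
    control in which each core is compared against a randomly chosen
    external core's columns.
    """
    shared = set(revised.cores) & set(external.cores) & set(initial.cores)
    if not shared:
        raise ValueError("no cores shared with the external dataset")
    kw = dict(positions=positions, threshold=threshold)
    frac_rev = across_dataset_agreement(revised, external, **kw).fraction_agreeing
    frac_init = across_dataset_agreement(initial, external, **kw).fraction_agreeing
    frac_rev_rand = across_dataset_agreement(
        revised, external, pairing_kind="random", seed=seed, **kw
    ).fraction_agreeing
    frac_init_rand = across_dataset_agreement(
        initial, external, pairing_kind="random", seed=seed, **kw
    ).fraction_agreeing
    return ExternalComparison(
        fraction_revised=frac_rev,
        fraction_initial=frac_init,
        delta=frac_rev - frac_init,
        fraction_revised_random_control=frac_rev_rand,
        fraction_initial_random_control=frac_init_rand,
        n_shared_cores=len(shared),
    )


def threshold_sweep(
    d1: PWMDataset,
    d2: PWMDataset,
    thresholds: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7),
    positions: Iterable[int] | None = None,
) -> dict[float, float]:
    """Agreement fraction as a function of the PCC threshold (robustness check)."""
    pairing = build_pairing(d1, d2, kind="corresponding", positions=positions)
    return {
        t: agreement_report(pairing, threshold=t).fraction_agreeing for t in thresholds
    }
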