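"""Data types and I/O for position weight matrices keyed by core sequence.

A *core sequence* is the concatenation of the base-contacting amino acids of
a DNA-binding domain (DBD) instance; DBDs identical at those positions are
treated as a single entity.  Every specificity is a 4 x k column-stochastic
matrix over the bases A, C, G, T (rows, in that fixed order) and k
binding-site positions (columns, 5'->3').  No reverse-complement matching is
performed anywhere: all matrices are assumed registered to a fixed
interface orientation.

Two on-disk dialects are supported:

* ``tabular`` -- one motif per block: a header line ``>CORE k=3`` followed by
  four rows labelled A/C/G/T with k tab-separated floats.
* ``meme`` -- MEME minimal motif format (version line, ``ALPHABET= ACGT``,
  ``MOTIF`` blocks with a letter-probability matrix).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: residues allowed in a core sequence (uppercase one-letter amino acid codes)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: tolerance for accepting a column as stochastic on read
STOCHASTIC_TOL = 1e-9
#: columns off by at most this much are silently renormalized (and logged)
RENORM_TOL = 1e-4


class PWMError(ValueError):
    """Raised for invalid matrices, malformed files or inconsistent datasets."""


def validate_core(core: str, n_positions: int | None = None) -> str:
    """Check that *core* is a valid core sequence and return it.

    Parameters
    ----------
    core:
        Concatenated base-contacting residues, uppercase one-letter codes.
    n_positions:
        Expected length (the number of base-contacting DBD positions);
        ``None`` skips the length check.
    """
    if not core or any(c not in AMINO_ACIDS for c in core):
        raise PWMError(
            f"invalid core sequence {core!r}: expected uppercase one-letter "
            "amino-acid codes"
        )
    if n_positions is not None and len(core) != n_positions:
        raise PWMError(
            f"core sequence {core!r} has length {len(core)}, expected "
            f"{n_positions} base-contacting positions"
        )
    return core


def _as_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 4 or arr.shape[1] < 1:
        raise PWMError(f"{name} must be a 4 x k matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative base counts per binding-site position (4 x k)."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_matrix(self.values, "CountMatrix")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise PWMError("counts must be finite and nonnegative")
        object.__setattr__(self, "values", arr)

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PWM:
    """Column-stochastic 4 x k matrix of base preferences."""

    values: np.ndarray

    def __post_init__(self):
        arr = _as_matrix(self.values, "PWM")
        if np.any(arr < -STOCHASTIC_TOL) or np.any(arr > 1 + STOCHASTIC_TOL):
            raise PWMError("PWM entries must lie in [0, 1]")
        sums = arr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > STOCHASTIC_TOL):
            raise PWMError(
                f"PWM columns must sum to 1 (found sums {sums}); "
                "use renormalize on read or normalize_counts for counts"
            )
        arr = np.clip(arr, 0.0, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]


@dataclass
class PWMDataset:
    """A set of PWMs keyed by (unique) core sequence, sharing one k."""

    entries: dict[str, PWM] = field(default_factory=dict)
    k: int | None = None
    label: str = ""

    def __post_init__(self):
        for core, pwm in self.entries.items():
            validate_core(core)
            if self.k is None:
                self.k = pwm.k
            elif pwm.k != self.k:
                raise PWMError(
                    f"dataset {self.label!r}: {core} has k={pwm.k}, "
                    f"expected {self.k}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, core: str) -> bool:
        return core in self.entries

    def __getitem__(self, core: str) -> PWM:
        return self.entries[core]

    @property
    def cores(self) -> list[str]:
        return list(self.entries)

    def subset(self, cores: Iterable[str], label: str | None = None) -> "PWMDataset":
        keep = {c: self.entries[c] for c in cores}
        return PWMDataset(keep, k=self.k, label=self.label if label is None else label)

    def replace(self, core: str, pwm: PWM) -> None:
        if pwm.k != self.k:
            raise PWMError("replacement PWM has mismatched k")
        self.entries[core] = pwm


def normalize_counts(counts: CountMatrix, pseudocount: float = 0.0) -> PWM:
    """Maximum-likelihood (optionally pseudocounted) frequencies from counts.

    Column j of the result is ``(C[b,j] + pc) / (sum_b' C[b',j] + 4 pc)``.
    """
    if pseudocount < 0:
        raise PWMError("pseudocount must be nonnegative")
    arr = counts.values + pseudocount
    totals = arr.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise PWMError(
            f"column {bad} has zero total count and pseudocount is 0; "
            "cannot form a frequency column"
        )
    return PWM(arr / totals)


def aggregate_by_core(pwms: Sequence[PWM]) -> PWM:
    """Merge PWMs that share one core sequence: entrywise mean, renormalized.

    The mean of column-stochastic matrices is column-stochastic, so the
    renormalization only corrects floating-point drift.
    """
    if len(pwms) == 0:
        raise PWMError("cannot aggregate an empty list of PWMs")
    ks = {p.k for p in pwms}
    if len(ks) != 1:
        raise PWMError(f"cannot aggregate PWMs with mixed k: {sorted(ks)}")
    mean = np.mean([p.values for p in pwms], axis=0)
    return PWM(mean / mean.sum(axis=0))


def information_content(pwm: PWM, background: Sequence[float] | None = None) -> np.ndarray:
    """Per-column information content in bits relative to *background*.

    Computes ``sum_b P[b,j] log2(P[b,j] / bg[b])`` with the convention
    ``0 log 0 = 0``.  Under the uniform background the value per column lies
    in [0, 2] bits and is 0 iff the column is uniform.
    """
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise PWMError("background must be a strictly positive 4-vector summing to 1")
    p = pwm.values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg[:, None]), 0.0)
    return terms.sum(axis=0)


# ---------------------------------------------------------------------------
# file formats

_HEADER_RE = re.compile(r"^>(\S+)\s+k=(\d+)\s*$")


def _check_columns(
    mat: np.ndarray, core: str, renormalize: bool, where: str
) -> np.ndarray:
    """Enforce column stochasticity per the read contract."""
    if np.any(mat < 0):
        raise PWMError(f"{where}: motif {core} has negative entries")
    sums = mat.sum(axis=0)
    if np.any(sums <= 0):
        raise PWMError(f"{where}: motif {core} has an all-zero column")
    dev = np.abs(sums - 1.0)
    if np.all(dev <= STOCHASTIC_TOL):
        return mat
    if renormalize or np.all(dev <= RENORM_TOL):
        logger.info("renormalizing columns of motif %s (max deviation %.3g)", core, dev.max())
        return mat / sums
    raise PWMError(
        f"{where}: motif {core} columns sum to {sums} (max deviation "
        f"{dev.max():.3g} > {RENORM_TOL:g}); pass renormalize=True to rescale"
    )


def _parse_tabular(lines: list[str], renormalize: bool, aggregate: bool, where: str):
    raw: dict[str, list[np.ndarray]] = {}
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _HEADER_RE.match(line)
        if not m:
            raise PWMError(f"{where}, line {i + 1}: expected '>CORE k=K' header, got {line!r}")
        core, k = m.group(1), int(m.group(2))
        validate_core(core)
        rows = {}
        for b in range(4):
            i += 1
            if i >= n:
                raise PWMError(f"{where}, line {i + 1}: truncated motif {core}")
            parts = lines[i].strip().split("\t")
            if len(parts) != k + 1 or parts[0] not in BASES:
                raise PWMError(
                    f"{where}, line {i + 1}: expected base row with {k} values"
                )
            try:
                rows[parts[0]] = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise PWMError(f"{where}, line {i + 1}: {exc}") from exc
        if set(rows) != set(BASES):
            raise PWMError(f"{where}: motif {core} is missing a base row")
        raw.setdefault(core, []).append(np.vstack([rows[b] for b in BASES]))
        i += 1
    return _finalize(raw, renormalize, aggregate, where)


def _parse_meme(lines: list[str], renormalize: bool, aggregate: bool, where: str):
    raw: dict[str, list[np.ndarray]] = {}
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise PWMError(f"{where}, line {i + 1}: MOTIF line lacks an identifier")
            core = validate_core(parts[1])
            # scan ahead for the letter-probability header
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise PWMError(f"{where}, line {i + 1}: motif {core} has no matrix")
                i += 1
            if i >= n:
                raise PWMError(f"{where}: motif {core} has no letter-probability matrix")
            header = lines[i].strip()
            wm = re.search(r"w=\s*(\d+)", header)
            if wm is None:
                raise PWMError(f"{where}, line {i + 1}: missing 'w=' in matrix header")
            w = int(wm.group(1))
            cols = []
            for _ in range(w):
                i += 1
                if i >= n:
                    raise PWMError(f"{where}, line {i + 1}: truncated matrix for {core}")
                vals = lines[i].split()
                if len(vals) != 4:
                    raise PWMError(
                        f"{where}, line {i + 1}: expected 4 probabilities per position"
                    )
                cols.append([float(x) for x in vals])
            raw.setdefault(core, []).append(np.array(cols).T)
        i += 1
    return _finalize(raw, renormalize, aggregate, where)


def _finalize(raw, renormalize: bool, aggregate: bool, where: str) -> dict[str, PWM]:
    entries: dict[str, PWM] = {}
    for core, mats in raw.items():
        if len(mats) > 1 and not aggregate:
            raise PWMError(
                f"{where}: duplicate core sequence {core}; pass aggregate=True "
                "to merge duplicates"
            )
        pwms = [PWM(_check_columns(m, core, renormalize, where)) for m in mats]
        entries[core] = pwms[0] if len(pwms) == 1 else aggregate_by_core(pwms)
    if not entries:
        raise PWMError(f"{where}: no motifs found")
    return entries


def read_pwm_dataset(
    path: str | Path,
    format: str = "tabular",
    renormalize: bool = False,
    aggregate: bool = False,
    label: str | None = None,
) -> PWMDataset:
    """Read a dataset of PWMs keyed by core sequence.

    Parameters
    ----------
    format:
        ``"tabular"`` or ``"meme"`` (MEME minimal).
    renormalize:
        Rescale columns that do not sum to 1.  Without this flag, columns off
        by more than 1e-4 raise; smaller deviations are renormalized and
        logged.
    aggregate:
        Merge motifs sharing a core sequence via :func:`aggregate_by_core`
        instead of raising a duplicate-key error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    where = str(path)
    if format == "tabular":
        entries = _parse_tabular(lines, renormalize, aggregate, where)
    elif format == "meme":
        entries = _parse_meme(lines, renormalize, aggregate, where)
    else:
        raise PWMError(f"unknown format {format!r}; expected 'tabular' or 'meme'")
    return PWMDataset(entries, label=path.stem if label is None else label)


def write_pwm_dataset(dataset: PWMDataset, path: str | Path, format: str = "tabular") -> None:
    """Write *dataset* in the named dialect (see :func:`read_pwm_dataset`)."""
    path = Path(path)
    out = []
    if format == "tabular":
        for core, pwm in dataset.entries.items():
            out.append(f">{core} k={pwm.k}")
            for b, row in zip(BASES, pwm.values):
                out.append(b + "\t" + "\t".join(f"{x:.12g}" for x in row))
            out.append("")
    elif format == "meme":
        out += ["MEME version 4", "", "ALPHABET= ACGT", ""]
        for core, pwm in dataset.entries.items():
            out.append(f"MOTIF {core}")
            out.append(
                f"letter-probability matrix: alength= 4 w= {pwm.k} nsites= 20 E= 0"
            )
            for j in range(pwm.k):
                out.append(" ".join(f"{x:.12g}" for x in pwm.values[:, j]))
            out.append("")
    else:
        raise PWMError(f"unknown format {format!r}")
    path.write_text("\n".join(out) + "\n")
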