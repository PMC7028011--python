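"""Structural interface model of a DNA-binding domain family.

The family's protein--DNA interaction scaffold is summarized by a contact
frequency matrix ``M`` where ``M[i, j]`` is the (uniqueness-weighted)
fraction of DBD--DNA co-complex instances in which an amino acid at aligned
DBD position ``i`` contacts a base at binding-site position ``j``.  Contact
calls are made upstream of this package from atomic coordinates (an amino
acid contacts a base when a non-hydrogen atom lies within 3.6 angstrom);
here we consume pre-aligned boolean contact maps or a ready-made ``M``.

From ``M`` the model derives

* the *base-contacting* DBD positions -- those contacting a base in at least
  ``contact_threshold`` (default 10%) of instances at some binding-site
  position; their concatenated residues form the core sequence; and
* the *key position* for each binding-site position ``j`` -- the DBD position
  most frequently contacting ``j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class InterfaceError(ValueError):
    """Raised for invalid contact maps or contact-frequency matrices."""


@dataclass(frozen=True)
class ContactInstance:
    """One aligned DBD--DNA co-complex: sequence plus boolean contact map."""

    dbd_sequence: str
    contacts: np.ndarray  # bool, (aligned DBD length, k)

    def __post_init__(self):
        arr = np.asarray(self.contacts, dtype=bool)
        if arr.ndim != 2:
            raise InterfaceError("contacts must be a 2-D boolean matrix")
        if arr.shape[0] != len(self.dbd_sequence):
            raise InterfaceError(
                f"contact map has {arr.shape[0]} rows but the aligned DBD "
                f"sequence has length {len(self.dbd_sequence)}"
            )
        object.__setattr__(self, "contacts", arr)


class NoKeyPositionError(InterfaceError):
    """Binding-site position has no contacting DBD position; pair weights
    at this position must be treated as 0 by callers."""


def call_base_contacting(M: np.ndarray, threshold: float = 0.10) -> tuple[int, ...]:
    """DBD positions whose row maximum of ``M`` reaches *threshold* (ascending).

    The threshold is inclusive: a position contacting a base in exactly 10%
    of instances is base-contacting under the default.
    """
    if not 0 < threshold <= 1:
        raise InterfaceError(f"threshold must lie in (0, 1], got {threshold}")
    M = np.asarray(M, dtype=float)
    return tuple(int(i) for i in np.flatnonzero(M.max(axis=1) >= threshold))


@dataclass
class ContactModel:
    """Contact-frequency matrix with derived interface annotations.

    ``key_positions[j]`` is the base-contacting DBD position with maximal
    ``M[i, j]`` (ties broken toward the lowest index), or ``None`` when no
    base-contacting position touches ``j``.
    """

    M: np.ndarray
    contact_threshold: float = 0.10
    base_contacting: tuple[int, ...] = field(init=False)
    key_positions: tuple[int | None, ...] = field(init=False)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2:
            raise InterfaceError("M must be 2-D (DBD position x binding-site position)")
        if np.any(M < 0) or np.any(M > 1) or not np.all(np.isfinite(M)):
            raise InterfaceError("M entries must lie in [0, 1]")
        M = M.copy()
        M.setflags(write=False)
        self.M = M
        self.base_contacting = call_base_contacting(M, self.contact_threshold)
        keys: list[int | None] = []
        bc = np.array(self.base_contacting, dtype=int)
        for j in range(M.shape[1]):
            if bc.size == 0 or not np.any(M[bc, j] > 0):
                keys.append(None)
            else:
                # argmax returns the first (lowest-index) maximizer: the tie-break
                keys.append(int(bc[int(np.argmax(M[bc, j]))]))
        self.key_positions = tuple(keys)

    @property
    def k(self) -> int:
        return self.M.shape[1]

    @property
    def n_contacting(self) -> int:
        return len(self.base_contacting)

    def key_position(self, j: int) -> int:
        """Key DBD position for binding-site position *j* (0-based)."""
        key = self.key_positions[j]
        if key is None:
            raise NoKeyPositionError(
                f"no base-contacting DBD position contacts binding-site position {j}"
            )
        return key


def compute_contact_frequency(
    instances: Sequence[ContactInstance], contact_threshold: float = 0.10
) -> ContactModel:
    """Uniqueness-weighted contact frequencies over co-complex instances.

    Each instance is weighted by the reciprocal of the number of instances
    sharing its aligned DBD sequence, so structurally redundant co-complexes
    of the same domain do not dominate ``M``.  Duplicating every instance
    leaves ``M`` unchanged.
    """
    if len(instances) == 0:
        raise InterfaceError("need at least one contact instance")
    shape = instances[0].contacts.shape
    if any(inst.contacts.shape != shape for inst in instances):
        raise InterfaceError("all contact maps must share the same dimensions")
    counts: dict[str, int] = {}
    for inst in instances:
        counts[inst.dbd_sequence] = counts.get(inst.dbd_sequence, 0) + 1
    weights = np.array([1.0 / counts[inst.dbd_sequence] for inst in instances])
    stacked = np.stack([inst.contacts for inst in instances]).astype(float)
    M = np.tensordot(weights, stacked, axes=1) / weights.sum()
    return ContactModel(M, contact_threshold=contact_threshold)


# ---------------------------------------------------------------------------
# TSV round-trip (binding-site positions are 1-based in files)


def write_contact_model(model: ContactModel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#contact_threshold\t{model.contact_threshold:g}\n")
        df = pd.DataFrame(
            model.M,
            index=pd.RangeIndex(1, model.M.shape[0] + 1, name="dbd_position"),
            columns=[str(j + 1) for j in range(model.k)],
        )
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_contact_model(path: str | Path) -> ContactModel:
    path = Path(path)
    threshold = 0.10
    lines = path.read_text().splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            key, _, value = line[1:].partition("\t")
            if key == "contact_threshold":
                threshold = float(value)
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), sep="\t", index_col=0)
    return ContactModel(df.to_numpy(dtype=float), contact_threshold=threshold)


def read_contact_instances(path: str | Path) -> list[ContactInstance]:
    """Read concatenated contact instances.

    Format: blocks separated by blank lines; each block is a line
    ``>SEQUENCE`` followed by one row of 0/1 flags (tab-separated, k columns)
    per aligned DBD position.
    """
    instances: list[ContactInstance] = []
    seq: str | None = None
    rows: list[list[int]] = []
    lines = Path(path).read_text().splitlines() + [""]
    for ln, line in enumerate(lines, 1):
        line = line.strip()
        if line.startswith(">"):
            if seq is not None:
                raise InterfaceError(f"line {ln}: unexpected new instance header")
            seq = line[1:]
            rows = []
        elif line:
            if seq is None:
                raise InterfaceError(f"line {ln}: contact row outside an instance block")
            rows.append([int(x) for x in line.split("\t")])
        else:
            if seq is not None:
                instances.append(ContactInstance(seq, np.array(rows, dtype=bool)))
                seq = None
    if not instances:
        raise InterfaceError(f"{path}: no contact instances found")
    return instances
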