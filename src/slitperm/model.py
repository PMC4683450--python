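"""Semiflexible chain on the cubic lattice, confined between two parallel walls.

The chain is a self-avoiding walk of ``n_monomers`` sites on the simple cubic
lattice (spacing ``a = 1``).  Four interactions define the model:

* **bending** — each right-angle joint between consecutive bonds costs
  ``bend_rigidity`` (in units of kBT); straight joints cost nothing and the
  back-fold (bending angle pi) is impossible because the chain is
  self-avoiding;
* **excluded volume** — no two monomers may occupy the same site;
* **contact attraction** — every *contact pair* (two non-bonded monomers at
  unit distance) contributes ``-epsilon``; the contact count ``Nc`` is the
  order parameter of the coil-globule transition;
* **slit walls** — two hard walls a distance ``H`` apart restrict the chain
  to ``H`` lattice planes.  ``H = 1`` is the strictly two-dimensional limit;
  ``slit_height=None`` means bulk (no walls).

Wall coordinates are translation-quotiented: a conformation is allowed in a
slit iff its z-extent fits between the walls (at most ``H`` occupied planes).
This makes the slit rule reduce *exactly* to the bulk rule whenever
``H >= n_monomers``, and it is the convention shared by the enumeration and
flatPERM modules.  For serialization the canonical placement puts the lowest
occupied plane at ``z = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "EnergyBreakdown",
    "as_conformation",
    "is_allowed",
    "bend_energy",
    "count_contacts",
    "total_energy",
    "persistence_length",
    "max_contacts_bound",
    "conformation_to_xyz",
    "conformation_from_xyz",
]

#: The six unit steps of the cubic lattice.
MOVES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class ModelParams:
    """One physical system: chain length, stiffness, and slit geometry.

    Parameters
    ----------
    n_monomers:
        Number of monomers Nm (>= 1).
    bend_rigidity:
        Bending energy per right-angle joint, in kBT (>= 0, finite).
    slit_height:
        Number of allowed lattice planes H (in units of the lattice
        spacing), or ``None`` for bulk.  ``H = 1`` is the pure 2-D case.
    """

    n_monomers: int
    bend_rigidity: float = 0.0
    slit_height: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.n_monomers, (int, np.integer)) or self.n_monomers < 1:
            raise ValueError(f"n_monomers must be a positive integer, got {self.n_monomers!r}")
        if not math.isfinite(self.bend_rigidity) or self.bend_rigidity < 0:
            raise ValueError(f"bend_rigidity must be finite and >= 0, got {self.bend_rigidity!r}")
        h = self.slit_height
        if h is not None and (not isinstance(h, (int, np.integer)) or h < 1):
            raise ValueError(f"slit_height must be a positive integer or None, got {h!r}")

    @property
    def is_bulk(self) -> bool:
        return self.slit_height is None

    @property
    def effective_slit(self) -> int:
        """Slit height actually constraining a chain of this length.

        A chain of Nm monomers spans at most Nm planes, so bulk behaves like
        any slit with ``H >= Nm``; kernels receive this finite value.
        """
        if self.slit_height is None:
            return self.n_monomers
        return min(self.slit_height, self.n_monomers)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Soft-interaction energies of one allowed conformation (in kBT)."""

    bend: float
    attract: float
    n_contacts: int

    @property
    def total(self) -> float:
        return self.bend + self.attract


def as_conformation(coords) -> np.ndarray:
    """Validate and return an ordered (N, 3) integer coordinate array.

    Raises ``ValueError`` if the input is not a unit-step lattice path
    (this is the 'malformed input' signal, distinct from a legal
    ``is_allowed(...) == False``).
    """
    arr = np.asarray(coords)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"conformation must have shape (N, 3), got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("conformation coordinates must be integers")
    arr = arr.astype(np.int64, copy=True)
    if len(arr) > 1:
        steps = np.diff(arr, axis=0)
        if not np.all(np.abs(steps).sum(axis=1) == 1):
            raise ValueError("consecutive monomers must differ by exactly one unit step")
    return arr


def is_allowed(c, p: ModelParams) -> bool:
    """True iff the conformation satisfies excluded volume and fits the slit.

    Self-avoidance subsumes the forbidden back-fold (a reversal revisits the
    previous-but-one site).  The slit criterion is the z-extent: the chain
    must occupy at most ``slit_height`` planes.
    """
    arr = as_conformation(c)
    if len(arr) != p.n_monomers:
        raise ValueError(
            f"conformation has {len(arr)} monomers, params expect {p.n_monomers}"
        )
    if len({tuple(row) for row in arr.tolist()}) != len(arr):
        return False
    if p.slit_height is not None:
        z = arr[:, 2]
        if int(z.max() - z.min()) >= p.slit_height:
            return False
    return True


def _require_allowed(c, p: ModelParams) -> np.ndarray:
    arr = as_conformation(c)
    if not is_allowed(arr, p):
        raise ValueError("conformation is not allowed under the given parameters")
    return arr


def bend_energy(c, p: ModelParams) -> float:
    """Total bending energy: ``bend_rigidity`` per right-angle joint (kBT)."""
    arr = _require_allowed(c, p)
    if len(arr) < 3:
        return 0.0
    steps = np.diff(arr, axis=0)
    dots = np.sum(steps[:-1] * steps[1:], axis=1)
    return float(p.bend_rigidity * int(np.count_nonzero(dots == 0)))


def count_contacts(c) -> int:
    """Number of contact pairs Nc: non-bonded monomer pairs at unit distance."""
    arr = as_conformation(c)
    site_index = {tuple(row): i for i, row in enumerate(arr.tolist())}
    if len(site_index) != len(arr):
        raise ValueError("conformation is self-overlapping")
    n = 0
    for i, row in enumerate(arr.tolist()):
        for mv in MOVES.tolist():
            j = site_index.get((row[0] + mv[0], row[1] + mv[1], row[2] + mv[2]))
            if j is not None and j > i + 1:
                n += 1
    return n


def total_energy(c, p: ModelParams, epsilon: float) -> EnergyBreakdown:
    """Soft energies of an allowed conformation at attraction strength epsilon.

    Hard interactions (overlap, walls) never appear as numbers: a disallowed
    conformation raises instead of returning an infinite energy.
    """
    arr = _require_allowed(c, p)
    nc = count_contacts(arr)
    return EnergyBreakdown(
        bend=bend_energy(arr, p),
        attract=-float(epsilon) * nc,
        n_contacts=nc,
    )


def persistence_length(bend_rigidity: float) -> float:
    """Persistence length lp/a implied by the bending rigidity.

    On the cubic lattice with the back-fold excluded, a bond is followed by
    one straight continuation (weight 1) and four right-angle continuations
    (weight ``exp(-bend_rigidity)`` each), so the bond-orientation
    correlation per step is ``<cos theta> = 1 / (1 + 4 exp(-bend_rigidity))``
    and ``lp/a = -1 / ln<cos theta>``.  Strictly increasing in the rigidity;
    a fully flexible chain (rigidity 0) has ``lp/a = 1/ln 5 ~ 0.62``.
    """
    if bend_rigidity < 0:
        raise ValueError("bend_rigidity must be >= 0")
    mean_cos = 1.0 / (1.0 + 4.0 * math.exp(-bend_rigidity))
    if mean_cos >= 1.0:
        return math.inf
    return -1.0 / math.log(mean_cos)


def max_contacts_bound(p: ModelParams) -> int:
    """Analytic upper bound on the contact number Nc.

    Among any Nm occupied sites the number of adjacent site pairs is bounded
    by a discrete isoperimetric argument; every adjacent pair is either one
    of the Nm-1 bonds or a contact, so

        ``Nc <= E_max(Nm, H) - (Nm - 1)``.

    In bulk ``E_max <= 3 Nm - 3 Nm^(2/3)`` (equality for perfect cubes); in a
    slit the in-plane edges obey the square-lattice bound ``2 N - 2 sqrt(N)``
    and the inter-plane edges cannot exceed ``N - N/H``.  For ``H = 1`` and
    Nm a perfect square s^2 the bound ``2 s (s-1) - (Nm - 1)`` is attained by
    a Hamiltonian path on the s x s grid; e.g. Nm = 1024 on a surface gives
    961 contacts, i.e. ~0.94 contacts per monomer.
    """
    n = p.n_monomers
    if n <= 1:
        return 0
    bulk_edges = math.floor(3.0 * n - 3.0 * math.cbrt(n) ** 2 + 1e-9)
    edges = bulk_edges
    if p.slit_height is not None:
        h = p.slit_height
        slit_edges = math.floor(3.0 * n - n / h - 2.0 * math.sqrt(n) + 1e-9)
        edges = min(edges, slit_edges)
    return max(edges - (n - 1), 0)


def conformation_to_xyz(c) -> str:
    """Serialize as plain text: one ``x y z`` integer triple per line."""
    arr = as_conformation(c)
    return "\n".join(f"{x} {y} {z}" for x, y, z in arr.tolist()) + "\n"


def conformation_from_xyz(text: str) -> np.ndarray:
    """Parse the plain-text triple-per-line format back into coordinates."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected three integers, got {line!r}")
        try:
            rows.append([int(v) for v in parts])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinate in {line!r}") from exc
    return as_conformation(np.array(rows, dtype=np.int64))
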