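"""Exhaustive enumeration of small chains: the exact ground truth.

For chains short enough to exhaust, a depth-first walk over the growth tree
counts every allowed shape, resolved jointly by contact number and number of
right-angle joints.  The joint integer counts are cached per geometry, so one
enumeration serves every bending rigidity exactly:

    g(Nc) = sum_b counts[Nc, b] * exp(-eps_bend * b).

This is the oracle the flatPERM sampler is validated against, and the source
of the bit-exact self-avoiding-walk totals (30, 150, 726, 3534, ... on the
cubic lattice; 12, 36, 100, 284, ... on the square lattice at H = a).
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.special import logsumexp

from .dos import DoSTable
from .errors import SizeGuardError
from .model import ModelParams, max_contacts_bound

__all__ = ["enumerate_dos", "total_walk_count", "enumeration_limit"]


def enumeration_limit(p: ModelParams) -> int:
    """Largest chain this module will exhaust for the given geometry.

    The growth tree has ~4.68^Nm nodes in bulk and ~2.64^Nm at H = 1; the
    limits keep a single enumeration in the seconds range.
    """
    h = p.effective_slit
    if h == 1:
        return 16
    if h == 2:
        return 13
    return 12


@functools.lru_cache(maxsize=64)
def _joint_counts(n_monomers: int, slit_h: int, nc_cap: int) -> np.ndarray:
    from ._kernels import enumerate_kernel

    counts = enumerate_kernel(n_monomers, slit_h, nc_cap)
    counts.setflags(write=False)
    return counts


def _counts_for(p: ModelParams) -> np.ndarray:
    limit = enumeration_limit(p)
    if p.n_monomers > limit:
        raise SizeGuardError(
            f"enumeration guard: n_monomers={p.n_monomers} exceeds the "
            f"limit of {limit} for slit_height={p.slit_height}"
        )
    cap = max_contacts_bound(p)
    return _joint_counts(p.n_monomers, p.effective_slit, cap)


def enumerate_dos(p: ModelParams) -> DoSTable:
    """Exact effective density of states for one small system.

    Deterministic; refuses (``SizeGuardError``) above the enumeration limit.
    Bins with no allowed shape are absent from the table.  At
    ``bend_rigidity = 0`` the returned table carries the integer counts as
    an exact side-channel.
    """
    counts = _counts_for(p)
    present = counts.sum(axis=1) > 0
    nc = np.nonzero(present)[0].astype(np.int64)
    bends = np.arange(counts.shape[1], dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts[present].astype(np.float64))
    log_g = logsumexp(log_counts - p.bend_rigidity * bends[None, :], axis=1)
    return DoSTable(
        params=p,
        nc=nc,
        log_g=log_g,
        provenance="enumeration",
        counts=counts[present].copy(),
    )


def total_walk_count(p: ModelParams) -> float:
    """Summed density of states over all Nc.

    At ``bend_rigidity = 0`` this is exactly the number of
    ``(n_monomers - 1)``-step self-avoiding walks in the given geometry
    (returned exactly; integer counts below 2**53 are float-representable).
    """
    counts = _counts_for(p)
    if p.bend_rigidity == 0.0:
        return float(counts.sum())
    bends = np.arange(counts.shape[1], dtype=np.float64)
    return float(np.sum(counts * np.exp(-p.bend_rigidity * bends)[None, :]))
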