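"""flatPERM: flat-histogram pruned-enriched Rosenbluth chain growth.

The sampler estimates the effective density of states g(Nc) at chain lengths
far beyond exhaustive enumeration.  Chains grow monomer by monomer from a
single tour start (n = 1); each growth step multiplies the Rosenbluth weight
by the bending-weighted atmosphere and the visit-flattening prune/enrich
rule keeps the (chain length, contact number) histogram uniformly covered.
Weights are carried in log space throughout — at production lengths they
span hundreds of orders of magnitude.

The heavy loop lives in :mod:`slitperm._kernels`; this module owns the
public contract: parameter validation, the returned :class:`DoSTable`, the
accumulated :class:`FlatPermState`, and convergence diagnostics.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dos import DoSTable
from .model import ModelParams, MOVES, as_conformation, max_contacts_bound

__all__ = ["FlatPermState", "run", "atmosphere", "convergence_report"]


@dataclass
class FlatPermState:
    """Accumulated flatPERM bookkeeping for one run.

    ``log_weight[n, nc]`` is the log of the summed Rosenbluth weights
    collected at chain length ``n`` with ``nc`` contacts (not yet normalized
    per tour); ``visits`` is the corresponding histogram.  The density of
    states estimate at full length is ``log_weight[n] - log(tours)``.
    """

    params: ModelParams
    log_weight: np.ndarray
    visits: np.ndarray
    tours_touched: np.ndarray
    tours: int
    seed: int
    bias: bool = True
    total_steps: int = 0
    dead_ends: int = 0
    wall_time: float = 0.0

    def log_g(
        self, n: int | None = None, min_tours: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """(nc, log_g) at chain length ``n`` (default: full length).

        ``min_tours`` drops bins reached by fewer independent tours than
        the cutoff.  Raw visit counts overstate the information in a bin
        (enrichment copies within one tour are strongly correlated), so the
        distinct-tour count is the effective sample size: a bin touched by
        a handful of tours carries an error of order its own magnitude, and
        landscape work should trim such bins.
        """
        n = self.params.n_monomers if n is None else n
        visited = self.tours_touched[n] >= max(min_tours, 1)
        nc = np.nonzero(visited)[0].astype(np.int64)
        return nc, self.log_weight[n, visited] - np.log(self.tours)

    def to_table(self, min_tours: int = 1) -> DoSTable:
        """Build the DoS table, keeping bins reached by >= ``min_tours`` tours."""
        nc, log_g = self.log_g(min_tours=min_tours)
        if len(nc) == 0:
            raise RuntimeError("no bin satisfies the tour-coverage cutoff")
        return DoSTable(
            params=self.params,
            nc=nc,
            log_g=log_g,
            provenance="flatperm",
            meta={
                "seed": self.seed,
                "tours": self.tours,
                "bias": str(self.bias).lower(),
                "min_tours": int(min_tours),
            },
        )


def atmosphere(coords, p: ModelParams) -> list[tuple[np.ndarray, float]]:
    """Allowed continuations of a partial chain with their bending weights.

    Returns ``(step, weight)`` pairs: every empty unit-step site that keeps
    the chain inside the slit, excluding the back-fold (blocked by the
    occupied predecessor site).  The weight is ``exp(-bend_rigidity)`` for a
    right-angle joint and 1 for a straight one; the first bond has no joint,
    so all its continuations carry weight 1.
    """
    arr = as_conformation(coords)
    if len(arr) >= p.n_monomers:
        raise ValueError("chain is already at full length")
    occupied = {tuple(row) for row in arr.tolist()}
    if len(occupied) != len(arr):
        raise ValueError("partial chain is self-overlapping")
    head = arr[-1]
    zlo = int(arr[:, 2].min())
    zhi = int(arr[:, 2].max())
    wb = float(np.exp(-p.bend_rigidity))
    last_step = arr[-1] - arr[-2] if len(arr) >= 2 else None
    out: list[tuple[np.ndarray, float]] = []
    h = p.effective_slit
    for mv in MOVES:
        site = head + mv
        if tuple(site.tolist()) in occupied:
            continue
        z = int(site[2])
        if max(zhi, z) - min(zlo, z) >= h:
            continue
        if last_step is None:
            w = 1.0
        else:
            w = 1.0 if int(np.dot(mv, last_step)) == 1 else wb
        out.append((mv.copy(), w))
    return out


def run(
    p: ModelParams,
    budget: int,
    seed: int,
    bias: bool = True,
) -> tuple[DoSTable, FlatPermState]:
    """Run flatPERM for ``budget`` tours and return the estimated DoS table.

    Deterministic: identical ``(p, budget, seed, bias)`` give bit-identical
    results.  If the budget leaves gaps between visited bins at full length,
    the table is returned with those bins absent and a warning is emitted.
    """
    if budget < 1:
        raise ValueError("budget must be at least one tour")
    if not (0 <= int(seed) < 2**32):
        raise ValueError("seed must fit in an unsigned 32-bit integer")
    from ._kernels import flatperm_kernel

    cap = max_contacts_bound(p)
    t0 = time.perf_counter()
    logW, visits, touched, total_steps, dead_ends = flatperm_kernel(
        p.n_monomers, p.effective_slit, cap, float(p.bend_rigidity), int(budget), int(seed), bool(bias)
    )
    state = FlatPermState(
        params=p,
        log_weight=logW,
        visits=visits,
        tours_touched=touched,
        tours=int(budget),
        seed=int(seed),
        bias=bool(bias),
        total_steps=int(total_steps),
        dead_ends=int(dead_ends),
        wall_time=time.perf_counter() - t0,
    )
    nc, _ = state.log_g()
    if len(nc) == 0:
        raise RuntimeError("no complete chain was grown; increase the budget")
    if np.any(np.diff(nc) > 1):
        warnings.warn(
            "flatPERM budget left gaps between visited contact bins at full "
            "length; the table is returned with those bins absent",
            stacklevel=2,
        )
    return state.to_table(), state


def convergence_report(state: FlatPermState) -> dict:
    """Visit-flatness and coverage diagnostics for a finished run.

    ``flatness`` per chain length is (min visits / max visits) over the bins
    visited at that length — 1.0 is a perfectly flat histogram.  Coverage at
    full length is reported against the analytic contact bound (an upper
    bound on the reachable bins, so the fraction may undershoot 1 even for a
    converged run).
    """
    if state.tours == 0 or not np.any(state.visits):
        return {}
    nm = state.params.n_monomers
    flatness = {}
    for n in range(1, nm + 1):
        row = state.visits[n]
        hit = row[row > 0]
        if len(hit):
            flatness[n] = float(hit.min() / hit.max())
    top = state.visits[nm]
    cap = state.visits.shape[1] - 1
    visited = np.nonzero(top > 0)[0]
    interior_gaps = 0
    if len(visited):
        lo, hi = int(visited[0]), int(visited[-1])
        interior_gaps = int(np.count_nonzero(top[lo : hi + 1] == 0))
    touched_top = state.tours_touched[nm]
    return {
        "tours": state.tours,
        "seed": state.seed,
        "total_steps": state.total_steps,
        "dead_ends": state.dead_ends,
        "wall_time_s": state.wall_time,
        "flatness": flatness,
        "full_length_bins_visited": int(len(visited)),
        "full_length_coverage_of_bound": float(len(visited) / (cap + 1)),
        "interior_gaps_at_full_length": interior_gaps,
        "full_length_median_tour_coverage": float(
            np.median(touched_top[touched_top > 0])
        )
        if np.any(touched_top > 0)
        else 0.0,
    }
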