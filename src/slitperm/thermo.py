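"""Density-of-states thermodynamics of the coil-globule transition.

Everything downstream of g(Nc).  Because the contact attraction enters the
total energy only as ``-epsilon * Nc``, the canonical weight of a contact
bin is ``g(Nc) exp(+epsilon * Nc)`` and one table yields, at any attraction
strength:

* the mean contact number and its fluctuation (variance), whose peak over
  epsilon locates the critical attraction ``eps*`` of the transition and
  whose full width at half maximum measures the transition sharpness;
* the landscape ``F(Nc) = -ln P(Nc; eps)`` (kBT), whose two minima are the
  coil and globule basins and whose interior maximum is the free-energy
  barrier of a discontinuous transition;
* the confinement free energy ``-ln[g_slit(Nc) / g_bulk(Nc)]``, independent
  of epsilon because the Boltzmann factors cancel in the ratio.

All reweighting is done in log space.  Outputs are shift-invariant: adding a
constant to ``log_g`` changes nothing here (the confinement free energy is
anchored at the smallest shared contact number, since its additive constant
depends on an unobservable absolute normalization).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .dos import DoSTable
from .errors import ConventionMismatchError, WindowError
from .model import ModelParams, persistence_length

__all__ = [
    "ThermoCurve",
    "TransitionSummary",
    "BarrierResult",
    "UnitMapping",
    "reweight",
    "fluctuation_curve",
    "find_critical_epsilon",
    "landscape",
    "barrier",
    "confinement_free_energy",
    "transition_summary",
    "phase_map",
    "critical_slit_height",
    "unit_mapping",
]

#: default attraction scan window (kBT) — brackets every regime with
#: bending rigidity <= 3 at the chain lengths this package targets
DEFAULT_WINDOW = (0.0, 2.0)
DEFAULT_COARSE_STEP = 1e-3


# --------------------------------------------------------------------- types
@dataclass
class ThermoCurve:
    """A tabulated thermodynamic quantity with its provenance.

    ``kind`` is one of mean_contacts | fluctuation | probability |
    free_energy | confinement_free_energy; ``x_name`` names the abscissa
    (``eps`` in kBT or ``Nc`` in counts).
    """

    kind: str
    x_name: str
    x: np.ndarray
    y: np.ndarray
    params: ModelParams
    epsilon: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be matching 1-D arrays")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("abscissa must be strictly increasing")

    def to_tsv(self) -> str:
        h = self.params.slit_height
        lines = [
            "# schema=slitperm-curve/1",
            f"# kind={self.kind}",
            f"# n_monomers={self.params.n_monomers}",
            f"# eps_bend={format(self.params.bend_rigidity, '.12g')}",
            f"# slit_height={'bulk' if h is None else h}",
        ]
        if self.epsilon is not None:
            lines.append(f"# epsilon={format(self.epsilon, '.12g')}")
        for key in sorted(self.meta):
            lines.append(f"# {key}={self.meta[key]}")
        lines.append(f"{self.x_name}\tvalue")
        for xv, yv in zip(self.x.tolist(), self.y.tolist()):
            lines.append(f"{format(xv, '.12g')}\t{format(yv, '.12g')}")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_tsv())


@dataclass
class BarrierResult:
    """Free-energy barrier read off one landscape curve."""

    height: float  # kBT, >= 0
    first_order: bool  # True iff two basins separated by an interior maximum
    coil_min_nc: int | None = None
    globule_min_nc: int | None = None
    barrier_nc: int | None = None


@dataclass
class TransitionSummary:
    """Location and sharpness of the coil-globule transition for one system."""

    eps_star: float  # kBT, fluctuation-peak location
    fwhm: float  # kBT, full width at half maximum of the peak
    peak_height: float  # contact-number variance at the peak
    barrier: float | None = None  # kBT at eps*, None if not evaluated
    first_order: bool | None = None
    coil_min_nc: int | None = None
    globule_min_nc: int | None = None
    all_peaks: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class UnitMapping:
    """Dimensionless chain mapped onto physical units via the persistence length."""

    lattice_nm: float  # lattice spacing a in nm (also the effective width)
    chain_width_nm: float
    contour_um: float
    lp_lattice: float  # model persistence length in units of a
    lp_below_spacing: bool  # flexible chains have lp < a; flagged, not an error


# ---------------------------------------------------------------- reweighting
def _log_weights(dos: DoSTable, eps) -> np.ndarray:
    """log of unnormalized Boltzmann weights g(Nc) e^{+eps Nc} (attraction
    lowers the energy by eps per contact)."""
    eps = np.asarray(eps, dtype=np.float64)
    return dos.log_g[None, :] + eps.reshape(-1, 1) * dos.nc[None, :]


def _moments(dos: DoSTable, eps) -> tuple[np.ndarray, np.ndarray]:
    lw = _log_weights(dos, eps)
    lse = logsumexp(lw, axis=1, keepdims=True)
    prob = np.exp(lw - lse)
    nc = dos.nc.astype(np.float64)
    mean = prob @ nc
    var = prob @ nc**2 - mean**2
    return mean, np.maximum(var, 0.0)


def reweight(dos: DoSTable, epsilon: float) -> tuple[float, float]:
    """Mean and variance of the contact number at attraction ``epsilon``."""
    mean, var = _moments(dos, [float(epsilon)])
    return float(mean[0]), float(var[0])


def probabilities(dos: DoSTable, epsilon: float) -> np.ndarray:
    """Normalized P(Nc; epsilon) on the table's support (sums to 1)."""
    lw = _log_weights(dos, [float(epsilon)])[0]
    return np.exp(lw - logsumexp(lw))


def mean_contacts_curve(dos: DoSTable, eps_grid) -> ThermoCurve:
    """<Nc> tabulated over an increasing attraction grid."""
    grid = np.asarray(eps_grid, dtype=np.float64)
    mean, _ = _moments(dos, grid)
    return ThermoCurve("mean_contacts", "eps", grid, mean, dos.params,
                       meta={"source_checksum": dos.checksum()})

def fluctuation_curve(dos: DoSTable, eps_grid, per_monomer: bool = False) -> ThermoCurve:
    """Contact-number variance over an attraction grid.

    The raw variance is returned by default; ``per_monomer`` divides by the
    chain length (both normalizations are in circulation for this quantity).
    """
    grid = np.asarray(eps_grid, dtype=np.float64)
    _, var = _moments(dos, grid)
    if per_monomer:
        var = var / dos.params.n_monomers
    return ThermoCurve(
        "fluctuation",
        "eps",
        grid,
        var,
        dos.params,
        meta={"per_monomer": str(per_monomer).lower(), "source_checksum": dos.checksum()},
    )


# ------------------------------------------------------- transition location
def _variance_at(dos: DoSTable, eps: float) -> float:
    return reweight(dos, eps)[1]


def find_critical_epsilon(
    dos: DoSTable,
    window: tuple[float, float] = DEFAULT_WINDOW,
    coarse_step: float = DEFAULT_COARSE_STEP,
    refine_xtol: float = 1e-9,
) -> TransitionSummary:
    """Locate the fluctuation peak: critical attraction eps* and its FWHM.

    A coarse grid scan over ``window`` finds candidate interior maxima
    (peaks below 1% relative prominence are treated as numerical ripple);
    the argmax is then refined by bounded minimization well past the stated
    1e-5 kBT tolerance, and the half-maximum crossings are located by root
    bracketing with linear-interpolation starting brackets.  If the variance
    has not fallen to half maximum inside the window, the crossing search
    extends beyond it (flagged ``window_extended``).  Raises
    :class:`WindowError` when the window contains no interior peak; multiple
    genuine peaks are all reported, flagged ``multimodal``, and the global
    one is refined.
    """
    if len(dos.nc) < 2:
        raise WindowError("table supports no fluctuation peak (single contact bin)")
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must be an increasing pair")
    grid = np.arange(lo, hi + coarse_step / 2, coarse_step)
    _, var = _moments(dos, grid)
    vmax = float(var.max())
    if vmax <= 0:
        raise WindowError("fluctuation vanishes over the scan window")
    idx, _ = find_peaks(var, prominence=0.01 * vmax)
    if len(idx) == 0:
        raise WindowError(
            f"no interior fluctuation peak in window [{lo}, {hi}]; "
            "the maximum sits on the boundary"
        )
    flags: list[str] = []
    all_peaks: list[float] = []

    def refine(i: int) -> float:
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda e: -_variance_at(dos, e),
            bounds=(a, b),
            method="bounded",
            options={"xatol": refine_xtol},
        )
        return float(res.x)

    for i in idx:
        all_peaks.append(refine(int(i)))
    if len(idx) > 1:
        flags.append("multimodal")
    best = int(idx[np.argmax(var[idx])])
    eps_star = all_peaks[int(np.argmax(var[idx]))]
    peak_height = _variance_at(dos, eps_star)
    half = peak_height / 2.0

    def crossing(side: int) -> float:
        """Half-maximum crossing left (side=-1) or right (side=+1) of the peak."""
        nonlocal flags
        step = side * coarse_step * 10
        a = eps_star
        fa = peak_height - half
        b = a
        limit = 8.0  # kBT beyond which no half-crossing is plausible here
        while True:
            b = b + step
            fb = _variance_at(dos, b) - half
            if fb < 0:
                break
            if abs(b - eps_star) > limit:
                raise WindowError("fluctuation never falls to half maximum")
            if (side < 0 and b < lo) or (side > 0 and b > hi):
                if "window_extended" not in flags:
                    flags.append("window_extended")
            a, fa = b, fb
        lo_b, hi_b = (b, a) if side < 0 else (a, b)
        return float(brentq(lambda e: _variance_at(dos, e) - half, lo_b, hi_b, xtol=1e-12))

    left = crossing(-1)
    right = crossing(+1)
    return TransitionSummary(
        eps_star=eps_star,
        fwhm=right - left,
        peak_height=peak_height,
        all_peaks=sorted(all_peaks),
        flags=flags,
    )


# ------------------------------------------------------------------ landscape
def _local_minima(y: np.ndarray) -> list[int]:
    """Indices of local minima; a plateau counts once, at its lowest index."""
    mins: list[int] = []
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] > y[i]
        right_ok = j == n - 1 or y[j + 1] > y[i]
        if left_ok and right_ok:
            mins.append(i)
        i = j + 1
    return mins


def _significant_minima(
    f: np.ndarray, min_prominence: float, max_depth: float
) -> list[int]:
    """Local minima that are real basins rather than ripple.

    Candidates (including boundaries and plateaus) are kept only if they lie
    within ``max_depth`` kBT of the deepest minimum — a basin 10 kBT up
    carries e^-10 of the probability and is sampling noise for our purposes
    — and adjacent minima not separated by a maximum at least
    ``min_prominence`` kBT above both are merged into the deeper one.
    """
    cand = _local_minima(f)
    if not cand:
        return cand
    fmin = min(f[i] for i in cand)
    cand = [i for i in cand if f[i] - fmin <= max_depth]
    changed = True
    while changed and len(cand) > 1:
        changed = False
        for a, b in zip(cand, cand[1:]):
            ridge = float(f[a : b + 1].max()) - max(f[a], f[b])
            if ridge < min_prominence:
                cand.remove(a if f[a] > f[b] else b)
                changed = True
                break
    return cand


def landscape(dos: DoSTable, epsilon: float) -> ThermoCurve:
    """Free-energy landscape F(Nc) = -ln P(Nc; eps) in kBT.

    Shifted so the coil-side (lowest-Nc) local minimum sits at zero; minima
    are located on the integer contact grid with plateaus resolved to the
    lower Nc.  The inverse relation ``P = exp(-F) / sum exp(-F)`` holds
    regardless of the shift.
    """
    lw = _log_weights(dos, [float(epsilon)])[0]
    f = -(lw - logsumexp(lw))
    mins = _local_minima(f)
    shift_at = mins[0] if mins else int(np.argmin(f))
    f = f - f[shift_at]
    return ThermoCurve(
        "free_energy",
        "Nc",
        dos.nc.astype(np.float64),
        f,
        dos.params,
        epsilon=float(epsilon),
        meta={"shift_nc": int(dos.nc[shift_at]), "source_checksum": dos.checksum()},
    )


def barrier(
    curve: ThermoCurve, min_prominence: float = 0.25, max_depth: float = 3.0
) -> BarrierResult:
    """Free-energy barrier of a landscape curve.

    The barrier is the interior maximum between the coil (lowest-Nc) and
    globule (highest-Nc) significant minima, measured from the coil
    minimum.  Basin significance (see ``min_prominence``/``max_depth``, in
    kBT) keeps sampling ripple and negligibly-occupied tail dips from
    masquerading as phases.  A single-basin curve — or one with no interior
    bin between its minima — has no barrier and is flagged as a continuous
    transition.
    """
    if curve.kind != "free_energy":
        raise ValueError("barrier expects a free_energy curve")
    f = curve.y
    mins = _significant_minima(f, min_prominence, max_depth)
    if len(mins) < 2:
        return BarrierResult(0.0, False)
    coil, glob = mins[0], mins[-1]
    if glob - coil < 2:
        return BarrierResult(
            0.0, False, int(curve.x[coil]), int(curve.x[glob])
        )
    seg = f[coil : glob + 1]
    k = int(np.argmax(seg)) + coil
    height = float(f[k] - f[coil])
    if k in (coil, glob) or height <= 0 or f[k] <= f[glob]:
        return BarrierResult(0.0, False, int(curve.x[coil]), int(curve.x[glob]))
    return BarrierResult(
        height, True, int(curve.x[coil]), int(curve.x[glob]), int(curve.x[k])
    )


# ------------------------------------------------------- confinement effects
def confinement_free_energy(slit: DoSTable, bulk: DoSTable) -> ThermoCurve:
    """Confinement free energy -ln[g_slit(Nc)/g_bulk(Nc)] in kBT.

    Both tables must describe the same chain (length and rigidity) under the
    same counting convention.  The contact attraction cancels in the ratio,
    so the curve is independent of epsilon by construction.  The additive
    constant depends on an unobservable absolute normalization, so the curve
    is anchored to zero at the smallest shared contact number; a slit at
    least as tall as the chain gives the identically-zero curve.
    """
    if slit.convention != bulk.convention:
        raise ConventionMismatchError(
            f"counting conventions differ: {slit.convention!r} vs {bulk.convention!r}"
        )
    ps, pb = slit.params, bulk.params
    if ps.n_monomers != pb.n_monomers or ps.bend_rigidity != pb.bend_rigidity:
        raise ConventionMismatchError(
            "tables describe different chains "
            f"(Nm {ps.n_monomers}/{pb.n_monomers}, "
            f"rigidity {ps.bend_rigidity}/{pb.bend_rigidity})"
        )
    common, is_, ib = np.intersect1d(slit.nc, bulk.nc, return_indices=True)
    if len(common) == 0:
        raise ConventionMismatchError("tables share no contact bins")
    df = -(slit.log_g[is_] - bulk.log_g[ib])
    df = df - df[0]
    return ThermoCurve(
        "confinement_free_energy",
        "Nc",
        common.astype(np.float64),
        df,
        ps,
        meta={
            "anchor_nc": int(common[0]),
            "bulk_checksum": bulk.checksum(),
            "slit_checksum": slit.checksum(),
        },
    )


# -------------------------------------------------------------- aggregation
def transition_summary(
    dos: DoSTable,
    window: tuple[float, float] = DEFAULT_WINDOW,
    coarse_step: float = DEFAULT_COARSE_STEP,
) -> TransitionSummary:
    """Full per-system summary: eps*, FWHM, and the barrier at eps*."""
    summ = find_critical_epsilon(dos, window=window, coarse_step=coarse_step)
    land = landscape(dos, summ.eps_star)
    bar = barrier(land)
    summ.barrier = bar.height
    summ.first_order = bar.first_order
    summ.coil_min_nc = bar.coil_min_nc
    summ.globule_min_nc = bar.globule_min_nc
    return summ


def phase_map(
    tables: list[DoSTable],
    window: tuple[float, float] = DEFAULT_WINDOW,
    coarse_step: float = DEFAULT_COARSE_STEP,
) -> pd.DataFrame:
    """Transition summaries across a set of geometries.

    One row per table (slit height ``inf`` encodes bulk).  Per-table
    failures are recorded in the ``error`` column and do not stop the rest.
    """
    rows = []
    for dos in tables:
        p = dos.params
        row = {
            "n_monomers": p.n_monomers,
            "eps_bend": p.bend_rigidity,
            "slit_height": math.inf if p.slit_height is None else float(p.slit_height),
            "eps_star": np.nan,
            "fwhm": np.nan,
            "peak_height": np.nan,
            "barrier": np.nan,
            "first_order": pd.NA,
            "error": None,
        }
        try:
            summ = transition_summary(dos, window=window, coarse_step=coarse_step)
            row.update(
                eps_star=summ.eps_star,
                fwhm=summ.fwhm,
                peak_height=summ.peak_height,
                barrier=summ.barrier,
                first_order=summ.first_order,
            )
        except (WindowError, ValueError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def critical_slit_height(
    heights, eps_stars, method: str = "crossing"
) -> tuple[float, str]:
    """Slit height H* minimizing eps*(H).

    ``method='argmin'`` returns the discrete minimizer.  ``method='crossing'``
    sharpens it by intersecting the segment through the two data points
    ending at the discrete minimum with the segment through the next two
    points on the rising side (falling back to the discrete minimum, with
    the method string saying so, when fewer points are available).
    Bulk entries (``inf``) are excluded.
    """
    h = np.asarray(heights, dtype=np.float64)
    e = np.asarray(eps_stars, dtype=np.float64)
    keep = np.isfinite(h) & np.isfinite(e)
    h, e = h[keep], e[keep]
    if len(h) < 1:
        raise ValueError("no finite slit heights supplied")
    order = np.argsort(h)
    h, e = h[order], e[order]
    k = int(np.argmin(e))
    if method == "argmin" or len(h) < 4 or k == 0 or k + 2 >= len(h):
        return float(h[k]), "argmin"
    # segment through (k-1, k), segment through (k+1, k+2)
    s1 = (e[k] - e[k - 1]) / (h[k] - h[k - 1])
    s2 = (e[k + 2] - e[k + 1]) / (h[k + 2] - h[k + 1])
    if s1 == s2:
        return float(h[k]), "argmin"
    hx = (e[k + 1] - e[k] + s1 * h[k] - s2 * h[k + 1]) / (s1 - s2)
    if not (h[k - 1] <= hx <= h[k + 2]):
        return float(h[k]), "argmin"
    return float(hx), "crossing"


# ------------------------------------------------------------- unit mapping
def unit_mapping(p: ModelParams, physical_lp_nm: float) -> UnitMapping:
    """Map the dimensionless chain onto physical units.

    The two dimensionless parameters of a semiflexible chain are L/lp and
    lp/w.  Matching the model persistence length to a physical one fixes the
    lattice spacing ``a = lp_physical / (lp/a)``; the effective chain width
    is ``a`` (the closest monomer-monomer approach) and the contour length
    is ``Nm * a``.  With the DNA persistence length of 50 nm and a chain of
    1024 monomers at bending rigidity 3 kBT this gives a ~9.3 um contour and
    a ~9 nm width — lambda-DNA territory.
    """
    if physical_lp_nm <= 0:
        raise ValueError("physical persistence length must be positive")
    lp = persistence_length(p.bend_rigidity)
    a_nm = physical_lp_nm / lp
    return UnitMapping(
        lattice_nm=a_nm,
        chain_width_nm=a_nm,
        contour_um=p.n_monomers * a_nm / 1000.0,
        lp_lattice=lp,
        lp_below_spacing=lp < 1.0,
    )
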