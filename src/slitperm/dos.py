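"""The density-of-states table: the artifact every module exchanges.

``DoSTable`` tabulates ``log g(Nc)``, the natural log of the *effective*
density of states: the bending-Boltzmann-weighted number of allowed chain
shapes with ``Nc`` contact pairs.  Attraction never enters ``g``; it is
re-applied downstream by Boltzmann reweighting, so one table serves every
attraction strength.

Tables are serialized as TSV with ``#``-prefixed ``key=value`` metadata
lines, then two columns ``Nc`` and ``log_g`` (12 significant digits).  The
counting convention (see ``slitperm.model``) is recorded in the metadata and
checked whenever two tables are compared.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .model import ModelParams

__all__ = ["DoSTable", "two_state_table"]

_SCHEMA = "slitperm-dos/1"
#: serialization convention label shared by enumerator and sampler
CONVENTION = "shape-once"


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


@dataclass
class DoSTable:
    """log of the effective density of states vs contact number.

    ``nc`` is strictly increasing; bins where no state exists (or that a
    finite sampling budget never visited) are simply absent — never stored
    as zeros.  ``counts``, when present (exact enumeration only), is the
    integer matrix ``counts[i, b]`` of shapes with ``nc[i]`` contacts and
    ``b`` right-angle joints; it reproduces ``log_g`` exactly for any
    bending rigidity and gives bit-exact walk counts at rigidity zero.
    """

    params: ModelParams
    nc: np.ndarray
    log_g: np.ndarray
    provenance: str  # "enumeration" | "flatperm" | "analytic"
    shift: str = "raw"  # "raw" | "pinned0"
    convention: str = CONVENTION
    counts: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nc = np.asarray(self.nc, dtype=np.int64)
        self.log_g = np.asarray(self.log_g, dtype=np.float64)
        if self.nc.shape != self.log_g.shape or self.nc.ndim != 1:
            raise ValueError("nc and log_g must be matching 1-D arrays")
        if len(self.nc) == 0:
            raise ValueError("empty density-of-states table")
        if np.any(np.diff(self.nc) <= 0):
            raise ValueError("nc values must be strictly increasing")
        if not np.all(np.isfinite(self.log_g)):
            raise ValueError("log_g must be finite wherever a state exists")

    # ------------------------------------------------------------------ ops
    def log_total(self) -> float:
        """log of the density of states summed over all contact bins."""
        from scipy.special import logsumexp

        return float(logsumexp(self.log_g))

    def pin_zero(self) -> "DoSTable":
        """Return a copy shifted so log_g at the smallest Nc is zero."""
        return replace(
            self,
            log_g=self.log_g - self.log_g[0],
            shift="pinned0",
            counts=None,
            meta=dict(self.meta),
        )

    def integer_g(self) -> np.ndarray:
        """Exact integer state counts per Nc (rigidity-zero enumeration only)."""
        if self.counts is None:
            raise ValueError("no integer side-channel on this table")
        if self.params.bend_rigidity != 0.0:
            raise ValueError("integer counts equal g only at bend_rigidity = 0")
        return self.counts.sum(axis=1)

    # ----------------------------------------------------------------- (de)serialization
    def to_tsv(self) -> str:
        h = self.params.slit_height
        lines = [
            f"# schema={_SCHEMA}",
            f"# n_monomers={self.params.n_monomers}",
            f"# eps_bend={_fmt(self.params.bend_rigidity)}",
            f"# slit_height={'bulk' if h is None else h}",
            f"# provenance={self.provenance}",
            f"# shift={self.shift}",
            f"# convention={self.convention}",
        ]
        for key in sorted(self.meta):
            lines.append(f"# {key}={self.meta[key]}")
        lines.append("Nc\tlog_g")
        for nc, lg in zip(self.nc.tolist(), self.log_g.tolist()):
            lines.append(f"{nc}\t{_fmt(lg)}")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "DoSTable":
        header: dict[str, str] = {}
        nc: list[int] = []
        log_g: list[float] = []
        saw_columns = False
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ConfigError(f"line {lineno}: malformed metadata {raw!r}")
                key, _, val = body.partition("=")
                header[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if not saw_columns:
                if parts != ["Nc", "log_g"]:
                    raise ConfigError(f"line {lineno}: expected column header 'Nc\\tlog_g'")
                saw_columns = True
                continue
            if len(parts) != 2:
                raise ConfigError(f"line {lineno}: expected two tab-separated fields, got {raw!r}")
            try:
                nc.append(int(parts[0]))
                log_g.append(float(parts[1]))
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: could not parse {raw!r}") from exc
        if header.get("schema") != _SCHEMA:
            raise ConfigError(f"unrecognized or missing schema header (need {_SCHEMA})")
        for key in ("n_monomers", "eps_bend", "slit_height", "provenance"):
            if key not in header:
                raise ConfigError(f"missing metadata key {key!r}")
        if not nc:
            raise ConfigError("table holds no (Nc, log_g) rows")
        hval = header["slit_height"]
        params = ModelParams(
            n_monomers=int(header["n_monomers"]),
            bend_rigidity=float(header["eps_bend"]),
            slit_height=None if hval in ("bulk", "inf") else int(hval),
        )
        meta = {
            k: v
            for k, v in header.items()
            if k
            not in (
                "schema",
                "n_monomers",
                "eps_bend",
                "slit_height",
                "provenance",
                "shift",
                "convention",
            )
        }
        return cls(
            params=params,
            nc=np.array(nc, dtype=np.int64),
            log_g=np.array(log_g, dtype=np.float64),
            provenance=header["provenance"],
            shift=header.get("shift", "raw"),
            convention=header.get("convention", CONVENTION),
            meta=meta,
        )

    @classmethod
    def read_tsv(cls, path) -> "DoSTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_tsv(fh.read())

    def checksum(self) -> str:
        """sha256 of the canonical TSV serialization (provenance tracking)."""
        return hashlib.sha256(self.to_tsv().encode("utf-8")).hexdigest()


def two_state_table(log_big: float, nc_max: int, n_monomers: int | None = None) -> DoSTable:
    """Analytic two-level toy: ``g(0) = exp(log_big)``, ``g(nc_max) = 1``.

    The crossover of this system is fully solvable — variance peak at
    ``eps* = log_big / nc_max`` with FWHM ``2 ln(3 + 2 sqrt(2)) / nc_max`` —
    which makes it the closed-form oracle for the transition-location code.
    """
    if nc_max < 1:
        raise ValueError("nc_max must be >= 1")
    params = ModelParams(n_monomers=n_monomers or (nc_max + 1))
    return DoSTable(
        params=params,
        nc=np.array([0, nc_max], dtype=np.int64),
        log_g=np.array([float(log_big), 0.0]),
        provenance="analytic",
        meta={"toy": "two-state"},
    )
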