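"""Net diversification rates from standing richness and crown ages.

The estimator is the constant-rate pure-birth (Yule) taxonomic likelihood
approximation: ``r = (ln N1 - ln N0) / t`` with ``N1`` the standing species
richness of a clade, ``N0`` the initial diversity (1 by default) and ``t``
its crown age in Ma.  Richness is supplied from taxonomy — it is never
counted from sampled tree tips, because real clades contain unsampled
species.  Rates from the lower/upper 95% HPD age bounds give the maximum /
minimum rate consistent with the dating uncertainty (younger age -> faster
rate).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd


class RateDomainError(ValueError):
    """Inputs outside the estimator's domain (t <= 0 or N1 < N0)."""


@dataclass(frozen=True)
class CladeRecord:
    """A named clade with standing richness and crown-age estimates (Ma)."""

    name: str
    n_species: int
    age_mean: float
    age_lower_hpd: Optional[float] = None
    age_upper_hpd: Optional[float] = None

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError(f"clade {self.name!r}: n_species must be >= 1")
        if not self.age_mean > 0:
            raise ValueError(f"clade {self.name!r}: age_mean must be > 0")
        lo, hi = self.age_lower_hpd, self.age_upper_hpd
        if (lo is None) != (hi is None):
            raise ValueError(f"clade {self.name!r}: provide both HPD bounds or neither")
        if lo is not None and not (0 < lo <= self.age_mean <= hi):
            raise ValueError(
                f"clade {self.name!r}: need 0 < lower HPD <= mean <= upper HPD, "
                f"got ({lo}, {self.age_mean}, {hi})"
            )

    @property
    def has_hpd(self) -> bool:
        return self.age_lower_hpd is not None


@dataclass(frozen=True)
class RateEstimate:
    """Per-clade net diversification rates (events / lineage / Ma).

    ``r_max`` comes from the younger (lower) HPD age bound and ``r_min``
    from the older (upper) bound, so ``r_max >= r_mean >= r_min``.
    """

    name: str
    r_mean: float
    r_max: Optional[float] = None
    r_min: Optional[float] = None


def net_rate(n1: int, t: float, n0: int = 1) -> float:
    """Net diversification rate ``(ln n1 - ln n0) / t`` in events/lineage/Ma.

    Parameters
    ----------
    n1 : int
        Standing species richness (>= n0).
    t : float
        Clade age in Ma (> 0).
    n0 : int, default 1
        Initial diversity.  The default follows the taxonomic-likelihood
        convention even for crown ages; pass ``n0=2`` for the strict crown
        convention (a crown group starts with two lineages).
    """
    if t <= 0:
        raise RateDomainError(f"age must be > 0, got {t}")
    if n0 < 1:
        raise RateDomainError(f"n0 must be >= 1, got {n0}")
    if n1 < n0:
        raise RateDomainError(f"n1 ({n1}) < n0 ({n0}): rate would be negative")
    return (math.log(n1) - math.log(n0)) / t


def rate_table(clades: Iterable[CladeRecord], n0: int = 1) -> list:
    """Per-clade rate estimates, in input order.

    ``r_mean`` uses the mean age; ``r_max``/``r_min`` use the lower/upper
    HPD ages and are absent when the record has no HPD bounds.  Domain
    errors are re-raised tagged with the clade name.
    """
    out = []
    for rec in clades:
        try:
            r_mean = net_rate(rec.n_species, rec.age_mean, n0)
            r_max = net_rate(rec.n_species, rec.age_lower_hpd, n0) if rec.has_hpd else None
            r_min = net_rate(rec.n_species, rec.age_upper_hpd, n0) if rec.has_hpd else None
        except RateDomainError as exc:
            raise RateDomainError(f"clade {rec.name!r}: {exc}") from exc
        out.append(RateEstimate(rec.name, r_mean, r_max, r_min))
    return out


def rate_dataframe(clades: Sequence[CladeRecord], n0: int = 1) -> pd.DataFrame:
    """Rates joined with their inputs, mirroring the published table layout."""
    ests = rate_table(clades, n0)
    return pd.DataFrame(
        {
            "clade": [c.name for c in clades],
            "n_species": [c.n_species for c in clades],
            "age_mean": [c.age_mean for c in clades],
            "age_lower_hpd": [c.age_lower_hpd for c in clades],
            "age_upper_hpd": [c.age_upper_hpd for c in clades],
            "r_mean": [e.r_mean for e in ests],
            "r_max": [e.r_max for e in ests],
            "r_min": [e.r_min for e in ests],
        }
    )


def read_clade_table(source: Union[str, Path, io.IOBase], sep: str = "\t") -> list:
    """Read clade records from delimited text.

    Required columns: ``clade`` (or ``name``), ``n_species``, ``age_mean``;
    optional: ``age_lower_hpd``, ``age_upper_hpd``.  Rows violating record
    invariants raise with their row number; nothing is silently skipped.
    """
    df = pd.read_csv(source, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    name_col = cols.get("clade") or cols.get("name")
    if name_col is None or "n_species" not in cols or "age_mean" not in cols:
        raise ValueError(
            "clade table needs columns: clade (or name), n_species, age_mean "
            f"[, age_lower_hpd, age_upper_hpd]; got {list(df.columns)}"
        )
    records, problems = [], []
    for i, row in df.iterrows():
        try:
            lo = row.get(cols.get("age_lower_hpd", ""), None)
            hi = row.get(cols.get("age_upper_hpd", ""), None)
            lo = None if pd.isna(lo) else float(lo)
            hi = None if pd.isna(hi) else float(hi)
            records.append(
                CladeRecord(
                    name=str(row[name_col]),
                    n_species=int(row[cols["n_species"]]),
                    age_mean=float(row[cols["age_mean"]]),
                    age_lower_hpd=lo,
                    age_upper_hpd=hi,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise ValueError("invalid clade table:\n" + "\n".join(problems))
    return records
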