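"""Model/Results objects tying the analysis together.

:class:`CladeDiversification` holds a clade table plus the analysis
settings; :meth:`~CladeDiversification.fit` computes per-clade net
diversification rates and exceptional-richness verdicts against the
background rate, returning a :class:`CladeDiversificationResults` that
carries the tables, the confidence bands and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .rates import CladeRecord, net_rate, rate_dataframe, read_clade_table
from .richness import (
    BDBackground,
    exceptionality_dataframe,
    figure_coordinates,
    test_exceptional,
)


class CladeDiversification:
    """Diversification analysis of a set of dated clades.

    Parameters
    ----------
    clades : sequence of CladeRecord
        Named clades with standing richness and crown ages (Ma).
    background : str or float
        Either the name of the clade whose mean-age rate defines the
        background diversification rate (that clade is then excluded from
        testing — it defines the null), or an explicit rate in
        events/lineage/Ma.
    epsilons : iterable of float, default (0.0, 0.9)
        Relative extinction fractions for the richness test: the pure-birth
        null and a high-extinction null.
    coverage : float, default 0.95
        Confidence band coverage.
    n0 : int, default 1
        Initial diversity for the rate estimator.
    """

    def __init__(
        self,
        clades: Sequence[CladeRecord],
        background: Union[str, float],
        epsilons: Iterable[float] = (0.0, 0.9),
        coverage: float = 0.95,
        n0: int = 1,
    ):
        self.clades = list(clades)
        if not self.clades:
            raise ValueError("no clades supplied")
        names = [c.name for c in self.clades]
        if len(set(names)) != len(names):
            raise ValueError("clade names must be unique")
        self.background = background
        self.epsilons = tuple(epsilons)
        self.coverage = coverage
        self.n0 = n0
        if isinstance(background, str) and background not in names:
            raise KeyError(
                f"background clade {background!r} not in table; available: {names}"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, background, **kwargs):
        """Build from a DataFrame with columns clade/n_species/age_mean
        [/age_lower_hpd/age_upper_hpd]."""
        records = []
        for _, row in df.iterrows():
            lo = row.get("age_lower_hpd")
            hi = row.get("age_upper_hpd")
            records.append(
                CladeRecord(
                    name=str(row["clade"] if "clade" in row else row["name"]),
                    n_species=int(row["n_species"]),
                    age_mean=float(row["age_mean"]),
                    age_lower_hpd=None if pd.isna(lo) else float(lo),
                    age_upper_hpd=None if pd.isna(hi) else float(hi),
                )
            )
        return cls(records, background, **kwargs)

    @classmethod
    def from_table(cls, path: Union[str, Path], background, sep: str = "\t", **kwargs):
        """Build from a delimited clade table on disk."""
        return cls(read_clade_table(path, sep=sep), background, **kwargs)

    # -- fitting ----------------------------------------------------------

    def background_rate(self) -> float:
        """The background net diversification rate (recomputed, not cached)."""
        if isinstance(self.background, str):
            rec = next(c for c in self.clades if c.name == self.background)
            return net_rate(rec.n_species, rec.age_mean, self.n0)
        return float(self.background)

    def fit(self) -> "CladeDiversificationResults":
        """Compute rates for every clade and richness verdicts for every
        non-background clade at every ε."""
        r_bg = self.background_rate()
        backgrounds = [BDBackground(r=r_bg, epsilon=e) for e in self.epsilons]
        testable = [
            c for c in self.clades
            if not (isinstance(self.background, str) and c.name == self.background)
        ]
        results = test_exceptional(testable, backgrounds, self.coverage)
        return CladeDiversificationResults(
            model=self,
            background_rate_=r_bg,
            rates_=rate_dataframe(self.clades, self.n0),
            exceptionality_results=results,
        )


@dataclass
class CladeDiversificationResults:
    """Fitted diversification analysis.

    Attributes
    ----------
    background_rate_ : float
        Net rate defining the null, in events/lineage/Ma.
    rates_ : DataFrame
        Per-clade r_mean/r_max/r_min joined with the inputs.
    exceptionality_results : list of ExceptionalityResult
        One verdict per testable clade per ε.
    """

    model: CladeDiversification
    background_rate_: float
    rates_: pd.DataFrame
    exceptionality_results: list

    @property
    def rates(self) -> pd.DataFrame:
        return self.rates_

    @property
    def exceptionality(self) -> pd.DataFrame:
        return exceptionality_dataframe(self.exceptionality_results)

    def verdicts(self, epsilon: float) -> dict:
        """Mapping clade -> verdict at one ε."""
        return {
            r.name: r.verdict
            for r in self.exceptionality_results
            if r.epsilon == epsilon
        }

    def figure_coordinates(self, n_grid: int = 200, t_min=None, t_max=None) -> pd.DataFrame:
        """Semi-log plot coordinates: observed clade points and per-ε
        confidence curves (long format: series, t, log10_value)."""
        testable = [
            c for c in self.model.clades
            if not (isinstance(self.model.background, str) and c.name == self.model.background)
        ]
        backgrounds = [
            BDBackground(r=self.background_rate_, epsilon=e) for e in self.model.epsilons
        ]
        return figure_coordinates(
            testable, backgrounds, self.model.coverage,
            n_grid=n_grid, t_min=t_min, t_max=t_max,
        )

    def summary(self, rounding: int = 3) -> str:
        """Printable report: rate table then verdict table."""
        lines = []
        lines.append("Clade diversification analysis")
        lines.append("=" * 70)
        lines.append(
            f"background rate r = {self.background_rate_:.{rounding + 2}f} "
            f"/lineage/Ma ({self._background_label()}), "
            f"epsilon = {list(self.model.epsilons)}, "
            f"coverage = {self.model.coverage:g}, N0 = {self.model.n0}"
        )
        lines.append("")
        lines.append("Net diversification rates (events/lineage/Ma)")
        rt = self.rates_.copy()
        for col in ("r_mean", "r_max", "r_min"):
            rt[col] = rt[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{rounding}f}"
            )
        lines.append(rt.to_string(index=False))
        lines.append("")
        lines.append("Exceptional richness test (strict 95% band)")
        lines.append(self.exceptionality.drop(columns="reason").to_string(index=False))
        return "\n".join(lines)

    def _background_label(self) -> str:
        if isinstance(self.model.background, str):
            return f"from clade {self.model.background!r}"
        return "user-specified"

    def to_files(self, outdir: Union[str, Path], n_grid: int = 200) -> dict:
        """Write rates, verdicts and plot coordinates as TSV; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rates": outdir / "rates.tsv",
            "exceptionality": outdir / "exceptionality.tsv",
            "figure_coordinates": outdir / "figure_coordinates.tsv",
        }
        self.rates_.to_csv(paths["rates"], sep="\t", index=False)
        self.exceptionality.to_csv(paths["exceptionality"], sep="\t", index=False)
        self.figure_coordinates(n_grid=n_grid).to_csv(
            paths["figure_coordinates"], sep="\t", index=False
        )
        return paths
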