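"""Packaged clade tables.

The New World *Hypericum* table ships the seven major clades of the genus
in the Americas — the whole-phylogeny background clade
(Triadenum+Myriandra+Brathys s.l.) and its nested subclades down to the
high-Andean Páramo clade — with standing species richness from taxonomy and
Bayesian relaxed-clock crown ages (mean and 95% HPD, Ma).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rates import CladeRecord, read_clade_table

HYPERICUM_BACKGROUND_CLADE = "Triadenum+Myriandra+Brathys s.l."
HYPERICUM_PARAMO_CLADE = "Páramo"


def load_new_world_hypericum(as_records: bool = False):
    """The seven-clade New World *Hypericum* table.

    Returns a DataFrame (columns: clade, n_species, age_mean,
    age_lower_hpd, age_upper_hpd) or, with ``as_records=True``, a list of
    :class:`~cladediv.rates.CladeRecord`.
    """
    path = resources.files("cladediv.data") / "new_world_hypericum_clades.tsv"
    with resources.as_file(path) as p:
        if as_records:
            return read_clade_table(p)
        return pd.read_csv(p, sep="\t")
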