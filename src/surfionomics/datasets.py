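"""Bundled reference tables of the five-pretreatment bagasse study.

Three small tables ship with the package:

* ``ion_particles`` — per-ion aggregate count, total area (µm²) and mean
  aggregate size (µm²) for the five pretreatments, from automated
  color-threshold particle analysis of the chemical images;
* ``li_free_oh`` — percent of -OH site area *free* of Li⁺ per pretreatment
  (the complement is the Li⁺-on-(-OH) coverage);
* ``ion_salt_activity`` — relative activities (%) of the cocktail enzymes
  under 10 mM ion salts in solution, no-ion control = 100%.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .curves import IonEffectTable, load_ion_effects

__all__ = [
    "load_ion_particle_table",
    "load_li_free_oh_table",
    "load_ion_salt_activity",
    "mean_size_consistency",
]


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("surfionomics.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kw)


def load_ion_particle_table() -> pd.DataFrame:
    """Tidy particle table: ion, treatment, count, area_um2, average_size_um2."""
    return _read("ion_particles.csv")


def load_li_free_oh_table() -> pd.DataFrame:
    """Per-treatment percent of -OH area free of Li⁺, with the coverage
    complement added as ``li_coverage_pct``."""
    df = _read("li_free_oh.csv")
    df["li_coverage_pct"] = 100.0 - df["li_free_oh_area_pct"]
    return df


def load_ion_salt_activity() -> IonEffectTable:
    """Salts × enzymes relative-activity table as an IonEffectTable."""
    return load_ion_effects(_read("ion_salt_activity.csv", index_col=0))


def mean_size_consistency(table: pd.DataFrame | None = None, decimals: int = 3) -> pd.DataFrame:
    """Recompute mean aggregate size as total area / count per table row.

    Adds ``recomputed_mean_um2`` (rounded to the table's printed precision)
    and a boolean ``consistent`` flag marking rows whose printed mean size
    equals the recomputed value.  Rows with zero count are consistent when
    the printed mean is zero.
    """
    df = (table if table is not None else load_ion_particle_table()).copy()
    rec = df["area_um2"] / df["count"].where(df["count"] > 0)
    rec = rec.fillna(0.0).round(decimals)
    df["recomputed_mean_um2"] = rec
    df["consistent"] = (rec - df["average_size_um2"]).abs() < 10.0 ** (-decimals) / 2
    return df
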