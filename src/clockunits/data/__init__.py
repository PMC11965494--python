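"""Packaged tables.

``table2_kd`` is the published table of simulated dissociation constants in
absolute units (copies/cell and nM, plus the ChIP-peak recalibrated column
and the PBM/EMA-derived estimates per target gene); it anchors the unit
conversions and their consistency checks.

``default_kinetics`` ships plausible, clearly NON-CANONICAL placeholder
translation/degradation rates per clock protein (the published per-gene
rate estimates are not redistributed here); analyses that need real rates
should supply their own table with the same columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..simple_model import ProteinKinetics


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("clockunits").joinpath("data").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def table2_kd() -> pd.DataFrame:
    """Simulated Kd table: (regulator, target, parameter, copies/cell, nM,
    nM per ChIP peak, protein, target gene, EMA estimate)."""
    return _read("table2_kd.csv")


def default_kinetics() -> dict[str, ProteinKinetics]:
    """Placeholder per-gene kinetics (non-canonical; see module docstring)."""
    out = {}
    for _, row in _read("kinetics_default.csv").iterrows():
        out[row["gene_id"]] = ProteinKinetics(
            gene_id=row["gene_id"], k_light=row["k_light_per_h"],
            k_dark=row["k_dark_per_h"],
            orf_length_codons=int(row["orf_length_codons"]))
    return out
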