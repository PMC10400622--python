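"""Dataset validation analytics: feature correlations, interface
waters, and per-record summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .structure import Residue, Structure

__all__ = [
    "FeatureCorrelationReport",
    "pearson_correlation",
    "interface_water_count",
    "summarize_dataset",
]


@dataclass
class FeatureCorrelationReport:
    feature_x: str
    feature_y: str
    pearson_r: float
    n_used: int


def pearson_correlation(
    x,
    y,
    feature_x: str = "x",
    feature_y: str = "y",
) -> FeatureCorrelationReport:
    """Product-moment correlation over complete (pairwise non-NaN)
    observations; fewer than two complete pairs is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise ValueError("correlation undefined: fewer than two complete pairs")
    r = float(stats.pearsonr(x[mask], y[mask]).statistic)
    return FeatureCorrelationReport(feature_x, feature_y, r, int(mask.sum()))


def interface_water_count(
    structure: Structure,
    interface_residues: list[Residue],
    radius: float = 10.0,
) -> int:
    """Water atoms within ``radius`` Å of any interface residue.

    The structure must still contain its waters (the count is taken
    before hetero/water stripping).  Distances are measured to the heavy
    atoms of the interface residues; each water atom is counted once and
    the boundary is inclusive.
    """
    water_coords = [
        a.coords
        for chain in structure.chains
        for res in chain.residues
        if res.is_water
        for a in res.atoms
    ]
    iface_coords = [a.coords for res in interface_residues for a in res.heavy_atoms()]
    if not water_coords or not iface_coords:
        return 0
    d = cdist(np.array(water_coords), np.array(iface_coords))
    return int((d.min(axis=1) <= radius).sum())


def summarize_dataset(records, out_path=None) -> pd.DataFrame:
    """Per-record residue/atom/label counts and feature NaN rates.

    Returns one row per pair record; written as TSV when ``out_path``
    is given.
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    for record in records:
        numeric_0 = record.table_0.select_dtypes(include=[np.number])
        numeric_1 = record.table_1.select_dtypes(include=[np.number])
        n_cells = numeric_0.size + numeric_1.size
        n_nan = int(numeric_0.isna().sum().sum() + numeric_1.isna().sum().sum())
        rows.append(
            {
                "name": record.name,
                "n_residues_0": len(record.table_0),
                "n_residues_1": len(record.table_1),
                "n_atoms": record.metadata.get("n_atoms", np.nan),
                "n_positives": len(record.positives),
                "n_negatives": len(record.negatives),
                "nan_rate": n_nan / n_cells if n_cells else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    if out_path is not None:
        summary.to_csv(out_path, sep="\t", index=False)
    return summary
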