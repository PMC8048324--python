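"""Panel-metabolite quantification by plain summation over ppm regions.

Integrals use the "sum all points in region" rule: the integral of a region
is the unweighted sum of the intensities of every spectral point whose ppm
falls inside the closed region.  No calibration to absolute concentrations
is attempted; integrals are relative (arbitrary units).

Each panel region declares the channel it is quantified on: lipid signals
come from the diffusion-edited-like spectrum, small metabolites from the
CPMG-like one.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import PanelRegion, validate_panel
from .spectra import Spectrum


class EmptyRegionError(ValueError):
    """A region containing no spectral points (distinct from a zero integral)."""


def integrate_region(spectrum: Spectrum, low: float, high: float) -> float:
    """Sum all intensities with ppm in the closed interval [low, high]."""
    if not low < high:
        raise ValueError(f"integration region requires low < high, got [{low}, {high}]")
    if not spectrum.covers(low, high):
        raise ValueError(
            f"region [{low}, {high}] outside spectrum range "
            f"[{spectrum.ppm.min():.3f}, {spectrum.ppm.max():.3f}]")
    sel = (spectrum.ppm >= low) & (spectrum.ppm <= high)
    if not sel.any():
        raise EmptyRegionError(f"no spectral points in region [{low}, {high}]")
    return float(spectrum.intensity[sel].sum())


def quantify_panel(
    spectra: Sequence[Spectrum],
    panel: Sequence[PanelRegion],
    region_half_width: float | None = None,
) -> pd.DataFrame:
    """Integrate every panel region for every sample.

    Samples are identified by ``(patient_id, timepoint)``; each needs one
    spectrum per channel used by the panel.  A sample missing a channel is
    kept but flagged incomplete (``complete == False``) with NaN integrals
    for the affected metabolites.

    Parameters
    ----------
    region_half_width
        Optional global override of each region's own half-width.

    Returns
    -------
    DataFrame indexed by sample id with one column per panel metabolite,
    plus ``patient_id``, ``timepoint`` and ``complete`` columns.
    """
    validate_panel(panel)
    by_sample: dict[tuple[str, str], dict[str, Spectrum]] = {}
    for s in spectra:
        by_sample.setdefault((s.patient_id, s.timepoint), {})[s.channel] = s

    rows = []
    for (patient_id, timepoint), channels in by_sample.items():
        row: dict[str, object] = {
            "sample_id": f"{patient_id}_{timepoint}",
            "patient_id": patient_id,
            "timepoint": timepoint,
            "complete": True,
        }
        for region in panel:
            spec = channels.get(region.channel)
            if spec is None:
                row[region.name] = np.nan
                row["complete"] = False
                continue
            hw = region_half_width if region_half_width is not None else region.half_width
            row[region.name] = integrate_region(
                spec, region.center_ppm - hw, region.center_ppm + hw)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return df


def write_metabolite_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)


def read_metabolite_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
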