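"""Metabolite panel: named ppm regions used for quantification.

The default panel is the serum metabolite set that discriminates pre- from
post-induction-chemotherapy samples in 400 MHz 1H CPMG/diffusion-edited
spectra: three lipid signals (CH3 ~0.9 ppm, CH2 ~1.3 ppm, CH=CH ~5.3 ppm,
quantified on the diffusion-edited channel), the alanine methyl doublet
(1.48 ppm), the composite N-acetyl-glycoprotein signal (NAG, 2.07 ppm) and
ten glucose regions (3.24-3.90 and 5.20 ppm), all quantified on the
CPMG-like channel.

The treatment-effect sign records the expected direction of change after
induction chemotherapy: +1 for the lipids (increase), -1 for alanine,
glucose and NAG (decrease).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .spectra import CHANNEL_CPMG, CHANNEL_DIFF

#: Water resonance window removed from all analyses, ppm (closed interval).
WATER_WINDOW = (4.38, 5.15)


@dataclass(frozen=True)
class PanelRegion:
    """A named quantification region.

    Attributes
    ----------
    name
        Metabolite/region label, e.g. ``"lipid_1.3"``.
    center_ppm
        Region center in ppm; must lie in [0.5, 9.0].
    half_width
        Half-width of the integration region in ppm (> 0).
    multiplicity
        Number of resolved lines the signal is modelled with (1 = singlet,
        2 = doublet, ...); used by the synthetic generator.
    effect_sign
        Expected post-vs-pre direction: +1 increase, -1 decrease, 0 none.
    channel
        Spectrum channel the region is quantified on (``cpmg``/``diff``).
    """

    name: str
    center_ppm: float
    half_width: float
    multiplicity: int = 1
    effect_sign: int = 0
    channel: str = CHANNEL_CPMG

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError(f"{self.name}: half_width must be > 0")
        if not 0.5 <= self.center_ppm <= 9.0:
            raise ValueError(f"{self.name}: center_ppm must be within [0.5, 9.0]")
        if self.effect_sign not in (-1, 0, 1):
            raise ValueError(f"{self.name}: effect_sign must be -1, 0 or +1")
        if self.multiplicity < 1:
            raise ValueError(f"{self.name}: multiplicity must be >= 1")

    @property
    def low(self) -> float:
        return self.center_ppm - self.half_width

    @property
    def high(self) -> float:
        return self.center_ppm + self.half_width


def validate_panel(panel: Sequence[PanelRegion],
                   water_window: tuple[float, float] = WATER_WINDOW) -> None:
    """Reject panels whose integration regions overlap the water window."""
    lo, hi = water_window
    for region in panel:
        if region.low <= hi and region.high >= lo:
            raise ValueError(
                f"panel region {region.name} [{region.low:.3f}, {region.high:.3f}] "
                f"overlaps the water window [{lo}, {hi}]"
            )


_GLUCOSE_PPM = (3.24, 3.42, 3.44, 3.51, 3.56, 3.72, 3.76, 3.83, 3.90, 5.20)

#: Default discriminating-metabolite panel.
DEFAULT_PANEL: tuple[PanelRegion, ...] = (
    PanelRegion("lipid_0.9", 0.90, 0.05, 1, +1, CHANNEL_DIFF),
    PanelRegion("lipid_1.3", 1.30, 0.05, 1, +1, CHANNEL_DIFF),
    PanelRegion("lipid_5.3", 5.30, 0.05, 1, +1, CHANNEL_DIFF),
    PanelRegion("alanine_1.48", 1.48, 0.012, 2, -1, CHANNEL_CPMG),
    PanelRegion("NAG_2.07", 2.07, 0.010, 1, -1, CHANNEL_CPMG),
) + tuple(
    PanelRegion(f"glucose_{ppm:.2f}", ppm, 0.010, 1, -1, CHANNEL_CPMG)
    for ppm in _GLUCOSE_PPM
)

validate_panel(DEFAULT_PANEL)

#: Maps panel region name -> underlying metabolite (concentration) key.
REGION_METABOLITE = {
    "lipid_0.9": "lipid_09",
    "lipid_1.3": "lipid_13",
    "lipid_5.3": "lipid_53",
    "alanine_1.48": "alanine",
    "NAG_2.07": "nag",
    **{f"glucose_{ppm:.2f}": "glucose" for ppm in _GLUCOSE_PPM},
}


def save_panel(panel: Iterable[PanelRegion], path: str | Path) -> None:
    """Write a panel to YAML (``.yml``/``.yaml``) or CSV (anything else)."""
    path = Path(path)
    rows = [asdict(r) for r in panel]
    if path.suffix.lower() in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump({"panel": rows}, sort_keys=False))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)


def load_panel(path: str | Path) -> tuple[PanelRegion, ...]:
    """Load a panel from YAML or CSV written by :func:`save_panel`."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        rows = yaml.safe_load(path.read_text())["panel"]
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    regions = tuple(
        PanelRegion(
            name=row["name"],
            center_ppm=float(row["center_ppm"]),
            half_width=float(row["half_width"]),
            multiplicity=int(row["multiplicity"]),
            effect_sign=int(row["effect_sign"]),
            channel=row["channel"],
        )
        for row in rows
    )
    validate_panel(regions)
    return regions
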