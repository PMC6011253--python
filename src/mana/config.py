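"""Pipeline configuration.

Every tunable of the segmentation pipeline lives here, each tagged with its
provenance: ``paper`` for constants stated by the published method (polynomial
order 15, the 25% small cutoff, the 5x big cutoff), ``implementation`` for
values the method leaves open and this package chooses (watershed seed
sensitivity, connectivity, tie-breaks).  The tags make it auditable which
numbers are part of the method and which are engineering choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any

import yaml

#: provenance of each config key: "paper" = stated by the published method,
#: "implementation" = chosen by this package where the method is silent.
PROVENANCE: dict[str, str] = {
    "poly_order": "paper",
    "small_factor": "paper",
    "big_factor": "paper",
    "solidity_cutoff": "implementation",
    "h_fraction_low": "implementation",
    "h_fraction_high": "implementation",
    "connectivity": "implementation",
    "threshold_comparison": "implementation",
    "tp_convention": "implementation",
    "match_tolerance_px": "implementation",
    "split_step": "implementation",
    "seed": "implementation",
}


@dataclass
class PipelineConfig:
    """Knobs of the nuclei-segmentation pipeline.

    Parameters
    ----------
    poly_order:
        Order of the polynomial fitted to the progressive-weighted-mean curve.
    small_factor:
        Objects with area below ``small_factor * mean_area`` are deleted.
    big_factor:
        Objects with area above ``big_factor * mean_area`` are split.
    solidity_cutoff:
        Objects with solidity at or above this value get the low-sensitivity
        seeding (one expects a single convex nucleus); below it, the
        high-sensitivity seeding (likely fused nuclei).
    h_fraction_low, h_fraction_high:
        Suppression depth of the extended-maxima transform, as a fraction of
        the object's maximum distance-transform value: ``h_fraction_low`` for
        high-solidity objects (few seeds), ``h_fraction_high`` for
        low-solidity objects (more seeds).
    connectivity:
        Pixel connectivity for components, 4 or 8.
    threshold_comparison:
        "le" segments pixels with value <= t as foreground; "lt" uses <.
    tp_convention:
        "per_center": every annotated center inside a detected region counts
        as a true positive (under-segmentation does not reduce F1).
        "per_region": a region contributes at most one true positive.
    match_tolerance_px:
        Radius within which a center just outside every region may still be
        matched to the nearest region (0 = strict point-in-region).
    split_step:
        Gray levels subtracted per iteration when splitting big objects.
    """

    poly_order: int = 15
    small_factor: float = 0.25
    big_factor: float = 5.0
    solidity_cutoff: float = 0.95
    h_fraction_low: float = 0.30
    h_fraction_high: float = 0.15
    connectivity: int = 8
    threshold_comparison: str = "le"
    tp_convention: str = "per_center"
    match_tolerance_px: float = 0.0
    split_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.small_factor < 1.0 < self.big_factor):
            raise ValueError(
                "require 0 < small_factor < 1 < big_factor, got "
                f"{self.small_factor}, {self.big_factor}"
            )
        if self.poly_order < 2:
            raise ValueError(f"poly_order must be >= 2, got {self.poly_order}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.threshold_comparison not in ("le", "lt"):
            raise ValueError("threshold_comparison must be 'le' or 'lt'")
        if self.tp_convention not in ("per_center", "per_region"):
            raise ValueError("tp_convention must be 'per_center' or 'per_region'")
        if self.split_step < 1:
            raise ValueError("split_step must be >= 1")

    @property
    def skimage_connectivity(self) -> int:
        """Connectivity in scikit-image convention (1 = 4-conn, 2 = 8-conn)."""
        return 2 if self.connectivity == 8 else 1

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self, path: str) -> None:
        """Write the config as YAML, one ``value``/``provenance`` pair per key."""
        doc = {
            name: {"value": value, "provenance": PROVENANCE.get(name, "implementation")}
            for name, value in self.to_dict().items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        """Load a config written by :meth:`to_yaml` or a plain key: value map."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for key, entry in doc.items():
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = entry["value"] if isinstance(entry, dict) else entry
        return cls(**kwargs)
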