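"""Pipeline configuration.

All tunable parameters of the detection pipeline live in
:class:`PipelineConfig`.  The defaults are the shipped operating point for
2-Mpx inflorescence photographs taken against dark cardboard; every field
can be overridden through a flat key-value config file (YAML mapping of
scalars) or CLI flags.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the flower-detection pipeline.

    Parameters
    ----------
    target_megapixels:
        Images larger than this are downscaled (area-preserving) before
        analysis; smaller images pass through untouched.
    connectivity:
        Pixel adjacency (4 or 8) used both for regional-maxima plateaus
        and for foreground connected components.
    background_lightness_threshold:
        Fixed L* threshold separating dark background from inflorescence.
        ``None`` selects an automatic bimodal-histogram (Otsu) threshold.
    background_chroma_ceiling:
        Pixels are only classed as background if their CIE chroma
        sqrt(a*^2 + b*^2) is at or below this ceiling; the dark cardboard
        is achromatic, flowers are not reliably so.
    min_foreground_fraction:
        Minimum fraction of image area a foreground speck must reach to
        survive ROI cleanup (0.0001 = 0.01% of pixels).
    size_filter_k:
        Multiplier on the median absolute deviation in the robust upper
        size fence ``median + k * MAD``.
    elongation_threshold:
        Candidates whose moment-ellipse axis ratio (major/minor) exceeds
        this are discarded as elongated glints, not flowers.
    min_candidate_area:
        Regional-maxima plateaus smaller than this many pixels are
        dropped before filtering; 1 keeps everything.
    h_maxima:
        Optional shallow-peak suppression depth (in L* units) applied
        before connected-component analysis; 0 disables it.
    """

    target_megapixels: float = 2.0
    connectivity: int = 8
    background_lightness_threshold: float | None = None
    background_chroma_ceiling: float = 15.0
    min_foreground_fraction: float = 0.0001
    size_filter_k: float = 3.0
    elongation_threshold: float = 2.0
    min_candidate_area: int = 1
    h_maxima: float = 0.0

    def __post_init__(self) -> None:
        if self.target_megapixels <= 0:
            raise ValueError("target_megapixels must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.elongation_threshold < 1:
            raise ValueError("elongation_threshold must be >= 1")
        if self.size_filter_k <= 0:
            raise ValueError("size_filter_k must be > 0")
        if self.min_candidate_area < 1:
            raise ValueError("min_candidate_area must be >= 1")
        if self.h_maxima < 0:
            raise ValueError("h_maxima must be >= 0")

    def replace(self, **changes: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Build a config from an optional flat YAML file plus overrides.

    Unknown keys in the file raise ``ValueError`` so typos do not pass
    silently; ``None``-valued overrides are ignored (convenient for CLI
    flags that were not given).
    """
    values: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
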