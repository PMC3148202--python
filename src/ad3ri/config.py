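"""Pipeline configuration: every tunable of the processing chain.

Defaults are the method's operating point: 5 illumination-refinement
iterations, 250 µm contrast window, 51 darkest windows, reference RMS
contrast 15, background grey 85, merge threshold 3, sectioning margin 10%,
quantification threshold 18%, baseline threshold 30%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field


@dataclass
class PipelineConfig:
    # illumination
    p: float | None = None  # None: derived from resolution
    iterations: int = 5
    decimation: int = 4
    # contrast
    window_um: float = 250.0
    n_windows: int = 51
    rmsc_reference: float = 15.0
    background: float = 85.0
    contrast_window: tuple[int, int] | None = None  # manual relocation
    # segmentation
    delta_a: float = 3.0
    # modelling
    margin_frac: float = 0.10
    min_component_px: int = 4
    sigma_min: float = 0.5
    s_f_range: tuple[float, float] = (0.2, 5.0)
    d_range: tuple[float, float] = (0.3, 3.0)
    max_iterations: int = 200
    free_baseline: bool = False
    # quantification
    threshold_frac: float = 0.18
    baseline_threshold_frac: float = 0.30
    # geometry
    roi_diameter_um: float = 3000.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        obj = json.loads(text)
        cfg = cls(**obj)
        if cfg.contrast_window is not None:
            cfg.contrast_window = tuple(cfg.contrast_window)
        cfg.s_f_range = tuple(cfg.s_f_range)
        cfg.d_range = tuple(cfg.d_range)
        return cfg
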