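"""Bundled reference tables from a published inter-grader drusen study.

Two small tables accompany the package for validating the agreement
statistics: per-image total drusen areas (mm², macular ROI) measured by eight
expert graders — four ophthalmologists (OP1-OP4) and four trained technicians
(TE1-TE4) — and by the automated method on 22 fundus photographs, and the
per-grader summary indicators (CV, ICC, sensitivity, specificity, kappa) of
the same study.  No image data is bundled; these are area measurements only.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_expert_areas", "load_grader_summary", "EXPERT_COLUMNS"]

EXPERT_COLUMNS = ["OP1", "OP2", "OP3", "OP4", "TE1", "TE2", "TE3", "TE4"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ad3ri.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_expert_areas() -> pd.DataFrame:
    """Per-image drusen areas (mm²): 22 images x 8 experts + automated method."""
    return _read("expert_areas.csv").set_index("image")


def load_grader_summary() -> pd.DataFrame:
    """Per-grader summary agreement indicators against the consensus truth."""
    return _read("grader_summary.csv").set_index("grader")
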