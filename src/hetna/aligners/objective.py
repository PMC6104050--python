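"""Configuration of the alpha-blended alignment objective."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

from ..conservation import DEFAULT_WEIGHTS

__all__ = ["ObjectiveConfig"]


@dataclass(frozen=True)
class ObjectiveConfig:
    """alpha * NC + (1 - alpha) * EC.

    NC is the mean similarity of aligned pairs; EC is homogeneous or
    heterogeneous S3 (``ec_measure`` in {"homs3", "hets3"}); ``weights``
    are the conservation weights for (2, 1, 0) endpoint color matches.
    """

    alpha: float = 0.5
    ec_measure: str = "hets3"
    weights: Tuple = DEFAULT_WEIGHTS

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.ec_measure not in ("homs3", "hets3"):
            raise ValueError(f"unknown ec_measure {self.ec_measure!r}")
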