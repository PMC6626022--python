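"""Imaging-modality detection from pixel-intensity skewness.

Brightfield frames of the mother machine are mostly bright with sparse
dark structures (walls, cells), so their intensity histogram is skewed
left (negative skewness).  Phase-contrast frames invert that contrast and
skew right.  With megapixel frames the sample size is large enough that
the uncorrected sample skewness

    G1 = m3 / m2^(3/2)

(m2, m3 the second and third central moments of the flattened pixel
values) needs no small-sample bias correction, and its sign alone decides
the modality: positive -> phase contrast, negative -> brightfield.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List

import numpy as np

logger = logging.getLogger(__name__)


class Modality(str, enum.Enum):
    BRIGHTFIELD = "brightfield"
    PHASE = "phase"


class UndefinedSkewnessError(ValueError):
    """Raised for a constant image, whose skewness is undefined (m2 = 0)."""


@dataclass(frozen=True)
class SkewnessReport:
    """Skewness of one frame's intensity distribution and the verdict."""

    g1: float
    m2: float
    m3: float
    n_pixels: int
    modality: Modality


def compute_skewness(image: np.ndarray) -> SkewnessReport:
    """Uncorrected sample skewness G1 of the flattened pixel values.

    Raises
    ------
    UndefinedSkewnessError
        If the image is constant (second central moment is zero).
    """
    values = np.asarray(image, dtype=np.float64).ravel()
    n = values.size
    if n == 0:
        raise UndefinedSkewnessError("empty image has no skewness")
    centred = values - values.mean()
    m2 = float(np.mean(centred**2))
    m3 = float(np.mean(centred**3))
    if m2 == 0.0:
        raise UndefinedSkewnessError("constant image: skewness undefined (m2 = 0)")
    g1 = m3 / m2**1.5
    modality = Modality.PHASE if g1 > 0 else Modality.BRIGHTFIELD
    return SkewnessReport(g1=g1, m2=m2, m3=m3, n_pixels=n, modality=modality)


def classify_modality(image: np.ndarray) -> Modality:
    """Phase contrast iff G1 > 0; brightfield otherwise (G1 = 0 ties break
    to brightfield, since only the positive branch indicates phase)."""
    return compute_skewness(image).modality


def vote_modality(per_frame: Iterable[Modality]) -> Modality:
    """Majority vote over per-frame decisions within one imaging area.

    One acquisition has one modality; a majority vote protects against
    outlier frames.  Disagreement is logged.  Ties break to brightfield.
    """
    decisions: List[Modality] = list(per_frame)
    if not decisions:
        raise ValueError("no per-frame modality decisions to vote over")
    counts = Counter(decisions)
    if len(counts) > 1:
        logger.warning(
            "per-frame modality decisions disagree (%s); using majority vote",
            dict(counts),
        )
    phase, bright = counts[Modality.PHASE], counts[Modality.BRIGHTFIELD]
    return Modality.PHASE if phase > bright else Modality.BRIGHTFIELD
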