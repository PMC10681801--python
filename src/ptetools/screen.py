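"""Candidate-PTE screens.

Two screens are implemented:

* The *reference-locus screen* finds regions that resemble a known strong
  PRC1 tethering element (the CCND2-type profile): strong MEL18 signal in
  the discovery cell line, a MEL18/SUZ12 signal ratio exceeding that of the
  reference locus, and strong MEL18 *and* SUZ12 binding in a second cell
  line.  Scores are summit-window sums on depth-normalized tracks; because
  the summit window is 1000 bp, the window sum already is the per-kb
  (RPKM-like) value, which keeps thresholds portable.

* The *high-confidence* rule keeps consensus peaks from the upper score
  quartiles (Q4/Q3 by default) whose position accuracy is better than
  +-301 bp (encoded as accuracy <= 300).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ScreenParams", "ccnd2_like_screen", "high_confidence_ptes"]


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds for the reference-locus screen and the high-confidence rule.

    Defaults are the thresholds appropriate for SPMR-normalized human
    ChIP-seq (summit-window RPKM); for other signal scales build parameters
    with :meth:`from_reference`.
    """

    mel18_min_rpkm: float = 3_000.0
    reference_ratio: float = 1.0  # MEL18/SUZ12 at the reference locus
    second_line_min_rpkm: float = 2_000.0
    hc_quartiles: tuple[str, ...] = ("Q4", "Q3")
    hc_max_accuracy: float = 300.0

    def __post_init__(self) -> None:
        if self.mel18_min_rpkm <= 0 or self.second_line_min_rpkm <= 0:
            raise ValueError("thresholds must be positive")
        if self.reference_ratio <= 0:
            raise ValueError("reference_ratio must be positive")
        if self.hc_max_accuracy < 0:
            raise ValueError("hc_max_accuracy must be >= 0")

    @classmethod
    def from_reference(
        cls,
        ref_mel18: float,
        ref_suz12: float,
        ref_mel18_second: float,
        ref_suz12_second: float,
        mel18_fraction: float = 0.5,
        second_fraction: float = 0.5,
        **kwargs,
    ) -> "ScreenParams":
        """Derive thresholds from the scores at a named reference locus.

        The MEL18 minimum is ``mel18_fraction`` of the reference MEL18
        score ("comparable to the reference"), the second-line minimum is
        ``second_fraction`` of the weaker of the reference's second-line
        scores, and the ratio criterion uses the reference's MEL18/SUZ12
        ratio itself.
        """
        return cls(
            mel18_min_rpkm=mel18_fraction * ref_mel18,
            reference_ratio=ref_mel18 / ref_suz12 if ref_suz12 > 0 else np.inf,
            second_line_min_rpkm=second_fraction
            * min(ref_mel18_second, ref_suz12_second),
            **kwargs,
        )


REQUIRED_SCREEN_COLUMNS = ["mel18", "suz12", "mel18_second", "suz12_second"]


def ccnd2_like_screen(
    scores: pd.DataFrame, params: ScreenParams
) -> pd.DataFrame:
    """Apply the three-criterion reference-locus screen to scored regions.

    ``scores`` must contain columns ``mel18``, ``suz12`` (discovery cell
    line) and ``mel18_second``, ``suz12_second`` (second cell line), all
    summit-window sums in the same units as the thresholds.  Returns a copy
    with per-criterion booleans (``pass_signal``, ``pass_ratio``,
    ``pass_second_line``) and the final ``pass_screen``.  A SUZ12 score of
    zero makes the ratio +inf, which passes the ratio criterion.
    """
    missing = set(REQUIRED_SCREEN_COLUMNS) - set(scores.columns)
    if missing:
        raise ValueError(f"missing score columns: {sorted(missing)}")
    out = scores.copy()
    with np.errstate(divide="ignore"):
        ratio = np.where(
            out["suz12"].to_numpy() > 0,
            out["mel18"].to_numpy() / np.maximum(out["suz12"].to_numpy(), 1e-300),
            np.inf,
        )
    out["mel18_suz12_ratio"] = ratio
    out["pass_signal"] = out["mel18"] > params.mel18_min_rpkm
    out["pass_ratio"] = ratio > params.reference_ratio
    out["pass_second_line"] = (
        out["mel18_second"] > params.second_line_min_rpkm
    ) & (out["suz12_second"] > params.second_line_min_rpkm)
    out["pass_screen"] = (
        out["pass_signal"] & out["pass_ratio"] & out["pass_second_line"]
    )
    return out


def high_confidence_ptes(
    peaks: pd.DataFrame, params: ScreenParams = ScreenParams()
) -> pd.DataFrame:
    """Flag consensus peaks that qualify as high-confidence PTEs.

    Requires columns ``quartile`` and ``accuracy``.  A peak qualifies when
    its quartile is in ``hc_quartiles`` and its accuracy is strictly better
    than +-(hc_max_accuracy + 1), i.e. ``accuracy <= hc_max_accuracy``.
    """
    for col in ("quartile", "accuracy"):
        if col not in peaks.columns:
            raise ValueError(f"missing column {col!r}")
    out = peaks.copy()
    out["high_confidence"] = out["quartile"].isin(params.hc_quartiles) & (
        out["accuracy"] <= params.hc_max_accuracy
    )
    return out
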