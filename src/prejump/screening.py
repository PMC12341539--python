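"""Expert-panel screening of candidate indicators.

Candidate influencing factors are rated by an expert panel on a 5-point
importance scale.  An item enters the preliminary indicator set when its
mean rating is strictly above a threshold (3.5 by convention) and, under
the default consensus rule, the across-rater standard deviation does not
exceed a cap (1.0) — a Delphi-style agreement criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientPanelError, InvalidSpecificationError

__all__ = ["ScreeningPanel", "screen_items"]

VALID_SCORES = frozenset({1, 2, 3, 4, 5})


@dataclass
class ScreeningPanel:
    """Raters × items table of integer importance scores in {1, …, 5}."""

    scores: pd.DataFrame  # rows = raters, columns = items
    mean_threshold: float = 3.5
    consensus_rule: str = "sd_max"  # or "none"
    sd_max: float = 1.0

    def __post_init__(self) -> None:
        if len(self.scores) < 2:
            raise InsufficientPanelError(
                f"screening needs at least 2 raters, got {len(self.scores)}"
            )
        if self.consensus_rule not in {"sd_max", "none"}:
            raise InvalidSpecificationError(
                f"unknown consensus rule {self.consensus_rule!r}"
            )
        if self.sd_max <= 0:
            raise InvalidSpecificationError("sd_max must be positive")
        vals = self.scores.to_numpy()
        ok = np.isin(vals, list(VALID_SCORES))
        if not ok.all():
            bad = sorted(set(np.asarray(vals)[~ok].ravel().tolist()))
            raise InvalidSpecificationError(
                f"scores must be integers in 1..5, found {bad}"
            )

    @property
    def item_names(self) -> list[str]:
        return list(self.scores.columns)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ScreeningPanel":
        """Read a panel CSV whose first column is the rater id."""
        frame = pd.read_csv(path, index_col=0)
        return cls(scores=frame, **kwargs)


def screen_items(panel: ScreeningPanel) -> pd.DataFrame:
    """Score every item and flag the retained ones.

    Returns a DataFrame in the panel's item order with columns
    ``item``, ``mean``, ``sd`` (n−1 divisor) and ``retained``.  An item is
    retained iff its mean is strictly greater than ``mean_threshold`` and,
    under the ``sd_max`` consensus rule, its SD is at most ``sd_max``.
    """
    means = panel.scores.mean(axis=0)
    sds = panel.scores.std(axis=0, ddof=1)
    retained = means > panel.mean_threshold
    if panel.consensus_rule == "sd_max":
        retained &= sds <= panel.sd_max
    return pd.DataFrame(
        {
            "item": panel.item_names,
            "mean": means.to_numpy(),
            "sd": sds.to_numpy(),
            "retained": retained.to_numpy(),
        }
    )
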