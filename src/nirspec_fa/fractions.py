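"""Arithmetic between lipid fractions.

Gas-chromatography reference work quantifies each fatty acid twice: in the
phospholipid (membrane) fraction and in the total extract.  The neutral
(storage) lipid value is not measured directly; it is the difference
``total - phospholipid``.  The phospholipid share of an analyte,
``phospholipid / total * 100``, summarises how membrane-bound that fatty
acid is: long-chain PUFA sit almost entirely in the phospholipid fraction
while storage-fat acids (e.g. oleic acid) do not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FractionPair:
    """Phospholipid and total concentration of one analyte, mg/100 g meat.

    ``phospholipid <= total`` is expected; violations (possible under
    measurement noise, since the two fractions are assayed separately) are
    logged rather than rejected.
    """

    phospholipid: float
    total: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.phospholipid) and math.isfinite(self.total)):
            raise ValueError("fraction values must be finite")
        if self.phospholipid < 0 or self.total < 0:
            raise ValueError("fraction values must be non-negative")
        if self.phospholipid > self.total:
            logger.warning(
                "phospholipid %.4g exceeds total %.4g (measurement noise?)",
                self.phospholipid, self.total,
            )


def neutral_from_total(pair: FractionPair) -> float:
    """Neutral-lipid concentration by difference, clipped at zero.

    A negative difference (phospholipid assayed above total) is clipped to 0
    with a warning.
    """
    diff = pair.total - pair.phospholipid
    if diff < 0:
        logger.warning("negative neutral fraction %.4g clipped to 0", diff)
        return 0.0
    return diff


def fraction_share(pair: FractionPair) -> float | None:
    """Phospholipid share of the total, in percent.

    Returns None when total is 0 (undefined share).
    """
    if pair.total == 0:
        logger.warning("fraction share undefined for zero total")
        return None
    return pair.phospholipid / pair.total * 100.0


def neutral_share(pair: FractionPair) -> float | None:
    """Neutral-lipid share of the total, in percent (complement of the
    phospholipid share when no clipping occurred)."""
    if pair.total == 0:
        return None
    return neutral_from_total(pair) / pair.total * 100.0
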