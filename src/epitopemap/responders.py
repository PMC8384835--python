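"""Responder calling from intracellular-cytokine-staining cell counts.

For every donor x stimulus x marker combination the assay yields a count of
cytokine-positive CD4+ cells out of a total CD4+ count, plus one
unstimulated (vehicle) control per donor and marker.  A response is called
with a one-sided Fisher exact test (stimulated positive fraction greater
than unstimulated), and p-values are Holm-Bonferroni adjusted within each
donor's family of stimulus x marker tests.  A donor is positive for a
stimulus if any of the measured cytokines is called (worst-case rule).
"""

from __future__ import annotations

import logging
import math
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Stimulus label of the unstimulated (vehicle) control rows.
UNSTIMULATED = "unstimulated"
#: Stimulus label of the superantigen positive control.
SEB = "SEB"

_POOL_RE = re.compile(r"^pool[_ ]?(\d+)$", re.IGNORECASE)


def pool_stimulus(pool_id: int) -> str:
    """Canonical stimulus label for peptide pool ``pool_id``."""
    return f"pool_{pool_id}"


def is_pool(stimulus: str) -> bool:
    """True for peptide-pool stimuli (as opposed to proteins and controls)."""
    return _POOL_RE.match(stimulus) is not None


class CountError(ValueError):
    """Raised on invalid cell counts."""


class MissingControlError(ValueError):
    """Raised when a donor/marker lacks its unstimulated control row."""


@dataclass(frozen=True)
class StimulationRecord:
    """Gated cell counts for one donor x stimulus x marker sample."""

    donor_id: str
    stimulus: str
    marker: str
    positive_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise CountError(
                f"{self.donor_id}/{self.stimulus}/{self.marker}: total count must be positive"
            )
        if not (0 <= self.positive_count <= self.total_count):
            raise CountError(
                f"{self.donor_id}/{self.stimulus}/{self.marker}: positive count "
                f"{self.positive_count} outside 0..{self.total_count}"
            )


@dataclass(frozen=True)
class ResponderCall:
    """Fisher/Holm test outcome for one donor x stimulus x marker."""

    donor_id: str
    stimulus: str
    marker: str
    raw_p: float
    adjusted_p: float
    positive: bool


def fisher_one_sided(
    stim_pos: int, stim_total: int, unstim_pos: int, unstim_total: int
) -> float:
    """One-sided Fisher exact p for enrichment of positives under stimulation.

    Tests, on the 2x2 table ``[[stim_pos, stim_total-stim_pos],
    [unstim_pos, unstim_total-unstim_pos]]``, the alternative that the
    stimulated positive fraction exceeds the unstimulated one.  Computed as
    the hypergeometric upper tail P(X >= stim_pos) conditioned on both
    margins; impossible enrichment yields p = 1, never an error.
    """
    if stim_total <= 0 or unstim_total <= 0:
        raise CountError("zero or negative total cell count")
    if not (0 <= stim_pos <= stim_total and 0 <= unstim_pos <= unstim_total):
        raise CountError("positive counts outside their totals")
    return float(
        hypergeom.sf(
            stim_pos - 1,
            stim_total + unstim_total,
            stim_pos + unstim_pos,
            stim_total,
        )
    )


def _fisher_one_sided_vec(
    stim_pos: np.ndarray,
    stim_total: np.ndarray,
    unstim_pos: np.ndarray,
    unstim_total: np.ndarray,
) -> np.ndarray:
    return hypergeom.sf(
        stim_pos - 1, stim_total + unstim_total, stim_pos + unstim_pos, stim_total
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    The i-th smallest p is multiplied by (m - i + 1), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    ps = list(p_values)
    if not ps:
        return []
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="holm")[1])


def call_responders(
    records: Sequence[StimulationRecord], alpha: float = 0.05
) -> list[ResponderCall]:
    """Call positive responses for every stimulated record.

    Each stimulated row is tested against its donor's unstimulated control
    for the same marker; Holm adjustment is applied within the family of all
    stimulus x marker tests of that donor (pools, proteins and controls
    alike).  A call is positive iff the adjusted p is below ``alpha``.
    """
    controls: dict[tuple[str, str], StimulationRecord] = {}
    for r in records:
        if r.stimulus == UNSTIMULATED:
            key = (r.donor_id, r.marker)
            if key in controls:
                raise MissingControlError(
                    f"duplicate unstimulated control for donor {r.donor_id!r}, "
                    f"marker {r.marker!r}"
                )
            controls[key] = r
    by_donor: dict[str, list[StimulationRecord]] = defaultdict(list)
    for r in records:
        if r.stimulus != UNSTIMULATED:
            by_donor[r.donor_id].append(r)

    calls: list[ResponderCall] = []
    for donor_id, tests in by_donor.items():
        for r in tests:
            if (donor_id, r.marker) not in controls:
                raise MissingControlError(
                    f"no unstimulated control for donor {donor_id!r}, marker {r.marker!r}"
                )
        ctrl = [controls[(donor_id, r.marker)] for r in tests]
        raw = _fisher_one_sided_vec(
            np.array([r.positive_count for r in tests]),
            np.array([r.total_count for r in tests]),
            np.array([c.positive_count for c in ctrl]),
            np.array([c.total_count for c in ctrl]),
        )
        adjusted = holm_adjust(raw.tolist())
        for r, p, q in zip(tests, raw, adjusted):
            calls.append(
                ResponderCall(donor_id, r.stimulus, r.marker, float(p), float(q), q < alpha)
            )
    return calls


def donor_positive(calls: Iterable[ResponderCall]) -> bool:
    """Worst-case rule: a donor responds to a stimulus if any marker is positive."""
    return any(c.positive for c in calls)


def positive_stimuli(
    calls: Iterable[ResponderCall], pools_only: bool = False
) -> dict[str, set[str]]:
    """Map each donor to the set of stimuli it responds to (OR over markers)."""
    out: dict[str, set[str]] = defaultdict(set)
    donors: set[str] = set()
    for c in calls:
        donors.add(c.donor_id)
        if c.positive and (not pools_only or is_pool(c.stimulus)):
            out[c.donor_id].add(c.stimulus)
    return {d: out.get(d, set()) for d in donors}


def percent_responders(calls: Iterable[ResponderCall], stimulus: str) -> float:
    """Percent of donors positive (any marker) for ``stimulus``."""
    per_donor: dict[str, bool] = {}
    for c in calls:
        if c.stimulus == stimulus:
            per_donor[c.donor_id] = per_donor.get(c.donor_id, False) or c.positive
    if not per_donor:
        raise ValueError(f"no calls for stimulus {stimulus!r}")
    return 100.0 * sum(per_donor.values()) / len(per_donor)


def percent_responders_table(calls: Sequence[ResponderCall]) -> pd.DataFrame:
    """Per-stimulus percent-responder table (the pool-promiscuity readout)."""
    stimuli = sorted({c.stimulus for c in calls})
    return pd.DataFrame(
        {
            "stimulus": stimuli,
            "percent_responders": [percent_responders(calls, s) for s in stimuli],
        }
    )


def pools_per_donor(calls: Iterable[ResponderCall]) -> dict[str, int]:
    """Number of positive peptide pools per donor (proteins/controls excluded)."""
    pos = positive_stimuli(calls, pools_only=True)
    return {d: len(s) for d, s in sorted(pos.items())}


def log_fold_change(
    stim_pos: int,
    stim_total: int,
    unstim_pos: int,
    unstim_total: int,
    pseudocount: float = 0.5,
    base: float = 2.0,
) -> float:
    """Log fold change of the positive-cell rate over the unstimulated control.

    ``log_base(((stim_pos+pc)/stim_total) / ((unstim_pos+pc)/unstim_total))``;
    the pseudocount guards zero counts.
    """
    if stim_total <= 0 or unstim_total <= 0:
        raise CountError("zero or negative total cell count")
    ratio = ((stim_pos + pseudocount) / stim_total) / (
        (unstim_pos + pseudocount) / unstim_total
    )
    return math.log(ratio, base)


def lfc_table(
    records: Sequence[StimulationRecord],
    pseudocount: float = 0.5,
    base: float = 2.0,
) -> pd.DataFrame:
    """Long-format log-fold-change table (donor, stimulus, marker, lfc)."""
    controls = {
        (r.donor_id, r.marker): r for r in records if r.stimulus == UNSTIMULATED
    }
    rows = []
    for r in records:
        if r.stimulus == UNSTIMULATED:
            continue
        ctrl = controls.get((r.donor_id, r.marker))
        if ctrl is None:
            raise MissingControlError(
                f"no unstimulated control for donor {r.donor_id!r}, marker {r.marker!r}"
            )
        rows.append(
            {
                "donor_id": r.donor_id,
                "stimulus": r.stimulus,
                "marker": r.marker,
                "log_fold_change": log_fold_change(
                    r.positive_count,
                    r.total_count,
                    ctrl.positive_count,
                    ctrl.total_count,
                    pseudocount,
                    base,
                ),
            }
        )
    return pd.DataFrame(rows)


def seb_quality_control(calls: Iterable[ResponderCall]) -> set[str]:
    """Donors whose superantigen (SEB) positive control failed to respond.

    Returns the failing donor ids (and logs a warning); such donors indicate
    an assay problem but are not removed automatically.
    """
    by_donor: dict[str, list[ResponderCall]] = defaultdict(list)
    for c in calls:
        if c.stimulus == SEB:
            by_donor[c.donor_id].append(c)
    failing = {d for d, cs in by_donor.items() if not donor_positive(cs)}
    for d in sorted(failing):
        logger.warning("donor %s failed SEB positive-control QC", d)
    return failing
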